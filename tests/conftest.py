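"""Shared fixtures: rate tables, random ORF builders, independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from ribodesign import Orf, builtin_trna_table, builtin_wobble_map, codon_rates
from ribodesign._codons import SENSE_CODONS


@pytest.fixture(scope="session")
def ecoli():
    """Rates from the shipped E. coli tRNA table and wobble map."""
    return codon_rates(builtin_trna_table(), builtin_wobble_map())


@pytest.fixture(scope="session")
def wobble():
    return builtin_wobble_map()


def random_orf(rng: np.random.Generator, length_codons: int, orf_id: str = "rand") -> Orf:
    """A random in-frame ORF over the 61 sense codons, ATG first."""
    body = rng.choice(len(SENSE_CODONS), size=length_codons - 1)
    return Orf(id=orf_id, dna="ATG" + "".join(SENSE_CODONS[i] for i in body))


def random_rates(rng: np.random.Generator):
    """A random complete rate table (max-normalized, all rates distinct)."""
    from ribodesign import CodonRateTable

    values = rng.uniform(0.01, 1.0, size=len(SENSE_CODONS))
    values[rng.integers(len(values))] = 1.0
    return CodonRateTable(rates=dict(zip(SENSE_CODONS, values)))


# ---- independent oracles (deliberately naive, loop-based) ----


def brute_smooth(raw, window):
    """O(L*w) windowed mean; positions lacking a full window are absent."""
    half = (window - 1) // 2
    out = {}
    for i in range(len(raw)):
        if i - half < 0 or i + half >= len(raw):
            continue
        out[i + 1] = sum(raw[i - half : i + half + 1]) / window
    return out


def brute_minima(positions, values, threshold, min_gap):
    """Boolean run finder over (position, smoothed value) pairs."""
    below = [(p, v) for p, v in zip(positions, values) if v < threshold]
    runs = []
    for p, v in below:
        if runs and p - runs[-1][-1][0] - 1 < min_gap:
            runs[-1].append((p, v))
        else:
            runs.append([(p, v)])
    sites = []
    lookup = dict(zip(positions, values))
    for run in runs:
        start, end = run[0][0], run[-1][0]
        span = [(p, lookup[p]) for p in range(start, end + 1)]
        argmin = min(span, key=lambda t: (t[1], t[0]))
        sites.append((start, end, argmin[0], argmin[1]))
    return sites


def percentile_linear(values, q):
    """Linear-interpolation percentile, written out longhand."""
    xs = sorted(values)
    if len(xs) == 1:
        return xs[0]
    rank = q / 100 * (len(xs) - 1)
    lo = int(rank)
    frac = rank - lo
    if lo + 1 >= len(xs):
        return xs[-1]
    return xs[lo] + frac * (xs[lo + 1] - xs[lo])
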