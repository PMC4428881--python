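"""Translation profiles over an ORF and attenuation-site detection.

A translation profile is the sequence of per-codon relative rates along an
open reading frame, smoothed with a centered sliding-window mean (default
19 codons).  Contiguous stretches whose smoothed rate falls below a
genome-wide threshold are called translational attenuation sites — regions
where ribosomes are predicted to transit slowly, transiently pausing the
nascent chain.  In multidomain proteins such sites sit characteristically
~20-70 aa (typically ~30 aa) downstream of structural domain boundaries,
the stretch of nascent peptide hidden in the ribosomal exit tunnel.

Coordinates are 1-based codon positions; codon 1 is the start codon.
Smoothed values exist only where a full window fits — no padding and no
shrinking windows at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from ._codons import STOP_CODONS, split_codons
from .kinetics import CodonRateTable

_DNA_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class Orf:
    """An in-frame protein-coding DNA sequence with optional 5' context.

    ``upstream`` is the nucleotide context immediately 5' of the start codon
    (vector/UTR sequence), used only for folding-energy windows.
    """

    id: str
    dna: str
    upstream: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "dna", self.dna.upper())
        object.__setattr__(self, "upstream", self.upstream.upper())
        bad = set(self.dna) - _DNA_ALPHABET
        if bad:
            raise ValueError(f"ORF {self.id}: non-DNA characters {sorted(bad)}")
        bad = set(self.upstream) - _DNA_ALPHABET
        if bad:
            raise ValueError(f"ORF {self.id}: non-DNA characters in upstream context {sorted(bad)}")
        if len(self.dna) % 3:
            raise ValueError(f"ORF {self.id}: length {len(self.dna)} not divisible by 3")
        for i, codon in enumerate(self.codons(), 1):
            if codon in STOP_CODONS and i < self.length_codons:
                raise ValueError(f"ORF {self.id}: internal stop codon {codon} at codon {i}")

    @property
    def length_codons(self) -> int:
        return len(self.dna) // 3

    def codons(self) -> list[str]:
        return split_codons(self.dna)


@dataclass(frozen=True)
class TranslationProfile:
    """Raw and (optionally) smoothed per-codon translation rates for one ORF.

    ``raw[i]`` is the rate of codon ``i+1`` (1-based positions).  Smoothed
    values exist exactly for positions ``(w+1)/2 .. L-(w-1)/2`` and are
    stored in ``smoothed``; ``smoothed_start`` is the 1-based position of
    ``smoothed[0]``.
    """

    orf_id: str
    raw: np.ndarray
    window: int | None = None
    smoothed: np.ndarray | None = None

    @property
    def length(self) -> int:
        return len(self.raw)

    @property
    def smoothed_start(self) -> int:
        if self.window is None:
            raise ValueError("profile has not been smoothed")
        return (self.window + 1) // 2

    def smoothed_positions(self) -> range:
        """1-based codon positions carrying a smoothed value."""
        start = self.smoothed_start
        return range(start, start + len(self.smoothed))

    def smoothed_at(self, pos: int) -> float:
        """Smoothed rate at 1-based codon position ``pos``."""
        idx = pos - self.smoothed_start
        if idx < 0 or idx >= len(self.smoothed):
            raise IndexError(f"no smoothed value at codon {pos}")
        return float(self.smoothed[idx])


@dataclass(frozen=True)
class Threshold:
    """A genome-wide slow-translation threshold on smoothed rates."""

    value: float
    method: str = "fixed"
    parameter: float = float("nan")
    reference_set_label: str = ""


@dataclass(frozen=True)
class AttenuationSite:
    """A maximal run of smoothed positions below the calling threshold."""

    start_codon: int
    end_codon: int
    argmin_codon: int
    depth: float
    threshold: float | None = None

    def __post_init__(self) -> None:
        if not self.start_codon <= self.argmin_codon <= self.end_codon:
            raise ValueError("argmin outside site bounds")


def raw_profile(orf: Orf, rates: CodonRateTable) -> TranslationProfile:
    """Per-codon rate lookup along the ORF (no smoothing)."""
    values = []
    for i, codon in enumerate(orf.codons(), 1):
        if codon in STOP_CODONS:
            if i < orf.length_codons:
                raise ValueError(f"ORF {orf.id}: internal stop codon at codon {i}")
            continue  # trailing stop carries no elongation rate
        if codon not in rates.rates:
            raise ValueError(f"ORF {orf.id}: codon {codon} at position {i} absent from rate table")
        values.append(rates[codon])
    return TranslationProfile(orf_id=orf.id, raw=np.asarray(values, dtype=float))


def smooth(profile: TranslationProfile, window: int = 19) -> TranslationProfile:
    """Centered sliding-window mean of the raw profile.

    The window must be odd and no longer than the profile.  Positions whose
    centered window does not fully fit carry no smoothed value.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window > profile.length:
        raise ValueError(f"window {window} exceeds ORF length {profile.length} codons")
    kernel = np.full(window, 1.0 / window)
    smoothed = np.convolve(profile.raw, kernel, mode="valid")
    return replace(profile, window=window, smoothed=smoothed)


def genome_threshold(
    reference_orfs: Iterable[Orf],
    rates: CodonRateTable | None,
    method: str = "percentile",
    parameter: float = 10.0,
    window: int = 19,
    label: str = "",
) -> Threshold:
    """Derive a genome-wide threshold from a reference set of ORFs.

    Smoothed values of all reference ORFs are pooled and reduced by the
    chosen method: ``percentile`` (linear-interpolation percentile of the
    pooled distribution, default 10th), ``mean_minus_sd`` (mean minus
    ``parameter`` standard deviations), or ``fixed`` (``parameter`` passed
    through, no reference set needed).
    """
    if method == "fixed":
        return Threshold(value=float(parameter), method="fixed", parameter=parameter, reference_set_label=label)
    orfs = list(reference_orfs)
    if not orfs:
        raise ValueError("empty reference set (use method='fixed' to supply a value directly)")
    pooled = np.concatenate(
        [smooth(raw_profile(o, rates), window=window).smoothed for o in orfs]
    )
    if method == "percentile":
        value = float(np.percentile(pooled, parameter))
    elif method == "mean_minus_sd":
        value = float(pooled.mean() - parameter * pooled.std(ddof=0))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return Threshold(value=value, method=method, parameter=parameter, reference_set_label=label)


def detect_minima(
    profile: TranslationProfile,
    threshold: Threshold,
    min_gap: int = 5,
) -> list[AttenuationSite]:
    """Attenuation sites: maximal below-threshold runs in the smoothed profile.

    Runs separated by fewer than ``min_gap`` above-threshold codons are
    merged into one site (a single biological pause should not fragment).
    Each site reports the position of its smoothed minimum (ties -> smallest
    position).  Sites are ordered by start; the empty list means no position
    is below threshold.
    """
    if profile.smoothed is None:
        raise ValueError("profile must be smoothed before minima detection")
    below = profile.smoothed < threshold.value
    runs: list[list[int]] = []  # [start_idx, end_idx] inclusive
    for idx in np.flatnonzero(below):
        if runs and idx - runs[-1][1] - 1 < min_gap:
            runs[-1][1] = int(idx)
        else:
            runs.append([int(idx), int(idx)])
    sites = []
    start0 = profile.smoothed_start
    for lo, hi in runs:
        seg = profile.smoothed[lo : hi + 1]
        argmin = lo + int(np.argmin(seg))  # np.argmin returns first minimum
        sites.append(
            AttenuationSite(
                start_codon=lo + start0,
                end_codon=hi + start0,
                argmin_codon=argmin + start0,
                depth=float(profile.smoothed[argmin]),
                threshold=threshold.value,
            )
        )
    return sites


def site_domain_offsets(
    sites: Sequence[AttenuationSite],
    domains: Sequence[tuple[int, int]],
) -> list[tuple[AttenuationSite, tuple[int, int] | None, int | None]]:
    """Pair each site with the nearest upstream domain boundary.

    ``domains`` are 1-based inclusive (start_aa, end_aa) pairs, sorted and
    non-overlapping.  The offset is ``argmin_codon - domain_end_aa`` for the
    closest domain ending at or before the site's minimum; sites upstream of
    every domain end get ``(site, None, None)``.
    """
    doms = list(domains)
    for (s1, e1), (s2, e2) in zip(doms, doms[1:]):
        if s2 <= e1:
            raise ValueError(f"domains must be sorted and non-overlapping: ({s1},{e1}) vs ({s2},{e2})")
    for s, e in doms:
        if s > e:
            raise ValueError(f"domain start {s} after end {e}")
    out: list[tuple[AttenuationSite, tuple[int, int] | None, int | None]] = []
    for site in sites:
        upstream = [d for d in doms if d[1] <= site.argmin_codon]
        if not upstream:
            out.append((site, None, None))
        else:
            nearest = max(upstream, key=lambda d: d[1])
            out.append((site, nearest, site.argmin_codon - nearest[1]))
    return out


def profile_to_tsv(orf: Orf, profile: TranslationProfile) -> str:
    """TSV export: ``codon_pos<TAB>codon<TAB>raw_rate<TAB>smoothed_rate``."""
    lines = ["codon_pos\tcodon\traw_rate\tsmoothed_rate"]
    codons = orf.codons()
    smoothed_pos = set(profile.smoothed_positions()) if profile.smoothed is not None else set()
    for i in range(1, profile.length + 1):
        sm = f"{profile.smoothed_at(i):.6g}" if i in smoothed_pos else ""
        lines.append(f"{i}\t{codons[i - 1]}\t{profile.raw[i - 1]:.6g}\t{sm}")
    return "\n".join(lines) + "\n"


def sites_to_tsv(
    paired: Sequence[tuple[AttenuationSite, tuple[int, int] | None, int | None]],
) -> str:
    """TSV export of sites with their nearest-upstream-domain offsets."""
    lines = ["start_codon\tend_codon\targmin_codon\tdepth\tdomain_end_aa\toffset_aa"]
    for site, dom, off in paired:
        dom_end = str(dom[1]) if dom else ""
        lines.append(
            f"{site.start_codon}\t{site.end_codon}\t{site.argmin_codon}\t"
            f"{site.depth:.6g}\t{dom_end}\t{'' if off is None else off}"
        )
    return "\n".join(lines) + "\n"
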