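"""Seeded synthetic fixtures: ORFs with planted attenuation sites.

Real redesign runs start from gene sequences and host tRNA measurements.
For testing and demonstration this module fabricates a fully synthetic but
biologically shaped bundle:

* a toy tRNAome — log-uniform concentrations over the anticodons of the
  shipped E. coli wobble map, deterministic for a given seed;
* background ORFs encoding random proteins with each residue's *fastest*
  synonymous codon (a smooth, fast profile, like codon-"optimized" genes);
* planted attenuation sites — window-length runs of slow-synonym codons
  centered at a stated offset downstream of a generated domain boundary,
  which minima detection must recover;
* reference ORFs of uniformly random sense codons, standing in for the
  genome-wide background from which the detection threshold is drawn.

Outputs are deterministic (byte-identical files for a fixed seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._codons import AA_TO_CODONS, SENSE_CODONS
from .kinetics import CodonRateTable, TrnaTable, WobbleMap, builtin_wobble_map, codon_rates
from .profile import Orf

_START = "ATG"


@dataclass(frozen=True)
class Fixture:
    """A self-contained synthetic input bundle."""

    orfs: list[Orf]
    reference_orfs: list[Orf]
    domains: dict[str, list[tuple[int, int]]]
    planted: dict[str, list[int]]  # orf_id -> planted site centers (codon pos)
    trna_table: TrnaTable
    wobble: WobbleMap
    rates: CodonRateTable


def _toy_trna_table(rng: np.random.Generator, wobble: WobbleMap) -> TrnaTable:
    anticodons = sorted({a for s in wobble.pairs.values() for a in s})
    conc = {a: float(np.round(np.exp(rng.uniform(np.log(100), np.log(5000))), 1)) for a in anticodons}
    return TrnaTable(entries=conc, source_label="toy (synthetic)")


def _soup_orf(rng: np.random.Generator, orf_id: str, length_codons: int) -> Orf:
    body = rng.choice(len(SENSE_CODONS), size=length_codons - 1)
    return Orf(id=orf_id, dna=_START + "".join(SENSE_CODONS[i] for i in body))


def generate_fixture(
    seed: int,
    n_orfs: int = 3,
    length_codons: int = 300,
    slow_fraction: float = 0.0,
    planted_sites: tuple[tuple[int, float], ...] = ((30, 0.1),),
    site_len: int = 19,
    n_reference: int = 20,
    out_dir: str | Path | None = None,
) -> Fixture:
    """Generate a deterministic synthetic fixture.

    ``planted_sites`` is a list of ``(offset_aa, depth)`` pairs: one
    attenuation site per pair, its slow-codon run centered ``offset_aa``
    amino acids downstream of a generated domain boundary, built from
    synonyms with relative rate <= ``depth``.  ``slow_fraction`` scatters
    additional isolated slow codons through the background (0 = clean
    control).  When ``out_dir`` is given, ``orfs.fasta``,
    ``reference.fasta``, ``domains.tsv`` and ``trna_toy.tsv`` are written
    there.
    """
    if length_codons < 19:
        raise ValueError("length_codons must be at least 19")
    if not 0 <= slow_fraction <= 1:
        raise ValueError("slow_fraction must be within [0, 1]")
    rng = np.random.default_rng(seed)
    wobble = builtin_wobble_map()
    trna = _toy_trna_table(rng, wobble)
    rates = codon_rates(trna, wobble)

    aas = sorted(AA_TO_CODONS)
    fastest = {aa: rates.fastest_synonym(AA_TO_CODONS[aa][0]) for aa in aas}
    slowest = {aa: rates.slowest_synonym(AA_TO_CODONS[aa][0]) for aa in aas}
    # The background emulates a smooth, fast profile, so its residues are
    # drawn from amino acids that actually have a fast codon under this
    # tRNAome; otherwise intrinsically slow residues would dent the profile.
    bg_pool = [aa for aa in aas if rates[fastest[aa]] >= 0.5]
    if len(bg_pool) < 8:
        bg_pool = sorted(aas, key=lambda a: -rates[fastest[a]])[:8]

    # domain layout: one boundary per planted site, evenly spaced
    k = len(planted_sites)
    domain_ends = [int(round((i + 1) * length_codons / (k + 2))) for i in range(k)] if k else []
    half_run = site_len // 2
    centers = []
    for (offset_aa, _), dom_end in zip(planted_sites, domain_ends):
        center = dom_end + offset_aa
        if center - half_run < 2 or center + half_run > length_codons:
            raise ValueError(
                f"planted site at offset {offset_aa} (codon {center}) falls outside the ORF"
            )
        centers.append(center)

    orfs, planted, domains = [], {}, {}
    for j in range(n_orfs):
        orf_id = f"synth_{seed}_{j}"
        protein = rng.choice(bg_pool, size=length_codons - 1)
        codons = [_START] + [fastest[aa] for aa in protein]
        if slow_fraction > 0:
            n_slow = int(round(slow_fraction * (length_codons - 1)))
            pos = rng.choice(np.arange(1, length_codons), size=n_slow, replace=False)
            for p in pos:
                codons[p] = slowest[protein[p - 1]]
        for (offset_aa, depth), center in zip(planted_sites, centers):
            slow_pool = sorted(
                c for aa, c in slowest.items() if rates[c] <= depth and aa != "M" and aa != "W"
            )
            if not slow_pool:  # fall back to the slowest available synonyms
                slow_pool = sorted(slowest.values(), key=lambda c: rates[c])[:5]
            run = rng.choice(len(slow_pool), size=site_len)
            for i, ci in enumerate(run):
                codons[center - half_run - 1 + i] = slow_pool[ci]
        orfs.append(Orf(id=orf_id, dna="".join(codons)))
        planted[orf_id] = list(centers)
        domains[orf_id] = [
            (1 if i == 0 else domain_ends[i - 1] + 1, e) for i, e in enumerate(domain_ends)
        ]

    reference = [
        _soup_orf(rng, f"ref_{seed}_{j}", length_codons) for j in range(n_reference)
    ]

    fixture = Fixture(
        orfs=orfs,
        reference_orfs=reference,
        domains=domains,
        planted=planted,
        trna_table=trna,
        wobble=wobble,
        rates=rates,
    )
    if out_dir is not None:
        _write_fixture(fixture, Path(out_dir))
    return fixture


def _write_fixture(fx: Fixture, out_dir: Path) -> None:
    from .io import write_fasta  # local import avoids a cycle

    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(fx.orfs, out_dir / "orfs.fasta")
    write_fasta(fx.reference_orfs, out_dir / "reference.fasta")
    lines = [
        f"{orf_id}\t{s}\t{e}" for orf_id, doms in sorted(fx.domains.items()) for s, e in doms
    ]
    (out_dir / "domains.tsv").write_text("\n".join(lines) + "\n" if lines else "")
    trna_lines = ["# toy tRNA table (synthetic)", "# anticodon\tconcentration"] + [
        f"{a}\t{c}" for a, c in sorted(fx.trna_table.entries.items())
    ]
    (out_dir / "trna_toy.tsv").write_text("\n".join(trna_lines) + "\n")
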