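"""mRNA folding energy around the start codon and 5'-coding-region optimization.

Stable mRNA secondary structure overlapping the translation-initiation
region hinders ribosome loading and depresses expression.  This module
computes a sliding-window minimum-free-energy (MFE) profile around the
start codon — by default a 39-nt window slid over centers -50..+50 nt,
position 0 being the first nucleotide of ATG — and weakens 5' structure by
synonymous third-base substitutions in the first coding codons (codons 3-7
by default; codons 1-2 are never touched).

Folding is delegated through the ``FoldingEngine`` contract: any callable
mapping an RNA string to its MFE in kcal/mol.  The default adapter binds
the ViennaRNA package (RNAfold) at default parameters (37 C).  Tests and
quick runs can substitute a cheap deterministic stub.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Protocol, runtime_checkable

import numpy as np

from ._codons import STOP_CODONS, is_synonymous, split_codons
from .design import Edit, SubstitutionPlan, apply_edits
from .profile import Orf


@runtime_checkable
class FoldingEngine(Protocol):
    """Callable contract: RNA string (5'->3') -> minimum free energy, kcal/mol.

    Implementations must be deterministic and return 0.0 for sequences that
    cannot form any base pair (e.g. poly-A).
    """

    def __call__(self, rna: str) -> float: ...


class ViennaFoldingEngine:
    """MFE via the ViennaRNA thermodynamic model at default parameters."""

    def __init__(self) -> None:
        import RNA  # deferred: the binding is optional at import time

        self._fold = RNA.fold

    def __call__(self, rna: str) -> float:
        _, mfe = self._fold(rna)
        return float(mfe)


@dataclass(frozen=True)
class FoldingEnergyProfile:
    """Windowed MFE values indexed by window-center position relative to ATG.

    ``center_positions[i]`` is the nucleotide position of the window center
    (0 = first nt of the start codon); ``dG[i]`` the MFE of the window_nt-
    long window centered there.  Centers lacking full sequence context on
    either side are omitted, never extrapolated.
    """

    center_positions: np.ndarray
    dG: np.ndarray
    window_nt: int = 39
    range: tuple[int, int] = (-50, 50)


def dg_profile(
    orf: Orf,
    engine: FoldingEngine,
    window_nt: int = 39,
    range: tuple[int, int] = (-50, 50),
) -> FoldingEnergyProfile:
    """Sliding-window folding-energy profile around the start codon.

    For every center position p in ``range`` (inclusive) for which
    (window_nt-1)/2 nt of context exist on both sides — drawing on
    ``orf.upstream`` for negative coordinates — the window's MFE is
    computed and assigned to p.
    """
    if window_nt % 2 == 0 or window_nt < 1:
        raise ValueError(f"window_nt must be odd and positive, got {window_nt}")
    lo, hi = range
    half = (window_nt - 1) // 2
    need_upstream = max(0, -lo + half)
    if len(orf.upstream) < need_upstream:
        raise ValueError(
            f"ORF {orf.id}: upstream context of {len(orf.upstream)} nt is too short; "
            f"{need_upstream} nt required for centers down to {lo} with a {window_nt}-nt window"
        )
    full = orf.upstream + orf.dna
    offset = len(orf.upstream)  # index of position 0
    centers, energies = [], []
    for p in np.arange(lo, hi + 1):
        a, b = offset + p - half, offset + p + half + 1
        if a < 0 or b > len(full):
            continue
        centers.append(int(p))
        energies.append(float(engine(full[a:b].replace("T", "U"))))
    return FoldingEnergyProfile(
        center_positions=np.asarray(centers, dtype=int),
        dG=np.asarray(energies, dtype=float),
        window_nt=window_nt,
        range=(lo, hi),
    )


def _third_base_choices(codon: str, base_preference: str, force: bool) -> list[str]:
    """Synonymous variants of ``codon`` differing only in the third base.

    In force mode: the preferred-base variant if synonymous, else the codon
    unchanged.  In search mode: all synonymous third-base variants.
    """
    variants = [codon[:2] + b for b in "ACGT"]
    syn = [v for v in variants if is_synonymous(codon, v)]
    if force:
        preferred = codon[:2] + base_preference
        return [preferred] if preferred in syn else [codon]
    return syn


def optimize_five_prime(
    orf: Orf,
    engine: FoldingEngine | None = None,
    codon_range: tuple[int, int] = (3, 7),
    base_preference: str = "A",
    mode: str = "force_preferred",
) -> SubstitutionPlan:
    """Weaken 5'-coding-region secondary structure by third-base synonymy.

    ``force_preferred`` sets the third base of every codon in
    ``codon_range`` to ``base_preference`` wherever that is synonymous
    (codons like ATG/TGG, or swaps that would create a stop, are skipped).
    ``search`` exhaustively enumerates all synonymous third-base variants
    over the range and returns the plan maximizing the minimum windowed dG
    over centers spanned by the edited codons (ties -> fewest edits, then
    most preferred bases, then lexicographically smallest sequence); it
    requires a folding engine.
    """
    lo, hi = codon_range
    if lo < 3:
        raise ValueError("codons 1-2 are never edited (initiation context)")
    if hi < lo:
        raise ValueError(f"empty codon range {codon_range}")
    codons = split_codons(orf.dna)
    if hi > len(codons):
        raise ValueError(f"codon range {codon_range} outside ORF of {len(codons)} codons")
    targets = codons[lo - 1 : hi]
    if any(c in STOP_CODONS for c in targets):
        raise ValueError(f"codon range {codon_range} overlaps a stop codon")

    if mode == "force_preferred":
        edits = []
        for i, codon in enumerate(targets):
            (new,) = _third_base_choices(codon, base_preference, force=True) or (codon,)
            if new != codon:
                edits.append(Edit(lo + i, codon, new, "five_prime"))
        return SubstitutionPlan(
            orf_id=orf.id, edits=tuple(edits), result_dna=apply_edits(orf.dna, edits)
        )

    if mode != "search":
        raise ValueError(f"unknown mode {mode!r}")
    if engine is None:
        raise ValueError("search mode requires a folding engine")

    # centers falling within the edited codons' nucleotide span
    span = ((lo - 1) * 3, hi * 3 - 1)
    choice_lists = [_third_base_choices(c, base_preference, force=False) for c in targets]
    best = None
    for combo in itertools.product(*choice_lists):
        edits = tuple(
            Edit(lo + i, old, new, "five_prime")
            for i, (old, new) in enumerate(zip(targets, combo))
            if old != new
        )
        dna = apply_edits(orf.dna, edits)
        prof = dg_profile(Orf(id=orf.id, dna=dna, upstream=orf.upstream), engine, range=span)
        if prof.dG.size == 0:
            raise ValueError(
                "no folding-energy window fits the edited span; provide upstream context"
            )
        objective = float(prof.dG.min())
        pref_count = sum(1 for c in combo if c[2] == base_preference)
        key = (-objective, len(edits), -pref_count, dna)
        if best is None or key < best[0]:
            best = (key, edits, dna)
    _, edits, dna = best
    return SubstitutionPlan(orf_id=orf.id, edits=edits, result_dna=dna)


def dg_profile_to_tsv(profile: FoldingEnergyProfile) -> str:
    """TSV export: ``center_pos<TAB>dG_kcal_mol``."""
    lines = ["center_pos\tdG_kcal_mol"]
    for p, g in zip(profile.center_positions, profile.dG):
        lines.append(f"{p}\t{g:.2f}")
    return "\n".join(lines) + "\n"
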