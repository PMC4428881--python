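"""Synonymous redesign of coding sequences around attenuation sites.

Two redesign directions, both strictly protein-preserving:

* slow-down (``insert_pause``): create a translational attenuation site
  20-70 aa downstream of a protein-domain boundary, so that the ribosome
  pauses once the finished domain has cleared the exit tunnel.  If the
  target window contains a leucine, the single Leu nearest the preferred
  offset (~30 aa) is swapped to CTA, the codon read by the rarest
  Leu-decoding tRNA in E. coli — one such swap is enough to create a
  pause.  Leu-free windows fall back to a greedy slowest-synonym search
  capped at a few codons.

* speed-up (``remove_pause`` / ``remove_all_pauses``): erase an existing
  attenuation site by swapping every below-threshold codon in it to its
  fastest synonym, yielding a near-uniform fast elongation profile.

Every edit can be annotated with the local mRNA folding-energy change
(ddG over the 39-nt window centered on the edited codon); edits whose
|ddG| exceeds a configurable guard are flagged as warnings rather than
silently applied, since synonymous changes can perturb mRNA structure
and stability.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

from Bio.Seq import Seq

from ._codons import CODON_TO_AA, is_synonymous, split_codons, synonyms
from .kinetics import CodonRateTable
from .profile import AttenuationSite, Orf, Threshold, detect_minima, raw_profile, smooth

EDIT_REASONS = ("insert_pause", "remove_pause", "five_prime")


@dataclass(frozen=True)
class Edit:
    """One synonymous codon replacement, 1-based codon position."""

    codon_pos: int
    old_codon: str
    new_codon: str
    reason: str
    local_ddG: float | None = None

    def __post_init__(self) -> None:
        if self.reason not in EDIT_REASONS:
            raise ValueError(f"unknown edit reason {self.reason!r}")
        if not is_synonymous(self.old_codon, self.new_codon):
            raise ValueError(
                f"edit at codon {self.codon_pos}: {self.old_codon}->{self.new_codon} is not synonymous"
            )


@dataclass(frozen=True)
class SubstitutionPlan:
    """An ordered set of synonymous edits and the resulting sequence."""

    orf_id: str
    edits: tuple[Edit, ...]
    result_dna: str
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        positions = [e.codon_pos for e in self.edits]
        if len(positions) != len(set(positions)):
            raise ValueError("plan contains multiple edits at one codon position")


@dataclass(frozen=True)
class DesignConfig:
    """Tunable parameters of the redesign procedures.

    offset_range_aa
        Window downstream of a domain boundary eligible for a pause site;
        20-70 aa is the span of nascent chain the ribosomal exit tunnel can
        cover.
    preferred_offset_aa
        Offset at which attenuation sites are characteristically found
        (~30 aa downstream of the boundary).
    preferred_slow_codon
        The single-codon pause workhorse (Leu CTA in E. coli).
    max_codons_per_site
        Cap on greedy slowest-synonym edits when no Leu is available.
    ddG_guard_kcal
        |local folding-energy change| above which an edit is flagged.
    """

    offset_range_aa: tuple[int, int] = (20, 70)
    preferred_offset_aa: int = 30
    preferred_slow_codon: str = "CTA"
    max_codons_per_site: int = 3
    ddG_guard_kcal: float = 2.0
    fast_mode_scope: str = "site"
    smoothing_window: int = 19

    def __post_init__(self) -> None:
        low, high = self.offset_range_aa
        if not (low <= self.preferred_offset_aa <= high):
            raise ValueError("preferred offset must lie within offset_range_aa")
        if self.ddG_guard_kcal < 0:
            raise ValueError("ddG guard must be non-negative")
        if self.fast_mode_scope not in ("site", "whole_orf"):
            raise ValueError(f"unknown fast_mode_scope {self.fast_mode_scope!r}")


def apply_edits(dna: str, edits: Sequence[Edit]) -> str:
    """Apply codon-level edits (1-based positions) to a DNA string."""
    codons = split_codons(dna)
    for e in edits:
        if not 1 <= e.codon_pos <= len(codons):
            raise ValueError(f"edit position {e.codon_pos} outside ORF of {len(codons)} codons")
        if codons[e.codon_pos - 1] != e.old_codon:
            raise ValueError(
                f"edit at codon {e.codon_pos}: expected {e.old_codon}, found {codons[e.codon_pos - 1]}"
            )
        codons[e.codon_pos - 1] = e.new_codon
    return "".join(codons)


def verify_synonymy(source: Orf, plan: SubstitutionPlan) -> bool:
    """True iff the plan's result encodes exactly the source protein."""
    if len(plan.result_dna) != len(source.dna):
        raise ValueError(
            f"length mismatch: result {len(plan.result_dna)} nt vs source {len(source.dna)} nt"
        )
    return str(Seq(source.dna).translate()) == str(Seq(plan.result_dna).translate())


def _local_ddG(
    orf: Orf,
    edit: Edit,
    engine: Callable[[str], float] | None,
    window_nt: int = 39,
) -> float | None:
    """Folding-energy change over the window centered on the edited codon.

    Returns None when no engine is supplied or the window does not fit in
    the available sequence context.
    """
    if engine is None:
        return None
    half = (window_nt - 1) // 2
    center = (edit.codon_pos - 1) * 3 + 1  # middle nt of the codon, 0-based in ORF
    full_before = orf.upstream + orf.dna
    full_after = orf.upstream + apply_edits(orf.dna, [replace(edit, local_ddG=None)])
    lo = len(orf.upstream) + center - half
    hi = len(orf.upstream) + center + half + 1
    if lo < 0 or hi > len(full_before):
        return None
    before = engine(full_before[lo:hi].replace("T", "U"))
    after = engine(full_after[lo:hi].replace("T", "U"))
    return after - before


def _annotate_and_warn(
    orf: Orf,
    edits: list[Edit],
    engine: Callable[[str], float] | None,
    guard: float,
) -> tuple[list[Edit], list[str]]:
    annotated, warnings = [], []
    for e in edits:
        ddG = _local_ddG(orf, e, engine)
        e = replace(e, local_ddG=ddG)
        if ddG is not None and abs(ddG) > guard:
            warnings.append(
                f"codon {e.codon_pos} {e.old_codon}->{e.new_codon}: "
                f"local ddG {ddG:+.2f} kcal/mol exceeds guard {guard:.2f}"
            )
        annotated.append(e)
    return annotated, warnings


def _window_smoothed_min(
    dna: str, rates: CodonRateTable, lo: int, hi: int, window: int
) -> float:
    """Minimum smoothed rate over codons lo..hi (1-based, clipped to valid)."""
    prof = smooth(raw_profile(Orf(id="_tmp", dna=dna), rates), window=window)
    vals = [prof.smoothed_at(p) for p in prof.smoothed_positions() if lo <= p <= hi]
    if not vals:  # window centers may all fall outside short ORFs
        vals = list(prof.smoothed)
    return min(vals)


def insert_pause(
    orf: Orf,
    domain_end_aa: int,
    rates: CodonRateTable,
    cfg: DesignConfig = DesignConfig(),
    threshold: Threshold | float | None = None,
    engine: Callable[[str], float] | None = None,
) -> SubstitutionPlan:
    """Introduce an attenuation site downstream of a domain boundary.

    The target window is ``[domain_end + low, domain_end + high]`` aa
    (defaults 20-70).  If the window already contains the preferred slow
    codon the site is considered slow and the plan is empty.  If it contains
    a Leu codon, exactly that Leu nearest the preferred offset is swapped
    to the preferred slow codon (CTA).  Otherwise up to
    ``max_codons_per_site`` codons are greedily swapped to their slowest
    synonyms (largest rate drop first) until the window's smoothed minimum
    falls below ``threshold`` (if given) or the cap is reached.
    """
    low, high = cfg.offset_range_aa
    L = orf.length_codons
    win_lo, win_hi = domain_end_aa + low, domain_end_aa + high
    if win_lo < 1 or win_lo > L:
        raise ValueError(
            f"target window [{win_lo}, {win_hi}] lies outside ORF of {L} codons"
        )
    win_hi = min(win_hi, L)
    codons = orf.codons()
    window_positions = range(win_lo, win_hi + 1)
    # codon positions carrying a trailing stop are not editable
    window_positions = [p for p in window_positions if CODON_TO_AA.get(codons[p - 1])]

    if any(codons[p - 1] == cfg.preferred_slow_codon for p in window_positions):
        return SubstitutionPlan(orf_id=orf.id, edits=(), result_dna=orf.dna)

    target_aa = CODON_TO_AA[cfg.preferred_slow_codon]
    leu_positions = [p for p in window_positions if CODON_TO_AA[codons[p - 1]] == target_aa]
    if leu_positions:
        preferred_pos = domain_end_aa + cfg.preferred_offset_aa
        pos = min(leu_positions, key=lambda p: (abs(p - preferred_pos), p))
        edits = [Edit(pos, codons[pos - 1], cfg.preferred_slow_codon, "insert_pause")]
    else:
        if all(len(synonyms(codons[p - 1])) == 1 for p in window_positions):
            raise ValueError(
                f"ORF {orf.id}: no synonymous slow-down possible in window "
                f"[{win_lo}, {win_hi}] (single-codon amino acids only)"
            )
        thr = threshold.value if isinstance(threshold, Threshold) else threshold
        edits = []
        current = list(codons)
        for _ in range(cfg.max_codons_per_site):
            candidates = [
                (rates[current[p - 1]] - rates[rates.slowest_synonym(current[p - 1])], p)
                for p in window_positions
                if rates.slowest_synonym(current[p - 1]) != current[p - 1]
            ]
            candidates = [(drop, p) for drop, p in candidates if drop > 0]
            if not candidates:
                break
            drop, pos = max(candidates, key=lambda t: (t[0], -t[1]))
            new = rates.slowest_synonym(current[pos - 1])
            edits.append(Edit(pos, current[pos - 1], new, "insert_pause"))
            current[pos - 1] = new
            if thr is not None and orf.length_codons >= cfg.smoothing_window:
                if _window_smoothed_min("".join(current), rates, win_lo, win_hi, cfg.smoothing_window) < thr:
                    break

    edits, warnings = _annotate_and_warn(orf, edits, engine, cfg.ddG_guard_kcal)
    return SubstitutionPlan(
        orf_id=orf.id,
        edits=tuple(edits),
        result_dna=apply_edits(orf.dna, edits),
        warnings=tuple(warnings),
    )


def remove_pause(
    orf: Orf,
    site: AttenuationSite,
    rates: CodonRateTable,
    cfg: DesignConfig = DesignConfig(),
    threshold: Threshold | float | None = None,
    engine: Callable[[str], float] | None = None,
) -> SubstitutionPlan:
    """Erase an attenuation site by accelerating its slow codons.

    Every codon within the site whose raw rate is below the site-call
    threshold is replaced by its fastest synonym (ties -> lexicographically
    smallest).  The smoothed profile over the site can only rise.
    """
    L = orf.length_codons
    if not (1 <= site.start_codon <= site.end_codon <= L):
        raise ValueError(f"site [{site.start_codon}, {site.end_codon}] outside ORF of {L} codons")
    thr = threshold.value if isinstance(threshold, Threshold) else threshold
    if thr is None:
        thr = site.threshold
    if thr is None:
        raise ValueError("no threshold available: pass one or use a site produced by detect_minima")
    codons = orf.codons()
    edits = []
    for pos in range(site.start_codon, site.end_codon + 1):
        codon = codons[pos - 1]
        if CODON_TO_AA.get(codon) is None:  # trailing stop
            continue
        if rates[codon] < thr:
            fastest = rates.fastest_synonym(codon)
            if fastest != codon:
                edits.append(Edit(pos, codon, fastest, "remove_pause"))
    edits, warnings = _annotate_and_warn(orf, edits, engine, cfg.ddG_guard_kcal)
    return SubstitutionPlan(
        orf_id=orf.id,
        edits=tuple(edits),
        result_dna=apply_edits(orf.dna, edits),
        warnings=tuple(warnings),
    )


def remove_all_pauses(
    orf: Orf,
    threshold: Threshold,
    rates: CodonRateTable,
    cfg: DesignConfig = DesignConfig(),
    engine: Callable[[str], float] | None = None,
) -> SubstitutionPlan:
    """Detect all attenuation sites and erase each — a uniformly fast variant."""
    prof = smooth(raw_profile(orf, rates), window=cfg.smoothing_window)
    sites = detect_minima(prof, threshold)
    merged: list[Edit] = []
    warnings: list[str] = []
    for site in sites:
        plan = remove_pause(orf, site, rates, cfg=cfg, threshold=threshold, engine=engine)
        merged.extend(plan.edits)
        warnings.extend(plan.warnings)
    # sites are disjoint, so positions cannot collide
    merged.sort(key=lambda e: e.codon_pos)
    return SubstitutionPlan(
        orf_id=orf.id,
        edits=tuple(merged),
        result_dna=apply_edits(orf.dna, merged),
        warnings=tuple(warnings),
    )


def plan_to_tsv(plan: SubstitutionPlan) -> str:
    """TSV export: ``codon_pos<TAB>old<TAB>new<TAB>reason<TAB>local_ddG``."""
    lines = ["codon_pos\told_codon\tnew_codon\treason\tlocal_ddG"]
    for e in plan.edits:
        ddg = "" if e.local_ddG is None else f"{e.local_ddG:.2f}"
        lines.append(f"{e.codon_pos}\t{e.old_codon}\t{e.new_codon}\t{e.reason}\t{ddg}")
    return "\n".join(lines) + "\n"
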