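"""File I/O: FASTA records, annotation tables, run configuration, reports."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import DesignConfig, SubstitutionPlan, verify_synonymy
from .kinetics import CodonRateTable
from .profile import (
    AttenuationSite,
    Orf,
    Threshold,
    detect_minima,
    raw_profile,
    site_domain_offsets,
    smooth,
)


def read_fasta(path: str | Path) -> list[Orf]:
    """Read in-frame DNA ORFs from a FASTA file.

    Every record is validated as an ORF (DNA alphabet, length divisible by
    3, no internal stop codons); errors name the offending record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return [Orf(id=rec.id, dna=str(rec.seq)) for rec in records]


def write_fasta(orfs: Iterable[Orf], path: str | Path) -> None:
    records = [SeqRecord(Seq(o.dna), id=o.id, description="") for o in orfs]
    SeqIO.write(records, str(path), "fasta")


def read_domains_tsv(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read domain annotations: ``seq_id<TAB>start_aa<TAB>end_aa`` (1-based, inclusive)."""
    domains: dict[str, list[tuple[int, int]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected seq_id<TAB>start_aa<TAB>end_aa")
        seq_id, start, end = fields[0], int(fields[1]), int(fields[2])
        if start < 1 or end < start:
            raise ValueError(f"{path}:{lineno}: invalid domain bounds ({start}, {end})")
        domains.setdefault(seq_id, []).append((start, end))
    for seq_id in domains:
        domains[seq_id].sort()
    return domains


def read_upstream(source: str | Path) -> str:
    """5' context from a FASTA file path or a literal DNA sequence string."""
    p = Path(str(source))
    if p.exists():
        records = list(SeqIO.parse(str(p), "fasta"))
        if len(records) != 1:
            raise ValueError(f"{source}: expected exactly one upstream-context record")
        return str(records[0].seq).upper()
    seq = str(source).upper().replace("U", "T")
    if set(seq) - set("ACGT"):
        raise ValueError(f"upstream context is neither an existing file nor a DNA string: {source!r}")
    return seq


@dataclass
class RunConfig:
    """All knobs of a redesign run, loadable from a flat YAML mapping."""

    orf_fasta: str | None = None
    trna_table: str | None = None
    wobble_map: str | None = None
    domains_tsv: str | None = None
    usage_table: str | None = None
    upstream: str | None = None
    output_dir: str = "."
    threshold_method: str = "percentile"
    threshold_parameter: float = 10.0
    codon_window: int = 19
    nt_window: int = 39
    dg_range: tuple[int, int] = (-50, 50)
    seed: int = 0
    design: DesignConfig = field(default_factory=DesignConfig)

    def __post_init__(self) -> None:
        if self.codon_window < 1 or self.codon_window % 2 == 0:
            raise ValueError("codon window must be a positive odd count")
        if self.nt_window < 1:
            raise ValueError("nt window must be positive")


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a flat key-value YAML file."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    design_keys = {f.name for f in dataclasses.fields(DesignConfig)}
    design_kwargs = {k: v for k, v in data.items() if k in design_keys}
    run_kwargs = {k: v for k, v in data.items() if k not in design_keys}
    unknown = set(run_kwargs) - {f.name for f in dataclasses.fields(RunConfig)}
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "dg_range" in run_kwargs:
        run_kwargs["dg_range"] = tuple(run_kwargs["dg_range"])
    if "offset_range_aa" in design_kwargs:
        design_kwargs["offset_range_aa"] = tuple(design_kwargs["offset_range_aa"])
    return RunConfig(design=DesignConfig(**design_kwargs), **run_kwargs)


def _site_dict(site: AttenuationSite, dom, off) -> dict[str, Any]:
    return {
        "start_codon": site.start_codon,
        "end_codon": site.end_codon,
        "argmin_codon": site.argmin_codon,
        "depth": site.depth,
        "nearest_upstream_domain": list(dom) if dom else None,
        "offset_aa": off,
    }


def _plan_dict(orf: Orf, plan: SubstitutionPlan) -> dict[str, Any]:
    return {
        "orf_id": plan.orf_id,
        "edits": [
            {
                "codon_pos": e.codon_pos,
                "old_codon": e.old_codon,
                "new_codon": e.new_codon,
                "reason": e.reason,
                "local_ddG": e.local_ddG,
            }
            for e in plan.edits
        ],
        "warnings": list(plan.warnings),
        "result_dna": plan.result_dna,
        "synonymous": verify_synonymy(orf, plan),
    }


def design_report(
    orfs: Sequence[Orf],
    rates: CodonRateTable,
    threshold: Threshold,
    domains: dict[str, list[tuple[int, int]]] | None = None,
    plans: dict[str, Sequence[SubstitutionPlan]] | None = None,
    dg_profiles: dict[str, Any] | None = None,
    window: int = 19,
    min_gap: int = 5,
    timestamp: str | None = None,
) -> dict[str, Any]:
    """Assemble a JSON-serializable report of a full analysis/design run.

    Deterministic for identical inputs; pass ``timestamp=None`` (default)
    for byte-reproducible output.
    """
    report: dict[str, Any] = {
        "threshold": {
            "value": threshold.value,
            "method": threshold.method,
            "parameter": threshold.parameter,
            "reference_set_label": threshold.reference_set_label,
        },
        "window_codons": window,
        "orfs": {},
    }
    if timestamp is not None:
        report["timestamp"] = timestamp
    for orf in orfs:
        prof = smooth(raw_profile(orf, rates), window=window)
        sites = detect_minima(prof, threshold, min_gap=min_gap)
        doms = (domains or {}).get(orf.id, [])
        paired = site_domain_offsets(sites, doms) if doms else [(s, None, None) for s in sites]
        entry: dict[str, Any] = {
            "length_codons": orf.length_codons,
            "profile_summary": {
                "raw_mean": float(prof.raw.mean()),
                "smoothed_min": float(prof.smoothed.min()),
                "smoothed_mean": float(prof.smoothed.mean()),
            },
            "sites": [_site_dict(s, d, o) for s, d, o in paired],
            "plans": [_plan_dict(orf, p) for p in (plans or {}).get(orf.id, [])],
        }
        if dg_profiles and orf.id in dg_profiles:
            entry["dg_profiles"] = dg_profiles[orf.id]
        report["orfs"][orf.id] = entry
    return report


def write_report(report: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict[str, Any]:
    report = json.loads(Path(path).read_text())
    if "orfs" not in report or "threshold" not in report:
        raise ValueError(f"{path}: not a design report")
    return report
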