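"""Per-codon translation kinetics from tRNA abundances.

The decoding speed of a codon in a given expression host is driven by the
cellular concentration of the tRNA species able to read it.  This module
turns a tRNA abundance table (anticodon -> concentration) together with a
codon -> anticodon wobble-compatibility map into a table of relative
per-codon translation rates:

    rate(c) = sum of concentrations of all anticodons decoding c,

normalized either by the maximum over the 61 sense codons (default, so the
fastest codon has rate 1.0) or by the sum.  A built-in E. coli table
(classic abundance measurements) and a curated E. coli wobble map ship as
package data.

When tRNA concentrations are unknown for a species, the usual fallback is
codon usage: the ``rare_codons`` helper returns the k least-used codons of
a usage table (k=10 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

from ._codons import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, synonyms

_RNA_ALPHABET = frozenset("ACGU")

_DATA = resources.files("ribodesign") / "data"
ECOLI_TRNA_TSV = "ecoli_trna_dong1996.tsv"
ECOLI_WOBBLE_TSV = "ecoli_wobble.tsv"


def _to_rna(seq: str) -> str:
    return seq.strip().upper().replace("T", "U")


def _to_dna(seq: str) -> str:
    return seq.strip().upper().replace("U", "T")


@dataclass(frozen=True)
class TrnaTable:
    """Anticodon -> relative concentration map defining a host tRNAome.

    Anticodons are 5'->3' RNA strings of length 3; concentrations are
    relative abundances in arbitrary positive units (scale does not matter:
    rate computation is scale-invariant).
    """

    entries: Mapping[str, float]
    source_label: str = ""

    def __post_init__(self) -> None:
        for anticodon, conc in self.entries.items():
            if len(anticodon) != 3 or set(anticodon) - _RNA_ALPHABET:
                raise ValueError(f"invalid anticodon {anticodon!r}: expected 3-letter RNA string")
            if not conc > 0:
                raise ValueError(f"non-positive concentration {conc!r} for anticodon {anticodon}")

    @classmethod
    def from_tsv(cls, path: str | Path, source_label: str | None = None) -> "TrnaTable":
        """Parse a TSV with columns ``anticodon<TAB>concentration[<TAB>note]``.

        ``#`` comment lines are skipped; T/U are normalized to RNA.
        Duplicate anticodons and non-positive concentrations are hard errors.
        """
        entries: dict[str, float] = {}
        text = Path(path).read_text()
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected anticodon<TAB>concentration")
            anticodon = _to_rna(fields[0])
            if anticodon in entries:
                raise ValueError(f"{path}:{lineno}: duplicate anticodon {anticodon}")
            try:
                conc = float(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad concentration {fields[1]!r}") from exc
            if not conc > 0:
                raise ValueError(f"{path}:{lineno}: non-positive concentration for {anticodon}")
            entries[anticodon] = conc
        if not entries:
            raise ValueError(f"{path}: no tRNA entries found")
        return cls(entries=entries, source_label=source_label or str(path))


@dataclass(frozen=True)
class WobbleMap:
    """Sense codon (DNA) -> set of anticodons able to decode it."""

    pairs: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for codon, anticodons in self.pairs.items():
            if codon in STOP_CODONS:
                raise ValueError(f"stop codon {codon} has no decoding entry in a wobble map")
            if codon not in CODON_TO_AA:
                raise ValueError(f"invalid codon {codon!r}")
            if not anticodons:
                raise ValueError(f"codon {codon} maps to no anticodon")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "WobbleMap":
        """Parse ``codon<TAB>anticodon`` pairs, one per line, ``#`` comments allowed."""
        pairs: dict[str, set[str]] = {}
        text = Path(path).read_text()
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected codon<TAB>anticodon")
            codon = _to_dna(fields[0])
            pairs.setdefault(codon, set()).add(_to_rna(fields[1]))
        return cls(pairs={c: frozenset(a) for c, a in pairs.items()})

    def complete(self) -> bool:
        """True iff all 61 sense codons have a decoding entry."""
        return set(self.pairs) == set(SENSE_CODONS)


@dataclass(frozen=True)
class CodonRateTable:
    """Relative translation rate per sense codon, in (0, 1] under mode "max"."""

    rates: Mapping[str, float]
    normalization_mode: str = "max"

    def __post_init__(self) -> None:
        if not self.rates:
            raise ValueError("empty rate table")
        extra = set(self.rates) - set(SENSE_CODONS)
        if extra:
            raise ValueError(f"non-sense-codon entries in rate table: {sorted(extra)}")
        for codon, rate in self.rates.items():
            if not rate > 0:
                raise ValueError(f"non-positive rate for {codon}")

    def __getitem__(self, codon: str) -> float:
        return self.rates[codon]

    @property
    def complete(self) -> bool:
        """True iff all 61 sense codons have a rate (toy tables may not)."""
        return set(self.rates) == set(SENSE_CODONS)

    def slowest_synonym(self, codon: str) -> str:
        """Slowest codon encoding the same amino acid (ties -> lexicographic)."""
        pool = [c for c in synonyms(codon) if c in self.rates] or [codon]
        return min(pool, key=lambda c: (self.rates[c], c))

    def fastest_synonym(self, codon: str) -> str:
        """Fastest codon encoding the same amino acid (ties -> lexicographic)."""
        pool = [c for c in synonyms(codon) if c in self.rates] or [codon]
        return min(pool, key=lambda c: (-self.rates[c], c))


@dataclass(frozen=True)
class CodonUsageTable:
    """Codon usage frequencies (per-mille or fractions) for one species."""

    freqs: Mapping[str, float]
    species_label: str = ""

    def __post_init__(self) -> None:
        if set(self.freqs) != set(SENSE_CODONS):
            raise ValueError("usage table must cover exactly the 61 sense codons")
        for codon, f in self.freqs.items():
            if f < 0:
                raise ValueError(f"negative frequency for {codon}")

    @classmethod
    def from_tsv(cls, path: str | Path, species_label: str | None = None) -> "CodonUsageTable":
        freqs: dict[str, float] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected codon<TAB>frequency")
            freqs[_to_dna(fields[0])] = float(fields[1])
        return cls(freqs=freqs, species_label=species_label or str(path))


def load_trna_table(path: str | Path) -> TrnaTable:
    """Load and validate a tRNA abundance table from TSV."""
    return TrnaTable.from_tsv(path)


def builtin_trna_table() -> TrnaTable:
    """The shipped E. coli tRNA abundance table."""
    with resources.as_file(_DATA / ECOLI_TRNA_TSV) as p:
        return TrnaTable.from_tsv(p, source_label="E. coli (built-in)")


def builtin_wobble_map() -> WobbleMap:
    """The shipped curated E. coli codon->anticodon decoding map."""
    with resources.as_file(_DATA / ECOLI_WOBBLE_TSV) as p:
        return WobbleMap.from_tsv(p)


def codon_rates(
    trna: TrnaTable,
    wobble: WobbleMap,
    normalization_mode: str = "max",
) -> CodonRateTable:
    """Relative translation rate of each sense codon.

    rate(c) is the summed concentration of every anticodon in ``wobble[c]``,
    normalized by the maximum (mode ``"max"``, fastest codon = 1.0) or the
    sum (mode ``"sum"``) over all codons in the wobble map.  Scale-invariant
    in the tRNA concentrations.
    """
    if normalization_mode not in ("max", "sum"):
        raise ValueError(f"unknown normalization mode {normalization_mode!r}")
    raw: dict[str, float] = {}
    for codon in sorted(wobble.pairs):
        total = 0.0
        known = [a for a in wobble.pairs[codon] if a in trna.entries]
        if not known:
            raise ValueError(f"codon {codon} has no decoding anticodon present in the tRNA table")
        for anticodon in known:
            total += trna.entries[anticodon]
        raw[codon] = total
    denom = max(raw.values()) if normalization_mode == "max" else sum(raw.values())
    return CodonRateTable(
        rates={c: v / denom for c, v in raw.items()},
        normalization_mode=normalization_mode,
    )


def ecoli_rates(normalization_mode: str = "max") -> CodonRateTable:
    """Convenience: rates from the built-in E. coli tRNA table and wobble map."""
    return codon_rates(builtin_trna_table(), builtin_wobble_map(), normalization_mode)


def rare_codons(usage: CodonUsageTable, k: int = 10) -> set[str]:
    """The ``k`` least-used sense codons of a usage table.

    Ties are broken lexicographically so the result is deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(SENSE_CODONS):
        raise ValueError(f"k={k} exceeds the number of sense codons")
    ranked = sorted(SENSE_CODONS, key=lambda c: (usage.freqs[c], c))
    return set(ranked[:k])
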