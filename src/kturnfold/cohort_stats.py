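"""Cohort-level 3b·3n statistics over k-turn sequence collections.

Reads alignment cohorts (Stockholm, Rfam dialect), tabulates the 16
ordered 3b·3n pairs, and summarizes rule-engine fractions.  Database
access is out of scope: the module consumes local files only, and rows
whose mapped columns are gapped are reported as unclassifiable rather
than dropped (cohort percentages depend on the denominator).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .errors import AnnotationError, ConfigError, FormatError
from .folding_rules import ALL_PAIRS, RuleClass, classify_pair
from .kturn_model import KTurn, Nucleotide, PairId, format_pair

__all__ = [
    "UNCLASSIFIABLE",
    "PairCountTable",
    "CohortSummary",
    "SpectrumRow",
    "read_column_map",
    "read_stockholm_cohort",
    "tabulate_pairs",
    "summarize",
    "folding_spectrum",
    "default_ranking",
]

UNCLASSIFIABLE = "unclassifiable"


def read_column_map(path) -> dict[str, int]:
    """Read a label→column map (JSON object, 1-based columns)."""
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"column map {path}: {exc}") from None
    if not isinstance(raw, dict) or not raw:
        raise ConfigError(f"column map {path}: expected a non-empty JSON object")
    out = {}
    for label, col in raw.items():
        if not isinstance(col, int) or col < 1:
            raise ConfigError(
                f"column map {path}: column for {label!r} must be a 1-based integer"
            )
        out[str(label)] = col
    return out


def read_stockholm_cohort(path, column_map: Mapping[str, int]) -> list[KTurn]:
    """One (possibly partial) k-turn per Stockholm alignment row.

    ``column_map`` maps position labels (``3b``, ``3n``, ...) to 1-based
    alignment columns as displayed by alignment viewers; it must cover
    at least 3b and 3n.  Gapped mapped columns yield GAP bases, which
    downstream tabulation counts as unclassifiable.
    """
    from Bio import AlignIO

    for required in ("3b", "3n"):
        if required not in column_map:
            raise ConfigError(f"column map must include label {required!r}")

    text = Path(path).read_text()
    first = text.splitlines()[0] if text.splitlines() else ""
    if not first.startswith("# STOCKHOLM"):
        raise FormatError(f"{path}:1: missing '# STOCKHOLM' header")
    try:
        alignment = AlignIO.read(str(path), "stockholm")
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None

    width = alignment.get_alignment_length()
    for label, col in column_map.items():
        if col > width:
            raise ConfigError(
                f"column map: label {label!r} → column {col} outside alignment width {width}"
            )

    cohort = []
    for row in alignment:
        bases = {
            label: Nucleotide.from_char(str(row.seq)[col - 1])
            for label, col in column_map.items()
        }
        cohort.append(KTurn.from_labelled_bases(bases, name=row.id))
    return cohort


@dataclass
class PairCountTable:
    """Counts of the 16 ordered pairs plus an unclassifiable bucket."""

    counts: dict = field(default_factory=dict)
    total: int = 0
    cohort_name: str = ""

    def fraction(self, key) -> float:
        if self.total == 0:
            raise AnnotationError("empty cohort has no fractions")
        return self.counts.get(key, 0) / self.total


def _pair_key(pair: PairId) -> tuple[Nucleotide, Nucleotide]:
    return (pair.b, pair.n)


def tabulate_pairs(cohort: Iterable[KTurn], cohort_name: str = "") -> PairCountTable:
    """Exact, deterministic 3b·3n pair counts for a cohort."""
    counts: dict = {_pair_key(p): 0 for p in ALL_PAIRS}
    counts[UNCLASSIFIABLE] = 0
    total = 0
    for kt in cohort:
        total += 1
        try:
            pair = kt.pair_at(3)
        except AnnotationError:
            counts[UNCLASSIFIABLE] += 1
            continue
        if pair.is_ambiguous:
            counts[UNCLASSIFIABLE] += 1
        else:
            counts[_pair_key(pair)] += 1
    return PairCountTable(counts=counts, total=total, cohort_name=cohort_name)


@dataclass(frozen=True)
class CohortSummary:
    """Headline fractions for a cohort (denominator = all rows)."""

    cohort_name: str
    n: int
    frac_AG: float
    frac_3nG: float
    frac_3bC: float
    frac_folders: float
    frac_nonfolders: float
    frac_indeterminate: float
    frac_unclassifiable: float


def summarize(table: PairCountTable) -> CohortSummary:
    """Fractions of interest; classification delegates to the rule engine."""
    if table.total == 0:
        raise AnnotationError("cannot summarize an empty cohort")
    by_class = {k: 0 for k in RuleClass}
    n_ag = n_3ng = n_3bc = 0
    for pair in ALL_PAIRS:
        count = table.counts.get(_pair_key(pair), 0)
        by_class[classify_pair(pair).klass] += count
        if pair.b is Nucleotide.A and pair.n is Nucleotide.G:
            n_ag += count
        if pair.n is Nucleotide.G:
            n_3ng += count
        if pair.b is Nucleotide.C:
            n_3bc += count
    t = table.total
    return CohortSummary(
        cohort_name=table.cohort_name,
        n=t,
        frac_AG=n_ag / t,
        frac_3nG=n_3ng / t,
        frac_3bC=n_3bc / t,
        frac_folders=by_class[RuleClass.ION_FOLDER] / t,
        frac_nonfolders=by_class[RuleClass.NON_FOLDER] / t,
        frac_indeterminate=by_class[RuleClass.INDETERMINATE] / t,
        frac_unclassifiable=table.counts.get(UNCLASSIFIABLE, 0) / t,
    )


@dataclass(frozen=True)
class SpectrumRow:
    pair: PairId
    count: int
    fraction: float
    klass: RuleClass


def default_ranking() -> list[PairId]:
    """Folders first, then indeterminate, then non-folders; alphabetical
    within each block."""
    def key(pair: PairId):
        order = {
            RuleClass.ION_FOLDER: 0,
            RuleClass.INDETERMINATE: 1,
            RuleClass.NON_FOLDER: 2,
        }
        return (order[classify_pair(pair).klass], pair.b.value + pair.n.value)

    return sorted(ALL_PAIRS, key=key)


def folding_spectrum(
    table: PairCountTable, ranking: Optional[Sequence[PairId]] = None
) -> list[SpectrumRow]:
    """Histogram rows ordered by folding ability (or a custom ranking)."""
    if ranking is None:
        ranking = default_ranking()
    if sorted((b.value, n.value) for b, n in map(_pair_key, ranking)) != sorted(
        (b.value, n.value) for b, n in map(_pair_key, ALL_PAIRS)
    ):
        raise ConfigError("ranking must be a permutation of the 16 ordered pairs")
    if table.total == 0:
        raise AnnotationError("cannot rank an empty cohort")
    return [
        SpectrumRow(
            pair=pair,
            count=table.counts.get(_pair_key(pair), 0),
            fraction=table.fraction(_pair_key(pair)),
            klass=classify_pair(pair).klass,
        )
        for pair in ranking
    ]


def counts_table_text(table: PairCountTable) -> str:
    """Counts as TSV (pair, count, fraction), unclassifiable last."""
    lines = [f"# cohort={table.cohort_name or 'unnamed'} total={table.total}"]
    lines.append("pair\tcount\tfraction")
    for pair in ALL_PAIRS:
        c = table.counts.get(_pair_key(pair), 0)
        frac = c / table.total if table.total else 0.0
        lines.append(f"{format_pair(pair)}\t{c}\t{frac:.6g}")
    c = table.counts.get(UNCLASSIFIABLE, 0)
    frac = c / table.total if table.total else 0.0
    lines.append(f"{UNCLASSIFIABLE}\t{c}\t{frac:.6g}")
    return "\n".join(lines) + "\n"
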