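"""Empirical 3b·3n sequence rules for ion-induced k-turn folding.

Two ordered rules classify the base pair that follows the conserved
G·A/A·G pairs:

* **Rule 1** (takes precedence): a Watson–Crick pair (A-U, U-A, G-C,
  C-G) or the G-U wobble cannot fold in metal ions alone → ``non_folder``.
* **Rule 2**: otherwise, 3n=G or 3b=C permits ion-induced folding →
  ``ion_folder``.

Pairs matched by neither rule are ``indeterminate`` — the source data
anchor only the extremes of the folding spectrum, so no guess is made.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Optional

from .errors import AnnotationError, ClassificationError, ConfigError
from .kturn_model import KTurn, Nucleotide, PairId, format_pair, pair_at

__all__ = [
    "RuleClass",
    "EmpiricalCategory",
    "RuleFiring",
    "FoldingPrediction",
    "EmpiricalTable",
    "ALL_PAIRS",
    "classify_pair",
    "predict",
    "enumerate_rule_partition",
    "rule_table_text",
]

_ACGU = (Nucleotide.A, Nucleotide.C, Nucleotide.G, Nucleotide.U)

#: The 16 ordered (3b, 3n) pairs in a fixed (b-major) order.
ALL_PAIRS: tuple[PairId, ...] = tuple(
    PairId(b, n, 3) for b, n in product(_ACGU, repeat=2)
)

_RULE1_PAIRS = frozenset(
    {
        (Nucleotide.A, Nucleotide.U),
        (Nucleotide.U, Nucleotide.A),
        (Nucleotide.G, Nucleotide.C),
        (Nucleotide.C, Nucleotide.G),
        (Nucleotide.G, Nucleotide.U),  # wobble with b=G only; (U,G) folds via 3n=G
    }
)


class RuleClass(enum.Enum):
    ION_FOLDER = "ion_folder"
    NON_FOLDER = "non_folder"
    INDETERMINATE = "indeterminate"


class EmpiricalCategory(enum.Enum):
    READILY_FOLDED = "readily_folded"
    POORLY_FOLDED = "poorly_folded"
    INTERMEDIATE = "intermediate"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class RuleFiring:
    rule_id: str
    condition: str


@dataclass(frozen=True)
class FoldingPrediction:
    """Rule-engine output for one 3b·3n pair."""

    pair: PairId
    klass: RuleClass
    rule_trace: tuple[RuleFiring, ...]
    empirical_category: EmpiricalCategory = EmpiricalCategory.UNKNOWN


@dataclass
class EmpiricalTable:
    """Empirical folding category per 3b·3n pair with provenance.

    ``entries`` maps each of the 16 ordered pairs to a category;
    ``provenance`` records whether the entry is text-anchored or loaded
    from a figure-derived configuration file.

    Thresholds on the saturation amplitude ΔE_FRET (``readily`` default
    0.5, ``poorly`` default 0.3) are kept configurable: the published
    account can be read as thresholding either ΔE_FRET or the endpoint
    efficiency, and the two readings are not reconciled here.
    """

    entries: dict[tuple[Nucleotide, Nucleotide], EmpiricalCategory] = field(
        default_factory=dict
    )
    provenance: dict[tuple[Nucleotide, Nucleotide], str] = field(default_factory=dict)
    readily_threshold: float = 0.5
    poorly_threshold: float = 0.3

    def category(self, pair: PairId) -> EmpiricalCategory:
        return self.entries.get((pair.b, pair.n), EmpiricalCategory.UNKNOWN)

    def categorize_amplitude(self, delta_efret: float) -> EmpiricalCategory:
        """Category from a measured ΔE_FRET under the current thresholds."""
        if delta_efret >= self.readily_threshold:
            return EmpiricalCategory.READILY_FOLDED
        if delta_efret <= self.poorly_threshold:
            return EmpiricalCategory.POORLY_FOLDED
        return EmpiricalCategory.INTERMEDIATE

    @classmethod
    def default(cls) -> "EmpiricalTable":
        """Table with only text-anchored entries; the rest are unknown.

        Anchors: A·G folds readily (the best-folding sequence), while
        the Watson–Crick pairs plus G-U are all poor folders.
        """
        table = cls()
        anchors_poor = [
            (Nucleotide.A, Nucleotide.U),
            (Nucleotide.U, Nucleotide.A),
            (Nucleotide.G, Nucleotide.C),
            (Nucleotide.C, Nucleotide.G),
            (Nucleotide.G, Nucleotide.U),
        ]
        for b, n in _pair_keys():
            table.entries[(b, n)] = EmpiricalCategory.UNKNOWN
            table.provenance[(b, n)] = "untabulated"
        table.entries[(Nucleotide.A, Nucleotide.G)] = EmpiricalCategory.READILY_FOLDED
        table.provenance[(Nucleotide.A, Nucleotide.G)] = "text-anchored"
        for bn in anchors_poor:
            table.entries[bn] = EmpiricalCategory.POORLY_FOLDED
            table.provenance[bn] = "text-anchored"
        return table

    @classmethod
    def from_file(cls, path, **thresholds) -> "EmpiricalTable":
        """Load figure-derived categories from a two-column TSV.

        Rows are ``<bn>\\t<value>`` where ``<bn>`` is two letters (b then
        n, e.g. ``AG``) and ``<value>`` is a category name or a numeric
        ΔE_FRET to be thresholded.  Entries not listed stay as in the
        default table.
        """
        table = cls.default()
        for key, val in thresholds.items():
            setattr(table, key, val)
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2 or len(parts[0]) != 2:
                raise ConfigError(f"{path}:{lineno}: expected '<bn> <category|dE>'")
            try:
                bn = (Nucleotide(parts[0][0].upper()), Nucleotide(parts[0][1].upper()))
            except ValueError:
                raise ConfigError(f"{path}:{lineno}: bad pair {parts[0]!r}") from None
            try:
                cat = table.categorize_amplitude(float(parts[1]))
            except ValueError:
                try:
                    cat = EmpiricalCategory(parts[1].lower())
                except ValueError:
                    raise ConfigError(
                        f"{path}:{lineno}: bad category {parts[1]!r}"
                    ) from None
            table.entries[bn] = cat
            table.provenance[bn] = "figure-derived"
        return table


def _pair_keys():
    return [(p.b, p.n) for p in ALL_PAIRS]


def classify_pair(
    pair: PairId, table: Optional[EmpiricalTable] = None
) -> FoldingPrediction:
    """Classify a 3b·3n pair under the two ordered folding rules."""
    if pair.is_ambiguous:
        raise ClassificationError(
            f"cannot classify ambiguous pair {format_pair(pair)}"
        )
    trace: list[RuleFiring] = []
    if (pair.b, pair.n) in _RULE1_PAIRS:
        trace.append(
            RuleFiring(
                "rule1",
                f"{format_pair(pair)} is Watson–Crick or G-U wobble",
            )
        )
        klass = RuleClass.NON_FOLDER
    elif pair.n is Nucleotide.G or pair.b is Nucleotide.C:
        cond = "3n=G" if pair.n is Nucleotide.G else "3b=C"
        trace.append(RuleFiring("rule2", f"{cond} permits ion-induced folding"))
        klass = RuleClass.ION_FOLDER
    else:
        trace.append(RuleFiring("none", "no rule condition matched"))
        klass = RuleClass.INDETERMINATE
    category = (table or _DEFAULT_TABLE).category(pair)
    return FoldingPrediction(
        pair=pair,
        klass=klass,
        rule_trace=tuple(trace),
        empirical_category=category,
    )


def predict(kturn: KTurn, table: Optional[EmpiricalTable] = None) -> FoldingPrediction:
    """Apply the rule engine to a k-turn's 3b·3n pair."""
    try:
        pair = pair_at(kturn, 3)
    except AnnotationError:
        raise AnnotationError(
            f"k-turn {kturn.name or '<unnamed>'} lacks 3b/3n labels"
        ) from None
    return classify_pair(pair, table=table)


def enumerate_rule_partition() -> dict[RuleClass, frozenset[PairId]]:
    """Partition of all 16 ordered pairs by rule class (disjoint, exhaustive)."""
    out: dict[RuleClass, set[PairId]] = {k: set() for k in RuleClass}
    for pair in ALL_PAIRS:
        out[classify_pair(pair).klass].add(pair)
    return {k: frozenset(v) for k, v in out.items()}


def rule_table_text(table: Optional[EmpiricalTable] = None) -> str:
    """All 16 pairs as TSV: pair, class, rule fired, empirical category."""
    buf = io.StringIO()
    buf.write("pair\tclass\trule\tempirical_category\n")
    for pair in ALL_PAIRS:
        pred = classify_pair(pair, table=table)
        buf.write(
            f"{format_pair(pair)}\t{pred.klass.value}\t"
            f"{pred.rule_trace[0].rule_id}\t{pred.empirical_category.value}\n"
        )
    return buf.getvalue()


_DEFAULT_TABLE = EmpiricalTable.default()
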