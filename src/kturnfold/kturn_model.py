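"""Positional model of the kink-turn (k-turn) motif.

A k-turn is represented as two strands: the bulge-containing strand
("b", 5'→3') and the non-bulged strand ("n", 5'→3'), with a loop of
(usually three) unpaired nucleotides on the b strand.  Positions are
addressed through the standard label set: loop nucleotides ``L1..Lk``,
``1b, 2b, ...`` ascending 3' of the loop (the NC helix), ``-1b, -2b, ...``
descending 5' of the loop (the C helix), and ``1n, 2n, ...`` /
``-1n, ...`` for their antiparallel pairing partners on the n strand.

Integer indices are 0-based and private to this module; position labels
are the public coordinate system.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .errors import AnnotationError, InputError

__all__ = [
    "Nucleotide",
    "PairId",
    "KTurn",
    "Deviation",
    "parse_strand",
    "strand_text",
    "parse_kturn",
    "pair_at",
    "validate_standard",
    "format_pair",
    "substitute_pair",
    "read_fasta_kturns",
    "write_fasta_kturns",
]


class Nucleotide(enum.Enum):
    """RNA nucleotide alphabet plus GAP and N for alignment input."""

    A = "A"
    C = "C"
    G = "G"
    U = "U"
    GAP = "-"
    N = "N"

    @property
    def is_concrete(self) -> bool:
        """True for A/C/G/U; False for GAP and N."""
        return self not in (Nucleotide.GAP, Nucleotide.N)

    @classmethod
    def from_char(cls, ch: str) -> "Nucleotide":
        """Parse one character; T normalizes to U, lowercase accepted.

        Ambiguity codes other than N are rejected — classifying rules on
        an ambiguous base would be misleading.
        """
        c = ch.upper()
        if c == "T":
            c = "U"
        if c in ".-~":
            return cls.GAP
        try:
            return cls(c)
        except ValueError:
            raise InputError(
                f"invalid nucleotide code {ch!r}: only A/C/G/U (T→U), N and gaps are accepted"
            ) from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def parse_strand(text: str) -> tuple[Nucleotide, ...]:
    """Parse strand text (5'→3') into a nucleotide tuple."""
    stripped = re.sub(r"\s", "", text)
    if not stripped:
        raise InputError("empty strand")
    return tuple(Nucleotide.from_char(c) for c in stripped)


def strand_text(seq: Iterable[Nucleotide]) -> str:
    """Render a nucleotide sequence back to uppercase strand text."""
    return "".join(n.value for n in seq)


@dataclass(frozen=True)
class PairId:
    """An ordered base pair (b-strand base, n-strand base) at a position.

    Order is significant and never swapped: ``PairId(A, G, 3)`` means
    3b=A, 3n=G.
    """

    b: Nucleotide
    n: Nucleotide
    position_index: int = 3

    @property
    def is_ambiguous(self) -> bool:
        return not (self.b.is_concrete and self.n.is_concrete)

    def formatted(self) -> str:
        return format_pair(self)

    def __str__(self) -> str:
        return self.formatted()


_WATSON_CRICK = {
    (Nucleotide.A, Nucleotide.U),
    (Nucleotide.U, Nucleotide.A),
    (Nucleotide.G, Nucleotide.C),
    (Nucleotide.C, Nucleotide.G),
}


def format_pair(pair: PairId) -> str:
    """Render a pair in standard notation.

    Watson–Crick pairs and the G-U wobble with b=G use "-"; every other
    combination uses "·"; ambiguous bases are joined with "?" to flag
    them. Order is always b then n.
    """
    if pair.is_ambiguous:
        return f"{pair.b.value}?{pair.n.value}"
    bn = (pair.b, pair.n)
    if bn in _WATSON_CRICK or bn == (Nucleotide.G, Nucleotide.U):
        sep = "-"
    else:
        sep = "·"
    return f"{pair.b.value}{sep}{pair.n.value}"


_B_LABEL = re.compile(r"^(-?\d+)b$")
_N_LABEL = re.compile(r"^(-?\d+)n$")
_L_LABEL = re.compile(r"^L(\d+)$")


@dataclass
class KTurn:
    """A positionally annotated k-turn motif.

    ``labels`` maps position labels to ``(strand, index)`` where strand
    is ``"b"`` or ``"n"`` and index is 0-based into that strand.
    """

    b_strand: tuple[Nucleotide, ...]
    n_strand: tuple[Nucleotide, ...]
    loop_start: int
    loop_length: int
    labels: dict[str, tuple[str, int]] = field(default_factory=dict)
    name: str = ""

    @property
    def b_text(self) -> str:
        return strand_text(self.b_strand)

    @property
    def n_text(self) -> str:
        return strand_text(self.n_strand)

    def has_label(self, label: str) -> bool:
        return label in self.labels

    def base_at(self, label: str) -> Nucleotide:
        """Base at a position label; raises AnnotationError if absent."""
        try:
            strand, idx = self.labels[label]
        except KeyError:
            raise AnnotationError(
                f"k-turn {self.name or '<unnamed>'} has no label {label!r}"
            ) from None
        seq = self.b_strand if strand == "b" else self.n_strand
        return seq[idx]

    def pair_at(self, position_index: int) -> PairId:
        return pair_at(self, position_index)

    @classmethod
    def from_labelled_bases(
        cls, bases: Mapping[str, Nucleotide], name: str = ""
    ) -> "KTurn":
        """Build a (possibly partial) k-turn from label→base assignments.

        Used for alignment rows where only a handful of columns are
        mapped to position labels.  Strand sequences are synthesized in
        5'→3' order from whichever labels are present.
        """

        def b_key(label: str) -> tuple[int, int]:
            m = _B_LABEL.match(label)
            if m:
                i = int(m.group(1))
                return (1, i) if i > 0 else (0, i)
            m = _L_LABEL.match(label)
            if m:
                return (0, 10_000 + int(m.group(1)))  # loop sits after -1b
            raise AnnotationError(f"unrecognized label {label!r}")

        b_labels = sorted(
            (l for l in bases if _B_LABEL.match(l) or _L_LABEL.match(l)), key=b_key
        )
        # n strand 5'→3' runs antiparallel: high positive labels first.
        n_labels = sorted(
            (l for l in bases if _N_LABEL.match(l)),
            key=lambda l: -int(_N_LABEL.match(l).group(1)),
        )
        labels: dict[str, tuple[str, int]] = {}
        for i, lab in enumerate(b_labels):
            labels[lab] = ("b", i)
        for i, lab in enumerate(n_labels):
            labels[lab] = ("n", i)
        loop = [l for l in b_labels if _L_LABEL.match(l)]
        loop_start = labels[loop[0]][1] if loop else 0
        return cls(
            b_strand=tuple(bases[l] for l in b_labels) or (Nucleotide.GAP,),
            n_strand=tuple(bases[l] for l in n_labels) or (Nucleotide.GAP,),
            loop_start=loop_start,
            loop_length=len(loop),
            labels=labels,
            name=name,
        )


def parse_kturn(
    b_strand: str,
    n_strand: str,
    loop_start: int,
    loop_length: int = 3,
    *,
    name: str = "",
) -> KTurn:
    """Parse two strands into an annotated :class:`KTurn`.

    Parameters
    ----------
    b_strand, n_strand:
        Strand texts, 5'→3'.  The b strand carries the loop.
    loop_start:
        0-based index into the b strand of the first loop nucleotide.
    loop_length:
        Number of loop nucleotides (3 for a standard k-turn).

    The pairing register is antiparallel and blunt at the NC end: the 3'
    terminal nucleotide of the b strand pairs the 5' terminal nucleotide
    of the n strand, and the loop is unpaired.  Labels are assigned as
    far as both strand lengths allow; ``1n..3n`` must be assignable.
    """
    b = parse_strand(b_strand)
    n = parse_strand(n_strand)
    if loop_start < 0 or loop_length < 1:
        raise InputError("loop_start must be ≥0 and loop_length ≥1")
    if loop_start + loop_length > len(b):
        raise InputError(
            f"loop ({loop_start}+{loop_length}) extends beyond b strand of length {len(b)}"
        )

    labels: dict[str, tuple[str, int]] = {}
    for k in range(loop_length):
        labels[f"L{k + 1}"] = ("b", loop_start + k)
    i = 1
    for j in range(loop_start + loop_length, len(b)):
        labels[f"{i}b"] = ("b", j)
        i += 1
    i = 1
    for j in range(loop_start - 1, -1, -1):
        labels[f"-{i}b"] = ("b", j)
        i += 1

    # Pairing partner on the n strand: NC-side b index j pairs n index
    # len(b)-1-j; C-side indices additionally skip the unpaired loop.
    for lab in list(labels):
        m = _B_LABEL.match(lab)
        if not m:
            continue
        pos = int(m.group(1))
        _, j = labels[lab]
        nj = len(b) - 1 - j if pos > 0 else len(b) - 1 - j - loop_length
        if 0 <= nj < len(n):
            labels[f"{pos}n"] = ("n", nj)

    for required in ("1n", "2n", "3n"):
        b_lab = required[:-1] + "b"
        if b_lab in labels and required not in labels:
            raise AnnotationError(
                f"n strand too short to pair label {required} (b strand has {b_lab})"
            )

    return KTurn(
        b_strand=b,
        n_strand=n,
        loop_start=loop_start,
        loop_length=loop_length,
        labels=labels,
        name=name,
    )


def pair_at(kturn: KTurn, position_index: int) -> PairId:
    """Ordered pair (base at ``ib``, base at ``in``) for position i."""
    b = kturn.base_at(f"{position_index}b")
    n = kturn.base_at(f"{position_index}n")
    return PairId(b=b, n=n, position_index=position_index)


@dataclass(frozen=True)
class Deviation:
    """One departure from the standard k-turn consensus."""

    label: str
    expected: str
    found: str

    def __str__(self) -> str:
        return f"{self.label}: expected {self.expected}, found {self.found}"


_STANDARD_PAIRS = {
    "1b": Nucleotide.G,
    "1n": Nucleotide.A,
    "2b": Nucleotide.A,
    "2n": Nucleotide.G,
}


def validate_standard(kturn: KTurn) -> list[Deviation]:
    """Check the standard-k-turn consensus; report, never raise.

    A standard k-turn has a 3-nucleotide loop followed by G·A then A·G
    pairs (1b·1n = G·A, 2b·2n = A·G).  Returns one record per deviation;
    empty list means fully standard.
    """
    deviations: list[Deviation] = []
    if kturn.loop_length != 3:
        deviations.append(
            Deviation("loop", "length 3", f"loop length {kturn.loop_length} ≠ 3")
        )
    for label, expected in _STANDARD_PAIRS.items():
        try:
            found = kturn.base_at(label)
        except AnnotationError:
            deviations.append(Deviation(label, expected.value, "<missing>"))
            continue
        if found is not expected:
            deviations.append(Deviation(label, expected.value, found.value))
    return deviations


def substitute_pair(kturn: KTurn, position_index: int, pair: PairId) -> KTurn:
    """Copy of ``kturn`` with the bases at ``ib``/``in`` replaced."""
    sb, jb = kturn.labels.get(f"{position_index}b", (None, None))
    sn, jn = kturn.labels.get(f"{position_index}n", (None, None))
    if sb is None or sn is None:
        raise AnnotationError(
            f"cannot substitute position {position_index}: labels missing"
        )
    b = list(kturn.b_strand)
    n = list(kturn.n_strand)
    b[jb] = pair.b
    n[jn] = pair.n
    return replace(kturn, b_strand=tuple(b), n_strand=tuple(n))


# ---------------------------------------------------------------------------
# FASTA I/O.  A k-turn is two consecutive records whose description lines
# carry key=value tokens: "strand=b loop_start=<i> loop_len=<k>" on the b
# record and "strand=n" on its partner.
# ---------------------------------------------------------------------------

def _description_tokens(description: str) -> dict[str, str]:
    return dict(
        tok.split("=", 1) for tok in description.split() if "=" in tok
    )


def read_fasta_kturns(path) -> list[KTurn]:
    """Read k-turns from FASTA (b/n record pairs, see module docs)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    kturns: list[KTurn] = []
    pending = None  # (name, seq, loop_start, loop_len)
    for rec in records:
        tokens = _description_tokens(rec.description)
        strand = tokens.get("strand")
        if strand == "b":
            if pending is not None:
                raise InputError(f"record {pending[0]}: b strand without n partner")
            try:
                loop_start = int(tokens["loop_start"])
                loop_len = int(tokens.get("loop_len", 3))
            except (KeyError, ValueError):
                raise InputError(
                    f"record {rec.id}: b strand needs loop_start=<i> [loop_len=<k>] tokens"
                ) from None
            pending = (rec.id, str(rec.seq), loop_start, loop_len)
        elif strand == "n":
            if pending is None:
                raise InputError(f"record {rec.id}: n strand without preceding b strand")
            name, bseq, loop_start, loop_len = pending
            kturns.append(
                parse_kturn(bseq, str(rec.seq), loop_start, loop_len, name=name)
            )
            pending = None
        else:
            raise InputError(
                f"record {rec.id}: description must carry strand=b or strand=n"
            )
    if pending is not None:
        raise InputError(f"record {pending[0]}: b strand without n partner")
    return kturns


def write_fasta_kturns(kturns: Iterable[KTurn], path) -> None:
    """Write k-turns as b/n FASTA record pairs readable by the reader."""
    with open(path, "w") as fh:
        for kt in kturns:
            name = kt.name or "kturn"
            fh.write(
                f">{name} strand=b loop_start={kt.loop_start} loop_len={kt.loop_length}\n"
            )
            fh.write(kt.b_text + "\n")
            fh.write(f">{name} strand=n\n")
            fh.write(kt.n_text + "\n")
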