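"""Seeded generators for every input the pipeline consumes.

Provides noisy two-state titration curves, the exhaustive 16-variant
3b·3n scan of a template k-turn, sequence cohorts drawn from pair
frequency profiles, and minimal PDB fixtures for the coordination
module.  All randomness flows through explicit seeds.

The shipped cohort profiles are paper-inspired stand-ins: a
riboswitch-like cohort dominated by A·G with a strong 3n=G marginal,
and a spliceosomal-like cohort concentrated on G-C/G-U.  The exact
frequency vectors are package defaults, not measured data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import AnnotationError, InputError
from .folding_rules import ALL_PAIRS
from .kturn_model import KTurn, Nucleotide, PairId, parse_kturn, substitute_pair
from .titration import TitrationCurve, model_efret

__all__ = [
    "TitrationSpec",
    "CohortProfile",
    "Variant",
    "kt7_template",
    "u4_like_template",
    "simulate_titration",
    "enumerate_3bn_variants",
    "sam_like_profile",
    "u4_like_profile",
    "generate_cohort",
    "write_stockholm_cohort",
    "write_fixture_structure",
    "FIXTURE_KINDS",
]

_N = Nucleotide


def kt7_template() -> KTurn:
    """The Kt-7 k-turn: GAA loop, G·A / A·G / A·G pairs (3b·3n = A·G)."""
    return parse_kturn("GGCGAAGAACC", "GGGGAGCC", loop_start=3, loop_length=3,
                       name="Kt-7")


def u4_like_template() -> KTurn:
    """A U4-like stand-in: the Kt-7 backbone with 3b·3n set to G-C.

    The defining feature of the spliceosomal U4 k-turn for this package
    is its Watson–Crick 3b·3n pair; the flanking sequence here is the
    Kt-7 scaffold, not the U4 sequence itself.
    """
    kt = substitute_pair(kt7_template(), 3, PairId(_N.G, _N.C, 3))
    kt.name = "U4-like"
    return kt


# ---------------------------------------------------------------------------
# titration curves
# ---------------------------------------------------------------------------

@dataclass
class TitrationSpec:
    """Generating parameters for a synthetic titration curve."""

    E0: float = 0.2
    dE: float = 0.36
    KA: float = 1.0 / 70.0
    n: float = 1.0
    conc_min: float = 1.0
    conc_max: float = 5000.0
    n_points: int = 12
    log_spacing: bool = True
    noise_sd: float = 0.0
    seed: int = 0
    ligand_name: str = "Mg2+"
    unit: str = "uM"
    include_zero: bool = False

    def __post_init__(self):
        if self.n_points < 5:
            raise InputError("need at least 5 concentration points")
        if self.noise_sd < 0:
            raise InputError("noise sd must be ≥0")
        if self.conc_min <= 0 and self.log_spacing:
            raise InputError("log-spaced grid requires conc_min > 0")
        if self.conc_max <= self.conc_min:
            raise InputError("conc_max must exceed conc_min")


def simulate_titration(spec: TitrationSpec) -> TitrationCurve:
    """Model curve on the spec's grid plus seeded Gaussian noise."""
    if spec.log_spacing:
        conc = np.logspace(
            np.log10(spec.conc_min), np.log10(spec.conc_max), spec.n_points
        )
    else:
        conc = np.linspace(spec.conc_min, spec.conc_max, spec.n_points)
    if spec.include_zero:
        conc = np.concatenate([[0.0], conc])
    efret = model_efret(spec.E0, spec.dE, spec.KA, spec.n, conc)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        efret = efret + rng.normal(0.0, spec.noise_sd, size=conc.size)
    efret = np.clip(efret, -0.1, 1.1)
    return TitrationCurve(
        concentrations=conc,
        efret=efret,
        ligand_name=spec.ligand_name,
        unit=spec.unit,
    )


# ---------------------------------------------------------------------------
# 3b·3n variant scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variant:
    pair: PairId
    kturn: KTurn
    is_natural: bool


def enumerate_3bn_variants(template: KTurn) -> list[Variant]:
    """All 16 ordered 3b·3n substitutions of the template.

    Exactly one entry per ordered pair; the template's natural pair is
    flagged, so a scan of the non-natural sequences has 15 entries.
    """
    if not (template.has_label("3b") and template.has_label("3n")):
        raise AnnotationError("template lacks 3b/3n labels")
    natural = template.pair_at(3)
    variants = []
    for pair in ALL_PAIRS:
        kt = substitute_pair(template, 3, pair)
        kt.name = f"{template.name or 'kturn'}_3bn_{pair.b.value}{pair.n.value}"
        variants.append(
            Variant(
                pair=pair,
                kturn=kt,
                is_natural=(pair.b is natural.b and pair.n is natural.n),
            )
        )
    return variants


# ---------------------------------------------------------------------------
# sequence cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortProfile:
    """A named 3b·3n frequency profile over a template k-turn."""

    name: str
    pair_probabilities: dict[tuple[Nucleotide, Nucleotide], float]
    template: KTurn = field(default_factory=kt7_template)

    def __post_init__(self):
        probs = np.array(list(self.pair_probabilities.values()), dtype=float)
        if np.any(probs < 0):
            raise InputError("pair probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise InputError(
                f"pair probabilities must sum to 1 (got {probs.sum():.12g})"
            )


def sam_like_profile() -> CohortProfile:
    """Riboswitch-like profile: 60% A·G, 3n=G marginal 0.92."""
    p = {
        (_N.A, _N.G): 0.600,
        (_N.G, _N.G): 0.150,
        (_N.U, _N.G): 0.130,
        (_N.C, _N.G): 0.040,
        (_N.C, _N.A): 0.040,
        (_N.C, _N.C): 0.020,
        (_N.C, _N.U): 0.013,
        (_N.G, _N.C): 0.001,
        (_N.A, _N.U): 0.001,
        (_N.U, _N.A): 0.001,
        (_N.G, _N.U): 0.002,
        (_N.A, _N.A): 0.002,
    }
    return CohortProfile(name="SAM-like", pair_probabilities=p)


def u4_like_profile() -> CohortProfile:
    """Spliceosomal-like profile: mass concentrated on G-C and G-U."""
    p = {
        (_N.G, _N.C): 0.700,
        (_N.G, _N.U): 0.260,
        (_N.A, _N.U): 0.010,
        (_N.U, _N.A): 0.005,
        (_N.C, _N.G): 0.005,
        (_N.U, _N.G): 0.005,
        (_N.C, _N.A): 0.005,
        (_N.A, _N.A): 0.005,
        (_N.G, _N.A): 0.005,
    }
    return CohortProfile(name="U4-like", pair_probabilities=p, template=u4_like_template())


def generate_cohort(profile: CohortProfile, n: int, seed: int) -> list[KTurn]:
    """n k-turns with 3b·3n drawn i.i.d. from the profile."""
    if n < 1:
        raise InputError("cohort size must be ≥1")
    pairs = list(profile.pair_probabilities)
    probs = np.array([profile.pair_probabilities[p] for p in pairs], dtype=float)
    probs = probs / probs.sum()  # guard rounding at the 1e-9 tolerance
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(pairs), size=n, p=probs)
    cohort = []
    for i, k in enumerate(picks):
        b, nn = pairs[k]
        kt = substitute_pair(profile.template, 3, PairId(b, nn, 3))
        kt.name = f"{profile.name}_{i + 1:05d}"
        cohort.append(kt)
    return cohort


def write_stockholm_cohort(cohort: list[KTurn], path) -> dict[str, int]:
    """Write a cohort as a Stockholm alignment; returns the column map.

    Each row is the b strand followed by the n strand (both 5'→3'), so
    all rows must share strand lengths.  The returned map gives 1-based
    alignment columns for every position label of the first k-turn and
    matches :func:`kturnfold.cohort_stats.read_stockholm_cohort`.
    """
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import AlignIO

    if not cohort:
        raise InputError("empty cohort")
    blen = len(cohort[0].b_strand)
    nlen = len(cohort[0].n_strand)
    records = []
    for i, kt in enumerate(cohort):
        if len(kt.b_strand) != blen or len(kt.n_strand) != nlen:
            raise InputError("all cohort members must share strand lengths")
        records.append(
            SeqRecord(Seq(kt.b_text + kt.n_text), id=kt.name or f"seq{i + 1:05d}",
                      description="")
        )
    AlignIO.write(MultipleSeqAlignment(records), str(path), "stockholm")

    column_map = {}
    for label, (strand, idx) in cohort[0].labels.items():
        column_map[label] = idx + 1 if strand == "b" else blen + idx + 1
    return column_map


# ---------------------------------------------------------------------------
# PDB fixtures for the coordination module
# ---------------------------------------------------------------------------

FIXTURE_KINDS = ("ideal_octahedron", "two_ion_kt7_like")

_MG_O = 2.1  # Å, canonical Mg–O bond length used for constructed geometry


def _octahedron(center: np.ndarray, bond: float = _MG_O) -> list[np.ndarray]:
    axes = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    return [center + bond * np.array(a, dtype=float) for a in axes]


def _fixture_atoms(kind: str):
    """(atom_name, element, res_name, chain, res_id, hetero, xyz) tuples."""
    if kind == "ideal_octahedron":
        atoms = [("MG", "MG", "MG", "M", 101, True, np.zeros(3))]
        for i, pos in enumerate(_octahedron(np.zeros(3))):
            atoms.append(("O", "O", "HOH", "W", 201 + i, True, pos))
        return atoms
    if kind == "two_ion_kt7_like":
        m1 = np.zeros(3)
        m2 = np.array([2.0 * _MG_O, 0.0, 0.0])
        atoms = [
            ("MG", "MG", "MG", "M", 101, True, m1),
            ("MG", "MG", "MG", "M", 102, True, m2),
            # guanine O6 ligands: G3n O6 sits midway, inner-sphere to both
            # metals; G2n O6 is cis-adjacent on M1 only.
            ("O6", "O", "G", "B", 3, False, np.array([_MG_O, 0.0, 0.0])),
            ("O6", "O", "G", "B", 2, False, np.array([0.0, _MG_O, 0.0])),
        ]
        water = 201
        for pos in [(-_MG_O, 0, 0), (0, -_MG_O, 0), (0, 0, _MG_O), (0, 0, -_MG_O)]:
            atoms.append(("O", "O", "HOH", "W", water, True, np.array(pos, float)))
            water += 1
        for off in [(_MG_O, 0, 0), (0, _MG_O, 0), (0, -_MG_O, 0), (0, 0, _MG_O),
                    (0, 0, -_MG_O)]:
            atoms.append(
                ("O", "O", "HOH", "W", water, True, m2 + np.array(off, float))
            )
            water += 1
        return atoms
    raise InputError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")


def write_fixture_structure(kind: str, path) -> None:
    """Write a minimal, re-parsable PDB fixture.

    ``ideal_octahedron``: one Mg with six waters at 2.1 Å along the
    axes.  ``two_ion_kt7_like``: two octahedral metals where M1 binds
    the O6 atoms of guanines at the 2n and 3n positions (chain B,
    residues 2 and 3) and the 3n O6 bridges both metals.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    spec = _fixture_atoms(kind)
    array = struc.AtomArray(len(spec))
    for i, (atom_name, element, res_name, chain, res_id, hetero, xyz) in enumerate(spec):
        array.atom_name[i] = atom_name
        array.element[i] = element
        array.res_name[i] = res_name
        array.chain_id[i] = chain
        array.res_id[i] = res_id
        array.hetero[i] = hetero
        array.coord[i] = xyz
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(array)
    pdb_file.write(str(path))


#: Label map matching the two_ion_kt7_like fixture.
TWO_ION_LABEL_MAP = {("B", 2): "2n", ("B", 3): "3n"}
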