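"""Metal-ion coordination analysis in RNA coordinate files.

Finds metal ions (default Mg/Na/K/Mn), collects inner-sphere O/N
ligands within a distance cutoff, scores octahedral geometry from the
cis ligand–metal–ligand angles, and reports direct guanine O6 contacts.

The default inner-sphere cutoff of 2.6 Å covers Mg–O (~2.05–2.15 Å) and
Na–O (~2.4 Å) bonds; the metal species is reported, never inferred, from
coordination distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import FormatError, GeometryError, InputError

__all__ = [
    "AtomRecord",
    "CoordinationSite",
    "O6Contact",
    "read_structure",
    "find_metal_sites",
    "octahedral_score",
    "guanine_O6_report",
    "site_report_text",
    "DEFAULT_METALS",
    "DEFAULT_CUTOFF",
]

DEFAULT_METALS = frozenset({"MG", "NA", "K", "MN"})
DEFAULT_CUTOFF = 2.6  # Å
_GUANINE_RESIDUES = {"G", "GUA", "DG", "GTP", "GDP", "GMP"}
_WATER_RESIDUES = {"HOH", "WAT", "H2O"}
CIS_ANGLE_MAX = 135.0  # degrees; larger angles are trans
OCTAHEDRAL_TOLERANCE = 15.0  # degrees, mean |cis angle − 90°|


@dataclass(frozen=True)
class AtomRecord:
    """One atom with Cartesian coordinates in Å."""

    atom_name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    xyz: tuple[float, float, float]

    def __post_init__(self):
        if not self.element:
            raise InputError("atom element must be non-empty")
        if not all(np.isfinite(self.xyz)):
            raise InputError("atom coordinates must be finite")

    @property
    def is_water(self) -> bool:
        return self.residue_name.upper() in _WATER_RESIDUES

    @property
    def is_guanine_o6(self) -> bool:
        return (
            self.residue_name.upper() in _GUANINE_RESIDUES
            and self.atom_name.upper() == "O6"
        )

    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)


@dataclass
class CoordinationSite:
    """A metal ion with its inner-sphere ligands."""

    metal: AtomRecord
    ligands: list[tuple[AtomRecord, float]]  # sorted by distance
    cis_angle_deviation: float = float("nan")
    is_octahedral: bool = False
    o6_contacts: list[AtomRecord] = field(default_factory=list)

    @property
    def n_ligands(self) -> int:
        return len(self.ligands)


def read_structure(path) -> list[AtomRecord]:
    """Read all atoms from a PDB or mmCIF file.

    The dialect is auto-detected from the extension (falling back to
    content sniffing); alternate locations are resolved to the highest
    occupancy.
    """
    import biotite.structure.io.pdb as pdb
    import biotite.structure.io.pdbx as pdbx

    p = Path(path)
    if not p.exists():
        raise FormatError(f"no such file: {path}")
    suffix = p.suffix.lower()
    text_head = p.read_text(errors="replace")[:2048]
    try:
        if suffix in {".cif", ".mmcif"} or text_head.lstrip().startswith("data_"):
            cif = pdbx.CIFFile.read(str(p))
            atoms = pdbx.get_structure(cif, model=1, altloc="occupancy")
        else:
            pdb_file = pdb.PDBFile.read(str(p))
            atoms = pdb_file.get_structure(model=1, altloc="occupancy")
    except Exception as exc:
        raise FormatError(f"cannot parse structure {path}: {exc}") from None
    if atoms.array_length() == 0:
        raise FormatError(f"structure {path} contains no atoms")

    records = []
    for i in range(atoms.array_length()):
        records.append(
            AtomRecord(
                atom_name=str(atoms.atom_name[i]),
                element=str(atoms.element[i]).upper(),
                residue_name=str(atoms.res_name[i]),
                chain_id=str(atoms.chain_id[i]),
                residue_number=int(atoms.res_id[i]),
                xyz=tuple(float(v) for v in atoms.coord[i]),
            )
        )
    return records


def find_metal_sites(
    atoms: Sequence[AtomRecord],
    metal_elements: Iterable[str] = DEFAULT_METALS,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[CoordinationSite]:
    """One coordination site per metal atom.

    Ligands are all O/N atoms within ``cutoff`` Å of the metal, sorted
    by distance (ties broken by chain/residue/atom identity for
    determinism).  An empty structure yields an empty list.
    """
    if not (1.5 < cutoff < 3.5):
        raise InputError(f"cutoff must lie in (1.5, 3.5) Å, got {cutoff}")
    metals_wanted = {m.upper() for m in metal_elements}

    atoms = list(atoms)
    if not atoms:
        return []
    coords = np.array([a.xyz for a in atoms], dtype=float)
    sites = []
    for i, atom in enumerate(atoms):
        if atom.element not in metals_wanted:
            continue
        d = np.linalg.norm(coords - coords[i], axis=1)
        ligands = []
        for j, other in enumerate(atoms):
            if j == i or other.element not in {"O", "N"}:
                continue
            if d[j] <= cutoff:
                ligands.append((other, float(d[j])))
        ligands.sort(
            key=lambda t: (
                round(t[1], 9),
                t[0].chain_id,
                t[0].residue_number,
                t[0].atom_name,
            )
        )
        site = CoordinationSite(metal=atom, ligands=ligands)
        if len(ligands) >= 2:
            site.cis_angle_deviation, site.is_octahedral = octahedral_score(site)
        site.o6_contacts = [a for a, _ in ligands if a.is_guanine_o6]
        sites.append(site)
    return sites


def octahedral_score(
    site: CoordinationSite, tolerance: float = OCTAHEDRAL_TOLERANCE
) -> tuple[float, bool]:
    """Mean |cis angle − 90°| and an octahedricity flag.

    Cis ligand pairs are those whose ligand–metal–ligand angle is below
    135°; an ideal octahedron has 12 such pairs, all at 90°.  The site
    is octahedral iff it has exactly 6 ligands and the mean deviation is
    within ``tolerance`` degrees.
    """
    if site.n_ligands < 2:
        raise GeometryError(
            f"octahedral score undefined for {site.n_ligands} ligand(s)"
        )
    m = np.array(site.metal.xyz)
    vecs = [np.array(a.xyz) - m for a, _ in site.ligands]
    deviations = []
    for i in range(len(vecs)):
        for j in range(i + 1, len(vecs)):
            cosang = np.dot(vecs[i], vecs[j]) / (
                np.linalg.norm(vecs[i]) * np.linalg.norm(vecs[j])
            )
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle < CIS_ANGLE_MAX:
                deviations.append(abs(angle - 90.0))
    if not deviations:
        raise GeometryError("no cis ligand pairs (all angles ≥ 135°)")
    deviation = float(np.mean(deviations))
    return deviation, site.n_ligands == 6 and deviation <= tolerance


@dataclass(frozen=True)
class O6Contact:
    metal_id: str
    guanine: AtomRecord
    position_label: str
    distance: float


def _metal_id(site: CoordinationSite, index: int) -> str:
    a = site.metal
    return f"M{index + 1}({a.element} {a.chain_id}{a.residue_number})"


def guanine_O6_report(
    sites: Sequence[CoordinationSite],
    kturn_label_map: Optional[Mapping[tuple[str, int], str]] = None,
) -> list[O6Contact]:
    """Rows for every inner-sphere guanine O6 ligand across sites.

    ``kturn_label_map`` optionally maps ``(chain_id, residue_number)`` to
    a k-turn position label (e.g. ``"3n"``); without it rows carry
    residue numbers only.
    """
    rows = []
    for idx, site in enumerate(sites):
        for atom, dist in site.ligands:
            if not atom.is_guanine_o6:
                continue
            label = ""
            if kturn_label_map is not None:
                label = kturn_label_map.get(atom.residue_key(), "")
            rows.append(
                O6Contact(
                    metal_id=_metal_id(site, idx),
                    guanine=atom,
                    position_label=label,
                    distance=dist,
                )
            )
    return rows


def shared_ligands(
    sites: Sequence[CoordinationSite],
) -> dict[tuple[str, int, str], list[str]]:
    """Ligand atoms inner-sphere to more than one metal → metal ids."""
    seen: dict[tuple[str, int, str], list[str]] = {}
    for idx, site in enumerate(sites):
        for atom, _ in site.ligands:
            key = (atom.chain_id, atom.residue_number, atom.atom_name)
            seen.setdefault(key, []).append(_metal_id(site, idx))
    return {k: v for k, v in seen.items() if len(v) > 1}


def site_report_text(
    sites: Sequence[CoordinationSite],
    kturn_label_map: Optional[Mapping[tuple[str, int], str]] = None,
) -> str:
    """Delimited-text report over all sites (one ligand per row)."""
    lines = ["metal\tn_ligands\toctahedral\tcis_dev_deg\tligand\tresidue\tdistance_A"]
    for idx, site in enumerate(sites):
        mid = _metal_id(site, idx)
        dev = f"{site.cis_angle_deviation:.3f}" if site.n_ligands >= 2 else "NA"
        for atom, dist in site.ligands:
            res = f"{atom.residue_name} {atom.chain_id}{atom.residue_number}"
            lines.append(
                f"{mid}\t{site.n_ligands}\t{site.is_octahedral}\t{dev}\t"
                f"{atom.atom_name}\t{res}\t{dist:.3f}"
            )
        if not site.ligands:
            lines.append(f"{mid}\t0\tFalse\tNA\t-\t-\t-")
    o6 = guanine_O6_report(sites, kturn_label_map)
    lines.append("")
    lines.append("metal\tguanine\tposition\tdistance_A")
    for row in o6:
        g = row.guanine
        lines.append(
            f"{row.metal_id}\t{g.residue_name} {g.chain_id}{g.residue_number}\t"
            f"{row.position_label or '-'}\t{row.distance:.3f}"
        )
    return "\n".join(lines) + "\n"
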