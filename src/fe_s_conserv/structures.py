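"""Protein complex structures: contact interfaces and solvent accessibility.

The supercomplex analysis starts from a multi-chain model (e.g. the cryo-EM
structure of the human (NFS1/ACP-ISD11/ISCU/FXN)2 assembly).  Two primitives
drive everything downstream:

- *interface extraction*: a residue belongs to the interface with a partner
  chain (or a named ligand such as the PLP cofactor) when any of its heavy
  atoms lies strictly closer than a distance cutoff (4.0 A by default) to a
  heavy atom of the partner;
- *solvent accessibility*: per-atom Shrake-Rupley sphere sampling, with the
  occluding context selectable per chain subset so that the accessibility of
  a residue can be compared between the isolated chain and the full complex
  (e.g. the frataxin tryptophan that buries on docking).

Parsing of PDB/mmCIF files is delegated to :mod:`gemmi`; this module owns the
light-weight atom container, the altloc/water policy, and the geometry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Structure",
    "ResidueId",
    "InterfaceSet",
    "SasaResult",
    "VDW_RADII",
    "MAX_SASA_TABLES",
    "parse_structure",
    "contact_residues",
    "shrake_rupley_sasa",
    "relative_sasa",
    "delta_sasa_on_binding",
]

# Van der Waals radii (A), Bondi set with the common protein extensions.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "D": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "FE": 2.00,
    "ZN": 1.39,
    "MG": 1.73,
    "MN": 2.00,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31,
}

# Theoretical maximum per-residue SASA (A^2) in an extended Gly-X-Gly context
# (Tien et al. 2013, theoretical column). Used for relative accessibility.
MAX_SASA_TABLES: dict[str, dict[str, float]] = {
    "tien2013_theoretical": {
        "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0,
        "CYS": 167.0, "GLN": 225.0, "GLU": 223.0, "GLY": 104.0,
        "HIS": 224.0, "ILE": 197.0, "LEU": 201.0, "LYS": 236.0,
        "MET": 224.0, "PHE": 240.0, "PRO": 159.0, "SER": 155.0,
        "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
    },
}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


@dataclass(frozen=True)
class Atom:
    """One atom with author chain/residue identity and coordinates (A)."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    occupancy: float
    coordinates: tuple[float, float, float]
    hetero: bool = False

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coordinates):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")


@dataclass(frozen=True, order=True)
class ResidueId:
    """Identity of one residue within a structure (author numbering)."""

    chain_id: str
    residue_number: int
    insertion_code: str = ""
    residue_name: str = ""

    def __str__(self) -> str:  # e.g. "A/TRP155"
        return f"{self.chain_id}/{self.residue_name}{self.residue_number}{self.insertion_code}"


@dataclass
class Structure:
    """A parsed structure: flat atom list plus chain bookkeeping."""

    atoms: list[Atom]
    source: str = ""
    format: str = ""

    @property
    def chains(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    def residue_ids(self, chain_id: str | None = None) -> list[ResidueId]:
        seen: dict[tuple, ResidueId] = {}
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            key = (a.chain_id, a.residue_number, a.insertion_code)
            if key not in seen:
                seen[key] = ResidueId(a.chain_id, a.residue_number,
                                      a.insertion_code, a.residue_name)
        return sorted(seen.values())

    def select(self, chain_ids: Iterable[str] | None = None,
               resname: str | None = None,
               heavy_only: bool = False) -> list[Atom]:
        chains = set(chain_ids) if chain_ids is not None else None
        out = []
        for a in self.atoms:
            if chains is not None and a.chain_id not in chains:
                continue
            if resname is not None and a.residue_name != resname:
                continue
            if heavy_only and not a.is_heavy:
                continue
            out.append(a)
        return out

    def coords(self, atoms: Sequence[Atom]) -> np.ndarray:
        return np.array([a.coordinates for a in atoms], dtype=float).reshape(-1, 3)


@dataclass
class InterfaceSet:
    """Residues of two partners in contact below a distance cutoff."""

    chain_a: str
    partner: str
    cutoff: float
    residues_a: list[ResidueId]
    residues_partner: list[ResidueId]
    min_distances_a: dict[ResidueId, float] = field(default_factory=dict)
    partner_map: dict[ResidueId, list[ResidueId]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.residues_a:
            rows.append({
                "chain": r.chain_id, "resnum": r.residue_number,
                "icode": r.insertion_code, "resname": r.residue_name,
                "min_distance_A": self.min_distances_a.get(r, float("nan")),
                "partner_residues": ";".join(str(q) for q in self.partner_map.get(r, [])),
            })
        return pd.DataFrame(rows, columns=["chain", "resnum", "icode", "resname",
                                           "min_distance_A", "partner_residues"])


@dataclass
class SasaResult:
    """Per-atom and per-residue solvent-accessible surface areas (A^2)."""

    per_atom_sasa: dict[int, float]          # index into structure.atoms subset order
    per_residue_sasa: dict[ResidueId, float]
    probe_radius: float
    n_sphere_points: int


def _infer_element(atom_name: str, residue_name: str) -> str:
    name = atom_name.strip()
    # Two-letter elements in common hetero groups (FE, ZN, MG, ...)
    if name[:2].upper() in VDW_RADII and not name[0].isdigit() and len(name) >= 2 \
            and name[:2].upper() in {"FE", "ZN", "MG", "MN", "NA", "CL", "BR", "SE", "CA"} \
            and residue_name not in _STANDARD_AA:
        return name[:2].upper()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise StructureParseError(f"cannot infer element from atom name {atom_name!r}")


_STANDARD_AA = set(MAX_SASA_TABLES["tien2013_theoretical"])


def parse_structure(source: str | Path, format: str | None = None,
                    keep_waters: bool = False) -> Structure:
    """Parse a PDB or mmCIF file into a :class:`Structure`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by the alphabetically first altloc id); waters are dropped
    unless ``keep_waters``; other hetero residues (cofactors, metals) are
    retained and flagged. Only the first model of multi-model files is used.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path} as {format}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models found")

    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for res in chain:
            if res.name in _WATER_NAMES and not keep_waters:
                continue
            hetero = res.het_flag == "H"
            # altloc resolution: group by atom name
            by_name: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                by_name.setdefault(at.name, []).append(at)
            for name, group in by_name.items():
                best = min(group, key=lambda a: (-a.occ, a.altloc or ""))
                el = best.element.name.upper() if best.element.name else ""
                if el in ("", "X"):
                    el = _infer_element(name, res.name)
                    warnings.warn(
                        f"element missing for {chain.name}/{res.name}{res.seqid.num}"
                        f"/{name}; inferred {el}", stacklevel=2)
                atoms.append(Atom(
                    chain_id=chain.name,
                    residue_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    residue_name=res.name,
                    atom_name=name,
                    element=el,
                    occupancy=float(np.clip(best.occ, 0.0, 1.0)),
                    coordinates=(best.pos.x, best.pos.y, best.pos.z),
                    hetero=hetero,
                ))
    if not atoms:
        raise StructureParseError(f"{path}: no atoms after filtering")
    return Structure(atoms=atoms, source=str(path), format=format)


def _partner_atoms(s: Structure, partner: str, heavy_only: bool) -> list[Atom]:
    """Resolve a partner spec: a chain id, or a ligand selector "CHAIN:RESNAME"
    / ":RESNAME" (the latter matches the residue name anywhere)."""
    if ":" in partner:
        chain_part, resname = partner.split(":", 1)
        chains = [chain_part] if chain_part else None
        sel = s.select(chain_ids=chains, resname=resname, heavy_only=heavy_only)
        if not sel:
            raise ValueError(f"ligand selector {partner!r} matched no atoms")
        return sel
    if partner not in s.chains:
        raise ValueError(f"chain {partner!r} not in structure (has {sorted(s.chains)})")
    return s.select(chain_ids=[partner], heavy_only=heavy_only)


def contact_residues(s: Structure, chain_a: str, partner: str,
                     cutoff: float = 4.0, heavy_only: bool = True) -> InterfaceSet:
    """Residues of ``chain_a`` and ``partner`` with any atom pair strictly
    closer than ``cutoff`` (A). ``partner`` is a chain id or ligand selector
    (``"C:PLP"``). Hetero atoms of chain_a itself are excluded from the query
    side unless chain_a is given as a selector."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if ":" in chain_a:
        atoms_a = _partner_atoms(s, chain_a, heavy_only)
    else:
        if chain_a not in s.chains:
            raise ValueError(f"chain {chain_a!r} not in structure")
        atoms_a = [a for a in s.select(chain_ids=[chain_a], heavy_only=heavy_only)
                   if not a.hetero]
    atoms_b = _partner_atoms(s, partner, heavy_only)
    if not atoms_a:
        raise ValueError(f"chain {chain_a!r} has no qualifying atoms")
    if not atoms_b:
        raise ValueError(f"partner {partner!r} has no qualifying atoms")

    xa, xb = s.coords(atoms_a), s.coords(atoms_b)
    tree_b = cKDTree(xb)
    pairs = cKDTree(xa).query_ball_tree(tree_b, r=cutoff)

    def rid(a: Atom) -> ResidueId:
        return ResidueId(a.chain_id, a.residue_number, a.insertion_code, a.residue_name)

    res_a: dict[ResidueId, float] = {}
    res_b: dict[ResidueId, float] = {}
    pmap: dict[ResidueId, set[ResidueId]] = {}
    for i, hits in enumerate(pairs):
        for j in hits:
            d = float(np.linalg.norm(xa[i] - xb[j]))
            if d >= cutoff:  # query_ball_tree is inclusive; enforce strict <
                continue
            ra, rb = rid(atoms_a[i]), rid(atoms_b[j])
            res_a[ra] = min(res_a.get(ra, np.inf), d)
            res_b[rb] = min(res_b.get(rb, np.inf), d)
            pmap.setdefault(ra, set()).add(rb)
    return InterfaceSet(
        chain_a=chain_a, partner=partner, cutoff=cutoff,
        residues_a=sorted(res_a), residues_partner=sorted(res_b),
        min_distances_a=res_a,
        partner_map={k: sorted(v) for k, v in pmap.items()},
    )


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def shrake_rupley_sasa(s: Structure, probe_radius: float = 1.4,
                       n_points: int = 960,
                       chain_subset: Iterable[str] | None = None,
                       radii: Mapping[str, float] | None = None) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area.

    Each heavy atom is covered with ``n_points`` quasi-uniform sphere points
    at radius ``r_vdw + probe_radius``; the accessible fraction is the share
    of points outside every neighbouring atom's probe-expanded sphere.
    ``chain_subset`` restricts both the atoms evaluated and the occluding
    context, which is how isolated-chain vs in-complex accessibility is
    computed.  Hydrogens are ignored; residues left without heavy atoms are
    dropped with a warning.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for usable quadrature")
    radii = dict(radii) if radii is not None else VDW_RADII
    atoms = s.select(chain_ids=chain_subset, heavy_only=True)
    if not atoms:
        raise ValueError("no heavy atoms in selection")
    missing = sorted({a.element for a in atoms if a.element not in radii})
    if missing:
        offending = [str(ResidueId(a.chain_id, a.residue_number, a.insertion_code,
                                   a.residue_name)) + ":" + a.atom_name
                     for a in atoms if a.element in missing]
        raise ValueError(f"no van der Waals radius for element(s) {missing}; "
                         f"atoms: {offending[:10]}")

    xyz = s.coords(atoms)
    rad = np.array([radii[a.element] + probe_radius for a in atoms])
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(xyz)
    max_r = rad.max()

    per_atom: dict[int, float] = {}
    per_res: dict[ResidueId, float] = {}
    for i, a in enumerate(atoms):
        pts = xyz[i] + rad[i] * sphere
        neigh = [j for j in tree.query_ball_point(xyz[i], rad[i] + max_r)
                 if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            # boundary points count as buried; exactly coincident atoms are
            # degenerate, so the lower-index copy keeps the shared surface
            if j > i and np.sum((xyz[j] - xyz[i]) ** 2) < 1e-16:
                continue
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            accessible &= d2 > rad[j] ** 2 + 1e-9
        area = 4.0 * np.pi * rad[i] ** 2 * accessible.mean()
        per_atom[i] = area
        r = ResidueId(a.chain_id, a.residue_number, a.insertion_code, a.residue_name)
        per_res[r] = per_res.get(r, 0.0) + area
    return SasaResult(per_atom_sasa=per_atom, per_residue_sasa=per_res,
                      probe_radius=probe_radius, n_sphere_points=n_points)


def relative_sasa(sasa: SasaResult, residue: ResidueId,
                  reference_table: str = "tien2013_theoretical") -> float:
    """Per-residue SASA as percent of the residue-type theoretical maximum."""
    table = MAX_SASA_TABLES[reference_table]
    if residue.residue_name not in table:
        raise ValueError(f"no reference maximum SASA for residue {residue.residue_name!r}")
    matches = [r for r in sasa.per_residue_sasa
               if (r.chain_id, r.residue_number, r.insertion_code) ==
                  (residue.chain_id, residue.residue_number, residue.insertion_code)]
    if not matches:
        raise KeyError(f"residue {residue} not in SASA result")
    return 100.0 * sasa.per_residue_sasa[matches[0]] / table[residue.residue_name]


def delta_sasa_on_binding(s: Structure, chain: str, partner_chains: Iterable[str],
                          probe_radius: float = 1.4, n_points: int = 960,
                          reference_table: str = "tien2013_theoretical") -> pd.DataFrame:
    """Per-residue SASA of ``chain`` isolated vs in complex with partners.

    Returns a DataFrame with columns sasa_free, sasa_complex (A^2) and the
    relative accessibilities (%) where a reference maximum exists.
    """
    partners = sorted(set(partner_chains))
    if not partners:
        raise ValueError("partner_chains must not be empty")
    for c in [chain, *partners]:
        if c not in s.chains:
            raise ValueError(f"chain {c!r} not in structure")
    free = shrake_rupley_sasa(s, probe_radius, n_points, chain_subset=[chain])
    complexed = shrake_rupley_sasa(s, probe_radius, n_points,
                                   chain_subset=[chain, *partners])
    table = MAX_SASA_TABLES[reference_table]
    rows = []
    for r, a_free in sorted(free.per_residue_sasa.items()):
        a_cplx = complexed.per_residue_sasa.get(r, 0.0)
        ref = table.get(r.residue_name)
        rows.append({
            "chain": r.chain_id, "resnum": r.residue_number,
            "icode": r.insertion_code, "resname": r.residue_name,
            "sasa_free": a_free, "sasa_complex": a_cplx,
            "relative_free_pct": 100.0 * a_free / ref if ref else float("nan"),
            "relative_complex_pct": 100.0 * a_cplx / ref if ref else float("nan"),
        })
    return pd.DataFrame(rows)
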