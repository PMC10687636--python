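"""Geometric typing of inter-chain contacts in a protein complex.

Four interaction types are detected between two chains of a PDB model, each
with a configurable distance cutoff:

* ``hbond`` — donor heavy atom (N/O/S bearing an explicit or implied H) to
  acceptor (N/O); X-ray files usually lack hydrogens, so the donor-angle
  criterion is applied only when hydrogens are present.
* ``attractive_charge`` — side-chain nitrogen of Arg/Lys (His optionally) to
  a carboxylate oxygen (Asp/Glu side chain, or O/OXT of a C-terminal residue).
* ``pi_pi_t_shaped`` — aromatic ring centroids with near-perpendicular planes.
* ``pi_alkyl`` — aromatic ring centroid to an aliphatic side-chain carbon.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

AA3 = frozenset([
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
])

# hydrogen-bond donor heavy atoms (implied hydrogens)
DONOR_SIDECHAIN = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "TRP": {"NE1"},
}
# hydrogen-bond acceptors (N/O only)
ACCEPTOR_SIDECHAIN = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}

POSITIVE_NITROGENS = {"ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}}
HIS_NITROGENS = {"ND1", "NE2"}
CARBOXYLATE_OXYGENS = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}

RING_ATOMS = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "TRP": [["CG", "CD1", "NE1", "CE2", "CD2"],
            ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]],
}

ALKYL_CARBONS = {
    "ALA": {"CB"}, "VAL": {"CB", "CG1", "CG2"}, "LEU": {"CB", "CG", "CD1", "CD2"},
    "ILE": {"CB", "CG1", "CG2", "CD1"}, "MET": {"CB", "CG", "CE"},
    "PRO": {"CB", "CG", "CD"}, "CYS": {"CB"},
}

TYPE_ORDER = ("hbond", "attractive_charge", "pi_pi_t_shaped", "pi_alkyl")


class Atom(NamedTuple):
    chain: str
    resname: str
    resnum: int
    name: str
    element: str
    coord: tuple[float, float, float]

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord)

    @property
    def selector(self) -> str:
        return f"{self.chain}:{self.resname}{self.resnum}:{self.name}"


@dataclass(frozen=True)
class StructureModel:
    """Flat atom list of one model, with chain/residue lookup indexes."""

    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for atom in self.atoms:
            key = (atom.chain, atom.resnum, atom.name)
            if key in seen:
                raise ValueError(f"duplicate atom {atom.selector}")
            seen.add(key)
            if not all(math.isfinite(c) for c in atom.coord):
                raise ValueError(f"non-finite coordinates for {atom.selector}")

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for atom in self.atoms:
            if atom.chain not in out:
                out.append(atom.chain)
        return out

    def chain_atoms(self, chain: str) -> list[Atom]:
        return [a for a in self.atoms if a.chain == chain]

    def residues(self, chain: str) -> dict[tuple[int, str], dict[str, Atom]]:
        """Residues of a chain keyed by (resnum, resname) -> atom-name map."""
        out: dict[tuple[int, str], dict[str, Atom]] = {}
        for atom in self.chain_atoms(chain):
            out.setdefault((atom.resnum, atom.resname), {})[atom.name] = atom
        return out

    def resolve(self, selector: str) -> Atom:
        """Resolve ``CHAIN:RESNAME+NUMBER:ATOM`` to exactly one atom."""
        parts = selector.split(":")
        if len(parts) != 3:
            raise ValueError(f"selector {selector!r} is not CHAIN:RES##:ATOM")
        chain, res, name = parts
        resname = res.rstrip("0123456789")
        if resname == res or not res[len(resname):].lstrip("-").isdigit():
            raise ValueError(f"selector {selector!r}: cannot parse residue {res!r}")
        resnum = int(res[len(resname):])
        hits = [a for a in self.atoms
                if a.chain == chain and a.resname == resname
                and a.resnum == resnum and a.name == name]
        if len(hits) != 1:
            raise ValueError(f"selector {selector!r} resolved to {len(hits)} atoms")
        return hits[0]


@dataclass(frozen=True)
class GeometryParams:
    """Distance cutoffs (Å) and angle windows for each interaction type."""

    hbond_max_dist: float = 3.5
    hbond_min_donor_angle: float = 120.0
    attractive_max_dist: float = 5.6
    pipi_max_dist: float = 6.0
    pipi_angle_window: tuple[float, float] = (60.0, 90.0)
    pialkyl_max_dist: float = 5.5
    his_positive: bool = False

    def __post_init__(self) -> None:
        for value in (self.hbond_max_dist, self.attractive_max_dist,
                      self.pipi_max_dist, self.pialkyl_max_dist):
            if value <= 0:
                raise ValueError("distance cutoffs must be > 0")
        lo, hi = self.pipi_angle_window
        if not (0 <= lo <= hi <= 90):
            raise ValueError("angle window must lie within [0, 90]")

    def cutoff(self, itype: str) -> float:
        return {
            "hbond": self.hbond_max_dist,
            "attractive_charge": self.attractive_max_dist,
            "pi_pi_t_shaped": self.pipi_max_dist,
            "pi_alkyl": self.pialkyl_max_dist,
        }[itype]


@dataclass(frozen=True)
class InteractionRecord:
    """One typed inter-chain contact with a 2-decimal distance in Å."""

    type: str
    from_sel: str
    to_sel: str
    distance: float
    roles: tuple[str, str]


def parse_structure(path: str | Path) -> StructureModel:
    """Load ATOM/HETATM records of the first model of a PDB file.

    Alternate locations are resolved by highest occupancy, ties toward
    altloc 'A'. Waters are skipped. Malformed coordinate fields raise with
    the offending line number; a file without ATOM records is an error.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    with open(path) as handle:
        lines = handle.readlines()
    n_atom_lines = 0
    for lineno, line in enumerate(lines, start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            n_atom_lines += 1
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise ValueError(
                        f"{path}: malformed coordinate field on line {lineno}: "
                        f"{line[lo:hi].strip()!r}")
    if n_atom_lines == 0:
        raise ValueError(f"{path}: no ATOM records")

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(path.stem, str(path))
    model = next(structure.get_models())  # first model only

    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            hetflag, resnum, _icode = residue.id
            resname = residue.get_resname().strip()
            if resname == "HOH":
                continue
            chosen: dict[str, object] = {}
            for atom in residue.get_unpacked_list():
                name = atom.get_name()
                prev = chosen.get(name)
                if prev is None:
                    chosen[name] = atom
                    continue
                key = (atom.get_occupancy() or 0.0,
                       -ord((atom.get_altloc() or "A")[0]))
                prev_key = (prev.get_occupancy() or 0.0,
                            -ord((prev.get_altloc() or "A")[0]))
                if key > prev_key:
                    chosen[name] = atom
            for name, atom in chosen.items():
                x, y, z = (float(v) for v in atom.get_coord())
                atoms.append(Atom(
                    chain=chain.id, resname=resname, resnum=int(resnum),
                    name=name, element=(atom.element or "").strip().upper(),
                    coord=(x, y, z),
                ))
    return StructureModel(atoms=tuple(atoms))


def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b))


def atom_distance(model: StructureModel, sel1: str, sel2: str) -> float:
    """Euclidean distance in Å between two single-atom selectors, 2 decimals."""
    a = model.resolve(sel1)
    b = model.resolve(sel2)
    return round(_dist(a.xyz, b.xyz), 2)


class _Ring(NamedTuple):
    chain: str
    resname: str
    resnum: int
    centroid: np.ndarray
    normal: np.ndarray

    @property
    def selector(self) -> str:
        return f"{self.chain}:{self.resname}{self.resnum}"


def _rings(model: StructureModel, chain: str) -> list[_Ring]:
    rings: list[_Ring] = []
    for (resnum, resname), atom_map in model.residues(chain).items():
        for names in RING_ATOMS.get(resname, []):
            if not all(n in atom_map for n in names):
                continue
            coords = np.array([atom_map[n].xyz for n in names])
            centroid = coords.mean(axis=0)
            centered = coords - centroid
            # plane normal = singular vector of least variance
            _, _, vt = np.linalg.svd(centered)
            rings.append(_Ring(chain, resname, resnum, centroid, vt[2]))
    return rings


def _interplane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    cosang = abs(float(np.dot(n1, n2)) /
                 (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return math.degrees(math.acos(min(1.0, cosang)))


def _donors(model: StructureModel, chain: str) -> list[Atom]:
    out = []
    for (resnum, resname), atom_map in model.residues(chain).items():
        if resname not in AA3:
            continue
        names = set(DONOR_SIDECHAIN.get(resname, set()))
        if resname != "PRO":
            names.add("N")
        out.extend(atom_map[n] for n in names if n in atom_map)
    return out


def _acceptors(model: StructureModel, chain: str) -> list[Atom]:
    out = []
    for (resnum, resname), atom_map in model.residues(chain).items():
        if resname not in AA3:
            continue
        names = set(ACCEPTOR_SIDECHAIN.get(resname, set())) | {"O", "OXT"}
        out.extend(atom_map[n] for n in names if n in atom_map)
    return out


def _hydrogens_on(model: StructureModel, donor: Atom) -> list[Atom]:
    out = []
    for atom in model.chain_atoms(donor.chain):
        if atom.resnum != donor.resnum or atom.element != "H":
            continue
        if _dist(atom.xyz, donor.xyz) <= 1.3:
            out.append(atom)
    return out


def _positive_nitrogens(model: StructureModel, chain: str,
                        params: GeometryParams) -> list[Atom]:
    out = []
    for (resnum, resname), atom_map in model.residues(chain).items():
        names = set(POSITIVE_NITROGENS.get(resname, set()))
        if params.his_positive and resname == "HIS":
            names |= HIS_NITROGENS
        out.extend(atom_map[n] for n in names if n in atom_map)
    return out


def _carboxylate_oxygens(model: StructureModel, chain: str) -> list[Atom]:
    out = []
    for (resnum, resname), atom_map in model.residues(chain).items():
        if resname not in AA3:
            continue
        names = set(CARBOXYLATE_OXYGENS.get(resname, set()))
        if "OXT" in atom_map:  # C-terminal carboxylate
            names |= {"O", "OXT"}
        out.extend(atom_map[n] for n in names if n in atom_map)
    return out


def detect_interactions(model: StructureModel, chain_a: str, chain_b: str,
                        params: GeometryParams = GeometryParams()) -> list[InteractionRecord]:
    """Typed contacts between two chains, sorted by type then distance.

    Duplicate records (same atom/group pair and type) are suppressed; for
    ring-residue contacts the nearest qualifying ring/carbon is reported.
    """
    for chain in (chain_a, chain_b):
        if chain not in model.chains:
            raise ValueError(f"chain {chain!r} not present in model")

    records: list[InteractionRecord] = []
    seen: set[tuple[str, frozenset[str]]] = set()

    def add(itype: str, from_sel: str, to_sel: str, distance: float,
            roles: tuple[str, str]) -> None:
        key = (itype, frozenset((from_sel, to_sel)))
        if key in seen:
            return
        seen.add(key)
        records.append(InteractionRecord(
            type=itype, from_sel=from_sel, to_sel=to_sel,
            distance=round(distance, 2), roles=roles,
        ))

    has_hydrogens = any(a.element == "H" for a in model.atoms)

    # hydrogen bonds, both donor directions
    for donor_chain, acceptor_chain in ((chain_a, chain_b), (chain_b, chain_a)):
        for donor in _donors(model, donor_chain):
            for acceptor in _acceptors(model, acceptor_chain):
                dist = _dist(donor.xyz, acceptor.xyz)
                if dist > params.hbond_max_dist:
                    continue
                if has_hydrogens:
                    hydrogens = _hydrogens_on(model, donor)
                    if hydrogens:
                        def angle(h: Atom) -> float:
                            v1 = donor.xyz - h.xyz
                            v2 = acceptor.xyz - h.xyz
                            cosang = float(np.dot(v1, v2) /
                                           (np.linalg.norm(v1) * np.linalg.norm(v2)))
                            return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                        if max(angle(h) for h in hydrogens) < params.hbond_min_donor_angle:
                            continue
                add("hbond", donor.selector, acceptor.selector, dist,
                    ("donor", "acceptor"))

    # attractive charges, both charge directions
    for pos_chain, neg_chain in ((chain_a, chain_b), (chain_b, chain_a)):
        for nitrogen in _positive_nitrogens(model, pos_chain, params):
            for oxygen in _carboxylate_oxygens(model, neg_chain):
                dist = _dist(nitrogen.xyz, oxygen.xyz)
                if dist <= params.attractive_max_dist:
                    add("attractive_charge", nitrogen.selector, oxygen.selector,
                        dist, ("positive", "negative"))

    # pi-pi T-shaped: nearest ring pair per residue pair
    rings_a = _rings(model, chain_a)
    rings_b = _rings(model, chain_b)
    best_pipi: dict[tuple[str, str], tuple[float, _Ring, _Ring]] = {}
    for ra in rings_a:
        for rb in rings_b:
            dist = _dist(ra.centroid, rb.centroid)
            if dist > params.pipi_max_dist:
                continue
            lo, hi = params.pipi_angle_window
            if not lo <= _interplane_angle(ra.normal, rb.normal) <= hi:
                continue
            key = (ra.selector, rb.selector)
            if key not in best_pipi or dist < best_pipi[key][0]:
                best_pipi[key] = (dist, ra, rb)
    for dist, ra, rb in best_pipi.values():
        add("pi_pi_t_shaped", ra.selector, rb.selector, dist, ("pi", "pi"))

    # pi-alkyl: nearest qualifying carbon per (ring, residue) pair
    for ring_chain_rings, alkyl_chain in ((rings_a, chain_b), (rings_b, chain_a)):
        alkyl_atoms = [
            atom for (resnum, resname), atom_map in model.residues(alkyl_chain).items()
            for name, atom in atom_map.items()
            if name in ALKYL_CARBONS.get(resname, set())
        ]
        for ring in ring_chain_rings:
            best: dict[tuple[str, int], tuple[float, Atom]] = {}
            for atom in alkyl_atoms:
                dist = _dist(ring.centroid, atom.xyz)
                if dist > params.pialkyl_max_dist:
                    continue
                key = (atom.resname, atom.resnum)
                if key not in best or dist < best[key][0]:
                    best[key] = (dist, atom)
            for dist, atom in best.values():
                add("pi_alkyl", ring.selector, atom.selector, dist, ("pi", "alkyl"))

    records.sort(key=lambda r: (TYPE_ORDER.index(r.type), r.distance,
                                r.from_sel, r.to_sel))
    return records


def interaction_table(records: Iterable[InteractionRecord]) -> pd.DataFrame:
    """Tabular layout: Interaction, Distance_A, Type, From_role, To_role."""
    rows = [
        {
            "Interaction": f"{r.from_sel} - {r.to_sel}",
            "Distance_A": f"{r.distance:.2f}",
            "Type": r.type,
            "From_role": r.roles[0],
            "To_role": r.roles[1],
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["Interaction", "Distance_A", "Type",
                                       "From_role", "To_role"])


def write_interactions_tsv(records: Iterable[InteractionRecord],
                           path: str | Path) -> None:
    interaction_table(records).to_csv(path, sep="\t", index=False)
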