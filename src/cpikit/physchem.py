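"""Per-peptide physicochemical panel computed from first principles.

Molecular weight uses average (not monoisotopic) residue masses plus one
water. The isoelectric point is the root of the Henderson-Hasselbalch net
charge over pH in [0, 14], found by bisection with the Bjellqvist-style pKa
set used by common web calculators (per-residue N-terminal overrides). The
formal charge is the pH-7 integer convention (K+R) - (D+E). The hydrophobic
ratio and Boman (protein-binding potential) index follow the conventions of
antimicrobial-peptide databases; all constant tables are configurable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from cpikit.records import PeptideRecord, STANDARD_AA_SET

# ExPASy average residue masses (Da)
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

# Bjellqvist pKa values (as used by ProtParam-style calculators)
SIDECHAIN_PKA_NEG: dict[str, float] = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
SIDECHAIN_PKA_POS: dict[str, float] = {"H": 5.98, "K": 10.0, "R": 12.0}
CTERM_PKA = 3.55
NTERM_PKA_DEFAULT = 7.5
NTERM_PKA_OVERRIDES: dict[str, float] = {
    "A": 7.59, "M": 7.00, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.70,
}

# Boman (2003) per-residue protein-binding-potential values, kcal/mol;
# higher = more protein-binding. Proline has no published value (0 by convention).
BOMAN_SCALE: dict[str, float] = {
    "L": -4.92, "I": -4.92, "V": -4.04, "F": -2.98, "M": -2.35, "W": -2.33,
    "A": -1.81, "C": -1.28, "G": -0.94, "Y": 0.14, "T": 2.57, "S": 3.40,
    "H": 4.66, "Q": 5.54, "K": 5.55, "N": 6.64, "E": 12.63, "D": 13.34,
    "R": 26.66, "P": 0.0,
}

HYDROPHOBIC_SET = frozenset("ACFILMVW")


@dataclass(frozen=True)
class PhyschemConstants:
    """Constant tables behind the panel; every field is overridable."""

    residue_masses: Mapping[str, float] = field(default_factory=lambda: dict(AVERAGE_RESIDUE_MASS))
    water_mass: float = WATER_MASS
    cterm_pka: float = CTERM_PKA
    nterm_pka_default: float = NTERM_PKA_DEFAULT
    nterm_pka_overrides: Mapping[str, float] = field(default_factory=lambda: dict(NTERM_PKA_OVERRIDES))
    sidechain_pka_neg: Mapping[str, float] = field(default_factory=lambda: dict(SIDECHAIN_PKA_NEG))
    sidechain_pka_pos: Mapping[str, float] = field(default_factory=lambda: dict(SIDECHAIN_PKA_POS))
    hydrophobic_set: frozenset[str] = HYDROPHOBIC_SET
    boman_scale: Mapping[str, float] = field(default_factory=lambda: dict(BOMAN_SCALE))

    def __post_init__(self) -> None:
        for name, table in (("residue_masses", self.residue_masses),
                            ("boman_scale", self.boman_scale)):
            missing = STANDARD_AA_SET - set(table)
            if missing:
                raise ValueError(f"{name} missing residues: {sorted(missing)}")


DEFAULT_CONSTANTS = PhyschemConstants()


@dataclass(frozen=True)
class PhyschemPanel:
    """MW, pI, formal charge, hydrophobic ratio and Boman index for one peptide."""

    id: str
    species: str
    mw: float
    pi: float
    charge: int
    hydrophobic_ratio: float
    boman: float


def _check_sequence(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - STANDARD_AA_SET
    if bad:
        raise ValueError(f"unknown residues in sequence: {sorted(bad)}")


def molecular_weight(seq: str, constants: PhyschemConstants = DEFAULT_CONSTANTS) -> float:
    """Sum of average residue masses plus one water, in Da (unrounded)."""
    _check_sequence(seq)
    return sum(constants.residue_masses[aa] for aa in seq) + constants.water_mass


def net_charge_continuous(seq: str, ph: float,
                          constants: PhyschemConstants = DEFAULT_CONSTANTS) -> float:
    """Henderson-Hasselbalch net charge of the peptide at a given pH.

    Strictly decreasing in pH: positive terms are the N-terminus, H, K, R;
    negative terms the C-terminus, D, E, C, Y.
    """
    _check_sequence(seq)

    def positive(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pka))

    def negative(pka: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pka - ph))

    nterm_pka = constants.nterm_pka_overrides.get(seq[0], constants.nterm_pka_default)
    charge = positive(nterm_pka) + negative(constants.cterm_pka)
    for aa in seq:
        if aa in constants.sidechain_pka_pos:
            charge += positive(constants.sidechain_pka_pos[aa])
        elif aa in constants.sidechain_pka_neg:
            charge += negative(constants.sidechain_pka_neg[aa])
    return charge


def isoelectric_point(seq: str, constants: PhyschemConstants = DEFAULT_CONSTANTS,
                      tol: float = 0.001) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14]."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge_continuous(seq, mid, constants) > 0.0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def net_charge(seq: str) -> int:
    """Formal pH-7 charge: (#K + #R) - (#D + #E); His and termini excluded."""
    _check_sequence(seq)
    return (seq.count("K") + seq.count("R")) - (seq.count("D") + seq.count("E"))


def hydrophobic_ratio(seq: str, constants: PhyschemConstants = DEFAULT_CONSTANTS) -> int:
    """Percentage of residues in the hydrophobic set, nearest integer."""
    _check_sequence(seq)
    count = sum(1 for aa in seq if aa in constants.hydrophobic_set)
    return round(100.0 * count / len(seq))


def boman_index(seq: str, constants: PhyschemConstants = DEFAULT_CONSTANTS) -> float:
    """Arithmetic mean of per-residue Boman values, kcal/mol (unrounded)."""
    _check_sequence(seq)
    return sum(constants.boman_scale[aa] for aa in seq) / len(seq)


def physchem_table(records: Iterable[PeptideRecord],
                   constants: PhyschemConstants = DEFAULT_CONSTANTS) -> list[PhyschemPanel]:
    """One panel row per record, stable input order, printed-table rounding."""
    panels: list[PhyschemPanel] = []
    for record in records:
        try:
            panels.append(PhyschemPanel(
                id=record.id,
                species=record.species,
                mw=round(molecular_weight(record.residues, constants), 2),
                pi=round(isoelectric_point(record.residues, constants), 2),
                charge=net_charge(record.residues),
                hydrophobic_ratio=hydrophobic_ratio(record.residues, constants),
                boman=round(boman_index(record.residues, constants), 2),
            ))
        except ValueError as exc:
            raise ValueError(f"record {record.id!r}: {exc}") from exc
    return panels


def write_panel_tsv(panels: Iterable[PhyschemPanel], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "species", "pI", "MW_Da",
                        "charge", "hydrophobic_pct", "boman_kcal_mol"])
        for p in panels:
            writer.writerow([p.id, p.species, f"{p.pi:.2f}", f"{p.mw:.2f}",
                             p.charge, p.hydrophobic_ratio, f"{p.boman:.2f}"])
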