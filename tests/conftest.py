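from __future__ import annotations

import numpy as np
import pytest


def pdb_atom_line(serial: int, name: str, resname: str, chain: str, resseq: int,
                  x: float, y: float, z: float, element: str,
                  altloc: str = " ", occupancy: float = 1.0,
                  record: str = "ATOM") -> str:
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (f"{record:<6s}{serial:5d} {name_field}{altloc}{resname:>3s} "
            f"{chain}{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{occupancy:6.2f}{0.0:6.2f}          {element:>2s}")


def build_pdb(atoms: list[tuple], path) -> str:
    """atoms: (name, resname, chain, resseq, x, y, z, element) tuples."""
    lines = [
        pdb_atom_line(i + 1, *atom)
        for i, atom in enumerate(atoms)
    ]
    text = "\n".join(lines) + "\nEND\n"
    path.write_text(text)
    return str(path)


def hexagon_ring(center: np.ndarray, normal: str = "z",
                 radius: float = 1.39) -> list[np.ndarray]:
    """Six points of an idealized aromatic ring lying in the plane ⟂ normal."""
    pts = []
    for k in range(6):
        angle = np.pi * k / 3
        if normal == "z":
            offset = np.array([np.cos(angle), np.sin(angle), 0.0])
        elif normal == "y":
            offset = np.array([np.cos(angle), 0.0, np.sin(angle)])
        else:
            offset = np.array([0.0, np.cos(angle), np.sin(angle)])
        pts.append(center + radius * offset)
    return pts


PHE_RING_NAMES = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]


def phe_ring_atoms(chain: str, resseq: int, center, normal: str = "z") -> list[tuple]:
    pts = hexagon_ring(np.asarray(center, dtype=float), normal)
    return [
        (name, "PHE", chain, resseq, *pt, "C")
        for name, pt in zip(PHE_RING_NAMES, pts)
    ]


@pytest.fixture
def fasta_writer(tmp_path):
    def write(entries: list[tuple[str, str]], name: str = "seqs.fasta") -> str:
        path = tmp_path / name
        path.write_text("".join(f">{h}\n{s}\n" for h, s in entries))
        return str(path)
    return write


@pytest.fixture
def clean_family():
    from cpikit.synth import SyntheticConfig, generate_family
    return generate_family(SyntheticConfig(n_sequences=20, seed=11))
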