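"""Per-column frequencies, threshold consensus and motif derivation.

The consensus rule mirrors MView-style calls: at threshold *t* a column emits
the residue letter when a single residue's relative frequency reaches *t*,
otherwise the symbol of the first qualifying physicochemical class, otherwise
nothing. Gaps count in the denominator, so a heavily gapped column cannot
reach a threshold.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from Bio import SeqIO

from cpikit.motif import SpacingMotif
from cpikit.records import STANDARD_AA_SET

GAP = "-"
NONE_CALL = "."


@dataclass(frozen=True)
class Alignment:
    """A multiple alignment as (id, aligned residues) rows of equal length."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty alignment")
        ncol = len(self.records[0][1])
        for rid, row in self.records:
            if len(row) != ncol:
                raise ValueError(f"row {rid!r} has length {len(row)}, expected {ncol}")

    @property
    def ncol(self) -> int:
        return len(self.records[0][1])

    @property
    def nrow(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def column(self, j: int) -> list[str]:
        return [row[j] for _, row in self.records]

    def degapped(self, i: int) -> str:
        return self.records[i][1].replace(GAP, "")


@dataclass(frozen=True)
class ResidueClassScheme:
    """Ordered mapping of class symbol -> residue set.

    The default follows the five Taylor-style MView symbols: h (hydrophobic),
    o (alcohol), p (polar), s (small), t (turnlike). Exact memberships are a
    configuration concern, not a constant of the method.
    """

    classes: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        symbols = [sym for sym, _ in self.classes]
        if len(symbols) != len(set(symbols)):
            raise ValueError("duplicate class symbols")
        for sym, members in self.classes:
            if not members <= STANDARD_AA_SET:
                raise ValueError(f"class {sym!r} contains non-standard residues")

    def items(self) -> tuple[tuple[str, frozenset[str]], ...]:
        return self.classes


DEFAULT_SCHEME = ResidueClassScheme((
    ("h", frozenset("ACFILMVWY")),
    ("o", frozenset("ST")),
    ("p", frozenset("CDEHKNQRST")),
    ("s", frozenset("ACDGNPSTV")),
    ("t", frozenset("ACDEGHKNQRST")),
))

DEFAULT_THRESHOLDS = (100.0, 90.0, 80.0, 70.0)


@dataclass(frozen=True)
class ConsensusProfile:
    """Threshold consensus calls plus the per-column frequency matrix."""

    thresholds: tuple[float, ...]
    calls: Mapping[float, tuple[str, ...]]
    freqs: tuple[Mapping[str, float], ...]

    @property
    def ncol(self) -> int:
        return len(self.freqs)


def read_alignment_fasta(path: str | Path) -> Alignment:
    """Read an aligned FASTA file (rows of equal length, '-' gaps)."""
    rows = [
        (entry.description.split("|")[0].strip(), str(entry.seq).upper())
        for entry in SeqIO.parse(str(path), "fasta")
    ]
    if not rows:
        raise ValueError(f"no FASTA entries in {path}")
    return Alignment(tuple(rows))


def column_frequencies(aln: Alignment) -> list[dict[str, float]]:
    """Relative frequency of each residue and of the gap, per column.

    The denominator is the number of rows, so each column's frequencies sum
    to 1 over residues plus gap.
    """
    nrow = aln.nrow
    tables: list[dict[str, float]] = []
    for j in range(aln.ncol):
        counts = Counter(aln.column(j))
        tables.append({ch: n / nrow for ch, n in sorted(counts.items())})
    return tables


def _column_call(freqs: Mapping[str, float], threshold: float,
                 scheme: ResidueClassScheme) -> str:
    frac = threshold / 100.0
    best_residue = None
    for residue, f in freqs.items():
        if residue == GAP:
            continue
        if residue not in STANDARD_AA_SET:
            raise ValueError(f"unknown residue {residue!r} in alignment")
        if f >= frac and (best_residue is None or f > freqs[best_residue]):
            best_residue = residue
    if best_residue is not None:
        return best_residue
    # class call: scheme order, ties toward the smaller member set
    qualifying: list[tuple[int, int, str]] = []
    for order, (symbol, members) in enumerate(scheme.items()):
        total = sum(f for residue, f in freqs.items() if residue in members)
        if total >= frac:
            qualifying.append((len(members), order, symbol))
    if qualifying:
        _, _, symbol = min(qualifying, key=lambda q: (q[1], q[0]))
        return symbol
    return NONE_CALL


def consensus_at_threshold(aln: Alignment, threshold: float,
                           scheme: ResidueClassScheme = DEFAULT_SCHEME) -> list[str]:
    """One consensus row: per-column identity call, class symbol, or '.'."""
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    freq_tables = column_frequencies(aln)
    return [_column_call(freqs, threshold, scheme) for freqs in freq_tables]


def consensus_profile(aln: Alignment,
                      thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
                      scheme: ResidueClassScheme = DEFAULT_SCHEME) -> ConsensusProfile:
    freq_tables = column_frequencies(aln)
    calls = {
        t: tuple(_column_call(freqs, t, scheme) for freqs in freq_tables)
        for t in thresholds
    }
    return ConsensusProfile(
        thresholds=tuple(thresholds),
        calls=calls,
        freqs=tuple(freq_tables),
    )


def derive_spacing_motif(aln: Alignment, anchor_threshold: float = 90.0) -> SpacingMotif:
    """Derive the anchor/spacer motif from conserved alignment columns.

    Anchor columns are the first five whose cysteine frequency reaches
    ``anchor_threshold``, plus the aspartate column immediately preceding the
    third such cysteine when its D frequency also qualifies. Each spacer is
    the modal count, across rows, of residues strictly between the matched
    anchors in the degapped row.
    """
    frac = anchor_threshold / 100.0
    freq_tables = column_frequencies(aln)
    cys_cols = [j for j, f in enumerate(freq_tables) if f.get("C", 0.0) >= frac]
    if len(cys_cols) < 5:
        raise ValueError("scaffold not found: fewer than five conserved cysteine columns")
    cys_cols = cys_cols[:5]

    anchor_cols: list[tuple[int, str]] = [(j, "C") for j in cys_cols]
    d_col = cys_cols[2] - 1
    if d_col >= 0 and freq_tables[d_col].get("D", 0.0) >= frac:
        anchor_cols.insert(2, (d_col, "D"))
    anchor_cols.sort()

    # modal residue count strictly between consecutive matched anchors
    spacers: list[int] = []
    for (col_a, res_a), (col_b, res_b) in zip(anchor_cols, anchor_cols[1:]):
        counts: Counter[int] = Counter()
        for _, row in aln.records:
            if row[col_a] != res_a or row[col_b] != res_b:
                continue
            between = row[col_a + 1:col_b].replace(GAP, "")
            counts[len(between)] += 1
        if not counts:
            raise ValueError("scaffold not found: no row matches consecutive anchors")
        # mode; ties toward the smaller spacer for determinism
        modal = min(counts, key=lambda n: (-counts[n], n))
        spacers.append(modal)

    anchors = tuple(
        (res, spacers[i] if i < len(spacers) else 0)
        for i, (_, res) in enumerate(anchor_cols)
    )
    return SpacingMotif(anchors)


def write_consensus_tsv(profile: ConsensusProfile, path: str | Path) -> None:
    """Consensus calls as TSV: one row per column, one call column per threshold."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["column"] + [f"call_{t:g}" for t in profile.thresholds])
        for j in range(profile.ncol):
            writer.writerow([j + 1] + [profile.calls[t][j] for t in profile.thresholds])


def write_frequencies_tsv(profile: ConsensusProfile, path: str | Path) -> None:
    """Logo-ready frequency matrix as TSV (column, residue/gap, frequency)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["column", "residue", "frequency"])
        for j, freqs in enumerate(profile.freqs):
            for residue, f in freqs.items():
                writer.writerow([j + 1, "gap" if residue == GAP else residue, f"{f:.6g}"])
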