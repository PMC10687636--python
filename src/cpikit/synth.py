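"""Seeded generator of scaffold-bearing peptide families and decoys.

Generated sequences carry the configured anchor scaffold with class-biased
wildcard segments, a hydrophobic-biased C-terminal tail, and an optional
random N-terminal propeptide (drawn without cysteines so the first cysteine
of every sequence is the first scaffold anchor). A controllable fraction of
sequences receives exactly one anchor-destroying substitution; the truth
labels record which.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from cpikit.conservation import Alignment, ResidueClassScheme, DEFAULT_SCHEME, GAP
from cpikit.motif import SpacingMotif, DEFAULT_MOTIF, scan_motif
from cpikit.records import PeptideRecord, STANDARD_AA

_AA = tuple(STANDARD_AA)

#: default wildcard-segment class preferences, by inter-anchor segment index
#: (segments of the default scaffold: C1-C2, C2-D, D-C3, C3-C4, C4-C5).
DEFAULT_SEGMENT_PREFS: dict[int, tuple[str, ...]] = {
    0: ("t",),
    1: ("p", "s", "t"),
    3: ("h",),
}


@dataclass(frozen=True)
class SyntheticConfig:
    n_sequences: int = 42
    seed: int = 0
    scaffold: SpacingMotif = DEFAULT_MOTIF
    scheme: ResidueClassScheme = DEFAULT_SCHEME
    segment_preferences: dict[int, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENT_PREFS))
    tail_length_range: tuple[int, int] = (2, 6)
    tail_bias: float = 0.8
    propeptide_length_range: tuple[int, int] = (0, 25)
    violation_rate: float = 0.0
    substitution_noise: float = 0.05
    gap_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if not 0.0 <= self.violation_rate <= 1.0:
            raise ValueError("violation_rate must be in [0, 1]")
        class_map = dict(self.scheme.items())
        for segment, symbols in self.segment_preferences.items():
            for symbol in symbols:
                members = class_map.get(symbol)
                if not members:
                    raise ValueError(
                        f"segment {segment}: class {symbol!r} undefined or empty")


def _draw(rng: np.random.Generator, pool: tuple[str, ...]) -> str:
    return pool[int(rng.integers(len(pool)))]


def generate_family(cfg: SyntheticConfig) -> tuple[
        list[PeptideRecord], Alignment, dict[str, bool]]:
    """Generate records, their mature-region alignment, and violation labels.

    Wildcard positions draw from the segment's preferred class(es) with
    probability ``1 - substitution_noise``, else uniformly over the 20
    residues. Exactly ``round(n * violation_rate)`` sequences get one anchor
    substituted by a non-anchor residue. Fully reproducible from the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    class_map = {sym: tuple(sorted(members)) for sym, members in cfg.scheme.items()}
    hydrophobic = class_map.get("h", _AA)
    non_cys = tuple(aa for aa in _AA if aa != "C")

    anchors = cfg.scaffold.anchors
    # scaffold-region offsets of each anchor
    anchor_offsets: list[int] = []
    pos = 0
    for residue, spacer in anchors:
        anchor_offsets.append(pos)
        pos += 1 + spacer

    scaffold_parts: list[list[str]] = []
    tails: list[str] = []
    propeptides: list[str] = []
    for _ in range(cfg.n_sequences):
        part: list[str] = []
        for segment, (residue, spacer) in enumerate(anchors):
            part.append(residue)
            prefs = cfg.segment_preferences.get(segment)
            for _ in range(spacer):
                if prefs is None or rng.random() < cfg.substitution_noise:
                    part.append(_draw(rng, _AA))
                else:
                    symbol = prefs[int(rng.integers(len(prefs)))]
                    part.append(_draw(rng, class_map[symbol]))
        scaffold_parts.append(part)

        lo, hi = cfg.tail_length_range
        tail_len = int(rng.integers(lo, hi + 1))
        tails.append("".join(
            _draw(rng, hydrophobic) if rng.random() < cfg.tail_bias else _draw(rng, _AA)
            for _ in range(tail_len)))

        lo, hi = cfg.propeptide_length_range
        prop_len = int(rng.integers(lo, hi + 1))
        propeptides.append("".join(_draw(rng, non_cys) for _ in range(prop_len)))

    # plant exactly round(n * rate) anchor violations
    n_violations = round(cfg.n_sequences * cfg.violation_rate)
    violators = set(
        int(i) for i in rng.choice(cfg.n_sequences, size=n_violations, replace=False)
    ) if n_violations else set()
    for i in violators:
        which = int(rng.integers(len(anchors)))
        offset = anchor_offsets[which]
        original = scaffold_parts[i][offset]
        allowed = tuple(aa for aa in _AA if aa not in {original, "C", "D"})
        scaffold_parts[i][offset] = _draw(rng, allowed)

    records: list[PeptideRecord] = []
    truth: dict[str, bool] = {}
    mature_rows: list[str] = []
    for i in range(cfg.n_sequences):
        scaffold_seq = "".join(scaffold_parts[i])
        row = scaffold_seq + tails[i]
        if cfg.gap_rate > 0.0:
            # stress option: drop wildcard residues, leaving gaps in the row
            chars = list(row)
            for j in range(len(scaffold_seq)):
                if j not in anchor_offsets and rng.random() < cfg.gap_rate:
                    chars[j] = GAP
            row = "".join(chars)
        rid = f"SYN{i + 1:03d}"
        mature = row.replace(GAP, "")
        records.append(PeptideRecord(
            id=rid, residues=propeptides[i] + mature,
            species="synthetic", source_db="cpikit",
        ))
        truth[rid] = i in violators
        mature_rows.append(row)

    width = max(len(row) for row in mature_rows)
    aln = Alignment(tuple(
        (record.id, row.ljust(width, GAP))
        for record, row in zip(records, mature_rows)
    ))
    return records, aln, truth


def generate_decoys(n: int, length_range: tuple[int, int] = (35, 50),
                    seed: int = 0,
                    scaffold: SpacingMotif = DEFAULT_MOTIF) -> list[PeptideRecord]:
    """Uniform-random sequences rejection-sampled to contain no scaffold match."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    records: list[PeptideRecord] = []
    while len(records) < n:
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(_draw(rng, _AA) for _ in range(length))
        if scan_motif(seq, scaffold):
            continue
        records.append(PeptideRecord(
            id=f"DECOY{len(records) + 1:03d}", residues=seq,
            species="synthetic", source_db="cpikit",
        ))
    return records


def write_truth_tsv(truth: dict[str, bool], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "violates_motif"])
        for rid, flag in truth.items():
            writer.writerow([rid, int(flag)])
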