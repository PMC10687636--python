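"""Inclusion filtering and mature-region trimming of peptide records.

Curation applies three machine-checkable exclusion rules, in order:

* ``redundant`` — exact duplicate of an earlier sequence (first occurrence wins);
* ``incomplete`` — ambiguity/non-standard codes (X, B, Z, J, U, O) or a stop ``*``;
* ``cysteine_pattern`` — fewer cysteines than the scaffold's anchor count.

Records whose species/annotation text reads "uncharacterized" are excluded
with reason ``uncharacterized`` before the sequence-level rules.

Trimming cuts each sequence three residues before the first anchor cysteine
of its best (leftmost) scaffold-motif match, clamped at the sequence start;
when the motif does not match, the first cysteine is the anchor.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from cpikit.motif import SpacingMotif, scan_motif
from cpikit.records import PeptideRecord, STANDARD_AA_SET

#: Codes whose presence marks a sequence as incomplete/ambiguous.
AMBIGUOUS_CODES = frozenset("XBZJUO*")

REASONS = ("redundant", "incomplete", "uncharacterized", "cysteine_pattern")


@dataclass
class CurationReport:
    """Partition of the input into kept records and (id, reason) rejections."""

    kept: list[PeptideRecord]
    rejected: list[tuple[str, str]]

    @property
    def kept_ids(self) -> list[str]:
        return [r.id for r in self.kept]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(["id", "reason"])
            writer.writerows(self.rejected)


def curate(records: list[PeptideRecord], min_cys: int = 5) -> CurationReport:
    """Filter records by the inclusion rules; rejections are reported, not raised.

    Deterministic given input order: among exact-duplicate sequences the first
    occurrence is kept.
    """
    if not records:
        raise ValueError("curate: no input records")
    if min_cys < 0:
        raise ValueError("curate: min_cys must be >= 0")

    kept: list[PeptideRecord] = []
    rejected: list[tuple[str, str]] = []
    seen_sequences: set[str] = set()

    for record in records:
        if "uncharacterized" in record.species.lower() or \
           "uncharacterized" in record.source_db.lower():
            rejected.append((record.id, "uncharacterized"))
            continue
        if record.residues in seen_sequences:
            rejected.append((record.id, "redundant"))
            continue
        seen_sequences.add(record.residues)
        if set(record.residues) & AMBIGUOUS_CODES or \
           not set(record.residues) <= STANDARD_AA_SET:
            rejected.append((record.id, "incomplete"))
            continue
        if record.residues.count("C") < min_cys:
            rejected.append((record.id, "cysteine_pattern"))
            continue
        kept.append(record)

    return CurationReport(kept=kept, rejected=rejected)


def trim_to_mature(record: PeptideRecord, motif: SpacingMotif) -> PeptideRecord:
    """Cut a record to its mature region: 3 residues before the anchor cysteine.

    The anchor is the first cysteine of the leftmost motif match; if the motif
    does not match anywhere, the first cysteine of the sequence. The cut start
    is clamped at position 1. Idempotent: an already-trimmed record is
    returned unchanged.
    """
    if record.trimmed:
        return record
    matches = scan_motif(record.residues, motif)
    if matches:
        c1 = matches[0]
    else:
        pos = record.residues.find("C")
        if pos < 0:
            raise ValueError(f"untrimmable: record {record.id!r} has no cysteine")
        c1 = pos + 1
    start = max(1, c1 - 3)
    return record.with_residues(
        record.residues[start - 1:], trimmed=True, trim_start=start,
    )
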