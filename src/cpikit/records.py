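"""Peptide records and FASTA I/O.

A :class:`PeptideRecord` holds one identified peptide sequence together with
its provenance (accession, species, source database) and its trim state.
FASTA headers of the form ``id|species|source_db`` are split into those three
fields; any other header is kept whole as the id.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
STANDARD_AA_SET = frozenset(STANDARD_AA)


@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide sequence with provenance and trim state.

    ``trim_start`` is the 1-based index into the original (untrimmed)
    sequence at which ``residues`` begins; it is only meaningful when
    ``trimmed`` is true.
    """

    id: str
    residues: str
    species: str = ""
    source_db: str = ""
    trimmed: bool = False
    trim_start: int | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.trimmed and (self.trim_start is None or self.trim_start < 1):
            raise ValueError(f"record {self.id!r}: trimmed without a valid trim_start")

    @property
    def header(self) -> str:
        if self.species or self.source_db:
            return f"{self.id}|{self.species}|{self.source_db}"
        return self.id

    def with_residues(self, residues: str, *, trimmed: bool = False,
                      trim_start: int | None = None) -> "PeptideRecord":
        return replace(self, residues=residues, trimmed=trimmed, trim_start=trim_start)


def _parse_header(header: str) -> tuple[str, str, str]:
    if "|" in header:
        parts = header.split("|")
        parts += [""] * (3 - len(parts))
        return parts[0].strip(), parts[1].strip(), parts[2].strip()
    return header.strip(), "", ""


def read_fasta(path: str | Path) -> list[PeptideRecord]:
    """Read unaligned peptide FASTA into records.

    Sequences are uppercased; non-standard characters are retained here and
    flagged later by curation. Raises on an empty file and on duplicate ids.
    """
    path = Path(path)
    records: list[PeptideRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid, species, source_db = _parse_header(entry.description)
        if rid in seen:
            raise ValueError(f"duplicate id in {path}: {rid!r}")
        seen.add(rid)
        records.append(PeptideRecord(
            id=rid, residues=str(entry.seq).upper(),
            species=species, source_db=source_db,
        ))
    if not records:
        raise ValueError(f"no FASTA entries in {path}")
    return records


def write_fasta(records: Iterable[PeptideRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.header, description="") for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")
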