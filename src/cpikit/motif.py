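"""Fixed-spacer anchor motifs and sequence scanning.

A :class:`SpacingMotif` is an ordered list of anchor residues, each followed
by a fixed number of wildcard positions before the next anchor. Two textual
syntaxes are supported and round-trip:

* compact: ``CXXXCXXXXDCXXXXXCXXC`` (X = any standard residue)
* PROSITE-like: ``C-x(3)-C-x(4)-D-C-x(5)-C-x(2)-C``
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from cpikit.records import PeptideRecord, STANDARD_AA_SET


@dataclass(frozen=True)
class SpacingMotif:
    """Ordered anchors with fixed spacer lengths.

    ``anchors`` is a tuple of ``(residue, spacer)`` pairs where ``spacer`` is
    the number of wildcard positions between this anchor and the next; the
    last anchor's spacer is 0.
    """

    anchors: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ValueError("motif needs at least one anchor")
        for residue, spacer in self.anchors:
            if residue not in STANDARD_AA_SET:
                raise ValueError(f"anchor {residue!r} is not a standard residue")
            if spacer < 0:
                raise ValueError("spacer lengths must be >= 0")
        if self.anchors[-1][1] != 0:
            raise ValueError("last anchor must have spacer 0")

    def __len__(self) -> int:
        return sum(1 + spacer for _, spacer in self.anchors)

    @property
    def compact(self) -> str:
        return "".join(res + "X" * spacer for res, spacer in self.anchors)

    @property
    def prosite(self) -> str:
        parts: list[str] = []
        for res, spacer in self.anchors:
            parts.append(res)
            if spacer:
                parts.append(f"x({spacer})")
        return "-".join(parts)

    @classmethod
    def from_compact(cls, text: str) -> "SpacingMotif":
        if not text or text[0] == "X":
            raise ValueError("compact motif must start with an anchor residue")
        anchors: list[tuple[str, int]] = []
        i = 0
        while i < len(text):
            residue = text[i]
            i += 1
            spacer = 0
            while i < len(text) and text[i] == "X":
                spacer += 1
                i += 1
            anchors.append((residue, spacer))
        return cls(tuple(anchors))

    @classmethod
    def from_prosite(cls, text: str) -> "SpacingMotif":
        tokens = text.strip().rstrip(".").split("-")
        anchors: list[tuple[str, int]] = []
        for token in tokens:
            match = re.fullmatch(r"x\((\d+)\)", token)
            if match:
                if not anchors:
                    raise ValueError("motif must start with an anchor residue")
                residue, spacer = anchors[-1]
                anchors[-1] = (residue, spacer + int(match.group(1)))
            elif token == "x":
                if not anchors:
                    raise ValueError("motif must start with an anchor residue")
                residue, spacer = anchors[-1]
                anchors[-1] = (residue, spacer + 1)
            elif len(token) == 1:
                anchors.append((token, 0))
            else:
                raise ValueError(f"cannot parse motif token {token!r}")
        return cls(tuple(anchors))


#: The family's 5-cysteine/1-aspartate consensus scaffold.
DEFAULT_MOTIF = SpacingMotif.from_prosite("C-x(3)-C-x(4)-D-C-x(5)-C-x(2)-C")


def scan_motif(seq: str, motif: SpacingMotif) -> list[int]:
    """Return all 1-based start positions where the motif matches ``seq``.

    Anchors must occur with exactly the specified spacers; wildcard positions
    match any of the 20 standard residues (a non-standard character never
    matches). Overlapping matches are all reported.
    """
    if "-" in seq:
        raise ValueError("scan_motif expects an ungapped sequence")
    window = len(motif)
    offsets: list[tuple[int, str | None]] = []
    pos = 0
    for residue, spacer in motif.anchors:
        offsets.append((pos, residue))
        for k in range(spacer):
            offsets.append((pos + 1 + k, None))
        pos += 1 + spacer

    matches: list[int] = []
    for start in range(len(seq) - window + 1):
        ok = True
        for offset, residue in offsets:
            ch = seq[start + offset]
            if residue is None:
                if ch not in STANDARD_AA_SET:
                    ok = False
                    break
            elif ch != residue:
                ok = False
                break
        if ok:
            matches.append(start + 1)
    return matches


def motif_match_rate(records: list[PeptideRecord], motif: SpacingMotif) -> float:
    """Percentage of records with at least one motif match."""
    if not records:
        raise ValueError("motif_match_rate: no input records")
    hits = sum(1 for r in records if scan_motif(r.residues, motif))
    return 100.0 * hits / len(records)
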