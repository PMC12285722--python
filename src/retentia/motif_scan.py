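"""Scanning intron sequences for m6A-related motifs.

DRACH (D=[AGU] R=[AG] A C H=[ACU]) is the degenerate m6A deposition
consensus; GGACT/GGACA ("GGACU/A") are its canonical, most frequently
methylated instances; GAAUGC is a YTHDC1-binding element.  Scanning is
strand-explicit: hits are reported on the supplied (transcript-orientation)
sequence only, all overlapping occurrences included.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator

from ._seq import normalize

# IUPAC nucleotide codes in the DNA frame (U normalized to T)
IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "U": "T",
    "R": "[AG]",
    "Y": "[CT]",
    "S": "[CG]",
    "W": "[AT]",
    "K": "[GT]",
    "M": "[AC]",
    "B": "[CGT]",
    "D": "[AGT]",
    "H": "[ACT]",
    "V": "[ACG]",
    "N": "[ACGT]",
}

DRACH = "DRACH"
CANONICAL_GGACW = "GGACW"  # GGACT | GGACA
YTHDC1_MOTIF = "GAAUGC"


class InvalidPatternError(ValueError):
    """Raised for a pattern containing a non-IUPAC symbol."""


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    position: int  # 0-based offset within the scanned sequence
    matched_subsequence: str


def _compile(pattern: str) -> re.Pattern:
    pattern = pattern.upper()
    try:
        regex = "".join(IUPAC[code] for code in pattern)
    except KeyError as exc:
        raise InvalidPatternError(f"invalid IUPAC code {exc.args[0]!r} in {pattern}") from exc
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({regex}))")


def find_motif(seq: str, pattern: str, motif_id: str | None = None) -> list[MotifHit]:
    """All (overlapping) occurrences of an IUPAC pattern in a sequence."""
    seq = normalize(seq)
    motif_id = motif_id or pattern.upper()
    return [
        MotifHit(motif_id=motif_id, position=m.start(), matched_subsequence=m.group(1))
        for m in _compile(pattern).finditer(seq)
    ]


def find_drach(seq: str) -> list[MotifHit]:
    """All DRACH consensus occurrences."""
    return find_motif(seq, DRACH, motif_id="DRACH")


def count_canonical(seq: str) -> int:
    """Number of canonical GGACU/GGACA motif occurrences (overlaps allowed)."""
    return len(find_motif(seq, CANONICAL_GGACW, motif_id="GGACW"))


def hits_to_bed(hits: list[MotifHit], sequence_id: str) -> Iterator[str]:
    """BED-like TSV lines: sequence_id, start, end, motif_id, matched sequence."""
    for h in hits:
        end = h.position + len(h.matched_subsequence)
        yield f"{sequence_id}\t{h.position}\t{end}\t{h.motif_id}\t{h.matched_subsequence}"
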