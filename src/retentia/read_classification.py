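"""Selection and four-pattern classification of exon-spanning reads.

A read informs the joint retention status of the two introns flanking a target
exon when its alignment covers the whole exon and extends at least
``min_overhang`` aligned bases beyond both exon boundaries.  Each flanking
intron is then called SPLICED (junction gap exactly matching the annotated
intron), RETAINED (contiguous alignment into the intron), or neither — in
which case the read is AMBIGUOUS.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator, Sequence

import pysam

from .gene_model import IntronRecord

DEFAULT_MIN_OVERHANG = 2
DEFAULT_MAX_DELETION = 3  # deletions up to this size do not break exon coverage

_REF_CONSUMING_ALIGNED = {0, 7, 8}  # M, =, X
_OP_N = 3
_OP_D = 2


class PatternClass(enum.Enum):
    """Joint retention call for (upstream intron, downstream intron)."""

    BOTH_SPLICED = "SS"
    R_UP_S_DOWN = "RS"
    S_UP_R_DOWN = "SR"
    BOTH_RETAINED = "RR"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class SpanningRead:
    """Gapped block structure of one alignment.

    ``blocks`` are strictly increasing, non-overlapping 0-based half-open
    reference intervals of aligned (match/mismatch) bases, with deletions up
    to ``DEFAULT_MAX_DELETION`` nt absorbed into a block.  ``gaps[i]`` is the
    reference gap between blocks i and i+1 together with its origin:
    ``"N"`` for a splice junction, ``"D"`` for a long deletion.
    """

    read_id: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    gaps: tuple[tuple[tuple[int, int], str], ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.gaps) != max(len(self.blocks) - 1, 0):
            raise ValueError("need exactly one gap between consecutive blocks")
        for (a, b), ((g0, g1), kind) in zip(
            zip(self.blocks, self.blocks[1:]), self.gaps
        ):
            if not (a[1] == g0 < g1 == b[0]):
                raise ValueError("gaps must exactly fill the space between blocks")
            if kind not in ("N", "D"):
                raise ValueError(f"unknown gap kind {kind!r}")

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """Reference gaps introduced by splice (CIGAR N) operations."""
        return tuple(iv for iv, kind in self.gaps if kind == "N")

    @property
    def reference_start(self) -> int:
        return self.blocks[0][0]

    @property
    def reference_end(self) -> int:
        return self.blocks[-1][1]


def spanning_read_from_alignment(
    aln: pysam.AlignedSegment, max_deletion: int = DEFAULT_MAX_DELETION
) -> SpanningRead:
    """Build the block/gap structure of a pysam alignment from its CIGAR."""
    blocks: list[list[int]] = []
    gaps: list[list] = []  # [[start, end], kind]; parallel to inter-block spaces
    pos = aln.reference_start
    extendable = False  # last block can absorb the next aligned run
    for op, length in aln.cigartuples or ():
        if op in _REF_CONSUMING_ALIGNED:
            if extendable:
                blocks[-1][1] = pos + length
            else:
                blocks.append([pos, pos + length])
                extendable = True
            pos += length
        elif op == _OP_D:
            if length <= max_deletion and extendable:
                blocks[-1][1] = pos + length  # small deletion stays contiguous
            else:
                _push_gap(gaps, blocks, pos, pos + length, "D")
                extendable = False
            pos += length
        elif op == _OP_N:
            _push_gap(gaps, blocks, pos, pos + length, "N")
            extendable = False
            pos += length
        # I, S, H, P consume no reference
    # drop any trailing gap not followed by a block
    gaps = gaps[: max(len(blocks) - 1, 0)]
    return SpanningRead(
        read_id=aln.query_name or "",
        chrom=aln.reference_name or "",
        strand="-" if aln.is_reverse else "+",
        blocks=tuple((s, e) for s, e in blocks),
        gaps=tuple(((g[0][0], g[0][1]), g[1]) for g in gaps),
    )


def _push_gap(gaps: list, blocks: list, start: int, end: int, kind: str) -> None:
    """Record a reference gap, merging with an immediately preceding gap."""
    if not blocks:
        return  # leading gap has no block to its left; ignore
    if gaps and len(gaps) == len(blocks) and gaps[-1][0][1] == start:
        # adjacent gap ops with no block between: one combined gap; a splice
        # op anywhere in the run marks it as junction-like
        gaps[-1][0][1] = end
        if kind == "N":
            gaps[-1][1] = "N"
    else:
        gaps.append([[start, end], kind])


def _covers_exon(read: SpanningRead, exon: tuple[int, int]) -> bool:
    """True if every exonic reference base falls in an aligned block.

    Small deletions were already absorbed into blocks, so any remaining gap
    inside the exon (junction or long deletion) breaks coverage.
    """
    start, end = exon
    cover = 0
    for s, e in read.blocks:
        lo, hi = max(s, start), min(e, end)
        if hi > lo:
            cover += hi - lo
    return cover == end - start


def _overhang(read: SpanningRead, exon: tuple[int, int]) -> tuple[int, int]:
    """Aligned bases strictly left of exon start / right of exon end."""
    left = sum(min(e, exon[0]) - s for s, e in read.blocks if s < exon[0])
    right = sum(e - max(s, exon[1]) for s, e in read.blocks if e > exon[1])
    return left, right


def select_spanning(
    reads: Iterable[SpanningRead],
    exon: tuple[int, int],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> list[SpanningRead]:
    """Spanning-read rule on already-parsed reads: full exon coverage plus
    >= min_overhang aligned bases beyond both exon boundaries."""
    out = []
    for read in reads:
        if not read.blocks or not _covers_exon(read, exon):
            continue
        left, right = _overhang(read, exon)
        if left >= min_overhang and right >= min_overhang:
            out.append(read)
    return out


def select_spanning_reads(
    alignments: Iterable[pysam.AlignedSegment] | str,
    exon: tuple[int, int],
    chrom: str | None = None,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    mapq_min: int = 1,
    primary_only: bool = True,
    max_deletion: int = DEFAULT_MAX_DELETION,
) -> list[SpanningRead]:
    """Select reads whose alignments span ``exon`` with >= min_overhang on both sides.

    ``alignments`` may be a SAM/BAM path or an iterable of pysam records.
    Filters (primary-only, MAPQ) are applied before the spanning rule.
    """
    opened = None
    if isinstance(alignments, str):
        opened = pysam.AlignmentFile(alignments)
        if chrom is not None and chrom not in opened.references:
            opened.close()
            raise ValueError(f"region chromosome {chrom!r} not in alignment header")
        stream: Iterable[pysam.AlignedSegment] = opened
    else:
        stream = alignments
    selected: list[SpanningRead] = []
    try:
        for aln in stream:
            if aln.is_unmapped:
                continue
            if primary_only and (aln.is_secondary or aln.is_supplementary):
                continue
            if aln.mapping_quality < mapq_min:
                continue
            if chrom is not None and aln.reference_name != chrom:
                continue
            read = spanning_read_from_alignment(aln, max_deletion=max_deletion)
            if not read.blocks:
                continue
            if not _covers_exon(read, exon):
                continue
            left, right = _overhang(read, exon)
            if left >= min_overhang and right >= min_overhang:
                selected.append(read)
    finally:
        if opened is not None:
            opened.close()
    return selected


def _call_boundary(
    read: SpanningRead,
    intron: tuple[int, int],
    exon_side: str,
    min_overhang: int,
) -> str:
    """Call one flanking intron: 'S', 'R' or 'A'.

    ``exon_side`` is 'left' when the intron lies genomically left of the exon.
    SPLICED needs a junction gap identical to the annotated intron plus
    >= min_overhang aligned bases immediately across it; RETAINED needs a
    contiguous block running >= min_overhang into the intron across the exon
    boundary.
    """
    istart, iend = intron
    boundary = iend if exon_side == "left" else istart  # exon edge shared with intron
    for (g0, g1), kind in read.gaps:
        if (g0, g1) == (istart, iend) and kind == "N":
            # aligned run immediately across the junction, inside the far exon
            if exon_side == "left":
                far = next((b for b in read.blocks if b[1] == istart), None)
                ok = far is not None and istart - far[0] >= min_overhang
            else:
                far = next((b for b in read.blocks if b[0] == iend), None)
                ok = far is not None and far[1] - iend >= min_overhang
            return "S" if ok else "A"
        if kind == "N" and (g0 < iend and g1 > istart):
            return "A"  # junction into the intron interior / not matching annotation
    for s, e in read.blocks:
        if s < boundary < e:  # block runs contiguously across the exon boundary
            into = boundary - s if exon_side == "left" else e - boundary
            return "R" if into >= min_overhang else "A"
    return "A"


def classify_read(
    read: SpanningRead,
    intron_up: IntronRecord,
    intron_down: IntronRecord,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> PatternClass:
    """Classify a selected spanning read into one of the four co-retention patterns.

    ``intron_up``/``intron_down`` are the introns 5' and 3' of the target exon
    in transcript orientation; their genomic sides follow from the strand.
    """
    up_iv, down_iv = intron_up.interval, intron_down.interval
    exon_lo = min(up_iv[1], down_iv[1])
    exon_hi = max(up_iv[0], down_iv[0])
    if read.reference_end <= exon_lo or read.reference_start >= exon_hi:
        raise ValueError(f"read {read.read_id} does not overlap the target exon")
    left_iv, right_iv = sorted((up_iv, down_iv))
    left_call = _call_boundary(read, left_iv, "left", min_overhang)
    right_call = _call_boundary(read, right_iv, "right", min_overhang)
    if up_iv == left_iv:
        up_call, down_call = left_call, right_call
    else:
        up_call, down_call = right_call, left_call
    mapping = {
        ("S", "S"): PatternClass.BOTH_SPLICED,
        ("R", "S"): PatternClass.R_UP_S_DOWN,
        ("S", "R"): PatternClass.S_UP_R_DOWN,
        ("R", "R"): PatternClass.BOTH_RETAINED,
    }
    return mapping.get((up_call, down_call), PatternClass.AMBIGUOUS)


@dataclass(frozen=True)
class PatternCounts:
    """Observed counts of the four classes plus ambiguous reads."""

    n_SS: int = 0
    n_RS: int = 0
    n_SR: int = 0
    n_RR: int = 0
    n_ambiguous: int = 0

    def __post_init__(self) -> None:
        if min(self.n_SS, self.n_RS, self.n_SR, self.n_RR, self.n_ambiguous) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_selected(self) -> int:
        return self.n_SS + self.n_RS + self.n_SR + self.n_RR + self.n_ambiguous

    @property
    def n_informative(self) -> int:
        return self.n_selected - self.n_ambiguous

    def as_dict(self) -> dict[str, int]:
        return {
            "SS": self.n_SS,
            "RS": self.n_RS,
            "SR": self.n_SR,
            "RR": self.n_RR,
            "ambiguous": self.n_ambiguous,
        }


def tally(labels: Iterable[PatternClass]) -> PatternCounts:
    """Count classification labels into a PatternCounts record."""
    c = {cls: 0 for cls in PatternClass}
    for label in labels:
        c[label] += 1
    return PatternCounts(
        n_SS=c[PatternClass.BOTH_SPLICED],
        n_RS=c[PatternClass.R_UP_S_DOWN],
        n_SR=c[PatternClass.S_UP_R_DOWN],
        n_RR=c[PatternClass.BOTH_RETAINED],
        n_ambiguous=c[PatternClass.AMBIGUOUS],
    )


def junction_coverage_floor(
    total_junction_reads: int, n_introns: int, fraction: float = 0.05
) -> tuple[int, Fraction]:
    """Sashimi display floor: ``fraction`` of the expected per-junction coverage.

    Expected coverage is total junction reads divided by the number of
    introns.  Returns the integer floor (half-up rounding) and the exact
    rational value.
    """
    if n_introns < 1:
        raise ValueError("n_introns must be >= 1")
    if total_junction_reads < 0:
        raise ValueError("total_junction_reads must be >= 0")
    exact = Fraction(fraction).limit_denominator(10**9) * Fraction(
        total_junction_reads, n_introns
    )
    rounded = int(exact + Fraction(1, 2))  # half-up for non-negative values
    return rounded, exact
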