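"""Transcript models, intron derivation and the internal-intron reference population.

Coordinates are 0-based half-open internally; GTF I/O converts to/from the
1-based inclusive convention.  Intron ordinals and splice-site sequences are
always given in transcript (5'->3') orientation, while genomic intervals stay
on the + reference frame.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from pyfaidx import Fasta

from ._seq import normalize, revcomp


class GTFParseError(ValueError):
    """Raised for a malformed GTF line (message names the line number)."""


class ModelValidationError(ValueError):
    """Raised when a transcript's exon structure violates the model invariants."""


@dataclass(frozen=True)
class TranscriptModel:
    """Ordered exon structure of one transcript on one strand.

    ``exons`` are genomic 0-based half-open intervals stored in transcript
    5'->3' order: ascending genomic start on '+', descending on '-'.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ModelValidationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise ModelValidationError(f"{self.transcript_id}: transcript has no exons")
        for start, end in self.exons:
            if end <= start:
                raise ModelValidationError(
                    f"{self.transcript_id}: empty exon interval [{start}, {end})"
                )
        genomic = sorted(self.exons)
        for (_, e0), (s1, _) in zip(genomic, genomic[1:]):
            if s1 <= e0:
                raise ModelValidationError(
                    f"{self.transcript_id}: overlapping or abutting exons "
                    f"(introns must have positive length)"
                )
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise ModelValidationError(
                f"{self.transcript_id}: exon order inconsistent with strand {self.strand}"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def span(self) -> tuple[int, int]:
        """Genomic [start, end) covered by the transcript."""
        genomic = sorted(self.exons)
        return genomic[0][0], genomic[-1][1]


@dataclass(frozen=True)
class IntronRecord:
    """One intron of one transcript; ``ordinal`` is 1-based in transcript order."""

    transcript_id: str
    ordinal: int
    chrom: str
    strand: str
    start: int
    end: int
    is_internal: bool

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ModelValidationError(
                f"{self.transcript_id} intron {self.ordinal}: non-positive length"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass(frozen=True)
class SpliceSiteSeqs:
    """Donor 9-mer (3 exonic + 6 intronic) and acceptor 23-mer (20 intronic + 3 exonic)."""

    donor9: str
    acceptor23: str

    def __post_init__(self) -> None:
        if len(self.donor9) != 9 or len(self.acceptor23) != 23:
            raise ModelValidationError("splice-site windows must be 9 and 23 nt")
        alphabet = set("ACGTN")
        if not (set(self.donor9) <= alphabet and set(self.acceptor23) <= alphabet):
            raise ModelValidationError("splice-site sequences restricted to A/C/G/T/N")


def _prevalidate_gtf(path: str) -> None:
    """Cheap structural scan so malformed lines are reported with their number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GTFParseError(
                    f"{path}: malformed GTF line {lineno}: expected 9 tab-separated "
                    f"fields, found {len(fields)}"
                )
            if fields[2] == "exon":
                try:
                    start, end = int(fields[3]), int(fields[4])
                except ValueError as exc:
                    raise GTFParseError(
                        f"{path}: malformed GTF line {lineno}: non-integer coordinates"
                    ) from exc
                if start < 1 or end < start:
                    raise GTFParseError(
                        f"{path}: malformed GTF line {lineno}: invalid interval "
                        f"{start}-{end}"
                    )


def parse_annotation(path: str) -> dict[str, TranscriptModel]:
    """Parse a GENCODE-dialect GTF into one TranscriptModel per transcript_id.

    Exon coordinates are converted from GTF 1-based inclusive to 0-based
    half-open and sorted 5'->3' in transcript orientation.
    """
    _prevalidate_gtf(path)
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=False,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    per_tx: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for exon in db.features_of_type("exon"):
        tx_ids = exon.attributes.get("transcript_id")
        if not tx_ids:
            raise GTFParseError(f"{path}: exon feature without transcript_id attribute")
        tx_id = tx_ids[0]
        per_tx.setdefault(tx_id, []).append((exon.start - 1, exon.end))
        meta[tx_id] = (exon.seqid, exon.strand)
    models: dict[str, TranscriptModel] = {}
    for tx_id, exons in per_tx.items():
        chrom, strand = meta[tx_id]
        ordered = sorted(exons, reverse=(strand == "-"))
        models[tx_id] = TranscriptModel(tx_id, chrom, strand, tuple(ordered))
    return models


def derive_introns(t: TranscriptModel) -> list[IntronRecord]:
    """Introns of ``t`` in transcript order; empty for a single-exon transcript.

    Intron i fills the genomic gap between exons i and i+1 (transcript order);
    its length is the genomic gap size.
    """
    n = t.n_introns
    introns = []
    for i, (up, down) in enumerate(zip(t.exons, t.exons[1:]), start=1):
        if t.strand == "+":
            start, end = up[1], down[0]
        else:
            start, end = down[1], up[0]
        introns.append(
            IntronRecord(
                transcript_id=t.transcript_id,
                ordinal=i,
                chrom=t.chrom,
                strand=t.strand,
                start=start,
                end=end,
                is_internal=1 < i < n,
            )
        )
    return introns


def internal_intron_population(
    transcripts: Iterable[TranscriptModel],
    min_introns: int = 3,
    per_transcript: bool = False,
) -> list[IntronRecord]:
    """Internal (non-first, non-last) introns from transcripts with >= min_introns introns.

    By default one record is kept per distinct (chrom, start, end, strand)
    locus; ``per_transcript=True`` keeps every transcript's copy.
    """
    out: list[IntronRecord] = []
    seen: set[tuple[str, int, int, str]] = set()
    for t in transcripts:
        if t.n_introns < min_introns:
            continue
        for intron in derive_introns(t):
            if not intron.is_internal:
                continue
            if not per_transcript:
                key = (intron.chrom, intron.start, intron.end, intron.strand)
                if key in seen:
                    continue
                seen.add(key)
            out.append(intron)
    return out


def splice_site_sequences(intron: IntronRecord, genome: Fasta | Mapping[str, str]) -> SpliceSiteSeqs:
    """Extract donor 9-mer and acceptor 23-mer around one intron, transcript orientation.

    Donor window: last 3 exonic + first 6 intronic bases; acceptor window:
    last 20 intronic + first 3 exonic bases.  On the - strand both windows are
    taken from the opposite genomic edges and reverse-complemented.
    """
    if isinstance(genome, Fasta):
        if intron.chrom not in genome:
            raise KeyError(f"chromosome {intron.chrom!r} missing from reference")
        chrom_seq = genome[intron.chrom]
        chrom_len = len(chrom_seq)

        def fetch(a: int, b: int) -> str:
            return str(chrom_seq[a:b])

    else:
        if intron.chrom not in genome:
            raise KeyError(f"chromosome {intron.chrom!r} missing from reference")
        raw = genome[intron.chrom]
        chrom_len = len(raw)

        def fetch(a: int, b: int) -> str:
            return raw[a:b]

    s, e = intron.start, intron.end
    if intron.strand == "+":
        d_lo, d_hi = s - 3, s + 6
        a_lo, a_hi = e - 20, e + 3
    else:
        d_lo, d_hi = e - 6, e + 3
        a_lo, a_hi = s - 3, s + 20
    for lo, hi, label in ((d_lo, d_hi, "donor"), (a_lo, a_hi, "acceptor")):
        if lo < 0 or hi > chrom_len:
            raise IndexError(
                f"{intron.transcript_id} intron {intron.ordinal}: {label} window "
                f"[{lo}, {hi}) outside reference bounds [0, {chrom_len})"
            )
    donor = normalize(fetch(d_lo, d_hi))
    acceptor = normalize(fetch(a_lo, a_hi))
    if intron.strand == "-":
        donor = revcomp(donor)
        acceptor = revcomp(acceptor)
    return SpliceSiteSeqs(donor9=donor, acceptor23=acceptor)


def intron_table(introns: Sequence[IntronRecord], deduplicated: bool | None = None) -> pd.DataFrame:
    """Tabulate intron records (TSV-ready); ``deduplicated`` is echoed as metadata."""
    df = pd.DataFrame(
        {
            "transcript_id": [i.transcript_id for i in introns],
            "chrom": [i.chrom for i in introns],
            "start": [i.start for i in introns],
            "end": [i.end for i in introns],
            "strand": [i.strand for i in introns],
            "ordinal": [i.ordinal for i in introns],
            "is_internal": [i.is_internal for i in introns],
            "length": [i.length for i in introns],
        }
    )
    if deduplicated is not None:
        df.attrs["deduplicated"] = bool(deduplicated)
        df["dedup_mode"] = "locus" if deduplicated else "per_transcript"
    return df


def write_gtf(models: Iterable[TranscriptModel], path: str | os.PathLike) -> None:
    """Write transcript models back to a GENCODE-dialect GTF (round-trip safe)."""
    with open(path, "w") as fh:
        for t in models:
            span = t.span
            attrs = f'gene_id "{t.transcript_id}.gene"; transcript_id "{t.transcript_id}";'
            fh.write(
                f"{t.chrom}\tretentia\ttranscript\t{span[0] + 1}\t{span[1]}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for n, (s, e) in enumerate(t.exons, start=1):
                fh.write(
                    f"{t.chrom}\tretentia\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                    f'{attrs} exon_number {n};\n'
                )
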