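"""Core genomic data model: intervals, transcript models and the
non-redundant reference transcriptome.

All coordinates are 0-based half-open throughout the package; format
readers/writers convert at the boundary (GTF is 1-based inclusive,
genePred/BED/bedGraph are native 0-based half-open).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


class RetspliceError(Exception):
    """Base class for package errors."""


class ValidationError(RetspliceError):
    """A record violates a structural invariant."""


def strands_compatible(a: str, b: str) -> bool:
    """Unstranded ('.') matches either strand; '+' and '-' never match."""
    return a == "." or b == "." or a == b


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval has empty chromosome name")
        if self.start >= self.end:
            raise ValidationError(
                f"interval start must precede end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class TranscriptModel:
    """A strand-aware exon chain with optional CDS bounds.

    ``exons`` are (start, end) pairs sorted by start, non-overlapping, with
    every intron (gap between consecutive exons) at least 1 bp. ``cds_start``
    and ``cds_end`` are genomic offsets of the coding span (half-open,
    including the stop codon) or ``None`` for non-coding transcripts.
    """

    id: str
    chrom: str
    strand: str
    exons: tuple
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    gene_id: str = ""
    source_track: str = ""

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"{self.id}: transcript has no exons")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if s >= e:
                raise ValidationError(f"{self.id}: exon start {s} >= end {e}")
            if prev_end is not None and s < prev_end + 1:
                raise ValidationError(
                    f"{self.id}: exons overlap or abut (end {prev_end}, next start {s})"
                )
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValidationError(f"{self.id}: cds_start/cds_end must both be set or absent")
        if self.cds_start is not None:
            if self.cds_start >= self.cds_end:
                raise ValidationError(f"{self.id}: cds_start >= cds_end")
            if not (self.start <= self.cds_start and self.cds_end <= self.end):
                raise ValidationError(f"{self.id}: CDS outside exon span")
            if not any(s <= self.cds_start < e for s, e in exons):
                raise ValidationError(f"{self.id}: cds_start not inside an exon")
            if not any(s < self.cds_end <= e for s, e in exons):
                raise ValidationError(f"{self.id}: cds_end not inside an exon")

    # -- basic geometry -------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def introns(self) -> list:
        """Gaps between consecutive exons as (start, end) pairs."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exon_intervals(self) -> list:
        return [
            GenomicInterval(self.chrom, s, e, self.strand) for s, e in self.exons
        ]

    def dedup_key(self) -> tuple:
        """Identity of the transcript: chrom, strand, exon chain and CDS bounds."""
        return (self.chrom, self.strand, self.exons, self.cds_start, self.cds_end)


# -- region classification ---------------------------------------------

CDS = "CDS"
UTR5 = "UTR5"
UTR3 = "UTR3"
INTRON = "intron"
OUTSIDE = "outside"
NONCODING = "noncoding"


def classify_region(position: int, tx: TranscriptModel) -> str:
    """Label a genomic position relative to a transcript.

    UTR5/UTR3 are assigned in transcription direction: on the minus strand
    the 5' UTR lies at genomic coordinates greater than the CDS.
    """
    if position < tx.start or position >= tx.end:
        return OUTSIDE
    in_exon = any(s <= position < e for s, e in tx.exons)
    if not in_exon:
        return INTRON
    if not tx.is_coding:
        return NONCODING
    if tx.cds_start <= position < tx.cds_end:
        return CDS
    if position < tx.cds_start:
        return UTR5 if tx.strand == "+" else UTR3
    return UTR3 if tx.strand == "+" else UTR5


def merge_intervals(pairs: Iterable) -> list:
    """Merge overlapping or book-ended (start, end) pairs into a sorted union."""
    pairs = sorted(pairs)
    merged: list = []
    for s, e in pairs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


class NRTranscriptome:
    """Non-redundant reference transcriptome built from one or more tracks.

    Two transcripts are duplicates iff they agree on chromosome, strand,
    the full exon chain, and CDS start/stop; the first-seen representative
    (in track input order) is kept. Derived catalogs:

    * ``exon_catalog`` — unique (chrom, start, end, strand) exon tuples
    * ``junction_catalog`` — unique annotated introns (chrom, start, end)
      mapped to the set of strands observed
    * ``loci`` — per-chromosome strand-merged transcript footprints; a
      position overlapping a footprint on either strand is not intergenic
      (an exon inside another gene's intron is not intergenic).
    """

    def __init__(self, transcripts: Sequence[TranscriptModel], dedup_report=None):
        if not transcripts:
            raise ValidationError("cannot build a reference from zero transcripts")
        self.transcripts: list = list(transcripts)
        self.by_id = {tx.id: tx for tx in self.transcripts}
        self.dedup_report = dedup_report

        self.exon_catalog: set = set()
        self.junction_catalog: dict = {}
        self._intron_hosts: dict = {}
        for tx in self.transcripts:
            for s, e in tx.exons:
                self.exon_catalog.add((tx.chrom, s, e, tx.strand))
            for s, e in tx.introns():
                key = (tx.chrom, s, e)
                self.junction_catalog.setdefault(key, set()).add(tx.strand)
                self._intron_hosts.setdefault(key, []).append(tx.id)

        # strand-merged locus footprints per chromosome
        self.loci: dict = {}
        per_chrom: dict = {}
        for tx in self.transcripts:
            per_chrom.setdefault(tx.chrom, []).append((tx.start, tx.end))
        for chrom, spans in per_chrom.items():
            self.loci[chrom] = merge_intervals(spans)

        self._locus_tree = {
            chrom: IntervalTree.from_tuples(spans)
            for chrom, spans in self.loci.items()
        }
        self._exon_tree: dict = {}
        for tx in self.transcripts:
            tree = self._exon_tree.setdefault(tx.chrom, IntervalTree())
            for s, e in tx.exons:
                tree.addi(s, e, tx.id)

        # splice-site indexes: intron left/right coordinate -> intron keys
        self._introns_by_left: dict = {}
        self._introns_by_right: dict = {}
        for (chrom, s, e), strands in self.junction_catalog.items():
            self._introns_by_left.setdefault((chrom, s), []).append((s, e))
            self._introns_by_right.setdefault((chrom, e), []).append((s, e))

    # -- queries --------------------------------------------------------

    @property
    def chroms(self) -> set:
        return set(self.loci)

    def intron_hosts(self, chrom: str, start: int, end: int) -> list:
        """Transcript ids having (start, end) as an intron."""
        return self._intron_hosts.get((chrom, start, end), [])

    def has_junction(self, chrom: str, start: int, end: int, strand: str = ".") -> bool:
        strands = self.junction_catalog.get((chrom, start, end))
        if strands is None:
            return False
        return any(strands_compatible(strand, s) for s in strands)

    def introns_sharing_left(self, chrom: str, pos: int) -> list:
        return self._introns_by_left.get((chrom, pos), [])

    def introns_sharing_right(self, chrom: str, pos: int) -> list:
        return self._introns_by_right.get((chrom, pos), [])

    def exons_at(self, chrom: str, start: int, end: int = None) -> set:
        """Transcript ids with an exon overlapping [start, end) (or the point)."""
        tree = self._exon_tree.get(chrom)
        if tree is None:
            return set()
        if end is None:
            hits = tree.at(start)
        else:
            hits = tree.overlap(start, end)
        return {h.data for h in hits}

    def transcripts_anchoring(self, chrom: str, pos: int) -> set:
        """Transcript ids with an exon containing ``pos`` (closed, boundaries
        included, so junction coordinates that abut an exon edge anchor)."""
        tree = self._exon_tree.get(chrom)
        if tree is None:
            return set()
        hits = tree.overlap(pos - 1, pos + 1)
        return {h.data for h in hits if h.begin <= pos <= h.end}

    def overlaps_locus(self, iv: GenomicInterval) -> bool:
        tree = self._locus_tree.get(iv.chrom)
        return bool(tree is not None and tree.overlap(iv.start, iv.end))

    def intergenic_intervals(self, chrom_lengths: dict) -> dict:
        """Complement of locus footprints per chromosome (strand-agnostic)."""
        out: dict = {}
        for chrom, length in chrom_lengths.items():
            spans = self.loci.get(chrom, [])
            gaps, cursor = [], 0
            for s, e in spans:
                if s > cursor:
                    gaps.append((cursor, s))
                cursor = max(cursor, e)
            if cursor < length:
                gaps.append((cursor, length))
            out[chrom] = gaps
        return out


def build_nonredundant(tracks: Sequence[Sequence[TranscriptModel]]) -> NRTranscriptome:
    """Collapse annotation tracks into a non-redundant reference.

    Tracks are processed in the given order; the first-seen transcript of
    each identity key is retained. Returns an :class:`NRTranscriptome`
    whose ``dedup_report`` lists (track, n_input, n_unique_contributed).
    """
    if not tracks:
        raise ValidationError("at least one annotation track is required")
    seen: dict = {}
    report = []
    for track in tracks:
        label = track[0].source_track if track else ""
        contributed = 0
        for tx in track:
            key = tx.dedup_key()
            if key not in seen:
                seen[key] = tx
                contributed += 1
        report.append({"track": label, "n_input": len(track), "n_unique": contributed})
    return NRTranscriptome(list(seen.values()), dedup_report=report)


def is_intergenic(iv: GenomicInterval, nrt: NRTranscriptome) -> bool:
    """True iff ``iv`` overlaps no locus footprint on either strand.

    Introns count as genic: an interval inside an annotated intron is not
    intergenic. Raises ``KeyError`` for a chromosome absent from the
    reference.
    """
    if iv.chrom not in nrt.loci:
        raise KeyError(f"chromosome {iv.chrom!r} not present in reference")
    return not nrt.overlaps_locus(iv)
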