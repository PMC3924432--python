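"""Synthetic study generator with planted ground truth.

Builds a self-contained miniature of a deep poly-A RNA-seq splicing
study: a random genome, several partially redundant annotation tracks, a
junction file whose annotated junctions carry ~two orders of magnitude
more reads in aggregate than the novel ones, a coverage track consistent
with the planted transcripts, and a machine-readable truth table.

The generator is constructive: every planted event is built so that its
downstream call (event class, reading-frame label, ratio class, capture
eligibility) follows from the construction, giving noise-free planted
truth. Design choices that make that guarantee hold:

* coding genes have a fully-UTR first and last exon, CDS exons whose
  lengths are multiples of 3 except two adjacent "frame-breaker" pairs
  (+1/+2 bp), so codon phase is zero at most introns, 1 or 2 within the
  breaker pairs — in-frame events are planted at phase-zero introns and
  frameshifts target the breakers;
* in-frame inserted sequence is written into the genome as stop-free
  codons; UTR "ORF-maintaining" inserts use a C/T-only alphabet ending in
  C, which cannot create a stop codon or ATG in any frame, even across
  insert boundaries;
* planted novel junctions are spaced so that no unintended pair falls in
  the 15-650 bp exon-pairing window (verified by a global post-check).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import write_gtf
from .coverage import CoverageTrack
from .junctions import Junction, write_junctions
from .model import (GenomicInterval, NRTranscriptome, RetspliceError,
                    TranscriptModel, build_nonredundant)
from .orf import STOP_CODONS, revcomp

BASES = np.frombuffer(b"ACGT", dtype="S1")
NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


class SimulationError(RetspliceError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults emulate the structure of a deep retinal-transcriptome
    splicing study at desk scale: a ~128-fold aggregate read excess of
    annotated over novel junctions, frame-consequence mixes of roughly
    18/30/52 (novel internal exons: in-frame / frameshift / UTR),
    15/53/32 (skips: in-frame / frameshift / ncRNA) and 23/56/21
    (alt sites), and a 40/60 split of alt-site events that add vs remove
    transcribed sequence.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 1_600_000
    n_genes: int = 100
    exons_per_gene: Tuple[int, int] = (18, 20)
    exon_len_range: Tuple[int, int] = (120, 240)
    intron_len_range: Tuple[int, int] = (800, 1400)
    intergenic_gap_range: Tuple[int, int] = (3000, 4800)
    frac_noncoding_genes: float = 0.18
    n_tracks: int = 3
    dup_probability: float = 0.6
    # planted event counts
    n_internal_exons: int = 200
    n_terminal_exons: int = 50
    n_skips: int = 150
    n_alt3: int = 75
    n_alt5: int = 75
    n_novel_genes: int = 20
    frac_coding_novel_genes: float = 0.15
    # frame-consequence design mixes
    internal_frame_mix: Tuple[float, float, float] = (0.18, 0.30, 0.52)  # orf/fs/utr
    utr_orf_frac: float = 0.34
    skip_frame_mix: Tuple[float, float, float] = (0.15, 0.53, 0.32)  # orf/fs/ncrna
    alt_frame_mix: Tuple[float, float, float] = (0.23, 0.56, 0.21)  # orf/fs/ncrna
    alt_adds_frac: float = 0.40
    # read model
    annotated_novel_read_ratio: float = 128.0
    novel_read_range: Tuple[int, int] = (5, 50)
    annotated_read_range: Tuple[int, int] = (200, 2000)
    # fractions of classifiable novel junctions planted at least as
    # abundant as their annotated counterpart
    frac_novel_major: float = 0.04
    frac_novel_equal: float = 0.09
    novel_depth_range: Tuple[int, int] = (8, 30)
    read_length: int = 100

    def __post_init__(self) -> None:
        for name in ("n_internal_exons", "n_terminal_exons", "n_skips",
                     "n_alt3", "n_alt5", "n_novel_genes"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        for mix in (self.internal_frame_mix, self.skip_frame_mix,
                    self.alt_frame_mix):
            if abs(sum(mix) - 1.0) > 1e-9:
                raise SimulationError("frame mix fractions must sum to 1")
        if not 0 <= self.dup_probability <= 1:
            raise SimulationError("dup_probability must be in [0, 1]")


@dataclass
class SimResult:
    config: SimConfig
    genome: Dict[str, str]
    chrom_lengths: Dict[str, int]
    tracks: List[List[TranscriptModel]]
    track_labels: List[str]
    junctions: List[Junction]
    coverage: CoverageTrack
    truth: pd.DataFrame

    def nrt(self) -> NRTranscriptome:
        return build_nonredundant(self.tracks)


# -- low-level sequence helpers -----------------------------------------


def _random_dna(rng, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def _nonstop_codons(rng, n_codons: int) -> str:
    idx = rng.integers(0, len(NONSTOP_CODONS), size=n_codons)
    return "".join(NONSTOP_CODONS[i] for i in idx)


def _ct_sequence(rng, n: int) -> str:
    """C/T-only sequence ending in C: contains no ATG and cannot form a
    stop codon in any frame, even combined with flanking bases."""
    seq = "".join("CT"[i] for i in rng.integers(0, 2, size=max(0, n - 1)))
    return seq + "C"


# -- gene plans ---------------------------------------------------------


@dataclass
class _GenePlan:
    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]  # genomic, left to right
    coding: bool
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    # allocator state over transcript-intron indices 1..N-1
    slot_state: Dict[int, str] = field(default_factory=dict)
    end_zone_used: bool = False
    depth: int = 0

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def tx_model(self, source_track: str) -> TranscriptModel:
        return TranscriptModel(
            id=f"{self.gene_id}.t1", chrom=self.chrom, strand=self.strand,
            exons=tuple(self.exons), cds_start=self.cds_start,
            cds_end=self.cds_end, gene_id=self.gene_id,
            source_track=source_track)

    # transcript index <-> genomic index (transcript exon 1 is 5'-most)
    def g_index(self, t: int) -> int:
        return t - 1 if self.strand == "+" else self.n_exons - t

    def t_exon(self, t: int) -> Tuple[int, int]:
        return self.exons[self.g_index(t)]

    def t_intron(self, t: int) -> Tuple[int, int]:
        """Genomic interval of the intron between transcript exons t, t+1."""
        if self.strand == "+":
            return (self.exons[t - 1][1], self.exons[t][0])
        gi = self.n_exons - t
        return (self.exons[gi - 1][1], self.exons[gi][0])

    # slot allocator
    def slot(self, t: int) -> str:
        return self.slot_state.get(t, "free")

    def take(self, introns: Sequence[int]) -> None:
        for t in introns:
            self.slot_state[t] = "used"
        lo, hi = min(introns) - 1, max(introns) + 1
        for t in (lo, hi):
            if 1 <= t <= self.n_exons - 1 and self.slot(t) == "free":
                self.slot_state[t] = "blocked"


def cds_intron_phases(tx: TranscriptModel) -> Dict[Tuple[int, int], int]:
    """Codon phase at each intron lying wholly inside the CDS span.

    Phase p means the donor-side exon ends p bases into a codon (p = 0:
    the junction is on a codon boundary), measured in transcription
    direction from the annotated start.
    """
    if not tx.is_coding:
        return {}
    exons = list(tx.exons)
    introns = tx.introns()
    phases: Dict[Tuple[int, int], int] = {}
    order = range(len(exons)) if tx.strand == "+" else range(len(exons) - 1, -1, -1)
    cum = 0
    for i in order:
        s, e = exons[i]
        cds_lo, cds_hi = max(s, tx.cds_start), min(e, tx.cds_end)
        cum += max(0, cds_hi - cds_lo)
        intron = None
        if tx.strand == "+" and i < len(introns):
            intron = introns[i]
        elif tx.strand == "-" and i > 0:
            intron = introns[i - 1]
        if intron and tx.cds_start <= intron[0] and intron[1] <= tx.cds_end:
            phases[intron] = cum % 3
    return phases


def plant_inframe_exon(tx: TranscriptModel, genome: Dict[str, bytearray],
                       length: int, rng,
                       intron: Optional[Tuple[int, int]] = None,
                       margin: int = 75) -> Optional[GenomicInterval]:
    """Write a stop-free, frame-preserving novel exon into an intron.

    Requires a coding transcript and an intron at codon phase zero with
    room for the exon plus ``margin`` bp on each side; the exon length is
    rounded up to a multiple of 3. Returns the planted interval, or None
    (with a warning) when no intron qualifies. The genome is modified in
    place.
    """
    if not tx.is_coding:
        raise SimulationError("plant_inframe_exon needs a coding transcript")
    length += (-length) % 3
    phases = cds_intron_phases(tx)
    if intron is not None:
        candidates = [intron] if phases.get(intron) == 0 else []
    else:
        candidates = [iv for iv, p in phases.items() if p == 0]
    candidates = [iv for iv in candidates
                  if iv[1] - iv[0] >= length + 2 * margin]
    if not candidates:
        warnings.warn(f"{tx.id}: no phase-zero intron can host a {length} bp exon")
        return None
    is_, ie = candidates[0]
    ns = is_ + (ie - is_ - length) // 2
    insert_tx = _nonstop_codons(rng, length // 3)
    seq = insert_tx if tx.strand == "+" else revcomp(insert_tx)
    genome[tx.chrom][ns:ns + length] = seq.encode()
    return GenomicInterval(tx.chrom, ns, ns + length, tx.strand)


# -- the simulator ------------------------------------------------------


def _mix_counts(total: int, fractions: Sequence[float]) -> List[int]:
    counts = [int(round(total * f)) for f in fractions]
    counts[0] += total - sum(counts)
    return counts


class _Simulator:
    def __init__(self, config: SimConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.genome: Dict[str, bytearray] = {}
        self.chrom_lengths: Dict[str, int] = {}
        self.genes: List[_GenePlan] = []
        self.gaps: List[dict] = []  # intergenic gaps available for reuse
        self.annotated_junctions: Dict[tuple, int] = {}
        self.novel_junctions: List[dict] = []  # {key, reads, kind, ...}
        self.truth_rows: List[dict] = []
        self.coverage_paint: List[tuple] = []  # (chrom, start, end, depth)

    # -- genome and genes ----------------------------------------------

    def build_genome(self) -> None:
        cfg = self.cfg
        for i in range(cfg.n_chroms):
            chrom = f"chr{i + 1}"
            self.genome[chrom] = bytearray(
                self.rng.choice(BASES, size=cfg.chrom_len).tobytes())
            self.chrom_lengths[chrom] = cfg.chrom_len

    def _gene_exon_lens(self, n_exons: int, coding: bool) -> List[int]:
        cfg = self.cfg
        lo, hi = cfg.exon_len_range
        lens = []
        for t in range(1, n_exons + 1):
            if not coding or t in (1, n_exons):
                lens.append(int(self.rng.integers(lo, hi + 1)))
            else:
                lens.append(3 * int(self.rng.integers(lo // 3, hi // 3 + 1)))
        if coding:
            # two adjacent frame-breaker pairs (+1/+2 then +2/+1 bp) keep
            # the total CDS length a multiple of 3 while giving nonzero
            # phase inside each pair
            b = [5, 6, 9, 10]
            for idx, extra in zip(b, (1, 2, 2, 1)):
                lens[idx - 1] += extra
        return lens

    def place_genes(self) -> None:
        cfg = self.cfg
        chroms = sorted(self.genome)
        per_chrom = {c: int(self.rng.integers(*cfg.intergenic_gap_range))
                     for c in chroms}
        n_noncoding = int(round(cfg.n_genes * cfg.frac_noncoding_genes))
        coding_flags = [i >= n_noncoding for i in range(cfg.n_genes)]
        self.rng.shuffle(coding_flags)
        ci = 0
        for gi in range(cfg.n_genes):
            coding = bool(coding_flags[gi])
            n_exons = int(self.rng.integers(cfg.exons_per_gene[0],
                                            cfg.exons_per_gene[1] + 1))
            n_exons = max(12, n_exons)
            lens = self._gene_exon_lens(n_exons, coding)
            introns = [int(self.rng.integers(*cfg.intron_len_range))
                       for _ in range(n_exons - 1)]
            span = sum(lens) + sum(introns)
            placed = False
            for _ in range(len(chroms)):
                chrom = chroms[ci % len(chroms)]
                start = per_chrom[chrom]
                if start + span + max(cfg.intergenic_gap_range) < self.chrom_lengths[chrom]:
                    placed = True
                    break
                ci += 1
            if not placed:
                raise SimulationError(
                    f"genome too small to place gene {gi + 1}/{cfg.n_genes}")
            strand = "+" if self.rng.integers(0, 2) == 0 else "-"
            exons = []
            pos = start
            for k, ln in enumerate(lens):
                exons.append((pos, pos + ln))
                pos += ln
                if k < len(introns):
                    pos += introns[k]
            gene = _GenePlan(gene_id=f"G{gi + 1:03d}", chrom=chrom,
                             strand=strand, exons=exons, coding=coding)
            if coding:
                # first and last genomic-order transcript exons are UTR;
                # CDS spans genomic exons 2..N-1 regardless of strand
                gene.cds_start = exons[1][0]
                gene.cds_end = exons[-2][1]
            self.genes.append(gene)
            gap = int(self.rng.integers(*cfg.intergenic_gap_range))
            self.gaps.append({"chrom": chrom, "start": pos, "end": pos + gap,
                              "left_gene": gene, "right_gene": None,
                              "used": False})
            per_chrom[chrom] = pos + gap
            ci += 1
        # link right-hand genes of gaps
        by_chrom: Dict[str, list] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for gap in self.gaps:
            for g in by_chrom.get(gap["chrom"], []):
                if g.exons[0][0] == gap["end"]:
                    gap["right_gene"] = g

    def write_gene_sequences(self) -> None:
        for gene in self.genes:
            n = gene.n_exons
            lens = [e - s for s, e in gene.exons]
            t_lens = lens if gene.strand == "+" else lens[::-1]
            if gene.coding:
                cds_len = sum(t_lens[1:-1])
                assert cds_len % 3 == 0
                cds = "ATG" + _nonstop_codons(self.rng, cds_len // 3 - 2) + "TAA"
                mrna = (_random_dna(self.rng, t_lens[0]) + cds
                        + _random_dna(self.rng, t_lens[-1]))
            else:
                mrna = _random_dna(self.rng, sum(t_lens))
            off = 0
            for t in range(1, n + 1):
                piece = mrna[off:off + t_lens[t - 1]]
                off += t_lens[t - 1]
                gs, ge = gene.t_exon(t)
                seq = piece if gene.strand == "+" else revcomp(piece)
                self.genome[gene.chrom][gs:ge] = seq.encode()

    # -- annotation tracks ----------------------------------------------

    def build_tracks(self) -> Tuple[List[List[TranscriptModel]], List[str]]:
        cfg = self.cfg
        labels = [f"track{chr(ord('A') + i)}" for i in range(cfg.n_tracks)]
        tracks: List[List[TranscriptModel]] = []
        for i, label in enumerate(labels):
            txs = []
            for gene in self.genes:
                if i == 0 or self.rng.random() < cfg.dup_probability:
                    txs.append(gene.tx_model(label))
            tracks.append(txs)
        return tracks, labels

    # -- event planting -------------------------------------------------

    def _phase_map(self, gene: _GenePlan) -> Dict[Tuple[int, int], int]:
        return cds_intron_phases(gene.tx_model("plan"))

    def _find_intron_slot(self, genes: Sequence[_GenePlan], want) -> Optional[tuple]:
        """First (gene, transcript-intron index) whose slot is free and
        satisfies predicate ``want(gene, t, genomic_intron, phase)``."""
        for gene in genes:
            phases = self._phase_map(gene) if gene.coding else {}
            for t in range(1, gene.n_exons):
                if gene.slot(t) != "free":
                    continue
                iv = gene.t_intron(t)
                phase = phases.get(iv)
                if want(gene, t, iv, phase):
                    return gene, t, iv
        return None

    def _exon_len_ending_at(self, gene: _GenePlan, pos: int) -> int:
        for s, e in gene.exons:
            if e == pos:
                return e - s
        return 0

    def _exon_len_starting_at(self, gene: _GenePlan, pos: int) -> int:
        for s, e in gene.exons:
            if s == pos:
                return e - s
        return 0

    def _eligible(self, feature_len: int, al: int, ar: int,
                  applies: bool = True) -> bool:
        from .capture import check_eligibility
        return check_eligibility(feature_len, al, ar,
                                 length_rule_applies=applies) is None

    def _add_novel_junction(self, chrom, start, end, strand, kind) -> dict:
        rec = {"chrom": chrom, "start": start, "end": end, "strand": strand,
               "kind": kind,
               "reads": int(self.rng.integers(*self.cfg.novel_read_range))}
        self.novel_junctions.append(rec)
        return rec

    def _paint(self, chrom, start, end, depth) -> None:
        self.coverage_paint.append((chrom, start, end, depth))

    def plant_internal_exons(self) -> None:
        cfg = self.cfg
        n_orf, n_fs, n_utr = _mix_counts(cfg.n_internal_exons,
                                         cfg.internal_frame_mix)
        n_utr_orf = int(round(n_utr * cfg.utr_orf_frac))
        coding = [g for g in self.genes if g.coding]
        ndepth = lambda: int(self.rng.integers(*cfg.novel_depth_range))

        def place(gene, t, iv, length, insert_tx):
            is_, ie = iv
            ns = is_ + (ie - is_ - length) // 2
            seq = insert_tx if gene.strand == "+" else revcomp(insert_tx)
            self.genome[gene.chrom][ns:ns + length] = seq.encode()
            gene.take([t])
            strand = gene.strand
            self._add_novel_junction(gene.chrom, is_, ns, strand, "internal_left")
            self._add_novel_junction(gene.chrom, ns + length, ie, strand,
                                     "internal_right")
            self._paint(gene.chrom, ns, ns + length, ndepth())
            return ns

        # in-frame CDS exons; ~10% are longer than the 400 bp capture cap
        for i in range(n_orf):
            length = 3 * int(self.rng.integers(33, 131))  # 99..390
            if i % 10 == 0:
                length = 3 * int(self.rng.integers(140, 200))  # 420..597
            hit = self._find_intron_slot(
                coding, lambda g, t, iv, p: p == 0
                and iv[1] - iv[0] >= length + 150)
            if hit is None:
                raise SimulationError("no slot for in-frame internal exon")
            gene, t, iv = hit
            ns = place(gene, t, iv, length, _nonstop_codons(self.rng, length // 3))
            self._truth_exon(gene, ns, length, "internal_exon",
                             "orf_maintained", "n/a", iv)

        # frameshifting CDS exons (length not a multiple of 3)
        for i in range(n_fs):
            length = 3 * int(self.rng.integers(33, 131)) + int(self.rng.integers(1, 3))
            if i % 10 == 0:
                length = 3 * int(self.rng.integers(140, 200)) + 1
            hit = self._find_intron_slot(
                coding, lambda g, t, iv, p: p is not None
                and iv[1] - iv[0] >= length + 150)
            if hit is None:
                raise SimulationError("no slot for frameshift internal exon")
            gene, t, iv = hit
            ns = place(gene, t, iv, length, _random_dna(self.rng, length))
            self._truth_exon(gene, ns, length, "internal_exon",
                             "frameshift_or_ptc", "n/a", iv)

        # UTR exons: transcript intron 1 (5' UTR) or N-1 (3' UTR)
        for i in range(n_utr):
            orf_like = i < n_utr_orf
            length = int(self.rng.integers(60, 200))
            hit = self._find_intron_slot(
                coding, lambda g, t, iv, p: t in (1, g.n_exons - 1)
                and p is None and iv[1] - iv[0] >= length + 150)
            if hit is None:
                raise SimulationError("no slot for UTR internal exon")
            gene, t, iv = hit
            if orf_like:
                insert = _ct_sequence(self.rng, length)
            else:
                insert = self._utr_stop_insert(gene, t, length)
            ns = place(gene, t, iv, length, insert)
            self._truth_exon(gene, ns, length, "internal_exon", "utr",
                             "utr_orf" if orf_like else "utr_disrupt", iv)

    def _utr_stop_insert(self, gene: _GenePlan, t: int, length: int) -> str:
        """Insert with a stop codon on the codon grid projected from the
        annotated start (transcript orientation)."""
        lens = [e - s for s, e in gene.exons]
        t_lens = lens if gene.strand == "+" else lens[::-1]
        t_ins = sum(t_lens[:t])  # offset of the insert in the modified mRNA
        if t == 1:  # 5' UTR: insertion shifts the CDS offset
            cds_off = t_lens[0] + length
        else:
            cds_off = t_lens[0]
        o0 = (cds_off - t_ins) % 3
        pos = o0 + 3 if o0 + 6 <= length else o0
        seq = list(_ct_sequence(self.rng, length))
        seq[pos:pos + 3] = "TAA"
        return "".join(seq)

    def _truth_exon(self, gene, ns, length, kind, frame, utr_sub, iv) -> None:
        al = self._exon_len_ending_at(gene, iv[0])
        ar = self._exon_len_starting_at(gene, iv[1])
        self.truth_rows.append({
            "kind": kind, "chrom": gene.chrom, "start": ns, "end": ns + length,
            "strand": gene.strand, "host": f"{gene.gene_id}.t1",
            "frame": frame, "utr_sub": utr_sub,
            "capture_eligible": self._eligible(length, al, ar),
            "detail": length})

    def plant_skips(self) -> None:
        cfg = self.cfg
        n_orf, n_fs, n_nc = _mix_counts(cfg.n_skips, cfg.skip_frame_mix)
        coding = [g for g in self.genes if g.coding]
        noncoding = [g for g in self.genes if not g.coding]

        def junction_for(gene: _GenePlan, t_first: int, m: int):
            """Skip transcript exons t_first..t_first+m-1."""
            introns = list(range(t_first - 1, t_first + m))
            if any(gene.slot(t) != "free" for t in introns):
                return None
            lo = gene.t_intron(t_first - 1)
            hi = gene.t_intron(t_first + m - 1)
            js, je = min(lo[0], hi[0]), max(lo[1], hi[1])
            skipped = sorted(gene.t_exon(t_first + k) for k in range(m))
            return introns, js, je, skipped

        def plant(gene, t_first, m, frame):
            got = junction_for(gene, t_first, m)
            if got is None:
                return False
            introns, js, je, skipped = got
            gene.take(introns)
            self._add_novel_junction(gene.chrom, js, je, gene.strand, "skip")
            al = self._exon_len_ending_at(gene, js)
            ar = self._exon_len_starting_at(gene, je)
            self.truth_rows.append({
                "kind": "skip", "chrom": gene.chrom, "start": js, "end": je,
                "strand": gene.strand, "host": f"{gene.gene_id}.t1",
                "frame": frame, "utr_sub": "n/a",
                "capture_eligible": self._eligible(0, al, ar, applies=False),
                "detail": m})
            return True

        def tx_exon_len(gene, t):
            s, e = gene.t_exon(t)
            return e - s

        # in-frame skips: 80% single multiple-of-3 exon at phase zero,
        # 20% the two-exon breaker pair (mean 1.2 exons skipped)
        n_orf2 = int(round(n_orf * 0.2))
        planted = 0
        for gene in coding * 3:
            if planted >= n_orf - n_orf2:
                break
            phases = self._phase_map(gene)
            for t in range(3, gene.n_exons - 1):
                if planted >= n_orf - n_orf2:
                    break
                if tx_exon_len(gene, t) % 3 != 0:
                    continue
                prev_intron = gene.t_intron(t - 1)
                if phases.get(prev_intron) != 0:
                    continue
                if plant(gene, t, 1, "orf_maintained"):
                    planted += 1
        if planted < n_orf - n_orf2:
            raise SimulationError("could not place all in-frame skips")
        planted2 = 0
        for gene in coding * 2:
            if planted2 >= n_orf2:
                break
            for t in range(3, gene.n_exons - 2):
                if planted2 >= n_orf2:
                    break
                l1, l2 = tx_exon_len(gene, t), tx_exon_len(gene, t + 1)
                if (l1 + l2) % 3 != 0:
                    continue
                prev_intron = gene.t_intron(t - 1)
                if self._phase_map(gene).get(prev_intron) != 0:
                    continue
                if plant(gene, t, 2, "orf_maintained"):
                    planted2 += 1
        if planted2 < n_orf2:
            raise SimulationError("could not place all two-exon in-frame skips")

        # frameshift skips: single breaker exons (length not 0 mod 3)
        planted = 0
        for gene in coding * 3:
            if planted >= n_fs:
                break
            for t in range(3, gene.n_exons - 1):
                if planted >= n_fs:
                    break
                if tx_exon_len(gene, t) % 3 == 0:
                    continue
                if plant(gene, t, 1, "frameshift_or_ptc"):
                    planted += 1
        if planted < n_fs:
            raise SimulationError("could not place all frameshift skips")

        # skips in non-coding transcripts
        planted = 0
        for gene in noncoding * 6:
            if planted >= n_nc:
                break
            for t in range(2, gene.n_exons):
                if planted >= n_nc:
                    break
                if plant(gene, t, 1, "ncrna"):
                    planted += 1
        if planted < n_nc:
            raise SimulationError("could not place all ncRNA skips")

    def plant_alt_sites(self) -> None:
        cfg = self.cfg
        requests = []
        for side, n_side in (("alt3", cfg.n_alt3), ("alt5", cfg.n_alt5)):
            n_orf, n_fs, n_nc = _mix_counts(n_side, cfg.alt_frame_mix)
            requests += [(side, "orf_maintained")] * n_orf
            requests += [(side, "frameshift_or_ptc")] * n_fs
            requests += [(side, "ncrna")] * n_nc
        coding = [g for g in self.genes if g.coding]
        noncoding = [g for g in self.genes if not g.coding]
        adds_pattern = [i < int(round(cfg.alt_adds_frac * 10)) for i in range(10)]
        for req_i, (side, frame) in enumerate(requests):
            adds = adds_pattern[req_i % 10]
            if frame == "orf_maintained":
                delta = 3 * int(self.rng.integers(5, 51))  # 15..150, phase safe
            else:
                delta = 3 * int(self.rng.integers(5, 51)) + int(self.rng.integers(1, 3))
            pool = noncoding if frame == "ncrna" else coding

            def want(g, t, iv, p, side=side, frame=frame, adds=adds, delta=delta):
                if frame == "ncrna":
                    if not (2 <= t <= g.n_exons - 2):
                        return False
                elif frame == "orf_maintained":
                    if p != 0:
                        return False
                elif p is None:  # frameshift must still hit the CDS
                    return False
                if adds:
                    return iv[1] - iv[0] >= delta + 120
                # removal shortens an exon; keep >= 60 bp of it
                vary_right = (side == "alt3") == (g.strand == "+")
                if vary_right:
                    adj = [e for e in g.exons if e[0] == iv[1]]
                else:
                    adj = [e for e in g.exons if e[1] == iv[0]]
                return bool(adj) and adj[0][1] - adj[0][0] > delta + 60

            hit = self._find_intron_slot(pool, want)
            if hit is None:
                raise SimulationError(f"no slot for alt site {side}/{frame}")
            gene, t, iv = hit
            is_, ie = iv
            vary_right = (side == "alt3") == (gene.strand == "+")
            if vary_right:
                if adds:
                    js, je = is_, ie - delta
                    added = (je, ie)
                else:
                    js, je = is_, ie + delta
                    added = None
                shift = je - ie
            else:
                if adds:
                    js, je = is_ + delta, ie
                    added = (is_, js)
                else:
                    js, je = is_ - delta, ie
                    added = None
                shift = js - is_
            if added is not None and frame == "orf_maintained":
                seg_tx = _nonstop_codons(self.rng, delta // 3)
                seq = seg_tx if gene.strand == "+" else revcomp(seg_tx)
                self.genome[gene.chrom][added[0]:added[1]] = seq.encode()
            if added is not None:
                self._paint(gene.chrom, added[0], added[1],
                            int(self.rng.integers(*cfg.novel_depth_range)))
            gene.take([t])
            self._add_novel_junction(gene.chrom, js, je, gene.strand, "alt")
            al = self._exon_len_ending_at(gene, is_)
            ar = self._exon_len_starting_at(gene, ie)
            self.truth_rows.append({
                "kind": side, "chrom": gene.chrom, "start": js, "end": je,
                "strand": gene.strand, "host": f"{gene.gene_id}.t1",
                "frame": frame, "utr_sub": "n/a",
                "capture_eligible": self._eligible(delta, al, ar),
                "detail": shift})

    def plant_terminal_exons(self) -> None:
        cfg = self.cfg
        ndepth = lambda: int(self.rng.integers(*cfg.novel_depth_range))
        planted = 0
        for gap in self.gaps:
            if planted >= cfg.n_terminal_exons:
                break
            # attach to the gene whose 3' end faces this gap
            left, right = gap["left_gene"], gap["right_gene"]
            gene = None
            if left is not None and left.strand == "+" and not left.end_zone_used:
                gene, rightward = left, True
            elif right is not None and right.strand == "-" and not right.end_zone_used:
                gene, rightward = right, False
            if gene is None or gap["used"]:
                continue
            # block the 3'-terminal intron so no other event sits next door
            t_last = gene.n_exons - 1
            if gene.slot(t_last) != "free":
                continue
            gene.take([t_last])
            gene.end_zone_used = True
            gap["used"] = True
            exon_len = int(self.rng.integers(60, 150))
            if rightward:
                last = gene.exons[-1]
                q = last[0] + (last[1] - last[0]) // 2
                p = gene.exons[-1][1] + 300
                if p + exon_len + 100 > gap["end"]:
                    continue
                self._add_novel_junction(gene.chrom, q, p, gene.strand, "terminal")
                ts, te = p, p + exon_len
            else:
                first = gene.exons[0]
                q = first[0] + (first[1] - first[0]) // 2
                p = gene.exons[0][0] - 300
                if p - exon_len - 100 < gap["start"]:
                    continue
                self._add_novel_junction(gene.chrom, p, q, gene.strand, "terminal")
                ts, te = p - exon_len, p
            self._paint(gene.chrom, ts, te, ndepth())
            self.truth_rows.append({
                "kind": "terminal_exon", "chrom": gene.chrom, "start": ts,
                "end": te, "strand": gene.strand, "host": f"{gene.gene_id}.t1",
                "frame": "", "utr_sub": "n/a",
                "capture_eligible": False, "detail": exon_len})
            planted += 1
        if planted < cfg.n_terminal_exons:
            raise SimulationError(
                f"placed only {planted}/{cfg.n_terminal_exons} terminal exons")

    def plant_novel_genes(self) -> None:
        cfg = self.cfg
        n_coding = int(round(cfg.n_novel_genes * cfg.frac_coding_novel_genes))
        planted = 0
        for gap in self.gaps:
            if planted >= cfg.n_novel_genes:
                break
            if gap["used"]:
                continue
            width = gap["end"] - gap["start"]
            # fit the exon count to the gap, keeping a 700 bp buffer to the
            # flanking annotated loci (> the 650 bp exon-pairing window)
            n_ex = int(self.rng.integers(3, 6))
            while n_ex > 3 and 150 * n_ex + 700 * (n_ex - 1) + 1400 > width:
                n_ex -= 1
            exon_lens = [int(self.rng.integers(60, 150)) for _ in range(n_ex)]
            intron_lens = [int(self.rng.integers(560, 700))
                           for _ in range(n_ex - 1)]
            span = sum(exon_lens) + sum(intron_lens)
            if span + 1400 > width:
                continue
            gap["used"] = True
            start = gap["start"] + 700
            exons = []
            pos = start
            for k, ln in enumerate(exon_lens):
                exons.append((pos, pos + ln))
                pos += ln
                if k < n_ex - 1:
                    pos += intron_lens[k]
            coding_gene = planted < n_coding
            chrom = gap["chrom"]
            total = sum(exon_lens)
            if coding_gene:
                orf = "ATG" + _nonstop_codons(self.rng, 89) + "TAA"  # 90 aa
                pad = total - len(orf)
                lead = int(self.rng.integers(0, max(1, pad - 1)))
                spliced = (_ct_sequence(self.rng, lead) + orf
                           + _ct_sequence(self.rng, pad - lead))
            else:
                spliced = _ct_sequence(self.rng, total)
            off = 0
            depth = int(self.rng.integers(*cfg.novel_depth_range))
            for (s, e) in exons:
                self.genome[chrom][s:e] = spliced[off:off + (e - s)].encode()
                off += e - s
                self._paint(chrom, s, e, depth)
            for k in range(n_ex - 1):
                self._add_novel_junction(chrom, exons[k][1], exons[k + 1][0],
                                         "+", "novel_gene")
            self.truth_rows.append({
                "kind": "novel_gene", "chrom": chrom, "start": exons[0][0],
                "end": exons[-1][1], "strand": "+", "host": "",
                "frame": "", "utr_sub": "n/a", "capture_eligible": False,
                "detail": f"{n_ex}:"
                          f"{'protein_coding' if coding_gene else 'lincRNA_candidate'}"})
            planted += 1
        if planted < cfg.n_novel_genes:
            raise SimulationError(
                f"placed only {planted}/{cfg.n_novel_genes} novel genes")

    # -- read counts, coverage, outputs ---------------------------------

    def assign_reads(self) -> None:
        cfg = self.cfg
        for gene in self.genes:
            tx = gene.tx_model("plan")
            for s, e in tx.introns():
                key = (gene.chrom, s, e, gene.strand)
                if key not in self.annotated_junctions:
                    self.annotated_junctions[key] = int(
                        self.rng.integers(*cfg.annotated_read_range))
        novel_total = sum(j["reads"] for j in self.novel_junctions)
        ann_total = sum(self.annotated_junctions.values())
        if novel_total > 0 and ann_total > 0:
            f = cfg.annotated_novel_read_ratio * novel_total / ann_total
            for k in self.annotated_junctions:
                self.annotated_junctions[k] = max(
                    1, int(round(self.annotated_junctions[k] * f)))

    def paint_coverage(self) -> CoverageTrack:
        depths = {c: np.zeros(n, dtype=np.int64)
                  for c, n in self.chrom_lengths.items()}
        for gene in self.genes:
            gene.depth = int(np.round(10 ** self.rng.uniform(0, 2.3)))
            for s, e in gene.exons:
                depths[gene.chrom][s:e] = gene.depth
        for chrom, s, e, d in self.coverage_paint:
            depths[chrom][s:e] = d
        return CoverageTrack(depths, read_length=self.cfg.read_length)

    def build_junction_list(self) -> List[Junction]:
        out = []
        i = 0
        for (chrom, s, e, strand), reads in sorted(self.annotated_junctions.items()):
            i += 1
            out.append(Junction(chrom=chrom, start=s, end=e, strand=strand,
                                reads=reads, name=f"ja{i:06d}"))
        for k, rec in enumerate(sorted(self.novel_junctions,
                                       key=lambda r: (r["chrom"], r["start"],
                                                      r["end"]))):
            out.append(Junction(chrom=rec["chrom"], start=rec["start"],
                                end=rec["end"], strand=rec["strand"],
                                reads=rec["reads"], name=f"jn{k + 1:06d}"))
        return out

    def annotate_ratio_classes(self) -> None:
        cfg = self.cfg
        # sharing annotated junction keys per novel junction
        ann_by_site: Dict[tuple, list] = {}
        for key in self.annotated_junctions:
            chrom, s, e, _ = key
            ann_by_site.setdefault((chrom, "L", s), []).append(key)
            ann_by_site.setdefault((chrom, "R", e), []).append(key)
        sharing: List[list] = []
        share_count: Dict[tuple, int] = {}
        for rec in self.novel_junctions:
            keys = sorted(set(
                ann_by_site.get((rec["chrom"], "L", rec["start"]), [])
                + ann_by_site.get((rec["chrom"], "R", rec["end"]), [])))
            sharing.append(keys)
            for k in keys:
                share_count[k] = share_count.get(k, 0) + 1
        # plant a minority of novel junctions at least as abundant as their
        # (sole, unshared) annotated counterpart, echoing the observed
        # novel:annotated abundance spectrum
        n_classifiable = sum(1 for keys in sharing if keys)
        n_major = int(round(cfg.frac_novel_major * n_classifiable))
        n_equal = int(round(cfg.frac_novel_equal * n_classifiable))
        for rec, keys in zip(self.novel_junctions, sharing):
            if n_major <= 0 and n_equal <= 0:
                break
            if len(keys) == 1 and share_count[keys[0]] == 1:
                self.annotated_junctions[keys[0]] = 30
                if n_major > 0:
                    rec["reads"] = 75  # 2.5-fold over the counterpart
                    n_major -= 1
                else:
                    rec["reads"] = 30  # equal abundance
                    n_equal -= 1
        by_site: Dict[tuple, int] = {}
        for (chrom, s, e, strand), reads in self.annotated_junctions.items():
            for key in ((chrom, "L", s), (chrom, "R", e)):
                by_site[key] = max(by_site.get(key, 0), reads)
        for rec in self.novel_junctions:
            best = max(by_site.get((rec["chrom"], "L", rec["start"]), 0),
                       by_site.get((rec["chrom"], "R", rec["end"]), 0))
            if best == 0:
                rec["ratio_class"] = ""
                continue
            fold = rec["reads"] / best
            rec["ratio_class"] = ("novel_major" if fold >= 2.0 else
                                  "annotated_major" if fold <= 0.5 else "equal")
        # attach computed ratio classes to matching truth rows
        cls_by_key = {(r["chrom"], r["start"], r["end"]): r["ratio_class"]
                      for r in self.novel_junctions}
        cls_by_left_end = {(r["chrom"], r["end"]): r["ratio_class"]
                           for r in self.novel_junctions
                           if r["kind"] == "internal_left"}
        for row in self.truth_rows:
            if row["kind"] in ("skip", "alt3", "alt5"):
                row["ratio_class"] = cls_by_key.get(
                    (row["chrom"], row["start"], row["end"]), "")
            elif row["kind"] == "internal_exon":
                row["ratio_class"] = cls_by_left_end.get(
                    (row["chrom"], row["start"]), "")
            else:
                row["ratio_class"] = ""

    def verify_spacing(self) -> None:
        """No unintended junction pair may fall in the exon-pairing window."""
        from .events import INTERNAL_EXON_MAX, INTERNAL_EXON_MIN
        recs = sorted(self.novel_junctions,
                      key=lambda r: (r["chrom"], r["start"]))
        intended = set()
        for a in recs:
            if a["kind"] == "internal_left":
                intended.add((a["chrom"], a["end"]))
            if a["kind"] == "novel_gene":
                intended.add((a["chrom"], a["end"]))
        for i, a in enumerate(recs):
            for b in recs:
                if a is b or a["chrom"] != b["chrom"]:
                    continue
                gap = b["start"] - a["end"]
                if INTERNAL_EXON_MIN <= gap <= INTERNAL_EXON_MAX:
                    ok = (a["kind"] == "internal_left" and b["kind"] == "internal_right"
                          and b["start"] - a["end"] == gap
                          and (a["chrom"], a["end"]) in intended) or (
                          a["kind"] == "novel_gene" and b["kind"] == "novel_gene")
                    if not ok:
                        raise SimulationError(
                            f"unintended junction pair at {a['chrom']}:"
                            f"{a['end']}+{gap} ({a['kind']} vs {b['kind']})")

    def run(self) -> SimResult:
        self.build_genome()
        self.place_genes()
        self.write_gene_sequences()
        self.plant_terminal_exons()
        self.plant_internal_exons()
        self.plant_skips()
        self.plant_alt_sites()
        self.plant_novel_genes()
        self.assign_reads()
        self.annotate_ratio_classes()
        self.verify_spacing()
        coverage = self.paint_coverage()
        tracks, labels = self.build_tracks()
        junctions = self.build_junction_list()
        truth = pd.DataFrame(self.truth_rows, columns=[
            "kind", "chrom", "start", "end", "strand", "host", "frame",
            "utr_sub", "ratio_class", "capture_eligible", "detail"])
        truth = truth.sort_values(["kind", "chrom", "start", "end"],
                                  kind="mergesort").reset_index(drop=True)
        genome = {c: bytes(v).decode() for c, v in self.genome.items()}
        return SimResult(config=self.cfg, genome=genome,
                         chrom_lengths=dict(self.chrom_lengths),
                         tracks=tracks, track_labels=labels,
                         junctions=junctions, coverage=coverage, truth=truth)


def simulate(config: SimConfig, outdir: Optional[str] = None,
             max_attempts: int = 3) -> SimResult:
    """Generate the synthetic study; optionally write all files to
    ``outdir`` (FASTA genome, one GTF per track, junction BED, bedGraph
    coverage, truth TSV). Fully deterministic given ``config.seed``."""
    last_exc: Optional[Exception] = None
    for attempt in range(max_attempts):
        cfg = config if attempt == 0 else dc_replace(
            config, seed=config.seed + 7919 * attempt)
        try:
            result = _Simulator(cfg).run()
            break
        except SimulationError as exc:
            last_exc = exc
    else:
        raise SimulationError(
            f"simulation failed after {max_attempts} attempts: {last_exc}")
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "genome.fa", "w") as fh:
            for chrom in sorted(result.genome):
                fh.write(f">{chrom}\n")
                seq = result.genome[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        for label, track in zip(result.track_labels, result.tracks):
            write_gtf(track, str(out / f"{label}.gtf"))
        write_junctions(result.junctions, str(out / "junctions.bed"))
        result.coverage.to_bedgraph(str(out / "coverage.bedGraph"))
        result.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return result


# -- capture simulation and subsampling ---------------------------------


def simulate_capture(junctions: Sequence[Junction],
                     sample_dropout: Dict[str, float],
                     seed: int = 0) -> Dict[str, List[Junction]]:
    """Per-sample capture junction calls with planted dropout: each
    junction is independently missed with the sample's dropout
    probability."""
    rng = np.random.default_rng(seed)
    out: Dict[str, List[Junction]] = {}
    for sample in sorted(sample_dropout):
        p = sample_dropout[sample]
        kept = [j for j in junctions if rng.random() >= p]
        out[sample] = [dc_replace(j, sample=sample) for j in kept]
    return out


def nested_subsamples(coverage: CoverageTrack, junctions: Sequence[Junction],
                      fractions: Sequence[float],
                      total_reads: Optional[int] = None) -> List[dict]:
    """Deterministic nested subsamples: depth and junction reads scaled by
    each fraction and floored, so every subsample is a prefix of the next
    and the fraction-1.0 endpoint reproduces the input exactly."""
    total = total_reads or coverage.total_mapped_reads
    out = []
    for f in sorted(fractions):
        if not 0 < f <= 1:
            raise RetspliceError("fractions must be in (0, 1]")
        depths = {c: (v * f).astype(np.int64) if f < 1.0 else v.copy()
                  for c, v in coverage.depths.items()}
        js = []
        for j in junctions:
            r = int(j.reads * f) if f < 1.0 else j.reads
            if r > 0:
                js.append(dc_replace(j, reads=r))
        out.append({"fraction": f, "n_reads": int(round(total * f)),
                    "coverage": CoverageTrack(depths,
                                              read_length=coverage.read_length,
                                              total_mapped_reads=int(round(total * f))),
                    "junctions": js})
    return out


# -- planted-truth comparison -------------------------------------------


def compare_to_truth(result: SimResult, events, novel_genes=None,
                     frame_calls: Optional[Dict[tuple, tuple]] = None) -> pd.DataFrame:
    """Recall / false-positive table of recovered calls vs planted truth.

    ``events`` is the :class:`~retsplice.events.EventSet` from the
    classifier; ``novel_genes`` the chained gene models; ``frame_calls``
    an optional mapping of truth key -> (label, utr_sub) for frame
    agreement accounting. Keys are (kind, chrom, start, end): exon
    coordinates for exon classes, junction coordinates for skips and alt
    sites, gene spans for novel genes.
    """
    truth = result.truth
    recovered: Dict[str, set] = {
        "internal_exon": {(e.exon.chrom, e.exon.start, e.exon.end)
                          for e in events.internal_exons},
        "terminal_exon": {(e.exon.chrom, e.exon.start, e.exon.end)
                          for e in events.terminal_exons if e.host_transcripts},
        "skip": {(s.junction.chrom, s.junction.start, s.junction.end)
                 for s in events.skips},
        "alt3": {(a.junction.chrom, a.junction.start, a.junction.end)
                 for a in events.alt_sites if a.side == "alt3"},
        "alt5": {(a.junction.chrom, a.junction.start, a.junction.end)
                 for a in events.alt_sites if a.side == "alt5"},
    }
    if novel_genes is not None:
        recovered["novel_gene"] = {
            (g.chrom, g.span[0], g.span[1]) for g in novel_genes}
    rows = []
    for kind, rec in recovered.items():
        sub = truth[truth["kind"] == kind]
        planted = {(r.chrom, r.start, r.end) for r in sub.itertuples()}
        tp = len(planted & rec)
        rows.append({"kind": kind, "n_planted": len(planted),
                     "n_recovered": len(rec), "n_matched": tp,
                     "recall_pct": 100.0 * tp / len(planted) if planted else 100.0,
                     "false_positives": len(rec - planted)})
    if frame_calls is not None:
        agree = total = 0
        for r in truth.itertuples():
            key = (r.kind, r.chrom, r.start, r.end)
            if key in frame_calls and r.frame:
                total += 1
                label, utr_sub = frame_calls[key]
                ok = label == r.frame and (r.frame != "utr" or utr_sub == r.utr_sub)
                agree += ok
        rows.append({"kind": "frame_agreement", "n_planted": total,
                     "n_recovered": total, "n_matched": agree,
                     "recall_pct": 100.0 * agree / total if total else 100.0,
                     "false_positives": total - agree})
    return pd.DataFrame(rows)


# -- boundary decoys ----------------------------------------------------


def boundary_decoys() -> dict:
    """Deterministic decoy set probing the closed classifier windows.

    Junction pairs at gaps 14/15/650/651 bp and alternate-site shifts of
    14/15/350/351 bp, each on its own well-separated host transcript.
    Returns the host reference, the decoy junctions, and the expected
    detection outcome per labelled decoy.
    """
    chrom = "chrT"
    txs = []
    junctions: List[Junction] = []
    expected = {}
    pos = 10_000
    # exon-pairing gap decoys
    for gap in (14, 15, 650, 651):
        e1 = (pos, pos + 300)
        e2 = (pos + 300 + 2000, pos + 300 + 2000 + 300)
        txs.append(TranscriptModel(id=f"tx_gap{gap}", chrom=chrom, strand="+",
                                   exons=(e1, e2)))
        a = Junction(chrom=chrom, start=e1[1], end=e1[1] + 200, strand="+",
                     reads=10, name=f"gapA{gap}")
        b = Junction(chrom=chrom, start=a.end + gap,
                     end=min(a.end + gap + 200, e2[0]), strand="+",
                     reads=10, name=f"gapB{gap}")
        junctions += [a, b]
        expected[f"gap_{gap}"] = {
            "detect": 15 <= gap <= 650,
            "key": (chrom, a.end, a.end + gap)}
        pos += 25_000
    # alt-site shift decoys (acceptor pulled into the intron: adds sequence)
    for shift in (14, 15, 350, 351):
        e1 = (pos, pos + 300)
        e2 = (pos + 300 + 1500, pos + 300 + 1500 + 300)
        txs.append(TranscriptModel(id=f"tx_shift{shift}", chrom=chrom,
                                   strand="+", exons=(e1, e2)))
        j = Junction(chrom=chrom, start=e1[1], end=e2[0] - shift, strand="+",
                     reads=10, name=f"alt{shift}")
        junctions.append(j)
        expected[f"shift_{shift}"] = {
            "detect": 15 <= shift <= 350,
            "key": j.coord_key()}
        pos += 25_000
    nrt = build_nonredundant([txs])
    return {"nrt": nrt, "junctions": junctions, "expected": expected}
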