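"""Detection and classification of novel splicing events.

Four event classes are called from junctions absent from the reference:

* novel internal exons — two novel junctions whose facing ends are
  15-650 bp apart delimit a new exon between them (closed bounds);
* novel terminal exons — an unpaired novel-junction end with consistent
  coverage extending away from the junction;
* exon skipping — a novel junction joining two non-adjacent exon
  boundaries of one transcript, spanning >= 1 whole annotated exon;
* alternate 3'/5' splice sites — one junction end on an annotated splice
  site, the other 15-350 bp from the annotated partner site (closed
  bounds), shortening or lengthening the adjacent exon.

Event priority is internal exon > skip > alt site: a junction consumed by
a higher-priority call is not re-reported by a lower one.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .coverage import CoverageTrack
from .junctions import Junction
from .model import (GenomicInterval, NRTranscriptome, RetspliceError,
                    strands_compatible)

INTERNAL_EXON_MIN = 15
INTERNAL_EXON_MAX = 650
ALT_SHIFT_MIN = 15
ALT_SHIFT_MAX = 350

INTERNAL = "internal"
TERMINAL = "terminal"
ALT3 = "alt3"
ALT5 = "alt5"
ADDS = "adds_sequence"
REMOVES = "removes_sequence"


@dataclass(frozen=True)
class NovelExon:
    exon: GenomicInterval
    left_junction: Optional[Junction]
    right_junction: Optional[Junction]
    host_transcripts: tuple
    kind: str  # internal | terminal

    def __post_init__(self) -> None:
        if self.kind == INTERNAL:
            n = len(self.exon)
            if not (INTERNAL_EXON_MIN <= n <= INTERNAL_EXON_MAX):
                raise RetspliceError(f"internal exon length {n} outside bounds")
            if (self.left_junction.end != self.exon.start
                    or self.right_junction.start != self.exon.end):
                raise RetspliceError("internal exon does not abut its junctions")

    @property
    def reads(self) -> int:
        return sum(j.reads for j in (self.left_junction, self.right_junction) if j)


@dataclass(frozen=True)
class ExonSkip:
    junction: Junction
    host_transcript: str
    skipped_exons: tuple  # (start, end) pairs of the host's enclosed exons
    n_skipped: int
    secondary_hosts: tuple = ()

    def __post_init__(self) -> None:
        if self.n_skipped < 1:
            raise RetspliceError("exon skip must enclose >= 1 exon")


@dataclass(frozen=True)
class AltSpliceSite:
    junction: Junction
    host_transcript: str
    anchored_end: str  # left | right
    shift_bp: int  # novel site minus annotated partner site (genomic)
    side: str  # alt3 | alt5
    effect: str  # adds_sequence | removes_sequence
    annotated_intron: tuple  # (start, end) of the matched annotated intron
    secondary_hosts: tuple = ()

    def __post_init__(self) -> None:
        if not (ALT_SHIFT_MIN <= abs(self.shift_bp) <= ALT_SHIFT_MAX):
            raise RetspliceError(f"alt-site shift {self.shift_bp} outside bounds")


@dataclass
class EventSet:
    """All calls from one classification run plus novel-gene candidates."""

    internal_exons: List[NovelExon] = field(default_factory=list)
    terminal_exons: List[NovelExon] = field(default_factory=list)
    skips: List[ExonSkip] = field(default_factory=list)
    alt_sites: List[AltSpliceSite] = field(default_factory=list)
    unanchored_exons: List[NovelExon] = field(default_factory=list)

    @property
    def anchored_internal(self) -> List[NovelExon]:
        return self.internal_exons


def _merged_strand(a: str, b: str) -> str:
    if a == ".":
        return b
    if b == "." or a == b:
        return a
    raise RetspliceError("incompatible strands")


# -- novel internal exons ----------------------------------------------


def find_novel_internal_exons(novel_junctions: Sequence[Junction],
                              nrt: Optional[NRTranscriptome] = None
                              ) -> List[NovelExon]:
    """Pair novel junctions whose facing ends are 15-650 bp apart.

    Every ordered pair (A, B) on one chromosome with compatible strands
    where ``B.start - A.end`` lies in the closed window yields exon
    [A.end, B.start). Host transcripts are those with annotated exons
    anchoring both outer junction ends (A.start and B.end, boundary
    positions included); pairs without a common host are still returned
    (they feed novel-gene chaining) with an empty host tuple. Identical
    exon intervals from different junction pairs are deduplicated.
    """
    by_chrom: Dict[str, List[Junction]] = {}
    for j in novel_junctions:
        by_chrom.setdefault(j.chrom, []).append(j)
    dedup: Dict[tuple, NovelExon] = {}
    for chrom, js in by_chrom.items():
        js_sorted = sorted(js, key=lambda j: (j.start, j.end))
        starts = [j.start for j in js_sorted]
        for a in js:
            lo = bisect_left(starts, a.end + INTERNAL_EXON_MIN)
            hi = bisect_right(starts, a.end + INTERNAL_EXON_MAX)
            for b in js_sorted[lo:hi]:
                if not strands_compatible(a.strand, b.strand):
                    continue
                strand = _merged_strand(a.strand, b.strand)
                hosts: tuple = ()
                if nrt is not None:
                    left = {
                        t for t in nrt.transcripts_anchoring(chrom, a.start)
                        if strands_compatible(strand, nrt.by_id[t].strand)
                    }
                    if left:
                        right = nrt.transcripts_anchoring(chrom, b.end)
                        hosts = tuple(sorted(left & right))
                exon = GenomicInterval(chrom, a.end, b.start, strand)
                key = (chrom, a.end, b.start)
                prev = dedup.get(key)
                if prev is None:
                    dedup[key] = NovelExon(exon, a, b, hosts, INTERNAL)
                else:
                    merged_hosts = tuple(sorted(set(prev.host_transcripts) | set(hosts)))
                    keep_a = prev.left_junction if prev.left_junction.reads >= a.reads else a
                    keep_b = prev.right_junction if prev.right_junction.reads >= b.reads else b
                    dedup[key] = NovelExon(prev.exon, keep_a, keep_b,
                                           merged_hosts, INTERNAL)
    return sorted(dedup.values(), key=lambda e: (e.exon.chrom, e.exon.start, e.exon.end))


# -- exon skipping ------------------------------------------------------


class _BoundaryIndex:
    """Exon start/end position -> transcript ids, per chromosome."""

    def __init__(self, nrt: NRTranscriptome):
        self.end_idx: Dict[tuple, Set[str]] = {}
        self.start_idx: Dict[tuple, Set[str]] = {}
        self.boundaries: Dict[str, Set[int]] = {}
        for tx in nrt.transcripts:
            bset = self.boundaries.setdefault(tx.id, set())
            for s, e in tx.exons:
                self.start_idx.setdefault((tx.chrom, s), set()).add(tx.id)
                self.end_idx.setdefault((tx.chrom, e), set()).add(tx.id)
                bset.add(s)
                bset.add(e)

    def ends_at(self, chrom: str, pos: int) -> Set[str]:
        return self.end_idx.get((chrom, pos), set())

    def starts_at(self, chrom: str, pos: int) -> Set[str]:
        return self.start_idx.get((chrom, pos), set())


def find_exon_skips(novel_junctions: Sequence[Junction], nrt: NRTranscriptome,
                    exclude: Optional[Set[tuple]] = None) -> List[ExonSkip]:
    """A novel junction from one exon end to a later exon start of the same
    transcript, enclosing >= 1 whole annotated exon, is an exon-skipping
    event. One event is reported per junction, attributed to the host
    transcript with the most skipped exons (other hosts listed as
    secondary).
    """
    idx = _BoundaryIndex(nrt)
    out = []
    for j in novel_junctions:
        if exclude and j.key() in exclude:
            continue
        hosts = idx.ends_at(j.chrom, j.start) & idx.starts_at(j.chrom, j.end)
        best: Optional[ExonSkip] = None
        qualifying = []
        for txid in sorted(hosts):
            tx = nrt.by_id[txid]
            if not strands_compatible(j.strand, tx.strand):
                continue
            skipped = tuple(
                (s, e) for s, e in tx.exons if s >= j.start and e <= j.end
            )
            if skipped:
                qualifying.append((len(skipped), txid, skipped))
        if not qualifying:
            continue
        qualifying.sort(key=lambda q: (-q[0], q[1]))
        n, txid, skipped = qualifying[0]
        secondary = tuple(q[1] for q in qualifying[1:])
        out.append(ExonSkip(j, txid, skipped, n, secondary))
    return sorted(out, key=lambda s: (s.junction.chrom, s.junction.start,
                                      s.junction.end))


# -- alternate 3'/5' splice sites ---------------------------------------


def find_alt_sites(novel_junctions: Sequence[Junction], nrt: NRTranscriptome,
                   exclude: Optional[Set[tuple]] = None) -> List[AltSpliceSite]:
    """One junction end on an annotated splice site, the other shifted
    15-350 bp from the annotated partner site.

    Side is strand-aware: the variant acceptor (intron 3' end in
    transcription direction) is alt3, the variant donor alt5. The effect
    is removes_sequence when the novel intron is longer than the annotated
    one, else adds_sequence. One event is reported per junction; when
    several annotated introns qualify the smallest absolute shift wins.
    """
    idx = _BoundaryIndex(nrt)
    out = []
    for j in novel_junctions:
        if exclude and j.key() in exclude:
            continue
        candidates = []
        # shared left coordinate (annotated intron starts at j.start)
        for (a_s, a_e) in nrt.introns_sharing_left(j.chrom, j.start):
            shift = j.end - a_e
            if not (ALT_SHIFT_MIN <= abs(shift) <= ALT_SHIFT_MAX):
                continue
            for txid in nrt.intron_hosts(j.chrom, a_s, a_e):
                tx = nrt.by_id[txid]
                if not strands_compatible(j.strand, tx.strand):
                    continue
                if j.end in idx.boundaries.get(txid, ()):  # both ends annotated
                    continue
                side = ALT3 if tx.strand == "+" else ALT5
                effect = REMOVES if j.length > (a_e - a_s) else ADDS
                candidates.append((abs(shift), txid, "left", shift, side,
                                   effect, (a_s, a_e)))
        # shared right coordinate (annotated intron ends at j.end)
        for (a_s, a_e) in nrt.introns_sharing_right(j.chrom, j.end):
            shift = j.start - a_s
            if not (ALT_SHIFT_MIN <= abs(shift) <= ALT_SHIFT_MAX):
                continue
            for txid in nrt.intron_hosts(j.chrom, a_s, a_e):
                tx = nrt.by_id[txid]
                if not strands_compatible(j.strand, tx.strand):
                    continue
                if j.start in idx.boundaries.get(txid, ()):
                    continue
                side = ALT5 if tx.strand == "+" else ALT3
                effect = REMOVES if j.length > (a_e - a_s) else ADDS
                candidates.append((abs(shift), txid, "right", shift, side,
                                   effect, (a_s, a_e)))
        if not candidates:
            continue
        candidates.sort(key=lambda c: (c[0], c[1]))
        top = candidates[0]
        same = [c for c in candidates if (c[0], c[2], c[3]) == (top[0], top[2], top[3])]
        secondary = tuple(c[1] for c in same[1:])
        out.append(AltSpliceSite(j, top[1], top[2], top[3], top[4], top[5],
                                 top[6], secondary))
    return sorted(out, key=lambda a: (a.junction.chrom, a.junction.start,
                                      a.junction.end))


# -- novel terminal exons -----------------------------------------------


def _utr_spans(tx) -> List[tuple]:
    if not tx.is_coding:
        return []
    spans = []
    if tx.start < tx.cds_start:
        spans.append((tx.start, tx.cds_start))
    if tx.cds_end < tx.end:
        spans.append((tx.cds_end, tx.end))
    return spans


def find_novel_terminal_exons(novel_junctions: Sequence[Junction],
                              coverage: CoverageTrack,
                              nrt: NRTranscriptome,
                              internal_exons: Sequence[NovelExon] = (),
                              used_junctions: Optional[Set[tuple]] = None,
                              min_consistent_bp: int = 50,
                              depth_threshold: float = 5.0,
                              max_len: int = INTERNAL_EXON_MAX
                              ) -> List[NovelExon]:
    """Call terminal exons at unpaired novel-junction ends.

    A candidate is a junction end with no internal-exon pairing partner
    and no annotated exon at the landing position. Acceptance requires:
    (1) if not attached to an annotated transcript, the connected novel
    chain must comprise >= 3 putative exons; (2) contiguous coverage at or
    above ``depth_threshold`` for >= ``min_consistent_bp`` bases from the
    junction-proximal edge; (3) if attached to an annotated transcript,
    the exon must lie outside the host's annotated UTR span and must not
    overlap any annotated exon. The exon extent is the covered run,
    capped at ``max_len``.
    """
    used_junctions = used_junctions or set()
    paired_sides: Set[tuple] = set()
    comp_parent: Dict[tuple, tuple] = {}

    def find(x):
        while comp_parent.setdefault(x, x) != x:
            comp_parent[x] = comp_parent[comp_parent[x]]
            x = comp_parent[x]
        return x

    def union(a, b):
        comp_parent[find(a)] = find(b)

    n_internal_in_comp: Dict[tuple, int] = {}
    for e in internal_exons:
        a, b = e.left_junction, e.right_junction
        paired_sides.add((a.key(), "R"))
        paired_sides.add((b.key(), "L"))
        union(a.key(), b.key())
    for e in internal_exons:
        root = find(e.left_junction.key())
        n_internal_in_comp[root] = n_internal_in_comp.get(root, 0) + 1

    # free sides per component (each is one putative terminal exon slot)
    free_sides: Dict[tuple, int] = {}
    candidates = []
    for j in novel_junctions:
        if j.key() in used_junctions:
            continue
        for side, edge, direction, anchor_pos in (
            ("L", j.start, -1, j.end),
            ("R", j.end, +1, j.start),
        ):
            if (j.key(), side) in paired_sides:
                continue
            if nrt.transcripts_anchoring(j.chrom, edge):
                continue  # junction lands in annotation; not a terminal end
            root = find(j.key())
            free_sides[root] = free_sides.get(root, 0) + 1
            candidates.append((j, side, edge, direction, anchor_pos))

    out = []
    for j, side, edge, direction, anchor_pos in candidates:
        hosts = tuple(sorted(
            t for t in nrt.transcripts_anchoring(j.chrom, anchor_pos)
            if strands_compatible(j.strand, nrt.by_id[t].strand)
        ))
        if not hosts:
            root = find(j.key())
            n_putative = n_internal_in_comp.get(root, 0) + free_sides.get(root, 0)
            if n_putative < 3:
                continue
        run = coverage.covered_run(j.chrom, edge, direction,
                                   depth_threshold, max_len=max_len)
        if run < min_consistent_bp:
            continue
        if direction > 0:
            exon = GenomicInterval(j.chrom, edge, edge + run, j.strand)
        else:
            exon = GenomicInterval(j.chrom, edge - run, edge, j.strand)
        if nrt.exons_at(j.chrom, exon.start, exon.end):
            continue  # overlaps annotation: not a novel terminal exon
        if hosts and any(
            exon.start < ue and us < exon.end
            for t in hosts for us, ue in _utr_spans(nrt.by_id[t])
        ):
            continue
        left = j if side == "R" else None
        right = j if side == "L" else None
        out.append(NovelExon(exon, left, right, hosts, TERMINAL))
    return sorted(out, key=lambda e: (e.exon.chrom, e.exon.start, e.exon.end))


# -- orchestration ------------------------------------------------------


def classify_all(novel_junctions: Sequence[Junction], nrt: NRTranscriptome,
                 coverage: Optional[CoverageTrack] = None,
                 terminal_depth_threshold: float = 5.0) -> EventSet:
    """Run the full classification with event priority applied."""
    all_internal = find_novel_internal_exons(novel_junctions, nrt)
    anchored = [e for e in all_internal if e.host_transcripts]
    unanchored = [e for e in all_internal if not e.host_transcripts]

    used: Set[tuple] = set()
    for e in anchored:
        used.add(e.left_junction.key())
        used.add(e.right_junction.key())
    skips = find_exon_skips(novel_junctions, nrt, exclude=used)
    for s in skips:
        used.add(s.junction.key())
    alts = find_alt_sites(novel_junctions, nrt, exclude=used)
    for a in alts:
        used.add(a.junction.key())

    terminals: List[NovelExon] = []
    if coverage is not None:
        terminals = find_novel_terminal_exons(
            novel_junctions, coverage, nrt, internal_exons=all_internal,
            used_junctions=used, depth_threshold=terminal_depth_threshold)

    return EventSet(internal_exons=anchored, terminal_exons=terminals,
                    skips=skips, alt_sites=alts, unanchored_exons=unanchored)


def summarize_events(events: EventSet) -> pd.DataFrame:
    """Per-class event counts plus unique host-transcript counts."""
    anchored_terms = [t for t in events.terminal_exons if t.host_transcripts]
    rows = [
        {"event_class": "novel_exon_internal",
         "n_events": len(events.internal_exons),
         "n_host_transcripts": len({h for e in events.internal_exons
                                    for h in e.host_transcripts})},
        {"event_class": "novel_exon_terminal",
         "n_events": len(events.terminal_exons),
         "n_host_transcripts": len({h for e in anchored_terms
                                    for h in e.host_transcripts})},
        {"event_class": "exon_skip",
         "n_events": len(events.skips),
         "n_host_transcripts": len({s.host_transcript for s in events.skips})},
        {"event_class": "alt_site",
         "n_events": len(events.alt_sites),
         "n_host_transcripts": len({a.host_transcript for a in events.alt_sites})},
        {"event_class": "alt3",
         "n_events": sum(1 for a in events.alt_sites if a.side == ALT3),
         "n_host_transcripts": len({a.host_transcript for a in events.alt_sites
                                    if a.side == ALT3})},
        {"event_class": "alt5",
         "n_events": sum(1 for a in events.alt_sites if a.side == ALT5),
         "n_host_transcripts": len({a.host_transcript for a in events.alt_sites
                                    if a.side == ALT5})},
    ]
    return pd.DataFrame(rows)


def events_table(events: EventSet) -> pd.DataFrame:
    """Master per-event table with deterministic ids (sorted by position)."""
    rows = []
    for e in events.internal_exons + events.terminal_exons:
        cls = f"novel_exon_{e.kind}"
        rows.append({"event_class": cls, "chrom": e.exon.chrom,
                     "start": e.exon.start, "end": e.exon.end,
                     "strand": e.exon.strand, "reads": e.reads,
                     "hosts": ",".join(e.host_transcripts) or ".",
                     "detail": len(e.exon)})
    for s in events.skips:
        rows.append({"event_class": "exon_skip", "chrom": s.junction.chrom,
                     "start": s.junction.start, "end": s.junction.end,
                     "strand": s.junction.strand, "reads": s.junction.reads,
                     "hosts": ",".join((s.host_transcript,) + s.secondary_hosts),
                     "detail": s.n_skipped})
    for a in events.alt_sites:
        rows.append({"event_class": f"alt_site_{a.side}",
                     "chrom": a.junction.chrom,
                     "start": a.junction.start, "end": a.junction.end,
                     "strand": a.junction.strand, "reads": a.junction.reads,
                     "hosts": ",".join((a.host_transcript,) + a.secondary_hosts),
                     "detail": a.shift_bp})
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["chrom", "start", "end", "event_class"],
                            kind="mergesort").reset_index(drop=True)
        df.insert(0, "event_id", [f"EV{i:06d}" for i in range(1, len(df) + 1)])
    return df


def _bed12(chrom, start, end, name, score, strand, blocks) -> str:
    sizes = ",".join(str(e - s) for s, e in blocks) + ","
    starts = ",".join(str(s - start) for s, _ in blocks) + ","
    return (f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}"
            f"\t{start}\t{end}\t0\t{len(blocks)}\t{sizes}\t{starts}\n")


def write_event_beds(events: EventSet, outdir) -> Dict[str, str]:
    """One BED12 file per event class (blocks mark the event anatomy:
    the novel exon, the 1 bp junction edges of a skip, or the shifted
    segment of an alt site). Returns class -> path."""
    import os
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    groups = {
        "novel_exon_internal": [
            (e.exon.chrom, e.exon.start, e.exon.end, e.exon.strand,
             e.reads, [(e.exon.start, e.exon.end)])
            for e in events.internal_exons],
        "novel_exon_terminal": [
            (e.exon.chrom, e.exon.start, e.exon.end, e.exon.strand,
             e.reads, [(e.exon.start, e.exon.end)])
            for e in events.terminal_exons],
        "exon_skip": [
            (s.junction.chrom, s.junction.start - 1, s.junction.end + 1,
             s.junction.strand, s.junction.reads,
             [(s.junction.start - 1, s.junction.start),
              (s.junction.end, s.junction.end + 1)])
            for s in events.skips],
        "alt_site": [
            (a.junction.chrom, seg[0], seg[1], a.junction.strand,
             a.junction.reads, [seg])
            for a in events.alt_sites
            for seg in [tuple(sorted((a.junction.end, a.annotated_intron[1]))
                              if a.anchored_end == "left" else
                              sorted((a.junction.start, a.annotated_intron[0])))]],
    }
    for cls, rows in groups.items():
        path = os.path.join(outdir, f"{cls}.bed")
        with open(path, "w") as fh:
            for i, (chrom, s, e, strand, score, blocks) in enumerate(
                    sorted(rows), start=1):
                blocks = [b for b in blocks if b[0] < b[1]] or [(s, e)]
                fh.write(_bed12(chrom, s, e, f"{cls}_{i}", score,
                                strand if strand != "." else ".", blocks))
        paths[cls] = path
    return paths
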