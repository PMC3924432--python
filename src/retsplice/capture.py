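"""Targeted RNA-capture design and validation-rate computation.

Targets are novel events packaged with annotated flanking sequence under
three eligibility rules: the novel feature (exon or alt-site shift) must
be 15-400 bp, at least 50 bp of annotated flank must be available on each
side, and the total captured sequence (novel + flanks) must fit in
300-500 bp. Flanks grow symmetrically from the 50 bp minimum until the
300 bp floor is reached, capped by available annotated sequence and the
500 bp ceiling.

Baits (default 120-mers) are tiled at a step of bait_len/3 for ~3x
coverage of the target interior, with the last bait right-aligned to the
target end. Tiling is done in the target's own (composite) coordinate
space.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .events import AltSpliceSite, ExonSkip, NovelExon
from .model import NRTranscriptome, RetspliceError

FEATURE_MIN = 15
FEATURE_MAX = 400
FLANK_MIN = 50
REGION_MIN = 300
REGION_MAX = 500


@dataclass
class CaptureTarget:
    event_id: str
    event_class: str
    chrom: str
    feature_len: int
    flank_left: int
    flank_right: int
    # genomic envelope of the captured pieces (for BED output)
    region_start: int
    region_end: int
    strand: str
    # the novel junction(s) whose detection validates the target
    novel_junction_keys: tuple
    annotated_junction_keys: tuple = ()

    @property
    def capture_length(self) -> int:
        """Total captured sequence: novel feature plus both flanks."""
        return self.feature_len + self.flank_left + self.flank_right


@dataclass(frozen=True)
class Bait:
    target_id: str
    start: int  # offset within the target's composite coordinate space
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class RejectedEvent:
    event_id: str
    reason: str


def _flank_lengths(event, nrt: NRTranscriptome) -> Tuple[int, int]:
    """Available annotated flank on each side of the novel feature, in bp."""
    if isinstance(event, NovelExon):
        hosts = event.host_transcripts
        left_pos = event.left_junction.start if event.left_junction else None
        right_pos = event.right_junction.end if event.right_junction else None
    elif isinstance(event, ExonSkip):
        hosts = (event.host_transcript,)
        left_pos = event.junction.start
        right_pos = event.junction.end
    else:  # AltSpliceSite
        hosts = (event.host_transcript,)
        if event.anchored_end == "left":
            left_pos, right_pos = event.junction.start, event.annotated_intron[1]
        else:
            left_pos, right_pos = event.annotated_intron[0], event.junction.end
    best_left = best_right = 0
    for host in hosts:
        tx = nrt.by_id.get(host)
        if tx is None:
            continue
        if left_pos is not None:
            for s, e in tx.exons:
                if e == left_pos or (s <= left_pos <= e):
                    best_left = max(best_left, left_pos - s)
        if right_pos is not None:
            for s, e in tx.exons:
                if s == right_pos or (s <= right_pos <= e):
                    best_right = max(best_right, e - right_pos)
    return best_left, best_right


def _feature_len(event) -> int:
    if isinstance(event, NovelExon):
        return len(event.exon)
    if isinstance(event, AltSpliceSite):
        return abs(event.shift_bp)
    return 0  # exon skip: no novel sequence, length rule does not apply


def check_eligibility(feature_len: int, avail_left: int, avail_right: int,
                      length_rule_applies: bool = True) -> Optional[str]:
    """Apply the three selection rules; return a rejection reason or None.

    Used both by :func:`select_targets` and as a freestanding filter.
    """
    if length_rule_applies and not (FEATURE_MIN <= feature_len <= FEATURE_MAX):
        return "feature_length"
    if avail_left < FLANK_MIN or avail_right < FLANK_MIN:
        return "insufficient_flank"
    if feature_len + min(avail_left, REGION_MAX) + min(avail_right, REGION_MAX) < REGION_MIN:
        return "region_too_short"
    if feature_len + 2 * FLANK_MIN > REGION_MAX:
        return "region_too_long"
    return None


def _grow_flanks(feature_len: int, avail_left: int, avail_right: int
                 ) -> Tuple[int, int]:
    """Symmetric flank growth from 50 bp to reach the 300 bp floor,
    capped by availability and the 500 bp ceiling."""
    fl, fr = FLANK_MIN, FLANK_MIN
    while feature_len + fl + fr < REGION_MIN:
        grew = False
        if fl <= fr and fl < avail_left and feature_len + fl + fr < REGION_MAX:
            fl += 1
            grew = True
        elif fr < avail_right and feature_len + fl + fr < REGION_MAX:
            fr += 1
            grew = True
        elif fl < avail_left and feature_len + fl + fr < REGION_MAX:
            fl += 1
            grew = True
        if not grew:
            break
    return fl, fr


def select_targets(events: Sequence, nrt: NRTranscriptome,
                   event_ids: Optional[Sequence[str]] = None
                   ) -> Tuple[List[CaptureTarget], List[RejectedEvent]]:
    """Filter classified events by the three capture rules and build
    targets; rejected events carry a per-criterion reason."""
    targets: List[CaptureTarget] = []
    rejected: List[RejectedEvent] = []
    for i, ev in enumerate(events):
        eid = event_ids[i] if event_ids is not None else f"T{i + 1:05d}"
        flen = _feature_len(ev)
        applies = not isinstance(ev, ExonSkip)
        al, ar = _flank_lengths(ev, nrt)
        reason = check_eligibility(flen, al, ar, length_rule_applies=applies)
        if reason is not None:
            rejected.append(RejectedEvent(eid, reason))
            continue
        fl, fr = _grow_flanks(flen, al, ar)
        if not (REGION_MIN <= flen + fl + fr <= REGION_MAX):
            rejected.append(RejectedEvent(eid, "region_bounds"))
            continue
        if isinstance(ev, NovelExon):
            cls = f"novel_exon_{ev.kind}"
            chrom = ev.exon.chrom
            strand = ev.exon.strand
            js = tuple(j.key() for j in (ev.left_junction, ev.right_junction) if j)
            g_lo = (ev.left_junction.start if ev.left_junction else ev.exon.start) - fl
            g_hi = (ev.right_junction.end if ev.right_junction else ev.exon.end) + fr
            ann_set = set()
            if ev.left_junction is not None:
                for (s, e) in nrt.introns_sharing_left(chrom, ev.left_junction.start):
                    ann_set.add((chrom, s, e))
            if ev.right_junction is not None:
                for (s, e) in nrt.introns_sharing_right(chrom, ev.right_junction.end):
                    ann_set.add((chrom, s, e))
            ann = tuple(sorted(ann_set))
        elif isinstance(ev, ExonSkip):
            cls = "exon_skip"
            chrom = ev.junction.chrom
            strand = ev.junction.strand
            js = (ev.junction.key(),)
            g_lo, g_hi = ev.junction.start - fl, ev.junction.end + fr
            tx = nrt.by_id[ev.host_transcript]
            ann = tuple((chrom, s, e) for s, e in tx.introns()
                        if s == ev.junction.start or e == ev.junction.end)
        else:
            cls = f"alt_site_{ev.side}"
            chrom = ev.junction.chrom
            strand = ev.junction.strand
            js = (ev.junction.key(),)
            a_s, a_e = ev.annotated_intron
            g_lo = min(ev.junction.start, a_s) - fl
            g_hi = max(ev.junction.end, a_e) + fr
            ann = ((chrom, a_s, a_e),)
        targets.append(CaptureTarget(
            event_id=eid, event_class=cls, chrom=chrom, feature_len=flen,
            flank_left=fl, flank_right=fr, region_start=max(0, g_lo),
            region_end=g_hi, strand=strand, novel_junction_keys=js,
            annotated_junction_keys=ann))
    return targets, rejected


# -- bait tiling --------------------------------------------------------


def tile_baits(target: CaptureTarget, bait_len: int = 120) -> List[Bait]:
    """Tile baits over the target's composite sequence at step bait_len/3.

    The last bait is right-aligned to the region end so every base is
    covered; a region shorter than one bait yields a single centered bait
    with a warning.
    """
    length = target.capture_length
    tid = target.event_id
    if length < bait_len:
        warnings.warn(f"target {tid} shorter than bait length; emitting one bait")
        start = max(0, (length - bait_len) // 2)
        return [Bait(tid, start, min(bait_len, length))]
    step = max(1, bait_len // 3)
    starts = list(range(0, length - bait_len + 1, step))
    if starts[-1] != length - bait_len:
        starts.append(length - bait_len)
    return [Bait(tid, s, bait_len) for s in starts]


def write_bait_table(targets: Sequence[CaptureTarget], path: str,
                     bait_len: int = 120) -> int:
    """Interval TSV of all baits (target id, offset in the target's
    composite sequence, genomic envelope). Returns the bait count."""
    n = 0
    with open(path, "w") as fh:
        fh.write("target_id\tbait_start\tbait_end\tchrom"
                 "\tregion_start\tregion_end\n")
        for t in targets:
            for b in tile_baits(t, bait_len=bait_len):
                fh.write(f"{t.event_id}\t{b.start}\t{b.end}\t{t.chrom}"
                         f"\t{t.region_start}\t{t.region_end}\n")
                n += 1
    return n


def bait_coverage_profile(baits: Sequence[Bait], length: int) -> List[int]:
    depth = [0] * length
    for b in baits:
        for i in range(b.start, min(b.end, length)):
            depth[i] += 1
    return depth


# -- validation ---------------------------------------------------------


def target_validated(target: CaptureTarget, detected_keys: Set[tuple],
                     min_reads_met: bool = True,
                     novel_exon_policy: str = "both") -> bool:
    """Whether a target's defining novel junction(s) are present in a
    sample's detected-junction key set. Novel-exon targets require both
    flanking junctions under the default strict policy ('both'); 'either'
    accepts one."""
    keys = [k[:3] for k in target.novel_junction_keys]
    if not keys:
        return False
    hits = [k in detected_keys for k in keys]
    if target.event_class.startswith("novel_exon") and len(keys) == 2:
        return all(hits) if novel_exon_policy == "both" else any(hits)
    return all(hits)


def validation_rate(targets: Sequence[CaptureTarget],
                    captured_junctions: Dict[str, Sequence],
                    per_sample_truth: Optional[Dict[str, Set[str]]] = None,
                    min_reads: int = 1,
                    novel_exon_policy: str = "both") -> pd.DataFrame:
    """Per-sample validation rates from capture-experiment junction calls.

    A target validates in a sample iff its defining novel junction(s)
    appear with >= ``min_reads`` reads at exact coordinates. The
    denominator is the sample-specific event-id set when
    ``per_sample_truth`` is given, else the full target set. The table
    also reports how many targets' corresponding annotated junctions were
    detected.
    """
    rows = []
    for sample, junctions in captured_junctions.items():
        detected = {(j.chrom, j.start, j.end) for j in junctions
                    if j.reads >= min_reads}
        if not detected:
            warnings.warn(f"sample {sample} has no detected junctions")
        if per_sample_truth is not None and sample in per_sample_truth:
            eligible = [t for t in targets
                        if t.event_id in per_sample_truth[sample]]
        else:
            eligible = list(targets)
        n_val = sum(
            1 for t in eligible
            if target_validated(t, detected, novel_exon_policy=novel_exon_policy))
        n_ann = sum(
            1 for t in eligible
            if t.annotated_junction_keys
            and all(k in detected for k in t.annotated_junction_keys))
        rows.append({"sample": sample, "n_targets": len(eligible),
                     "n_validated": n_val,
                     "rate": 100.0 * n_val / len(eligible) if eligible else 0.0,
                     "n_annotated_detected": n_ann})
    return pd.DataFrame(rows)


def validated_sets(targets: Sequence[CaptureTarget],
                   captured_junctions: Dict[str, Sequence],
                   min_reads: int = 1,
                   novel_exon_policy: str = "both") -> Dict[str, Set[str]]:
    """Per-sample sets of validated target event ids."""
    out: Dict[str, Set[str]] = {}
    for sample, junctions in captured_junctions.items():
        detected = {(j.chrom, j.start, j.end) for j in junctions
                    if j.reads >= min_reads}
        out[sample] = {
            t.event_id for t in targets
            if target_validated(t, detected, novel_exon_policy=novel_exon_policy)}
    return out


def tissue_sharing(validated: Dict[str, Set[str]],
                   retina_samples: Sequence[str] = ()) -> pd.DataFrame:
    """Set-algebra summary across samples: targets validated in every
    sample, targets validated in all retina samples but no other sample,
    and per-sample exclusive counts."""
    if len(validated) < 2:
        raise RetspliceError("tissue sharing needs >= 2 samples")
    samples = sorted(validated)
    all_shared = set.intersection(*(validated[s] for s in samples))
    rows = [{"category": "shared_all_samples", "n": len(all_shared)}]
    retina = [s for s in samples if s in set(retina_samples)]
    other = [s for s in samples if s not in set(retina_samples)]
    if retina and other:
        retina_all = set.intersection(*(validated[s] for s in retina))
        non_retina_any = set.union(*(validated[s] for s in other))
        rows.append({"category": "retina_specific",
                     "n": len(retina_all - non_retina_any)})
    for s in samples:
        others = set.union(*(validated[t] for t in samples if t != s)) \
            if len(samples) > 1 else set()
        rows.append({"category": f"exclusive_{s}",
                     "n": len(validated[s] - others)})
    return pd.DataFrame(rows)
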