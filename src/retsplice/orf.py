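"""Reading-frame consequences of novel splicing events.

Each event is spliced into its host transcript model, the modified mRNA
is rebuilt from the genome, and translation from the annotated CDS start
decides the call:

* ``orf_maintained`` — net CDS length change divisible by 3 and the first
  stop codon encountered is the annotated stop;
* ``frameshift_or_ptc`` — anything else that touches the CDS (the two are
  merged into one label);
* ``utr`` — the edit lies wholly in an untranslated region, subdivided
  into ``utr_orf`` / ``utr_disrupt`` (see :func:`classify_frame`);
* ``ncrna`` — the host transcript has no CDS.

Standard genetic code (table 1). A codon containing N is skipped as
non-stop.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
import pyfaidx

from .events import (ADDS, ALT3, ALT5, AltSpliceSite, EventSet, ExonSkip,
                     INTERNAL, NovelExon, REMOVES)
from .model import NRTranscriptome, RetspliceError, TranscriptModel

ORF_MAINTAINED = "orf_maintained"
FRAMESHIFT_OR_PTC = "frameshift_or_ptc"
UTR = "utr"
NCRNA = "ncrna"
UTR_ORF = "utr_orf"
UTR_DISRUPT = "utr_disrupt"

STOP_CODONS = {"TAA", "TAG", "TGA"}

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class FrameError(RetspliceError):
    """The event cannot be classified against this host (e.g. the CDS
    start codon was removed by the edit)."""


class GenomeSource:
    """Uppercase sequence access over a FASTA file or an in-memory dict."""

    def __init__(self, source: Union[str, Dict[str, str]]):
        if isinstance(source, dict):
            self._seqs = {c: s.upper() for c, s in source.items()}
            self._fa = None
        else:
            self._fa = pyfaidx.Fasta(source)
            self._seqs = None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if self._seqs is not None:
            if chrom not in self._seqs:
                raise KeyError(f"chromosome {chrom!r} not in genome")
            seq = self._seqs[chrom]
            if start < 0 or end > len(seq):
                raise RetspliceError(
                    f"coordinates {chrom}:{start}-{end} outside genome")
            return seq[start:end]
        if chrom not in self._fa:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        if start < 0 or end > len(self._fa[chrom]):
            raise RetspliceError(f"coordinates {chrom}:{start}-{end} outside genome")
        return str(self._fa[chrom][start:end]).upper()


@dataclass(frozen=True)
class FrameCall:
    label: str
    utr_sub: str = "n/a"  # utr_orf | utr_disrupt | n/a
    stop_offset: Optional[int] = None  # codon index of first stop in modified CDS
    # audit trail for the utr_orf policy
    cds_unchanged: Optional[bool] = None
    insert_stop_free: Optional[bool] = None
    new_upstream_atg: Optional[bool] = None


@dataclass(frozen=True)
class ModifiedTranscript:
    base: str  # host transcript id
    sequence: str  # spliced mRNA after the edit (transcript orientation)
    cds_offset: Optional[int]  # first base of the start codon, or None
    chain: tuple  # modified genomic exon chain


# -- splicing machinery -------------------------------------------------


def _splice(chain: Sequence[tuple], chrom: str, strand: str,
            genome: GenomeSource) -> str:
    seq = "".join(genome.fetch(chrom, s, e) for s, e in chain)
    return revcomp(seq) if strand == "-" else seq


def _tx_offset(chain: Sequence[tuple], strand: str, pos: int) -> int:
    """Transcript-orientation offset of a genomic base contained in the chain."""
    if strand == "-":
        off = 0
        for s, e in reversed(chain):
            if s <= pos < e:
                return off + (e - 1 - pos)
            off += e - s
    else:
        off = 0
        for s, e in chain:
            if s <= pos < e:
                return off + (pos - s)
            off += e - s
    raise FrameError(f"position {pos} not in modified exon chain")


def _modified_chain(tx: TranscriptModel, event) -> List[tuple]:
    chain = list(tx.exons)
    if isinstance(event, NovelExon):
        ne = (event.exon.start, event.exon.end)
        for s, e in chain:
            if ne[0] < e and s < ne[1]:
                raise FrameError("novel exon overlaps a host exon")
        chain.append(ne)
        chain.sort()
    elif isinstance(event, ExonSkip):
        skipped = set(event.skipped_exons)
        chain = [ex for ex in chain if ex not in skipped]
        if len(chain) == len(tx.exons):
            raise FrameError("skipped exons are not exons of this host")
    elif isinstance(event, AltSpliceSite):
        a_s, a_e = event.annotated_intron
        j = event.junction
        if (a_s, a_e) not in tx.introns():
            raise FrameError("annotated intron of the alt event not in host")
        new_chain = []
        for s, e in chain:
            if event.anchored_end == "left" and s == a_e:
                s = j.end  # acceptor moved: downstream exon starts at novel end
            elif event.anchored_end == "right" and e == a_s:
                e = j.start  # donor moved: upstream exon ends at novel start
            if s >= e:
                raise FrameError("alt-site shift consumed the whole exon")
            new_chain.append((s, e))
        chain = sorted(new_chain)
    else:
        raise TypeError(f"unsupported event type {type(event).__name__}")
    return chain


def _cds_first_base(tx: TranscriptModel) -> int:
    return tx.cds_start if tx.strand == "+" else tx.cds_end - 1


def _cds_last_base(tx: TranscriptModel) -> int:
    return tx.cds_end - 1 if tx.strand == "+" else tx.cds_start


def apply_event(tx: TranscriptModel, event, genome: GenomeSource) -> ModifiedTranscript:
    """Splice an event into a host transcript and rebuild its mRNA.

    The CDS offset is recomputed on the modified chain, so it shifts only
    when the edit lies 5' of the start codon in transcript orientation.
    """
    chain = tuple(_modified_chain(tx, event))
    seq = _splice(chain, tx.chrom, tx.strand, genome)
    cds_offset = None
    if tx.is_coding:
        cds_offset = _tx_offset(chain, tx.strand, _cds_first_base(tx))
    return ModifiedTranscript(base=tx.id, sequence=seq, cds_offset=cds_offset,
                              chain=chain)


# -- translation --------------------------------------------------------


def first_stop_codon(seq: str, offset: int) -> Optional[int]:
    """Codon index (from ``offset``) of the first stop codon; codons with N
    are skipped as non-stop; None if no stop before the sequence end."""
    i = offset
    idx = 0
    while i + 3 <= len(seq):
        codon = seq[i:i + 3]
        if codon in STOP_CODONS:
            return idx
        i += 3
        idx += 1
    return None


def _edit_region(tx: TranscriptModel, event) -> str:
    """'utr5' / 'utr3' (transcript orientation) when the edited bases lie
    wholly in a UTR of the host, else 'cds'."""
    if isinstance(event, NovelExon):
        g_lo, g_hi = event.exon.start, event.exon.end
    elif isinstance(event, ExonSkip):
        g_lo = min(s for s, _ in event.skipped_exons)
        g_hi = max(e for _, e in event.skipped_exons)
    else:
        a_s, a_e = event.annotated_intron
        j = event.junction
        if event.anchored_end == "left":
            g_lo, g_hi = min(a_e, j.end), max(a_e, j.end)
        else:
            g_lo, g_hi = min(a_s, j.start), max(a_s, j.start)
    if g_hi <= tx.cds_start:
        return "utr5" if tx.strand == "+" else "utr3"
    if g_lo >= tx.cds_end:
        return "utr3" if tx.strand == "+" else "utr5"
    return "cds"


def _inserted_tx_interval(tx: TranscriptModel, event, mod: ModifiedTranscript
                          ) -> Optional[Tuple[int, int]]:
    """Transcript-orientation interval of bases ADDED by the event in the
    modified transcript, or None when the event only removes sequence."""
    if isinstance(event, NovelExon):
        g_s, g_e = event.exon.start, event.exon.end
    elif isinstance(event, AltSpliceSite) and event.effect == ADDS:
        a_s, a_e = event.annotated_intron
        j = event.junction
        if event.anchored_end == "left":
            g_s, g_e = j.end, a_e
        else:
            g_s, g_e = a_s, j.start
    else:
        return None
    lo = _tx_offset(mod.chain, tx.strand, g_s)
    hi = _tx_offset(mod.chain, tx.strand, g_e - 1)
    lo, hi = min(lo, hi), max(lo, hi)
    return (lo, hi + 1)


def classify_frame(tx: TranscriptModel, event, genome: GenomeSource) -> FrameCall:
    """Frame-consequence call of one event against one host transcript.

    Non-coding host -> ``ncrna``. An edit wholly within a UTR -> ``utr``
    with sub-label ``utr_orf`` when (a) translation from the annotated
    start still ends at the annotated stop, (b) the added sequence read in
    the codon frame projected out from the annotated start contains no
    stop codon, and (c) for 5' UTR edits no new in-frame upstream ATG
    (without an intervening in-frame stop) is created; else
    ``utr_disrupt``. CDS-touching edits translate from the annotated
    start: ``orf_maintained`` iff the net CDS length change is divisible
    by 3 and the first stop is the annotated stop.
    """
    if not tx.is_coding:
        return FrameCall(label=NCRNA)
    mod = apply_event(tx, event, genome)
    orig_chain = tuple(tx.exons)
    orig_seq = _splice(orig_chain, tx.chrom, tx.strand, genome)
    orig_off = _tx_offset(orig_chain, tx.strand, _cds_first_base(tx))
    if mod.sequence[mod.cds_offset:mod.cds_offset + 3] != orig_seq[orig_off:orig_off + 3]:
        raise FrameError(f"{tx.id}: CDS start codon absent from modified sequence")

    # annotated stop position (transcript offset of the stop codon's first
    # base) in original and modified coordinates
    last = _cds_last_base(tx)
    try:
        mod_stop_first = _tx_offset(mod.chain, tx.strand, last) - 2
    except FrameError:
        mod_stop_first = None  # stop codon removed by the edit
    orig_stop_first = _tx_offset(orig_chain, tx.strand, last) - 2

    region = _edit_region(tx, event)
    if region in ("utr5", "utr3"):
        return _classify_utr(tx, event, genome, mod, orig_seq, orig_off,
                             orig_stop_first, mod_stop_first, region)

    # CDS-affecting edit
    if mod_stop_first is None:
        stop_idx = first_stop_codon(mod.sequence, mod.cds_offset)
        return FrameCall(label=FRAMESHIFT_OR_PTC, stop_offset=stop_idx)
    net_change = mod_stop_first - mod.cds_offset - (orig_stop_first - orig_off)
    stop_idx = first_stop_codon(mod.sequence, mod.cds_offset)
    annotated_idx = None
    if (mod_stop_first - mod.cds_offset) % 3 == 0:
        annotated_idx = (mod_stop_first - mod.cds_offset) // 3
    if net_change % 3 == 0 and stop_idx is not None and stop_idx == annotated_idx:
        return FrameCall(label=ORF_MAINTAINED, stop_offset=stop_idx)
    return FrameCall(label=FRAMESHIFT_OR_PTC, stop_offset=stop_idx)


def _classify_utr(tx, event, genome, mod, orig_seq, orig_off,
                  orig_stop_first, mod_stop_first, region) -> FrameCall:
    # (a) CDS translation unchanged: same peptide, stop still the annotated one
    cds_unchanged = False
    if mod_stop_first is not None and (mod_stop_first - mod.cds_offset) == (
            orig_stop_first - orig_off):
        cds_mod = mod.sequence[mod.cds_offset:mod_stop_first + 3]
        cds_orig = orig_seq[orig_off:orig_stop_first + 3]
        first = first_stop_codon(mod.sequence, mod.cds_offset)
        cds_unchanged = (cds_mod == cds_orig
                         and first is not None
                         and first == (mod_stop_first - mod.cds_offset) // 3)
    stop_idx = first_stop_codon(mod.sequence, mod.cds_offset)

    # (b) added sequence, read in the frame projected from the annotated
    # start, must contain no stop codon (codons overlapping the insert
    # boundaries included); removal-only edits pass vacuously
    insert_stop_free = True
    new_upstream_atg = False
    ins = _inserted_tx_interval(tx, event, mod)
    if ins is not None:
        lo, hi = ins
        anchor = mod.cds_offset
        first_codon = anchor + 3 * ((lo - anchor) // 3)  # floor for negatives too
        t = first_codon
        while t < hi:
            codon = mod.sequence[t:t + 3] if t >= 0 else ""
            if len(codon) == 3 and codon in STOP_CODONS:
                insert_stop_free = False
            t += 3
        if region == "utr5":
            # (c) a new in-frame ATG in the insert with no in-frame stop
            # before the annotated start would create an overlapping uORF
            t = first_codon
            atg_positions = []
            while t < hi:
                codon = mod.sequence[t:t + 3] if t >= 0 else ""
                if codon == "ATG":
                    atg_positions.append(t)
                t += 3
            for pos in atg_positions:
                t = pos
                blocked = False
                while t + 3 <= mod.cds_offset:
                    if mod.sequence[t:t + 3] in STOP_CODONS:
                        blocked = True
                        break
                    t += 3
                if not blocked:
                    new_upstream_atg = True
                    break
    sub = (UTR_ORF if cds_unchanged and insert_stop_free and not new_upstream_atg
           else UTR_DISRUPT)
    return FrameCall(label=UTR, utr_sub=sub, stop_offset=stop_idx,
                     cds_unchanged=cds_unchanged,
                     insert_stop_free=insert_stop_free,
                     new_upstream_atg=new_upstream_atg)


# -- event-level classification -----------------------------------------

_PREFERENCE = {ORF_MAINTAINED: 0, UTR: 1, FRAMESHIFT_OR_PTC: 2, NCRNA: 3}


def _hosts_of(event) -> tuple:
    if isinstance(event, NovelExon):
        return event.host_transcripts
    if isinstance(event, ExonSkip):
        return (event.host_transcript,) + event.secondary_hosts
    return (event.host_transcript,) + event.secondary_hosts


def classify_event(event, nrt: NRTranscriptome, genome: GenomeSource,
                   policy: str = "most_preserving") -> Tuple[FrameCall, str]:
    """Classify an event against every host; report the most ORF-preserving
    call (or most disruptive under ``policy='most_disruptive'``)."""
    calls = []
    errors = []
    for host in _hosts_of(event):
        tx = nrt.by_id[host]
        try:
            calls.append((classify_frame(tx, event, genome), host))
        except FrameError as exc:
            errors.append((host, exc))
    if not calls:
        if errors:
            raise errors[0][1]
        raise FrameError("event has no host transcript")
    def rank(item):
        call, host = item
        r = _PREFERENCE[call.label]
        if call.label == UTR:
            r += 0.0 if call.utr_sub == UTR_ORF else 0.5
        return (r, host)
    calls.sort(key=rank, reverse=(policy == "most_disruptive"))
    return calls[0]


def frame_breakdown(events: EventSet, nrt: NRTranscriptome,
                    genome: GenomeSource,
                    policy: str = "most_preserving") -> Tuple[pd.DataFrame, dict]:
    """Per-class frame-consequence percentage table.

    Novel internal exons report {orf_maintained, frameshift_or_ptc, utr}
    plus the utr_orf share of the utr category; skips and alt sites report
    {orf_maintained, frameshift_or_ptc, ncrna}. Also returns the mean
    number of exons skipped conditional on the frame class of the skips.
    """
    rows = []
    extras: dict = {}

    def tally(event_list, class_name):
        counts: Dict[str, int] = {}
        per_event = []
        for ev in event_list:
            call, host = classify_event(ev, nrt, genome, policy=policy)
            counts[call.label] = counts.get(call.label, 0) + 1
            per_event.append((ev, call))
        total = sum(counts.values())
        for label, n in sorted(counts.items()):
            rows.append({"event_class": class_name, "frame_label": label,
                         "n": n, "pct": 100.0 * n / total if total else 0.0})
        return per_event

    internal_calls = tally(events.internal_exons, "novel_exon_internal")
    utr_calls = [c for _, c in internal_calls if c.label == UTR]
    if utr_calls:
        n_orf = sum(1 for c in utr_calls if c.utr_sub == UTR_ORF)
        extras["utr_orf_pct_of_utr"] = 100.0 * n_orf / len(utr_calls)

    skip_calls = tally(events.skips, "exon_skip")
    for label in (ORF_MAINTAINED, FRAMESHIFT_OR_PTC):
        ns = [ev.n_skipped for ev, c in skip_calls if c.label == label]
        if ns:
            extras[f"mean_exons_skipped_{label}"] = sum(ns) / len(ns)

    tally(events.alt_sites, "alt_site")
    return pd.DataFrame(rows), extras


def frame_table(events: EventSet, nrt: NRTranscriptome, genome: GenomeSource,
                policy: str = "most_preserving") -> pd.DataFrame:
    """Per-event table augmented with frame-consequence columns."""
    rows = []
    specs = ([("novel_exon_internal", e,
               (e.exon.chrom, e.exon.start, e.exon.end, e.exon.strand))
              for e in events.internal_exons]
             + [("exon_skip", s,
                 (s.junction.chrom, s.junction.start, s.junction.end,
                  s.junction.strand)) for s in events.skips]
             + [(f"alt_site_{a.side}", a,
                 (a.junction.chrom, a.junction.start, a.junction.end,
                  a.junction.strand)) for a in events.alt_sites])
    for cls, ev, (chrom, start, end, strand) in specs:
        call, host = classify_event(ev, nrt, genome, policy=policy)
        rows.append({"event_class": cls, "chrom": chrom, "start": start,
                     "end": end, "strand": strand, "host": host,
                     "frame_label": call.label, "utr_sub": call.utr_sub,
                     "stop_codon_index": (call.stop_offset
                                          if call.stop_offset is not None
                                          else "")})
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["chrom", "start", "end", "event_class"],
                            kind="mergesort").reset_index(drop=True)
    return df


def added_removed_sequence(alt_sites: Sequence[AltSpliceSite]) -> Tuple[int, int]:
    """Total bases added and removed by alt-site events (sum of absolute
    shifts, split by effect)."""
    added = sum(abs(a.shift_bp) for a in alt_sites if a.effect == ADDS)
    removed = sum(abs(a.shift_bp) for a in alt_sites if a.effect == REMOVES)
    return added, removed
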