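"""Reading-frame consequence calls, checked against an independent
naive re-splicer / codon-by-codon translation oracle built on Biopython."""

import random

import pytest
from Bio.Seq import Seq

from retsplice.events import AltSpliceSite, ExonSkip, NovelExon
from retsplice.junctions import Junction
from retsplice.model import GenomicInterval, TranscriptModel, build_nonredundant
from retsplice.orf import (FrameError, GenomeSource, added_removed_sequence,
                           apply_event, classify_event, classify_frame,
                           frame_breakdown)

STOPS = {"TAA", "TAG", "TGA"}


# -- independent oracle -------------------------------------------------


def oracle_chain(tx, event):
    """Rebuild the modified exon chain from scratch (independent of the
    implementation's chain editing)."""
    chain = sorted(tx.exons)
    if isinstance(event, NovelExon):
        chain = sorted(chain + [(event.exon.start, event.exon.end)])
    elif isinstance(event, ExonSkip):
        chain = [e for e in chain if e not in set(event.skipped_exons)]
    else:
        a_s, a_e = event.annotated_intron
        j = event.junction
        out = []
        for s, e in chain:
            if event.anchored_end == "left" and s == a_e:
                s = j.end
            if event.anchored_end == "right" and e == a_s:
                e = j.start
            out.append((s, e))
        chain = sorted(out)
    return chain


def oracle_splice(chain, tx, genome_str):
    seq = "".join(genome_str[s:e] for s, e in chain)
    return str(Seq(seq).reverse_complement()) if tx.strand == "-" else seq


def oracle_offset(chain, tx, gpos):
    """Transcript offset of a genomic base, by explicit enumeration."""
    positions = []
    for s, e in chain:
        positions.extend(range(s, e))
    if tx.strand == "-":
        positions = positions[::-1]
    return positions.index(gpos)


def oracle_classify(tx, event, genome_str):
    if not tx.is_coding:
        return "ncrna"
    chain = oracle_chain(tx, event)
    seq = oracle_splice(chain, tx, genome_str)
    start_base = tx.cds_start if tx.strand == "+" else tx.cds_end - 1
    stop_last = tx.cds_end - 1 if tx.strand == "+" else tx.cds_start
    off = oracle_offset(chain, tx, start_base)
    # edit footprint vs the CDS genomic span
    if isinstance(event, NovelExon):
        lo, hi = event.exon.start, event.exon.end
    elif isinstance(event, ExonSkip):
        lo = min(s for s, _ in event.skipped_exons)
        hi = max(e for _, e in event.skipped_exons)
    else:
        a_s, a_e = event.annotated_intron
        j = event.junction
        if event.anchored_end == "left":
            lo, hi = min(a_e, j.end), max(a_e, j.end)
        else:
            lo, hi = min(a_s, j.start), max(a_s, j.start)
    in_utr = hi <= tx.cds_start or lo >= tx.cds_end
    # translate codon-by-codon with Biopython
    tail = seq[off:]
    tail = tail[:len(tail) - len(tail) % 3]
    peptide = str(Seq(tail).translate())
    first_stop = peptide.find("*")
    try:
        stop_end = oracle_offset(chain, tx, stop_last) + 1
    except ValueError:
        stop_end = None
    if in_utr:
        return "utr"
    if stop_end is None:
        return "frameshift_or_ptc"
    expected_idx = (stop_end - off) // 3 - 1 if (stop_end - off) % 3 == 0 else None
    orig_positions = sum(e - s for s, e in tx.exons)
    orig_cds_len = (oracle_offset(tuple(tx.exons), tx, stop_last) + 1
                    - oracle_offset(tuple(tx.exons), tx, start_base))
    net = (stop_end - off) - orig_cds_len
    if net % 3 == 0 and first_stop != -1 and first_stop == expected_idx:
        return "orf_maintained"
    return "frameshift_or_ptc"


# -- direct examples ----------------------------------------------------


@pytest.fixture(scope="module")
def coding_setting():
    # 300 bp CDS over three exons, flanked by UTR exons
    cds = "ATG" + "GCT" * 98 + "TAA"
    utr5, utr3 = "TTCTC" * 12, "CCTTC" * 12
    g = ["N"] * 5000
    exons = [(100, 160), (300, 400), (1000, 1100), (1200, 1300), (1400, 1460)]
    mrna = utr5 + cds + utr3
    off = 0
    for s, e in exons:
        g[s:e] = mrna[off:off + e - s]
        off += e - s
    genome_str = "".join(g)
    tx = TranscriptModel(id="t", chrom="c", strand="+", exons=tuple(exons),
                         cds_start=300, cds_end=1300)
    return tx, GenomeSource({"c": genome_str}), genome_str


def make_exon_event(tx, start, length, seq_genome):
    left = Junction(chrom=tx.chrom, start=tx.exons[1][1], end=start,
                    strand="+", reads=5)
    right = Junction(chrom=tx.chrom, start=start + length, end=tx.exons[2][0],
                     strand="+", reads=5)
    return NovelExon(GenomicInterval(tx.chrom, start, start + length, "+"),
                     left, right, (tx.id,), "internal")


class TestApplyEvent:
    def test_insertion_length_and_cds_offset(self, coding_setting):
        tx, genome, gs = coding_setting
        ev = make_exon_event(tx, 430, 99, gs)
        mod = apply_event(tx, ev, genome)
        assert len(mod.sequence) == tx.exonic_length() + 99
        assert mod.cds_offset == 60  # insertion is 3' of the start codon

    def test_skip_in_utr_leaves_cds_bytes_identical(self, coding_setting):
        tx, genome, gs = coding_setting
        skip = ExonSkip(Junction(chrom="c", start=1300, end=4000, strand="+",
                                 reads=3),
                        tx.id, ((1400, 1460),), 1)
        # skipping the 3' UTR exon: CDS region of the mRNA is unchanged
        mod = apply_event(tx, skip, genome)
        assert mod.sequence[mod.cds_offset:mod.cds_offset + 300] \
            == gs[300:400] + gs[1000:1100] + gs[1200:1300]

    def test_event_outside_host_errors(self, coding_setting):
        tx, genome, _ = coding_setting
        bad = ExonSkip(Junction(chrom="c", start=1, end=50, strand="+",
                                reads=1), tx.id, ((2000, 2100),), 1)
        with pytest.raises(FrameError):
            apply_event(tx, bad, genome)


class TestClassifyFrame:
    def test_inframe_stopfree_insert_maintains_orf(self, coding_setting):
        tx, genome, gs = coding_setting
        ev = make_exon_event(tx, 430, 99, gs)
        # the intron is random-free Ns; write stop-free codons there
        genome._seqs["c"] = gs[:430] + "GCC" * 33 + gs[529:]
        call = classify_frame(tx, ev, genome)
        assert call.label == "orf_maintained"
        assert call.stop_offset == (300 + 99) // 3 - 1

    def test_non_multiple_of_three_insert_shifts_frame(self, coding_setting):
        tx, genome, gs = coding_setting
        ev = make_exon_event(tx, 430, 100, gs)
        genome._seqs["c"] = gs[:430] + "GC" + "GCC" * 32 + "CC" + gs[530:]
        assert classify_frame(tx, ev, genome).label == "frameshift_or_ptc"

    def test_noncoding_host_is_ncrna(self):
        tx = TranscriptModel(id="nc", chrom="c", strand="+",
                             exons=((0, 100), (200, 300), (400, 500)))
        genome = GenomeSource({"c": "A" * 600})
        skip = ExonSkip(Junction(chrom="c", start=100, end=400, strand="+",
                                 reads=1), "nc", ((200, 300),), 1)
        assert classify_frame(tx, skip, genome).label == "ncrna"

    def test_null_like_skip_of_utr_exon_is_utr_orf(self, coding_setting):
        tx, genome, gs = coding_setting
        genome._seqs["c"] = gs
        skip = ExonSkip(Junction(chrom="c", start=1300, end=4000, strand="+",
                                 reads=3), tx.id, ((1400, 1460),), 1)
        call = classify_frame(tx, skip, genome)
        assert (call.label, call.utr_sub) == ("utr", "utr_orf")
        assert call.cds_unchanged

    def test_skip_removing_start_codon_reports_error(self, coding_setting):
        tx, genome, gs = coding_setting
        genome._seqs["c"] = gs
        skip = ExonSkip(Junction(chrom="c", start=160, end=1000, strand="+",
                                 reads=1), tx.id, ((300, 400),), 1)
        with pytest.raises(FrameError):
            classify_frame(tx, skip, genome)


class TestClosedFormProperty:
    @pytest.mark.parametrize("length", [99, 102, 150, 300])
    def test_stopfree_cds_insert_maintained_iff_mod3(self, coding_setting,
                                                     length):
        tx, genome, gs = coding_setting
        genome._seqs["c"] = gs[:430] + "GCA" * 100 + gs[430 + 300:]
        ev = make_exon_event(tx, 430, length, gs)
        call = classify_frame(tx, ev, genome)
        assert (call.label == "orf_maintained") == (length % 3 == 0)


class TestOracleAgreement:
    def test_sim_events_match_independent_translation(self, study):
        """Every classified event agrees with the naive re-splice +
        Biopython translation oracle (UTR subdivision excluded: the oracle
        stops at the coarse label)."""
        ev = study.events
        genome_strs = study.res.genome
        rng = random.Random(0)
        pool = (
            [(e, "exon") for e in ev.internal_exons]
            + [(s, "skip") for s in ev.skips]
            + [(a, "alt") for a in ev.alt_sites])
        sample = rng.sample(pool, 200)
        n = 0
        for event, _ in sample:
            call, host = classify_event(event, study.nrt, study.genome)
            tx = study.nrt.by_id[host]
            expect = oracle_classify(tx, event, genome_strs[tx.chrom])
            assert call.label == expect, (event, call, expect)
            n += 1
        assert n == 200


class TestBreakdownAndTotals:
    def test_breakdown_percentages_sum_to_100(self, study):
        df, extras = frame_breakdown(study.events, study.nrt, study.genome)
        for cls, sub in df.groupby("event_class"):
            assert sub["pct"].sum() == pytest.approx(100.0, abs=0.1)

    def test_added_removed_totals_match_bruteforce(self, study):
        alts = study.events.alt_sites
        added, removed = added_removed_sequence(alts)
        assert added == sum(abs(a.shift_bp) for a in alts
                            if a.effect == "adds_sequence")
        assert removed == sum(abs(a.shift_bp) for a in alts
                              if a.effect == "removes_sequence")
        assert added > 0 and removed > 0

    @pytest.mark.parametrize("shifts,expect", [
        ([(100, "adds_sequence")], (100, 0)),
        ([(100, "adds_sequence"), (-250, "removes_sequence")], (100, 250)),
    ])
    def test_added_removed_examples(self, shifts, expect):
        tx = TranscriptModel(id="t", chrom="c", strand="+",
                             exons=((0, 100), (1000, 1100)))
        alts = []
        for shift, effect in shifts:
            alts.append(AltSpliceSite(
                junction=Junction(chrom="c", start=100, end=1000 + shift,
                                  strand="+", reads=1),
                host_transcript="t", anchored_end="left", shift_bp=shift,
                side="alt3", effect=effect, annotated_intron=(100, 1000)))
        assert added_removed_sequence(alts) == expect


def test_frame_table_covers_every_classified_event(study):
    from retsplice.orf import frame_table
    df = frame_table(study.events, study.nrt, study.genome)
    n_events = (len(study.events.internal_exons) + len(study.events.skips)
                + len(study.events.alt_sites))
    assert len(df) == n_events
    assert set(df["frame_label"]) <= {"orf_maintained", "frameshift_or_ptc",
                                      "utr", "ncrna"}
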