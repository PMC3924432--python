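"""Novel-event classification: exon pairing, skips, alt sites, terminals."""

import random

import numpy as np
import pytest

from retsplice.coverage import CoverageTrack
from retsplice.events import (classify_all, find_alt_sites, find_exon_skips,
                              find_novel_internal_exons,
                              find_novel_terminal_exons, summarize_events,
                              events_table)
from retsplice.junctions import Junction, partition
from retsplice.model import TranscriptModel, build_nonredundant


def J(start, end, reads=10, strand="+", chrom="chr1"):
    return Junction(chrom=chrom, start=start, end=end, reads=reads,
                    strand=strand)


class TestInternalExonPairing:
    def test_gap_inside_window_yields_exon(self):
        exons = find_novel_internal_exons([J(500, 1000), J(1100, 1500)])
        assert len(exons) == 1
        e = exons[0].exon
        assert (e.start, e.end, len(e)) == (1000, 1100, 100)

    @pytest.mark.parametrize("gap", [10, 14, 651, 700])
    def test_gap_outside_window_rejected(self, gap):
        assert not find_novel_internal_exons([J(500, 1000),
                                              J(1000 + gap, 2000 + gap)])

    @pytest.mark.parametrize("gap", [15, 650])
    def test_closed_bounds_included(self, gap):
        exons = find_novel_internal_exons([J(500, 1000),
                                           J(1000 + gap, 2000 + gap)])
        assert len(exons) == 1 and len(exons[0].exon) == gap

    def test_opposite_strands_do_not_pair(self):
        assert not find_novel_internal_exons([J(500, 1000, strand="+"),
                                              J(1100, 1500, strand="-")])

    def test_unstranded_pairs_with_either(self):
        assert find_novel_internal_exons([J(500, 1000, strand="."),
                                          J(1100, 1500, strand="-")])

    def test_random_junctions_match_allpairs_oracle(self):
        rng = random.Random(17)
        js = []
        for _ in range(100):
            s = rng.randrange(0, 50_000)
            js.append(J(s, s + rng.randrange(50, 2000)))
        got = {(e.exon.start, e.exon.end)
               for e in find_novel_internal_exons(js)}
        oracle = {(a.end, b.start) for a in js for b in js
                  if 15 <= b.start - a.end <= 650}
        assert got == oracle

    def test_emitted_lengths_respect_bounds(self, study):
        for e in (study.events.internal_exons + study.events.unanchored_exons):
            assert 15 <= len(e.exon) <= 650


class TestExonSkips:
    @pytest.fixture(scope="class")
    @staticmethod
    def nrt():
        tx = TranscriptModel(id="t1", chrom="chr1", strand="+",
                             exons=((0, 100), (200, 300), (400, 500),
                                    (600, 700)))
        return build_nonredundant([[tx]])

    def test_single_skip(self, nrt):
        (skip,) = find_exon_skips([J(100, 400)], nrt)
        assert skip.n_skipped == 1 and skip.skipped_exons == ((200, 300),)

    def test_adjacent_junction_is_not_a_skip(self, nrt):
        assert not find_exon_skips([J(100, 200)], nrt)

    def test_misaligned_ends_are_not_skips(self, nrt):
        assert not find_exon_skips([J(101, 400)], nrt)
        assert not find_exon_skips([J(100, 399)], nrt)

    def test_multi_exon_skip_counts_enclosed(self, nrt):
        (skip,) = find_exon_skips([J(100, 600)], nrt)
        assert skip.n_skipped == 2

    def test_random_transcripts_match_enclosure_oracle(self):
        rng = random.Random(23)
        exons, pos = [], 0
        for _ in range(20):
            exons.append((pos, pos + rng.randrange(50, 200)))
            pos = exons[-1][1] + rng.randrange(100, 500)
        tx = TranscriptModel(id="t", chrom="chr1", strand="+",
                             exons=tuple(exons))
        nrt = build_nonredundant([[tx]])
        js = []
        for _ in range(30):
            i, j = sorted(rng.sample(range(20), 2))
            js.append(J(exons[i][1], exons[j][0]))
        skips = {(s.junction.start, s.junction.end): s.n_skipped
                 for s in find_exon_skips(js, nrt)}
        for j in js:
            enclosed = sum(1 for s, e in exons if s >= j.start and e <= j.end)
            if enclosed:
                assert skips[(j.start, j.end)] == enclosed
            else:
                assert (j.start, j.end) not in skips

    def test_host_with_most_skipped_exons_wins(self):
        long_tx = TranscriptModel(id="long", chrom="chr1", strand="+",
                                  exons=((0, 100), (200, 300), (350, 380),
                                         (400, 500)))
        short_tx = TranscriptModel(id="short", chrom="chr1", strand="+",
                                   exons=((0, 100), (200, 300), (400, 500)))
        nrt = build_nonredundant([[long_tx, short_tx]])
        (skip,) = find_exon_skips([J(100, 400)], nrt)
        assert skip.host_transcript == "long" and skip.n_skipped == 2
        assert skip.secondary_hosts == ("short",)


class TestAltSites:
    @pytest.fixture(scope="class")
    @staticmethod
    def nrt():
        plus = TranscriptModel(id="p", chrom="chr1", strand="+",
                               exons=((500, 1000), (2000, 2600)))
        minus = TranscriptModel(id="m", chrom="chr2", strand="-",
                                exons=((500, 1000), (2000, 2600)))
        return build_nonredundant([[plus, minus]])

    def test_acceptor_shift_plus_strand_is_alt3_removes(self, nrt):
        (alt,) = find_alt_sites([J(1000, 2100)], nrt)
        assert (alt.side, alt.shift_bp, alt.effect) == \
            ("alt3", 100, "removes_sequence")
        assert alt.anchored_end == "left"

    def test_small_shift_rejected(self, nrt):
        assert not find_alt_sites([J(1000, 2010)], nrt)

    @pytest.mark.parametrize("shift", [15, 350])
    def test_closed_shift_bounds(self, nrt, shift):
        assert find_alt_sites([J(1000, 2000 - shift)], nrt)

    @pytest.mark.parametrize("shift", [14, 351])
    def test_open_shift_bounds_rejected(self, nrt, shift):
        assert not find_alt_sites([J(1000, 2000 - shift)], nrt)

    def test_same_geometry_minus_strand_is_alt5(self, nrt):
        (alt,) = find_alt_sites([J(1000, 2100, chrom="chr2", strand="-")], nrt)
        assert alt.side == "alt5"

    def test_donor_shift_plus_strand_is_alt5_adds(self, nrt):
        (alt,) = find_alt_sites([J(1100, 2000)], nrt)
        assert (alt.side, alt.shift_bp, alt.effect) == \
            ("alt5", 100, "adds_sequence")

    def test_junction_matching_two_boundaries_is_not_alt(self, nrt):
        # both ends on annotated exon boundaries of the host: skip territory
        tx = TranscriptModel(id="t", chrom="chr3", strand="+",
                             exons=((0, 100), (200, 300), (400, 500)))
        n2 = build_nonredundant([[tx]])
        assert not find_alt_sites([J(100, 400, chrom="chr3")], n2)


class TestTerminalExons:
    @pytest.fixture(scope="class")
    @staticmethod
    def setting():
        tx = TranscriptModel(id="t1", chrom="chr1", strand="+",
                             exons=((0, 200), (400, 700)), cds_start=100,
                             cds_end=500)
        nrt = build_nonredundant([[tx]])
        depth = np.zeros(10_000, dtype=np.int64)
        return tx, nrt, depth

    def make_cov(self, depth):
        return CoverageTrack({"chr1": depth.copy()})

    def test_accepted_outside_utr_with_consistent_coverage(self, setting):
        tx, nrt, depth = setting
        depth = depth.copy()
        depth[1000:1060] = 10
        cov = self.make_cov(depth)
        terms = find_novel_terminal_exons([J(600, 1000)], cov, nrt)
        assert len(terms) == 1
        e = terms[0]
        assert (e.exon.start, e.exon.end) == (1000, 1060)
        assert e.host_transcripts == ("t1",)

    def test_short_coverage_run_rejected(self, setting):
        tx, nrt, depth = setting
        depth = depth.copy()
        depth[1000:1030] = 10  # only 30 bp covered
        assert not find_novel_terminal_exons([J(600, 1000)],
                                             self.make_cov(depth), nrt)

    def test_candidate_inside_annotated_utr_rejected(self, setting):
        # landing point inside the transcript's 3' UTR span
        tx, nrt, depth = setting
        depth = depth.copy()
        depth[550:650] = 10
        assert not find_novel_terminal_exons([J(250, 550)],
                                             self.make_cov(depth), nrt)

    def test_unattached_short_chain_rejected(self, setting):
        tx, nrt, depth = setting
        depth = depth.copy()
        depth[5000:5100] = 10
        # isolated junction: 2 putative exons at most, below the 3-exon rule
        assert not find_novel_terminal_exons([J(4800, 5000)],
                                             self.make_cov(depth), nrt)

    def test_missing_chromosome_errors(self, setting):
        tx, nrt, _ = setting
        cov = CoverageTrack({"chrX": np.zeros(10, dtype=np.int64)})
        with pytest.raises(KeyError):
            find_novel_terminal_exons([J(600, 1000)], cov, nrt)


class TestOrchestration:
    def test_no_junction_reported_in_two_classes(self, study):
        ev = study.events
        internal = {j.key() for e in ev.internal_exons
                    for j in (e.left_junction, e.right_junction)}
        skips = {s.junction.key() for s in ev.skips}
        alts = {a.junction.key() for a in ev.alt_sites}
        assert not internal & skips
        assert not internal & alts
        assert not skips & alts

    def test_classification_is_order_independent(self, small_study):
        res, nrt = small_study.res, small_study.nrt
        shuffled = list(small_study.novel)
        random.Random(4).shuffle(shuffled)
        ev2 = classify_all(shuffled, nrt, res.coverage)
        for attr in ("internal_exons", "skips", "alt_sites", "terminal_exons"):
            a = getattr(small_study.events, attr)
            b = getattr(ev2, attr)
            assert a == b

    def test_summary_counts_add_up(self, study):
        df = summarize_events(study.events).set_index("event_class")
        assert (df.loc["alt3", "n_events"] + df.loc["alt5", "n_events"]
                == df.loc["alt_site", "n_events"])
        assert df.loc["novel_exon_internal", "n_events"] \
            == len(study.events.internal_exons)

    def test_empty_input_summary_is_all_zero(self, study):
        from retsplice.events import EventSet
        df = summarize_events(EventSet())
        assert (df["n_events"] == 0).all()

    def test_events_table_ids_deterministic(self, small_study):
        t1 = events_table(small_study.events)
        t2 = events_table(small_study.events)
        assert t1.equals(t2)
        assert t1["event_id"].is_unique


def test_event_bed12_files_are_well_formed(tmp_path, small_study):
    from retsplice.events import write_event_beds
    paths = write_event_beds(small_study.events, tmp_path)
    assert set(paths) == {"novel_exon_internal", "novel_exon_terminal",
                          "exon_skip", "alt_site"}
    for cls, path in paths.items():
        for line in open(path):
            f = line.rstrip("\n").split("\t")
            assert len(f) == 12
            start, end, n_blocks = int(f[1]), int(f[2]), int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            assert len(sizes) == len(starts) == n_blocks
            assert starts[0] == 0
            assert start + starts[-1] + sizes[-1] <= end
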