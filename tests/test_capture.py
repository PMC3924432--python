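"""Capture-target selection, bait tiling, validation and tissue sharing."""

import random

import pytest

from retsplice.capture import (Bait, CaptureTarget, bait_coverage_profile,
                               check_eligibility, select_targets, tile_baits,
                               target_validated, tissue_sharing,
                               validation_rate, validated_sets)
from retsplice.junctions import Junction
from retsplice.model import RetspliceError


def make_target(feature=100, fl=100, fr=100, event_id="T1",
                cls="novel_exon_internal", keys=(("chr1", 10, 20),)):
    return CaptureTarget(event_id=event_id, event_class=cls, chrom="chr1",
                         feature_len=feature, flank_left=fl, flank_right=fr,
                         region_start=0, region_end=1000, strand="+",
                         novel_junction_keys=tuple(keys))


class TestEligibility:
    @pytest.mark.parametrize("feature,al,ar,ok", [
        (100, 100, 100, True),    # exactly reaches the 300 bp floor
        (500, 300, 300, False),   # feature too long
        (14, 300, 300, False),    # feature too short
        (100, 49, 300, False),    # flank below 50
        (100, 60, 60, False),     # cannot reach 300 bp total
        (401, 300, 300, False),   # 400 bp cap is strict
        (400, 300, 300, True),
    ])
    def test_rule_combinations(self, feature, al, ar, ok):
        assert (check_eligibility(feature, al, ar) is None) == ok

    def test_random_features_match_independent_filter_oracle(self):
        rng = random.Random(31)
        agree = 0
        for _ in range(1000):
            f = rng.randint(1, 700)
            al, ar = rng.randint(0, 400), rng.randint(0, 400)
            got = check_eligibility(f, al, ar) is None
            # independent statement of the three selection rules
            rule1 = 15 <= f <= 400
            rule2 = al >= 50 and ar >= 50
            rule3 = (f + min(al, 500) + min(ar, 500) >= 300
                     and f + 100 <= 500)
            assert got == (rule1 and rule2 and rule3)
            agree += 1
        assert agree == 1000

    def test_selected_targets_satisfy_rules_posthoc(self, study):
        events = (study.events.internal_exons + study.events.skips
                  + study.events.alt_sites)
        targets, rejected = select_targets(events, study.nrt)
        for t in targets:
            assert 300 <= t.capture_length <= 500
            assert t.flank_left >= 50 and t.flank_right >= 50
            if not t.event_class == "exon_skip":
                assert 15 <= t.feature_len <= 400
        assert len(targets) + len(rejected) == len(events)


class TestTiling:
    def test_300bp_region_step40_right_aligned(self):
        baits = tile_baits(make_target(100, 100, 100))  # 300 bp composite
        assert [b.start for b in baits] == [0, 40, 80, 120, 160, 180]
        assert all(b.length == 120 for b in baits)

    def test_region_equal_to_bait_gives_single_bait(self):
        t = make_target(100, 50, 50)  # below floor, but tiling is separate
        t.flank_left = t.flank_right = 10
        baits = tile_baits(t, bait_len=120)
        assert len(baits) == 1 and baits[0].start == 0

    def test_short_region_warns_and_centers(self):
        t = make_target(30, 20, 20)
        with pytest.warns(UserWarning):
            baits = tile_baits(t, bait_len=120)
        assert len(baits) == 1

    def test_baits_contained_and_cover_every_base(self):
        for fl in (100, 150, 190):
            t = make_target(120, fl, fl)
            length = t.capture_length
            baits = tile_baits(t)
            assert all(0 <= b.start and b.end <= length for b in baits)
            prof = bait_coverage_profile(baits, length)
            assert min(prof) >= 1

    def test_interior_mean_coverage_near_threefold(self):
        t = make_target(200, 150, 150)  # 500 bp
        prof = bait_coverage_profile(tile_baits(t), t.capture_length)
        interior = prof[120:-120]
        mean = sum(interior) / len(interior)
        assert 2.5 <= mean <= 3.0


class TestValidation:
    def test_all_targets_present_is_100pct(self):
        targets = [make_target(event_id=f"T{i}", keys=((("chr1", i, i + 50)),))
                   for i in range(10)]
        js = [Junction(chrom="chr1", start=i, end=i + 50, reads=3)
              for i in range(10)]
        df = validation_rate(targets, {"s": js})
        assert df.loc[0, "rate"] == 100.0

    def test_93_of_100_present(self):
        targets = [make_target(event_id=f"T{i}", keys=(("chr1", i * 100, i * 100 + 50),))
                   for i in range(100)]
        js = [Junction(chrom="chr1", start=i * 100, end=i * 100 + 50, reads=1)
              for i in range(93)]
        df = validation_rate(targets, {"s": js})
        assert df.loc[0, "rate"] == pytest.approx(93.0)

    def test_novel_exon_requires_both_junctions_by_default(self):
        t = make_target(keys=(("chr1", 0, 50, "+"), ("chr1", 100, 150, "+")))
        detected = {("chr1", 0, 50)}
        assert not target_validated(t, detected)
        assert target_validated(t, detected, novel_exon_policy="either")

    def test_min_read_threshold(self):
        t = make_target(keys=(("chr1", 0, 50),), cls="exon_skip")
        js = [Junction(chrom="chr1", start=0, end=50, reads=1)]
        assert validation_rate([t], {"s": js}, min_reads=2).loc[0, "rate"] == 0.0

    def test_rate_is_monotone_in_detected_junctions(self):
        rng = random.Random(2)
        targets = [make_target(event_id=f"T{i}",
                               keys=(("chr1", i * 10, i * 10 + 5),),
                               cls="exon_skip")
                   for i in range(50)]
        js = [Junction(chrom="chr1", start=i * 10, end=i * 10 + 5, reads=1)
              for i in range(50)]
        rng.shuffle(js)
        prev = -1.0
        for k in range(0, 51, 10):
            rate = validation_rate(targets, {"s": js[:k]}).loc[0, "rate"]
            assert rate >= prev
            prev = rate

    def test_per_sample_truth_restricts_denominator(self):
        targets = [make_target(event_id="A", keys=(("chr1", 0, 5),),
                               cls="exon_skip"),
                   make_target(event_id="B", keys=(("chr1", 10, 15),),
                               cls="exon_skip")]
        js = [Junction(chrom="chr1", start=0, end=5, reads=1)]
        full = validation_rate(targets, {"s": js})
        restricted = validation_rate(targets, {"s": js},
                                     per_sample_truth={"s": {"A"}})
        assert full.loc[0, "rate"] == 50.0
        assert restricted.loc[0, "rate"] == 100.0

    def test_empty_sample_warns_with_zero_rate(self):
        t = make_target(cls="exon_skip")
        with pytest.warns(UserWarning):
            df = validation_rate([t], {"s": []})
        assert df.loc[0, "rate"] == 0.0


class TestTissueSharing:
    def test_identical_sets_all_shared(self):
        v = {"a": {"x", "y"}, "b": {"x", "y"}}
        df = tissue_sharing(v).set_index("category")
        assert df.loc["shared_all_samples", "n"] == 2
        assert df.loc["exclusive_a", "n"] == 0

    def test_disjoint_sets_share_nothing(self):
        v = {"a": {"x"}, "b": {"y"}}
        df = tissue_sharing(v).set_index("category")
        assert df.loc["shared_all_samples", "n"] == 0

    def test_single_sample_rejected(self):
        with pytest.raises(RetspliceError):
            tissue_sharing({"a": {"x"}})

    def test_random_membership_matches_set_algebra_oracle(self):
        rng = random.Random(77)
        samples = ["r1", "r2", "r3", "brain", "liver"]
        universe = [f"e{i}" for i in range(200)]
        v = {s: {e for e in universe if rng.random() < 0.6} for s in samples}
        df = tissue_sharing(v, retina_samples=["r1", "r2", "r3"]).set_index(
            "category")
        shared = set(universe)
        for s in samples:
            shared &= v[s]
        assert df.loc["shared_all_samples", "n"] == len(shared)
        retina_only = (v["r1"] & v["r2"] & v["r3"]) - (v["brain"] | v["liver"])
        assert df.loc["retina_specific", "n"] == len(retina_only)
        for s in samples:
            others = set().union(*(v[t] for t in samples if t != s))
            assert df.loc[f"exclusive_{s}", "n"] == len(v[s] - others)


class TestPlantedDropout:
    def test_30pct_dropout_gives_roughly_70pct_validation(self, small_sim):
        """Single-junction targets under 30% planted junction dropout
        validate at ~70% (within binomial error)."""
        from retsplice.simulate import simulate_capture
        targets = [make_target(event_id=f"T{i}",
                               keys=((("chr1", i * 100, i * 100 + 60)),),
                               cls="exon_skip")
                   for i in range(400)]
        js = [Junction(chrom="chr1", start=i * 100, end=i * 100 + 60, reads=2)
              for i in range(400)]
        caps = simulate_capture(js, {"s": 0.30}, seed=8)
        rate = validation_rate(targets, caps).loc[0, "rate"]
        # 3-sigma binomial band around 70% with n = 400
        assert abs(rate - 70.0) <= 3 * 100 * (0.3 * 0.7 / 400) ** 0.5


def test_bait_table_counts_match_tiling(tmp_path, study):
    from retsplice.capture import write_bait_table
    events = study.events.internal_exons + study.events.skips
    targets, _ = select_targets(events, study.nrt)
    n = write_bait_table(targets, str(tmp_path / "baits.tsv"))
    assert n == sum(len(tile_baits(t)) for t in targets)
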