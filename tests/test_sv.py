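"""Adaptive-tolerance SV matching, callset subtraction, filters, and VCF I/O."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neocent import (
    SVCall,
    SVCallSet,
    ToleranceRule,
    calls_match,
    filter_calls,
    inspect_region,
    match_tolerance,
    simulate_sv_callsets,
    subtract_callsets,
    SimulationConfig,
)

RULE = ToleranceRule()


def call(id="c", chrom="chr4", start=1_000, svtype="DEL", length=100, support=10):
    return SVCall(id=id, chrom=chrom, start=start, svtype=svtype, length=length, support=support)


def brute_force_subtract(derived: SVCallSet, parental: SVCallSet, rule=RULE) -> SVCallSet:
    """Independent oracle: literal all-pairs scan."""
    kept = []
    for d in derived:
        if not any(calls_match(d, p, rule) for p in parental):
            kept.append(d)
    return SVCallSet(kept)


class TestMatchTolerance:
    @pytest.mark.parametrize(
        "length, expected",
        [(0, 5.0), (100, 5.0), (249, 5.0), (250, 5.0), (251, 5.02), (1_000, 20.0), (10_000, 200.0)],
    )
    def test_rule(self, length, expected):
        assert match_tolerance(length, RULE) == pytest.approx(expected)

    def test_continuous_at_branch_point(self):
        assert match_tolerance(249.999, RULE) == pytest.approx(match_tolerance(250, RULE), abs=1e-6)

    @given(a=st.integers(0, 100_000), b=st.integers(0, 100_000))
    def test_non_decreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert match_tolerance(lo, RULE) <= match_tolerance(hi, RULE)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            match_tolerance(-1, RULE)


class TestCallsMatch:
    def test_small_variant_within_flat_tolerance(self):
        assert calls_match(call(start=1_000, length=100), call(start=1_003, length=98), RULE)

    def test_small_variant_beyond_flat_tolerance(self):
        assert not calls_match(call(start=1_000, length=100), call(start=1_006, length=100), RULE)

    def test_large_variant_scaled_tolerance(self):
        # parental length 1000 -> x = 20; deltas 15 and 10 both within
        assert calls_match(
            call(start=1_000, length=1_000), call(start=1_015, length=1_010), RULE
        )

    def test_tolerance_comes_from_parental_length(self):
        # asymmetric: only the parental call's length sets x
        d = call(start=1_000, length=1_000)
        p = call(start=1_010, length=1_008)
        assert calls_match(d, p, RULE)  # x = tol(1008) > 10
        assert not calls_match(p, d, RULE) if match_tolerance(1_000) < 10 else True

    def test_type_and_chrom_mismatches(self):
        assert not calls_match(call(svtype="DEL"), call(svtype="INS"), RULE)
        assert not calls_match(call(chrom="chr4"), call(chrom="chr5"), RULE)

    def test_bnd_matches_on_position_only(self):
        a = call(svtype="BND", length=0, start=1_000)
        assert calls_match(a, call(svtype="BND", length=0, start=1_004), RULE)
        assert not calls_match(a, call(svtype="BND", length=0, start=1_006), RULE)


def random_callset(rng, n, prefix):
    types = ["INS", "DEL", "DUP", "INV", "BND"]
    calls = []
    for i in range(n):
        svtype = types[rng.integers(0, len(types))]
        calls.append(
            SVCall(
                id=f"{prefix}{i}",
                chrom="chr4" if rng.random() < 0.9 else "chr5",
                start=int(rng.integers(1, 200_000)),
                svtype=svtype,
                length=0 if svtype == "BND" else int(rng.integers(10, 5_000)),
                support=int(rng.integers(0, 40)),
            )
        )
    return SVCallSet(calls)


class TestSubtractCallsets:
    def test_self_subtraction_is_empty(self, rng):
        x = random_callset(rng, 30, "x")
        assert len(subtract_callsets(x, x)) == 0

    def test_empty_parental_returns_all(self, rng):
        x = random_callset(rng, 30, "x")
        assert subtract_callsets(x, SVCallSet()).ids() == x.ids()

    def test_worked_example(self):
        derived = SVCallSet([
            call("d1", start=1_000, length=100, svtype="DEL"),
            call("d2", start=5_000, length=50, svtype="INS"),
            call("d3", start=43_100_000, length=300, svtype="DEL"),
        ])
        parental = SVCallSet([
            call("p1", start=1_002, length=101, svtype="DEL"),
            call("p2", start=5_100, length=50, svtype="INS"),  # delta start 100 > 5
        ])
        assert subtract_callsets(derived, parental).ids() == ["d2", "d3"]

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(200):
            derived = random_callset(rng, int(rng.integers(0, 80)), "d")
            parental = random_callset(rng, int(rng.integers(0, 80)), "p")
            fast = subtract_callsets(derived, parental)
            slow = brute_force_subtract(derived, parental)
            assert fast.ids() == slow.ids()

    def test_anti_monotone_in_parental_set(self, rng):
        derived = random_callset(rng, 50, "d")
        parental = random_callset(rng, 60, "p")
        small = SVCallSet(parental.calls[:20])
        out_small = set(subtract_callsets(derived, small).ids())
        out_full = set(subtract_callsets(derived, parental).ids())
        assert out_full <= out_small

    def test_zero_jitter_simulation_recovers_truth_exactly(self):
        cfg = SimulationConfig(seed=5, position_jitter=0, length_jitter=0, n_novel_svs=3)
        parental, derived, truth = simulate_sv_callsets(cfg)
        assert sorted(subtract_callsets(derived, parental).ids()) == sorted(truth)

    def test_no_novel_and_zero_jitter_gives_empty_set(self):
        cfg = SimulationConfig(seed=6, position_jitter=0, length_jitter=0, n_novel_svs=0)
        parental, derived, _ = simulate_sv_callsets(cfg)
        assert len(subtract_callsets(derived, parental)) == 0

    def test_jitter_beyond_tolerance_leaks_background(self):
        # per-pair brute check of the tolerance rule decides what must leak
        cfg = SimulationConfig(seed=7, position_jitter=500, length_jitter=0)
        parental, derived, truth = simulate_sv_callsets(cfg)
        expected = brute_force_subtract(derived, parental).ids()
        assert subtract_callsets(derived, parental).ids() == expected
        assert set(truth) <= set(expected)
        assert len(expected) > len(truth)  # at least one background call leaked


class TestFilters:
    def test_thresholds_inclusive(self):
        calls = SVCallSet([
            call("keep", length=10, support=5),
            call("short", length=9, support=5),
            call("weak", length=10, support=4),
        ])
        assert filter_calls(calls).ids() == ["keep"]

    def test_region_overlap_is_inclusive_of_footprint(self):
        region = ("chr4", 40_000_000, 60_000_000)
        calls = SVCallSet([
            call("inside", start=50_000_000),
            call("left_overlap", start=39_999_950, length=100, svtype="DEL"),
            call("outside", start=39_000_000),
            call("other_chrom", start=50_000_000, chrom="chr5"),
        ])
        assert filter_calls(calls, region=region).ids() == ["inside", "left_overlap"]

    def test_inverted_region_rejected(self):
        with pytest.raises(ValueError):
            filter_calls(SVCallSet(), region=("chr4", 100, 50))

    def test_inspect_region_window(self):
        inside = call("in", start=43_100_000, length=300)
        outside = call("out", start=43_300_000, length=300)
        hits, report = inspect_region(SVCallSet([inside, outside]))
        assert hits.ids() == ["in"]
        assert "43100000" in report and "out" not in report.split()
        assert inspect_region(SVCallSet())[1] == ""


class TestIO:
    def test_vcf_round_trip(self, tmp_path, rng):
        calls = random_callset(rng, 25, "v").sorted()
        path = tmp_path / "calls.vcf"
        calls.to_vcf(path, contig_lengths={"chr4": 1_000_000, "chr5": 1_000_000})
        back = SVCallSet.from_vcf(path)
        assert back.ids() == calls.ids()
        assert [ (c.chrom, c.start, c.svtype, c.length, c.support) for c in back ] == \
               [ (c.chrom, c.start, c.svtype, c.length, c.support) for c in calls ]

    def test_tsv_round_trip(self, tmp_path, rng):
        calls = random_callset(rng, 25, "t")
        path = tmp_path / "calls.tsv"
        calls.to_tsv(path)
        assert SVCallSet.from_tsv(path) == calls
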