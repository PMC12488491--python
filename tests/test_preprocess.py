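"""Bin aggregation, depth scaling, statistical flags and hom-del eligibility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clonecn.core import CloneProportions, SegmentTable, ValidationError
from clonecn.preprocess import (
    aggregate_bins,
    classify_clonality,
    homdel_eligibility,
    rebalance_alleles,
    scale_depth_to_fractional,
    flag_allelic_imbalance,
)
from clonecn.tree import CloneTree

from conftest import make_fractional


def bins_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "depth", "baf"])


class TestAggregateBins:
    def test_mean_depth_and_baf(self, two_segments):
        bins = bins_frame(
            [
                ("1", 1, 500_000, "R1", 10, 0.5),
                ("1", 500_001, 1_000_000, "R1", 20, 0.5),
            ]
        )
        agg = aggregate_bins(bins, two_segments_subset(two_segments, ["s1"]))
        row = agg.iloc[0]
        assert row["depth"] == pytest.approx(15.0)
        assert row["baf"] == pytest.approx(0.5)

    def test_straddling_bin_counts_in_both_segments(self):
        segments = SegmentTable(
            pd.DataFrame(
                {
                    "segment": ["a", "b"],
                    "chrom": ["1", "1"],
                    "start": [1, 101],
                    "end": [100, 200],
                }
            )
        )
        bins = bins_frame(
            [
                ("1", 1, 80, "R1", 10, 0.5),
                ("1", 81, 120, "R1", 30, 0.5),   # overlaps both
                ("1", 121, 200, "R1", 50, 0.5),
            ]
        )
        agg = aggregate_bins(bins, segments).set_index("segment")
        assert agg.loc["a", "depth"] == pytest.approx(20.0)  # (10+30)/2
        assert agg.loc["b", "depth"] == pytest.approx(40.0)  # (30+50)/2

    def test_uncovered_segment_is_an_error(self, two_segments):
        bins = bins_frame([("1", 1, 1_000_000, "R1", 10, 0.5)])
        with pytest.raises(ValidationError, match="s2"):
            aggregate_bins(bins, two_segments)

    @settings(max_examples=25, deadline=None)
    @given(depths=st.lists(st.floats(0.1, 100), min_size=1, max_size=8))
    def test_matches_naive_mean(self, depths):
        segments = SegmentTable(
            pd.DataFrame({"segment": ["a"], "chrom": ["1"], "start": [1], "end": [10_000]})
        )
        bins = bins_frame(
            [("1", 1 + i, 2 + i, "R1", d, 0.4) for i, d in enumerate(depths)]
        )
        agg = aggregate_bins(bins, segments)
        assert agg["depth"].iloc[0] == pytest.approx(sum(depths) / len(depths))


def two_segments_subset(table, keep):
    return SegmentTable(table.frame[table.frame["segment"].isin(keep)].reset_index(drop=True))


class TestScaleDepth:
    def test_constant_gamma_recovers_reference(self):
        agg = pd.DataFrame(
            {
                "segment": ["a", "b"],
                "sample": ["R1", "R1"],
                "depth": [10.0, 20.0],
                "baf": [0.5, 0.25],
            }
        )
        ref = pd.DataFrame(
            {"segment": ["a", "b"], "sample": ["R1", "R1"], "F": [1.0, 2.0]}
        )
        out = scale_depth_to_fractional(agg, ref).set_index("segment")
        assert out.loc["a", "fA"] + out.loc["a", "fB"] == pytest.approx(1.0)
        assert out.loc["b", "fB"] == pytest.approx(0.5)  # 2.0 * 0.25

    def test_mean_gamma_applied(self):
        # gammas 1.0 and 3.0 -> mean 2.0 -> F = 2 * depth
        agg = pd.DataFrame(
            {
                "segment": ["a", "b"],
                "sample": ["R1", "R1"],
                "depth": [2.0, 1.0],
                "baf": [0.5, 0.5],
            }
        )
        ref = pd.DataFrame(
            {"segment": ["a", "b"], "sample": ["R1", "R1"], "F": [2.0, 3.0]}
        )
        out = scale_depth_to_fractional(agg, ref).set_index("segment")
        total_a = out.loc["a", "fA"] + out.loc["a", "fB"]
        total_b = out.loc["b", "fA"] + out.loc["b", "fB"]
        assert total_a == pytest.approx(4.0)
        assert total_b == pytest.approx(2.0)

    def test_zero_depth_rejected(self):
        agg = pd.DataFrame(
            {"segment": ["a"], "sample": ["R1"], "depth": [0.0], "baf": [0.5]}
        )
        ref = pd.DataFrame({"segment": ["a"], "sample": ["R1"], "F": [1.0]})
        with pytest.raises(ValidationError):
            scale_depth_to_fractional(agg, ref)


def replicate_frame(segment, sample, allele, values):
    return pd.DataFrame(
        {
            "segment": segment,
            "sample": sample,
            "allele": allele,
            "value": list(values),
        }
    )


class TestClonalityAndImbalance:
    def test_integer_values_are_clonal(self):
        frac = make_fractional(["s1"], ["R1"], [[[2.0, 1.0]]])
        reps = replicate_frame("s1", "R1", "A", np.full(30, 2.0) + np.linspace(-0.01, 0.01, 30))
        flags = classify_clonality(frac, reps)
        assert not flags["subclonal"].iloc[0]

    def test_halfway_values_are_subclonal(self):
        frac = make_fractional(["s1"], ["R1"], [[[2.5, 1.0]]])
        rng = np.random.default_rng(0)
        reps = replicate_frame("s1", "R1", "A", 2.5 + rng.normal(0, 0.01, 50))
        flags = classify_clonality(frac, reps)
        assert flags["subclonal"].iloc[0]

    def test_single_replicate_untestable(self):
        frac = make_fractional(["s1"], ["R1"], [[[2.3, 1.0]]])
        reps = replicate_frame("s1", "R1", "A", [2.3])
        flags = classify_clonality(frac, reps)
        assert not flags["testable"].iloc[0]
        assert not flags["subclonal"].iloc[0]

    def test_distinct_alleles_imbalanced(self):
        rng = np.random.default_rng(1)
        reps = pd.concat(
            [
                replicate_frame("s1", "R1", "A", 1.0 + rng.normal(0, 0.05, 30)),
                replicate_frame("s1", "R1", "B", 2.0 + rng.normal(0, 0.05, 30)),
            ]
        )
        flags = flag_allelic_imbalance(reps)
        assert flags["imbalanced"].iloc[0]

    def test_identical_alleles_balanced(self):
        vals = np.linspace(0.9, 1.1, 20)
        reps = pd.concat(
            [
                replicate_frame("s1", "R1", "A", vals),
                replicate_frame("s1", "R1", "B", vals),
            ]
        )
        flags = flag_allelic_imbalance(reps)
        assert not flags["imbalanced"].iloc[0]


class TestRebalance:
    def flags(self, subclonal=True, imbalanced=False):
        return pd.DataFrame(
            {"segment": ["s1"], "subclonal": [subclonal], "imbalanced": [imbalanced]}
        )

    def test_both_above_snaps_allele_b(self):
        frac = make_fractional(["s1"], ["R1"], [[[2.3, 1.4]]])
        out = rebalance_alleles(frac, self.flags())
        assert out.est[0, 0, 1] == pytest.approx(1.0)         # B -> nearest int
        assert out.est[0, 0, 0] == pytest.approx(2.7)         # A absorbs remainder
        assert out.est[0, 0].sum() == pytest.approx(3.7)      # total conserved

    def test_both_below_snaps_allele_a(self):
        frac = make_fractional(["s1"], ["R1"], [[[1.8, 0.9]]])
        out = rebalance_alleles(frac, self.flags())
        assert out.est[0, 0, 0] == pytest.approx(2.0)
        assert out.est[0, 0, 1] == pytest.approx(0.7)
        assert out.est[0, 0].sum() == pytest.approx(2.7)

    def test_clonal_segment_untouched(self):
        frac = make_fractional(["s1"], ["R1"], [[[2.3, 1.4]]])
        out = rebalance_alleles(frac, self.flags(subclonal=False))
        np.testing.assert_allclose(out.est, frac.est)

    def test_mixed_case_untouched(self):
        frac = make_fractional(["s1"], ["R1"], [[[2.3, 0.8]]])  # A above, B below
        out = rebalance_alleles(frac, self.flags())
        np.testing.assert_allclose(out.est, frac.est)

    @settings(max_examples=30, deadline=None)
    @given(
        fa=st.floats(0.05, 5.0),
        fb=st.floats(0.05, 5.0),
    )
    def test_total_always_conserved(self, fa, fb):
        frac = make_fractional(["s1"], ["R1"], [[[fa, fb]]])
        out = rebalance_alleles(frac, self.flags())
        assert out.est[0, 0].sum() == pytest.approx(fa + fb, abs=1e-9)


class TestHomDelEligibility:
    def setup_case(self, seg_len=1_000_000, est=None):
        tree = CloneTree(
            [
                ("diploid", "clone1"),
                ("clone1", "clone2"),
                ("clone1", "clone3"),
            ]
        )
        props = CloneProportions(
            ("diploid", "clone1", "clone2", "clone3"),
            ("R1", "R2"),
            np.array([[0.2, 0.2], [0.3, 0.8], [0.5, 0.0], [0.0, 0.0]]),
        )
        segments = SegmentTable(
            pd.DataFrame(
                {"segment": ["s1"], "chrom": ["1"], "start": [1], "end": [seg_len]}
            )
        )
        if est is None:
            est = [[[0.4, 0.3], [2.0, 1.0]]]
        frac = make_fractional(["s1"], ["R1", "R2"], est, half_width=0.1)
        return tree, props, frac, segments

    def test_long_segment_never_eligible(self):
        tree, props, frac, segments = self.setup_case(seg_len=60_000_000)
        elig = homdel_eligibility(tree, props, frac, segments)
        assert not elig.eligible.any()

    def test_low_cn_sample_with_presence(self):
        tree, props, frac, segments = self.setup_case()
        elig = homdel_eligibility(tree, props, frac, segments).for_segment("s1")
        # clone2 present in R1 where both alleles < 1 -> eligible
        assert elig["clone2"]
        # clone3 absent everywhere -> no supporting sample
        assert not elig["clone3"]
        # clone1 present in R1 itself -> eligible
        assert elig["clone1"]

    def test_ancestors_inherit_eligibility_from_descendants(self):
        # clone2 qualifies through R1; its ancestor clone1 must too (monotone)
        tree, props, frac, segments = self.setup_case()
        props2 = CloneProportions(
            ("diploid", "clone1", "clone2", "clone3"),
            ("R1", "R2"),
            np.array([[0.2, 0.2], [0.0, 0.8], [0.8, 0.0], [0.0, 0.0]]),
        )
        elig = homdel_eligibility(tree, props2, frac, segments).for_segment("s1")
        assert elig["clone2"] and elig["clone1"]
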