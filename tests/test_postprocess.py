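"""Ploidy, WGD calls, event calling, SCNA counting, clone classes and CCD."""

import numpy as np
import pandas as pd
import pytest

from clonecn.core import CloneCNProfile, CloneProportions, SegmentTable
from clonecn.postprocess import (
    call_arm_events,
    call_segment_events,
    classify_clones,
    clone_ploidy,
    compute_ccd,
    count_scnas_per_edge,
    detect_wgd,
    sample_level_arm_loh,
)
from clonecn.tree import CloneTree

from conftest import make_fractional


def profile_from(segments, clones, cA, cB):
    return CloneCNProfile(tuple(segments), tuple(clones), np.array(cA), np.array(cB))


def segment_table(lengths, chrom="1", arm="p"):
    rows, pos = [], 1
    for i, ln in enumerate(lengths):
        rows.append(
            {"segment": f"s{i+1}", "chrom": chrom, "start": pos, "end": pos + ln - 1,
             "arm": arm}
        )
        pos += ln
    return SegmentTable(pd.DataFrame(rows))


class TestPloidy:
    def test_diploid(self):
        segs = segment_table([100, 100])
        p = profile_from(["s1", "s2"], ["diploid", "c1"], [[1, 1], [1, 1]], [[1, 1], [1, 1]])
        assert clone_ploidy(p, segs)["c1"] == pytest.approx(2.0)

    def test_equal_lengths(self):
        segs = segment_table([100, 100])
        p = profile_from(["s1", "s2"], ["c1"], [[1], [2]], [[1], [2]])
        assert clone_ploidy(p, segs)["c1"] == pytest.approx(3.0)

    def test_length_weighted(self):
        segs = segment_table([1_000_000, 3_000_000])
        p = profile_from(["s1", "s2"], ["c1"], [[1], [2]], [[1], [2]])
        # (1M * 2 + 3M * 4) / 4M = 3.5
        assert clone_ploidy(p, segs)["c1"] == pytest.approx(3.5)


class TestWgd:
    def make(self, totals_by_clone, edges):
        segs = segment_table([100] * len(next(iter(totals_by_clone.values()))))
        clones = list(totals_by_clone)
        cA = np.array([[totals_by_clone[c][i] for c in clones] for i in range(len(segs))])
        cB = np.zeros_like(cA)
        profile = CloneCNProfile(tuple(segs.segments), tuple(clones), cA, cB)
        return profile, CloneTree(edges), segs

    def test_doubling_flagged(self):
        profile, tree, segs = self.make(
            {"c1": [2, 2], "c2": [4, 4]},
            [("diploid", "c1"), ("c1", "c2")],
        )
        flags = detect_wgd(profile, tree, segs)
        assert flags["c2"] and not flags["c1"]

    def test_unchanged_not_flagged(self):
        profile, tree, segs = self.make(
            {"c1": [2, 2], "c2": [2, 2]},
            [("diploid", "c1"), ("c1", "c2")],
        )
        assert not detect_wgd(profile, tree, segs).any()

    def test_two_step_doubling_caught_by_grandparent_rule(self):
        # 1.4x then 1.4x: neither edge alone exceeds 1.5, but child vs
        # grandparent is 1.96 > 1.5 and the parent is unflagged
        profile, tree, segs = self.make(
            {"c1": [10, 10], "c2": [14, 14], "c3": [20, 20]},
            [("diploid", "c1"), ("c1", "c2"), ("c2", "c3")],
        )
        flags = detect_wgd(profile, tree, segs)
        assert not flags["c2"]
        assert flags["c3"]


class TestSegmentEvents:
    def test_loss_with_loh(self):
        tree = CloneTree([("diploid", "c1"), ("c1", "c2")])
        p = profile_from(["s1"], ["c1", "c2"], [[2, 2]], [[1, 0]])
        ploidy = clone_ploidy(p, segment_table([100]))
        ev = call_segment_events(p, tree, ploidy)
        row = ev[(ev.child == "c2")].iloc[0]
        assert row.loss and row.loh and not row.gain and not row.amplification

    def test_amplification_requires_all_three_criteria(self):
        tree = CloneTree([("diploid", "c1"), ("c1", "c2")])
        # child 5 from parent 2 on s1: 5 > 2*2, 5 >= 4, and 5 > child ploidy
        # (child ploidy is (5+2+1+1)/2 = 4.5 over the two equal segments)
        p = profile_from(
            ["s1", "s2"], ["c1", "c2"], [[2, 5], [1, 1]], [[2, 2], [1, 1]]
        )
        ploidy = clone_ploidy(p, segment_table([100, 100]))
        ev = call_segment_events(p, tree, ploidy)
        row = ev[(ev.child == "c2") & (ev.segment == "s1")].iloc[0]
        assert row.amplification and row.gain

    def test_no_change_no_flags(self):
        tree = CloneTree([("diploid", "c1")])
        p = profile_from(["s1"], ["c1"], [[1]], [[1]])
        ev = call_segment_events(p, tree, clone_ploidy(p, segment_table([100])))
        row = ev.iloc[0]
        assert not (row.gain or row.loss or row.loh or row.amplification)

    def test_amplification_implies_gain_property(self):
        rng = np.random.default_rng(5)
        tree = CloneTree([("diploid", "c1"), ("c1", "c2")])
        segs = segment_table([100] * 10)
        cA = np.column_stack([rng.integers(0, 3, 10), rng.integers(0, 7, 10)])
        cB = np.column_stack([rng.integers(0, 3, 10), rng.integers(0, 7, 10)])
        p = CloneCNProfile(tuple(segs.segments), ("c1", "c2"), cA, cB)
        ev = call_segment_events(p, tree, clone_ploidy(p, segs))
        assert (~ev.amplification | ev.gain).all()
        assert (~ev.loh | ev.loss).all()


class TestArmEvents:
    def arm_case(self, lengths, child_cA, parent_cA=None):
        segs = segment_table(lengths)
        m = len(lengths)
        parent_cA = parent_cA if parent_cA is not None else [2] * m
        tree = CloneTree([("diploid", "c1"), ("c1", "c2")])
        cA = np.column_stack([parent_cA, child_cA])
        cB = np.ones((m, 2), dtype=int)
        p = CloneCNProfile(tuple(segs.segments), ("c1", "c2"), cA, cB)
        ev = call_segment_events(p, tree, clone_ploidy(p, segs))
        return call_arm_events(ev, segs, p, tree), p

    def test_full_arm_loss(self):
        arm, _ = self.arm_case([100], [1])
        row = arm[arm.child == "c2"].iloc[0]
        assert row.loss

    def test_85_percent_not_enough(self):
        arm, _ = self.arm_case([85, 15], [1, 2])
        row = arm[arm.child == "c2"].iloc[0]
        assert not row.loss

    def test_arm_loh_parent_threshold(self):
        # child at 0 on 95% of the arm; parent at 0 on 15% -> arm LOH
        arm, _ = self.arm_case([15, 80, 5], [0, 0, 1], parent_cA=[0, 2, 2])
        assert arm[arm.child == "c2"].iloc[0].loh
        # parent at 0 on 25% -> no arm LOH
        arm2, _ = self.arm_case([25, 70, 5], [0, 0, 1], parent_cA=[0, 2, 2])
        assert not arm2[arm2.child == "c2"].iloc[0].loh


class TestSampleArmLoh:
    def test_uniformly_low_called(self):
        segs = segment_table([100])
        frac = make_fractional(["s1"], ["R1"], [[[0.2, 1.0]]], half_width=0.05)
        calls = sample_level_arm_loh(frac, segs)
        assert calls.iloc[0].arm_loh

    def test_97_percent_not_called(self):
        segs = segment_table([97, 3])
        frac = make_fractional(
            ["s1", "s2"], ["R1"], [[[0.2, 1.0]], [[1.0, 1.0]]], half_width=0.05
        )
        calls = sample_level_arm_loh(frac, segs)
        assert not calls.iloc[0].arm_loh

    def test_alleles_not_pooled(self):
        # A low on 60%, B low on the disjoint 40%: neither allele alone reaches 98%
        segs = segment_table([60, 40])
        frac = make_fractional(
            ["s1", "s2"], ["R1"], [[[0.2, 1.0]], [[1.0, 0.2]]], half_width=0.05
        )
        calls = sample_level_arm_loh(frac, segs)
        assert not calls.iloc[0].arm_loh


class TestCountScnas:
    def count(self, deltasA, chroms=None):
        m = len(deltasA)
        if chroms is None:
            chroms = ["1"] * m
        rows, pos = [], {}
        recs = []
        for i, ch in enumerate(chroms):
            p = pos.get(ch, 1)
            recs.append({"segment": f"s{i+1}", "chrom": ch, "start": p, "end": p + 99})
            pos[ch] = p + 100
        segs = SegmentTable(pd.DataFrame(recs))
        tree = CloneTree([("diploid", "c1"), ("c1", "c2")])
        cA = np.array([[2, 2 + d] for d in deltasA])
        cB = np.full((m, 2), 2, dtype=int)
        profile = CloneCNProfile(tuple(f"s{i+1}" for i in range(m)), ("c1", "c2"), cA, cB)
        counts = count_scnas_per_edge(profile, tree, segs)
        return counts[counts.child == "c2"].iloc[0]

    def test_zero_breaks_run(self):
        row = self.count([1, 1, 0, 1])
        assert row.n_gains == 2 and row.n_losses == 0

    def test_amplitude_breaks_run(self):
        row = self.count([2, 1])
        assert row.n_gains == 2  # different amplitude: two events

    def test_gain_and_loss(self):
        row = self.count([1, -1])
        assert row.n_gains == 1 and row.n_losses == 1 and row.n_scnas == 2

    def test_chromosome_breaks_run(self):
        row = self.count([1, 1], chroms=["1", "2"])
        assert row.n_gains == 2

    def test_matches_naive_oracle_on_random_profiles(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            deltas = rng.integers(-2, 3, size=12).tolist()
            chroms = sorted(rng.choice(["1", "2", "3"], size=12).tolist())
            row = self.count(deltas, chroms)
            # naive per-position oracle
            gains = losses = 0
            prev = (None, 0)
            for ch, d in zip(chroms, deltas):
                if d != 0 and (ch, d) != prev:
                    if d > 0:
                        gains += 1
                    else:
                        losses += 1
                prev = (ch, d)
            assert (row.n_gains, row.n_losses) == (gains, losses)

    def test_run_count_bounded_by_total_events(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            deltas = rng.integers(-2, 3, size=10).tolist()
            row = self.count(deltas)
            assert row.n_scnas <= sum(abs(d) for d in deltas)


class TestClassifyClones:
    def classify(self, u, samples, sites, edges):
        clones = ["diploid"] + [c for _, c in edges if c != "diploid"]
        tree = CloneTree(edges)
        props = CloneProportions(tuple(clones), tuple(samples), np.array(u))
        return classify_clones(tree, props, sites)

    def test_most_recent_shared_is_seeding(self):
        edges = [("diploid", "c1"), ("c1", "c2"), ("c2", "c3")]
        # c3 only in metastasis, c2 in both, c1 primary+met via descendants
        u = [
            [0.2, 0.2],
            [0.5, 0.0],
            [0.3, 0.3],
            [0.0, 0.5],
        ]
        labels = self.classify(
            u, ["P1", "M1"], {"P1": "primary", "M1": "metastasis"}, edges
        )
        assert labels.loc["c2", "clone_class"] == "seeding"
        assert labels.loc["c3", "clone_class"] == "metastasis-specific"

    def test_truncal_seeding_marks_mrca(self):
        edges = [("diploid", "c1"), ("c1", "c2"), ("c1", "c3")]
        u = [
            [0.2, 0.2],
            [0.2, 0.8],
            [0.6, 0.0],   # primary only
            [0.0, 0.0],
        ]
        labels = self.classify(
            u, ["P1", "M1"], {"P1": "primary", "M1": "metastasis"}, edges
        )
        assert labels.loc["c1", "clone_class"] == "MRCA"
        assert labels.loc["c1", "is_seeding"]

    def test_polyclonal_seeding(self):
        edges = [("diploid", "c1"), ("c1", "c2"), ("c1", "c3")]
        # both c2 and c3 are present in the primary and in one metastasis
        # each, with no shared descendants: polyclonal seeding
        u = [
            [0.2, 0.2, 0.2],
            [0.2, 0.4, 0.0],
            [0.4, 0.4, 0.0],
            [0.2, 0.0, 0.8],
        ]
        labels = self.classify(
            u,
            ["P1", "M1", "M2"],
            {"P1": "primary", "M1": "metastasis", "M2": "metastasis"},
            edges,
        )
        assert labels.loc["c2", "is_seeding"] and labels.loc["c3", "is_seeding"]

    def test_no_metastatic_samples(self):
        edges = [("diploid", "c1"), ("c1", "c2")]
        u = [[0.2], [0.3], [0.5]]
        labels = self.classify(u, ["P1"], {"P1": "primary"}, edges)
        assert labels.loc["c2", "clone_class"] == "primary-specific"
        assert not labels["is_seeding"].any()


class TestCcd:
    def test_identical_clones_zero(self):
        p = profile_from(["s1", "s2"], ["c1", "c2"], [[2, 2], [1, 1]], [[1, 1], [1, 1]])
        assert compute_ccd(p) == 0.0

    def test_four_unit_differences(self):
        # clones differ by 1 copy in exactly 4 segment-allele entries -> sqrt(4)
        p = profile_from(
            ["s1", "s2"],
            ["c1", "c2"],
            [[2, 1], [2, 1]],
            [[1, 0], [1, 0]],
        )
        assert compute_ccd(p) == pytest.approx(2.0)

    def test_three_clones_equals_pairwise_max(self):
        rng = np.random.default_rng(13)
        cA = rng.integers(0, 4, (5, 3))
        cB = rng.integers(0, 4, (5, 3))
        p = profile_from([f"s{i}" for i in range(5)], ["c1", "c2", "c3"], cA, cB)
        brute = max(
            np.linalg.norm(
                np.concatenate([cA[:, i] - cA[:, j], cB[:, i] - cB[:, j]]).astype(float)
            )
            for i in range(3)
            for j in range(i + 1, 3)
        )
        assert compute_ccd(p) == pytest.approx(brute)

    def test_adding_clones_never_decreases(self):
        rng = np.random.default_rng(17)
        cA = rng.integers(0, 4, (4, 4))
        cB = rng.integers(0, 4, (4, 4))
        segs = [f"s{i}" for i in range(4)]
        p3 = profile_from(segs, ["c1", "c2", "c3"], cA[:, :3], cB[:, :3])
        p4 = profile_from(segs, ["c1", "c2", "c3", "c4"], cA, cB)
        assert compute_ccd(p4) >= compute_ccd(p3)

    def test_empty_selection_rejected(self):
        p = profile_from(["s1"], ["c1"], [[1]], [[1]])
        with pytest.raises(Exception):
            compute_ccd(p, include_clones=[])
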