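import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import exact_mann_whitney_p
from stoch_m6a import comparative_analysis as ca
from stoch_m6a.peak_calling import Peak, PeakSet
from stoch_m6a.synthetic_data import PlantedPeak, SyntheticTruth


def make_peak(tid, start, end):
    return Peak(tid, start, end, 9.0, 2.0, 4.0, frozenset({"rep1"}))


class TestTranscriptOverlap:
    def test_equal_nonempty_sets_share_everything(self):
        report = ca.transcript_overlap({"a", "b"}, {"a", "b"})
        assert report.percent_shared == 100.0

    def test_union_denominator_example(self):
        report = ca.transcript_overlap({"a", "b", "c"}, {"b", "c", "d"})
        assert (report.n_intersection, report.n_union) == (2, 4)
        assert report.percent_shared == 50.0

    def test_disjoint_sets_share_nothing(self):
        assert ca.transcript_overlap({"a"}, {"b"}).percent_shared == 0.0

    def test_empty_sets_give_nan(self):
        assert math.isnan(ca.transcript_overlap(set(), set()).percent_shared)

    @given(
        a=st.sets(st.integers(0, 30)),
        b=st.sets(st.integers(0, 30)),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_symmetric_and_100_iff_equal(self, a, b):
        a = {str(x) for x in a}
        b = {str(x) for x in b}
        fwd = ca.transcript_overlap(a, b).percent_shared
        rev = ca.transcript_overlap(b, a).percent_shared
        assert (fwd == rev) or (math.isnan(fwd) and math.isnan(rev))
        if a or b:
            assert (fwd == 100.0) == (a == b)


class TestPeaksEncompassingSites:
    def test_no_sites_gives_zero_zero(self):
        ps = PeakSet(peaks=[make_peak("g1", 0, 50)])
        assert ca.peaks_encompassing_sites(ps, set()) == (0, 0)

    def test_one_peak_with_three_sites_counts_once_and_thrice(self):
        ps = PeakSet(peaks=[make_peak("g1", 10, 60)])
        sites = {("g1", 10), ("g1", 30), ("g1", 59)}
        assert ca.peaks_encompassing_sites(ps, sites) == (1, 3)

    def test_site_at_peak_end_is_outside_the_half_open_interval(self):
        ps = PeakSet(peaks=[make_peak("g1", 10, 60)])
        assert ca.peaks_encompassing_sites(ps, {("g1", 60)}) == (0, 0)
        assert ca.peaks_encompassing_sites(ps, {("g1", 9)}) == (0, 0)
        assert ca.peaks_encompassing_sites(ps, {("g2", 30)}) == (0, 0)


class TestMetageneProfile:
    def test_boundary_positions_fall_in_first_and_last_bins(self):
        # one motif at p=0 and one at p=0.99 on a 500-nt transcript
        seq = list("C" * 500)
        seq[0:5] = "GCCAU"
        seq[495:500] = "GCCAU"
        ps = PeakSet(peaks=[])
        profile = ca.metagene_profile(ps, {"g1": "".join(seq)}, ["GCCAU"])
        assert profile.denominators[0] == 1 and profile.denominators[9] == 1

    def test_peaks_over_first_half_give_step_profile(self):
        # 10 motifs, one per bin, peaks covering bins 1-5 exactly
        seq = []
        for _ in range(10):
            seq.append("GCCAU" + "C" * 45)
        sequence = "".join(seq)  # length 500, motif at start of each bin
        ps = PeakSet(peaks=[make_peak("g1", 0, 250)])
        profile = ca.metagene_profile(ps, {"g1": sequence}, ["GCCAU"])
        assert profile.denominators.tolist() == [1] * 10
        assert profile.bins.tolist() == [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]

    def test_no_peaks_gives_all_zero_profile(self):
        sequence = ("GCCAU" + "C" * 45) * 10
        profile = ca.metagene_profile(PeakSet(), {"g1": sequence}, ["GCCAU"])
        assert profile.numerators.sum() == 0
        assert all(v == 0 for v in profile.bins)

    def test_empty_bins_are_nan_and_numerator_bounded(self):
        sequence = "GCCAU" + "C" * 495
        profile = ca.metagene_profile(PeakSet(), {"g1": sequence}, ["GCCAU"])
        assert math.isnan(profile.bins[5])
        assert (profile.numerators <= profile.denominators).all()

    def test_pooling_is_additive_over_transcripts(self):
        seq_a = "GCCAU" + "C" * 95
        seq_b = "C" * 50 + "GCCAU" + "C" * 45
        ps = PeakSet(peaks=[make_peak("a", 0, 100)])
        pooled = ca.metagene_profile(ps, {"a": seq_a, "b": seq_b}, ["GCCAU"])
        only_a = ca.metagene_profile(ps, {"a": seq_a}, ["GCCAU"])
        only_b = ca.metagene_profile(ps, {"b": seq_b}, ["GCCAU"])
        assert (pooled.numerators == only_a.numerators + only_b.numerators).all()
        assert (pooled.denominators == only_a.denominators + only_b.denominators).all()


class TestMannWhitney:
    def test_identical_samples_are_not_significant(self):
        x = [0.1, 0.2, 0.3, 0.4, 0.5]
        assert ca.mann_whitney(x, x) > 0.9

    def test_fully_separated_samples_are_significant(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.0, 0.1, size=20)
        y = rng.uniform(0.9, 1.0, size=20)
        assert ca.mann_whitney(x, y) < 1e-6

    def test_too_few_observations_gives_nan(self):
        assert math.isnan(ca.mann_whitney([0.1], [0.2, 0.3]))

    @given(
        n1=st.integers(2, 8),
        n2=st.integers(2, 8),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_exact_enumeration_for_small_samples(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        values = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
        x, y = values[:n1], values[n1:]
        assert ca.mann_whitney(x, y) == pytest.approx(
            exact_mann_whitney_p(x, y), abs=1e-12
        )

    def test_compare_profiles_uses_modified_positions(self):
        a = ca.MetageneProfile(None, np.zeros(10, int), np.ones(10, int),
                               modified_positions=[0.05] * 12)
        b = ca.MetageneProfile(None, np.zeros(10, int), np.ones(10, int),
                               modified_positions=[0.95] * 12)
        assert ca.compare_profiles(a, b) < 1e-3


class TestRpkm:
    def test_unit_case(self):
        table = ca.compute_rpkm(pd.Series({"g": 10}), {"g": 1000}, library_size=10**6)
        assert table.loc["g", "rpkm"] == pytest.approx(10.0)

    def test_zero_count_gives_zero_rpkm(self):
        table = ca.compute_rpkm(pd.Series({"g": 0}), {"g": 500}, library_size=10**6)
        assert table.loc["g", "rpkm"] == 0.0

    def test_arithmetic_example(self):
        table = ca.compute_rpkm(pd.Series({"g": 7}), {"g": 350}, library_size=2 * 10**6)
        assert table.loc["g", "rpkm"] == pytest.approx(10.0)

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError, match="library size"):
            ca.compute_rpkm(pd.Series({"g": 0}), {"g": 100}, library_size=0)


class TestExpressionGroups:
    def test_nine_genes_split_three_ways(self):
        values = pd.Series({f"g{i}": float(i) for i in range(9)})
        groups = ca.expression_groups(values)
        assert list(groups.value_counts()[["low", "mid", "high"]]) == [3, 3, 3]
        assert set(groups[groups == "low"].index) == {"g0", "g1", "g2"}

    def test_ten_genes_remainder_goes_to_low(self):
        values = pd.Series({f"g{i}": float(i) for i in range(10)})
        counts = ca.expression_groups(values).value_counts()
        assert (counts["low"], counts["mid"], counts["high"]) == (4, 3, 3)

    def test_all_equal_values_partition_deterministically_by_id(self):
        values = pd.Series({f"g{i}": 1.0 for i in range(9)})
        groups = ca.expression_groups(values)
        assert set(groups[groups == "low"].index) == {"g0", "g1", "g2"}
        assert groups.equals(ca.expression_groups(values.sample(frac=1, random_state=1)
                                                  .loc[values.index]))

    def test_fewer_genes_than_groups_rejected(self):
        with pytest.raises(ValueError):
            ca.expression_groups(pd.Series({"a": 1.0, "b": 2.0}), k=3)


class TestExpressionComparison:
    def test_identical_conditions_have_zero_fc_and_r_one(self):
        rpkm = pd.Series({"a": 5.0, "b": 50.0, "c": 500.0})
        frame, r = ca.expression_comparison(rpkm, rpkm)
        assert (frame["log2fc"] == 0).all()
        assert not frame["de_flag"].any()
        assert r == pytest.approx(1.0)

    def test_fourfold_change_is_flagged(self):
        ctrl = pd.Series({"a": 100.0, "b": 200.0, "c": 300.0})
        stress = ctrl.copy()
        stress["a"] = 400.0
        frame, _ = ca.expression_comparison(ctrl, stress)
        assert frame.loc["a", "log2fc"] == pytest.approx(2.0, abs=1e-3)
        assert bool(frame.loc["a", "de_flag"])
        assert not frame.loc["b", "de_flag"]

    def test_injected_fold_changes_recovered_exactly(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(200)]
        ctrl = pd.Series(rng.uniform(5, 500, size=200), index=genes)
        fc = rng.choice([0.25, 1.0, 4.0], size=200, p=[0.1, 0.8, 0.1])
        stress = ctrl * fc
        frame, _ = ca.expression_comparison(ctrl, stress)
        assert (frame["de_flag"].to_numpy() == (fc != 1.0)).all()

    def test_pearson_r_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(100)]
        ctrl = pd.Series(2.0 ** rng.normal(4, 1, size=100), index=genes)
        stress = pd.Series(2.0 ** rng.normal(4, 1, size=100), index=genes)
        _, r1 = ca.expression_comparison(ctrl, stress, pseudocount=0)
        # scaling RPKM by 2**c shifts log2 by c, an affine map
        _, r2 = ca.expression_comparison(ctrl * 8, stress * 2, pseudocount=0)
        assert r1 == pytest.approx(r2)

    def test_no_shared_genes_is_an_error(self):
        with pytest.raises(ValueError, match="shared"):
            ca.expression_comparison(pd.Series({"a": 1.0}), pd.Series({"b": 1.0}))


class TestMethylationByExpression:
    def groups(self, mapping):
        return pd.Series(mapping)

    def test_no_methylated_transcripts_gives_zero_table(self):
        out = ca.methylation_by_expression(
            {"ctrl": set()}, {"ctrl": self.groups({"a": "low", "b": "high"})}
        )
        assert (out.counts.to_numpy() == 0).all()

    def test_all_planted_on_high_tertile(self):
        groups = self.groups({"a": "low", "b": "mid", "c": "high", "d": "high"})
        out = ca.methylation_by_expression({"ctrl": {"c", "d"}}, {"ctrl": groups})
        assert out.counts.loc["ctrl", "high"] == 2
        assert out.counts.loc["ctrl"].drop("high").sum() == 0

    def test_identical_peaksets_lose_nothing(self):
        groups = self.groups({"a": "high", "b": "high", "c": "low"})
        out = ca.methylation_by_expression(
            {"ctrl": {"a", "b"}, "stress": {"a", "b"}},
            {"ctrl": groups, "stress": groups},
            tracked_subset={"a", "b"},
            baseline_condition="ctrl",
        )
        assert out.tracked["stress"]["lost"] == 0
        assert out.tracked["stress"]["retained"] == 2

    def test_lost_and_redistributed(self):
        out = ca.methylation_by_expression(
            {"ctrl": {"a", "b"}, "stress": {"b"}},
            {
                "ctrl": self.groups({"a": "high", "b": "high"}),
                "stress": self.groups({"a": "low", "b": "high"}),
            },
            tracked_subset={"a", "b"},
            baseline_condition="ctrl",
        )
        tracked = out.tracked["stress"]
        assert tracked == {
            "retained": 1,
            "lost": 1,
            "redistribution": {"high": 1, "low": 1},
        }


class TestRecoveryMetrics:
    def truth(self, intervals):
        return SyntheticTruth(
            planted_peaks=[PlantedPeak("g1", s, e, "GCCAU", 8.0) for s, e in intervals]
        )

    def test_perfect_recovery(self):
        truth = self.truth([(0, 50), (100, 150)])
        ps = PeakSet(peaks=[make_peak("g1", 0, 50), make_peak("g1", 100, 150)])
        metrics = ca.peak_recovery_metrics(ps, truth)
        assert (metrics.precision, metrics.recall) == (1.0, 1.0)

    def test_empty_calls_give_nan_precision_zero_recall(self):
        metrics = ca.peak_recovery_metrics(PeakSet(), self.truth([(0, 50)]))
        assert math.isnan(metrics.precision) and metrics.recall == 0.0

    def test_empty_truth_gives_nan_recall(self):
        metrics = ca.peak_recovery_metrics(PeakSet(peaks=[make_peak("g1", 0, 50)]),
                                           self.truth([]))
        assert math.isnan(metrics.recall)

    def test_partial_recovery_counts(self):
        truth = self.truth([(i * 100, i * 100 + 50) for i in range(10)])
        called = [make_peak("g1", i * 100 + 40, i * 100 + 90) for i in range(8)]
        called += [make_peak("g1", 5000, 5050), make_peak("g1", 6000, 6050)]
        metrics = ca.peak_recovery_metrics(PeakSet(peaks=called), truth)
        assert metrics.precision == pytest.approx(0.8)
        assert metrics.recall == pytest.approx(0.8)

    def test_one_nt_overlap_counts_as_recovered(self):
        truth = self.truth([(100, 150)])
        ps = PeakSet(peaks=[make_peak("g1", 50, 101)])
        assert ca.peak_recovery_metrics(ps, truth).recall == 1.0
        ps_touch = PeakSet(peaks=[make_peak("g1", 50, 100)])
        assert ca.peak_recovery_metrics(ps_touch, truth).recall == 0.0

    def test_site_recovery_exact_position(self):
        metrics = ca.site_recovery_metrics(
            {("g1", 5), ("g1", 7)}, [("g1", 5), ("g1", 9)]
        )
        assert metrics.precision == 0.5 and metrics.recall == 0.5
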