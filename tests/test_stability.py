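"""MAD stability scoring, threshold windows, clustering and cosinor."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_
from sklearn.metrics import adjusted_rand_score

import mirstab as ms

finite_vectors = st_.lists(
    st_.floats(min_value=-100, max_value=100, allow_nan=False),
    min_size=1, max_size=30,
)


class TestMadScore:
    def test_constant_vector_has_zero_mad(self):
        assert ms.mad_score([3.7] * 9) == 0.0

    def test_hand_computed_value(self):
        # median 0, abs deviations (0.2, 0.1, 0, 0.1, 0.2) -> median 0.1
        assert ms.mad_score([-0.2, -0.1, 0, 0.1, 0.2]) == pytest.approx(
            1.4826 * 0.1, abs=1e-15
        )

    def test_matches_scipy_normal_scaled_mad(self):
        from scipy.stats import median_abs_deviation

        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.normal(size=rng.integers(3, 50))
            # b = 1.4826 is the conventional rounding of scipy's exact
            # Gaussian factor 1/Phi^-1(3/4) = 1.4826022...
            assert ms.mad_score(x) == pytest.approx(
                median_abs_deviation(x, scale="normal"), rel=1e-5
            )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(finite_vectors, st_.floats(-50, 50, allow_nan=False))
    def test_translation_invariance(self, x, c):
        assert ms.mad_score(np.array(x) + c) == pytest.approx(
            ms.mad_score(x), abs=1e-12
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(finite_vectors, st_.floats(-20, 20, allow_nan=False))
    def test_scale_equivariance(self, x, c):
        assert ms.mad_score(np.array(x) * c) == pytest.approx(
            abs(c) * ms.mad_score(x), abs=1e-10
        )

    def test_breakdown_point(self):
        # corrupting floor((n-1)/2) entries cannot blow up the MAD
        x = np.zeros(9)
        x[:4] = 1e12
        assert ms.mad_score(x) == 0.0

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            ms.mad_score([])


class TestThresholdWindow:
    def test_hand_computed_window(self):
        lo, hi = ms.threshold_window([-0.2, -0.1, 0, 0.1, 0.2], k=3)
        assert lo == pytest.approx(-0.44478, abs=1e-10)
        assert hi == pytest.approx(+0.44478, abs=1e-10)

    def test_constant_vector_degenerate_window(self):
        assert ms.threshold_window([2.0] * 5) == (2.0, 2.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(finite_vectors, st_.floats(-10, 10, allow_nan=False))
    def test_shift_equivariance(self, x, c):
        lo1, hi1 = ms.threshold_window(x)
        lo2, hi2 = ms.threshold_window(np.array(x) + c)
        assert lo2 == pytest.approx(lo1 + c, abs=1e-9)
        assert hi2 == pytest.approx(hi1 + c, abs=1e-9)

    def test_half_width_is_k_times_mad(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=9)
        lo, hi = ms.threshold_window(x, k=3)
        assert hi - lo == pytest.approx(2 * 3 * ms.mad_score(x), rel=1e-12)


class TestTimepointLog2FC:
    @staticmethod
    def _sheet(tps, n_subj):
        rows = [(f"p{s}_t{t:g}", f"p{s}", t, "healthy", "d")
                for t in tps for s in range(n_subj)]
        return ms.SampleTable(pd.DataFrame(
            rows, columns=["sample_id", "subject_id", "timepoint_h",
                           "condition", "dataset_id"]))

    def test_identical_means_give_zero_vector(self):
        st = self._sheet([0, 3, 6], 2)
        vals = pd.DataFrame(100.0, index=["m1"], columns=st.sample_ids)
        nm = ms.NormalizedMatrix(vals, pd.Series(1.0, index=st.sample_ids))
        x = ms.timepoint_log2fc(nm, st, pseudocount=1.0)
        np.testing.assert_allclose(x.to_numpy(), 0.0, atol=1e-12)

    def test_doubled_timepoint_mean_gives_unit_log2fc(self):
        st = self._sheet([0, 3, 6], 1)
        # means per timepoint 40, 10, 10 -> overall 20; with pc -> ~1 at t=0
        vals = pd.DataFrame([[40.0, 10.0, 10.0]], index=["m1"],
                            columns=st.sample_ids)
        nm = ms.NormalizedMatrix(vals, pd.Series(1.0, index=st.sample_ids))
        x = ms.timepoint_log2fc(nm, st, pseudocount=1e-9)
        assert x.iloc[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force_group_means(self, healthy_normalized):
        nm, st = healthy_normalized
        x = ms.timepoint_log2fc(nm, st, pseudocount=1.0)
        rng = np.random.default_rng(4)
        for fid in rng.choice(nm.values.index, 5, replace=False):
            row = nm.values.loc[fid]
            overall = row.mean()
            for t in st.timepoints_h:
                expected = np.log2((row[st.samples_at(t)].mean() + 1) / (overall + 1))
                assert x.at[fid, t] == pytest.approx(expected, rel=1e-12)

    def test_columns_ordered_by_time(self, healthy_normalized):
        nm, st = healthy_normalized
        x = ms.timepoint_log2fc(nm, st)
        assert list(x.columns) == sorted(x.columns)


class TestSelectStable:
    def test_cutoff_is_strict(self):
        mads = pd.Series({"at": 0.2, "below": 0.19999, "above": 0.3})
        assert ms.select_stable(mads, 0.2) == {"below"}

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(8)
        mads = pd.Series(rng.uniform(0, 0.5, 50),
                         index=[f"m{i}" for i in range(50)])
        assert ms.select_stable(mads, 0.1) <= ms.select_stable(mads, 0.3)

    def test_infinite_cutoff_selects_all(self):
        mads = pd.Series({"a": 0.1, "b": 99.0})
        assert ms.select_stable(mads, np.inf) == {"a", "b"}


class TestClusterProfiles:
    def test_two_separable_groups_recovered_exactly(self):
        rng = np.random.default_rng(1)
        tps = np.array([0, 3, 6, 24, 48, 72, 168, 720, 1440.0])
        flat = rng.normal(0, 0.02, (20, 9))
        cosine = 2 * np.cos(2 * np.pi * tps / 100) + rng.normal(0, 0.02, (20, 9))
        x = pd.DataFrame(np.vstack([flat, cosine]),
                         index=[f"m{i}" for i in range(40)])
        labels = ms.cluster_profiles(x, k=2)
        truth = [0] * 20 + [1] * 20
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_five_pattern_scenario_recovers_coarse_structure(self):
        """Random acrophases make the rhythmic class heterogeneous in
        profile space, so agreement with the generative kinds is partial
        by construction; the clustering must still find the coarse
        structure (measured ~0.47 mean ARI across seeds)."""
        aris = []
        for seed in range(5):
            sc = ms.generate_scenario(ms.PipelineConfig(), seed=seed)
            cm, st = sc.healthy
            nm = ms.normalize(cm)
            x = ms.timepoint_log2fc(nm, st)
            labels = ms.cluster_profiles(x, k=5)
            aris.append(adjusted_rand_score(sc.truth.kinds().loc[x.index], labels))
        assert np.mean(aris) >= 0.3

    def test_identical_profiles_share_one_label(self):
        x = pd.DataFrame(np.ones((6, 4)), index=[f"m{i}" for i in range(6)])
        labels = ms.cluster_profiles(x, k=2)
        assert labels.nunique() <= 2
        assert (labels == labels.iloc[0]).all()  # ties collapse to one group

    def test_stable_cluster_is_lowest_mean_mad(self):
        labels = pd.Series([0, 0, 1, 1], index=list("abcd"))
        mads = pd.Series([0.5, 0.6, 0.01, 0.02], index=list("abcd"))
        assert ms.stable_cluster(labels, mads) == 1

    @pytest.mark.parametrize("k", [1, 41])
    def test_bad_k_rejected(self, k):
        x = pd.DataFrame(np.random.default_rng(0).normal(size=(40, 9)))
        with pytest.raises(ValueError):
            ms.cluster_profiles(x, k=k)


class TestCosinor:
    def test_noiseless_recovery_to_machine_precision(self):
        t = np.arange(0, 24, 3.0)
        y = 5 + 2 * np.cos(2 * np.pi * t / 24)
        fit = ms.cosinor_fit(y, t, period_h=24)
        assert fit.mesor == pytest.approx(5, abs=1e-6)
        assert fit.amplitude == pytest.approx(2, abs=1e-6)
        # acrophase is circular: 0 and 24 h are the same phase
        assert min(fit.acrophase_h, 24 - fit.acrophase_h) == pytest.approx(0, abs=1e-6)
        assert fit.p_amplitude < 1e-6

    def test_acrophase_recovery(self):
        t = np.arange(0, 24, 3.0)
        y = 1 + 0.5 * np.cos(2 * np.pi * (t - 7.0) / 24)
        fit = ms.cosinor_fit(y, t, period_h=24)
        assert fit.acrophase_h == pytest.approx(7.0, abs=1e-6)

    def test_constant_series_is_arrhythmic(self):
        fit = ms.cosinor_fit([3.0] * 8, np.arange(0, 24, 3.0), period_h=24)
        assert fit.amplitude == pytest.approx(0, abs=1e-9)
        assert fit.p_amplitude > 0.5

    def test_p_value_matches_statsmodels_f_test(self):
        smf = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(9)
        t = np.arange(0, 72, 3.0)
        y = 2 + 0.4 * np.cos(2 * np.pi * t / 24) + rng.normal(0, 0.5, t.size)
        fit = ms.cosinor_fit(y, t, period_h=24)
        w = 2 * np.pi * t / 24
        design = np.column_stack([np.ones(t.size), np.cos(w), np.sin(w)])
        res = smf.OLS(y, design).fit()
        f_test = res.f_test(np.array([[0, 1, 0], [0, 0, 1]]))
        assert fit.p_amplitude == pytest.approx(float(f_test.pvalue), rel=1e-6)

    def test_planted_rhythm_detected_across_seeds(self):
        """A 24 h rhythm of amplitude 1 (log2) survives the full count
        pipeline and is flagged by the cosinor screen on the 0-72 h points;
        flat miRNAs are not."""
        detected, false_pos = [], []
        for seed in range(10):
            # enough flat features that the size factors are well estimated
            specs = {f"flat{i:02d}": ms.PatternSpec("flat", 300.0)
                     for i in range(30)}
            specs["rhythmic"] = ms.PatternSpec(
                "cosine", 300.0, amplitude_log2=1.0, period_h=24.0,
                acrophase_h=5.0)
            cm, st, _ = ms.generate_healthy_timecourse(specs, seed=seed)
            nm = ms.normalize(cm)
            tab = ms.stability_table(nm, st, ms.PipelineConfig())
            detected.append(tab.at["rhythmic", "cosinor_p"] < 0.05)
            false_pos.append((tab.filter(regex="^flat", axis=0)["cosinor_p"]
                              < 0.05).mean())
        assert np.mean(detected) >= 0.9
        assert np.mean(false_pos) <= 0.15  # nominal type-I level is 0.05

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            ms.cosinor_fit([1, 2, 3], [0, 3, 6], period_h=24)


class TestStabilityTable:
    def test_window_and_flag_invariants(self, healthy_normalized):
        nm, st = healthy_normalized
        tab = ms.stability_table(nm, st, ms.PipelineConfig())
        np.testing.assert_allclose(
            tab["lower"], tab["median_fc"] - 3 * tab["mad"], rtol=1e-12)
        np.testing.assert_allclose(
            tab["upper"], tab["median_fc"] + 3 * tab["mad"], rtol=1e-12)
        assert (tab["lower"] <= tab["median_fc"]).all()
        assert (tab["median_fc"] <= tab["upper"]).all()
        assert ((tab["mad"] < 0.2) == tab["stable"]).all()
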