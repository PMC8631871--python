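import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenoforecast import validate as val


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        g = [np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0])]
        f, p = val.anova_one_way(g)
        assert f == 0.0 and p == 1.0

    def test_zero_variance_equal_means_convention(self):
        g = [np.array([2.0, 2.0]), np.array([2.0, 2.0])]
        f, p = val.anova_one_way(g)
        assert (f, p) == (0.0, 1.0)

    def test_matches_reference_implementation_on_random_fixtures(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            groups = [
                rng.normal(rng.uniform(-1, 1), 1.0, size=rng.integers(4, 12))
                for _ in range(rng.integers(2, 5))
            ]
            f, p = val.anova_one_way(groups)
            ref = stats.f_oneway(*groups)
            assert f == pytest.approx(ref.statistic, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_textbook_fixture_against_sums_of_squares_oracle(self):
        groups = [np.array([6.0, 8.0, 4.0, 5.0, 3.0, 4.0]),
                  np.array([8.0, 12.0, 9.0, 11.0, 6.0, 8.0]),
                  np.array([13.0, 9.0, 11.0, 8.0, 7.0, 12.0])]
        f, _ = val.anova_one_way(groups)
        # brute-force decomposition
        allx = np.concatenate(groups)
        grand = allx.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_oracle = (ssb / 2) / (ssw / 15)
        assert f == pytest.approx(f_oracle, abs=1e-10)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            val.anova_one_way([np.array([1.0]), np.array([2.0, 3.0])])


class TestTukey:
    def test_identical_groups_no_pair_significant(self):
        g = [np.array([1.0, 2.0, 3.0])] * 3
        table = val.tukey_hsd(g)
        assert not table.significant.any()
        assert (table.p_adj == 1.0).all()

    def test_shifted_group_dominates_critical_range(self):
        rng = np.random.default_rng(3)
        base = [rng.normal(0.0, 1.0, 12) for _ in range(3)]
        shifted = rng.normal(10.0, 1.0, 12)  # 10 within-SDs away
        table = val.tukey_hsd(base + [shifted], labels=["a", "b", "c", "far"])
        far = table[(table.group_a == "far") | (table.group_b == "far")]
        rest = table[(table.group_a != "far") & (table.group_b != "far")]
        assert far.significant.all()
        assert not rest.significant.any()

    def test_adjusted_p_dominates_pairwise_t(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(m, 1.0, 10) for m in (0.0, 0.4, 1.0)]
        table = val.tukey_hsd(groups)
        pairs = [(0, 1), (0, 2), (1, 2)]
        for (i, j), (_, row) in zip(pairs, table.iterrows()):
            t_p = stats.ttest_ind(groups[i], groups[j]).pvalue
            assert row.p_adj >= t_p - 1e-12

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(17)
        for _ in range(10):
            groups = [rng.normal(m, 1.0, 8) for m in rng.uniform(-1, 1, 3)]
            ours = val.tukey_hsd(groups, labels=["g0", "g1", "g2"])
            data = np.concatenate(groups)
            labs = np.repeat(["g0", "g1", "g2"], 8)
            ref = pairwise_tukeyhsd(data, labs)
            # statsmodels reports (groupB - groupA); ours is (A - B)
            assert np.allclose(-ours.mean_diff.to_numpy(), ref.meandiffs, atol=1e-10)
            assert np.allclose(ours.p_adj.to_numpy(), ref.pvalues, atol=1e-6)

    def test_interval_symmetry_in_pair_order(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(m, 1.0, 10) for m in (0.0, 1.0)]
        fwd = val.tukey_hsd(groups, labels=["a", "b"])
        rev = val.tukey_hsd(groups[::-1], labels=["b", "a"])
        assert fwd.mean_diff.iloc[0] == pytest.approx(-rev.mean_diff.iloc[0])
        assert fwd.low.iloc[0] == pytest.approx(-rev.high.iloc[0])
        assert fwd.p_adj.iloc[0] == pytest.approx(rev.p_adj.iloc[0], abs=1e-12)


def _checkpoint_frame(windows, obs, preds):
    frames = []
    for w, pred in zip(windows, preds):
        frames.append(
            pd.DataFrame(
                {
                    "window": w,
                    "plant_id": np.arange(1, len(obs) + 1),
                    "horizon_h": 24,
                    "time_step": 165,
                    "das": 23.67,
                    "observed_pa": obs,
                    "predicted_pa": pred,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestObservedVsPredicted:
    def test_perfect_prediction_p_one_r_one(self, rng):
        obs = rng.uniform(500, 1500, 12)
        frame = _checkpoint_frame(["T1"], obs, [obs.copy()])
        table = val.observed_vs_predicted_tests(frame)
        assert table.t_p.iloc[0] == 1.0
        assert table.spearman_r.iloc[0] == 1.0
        assert not table.significant.iloc[0]

    def test_large_constant_shift_detected(self, rng):
        obs = rng.uniform(500, 1500, 12)
        frame = _checkpoint_frame(["T1"], obs, [obs + 500.0])
        table = val.observed_vs_predicted_tests(frame)
        assert table.t_p.iloc[0] < 0.01
        assert table.significant.iloc[0]

    def test_paired_test_matches_reference(self, rng):
        obs = rng.uniform(500, 1500, 15)
        pred = obs + rng.normal(20, 30, 15)
        frame = _checkpoint_frame(["T1"], obs, [pred])
        table = val.observed_vs_predicted_tests(frame)
        assert table.t_p.iloc[0] == pytest.approx(
            stats.ttest_rel(obs, pred).pvalue, abs=1e-12
        )

    def test_tiny_samples_rejected(self):
        frame = _checkpoint_frame(["T1"], np.array([1.0, 2.0]), [np.array([1.0, 2.0])])
        with pytest.raises(ValueError, match="n=2"):
            val.observed_vs_predicted_tests(frame)


class TestRunValidation:
    def test_report_structure_and_text(self, rng):
        obs = rng.uniform(800, 1200, 10)
        preds = [obs + rng.normal(0, 20, 10) for _ in range(4)]
        frame = _checkpoint_frame(["T1", "T2", "T3", "T4"], obs, preds)
        report = val.run_validation(frame)
        assert report.checkpoint_step == 165
        assert len(report.window_tests) == 4
        # 4 windows + observed group -> C(5,2)=10 Tukey pairs
        assert len(report.tukey) == 10
        text = report.to_text()
        assert "ANOVA" in text and "Tukey" in text

    def test_repeated_runs_different_seeds_agree_in_rank_correlation(self):
        """Two independently seeded synthetic experiments produce Spearman R
        estimates that differ by less than their sampling spread (the
        repeatability check between the two experiments)."""
        from phenoforecast import forecast as fc
        from phenoforecast import synthgen as sg
        from phenoforecast.timegrid import CANONICAL_WINDOWS

        rs = []
        for seed in (101, 202):
            rec = sg.simulate_growth_curves(
                sg.GrowthSimConfig(n_plants=10, seed=seed)
            )
            cfg = fc.ForecastConfig(horizons=(24,), lookback=6, learner="gbt",
                                    seed=seed)
            w = CANONICAL_WINDOWS["T3"]
            fitted = fc.fit_forecaster(fc.build_design(rec, w, cfg), w, cfg)
            preds = fc.predict_window(fitted, rec).predictions
            cp = preds[preds.time_step == 165]
            rs.append(stats.spearmanr(cp.observed_pa, cp.predicted_pa).statistic)
        # bootstrap CI width for Spearman R at n=10 is far wider than 0.35
        assert abs(rs[0] - rs[1]) < 0.35
        assert min(rs) > 0.5
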