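"""Repeated-measures correlation, mixed models, contrasts, J-N regions, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lcmem.association_stats import (
    LmmSpec,
    StatsError,
    fdr_adjust,
    marginal_contrasts,
    pearson,
    region_of_significance,
    rmcorr,
    rmcorr_bootstrap,
    stage_lmm,
)


def _rm_table(rng, n_subjects=20, n_stages=4, rho=0.5, noise=1.0):
    rows = []
    for s in range(n_subjects):
        offset = rng.normal(0, 3)
        x = rng.normal(0, 1, n_stages)
        y = rho * x + np.sqrt(max(1 - rho**2, 0)) * rng.normal(0, noise, n_stages) + offset
        for xi, yi in zip(x, y):
            rows.append({"subject": s, "x": xi, "y": yi})
    return pd.DataFrame(rows)


class TestRmcorr:
    def test_perfect_within_subject_correlation(self):
        rng = np.random.default_rng(0)
        rows = []
        for s in range(8):
            x = rng.normal(0, 1, 4)
            for xi in x:
                rows.append({"subject": s, "x": xi, "y": xi + 10 * s})
        table = pd.DataFrame(rows)
        assert rmcorr(table, "x", "y").r == pytest.approx(1.0, abs=1e-10)
        table["y"] = -table["y"] + 20 * table["subject"]
        assert rmcorr(table, "x", "y").r == pytest.approx(-1.0, abs=1e-10)

    def test_df_convention(self):
        table = _rm_table(np.random.default_rng(1))
        res = rmcorr(table, "x", "y")
        assert res.df == res.n_observations - res.n_subjects - 1

    def test_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        table = _rm_table(np.random.default_rng(2))
        res = rmcorr(table, "x", "y")
        ref = pingouin.rm_corr(data=table, x="x", y="y", subject="subject")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.df == int(ref["dof"].iloc[0])
        assert res.p == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-8)

    def test_recovery_of_generated_correlation(self):
        rng = np.random.default_rng(3)
        estimates = [rmcorr(_rm_table(rng, rho=0.5), "x", "y").r for _ in range(200)]
        assert np.mean(estimates) == pytest.approx(0.5, abs=0.05)

    def test_single_subject_reduces_to_pearson(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 30)
        y = 0.6 * x + rng.normal(0, 0.8, 30)
        table = pd.DataFrame({"subject": np.zeros(30, int), "x": x, "y": y})
        with pytest.raises(StatsError):
            rmcorr(table, "x", "y")  # a lone subject is not a repeated-measures design
        # but two balanced centered copies give the pooled Pearson r
        table2 = pd.concat(
            [table, table.assign(subject=1)], ignore_index=True
        )
        r_expected = stats.pearsonr(x, y).statistic
        assert rmcorr(table2, "x", "y").r == pytest.approx(r_expected, abs=1e-10)

    def test_subjects_with_single_pair_dropped(self):
        table = _rm_table(np.random.default_rng(5), n_subjects=6)
        table = pd.concat(
            [table, pd.DataFrame([{"subject": 99, "x": 1.0, "y": 2.0}])], ignore_index=True
        )
        with pytest.warns(UserWarning):
            res = rmcorr(table, "x", "y")
        assert res.n_subjects == 6


class TestRmcorrBootstrap:
    def test_collinear_data_degenerate_ci(self):
        rows = []
        for s in range(6):
            for xi in (0.0, 1.0, 2.0, 3.0):
                rows.append({"subject": s, "x": xi, "y": xi + s})
        lo, hi = rmcorr_bootstrap(pd.DataFrame(rows), "x", "y", n_boot=200, seed=0)
        assert lo == pytest.approx(1.0, abs=1e-9) and hi == pytest.approx(1.0, abs=1e-9)

    def test_seeded_reproducibility(self):
        table = _rm_table(np.random.default_rng(6))
        a = rmcorr_bootstrap(table, "x", "y", n_boot=200, seed=3)
        b = rmcorr_bootstrap(table, "x", "y", n_boot=200, seed=3)
        assert a == b

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(7)
        contained = 0
        for i in range(50):
            table = _rm_table(rng, n_subjects=12)
            res = rmcorr(table, "x", "y")
            lo, hi = rmcorr_bootstrap(table, "x", "y", n_boot=300, seed=i)
            contained += lo <= res.r <= hi
        assert contained >= 49


class TestPearson:
    def test_exact_cases(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x)[0] == pytest.approx(1.0)
        # contrasts designed with zero means and zero cross-product
        x0 = np.array([-1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0])
        y0 = np.array([-1.0, -1.0, 1.0, 1.0, -1.0, -1.0, 1.0, 1.0])
        assert pearson(x0, y0)[0] == pytest.approx(0.0, abs=1e-12)

    def test_t_transform_consistency(self):
        # r = 0.452 with N = 18 implies p ~ 0.0597 under the t-transform
        r, n = 0.452, 18
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        p_expected = 2 * stats.t.sf(t, n - 2)
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, n)
        y = 0.5 * x + rng.normal(0, 1, n)
        r_obs, p_obs = pearson(x, y)
        t_obs = r_obs * np.sqrt(n - 2) / np.sqrt(1 - r_obs**2)
        assert p_obs == pytest.approx(2 * stats.t.sf(abs(t_obs), n - 2), rel=1e-9)
        assert p_expected == pytest.approx(0.0597, abs=0.001)

    def test_degenerate_inputs(self):
        with pytest.raises(StatsError):
            pearson(np.ones(5), np.arange(5.0))
        with pytest.raises(StatsError):
            pearson(np.arange(2.0), np.arange(2.0))


def _stage_table(rng, n_subjects=20, effects=None, icc_sd=3.0, noise=5.0):
    effects = effects or {}
    stages = ["baseline", "encoding", "consolidation", "recollection"]
    rows = []
    for s in range(n_subjects):
        intercept = rng.normal(0, icc_sd)
        for stage in stages:
            rows.append({"subject": s, "stage": stage,
                         "y": 10 + effects.get(stage, 0.0) + intercept + rng.normal(0, noise)})
    return pd.DataFrame(rows)


class TestStageLmm:
    def test_exact_recovery_without_noise(self):
        table = _stage_table(np.random.default_rng(9), effects={"consolidation": 60.0},
                             icc_sd=0.0, noise=0.0)
        with pytest.warns(UserWarning):
            fit = stage_lmm(table, LmmSpec(outcome="y"))
        assert fit.params["Intercept"] == pytest.approx(10.0, abs=1e-6)
        assert fit.params[fit.stage_param("consolidation")] == pytest.approx(60.0, abs=1e-6)

    def test_stage_effect_recovered_within_two_se(self):
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(100):
            table = _stage_table(rng, effects={"consolidation": 60.0})
            fit = stage_lmm(table, LmmSpec(outcome="y"))
            name = fit.stage_param("consolidation")
            hits += abs(fit.params[name] - 60.0) <= 2 * fit.se[name]
        assert hits >= 90  # nominal ~95 % coverage

    def test_zero_icc_gives_near_zero_intercept_variance(self):
        table = _stage_table(np.random.default_rng(11), icc_sd=0.0, noise=5.0, n_subjects=40)
        fit = stage_lmm(table, LmmSpec(outcome="y"))
        resid_var = float(fit.fit.scale)
        group_var = float(fit.fit.cov_re.iloc[0, 0]) if hasattr(fit.fit, "cov_re") else 0.0
        assert group_var / resid_var < 0.1


class TestMarginalContrasts:
    def test_two_level_tukey_equals_unadjusted(self):
        rng = np.random.default_rng(12)
        table = _stage_table(rng)
        table = table[table["stage"].isin(["baseline", "consolidation"])]
        fit = stage_lmm(table, LmmSpec(outcome="y"))
        out = marginal_contrasts(fit)
        assert out["p_adj"].iloc[0] == pytest.approx(out["p_raw"].iloc[0], rel=1e-4)

    def test_contrast_cycle_sums_to_zero(self):
        fit = stage_lmm(_stage_table(np.random.default_rng(13)), LmmSpec(outcome="y"))
        out = marginal_contrasts(fit).set_index(["stage_a", "stage_b"])["estimate"]
        cycle = (out[("baseline", "encoding")] + out[("encoding", "recollection")]
                 - out[("baseline", "recollection")])
        assert cycle == pytest.approx(0.0, abs=1e-10)

    def test_familywise_error_controlled_under_null(self):
        rng = np.random.default_rng(14)
        any_sig = 0
        reps = 100
        for _ in range(reps):
            fit = stage_lmm(_stage_table(rng), LmmSpec(outcome="y"))
            any_sig += (marginal_contrasts(fit)["p_adj"] < 0.05).any()
        assert any_sig / reps <= 0.10  # nominal 0.05 familywise level


def _interaction_table(rng, crossover=0.25, slope_gap=2.0, noise=0.05, n_subjects=20):
    freqs = np.linspace(0.01, 0.5, 45)
    rows = []
    for s in range(n_subjects):
        intercept = rng.normal(0, 0.05)
        for stage, (b0, b1) in {
            "baseline": (0.5, -0.4),
            "consolidation": (0.5 - crossover * slope_gap, -0.4 + slope_gap),
        }.items():
            for f in freqs:
                rows.append({"subject": s, "stage": stage, "freq": f,
                             "msc": b0 + b1 * f + intercept + rng.normal(0, noise)})
    return pd.DataFrame(rows)


class TestRegionOfSignificance:
    def _grid_oracle(self, fit, a, b, alpha=0.05):
        """Dense pointwise scan of the conditional stage difference."""
        from lcmem.association_stats import _pair_contrast

        t_crit = stats.t.ppf(1 - alpha / 2, fit.df)
        grid = np.linspace(fit.data["freq"].min(), fit.data["freq"].max(), 4001)
        beta = fit.params.to_numpy()
        cov = fit.cov.to_numpy()
        sig = []
        for f in grid:
            c = _pair_contrast(fit, a, b, f)
            t = (c @ beta) / np.sqrt(c @ cov @ c)
            sig.append(abs(t) > t_crit)
        sig = np.asarray(sig)
        changes = np.nonzero(np.diff(sig.astype(int)))[0]
        return grid[changes]

    def test_crossover_boundary_matches_grid_oracle(self):
        rng = np.random.default_rng(15)
        table = _interaction_table(rng, crossover=0.25)
        fit = stage_lmm(table, LmmSpec(outcome="msc", predictor="freq", interaction=True))
        ros = region_of_significance(fit, "baseline", "consolidation")
        oracle = self._grid_oracle(fit, "baseline", "consolidation")
        assert len(ros.boundaries) == len(oracle)
        for b, o in zip(ros.boundaries, oracle):
            assert b == pytest.approx(o, abs=0.02)

    def test_zero_interaction_gives_no_boundary(self):
        rng = np.random.default_rng(16)
        table = _interaction_table(rng, crossover=0.0, slope_gap=0.0)
        fit = stage_lmm(table, LmmSpec(outcome="msc", predictor="freq", interaction=True))
        ros = region_of_significance(fit, "baseline", "consolidation")
        assert ros.significant in ("nowhere", "everywhere")

    def test_boundary_equivariant_under_rescaling(self):
        rng = np.random.default_rng(17)
        table = _interaction_table(rng, crossover=0.25)
        fit = stage_lmm(table, LmmSpec(outcome="msc", predictor="freq", interaction=True))
        ros = region_of_significance(fit, "baseline", "consolidation")
        table_mhz = table.assign(freq=table["freq"] * 1000.0)
        fit_mhz = stage_lmm(table_mhz, LmmSpec(outcome="msc", predictor="freq", interaction=True))
        ros_mhz = region_of_significance(fit_mhz, "baseline", "consolidation")
        assert len(ros.boundaries) == len(ros_mhz.boundaries)
        for b, bm in zip(ros.boundaries, ros_mhz.boundaries):
            assert bm == pytest.approx(1000.0 * b, rel=1e-3)


class TestFdr:
    def test_all_ones_unchanged(self):
        assert np.allclose(fdr_adjust(np.ones(5)), 1.0)

    def test_hand_traced_example(self):
        # BH step-up: adjusted_i = min_{k >= i} m p_(k) / k  => all 0.04 here
        out = fdr_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out, 0.04)

    def test_single_value_unchanged(self):
        assert fdr_adjust(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_monotone_and_dominating(self):
        rng = np.random.default_rng(18)
        p = rng.random(50)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_invalid_rejected(self):
        with pytest.raises(StatsError):
            fdr_adjust(np.array([0.5, 1.2]))
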