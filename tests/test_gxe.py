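"""Genotype means, genetic gain, variance partition, factorial regression."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

import breedscan as bs


def _toy_trial(rng, n_h=6, n_e=4, exp_eff=None, noise=1.0, drop=()):
    exp_eff = exp_eff if exp_eff is not None else rng.normal(0, 5, n_e)
    rows = []
    for h in range(n_h):
        for e in range(n_e):
            if (h, e) in drop:
                continue
            rows.append(
                {
                    "hybrid": f"h{h}",
                    "experiment": f"e{e}",
                    "scenario": "cool-WW",
                    "grain_number": 100.0 + 7.0 * h + exp_eff[e] + rng.normal(0, noise),
                }
            )
    return pd.DataFrame(rows)


class TestGenotypeMeans:
    def test_zero_experiment_variance_equals_arithmetic_means(self):
        rng = np.random.default_rng(0)
        df = _toy_trial(rng, exp_eff=np.zeros(4), noise=0.5)
        means = bs.genotype_means(df, group_by="none")
        arith = df.groupby("hybrid")["grain_number"].mean()
        np.testing.assert_allclose(
            means["all"].to_numpy(), arith.to_numpy(), atol=1e-6
        )

    def test_balanced_design_equals_simple_means(self):
        rng = np.random.default_rng(1)
        df = _toy_trial(rng, exp_eff=rng.normal(0, 10, 4))
        means = bs.genotype_means(df, group_by="none")
        arith = df.groupby("hybrid")["grain_number"].mean()
        np.testing.assert_allclose(means["all"].to_numpy(), arith.to_numpy(), atol=1e-8)

    def test_unbalanced_matches_mixedlm_oracle(self):
        rng = np.random.default_rng(2)
        df = _toy_trial(rng, n_h=5, n_e=4, drop={(1, 0), (2, 3), (4, 1)})
        means = bs.genotype_means(df, group_by="none")
        fit = smf.mixedlm(
            "grain_number ~ 0 + hybrid", df, groups=df["experiment"]
        ).fit(reml=True)
        np.testing.assert_allclose(
            means["all"].to_numpy(), fit.fe_params.to_numpy(), atol=1e-5
        )

    def test_single_experiment_group_falls_back_with_warning(self):
        rng = np.random.default_rng(3)
        df = _toy_trial(rng, n_e=1, exp_eff=np.zeros(1))
        with pytest.warns(UserWarning, match="fewer than 2 experiments"):
            means = bs.genotype_means(df, group_by="none")
        arith = df.groupby("hybrid")["grain_number"].mean()
        np.testing.assert_allclose(means["all"].to_numpy(), arith.to_numpy())

    def test_absent_hybrid_is_nan_not_imputed(self):
        rng = np.random.default_rng(4)
        df = _toy_trial(rng)
        df.loc[len(df)] = {
            "hybrid": "h9",
            "experiment": "e0",
            "scenario": "hot-WD",
            "grain_number": 50.0,
        }
        means = bs.genotype_means(df, group_by="scenario")
        assert np.isnan(means.loc["h9", "cool-WW"])
        assert np.isnan(means.loc["h0", "hot-WD"])


class TestGeneticGain:
    def test_constant_trait(self):
        gg = bs.genetic_gain(np.full(20, 5.0), np.arange(1950, 1970, dtype=float))
        assert gg.slope == 0.0 and gg.pvalue == pytest.approx(1.0)

    def test_noiseless_line(self):
        years = np.arange(1950, 2000, dtype=float)
        gg = bs.genetic_gain(2.0 * years, years)
        assert gg.slope == pytest.approx(2.0)
        assert gg.r2 == pytest.approx(1.0)

    def test_nan_means_dropped(self):
        years = np.arange(10, dtype=float)
        vals = years * 3.0
        vals[4] = np.nan
        gg = bs.genetic_gain(vals, years)
        assert gg.n == 9 and gg.slope == pytest.approx(3.0)


class TestPartition:
    def test_pure_noise_components_small(self):
        rng = np.random.default_rng(5)
        n_h, n_e = 70, 90  # a few thousand records, modest factor dfs
        scen = np.array([str(s) for s in bs.ALL_SCENARIOS])
        rows = []
        for h in range(n_h):
            for e in range(n_e):
                rows.append(
                    {
                        "hybrid": f"h{h}",
                        "experiment": f"e{e}",
                        "scenario": scen[e % 6],
                        "year": 1950.0 + h,
                        "grain_number": rng.normal(0, 1),
                    }
                )
        vp = bs.partition_variance(pd.DataFrame(rows))
        for term, prop in vp.proportion.items():
            assert prop < 0.02, term

    def test_pure_year_trend(self):
        rows = []
        for h in range(40):
            for e in range(6):
                rows.append(
                    {
                        "hybrid": f"h{h:02d}",
                        "experiment": f"e{e}",
                        "scenario": str(bs.ALL_SCENARIOS[e // 2]),  # 2 exps/scenario
                        "year": 1950.0 + h,
                        "grain_number": 10.0 * (1950.0 + h),
                    }
                )
        vp = bs.partition_variance(pd.DataFrame(rows))
        assert vp.proportion["G_year"] > 0.98

    def test_orthogonal_design_hand_computed(self):
        # 4 hybrids x 2 scenarios x 2 experiments/scenario, fully crossed;
        # year, scenario and experiment contrasts are mutually orthogonal so
        # every component sum of squares is known in closed form
        hybrids = [("h0", -1.5), ("h1", -0.5), ("h2", 0.5), ("h3", 1.5)]
        rows = []
        for h, yv in hybrids:
            for scen, sv in [("cool-WW", -2.0), ("hot-WD", 2.0)]:
                for k, ev in [(0, -0.5), (1, 0.5)]:
                    rows.append(
                        {
                            "hybrid": h,
                            "experiment": f"{scen}_e{k}",
                            "scenario": scen,
                            "year": 2000.0 + yv,
                            "grain_number": 10.0 + yv * 3.0 + sv + ev,
                        }
                    )
        df = pd.DataFrame(rows)
        n = len(df)
        ss_year = n * 3.0**2 * 1.25  # slope 3, mean(yv^2) = 1.25
        ss_scen = n * 2.0**2
        ss_exp = n * 0.5**2
        total = ss_year + ss_scen + ss_exp
        vp = bs.partition_variance(df)
        assert vp.total_ss == pytest.approx(total)
        assert vp.proportion["G_year"] == pytest.approx(ss_year / total)
        assert vp.proportion["G_res"] == pytest.approx(0.0, abs=1e-12)
        assert vp.proportion["Scen"] == pytest.approx(ss_scen / total)
        assert vp.proportion["E_res"] == pytest.approx(ss_exp / total)
        assert vp.residual_ss == pytest.approx(0.0, abs=1e-12 * total)

    def test_proportions_sum_to_one_and_affine_invariant(self, trial):
        table, _ = trial
        vp = bs.partition_variance(table)
        s = sum(vp.proportion.values()) + vp.residual_proportion
        assert s == pytest.approx(1.0, abs=1e-8)
        t2 = table.copy()
        t2["grain_number"] = 3.5 * t2["grain_number"] + 111.0
        vp2 = bs.partition_variance(t2)
        for k in vp.proportion:
            assert vp2.proportion[k] == pytest.approx(vp.proportion[k], abs=1e-8)

    def test_reversed_order_changes_attribution_not_residual(self, trial):
        table, _ = trial
        vp = bs.partition_variance(table)
        vp3 = bs.partition_variance(table, covariates=("veg", "silk", "rh_pad"))
        # covariates absorb year-mediated signal, G_year attribution shrinks
        assert vp3.proportion["G_year"] < vp.proportion["G_year"]
        # covariates are hybrid-level, so the full hybrid space is unchanged
        # and the residual is identical
        assert vp3.residual_ss == pytest.approx(vp.residual_ss, rel=1e-10)

    def test_forward_backward_drops_null_terms(self):
        rng = np.random.default_rng(6)
        rows = []
        for h in range(30):
            for e in range(8):
                rows.append(
                    {
                        "hybrid": f"h{h:02d}",
                        "experiment": f"e{e}",
                        "scenario": str(bs.ALL_SCENARIOS[e % 3]),
                        "year": 1950.0 + h,
                        "grain_number": 5.0 * h + rng.normal(0, 1),
                    }
                )
        vp = bs.partition_variance(pd.DataFrame(rows), selection="forward-backward")
        assert vp.proportion["G_year"] > 0.9
        assert vp.proportion["G_year_x_Scen"] == 0.0


class TestFactorialRegression:
    def test_planted_sensitivity_groups_separate(self, small_config, qc_panel):
        G2, meta, truth, _ = qc_panel
        group1 = np.arange(60) % 2 == 0  # alternating, uncorrelated with year
        b1 = np.where(group1, -500.0, 0.0)
        cfg = small_config.with_(beta_psi=b1, gei_year_slope_sd=0.0)
        envs = bs.simulate_environments(cfg)
        table, _ = bs.simulate_trial(cfg, G2, meta, envs)
        sens = bs.factorial_regression(table)
        assert sens.psi_included
        est = sens.table["beta1"].to_numpy()
        g1, g2 = est[group1], est[~group1]
        se = np.sqrt(g1.var(ddof=1) / len(g1) + g2.var(ddof=1) / len(g2))
        assert abs(g1.mean() - g2.mean()) > 3 * se
        # identified up to a common constant: the contrast matches the truth
        assert g1.mean() - g2.mean() == pytest.approx(-500.0, abs=6 * se)

    def test_environment_invariant_genotypes_null(self, small_config, qc_panel):
        G2, meta, truth, _ = qc_panel
        cfg = small_config.with_(gei_year_slope_sd=0.0)
        envs = bs.simulate_environments(cfg)
        table, _ = bs.simulate_trial(cfg, G2, meta, envs)
        sens = bs.factorial_regression(table)
        if sens.psi_included:
            t = sens.table["beta1"] / sens.table["se1"]
            assert (np.abs(t) < 2).mean() >= 0.9

    def test_constant_index_rejected(self):
        rng = np.random.default_rng(7)
        rows = []
        for h in range(10):
            for e in range(6):
                rows.append(
                    {
                        "hybrid": f"h{h}",
                        "experiment": f"e{e}",
                        "scenario": str(bs.ALL_SCENARIOS[e % 2]),
                        "year": 1950.0 + h,
                        "psi": -0.05,  # constant across experiments
                        "r_int": 400.0 + 10 * e,
                        "grain_number": rng.normal(100, 5),
                    }
                )
        sens = bs.factorial_regression(pd.DataFrame(rows))
        assert not sens.psi_included
        assert np.isnan(sens.table["beta1"]).all()
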