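"""Bivariate mixed model: design, sampler, derived statistics, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from skatemove.syndrome import (McmcSettings, ModelSpec, _rinvwishart, among_correlation,
                                build_design, diagnostics, gibbs_fit, orthogonal_poly,
                                repeatability, split_psrf, summarize)


def _table(rng, n_ind=12, n_rows=24, y=None, philopatry=("CR", "SR", "SF")):
    rows = []
    for i in range(n_ind):
        for j in range(n_rows):
            rows.append({
                "transmitter_id": f"T{i:03d}",
                "iso_week": int(rng.integers(1, 54)),
                "diel": "day" if j % 2 else "night",
                "disc_length": float(rng.uniform(24, 59)),
                "sex": str(rng.choice(["female", "male"])),
                "philopatry": str(philopatry[i % len(philopatry)]),
            })
    tbl = pd.DataFrame(rows)
    if y is None:
        y = rng.standard_normal((len(tbl), 2))
    tbl["log_space"] = y[:, 0]
    tbl["log_activity"] = y[:, 1]
    return tbl


class TestDesign:
    def test_orthogonal_basis_gram_matrix(self, rng):
        basis = orthogonal_poly(rng.integers(1, 54, 500).astype(float), 3)
        gram = basis.T @ basis
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-8)
        assert abs(basis.sum(axis=0)).max() < 1e-8  # centered

    def test_stacked_layout_counts(self, rng):
        tbl = _table(rng)
        design = build_design(tbl)
        assert design.n_response_entries == 2 * len(tbl)
        assert design.X.shape[0] == len(tbl)
        assert design.n_ind == 12

    def test_absent_philopatry_level_dropped_with_warning(self, rng):
        tbl = _table(rng, philopatry=("CR", "SR"))
        with pytest.warns(UserWarning, match="SF"):
            design = build_design(tbl)
        assert "philopatry_SF" not in design.columns
        assert "philopatry_SR" in design.columns

    def test_rank_deficiency_names_aliased_column(self, rng):
        tbl = _table(rng)
        tbl["sex"] = "female"  # zero male column
        with pytest.raises(ValueError, match="sex_male"):
            build_design(tbl)

    def test_single_individual_rejected(self, rng):
        tbl = _table(rng, n_ind=1)
        with pytest.raises(ValueError, match="individuals"):
            build_design(tbl)

    def test_missing_diel_level_rejected(self, rng):
        tbl = _table(rng)
        tbl["diel"] = "day"
        with pytest.raises(ValueError, match="diel"):
            build_design(tbl)


class TestDerivedStatistics:
    def test_repeatability_published_variance_components(self):
        # activity space: among 0.202, within 0.706 -> 0.22 at two decimals
        assert round(repeatability(0.202, 0.706), 2) == 0.22
        # activity: among 0.285, within 0.533 -> 0.3484...
        assert repeatability(0.285, 0.533) == pytest.approx(0.3484, abs=5e-5)

    def test_repeatability_limits_and_errors(self):
        assert repeatability(1.7, 0.0) == 1.0
        assert repeatability(0.0, 2.0) == 0.0
        with pytest.raises(ValueError):
            repeatability(0.0, 0.0)
        with pytest.raises(ValueError):
            repeatability(-0.1, 1.0)

    def test_among_correlation_published_components(self):
        # covariance 0.087 over sqrt(0.202 * 0.285) -> 0.36 at two decimals
        assert round(among_correlation(0.087, 0.202, 0.285), 2) == 0.36

    def test_among_correlation_bounds_and_errors(self):
        assert among_correlation(0.0, 1.0, 2.0) == 0.0
        g11, g22 = 0.3, 0.7
        assert among_correlation(np.sqrt(g11 * g22), g11, g22) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            among_correlation(0.1, 0.0, 1.0)


def test_inverse_wishart_kernel_matches_scipy(rng):
    from scipy import stats

    df, scale = 12.4, np.array([[2.0, 0.6], [0.6, 1.5]])
    draws = np.array([_rinvwishart(rng, df, scale) for _ in range(4000)])
    expected = scale / (df - 3)  # mean of IW_2(df, scale), df > p + 1
    se = np.abs(expected) * np.sqrt(2.0 / 4000) * 4
    assert np.all(np.abs(draws.mean(axis=0) - expected) < 4 * se + 0.02)
    sp = stats.invwishart(df, scale).rvs(size=4000, random_state=rng)
    assert np.all(np.abs(draws.mean(axis=0) - sp.mean(axis=0)) < 0.05)


class TestSampler:
    def _fit(self, tbl, seed=1, n_iter=2500, burn=500, chains=2):
        spec = ModelSpec(mcmc=McmcSettings(n_chains=chains, n_iter=n_iter,
                                           burn_in=burn, thin=5, seed=seed))
        design = build_design(tbl)
        return design, gibbs_fit(design, spec)

    def test_draws_are_spd_and_ratios_bounded(self, rng):
        _, chains = self._fit(_table(rng), n_iter=800, burn=200)
        for c in chains:
            for mat in ("G", "R"):
                eig = np.linalg.eigvalsh(c[mat])
                assert (eig > 0).all()
            r = c["G"][:, 0, 0] / (c["G"][:, 0, 0] + c["R"][:, 0, 0])
            assert ((r >= 0) & (r <= 1)).all()
            rho = c["G"][:, 0, 1] / np.sqrt(c["G"][:, 0, 0] * c["G"][:, 1, 1])
            assert ((rho >= -1) & (rho <= 1)).all()

    def test_balanced_one_way_matches_anova_oracle(self, rng):
        """Single-trait submodel in the balanced limit: posterior means of the
        variance components agree with closed-form one-way ANOVA estimates."""
        m, n = 40, 20
        sa2, se2 = 0.8, 1.2
        a = rng.normal(0, np.sqrt(sa2), m)
        y1 = np.repeat(a, n) + rng.normal(0, np.sqrt(se2), m * n)
        y2 = rng.normal(0, 1.0, m * n)  # independent second trait
        tbl = _table(rng, n_ind=m, n_rows=n, y=np.column_stack([y1, y2]))
        ybar_i = y1.reshape(m, n).mean(axis=1)
        msb = n * np.var(ybar_i, ddof=1)
        msw = np.var(y1.reshape(m, n) - ybar_i[:, None], ddof=m)
        anova_sa2 = (msb - msw) / n
        anova_se2 = msw
        design, chains = self._fit(tbl, n_iter=4000, burn=1000)
        G = np.concatenate([c["G"] for c in chains]).mean(axis=0)
        R = np.concatenate([c["R"] for c in chains]).mean(axis=0)
        assert G[0, 0] == pytest.approx(anova_sa2, rel=0.25)
        assert R[0, 0] == pytest.approx(anova_se2, rel=0.05)
        assert abs(G[0, 1]) < 0.15  # no among-individual structure in trait 2

    def test_degenerate_constant_data_shrinks_to_prior_scale(self, rng):
        m, n_rows = 40, 24
        tbl = _table(rng, n_ind=m, n_rows=n_rows, y=np.zeros((m * n_rows, 2)))
        _, chains = self._fit(tbl, n_iter=1200, burn=400)
        G = np.concatenate([c["G"] for c in chains]).mean(axis=0)
        R = np.concatenate([c["R"] for c in chains]).mean(axis=0)
        nu0 = 1.002
        # with no signal the IW posterior mean sits near prior_scale/(df - 3)
        g_scale = nu0 / (nu0 + m - 3)
        r_scale = nu0 / (nu0 + m * n_rows - 3)
        assert G[0, 0] < 3 * g_scale and G[1, 1] < 3 * g_scale
        assert R[0, 0] < 3 * r_scale + 1e-3 and R[1, 1] < 3 * r_scale + 1e-3

    def test_parameter_recovery_small_cohort(self):
        from skatemove.synthetic import SimConfig, simulate_balanced_rows

        cfg = SimConfig(n_individuals=80, seed=19)
        rows = simulate_balanced_rows(cfg, n_weeks=10)
        design, chains = self._fit(rows, n_iter=4000, burn=1000)
        G = np.concatenate([c["G"] for c in chains])
        R = np.concatenate([c["R"] for c in chains])
        for mat, truth in ((G, cfg.G_true), (R, cfg.R_true)):
            post_mean = mat.mean(axis=0)
            post_sd = mat.std(axis=0)
            assert np.all(np.abs(post_mean - truth) < 3.5 * post_sd + 0.02)

    def test_row_order_invariance_after_canonical_sort(self, rng):
        tbl = _table(rng)
        keys = ["transmitter_id", "iso_week", "diel", "disc_length"]
        a = tbl.sort_values(keys, kind="mergesort").reset_index(drop=True)
        b = tbl.sample(frac=1.0, random_state=9).sort_values(
            keys, kind="mergesort").reset_index(drop=True)
        da, ca = self._fit(a, n_iter=600, burn=200)
        db, cb = self._fit(b, n_iter=600, burn=200)
        np.testing.assert_allclose(ca[0]["G"], cb[0]["G"])
        np.testing.assert_allclose(ca[0]["beta"], cb[0]["beta"])

    def test_power_against_generator_diel_effect(self):
        """Night > day in the generator: the day coefficient comes out
        significantly negative for both traits."""
        from skatemove.synthetic import SimConfig, simulate_balanced_rows

        cfg = SimConfig(n_individuals=60, seed=41)
        rows = simulate_balanced_rows(cfg, n_weeks=10)
        design, chains = self._fit(rows, n_iter=2500, burn=500)
        s = summarize(chains, design)
        fe = s.fixed_effects.set_index(["trait", "parameter"])
        for trait in ("log_space", "log_activity"):
            row = fe.loc[(trait, "diel_day")]
            assert row["significant"] and row["ci_upper"] < 0

    def test_null_philopatry_effects_rarely_significant(self):
        """Generator philopatry contrasts are zero: across replicate fits the
        SF/SR coefficients should be non-significant in >= 90% of cases."""
        from skatemove.synthetic import SimConfig, simulate_balanced_rows

        flags = []
        for seed in range(8):
            cfg = SimConfig(n_individuals=50, seed=100 + seed)
            rows = simulate_balanced_rows(cfg, n_weeks=8)
            design, chains = self._fit(rows, seed=seed, n_iter=1500, burn=400)
            fe = summarize(chains, design).fixed_effects
            sub = fe[fe["parameter"].str.startswith("philopatry_")]
            flags.extend(sub["significant"].tolist())
        assert np.mean(flags) <= 0.10


class TestDiagnostics:
    def test_iid_chains_psrf_near_one(self, rng):
        draws = rng.standard_normal((4, 2000))
        assert split_psrf(draws) == pytest.approx(1.0, abs=0.05)

    def test_shifted_chains_flagged(self, rng):
        draws = rng.standard_normal((2, 1000))
        draws[1] += 5.0
        assert split_psrf(draws) > 1.5

    def test_psrf_agrees_with_arviz_on_stationary_chains(self, rng):
        import arviz as az

        draws = rng.standard_normal((4, 1500))
        mine = split_psrf(draws)
        theirs = float(az.rhat(az.convert_to_dataset(draws))["x"])
        assert mine == pytest.approx(theirs, abs=0.01)

    def test_ar1_lag_one_autocorrelation(self, rng):
        phi, n = 0.9, 20000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + eps[t]
        import arviz as az

        assert az.autocorr(x)[1] == pytest.approx(phi, abs=0.03)

    def test_diagnostics_table_shape(self, rng):
        tbl = _table(rng)
        spec = ModelSpec(mcmc=McmcSettings(n_chains=2, n_iter=600, burn_in=200,
                                           thin=5, seed=0))
        design = build_design(tbl)
        chains = gibbs_fit(design, spec)
        d = diagnostics(chains, design, max_lag=5)
        assert {"parameter", "psrf", "acf_lag1", "acf_lag5"} <= set(d.columns)
        assert len(d) == 2 * len(design.columns) + 6


class TestSummaries:
    def test_constant_chains_zero_width_interval(self):
        p = 3
        chains = [{"beta": np.full((50, p, 2), 0.7),
                   "G": np.tile(np.eye(2) * 0.2, (50, 1, 1)),
                   "R": np.tile(np.eye(2) * 0.5, (50, 1, 1))}]
        design = type("D", (), {"columns": ["intercept", "a", "b"]})()
        s = summarize(chains, design)
        fe = s.fixed_effects
        assert (fe["ci_upper"] - fe["ci_lower"]).abs().max() == 0
        assert fe["significant"].all()  # constant 0.7 excludes zero
        assert s.repeatability["mean"].iloc[0] == pytest.approx(0.2 / 0.7)

    def test_report_mentions_both_traits(self, rng):
        tbl = _table(rng)
        spec = ModelSpec(mcmc=McmcSettings(n_chains=2, n_iter=600, burn_in=200,
                                           thin=5, seed=0))
        design = build_design(tbl)
        s = summarize(gibbs_fit(design, spec), design)
        text = s.report()
        assert "Activity space size" in text and "Activity" in text
        assert "R_ind" in text
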