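"""Paired mixed models: binomial (Laplace/AGQ) and Gaussian (REML)."""

import numpy as np
import pandas as pd
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, stats
from scipy.special import expit

from pairdmr.mixed_models import fit_multilocus, fit_region_glmm, fit_region_lmm, paired_t
from pairdmr.mixed_models import test_interaction as interaction_lrt
from pairdmr.region_transform import RegionCounts

from conftest import make_cohort


def _values_frame(rng, cohort, n_units=1, effect=0.0, pair_sd=1.0, resid_sd=1.0):
    ids = [i.sample_id for i in cohort.individuals]
    exposure = cohort.exposure_vector(ids)
    pair_eff = rng.normal(0, pair_sd, cohort.n_pairs)
    pair_col = np.repeat(pair_eff, 2)
    unit_means = rng.normal(50, 3, n_units)
    vals = (
        unit_means[:, None]
        + pair_col[None, :]
        + effect * exposure[None, :]
        + rng.normal(0, resid_sd, (n_units, len(ids)))
    )
    return pd.DataFrame(vals, index=[f"u{j}" for j in range(n_units)], columns=ids)


def _simulate_counts(rng, cohort, k=1, beta_exp=0.0, pair_sd=0.4, slope_sd=0.0,
                     depth_low=20, depth_high=50, intercept=0.2):
    ids = [i.sample_id for i in cohort.individuals]
    exposure = cohort.exposure_vector(ids)
    pair_eff = rng.normal(0, pair_sd, cohort.n_pairs)
    slope_eff = rng.normal(0, slope_sd, cohort.n_pairs) if slope_sd else np.zeros(cohort.n_pairs)
    T = rng.integers(depth_low, depth_high, size=(len(ids), k))
    eta = (intercept
           + ((beta_exp + np.repeat(slope_eff, 2)) * exposure)[:, None]
           + np.repeat(pair_eff, 2)[:, None])
    M = rng.binomial(T, expit(eta))
    return RegionCounts("r", ids, M, T)


class TestPairedT:
    def test_textbook_vector(self):
        d = np.array([2.0, -1.0, 3.0, 0.0, 1.0])
        res = paired_t(d)
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert res.t == pytest.approx(expected_t, rel=1e-12)
        assert res.p == pytest.approx(2 * stats.t.sf(abs(expected_t), 4), rel=1e-12)

    def test_zero_variance_flagged(self):
        res = paired_t([1.0, 1.0, 1.0, 1.0])
        assert res.zero_variance and np.isnan(res.p)

    def test_sign_flip_symmetry(self):
        d = [0.4, -1.1, 2.0, 0.3]
        res = paired_t(d)
        flipped = paired_t([-x for x in d])
        assert flipped.t == pytest.approx(-res.t)
        assert flipped.p == pytest.approx(res.p)


class TestLinearMixedModel:
    def test_equals_paired_t_in_degenerate_case(self, rng):
        """Single CpG, complete data, no covariates: the mixed model with
        pair intercept and correlated exposure slope collapses to the paired
        t-test."""
        for n_pairs in (5, 12, 24):
            cohort = make_cohort(n_pairs)
            vals = _values_frame(rng, cohort, n_units=1, effect=1.5)
            fit = fit_region_lmm(vals, cohort)
            exposed_cols = [cohort.pair(p)[0].sample_id for p in cohort.pair_ids]
            control_cols = [cohort.pair(p)[1].sample_id for p in cohort.pair_ids]
            d = vals.iloc[0][exposed_cols].to_numpy() - vals.iloc[0][control_cols].to_numpy()
            tres = paired_t(d)
            assert fit.p_value == pytest.approx(tres.p, rel=1e-6)
            assert fit.beta_exposure == pytest.approx(d.mean(), rel=1e-9)

    def test_translation_invariance(self, rng):
        cohort = make_cohort(8)
        vals = _values_frame(rng, cohort, n_units=3, effect=1.0)
        vals.iloc[1, 4] = np.nan  # exercise the general numeric path
        fit = fit_region_lmm(vals, cohort)
        fit_shift = fit_region_lmm(vals + 100.0, cohort)
        assert fit_shift.beta_exposure == pytest.approx(fit.beta_exposure, abs=1e-5)

    def test_matches_statsmodels_mixedlm(self, rng):
        import statsmodels.formula.api as smf

        cohort = make_cohort(10)
        vals = _values_frame(rng, cohort, n_units=3, effect=2.0,
                             pair_sd=2.0, resid_sd=1.0)
        fit = fit_region_lmm(vals, cohort)
        rows = []
        for u in vals.index:
            for ind in cohort.individuals:
                rows.append({
                    "y": vals.loc[u, ind.sample_id],
                    "unit": u,
                    "exposed": float(ind.exposed),
                    "pair": ind.pair_id,
                })
        df = pd.DataFrame(rows)
        sm_fit = smf.mixedlm("y ~ exposed + C(unit)", df, groups=df["pair"],
                             re_formula="~exposed").fit(reml=True)
        assert fit.beta_exposure == pytest.approx(sm_fit.params["exposed"], abs=2e-3)
        assert fit.se == pytest.approx(sm_fit.bse["exposed"], rel=0.05)

    def test_attenuated_platform_recovers_scaled_effect(self, rng):
        # measurement = attenuation * latent: the fitted exposure effect is
        # the attenuated one (linearity of the model)
        cohort = make_cohort(20)
        vals = _values_frame(rng, cohort, n_units=2, effect=6.0,
                             pair_sd=1.0, resid_sd=0.5)
        att = fit_region_lmm(vals * 0.5, cohort)
        full = fit_region_lmm(vals, cohort)
        assert att.beta_exposure == pytest.approx(0.5 * full.beta_exposure, rel=1e-6)
        assert att.beta_exposure == pytest.approx(3.0, abs=1.0)

    def test_all_missing_unit_dropped(self, rng):
        cohort = make_cohort(6)
        vals = _values_frame(rng, cohort, n_units=2)
        vals.iloc[1] = np.nan
        fit = fit_region_lmm(vals, cohort)
        assert fit.n_obs == 12


class TestBinomialMixedModel:
    def test_identical_counts_within_pairs_null(self):
        cohort = make_cohort(6)
        ids = [i.sample_id for i in cohort.individuals]
        T = np.full((12, 2), 30)
        M = np.tile(np.array([[12, 20]]), (12, 1))
        fit = fit_region_glmm(RegionCounts("r", ids, M, T), cohort)
        assert abs(fit.beta_exposure) < 1e-4
        assert fit.p_value > 0.99

    def test_matches_quadrature_oracle(self, rng):
        """Log-odds estimate agrees with an independent dense Gauss-Hermite
        quadrature ML fit of the same likelihood on a small instance."""
        cohort = make_cohort(6)
        counts = _simulate_counts(rng, cohort, k=1, beta_exp=0.8)
        fit = fit_region_glmm(counts, cohort)
        assert fit.fit_criterion == "AGQ-ML"
        beta_oracle = _dense_quadrature_ml(
            counts, cohort, extra_starts=[_laplace_start(counts, cohort)]
        )
        assert fit.beta_exposure == pytest.approx(beta_oracle, abs=1e-3)

    def test_wald_ci_coverage_on_simulated_regions(self, rng):
        """95% Wald CIs on the log-odds exposure effect cover the truth at
        close to nominal rate across simulated regions."""
        cohort = make_cohort(16)
        beta_true = 0.5
        n_regions, covered, n_conv = 200, 0, 0
        for _ in range(n_regions):
            counts = _simulate_counts(rng, cohort, k=2, beta_exp=beta_true,
                                      pair_sd=0.3, slope_sd=0.3)
            fit = fit_region_glmm(counts, cohort, method="laplace")
            if not fit.converged or fit.se == 0:
                continue
            n_conv += 1
            lo = fit.beta_exposure - 1.96 * fit.se
            hi = fit.beta_exposure + 1.96 * fit.se
            covered += lo <= beta_true <= hi
        assert n_conv >= 0.9 * n_regions
        assert 0.90 <= covered / n_conv <= 0.98

    def test_pair_relabeling_invariance(self, rng):
        cohort = make_cohort(5)
        counts = _simulate_counts(rng, cohort, k=2, beta_exp=0.5)
        fit = fit_region_glmm(counts, cohort)
        # relabel pairs by permuting whole pair blocks
        perm_pairs = [3, 1, 4, 0, 2]
        order = [x for p in perm_pairs for x in (2 * p, 2 * p + 1)]
        ids = [counts.sample_ids[i] for i in order]
        counts2 = RegionCounts("r", ids, counts.M[order], counts.T[order])
        cohort2 = make_cohort(5)
        fit2 = fit_region_glmm(counts2, cohort2)
        assert fit2.beta_exposure == pytest.approx(fit.beta_exposure, abs=1e-4)

    def test_loglik_beats_null_fit(self, rng):
        cohort = make_cohort(6)
        counts = _simulate_counts(rng, cohort, k=1, beta_exp=1.0)
        full = fit_region_glmm(counts, cohort, use_lrt=True)
        assert full.p_value <= 1.0  # LRT defined, i.e. ll_full >= ll_null


def _laplace_start(counts, cohort):
    """Warm start for the oracle optimizer taken from the package's Laplace
    fit (single-CpG instances: fixed effects are intercept and exposure)."""
    from pairdmr.mixed_models import _glmm_optimize, _long_design

    present = counts.T > 0
    X, _cn, og, _oi, _ou, Zr, ng, _ = _long_design(
        counts.sample_ids, counts.k, present, cohort, None
    )
    m = counts.M[present].astype(float)
    t = counts.T[present].astype(float)
    beta, _cov, theta, _ll, _conv = _glmm_optimize(X, Zr, og, m, t, ng)
    return [beta[0], beta[1], *theta]


def _dense_quadrature_ml(counts, cohort, extra_starts=()):
    """Independent oracle: marginal binomial likelihood integrated on a
    dense standardized Gauss-Hermite tensor grid, maximized numerically.

    Multi-start Nelder-Mead; ``extra_starts`` lets the caller add warm
    starts (the likelihood surface has boundary local optima in the
    variance parameters)."""
    nodes, weights = hermegauss(40)
    N1, N2 = np.meshgrid(nodes, nodes)
    V = np.vstack([N1.ravel(), N2.ravel()])
    logW = np.log(np.outer(weights, weights).ravel()) - np.log(2 * np.pi)
    ids = counts.sample_ids
    exposure = cohort.exposure_vector(ids)
    m = counts.M[:, 0].astype(float)
    t = counts.T[:, 0].astype(float)

    def negll(params):
        b0, b1, l11, l21, l22 = params
        L = np.array([[np.exp(np.clip(l11, -6, 6)), 0.0],
                      [l21, np.exp(np.clip(l22, -6, 6))]])
        U = L @ V
        ll = 0.0
        for g, pid in enumerate(cohort.pair_ids):
            idx = [i for i, ind in enumerate(cohort.individuals)
                   if ind.pair_id == pid]
            contrib = np.zeros(V.shape[1])
            for i in idx:
                eta = b0 + b1 * exposure[i] + U[0] + exposure[i] * U[1]
                mu = expit(eta)
                contrib += m[i] * np.log(mu + 1e-300) + (t[i] - m[i]) * np.log(
                    1 - mu + 1e-300
                )
            ll += np.logaddexp.reduce(contrib + logW)
        return -ll

    starts = [
        [0.0, 0.5, np.log(0.3), 0.0, np.log(0.3)],
        [0.0, 0.0, np.log(0.6), 0.0, np.log(0.6)],
        [0.0, 0.5, -4.0, 0.0, -4.0],
        *[list(s) for s in extra_starts],
    ]
    best = None
    for s in starts:
        res = optimize.minimize(
            negll, s, method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 5000,
                     "maxfev": 5000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x[1]


class TestInteraction:
    def test_step_window_interaction_detected(self, rng):
        # modifier 1 for half the pairs (effect present), 0 for the rest
        detected = 0
        for rep in range(10):
            cohort = make_cohort(16)
            ids = [i.sample_id for i in cohort.individuals]
            exposure = cohort.exposure_vector(ids)
            window = np.array([1.0 if (i // 2) < 8 else 0.0 for i in range(32)])
            vals = _values_frame(rng, cohort, n_units=2, effect=0.0,
                                 resid_sd=0.8)
            vals += 4.0 * (exposure * window)[None, :]
            modifier = pd.Series(window, index=ids)
            p = interaction_lrt(vals, cohort, modifier)
            detected += p < 0.05
        assert detected >= 8

    def test_null_modifier_uniform_p(self, rng):
        ps = []
        for rep in range(40):
            cohort = make_cohort(10)
            ids = [i.sample_id for i in cohort.individuals]
            vals = _values_frame(rng, cohort, n_units=1, effect=2.0)
            modifier = pd.Series(rng.normal(size=20), index=ids)
            ps.append(interaction_lrt(vals, cohort, modifier))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_modifier_rejected(self, rng):
        cohort = make_cohort(4)
        ids = [i.sample_id for i in cohort.individuals]
        vals = _values_frame(rng, cohort)
        with pytest.raises(ValueError, match="constant"):
            interaction_lrt(vals, cohort, pd.Series(1.0, index=ids))


class TestMultilocus:
    def test_single_region_degenerates_to_region_model(self, rng):
        cohort = make_cohort(8)
        vals = _values_frame(rng, cohort, n_units=2, effect=2.0)
        joint = fit_multilocus([vals], cohort)
        single = fit_region_lmm(vals, cohort)
        assert joint.p_value == pytest.approx(single.p_value, rel=1e-9)

    def test_pooling_improves_on_median_single_region_p(self, rng):
        wins = 0
        for rep in range(8):
            cohort = make_cohort(10)
            regions = [
                _values_frame(rng, cohort, n_units=2, effect=1.2, resid_sd=1.0)
                for _ in range(6)
            ]
            joint = fit_multilocus(regions, cohort)
            singles = [fit_region_lmm(v, cohort).p_value for v in regions]
            if joint.p_value <= np.median(singles):
                wins += 1
        assert wins >= 6

    def test_all_null_pooled_p_uniform(self, rng):
        ps = []
        for rep in range(30):
            cohort = make_cohort(8)
            regions = [_values_frame(rng, cohort, n_units=1) for _ in range(3)]
            ps.append(fit_multilocus(regions, cohort).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_count_regions_joint_fit(self, rng):
        cohort = make_cohort(6)
        regions = [_simulate_counts(rng, cohort, k=2, beta_exp=0.8)
                   for _ in range(3)]
        fit = fit_multilocus(regions, cohort)
        assert fit.model_kind == "binomial"
        assert np.isfinite(fit.p_value)
        assert fit.beta_exposure > 0
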