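"""Per-region paired mixed models.

Two model families share one fixed/random structure:

* a binomial logistic mixed model for bisulfite read counts — methylated
  reads out of total reads, which is equivalent to modelling each read as a
  Bernoulli outcome — fitted by Laplace-approximated maximum likelihood;
* a linear mixed model for continuous platform measurements, fitted by REML
  (ML when model fits are compared).

Fixed effects: intercept, exposure, a dummy per CpG (or CpG unit) beyond the
first, plus optional covariates. Random effects: a per-sibling-pair
intercept and a per-pair exposure slope, possibly correlated. Because each
pair consists of one exposed and one unexposed sibling, the random exposure
slope is equivalent to an individual-level random effect, so the same model
serves single- and multi-CpG regions.

The fitting numerics are written here: penalized IRLS over (fixed effects,
random modes) inside a Laplace objective for the binomial model, and a
profiled REML/ML criterion over a log-Cholesky relative-covariance
parameterization for the Gaussian model. In the balanced complete case
(one observation per individual, no covariates) the Gaussian REML optimum
is available in closed form and reproduces the paired t-test exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, stats
from scipy.special import expit, gammaln

from .io_formats import Cohort
from .region_transform import RegionCounts

__all__ = [
    "RegionFit",
    "PairedTResult",
    "fit_region_glmm",
    "fit_region_lmm",
    "test_interaction",
    "fit_multilocus",
    "paired_t",
]

_SD_FLOOR = 1e-4  # random-effect s.d. below this is reported as a boundary fit
_GRAD_TOL = 1e-8
_MAX_OUTER = 500


@dataclass
class RegionFit:
    region_id: str
    beta_exposure: float
    se: float
    p_value: float
    converged: bool
    model_kind: str  # "binomial" | "linear"
    fit_criterion: str  # "REML" | "ML" | "Laplace-ML"
    covariates: list[str] = field(default_factory=list)
    variance_components: dict[str, float] = field(default_factory=dict)
    boundary: bool = False
    n_pairs: int = 0
    n_obs: int = 0
    loglik: float = np.nan
    note: str = ""


class PairedTResult(NamedTuple):
    t: float
    p: float
    zero_variance: bool


def paired_t(differences: Sequence[float]) -> PairedTResult:
    """Classic two-sided paired t-test on within-pair differences."""
    d = np.asarray(differences, dtype=float)
    if len(d) < 2 or not np.all(np.isfinite(d)):
        raise ValueError("need >=2 finite differences")
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        return PairedTResult(t=np.nan, p=np.nan, zero_variance=True)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return PairedTResult(t=float(t), p=float(min(p, 1.0)), zero_variance=False)


# ---------------------------------------------------------------------------
# design construction helpers


def _covariate_matrix(
    covariates: pd.DataFrame | None, sample_ids: list[str]
) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.empty((len(sample_ids), 0)), []
    cov = covariates.reindex(sample_ids)
    if cov.isna().any().any():
        raise ValueError("covariates missing for some individuals")
    cov = pd.get_dummies(cov, drop_first=True, dtype=float)
    return cov.to_numpy(dtype=float), list(cov.columns)


def _long_design(
    sample_ids: list[str],
    unit_count: int,
    present: np.ndarray,  # (n_individuals, n_units) bool
    cohort: Cohort,
    covariates: pd.DataFrame | None,
):
    """Build the long-format fixed/random design shared by both models.

    Returns X (intercept, exposure, unit dummies, covariates), the exposure
    column index, per-observation pair index, per-observation random design
    rows [1, exposed], and the covariate names.
    """
    cov_mat, cov_names = _covariate_matrix(covariates, sample_ids)
    exposure = cohort.exposure_vector(sample_ids)
    pair_of = {i.sample_id: i.pair_id for i in cohort.individuals}
    pair_ids = cohort.pair_ids
    pair_index = {pid: g for g, pid in enumerate(pair_ids)}

    rows_X, rows_Z, obs_group, obs_ind, obs_unit = [], [], [], [], []
    for i, sid in enumerate(sample_ids):
        for j in range(unit_count):
            if not present[i, j]:
                continue
            dummies = [1.0 if j == u else 0.0 for u in range(1, unit_count)]
            rows_X.append([1.0, exposure[i], *dummies, *cov_mat[i]])
            rows_Z.append([1.0, exposure[i]])
            obs_group.append(pair_index[pair_of[sid]])
            obs_ind.append(i)
            obs_unit.append(j)
    X = np.asarray(rows_X, dtype=float)
    Zrows = np.asarray(rows_Z, dtype=float)
    colnames = (
        ["intercept", "exposure"]
        + [f"unit_{u}" for u in range(1, unit_count)]
        + cov_names
    )
    return (
        X,
        colnames,
        np.asarray(obs_group),
        np.asarray(obs_ind),
        np.asarray(obs_unit),
        Zrows,
        len(pair_ids),
        cov_names,
    )


def _chol2x2(theta: np.ndarray) -> np.ndarray:
    """Log-Cholesky parameterization of a 2x2 covariance factor.

    Log-diagonals are clipped to [-8, 8] so degenerate (zero-variance)
    components stay on a numerically benign boundary instead of diverging.
    """
    t0 = min(max(theta[0], -8.0), 8.0)
    t1 = min(max(theta[1], -50.0), 50.0)
    t2 = min(max(theta[2], -8.0), 8.0)
    return np.array([[math.exp(t0), 0.0], [t1, math.exp(t2)]])


def _expand_random(Zrows: np.ndarray, obs_group: np.ndarray, n_groups: int, q: int):
    """Full (n_obs x n_groups*q) random-effects design, block per group."""
    n = len(Zrows)
    Zf = np.zeros((n, n_groups * q))
    for r in range(n):
        g = obs_group[r]
        Zf[r, g * q : (g + 1) * q] = Zrows[r]
    return Zf


# ---------------------------------------------------------------------------
# binomial GLMM (Laplace)


def _binom_loglik(m, t, eta):
    mu = expit(eta)
    eps = 1e-12
    return float(np.sum(m * np.log(mu + eps) + (t - m) * np.log(1 - mu + eps)))


def _pirls(X, Zf, m, t, Ginv_big, beta, u, max_iter=200, tol=_GRAD_TOL):
    """Jointly maximize the u-penalized binomial log-likelihood over (beta, u)."""
    p, qtot = X.shape[1], Zf.shape[1]

    def objective(b, v):
        return _binom_loglik(m, t, X @ b + Zf @ v) - 0.5 * v @ Ginv_big @ v

    current = objective(beta, u)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta + Zf @ u
        mu = expit(eta)
        W = t * mu * (1 - mu)
        resid = m - t * mu
        g = np.concatenate([X.T @ resid, Zf.T @ resid - Ginv_big @ u])
        if np.max(np.abs(g)) < tol * (1 + abs(current)):
            converged = True
            break
        XW = X.T * W
        ZW = Zf.T * W
        H = np.block([[XW @ X, XW @ Zf], [ZW @ X, ZW @ Zf + Ginv_big]])
        H[np.diag_indices_from(H)] += 1e-10
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(30):
            nb = beta + scale * step[:p]
            nu = u + scale * step[p:]
            cand = objective(nb, nu)
            if cand >= current - 1e-12:
                beta, u, current = nb, nu, cand
                break
            scale *= 0.5
        else:
            break
    return beta, u, current, converged


def _laplace_negll(theta, X, Zrows, obs_group, m, t, n_groups, state):
    L = _chol2x2(theta)
    G = L @ L.T + 1e-10 * np.eye(2)
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        return 1e10
    Zf = state["Zf"]
    Ginv_big = np.kron(np.eye(n_groups), Ginv)
    beta, u, pen_ll, inner_ok = _pirls(
        X, Zf, m, t, Ginv_big, state["beta"].copy(), state["u"].copy()
    )
    if not np.all(np.isfinite(beta)):
        return 1e10
    eta = X @ beta + Zf @ u
    mu = expit(eta)
    W = t * mu * (1 - mu)
    ZW = Zf.T * W
    A = ZW @ Zf + Ginv_big
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        return 1e10
    _, logdet_G = np.linalg.slogdet(G)
    ll = pen_ll - 0.5 * n_groups * logdet_G - 0.5 * logdet_A
    if not np.isfinite(ll):
        return 1e10
    # warm-start the next PIRLS call from here
    state["beta"], state["u"] = beta, u
    state["last"] = (beta, u, W, Ginv_big, ll, inner_ok)
    return -ll


def _agq_loglik(beta, theta, X, Zrows, obs_group, m, t, n_groups, nodes=9):
    """Marginal log-likelihood by adaptive Gauss-Hermite quadrature.

    Per pair the 2-d random-effect integral is evaluated on a tensor grid
    centered and scaled at the conditional mode (Newton) — accurate on the
    small instances where the Laplace approximation is too coarse.
    """
    from numpy.polynomial.hermite_e import hermegauss

    gh_nodes, gh_weights = hermegauss(nodes)
    V1, V2 = np.meshgrid(gh_nodes, gh_nodes)
    Vs = np.vstack([V1.ravel(), V2.ravel()])
    logW = np.log(np.outer(gh_weights, gh_weights).ravel()) + 0.5 * np.sum(
        Vs**2, axis=0
    )
    L = _chol2x2(theta)
    G = L @ L.T + 1e-10 * np.eye(2)
    Ginv = np.linalg.inv(G)
    _, logdet_G = np.linalg.slogdet(G)
    offset = X @ beta
    total = 0.0
    eps = 1e-12
    for g in range(n_groups):
        idx = obs_group == g
        Zg, xg = Zrows[idx], offset[idx]
        mg, tg = m[idx], t[idx]
        u = np.zeros(2)
        for _ in range(100):
            mu = expit(xg + Zg @ u)
            grad = Zg.T @ (mg - tg * mu) - Ginv @ u
            H = (Zg.T * (tg * mu * (1 - mu))) @ Zg + Ginv
            u = u + np.linalg.solve(H, grad)
            if np.max(np.abs(grad)) < 1e-10:
                break
        C = np.linalg.cholesky(np.linalg.inv(H))
        U = u[:, None] + C @ Vs
        etaK = xg[:, None] + Zg @ U
        muK = expit(etaK)
        h = (mg[:, None] * np.log(muK + eps)
             + (tg - mg)[:, None] * np.log(1 - muK + eps)).sum(axis=0)
        h -= 0.5 * np.einsum("ik,ij,jk->k", U, Ginv, U)
        logdet_C = float(np.sum(np.log(np.diag(C))))
        total += logdet_C + np.logaddexp.reduce(h + logW)
        total += -0.5 * logdet_G - np.log(2 * math.pi)
    return total


def _agq_refine(X, Zrows, obs_group, m, t, n_groups, beta0, theta0, nodes=9):
    """Joint (beta, theta) maximization of the quadrature likelihood, warm
    started from the Laplace solution; returns (beta, cov_beta, theta, ll)."""
    p = X.shape[1]

    def neg(params):
        val = _agq_loglik(params[:p], params[p:], X, Zrows, obs_group, m, t,
                          n_groups, nodes)
        return -val if np.isfinite(val) else 1e10

    start = np.concatenate([beta0, theta0])
    res = optimize.minimize(
        neg, start, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 4000, "maxfev": 4000},
    )
    beta, theta = res.x[:p], res.x[p:]
    # observed information over beta at the optimum (theta held fixed)
    h = 1e-4
    Hbb = np.zeros((p, p))
    f0 = -neg(res.x)
    for a in range(p):
        for b in range(a, p):
            pa = res.x.copy(); pa[a] += h; pa[b] += h
            pb = res.x.copy(); pb[a] += h; pb[b] -= h
            pc = res.x.copy(); pc[a] -= h; pc[b] += h
            pd_ = res.x.copy(); pd_[a] -= h; pd_[b] -= h
            Hbb[a, b] = Hbb[b, a] = -(-neg(pa) + neg(pb) + neg(pc) - neg(pd_)) / (
                4 * h * h
            )
    try:
        cov_beta = np.linalg.inv(Hbb)
    except np.linalg.LinAlgError:
        cov_beta = np.full((p, p), np.nan)
    ll_const = float(np.sum(gammaln(t + 1) - gammaln(m + 1) - gammaln(t - m + 1)))
    return beta, cov_beta, theta, f0 + ll_const, bool(res.success)


def fit_region_glmm(
    region: RegionCounts,
    cohort: Cohort,
    covariates: pd.DataFrame | None = None,
    use_lrt: bool = False,
    method: str = "auto",
) -> RegionFit:
    """Binomial logistic mixed model for one region.

    logit Pr(methylated) ~ exposure + CpG id (+ covariates), random per-pair
    intercept and correlated per-pair exposure slope; observations weighted
    by their read totals via the binomial denominator. The exposure effect
    is on the log-odds scale; p is Wald by default, likelihood-ratio with
    ``use_lrt``.

    ``method``: "laplace" (Laplace-approximated ML), "agq" (adaptive
    Gauss-Hermite refinement of the Laplace fit) or "auto", which refines by
    quadrature on small instances (few fixed effects, few observations)
    where the Laplace approximation is coarsest.
    """
    if cohort.n_pairs < 2:
        raise ValueError("need >=2 pairs")
    present = region.T > 0
    (X, colnames, obs_group, _oi, _ou, Zrows, n_groups, cov_names) = _long_design(
        region.sample_ids, region.k, present, cohort, covariates
    )
    m = region.M[present].astype(float)
    t = region.T[present].astype(float)
    exp_col = colnames.index("exposure")

    beta, cov_beta, theta, ll, converged = _glmm_optimize(
        X, Zrows, obs_group, m, t, n_groups
    )
    refine = method == "agq" or (
        method == "auto" and X.shape[1] <= 4 and len(m) <= 80
    )
    criterion = "Laplace-ML"
    if refine:
        beta, cov_beta, theta, ll, converged = _agq_refine(
            X, Zrows, obs_group, m, t, n_groups, beta, theta
        )
        criterion = "AGQ-ML"
    se = math.sqrt(max(cov_beta[exp_col, exp_col], 0.0))
    b_exp = beta[exp_col]
    if use_lrt:
        X0 = np.delete(X, exp_col, axis=1)
        fit0 = _glmm_optimize(X0, Zrows, obs_group, m, t, n_groups)
        ll0 = fit0[3]
        if refine:
            ll0 = _agq_refine(X0, Zrows, obs_group, m, t, n_groups,
                              fit0[0], fit0[2])[3]
        lr = max(2 * (ll - ll0), 0.0)
        p = stats.chi2.sf(lr, df=1)
    else:
        p = 2 * stats.norm.sf(abs(b_exp) / se) if se > 0 else np.nan
    L = _chol2x2(theta)
    G = L @ L.T
    sd_int = math.sqrt(G[0, 0])
    sd_slope = math.sqrt(G[1, 1])
    corr = G[0, 1] / (sd_int * sd_slope) if sd_int > 0 and sd_slope > 0 else np.nan
    boundary = sd_int < _SD_FLOOR or sd_slope < _SD_FLOOR
    note = ""
    if abs(b_exp) > 15:
        converged = False
        note = "possible separation: extreme log-odds estimate"
    return RegionFit(
        region_id=region.region_id,
        beta_exposure=float(b_exp),
        se=float(se),
        p_value=float(min(p, 1.0)) if np.isfinite(p) else np.nan,
        converged=converged,
        model_kind="binomial",
        fit_criterion=criterion,
        covariates=cov_names,
        variance_components={
            "pair_intercept_sd": sd_int,
            "exposure_slope_sd": sd_slope,
            "intercept_slope_corr": corr,
        },
        boundary=boundary,
        n_pairs=n_groups,
        n_obs=len(m),
        loglik=ll,
        note=note,
    )


def _glmm_optimize(X, Zrows, obs_group, m, t, n_groups):
    """Outer optimization of the Laplace objective over the random-effect
    covariance; returns (beta, cov_beta, theta, loglik, converged)."""
    q = 2
    Zf = _expand_random(Zrows, obs_group, n_groups, q)
    state = {
        "beta": np.zeros(X.shape[1]),
        "u": np.zeros(n_groups * q),
        "Zf": Zf,
        "last": None,
    }
    theta0 = np.array([math.log(0.3), 0.0, math.log(0.3)])
    res = optimize.minimize(
        _laplace_negll,
        theta0,
        args=(X, Zrows, obs_group, m, t, n_groups, state),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": _MAX_OUTER},
    )
    # one final evaluation at the optimum to refresh the state
    _laplace_negll(res.x, X, Zrows, obs_group, m, t, n_groups, state)
    beta, u, W, Ginv_big, ll, inner_ok = state["last"]
    XW = X.T * W
    ZW = Zf.T * W
    H = np.block([[XW @ X, XW @ Zf], [ZW @ X, ZW @ Zf + Ginv_big]])
    H[np.diag_indices_from(H)] += 1e-10
    p = X.shape[1]
    try:
        cov_full = np.linalg.inv(H)
        cov_beta = cov_full[:p, :p]
    except np.linalg.LinAlgError:
        cov_beta = np.full((p, p), np.nan)
    # include the binomial normalizing constant in the reported log-likelihood
    ll_const = float(np.sum(gammaln(t + 1) - gammaln(m + 1) - gammaln(t - m + 1)))
    return beta, cov_beta, res.x, ll + ll_const, bool(res.success and inner_ok)


# ---------------------------------------------------------------------------
# Gaussian LMM (profiled REML / ML)


def _lmm_profiled(theta, y, X, Zrows, obs_group, n_groups, reml):
    """Profiled -2 log-likelihood; sigma^2 and beta are profiled out.

    theta parameterizes the relative covariance factor Lambda of the pair
    random effects: V0 = Z Lambda Lambda' Z' + I per pair, V = sigma^2 V0.
    Returns (criterion, beta, cov_beta_over_sigma2, sigma2).
    """
    Lam = _chol2x2(theta)
    GG = Lam @ Lam.T
    n, p = X.shape
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    yVy = 0.0
    logdet = 0.0
    for g in range(n_groups):
        idx = obs_group == g
        if not np.any(idx):
            continue
        Zg = Zrows[idx]
        V0 = Zg @ GG @ Zg.T + np.eye(int(idx.sum()))
        c = sla.cho_factor(V0)
        logdet += 2 * np.sum(np.log(np.diag(c[0])))
        Xi = sla.cho_solve(c, X[idx])
        yi = sla.cho_solve(c, y[idx])
        XtVX += X[idx].T @ Xi
        XtVy += X[idx].T @ yi
        yVy += float(y[idx] @ yi)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = max(yVy - float(beta @ XtVy), 1e-300)
    dof = (n - p) if reml else n
    sigma2 = rss / dof
    crit = dof * (1 + math.log(2 * math.pi * sigma2)) + logdet
    if reml:
        sign, ld = np.linalg.slogdet(XtVX)
        crit += ld
    cov_beta_rel = np.linalg.inv(XtVX)
    return crit, beta, cov_beta_rel, sigma2


def _lmm_balanced_fast_path(y, X, Zrows, obs_group, n_groups, colnames):
    """Closed-form REML for the balanced two-observations-per-pair case.

    With one observation per sibling and only intercept + exposure fixed
    effects, the marginal per-pair covariance is saturated and its REML
    estimate is the unbiased sample covariance; the exposure Wald test then
    coincides with the paired t-test.
    """
    exp_col = colnames.index("exposure")
    d = np.empty(n_groups)
    pair_cov = np.empty((n_groups, 2))
    for g in range(n_groups):
        idx = np.where(obs_group == g)[0]
        e = X[idx, exp_col]
        y_exp = y[idx[e == 1][0]]
        y_ctl = y[idx[e == 0][0]]
        d[g] = y_exp - y_ctl
        pair_cov[g] = (y_ctl, y_exp)
    res = paired_t(d)
    S = np.cov(pair_cov.T, ddof=1)
    beta = np.array([pair_cov[:, 0].mean(), d.mean()])
    se = d.std(ddof=1) / math.sqrt(n_groups)
    # map the saturated covariance back to random-effect components (sigma->0)
    s11 = max(S[0, 0], 0.0)
    s12 = S[0, 1] - S[0, 0]
    s22 = S[1, 1] + S[0, 0] - 2 * S[0, 1]
    return beta, se, res, {"pair_intercept_sd": math.sqrt(max(s11, 0.0)),
                           "exposure_slope_sd": math.sqrt(max(s22, 0.0)),
                           "intercept_slope_corr": (s12 / math.sqrt(s11 * s22)
                                                    if s11 > 0 and s22 > 0 else np.nan),
                           "residual_sd": 0.0}


def fit_region_lmm(
    values: pd.DataFrame,
    cohort: Cohort,
    covariates: pd.DataFrame | None = None,
    reml: bool = True,
    region_id: str = "",
) -> RegionFit:
    """Linear mixed model for continuous per-CpG-unit methylation.

    ``values`` is (CpG units x individuals), NaN marking missing cells.
    Same fixed/random structure as the binomial model; fitted by REML
    (``reml=False`` for ML, used when model fits are compared). The exposure
    effect is in the units of ``values`` (percentage points); Wald p uses a
    t reference with n_pairs - 1 degrees of freedom, which reduces exactly
    to the paired t-test for a single complete CpG with no covariates.
    """
    if cohort.n_pairs < 2:
        raise ValueError("need >=2 pairs")
    vals = values.to_numpy(dtype=float).T  # (individuals x units)
    sample_ids = list(values.columns)
    all_missing = np.all(np.isnan(vals), axis=0)
    if np.any(all_missing):
        vals = vals[:, ~all_missing]
    present = ~np.isnan(vals)
    n_units = vals.shape[1]
    if n_units == 0:
        raise ValueError("no units with data")
    (X, colnames, obs_group, obs_ind, obs_unit, Zrows, n_groups, cov_names) = (
        _long_design(sample_ids, n_units, present, cohort, covariates)
    )
    y = np.array([vals[i, j] for i, j in zip(obs_ind, obs_unit)])

    balanced = (
        reml
        and n_units == 1
        and covariates is None
        and len(y) == 2 * n_groups
        and all(np.sum(obs_group == g) == 2 for g in range(n_groups))
    )
    if balanced:
        beta, se, tres, vc = _lmm_balanced_fast_path(
            y, X, Zrows, obs_group, n_groups, colnames
        )
        return RegionFit(
            region_id=region_id,
            beta_exposure=float(beta[1]),
            se=float(se),
            p_value=float(tres.p) if not tres.zero_variance else np.nan,
            converged=True,
            model_kind="linear",
            fit_criterion="REML",
            covariates=[],
            variance_components=vc,
            boundary=True,  # residual variance at the zero boundary
            n_pairs=n_groups,
            n_obs=len(y),
            note="balanced closed-form REML" + (
                "; zero within-pair variance" if tres.zero_variance else ""
            ),
        )

    theta0 = np.array([math.log(1.0), 0.0, math.log(1.0)])
    res = optimize.minimize(
        lambda th: _lmm_profiled(th, y, X, Zrows, obs_group, n_groups, reml)[0],
        theta0,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
    )
    crit, beta, cov_rel, sigma2 = _lmm_profiled(
        res.x, y, X, Zrows, obs_group, n_groups, reml
    )
    exp_col = colnames.index("exposure")
    se = math.sqrt(max(sigma2 * cov_rel[exp_col, exp_col], 0.0))
    tval = beta[exp_col] / se if se > 0 else np.nan
    p = 2 * stats.t.sf(abs(tval), df=n_groups - 1) if np.isfinite(tval) else np.nan
    Lam = _chol2x2(res.x)
    GG = Lam @ Lam.T * sigma2
    sd_int, sd_slope = math.sqrt(GG[0, 0]), math.sqrt(GG[1, 1])
    return RegionFit(
        region_id=region_id,
        beta_exposure=float(beta[exp_col]),
        se=float(se),
        p_value=float(min(p, 1.0)) if np.isfinite(p) else np.nan,
        converged=bool(res.success),
        model_kind="linear",
        fit_criterion="REML" if reml else "ML",
        covariates=cov_names,
        variance_components={
            "pair_intercept_sd": sd_int,
            "exposure_slope_sd": sd_slope,
            "intercept_slope_corr": (
                GG[0, 1] / (sd_int * sd_slope) if sd_int > 0 and sd_slope > 0 else np.nan
            ),
            "residual_sd": math.sqrt(sigma2),
        },
        boundary=sd_int < _SD_FLOOR or sd_slope < _SD_FLOOR,
        n_pairs=n_groups,
        n_obs=len(y),
        loglik=-0.5 * crit,
    )


def _lmm_loglik_full(y, X, Zrows, obs_group, n_groups, theta):
    """Unprofiled ML log-likelihood at the profiled optimum (for LRTs)."""
    crit, *_ = _lmm_profiled(theta, y, X, Zrows, obs_group, n_groups, reml=False)
    return -0.5 * crit


def test_interaction(
    data: pd.DataFrame | RegionCounts,
    cohort: Cohort,
    modifier: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> float:
    """Likelihood-ratio p-value for an exposure x modifier interaction.

    ``modifier`` is indexed by sample id (continuous, e.g. conception date
    in days, or dichotomous, e.g. a pre/post critical-window indicator);
    main effects of exposure and modifier are always retained. ML fits are
    compared for both the Gaussian and binomial models.
    """
    if modifier.nunique() < 2:
        raise ValueError("modifier is constant")
    if isinstance(data, RegionCounts):
        return _glmm_interaction(data, cohort, modifier, covariates)
    vals = data.to_numpy(dtype=float).T
    sample_ids = list(data.columns)
    present = ~np.isnan(vals)
    n_units = vals.shape[1]
    (X, colnames, obs_group, obs_ind, obs_unit, Zrows, n_groups, _cn) = _long_design(
        sample_ids, n_units, present, cohort, covariates
    )
    y = np.array([vals[i, j] for i, j in zip(obs_ind, obs_unit)])
    mod = modifier.reindex(sample_ids).to_numpy(dtype=float)
    if np.any(np.isnan(mod)):
        raise ValueError("modifier missing for some individuals")
    mod = (mod - mod.mean()) / (mod.std() or 1.0)
    mod_obs = mod[obs_ind]
    exp_col = colnames.index("exposure")
    X_main = np.column_stack([X, mod_obs])
    X_int = np.column_stack([X_main, X[:, exp_col] * mod_obs])

    def fit(Xd):
        theta0 = np.array([0.0, 0.0, 0.0])
        res = optimize.minimize(
            lambda th: _lmm_profiled(th, y, Xd, Zrows, obs_group, n_groups, False)[0],
            theta0,
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000},
        )
        return _lmm_loglik_full(y, Xd, Zrows, obs_group, n_groups, res.x)

    lr = max(2 * (fit(X_int) - fit(X_main)), 0.0)
    return float(stats.chi2.sf(lr, df=1))


def _glmm_interaction(region, cohort, modifier, covariates):
    present = region.T > 0
    (X, colnames, obs_group, obs_ind, _ou, Zrows, n_groups, _cn) = _long_design(
        region.sample_ids, region.k, present, cohort, covariates
    )
    m = region.M[present].astype(float)
    t = region.T[present].astype(float)
    mod = modifier.reindex(region.sample_ids).to_numpy(dtype=float)
    mod = (mod - mod.mean()) / (mod.std() or 1.0)
    mod_obs = mod[obs_ind]
    exp_col = colnames.index("exposure")
    X_main = np.column_stack([X, mod_obs])
    X_int = np.column_stack([X_main, X[:, exp_col] * mod_obs])
    ll_main = _glmm_optimize(X_main, Zrows, obs_group, m, t, n_groups)[3]
    ll_int = _glmm_optimize(X_int, Zrows, obs_group, m, t, n_groups)[3]
    lr = max(2 * (ll_int - ll_main), 0.0)
    return float(stats.chi2.sf(lr, df=1))


def fit_multilocus(
    regions: Sequence[pd.DataFrame] | Sequence[RegionCounts],
    cohort: Cohort,
    covariates: pd.DataFrame | None = None,
    region_ids: Sequence[str] | None = None,
) -> RegionFit:
    """Joint model across regions yielding one pooled exposure p-value.

    The per-pair random exposure slope of the single-region model is
    replaced by an individual random intercept with a region random effect
    nested within individual; region and unit identities enter as fixed
    effects. A single region degenerates to the single-region model.
    """
    regions = list(regions)
    if len(regions) == 0:
        raise ValueError("no regions supplied")
    if len(regions) == 1:
        only = regions[0]
        if isinstance(only, RegionCounts):
            return fit_region_glmm(only, cohort, covariates)
        return fit_region_lmm(only, cohort, covariates)
    if isinstance(regions[0], RegionCounts):
        return _multilocus_glmm(regions, cohort, covariates)
    return _multilocus_lmm(regions, cohort, covariates, region_ids)


def _stack_continuous(regions, region_ids):
    frames = []
    for r, df in enumerate(regions):
        name = region_ids[r] if region_ids else f"region{r}"
        sub = df.copy()
        sub.index = [f"{name}:{u}" for u in df.index]
        sub["__region__"] = r
        frames.append(sub)
    return frames


def _multilocus_design(sample_ids, units_by_region, present, cohort, covariates):
    """Long design with random structure: pair intercept, individual
    intercept, and region-within-individual intercept (independent
    components)."""
    cov_mat, cov_names = _covariate_matrix(covariates, sample_ids)
    exposure = cohort.exposure_vector(sample_ids)
    pair_of = {i.sample_id: i.pair_id for i in cohort.individuals}
    pair_ids = cohort.pair_ids
    pair_index = {pid: g for g, pid in enumerate(pair_ids)}
    n_regions = len(units_by_region)
    total_units = sum(units_by_region)
    # member slot within pair (0/1) for nesting random effects
    slot = {}
    for pid in pair_ids:
        exposed, control = cohort.pair(pid)
        slot[exposed.sample_id] = 0
        slot[control.sample_id] = 1
    q = 1 + 2 + 2 * n_regions  # pair + individuals + region-in-individual
    rows_X, rows_Z, obs_group, ys_idx = [], [], [], []
    unit_offset = np.cumsum([0] + units_by_region[:-1])
    for i, sid in enumerate(sample_ids):
        for r in range(n_regions):
            for j in range(units_by_region[r]):
                col = unit_offset[r] + j
                if not present[i, col]:
                    continue
                unit_dummies = [1.0 if col == u else 0.0 for u in range(1, total_units)]
                rows_X.append([1.0, exposure[i], *unit_dummies, *cov_mat[i]])
                z = np.zeros(q)
                z[0] = 1.0
                z[1 + slot[sid]] = 1.0
                z[3 + slot[sid] * n_regions + r] = 1.0
                rows_Z.append(z)
                obs_group.append(pair_index[pair_of[sid]])
                ys_idx.append((i, col))
    colnames = (
        ["intercept", "exposure"]
        + [f"unit_{u}" for u in range(1, total_units)]
        + cov_names
    )
    return (
        np.asarray(rows_X),
        colnames,
        np.asarray(obs_group),
        np.asarray(rows_Z),
        len(pair_ids),
        q,
        ys_idx,
        cov_names,
    )


def _varcomp_G(theta, q, n_regions):
    """Diagonal variance-component covariance for the multilocus structure."""
    v_pair, v_ind, v_reg = np.exp(2 * np.clip(np.asarray(theta), -8.0, 8.0))
    diag = np.concatenate(
        [[v_pair], [v_ind, v_ind], np.full(2 * n_regions, v_reg)]
    )
    return np.diag(diag)


def _multilocus_lmm(regions, cohort, covariates, region_ids):
    sample_ids = list(regions[0].columns)
    mats = [df.reindex(columns=sample_ids).to_numpy(dtype=float).T for df in regions]
    vals = np.hstack(mats)
    present = ~np.isnan(vals)
    units_by_region = [m.shape[1] for m in mats]
    (X, colnames, obs_group, Zrows, n_groups, q, ys_idx, cov_names) = (
        _multilocus_design(sample_ids, units_by_region, present, cohort, covariates)
    )
    y = np.array([vals[i, j] for i, j in ys_idx])
    n_regions = len(regions)

    def profiled(theta):
        GG = _varcomp_G(theta, q, n_regions)
        n, p = X.shape
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        yVy = 0.0
        logdet = 0.0
        for g in range(n_groups):
            idx = obs_group == g
            Zg = Zrows[idx]
            V0 = Zg @ GG @ Zg.T + np.eye(int(idx.sum()))
            c = sla.cho_factor(V0)
            logdet += 2 * np.sum(np.log(np.diag(c[0])))
            Xi = sla.cho_solve(c, X[idx])
            yi = sla.cho_solve(c, y[idx])
            XtVX += X[idx].T @ Xi
            XtVy += X[idx].T @ yi
            yVy += float(y[idx] @ yi)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = max(yVy - float(beta @ XtVy), 1e-300)
        sigma2 = rss / (n - p)
        sign, ld = np.linalg.slogdet(XtVX)
        crit = (n - p) * (1 + math.log(2 * math.pi * sigma2)) + logdet + ld
        return crit, beta, np.linalg.inv(XtVX), sigma2

    res = optimize.minimize(
        lambda th: profiled(th)[0],
        np.zeros(3),
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000},
    )
    crit, beta, cov_rel, sigma2 = profiled(res.x)
    exp_col = colnames.index("exposure")
    se = math.sqrt(max(sigma2 * cov_rel[exp_col, exp_col], 0.0))
    tval = beta[exp_col] / se if se > 0 else np.nan
    p = 2 * stats.t.sf(abs(tval), df=n_groups - 1) if np.isfinite(tval) else np.nan
    sds = np.exp(res.x) * math.sqrt(sigma2)
    return RegionFit(
        region_id="+".join(region_ids) if region_ids else f"multilocus({len(regions)})",
        beta_exposure=float(beta[exp_col]),
        se=float(se),
        p_value=float(min(p, 1.0)) if np.isfinite(p) else np.nan,
        converged=bool(res.success),
        model_kind="linear",
        fit_criterion="REML",
        covariates=cov_names,
        variance_components={
            "pair_sd": float(sds[0]),
            "individual_sd": float(sds[1]),
            "region_in_individual_sd": float(sds[2]),
            "residual_sd": math.sqrt(sigma2),
        },
        boundary=bool(np.any(sds < _SD_FLOOR)),
        n_pairs=n_groups,
        n_obs=len(y),
        loglik=-0.5 * crit,
    )


def _multilocus_glmm(regions, cohort, covariates):
    sample_ids = regions[0].sample_ids
    for r in regions[1:]:
        if r.sample_ids != sample_ids:
            raise ValueError("regions cover disjoint or differently-ordered individuals")
    Ms = [r.M for r in regions]
    Ts = [r.T for r in regions]
    vals = np.hstack(Ts)
    present = vals > 0
    units_by_region = [r.k for r in regions]
    (X, colnames, obs_group, Zrows, n_groups, q, ys_idx, cov_names) = (
        _multilocus_design(sample_ids, units_by_region, present, cohort, covariates)
    )
    Mfull = np.hstack(Ms)
    m = np.array([Mfull[i, j] for i, j in ys_idx], dtype=float)
    t = np.array([vals[i, j] for i, j in ys_idx], dtype=float)
    n_regions = len(regions)
    Zf = _expand_random(Zrows, obs_group, n_groups, q)
    state = {"beta": np.zeros(X.shape[1]), "u": np.zeros(n_groups * q)}

    def negll(theta):
        GG = _varcomp_G(theta, q, n_regions) + 1e-10 * np.eye(q)
        Ginv = np.linalg.inv(GG)
        Ginv_big = np.kron(np.eye(n_groups), Ginv)
        beta, u, pen_ll, _ok = _pirls(
            X, Zf, m, t, Ginv_big, state["beta"].copy(), state["u"].copy()
        )
        eta = X @ beta + Zf @ u
        mu = expit(eta)
        W = t * mu * (1 - mu)
        A = (Zf.T * W) @ Zf + Ginv_big
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0 or not np.all(np.isfinite(beta)):
            return 1e10
        _, logdet_G = np.linalg.slogdet(GG)
        state["beta"], state["u"] = beta, u
        state["last"] = (beta, u, W, Ginv_big)
        return -(pen_ll - 0.5 * n_groups * logdet_G - 0.5 * logdet_A)

    res = optimize.minimize(
        negll, np.log([0.3, 0.3, 0.3]), method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": _MAX_OUTER},
    )
    negll(res.x)
    beta, u, W, Ginv_big = state["last"]
    XW = X.T * W
    ZW = Zf.T * W
    H = np.block([[XW @ X, XW @ Zf], [ZW @ X, ZW @ Zf + Ginv_big]])
    H[np.diag_indices_from(H)] += 1e-10
    p_fixed = X.shape[1]
    cov_beta = np.linalg.inv(H)[:p_fixed, :p_fixed]
    exp_col = colnames.index("exposure")
    se = math.sqrt(max(cov_beta[exp_col, exp_col], 0.0))
    b = beta[exp_col]
    p = 2 * stats.norm.sf(abs(b) / se) if se > 0 else np.nan
    sds = np.exp(res.x)
    return RegionFit(
        region_id=f"multilocus({n_regions})",
        beta_exposure=float(b),
        se=float(se),
        p_value=float(min(p, 1.0)) if np.isfinite(p) else np.nan,
        converged=bool(res.success),
        model_kind="binomial",
        fit_criterion="Laplace-ML",
        covariates=cov_names,
        variance_components={
            "pair_sd": float(sds[0]),
            "individual_sd": float(sds[1]),
            "region_in_individual_sd": float(sds[2]),
        },
        boundary=bool(np.any(sds < _SD_FLOOR)),
        n_pairs=n_groups,
        n_obs=len(m),
        loglik=-res.fun,
    )
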