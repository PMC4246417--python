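"""Multiple testing, replication bounds, enrichment and downstream inference.

Contains the generic statistical utilities used after region-level testing:
Benjamini-Hochberg FDR adjustment, the Simes-based closed testing procedure
that yields simultaneous confidence bounds on the number of true discoveries
(the "replication rate"), Fisher exact enrichment, cross-platform
concordance filtering, triplicate-measurement QC and phenotype association
models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClosedTestingResult",
    "EnrichmentResult",
    "bh_fdr",
    "closed_testing_simes",
    "fisher_enrichment",
    "platform_concordance",
    "epityper_qc",
    "phenotype_association",
]


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ClosedTestingResult:
    """Simultaneous lower bound on true discoveries among k hypotheses.

    ``lower_bound`` is the (1 - alpha) confidence lower bound on the number
    of false null hypotheses; ``pi1_point`` is the median-unbiased point
    estimate (the same bound computed at alpha = 0.5).
    """

    alpha: float
    k: int
    lower_bound: int
    pi1_point: int

    def __post_init__(self) -> None:
        assert 0 <= self.lower_bound <= self.pi1_point <= self.k


def _simes_rejects(p_sorted: np.ndarray, alpha: float) -> bool:
    """Simes test of the intersection null over the given (sorted) p-values."""
    m = len(p_sorted)
    ranks = np.arange(1, m + 1)
    return bool(np.any(m * p_sorted / ranks <= alpha))


def _max_nonrejected_subset(p: np.ndarray, alpha: float) -> int:
    """Size of the largest subset whose Simes intersection test survives alpha.

    Shortcut: replacing any member of a subset by a larger p-value can only
    increase every sorted Simes term, so the hardest-to-reject subset of each
    size consists of the largest p-values. Scan sizes from largest down.
    """
    p_desc = np.sort(p)[::-1]
    k = len(p)
    for m in range(k, 0, -1):
        subset = np.sort(p_desc[:m])
        if not _simes_rejects(subset, alpha):
            return m
    return 0


def closed_testing_simes(pvals, alpha: float = 0.05) -> ClosedTestingResult:
    """Closed testing with the Simes local test.

    The lower confidence bound on the number of true discoveries equals
    k minus the size of the largest subset of hypotheses whose Simes
    intersection test is not rejected at ``alpha``. All 2^k intersection
    hypotheses are covered implicitly through the sorted-p shortcut.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    k = len(p)
    lower = k - _max_nonrejected_subset(p, alpha)
    pi1 = k - _max_nonrejected_subset(p, 0.5)
    # closed testing at a stricter alpha can never claim more discoveries
    if pi1 < lower:  # pragma: no cover - guarded by theory, alpha<=0.5 usage
        pi1 = lower
    return ClosedTestingResult(alpha=alpha, k=k, lower_bound=lower, pi1_point=pi1)


@dataclass
class EnrichmentResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    table: np.ndarray
    degenerate: bool = False


def fisher_enrichment(table) -> EnrichmentResult:
    """Two-sided Fisher exact test with conditional-MLE odds ratio and exact
    95% CI for a 2x2 contingency table."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a non-negative 2x2 integer array")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return EnrichmentResult(
            odds_ratio=np.nan,
            ci_low=np.nan,
            ci_high=np.nan,
            p_value=1.0,
            table=t,
            degenerate=True,
        )
    _, p = stats.fisher_exact(t, alternative="two-sided")
    res = _odds_ratio(t, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    return EnrichmentResult(
        odds_ratio=float(res.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_value=float(min(p, 1.0)),
        table=t,
    )


def platform_concordance(
    rrbs: pd.DataFrame, epityper: pd.DataFrame, threshold: float = 0.7
) -> pd.DataFrame:
    """Per-region Pearson correlation between two platforms.

    Both inputs are (region x individual) mean-methylation tables; only
    individuals shared by both platforms enter each correlation. Returns one
    row per shared region with columns r, n_shared, keep, degenerate. The
    pooled correlation over all region/individual cells is attached as
    ``result.attrs['overall_r']``.
    """
    shared_regions = [r for r in rrbs.index if r in epityper.index]
    rows = []
    pooled_x: list[float] = []
    pooled_y: list[float] = []
    for region in shared_regions:
        x = rrbs.loc[region]
        y = epityper.loc[region]
        common = x.index.intersection(y.index)
        xv = x[common].astype(float)
        yv = y[common].astype(float)
        mask = xv.notna() & yv.notna()
        xv, yv = xv[mask].to_numpy(), yv[mask].to_numpy()
        if len(xv) < 3:
            rows.append((region, np.nan, len(xv), False, True))
            continue
        if np.std(xv) == 0 or np.std(yv) == 0:
            rows.append((region, np.nan, len(xv), False, True))
            continue
        r = float(stats.pearsonr(xv, yv).statistic)
        rows.append((region, r, len(xv), r > threshold, False))
        pooled_x.extend(xv)
        pooled_y.extend(yv)
    out = pd.DataFrame(
        rows, columns=["region_id", "r", "n_shared", "keep", "degenerate"]
    ).set_index("region_id")
    if len(pooled_x) >= 3 and np.std(pooled_x) > 0 and np.std(pooled_y) > 0:
        out.attrs["overall_r"] = float(stats.pearsonr(pooled_x, pooled_y).statistic)
    else:
        out.attrs["overall_r"] = np.nan
    return out


def epityper_qc(
    triplicates: pd.DataFrame,
    max_sd: float = 10.0,
    min_success: float = 0.75,
    snp_mask: set[str] | None = None,
) -> pd.DataFrame:
    """QC for triplicate continuous methylation measurements.

    ``triplicates`` is long-format with columns (unit_id, sample_id,
    replicate, value); failed wells are NaN. A cell (unit, individual) is
    retained iff >=2 of 3 wells succeeded and their s.d. is below ``max_sd``
    percentage points; a unit is retained globally iff its post-cell success
    rate exceeds ``min_success``; units in ``snp_mask`` are removed. Returns
    a (unit x individual) table of triplicate means.
    """
    required = {"unit_id", "sample_id", "replicate", "value"}
    if not required.issubset(triplicates.columns):
        raise ValueError(f"triplicates table needs columns {sorted(required)}")
    snp_mask = snp_mask or set()
    df = triplicates[~triplicates["unit_id"].isin(snp_mask)]
    cells = {}
    for (unit, sample), grp in df.groupby(["unit_id", "sample_id"], sort=True):
        vals = grp["value"].to_numpy(dtype=float)
        ok = vals[np.isfinite(vals)]
        if len(ok) >= 2 and np.std(ok, ddof=1) < max_sd:
            cells[(unit, sample)] = float(np.mean(ok))
        else:
            cells[(unit, sample)] = np.nan
    if not cells:
        return pd.DataFrame()
    wide = pd.Series(cells).unstack()
    success = wide.notna().mean(axis=1)
    return wide.loc[success > min_success]


def phenotype_association(
    methylation: pd.DataFrame,
    phenotypes: pd.DataFrame,
    pairs: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Exploratory region-methylation ~ phenotype regressions.

    ``methylation``: (region x individual) mean methylation in percent.
    ``phenotypes``: (individual x phenotype) with NaN for missing (for a
    phenotype recorded in one exposure group only, the other group is NaN
    and simply drops out). ``pairs`` maps individual -> pair id; when both
    siblings of at least one pair contribute, a mixed model with a pair
    random intercept is used, otherwise OLS. The slope is in percentage
    points of methylation per phenotype unit. BH adjustment runs across the
    full region x phenotype grid.
    """
    import warnings

    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    rows = []
    for region in methylation.index:
        for pheno in phenotypes.columns:
            meth = methylation.loc[region]
            ph = phenotypes[pheno]
            df = pd.DataFrame({"meth": meth, "pheno": ph})
            df["pair"] = pairs.reindex(df.index)
            if covariates is not None:
                for c in covariates.columns:
                    df[c] = covariates[c].reindex(df.index)
            df = df.dropna()
            if len(df) < 3 or df["pheno"].nunique() < 2:
                rows.append((region, pheno, np.nan, np.nan, np.nan, len(df)))
                continue
            cov_terms = (
                " + " + " + ".join(covariates.columns) if covariates is not None else ""
            )
            formula = "meth ~ pheno" + cov_terms
            paired = df["pair"].duplicated().any()
            if paired:
                # boundary fits (pair variance ~ 0) are routine here; the
                # fixed-effect inference remains valid
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", UserWarning)
                    fit = smf.mixedlm(formula, df, groups=df["pair"]).fit(reml=True)
                beta, se = fit.params["pheno"], fit.bse["pheno"]
                p = float(fit.pvalues["pheno"])
            else:
                X = sm.add_constant(
                    df[["pheno"] + (list(covariates.columns) if covariates is not None else [])]
                )
                fit = sm.OLS(df["meth"], X).fit()
                beta, se = fit.params["pheno"], fit.bse["pheno"]
                p = float(fit.pvalues["pheno"])
            rows.append((region, pheno, float(beta), float(se), min(p, 1.0), len(df)))
    out = pd.DataFrame(
        rows, columns=["region_id", "phenotype", "beta", "se", "p", "n"]
    )
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    return out
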