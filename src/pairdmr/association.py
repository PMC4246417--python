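"""Grouped global testing of region methylation scores against exposure.

The test asks whether a whole set of features (transformed region scores)
is associated with exposure, rather than testing features one at a time.
The statistic is the score-test quadratic form

    Q = (e - e_bar)' Z' Z (e - e_bar)

with ``e`` the 0/1 exposure vector and ``Z`` the column-centered (optionally
standardized and covariate-residualized) feature matrix. Because the design
is sibling pairs discordant for exposure, the null distribution is obtained
by swapping exposure labels within pairs: exhaustively over all 2^n_pairs
assignments when feasible, otherwise by seeded Monte Carlo with the
add-one correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import bh_fdr
from .io_formats import Cohort, GeneSetCollection, RegionIndex

__all__ = [
    "GlobalTestResult",
    "global_test",
    "annotation_scan",
    "pathway_scan",
    "sanity_set_check",
]

ENUMERATION_CAP = 2**20
DEFAULT_MC_PERMUTATIONS = 10_000
_TIE_RTOL = 1e-12


@dataclass
class GlobalTestResult:
    set_name: str
    Q: float
    p_nominal: float
    n_features: int
    n_permutations_used: int
    method: str  # "exact-enumeration" | "monte-carlo"

    def __post_init__(self) -> None:
        assert self.Q >= 0
        assert 0 < self.p_nominal <= 1


def _pair_columns(cohort: Cohort, sample_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Column indices of (exposed, control) members, one row per pair."""
    col = {s: i for i, s in enumerate(sample_ids)}
    exposed_idx, control_idx = [], []
    for pid in cohort.pair_ids:
        exposed, control = cohort.pair(pid)
        if exposed.sample_id not in col or control.sample_id not in col:
            raise ValueError(f"pair {pid}: members missing from the feature matrix")
    for pid in cohort.pair_ids:
        exposed, control = cohort.pair(pid)
        exposed_idx.append(col[exposed.sample_id])
        control_idx.append(col[control.sample_id])
    return np.array(exposed_idx), np.array(control_idx)


def _residualize(rows: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residualize each row on an intercept plus optional covariate columns."""
    n = rows.shape[-1]
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.hstack([X, C])
    coef, *_ = np.linalg.lstsq(X, rows.T, rcond=None)
    return rows - (X @ coef).T


def _sign_matrix(n_pairs: int, chunk_start: int, chunk_end: int) -> np.ndarray:
    """Rows are +/-1 sign vectors for permutation indices [chunk_start, chunk_end)."""
    idx = np.arange(chunk_start, chunk_end, dtype=np.int64)
    bits = (idx[:, None] >> np.arange(n_pairs)) & 1
    return (1.0 - 2.0 * bits).astype(float)


def global_test(
    Z: np.ndarray,
    cohort: Cohort,
    sample_ids: list[str],
    covariates: np.ndarray | None = None,
    standardize: bool = True,
    set_name: str = "",
    n_permutations: int = DEFAULT_MC_PERMUTATIONS,
    enumeration_cap: int = ENUMERATION_CAP,
    rng: np.random.Generator | None = None,
) -> GlobalTestResult:
    """Within-pair permutation global test of features against exposure.

    ``Z`` is (features x individuals) with columns ordered as ``sample_ids``.
    With ``standardize`` each residualized feature is scaled to unit variance
    so CpG-rich/high-variance regions do not dominate the quadratic form.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != len(sample_ids):
        raise ValueError("feature matrix columns must match sample_ids")
    n_pairs = cohort.n_pairs
    if n_pairs < 2:
        raise ValueError("global test needs >=2 pairs")
    exposure = cohort.exposure_vector(sample_ids)
    if exposure.min() == exposure.max():
        raise ValueError("constant exposure vector")

    Zt = _residualize(Z, covariates)
    if standardize:
        sd = Zt.std(axis=1, ddof=1)
        keep = sd > 0
        if not keep.any():
            raise ValueError("no non-constant features to test")
        Zt = Zt[keep] / sd[keep][:, None]

    exp_idx, ctl_idx = _pair_columns(cohort, sample_ids)
    # within-pair feature differences (residualized), one column per pair;
    # Q under sign vector s is 0.25 * s' G s with G the pair Gram matrix
    D = Zt[:, exp_idx] - Zt[:, ctl_idx]
    G = D.T @ D
    q_obs = 0.25 * float(np.ones(n_pairs) @ G @ np.ones(n_pairs))

    total = 2**n_pairs
    if total <= enumeration_cap:
        n_geq = 0
        chunk = 1 << 16
        for start in range(0, total, chunk):
            S = _sign_matrix(n_pairs, start, min(start + chunk, total))
            q_perm = 0.25 * np.einsum("ij,jk,ik->i", S, G, S)
            n_geq += int(np.sum(q_perm >= q_obs * (1 - _TIE_RTOL) - _TIE_RTOL))
        p = n_geq / total
        method, n_used = "exact-enumeration", total
    else:
        rng = np.random.default_rng(0) if rng is None else rng
        S = rng.choice([-1.0, 1.0], size=(n_permutations, n_pairs))
        q_perm = 0.25 * np.einsum("ij,jk,ik->i", S, G, S)
        b = int(np.sum(q_perm >= q_obs * (1 - _TIE_RTOL) - _TIE_RTOL))
        p = (b + 1) / (n_permutations + 1)
        method, n_used = "monte-carlo", n_permutations
    return GlobalTestResult(
        set_name=set_name,
        Q=q_obs,
        p_nominal=float(min(max(p, np.nextafter(0, 1)), 1.0)),
        n_features=Zt.shape[0],
        n_permutations_used=n_used,
        method=method,
    )


def annotation_scan(
    feature_matrices: dict[str, np.ndarray],
    cohort: Cohort,
    sample_ids: list[str],
    covariates: np.ndarray | None = None,
    q_threshold: float = 0.05,
    rng: np.random.Generator | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Global-test every annotation; BH-adjust across annotations.

    Failures (e.g. an annotation with no usable features) are recorded with
    NaN statistics rather than aborting the scan.
    """
    rows = []
    for name, Z in feature_matrices.items():
        try:
            res = global_test(
                Z, cohort, sample_ids, covariates=covariates, set_name=name,
                rng=rng, **kwargs
            )
            rows.append((name, res.n_features, res.Q, res.p_nominal,
                         res.method, res.n_permutations_used, None))
        except (ValueError, np.linalg.LinAlgError) as exc:
            rows.append((name, 0, np.nan, np.nan, "failed", 0, str(exc)))
    out = pd.DataFrame(
        rows, columns=["set", "n_features", "Q", "p_nominal", "method", "n_perm", "error"]
    )
    tested = out["p_nominal"].notna()
    out["q_bh"] = np.nan
    if tested.any():
        out.loc[tested, "q_bh"] = bh_fdr(out.loc[tested, "p_nominal"].to_numpy())
    out["significant"] = out["q_bh"] < q_threshold
    return out


def pathway_scan(
    gene_sets: GeneSetCollection,
    region_index: RegionIndex,
    transformed: dict[str, np.ndarray],
    cohort: Cohort,
    sample_ids: list[str],
    excluded_genes: set[str] | None = None,
    restrict_to_genes: set[str] | None = None,
    covariates: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Gene-set level global testing of region scores.

    Features of a set are the transformed scores of regions whose nearest
    gene belongs to the set, after removing ``excluded_genes`` (used to drop
    the focal genes themselves for an unbiased scan). With
    ``restrict_to_genes`` only sets containing at least one of those genes
    are tested (the focal-pathway mode); otherwise the full collection runs.
    Sets with no remaining regions are recorded as untestable.
    """
    excluded_genes = excluded_genes or set()
    gene_to_regions: dict[str, list[str]] = {}
    for region_id, gene in region_index.nearest_genes.items():
        if gene is not None and region_id in transformed:
            gene_to_regions.setdefault(gene, []).append(region_id)
    rows = []
    for set_name, members in gene_sets.sets.items():
        member_set = set(members)
        if restrict_to_genes is not None and not (member_set & restrict_to_genes):
            continue
        usable = sorted(member_set - excluded_genes)
        region_ids = sorted(
            {rid for g in usable for rid in gene_to_regions.get(g, [])}
        )
        if not region_ids:
            rows.append((set_name, 0, np.nan, np.nan, "untestable", 0, None))
            continue
        Z = np.vstack([transformed[rid] for rid in region_ids])
        res = global_test(
            Z, cohort, sample_ids, covariates=covariates, set_name=set_name,
            rng=rng, **kwargs
        )
        rows.append((set_name, len(region_ids), res.Q, res.p_nominal,
                     res.method, res.n_permutations_used, ";".join(region_ids)))
    out = pd.DataFrame(
        rows, columns=["set", "n_regions", "Q", "p_nominal", "method", "n_perm", "regions"]
    )
    tested = out["p_nominal"].notna()
    out["q_bh"] = np.nan
    if tested.any():
        out.loc[tested, "q_bh"] = bh_fdr(out.loc[tested, "p_nominal"].to_numpy())
    return out


def sanity_set_check(
    positive_regions: list[str],
    negative_regions: list[str],
    transformed: dict[str, np.ndarray],
    cohort: Cohort,
    sample_ids: list[str],
    rng: np.random.Generator | None = None,
    **kwargs,
) -> tuple[float, float]:
    """Pipeline self-test: global-test a putatively associated region set and
    a null set; returns (p_positive, p_negative). The sets must be disjoint."""
    overlap = set(positive_regions) & set(negative_regions)
    if overlap:
        raise ValueError(f"positive and negative sets overlap: {sorted(overlap)[:5]}")
    results = []
    for name, ids in (("positive", positive_regions), ("negative", negative_regions)):
        Z = np.vstack([transformed[r] for r in ids])
        res = global_test(Z, cohort, sample_ids, set_name=name, rng=rng, **kwargs)
        results.append(res.p_nominal)
    return results[0], results[1]
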