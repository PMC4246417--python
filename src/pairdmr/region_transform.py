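"""Region-level aggregation and coverage-shrinkage transformation.

Per-CpG bisulfite counts are summed within a region for each individual and
converted to a single approximately-normal methylation score. The score is
an empirical-Bayes shrunken fraction: individuals with little coverage are
pulled toward the population-average methylation of the region, individuals
with deep coverage keep essentially their raw fraction. This puts regions
with different CpG numbers, coverages and missingness on one common scale
suitable for the grouped global test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import MethylomeSample, RegionIndex

__all__ = [
    "RegionCounts",
    "TransformedRegion",
    "aggregate_region",
    "shrink_transform",
    "transform_regions",
]


@dataclass
class RegionCounts:
    """Per-region counts: one row per individual, one column per CpG.

    ``M[i, j]`` / ``T[i, j]`` are methylated/total reads of individual ``i``
    at CpG ``j``; a missing observation has ``T[i, j] == 0``. ``k`` is the
    number of CpG sites in the region.
    """

    region_id: str
    sample_ids: list[str]
    M: np.ndarray  # (n_individuals, k) int
    T: np.ndarray  # (n_individuals, k) int

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.int64)
        self.T = np.asarray(self.T, dtype=np.int64)
        if self.M.shape != self.T.shape:
            raise ValueError("M and T shapes differ")
        if self.M.ndim != 2 or self.M.shape[1] < 1:
            raise ValueError("counts must be 2-D with k >= 1 CpGs")
        if np.any(self.M < 0) or np.any(self.M > self.T):
            raise ValueError(f"region {self.region_id}: invalid counts (M > T or M < 0)")

    @property
    def k(self) -> int:
        return self.M.shape[1]

    @property
    def m_total(self) -> np.ndarray:
        """M_i. — methylated reads summed over CpGs, per individual."""
        return self.M.sum(axis=1)

    @property
    def t_total(self) -> np.ndarray:
        """T_i. — total reads summed over CpGs, per individual."""
        return self.T.sum(axis=1)


@dataclass
class TransformedRegion:
    region_id: str
    sample_ids: list[str]
    z: np.ndarray  # (n_individuals,), finite


def aggregate_region(
    samples: list[MethylomeSample], region_index: RegionIndex, region_id: str
) -> RegionCounts:
    """Collect the per-CpG count matrices of one region across individuals.

    CpGs missing in an individual contribute 0 to both sums.
    """
    try:
        keys = region_index.cpgs[region_id]
    except KeyError:
        raise KeyError(f"region {region_id} has no covered CpGs") from None
    n, k = len(samples), len(keys)
    M = np.zeros((n, k), dtype=np.int64)
    T = np.zeros((n, k), dtype=np.int64)
    for i, sample in enumerate(samples):
        lookup = sample.as_dict()
        for j, key in enumerate(keys):
            rec = lookup.get(key)
            if rec is not None:
                M[i, j] = rec.methylated_reads
                T[i, j] = rec.total_reads
    return RegionCounts(
        region_id=region_id,
        sample_ids=[s.sample_id for s in samples],
        M=M,
        T=T,
    )


def shrink_transform(
    region: RegionCounts, prior_strength: float | None = None
) -> TransformedRegion:
    """Shrunken methylation fraction per individual.

    z_i = (M_i. + λ p̄) / (T_i. + λ) with p̄ = Σ M_i. / Σ T_i. the population
    average fraction and λ the prior strength (default: population median of
    T_i.). Individuals with zero coverage get exactly p̄; as T_i. grows the
    score approaches the raw fraction M_i./T_i..
    """
    m = region.m_total.astype(float)
    t = region.t_total.astype(float)
    if np.count_nonzero(t) == 0:
        raise ValueError(f"region {region.region_id}: all individuals have zero coverage")
    if len(t) < 2:
        raise ValueError("shrink_transform needs >=2 individuals")
    p_bar = m.sum() / t.sum()
    lam = float(np.median(t)) if prior_strength is None else float(prior_strength)
    if lam < 0:
        raise ValueError("prior_strength must be non-negative")
    if lam == 0 and np.any(t == 0):
        raise ValueError("prior_strength 0 with zero-coverage individuals")
    z = (m + lam * p_bar) / (t + lam)
    if not np.all(np.isfinite(z)):
        raise AssertionError("non-finite transformed score")
    return TransformedRegion(region_id=region.region_id, sample_ids=list(region.sample_ids), z=z)


def transform_regions(
    samples: list[MethylomeSample],
    region_index: RegionIndex,
    prior_strength: float | None = None,
):
    """Aggregate + transform every indexed region.

    Returns a (regions x individuals) matrix as a dict region_id -> z plus
    the ordered sample ids; convenience wrapper used by the pipeline.
    """
    sample_ids = [s.sample_id for s in samples]
    out: dict[str, np.ndarray] = {}
    for region_id in region_index.cpgs:
        counts = aggregate_region(samples, region_index, region_id)
        if np.count_nonzero(counts.t_total) == 0:
            continue
        out[region_id] = shrink_transform(counts, prior_strength).z
    return out, sample_ids
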