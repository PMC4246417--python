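"""Orchestration of the two-stage discovery -> validation workflow.

Discovery: CpG filtering, annotation grouping, region transformation,
annotation-level global testing with BH selection, per-region binomial
mixed-model testing within the selected annotations, and BH-based calling
of differentially methylated regions (DMRs). Validation: attenuated
continuous re-measurements, QC and platform concordance filtering,
region-level linear mixed models, critical-window stratification and
interaction tests, and a closed-testing replication bound.

Runs either on files (per the io_formats readers) or on a simulation block
that generates the dataset in memory with known ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats as iof
from .association import annotation_scan
from .inference import (
    ClosedTestingResult,
    bh_fdr,
    closed_testing_simes,
    epityper_qc,
    platform_concordance,
)
from .mixed_models import RegionFit, fit_region_glmm, fit_region_lmm, test_interaction
from .region_transform import aggregate_region, shrink_transform
from .synthetic_data import (
    GroundTruth,
    SimulationConfig,
    simulate_cohort,
    simulate_epityper,
    simulate_methylome,
    simulate_phenotypes,
)

log = logging.getLogger("pairdmr")

__all__ = ["PipelineConfig", "DiscoveryBundle", "ValidationBundle",
           "run_discovery", "run_validation"]


@dataclass
class PipelineConfig:
    simulation: SimulationConfig | None = None
    methylome_paths: list[str] = field(default_factory=list)
    annotation_paths: dict[str, str] = field(default_factory=dict)
    sample_sheet_path: str | None = None
    gene_sets_path: str | None = None
    annotation_q: float = 0.05
    region_q: float = 0.05
    concordance_r: float = 0.7
    n_permutations: int = 10_000
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.simulation is None and not self.methylome_paths:
            raise ValueError("config needs either a simulation block or input paths")
        for name in ("annotation_q", "region_q", "concordance_r"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class DiscoveryBundle:
    cohort: iof.Cohort
    samples: list[iof.MethylomeSample]
    filter_report: iof.CpGFilterReport
    region_indexes: dict[str, iof.RegionIndex]
    transformed: dict[str, np.ndarray]
    sample_ids: list[str]
    annotation_table: pd.DataFrame
    selected_annotations: list[str]
    region_fits: pd.DataFrame
    pdmr_table: pd.DataFrame
    truth: GroundTruth | None = None

    @property
    def n_hyper(self) -> int:
        return int((self.pdmr_table["within_pair_diff"] > 0).sum())

    @property
    def n_hypo(self) -> int:
        return int((self.pdmr_table["within_pair_diff"] < 0).sum())


@dataclass
class ValidationBundle:
    epityper_clean: pd.DataFrame
    concordance: pd.DataFrame
    validated_fits: pd.DataFrame
    window_stratified: pd.DataFrame
    interaction_p: float | None
    closed_testing: ClosedTestingResult | None


def _within_pair_diff(counts, cohort: iof.Cohort) -> float:
    """Mean over pairs of exposed-minus-control region methylation, in
    percentage points of the raw aggregated fraction."""
    col = {s: i for i, s in enumerate(counts.sample_ids)}
    m, t = counts.m_total, counts.t_total
    diffs = []
    for pid in cohort.pair_ids:
        exposed, control = cohort.pair(pid)
        ie, ic = col[exposed.sample_id], col[control.sample_id]
        if t[ie] == 0 or t[ic] == 0:
            continue
        diffs.append(100.0 * (m[ie] / t[ie] - m[ic] / t[ic]))
    return float(np.mean(diffs)) if diffs else np.nan


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        sim = config.simulation
        cohort = simulate_cohort(sim, seed=config.seed)
        samples, truth = simulate_methylome(sim, cohort, seed=config.seed)
        annotations = truth.annotation_sets
        return cohort, samples, annotations, truth
    cohort = iof.read_sample_sheet(config.sample_sheet_path)
    samples = [iof.read_methylation_table(p) for p in config.methylome_paths]
    annotations = {
        name: iof.read_annotation_bed(path, name)
        for name, path in config.annotation_paths.items()
    }
    return cohort, samples, annotations, None


def run_discovery(config: PipelineConfig) -> DiscoveryBundle:
    """Full discovery stage; every step logged with counts."""
    cohort, samples, annotations, truth = _load_inputs(config)
    sample_ids = [s.sample_id for s in samples]
    log.info("discovery: %d individuals, %d pairs, %d annotations",
             len(samples), cohort.n_pairs, len(annotations))

    kept, report = iof.filter_cpgs(samples)
    log.info("CpG filter: %d/%d kept (low=%d high=%d random=%d uninformative=%d)",
             report.n_kept, report.n_input, report.n_low_coverage,
             report.n_high_coverage, report.n_random_chrom, report.n_uninformative)

    region_indexes = {
        name: iof.assign_cpgs_to_regions(kept, ann) for name, ann in annotations.items()
    }
    transformed: dict[str, np.ndarray] = {}
    counts_cache = {}
    for name, index in region_indexes.items():
        for rid in index.cpgs:
            if rid in transformed:
                continue
            counts = aggregate_region(samples, index, rid)
            if np.count_nonzero(counts.t_total) < 2:
                continue
            counts_cache[rid] = counts
            transformed[rid] = shrink_transform(counts).z
    log.info("transformed %d regions", len(transformed))

    rng = np.random.default_rng(config.seed + 17)
    feature_matrices = {}
    for name, index in region_indexes.items():
        rids = [r for r in index.cpgs if r in transformed]
        if rids:
            feature_matrices[name] = np.vstack([transformed[r] for r in rids])
    ann_table = annotation_scan(
        feature_matrices, cohort, sample_ids,
        q_threshold=config.annotation_q,
        n_permutations=config.n_permutations, rng=rng,
    )
    selected = list(ann_table.loc[ann_table["significant"], "set"])
    log.info("annotation scan: %d/%d selected at q<%g",
             len(selected), len(ann_table), config.annotation_q)

    # regions in multiple selected annotations are tested once
    region_pool: dict[str, list[str]] = {}
    for name in selected:
        for rid in region_indexes[name].cpgs:
            if rid in transformed:
                region_pool.setdefault(rid, []).append(name)
    fit_rows = []
    for rid in sorted(region_pool):
        counts = counts_cache[rid]
        fit = fit_region_glmm(counts, cohort)
        fit_rows.append({
            "region_id": rid,
            "annotations": ";".join(region_pool[rid]),
            "beta": fit.beta_exposure,
            "se": fit.se,
            "p": fit.p_value,
            "converged": fit.converged,
            "boundary": fit.boundary,
            "within_pair_diff": _within_pair_diff(counts, cohort),
            "n_pairs": fit.n_pairs,
        })
    region_fits = pd.DataFrame(
        fit_rows,
        columns=["region_id", "annotations", "beta", "se", "p",
                 "converged", "boundary", "within_pair_diff", "n_pairs"],
    )
    if len(region_fits):
        ok = region_fits["p"].notna()
        region_fits["q"] = np.nan
        region_fits.loc[ok, "q"] = bh_fdr(region_fits.loc[ok, "p"].to_numpy())
        pdmr = region_fits[region_fits["q"] < config.region_q].reset_index(drop=True)
    else:
        region_fits["q"] = pd.Series(dtype=float)
        pdmr = region_fits.copy()
    log.info("region testing: %d regions, %d DMRs at q<%g",
             len(region_fits), len(pdmr), config.region_q)
    bundle = DiscoveryBundle(
        cohort=cohort, samples=samples, filter_report=report,
        region_indexes=region_indexes, transformed=transformed,
        sample_ids=sample_ids, annotation_table=ann_table,
        selected_annotations=selected, region_fits=region_fits,
        pdmr_table=pdmr, truth=truth,
    )
    if config.output_dir:
        _write_discovery(bundle, config)
    return bundle


def run_validation(
    config: PipelineConfig,
    bundle: DiscoveryBundle,
    pdmr_ids: list[str] | None = None,
) -> ValidationBundle:
    """Validation stage on the continuous platform, with the critical-window
    analyses and the closed-testing replication bound."""
    if config.simulation is None:
        raise ValueError("validation currently requires a simulation block")
    if bundle.truth is None:
        raise ValueError("discovery bundle carries no ground truth")
    cohort = bundle.cohort
    candidates = (
        pdmr_ids if pdmr_ids is not None else list(bundle.pdmr_table["region_id"])
    )
    if not candidates:
        return ValidationBundle(pd.DataFrame(), pd.DataFrame(), pd.DataFrame(),
                                pd.DataFrame(), None, None)
    triplicates = simulate_epityper(
        bundle.truth, config.simulation, seed=config.seed, region_ids=candidates
    )
    clean = epityper_qc(triplicates)
    log.info("platform QC: %d units retained", len(clean))

    # region means on both platforms for concordance
    unit_region = pd.Series({u: u.split(":")[0] for u in clean.index})
    epi_region_means = clean.groupby(unit_region).mean()
    rrbs_means = {}
    for rid in candidates:
        # raw aggregated fraction in percent
        idx = next(ix for ix in bundle.region_indexes.values() if rid in ix.cpgs)
        counts = aggregate_region(bundle.samples, idx, rid)
        with np.errstate(invalid="ignore"):
            frac = 100.0 * counts.m_total / np.where(counts.t_total > 0,
                                                     counts.t_total, np.nan)
        rrbs_means[rid] = pd.Series(frac, index=counts.sample_ids)
    rrbs_df = pd.DataFrame(rrbs_means).T
    concordance = platform_concordance(rrbs_df, epi_region_means,
                                       threshold=config.concordance_r)
    keep = list(concordance.index[concordance["keep"]])
    log.info("concordance: %d/%d regions kept at r>%g (overall r=%.3f)",
             len(keep), len(concordance), config.concordance_r,
             concordance.attrs.get("overall_r", np.nan))

    lmp_days = _lmp_days(cohort)
    pre_pairs = [pid for pid in cohort.pair_ids
                 if cohort.pair(pid)[0].lmp_date is not None
                 and cohort.pair(pid)[0].lmp_date < config.simulation.window_end]
    post_pairs = [pid for pid in cohort.pair_ids if pid not in pre_pairs]

    fit_rows, strat_rows = [], []
    for rid in keep:
        units = [u for u in clean.index if u.split(":")[0] == rid]
        vals = clean.loc[units]
        fit = fit_region_lmm(vals, cohort, region_id=rid)
        fit_rows.append({"region_id": rid, "beta": fit.beta_exposure,
                         "se": fit.se, "p": fit.p_value,
                         "converged": fit.converged})
        for label, pair_set in (("pre_window", pre_pairs), ("post_window", post_pairs)):
            sub = _subset_cohort(cohort, pair_set)
            if sub is None or sub.n_pairs < 3:
                continue
            cols = [i.sample_id for i in sub.individuals]
            sfit = fit_region_lmm(vals[cols], sub, region_id=rid)
            strat_rows.append({"region_id": rid, "stratum": label,
                               "beta": sfit.beta_exposure, "p": sfit.p_value,
                               "n_pairs": sub.n_pairs})
    validated = pd.DataFrame(fit_rows, columns=["region_id", "beta", "se", "p",
                                                "converged"])
    stratified = pd.DataFrame(strat_rows, columns=["region_id", "stratum", "beta",
                                                   "p", "n_pairs"])

    interaction_p = None
    if keep and lmp_days.notna().any():
        # orient each region by its discovery effect sign so hyper- and
        # hypomethylated regions do not cancel in the pooled interaction term
        sign_of = dict(zip(bundle.region_fits["region_id"],
                           np.sign(bundle.region_fits["beta"]).replace(0, 1)))
        units = [u for u in clean.index if u.split(":")[0] in keep]
        oriented = clean.loc[units].copy()
        for u in units:
            oriented.loc[u] *= sign_of.get(u.split(":")[0], 1.0)
        interaction_p = test_interaction(oriented, cohort, lmp_days)

    closed = None
    pvec = validated["p"].dropna()
    if len(pvec):
        closed = closed_testing_simes(pvec.to_numpy(), alpha=0.05)
        log.info("replication bound: %d/%d (point estimate %d/%d)",
                 closed.lower_bound, closed.k, closed.pi1_point, closed.k)
    return ValidationBundle(
        epityper_clean=clean, concordance=concordance, validated_fits=validated,
        window_stratified=stratified, interaction_p=interaction_p,
        closed_testing=closed,
    )


def _lmp_days(cohort: iof.Cohort) -> pd.Series:
    """Conception date of the pair's exposed member, as days from the first
    observed LMP; defined for both members of a pair."""
    lmp = {}
    for pid in cohort.pair_ids:
        exposed, control = cohort.pair(pid)
        lmp[exposed.sample_id] = exposed.lmp_date
        lmp[control.sample_id] = exposed.lmp_date
    dates = [d for d in lmp.values() if d is not None]
    origin = min(dates) if dates else None
    return pd.Series({
        s: (float((d - origin).days) if d is not None else np.nan)
        for s, d in lmp.items()
    })


def _subset_cohort(cohort: iof.Cohort, pair_ids: list[str]) -> iof.Cohort | None:
    members = [i for i in cohort.individuals if i.pair_id in pair_ids]
    if not members:
        return None
    return iof.Cohort(individuals=members)


def _write_discovery(bundle: DiscoveryBundle, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.annotation_table.to_csv(out / "annotation_scan.tsv", sep="\t", index=False)
    bundle.region_fits.to_csv(out / "region_fits.tsv", sep="\t", index=False)
    bundle.pdmr_table.to_csv(out / "pdmr_table.tsv", sep="\t", index=False)
    meta = {
        "seed": config.seed,
        "n_pairs": bundle.cohort.n_pairs,
        "cpg_filter": dataclasses.asdict(bundle.filter_report),
        "selected_annotations": bundle.selected_annotations,
        "n_pdmr": len(bundle.pdmr_table),
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, default=str))
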