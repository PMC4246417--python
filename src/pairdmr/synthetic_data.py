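"""Synthetic paired-sibling bisulfite datasets with known ground truth.

The generator emulates the structure of a famine-exposure sibling cohort
profiled by reduced representation bisulfite sequencing: same-sex pairs
discordant for periconceptional exposure, a bimodal CpG methylation
landscape (population mean ~61.2%, between-individual s.d. of the mean
~1.7 points), overdispersed sequencing depth with median ~28x,
per-CpG data completeness ~99.8%, regions of median ~1.4 kb carrying ~6.7
CpGs, a minority of regions with planted exposure effects (median
within-pair difference ~4.6 percentage points, ~60:40 hyper:hypo), effects
that vanish for conceptions at or after a critical-window end date, an
attenuated noisy continuous re-measurement platform, and phenotypes linearly
linked to methylation at designated regions.

Latent methylation is modelled on the logit scale with additive individual,
pair and exposure terms; planted effects configured in percentage points are
converted to logit offsets at each region's baseline so probabilities stay
valid. Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io_formats import (
    AnnotationSet,
    Cohort,
    CpGRecord,
    Individual,
    MethylomeSample,
    Region,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_methylome",
    "simulate_epityper",
    "simulate_phenotypes",
]

FAMINE_LMP_START = date(1944, 11, 28)
FAMINE_LMP_END = date(1945, 5, 15)


@dataclass
class SimulationConfig:
    """Study-condition parameters of the generator (defaults emulate the
    famine sibling cohort; sizes are desk-scale)."""

    n_pairs: int = 24
    n_regions: int = 40
    n_annotations: int = 8
    n_affected_annotations: int = 2
    cpgs_per_region_mean: float = 6.7
    region_length_median_bp: float = 1400.0
    region_length_log_sd: float = 0.5
    depth_mean: float = 30.0
    depth_dispersion: float = 8.0  # negative-binomial size; smaller = more spread
    completeness: float = 0.998
    meth_low_mean: float = 0.08
    meth_high_mean: float = 0.90
    meth_high_weight: float = 0.6488  # solves 0.90 w + 0.08 (1 - w) = 0.612
    cpg_baseline_logit_sd: float = 0.3
    individual_logit_sd: float = 0.2  # gives ~1.7-point s.d. of per-individual means
    pair_logit_sd: float = 0.3
    cpg_noise_logit_sd: float = 0.15
    n_pdmr: int = 8
    effect_median_pp: float = 4.6
    effect_log_sd: float = 0.45
    hyper_fraction: float = 0.608
    window_end: date = date(1945, 4, 1)
    window_ramp_days: int = 0  # 0 = step window
    epityper_attenuation: float = 0.7
    epityper_noise_sd: float = 2.0  # percentage points per well
    epityper_fail_rate: float = 0.05
    epityper_units_per_region: int = 3
    birth_weight_slope: float = 3.9  # percentage points per kg
    ldl_slope: float = 2.4  # percentage points per mmol/l
    phenotype_noise_sd: float = 0.15  # on the phenotype scale (relative)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("completeness", "meth_low_mean", "meth_high_mean",
                     "meth_high_weight", "hyper_fraction", "epityper_fail_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_pdmr > self.n_regions:
            raise ValueError("n_pdmr cannot exceed n_regions")
        for name in ("depth_dispersion", "depth_mean", "region_length_median_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline must recover."""

    regions: AnnotationSet  # all regions
    annotation_sets: dict[str, AnnotationSet]
    affected_annotations: list[str]
    region_baseline: dict[str, float]  # fraction in [0, 1]
    effect_pp: dict[str, float]  # signed percentage points; 0 for null regions
    latent_region_meth: pd.DataFrame  # (region x individual), percent
    pdmr_regions: list[str]
    phenotype_links: dict[str, tuple[str, float]] = field(default_factory=dict)


def _window_multiplier(lmp: date | None, cfg: SimulationConfig) -> float:
    """Exposure-effect multiplier: 1 before the window end, 0 at/after it,
    with an optional linear ramp ending at window_end."""
    if lmp is None:
        return 0.0
    if lmp >= cfg.window_end:
        return 0.0
    if cfg.window_ramp_days > 0:
        ramp_start = cfg.window_end - timedelta(days=cfg.window_ramp_days)
        if lmp > ramp_start:
            return (cfg.window_end - lmp).days / cfg.window_ramp_days
    return 1.0


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> Cohort:
    """Same-sex sibling pairs, one member exposed around conception.

    Sexes split evenly across pairs; the exposed member's estimated LMP is
    uniform over the famine window; control siblings are conceived before or
    after the famine, split evenly within each sex.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    individuals = []
    window_days = (FAMINE_LMP_END - FAMINE_LMP_START).days
    for p in range(config.n_pairs):
        sex = "M" if p % 2 == 0 else "F"
        # alternate control conception timing within each sex
        control_after = (p // 2) % 2 == 1
        lmp = FAMINE_LMP_START + timedelta(days=int(rng.integers(0, window_days + 1)))
        age_exposed = float(np.clip(rng.normal(58.1, 0.35), 50, 70))
        age_gap = float(rng.uniform(0.8, 4.5)) * (-1 if control_after else 1)
        batch = "B1" if rng.random() < 0.5 else "B2"
        individuals.append(
            Individual(
                sample_id=f"P{p:03d}E",
                pair_id=f"pair{p:03d}",
                exposed=True,
                sex=sex,
                age=age_exposed,
                batch=batch,
                lmp_date=lmp,
            )
        )
        individuals.append(
            Individual(
                sample_id=f"P{p:03d}C",
                pair_id=f"pair{p:03d}",
                exposed=False,
                sex=sex,
                age=age_exposed + age_gap,
                batch=batch,
                lmp_date=None,
            )
        )
    return Cohort(individuals=individuals)


def _draw_regions(cfg: SimulationConfig, rng: np.random.Generator):
    """Region coordinates and CpG positions along a single synthetic
    chromosome, with regions assigned round-robin to annotation classes."""
    regions: list[Region] = []
    cpg_positions: dict[str, np.ndarray] = {}
    cursor = 10_000
    for r in range(cfg.n_regions):
        length = int(
            cfg.region_length_median_bp * np.exp(rng.normal(0, cfg.region_length_log_sd))
        )
        length = max(length, 200)
        k = max(1, int(rng.poisson(cfg.cpgs_per_region_mean)))
        start, end = cursor, cursor + length
        pos = np.sort(rng.choice(np.arange(start, end), size=min(k, length), replace=False))
        rid = f"reg{r:04d}"
        regions.append(Region("chrS", start, end, rid))
        cpg_positions[rid] = pos
        cursor = end + int(rng.integers(2_000, 10_000))
    return regions, cpg_positions


def simulate_methylome(
    config: SimulationConfig, cohort: Cohort, seed: int | None = None
) -> tuple[list[MethylomeSample], GroundTruth]:
    """Per-individual CpG count tables plus the generating ground truth."""
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    regions, cpg_positions = _draw_regions(config, rng)
    n_ind = len(cohort.individuals)
    sample_ids = [i.sample_id for i in cohort.individuals]
    pair_ids = cohort.pair_ids
    pair_idx = {pid: g for g, pid in enumerate(pair_ids)}

    # planted regions live only in the affected annotation classes
    ann_names = [f"ann{a:02d}" for a in range(config.n_annotations)]
    affected = ann_names[: config.n_affected_annotations]
    region_ids = [r.region_id for r in regions]
    pdmr_ids = list(rng.choice(region_ids, size=config.n_pdmr, replace=False))
    ann_assignment: dict[str, str] = {}
    null_cycle = 0
    for rid in region_ids:
        if rid in pdmr_ids:
            ann_assignment[rid] = affected[null_cycle % len(affected)]
        else:
            ann_assignment[rid] = ann_names[null_cycle % len(ann_names)]
        null_cycle += 1

    # baselines and effects
    region_baseline: dict[str, float] = {}
    effect_pp: dict[str, float] = {}
    for rid in region_ids:
        if rng.random() < config.meth_high_weight:
            base = rng.beta(
                config.meth_high_mean * 30, (1 - config.meth_high_mean) * 30
            )
        else:
            base = rng.beta(
                config.meth_low_mean * 30, (1 - config.meth_low_mean) * 30
            )
        p0 = float(np.clip(base, 0.02, 0.98))
        region_baseline[rid] = p0
        if rid in pdmr_ids:
            mag = config.effect_median_pp * np.exp(rng.normal(0, config.effect_log_sd))
            sign = 1.0 if rng.random() < config.hyper_fraction else -1.0
            # record the realized effect: near the probability boundaries the
            # requested shift is truncated to keep methylation in (0, 1)
            target = float(np.clip(p0 + sign * mag / 100.0, 0.005, 0.995))
            effect_pp[rid] = 100.0 * (target - p0)
        else:
            effect_pp[rid] = 0.0

    indiv_offset = rng.normal(0, config.individual_logit_sd, size=n_ind)
    exposure = cohort.exposure_vector(sample_ids)
    lmp_by_pair = {}
    for pid in pair_ids:
        exposed, _ = cohort.pair(pid)
        lmp_by_pair[pid] = exposed.lmp_date
    pair_of_sample = {i.sample_id: i.pair_id for i in cohort.individuals}

    records: list[list[CpGRecord]] = [[] for _ in range(n_ind)]
    latent_rows = {}
    for region in regions:
        rid = region.region_id
        pos = cpg_positions[rid]
        k = len(pos)
        base_logit = logit(region_baseline[rid])
        cpg_logits = base_logit + rng.normal(0, config.cpg_baseline_logit_sd, size=k)
        pair_effects = rng.normal(0, config.pair_logit_sd, size=len(pair_ids))
        # percentage-point effect converted to a logit offset at the baseline
        p0 = region_baseline[rid]
        delta_logit = logit(p0 + effect_pp[rid] / 100.0) - logit(p0)
        latent_region = np.zeros(n_ind)
        for i, sid in enumerate(sample_ids):
            pid = pair_of_sample[sid]
            mult = _window_multiplier(lmp_by_pair[pid], config) if exposure[i] else 0.0
            eta = (
                cpg_logits
                + indiv_offset[i]
                + pair_effects[pair_idx[pid]]
                + mult * delta_logit
                + rng.normal(0, config.cpg_noise_logit_sd, size=k)
            )
            p = expit(eta)
            latent_region[i] = 100.0 * p.mean()
            depth = rng.negative_binomial(
                config.depth_dispersion,
                config.depth_dispersion / (config.depth_dispersion + config.depth_mean),
                size=k,
            )
            depth = np.maximum(depth, 1)
            observed = rng.random(k) < config.completeness
            meth = rng.binomial(depth, p)
            for j in range(k):
                if observed[j]:
                    records[i].append(
                        CpGRecord("chrS", int(pos[j]), int(meth[j]), int(depth[j]))
                    )
        latent_rows[rid] = latent_region

    samples = [
        MethylomeSample(sample_id=sid, records=records[i])
        for i, sid in enumerate(sample_ids)
    ]
    ann_sets = {
        name: AnnotationSet(
            name=name,
            regions=[r for r in regions if ann_assignment[r.region_id] == name],
        )
        for name in ann_names
    }
    ann_sets = {name: s for name, s in ann_sets.items() if s.regions}
    latent = pd.DataFrame.from_dict(latent_rows, orient="index", columns=sample_ids)
    # phenotype links: first planted hyper region -> birth weight, next -> LDL
    links: dict[str, tuple[str, float]] = {}
    if pdmr_ids:
        links["birth_weight"] = (pdmr_ids[0], config.birth_weight_slope)
        links["ldl"] = (pdmr_ids[min(1, len(pdmr_ids) - 1)], config.ldl_slope)
    truth = GroundTruth(
        regions=AnnotationSet(name="all", regions=regions),
        annotation_sets=ann_sets,
        affected_annotations=affected,
        region_baseline=region_baseline,
        effect_pp=effect_pp,
        latent_region_meth=latent,
        pdmr_regions=sorted(pdmr_ids),
        phenotype_links=links,
    )
    return samples, truth


def simulate_epityper(
    truth: GroundTruth,
    config: SimulationConfig,
    seed: int | None = None,
    region_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Triplicate continuous re-measurements of region methylation.

    Each region yields a few CpG units; every well reports
    attenuation * latent methylation (percent) + Gaussian noise, and fails
    (NaN) with the configured probability. Long format: unit_id, sample_id,
    replicate, value.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2)
    region_ids = region_ids if region_ids is not None else list(truth.latent_region_meth.index)
    rows = []
    for rid in region_ids:
        latent = truth.latent_region_meth.loc[rid]
        for u in range(config.epityper_units_per_region):
            unit_id = f"{rid}:u{u}"
            unit_shift = rng.normal(0, 1.0)
            for sid, val in latent.items():
                for rep in range(3):
                    if rng.random() < config.epityper_fail_rate:
                        value = np.nan
                    else:
                        value = (
                            config.epityper_attenuation * val
                            + unit_shift
                            + rng.normal(0, config.epityper_noise_sd)
                        )
                    rows.append((unit_id, sid, rep, value))
    return pd.DataFrame(rows, columns=["unit_id", "sample_id", "replicate", "value"])


def simulate_phenotypes(
    truth: GroundTruth,
    cohort: Cohort,
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Phenotype table linked to methylation at designated regions.

    Birth weight is generated for exposed individuals only (records exist
    only for the hospital-born exposed series); LDL and total cholesterol
    for everyone; BMI and glucose are pure noise. A linked phenotype is
    drawn so that regressing methylation (percent) on it recovers the
    configured slope (percentage points per phenotype unit) at low noise.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 3)
    sample_ids = [i.sample_id for i in cohort.individuals]
    exposed = cohort.exposure_vector(sample_ids).astype(bool)
    n = len(sample_ids)
    out = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))

    def linked(pheno: str, center: float, scale_noise: float) -> np.ndarray:
        rid, slope = truth.phenotype_links[pheno]
        meth = truth.latent_region_meth.loc[rid, sample_ids].to_numpy(dtype=float)
        dev = meth - meth.mean()
        return center + dev / slope + rng.normal(0, scale_noise, size=n)

    bw = linked("birth_weight", 3.4, config.phenotype_noise_sd)
    bw[~exposed] = np.nan
    out["birth_weight"] = bw
    ldl = linked("ldl", 3.6, config.phenotype_noise_sd)
    out["ldl"] = ldl
    out["total_cholesterol"] = ldl + 1.9 + rng.normal(0, 0.3, size=n)
    out["bmi"] = rng.normal(27.0, 3.5, size=n)
    out["glucose"] = rng.normal(5.5, 0.8, size=n)
    return out
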