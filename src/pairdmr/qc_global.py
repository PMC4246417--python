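"""Cohort-level methylation QC.

Checks that exposure is not confounded with global methylation: compares
read-weighted overall methylation between exposed and control siblings, and
scans repeat-class methylation (a common proxy for global methylation) for
exposure differences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inference import bh_fdr
from .io_formats import Cohort, MethylomeSample
from .mixed_models import paired_t

__all__ = ["overall_methylation_compare", "repeat_class_scan"]


def overall_methylation_compare(
    samples: list[MethylomeSample], cohort: Cohort
) -> dict:
    """Read-weighted mean methylation per individual, compared within pairs.

    The per-individual mean is total methylated reads / total reads (the
    read-weighted average over CpGs). Returns group means (percent) and the
    paired-t p-value across pairs.
    """
    means = {}
    for s in samples:
        m = sum(r.methylated_reads for r in s.records)
        t = sum(r.total_reads for r in s.records)
        means[s.sample_id] = 100.0 * m / t if t else np.nan
    diffs, exp_vals, ctl_vals = [], [], []
    for pid in cohort.pair_ids:
        exposed, control = cohort.pair(pid)
        e, c = means.get(exposed.sample_id), means.get(control.sample_id)
        if e is None or c is None or np.isnan(e) or np.isnan(c):
            continue
        diffs.append(e - c)
        exp_vals.append(e)
        ctl_vals.append(c)
    res = paired_t(diffs)
    return {
        "mean_exposed": float(np.mean(exp_vals)),
        "mean_control": float(np.mean(ctl_vals)),
        "p": float(res.p) if not res.zero_variance else 1.0,
        "zero_variance": res.zero_variance,
        "per_individual": means,
    }


def repeat_class_scan(
    repeat_counts: pd.DataFrame, cohort: Cohort, min_median_cov: float = 5
) -> pd.DataFrame:
    """Per-repeat-class paired comparison of summed methylation fractions.

    ``repeat_counts`` is long format with columns (repeat_name, sample_id,
    methylated, total): reads summed over the class's consensus CpGs. A
    class enters only when its median total coverage across individuals is
    strictly greater than ``min_median_cov``. BH adjustment runs across the
    included classes.
    """
    required = {"repeat_name", "sample_id", "methylated", "total"}
    if not required.issubset(repeat_counts.columns):
        raise ValueError(f"repeat table needs columns {sorted(required)}")
    rows = []
    for name, grp in repeat_counts.groupby("repeat_name", sort=True):
        totals = grp.set_index("sample_id")["total"]
        meths = grp.set_index("sample_id")["methylated"]
        if float(np.median(totals)) <= min_median_cov:
            continue
        frac = 100.0 * meths / totals
        diffs = []
        for pid in cohort.pair_ids:
            exposed, control = cohort.pair(pid)
            if exposed.sample_id in frac and control.sample_id in frac:
                diffs.append(frac[exposed.sample_id] - frac[control.sample_id])
        if len(diffs) < 2:
            continue
        res = paired_t(diffs)
        p = res.p if not res.zero_variance else 1.0
        rows.append((name, float(np.mean(diffs)), p, len(diffs)))
    if not rows:
        raise ValueError("no repeat classes pass the median-coverage filter")
    out = pd.DataFrame(rows, columns=["repeat_name", "mean_diff", "p", "n_pairs"])
    out["q_bh"] = bh_fdr(out["p"].to_numpy())
    return out
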