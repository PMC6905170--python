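"""Differential methylation between normal and age-related tumor samples.

Per site: group means, fold change FC = mean_tumor / mean_normal (with a tiny
pseudocount guarding empty denominators), Welch's unequal-variance t-test,
Benjamini-Hochberg FDR across the tested site set.  A site is significant
when q < 0.01 and FC > 2 or FC < 0.5 (equivalently |log2 FC| > 1); FC > 1 is
called hyper-methylated, FC < 1 hypo-methylated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import BetaMatrix, PipelineError

__all__ = ["welch_t", "bh_fdr", "call_differential_sites"]


def welch_t(group_a, group_b) -> tuple[float, float]:
    """Welch's two-sample t-test (unequal variances, two-sided).

    Returns (t, p) for *group_a* versus *group_b*; t > 0 means group A has
    the larger mean.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise PipelineError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise PipelineError("non-finite values in t-test input")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, q >= p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise PipelineError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential_sites(
    matrix: BetaMatrix,
    normal_ids,
    tumor_ids,
    fdr_threshold: float = 0.01,
    fc_bounds: tuple[float, float] = (2.0, 0.5),
    eps: float = 1e-8,
) -> pd.DataFrame:
    """Test every site in *matrix* between a normal and a tumor sample set.

    Returns a table indexed by site id with columns ``mean_normal``,
    ``mean_tumor``, ``fc``, ``log2_fc``, ``t_stat`` (tumor vs normal),
    ``p_value``, ``q_value``, ``significant`` and ``direction``, sorted by
    q then descending |log2 FC|.
    """
    normal_ids = list(normal_ids)
    tumor_ids = list(tumor_ids)
    if not normal_ids or not tumor_ids:
        raise PipelineError("both sample sets must be nonempty")
    overlap = set(normal_ids) & set(tumor_ids)
    if overlap:
        raise PipelineError(f"sample sets overlap: {sorted(overlap)[:5]}")
    if len(normal_ids) < 2 or len(tumor_ids) < 2:
        raise PipelineError("each group needs at least 2 samples")

    a = matrix.restrict_samples(normal_ids).values.to_numpy(dtype=float)
    b = matrix.restrict_samples(tumor_ids).values.to_numpy(dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise PipelineError("matrix contains missing values; impute first")

    mean_normal = a.mean(axis=1)
    mean_tumor = b.mean(axis=1)
    # t > 0 <=> tumor mean higher, matching FC > 1
    res = stats.ttest_ind(b, a, axis=1, equal_var=False)
    t_stat = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # zero-variance-in-both sites give nan; treat as no evidence
    nanmask = np.isnan(p)
    t_stat[nanmask] = 0.0
    p[nanmask] = 1.0

    fc = (mean_tumor + eps) / (mean_normal + eps)
    log2_fc = np.log2(fc)
    q = bh_fdr(p)
    hi, lo = fc_bounds
    significant = (q < fdr_threshold) & ((fc > hi) | (fc < lo))
    direction = np.where(fc > 1.0, "hyper", "hypo")

    out = pd.DataFrame(
        {
            "mean_normal": mean_normal,
            "mean_tumor": mean_tumor,
            "fc": fc,
            "log2_fc": log2_fc,
            "t_stat": t_stat,
            "p_value": p,
            "q_value": q,
            "significant": significant,
            "direction": direction,
        },
        index=pd.Index(matrix.site_ids, name="site_id"),
    )
    out["_abs_lfc"] = -np.abs(out["log2_fc"])
    out = out.sort_values(["q_value", "_abs_lfc"], kind="stable").drop(
        columns="_abs_lfc"
    )
    return out
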