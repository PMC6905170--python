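"""Screening of age-associated methylation sites on normal samples.

Each site's beta values are correlated with chronological age by Spearman
rank correlation (mid-ranks for ties).  A site is selected when its two-sided
p-value is below ``p_threshold`` and |SCC| exceeds ``scc_threshold``
(defaults 0.05 and 0.3).  p-values use the t-distribution approximation
``t = scc * sqrt((n - 2) / (1 - scc^2))`` on n - 2 degrees of freedom, which
is accurate at the sample sizes of interest; an exact permutation option
exists for very small n.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BetaMatrix, PipelineError, get_logger
from .diffmeth import bh_fdr

__all__ = [
    "ScreenedSites",
    "SignSummary",
    "spearman_screen",
    "summarize_sign",
    "per_group_correlation",
]

log = get_logger(__name__)


@dataclass
class ScreenedSites:
    """Per-site screening results.

    ``table`` is indexed by site id with columns ``scc``, ``p_value``,
    ``selected``, ``sign`` ('+'/'-'/'' for constant sites) and ``constant``.
    """

    table: pd.DataFrame
    scc_threshold: float
    p_threshold: float

    @property
    def selected_ids(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


@dataclass
class SignSummary:
    n_selected: int
    n_positive: int
    n_negative: int
    frac_positive: float | None  # None when nothing selected


def _rank_correlation(values: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Vectorized Spearman correlation of each row of *values* with *ages*.

    Rows with zero rank variance (constant sites) yield NaN.
    """
    ranks = stats.rankdata(values, axis=1)
    age_ranks = stats.rankdata(ages)
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    ac = age_ranks - age_ranks.mean()
    denom_sites = (rc**2).sum(axis=1)
    denom_age = float((ac**2).sum())
    if denom_age == 0.0:
        raise PipelineError("ages are constant; correlation undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        scc = (rc @ ac) / np.sqrt(denom_sites * denom_age)
    scc[denom_sites == 0.0] = np.nan
    return np.clip(scc, -1.0, 1.0, out=scc)


def _t_approx_p(scc: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        t = scc * np.sqrt((n - 2) / (1.0 - scc**2))
    p = np.where(
        np.abs(scc) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    )
    p[np.isnan(scc)] = np.nan
    return p


def _exact_perm_p(x: np.ndarray, ages: np.ndarray) -> float:
    obs = abs(_rank_correlation(x[None, :], ages)[0])
    count = 0
    total = 0
    for perm in permutations(range(len(ages))):
        r = _rank_correlation(x[None, :], ages[list(perm)])[0]
        count += abs(r) >= obs - 1e-12
        total += 1
    return count / total


def spearman_screen(
    matrix: BetaMatrix,
    ages: np.ndarray | pd.Series,
    scc_threshold: float = 0.3,
    p_threshold: float = 0.05,
    use_fdr: bool = False,
    method: str = "t",
) -> ScreenedSites:
    """Screen every site for monotone association with age.

    *ages* must align with the matrix samples (a Series indexed by sample id
    or an array in column order).  ``use_fdr`` applies Benjamini-Hochberg to
    the p-values before thresholding.  ``method='exact'`` (n <= 8 only)
    replaces the t approximation by full permutation enumeration.
    """
    if isinstance(ages, pd.Series):
        ages = ages.reindex(matrix.sample_ids).to_numpy(dtype=float)
    else:
        ages = np.asarray(ages, dtype=float)
    if ages.shape[0] != matrix.n:
        raise PipelineError("ages do not align with matrix samples")
    if not np.isfinite(ages).all():
        raise PipelineError("ages must be finite")
    if matrix.n < 4:
        raise PipelineError("need at least 4 samples to screen")
    vals = matrix.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise PipelineError("matrix contains missing values; impute first")

    scc = _rank_correlation(vals, ages)
    if method == "t":
        p = _t_approx_p(scc, matrix.n)
    elif method == "exact":
        if matrix.n > 8:
            raise PipelineError("exact permutation p only supported for n <= 8")
        p = np.array([_exact_perm_p(row, ages) for row in vals])
        p[np.isnan(scc)] = np.nan
    else:
        raise PipelineError(f"unknown method {method!r}")

    constant = np.isnan(scc)
    p_sel = p.copy()
    if use_fdr:
        ok = ~np.isnan(p)
        p_sel[ok] = bh_fdr(p[ok])
    with np.errstate(invalid="ignore"):
        selected = (~constant) & (p_sel < p_threshold) & (np.abs(scc) > scc_threshold)
    sign = np.where(constant, "", np.where(scc > 0, "+", "-"))

    table = pd.DataFrame(
        {
            "scc": scc,
            "p_value": p,
            "selected": selected,
            "sign": sign,
            "constant": constant,
        },
        index=pd.Index(matrix.site_ids, name="site_id"),
    )
    n_const = int(constant.sum())
    if n_const:
        log.info("screen: %d constant sites reported unselected", n_const)
    log.info(
        "screen: %d of %d sites selected (p<%g, |scc|>%g)",
        int(selected.sum()), matrix.m, p_threshold, scc_threshold,
    )
    return ScreenedSites(table, scc_threshold, p_threshold)


def summarize_sign(screened: ScreenedSites) -> SignSummary:
    """Count selected sites by correlation sign."""
    sel = screened.table[screened.table["selected"]]
    n_pos = int((sel["sign"] == "+").sum())
    n_neg = int((sel["sign"] == "-").sum())
    n_sel = len(sel)
    assert n_pos + n_neg == n_sel
    frac = n_pos / n_sel if n_sel else None
    return SignSummary(n_sel, n_pos, n_neg, frac)


def per_group_correlation(
    matrix: BetaMatrix,
    ages: np.ndarray | pd.Series,
    group_labels: np.ndarray | pd.Series,
    min_group_size: int = 4,
) -> pd.DataFrame:
    """Spearman correlation with age within each tissue/cohort group.

    Returns a table indexed by site with one column per group, a ``pooled``
    column, and ``diff_<group>`` columns holding pooled minus per-group SCC.
    Groups smaller than *min_group_size* are skipped with a log note.
    """
    if isinstance(ages, pd.Series):
        ages = ages.reindex(matrix.sample_ids).to_numpy(dtype=float)
    else:
        ages = np.asarray(ages, dtype=float)
    if isinstance(group_labels, pd.Series):
        group_labels = group_labels.reindex(matrix.sample_ids).to_numpy()
    else:
        group_labels = np.asarray(group_labels)
    vals = matrix.values.to_numpy(dtype=float)

    out = pd.DataFrame(index=pd.Index(matrix.site_ids, name="site_id"))
    out["pooled"] = _rank_correlation(vals, ages)
    for group in pd.unique(group_labels):
        mask = group_labels == group
        if mask.sum() < min_group_size:
            log.info(
                "per-group correlation: skipping group %r (%d samples < %d)",
                group, int(mask.sum()), min_group_size,
            )
            continue
        out[str(group)] = _rank_correlation(vals[:, mask], ages[mask])
        out[f"diff_{group}"] = out["pooled"] - out[str(group)]
    return out
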