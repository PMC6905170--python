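"""Missingness filtering, k-nearest-neighbor imputation, WHO age segmentation.

Sites whose missing fraction across samples exceeds the threshold (strictly
greater than 10% by default) are dropped; remaining missing cells are filled
by averaging the k most similar sample columns, similarity being Euclidean
distance over co-observed sites.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics.pairwise import nan_euclidean_distances

from .core_io import BetaMatrix, PipelineError, get_logger

__all__ = [
    "filter_sites_by_missingness",
    "knn_impute",
    "assign_age_segment",
]

log = get_logger(__name__)

# WHO-style age bins; boundary ages 45, 60 and 75 open the next bin upward,
# so the four bins partition [0, inf).
_SEGMENT_EDGES = [(45.0, "young"), (60.0, "middle"), (75.0, "older_young")]


def assign_age_segment(age_years: float) -> str:
    """Map an age in years to its segment label.

    young: age <= 44; middle: 45-59; older_young: 60-74; old: >= 75.
    """
    if age_years is None or not np.isfinite(age_years) or age_years < 0:
        raise PipelineError(f"invalid age {age_years!r}")
    for edge, label in _SEGMENT_EDGES:
        if age_years < edge:
            return label
    return "old"


def filter_sites_by_missingness(
    matrix: BetaMatrix, max_na_fraction: float = 0.10
) -> BetaMatrix:
    """Drop sites whose missing fraction is strictly above *max_na_fraction*.

    A site missing in exactly 10 of 100 samples is retained at the default
    threshold; removal requires strictly more.
    """
    if matrix.m == 0 or matrix.n == 0:
        raise PipelineError("empty matrix")
    frac = matrix.values.isna().mean(axis=1)
    keep = frac <= max_na_fraction
    if not keep.any():
        raise PipelineError(
            "all sites exceed the missingness threshold; "
            "review max_na_fraction or the input matrix"
        )
    removed = int((~keep).sum())
    log.info(
        "missingness filter: %d sites in, %d removed (>%g%% NA), %d retained",
        matrix.m, removed, 100 * max_na_fraction, int(keep.sum()),
    )
    return BetaMatrix(matrix.values.loc[keep])


def knn_impute(matrix: BetaMatrix, k: int = 10, weighted: bool = False) -> BetaMatrix:
    """Fill missing cells from the k nearest sample columns.

    Distance between two samples is Euclidean over the sites observed in both,
    scaled up by the fraction of co-observed sites so sparsity does not make
    columns look artificially close.  A missing cell (site i, sample j) is the
    unweighted mean (optionally inverse-distance weighted) of the k nearest
    samples that observe site i; with fewer than k usable neighbors all
    available ones are used, and with none the site median across samples.
    Observed cells are never altered; imputed values are clipped to [0, 1].
    """
    if k < 1:
        raise PipelineError("k must be >= 1")
    vals = matrix.values.to_numpy(dtype=float).copy()
    m, n = vals.shape
    col_all_missing = np.isnan(vals).all(axis=0)
    if col_all_missing.any():
        j = int(np.argmax(col_all_missing))
        raise PipelineError(
            f"sample {matrix.sample_ids[j]!r} has no observed values"
        )
    if not np.isnan(vals).any():
        return matrix.copy()

    # pairwise sample distances over co-observed sites (scaled by coverage)
    dist = nan_euclidean_distances(vals.T)
    np.fill_diagonal(dist, np.inf)
    site_medians = np.nanmedian(vals, axis=1)

    out = vals.copy()
    for j in range(n):
        miss_sites = np.nonzero(np.isnan(vals[:, j]))[0]
        if miss_sites.size == 0:
            continue
        dj = dist[j]
        order = np.argsort(dj, kind="stable")
        order = order[np.isfinite(dj[order])]
        for i in miss_sites:
            donors = order[~np.isnan(vals[i, order])]
            if donors.size == 0:
                out[i, j] = site_medians[i]
                continue
            chosen = donors[:k]
            if weighted:
                w = 1.0 / np.maximum(dj[chosen], 1e-12)
                out[i, j] = float(np.average(vals[i, chosen], weights=w))
            else:
                out[i, j] = float(vals[i, chosen].mean())
    out = np.clip(out, 0.0, 1.0)
    n_filled = int(np.isnan(vals).sum())
    log.info("knn imputation: filled %d cells (k=%d)", n_filled, k)
    df = matrix.values.copy()
    df.iloc[:, :] = out
    return BetaMatrix(df)
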