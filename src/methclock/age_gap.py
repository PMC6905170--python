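"""Per-cohort m-age vs chronological-age gaps and age-related sample calls.

The gap of a sample is predicted m-age minus chronological age.  A cohort's
age difference score is the 75th percentile of |gap|; each sample's gap is
classified up / down / unchanged against a symmetric band (by default the
normal-cohort quartile error of the clock), and the 25% of samples with the
largest |gap| in each cohort are flagged "age-related".
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core_io import PipelineError, get_logger

__all__ = [
    "compute_gaps",
    "age_difference_score",
    "classify_direction",
    "direction_summary",
    "select_age_related_samples",
]

log = get_logger(__name__)


def _aligned(gaps, cohorts) -> tuple[pd.Series, pd.Series]:
    gaps = pd.Series(gaps, dtype=float)
    cohorts = pd.Series(cohorts)
    if not gaps.index.equals(cohorts.index):
        cohorts = cohorts.reindex(gaps.index)
        if cohorts.isna().any():
            raise PipelineError("cohort labels do not cover all samples")
    return gaps, cohorts


def compute_gaps(predicted: pd.Series, ages: pd.Series) -> pd.Series:
    """gap = m-age - chronological age, per sample (years)."""
    ages = ages.reindex(predicted.index)
    if ages.isna().any():
        raise PipelineError("ages missing for some predicted samples")
    out = predicted - ages
    out.name = "gap"
    return out


def age_difference_score(gaps, cohorts, min_cohort_size: int = 4) -> pd.Series:
    """75th percentile (linear interpolation) of |gap| per cohort.

    Cohorts smaller than *min_cohort_size* are skipped with a log note.
    """
    gaps, cohorts = _aligned(gaps, cohorts)
    scores = {}
    for name, grp in gaps.groupby(cohorts):
        if len(grp) < min_cohort_size:
            log.info("age difference score: skipping %r (%d samples)", name, len(grp))
            continue
        scores[name] = float(np.percentile(np.abs(grp.to_numpy()), 75))
    return pd.Series(scores, name="difference_score", dtype=float)


def classify_direction(gaps, threshold_years: float) -> pd.Series:
    """up if gap > threshold, down if gap < -threshold, else unchanged."""
    if threshold_years < 0:
        raise PipelineError("threshold must be >= 0")
    gaps = pd.Series(gaps, dtype=float)
    out = pd.Series(
        np.where(
            gaps > threshold_years,
            "up",
            np.where(gaps < -threshold_years, "down", "unchanged"),
        ),
        index=gaps.index,
        name="direction",
    )
    return out


def direction_summary(directions: pd.Series, cohorts) -> pd.DataFrame:
    """Fractions of up / down / unchanged per cohort (rows sum to 1)."""
    directions, cohorts = _aligned(directions.astype(object), cohorts)
    tab = (
        pd.crosstab(cohorts, directions, normalize="index")
        .reindex(columns=["up", "down", "unchanged"], fill_value=0.0)
    )
    tab.index.name = "cohort"
    return tab


def select_age_related_samples(
    gaps, cohorts, top_fraction: float = 0.25
) -> dict[str, list[str]]:
    """Per cohort, the ceil(top_fraction * n) samples with largest |gap|.

    Ties at the cut break by sample-id lexical order, so selection is
    deterministic and nested as the fraction grows.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise PipelineError("top_fraction must lie in (0, 1]")
    gaps, cohorts = _aligned(gaps, cohorts)
    out: dict[str, list[str]] = {}
    for name, grp in gaps.groupby(cohorts):
        k = math.ceil(top_fraction * len(grp))
        order = sorted(grp.index, key=lambda s: (-abs(grp[s]), s))
        out[name] = order[:k]
    return out
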