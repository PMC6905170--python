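"""Survival association of differential methylation sites.

Per cohort: each candidate site is dichotomized at its median methylation
level and screened in a multivariate Cox model (site indicator + stage,
gender, age); sites with Wald p < 0.05 for the methylation term enter one
joint Cox model whose methylation coefficients weight the per-sample risk
score.  Patients split at the median risk score form high/low groups that
are compared by Kaplan-Meier curves and a two-group log-rank test.

Cox models maximize the partial likelihood with Efron tie handling (via
lifelines); Kaplan-Meier is the product-limit estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import ConvergenceWarning

from .core_io import BetaMatrix, PipelineConfig, PipelineError, get_logger

__all__ = [
    "CoxFit",
    "SurvivalResult",
    "dichotomize_by_median",
    "cox_fit",
    "select_survival_sites",
    "compute_risk_scores",
    "km_estimate",
    "logrank_2group",
    "survival_pipeline",
]

log = get_logger(__name__)


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model (Efron ties)."""

    terms: list[str]
    coef: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    loglik: float
    converged: bool
    n: int
    n_events: int


@dataclass
class SurvivalResult:
    """Per-cohort survival stratification by methylation risk score."""

    cohort: str
    retained_sites: list[str]
    joint_fit: CoxFit | None
    risk_scores: pd.Series
    risk_group: pd.Series
    km_curves: dict[str, pd.DataFrame]
    logrank_chi2: float
    logrank_p: float
    significant: bool


def dichotomize_by_median(values) -> np.ndarray:
    """Label 'high' where value > median, else 'low' (ties go low)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise PipelineError("need at least 2 values to dichotomize")
    med = float(np.median(v))
    return np.where(v > med, "high", "low")


def cox_fit(
    df: pd.DataFrame, duration_col: str = "time", event_col: str = "event"
) -> CoxFit:
    """Fit a Cox model on *df* (covariates = all other columns).

    Monotone likelihood / separation yields ``converged=False`` with the
    last iterate's estimates rather than an exception.
    """
    if df[event_col].sum() == 0:
        raise PipelineError("no events observed; Cox model undefined")
    covs = [c for c in df.columns if c not in (duration_col, event_col)]
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col=duration_col, event_col=event_col)
        except ConvergenceError as exc:
            log.warning("cox fit did not converge: %s", exc)
            nan = pd.Series(np.nan, index=covs)
            return CoxFit(covs, nan, nan, nan, nan, float("nan"), False,
                          len(df), int(df[event_col].sum()))
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        converged = False
    summ = cph.summary
    return CoxFit(
        terms=list(summ.index),
        coef=summ["coef"].copy(),
        se=summ["se(coef)"].copy(),
        z=summ["z"].copy(),
        p=summ["p"].copy(),
        loglik=float(cph.log_likelihood_),
        converged=converged,
        n=len(df),
        n_events=int(df[event_col].sum()),
    )


def _clinical_covariates(clin: pd.DataFrame) -> pd.DataFrame:
    """age (years), male indicator, ordinal stage; columns of *clin* rows."""
    out = pd.DataFrame(index=clin.index)
    out["age"] = clin["age_years"].astype(float)
    out["male"] = (clin["gender"] == "male").astype(float)
    out["stage"] = pd.to_numeric(clin["stage"], errors="coerce")
    return out


def _design(
    matrix: BetaMatrix,
    clin: pd.DataFrame,
    sites: list[str],
    continuous: bool,
) -> pd.DataFrame:
    """time/event + per-site methylation terms + clinical covariates."""
    samples = list(clin.index)
    df = pd.DataFrame(index=clin.index)
    df["time"] = clin["survival_days"].astype(float)
    df["event"] = clin["event"].astype(float)
    sub = matrix.restrict_sites(sites).restrict_samples(samples).values
    for s in sites:
        vals = sub.loc[s].to_numpy(dtype=float)
        if continuous:
            df[s] = vals
        else:
            df[s] = (dichotomize_by_median(vals) == "high").astype(float)
    df = pd.concat([df, _clinical_covariates(clin)], axis=1)
    df = df.dropna()
    # constant covariates carry no information and break the fit
    for c in list(df.columns):
        if c in ("time", "event"):
            continue
        if df[c].nunique() <= 1:
            df = df.drop(columns=c)
    return df


def select_survival_sites(
    matrix: BetaMatrix,
    clin: pd.DataFrame,
    candidate_sites,
    p_threshold: float = 0.05,
    continuous: bool = False,
) -> tuple[list[str], pd.DataFrame]:
    """Screen candidate sites one at a time in a multivariate Cox model.

    *clin* is indexed by sample id with ``age_years``, ``gender``,
    ``stage``, ``survival_days`` and ``event`` columns.  A site is retained
    when its methylation term has Wald p < *p_threshold*.  Sites whose fit
    fails are dropped with a log note.
    """
    candidate_sites = list(candidate_sites)
    if not candidate_sites:
        raise PipelineError("no candidate sites for survival screening")
    retained, rows = [], []
    for site in candidate_sites:
        try:
            df = _design(matrix, clin, [site], continuous)
            if site not in df.columns or len(df) < 3:
                raise PipelineError("degenerate design")
            fit = cox_fit(df)
        except Exception as exc:  # noqa: BLE001 - a failed site fit is not fatal
            log.info("survival screen: site %s dropped (%s)", site, exc)
            continue
        coef = float(fit.coef.get(site, np.nan))
        p = float(fit.p.get(site, np.nan))
        keep = bool(fit.converged and np.isfinite(p) and p < p_threshold)
        rows.append({"site_id": site, "coef": coef, "p": p, "retained": keep})
        if keep:
            retained.append(site)
    table = pd.DataFrame(rows, columns=["site_id", "coef", "p", "retained"])
    return retained, table


def compute_risk_scores(
    fit: CoxFit, design: pd.DataFrame, meth_terms
) -> pd.Series:
    """Coefficient-weighted sum of the methylation terms only.

    score_j = sum over retained methylation terms of coef_s * value_sj;
    clinical terms do not enter the score.
    """
    meth_terms = [t for t in meth_terms if t in fit.terms]
    if not meth_terms:
        warnings.warn("no retained methylation terms; empty risk score")
        return pd.Series(dtype=float, name="risk_score")
    coef = fit.coef[meth_terms].to_numpy(dtype=float)
    score = design[meth_terms].to_numpy(dtype=float) @ coef
    return pd.Series(score, index=design.index, name="risk_score")


def km_estimate(time, event, group_labels) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group: S(t) = prod (1 - d_k/n_k)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    groups = np.asarray(group_labels)
    out = {}
    for g in pd.unique(groups):
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask])
        sf = kmf.survival_function_
        out[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        ).reset_index(drop=True)
    return out


def logrank_2group(time, event, group_labels) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) on 1 df."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    groups = np.asarray(group_labels)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise PipelineError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    a = groups == labels[0]
    b = ~a
    if a.sum() == 0 or b.sum() == 0:
        raise PipelineError("one group is empty")
    if event.sum() == 0:
        raise PipelineError("no events observed")
    res = _ll_logrank(time[a], time[b], event_observed_A=event[a],
                      event_observed_B=event[b])
    return float(res.test_statistic), float(res.p_value)


def survival_pipeline(
    matrix: BetaMatrix,
    annotations,
    diff_sites_by_cohort: dict[str, list[str]],
    config: PipelineConfig | None = None,
    continuous: bool = False,
) -> dict[str, SurvivalResult]:
    """Run the survival stack for every cohort with differential sites.

    Cohorts with fewer than ``min_cohort`` subjects carrying survival data
    or fewer than ``min_events`` events are skipped with a log note, as are
    cohorts where no site survives the per-site screen.
    """
    config = config or PipelineConfig()
    from .core_io import annotations_to_frame

    clin_all = annotations_to_frame(annotations).set_index("sample_id")
    in_matrix = set(matrix.sample_ids)
    results: dict[str, SurvivalResult] = {}
    for cohort, candidates in diff_sites_by_cohort.items():
        clin = clin_all[
            (clin_all["cohort"] == cohort)
            & clin_all["survival_days"].notna()
            & clin_all["event"].notna()
            & clin_all.index.isin(in_matrix)
        ]
        n_events = int(clin["event"].sum()) if len(clin) else 0
        if len(clin) < config.min_cohort or n_events < config.min_events:
            log.info(
                "survival: skipping cohort %s (%d subjects, %d events)",
                cohort, len(clin), n_events,
            )
            continue
        if not candidates:
            log.info("survival: cohort %s has no candidate sites", cohort)
            continue
        retained, _tab = select_survival_sites(
            matrix, clin, candidates, p_threshold=config.survival_p,
            continuous=continuous,
        )
        if not retained:
            log.info("survival: cohort %s retained no sites", cohort)
            continue
        design = _design(matrix, clin, retained, continuous)
        joint = cox_fit(design)
        if not joint.converged:
            log.info("survival: cohort %s joint fit did not converge", cohort)
            continue
        scores = compute_risk_scores(joint, design, retained)
        group = pd.Series(
            dichotomize_by_median(scores.to_numpy()), index=scores.index,
            name="risk_group",
        )
        if group.nunique() < 2:
            log.info("survival: cohort %s risk scores degenerate", cohort)
            continue
        t = design["time"].to_numpy()
        e = design["event"].to_numpy()
        curves = km_estimate(t, e, group.to_numpy())
        chi2, p = logrank_2group(t, e, group.to_numpy())
        results[cohort] = SurvivalResult(
            cohort=cohort,
            retained_sites=retained,
            joint_fit=joint,
            risk_scores=scores,
            risk_group=group,
            km_curves=curves,
            logrank_chi2=chi2,
            logrank_p=p,
            significant=bool(p < config.logrank_p),
        )
    return results
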