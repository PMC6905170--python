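"""Synthetic 450K-style cohorts with the structure the analysis assumes.

The generator emulates, at desk scale, a pan-cancer methylation study: a
normal reference cohort whose "clock" CpG sites drift monotonically with
age, tumor cohorts whose clock sites behave as if generated at a shifted
effective age, tumor-specific mean-shifted differential sites, and survival
times whose hazard depends on designated methylation sites.

Generative model
----------------
For a clock site *i* and sample *j* the mean beta value is

    mu_ij = sigmoid(b_i + s_i * (a_eff_j - 50) / 10)

with baseline ``b_i`` on the logit scale and slope ``s_i`` per decade of
age.  ``a_eff`` equals chronological age for normal samples; for a tumor
cohort *c* it is ``age + Delta_j`` with ``Delta_j ~ Normal(delta_c, tau^2)``
— tumors look epigenetically older or younger than they are.  Non-clock
sites are constant on the logit scale; each tumor cohort additionally
shifts a designated set of differential sites by ``diff_shift`` logits.
Observed values are ``clip(mu + eps, 0, 1)`` with Gaussian noise ``eps``.

A subset of each cohort's differential sites ("risk sites") receives extra
per-sample logit jitter, and tumor survival times are exponential with rate
``h0 * exp(theta * sum of risk-site betas)``, censored at an independent
Uniform(0, horizon) draw.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import BetaMatrix, PipelineError, SampleAnnotation
from .preprocess import assign_age_segment

__all__ = ["TumorCohortSpec", "SimConfig", "GroundTruth", "generate_cohort", "inject_missing"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class TumorCohortSpec:
    """One simulated tumor cohort: name, size, effective-age shift."""

    name: str
    n_samples: int
    age_shift_mean: float = -10.0  # delta_c, years
    age_shift_sd: float = 2.0  # tau, years


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults: 5,000 sites of which 300 are clock sites, 98.7% of them with a
    positive age slope (matching the observed preponderance of positively
    age-correlated CpGs); ages uniform on 14-89 years; 500 normal samples
    and three tumor cohorts whose clock sites run 10 or 15 years young or
    8 years old; 20 differential sites per cohort shifted ~2 logits from a
    baseline near beta = 0.1 (fold change ~ 4.5); beta noise sd 0.03;
    5 risk sites per cohort with log-hazard 1.0 per unit beta.
    """

    n_sites: int = 5000
    n_clock_sites: int = 300
    frac_positive: float = 0.987
    age_range: tuple[float, float] = (14.0, 89.0)
    n_normal: int = 500
    tumor_cohorts: list[TumorCohortSpec] = field(
        default_factory=lambda: [
            TumorCohortSpec("TUMA", 200, -10.0, 2.0),
            TumorCohortSpec("TUMB", 150, -15.0, 2.0),
            TumorCohortSpec("TUMC", 150, 8.0, 2.0),
        ]
    )
    n_diff_sites: int = 20
    diff_shift: float = 2.0  # logit-scale mean shift of differential sites
    noise_sd: float = 0.03  # sigma, beta-scale Gaussian noise
    slope_range: tuple[float, float] = (0.05, 0.25)  # |s_i|, logits per decade
    n_risk_sites: int = 5
    risk_effect: float = 1.0  # theta, log-hazard per unit beta
    risk_beta_sd: float = 1.5  # per-sample logit jitter of risk sites
    baseline_hazard: float = 1e-3  # h0, events per day
    censor_horizon: float = 2000.0  # days
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_positive <= 1.0):
            raise PipelineError("frac_positive must be in [0, 1]")
        if self.n_clock_sites > self.n_sites:
            raise PipelineError("n_clock_sites cannot exceed n_sites")
        for sd in (self.noise_sd, self.risk_beta_sd):
            if sd < 0:
                raise PipelineError("standard deviations must be >= 0")
        for c in self.tumor_cohorts:
            if c.n_samples <= 0:
                raise PipelineError(f"tumor cohort {c.name!r} has no samples")
            if c.age_shift_sd < 0:
                raise PipelineError(f"tumor cohort {c.name!r}: negative shift sd")
        free = self.n_sites - self.n_clock_sites
        if self.n_diff_sites * len(self.tumor_cohorts) > free:
            raise PipelineError("not enough non-clock sites for differential sets")
        if self.n_risk_sites > self.n_diff_sites:
            raise PipelineError("n_risk_sites cannot exceed n_diff_sites")


@dataclass
class GroundTruth:
    """What the generator planted, for closing the loop in tests."""

    clock_sites: list[str]
    slopes: dict[str, float]  # logit slope per decade, signed
    baselines: dict[str, float]
    diff_sites: dict[str, list[str]]  # cohort -> shifted sites
    diff_shift: float
    risk_sites: dict[str, list[str]]  # cohort -> hazard-linked sites
    risk_effect: float
    age_shifts: dict[str, float]  # sample -> Delta_j (0 for normals)
    cohort_shift_means: dict[str, float]  # cohort -> delta_c


def generate_cohort(
    cfg: SimConfig,
) -> tuple[BetaMatrix, list[SampleAnnotation], GroundTruth]:
    """Generate a beta matrix, clinical table and ground truth per *cfg*."""
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_sites
    n_tumor = sum(c.n_samples for c in cfg.tumor_cohorts)
    n = cfg.n_normal + n_tumor

    site_ids = [f"cg{i:08d}" for i in range(m)]
    sample_ids = [f"NORM{i:05d}" for i in range(cfg.n_normal)]
    cohorts = ["NORMAL"] * cfg.n_normal
    conditions = ["normal"] * cfg.n_normal
    for c in cfg.tumor_cohorts:
        sample_ids += [f"{c.name}{i:05d}" for i in range(c.n_samples)]
        cohorts += [c.name] * c.n_samples
        conditions += ["tumor"] * c.n_samples

    ages = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n)

    # clock-site slopes: round(frac_positive * n_clock) positive, rest negative
    n_pos = int(round(cfg.frac_positive * cfg.n_clock_sites))
    signs = np.concatenate(
        [np.ones(n_pos), -np.ones(cfg.n_clock_sites - n_pos)]
    )
    rng.shuffle(signs)
    mags = rng.uniform(cfg.slope_range[0], cfg.slope_range[1], cfg.n_clock_sites)
    slopes = signs * mags

    baselines = np.empty(m)
    baselines[: cfg.n_clock_sites] = rng.uniform(-1.5, 1.5, cfg.n_clock_sites)
    baselines[cfg.n_clock_sites :] = rng.uniform(-3.0, 3.0, m - cfg.n_clock_sites)

    # reserve differential sites per cohort among non-clock sites, with low
    # baselines (beta ~ 0.1) so a +diff_shift logit move is a clear FC > 2
    diff_idx: dict[str, np.ndarray] = {}
    cursor = cfg.n_clock_sites
    for c in cfg.tumor_cohorts:
        idx = np.arange(cursor, cursor + cfg.n_diff_sites)
        diff_idx[c.name] = idx
        baselines[idx] = rng.uniform(-2.4, -2.0, cfg.n_diff_sites)
        cursor += cfg.n_diff_sites

    # effective ages
    eff_age = ages.copy()
    age_shift = np.zeros(n)
    col0 = cfg.n_normal
    cohort_cols: dict[str, np.ndarray] = {}
    for c in cfg.tumor_cohorts:
        cols = np.arange(col0, col0 + c.n_samples)
        cohort_cols[c.name] = cols
        age_shift[cols] = rng.normal(c.age_shift_mean, c.age_shift_sd, c.n_samples)
        eff_age[cols] = ages[cols] + age_shift[cols]
        col0 += c.n_samples

    # mean beta on the logit scale
    logit = np.tile(baselines[:, None], (1, n))
    decades = (eff_age - 50.0) / 10.0
    logit[: cfg.n_clock_sites, :] = (
        baselines[: cfg.n_clock_sites, None] + slopes[:, None] * decades[None, :]
    )
    risk_idx: dict[str, np.ndarray] = {}
    for c in cfg.tumor_cohorts:
        cols = cohort_cols[c.name]
        logit[np.ix_(diff_idx[c.name], cols)] += cfg.diff_shift
        ridx = diff_idx[c.name][: cfg.n_risk_sites]
        risk_idx[c.name] = ridx
        logit[np.ix_(ridx, cols)] += rng.normal(
            0.0, cfg.risk_beta_sd, (len(ridx), len(cols))
        )

    mu = _sigmoid(logit)
    if cfg.noise_sd > 0:
        mu = mu + rng.normal(0.0, cfg.noise_sd, mu.shape)
    beta = np.clip(mu, 0.0, 1.0)

    df = pd.DataFrame(beta, index=site_ids, columns=sample_ids)
    df.index.name = "site_id"
    matrix = BetaMatrix(df)

    # survival for tumor samples: exponential hazard driven by risk sites
    survival = np.full(n, np.nan)
    event = np.full(n, -1)
    for c in cfg.tumor_cohorts:
        cols = cohort_cols[c.name]
        score = beta[np.ix_(risk_idx[c.name], cols)].sum(axis=0)
        rate = cfg.baseline_hazard * np.exp(cfg.risk_effect * score)
        t_event = rng.exponential(1.0 / rate)
        t_cens = rng.uniform(0.0, cfg.censor_horizon, size=len(cols))
        survival[cols] = np.minimum(t_event, t_cens)
        event[cols] = (t_event <= t_cens).astype(int)

    genders = rng.choice(["female", "male"], size=n)
    stages = rng.integers(1, 5, size=n)

    annotations = []
    for j in range(n):
        tumor = conditions[j] == "tumor"
        annotations.append(
            SampleAnnotation(
                sample_id=sample_ids[j],
                age_years=float(ages[j]),
                cohort=cohorts[j],
                condition=conditions[j],
                gender=str(genders[j]),
                stage=int(stages[j]) if tumor else None,
                survival_days=float(survival[j]) if tumor else None,
                event=int(event[j]) if tumor else None,
                age_segment=assign_age_segment(float(ages[j])),
            )
        )

    truth = GroundTruth(
        clock_sites=site_ids[: cfg.n_clock_sites],
        slopes={site_ids[i]: float(slopes[i]) for i in range(cfg.n_clock_sites)},
        baselines={site_ids[i]: float(baselines[i]) for i in range(m)},
        diff_sites={c: [site_ids[i] for i in idx] for c, idx in diff_idx.items()},
        diff_shift=cfg.diff_shift,
        risk_sites={c: [site_ids[i] for i in idx] for c, idx in risk_idx.items()},
        risk_effect=cfg.risk_effect,
        age_shifts={sample_ids[j]: float(age_shift[j]) for j in range(n)},
        cohort_shift_means={c.name: c.age_shift_mean for c in cfg.tumor_cohorts},
    )

    if cfg.missing_rate > 0:
        matrix = inject_missing(
            matrix, cfg.missing_rate, seed=int(rng.integers(0, 2**31 - 1))
        )
    return matrix, annotations, truth


def inject_missing(matrix: BetaMatrix, rate: float, seed: int = 0) -> BetaMatrix:
    """Independently replace each cell by missing with probability *rate*."""
    if not (0.0 <= rate < 1.0):
        raise PipelineError("missing rate must satisfy 0 <= rate < 1")
    if rate == 0.0:
        return matrix.copy()
    rng = np.random.default_rng(seed)
    mask = rng.random(matrix.values.shape) < rate
    arr = matrix.values.to_numpy(dtype=float, copy=True)
    arr[mask] = np.nan
    df = pd.DataFrame(arr, index=matrix.values.index, columns=matrix.values.columns)
    df.index.name = matrix.values.index.name
    return BetaMatrix(df)


def truth_to_dict(truth: GroundTruth) -> dict:
    """JSON-safe view of the ground truth (for the `simulate` CLI)."""
    return dataclasses.asdict(truth)
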