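"""Shared data model, file I/O, configuration and logging.

The pipeline exchanges three kinds of objects: a site-by-sample matrix of
methylation beta values (fractions in [0, 1], ``NA``-capable), a per-sample
clinical annotation table (age, cohort, normal/tumor status, gender, stage,
survival), and a trained clock model.  All exchange formats are plain text
(TSV for tables, JSON for models, YAML for configuration) so pipeline runs
are diffable and byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PipelineError",
    "ParseError",
    "BetaMatrix",
    "SampleAnnotation",
    "PipelineConfig",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_clinical",
    "write_clinical",
    "annotations_to_frame",
    "frame_to_annotations",
    "write_model",
    "read_model",
    "get_logger",
]

CONDITIONS = ("normal", "tumor")
GENDERS = ("female", "male", "unknown")
AGE_SEGMENTS = ("young", "middle", "older_young", "old")

#: default float format for all TSV output (stable, diffable)
FLOAT_FORMAT = "%.10g"


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(PipelineError):
    """A file could not be parsed or violated a data-model invariant."""


# ---------------------------------------------------------------------------
# beta matrix
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Site x sample grid of methylation beta values.

    Rows are CpG probes (e.g. ``cg16867657``), columns are samples.  Values
    are methylation fractions in [0, 1]; missing values are ``NaN``.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ParseError(f"duplicate site id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ParseError(f"duplicate sample id {dup!r}")
        try:
            arr = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-numeric beta value: {exc}") from exc
        bad = ((arr < 0.0) | (arr > 1.0)) & ~np.isnan(arr)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ParseError(
                f"beta value {arr[i, j]!r} outside [0, 1] at site "
                f"{df.index[i]!r}, sample {df.columns[j]!r}"
            )
        self.values = df.astype(float)

    # -- basic views -------------------------------------------------------

    @property
    def site_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def m(self) -> int:
        """Number of sites (rows)."""
        return self.values.shape[0]

    @property
    def n(self) -> int:
        """Number of samples (columns)."""
        return self.values.shape[1]

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(self.values.copy())

    def restrict_sites(self, site_ids: Sequence[str]) -> "BetaMatrix":
        missing = [s for s in site_ids if s not in self.values.index]
        if missing:
            raise PipelineError(f"sites absent from matrix: {missing[:5]}")
        return BetaMatrix(self.values.loc[list(site_ids)])

    def restrict_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise PipelineError(f"samples absent from matrix: {missing[:5]}")
        return BetaMatrix(self.values[list(sample_ids)])

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


def read_beta_matrix(path: str | Path, missing_token: str = "NA") -> BetaMatrix:
    """Read a beta matrix from TSV (first column site ids, header sample ids).

    Cells equal to *missing_token* become missing; any other non-numeric cell
    or a value outside [0, 1] raises :class:`ParseError` naming the cell.
    """
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    if raw.index.name is None and raw.shape[1] == 0:
        raise ParseError(f"{path}: malformed header or empty table")
    parsed = {}
    for col in raw.columns:
        s = raw[col].where(raw[col] != missing_token)
        num = pd.to_numeric(s, errors="coerce")
        bad = num.isna() & s.notna()
        if bad.any():
            site = raw.index[bad.to_numpy().nonzero()[0][0]]
            val = s[bad].iloc[0]
            raise ParseError(
                f"{path}: unparseable value {val!r} at site {site!r}, sample {col!r}"
            )
        parsed[col] = num
    df = pd.DataFrame(parsed, index=raw.index)
    df.index.name = "site_id"
    return BetaMatrix(df)


def write_beta_matrix(
    matrix: BetaMatrix, path: str | Path, missing_token: str = "NA"
) -> None:
    df = matrix.values.copy()
    df.index.name = "site_id"
    df.to_csv(path, sep="\t", na_rep=missing_token, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# clinical annotations
# ---------------------------------------------------------------------------


@dataclass
class SampleAnnotation:
    """Per-sample clinical record.

    ``survival_days``/``event`` describe right-censored overall survival;
    ``event`` = 1 means death observed.  ``age_segment`` is the WHO age bin
    derived from ``age_years`` (young / middle / older_young / old).
    """

    sample_id: str
    age_years: float
    cohort: str
    condition: str
    gender: str = "unknown"
    stage: int | None = None
    survival_days: float | None = None
    event: int | None = None
    age_segment: str | None = None

    def __post_init__(self) -> None:
        if self.age_years is None or not np.isfinite(self.age_years) or self.age_years < 0:
            raise ParseError(
                f"sample {self.sample_id!r}: invalid age {self.age_years!r}"
            )
        if self.condition not in CONDITIONS:
            raise ParseError(
                f"sample {self.sample_id!r}: condition must be one of {CONDITIONS}"
            )
        if self.gender not in GENDERS:
            raise ParseError(
                f"sample {self.sample_id!r}: gender must be one of {GENDERS}"
            )
        if self.stage is not None and self.stage not in (1, 2, 3, 4):
            raise ParseError(f"sample {self.sample_id!r}: stage {self.stage!r}")
        if self.survival_days is not None:
            if self.survival_days < 0:
                raise ParseError(
                    f"sample {self.sample_id!r}: negative survival_days"
                )
            if self.event is None:
                raise ParseError(
                    f"sample {self.sample_id!r}: survival_days given without event flag"
                )
        if self.event is not None and self.event not in (0, 1):
            raise ParseError(f"sample {self.sample_id!r}: event must be 0/1")
        if self.age_segment is not None and self.age_segment not in AGE_SEGMENTS:
            raise ParseError(
                f"sample {self.sample_id!r}: unknown age segment {self.age_segment!r}"
            )


_CLINICAL_COLUMNS = [
    "sample_id",
    "age_years",
    "cohort",
    "condition",
    "gender",
    "stage",
    "survival_days",
    "event",
    "age_segment",
]


def annotations_to_frame(annotations: Iterable[SampleAnnotation]) -> pd.DataFrame:
    rows = [dataclasses.asdict(a) for a in annotations]
    df = pd.DataFrame(rows, columns=_CLINICAL_COLUMNS)
    return df


def frame_to_annotations(df: pd.DataFrame) -> list[SampleAnnotation]:
    required = {"sample_id", "age_years", "cohort", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"clinical table missing columns: {sorted(missing)}")

    def opt(v, cast):
        if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
            return None
        return cast(v)

    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            SampleAnnotation(
                sample_id=str(d["sample_id"]),
                age_years=float(d["age_years"]),
                cohort=str(d["cohort"]),
                condition=str(d["condition"]),
                gender=opt(d.get("gender"), str) or "unknown",
                stage=opt(d.get("stage"), lambda v: int(float(v))),
                survival_days=opt(d.get("survival_days"), float),
                event=opt(d.get("event"), lambda v: int(float(v))),
                age_segment=opt(d.get("age_segment"), str),
            )
        )
    return out


def read_clinical(path: str | Path) -> list[SampleAnnotation]:
    """Read a per-sample clinical TSV; optional columns are missing-tolerant."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
    return frame_to_annotations(df)


def write_clinical(annotations: Iterable[SampleAnnotation], path: str | Path) -> None:
    df = annotations_to_frame(annotations)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------


def write_model(model, path: str | Path) -> None:
    """Serialize a clock model to JSON (human-inspectable and diffable)."""
    d = model.to_dict()
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_model(path: str | Path):
    from .clock import ClockModel  # local import avoids a cycle

    try:
        with open(path) as fh:
            d = json.load(fh)
        return ClockModel.from_dict(d)
    except (json.JSONDecodeError, KeyError, TypeError, OSError) as exc:
        raise ParseError(f"cannot load clock model from {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All stage thresholds of the analysis pipeline, with defaults.

    Defaults mirror the published analysis protocol: sites with >10% missing
    values removed, 10-nearest-neighbor imputation, age-site screening at
    p < 0.05 and |SCC| > 0.3, 10-fold cross-validated LASSO, top-25% gap
    selection, differential calls at FDR < 0.01 with FC > 2 or < 0.5, and
    survival screening/log-rank significance at p < 0.05.
    """

    missing_token: str = "NA"
    max_na_fraction: float = 0.10
    knn_k: int = 10
    scc_threshold: float = 0.3
    p_threshold: float = 0.05
    screen_fdr: bool = False
    cv_folds: int = 10
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    tol_years: float = 5.0
    train_fraction: float = 0.75
    top_gap_fraction: float = 0.25
    fdr_threshold: float = 0.01
    fc_upper: float = 2.0
    fc_lower: float = 0.5
    #: site universe for differential testing: all processed sites, or only
    #: the screened age-associated set
    diff_universe: str = "all"
    survival_p: float = 0.05
    logrank_p: float = 0.05
    min_cohort: int = 20
    min_events: int = 5
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        checks = [
            (0.0 <= self.max_na_fraction < 1.0, "max_na_fraction in [0, 1)"),
            (self.knn_k >= 1, "knn_k >= 1"),
            (0.0 < self.scc_threshold < 1.0, "scc_threshold in (0, 1)"),
            (0.0 < self.p_threshold <= 1.0, "p_threshold in (0, 1]"),
            (self.cv_folds >= 2, "cv_folds >= 2"),
            (self.n_lambda >= 2, "n_lambda >= 2"),
            (0.0 < self.lambda_min_ratio < 1.0, "lambda_min_ratio in (0, 1)"),
            (0.0 < self.train_fraction < 1.0, "train_fraction in (0, 1)"),
            (0.0 < self.top_gap_fraction <= 1.0, "top_gap_fraction in (0, 1]"),
            (0.0 < self.fdr_threshold <= 1.0, "fdr_threshold in (0, 1]"),
            (self.fc_upper > 1.0 and 0.0 < self.fc_lower < 1.0, "fc bounds"),
            (self.diff_universe in ("all", "screened"), "diff_universe"),
            (isinstance(self.seed, int) and self.seed >= 0, "seed >= 0 integer"),
        ]
        for ok, what in checks:
            if not ok:
                raise PipelineError(f"config: {what} violated")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.pop("simulation", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# logging
# ---------------------------------------------------------------------------


def get_logger(name: str = "methclock", level: str | int = "INFO") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s: %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)
    return logger
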