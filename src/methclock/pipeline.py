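"""End-to-end orchestration: simulate -> preprocess -> screen -> train ->
predict -> age gaps -> differential sites -> survival.

Every stage writes plain-text outputs into the run directory; given the same
configuration and seed, re-running reproduces them byte for byte.  The
returned summary dictionary collects the headline numbers of the run.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import age_gap as ag
from . import diffmeth as dm
from . import survival as sv
from .clock import evaluate_clock, predict_mage, train_clock
from .core_io import (
    FLOAT_FORMAT,
    PipelineConfig,
    annotations_to_frame,
    get_logger,
    write_beta_matrix,
    write_clinical,
    write_model,
)
from .preprocess import filter_sites_by_missingness, knn_impute
from .screening import spearman_screen, summarize_sign
from .synthetic import SimConfig, generate_cohort, truth_to_dict

__all__ = ["run_all"]

log = get_logger(__name__)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def _metrics_dict(m) -> dict:
    return {
        "pearson_r": m.pearson_r,
        "pearson_p": m.pearson_p,
        "accuracy_at_tol": m.accuracy_at_tol,
        "tol": m.tol,
        "error_value": m.error_value,
        "rss": m.rss,
    }


def run_all(
    sim_cfg: SimConfig, config: PipelineConfig, outdir: str | Path
) -> dict:
    """Run the whole analysis on a freshly simulated cohort.

    Returns the summary dictionary (also written to ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("stage: simulate")
    matrix, annotations, truth = generate_cohort(sim_cfg)
    write_beta_matrix(matrix, outdir / "beta.tsv", config.missing_token)
    write_clinical(annotations, outdir / "clinical.tsv")
    _write_json(truth_to_dict(truth), outdir / "ground_truth.json")

    log.info("stage: preprocess")
    filtered = filter_sites_by_missingness(matrix, config.max_na_fraction)
    n_missing = filtered.n_missing()
    imputed = knn_impute(filtered, k=config.knn_k) if n_missing else filtered
    write_beta_matrix(imputed, outdir / "beta_processed.tsv", config.missing_token)
    _write_json(
        {
            "sites_in": matrix.m,
            "sites_removed": matrix.m - filtered.m,
            "cells_imputed": n_missing,
        },
        outdir / "qc.json",
    )

    clin = annotations_to_frame(annotations).set_index("sample_id")
    ages = clin["age_years"].astype(float)
    normal_ids = sorted(clin.index[clin["condition"] == "normal"])
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(normal_ids))
    n_train = int(round(config.train_fraction * len(normal_ids)))
    train_ids = [normal_ids[i] for i in sorted(perm[:n_train])]
    test_ids = [normal_ids[i] for i in sorted(perm[n_train:])]

    log.info("stage: screen (%d training normals)", len(train_ids))
    screened = spearman_screen(
        imputed.restrict_samples(train_ids),
        ages[train_ids],
        scc_threshold=config.scc_threshold,
        p_threshold=config.p_threshold,
        use_fdr=config.screen_fdr,
    )
    screened.table.to_csv(
        outdir / "screen.tsv", sep="\t", float_format=FLOAT_FORMAT
    )
    sign = summarize_sign(screened)

    log.info("stage: train")
    train_annotations = [a for a in annotations if a.sample_id in set(train_ids)]
    model, train_metrics = train_clock(imputed, train_annotations, screened, config)
    write_model(model, outdir / "model.json")
    pd.DataFrame(model.cv_table).to_csv(
        outdir / "cv_curve.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )

    log.info("stage: predict")
    predictions = predict_mage(model, imputed)
    predictions.rename("mage").to_frame().to_csv(
        outdir / "predictions.tsv", sep="\t", float_format=FLOAT_FORMAT
    )
    test_metrics = evaluate_clock(
        predictions[test_ids].to_numpy(), ages[test_ids].to_numpy(),
        tol=config.tol_years,
    )
    _write_json(
        {"train": _metrics_dict(train_metrics), "test": _metrics_dict(test_metrics)},
        outdir / "clock_metrics.json",
    )

    log.info("stage: age gap")
    gaps = ag.compute_gaps(predictions, ages)
    tumor_ids = list(clin.index[clin["condition"] == "tumor"])
    tumor_gaps = gaps[tumor_ids]
    tumor_cohorts = clin.loc[tumor_ids, "cohort"]
    scores = ag.age_difference_score(tumor_gaps, tumor_cohorts)
    threshold = train_metrics.error_value
    directions = ag.classify_direction(tumor_gaps, threshold)
    dir_summary = ag.direction_summary(directions, tumor_cohorts)
    age_related = ag.select_age_related_samples(
        tumor_gaps, tumor_cohorts, config.top_gap_fraction
    )
    scores.rename("difference_score").to_frame().to_csv(
        outdir / "agegap_scores.tsv", sep="\t", float_format=FLOAT_FORMAT
    )
    pd.DataFrame({"gap": tumor_gaps, "direction": directions}).to_csv(
        outdir / "directions.tsv", sep="\t", float_format=FLOAT_FORMAT
    )
    _write_json(age_related, outdir / "age_related_samples.json")

    log.info("stage: differential methylation")
    universe = (
        imputed.restrict_sites(screened.selected_ids)
        if config.diff_universe == "screened"
        else imputed
    )
    diff_tables: dict[str, pd.DataFrame] = {}
    diff_sites: dict[str, list[str]] = {}
    for cohort, samples in age_related.items():
        table = dm.call_differential_sites(
            universe,
            normal_ids,
            samples,
            fdr_threshold=config.fdr_threshold,
            fc_bounds=(config.fc_upper, config.fc_lower),
        )
        diff_tables[cohort] = table
        diff_sites[cohort] = list(table.index[table["significant"]])
        table.to_csv(
            outdir / f"diffmeth_{cohort}.tsv", sep="\t", float_format=FLOAT_FORMAT
        )

    log.info("stage: survival")
    surv = sv.survival_pipeline(imputed, annotations, diff_sites, config)
    surv_rows = []
    for cohort, res in surv.items():
        surv_rows.append(
            {
                "cohort": cohort,
                "n_retained_sites": len(res.retained_sites),
                "logrank_chi2": res.logrank_chi2,
                "logrank_p": res.logrank_p,
                "significant": res.significant,
            }
        )
        res.risk_scores.to_frame().assign(risk_group=res.risk_group).to_csv(
            outdir / f"risk_scores_{cohort}.tsv", sep="\t",
            float_format=FLOAT_FORMAT,
        )
        pd.concat(
            {g: c for g, c in res.km_curves.items()}, names=["risk_group"]
        ).to_csv(outdir / f"km_{cohort}.tsv", sep="\t", float_format=FLOAT_FORMAT)
    pd.DataFrame(
        surv_rows,
        columns=["cohort", "n_retained_sites", "logrank_chi2", "logrank_p",
                 "significant"],
    ).to_csv(outdir / "survival_summary.tsv", sep="\t", index=False,
             float_format=FLOAT_FORMAT)

    summary = {
        "n_sites": matrix.m,
        "n_samples": matrix.n,
        "n_train_normals": len(train_ids),
        "n_test_normals": len(test_ids),
        "n_selected_sites": sign.n_selected,
        "n_positive_sites": sign.n_positive,
        "frac_positive_pct": (
            100.0 * sign.frac_positive if sign.frac_positive is not None else None
        ),
        "lambda_selected": model.lam,
        "n_model_features": len(model.feature_ids),
        "beta0_years": model.beta0,
        "train": _metrics_dict(train_metrics),
        "test": _metrics_dict(test_metrics),
        "direction_threshold_years": threshold,
        "difference_scores": scores.to_dict(),
        "mean_gap_by_cohort": tumor_gaps.groupby(tumor_cohorts).mean().to_dict(),
        "direction_fractions": {
            c: dir_summary.loc[c].to_dict() for c in dir_summary.index
        },
        "n_diff_significant": {c: len(s) for c, s in diff_sites.items()},
        "survival": {
            c: {
                "n_retained_sites": len(r.retained_sites),
                "logrank_chi2": r.logrank_chi2,
                "logrank_p": r.logrank_p,
                "significant": r.significant,
            }
            for c, r in surv.items()
        },
    }
    _write_json(summary, outdir / "summary.json")
    log.info("pipeline complete: outputs in %s", outdir)
    return summary
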