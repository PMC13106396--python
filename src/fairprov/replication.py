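"""Replicate-seed audit studies.

Single-split audit statistics at n = 1,000 are seed-noisy (fairness metrics
especially: subgroup TPRs on a 300-patient test set have SDs near 0.1), so
summary claims about the audit are made on replicate means: the full audit is
repeated under many master seeds and each statistic averaged across
replicates. This module runs that study; it is what the reproduction script
and the replicate-level tests call.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .audit_stats import cv_audit, permutation_test_eod
from .cohort_sim import CohortSpec, generate_cohort, stratified_split
from .counterfactual_audit import gender_flip_audit
from .fairness_metrics import (
    UndefinedMetricError,
    demographic_parity_difference,
    equal_opportunity_difference,
)
from .model_provenance import (
    DEFAULT_FEATURES,
    PAPER_GRID,
    fit_forest,
    fit_logistic,
    refit_without_feature,
    tune_forest,
)
from .seeding import substream_seed

logger = logging.getLogger(__name__)

__all__ = ["single_seed_audit", "replicate_study", "replicate_means"]


def single_seed_audit(
    master_seed: int,
    n: int = 1000,
    test_fraction: float = 0.3,
    cv_folds: int = 5,
    n_permutations: int = 1000,
    tune: bool = True,
) -> dict:
    """One complete audit under one master seed; returns its statistics.

    Keys: lr/rf cross-validated accuracy and ROC-AUC; single-split LR EOD,
    DPD and RF EOD; RF gender importance; tuned-RF test accuracy; LR
    counterfactual flip fraction; gender-ablated LR DPD; permutation
    p-values for both models.
    """
    spec = CohortSpec(n_patients=n, seed=substream_seed(master_seed, "cohort"))
    cohort = generate_cohort(spec)
    split = stratified_split(cohort, test_fraction, seed=substream_seed(master_seed, "split"))
    train, test = cohort.view(split.train_ids), cohort.view(split.test_ids)
    y = test["outcome"].to_numpy()
    g = test["gender"].to_numpy()

    out: dict = {"seed": master_seed}

    lr = fit_logistic(train, DEFAULT_FEATURES)
    lr_pred = lr.predict(test)
    out["lr_eod"] = float(equal_opportunity_difference(y, lr_pred, g))
    out["lr_dpd"] = float(demographic_parity_difference(y, lr_pred, g))
    out["lr_perm_p"] = permutation_test_eod(
        y, lr_pred, g, n_permutations, seed=substream_seed(master_seed, "perm-lr")
    ).p_value

    rf = fit_forest(train, DEFAULT_FEATURES, seed=substream_seed(master_seed, "forest"))
    rf_pred = rf.predict(test)
    out["rf_eod"] = float(equal_opportunity_difference(y, rf_pred, g))
    out["rf_gender_importance"] = rf.importances["gender"]
    out["rf_age_importance"] = rf.importances["age_std"]
    out["rf_bmi_importance"] = rf.importances["bmi_std"]
    out["rf_perm_p"] = permutation_test_eod(
        y, rf_pred, g, n_permutations, seed=substream_seed(master_seed, "perm-rf")
    ).p_value

    lr_cv = cv_audit(cohort, "logistic", k=cv_folds, seed=substream_seed(master_seed, "cv-lr"))
    out["lr_cv_acc"] = lr_cv.summary["accuracy"]["mean"]
    out["lr_cv_auc"] = lr_cv.summary["roc_auc"]["mean"]
    rf_cv = cv_audit(cohort, "forest", k=cv_folds, seed=substream_seed(master_seed, "cv-rf"))
    out["rf_cv_acc"] = rf_cv.summary["accuracy"]["mean"]
    out["rf_cv_auc"] = rf_cv.summary["roc_auc"]["mean"]

    cf = gender_flip_audit(lr, test)
    out["lr_flip_fraction"] = cf.flip_fraction
    out["lr_n_boundary"] = cf.n_boundary

    ablated = refit_without_feature(lr, train, "gender")
    out["lr_ablated_dpd"] = float(
        demographic_parity_difference(y, ablated.predict(test), g)
    )

    if tune:
        gs = tune_forest(train, PAPER_GRID, cv_folds=3, seed=substream_seed(master_seed, "tune"))
        tuned = fit_forest(
            train, DEFAULT_FEATURES, hyperparams=gs.selected,
            seed=substream_seed(master_seed, "forest-tuned"),
        )
        out["rf_tuned_test_acc"] = float((tuned.predict(test) == y).mean())
        out["rf_tuned_cv_auc"] = gs.selected_score
    return out


def replicate_study(
    n_seeds: int = 50,
    base_seed: int = 1,
    n: int = 1000,
    tune: bool = True,
    n_permutations: int = 1000,
) -> pd.DataFrame:
    """Run the full audit under ``n_seeds`` master seeds; one row per seed."""
    rows = []
    for i in range(n_seeds):
        seed = substream_seed(base_seed, f"replicate-{i}")
        try:
            rows.append(single_seed_audit(seed, n=n, tune=tune, n_permutations=n_permutations))
        except UndefinedMetricError as exc:  # pragma: no cover - rare degenerate seed
            logger.warning("replicate %d (seed %d) skipped: %s", i, seed, exc)
        if (i + 1) % 10 == 0:
            logger.info("replicate study: %d/%d done", i + 1, n_seeds)
    return pd.DataFrame(rows)


def replicate_means(study: pd.DataFrame, columns: Sequence[str] | None = None) -> dict:
    """Replicate means of the study's numeric columns."""
    cols = columns or [c for c in study.columns if c != "seed"]
    return {c: float(np.nanmean(study[c].to_numpy(dtype=float))) for c in cols}
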