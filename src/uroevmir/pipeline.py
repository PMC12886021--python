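"""End-to-end training and evaluation over a quantified cohort.

Ties the stages together in the order the analysis prescribes:
sample QC (total counts > 1e4) -> balanced 80/20 split -> 80% prevalence
filter fit on the training samples -> per-sample CPM -> bootstrap feature
ranking -> forward selection by CV AUC -> log-loss-tuned LightGBM ->
threshold calibrated to a target training sensitivity -> hold-out report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify, evaluate, preprocess, quant
from .classify import ClassifierBundle


@dataclass
class TrainConfig:
    train_fraction: float = 0.8
    candidate_split_seeds: tuple[int, ...] = tuple(range(20))
    prevalence_min_count: int = 2
    prevalence_min_fraction: float = 0.8
    n_iter: int = 500
    subset_fraction: float = 0.3
    k_folds: int = 10
    max_features: int = 20
    search_budget: int = 20
    target_sensitivity: float = 0.8
    min_total_counts: int = 10_000
    seed: int = 0


def train_pipeline(counts: pd.DataFrame, meta: pd.DataFrame,
                   config: TrainConfig | None = None):
    """Train the PDAC-vs-HR classifier; returns ``(bundle, artifacts)``.

    ``counts`` is the raw UMI-deduplicated matrix (miRNAs x samples) and
    ``meta`` its sample metadata.  Only PDAC and HR samples enter the model;
    the hold-out side of the split is never touched during training.
    ``artifacts`` carries the intermediate tables (split, ranking, feature
    matrices) for inspection and hold-out evaluation.
    """
    cfg = config or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    seeds = {name: int(rng.integers(0, 2**31 - 1))
             for name in ("ranking", "selection", "tuning")}

    counts, dropped = quant.qc_filter_samples(counts, cfg.min_total_counts)
    meta = meta.loc[counts.columns]
    eligible = meta[meta["cohort"].isin(["PDAC", "HR"])]
    split = classify.stratified_split(eligible, cfg.train_fraction,
                                      cfg.candidate_split_seeds)

    # totals over all quantified miRNAs, fixed before any row filtering
    totals = counts.sum(axis=0)
    train_counts = counts[split.train_ids]
    filtered = preprocess.prevalence_filter(
        train_counts, cfg.prevalence_min_count, cfg.prevalence_min_fraction)
    cpm_train = preprocess.cpm_normalize(filtered, totals)
    X_train, y_train = classify.build_feature_table(
        cpm_train, meta.loc[split.train_ids])

    ranking = classify.bootstrap_feature_ranking(
        X_train, y_train, n_iter=cfg.n_iter,
        subset_fraction=cfg.subset_fraction, k=cfg.k_folds,
        seed=seeds["ranking"])
    selected, auc_path = classify.forward_select(
        ranking, X_train, y_train, k=cfg.k_folds,
        max_features=cfg.max_features, seed=seeds["selection"])
    fit = classify.tune_and_train(
        X_train, y_train, selected, search_budget=cfg.search_budget,
        k=cfg.k_folds, seed=seeds["tuning"])
    threshold, achieved = classify.calibrate_threshold(
        fit["oof_scores"], y_train, cfg.target_sensitivity)

    fold_metrics = []
    for i, (_, va_idx) in enumerate(fit["folds"]):
        yv = np.asarray(y_train)[va_idx]
        sv = fit["oof_scores"][va_idx]
        sens, spec, _ = evaluate.confusion_at_threshold(yv, sv, threshold)
        auc = evaluate.roc_auc(yv, sv) if len(np.unique(yv)) == 2 else None
        fold_metrics.append({"fold": i, "auc": auc, "sensitivity": sens,
                             "specificity": spec})

    hyper = {k: v for k, v in fit["params"].items()}
    bundle = ClassifierBundle(
        selected_features=list(selected),
        model_string=fit["booster"].model_to_string(),
        hyperparameters=hyper,
        num_boost_round=fit["num_rounds"],
        threshold=threshold,
        target_sensitivity=cfg.target_sensitivity,
        achieved_train_sensitivity=achieved,
        cv_fold_metrics=fold_metrics,
        auc_path=[float(a) for a in auc_path],
        split={"train_ids": split.train_ids,
               "holdout_ids": split.holdout_ids,
               "chosen_seed": split.chosen_seed,
               "balance_score": split.balance_score,
               "dropped_low_count": dropped},
    )
    artifacts = {
        "split": split,
        "ranking": ranking,
        "totals": totals,
        "filtered_mirnas": list(filtered.index),
        "X_train": X_train,
        "y_train": y_train,
        "oof_scores": fit["oof_scores"],
        "cv_log_loss": fit["cv_log_loss"],
    }
    return bundle, artifacts


def holdout_features(counts: pd.DataFrame, meta: pd.DataFrame,
                     bundle: ClassifierBundle):
    """Feature table for new samples: CPM with each sample's own totals
    (over all quantified miRNAs), restricted to the bundle's miRNAs."""
    totals = counts.sum(axis=0)
    mirnas = [f for f in bundle.selected_features
              if f not in ("age", "sex")]
    cpm = preprocess.cpm_normalize(counts.loc[mirnas], totals)
    X, y = classify.build_feature_table(cpm, meta.loc[counts.columns])
    return X, y


def evaluate_holdout(counts: pd.DataFrame, meta: pd.DataFrame,
                     bundle: ClassifierBundle,
                     prevalence: float = 0.01) -> dict:
    """Score hold-out samples and assemble the diagnostic report."""
    ids = bundle.split["holdout_ids"]
    X, y = holdout_features(counts[ids], meta.loc[ids], bundle)
    scores, calls = bundle.predict(X)
    sens, spec, cmat = evaluate.confusion_at_threshold(
        y.to_numpy(), scores.to_numpy(), bundle.threshold)
    auc = evaluate.roc_auc(y.to_numpy(), scores.to_numpy())
    ppv, npv = evaluate.ppv_npv(sens, spec, prevalence)
    report = {
        "n_holdout": len(ids),
        "auc": auc,
        "sensitivity": sens,
        "sensitivity_ci": evaluate.wilson_ci(cmat["tp"],
                                             cmat["tp"] + cmat["fn"]),
        "specificity": spec,
        "specificity_ci": evaluate.wilson_ci(cmat["tn"],
                                             cmat["tn"] + cmat["fp"]),
        "confusion": cmat,
        "by_stage": evaluate.stage_stratified_sensitivity(
            meta.loc[ids], scores, bundle.threshold),
        "ppv": ppv,
        "npv": npv,
        "prevalence_assumed": prevalence,
    }
    return report
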