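"""Stratified cross-validation protocol and classification metrics.

The study design: subjects are split into 10 stratified folds (class
proportions preserved per fold).  Because patient/control counts are
rarely equal, the training portion of each fold is balanced either by
upsampling (duplicating minority-class subjects) or downsampling
(random subsetting of the majority class).  Each fold trains the three
base GNNs and the stacking ensemble on the balanced training set and
scores the untouched test fold; accuracy, sensitivity, specificity
(confusion-matrix ratios) and the area under the ROC curve are reported
per fold and as the unweighted mean over folds, for every base model
and the ensemble.

Resampling scope matters: the leak-free default balances only the
training folds (``train_folds_only``).  Balancing the whole cohort
before the fold split (``before_split``) lets duplicated subjects
straddle the train/test boundary; the pipeline supports that protocol
for comparison and counts the resulting cross-fold duplicate leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .connectome import ConnectomeGraph
from .gnn_models import (
    EnsembleConfig,
    OptimizerConfig,
    ensemble_fit,
    prepare_graphs,
    train_base,
)

__all__ = [
    "Cohort",
    "FoldPlan",
    "ResamplingPolicy",
    "ConfusionCounts",
    "MetricReport",
    "stratified_kfold",
    "apply_resampling",
    "compute_confusion",
    "compute_metrics",
    "compute_auc",
    "run_cv",
    "report_tables",
]

MODEL_NAMES = ("gcn", "gat", "sage", "ensemble")


@dataclass
class Cohort:
    """Labelled subject graphs; `positive_class` defines SEN/SPE
    (patients are positive by default)."""

    graphs: list
    labels: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    positive_class: int = 1
    sites: list | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.labels) != len(self.graphs):
            raise ValueError("labels not aligned with graphs")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ValueError("labels must be in {0, 1}")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("cohort must contain both classes")
        if not self.subject_ids:
            self.subject_ids = [getattr(g, "subject_id", str(i)) or str(i)
                                for i, g in enumerate(self.graphs)]
        for g, y in zip(self.graphs, self.labels):
            if isinstance(g, ConnectomeGraph):
                g.label = int(y)

    def __len__(self) -> int:
        return len(self.graphs)


@dataclass
class FoldPlan:
    n_folds: int
    assignments: np.ndarray
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


@dataclass
class ResamplingPolicy:
    """How and when class balance is enforced.

    mode: ``upsample`` duplicates minority subjects, ``downsample``
    subsets the majority, ``none`` leaves counts alone.
    scope: ``train_folds_only`` (leak-free default) or ``before_split``.
    """

    mode: str = "upsample"
    scope: str = "train_folds_only"
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("upsample", "downsample", "none"):
            raise ValueError(f"unknown resampling mode {self.mode!r}")
        if self.scope not in ("train_folds_only", "before_split"):
            raise ValueError(f"unknown resampling scope {self.scope!r}")


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def stratified_kfold(labels, n_folds: int = 10, seed: int = 0) -> FoldPlan:
    """Assign subjects to stratified folds, deterministic given `seed`.

    Every fold's class counts are within one subject of the
    floor/ceiling of the global proportions.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small} has {counts.min()} members, fewer than "
            f"{n_folds} folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignments = np.empty(len(labels), dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)),
                                                   labels)):
        assignments[test_idx] = fold
    return FoldPlan(n_folds=n_folds, assignments=assignments, seed=seed)


def apply_resampling(ids: Sequence[int], labels,
                     policy: ResamplingPolicy) -> np.ndarray:
    """Return the balanced id multiset per the policy.

    Upsampling keeps every original id at least once and duplicates
    randomly chosen minority ids; downsampling returns a subset of the
    majority ids.  `mode="none"` is the identity.
    """
    ids = np.asarray(ids)
    labels = np.asarray(labels)
    if len(ids) != len(labels):
        raise ValueError("ids/labels length mismatch")
    if policy.mode == "none":
        return ids.copy()
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("resampling needs both classes present")
    rng = np.random.default_rng(policy.seed)
    by_class = {c: ids[labels == c] for c in classes}
    if policy.mode == "upsample":
        target = counts.max()
        parts = []
        for c in classes:
            pool = by_class[c]
            parts.append(pool)
            deficit = target - len(pool)
            if deficit > 0:
                parts.append(rng.choice(pool, size=deficit, replace=True))
        out = np.concatenate(parts)
    else:
        target = counts.min()
        parts = []
        for c in classes:
            pool = by_class[c]
            if len(pool) > target:
                parts.append(rng.choice(pool, size=target, replace=False))
            else:
                parts.append(pool)
        out = np.concatenate(parts)
    return np.sort(out)


def compute_confusion(true_labels, predicted_labels,
                      positive_class: int = 1) -> ConfusionCounts:
    """Count TP/TN/FP/FN with respect to `positive_class`."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("length mismatch")
    for arr in (t, p):
        if not np.all(np.isin(arr, (0, 1))):
            raise ValueError("labels must be in {0, 1}")
    pos = t == positive_class
    hit = t == p
    return ConfusionCounts(
        TP=int(np.sum(pos & hit)), TN=int(np.sum(~pos & hit)),
        FP=int(np.sum(~pos & ~hit)), FN=int(np.sum(pos & ~hit)))


def compute_metrics(c: ConfusionCounts) -> tuple[float | None, float | None,
                                                 float | None]:
    """(ACC, SEN, SPE) = ((TP+TN)/total, TP/(TP+FN), TN/(TN+FP)).

    A metric whose denominator is zero is returned as None (undefined),
    never silently as 0.
    """
    acc = (c.TP + c.TN) / c.total if c.total > 0 else None
    sen = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else None
    spe = c.TN / (c.TN + c.FP) if (c.TN + c.FP) > 0 else None
    return acc, sen, spe


def compute_auc(true_labels, positive_scores, positive_class: int = 1) -> float:
    """Area under the ROC curve of `positive_scores`.

    Trapezoidal area, equal to the Mann-Whitney U statistic normalised
    by n_pos * n_neg with ties counted 0.5.
    """
    t = np.asarray(true_labels)
    s = np.asarray(positive_scores, dtype=np.float64)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    y = (t == positive_class).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y, s))


@dataclass
class MetricReport:
    """Per-fold and mean ACC/SEN/SPE/AUC for each model.

    `per_fold[model]` is a list of dicts (fold, ACC, SEN, SPE, AUC,
    TP, TN, FP, FN); `summary[model]` holds the unweighted mean over
    folds (undefined fold metrics are excluded from the mean).
    `predictions` is a tidy DataFrame of per-subject test predictions.
    `leakage_count` counts test subjects whose id also occurs in their
    fold's training multiset (only possible with before_split scope).
    """

    per_fold: dict
    summary: dict
    predictions: pd.DataFrame
    leakage_count: int
    config_echo: dict

    def mean(self, model: str, metric: str):
        return self.summary[model][metric]


def _mean_or_none(values):
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None


def _score_fold(y_true, probs, positive_class):
    preds = np.argmax(probs, axis=1)
    conf = compute_confusion(y_true, preds, positive_class)
    acc, sen, spe = compute_metrics(conf)
    try:
        auc = compute_auc(y_true, probs[:, positive_class], positive_class)
    except ValueError:
        auc = None
    return conf, acc, sen, spe, auc, preds


def _derive_seed(base: int, *keys: int) -> int:
    s = int(base)
    for k in keys:
        s = (s * 1000003 + int(k) + 1) % (2 ** 31 - 1)
    return s


def run_cv(cohort: Cohort, ensemble_cfg: EnsembleConfig,
           opt_cfg: OptimizerConfig, fold_seed: int = 0,
           policy: ResamplingPolicy | None = None,
           n_folds: int = 10) -> MetricReport:
    """Stratified k-fold evaluation of the three bases and the ensemble.

    Per fold: balance the training subjects per `policy`, train the
    bases independently, fit the stacking meta head on the same
    training fold, then score every model on the untouched test fold.
    Reproducible given (fold_seed, policy.seed, opt_cfg.seed).
    """
    policy = policy or ResamplingPolicy()
    prepped = prepare_graphs(cohort.graphs) \
        if not hasattr(cohort.graphs[0], "src_sl") else list(cohort.graphs)
    labels = cohort.labels
    pos = cohort.positive_class

    if policy.scope == "before_split" and policy.mode != "none":
        pool = apply_resampling(np.arange(len(cohort)), labels, policy)
    else:
        pool = np.arange(len(cohort))
    pool_labels = labels[pool]
    plan = stratified_kfold(pool_labels, n_folds=n_folds, seed=fold_seed)

    per_fold: dict[str, list] = {m: [] for m in MODEL_NAMES}
    pred_rows = []
    leakage = 0
    for fold in range(n_folds):
        test_pos = plan.test_indices(fold)
        train_pos = plan.train_indices(fold)
        test_ids = pool[test_pos]
        train_ids = pool[train_pos]
        if policy.scope == "train_folds_only" and policy.mode != "none":
            fold_policy = ResamplingPolicy(
                mode=policy.mode, scope=policy.scope,
                seed=_derive_seed(policy.seed, fold))
            train_ids = apply_resampling(train_ids, labels[train_ids],
                                         fold_policy)
        leakage += int(np.isin(test_ids, train_ids).sum())

        train_graphs = [prepped[i] for i in train_ids]
        for g, y in zip(train_graphs, labels[train_ids]):
            g.label = int(y)
        test_graphs = [prepped[i] for i in test_ids]
        y_test = labels[test_ids]

        bases = []
        outputs = {}
        try:
            for ai, cfg in enumerate(ensemble_cfg.base_configs):
                arch_opt = OptimizerConfig(
                    learning_rate=opt_cfg.learning_rate,
                    weight_decay=opt_cfg.weight_decay, epochs=opt_cfg.epochs,
                    batch_size=opt_cfg.batch_size,
                    seed=_derive_seed(opt_cfg.seed, fold, ai))
                model = train_base(train_graphs, cfg, arch_opt)
                bases.append(model)
                outputs[cfg.arch] = model.predict_proba(test_graphs)
            meta_opt = OptimizerConfig(
                learning_rate=opt_cfg.learning_rate,
                weight_decay=opt_cfg.weight_decay, epochs=opt_cfg.epochs,
                batch_size=opt_cfg.batch_size,
                seed=_derive_seed(opt_cfg.seed, fold, 99))
            ens = ensemble_fit(bases, train_graphs, ensemble_cfg, meta_opt)
            outputs["ensemble"] = ens.predict_proba(test_graphs)
        except ValueError as exc:
            raise ValueError(f"fold {fold}: {exc}") from exc

        for model_name in MODEL_NAMES:
            probs = outputs[model_name]
            conf, acc, sen, spe, auc, preds = _score_fold(y_test, probs, pos)
            per_fold[model_name].append(dict(
                fold=fold, ACC=acc, SEN=sen, SPE=spe, AUC=auc,
                TP=conf.TP, TN=conf.TN, FP=conf.FP, FN=conf.FN))
            if model_name == "ensemble":
                for sid_idx, yt, pp, pd_ in zip(test_ids, y_test,
                                                probs[:, pos], preds):
                    pred_rows.append(dict(
                        subject_id=cohort.subject_ids[sid_idx], fold=fold,
                        true=int(yt), prob_positive=float(pp),
                        pred=int(pd_)))

    summary = {
        m: {k: _mean_or_none(row[k] for row in per_fold[m])
            for k in ("ACC", "SEN", "SPE", "AUC")}
        for m in MODEL_NAMES
    }
    predictions = pd.DataFrame(
        pred_rows, columns=["subject_id", "fold", "true",
                            "prob_positive", "pred"])
    config_echo = dict(
        fold_seed=fold_seed, n_folds=n_folds,
        policy=dict(mode=policy.mode, scope=policy.scope, seed=policy.seed),
        optimizer=dict(learning_rate=opt_cfg.learning_rate,
                       weight_decay=opt_cfg.weight_decay,
                       epochs=opt_cfg.epochs, batch_size=opt_cfg.batch_size,
                       seed=opt_cfg.seed),
        combine=ensemble_cfg.combine, meta_hidden=ensemble_cfg.meta_hidden,
        freeze_bases=ensemble_cfg.freeze_bases,
        positive_class=cohort.positive_class)
    return MetricReport(per_fold=per_fold, summary=summary,
                        predictions=predictions, leakage_count=leakage,
                        config_echo=config_echo)


def _fmt(v) -> str:
    return "" if v is None else f"{v:.6f}"


def report_tables(report: MetricReport, path, sampling_label: str = "") -> list:
    """Write the summary and per-fold tables as CSV files.

    `summary.csv`: one row per model with mean ACC/SEN/SPE/AUC (and the
    sampling mode label); `folds.csv`: one row per model per fold;
    `predictions.csv`: per-subject ensemble test predictions.  Output is
    byte-deterministic for a given report.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    label = sampling_label or report.config_echo["policy"]["mode"]

    summary_path = path / "summary.csv"
    with open(summary_path, "w", newline="") as fh:
        fh.write("model,sampling,ACC,SEN,SPE,AUC\n")
        for m in MODEL_NAMES:
            s = report.summary[m]
            fh.write(f"{m},{label},{_fmt(s['ACC'])},{_fmt(s['SEN'])},"
                     f"{_fmt(s['SPE'])},{_fmt(s['AUC'])}\n")

    folds_path = path / "folds.csv"
    with open(folds_path, "w", newline="") as fh:
        fh.write("model,sampling,fold,ACC,SEN,SPE,AUC,TP,TN,FP,FN\n")
        for m in MODEL_NAMES:
            for row in report.per_fold[m]:
                fh.write(f"{m},{label},{row['fold']},{_fmt(row['ACC'])},"
                         f"{_fmt(row['SEN'])},{_fmt(row['SPE'])},"
                         f"{_fmt(row['AUC'])},{row['TP']},{row['TN']},"
                         f"{row['FP']},{row['FN']}\n")

    pred_path = path / "predictions.csv"
    with open(pred_path, "w", newline="") as fh:
        fh.write("subject_id,fold,true,prob_positive,pred\n")
        for row in report.predictions.itertuples(index=False):
            fh.write(f"{row.subject_id},{row.fold},{row.true},"
                     f"{row.prob_positive:.6f},{row.pred}\n")
    return [summary_path, folds_path, pred_path]
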