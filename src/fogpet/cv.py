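"""10-fold cross-validation protocol, metrics, and concatenated-fold ROC.

Subjects are shuffled once with the run seed and partitioned into k
non-overlapping folds of near-equal size (sizes differ by at most one). In
each iteration one fold is the independent test set; the remaining subjects
are split 80/20 into training and validation sets (stratified by class when
feasible) for early stopping. Per-fold classification or regression metrics
are aggregated as mean +/- sample SD; the prediction scores of all test
folds are concatenated into one global ROC, whose AUC is reported as
max(AUC, 1 - AUC) with an inversion flag whenever the raw value was below
0.5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "FoldPlan", "MetricsReport", "make_folds", "run_cv", "select_task",
    "classification_metrics", "roc_auc_corrected", "regression_metrics",
    "concat_global_roc",
]

TASKS = ("pd_vs_hc", "fog_vs_nfog", "fogq_regress")


@dataclass
class FoldPlan:
    """k non-overlapping test folds plus an inner 80/20 train/val split each."""

    subject_ids: list
    k: int
    seed: int
    folds: list[list]                      # test ids per fold
    inner: list[tuple[list, list]]         # (train ids, val ids) per fold

    @property
    def assignments(self) -> dict:
        return {sid: f for f, ids in enumerate(self.folds) for sid in ids}


def make_folds(subject_ids, k: int = 10, seed: int = 0, labels=None,
               val_fraction: float = 0.2) -> FoldPlan:
    """Shuffle-once k-fold plan with stratified-when-possible inner splits.

    ``labels``, if given, maps subject position to its class and is used only
    to stratify the inner validation split (each class contributes ~20% of
    its training-pool members, at least one when it has two or more).
    """
    subject_ids = list(subject_ids)
    n = len(subject_ids)
    if len(set(subject_ids)) != n:
        raise ValueError("subject ids must be unique")
    if n < k:
        raise ValueError(f"need at least k={k} subjects, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [subject_ids[i] for i in order]
    folds = [list(chunk) for chunk in np.array_split(np.asarray(shuffled, dtype=object), k)]

    label_of = None
    if labels is not None:
        label_of = {sid: lab for sid, lab in zip(subject_ids, labels)}

    inner = []
    for f in range(k):
        pool = [sid for g, ids in enumerate(folds) if g != f for sid in ids]
        pool_rng = np.random.default_rng(seed * 1000 + f + 1)
        if label_of is not None:
            classes: dict = {}
            for sid in pool:
                classes.setdefault(label_of[sid], []).append(sid)
            val: list = []
            for members in classes.values():
                m = len(members)
                n_val = max(1, round(val_fraction * m)) if m >= 2 else 0
                pick = pool_rng.choice(m, size=n_val, replace=False)
                val += [members[i] for i in pick]
        else:
            n_val = max(1, round(val_fraction * len(pool)))
            pick = pool_rng.choice(len(pool), size=n_val, replace=False)
            val = [pool[i] for i in pick]
        val_set = set(val)
        train = [sid for sid in pool if sid not in val_set]
        if not train:
            raise ValueError("empty training split; too few subjects for this k")
        inner.append((train, val))
    return FoldPlan(subject_ids=subject_ids, k=k, seed=seed, folds=folds, inner=inner)


def classification_metrics(y_true, y_pred, positive_class=1) -> dict:
    """Accuracy, precision, recall, F1 in percent from the confusion counts.

    Undefined ratios (no predicted positives, or no true positives) are
    reported as NaN with a warning, never silently coerced to 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    tp = int(np.sum((y_pred == positive_class) & (y_true == positive_class)))
    fp = int(np.sum((y_pred == positive_class) & (y_true != positive_class)))
    fn = int(np.sum((y_pred != positive_class) & (y_true == positive_class)))
    tn = int(np.sum((y_pred != positive_class) & (y_true != positive_class)))
    acc = 100.0 * (tp + tn) / len(y_true)
    if tp + fp == 0:
        warnings.warn("precision undefined (no positive predictions)")
        prec = np.nan
    else:
        prec = 100.0 * tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("recall undefined (no positive ground truth)")
        rec = np.nan
    else:
        rec = 100.0 * tp / (tp + fn)
    if np.isnan(prec) or np.isnan(rec) or prec + rec == 0:
        f1 = np.nan
    else:
        f1 = 2.0 * prec * rec / (prec + rec)
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1,
            "tp": tp, "fp": fp, "fn": fn, "tn": tn}


def roc_auc_corrected(y_true, scores) -> tuple[float, bool]:
    """Mann-Whitney AUC with the direction-invariance convention: if the raw
    AUC is below 0.5 (label inversion), report 1 - AUC and flag it."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC needs both classes present")
    raw = float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))
    if raw < 0.5:
        return 1.0 - raw, True
    return raw, False


def concat_global_roc(fold_scores: dict, fold_labels: dict):
    """Pool per-fold test scores into one global ROC.

    ``fold_scores[f]`` and ``fold_labels[f]`` map fold index to
    ``{subject_id: value}``. Every subject must be scored exactly once.
    Returns (fpr, tpr, auc, inversion_applied).
    """
    seen: dict = {}
    labels: dict = {}
    for f, scores in fold_scores.items():
        for sid, s in scores.items():
            if sid in seen:
                raise ValueError(f"subject {sid!r} scored in more than one fold")
            seen[sid] = s
            labels[sid] = fold_labels[f][sid]
    sids = sorted(seen)
    y = np.asarray([labels[s] for s in sids])
    sc = np.asarray([seen[s] for s in sids], dtype=float)
    auc, inverted = roc_auc_corrected(y, sc)
    fpr, tpr, _ = roc_curve(y, -sc if inverted else sc)
    return fpr, tpr, auc, inverted


def regression_metrics(y_true, y_pred, fold_assignments) -> pd.DataFrame:
    """Per-fold MSE, MAE, RMSE. ``fold_assignments`` gives each sample's fold."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    folds = np.asarray(fold_assignments)
    if not (len(y_true) == len(y_pred) == len(folds)):
        raise ValueError("y_true, y_pred and fold_assignments must align")
    rows = []
    for f in sorted(set(folds.tolist())):
        sel = folds == f
        if not sel.any():
            raise ValueError(f"fold {f} is empty")
        err = y_pred[sel] - y_true[sel]
        mse = float((err**2).mean())
        rows.append({"fold": f, "mse": mse, "mae": float(np.abs(err).mean()),
                     "rmse": float(np.sqrt(mse)), "n": int(sel.sum())})
    return pd.DataFrame(rows)


@dataclass
class MetricsReport:
    """Per-fold and aggregated cross-validation results."""

    task: str
    model_kind: str
    per_fold: pd.DataFrame
    aggregate: dict                     # metric -> (mean, sample SD)
    auc: float = np.nan
    inversion_applied: bool = False
    roc: tuple | None = None            # (fpr, tpr)
    n_subjects: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "task": self.task,
            "model": self.model_kind,
            "n_subjects": self.n_subjects,
            "per_fold": self.per_fold.where(pd.notna(self.per_fold), None).to_dict(orient="records"),
            "aggregate": {k: {"mean": v[0], "sd": v[1]} for k, v in self.aggregate.items()},
            "auc": None if np.isnan(self.auc) else self.auc,
            "inversion_applied": self.inversion_applied,
            "warnings": self.warnings,
        }
        if self.roc is not None:
            payload["roc"] = {"fpr": list(map(float, self.roc[0])), "tpr": list(map(float, self.roc[1]))}
        return json.dumps(payload, indent=1)


def _aggregate(per_fold: pd.DataFrame, metrics) -> dict:
    out = {}
    for m in metrics:
        vals = per_fold[m].dropna().to_numpy(dtype=float)
        mean = float(vals.mean()) if len(vals) else np.nan
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[m] = (mean, sd)
    return out


def select_task(records, task: str):
    """Map subject records to (indices, targets) for one of the three tasks.

    * ``pd_vs_hc``: all subjects; positive class 1 = PD (FOG or NFOG).
    * ``fog_vs_nfog``: PD subjects only; positive class 1 = PD-FOG.
    * ``fogq_regress``: PD subjects only; target = FOG-Q total.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; choose from {TASKS}")
    if task == "pd_vs_hc":
        idx = list(range(len(records)))
        y = [0 if records[i].group == "HC" else 1 for i in idx]
    elif task == "fog_vs_nfog":
        idx = [i for i, r in enumerate(records) if r.group != "HC"]
        y = [1 if records[i].group == "PD-FOG" else 0 for i in idx]
    else:
        idx = [i for i, r in enumerate(records) if r.group != "HC"]
        y = [records[i].fogq for i in idx]
    return idx, np.asarray(y)


def run_cv(volumes, y, model_factory, task_kind: str = "classify", k: int = 10,
           seed: int = 0, subject_ids=None, task_name: str = "", model_name: str = "") -> MetricsReport:
    """Run the full k-fold protocol for one model.

    ``model_factory(fold_seed)`` must return a fresh wrapper following the
    harness contract (see :mod:`fogpet.baselines`). ``task_kind`` is
    'classify' or 'regress'.
    """
    n = len(volumes)
    if subject_ids is None:
        subject_ids = list(range(n))
    pos = {sid: i for i, sid in enumerate(subject_ids)}
    labels = list(y) if task_kind == "classify" else None
    plan = make_folds(subject_ids, k=k, seed=seed, labels=labels)
    y = np.asarray(y)

    rows, warns = [], []
    fold_scores: dict = {}
    fold_labels: dict = {}
    all_true, all_pred, all_fold = [], [], []
    for f in range(k):
        tr_ids, va_ids = plan.inner[f]
        te_ids = plan.folds[f]
        tr = [pos[s] for s in tr_ids]
        va = [pos[s] for s in va_ids]
        te = [pos[s] for s in te_ids]
        fold_seed = int((seed * 1000 + f) % (2**31 - 1))
        model = model_factory(fold_seed)
        model.fit([volumes[i] for i in tr], y[tr], [volumes[i] for i in va], y[va], seed=fold_seed)
        if task_kind == "classify":
            scores = model.predict_scores([volumes[i] for i in te])
            preds = model.predict_labels([volumes[i] for i in te])
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                m = classification_metrics(y[te], preds)
            warns += [f"fold {f}: {w.message}" for w in wlist]
            m["fold"] = f
            rows.append(m)
            fold_scores[f] = {s: float(sc) for s, sc in zip(te_ids, scores)}
            fold_labels[f] = {s: int(y[pos[s]]) for s in te_ids}
        else:
            preds = model.predict([volumes[i] for i in te])
            all_true += list(y[te])
            all_pred += list(preds)
            all_fold += [f] * len(te)

    if task_kind == "classify":
        per_fold = pd.DataFrame(rows)
        agg = _aggregate(per_fold, ["accuracy", "precision", "recall", "f1"])
        fpr, tpr, auc, inverted = concat_global_roc(fold_scores, fold_labels)
        return MetricsReport(task=task_name or "classify", model_kind=model_name,
                             per_fold=per_fold, aggregate=agg, auc=auc,
                             inversion_applied=inverted, roc=(fpr, tpr),
                             n_subjects=n, warnings=warns)
    per_fold = regression_metrics(all_true, all_pred, all_fold)
    agg = _aggregate(per_fold, ["mse", "mae", "rmse"])
    return MetricsReport(task=task_name or "regress", model_kind=model_name,
                         per_fold=per_fold, aggregate=agg, n_subjects=n, warnings=warns)
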