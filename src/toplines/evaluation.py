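"""Classification metrics, the nested 5x10 cross-validation harness, and
relative-efficiency reporting.

Metrics follow the standard confusion-matrix definitions: Sensitivity
TP/(TP+FN), Specificity TN/(TN+FP), Precision TP/(TP+FP), F1 the harmonic
mean of Precision and Sensitivity, and Cohen's kappa (P0 - Pe)/(1 - Pe)
with P0 = (TP+TN)/N and Pe the chance-agreement term.  Degenerate cells
(0/0) yield NaN — flagged undefined, excluded from aggregation with a
logged count, never coerced to zero.

The harness runs one (environment, trait) slice at a time: outer 5-fold CV
assesses test performance; models RO/BO additionally tune their threshold
by an inner 10-fold CV on the outer-training set (method "O" refits the
model per inner fold; method "S" fits once and splits its in-sample fitted
values).  Test labels never influence any threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grm import GenomicRelationship
from .models import MCMCSettings, GBLUP, ProbitGBLUP
from . import selection as sel

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "CVPlan",
    "FoldResult",
    "confusion",
    "metric_set",
    "make_folds",
    "evaluate_fold",
    "run_nested_cv",
    "aggregate",
    "relative_efficiency",
    "RelativeEfficiency",
    "MODELS",
    "METRIC_NAMES",
]

logger = logging.getLogger(__name__)

MODELS = ("B", "BO", "R", "RC", "RO")
METRIC_NAMES = ("sensitivity", "specificity", "precision", "f1", "kappa")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.n < 1:
            raise ValueError("empty confusion matrix")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Sensitivity/Specificity/Precision/F1/kappa; NaN marks undefined."""

    sensitivity: float
    specificity: float
    precision: float
    f1: float
    kappa: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def confusion(observed, predicted) -> ConfusionMatrix:
    obs = np.asarray(observed)
    pred = np.asarray(predicted)
    if obs.shape != pred.shape or obs.size < 1:
        raise ValueError("observed and predicted must have equal length >= 1")
    for arr in (obs, pred):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
    obs = obs.astype(bool)
    pred = pred.astype(bool)
    return ConfusionMatrix(
        tp=int((obs & pred).sum()),
        tn=int((~obs & ~pred).sum()),
        fp=int((~obs & pred).sum()),
        fn=int((obs & ~pred).sum()),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metric_set(cm: ConfusionMatrix) -> MetricSet:
    n = cm.n
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    prec = _ratio(cm.tp, cm.tp + cm.fp)
    f1 = _ratio(2.0 * prec * sens, prec + sens) if np.isfinite(prec) and np.isfinite(sens) else float("nan")
    p0 = (cm.tp + cm.tn) / n
    pe = ((cm.tp + cm.fn) / n) * ((cm.tp + cm.fp) / n) + ((cm.fp + cm.tn) / n) * ((cm.fn + cm.tn) / n)
    kappa = (p0 - pe) / (1.0 - pe) if pe < 1.0 else float("nan")
    return MetricSet(sens, spec, prec, f1, kappa)


@dataclass(frozen=True)
class CVPlan:
    """Nested cross-validation layout: 5 outer folds, 10 inner folds."""

    outer_k: int = 5
    inner_k: int = 10
    seed: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("CVPlan.seed is mandatory")
        if self.outer_k < 2 or self.inner_k < 2:
            raise ValueError("need at least 2 folds at each level")


def make_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Random partition of range(n) into k near-equal folds."""
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def fold_assignment_frame(line_ids, folds) -> pd.DataFrame:
    rows = []
    for f, idx in enumerate(folds, start=1):
        for i in idx:
            rows.append({"line_id": line_ids[i], "outer_fold": f})
    return pd.DataFrame(rows)


@dataclass
class FoldResult:
    fold: int
    metrics: MetricSet
    confusion: ConfusionMatrix
    base_rule: sel.ThresholdRule
    rule: sel.ThresholdRule
    labeled: sel.LabeledPredictions


def _inner_seed(seed: int, fold: int) -> int:
    # independent seeded partitions per outer fold, kept below 2^31
    return (seed * 1009 + 7919 * fold) % (2**31 - 1)


def evaluate_fold(model: str, method: str, y: np.ndarray, grm: GenomicRelationship,
                  train_idx: np.ndarray, test_idx: np.ndarray, *, tau: float = 0.8,
                  direction: str = "top", settings: MCMCSettings, plan: CVPlan,
                  fold: int = 1) -> FoldResult:
    """Run one outer fold of one scheme.

    All thresholds are built from training/validation structures only; the
    test responses enter only through their observed labels, computed after
    classification thresholds are fixed.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if method not in ("O", "S"):
        raise ValueError(f"unknown method {method!r}")
    n = len(y)
    masked = np.zeros(n, dtype=bool)
    masked[test_idx] = True
    y_train = y[train_idx]
    base_rule = sel.quantile_threshold(y_train, tau=tau, direction=direction)
    inner_seed = _inner_seed(plan.seed, fold)
    fit_seed = _inner_seed(plan.seed, 100 + fold)

    if model in ("RC", "R", "RO"):
        full_fit = GBLUP(y, grm, masked=masked).fit(
            MCMCSettings(settings.n_iter, settings.burn_in, settings.thin, fit_seed))
        pred_test = full_fit._scores[test_idx]
        if model == "RC":
            labeled = sel.classify_rc(y[test_idx], pred_test, base_rule,
                                      line_ids=[grm.line_ids[i] for i in test_idx])
            rule = base_rule
        elif model == "R":
            predicted = sel.classify_r(pred_test, base_rule)
            rule = base_rule
        else:  # RO
            if method == "O":
                inner_cv = []
                inner_folds = make_folds(len(train_idx), plan.inner_k, inner_seed)
                for j, val_local in enumerate(inner_folds):
                    val_idx = train_idx[val_local]
                    m = masked.copy()
                    m[val_idx] = True
                    inner_fit = GBLUP(y, grm, masked=m).fit(
                        MCMCSettings(settings.n_iter, settings.burn_in, settings.thin,
                                     _inner_seed(inner_seed, j)))
                    inner_cv.append((inner_fit._scores[val_idx],
                                     sel.observed_labels(y[val_idx], base_rule)))
                rule = sel.optimize_regression_threshold(inner_cv, base_rule)
            else:  # S
                fitted = full_fit._scores[train_idx]
                labels = sel.observed_labels(y_train, base_rule)
                inner_cv = sel.simple_tuning_scores(fitted, labels, k_folds=plan.inner_k,
                                                    seed=inner_seed)
                rule = sel.optimize_regression_threshold(inner_cv, base_rule,
                                                         provenance="optimized_simple")
            predicted = sel.classify_r(pred_test, rule)
        if model != "RC":
            observed = sel.observed_labels(y[test_idx], base_rule)
            labeled = sel.LabeledPredictions([grm.line_ids[i] for i in test_idx],
                                             observed, predicted, pred_test)
    else:  # B / BO: probit on binarized labels
        yb = sel.observed_labels(y, base_rule).astype(float)
        yb[masked] = np.nan  # test labels are never shown to the model
        full_fit = ProbitGBLUP(np.where(masked, 0.0, yb), grm, masked=masked).fit(
            MCMCSettings(settings.n_iter, settings.burn_in, settings.thin, fit_seed))
        p_test = full_fit._scores[test_idx]
        if model == "B":
            predicted = sel.classify_b(p_test)
            rule = sel.ThresholdRule(scale="probability", value=0.5, direction=direction,
                                     tau=tau, provenance="fixed_half")
        else:  # BO
            if method == "O":
                inner_cv = []
                inner_folds = make_folds(len(train_idx), plan.inner_k, inner_seed)
                for j, val_local in enumerate(inner_folds):
                    val_idx = train_idx[val_local]
                    m = masked.copy()
                    m[val_idx] = True
                    yb_in = sel.observed_labels(y, base_rule).astype(float)
                    inner_fit = ProbitGBLUP(np.where(m, 0.0, yb_in), grm, masked=m).fit(
                        MCMCSettings(settings.n_iter, settings.burn_in, settings.thin,
                                     _inner_seed(inner_seed, j)))
                    inner_cv.append((inner_fit._scores[val_idx],
                                     sel.observed_labels(y[val_idx], base_rule)))
                rule = sel.optimize_probability_threshold(inner_cv, direction=direction, tau=tau)
            else:  # S
                fitted = full_fit._scores[train_idx]
                labels = sel.observed_labels(y_train, base_rule)
                inner_cv = sel.simple_tuning_scores(fitted, labels, k_folds=plan.inner_k,
                                                    seed=inner_seed)
                rule = sel.optimize_probability_threshold(inner_cv, direction=direction,
                                                          tau=tau, provenance="optimized_simple")
            predicted = sel.classify_probability(p_test, rule.value)
        observed = sel.observed_labels(y[test_idx], base_rule)
        labeled = sel.LabeledPredictions([grm.line_ids[i] for i in test_idx],
                                         observed, predicted, p_test)

    cm = confusion(labeled.observed, labeled.predicted)
    return FoldResult(fold=fold, metrics=metric_set(cm), confusion=cm,
                      base_rule=base_rule, rule=rule, labeled=labeled)


def run_nested_cv(y, grm: GenomicRelationship, model: str, method: str = "O", *,
                  plan: CVPlan, settings: MCMCSettings, tau: float = 0.8,
                  direction: str = "top", dataset: str = "synthetic",
                  environment: str = "env1", trait: str = "trait1",
                  return_details: bool = False):
    """Nested CV for one scheme on one (environment, trait) slice.

    Returns a long-format metrics DataFrame (one row per fold x metric);
    with ``return_details`` also the per-fold :class:`FoldResult` list.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    folds = make_folds(n, plan.outer_k, plan.seed)
    rows, details = [], []
    for f, test_idx in enumerate(folds, start=1):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if len(train_idx) < plan.inner_k * 2:
            raise ValueError(
                f"outer-training fold has {len(train_idx)} lines; need >= {plan.inner_k * 2}")
        res = evaluate_fold(model, method, y, grm, train_idx, test_idx, tau=tau,
                            direction=direction, settings=settings, plan=plan, fold=f)
        details.append(res)
        for metric, value in res.metrics.as_dict().items():
            rows.append({"dataset": dataset, "environment": environment, "trait": trait,
                         "model": model, "method": method, "fold": f,
                         "metric": metric, "value": value})
    table = pd.DataFrame(rows)
    return (table, details) if return_details else table


def aggregate(rows: pd.DataFrame, level: str = "dataset") -> pd.DataFrame:
    """Hierarchical aggregation of a long-format metrics table.

    level="trait-env": mean over folds per (dataset, environment, trait,
    model, method, metric).  level="dataset": additionally mean and SE
    across the (environment, trait) combinations of each dataset.
    level="across-data": unweighted mean of the dataset means, reported
    under dataset="Across_Data".  Undefined (NaN) metric values are
    excluded, with the exclusion count in ``n_undefined``.
    """
    if len(rows) == 0:
        raise ValueError("empty metrics table")
    n_undef = int(rows["value"].isna().sum())
    if n_undef:
        logger.info("aggregate: excluding %d undefined metric values", n_undef)
    per_combo = (rows.groupby(["dataset", "environment", "trait", "model", "method", "metric"],
                              as_index=False)
                 .agg(value=("value", "mean"),
                      n_undefined=("value", lambda s: int(s.isna().sum()))))
    if level == "trait-env":
        return per_combo
    per_dataset = (per_combo.groupby(["dataset", "model", "method", "metric"], as_index=False)
                   .agg(value=("value", "mean"),
                        se=("value", lambda s: float(np.std(s, ddof=1) / np.sqrt(len(s)))
                            if len(s) > 1 else float("nan")),
                        n_undefined=("n_undefined", "sum")))
    if level == "dataset":
        return per_dataset
    if level == "across-data":
        out = (per_dataset.groupby(["model", "method", "metric"], as_index=False)
               .agg(value=("value", "mean"),
                    se=("value", lambda s: float(np.std(s, ddof=1) / np.sqrt(len(s)))
                        if len(s) > 1 else float("nan")),
                    n_undefined=("n_undefined", "sum")))
        out.insert(0, "dataset", "Across_Data")
        return out
    raise ValueError(f"unknown aggregation level {level!r}")


@dataclass(frozen=True)
class RelativeEfficiency:
    """Metric ratio between two methods, reported as a percentage."""

    metric: str
    model_y: str
    model_z: str
    re: float
    form: str      # "improvement" | "decrease"
    percent: float  # rounded to two decimals for reporting

    def __str__(self) -> str:
        sign = "+" if self.form == "improvement" else "-"
        return (f"RE_{self.metric}({self.model_y}/{self.model_z}) = {self.re:.4f} "
                f"({sign}{abs(self.percent):.2f}%)")


def relative_efficiency(metric_y: float, metric_z: float, form: str = "improvement",
                        metric: str = "", model_y: str = "y", model_z: str = "z") -> RelativeEfficiency:
    """RE = metric_y / metric_z.

    form="improvement": percent = (RE - 1) * 100 (how much y beats z).
    form="decrease": percent = (1 - y/z) * 100 (how far the smaller y falls
    below z).
    """
    if metric_z <= 0:
        raise ValueError("reference metric must be positive")
    if metric_y <= 0:
        raise ValueError("compared metric must be positive")
    re = metric_y / metric_z
    if form == "improvement":
        pct = (re - 1.0) * 100.0
    elif form == "decrease":
        pct = (1.0 - re) * 100.0
    else:
        raise ValueError(f"unknown form {form!r}")
    return RelativeEfficiency(metric=metric, model_y=model_y, model_z=model_z,
                              re=re, form=form, percent=round(pct, 2))
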