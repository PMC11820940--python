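"""Classification rules for top (or bottom) line selection.

Five schemes share the same ingredients:

* RC — rank-matching: the test lines are ranked by prediction and the same
  number of lines as observed above the quantile threshold is selected.
* R  — fixed threshold: predicted value compared directly to the training
  quantile Y_tau (tau = 0.8 by default).
* RO — optimized threshold: inner cross-validation picks the trait-scale
  cutoff Y_o minimizing the squared Sensitivity-Specificity gap.
* B  — probit probability compared to 0.5.
* BO — probit probability compared to an optimized cutoff tau_0 found the
  same way as Y_o.

All comparisons are strict: a score exactly at the threshold is classified
as NOT top (not bottom).  ``direction="bottom"`` mirrors every rule for
traits where low values are desirable, keeping thresholds on the trait
scale (quantile level 1 - tau, reversed inequalities).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ThresholdRule",
    "LabeledPredictions",
    "quantile_threshold",
    "observed_labels",
    "classify_r",
    "classify_rc",
    "classify_b",
    "classify_probability",
    "optimize_regression_threshold",
    "optimize_probability_threshold",
    "adjusted_predictions",
    "simple_tuning_scores",
    "DegenerateFoldsWarning",
]


class DegenerateFoldsWarning(UserWarning):
    """All inner folds were single-class; the base rule is used instead."""


@dataclass(frozen=True)
class ThresholdRule:
    """A classification cutoff with its scale, direction and provenance.

    ``fold_values`` records the per-inner-fold optima whose mean equals
    ``value`` for optimized rules.
    """

    scale: str               # "phenotype" | "probability"
    value: float
    direction: str = "top"   # "top" | "bottom"
    tau: float = 0.8
    provenance: str = "fixed_quantile"  # | "fixed_half" | "optimized" | "optimized_simple"
    fold_values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("phenotype", "probability"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.direction not in ("top", "bottom"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.scale == "probability" and not (0.0 < self.value < 1.0):
            raise ValueError("probability-scale threshold must lie in (0, 1)")
        if self.fold_values is not None:
            if abs(float(np.mean(self.fold_values)) - self.value) > 1e-12:
                raise ValueError("value must equal the mean of fold_values")

    def to_json(self) -> str:
        d = {"scale": self.scale, "value": self.value, "direction": self.direction,
             "tau": self.tau, "provenance": self.provenance,
             "fold_values": list(self.fold_values) if self.fold_values is not None else None}
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "ThresholdRule":
        d = json.loads(s)
        fv = d.pop("fold_values")
        return cls(fold_values=tuple(fv) if fv is not None else None, **d)


@dataclass
class LabeledPredictions:
    """Observed and predicted top/non-top labels with underlying scores."""

    line_ids: list
    observed: np.ndarray
    predicted: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=int)
        self.predicted = np.asarray(self.predicted, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.line_ids)
        if not (self.observed.shape == self.predicted.shape == self.scores.shape == (n,)):
            raise ValueError("length mismatch")
        for arr in (self.observed, self.predicted):
            if not np.isin(arr, (0, 1)).all():
                raise ValueError("labels must be 0/1")


def quantile_threshold(y_train, tau: float = 0.8, direction: str = "top") -> ThresholdRule:
    """Empirical quantile threshold Y_tau from training responses.

    Linear-interpolation (type-7) quantile at level tau for top selection,
    1 - tau for bottom.
    """
    y = np.asarray(y_train, dtype=float)
    if y.size < 5:
        raise ValueError("need at least 5 training values for a quantile threshold")
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must lie in (0, 1)")
    level = tau if direction == "top" else 1.0 - tau
    value = float(np.quantile(y, level, method="linear"))
    return ThresholdRule(scale="phenotype", value=value, direction=direction, tau=tau,
                         provenance="fixed_quantile")


def _exceeds(values: np.ndarray, cutoff: float, direction: str) -> np.ndarray:
    """Strict threshold comparison; equality is never a positive."""
    values = np.asarray(values, dtype=float)
    return (values > cutoff) if direction == "top" else (values < cutoff)


def observed_labels(y, rule: ThresholdRule) -> np.ndarray:
    """1 for lines strictly beyond the trait-scale threshold, else 0."""
    if rule.scale != "phenotype":
        raise ValueError("observed labels need a phenotype-scale rule")
    return _exceeds(y, rule.value, rule.direction).astype(int)


def classify_r(y_pred, rule: ThresholdRule) -> np.ndarray:
    """Model R: predicted label 1 iff the prediction strictly exceeds Y_tau."""
    if rule.scale != "phenotype":
        raise ValueError("model R needs a phenotype-scale rule")
    return _exceeds(y_pred, rule.value, rule.direction).astype(int)


def classify_probability(p_hat, cutoff: float, direction: str = "top") -> np.ndarray:
    """Label 1 iff probability strictly exceeds the cutoff.

    The probit model predicts the probability of being a top (or bottom)
    line directly, so no direction reversal applies to the comparison.
    """
    p = np.asarray(p_hat, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("probabilities must lie in (0, 1)")
    return (p > cutoff).astype(int)


def classify_b(p_hat) -> np.ndarray:
    """Model B: the fixed probability threshold of one half."""
    return classify_probability(p_hat, 0.5)


def classify_rc(y_obs_test, y_pred_test, rule: ThresholdRule, line_ids=None) -> LabeledPredictions:
    """Model RC rank-matching.

    k = number of observed test responses strictly beyond Y_tau; the k best
    predicted lines get predicted label 1.  Ties at rank k are broken by
    input (line-id) order — a stable sort keeps earlier lines first.
    Consequence: predicted and observed positive counts are equal.
    """
    y_obs = np.asarray(y_obs_test, dtype=float)
    y_pred = np.asarray(y_pred_test, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.size < 1:
        raise ValueError("observed and predicted must have equal length >= 1")
    if line_ids is None:
        line_ids = list(range(y_obs.size))
    observed = observed_labels(y_obs, rule)
    k = int(observed.sum())
    predicted = np.zeros(y_obs.size, dtype=int)
    if k > 0:
        key = -y_pred if rule.direction == "top" else y_pred
        order = np.argsort(key, kind="stable")
        predicted[order[:k]] = 1
    return LabeledPredictions(list(line_ids), observed, predicted, y_pred)


def _sens_spec(labels: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    pos = labels == 1
    sens = float(predicted[pos].mean()) if pos.any() else np.nan
    spec = float(1.0 - predicted[~pos].mean()) if (~pos).any() else np.nan
    return sens, spec


def _optimize_folds(inner_cv, candidates_fn, base: float, direction: str):
    """Shared search: per fold, pick the candidate cutoff minimizing
    (Sensitivity - Specificity)^2; ties go to the candidate closest to the
    base cutoff, then to the smaller candidate.  Returns per-fold optima
    (degenerate single-class folds skipped)."""
    fold_optima = []
    for scores, labels in inner_cv:
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=int)
        if labels.min() == labels.max():
            continue  # degenerate: objective undefined
        best = None
        for c in candidates_fn(scores):
            predicted = _exceeds(scores, c, direction).astype(int)
            sens, spec = _sens_spec(labels, predicted)
            obj = (sens - spec) ** 2
            key = (obj, abs(c - base), c)
            if best is None or key < best[0]:
                best = (key, c)
        fold_optima.append(best[1])
    return fold_optima


def _phenotype_candidates(scores: np.ndarray) -> np.ndarray:
    s = np.unique(scores)
    pad = 0.5 * max(float(s[-1] - s[0]), 1.0)
    if s.size == 1:
        return np.array([s[0] - pad, s[0] + pad])
    mids = (s[:-1] + s[1:]) / 2.0
    return np.concatenate(([s[0] - pad], mids, [s[-1] + pad]))


def _probability_candidates(scores: np.ndarray) -> np.ndarray:
    s = np.unique(scores)
    mids = (s[:-1] + s[1:]) / 2.0 if s.size > 1 else np.empty(0)
    return np.unique(np.concatenate((mids, [0.5])))


def optimize_regression_threshold(inner_cv, base_rule: ThresholdRule,
                                  provenance: str = "optimized") -> ThresholdRule:
    """Trait-scale threshold Y_o balancing Sensitivity and Specificity.

    ``inner_cv`` is an iterable of (validation scores, validation observed
    labels) pairs, one per inner fold.  Candidates per fold are the
    midpoints of consecutive sorted validation scores plus one candidate
    below the minimum and one above the maximum, so every distinct
    confusion matrix is reachable.  The returned value is the mean of the
    per-fold optima; single-class folds are skipped, and if every fold is
    degenerate the base rule is returned with a warning.
    """
    if base_rule.scale != "phenotype":
        raise ValueError("base rule must be on the phenotype scale")
    optima = _optimize_folds(inner_cv, _phenotype_candidates, base_rule.value,
                             base_rule.direction)
    if not optima:
        warnings.warn("all inner folds degenerate; falling back to the base quantile rule",
                      DegenerateFoldsWarning)
        return base_rule
    return ThresholdRule(scale="phenotype", value=float(np.mean(optima)),
                         direction=base_rule.direction, tau=base_rule.tau,
                         provenance=provenance, fold_values=tuple(optima))


def optimize_probability_threshold(inner_cv, direction: str = "top", tau: float = 0.8,
                                   provenance: str = "optimized") -> ThresholdRule:
    """Probability threshold tau_0 balancing Sensitivity and Specificity.

    Candidates per fold are the midpoints of sorted unique validation
    probabilities plus 0.5 (so the optimized objective can never exceed the
    fixed-half rule's).  Falls back to 0.5 if every fold is degenerate.
    """
    optima = _optimize_folds(inner_cv, _probability_candidates, 0.5, "top")
    if not optima:
        warnings.warn("all inner folds degenerate; falling back to the 0.5 rule",
                      DegenerateFoldsWarning)
        return ThresholdRule(scale="probability", value=0.5, direction=direction,
                             tau=tau, provenance="fixed_half")
    return ThresholdRule(scale="probability", value=float(np.mean(optima)),
                         direction=direction, tau=tau, provenance=provenance,
                         fold_values=tuple(optima))


def adjusted_predictions(y_pred, rule_base: ThresholdRule, rule_opt: ThresholdRule) -> np.ndarray:
    """Adjusted predictions Y* = Y_hat * (Y_tau / Y_o).

    Classifying Y* against Y_tau reproduces classifying Y_hat against Y_o
    whenever Y_tau / Y_o > 0; with opposite signs the equivalence breaks and
    the direct Y_o rule stays authoritative (a warning is emitted).
    """
    if rule_opt.value == 0.0:
        raise ValueError("optimized threshold is zero; rescaling undefined")
    ratio = rule_base.value / rule_opt.value
    if ratio < 0:
        warnings.warn(
            "base and optimized thresholds have opposite signs; adjusted "
            "predictions do not reproduce the optimized rule — classify "
            "against Y_o directly", UserWarning)
    return np.asarray(y_pred, dtype=float) * ratio


def simple_tuning_scores(scores, labels, k_folds: int = 10, seed: int = 0):
    """Partition in-sample fitted scores into inner-CV units for the
    threshold optimizers (the Simple method: the model is fitted once and
    its training-set scores are split instead of refitting per fold).

    Returns a list of (scores, labels) pairs, one per fold; deterministic
    under ``seed``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n = scores.size
    if n < 2 * k_folds:
        raise ValueError(f"need at least 2 lines per fold ({n} lines, {k_folds} folds)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [(scores[idx], labels[idx]) for idx in np.array_split(perm, k_folds)]
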