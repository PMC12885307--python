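"""Rule-pair weak classifiers and their boosted combination.

Every (benign rule, malignant rule) pair forms one weak classifier: a test
sample is projected onto each rule's feature subset and its Euclidean
distance to the rule vector is divided by the range norm of those columns
in the training matrix; the closer rule wins (ties go to malignant — the
conservative call for a screening tool).  With l benign and k malignant
rules there are l*k weak classifiers.

Discrete two-class AdaBoost then weights them: the pool is fixed (weak
classifiers are not re-fit), each round selects the pool member minimizing
the weighted error on the current sample distribution (selection with
replacement), and the usual multiplicative re-weighting follows.  The
number of rounds equals the pool size; a round whose best error reaches
0.5 stops training early.  The final strong classifier is the sign of the
weighted vote.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .rule_mining import DiagnosisRule
from .schema_io import BENIGN, MALIGNANT, NormalizedMatrix

__all__ = [
    "WeakClassifier",
    "StrongClassifier",
    "pair_weak_classifiers",
    "rule_distance",
    "weak_predict",
    "adaboost_train",
    "strong_predict",
]

logger = logging.getLogger(__name__)

_EPS_CLAMP = 1e-10


@dataclass(frozen=True)
class WeakClassifier:
    """One benign/malignant rule pair with precomputed range denominators."""

    benign_rule: DiagnosisRule
    malignant_rule: DiagnosisRule
    denom_b: float
    denom_m: float

    def __post_init__(self) -> None:
        if self.denom_b <= 0 or self.denom_m <= 0:
            raise ValueError("range denominators must be positive")


@dataclass
class StrongClassifier:
    """Weighted weak-classifier committee: predicts sign(sum w_t * wc_t(s))."""

    members: list[tuple[WeakClassifier, float]]
    training_summary: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a strong classifier needs at least one member")


def _range_denominator(norm: NormalizedMatrix | np.ndarray, cols) -> float:
    values = norm.values if isinstance(norm, NormalizedMatrix) else np.asarray(norm)
    cols = np.asarray(cols)
    spans = values[:, cols].max(axis=0) - values[:, cols].min(axis=0)
    return float(np.linalg.norm(spans))


def pair_weak_classifiers(
    benign_rules: list[DiagnosisRule],
    malignant_rules: list[DiagnosisRule],
    norm: NormalizedMatrix | np.ndarray,
) -> list[WeakClassifier]:
    """All l*k rule pairs, with range denominators from the training matrix.

    Pairs whose denominator vanishes (every rule column constant in the
    training matrix) are skipped with a warning.
    """
    if not benign_rules:
        raise ValueError("no benign rules mined")
    if not malignant_rules:
        raise ValueError("no malignant rules mined")
    out: list[WeakClassifier] = []
    for rb in benign_rules:
        db = _range_denominator(norm, rb.col_indices)
        for rm in malignant_rules:
            dm = _range_denominator(norm, rm.col_indices)
            if db <= 0 or dm <= 0:
                logger.warning(
                    "skipping rule pair with zero range denominator "
                    "(all rule columns constant in training matrix)"
                )
                continue
            out.append(WeakClassifier(rb, rm, denom_b=db, denom_m=dm))
    return out


def rule_distance(sample: np.ndarray, rule: DiagnosisRule, denom: float) -> float:
    """Range-normalized Euclidean distance from a sample to a rule vector."""
    if denom <= 0:
        raise ValueError("denominator must be positive")
    sample = np.asarray(sample, dtype=float)
    diff = sample[np.asarray(rule.col_indices)] - np.asarray(rule.rule_values)
    return float(np.linalg.norm(diff) / denom)


def weak_predict(wc: WeakClassifier, sample: np.ndarray) -> int:
    """+1 (benign) iff the benign-rule distance is strictly smaller."""
    db = rule_distance(sample, wc.benign_rule, wc.denom_b)
    dm = rule_distance(sample, wc.malignant_rule, wc.denom_m)
    return BENIGN if db < dm else MALIGNANT


def _weak_predict_matrix(weaks: list[WeakClassifier], X: np.ndarray) -> np.ndarray:
    """(n_weak, n_samples) matrix of +/-1 votes, vectorized over samples."""
    X = np.asarray(X, dtype=float)
    preds = np.empty((len(weaks), X.shape[0]), dtype=np.int8)
    for t, wc in enumerate(weaks):
        cb = np.asarray(wc.benign_rule.col_indices)
        cm = np.asarray(wc.malignant_rule.col_indices)
        db = np.linalg.norm(
            X[:, cb] - np.asarray(wc.benign_rule.rule_values), axis=1
        ) / wc.denom_b
        dm = np.linalg.norm(
            X[:, cm] - np.asarray(wc.malignant_rule.rule_values), axis=1
        ) / wc.denom_m
        preds[t] = np.where(db < dm, BENIGN, MALIGNANT)
    return preds


def adaboost_train(
    weaks: list[WeakClassifier],
    X_norm: np.ndarray,
    y: np.ndarray,
) -> StrongClassifier:
    """Discrete AdaBoost over the fixed weak-classifier pool.

    T = pool size rounds; each round picks the member with minimum weighted
    error eps_t (with replacement), weights it w_t = 0.5*ln((1-eps)/eps)
    (eps clamped away from 0 and 1), and re-weights samples.  Training
    stops early when no member beats chance on the current distribution;
    if that happens in round one, an error is raised.  Duplicate selections
    are merged by summing their weights.
    """
    if not weaks:
        raise ValueError("no weak classifiers to boost")
    y = np.asarray(y, dtype=float)
    n = y.size
    preds = _weak_predict_matrix(weaks, X_norm).astype(float)
    wrong = preds != y[np.newaxis, :]  # (T_pool, n)

    dist = np.full(n, 1.0 / n)
    summary: list[dict] = []
    weight_by_member: dict[int, float] = {}
    for t in range(len(weaks)):
        errs = wrong @ dist
        best = int(np.argmin(errs))
        eps = float(errs[best])
        if eps >= 0.5:
            if t == 0:
                raise ValueError("no better-than-chance weak classifier")
            break
        eps_c = min(max(eps, _EPS_CLAMP), 1.0 - _EPS_CLAMP)
        w = 0.5 * np.log((1.0 - eps_c) / eps_c)
        summary.append({"round": t, "selected": best, "eps": eps, "weight": w})
        weight_by_member[best] = weight_by_member.get(best, 0.0) + w
        dist = dist * np.exp(-w * y * preds[best])
        dist /= dist.sum()

    members = [(weaks[i], wt) for i, wt in weight_by_member.items()]
    return StrongClassifier(members=members, training_summary=summary)


def strong_predict(
    strong: StrongClassifier, X_norm: np.ndarray, return_margin: bool = False
):
    """Sign of the weighted vote; an exactly-zero vote reads as benign."""
    X_norm = np.atleast_2d(np.asarray(X_norm, dtype=float))
    weaks = [wc for wc, _ in strong.members]
    weights = np.asarray([w for _, w in strong.members])
    preds = _weak_predict_matrix(weaks, X_norm).astype(float)
    margin = weights @ preds
    labels = np.where(margin >= 0, BENIGN, MALIGNANT).astype(np.int8)
    if return_margin:
        return labels, margin
    return labels
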