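"""The end-to-end boosted rule classifier (scikit-learn estimator).

``fit`` runs the whole pipeline on a discrete feature table: optional
minority oversampling, min-max normalization, cocluster mining, rule
extraction, rule pairing and boosting.  ``predict`` normalizes new samples
with the training extrema (clipping) and applies the strong classifier.
"""

from __future__ import annotations

import json
import logging

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import ensemble, rule_mining
from .coclustering import MiningParams, mine
from .oversampling import DiscreteSMOTE
from .schema_io import (
    BENIGN,
    MALIGNANT,
    NormalizedMatrix,
    default_schema,
    encode_labels,
    minmax_normalize,
)

__all__ = ["IsccadClassifier"]

logger = logging.getLogger(__name__)


class IsccadClassifier(ClassifierMixin, BaseEstimator):
    """Improved-SMOTE + coclustering + AdaBoost lesion classifier.

    Parameters
    ----------
    oversample : bool, default True
        Balance the training classes with :class:`DiscreteSMOTE` before
        mining.
    k_neighbors, damping, preference, ap_max_iter
        Oversampler controls (neighbour count for modal synthesis and the
        affinity-propagation settings).
    mic : float, default 0.1
        Cut height of the per-column hierarchical clustering that seeds
        coclusters.  Values below the smallest normalized level gap (0.2
        for the 6-level echo-pattern descriptor) reduce seeding to exact
        value groups.
    delta : float, default 0.05
        Maximum allowed mean entropy score of an emitted cocluster (nats).
    min_rows, min_cols : int
        Size floors of emitted coclusters (5 rows x 3 columns by default).
    vote_threshold : float, default 0.65
        Strict winning rate a cocluster's majority label must exceed to
        become a rule.
    fallback : {"raise", "majority"}, default "raise"
        What to do when no usable rule pair or no better-than-chance weak
        classifier emerges: raise, or degrade to majority-class prediction
        (useful inside parameter grid searches).
    random_state : int or None
        Seeds the oversampler.
    """

    def __init__(
        self,
        oversample: bool = True,
        k_neighbors: int = 5,
        damping: float = 0.9,
        preference: float | None = None,
        ap_max_iter: int = 1000,
        mic: float = 0.1,
        delta: float = 0.05,
        min_rows: int = 5,
        min_cols: int = 3,
        vote_threshold: float = 0.65,
        fallback: str = "raise",
        random_state: int | None = None,
    ):
        self.oversample = oversample
        self.k_neighbors = k_neighbors
        self.damping = damping
        self.preference = preference
        self.ap_max_iter = ap_max_iter
        self.mic = mic
        self.delta = delta
        self.min_rows = min_rows
        self.min_cols = min_cols
        self.vote_threshold = vote_threshold
        self.fallback = fallback
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D discrete feature matrix")
        y_enc = encode_labels(np.asarray(y))
        if np.unique(y_enc).size < 2:
            raise ValueError("training data must contain both classes")
        self.classes_ = np.array([BENIGN, MALIGNANT], dtype=np.int8)
        self.n_features_in_ = X.shape[1]

        # normalization extrema fitted on the raw training matrix; synthetic
        # rows copy observed values so the extrema cover them too
        norm_full = minmax_normalize(X)
        self.col_min_ = norm_full.col_min
        self.col_max_ = norm_full.col_max

        X_aug, y_aug = X, y_enc
        self.oversample_report_ = None
        if self.oversample:
            seed = self.random_state if self.random_state is not None else 0
            smote = DiscreteSMOTE(
                k_neighbors=self.k_neighbors,
                damping=self.damping,
                preference=self.preference,
                max_iter=self.ap_max_iter,
                random_state=seed,
            )
            X_aug, y_aug = smote.fit_resample(X, y_enc)
            self.oversample_report_ = smote.report_

        norm_values = norm_full.transform(X_aug)
        self.norm_ = NormalizedMatrix(
            values=norm_values, col_min=self.col_min_, col_max=self.col_max_
        )

        params = MiningParams(
            mic=self.mic,
            delta=self.delta,
            min_rows=self.min_rows,
            min_cols=self.min_cols,
        )
        self.coclusters_ = mine(self.norm_, params)
        rules = rule_mining.extract_rules(
            self.coclusters_, self.norm_, y_aug, self.vote_threshold
        )
        self.rules_ = rules
        self.benign_rules_, self.malignant_rules_ = rule_mining.partition_rules(rules)

        counts = {c: int((y_enc == c).sum()) for c in (BENIGN, MALIGNANT)}
        self.majority_label_ = max(counts, key=counts.get)

        self.strong_ = None
        try:
            weaks = ensemble.pair_weak_classifiers(
                self.benign_rules_, self.malignant_rules_, self.norm_
            )
            if not weaks:
                raise ValueError("every rule pair had a zero range denominator")
            self.weak_classifiers_ = weaks
            self.strong_ = ensemble.adaboost_train(weaks, norm_values, y_aug)
        except ValueError as exc:
            self.weak_classifiers_ = []
            if self.fallback == "majority":
                logger.warning("falling back to majority-class prediction: %s", exc)
            else:
                raise
        return self

    # -------------------------------------------------------------- predict
    def _normalize(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X must have {self.n_features_in_} feature columns"
            )
        span = self.col_max_ - self.col_min_
        safe = np.where(span > 0, span, 1.0)
        out = (X - self.col_min_) / safe
        out[:, span == 0] = 0.0
        return np.clip(out, 0.0, 1.0)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        Xn = self._normalize(X)
        if self.strong_ is None:
            return np.full(Xn.shape[0], self.majority_label_, dtype=np.int8)
        return ensemble.strong_predict(self.strong_, Xn)

    def vote_margin(self, X) -> np.ndarray:
        """Weighted-vote sum per sample (positive leans benign)."""
        check_is_fitted(self, "classes_")
        Xn = self._normalize(X)
        if self.strong_ is None:
            return np.zeros(Xn.shape[0])
        _, margin = ensemble.strong_predict(self.strong_, Xn, return_margin=True)
        return margin

    # ------------------------------------------------------------ artifacts
    def to_json(self) -> str:
        """Serialize the fitted model (rules, pairs, weights) to JSON."""
        check_is_fitted(self, "classes_")

        def rule_dict(r):
            return {
                "col_indices": list(r.col_indices),
                "rule_values": list(r.rule_values),
                "label": "benign" if r.label == BENIGN else "malignant",
                "support": r.support,
                "purity": r.purity,
            }

        data = {
            "col_min": self.col_min_.tolist(),
            "col_max": self.col_max_.tolist(),
            "rules": [rule_dict(r) for r in self.rules_],
            "members": [],
            "training_summary": (
                self.strong_.training_summary if self.strong_ else []
            ),
            "majority_label": int(self.majority_label_),
        }
        if self.strong_ is not None:
            for wc, w in self.strong_.members:
                data["members"].append(
                    {
                        "benign_rule": rule_dict(wc.benign_rule),
                        "malignant_rule": rule_dict(wc.malignant_rule),
                        "denom_b": wc.denom_b,
                        "denom_m": wc.denom_m,
                        "weight": w,
                    }
                )
        return json.dumps(data, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "IsccadClassifier":
        """Rehydrate a fitted model serialized with :meth:`to_json`."""
        from .rule_mining import DiagnosisRule

        data = json.loads(text)

        def mk_rule(d):
            return DiagnosisRule(
                col_indices=tuple(d["col_indices"]),
                rule_values=tuple(d["rule_values"]),
                label=BENIGN if d["label"] == "benign" else MALIGNANT,
                support=d["support"],
                purity=d["purity"],
            )

        clf = cls()
        clf.classes_ = np.array([BENIGN, MALIGNANT], dtype=np.int8)
        clf.col_min_ = np.asarray(data["col_min"], dtype=float)
        clf.col_max_ = np.asarray(data["col_max"], dtype=float)
        clf.n_features_in_ = clf.col_min_.size
        clf.majority_label_ = int(data["majority_label"])
        clf.rules_ = [mk_rule(d) for d in data["rules"]]
        clf.benign_rules_, clf.malignant_rules_ = rule_mining.partition_rules(
            clf.rules_
        )
        members = []
        for m in data["members"]:
            wc = ensemble.WeakClassifier(
                benign_rule=mk_rule(m["benign_rule"]),
                malignant_rule=mk_rule(m["malignant_rule"]),
                denom_b=m["denom_b"],
                denom_m=m["denom_m"],
            )
            members.append((wc, m["weight"]))
        clf.weak_classifiers_ = [wc for wc, _ in members]
        clf.strong_ = (
            ensemble.StrongClassifier(
                members=members, training_summary=data["training_summary"]
            )
            if members
            else None
        )
        return clf
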