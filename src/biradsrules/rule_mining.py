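"""Turning coclusters into labelled diagnosis rules.

A mined cocluster becomes a rule by averaging each of its columns (the
rule's precondition, in normalized units) and majority-voting its rows'
labels (the postcondition).  The vote must be decisive: the winning class
must hold strictly more than 65% of the rows, a deliberately stricter
threshold than a bare majority so that rules generalize.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coclustering import Cocluster
from .schema_io import BENIGN, MALIGNANT, FeatureSchema, NormalizedMatrix

__all__ = ["DiagnosisRule", "extract_rule", "extract_rules", "partition_rules", "describe_rule"]

VOTE_THRESHOLD = 0.65


@dataclass(frozen=True)
class DiagnosisRule:
    """Feature-subset rule: per-column mean values plus a class label.

    ``rule_values`` are in normalized [0, 1] units; ``support`` is the
    number of cocluster rows behind the rule and ``purity`` the winning
    class's share of them.
    """

    col_indices: tuple[int, ...]
    rule_values: tuple[float, ...]
    label: int
    support: int
    purity: float

    def __post_init__(self) -> None:
        if self.label not in (BENIGN, MALIGNANT):
            raise ValueError("rule label must be +1 (benign) or -1 (malignant)")


def extract_rule(
    cc: Cocluster,
    norm: NormalizedMatrix | np.ndarray,
    labels: np.ndarray,
    vote_threshold: float = VOTE_THRESHOLD,
) -> DiagnosisRule | None:
    """Average a cocluster's columns and label it by majority vote.

    Returns ``None`` when the winning class's count is not strictly greater
    than ``vote_threshold * support`` (an exactly-threshold vote discards).
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else np.asarray(norm)
    rows = np.asarray(cc.row_indices)
    cols = np.asarray(cc.col_indices)
    sub_labels = np.asarray(labels)[rows]
    n = rows.size
    nb = int((sub_labels == BENIGN).sum())
    nm = int((sub_labels == MALIGNANT).sum())
    winner = max(nb, nm)
    if winner <= vote_threshold * n:
        return None
    label = BENIGN if nb >= nm else MALIGNANT
    means = values[np.ix_(rows, cols)].mean(axis=0)
    return DiagnosisRule(
        col_indices=tuple(int(j) for j in cols),
        rule_values=tuple(float(v) for v in means),
        label=label,
        support=n,
        purity=winner / n,
    )


def extract_rules(
    coclusters,
    norm: NormalizedMatrix | np.ndarray,
    labels: np.ndarray,
    vote_threshold: float = VOTE_THRESHOLD,
) -> list[DiagnosisRule]:
    out = []
    for cc in coclusters:
        rule = extract_rule(cc, norm, labels, vote_threshold)
        if rule is not None:
            out.append(rule)
    return out


def partition_rules(
    rules,
) -> tuple[list[DiagnosisRule], list[DiagnosisRule]]:
    """Stable split into (benign rules, malignant rules)."""
    benign = [r for r in rules if r.label == BENIGN]
    malignant = [r for r in rules if r.label == MALIGNANT]
    return benign, malignant


def describe_rule(
    rule: DiagnosisRule,
    schema: FeatureSchema,
    norm: NormalizedMatrix,
) -> dict:
    """Human-readable form: de-normalize values back to raw score scale."""
    raw = []
    for j, v in zip(rule.col_indices, rule.rule_values):
        lo, hi = norm.col_min[j], norm.col_max[j]
        raw_val = v * (hi - lo) + lo
        raw.append(
            {
                "feature": schema.names[j],
                "normalized_value": v,
                "raw_value": float(raw_val),
                "nearest_level": int(round(raw_val)),
            }
        )
    return {
        "label": "benign" if rule.label == BENIGN else "malignant",
        "support": rule.support,
        "purity": rule.purity,
        "conditions": raw,
    }
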