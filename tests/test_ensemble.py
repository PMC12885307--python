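import math

import numpy as np
import pytest

from biradsrules.ensemble import (
    StrongClassifier,
    WeakClassifier,
    adaboost_train,
    pair_weak_classifiers,
    rule_distance,
    strong_predict,
    weak_predict,
)
from biradsrules.rule_mining import DiagnosisRule
from biradsrules.schema_io import BENIGN, MALIGNANT


def rule(cols, values, label):
    return DiagnosisRule(
        col_indices=tuple(cols),
        rule_values=tuple(values),
        label=label,
        support=10,
        purity=1.0,
    )


RB = rule((0, 1, 2), (0.0, 0.0, 0.0), BENIGN)
RM = rule((3, 4, 5), (1.0, 1.0, 1.0), MALIGNANT)


def training_matrix():
    # 14 columns, each spanning {0,1} so every range denominator is sqrt(c)
    rng = np.random.default_rng(0)
    m = rng.integers(0, 2, (20, 14)).astype(float)
    m[0] = 0.0
    m[1] = 1.0  # force full span
    return m


class TestPairing:
    def test_all_lk_pairs(self):
        m = training_matrix()
        weaks = pair_weak_classifiers([RB] * 3, [RM] * 2, m)
        assert len(weaks) == 6

    def test_single_pair(self):
        weaks = pair_weak_classifiers([RB], [RM], training_matrix())
        assert len(weaks) == 1
        assert weaks[0].denom_b == pytest.approx(math.sqrt(3))

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError, match="benign"):
            pair_weak_classifiers([], [RM], training_matrix())
        with pytest.raises(ValueError, match="malignant"):
            pair_weak_classifiers([RB], [], training_matrix())

    def test_zero_denominator_pair_skipped(self):
        m = training_matrix()
        m[:, 6:9] = 0.5  # constant columns
        flat = rule((6, 7, 8), (0.5, 0.5, 0.5), MALIGNANT)
        weaks = pair_weak_classifiers([RB], [flat, RM], m)
        assert len(weaks) == 1  # the constant-column pair is dropped


class TestRuleDistance:
    def test_identity_zero(self):
        s = np.zeros(14)
        assert rule_distance(s, RB, math.sqrt(3)) == 0.0

    def test_unit_cube_diagonal(self):
        # rule (0,0,0) over 3 binary columns, sample (1,1,1), ranges all 1
        s = np.zeros(14)
        s[[0, 1, 2]] = 1.0
        assert rule_distance(s, RB, math.sqrt(3)) == pytest.approx(1.0)

    def test_linear_in_inverse_denominator(self):
        s = np.full(14, 0.7)
        d1 = rule_distance(s, RB, 1.0)
        d2 = rule_distance(s, RB, 2.0)
        assert d2 == pytest.approx(d1 / 2)


class TestWeakPredict:
    def _wc(self):
        return WeakClassifier(RB, RM, denom_b=math.sqrt(3), denom_m=math.sqrt(3))

    def test_on_benign_rule(self):
        s = np.zeros(14)  # exactly on benign rule, far from malignant
        assert weak_predict(self._wc(), s) == BENIGN

    def test_on_malignant_rule(self):
        s = np.zeros(14)
        s[[3, 4, 5]] = 1.0
        assert weak_predict(self._wc(), s) == MALIGNANT

    def test_tie_is_malignant(self):
        # equidistant from both rules -> conservative malignant call
        s = np.zeros(14)
        s[[0, 1, 2]] = 0.5
        s[[3, 4, 5]] = 0.5
        assert weak_predict(self._wc(), s) == MALIGNANT

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            s = rng.random(14)
            a = WeakClassifier(RB, RM, denom_b=1.0, denom_m=2.0)
            b = WeakClassifier(RB, RM, denom_b=3.0, denom_m=6.0)
            assert weak_predict(a, s) == weak_predict(b, s)


def planted_training_data(n=40, seed=0):
    """Benign samples near the benign rule, malignant near the malignant."""
    rng = np.random.default_rng(seed)
    X = rng.random((n, 14)) * 0.2 + 0.4
    y = np.array([BENIGN] * (n // 2) + [MALIGNANT] * (n // 2), dtype=float)
    X[: n // 2, [0, 1, 2]] = rng.random((n // 2, 3)) * 0.2
    X[n // 2 :, [3, 4, 5]] = 0.8 + rng.random((n // 2, 3)) * 0.2
    return X, y


class TestAdaboost:
    def test_closed_form_round_weight(self):
        # eps = 0.25 -> w = 0.5*ln(3)
        assert 0.5 * math.log((1 - 0.25) / 0.25) == pytest.approx(
            0.5 * math.log(3)
        )
        X, y = planted_training_data()
        wc = WeakClassifier(RB, RM, math.sqrt(3), math.sqrt(3))
        strong = adaboost_train([wc], X, y)
        (m,) = strong.members
        eps = strong.training_summary[0]["eps"]
        expected_w = 0.5 * math.log((1 - max(eps, 1e-10)) / max(eps, 1e-10))
        assert m[1] == pytest.approx(expected_w)

    def test_perfect_weak_reproduced(self):
        X, y = planted_training_data()
        wc = WeakClassifier(RB, RM, math.sqrt(3), math.sqrt(3))
        strong = adaboost_train([wc], X, y)
        np.testing.assert_array_equal(strong_predict(strong, X), y.astype(int))

    def test_training_error_bounds(self):
        X, y = planted_training_data(seed=3)
        # a pool of noisy variants of the two rules
        rng = np.random.default_rng(4)
        pool = []
        for _ in range(8):
            rb = rule((0, 1, 2), tuple(rng.random(3) * 0.3), BENIGN)
            rm = rule((3, 4, 5), tuple(0.7 + rng.random(3) * 0.3), MALIGNANT)
            pool.append(WeakClassifier(rb, rm, math.sqrt(3), math.sqrt(3)))
        strong = adaboost_train(pool, X, y)
        pred = strong_predict(strong, X)
        err = float((pred != y).mean())
        bound = float(
            np.prod(
                [
                    2 * math.sqrt(s["eps"] * (1 - s["eps"]))
                    for s in strong.training_summary
                ]
            )
        )
        assert err <= bound + 1e-12
        # never worse than the best single pool member
        singles = []
        for wc in pool:
            p = np.array([weak_predict(wc, x) for x in X])
            singles.append(float((p != y).mean()))
        assert err <= min(singles) + 1e-12

    def test_all_weaks_at_chance_rejected(self):
        X, y = planted_training_data()
        # a rule pair orthogonal to the signal: columns that are pure noise
        bad_b = rule((6, 7, 8), (0.0, 0.0, 0.0), BENIGN)
        bad_m = rule((6, 7, 8), (0.0, 0.0, 0.0), MALIGNANT)
        wc = WeakClassifier(bad_b, bad_m, 1.0, 1.0)
        with pytest.raises(ValueError, match="chance"):
            adaboost_train([wc], X, y)

    def test_distribution_stays_normalized(self):
        # conservation is internal; assert via the summary eps values being
        # proper probabilities in every round
        X, y = planted_training_data(seed=5)
        wc = WeakClassifier(RB, RM, math.sqrt(3), math.sqrt(3))
        strong = adaboost_train([wc, wc], X, y)
        for s in strong.training_summary:
            assert 0.0 <= s["eps"] < 0.5


class TestStrongPredict:
    def test_weighted_vote(self):
        wc_b = WeakClassifier(RB, RM, math.sqrt(3), math.sqrt(3))
        # a flipped classifier: swaps the rule roles so it votes the other way
        wc_m = WeakClassifier(
            rule((3, 4, 5), (1.0, 1.0, 1.0), BENIGN),
            rule((0, 1, 2), (0.0, 0.0, 0.0), MALIGNANT),
            math.sqrt(3),
            math.sqrt(3),
        )
        s = np.zeros((1, 14))  # wc_b votes benign, wc_m votes malignant
        strong = StrongClassifier(members=[(wc_b, 2.0), (wc_m, 1.0)])
        assert strong_predict(strong, s)[0] == BENIGN  # 2 - 1 > 0

    def test_zero_margin_reads_benign(self):
        wc = WeakClassifier(RB, RM, math.sqrt(3), math.sqrt(3))
        flipped = WeakClassifier(
            rule((3, 4, 5), (1.0, 1.0, 1.0), BENIGN),
            rule((0, 1, 2), (0.0, 0.0, 0.0), MALIGNANT),
            math.sqrt(3),
            math.sqrt(3),
        )
        s = np.zeros((1, 14))
        strong = StrongClassifier(members=[(wc, 1.0), (flipped, 1.0)])
        labels, margin = strong_predict(strong, s, return_margin=True)
        assert margin[0] == pytest.approx(0.0)
        assert labels[0] == BENIGN

    def test_unanimous_vote(self):
        wc = WeakClassifier(RB, RM, math.sqrt(3), math.sqrt(3))
        strong = StrongClassifier(members=[(wc, 0.5), (wc, 1.5)])
        s = np.zeros((1, 14))
        assert strong_predict(strong, s)[0] == BENIGN
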