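"""Discrimination metrics, reclassification and survival curves."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mcci import (
    SeparationError,
    c_statistic,
    compare_c,
    compare_indices,
    continuous_nri,
    fit_risk_model,
    km_curve,
    score_cohort,
    WeightTable,
)
from mcci.validation import RiskModelSpec


def brute_force_auc(pred, outcome):
    """Pairwise enumeration oracle: P(event > nonevent) + 0.5 P(tie)."""
    pos = [p for p, y in zip(pred, outcome) if y]
    neg = [p for p, y in zip(pred, outcome) if not y]
    total = 0.0
    for a, b in itertools.product(pos, neg):
        total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestCStatistic:
    def test_perfect_separation(self):
        c, lo, hi = c_statistic([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert c == 1.0

    def test_all_ties(self):
        c, lo, hi = c_statistic([0.5] * 6, [1, 1, 0, 0, 0, 0])
        assert c == 0.5

    def test_hand_enumerated_case(self):
        # pairs: (.9,.5)+, (.9,.1)+, (.4,.5)-, (.4,.1)+ -> 3/4
        c, _, _ = c_statistic([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0])
        assert c == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        pred = rng.integers(0, 5, n) / 4.0  # coarse grid to force ties
        outcome = rng.random(n) < 0.4
        if outcome.all() or not outcome.any():
            outcome[0] = not outcome[0]
        c, lo, hi = c_statistic(pred, outcome)
        assert c == pytest.approx(brute_force_auc(pred, outcome), abs=1e-12)
        assert lo <= c <= hi

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        pred = rng.random(200)
        outcome = rng.random(200) < 0.3
        c, _, _ = c_statistic(pred, outcome)
        assert c == pytest.approx(roc_auc_score(outcome, pred), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        pred = rng.random(100)
        outcome = rng.random(100) < 0.3
        base = c_statistic(pred, outcome)
        for f in (lambda x: 3 * x + 1, np.exp, lambda x: x**3):
            assert c_statistic(f(pred), outcome)[0] == pytest.approx(base[0])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            c_statistic([0.1, 0.2], [1, 1])


class TestCompareC:
    def test_self_comparison(self):
        pred = [0.9, 0.4, 0.5, 0.1]
        res = compare_c(pred, pred, [1, 1, 0, 0])
        assert res.difference == 0 and res.p_value == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(40), rng.random(40)
        y = rng.random(40) < 0.5
        r1 = compare_c(a, b, y)
        r2 = compare_c(b, a, y)
        assert r1.difference == pytest.approx(-r2.difference)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_small_case_against_placement_oracle(self):
        # n=6: recompute the paired placement components by hand
        a = np.array([0.9, 0.6, 0.3, 0.8, 0.2, 0.1])
        b = np.array([0.7, 0.2, 0.5, 0.6, 0.4, 0.3])
        y = np.array([1, 1, 1, 0, 0, 0], bool)

        def placements(pred):
            pos, neg = pred[y], pred[~y]
            v01 = np.array(
                [np.mean([1.0 if p > q else 0.5 if p == q else 0.0 for q in neg]) for p in pos]
            )
            v10 = np.array(
                [np.mean([1.0 if p > q else 0.5 if p == q else 0.0 for p in pos]) for q in neg]
            )
            return v01, v10

        va01, va10 = placements(a)
        vb01, vb10 = placements(b)
        auc_a, auc_b = va01.mean(), vb01.mean()
        m, n = 3, 3
        s01 = np.cov(np.vstack([va01, vb01]))
        s10 = np.cov(np.vstack([va10, vb10]))
        S = s01 / m + s10 / n
        var = S[0, 0] + S[1, 1] - 2 * S[0, 1]
        res = compare_c(a, b, y)
        assert res.difference == pytest.approx(auc_a - auc_b, abs=1e-12)
        assert res.se == pytest.approx(np.sqrt(var), abs=1e-12)


class TestContinuousNri:
    def test_no_reclassification(self):
        pred = [0.1, 0.2, 0.3, 0.4]
        nri = continuous_nri(pred, pred, [1, 0, 1, 0])
        assert nri.event.estimate == 0
        assert nri.nonevent.estimate == 0
        assert nri.total.estimate == 0

    def test_maximal_improvement(self):
        old = [0.5, 0.5, 0.5, 0.5]
        new = [0.9, 0.8, 0.1, 0.2]  # every death up, every survivor down
        nri = continuous_nri(old, new, [1, 1, 0, 0])
        assert nri.event.estimate == 100
        assert nri.nonevent.estimate == 100
        assert nri.total.estimate == 200

    def test_direct_counting_oracle(self):
        # 3 deaths: 2 up, 1 down -> 33.3%; 4 survivors: 1 up, 3 down -> 50%
        old = [0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5]
        new = [0.6, 0.7, 0.4, 0.6, 0.4, 0.3, 0.2]
        y = [1, 1, 1, 0, 0, 0, 0]
        nri = continuous_nri(old, new, y)
        assert nri.event.estimate == pytest.approx(100 / 3)
        assert nri.nonevent.estimate == pytest.approx(50.0)
        assert nri.total.estimate == pytest.approx(100 / 3 + 50.0)

    def test_total_identity_and_swap_negation(self):
        rng = np.random.default_rng(11)
        old, new = rng.random(60), rng.random(60)
        y = rng.random(60) < 0.35
        nri = continuous_nri(old, new, y)
        assert nri.total.estimate == pytest.approx(
            nri.event.estimate + nri.nonevent.estimate, abs=1e-12
        )
        swapped = continuous_nri(new, old, y)
        for comp in ("event", "nonevent", "total"):
            assert getattr(swapped, comp).estimate == pytest.approx(
                -getattr(nri, comp).estimate, abs=1e-12
            )

    def test_bootstrap_ci_contains_estimate(self):
        rng = np.random.default_rng(2)
        old, new = rng.random(120), rng.random(120)
        y = rng.random(120) < 0.4
        nri = continuous_nri(old, new, y, bootstrap=200, seed=5)
        assert nri.total.ci_low <= nri.total.estimate <= nri.total.ci_high

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            continuous_nri([0.1], [0.2], [1])


class TestRiskModels:
    def test_constant_score_reduces_to_intercept_only(self, small_cohort):
        probs = fit_risk_model(small_cohort, np.zeros(len(small_cohort)), "model1_univariate")
        assert np.allclose(probs, small_cohort["death"].mean())

    def test_perfectly_separating_score_raises(self, small_cohort):
        score = small_cohort["death"].astype(float) * 100
        with pytest.raises(SeparationError):
            fit_risk_model(small_cohort, score, "model1_univariate")

    def test_fitted_probabilities_monotone_in_score(self, small_cohort):
        scores = score_cohort(small_cohort, WeightTable.builtin("mcci_a"))
        probs = fit_risk_model(small_cohort, scores, "model1_univariate")
        assert ((probs > 0) & (probs < 1)).all()
        order = np.argsort(scores.to_numpy())
        assert (np.diff(probs[order]) >= -1e-12).all()

    def test_model2_uses_covariates(self, small_cohort):
        scores = score_cohort(small_cohort, WeightTable.builtin("mcci_a"))
        p1 = fit_risk_model(small_cohort, scores, "model1_univariate")
        p2 = fit_risk_model(small_cohort, scores, "model2_adjusted")
        # adjusted model must differ (age drives mortality in the generator)
        assert not np.allclose(p1, p2)

    def test_unknown_model_id(self):
        with pytest.raises(ValueError):
            RiskModelSpec(model_id="model3")


class TestKmCurve:
    def test_no_censoring_closed_form(self):
        curves = km_curve([1, 2, 3, 4], [1, 1, 0, 0], ["g"] * 4)
        g = curves["g"].set_index("month")
        assert g.loc[1, "survival"] == pytest.approx(0.75)
        assert g.loc[2, "survival"] == pytest.approx(0.5)

    def test_all_censored(self):
        curves = km_curve([5, 6, 7], [0, 0, 0], ["g"] * 3)
        assert (curves["g"]["survival"] == 1.0).all()

    def test_hand_computed_product_limit(self):
        # (t,event): (1,1),(2,0),(2,1),(3,1),(4,0)
        # S(1)=4/5; t=2: 4 at risk, 1 death -> S=3/5; t=3: 2 at risk -> S=3/10
        curves = km_curve([1, 2, 2, 3, 4], [1, 0, 1, 1, 0], ["g"] * 5)
        g = curves["g"].set_index("month")
        assert g.loc[1, "survival"] == pytest.approx(0.8)
        assert g.loc[2, "survival"] == pytest.approx(0.6)
        assert g.loc[3, "survival"] == pytest.approx(0.3)
        assert g.loc[1, "at_risk"] == 5
        assert g.loc[2, "at_risk"] == 4

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(4)
        t = rng.integers(1, 30, 50)
        curves = km_curve(t, np.ones(50, bool), ["g"] * 50)
        g = curves["g"]
        for _, row in g.iterrows():
            assert row["survival"] == pytest.approx(np.mean(t > row["month"]))

    def test_groups_separate_and_empty_group_omitted(self):
        curves = km_curve([1, 2, 3, 4], [1, 1, 0, 0], ["a", "a", "b", "b"])
        assert set(curves) == {"a", "b"}

    def test_zero_followup_rejected(self):
        with pytest.raises(ValueError):
            km_curve([0, 1], [1, 0], ["g", "g"])


def test_compare_indices_report_structure(small_cohort):
    s_old = score_cohort(small_cohort, WeightTable.builtin("original_cci"))
    s_new = score_cohort(small_cohort, WeightTable.builtin("mcci_a"))
    report = compare_indices(small_cohort, s_old, s_new).to_dict()
    for model in ("model1_univariate", "model2_adjusted"):
        block = report[model]
        assert 0 < block["CCI"]["c"] < 1
        assert 0 < block["mCCI-A"]["c"] < 1
        lo, hi = block["CCI"]["c_ci"]
        assert lo <= block["CCI"]["c"] <= hi
        cnri = block["cnri"]
        assert cnri["total"]["estimate"] == pytest.approx(
            cnri["event"]["estimate"] + cnri["nonevent"]["estimate"], abs=1e-9
        )
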