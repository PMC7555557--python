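import math

import numpy as np
import pandas as pd
import pytest

from conftest import toy_cohort
from dopplercad.cohort import cohort_from_frame
from dopplercad.errors import ValidationError
from dopplercad.evaluation import roc
from dopplercad.ultraboost import (
    UltraBoostEnsemble,
    boost_once,
    train_lr,
    train_nb,
)


class TestNaiveBayes:
    def _six_case(self):
        df = pd.DataFrame({"birads": ["A", "A", "A", "B", "B", "B"]})
        y = np.array([0, 0, 0, 1, 1, 1])
        return df, y

    def test_hand_computed_posterior_with_add_one_smoothing(self):
        # equal priors; P(A|mal) = (0+1)/(3+2) = 0.2, P(A|ben) = (3+1)/(3+2)
        df, y = self._six_case()
        model = train_nb(df, y, np.ones(6), ("birads",))
        assert model.predict_proba({"birads": "A"}) == pytest.approx(0.2)
        assert model.predict_proba({"birads": "B"}) == pytest.approx(0.8)

    def test_missing_category_falls_back_to_prior(self):
        df, y = self._six_case()
        w = np.array([1, 1, 1, 1, 1, 2.0])  # malignant prior 4/7
        model = train_nb(df, y, w, ("birads",))
        assert model.predict_proba({"birads": np.nan}) == pytest.approx(4 / 7)

    def test_weight_equals_duplication(self):
        df, y = self._six_case()
        w = np.array([2.0, 1, 1, 1, 1, 1])
        weighted = train_nb(df, y, w, ("birads",))
        df_dup = pd.concat([df.iloc[[0]], df], ignore_index=True)
        y_dup = np.concatenate([[0], y])
        duplicated = train_nb(df_dup, y_dup, np.ones(7), ("birads",))
        assert weighted.priors == pytest.approx(duplicated.priors)
        for c in (0, 1):
            assert weighted.cond["birads"][c] == pytest.approx(
                duplicated.cond["birads"][c]
            )

    def test_single_class_rejected(self):
        df = pd.DataFrame({"birads": ["A", "B"]})
        with pytest.raises(ValidationError):
            train_nb(df, np.array([1, 1]), np.ones(2), ("birads",))


class TestLogisticRegression:
    def test_separable_feature_gives_monotone_probability(self):
        df = pd.DataFrame({"x": [-2.0, -1.0, -0.5, 0.5, 1.0, 2.0]})
        y = np.array([0, 0, 0, 1, 1, 1])
        model = train_lr(df, y, np.ones(6), ("x",))
        p = model.predict_proba_many(df)
        assert np.all(np.diff(p) > 0)
        scored = pd.DataFrame({"mass_id": range(6), "label": y, "p": p})
        assert roc(scored).auc == 1.0

    def test_constant_feature_dropped(self):
        df = pd.DataFrame({"x": [-1.0, -1.0, 1.0, 1.0], "flat": [3.0] * 4})
        model = train_lr(df, np.array([0, 0, 1, 1]), np.ones(4), ("x", "flat"))
        assert model.dropped == ("flat",)
        assert model.features == ("x",)

    def test_symmetric_classes_give_zero_intercept(self):
        df = pd.DataFrame({"x": [-1.0, 1.0]})
        model = train_lr(df, np.array([0, 1]), np.ones(2), ("x",))
        assert model.intercept == pytest.approx(0.0, abs=1e-3)

    def test_effect_sizes_are_directionless_odds_ratios(self):
        df = pd.DataFrame({"up": [-1.0, -0.5, 0.5, 1.0],
                           "down": [1.0, 0.5, -0.5, -1.0]})
        model = train_lr(df, np.array([0, 0, 1, 1]), np.ones(4), ("up", "down"),
                         ridge=1.0)
        es = model.effect_sizes()
        assert es["up"][0] >= 1.0 and es["up"][1] == "+"
        assert es["down"][0] >= 1.0 and es["down"][1] == ""

    def test_non_finite_input_rejected(self):
        df = pd.DataFrame({"x": [np.nan, 1.0]})
        with pytest.raises(ValidationError):
            train_lr(df, np.array([0, 1]), np.ones(2), ("x",))


def _mixed_cohort(birads, bd, labels):
    from dopplercad.cohort import NUMERIC_FEATURES

    df = pd.DataFrame({
        "mass_id": [f"m{i}" for i in range(len(labels))],
        "age": 50.0,
        "BD": bd,
        "label": labels,
    })
    for feat in NUMERIC_FEATURES:  # constants; dropped by the logistic stage
        if feat not in df.columns:
            df[feat] = 0.0
    df["birads"] = pd.array(birads, dtype="Int64")
    return cohort_from_frame(df)


class TestBoostOnce:
    def test_uninformative_stage1_yields_stage2_output(self):
        # single BI-RADS category: NB predicts the (equal) prior 0.5 for all,
        # counts as malignant, weighted error 0.5 -> alpha1 = 0
        coh = _mixed_cohort([4, 4, 4, 4], [1.0, 2.0, 8.0, 9.0], [0, 0, 1, 1])
        ens = boost_once(coh, feature_set="clinical+gs")
        assert ens.stages[0].alpha == 0.0
        p2 = ens.stages[1].model.predict_proba_many(coh.df)
        np.testing.assert_allclose(ens.predict_proba_many(coh.df), p2)

    def test_four_case_weight_update_hand_oracle(self):
        # stage 1 (NB on BI-RADS) misclassifies exactly the malignant B case:
        # eps = 1/4, alpha = ln(3)/2; weights 1/4 * exp(+-alpha), normalized,
        # give 1/2 for the miss and 1/6 for each correct case
        coh = _mixed_cohort([3, 3, 4, 4], [0.0, 0.0, 0.0, 0.0], [0, 0, 0, 1])
        ens = boost_once(coh, feature_set="birads")
        st = ens.stages[0]
        assert st.epsilon == pytest.approx(0.25)
        assert st.alpha == pytest.approx(0.5 * math.log(3))
        np.testing.assert_allclose(ens.weight_history[0],
                                   [1 / 6, 1 / 6, 1 / 6, 1 / 2])

    def test_numeric_only_degenerates_to_logistic(self):
        from dopplercad.cohort import NUMERIC_FEATURES

        df = pd.DataFrame({
            "mass_id": list("abcd"), "age": 50.0,
            "BD": [1.0, 2.0, 8.0, 9.0], "label": [0, 0, 1, 1],
        })
        for feat in NUMERIC_FEATURES:
            if feat not in df.columns:
                df[feat] = 0.0
        coh = cohort_from_frame(df)  # BI-RADS entirely missing
        ens = boost_once(coh, feature_set="clinical+gs")
        assert len(ens.stages) == 1
        lr = train_lr(coh.df, coh.labels, np.ones(4), ("age", "BD"))
        # age is constant and dropped; predictions match the bare logistic fit
        np.testing.assert_allclose(ens.predict_proba_many(coh.df),
                                   lr.predict_proba_many(coh.df))

    def test_six_case_convex_combination_oracle(self):
        # the ensemble probability must equal the alpha-weighted convex
        # combination of the constituent probabilities, recomputed by hand
        coh = _mixed_cohort([3, 3, 4, 4, 5, 5],
                            [20.0, 15.0, 14.0, 9.0, 8.0, 2.0],
                            [0, 0, 0, 1, 1, 1])
        ens = boost_once(coh, feature_set="clinical+gs")
        p1 = ens.stages[0].model.predict_proba_many(coh.df)
        p2 = ens.stages[1].model.predict_proba_many(coh.df)
        a1, a2 = ens.stages[0].alpha, ens.stages[1].alpha
        expected = (a1 * p1 + a2 * p2) / (a1 + a2)
        np.testing.assert_allclose(ens.predict_proba_many(coh.df), expected)
        assert np.all((expected >= 0) & (expected <= 1))

    def test_epsilon_clamped_alpha_finite_on_perfect_stage(self):
        coh = _mixed_cohort([2, 2, 5, 5], [0.0] * 4, [0, 0, 1, 1])
        ens = boost_once(coh, feature_set="birads")
        assert ens.stages[0].epsilon == pytest.approx(1e-6)
        assert math.isfinite(ens.stages[0].alpha)

    def test_case_weights_sum_to_one(self):
        coh = _mixed_cohort([3, 4, 4, 5], [1.0, 2.0, 8.0, 9.0], [0, 0, 1, 1])
        ens = boost_once(coh, feature_set="all")
        assert ens.case_weights.sum() == pytest.approx(1.0)

    def test_affine_feature_rescaling_invariance(self):
        coh = _mixed_cohort([3, 3, 4, 4, 5, 5],
                            [20.0, 15.0, 14.0, 9.0, 8.0, 2.0],
                            [0, 0, 0, 1, 1, 1])
        scaled = coh.df.copy()
        scaled["BD"] = scaled["BD"] * 1000.0 + 5.0
        coh2 = cohort_from_frame(scaled)
        e1 = boost_once(coh, feature_set="clinical+gs")
        e2 = boost_once(coh2, feature_set="clinical+gs")
        np.testing.assert_allclose(e1.predict_proba_many(coh.df),
                                   e2.predict_proba_many(coh2.df), atol=1e-6)

    def test_json_round_trip(self):
        coh = _mixed_cohort([3, 3, 4, 4, 5, 5],
                            [20.0, 15.0, 14.0, 9.0, 8.0, 2.0],
                            [0, 0, 0, 1, 1, 1])
        ens = boost_once(coh, feature_set="all")
        back = UltraBoostEnsemble.from_json(ens.to_json())
        np.testing.assert_allclose(back.predict_proba_many(coh.df),
                                   ens.predict_proba_many(coh.df))
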