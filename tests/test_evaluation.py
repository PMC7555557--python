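import numpy as np
import pandas as pd
import pytest

from dopplercad.cohort import NUMERIC_FEATURES, cohort_from_frame
from dopplercad.errors import ValidationError
from dopplercad.evaluation import (
    delong_paired,
    drop_rate_curve,
    loocv,
    prune,
    roc,
    spec_at_sensitivity,
    youden_index,
)


def scored(labels, ps, ids=None):
    return pd.DataFrame({
        "mass_id": ids or [f"m{i}" for i in range(len(labels))],
        "label": labels,
        "p": ps,
    })


def pair_count_auc(labels, ps):
    """Exhaustive concordant-pair oracle: ties count one half."""
    pos = [p for y, p in zip(labels, ps) if y == 1]
    neg = [p for y, p in zip(labels, ps) if y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        r = roc(scored([0, 0, 1, 1], [0.1, 0.2, 0.3, 0.4]))
        assert r.auc == 1.0
        assert r.youden == 1.0

    def test_chance_level_from_pair_counting(self):
        # concordant pairs: (.3,.1),(.2,.1) -> 2 of 4
        labels, ps = [0, 0, 1, 1], [0.1, 0.4, 0.3, 0.2]
        assert pair_count_auc(labels, ps) == 0.5
        assert roc(scored(labels, ps)).auc == 0.5

    @pytest.mark.parametrize("seed", range(6))
    def test_auc_matches_exhaustive_pair_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        labels = np.zeros(n, dtype=int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        # quantized scores force ties into the comparison
        ps = np.round(rng.uniform(size=n), 1)
        assert roc(scored(labels, ps)).auc == pytest.approx(
            pair_count_auc(labels, ps)
        )

    def test_monotone_transform_invariance(self, rng):
        labels = rng.integers(0, 2, size=20)
        labels[:2] = [0, 1]
        ps = rng.uniform(size=20)
        a = roc(scored(labels, ps)).auc
        b = roc(scored(labels, np.exp(3 * ps))).auc
        assert a == pytest.approx(b)

    def test_label_flip_complements_auc(self, rng):
        labels = np.array([0] * 8 + [1] * 7)
        ps = rng.permutation(np.linspace(0.01, 0.99, 15))  # tie-free
        a = roc(scored(labels, ps)).auc
        b = roc(scored(1 - labels, ps)).auc
        assert a + b == pytest.approx(1.0)

    def test_youden_tie_breaks_toward_sensitivity(self):
        # thresholds 0.2 and 0.4 both give J = 0.5; the lower threshold has
        # Se = 1.0 and must win
        r = roc(scored([0, 1, 0, 1], [0.1, 0.2, 0.3, 0.4]))
        assert r.youden == pytest.approx(0.5)
        assert r.se_at_youden == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc(scored([1, 1], [0.2, 0.8]))


class TestSpecAtSensitivity:
    def _scores_64_pos(self, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.array([1] * 64 + [0] * 95)
        ps = rng.permutation(np.linspace(0.001, 0.999, 159))
        return scored(labels, ps)

    def test_attainable_sensitivities_with_64_positives(self):
        # smallest k/64 >= 0.95 is 61/64 = 95.3%; >= 0.98 is 63/64 = 98.4%
        s = self._scores_64_pos()
        se95, _ = spec_at_sensitivity(s, 0.95)
        se98, _ = spec_at_sensitivity(s, 0.98)
        assert se95 == pytest.approx(61 / 64)
        assert se98 == pytest.approx(63 / 64)

    def test_zero_sensitivity_gives_full_specificity(self):
        se, sp = spec_at_sensitivity(self._scores_64_pos(), 0.0)
        assert se == 0.0
        assert sp == 1.0

    def test_min_se_above_one_rejected(self):
        with pytest.raises(ValidationError):
            spec_at_sensitivity(self._scores_64_pos(), 1.0001)


class TestDelongPaired:
    def test_identical_scores_give_p_one(self, rng):
        labels = rng.integers(0, 2, size=20)
        labels[:2] = [0, 1]
        s = scored(labels, rng.uniform(size=20))
        assert delong_paired(s, s) == 1.0

    def test_perfect_vs_antiperfect(self):
        labels = [0] * 5 + [1] * 5
        ps = np.linspace(0.05, 0.95, 10)
        a = scored(labels, ps)
        b = scored(labels, 1 - ps)
        assert roc(a).auc - roc(b).auc == pytest.approx(1.0)
        assert delong_paired(a, b) < 0.01

    def test_symmetry_and_order_invariance(self, rng):
        labels = np.array([0] * 10 + [1] * 8)
        a = scored(labels, rng.uniform(size=18))
        b = scored(labels, rng.uniform(size=18))
        p_ab = delong_paired(a, b)
        assert p_ab == pytest.approx(delong_paired(b, a))
        perm = rng.permutation(18)
        a_perm = a.iloc[perm].reset_index(drop=True)
        b_perm = b.iloc[perm].reset_index(drop=True)
        assert delong_paired(a_perm, b_perm) == pytest.approx(p_ab)

    def test_case_mismatch_rejected(self, rng):
        labels = [0, 0, 1, 1]
        a = scored(labels, [0.1, 0.2, 0.8, 0.9])
        b = scored(labels, [0.1, 0.2, 0.8, 0.9], ids=["x0", "x1", "x2", "x3"])
        with pytest.raises(ValidationError):
            delong_paired(a, b)


class TestPrune:
    def test_zero_rate_is_identity(self, rng):
        s = scored([0, 1] * 5, rng.uniform(size=10))
        res = prune(s, 0.0)
        assert res.n_pruned == 0
        assert len(res.retained) == 10

    def test_twenty_percent_of_159_removes_32(self, rng):
        labels = np.array([0] * 95 + [1] * 64)
        ps = rng.permutation(np.linspace(0.01, 0.99, 159))  # distinct |p - .5|?
        s = scored(labels, ps)
        # ensure all-distinct confidence by nudging mirrored pairs
        s["p"] = s["p"] + np.linspace(0, 1e-6, 159)
        assert s["p"].sub(0.5).abs().nunique() == 159
        res = prune(s, 0.20)
        assert res.n_pruned == 32  # round(0.20 * 159) = 32

    def test_boundary_ties_pruned_together(self):
        ps = [0.5, 0.52, 0.48, 0.6, 0.4, 0.7, 0.3, 0.8, 0.2, 0.9]
        # budget 2 but |p-0.5| = 0.02 ties at ranks 2-3 -> 3 pruned
        s = scored([0, 1] * 5, ps)
        res = prune(s, 0.20)
        assert res.n_pruned == 3

    def test_confident_classifier_unchanged_when_budget_zero(self):
        s = scored([0, 0, 1, 1], [0.01, 0.02, 0.98, 0.99])
        res = prune(s, 0.1)  # budget = round(0.4) = 0
        assert res.n_pruned == 0

    def test_single_class_remainder_flagged_undefined(self):
        s = scored([0, 0, 0, 1], [0.1, 0.1, 0.1, 0.5])
        res = prune(s, 0.25)
        assert not res.summary.defined

    def test_invalid_rate_rejected(self):
        s = scored([0, 1], [0.2, 0.8])
        with pytest.raises(ValidationError):
            prune(s, 1.0)


class TestDropRateCurve:
    def test_n_pruned_nondecreasing(self, rng):
        s = scored(rng.integers(0, 2, size=40).tolist(), rng.uniform(size=40))
        s.loc[0, "label"], s.loc[1, "label"] = 0, 1
        curve = drop_rate_curve(s, [0.0, 0.1, 0.2, 0.3])
        counts = [r.n_pruned for r in curve]
        assert counts == sorted(counts)

    def test_perfect_scores_stay_perfect(self):
        s = scored([0] * 10 + [1] * 10,
                   list(np.linspace(0.0, 0.3, 10)) + list(np.linspace(0.7, 1.0, 10)))
        for r in drop_rate_curve(s, [0.0, 0.2, 0.4]):
            assert r.summary.auc == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_overlapping_gaussian_scores_auc_nondecreasing(self, seed):
        # oracle resimulation: pruning indeterminate cases of an
        # overlapping-Gaussian score mixture cannot hurt AUC much
        rng = np.random.default_rng(seed)
        n = 400
        labels = np.array([0] * n + [1] * n)
        raw = np.concatenate([rng.normal(-1, 1, n), rng.normal(1, 1, n)])
        ps = 1 / (1 + np.exp(-raw))
        s = scored(labels.tolist(), ps)
        aucs = [r.summary.auc for r in drop_rate_curve(s, [0.0, 0.2, 0.4, 0.6])]
        assert all(b >= a - 0.01 for a, b in zip(aucs, aucs[1:]))


class TestLoocv:
    def _cohort(self, bd, labels, birads=None):
        df = pd.DataFrame({
            "mass_id": [f"m{i}" for i in range(len(labels))],
            "age": np.linspace(40, 60, len(labels)),
            "BD": bd, "label": labels,
        })
        for feat in NUMERIC_FEATURES:
            if feat not in df.columns:
                df[feat] = 0.0
        if birads is not None:
            df["birads"] = pd.array(birads, dtype="Int64")
        return cohort_from_frame(df)

    def test_separable_cohort_scores_on_correct_side(self):
        coh = self._cohort([1.0, 2.0, 3.0, 11.0, 12.0, 13.0],
                           [1, 1, 1, 0, 0, 0])
        out = loocv(coh, feature_set="clinical+gs", smote=False)
        assert len(out) == 6
        for _, row in out.iterrows():
            if row["label"] == 1:
                assert row["p"] > 0.5
            else:
                assert row["p"] < 0.5

    def test_one_score_per_real_case_and_no_synthetic_scored(self):
        rng = np.random.default_rng(0)
        n = 24
        coh = self._cohort(rng.normal(size=n),
                           [0] * 16 + [1] * 8,
                           birads=rng.integers(0, 6, size=n).tolist())
        out = loocv(coh, feature_set="all", smote=True, seed=3, smote_k=3)
        assert len(out) == n
        assert sorted(out["mass_id"]) == sorted(coh.df["mass_id"])
        assert not out["mass_id"].str.startswith("syn").any()

    def test_degenerate_fold_scored_at_prior(self):
        # removing the single malignant case leaves a one-class fold
        coh = self._cohort([1.0, 2.0, 3.0, 9.0], [0, 0, 0, 1])
        out = loocv(coh, feature_set="clinical+gs", smote=False)
        assert len(out) == 4
        lone = out[out["mass_id"] == "m3"]["p"].iloc[0]
        assert lone == pytest.approx(0.0)  # prior of an all-benign fold

    def test_determinism(self):
        rng = np.random.default_rng(1)
        coh = self._cohort(rng.normal(size=12), [0] * 8 + [1] * 4)
        a = loocv(coh, feature_set="clinical+gs", smote=True, seed=5, smote_k=3)
        b = loocv(coh, feature_set="clinical+gs", smote=True, seed=5, smote_k=3)
        pd.testing.assert_frame_equal(a, b)


def test_youden_index_arithmetic():
    assert youden_index(0.8, 0.9) == pytest.approx(0.7)
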