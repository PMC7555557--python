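"""One-step boosted heterogeneous ensemble: naive Bayes + logistic regression.

Two already-strong constituents are combined by a single AdaBoost-style
boost rather than by iterated boosting of a weak learner: the categorical
attribute (BI-RADS) is routed to a weighted naive Bayes classifier, the
numeric attributes (age, grayscale, color-Doppler) to a case-weighted
ridge-stabilized logistic regression on standardized features.  Stage 1 is
trained on uniform case weights; its weighted training error sets its stage
weight ``alpha = 0.5 * ln((1-eps)/eps)`` (eps clamped to [1e-6, 0.5]) and
reweights the cases (up for misclassified, down for correct) before stage 2
trains.  The ensemble's malignancy probability is the alpha-weighted convex
combination of the two constituent probabilities, keeping a continuous
score for ROC analysis and confidence-based pruning.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .cohort import FEATURE_SETS, Cohort
from .errors import ValidationError

__all__ = [
    "NaiveBayesModel",
    "LogisticModel",
    "BoostStage",
    "UltraBoostEnsemble",
    "train_nb",
    "train_lr",
    "boost_once",
    "predict_proba",
]

EPS_CLAMP = (1e-6, 0.5)
RIDGE = 1e-8


@dataclass
class NaiveBayesModel:
    """Weighted categorical naive Bayes with Laplace add-1 smoothing.

    Weights act as fractional case counts (a case of weight 2 is exactly two
    duplicated unit-weight cases).  A missing category is skipped in the
    likelihood product, so a query with every attribute missing falls back
    to the class priors.
    """

    attributes: tuple[str, ...]
    priors: dict[int, float]
    # cond[attr][cls][category] = smoothed P(category | cls)
    cond: dict[str, dict[int, dict[str, float]]]
    categories: dict[str, tuple[str, ...]]

    def predict_proba(self, record: pd.Series | dict) -> float:
        """P(malignant | categorical attributes of the record)."""
        log_post = {c: math.log(self.priors[c]) for c in (0, 1)}
        for attr in self.attributes:
            val = record.get(attr) if isinstance(record, dict) else record[attr]
            if pd.isna(val):
                continue  # missing attribute: omitted from the product
            key = _cat_key(val)
            if key not in self.categories[attr]:
                continue  # unseen category carries no evidence
            for c in (0, 1):
                log_post[c] += math.log(self.cond[attr][c][key])
        m = max(log_post.values())
        z = sum(math.exp(v - m) for v in log_post.values())
        return math.exp(log_post[1] - m) / z

    def predict_proba_many(self, df: pd.DataFrame) -> np.ndarray:
        return np.array([self.predict_proba(row) for _, row in df.iterrows()])


def _cat_key(val) -> str:
    """Canonical string key of a category value (3, 3.0 and "3" coincide)."""
    try:
        f = float(val)
        if f == int(f):
            return str(int(f))
    except (TypeError, ValueError):
        pass
    return str(val)


def train_nb(df: pd.DataFrame, y: np.ndarray, w: np.ndarray,
             attributes: tuple[str, ...]) -> NaiveBayesModel:
    """Train weighted categorical naive Bayes.

    Priors are weighted class frequencies; conditionals are Laplace-smoothed
    weighted category frequencies over the categories observed in training.
    Cases with a missing attribute value are omitted from that attribute's
    frequency table.
    """
    y = np.asarray(y)
    w = np.asarray(w, dtype=float)
    if len({0, 1} - set(np.unique(y[w > 0]))) > 0:
        raise ValidationError("naive Bayes needs both classes with nonzero weight")
    wsum = {c: float(w[y == c].sum()) for c in (0, 1)}
    total = wsum[0] + wsum[1]
    priors = {c: wsum[c] / total for c in (0, 1)}
    cond: dict[str, dict[int, dict[str, float]]] = {}
    categories: dict[str, tuple[str, ...]] = {}
    for attr in attributes:
        col = df[attr]
        present = col.notna().to_numpy()
        keys = np.array([_cat_key(v) for v in col[present]])
        cats = tuple(sorted(set(keys.tolist())))
        categories[attr] = cats
        k = len(cats)
        cond[attr] = {}
        for c in (0, 1):
            sel = present & (y == c)
            sel_keys = np.array([_cat_key(v) for v in col[sel]]) if sel.any() else np.array([])
            wc = w[sel]
            denom = float(wc.sum()) + k
            cond[attr][c] = {
                cat: (float(wc[sel_keys == cat].sum()) + 1.0) / denom for cat in cats
            }
    return NaiveBayesModel(attributes=tuple(attributes), priors=priors,
                           cond=cond, categories=categories)


@dataclass
class LogisticModel:
    """Case-weighted logistic regression on standardized numeric features.

    Standardization parameters (weighted mean/SD) come from the training
    cases only; zero-variance features are dropped with a warning flag.
    A small ridge penalty keeps separable problems finite.
    """

    features: tuple[str, ...]
    coef: np.ndarray
    intercept: float
    mean: np.ndarray
    sd: np.ndarray
    dropped: tuple[str, ...] = ()

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd

    def predict_proba_many(self, df: pd.DataFrame) -> np.ndarray:
        X = df[list(self.features)].to_numpy(dtype=float)
        if not np.isfinite(X).all():
            raise ValidationError("non-finite numeric feature at prediction time")
        z = self._standardize(X) @ self.coef + self.intercept
        return expit(z)

    def predict_proba(self, record: pd.Series | dict) -> float:
        df = pd.DataFrame([record])
        return float(self.predict_proba_many(df)[0])

    def effect_sizes(self) -> dict[str, tuple[float, str]]:
        """Standardized directionless odds ratios.

        Per feature: ``exp(|coef|)`` — the multiplicative change in odds for
        a one-SD increase — tagged "+" when the increase raises the odds of
        malignancy and "" when it raises the odds of benignity.
        """
        return {
            f: (float(np.exp(abs(c))), "+" if c > 0 else "")
            for f, c in zip(self.features, self.coef)
        }


def train_lr(df: pd.DataFrame, y: np.ndarray, w: np.ndarray,
             features: tuple[str, ...], ridge: float = RIDGE) -> LogisticModel:
    """Train weighted ridge-stabilized logistic regression."""
    y = np.asarray(y)
    w = np.asarray(w, dtype=float)
    if len({0, 1} - set(np.unique(y[w > 0]))) > 0:
        raise ValidationError("logistic regression needs both classes")
    X = df[list(features)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("non-finite numeric feature in training data")
    wn = w / w.sum()
    mean = wn @ X
    var = wn @ (X - mean) ** 2
    keep = var > 1e-12
    dropped = tuple(f for f, k in zip(features, keep) if not k)
    kept = tuple(f for f, k in zip(features, keep) if k)
    if not kept:
        raise ValidationError("no numeric feature with nonzero variance")
    mean, sd = mean[keep], np.sqrt(var[keep])
    Z = (X[:, keep] - mean) / sd
    clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=2000,
                             tol=1e-10)
    clf.fit(Z, y, sample_weight=w)
    return LogisticModel(features=kept, coef=clf.coef_[0].copy(),
                         intercept=float(clf.intercept_[0]), mean=mean, sd=sd,
                         dropped=dropped)


@dataclass
class BoostStage:
    model: NaiveBayesModel | LogisticModel
    alpha: float
    epsilon: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.alpha):
            raise ValidationError("stage alpha must be finite")


@dataclass
class UltraBoostEnsemble:
    """Two-stage boosted ensemble producing a malignancy probability."""

    stages: list[BoostStage]
    case_weights: np.ndarray = field(repr=False)  # weights after reweighting, sum 1
    feature_set: str = "all"
    # normalized weight vector after each stage's reweighting (diagnostics)
    weight_history: list[np.ndarray] = field(default_factory=list, repr=False)

    def predict_proba_many(self, df: pd.DataFrame) -> np.ndarray:
        ps = [st.model.predict_proba_many(df) for st in self.stages]
        alphas = [st.alpha for st in self.stages]
        total = sum(alphas)
        if total == 0:
            # both stages uninformative at their training weights: fall back
            # to the stage with the smaller training error
            best = min(range(len(self.stages)), key=lambda i: self.stages[i].epsilon)
            return ps[best]
        return sum(a * p for a, p in zip(alphas, ps)) / total

    def predict_proba(self, record: pd.Series | dict) -> float:
        return float(self.predict_proba_many(pd.DataFrame([record]))[0])

    def to_json(self) -> str:
        blobs = []
        for st in self.stages:
            m = st.model
            if isinstance(m, NaiveBayesModel):
                blob = {"kind": "nb", "attributes": m.attributes,
                        "priors": {str(k): v for k, v in m.priors.items()},
                        "cond": {a: {str(c): t for c, t in d.items()}
                                 for a, d in m.cond.items()},
                        "categories": m.categories}
            else:
                blob = {"kind": "lr", "features": m.features,
                        "coef": m.coef.tolist(), "intercept": m.intercept,
                        "mean": m.mean.tolist(), "sd": m.sd.tolist(),
                        "dropped": m.dropped}
            blobs.append({"model": blob, "alpha": st.alpha, "epsilon": st.epsilon})
        return json.dumps({"stages": blobs, "feature_set": self.feature_set,
                           "case_weights": self.case_weights.tolist()}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "UltraBoostEnsemble":
        payload = json.loads(text)
        stages = []
        for b in payload["stages"]:
            mb = b["model"]
            if mb["kind"] == "nb":
                model = NaiveBayesModel(
                    attributes=tuple(mb["attributes"]),
                    priors={int(k): v for k, v in mb["priors"].items()},
                    cond={a: {int(c): t for c, t in d.items()}
                          for a, d in mb["cond"].items()},
                    categories={a: tuple(v) for a, v in mb["categories"].items()},
                )
            else:
                model = LogisticModel(
                    features=tuple(mb["features"]), coef=np.asarray(mb["coef"]),
                    intercept=mb["intercept"], mean=np.asarray(mb["mean"]),
                    sd=np.asarray(mb["sd"]), dropped=tuple(mb["dropped"]),
                )
            stages.append(BoostStage(model=model, alpha=b["alpha"],
                                     epsilon=b["epsilon"]))
        return cls(stages=stages,
                   case_weights=np.asarray(payload["case_weights"]),
                   feature_set=payload["feature_set"])


def _stage_alpha(epsilon: float) -> tuple[float, float]:
    eps = min(max(epsilon, EPS_CLAMP[0]), EPS_CLAMP[1])
    return 0.5 * math.log((1.0 - eps) / eps), eps


def boost_once(cohort: Cohort, feature_set: str = "all",
               order: tuple[str, str] = ("nb", "lr"),
               ridge: float = RIDGE) -> UltraBoostEnsemble:
    """Train the two constituents with a single boost step between them.

    Stage 1 trains on uniform weights; its weighted 0.5-threshold error sets
    ``alpha_1`` and reweights cases (``w *= exp(+-alpha_1)``, up for
    misclassified) before stage 2 trains on the new weights.  When one
    attribute group is empty the ensemble degenerates to the other
    constituent alone.
    """
    if feature_set not in FEATURE_SETS:
        raise ValidationError(f"unknown feature set {feature_set!r}")
    cat_attrs, num_attrs = FEATURE_SETS[feature_set]
    df, y = cohort.df, cohort.labels
    n = len(df)
    if n < 2 or len(np.unique(y)) < 2:
        raise ValidationError("training needs both classes")

    def trainer(kind: str):
        if kind == "nb":
            if not cat_attrs or df[list(cat_attrs)].isna().all().all():
                return None
            return lambda w: train_nb(df, y, w, cat_attrs)
        if not num_attrs:
            return None
        return lambda w: train_lr(df, y, w, num_attrs, ridge=ridge)

    trainers = [(kind, trainer(kind)) for kind in order]
    trainers = [(k, t) for k, t in trainers if t is not None]
    if not trainers:
        raise ValidationError("no usable attributes for the requested feature set")

    w = np.full(n, 1.0 / n)
    stages: list[BoostStage] = []
    history: list[np.ndarray] = []
    for _, train in trainers:
        model = train(w * n)  # constituents take weights as case counts
        p = model.predict_proba_many(df)
        wrong = (p >= 0.5).astype(int) != y
        alpha, eps = _stage_alpha(float(w[wrong].sum()))
        stages.append(BoostStage(model=model, alpha=alpha, epsilon=eps))
        w = w * np.exp(np.where(wrong, alpha, -alpha))
        w = w / w.sum()
        history.append(w.copy())
    return UltraBoostEnsemble(stages=stages, case_weights=w,
                              feature_set=feature_set, weight_history=history)


def predict_proba(model: UltraBoostEnsemble, case: pd.Series | dict) -> float:
    """Malignancy probability of one case (diagnosis malignant iff p >= 0.5)."""
    return model.predict_proba(case)
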