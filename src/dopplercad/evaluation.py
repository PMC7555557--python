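"""LOOCV scoring, ROC analysis, paired AUC comparison, drop-rate pruning.

Each real case is scored by a model trained on all the other real cases
(leave-one-out), with SMOTE synthetics regenerated inside each training
fold so they never leak into testing.  ROC summaries use the Mann-Whitney
AUC (ties counted 1/2) with DeLong standard errors and confidence
intervals, the Youden operating point (ties broken toward sensitivity,
since missing a cancer costs more than a false alarm), and specificities at
fixed high-sensitivity thresholds.  Low-confidence predictions — those with
probability nearest the 0.5 decision threshold — can be pruned at a given
drop rate, cases tied at the boundary confidence pruned together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import FEATURE_SETS, NUMERIC_FEATURES, Cohort, impute_age
from .errors import ValidationError
from .resampling import SmoteConfig, smote_balance
from .ultraboost import boost_once

__all__ = [
    "RocSummary",
    "PruneResult",
    "loocv",
    "roc",
    "youden_index",
    "spec_at_sensitivity",
    "delong_paired",
    "prune",
    "drop_rate_curve",
    "fold_seed",
]


@dataclass
class RocSummary:
    auc: float
    se: float
    ci95: tuple[float, float]
    youden: float
    se_at_youden: float
    sp_at_youden: float
    threshold_at_youden: float
    sp_at_fixed_se: dict[float, tuple[float, float]] = field(default_factory=dict)
    defined: bool = True

    def as_dict(self) -> dict:
        return {
            "auc": self.auc, "se": self.se, "ci95": list(self.ci95),
            "youden": self.youden, "se_at_youden": self.se_at_youden,
            "sp_at_youden": self.sp_at_youden,
            "threshold_at_youden": self.threshold_at_youden,
            "sp_at_fixed_se": {str(k): list(v)
                               for k, v in self.sp_at_fixed_se.items()},
            "defined": self.defined,
        }


@dataclass
class PruneResult:
    drop_rate: float
    n_pruned: int
    retained: pd.DataFrame
    summary: RocSummary | None


def fold_seed(master_seed: int, fold: int) -> int:
    """Deterministic per-fold seed fanned out from a master seed."""
    return int((master_seed * 100_003 + fold * 7919 + 1) % (2**31 - 1))


def loocv(cohort: Cohort, feature_set: str = "all", smote: bool = False,
          seed: int = 0, smote_k: int = 5,
          order: tuple[str, str] = ("nb", "lr")) -> pd.DataFrame:
    """Leave-one-out scores for every real case.

    Fold i trains on all real cases except i — after fold-local age
    imputation and (optionally) fold-local SMOTE balancing — and scores
    case i.  Returns a frame with one row per real case: ``mass_id``,
    ``label``, ``p`` and ``confidence_distance`` = |p - 0.5|.  A fold whose
    training set degenerates to a single class scores its case at the
    training prevalence.
    """
    if feature_set not in FEATURE_SETS:
        raise ValidationError(f"unknown feature set {feature_set!r}")
    real = cohort.df[~cohort.df["synthetic"]].reset_index(drop=True)
    n = len(real)
    if n < 4:
        raise ValidationError("LOOCV needs at least 4 real cases")
    if real["label"].nunique() < 2:
        raise ValidationError("LOOCV needs both classes")
    _, num_attrs = FEATURE_SETS[feature_set]
    records = []
    for i in range(n):
        train_df = real.drop(index=i)
        test = real.iloc[i].copy()
        train = Cohort(train_df)
        obs = train.df["age"].dropna()
        if obs.empty:
            raise ValidationError("no observed ages in a training fold")
        train = impute_age(train)
        if pd.isna(test["age"]):
            test["age"] = float(obs.mean())
        try:
            if smote:
                smote_feats = tuple(num_attrs) if num_attrs else NUMERIC_FEATURES
                train = smote_balance(
                    train, SmoteConfig(k=smote_k, seed=fold_seed(seed, i)),
                    features=smote_feats,
                )
            model = boost_once(train, feature_set=feature_set, order=order)
            p = model.predict_proba(test)
        except ValidationError:
            # degenerate fold: score at the training prevalence
            p = float(train.labels.mean())
        records.append({"mass_id": real.iloc[i]["mass_id"],
                        "label": int(real.iloc[i]["label"]), "p": p})
    out = pd.DataFrame(records)
    out["confidence_distance"] = (out["p"] - 0.5).abs()
    return out


# ---------------------------------------------------------------------------
# DeLong machinery (midrank form)

def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """AUC plus the DeLong structural components V10 (per positive) and V01."""
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    r_all = _midrank(allv)
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return auc, v10, v01


def _split_scores(scored: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    y = scored["label"].to_numpy()
    p = scored["p"].to_numpy(dtype=float)
    pos, neg = p[y == 1], p[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("ROC analysis needs both classes")
    return pos, neg


def _auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    auc, v10, v01 = _delong_components(pos, neg)
    m, n = len(pos), len(neg)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def youden_index(se: float, sp: float) -> float:
    """J = sensitivity + specificity - 1 (fractions in, fraction out)."""
    return se + sp - 1.0


def roc(scored: pd.DataFrame,
        fixed_se: tuple[float, ...] = (0.95, 0.98)) -> RocSummary:
    """ROC summary of a scored case set.

    AUC is the Mann-Whitney statistic (ties 1/2); SE and the 95% CI come
    from the DeLong variance.  The Youden point maximizes Se + Sp - 1, ties
    resolved toward the higher-sensitivity threshold.
    """
    pos, neg = _split_scores(scored)
    auc, var = _auc_variance(pos, neg)
    se_auc = math.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - 1.96 * se_auc), min(1.0, auc + 1.96 * se_auc))
    # operating points: predicted malignant iff p >= threshold
    thresholds = np.unique(np.concatenate([pos, neg]))
    best = (-np.inf, 0.0, 0.0, 0.0)  # J, Se, Sp, threshold
    for t in thresholds[::-1]:  # descending: Se nondecreasing as we scan
        se = float((pos >= t).mean())
        sp = float((neg < t).mean())
        j = youden_index(se, sp)
        if j >= best[0]:  # >= keeps the later (higher-Se) tie
            best = (j, se, sp, float(t))
    j, se_y, sp_y, thr = best
    fixed = {}
    for target in fixed_se:
        if target > 1:
            raise ValidationError("fixed sensitivity must be a fraction <= 1")
        fixed[target] = spec_at_sensitivity(scored, target)
    return RocSummary(auc=float(auc), se=float(se_auc), ci95=ci,
                      youden=float(j), se_at_youden=se_y, sp_at_youden=sp_y,
                      threshold_at_youden=thr, sp_at_fixed_se=fixed)


def spec_at_sensitivity(scored: pd.DataFrame,
                        min_se: float) -> tuple[float, float]:
    """(attained Se, Sp) at the largest threshold whose Se >= ``min_se``."""
    if min_se > 1:
        raise ValidationError("min_se must be a fraction <= 1")
    pos, neg = _split_scores(scored)
    observed = np.unique(np.concatenate([pos, neg]))
    # include a supremum threshold above all scores (Se = 0, Sp = 1)
    thresholds = np.concatenate([observed, [observed[-1] + 1.0]])
    for t in thresholds[::-1]:
        se = float((pos >= t).mean())
        if se >= min_se:
            return se, float((neg < t).mean())
    return 1.0, float((neg < thresholds[0]).mean())


def delong_paired(scored_a: pd.DataFrame, scored_b: pd.DataFrame) -> float:
    """Two-sided DeLong p-value for the paired AUC difference.

    Both score sets must cover the same cases with the same labels (any
    case order).  Identical score sets give p = 1 exactly.
    """
    a = scored_a.sort_values("mass_id").reset_index(drop=True)
    b = scored_b.sort_values("mass_id").reset_index(drop=True)
    if (len(a) != len(b)
            or not (a["mass_id"].to_numpy() == b["mass_id"].to_numpy()).all()
            or not (a["label"].to_numpy() == b["label"].to_numpy()).all()):
        raise ValidationError("paired DeLong requires identical cases and labels")
    y = a["label"].to_numpy()
    pa, na = a["p"].to_numpy(float)[y == 1], a["p"].to_numpy(float)[y == 0]
    pb, nb = b["p"].to_numpy(float)[y == 1], b["p"].to_numpy(float)[y == 0]
    if len(pa) == 0 or len(na) == 0:
        raise ValidationError("paired DeLong needs both classes")
    auc_a, v10_a, v01_a = _delong_components(pa, na)
    auc_b, v10_b, v01_b = _delong_components(pb, nb)
    m, n = len(pa), len(na)
    delta = auc_a - auc_b
    if m < 2 or n < 2:
        return 1.0 if delta == 0 else 0.0
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return 1.0 if abs(delta) < 1e-12 else 0.0
    z = delta / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def prune(scored: pd.DataFrame, drop_rate: float) -> PruneResult:
    """Remove the least-confident fraction of cases and re-summarize.

    The budget is ``round(drop_rate * n)`` (half rounds up); the budget
    cases with smallest |p - 0.5| are removed, and any further cases tied at
    the boundary confidence are pruned together.  If the remainder is
    single-class, the ROC summary is flagged undefined.
    """
    if not (0.0 <= drop_rate < 1.0):
        raise ValidationError("drop_rate must lie in [0, 1)")
    n = len(scored)
    budget = math.floor(drop_rate * n + 0.5)  # round half up
    df = scored.copy()
    df["confidence_distance"] = (df["p"] - 0.5).abs()
    if budget == 0:
        return PruneResult(drop_rate, 0, df, roc(df))
    order = df["confidence_distance"].sort_values(kind="mergesort").index
    boundary = df.loc[order[budget - 1], "confidence_distance"]
    pruned_idx = df.index[df["confidence_distance"] <= boundary]
    retained = df.drop(index=pruned_idx)
    n_pruned = len(pruned_idx)
    try:
        summary = roc(retained) if len(retained) else None
    except ValidationError:
        summary = None
    if summary is None:
        summary = RocSummary(auc=float("nan"), se=float("nan"),
                             ci95=(float("nan"), float("nan")),
                             youden=float("nan"), se_at_youden=float("nan"),
                             sp_at_youden=float("nan"),
                             threshold_at_youden=float("nan"), defined=False)
    return PruneResult(drop_rate, n_pruned, retained, summary)


def drop_rate_curve(scored: pd.DataFrame, rates) -> list[PruneResult]:
    """Prune at each rate of a grid; n_pruned is nondecreasing in the rate."""
    return [prune(scored, float(r)) for r in rates]
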