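"""Per-mass case records: ROI aggregation, age imputation, CSV round trips.

A cohort is a table of cases, one row per solid mass, holding the clinical
attributes (age in years, BI-RADS ultrasound category 0-5, both possibly
missing), the nine grayscale features averaged across the mass's ROIs, the
two color-Doppler features, the biopsy label (0 = benign, 1 = malignant), a
nonnegative case weight, and a flag marking SMOTE-synthesized cases.

BI-RADS is kept as an unordered categorical attribute: it is routed only to
the naive Bayes constituent, which skips missing categories in its
likelihood product, so missing BI-RADS is never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cd_features import CD_FEATURE_NAMES
from .errors import ValidationError
from .gs_features import GS_FEATURE_NAMES

__all__ = [
    "Cohort",
    "NUMERIC_FEATURES",
    "CATEGORICAL_FEATURES",
    "COHORT_COLUMNS",
    "FEATURE_SETS",
    "aggregate_rois",
    "impute_age",
    "read_cohort_csv",
    "write_cohort_csv",
    "cohort_from_frame",
]

NUMERIC_FEATURES = ("age",) + GS_FEATURE_NAMES + CD_FEATURE_NAMES
CATEGORICAL_FEATURES = ("birads",)
COHORT_COLUMNS = (
    "mass_id", "age", "birads",
    "AVI", "AVM", "BD", "MS", "AR", "DWR", "RV", "ENS", "tortuosity",
    "VI", "VFA", "label", "weight", "synthetic",
)

# Feature-set selectors used throughout training/evaluation: each maps to
# (categorical attributes, numeric attributes).
FEATURE_SETS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "birads": (("birads",), ()),
    "clinical": (("birads",), ("age",)),
    "clinical+gs": (("birads",), ("age",) + GS_FEATURE_NAMES),
    "clinical+cd": (("birads",), ("age",) + CD_FEATURE_NAMES),
    "all": (("birads",), NUMERIC_FEATURES),
    # numeric-only: degenerates the ensemble to the logistic constituent
    "numeric": ((), NUMERIC_FEATURES),
}


@dataclass
class Cohort:
    """A table of per-mass cases backed by a pandas DataFrame."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort missing columns: {missing}")
        labels = df["label"]
        if labels.isna().any() or not labels.isin([0, 1]).all():
            bad = sorted(set(labels[~labels.isin([0, 1])].tolist()))
            raise ValidationError(f"labels must be 0/1; found {bad}")
        df["label"] = df["label"].astype(int)
        df["weight"] = df["weight"].astype(float)
        if (df["weight"] < 0).any():
            raise ValidationError("case weights must be nonnegative")
        df["synthetic"] = df["synthetic"].astype(bool)
        df["birads"] = df["birads"].astype("Int64")
        ok_birads = df["birads"].dropna().isin(range(6))
        if not ok_birads.all():
            raise ValidationError("BI-RADS categories must lie in 0..5")
        self.df = df.reset_index(drop=True)[list(COHORT_COLUMNS)]

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy()

    @property
    def real(self) -> "Cohort":
        """The non-synthetic cases."""
        return Cohort(self.df[~self.df["synthetic"]])

    def class_counts(self) -> tuple[int, int]:
        """(n_benign, n_malignant)."""
        return int((self.labels == 0).sum()), int((self.labels == 1).sum())

    def numeric(self, features=NUMERIC_FEATURES) -> pd.DataFrame:
        return self.df[list(features)].astype(float)


def cohort_from_frame(df: pd.DataFrame) -> Cohort:
    """Build a Cohort from a partial frame, defaulting weight/synthetic."""
    df = df.copy()
    if "weight" not in df.columns:
        df["weight"] = 1.0
    if "synthetic" not in df.columns:
        df["synthetic"] = False
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return Cohort(df)


def aggregate_rois(rows: pd.DataFrame) -> pd.Series:
    """Per-mass numeric features: arithmetic mean across the mass's ROI rows.

    Clinical practice draws one to ten ROIs per mass; each numeric feature
    is averaged across them.
    """
    if len(rows) == 0:
        raise ValidationError("no ROI rows to aggregate")
    if len(rows) > 10:
        raise ValidationError("more than 10 ROIs per mass")
    numeric_cols = [c for c in rows.columns if c in NUMERIC_FEATURES or
                    c in GS_FEATURE_NAMES or c in CD_FEATURE_NAMES]
    return rows[numeric_cols].astype(float).mean(axis=0)


def impute_age(cohort: Cohort) -> Cohort:
    """Replace missing ages by the mean of the observed ages.

    Observed ages are left untouched, so the observed-age mean and count
    are preserved.
    """
    ages = cohort.df["age"]
    observed = ages.dropna()
    if observed.empty:
        raise ValidationError("cannot impute age: no observed ages")
    if not ages.isna().any():
        return Cohort(cohort.df)
    df = cohort.df.copy()
    df["age"] = ages.fillna(float(observed.mean()))
    return Cohort(df)


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a cohort CSV; missing values become empty cells."""
    df = cohort.df.copy()
    df["synthetic"] = df["synthetic"].astype(int)
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> Cohort:
    """Read a cohort CSV written by :func:`write_cohort_csv` (lossless)."""
    df = pd.read_csv(path, dtype={"mass_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort CSV missing columns: {missing}")
    if df["label"].isna().any():
        raise ValidationError("cohort CSV contains missing labels")
    return Cohort(df)
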