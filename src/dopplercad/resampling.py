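"""SMOTE minority oversampling, applied inside training folds only.

Synthetic minority cases are convex combinations of a real minority case
and one of its k nearest minority neighbors (Euclidean distance in
standardized numeric feature space).  The categorical BI-RADS attribute is
copied from the seed case, never interpolated; synthetic cases carry
``synthetic=True`` so the evaluation layer can guarantee they never reach a
test fold.  The cohort is balanced to class equality: the number of
synthetic cases equals majority minus minority count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .cohort import NUMERIC_FEATURES, Cohort
from .errors import ValidationError

__all__ = ["SmoteConfig", "smote_balance"]


@dataclass
class SmoteConfig:
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("SMOTE k must be >= 1")


def smote_balance(train: Cohort, cfg: SmoteConfig | None = None,
                  features=NUMERIC_FEATURES) -> Cohort:
    """Balance a training cohort to class equality with SMOTE.

    Deterministic for a fixed ``cfg.seed``.  Requires minority count > k;
    an already balanced cohort is returned unchanged (0 synthetics).
    """
    cfg = cfg or SmoteConfig()
    n_ben, n_mal = train.class_counts()
    if n_ben == 0 or n_mal == 0:
        raise ValidationError("SMOTE requires both classes present")
    if n_ben == n_mal:
        return Cohort(train.df)
    minority_label = 1 if n_mal < n_ben else 0
    n_needed = abs(n_ben - n_mal)
    minority = train.df[train.df["label"] == minority_label].reset_index(drop=True)
    m = len(minority)
    if m <= cfg.k:
        raise ValidationError(
            f"minority count {m} <= k={cfg.k}; use a smaller k"
        )
    X = minority[list(features)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("SMOTE requires finite numeric features "
                              "(impute age first)")
    # neighbors in standardized space (SD from the full training cohort)
    full = train.df[list(features)].to_numpy(dtype=float)
    mean, sd = full.mean(axis=0), full.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    nn = NearestNeighbors(n_neighbors=cfg.k + 1).fit(Z)
    neigh = nn.kneighbors(Z, return_distance=False)[:, 1:]  # drop self

    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, m, size=n_needed)
    picks = rng.integers(0, cfg.k, size=n_needed)
    us = rng.uniform(0.0, 1.0, size=n_needed)

    rows = []
    for j, (i, kpick, u) in enumerate(zip(seeds, picks, us)):
        i_nn = neigh[i, kpick]
        # convex combination in original units equals one in standardized units
        x_new = X[i] + u * (X[i_nn] - X[i])
        row = minority.iloc[i].copy()
        row[list(features)] = x_new
        row["mass_id"] = f"syn{j}_{minority.iloc[i]['mass_id']}"
        row["synthetic"] = True
        row["weight"] = 1.0
        rows.append(row)
    out = pd.concat([train.df, pd.DataFrame(rows)], ignore_index=True)
    return Cohort(out)
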