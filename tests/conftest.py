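import numpy as np
import pandas as pd
import pytest

from dopplercad.cohort import cohort_from_frame
from dopplercad.image_io import RoiMask


def disc_mask(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return RoiMask((rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2)


def ellipse_mask(shape, center, a_lateral, b_axial):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return RoiMask(
        ((rr - center[0]) / b_axial) ** 2 + ((cc - center[1]) / a_lateral) ** 2 <= 1.0
    )


def toy_cohort(features, labels, birads=None, mass_ids=None):
    """Minimal cohort: one numeric feature column 'BD' plus optional BI-RADS."""
    n = len(labels)
    df = pd.DataFrame(
        {
            "mass_id": mass_ids or [f"m{i}" for i in range(n)],
            "age": 50.0,
            "BD": np.asarray(features, dtype=float),
            "label": labels,
        }
    )
    if birads is not None:
        df["birads"] = pd.array(birads, dtype="Int64")
    return cohort_from_frame(df)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
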