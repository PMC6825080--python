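from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from abustex.features import FEATURE_NAMES
from abustex.preprocessing import QuantizedROI
from abustex.synthetic import (
    CohortSpec,
    ROISample,
    default_class_params,
    generate_cohort,
)


def make_sample(image: np.ndarray, mask: np.ndarray | None = None, **kwargs) -> ROISample:
    image = np.asarray(image)
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    defaults = dict(class_label="benign", patient_id="p0", image_id="p0-img0")
    defaults.update(kwargs)
    return ROISample(image=image, mask=np.asarray(mask, dtype=bool), **defaults)


def quantized(levels: np.ndarray, Ng: int) -> QuantizedROI:
    levels = np.asarray(levels, dtype=np.int32)
    return QuantizedROI(levels=levels, Ng=Ng, n_pixels=int((levels > 0).sum()))


@pytest.fixture(scope="session")
def small_cohort():
    """A small fully separated cohort (shared across tests; read-only)."""
    spec = CohortSpec(
        class_params=default_class_params(),
        n_patients_per_class=3,
        images_per_lesion=(2, 4),
        image_shape=(64, 64),
        lesion_radius_px=(8, 14),
        images_per_tissue=2,
        seed=42,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def feature_table(small_cohort):
    from abustex.features import extract_table

    return extract_table(small_cohort)


def synthetic_feature_frame(
    rng: np.random.Generator,
    n_patients_per_class: int = 12,
    images_per_patient: int = 4,
    n_informative: int = 5,
    shift: float = 2.0,
) -> pd.DataFrame:
    """Feature-table-shaped frame with a few informative columns.

    Classes malignant/benign differ by ``shift`` on the first
    ``n_informative`` features (with a shared patient-level random
    effect); all other columns are pure noise.
    """
    rows = []
    for label, offset in (("malignant", shift), ("benign", 0.0)):
        for p in range(n_patients_per_class):
            patient_effect = rng.normal(scale=0.3, size=47)
            for i in range(images_per_patient):
                x = rng.normal(size=47) + patient_effect
                x[:n_informative] += offset
                row = {
                    "image_id": f"{label[:3]}-{p:03d}-img{i:02d}",
                    "patient_id": f"{label[:3]}-{p:03d}",
                    "class_label": label,
                    "reader_id": "reader1",
                }
                row.update({n: v for n, v in zip(FEATURE_NAMES, x)})
                rows.append(row)
    return pd.DataFrame(rows)
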