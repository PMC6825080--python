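"""Disk round-trip of synthetic cohorts and feature tables.

A cohort directory holds 8-bit greyscale PNG images, 0/255 PNG masks and
one ``manifest.csv`` with columns image_id, patient_id, class_label,
reader_id, image_path, mask_path (paths relative to the manifest).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ParameterError
from .synthetic import ROISample

__all__ = ["write_cohort", "read_cohort", "write_feature_table", "read_feature_table"]

MANIFEST_COLUMNS = ["image_id", "patient_id", "class_label", "reader_id", "image_path", "mask_path"]


def write_cohort(samples: list[ROISample], out_dir: str | Path) -> Path:
    """Write images + masks + manifest; returns the manifest path."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        img_rel = f"images/{s.image_id}.png"
        mask_rel = f"masks/{s.image_id}.png"
        Image.fromarray(s.image.astype(np.uint8), mode="L").save(out / img_rel)
        Image.fromarray((s.mask.astype(np.uint8) * 255), mode="L").save(out / mask_rel)
        rows.append(
            {
                "image_id": s.image_id,
                "patient_id": s.patient_id,
                "class_label": s.class_label,
                "reader_id": s.reader_id or "",
                "image_path": img_rel,
                "mask_path": mask_rel,
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[ROISample]:
    """Load a cohort from its manifest CSV."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    frame = pd.read_csv(manifest_path, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(frame.columns)
    if missing:
        raise ParameterError(f"manifest lacks columns: {sorted(missing)}")
    samples = []
    for row in frame.itertuples(index=False):
        image = np.asarray(Image.open(root / row.image_path).convert("L"))
        mask = np.asarray(Image.open(root / row.mask_path).convert("L")) > 127
        samples.append(
            ROISample(
                image=image,
                mask=mask,
                class_label=row.class_label,
                patient_id=str(row.patient_id),
                image_id=str(row.image_id),
                reader_id=str(row.reader_id) or None,
            )
        )
    return samples


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False, na_values=[])
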