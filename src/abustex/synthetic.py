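"""Synthetic ultrasound-like cohorts of masked ROIs.

Real automated breast ultrasound images are dominated by speckle: a
granular interference texture whose intensity statistics are well
described by gamma-distributed multiplicative noise.  The generator here
builds four tissue classes (malignant, benign, fat, glandular) from that
model: an i.i.d. gamma field is smoothed by a Gaussian kernel (setting
the spatial correlation length of the texture), standardised, and
affinely mapped around a class-specific mean grey level before rounding
to 8-bit.  The gamma shape parameter directly controls histogram
skewness/kurtosis, so first-order texture separation between classes can
be dialled in or switched off (for null-calibration experiments) without
touching the rest of the pipeline.

Cohorts are organised as patients -> lesions -> images.  All images of a
lesion share one patient id and one lesion mask (a randomly perturbed
ellipse); fat and glandular samples get a large rectangular mask
emulating the "maximal continuous area" of tissue a reader would trace,
and their own patient ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .seeding import derive_seed

__all__ = [
    "ClassTextureParams",
    "CohortSpec",
    "ROISample",
    "generate_texture_field",
    "generate_lesion_mask",
    "generate_cohort",
    "reader_variant",
    "default_class_params",
    "default_cohort_spec",
    "null_pair_cohort_spec",
    "CLASS_LABELS",
    "LESION_CLASSES",
    "TISSUE_CLASSES",
]

CLASS_LABELS = ("malignant", "benign", "fat", "glandular")
LESION_CLASSES = ("malignant", "benign")
TISSUE_CLASSES = ("fat", "glandular")

MIN_MASK_PIXELS = 16


@dataclass(frozen=True)
class ClassTextureParams:
    """Texture parameters of one tissue class.

    Parameters
    ----------
    class_label:
        One of ``malignant | benign | fat | glandular``.
    mean_level:
        Target mean grey level in (0, 255).
    contrast_scale:
        Speckle amplitude (grey levels per unit of the standardised
        noise field); must be positive.
    correlation_length_px:
        Standard deviation (pixels) of the Gaussian smoothing kernel;
        larger values give coarser, more spatially correlated texture.
    skew_shape:
        Shape parameter of the gamma speckle distribution; small values
        give strongly right-skewed, heavy-tailed histograms, large
        values approach a Gaussian.
    """

    class_label: str
    mean_level: float
    contrast_scale: float
    correlation_length_px: float
    skew_shape: float

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ParameterError(f"unknown class label {self.class_label!r}")
        if not 0.0 < self.mean_level < 255.0:
            raise ParameterError("mean_level must lie in (0, 255)")
        for name in ("contrast_scale", "correlation_length_px", "skew_shape"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")


@dataclass(frozen=True)
class ROISample:
    """One image with its binary ROI mask and identifiers."""

    image: np.ndarray
    mask: np.ndarray
    class_label: str
    patient_id: str
    image_id: str
    reader_id: str | None = None

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ParameterError("image and mask shapes differ")
        if self.mask.dtype != bool:
            raise ParameterError("mask must be boolean")
        if int(self.mask.sum()) < MIN_MASK_PIXELS:
            raise ParameterError(f"mask must cover >= {MIN_MASK_PIXELS} pixels")


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; spec + seed is bit-reproducible."""

    class_params: dict[str, ClassTextureParams]
    n_patients_per_class: int
    images_per_lesion: tuple[int, int]
    image_shape: tuple[int, int] = (128, 128)
    lesion_radius_px: tuple[int, int] = (16, 28)
    images_per_tissue: int = 2
    mask_perturbation: float = 0.15
    background_params: ClassTextureParams = field(
        default_factory=lambda: ClassTextureParams(
            "glandular", mean_level=128.0, contrast_scale=20.0,
            correlation_length_px=1.5, skew_shape=6.0,
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.class_params) != set(CLASS_LABELS):
            raise ParameterError(f"class_params must cover exactly {CLASS_LABELS}")
        for label, p in self.class_params.items():
            if p.class_label != label:
                raise ParameterError(f"class_params[{label!r}] labelled {p.class_label!r}")
        if self.n_patients_per_class < 1:
            raise ParameterError("n_patients_per_class must be positive")
        lo, hi = self.images_per_lesion
        if not 1 <= lo <= hi:
            raise ParameterError("images_per_lesion must be an increasing range >= 1")
        if self.images_per_tissue < 1:
            raise ParameterError("images_per_tissue must be positive")
        if min(self.image_shape) < 16:
            raise ParameterError("image_shape must be at least 16x16")


def generate_texture_field(
    params: ClassTextureParams, shape: tuple[int, int], seed: int
) -> np.ndarray:
    """Generate one speckle texture field as an 8-bit image.

    Gamma(shape=``skew_shape``) noise is smoothed with a Gaussian kernel
    of width ``correlation_length_px``, standardised to zero mean / unit
    variance, scaled by ``contrast_scale`` around ``mean_level``, clipped
    to [0, 255] and rounded.
    """
    if min(shape) < 16:
        raise ParameterError("field shape must be at least 16x16")
    rng = np.random.default_rng(seed)
    raw = rng.gamma(params.skew_shape, 1.0, size=shape)
    smooth = ndimage.gaussian_filter(raw, sigma=params.correlation_length_px, mode="reflect")
    sd = smooth.std()
    z = (smooth - smooth.mean()) / sd if sd > 1e-12 else np.zeros(shape)
    img = params.mean_level + params.contrast_scale * z
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_lesion_mask(
    shape: tuple[int, int],
    radius_range: tuple[int, int],
    seed: int,
    perturbation: float = 0.15,
    border_margin: int = 2,
) -> np.ndarray:
    """Rasterise a randomly perturbed ellipse as a boolean lesion mask.

    The boundary is a star-shaped radial function (an ellipse modulated
    by a low-order Fourier perturbation), which guarantees a single
    connected blob.  The mask never touches the image border.
    """
    rmin, rmax = radius_range
    if not 0 < rmin <= rmax:
        raise ParameterError("radius_range must satisfy 0 < rmin <= rmax")
    if perturbation < 0 or perturbation >= 1:
        raise ParameterError("perturbation must lie in [0, 1)")
    limit = rmax * (1.0 + perturbation) + border_margin + 1
    if 2 * limit > min(shape):
        raise ParameterError("maximum lesion radius does not fit inside the image")

    rng = np.random.default_rng(seed)
    a = rng.uniform(rmin, rmax)
    b = rng.uniform(rmin, rmax)
    theta0 = rng.uniform(0.0, np.pi)
    # centre jitter constrained so the perturbed ellipse stays inside the border
    slack_r = shape[0] / 2 - limit
    slack_c = shape[1] / 2 - limit
    cr = shape[0] / 2 + rng.uniform(-slack_r, slack_r) if slack_r > 0 else shape[0] / 2
    cc = shape[1] / 2 + rng.uniform(-slack_c, slack_c) if slack_c > 0 else shape[1] / 2

    rows, cols = np.indices(shape)
    dr = rows - cr
    dc = cols - cc
    # rotate into the ellipse frame
    u = np.cos(theta0) * dc + np.sin(theta0) * dr
    v = -np.sin(theta0) * dc + np.cos(theta0) * dr
    s = np.sqrt((u / a) ** 2 + (v / b) ** 2)

    if perturbation > 0:
        phi = np.arctan2(v, u)
        coeffs = rng.normal(size=(3, 2))
        f = np.zeros(shape)
        for k, (ck, sk) in zip((2, 3, 4), coeffs):
            f += ck * np.cos(k * phi) + sk * np.sin(k * phi)
        peak = np.max(np.abs(f))
        if peak > 0:
            f = f / peak
        boundary = 1.0 + perturbation * f
    else:
        boundary = 1.0

    mask = s <= boundary
    if int(mask.sum()) < MIN_MASK_PIXELS:
        raise ParameterError("generated mask smaller than 16 pixels; enlarge radius_range")
    return mask


def _tissue_mask(shape: tuple[int, int]) -> np.ndarray:
    """Large centred rectangle, inset from the border."""
    inset_r = max(2, shape[0] // 10)
    inset_c = max(2, shape[1] // 10)
    mask = np.zeros(shape, dtype=bool)
    mask[inset_r : shape[0] - inset_r, inset_c : shape[1] - inset_c] = True
    return mask


def generate_cohort(spec: CohortSpec) -> list[ROISample]:
    """Generate the full cohort described by ``spec``.

    Lesion classes: one lesion mask per patient, several independently
    speckled images of it composited into a shared-parameter background.
    Tissue classes: ``images_per_tissue`` rectangular-ROI images per
    patient.
    """
    samples: list[ROISample] = []
    for label in CLASS_LABELS:
        params = spec.class_params[label]
        is_lesion = label in LESION_CLASSES
        for p in range(spec.n_patients_per_class):
            patient_id = f"{label[:3]}-{p:03d}"
            patient_rng = np.random.default_rng(derive_seed(spec.seed, label, p, "patient"))
            if is_lesion:
                lo, hi = spec.images_per_lesion
                n_images = int(patient_rng.integers(lo, hi + 1))
                mask = generate_lesion_mask(
                    spec.image_shape,
                    spec.lesion_radius_px,
                    seed=derive_seed(spec.seed, label, p, "mask"),
                    perturbation=spec.mask_perturbation,
                )
            else:
                n_images = spec.images_per_tissue
                mask = _tissue_mask(spec.image_shape)
            for i in range(n_images):
                field = generate_texture_field(
                    params, spec.image_shape, seed=derive_seed(spec.seed, label, p, i, "fg")
                )
                if is_lesion:
                    image = generate_texture_field(
                        spec.background_params,
                        spec.image_shape,
                        seed=derive_seed(spec.seed, label, p, i, "bg"),
                    ).copy()
                    image[mask] = field[mask]
                else:
                    image = field
                samples.append(
                    ROISample(
                        image=image,
                        mask=mask,
                        class_label=label,
                        patient_id=patient_id,
                        image_id=f"{patient_id}-img{i:02d}",
                        reader_id="reader1",
                    )
                )
    return samples


def reader_variant(sample: ROISample, seed: int) -> ROISample:
    """Simulate a second reader's ROI: the mask dilated or eroded by 1 px."""
    rng = np.random.default_rng(seed)
    if rng.random() < 0.5:
        new_mask = ndimage.binary_dilation(sample.mask)
        # keep the reader mask off the image border
        new_mask[0, :] = new_mask[-1, :] = False
        new_mask[:, 0] = new_mask[:, -1] = False
    else:
        new_mask = ndimage.binary_erosion(sample.mask)
    if int(new_mask.sum()) < MIN_MASK_PIXELS:
        new_mask = sample.mask.copy()
    return replace(sample, mask=new_mask, reader_id="reader2")


def default_class_params(separation: float = 1.0) -> dict[str, ClassTextureParams]:
    """Strongly separated four-class texture parameters.

    ``separation`` in [0, 1] interpolates every class towards a common
    midpoint; 1 keeps full separation, 0 collapses all classes onto the
    same parameters (useful for partial null experiments).
    """
    base = {
        "malignant": (90.0, 40.0, 2.5, 2.0),
        "benign": (115.0, 30.0, 1.5, 4.0),
        "fat": (140.0, 22.0, 1.0, 8.0),
        "glandular": (160.0, 34.0, 3.5, 16.0),
    }
    mid = (128.0, 30.0, 2.0, 6.0)
    out = {}
    for label, vals in base.items():
        mixed = tuple(m + separation * (v - m) for v, m in zip(vals, mid))
        out[label] = ClassTextureParams(label, *mixed)
    return out


def default_cohort_spec(seed: int, n_patients_per_class: int = 20) -> CohortSpec:
    """The standard strongly separated study cohort.

    Defaults mirror a small ABUS reading study: tens of patients per
    class, 2-16 images per lesion, two tissue images per patient, lesion
    ROIs of roughly 1-3 thousand pixels and tissue ROIs of roughly ten
    thousand pixels.
    """
    return CohortSpec(
        class_params=default_class_params(),
        n_patients_per_class=n_patients_per_class,
        images_per_lesion=(2, 16),
        seed=seed,
    )


def null_pair_cohort_spec(
    seed: int,
    classes: Sequence[str] = ("malignant", "benign"),
    n_patients_per_class: int = 20,
    **kwargs,
) -> CohortSpec:
    """Cohort in which the two given classes share identical texture parameters.

    Used for null calibration: a classifier separating the two listed
    classes should perform at chance level.
    """
    params = default_class_params()
    ref = params[classes[0]]
    for label in classes[1:]:
        params[label] = replace(ref, class_label=label)
    return CohortSpec(
        class_params=params,
        n_patients_per_class=n_patients_per_class,
        images_per_lesion=kwargs.pop("images_per_lesion", (2, 16)),
        seed=seed,
        **kwargs,
    )
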