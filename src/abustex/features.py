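"""The 47-feature texture engine.

Feature groups and canonical order (47 names total):

* ``hist``  (4): histogram entropy, variance, skewness, excess kurtosis
  of the normalized masked grey values.
* ``cooc1`` (4): GLCM contrast, correlation, energy, homogeneity at
  pixel distance 1 (symmetric, accumulated over 0/45/90/135 deg).
* ``cooc2`` (4): the same four at distance 2.
* ``rlm_a`` (11): run-length features (SRE, LRE, GLN, RLN, RP, LGRE,
  HGRE, SRLGE, SRHGE, LRLGE, LRHGE) with run counts summed over the four
  directions.
* ``rlm_b`` (11): the same eleven from horizontal runs only.
* ``szm``  (13): size-zone features (SZE, LZE, GLN, ZSN, ZP, LGZE,
  HGZE, SZLGE, SZHGE, LZLGE, LZHGE, GLV, ZSV) with 8-connected zones.

Entropy uses log base 2 (bits).  A co-occurrence matrix whose marginal
variance vanishes has no defined correlation; by convention the feature
is reported as 0 (with a warning) so every vector stays finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .matrices import ALL_DIRECTIONS, GLCM, GLRLM, GLSZM, HORIZONTAL, build_glcm, build_glrlm, build_glszm
from .preprocessing import (
    DEFAULT_GREY_LEVELS,
    NormalizationResult,
    crop_to_mask,
    normalize_roi,
    quantize,
)
from .synthetic import ROISample

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "FEATURE_NAMES",
    "histogram_features",
    "first_order_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "extract_features",
    "extract_table",
]

_HIST = ("entropy", "variance", "skewness", "kurtosis")
_COOC = ("contrast", "correlation", "energy", "homogeneity")
_RLM = ("sre", "lre", "gln", "rln", "rp", "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge")
_SZM = ("sze", "lze", "gln", "zsn", "zp", "lgze", "hgze", "szlge", "szhge", "lzlge", "lzhge",
        "glv", "zsv")

FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"hist_{n}" for n in _HIST)
    + tuple(f"glcm_d1_{n}" for n in _COOC)
    + tuple(f"glcm_d2_{n}" for n in _COOC)
    + tuple(f"glrlm_avg_{n}" for n in _RLM)
    + tuple(f"glrlm_h_{n}" for n in _RLM)
    + tuple(f"glszm_{n}" for n in _SZM)
)
assert len(FEATURE_NAMES) == 47

METADATA_COLUMNS = ("image_id", "patient_id", "class_label", "reader_id")


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the texture engine (defaults are the package convention)."""

    n_grey_levels: int = DEFAULT_GREY_LEVELS
    n_hist_bins: int = DEFAULT_GREY_LEVELS
    glcm_distances: tuple[int, int] = (1, 2)
    szm_connectivity: int = 8


@dataclass(frozen=True)
class FeatureVector:
    """Exactly 47 named finite texture features, in canonical order."""

    values: np.ndarray
    names: tuple[str, ...] = field(default=FEATURE_NAMES)

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ParameterError("feature vector length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("non-finite feature value")

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def histogram_features(values: np.ndarray, n_bins: int) -> tuple[float, float, float, float]:
    """Entropy (bits, from an equal-width histogram), population variance,
    skewness and excess kurtosis of a 1-D value sample."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    hist, _ = np.histogram(values, bins=n_bins)
    p = hist[hist > 0] / values.size
    entropy = float(-(p * np.log2(p)).sum())
    centred = values - values.mean()
    m2 = float(np.mean(centred**2))
    if m2 > 0:
        m3 = float(np.mean(centred**3))
        m4 = float(np.mean(centred**4))
        skewness = m3 / m2**1.5
        kurtosis = m4 / m2**2 - 3.0
    else:
        skewness = kurtosis = 0.0
    return entropy, m2, skewness, kurtosis


def first_order_features(norm: NormalizationResult, n_bins: int) -> tuple[float, float, float, float]:
    """First-order features of the normalized masked grey values."""
    return histogram_features(norm.masked_values, n_bins)


def glcm_features(g: GLCM) -> tuple[float, float, float, float]:
    """Contrast, correlation, energy, homogeneity of a normalized GLCM."""
    P = g.matrix
    Ng = P.shape[0]
    i = np.arange(1, Ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float(((ii - jj) ** 2 * P).sum())
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float((i * pi).sum())
    mu_j = float((i * pj).sum())
    var_i = float(((i - mu_i) ** 2 * pi).sum())
    var_j = float(((i - mu_j) ** 2 * pj).sum())
    if var_i > 0 and var_j > 0:
        correlation = float((((ii - mu_i) * (jj - mu_j) * P).sum()) / np.sqrt(var_i * var_j))
    else:
        warnings.warn("degenerate GLCM marginals: correlation reported as 0", RuntimeWarning,
                      stacklevel=2)
        correlation = 0.0
    energy = float((P**2).sum())
    homogeneity = float((P / (1.0 + np.abs(ii - jj))).sum())
    return contrast, correlation, energy, homogeneity


def _rl_weights(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    Ng, Lmax = counts.shape
    i = np.arange(1, Ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, Lmax + 1, dtype=np.float64)[None, :]
    return i, j, float(counts.sum())


def glrlm_features(r: GLRLM) -> tuple[float, ...]:
    """The eleven Galloway/Chu run-length features.

    Run percentage uses the per-direction pixel total, so it stays in
    (0, 1] when run counts are summed over several directions.
    """
    c = r.counts.astype(np.float64)
    i, j, Nr = _rl_weights(c)
    sre = float((c / j**2).sum() / Nr)
    lre = float((c * j**2).sum() / Nr)
    gln = float((c.sum(axis=1) ** 2).sum() / Nr)
    rln = float((c.sum(axis=0) ** 2).sum() / Nr)
    rp = float(Nr / (r.n_pixels * len(r.directions)))
    lgre = float((c / i**2).sum() / Nr)
    hgre = float((c * i**2).sum() / Nr)
    srlge = float((c / (i**2 * j**2)).sum() / Nr)
    srhge = float((c * i**2 / j**2).sum() / Nr)
    lrlge = float((c * j**2 / i**2).sum() / Nr)
    lrhge = float((c * i**2 * j**2).sum() / Nr)
    return sre, lre, gln, rln, rp, lgre, hgre, srlge, srhge, lrlge, lrhge


def glszm_features(z: GLSZM) -> tuple[float, ...]:
    """The thirteen Thibault size-zone features (zone size plays the role
    of run length; GLV/ZSV are variances under the zone distribution)."""
    c = z.counts.astype(np.float64)
    i, j, Nz = _rl_weights(c)
    p = c / Nz
    sze = float((c / j**2).sum() / Nz)
    lze = float((c * j**2).sum() / Nz)
    gln = float((c.sum(axis=1) ** 2).sum() / Nz)
    zsn = float((c.sum(axis=0) ** 2).sum() / Nz)
    zp = float(Nz / z.n_pixels)
    lgze = float((c / i**2).sum() / Nz)
    hgze = float((c * i**2).sum() / Nz)
    szlge = float((c / (i**2 * j**2)).sum() / Nz)
    szhge = float((c * i**2 / j**2).sum() / Nz)
    lzlge = float((c * j**2 / i**2).sum() / Nz)
    lzhge = float((c * i**2 * j**2).sum() / Nz)
    mu_i = float((p * i).sum())
    glv = float((p * (i - mu_i) ** 2).sum())
    mu_j = float((p * j).sum())
    zsv = float((p * (j - mu_j) ** 2).sum())
    return sze, lze, gln, zsn, zp, lgze, hgze, szlge, szhge, lzlge, lzhge, glv, zsv


def extract_features(sample: ROISample, config: FeatureConfig = FeatureConfig()) -> FeatureVector:
    """Run the full texture engine on one masked ROI.

    The sample is cropped to its mask bounding box, normalized to
    mu +/- 3 sigma, quantized to ``n_grey_levels``, and all 47 features
    are assembled in canonical order.
    """
    cropped = crop_to_mask(sample)
    norm = normalize_roi(cropped)
    q = quantize(norm, config.n_grey_levels)
    d1, d2 = config.glcm_distances
    vals = (
        first_order_features(norm, config.n_hist_bins)
        + glcm_features(build_glcm(q, distance=d1, directions=ALL_DIRECTIONS, symmetric=True))
        + glcm_features(build_glcm(q, distance=d2, directions=ALL_DIRECTIONS, symmetric=True))
        + glrlm_features(build_glrlm(q, directions=ALL_DIRECTIONS))
        + glrlm_features(build_glrlm(q, directions=HORIZONTAL))
        + glszm_features(build_glszm(q, connectivity=config.szm_connectivity))
    )
    return FeatureVector(values=np.asarray(vals, dtype=np.float64))


def extract_table(samples, config: FeatureConfig = FeatureConfig()):
    """Extract features for a cohort into a tidy DataFrame.

    One row per sample; metadata columns followed by the 47 canonical
    feature columns.
    """
    import pandas as pd

    rows = []
    for s in samples:
        fv = extract_features(s, config)
        row = {
            "image_id": s.image_id,
            "patient_id": s.patient_id,
            "class_label": s.class_label,
            "reader_id": s.reader_id,
        }
        row.update(fv.as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=list(METADATA_COLUMNS) + list(FEATURE_NAMES))
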