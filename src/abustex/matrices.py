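"""Grey-level texture matrices: co-occurrence, run-length, size-zone.

All builders operate on a :class:`~abustex.preprocessing.QuantizedROI`
whose ``levels`` array codes 0 outside the mask; out-of-mask cells never
contribute to a pair, break every run, and belong to no zone.

Directions follow the usual 2D convention: 0 deg = horizontal (0, +1),
45 deg = (-1, +1), 90 deg = (-1, 0), 135 deg = (-1, -1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyMatrixError, ParameterError
from .preprocessing import QuantizedROI

__all__ = [
    "DIRECTIONS",
    "HORIZONTAL",
    "GLCM",
    "GLRLM",
    "GLSZM",
    "build_glcm",
    "build_glrlm",
    "build_glszm",
]

DIRECTIONS: dict[int, tuple[int, int]] = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
HORIZONTAL = (0,)
ALL_DIRECTIONS = tuple(DIRECTIONS)


@dataclass(frozen=True)
class GLCM:
    """Normalized grey-level co-occurrence matrix (sums to 1)."""

    matrix: np.ndarray
    distance: int
    directions: tuple[int, ...]
    symmetric: bool


@dataclass(frozen=True)
class GLRLM:
    """Grey-level run-length counts, summed over the given directions."""

    counts: np.ndarray  # Ng x Rmax
    n_runs: int
    n_pixels: int
    directions: tuple[int, ...]


@dataclass(frozen=True)
class GLSZM:
    """Grey-level size-zone counts (zones partition the mask)."""

    counts: np.ndarray  # Ng x Smax
    n_zones: int
    n_pixels: int
    connectivity: int


def _shifted_pairs(levels: np.ndarray, dr: int, dc: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (a, b) level arrays for all pixel pairs p, p+offset inside the frame."""
    nr, nc = levels.shape
    r0, r1 = max(0, -dr), min(nr, nr - dr)
    c0, c1 = max(0, -dc), min(nc, nc - dc)
    a = levels[r0:r1, c0:c1]
    b = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    return a.ravel(), b.ravel()


def build_glcm(
    q: QuantizedROI,
    distance: int = 1,
    directions: tuple[int, ...] = ALL_DIRECTIONS,
    symmetric: bool = True,
) -> GLCM:
    """Count co-occurring level pairs at the given pixel distance.

    Pairs with either pixel outside the mask are discarded.  Counts are
    accumulated over all requested directions, optionally symmetrized
    (each pair counted in both orders), then normalized to sum to 1.
    """
    if distance < 1:
        raise ParameterError("distance must be >= 1")
    if not directions:
        raise ParameterError("at least one direction required")
    Ng = q.Ng
    counts = np.zeros((Ng, Ng), dtype=np.float64)
    for d in directions:
        dr, dc = DIRECTIONS[d]
        a, b = _shifted_pairs(q.levels, dr * distance, dc * distance)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        idx = (a[valid] - 1) * Ng + (b[valid] - 1)
        counts += np.bincount(idx, minlength=Ng * Ng).reshape(Ng, Ng)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise EmptyMatrixError("no valid in-mask pixel pairs at this offset")
    return GLCM(matrix=counts / total, distance=distance, directions=tuple(directions),
                symmetric=symmetric)


def _lines_for_direction(levels: np.ndarray, direction: int):
    """Yield the 1-D pixel lines collinear with the given direction."""
    if direction == 0:
        yield from levels
    elif direction == 90:
        yield from levels.T
    elif direction == 135:  # collinear with (1, 1): main diagonals
        nr, nc = levels.shape
        for off in range(-nr + 1, nc):
            yield levels.diagonal(off)
    elif direction == 45:  # collinear with (-1, 1): anti-diagonals
        flipped = levels[::-1]
        nr, nc = flipped.shape
        for off in range(-nr + 1, nc):
            yield flipped.diagonal(off)
    else:
        raise ParameterError(f"unsupported direction {direction}")


def _runs_in_line(line: np.ndarray):
    """Yield (level, run_length) for maximal runs of equal nonzero level."""
    if line.size == 0:
        return
    change = np.flatnonzero(np.diff(line) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [line.size]))
    for s, e in zip(starts, ends):
        lvl = int(line[s])
        if lvl > 0:
            yield lvl, int(e - s)


def build_glrlm(q: QuantizedROI, directions: tuple[int, ...] = ALL_DIRECTIONS) -> GLRLM:
    """Count maximal runs of equal grey level along each direction.

    Runs are restricted to in-mask collinear segments (an out-of-mask
    cell terminates a run).  With several directions the per-direction
    count matrices are summed before feature computation.
    """
    if not directions:
        raise ParameterError("at least one direction required")
    Ng = q.Ng
    max_len = max(q.levels.shape) if q.levels.size else 1
    counts = np.zeros((Ng, max_len), dtype=np.int64)
    for d in directions:
        for line in _lines_for_direction(q.levels, d):
            for lvl, length in _runs_in_line(np.asarray(line)):
                counts[lvl - 1, length - 1] += 1
    n_runs = int(counts.sum())
    if n_runs == 0:
        raise EmptyMatrixError("empty mask: no runs")
    # trim trailing all-zero run-length columns
    last = int(np.max(np.nonzero(counts.any(axis=0))[0])) + 1
    return GLRLM(counts=counts[:, :last], n_runs=n_runs, n_pixels=q.n_pixels,
                 directions=tuple(directions))


def build_glszm(q: QuantizedROI, connectivity: int = 8) -> GLSZM:
    """Count connected zones of equal grey level by level and zone size."""
    if connectivity not in (4, 8):
        raise ParameterError("connectivity must be 4 or 8")
    structure = np.ones((3, 3), dtype=bool) if connectivity == 8 else ndimage.generate_binary_structure(2, 1)
    Ng = q.Ng
    sizes_by_level: list[tuple[int, np.ndarray]] = []
    max_size = 1
    for lvl in np.unique(q.levels[q.levels > 0]):
        labelled, n = ndimage.label(q.levels == lvl, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labelled.ravel())[1:]
        sizes_by_level.append((int(lvl), sizes))
        max_size = max(max_size, int(sizes.max()))
    if not sizes_by_level:
        raise EmptyMatrixError("empty mask: no zones")
    counts = np.zeros((Ng, max_size), dtype=np.int64)
    for lvl, sizes in sizes_by_level:
        for s in sizes:
            counts[lvl - 1, s - 1] += 1
    return GLSZM(counts=counts, n_zones=int(counts.sum()), n_pixels=q.n_pixels,
                 connectivity=connectivity)
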