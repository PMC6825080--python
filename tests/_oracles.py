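"""Brute-force reference implementations used only by the tests.

Everything here is written as direct enumeration over pixels, pairs,
runs and zones (pure Python loops), independent of the vectorised code
paths in the package.
"""

from __future__ import annotations

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_glcm(levels: np.ndarray, Ng: int, distance: int, directions, symmetric: bool) -> np.ndarray:
    counts = np.zeros((Ng, Ng))
    nr, nc = levels.shape
    for d in directions:
        dr, dc = OFFSETS[d]
        dr, dc = dr * distance, dc * distance
        for r in range(nr):
            for c in range(nc):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < nr and 0 <= c2 < nc:
                    a, b = levels[r, c], levels[r2, c2]
                    if a > 0 and b > 0:
                        counts[a - 1, b - 1] += 1
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    return counts / total if total else counts


def brute_glcm_features(P: np.ndarray) -> dict[str, float]:
    Ng = P.shape[0]
    contrast = correlation = energy = homogeneity = 0.0
    mu_i = mu_j = 0.0
    for i in range(Ng):
        for j in range(Ng):
            mu_i += (i + 1) * P[i, j]
            mu_j += (j + 1) * P[i, j]
    var_i = var_j = 0.0
    for i in range(Ng):
        for j in range(Ng):
            var_i += (i + 1 - mu_i) ** 2 * P[i, j]
            var_j += (j + 1 - mu_j) ** 2 * P[i, j]
    cov = 0.0
    for i in range(Ng):
        for j in range(Ng):
            p = P[i, j]
            contrast += (i - j) ** 2 * p
            energy += p * p
            homogeneity += p / (1 + abs(i - j))
            cov += (i + 1 - mu_i) * (j + 1 - mu_j) * p
    correlation = cov / np.sqrt(var_i * var_j) if var_i > 0 and var_j > 0 else 0.0
    return {"contrast": contrast, "correlation": correlation, "energy": energy,
            "homogeneity": homogeneity}


def brute_runs(levels: np.ndarray, direction: int) -> list[tuple[int, int]]:
    """All maximal runs of equal nonzero level along one direction."""
    nr, nc = levels.shape
    dr, dc = OFFSETS[direction]
    runs = []
    seen = set()
    for r in range(nr):
        for c in range(nc):
            pr, pc = r - dr, c - dc
            # start of a line-maximal run only
            if 0 <= pr < nr and 0 <= pc < nc and levels[pr, pc] == levels[r, c]:
                continue
            lvl = levels[r, c]
            if lvl <= 0:
                continue
            length = 0
            rr, cc = r, c
            while 0 <= rr < nr and 0 <= cc < nc and levels[rr, cc] == lvl:
                length += 1
                rr, cc = rr + dr, cc + dc
            key = (r, c, direction)
            if key not in seen:
                seen.add(key)
                runs.append((int(lvl), length))
    return runs


def brute_glrlm(levels: np.ndarray, Ng: int, directions) -> np.ndarray:
    all_runs = []
    for d in directions:
        all_runs.extend(brute_runs(levels, d))
    max_len = max((l for _, l in all_runs), default=1)
    counts = np.zeros((Ng, max_len), dtype=np.int64)
    for lvl, length in all_runs:
        counts[lvl - 1, length - 1] += 1
    return counts


def brute_rlm_features(counts: np.ndarray, n_pixels: int, n_directions: int) -> dict[str, float]:
    Ng, Lmax = counts.shape
    Nr = counts.sum()
    out = dict.fromkeys(
        ["sre", "lre", "gln", "rln", "rp", "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge"], 0.0
    )
    for i in range(Ng):
        for j in range(Lmax):
            r = counts[i, j]
            if r == 0:
                continue
            gi, rj = (i + 1) ** 2, (j + 1) ** 2
            out["sre"] += r / rj
            out["lre"] += r * rj
            out["lgre"] += r / gi
            out["hgre"] += r * gi
            out["srlge"] += r / (gi * rj)
            out["srhge"] += r * gi / rj
            out["lrlge"] += r * rj / gi
            out["lrhge"] += r * gi * rj
    for k in ("sre", "lre", "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge"):
        out[k] /= Nr
    out["gln"] = sum(counts[i, :].sum() ** 2 for i in range(Ng)) / Nr
    out["rln"] = sum(counts[:, j].sum() ** 2 for j in range(Lmax)) / Nr
    out["rp"] = Nr / (n_pixels * n_directions)
    return out


def brute_zones(levels: np.ndarray, connectivity: int = 8) -> list[tuple[int, int]]:
    """(level, size) of every connected equal-level zone, by flood fill."""
    nr, nc = levels.shape
    visited = np.zeros_like(levels, dtype=bool)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    zones = []
    for r in range(nr):
        for c in range(nc):
            if visited[r, c] or levels[r, c] <= 0:
                continue
            lvl = levels[r, c]
            stack = [(r, c)]
            visited[r, c] = True
            size = 0
            while stack:
                cr, cc = stack.pop()
                size += 1
                for dr, dc in nbrs:
                    rr, cc2 = cr + dr, cc + dc
                    if 0 <= rr < nr and 0 <= cc2 < nc and not visited[rr, cc2] \
                            and levels[rr, cc2] == lvl:
                        visited[rr, cc2] = True
                        stack.append((rr, cc2))
            zones.append((int(lvl), size))
    return zones


def brute_glszm(levels: np.ndarray, Ng: int, connectivity: int = 8) -> np.ndarray:
    zones = brute_zones(levels, connectivity)
    max_size = max((s for _, s in zones), default=1)
    counts = np.zeros((Ng, max_size), dtype=np.int64)
    for lvl, s in zones:
        counts[lvl - 1, s - 1] += 1
    return counts


def brute_szm_features(counts: np.ndarray, n_pixels: int) -> dict[str, float]:
    Ng, Smax = counts.shape
    Nz = counts.sum()
    base = brute_rlm_features(counts, n_pixels, 1)
    out = {
        "sze": base["sre"], "lze": base["lre"], "gln": base["gln"], "zsn": base["rln"],
        "zp": Nz / n_pixels, "lgze": base["lgre"], "hgze": base["hgre"],
        "szlge": base["srlge"], "szhge": base["srhge"], "lzlge": base["lrlge"],
        "lzhge": base["lrhge"],
    }
    mu_i = sum((i + 1) * counts[i, :].sum() for i in range(Ng)) / Nz
    mu_j = sum((j + 1) * counts[:, j].sum() for j in range(Smax)) / Nz
    out["glv"] = sum((i + 1 - mu_i) ** 2 * counts[i, j]
                     for i in range(Ng) for j in range(Smax)) / Nz
    out["zsv"] = sum((j + 1 - mu_j) ** 2 * counts[i, j]
                     for i in range(Ng) for j in range(Smax)) / Nz
    return out


def brute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Pair-counting AUC: ties weighted 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for x in pos:
        for y in neg:
            if x > y:
                total += 1.0
            elif x == y:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_lag1_autocorr(img: np.ndarray) -> float:
    """Mean horizontal/vertical lag-1 autocorrelation by direct pixel-pair sums."""
    x = img.astype(float)
    x = x - x.mean()
    var = (x * x).mean()
    if var == 0:
        return 0.0
    h = (x[:, :-1] * x[:, 1:]).mean() / var
    v = (x[:-1, :] * x[1:, :]).mean() / var
    return 0.5 * (h + v)


def random_masked_levels(rng: np.random.Generator, max_side: int = 12, Ng: int = 6):
    """A random quantized ROI: levels 1..Ng inside a random mask, 0 outside."""
    nr = int(rng.integers(4, max_side + 1))
    nc = int(rng.integers(4, max_side + 1))
    levels = rng.integers(1, Ng + 1, size=(nr, nc)).astype(np.int32)
    mask = rng.random((nr, nc)) < 0.75
    while mask.sum() < 16:
        mask |= rng.random((nr, nc)) < 0.5
    levels[~mask] = 0
    return levels
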