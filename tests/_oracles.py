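"""Independent brute-force oracles for texture matrices and features.

Everything here is written for clarity, not speed: explicit Python loops
over voxels, neighbours, runs and flood-filled zones.  The production
implementations are vectorized and must agree with these to 1e-12 on
small volumes.
"""

from itertools import product

import numpy as np

# 13 unique unit directions (first nonzero component positive), and the
# full 26-neighbourhood
DIRECTIONS_13 = [
    d
    for d in product((-1, 0, 1), repeat=3)
    if any(d) and (d[0] > 0 or (d[0] == 0 and (d[1] > 0 or (d[1] == 0 and d[2] > 0))))
]
NEIGHBORS_26 = [d for d in product((-1, 0, 1), repeat=3) if any(d)]


def _in_bounds(p, shape):
    return all(0 <= p[k] < shape[k] for k in range(3))


def oracle_glcm(levels: np.ndarray, n_bins: int) -> np.ndarray:
    """Counts every ordered in-mask neighbour pair over the full
    26-neighbourhood (equivalent to 13 directions + transpose), then
    normalizes."""
    counts = np.zeros((n_bins, n_bins))
    shape = levels.shape
    for p in product(*(range(s) for s in shape)):
        if levels[p] == 0:
            continue
        for d in NEIGHBORS_26:
            q = tuple(p[k] + d[k] for k in range(3))
            if _in_bounds(q, shape) and levels[q] > 0:
                counts[levels[p] - 1, levels[q] - 1] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no pairs")
    return counts / total


def oracle_glrlm(levels: np.ndarray, n_bins: int) -> np.ndarray:
    """Maximal equal-level in-mask runs along the 13 directions, found by
    walking from every run start (voxel whose predecessor breaks the run)."""
    shape = levels.shape
    runs = {}
    for d in DIRECTIONS_13:
        for p in product(*(range(s) for s in shape)):
            lvl = levels[p]
            if lvl == 0:
                continue
            prev = tuple(p[k] - d[k] for k in range(3))
            if _in_bounds(prev, shape) and levels[prev] == lvl:
                continue  # not a run start
            length = 0
            q = p
            while _in_bounds(q, shape) and levels[q] == lvl:
                length += 1
                q = tuple(q[k] + d[k] for k in range(3))
            runs[(lvl, length)] = runs.get((lvl, length), 0) + 1
    max_len = max(j for _, j in runs)
    r = np.zeros((n_bins, max_len))
    for (lvl, length), c in runs.items():
        r[lvl - 1, length - 1] += c
    return r


def oracle_glszm(levels: np.ndarray, n_bins: int) -> np.ndarray:
    """26-connected constant-level zones found by explicit flood fill."""
    shape = levels.shape
    visited = np.zeros(shape, dtype=bool)
    zones = {}
    for p in product(*(range(s) for s in shape)):
        if levels[p] == 0 or visited[p]:
            continue
        lvl = levels[p]
        stack = [p]
        visited[p] = True
        size = 0
        while stack:
            q = stack.pop()
            size += 1
            for d in NEIGHBORS_26:
                nq = tuple(q[k] + d[k] for k in range(3))
                if _in_bounds(nq, shape) and not visited[nq] and levels[nq] == lvl:
                    visited[nq] = True
                    stack.append(nq)
        zones[(lvl, size)] = zones.get((lvl, size), 0) + 1
    max_size = max(j for _, j in zones)
    s = np.zeros((n_bins, max_size))
    for (lvl, size), c in zones.items():
        s[lvl - 1, size - 1] += c
    return s


def oracle_glcm_features(p: np.ndarray) -> dict:
    """Double-loop GLCM feature computation (entropy bits, inverse
    difference, contrast, correlation with correlation := 1 at zero
    marginal variance)."""
    n = p.shape[0]
    entropy = 0.0
    homog = 0.0
    contrast = 0.0
    mu_i = mu_j = 0.0
    for i in range(n):
        for j in range(n):
            pij = p[i, j]
            if pij > 0:
                entropy -= pij * np.log2(pij)
            homog += pij / (1 + abs(i - j))
            contrast += pij * (i - j) ** 2
            mu_i += (i + 1) * pij
            mu_j += (j + 1) * pij
    var_i = var_j = cov = 0.0
    for i in range(n):
        for j in range(n):
            pij = p[i, j]
            var_i += (i + 1 - mu_i) ** 2 * pij
            var_j += (j + 1 - mu_j) ** 2 * pij
            cov += (i + 1 - mu_i) * (j + 1 - mu_j) * pij
    sd = np.sqrt(var_i) * np.sqrt(var_j)
    corr = 1.0 if sd == 0 else cov / sd
    return {"entropy": entropy, "homogeneity": homog, "contrast": contrast, "correlation": corr}


def oracle_glrlm_features(r: np.ndarray, normalized_rlnu: bool = True) -> dict:
    n_r = r.sum()
    sre = lre = 0.0
    for i in range(r.shape[0]):
        for j in range(r.shape[1]):
            sre += r[i, j] / (j + 1) ** 2
            lre += r[i, j] * (j + 1) ** 2
    rlnu = 0.0
    for j in range(r.shape[1]):
        rlnu += r[:, j].sum() ** 2
    rlnu /= n_r**2 if normalized_rlnu else n_r
    return {"sre": sre / n_r, "lre": lre / n_r, "rlnu": rlnu}


def oracle_glszm_features(s: np.ndarray) -> dict:
    n_z = s.sum()
    lgze = hgze = 0.0
    for i in range(s.shape[0]):
        for j in range(s.shape[1]):
            lgze += s[i, j] / (i + 1) ** 2
            hgze += s[i, j] * (i + 1) ** 2
    return {"lgze": lgze / n_z, "hgze": hgze / n_z}


def random_level_volume(rng: np.random.Generator, max_side: int = 5, max_levels: int = 8):
    """Random small level volume with a random mask (at least 2 voxels)."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    n_bins = int(rng.integers(2, max_levels + 1))
    levels = rng.integers(1, n_bins + 1, size=shape)
    mask = rng.random(shape) < 0.7
    while mask.sum() < 2:
        mask = rng.random(shape) < 0.7
    levels = np.where(mask, levels, 0).astype(np.int32)
    return levels, n_bins
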