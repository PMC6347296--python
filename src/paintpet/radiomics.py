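"""Texture metrology for painted-phantom images.

The evaluation protocol is: delineate the object with a 40%-of-maximum
isocontour (largest 26-connected component containing the maximum),
discretize the in-mask intensities to a fixed number of grey levels
(64 by default, min–max based), build grey-level co-occurrence (GLCM),
run-length (GLRLM) and size-zone (GLSZM) matrices over the fully
connected 3-D neighbourhood, and report nine texture indices plus
first-order statistics.

Conventions (fixed, switchable where noted):

* All 13 unique unit-displacement 3-D directions (half of the
  26-neighbourhood; a direction and its negation index the same pairs
  and runs) are merged into a single matrix, not averaged per direction.
* GLCM is symmetrized (each pair counted in both orders) and normalized
  to probabilities.
* RLNU defaults to the run-count-normalized variant (divide by N_r^2,
  values in (0, 1]); the raw Galloway variant (divide by N_r) is
  available via ``normalized=False``.
* Population SD (divide by N) throughout; entropy in bits.
* GLCM correlation is defined as 1 when either marginal SD is zero
  (perfectly predictable co-occurrence).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage

from .image import VoxelImage

__all__ = [
    "VOIMask",
    "LevelVolume",
    "FeatureSet",
    "FEATURE_COLUMNS",
    "segment_isocontour",
    "discretize_fbn",
    "build_glcm",
    "glcm_features",
    "build_glrlm",
    "glrlm_features",
    "build_glszm",
    "glszm_features",
    "first_order_stats",
    "feature_set",
]

# the 13 unique distance-1 directions: first nonzero component positive
DIRECTIONS = tuple(
    d
    for d in product((-1, 0, 1), repeat=3)
    if any(d) and (d[0] > 0 or (d[0] == 0 and (d[1] > 0 or (d[1] == 0 and d[2] > 0))))
)
assert len(DIRECTIONS) == 13

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

# Feature-table column order used in all reports
FEATURE_COLUMNS = (
    "Entropy",
    "Homogeneity",
    "Correlation",
    "Contrast",
    "SRE",
    "LRE",
    "RLNU",
    "LGZE",
    "HGZE",
    "COV",
    "Volume",
)


@dataclass
class VOIMask:
    """Boolean volume-of-interest aligned to an image grid."""

    mask: np.ndarray
    voxel_size: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not np.any(self.mask):
            raise ValueError("mask is empty")
        self.voxel_size = np.atleast_1d(np.asarray(self.voxel_size, dtype=float))
        if self.voxel_size.size == 1:
            self.voxel_size = np.repeat(self.voxel_size, 3)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * float(np.prod(self.voxel_size)) / 1000.0


@dataclass
class LevelVolume:
    """Discretized grey levels: 1..n_bins inside the mask, 0 outside."""

    levels: np.ndarray
    n_bins: int
    v_min: float
    v_max: float

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=np.int32)
        inmask = self.levels > 0
        if not np.any(inmask):
            raise ValueError("level volume has no in-mask voxels")
        if self.levels.max() > self.n_bins or self.levels.min() < 0:
            raise ValueError("levels must lie in [0, n_bins]")

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0


@dataclass
class FeatureSet:
    """First-order and texture features of one delineated VOI."""

    mean: float
    max: float
    min: float
    sd: float
    cov: float          # percent
    volume_cm3: float
    entropy: float      # bits
    homogeneity: float
    correlation: float
    contrast: float
    sre: float
    lre: float
    rlnu: float
    lgze: float
    hgze: float

    def to_dict(self) -> dict:
        return {
            "Entropy": self.entropy,
            "Homogeneity": self.homogeneity,
            "Correlation": self.correlation,
            "Contrast": self.contrast,
            "SRE": self.sre,
            "LRE": self.lre,
            "RLNU": self.rlnu,
            "LGZE": self.lgze,
            "HGZE": self.hgze,
            "COV": self.cov,
            "Volume": self.volume_cm3,
            "Mean": self.mean,
            "Max": self.max,
            "Min": self.min,
            "SD": self.sd,
        }

    def texture_dict(self) -> dict:
        """The nine texture indices only (scale/shift-invariant set)."""
        d = self.to_dict()
        return {k: d[k] for k in FEATURE_COLUMNS[:9]}


def segment_isocontour(img: VoxelImage, fraction: float = 0.40) -> VOIMask:
    """Isocontour VOI: voxels >= fraction * max, reduced to the largest
    26-connected component containing the global maximum (first index wins
    on ties)."""
    vmax = img.values.max()
    if vmax <= 0:
        raise ValueError("no signal: image maximum is not positive")
    above = img.values >= fraction * vmax
    labels, _ = ndimage.label(above, structure=_STRUCT_26)
    peak_idx = np.unravel_index(int(np.argmax(img.values)), img.shape)
    keep = labels == labels[peak_idx]
    return VOIMask(mask=keep, voxel_size=img.voxel_size)


def discretize_fbn(img: VoxelImage, mask: VOIMask, n_bins: int = 64) -> LevelVolume:
    """Fixed-bin-number discretization over the in-mask min–max range.

    ``level = min(floor(n_bins * (v - v_min)/(v_max - v_min)) + 1, n_bins)``;
    a constant region maps entirely to level 1.
    """
    if mask.mask.shape != img.shape:
        raise ValueError("mask shape does not match image")
    m = mask.mask
    if not np.any(m):
        raise ValueError("empty mask")
    vals = img.values[m]
    v_min, v_max = float(vals.min()), float(vals.max())
    levels = np.zeros(img.shape, dtype=np.int32)
    if v_max == v_min:
        levels[m] = 1
    else:
        raw = np.floor(n_bins * (img.values[m] - v_min) / (v_max - v_min)).astype(np.int32) + 1
        levels[m] = np.minimum(raw, n_bins)
    return LevelVolume(levels=levels, n_bins=n_bins, v_min=v_min, v_max=v_max)


def _pair_slices(d):
    """Slices (sa, sb) so that a[sa] and a[sb] are shifted by d."""
    sa, sb = [], []
    for dk in d:
        if dk == 0:
            sa.append(slice(None))
            sb.append(slice(None))
        elif dk > 0:
            sa.append(slice(None, -dk))
            sb.append(slice(dk, None))
        else:
            sa.append(slice(-dk, None))
            sb.append(slice(None, dk))
    return tuple(sa), tuple(sb)


def build_glcm(lv: LevelVolume) -> np.ndarray:
    """Merged, symmetrized, normalized co-occurrence matrix.

    Counts in-mask level pairs over the 13 unique unit directions, adds
    the transpose, merges directions and normalizes to probabilities.
    """
    n = lv.n_bins
    counts = np.zeros((n, n), dtype=np.int64)
    lev = lv.levels
    for d in DIRECTIONS:
        sa, sb = _pair_slices(d)
        a, b = lev[sa], lev[sb]
        ok = (a > 0) & (b > 0)
        if not np.any(ok):
            continue
        flat = (a[ok].astype(np.int64) - 1) * n + (b[ok] - 1)
        counts += np.bincount(flat, minlength=n * n).reshape(n, n)
    counts = counts + counts.T  # symmetrize
    total = counts.sum()
    if total == 0:
        raise ValueError("no neighboring pairs: mask too small for a GLCM")
    return counts / total


def glcm_features(glcm: np.ndarray) -> dict:
    """Joint entropy (bits), inverse-difference homogeneity, contrast and
    correlation of a normalized symmetric GLCM."""
    p = np.asarray(glcm, dtype=float)
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("GLCM must be normalized to sum 1")
    n = p.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    homogeneity = float((p / (1.0 + np.abs(ii - jj))).sum())
    contrast = float((p * (ii - jj) ** 2).sum())
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    sd_i = np.sqrt(float(((ii - mu_i) ** 2 * p).sum()))
    sd_j = np.sqrt(float(((jj - mu_j) ** 2 * p).sum()))
    if sd_i * sd_j == 0:
        correlation = 1.0
    else:
        correlation = float(((ii - mu_i) * (jj - mu_j) * p).sum() / (sd_i * sd_j))
    return {
        "entropy": entropy,
        "homogeneity": homogeneity,
        "contrast": contrast,
        "correlation": correlation,
    }


def build_glrlm(lv: LevelVolume) -> np.ndarray:
    """Merged run-length matrix r(i, j): maximal in-mask runs of equal
    level along each of the 13 directions (a direction and its negation
    are the same runs, counted once).

    Returns an (n_bins, max_run) count array.
    """
    lev = lv.levels
    inmask = lev > 0
    coords = np.argwhere(inmask)
    if len(coords) == 0:
        raise ValueError("empty mask")
    levels_flat = lev[inmask]
    runs = {}  # (level, length) -> count
    for d in DIRECTIONS:
        dv = np.asarray(d)
        norm2 = int(dv @ dv)
        pos = coords @ dv
        key = coords * norm2 - pos[:, None] * dv  # constant along each line
        order = np.lexsort((pos, key[:, 2], key[:, 1], key[:, 0]))
        k_s = key[order]
        p_s = pos[order]
        l_s = levels_flat[order]
        same_line = np.all(k_s[1:] == k_s[:-1], axis=1)
        consecutive = (p_s[1:] - p_s[:-1]) == norm2
        same_level = l_s[1:] == l_s[:-1]
        new_run = np.concatenate([[True], ~(same_line & consecutive & same_level)])
        run_ids = np.cumsum(new_run) - 1
        lengths = np.bincount(run_ids)
        run_levels = l_s[new_run]
        for lvl, length in zip(run_levels, lengths):
            kk = (int(lvl), int(length))
            runs[kk] = runs.get(kk, 0) + 1
    max_len = max(j for _, j in runs)
    r = np.zeros((lv.n_bins, max_len), dtype=np.int64)
    for (lvl, length), c in runs.items():
        r[lvl - 1, length - 1] = r[lvl - 1, length - 1] + c
    return r


def glrlm_features(glrlm: np.ndarray, normalized_rlnu: bool = True) -> dict:
    """Short-run emphasis, long-run emphasis, run-length non-uniformity.

    RLNU defaults to the run-count-normalized variant
    ``sum_j (sum_i r)^2 / N_r^2`` (in (0, 1]); ``normalized_rlnu=False``
    gives the raw variant (divide by N_r).
    """
    r = np.asarray(glrlm, dtype=float)
    n_r = r.sum()
    if n_r < 1:
        raise ValueError("run-length matrix has no runs")
    j = np.arange(1, r.shape[1] + 1)
    sre = float((r / j**2).sum() / n_r)
    lre = float((r * j**2).sum() / n_r)
    run_len_totals = r.sum(axis=0)
    rlnu = float((run_len_totals**2).sum() / (n_r**2 if normalized_rlnu else n_r))
    return {"sre": sre, "lre": lre, "rlnu": rlnu}


def build_glszm(lv: LevelVolume) -> np.ndarray:
    """Merged size-zone matrix s(i, j): 26-connected zones of constant
    level inside the mask, counted by level i and zone size j."""
    lev = lv.levels
    if not np.any(lev > 0):
        raise ValueError("empty mask")
    zones = {}  # (level, size) -> count
    for lvl in np.unique(lev[lev > 0]):
        labels, n_zones = ndimage.label(lev == lvl, structure=_STRUCT_26)
        if n_zones == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        for size in sizes:
            kk = (int(lvl), int(size))
            zones[kk] = zones.get(kk, 0) + 1
    max_size = max(j for _, j in zones)
    s = np.zeros((lv.n_bins, max_size), dtype=np.int64)
    for (lvl, size), c in zones.items():
        s[lvl - 1, size - 1] += c
    return s


def glszm_features(glszm: np.ndarray) -> dict:
    """Low and high grey-level zone emphasis."""
    s = np.asarray(glszm, dtype=float)
    n_z = s.sum()
    if n_z < 1:
        raise ValueError("size-zone matrix has no zones")
    i = np.arange(1, s.shape[0] + 1)[:, None]
    lgze = float((s / i**2).sum() / n_z)
    hgze = float((s * i**2).sum() / n_z)
    return {"lgze": lgze, "hgze": hgze}


def first_order_stats(img: VoxelImage, mask: VOIMask) -> dict:
    """Mean, max, min, population SD, percent COV and VOI volume (cm^3)."""
    if mask.mask.shape != img.shape:
        raise ValueError("mask shape does not match image")
    vals = img.values[mask.mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    mean = float(vals.mean())
    sd = float(vals.std())
    if mean == 0:
        if sd > 0:
            raise ValueError("COV undefined: zero mean with nonzero SD")
        cov = 0.0
    else:
        cov = 100.0 * sd / mean
    return {
        "mean": mean,
        "max": float(vals.max()),
        "min": float(vals.min()),
        "sd": sd,
        "cov": cov,
        "volume_cm3": mask.volume_cm3,
    }


def feature_set(
    img: VoxelImage,
    mask: VOIMask | None = None,
    n_bins: int = 64,
    isocontour_fraction: float = 0.40,
    normalized_rlnu: bool = True,
) -> FeatureSet:
    """Full evaluation of one VOI: first-order statistics plus the nine
    texture indices from GLCM, GLRLM and GLSZM.

    With no mask, the VOI is delineated by the 40% isocontour.  The input
    image is used as-is (no smoothing, interpolation or resampling).
    """
    if mask is None:
        mask = segment_isocontour(img, isocontour_fraction)
    fo = first_order_stats(img, mask)
    lv = discretize_fbn(img, mask, n_bins)
    g = glcm_features(build_glcm(lv))
    r = glrlm_features(build_glrlm(lv), normalized_rlnu=normalized_rlnu)
    z = glszm_features(build_glszm(lv))
    return FeatureSet(
        mean=fo["mean"],
        max=fo["max"],
        min=fo["min"],
        sd=fo["sd"],
        cov=fo["cov"],
        volume_cm3=fo["volume_cm3"],
        entropy=g["entropy"],
        homogeneity=g["homogeneity"],
        correlation=g["correlation"],
        contrast=g["contrast"],
        sre=r["sre"],
        lre=r["lre"],
        rlnu=r["rlnu"],
        lgze=z["lgze"],
        hgze=z["hgze"],
    )
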