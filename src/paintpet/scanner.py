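"""Virtual PET scanner for activity-painting trajectories.

The scanner is modelled as an effective linear system rather than a full
acquisition/reconstruction chain: each source stop deposits a 3-D
Gaussian point-spread function weighted by its dwell time (and decay),
the result is sampled on the scanner voxel grid, and Poisson count noise
is optionally applied.  Vendor reconstruction internals (OSEM iterations,
TOF kernels, scatter/attenuation) are deliberately outside the model —
measurements of this kind are made in air and evaluated relative to each
other, so resolution, sampling and counting statistics carry the signal.

The transaxial PSF width grows linearly with radial distance from the
scanner axis, which is what makes radial-position studies non-trivial;
"PSF correction on" is modelled as a multiplicative shrink of the
effective FWHM.

Calibration closure: the scale factor κ is fixed so that an isolated
1 s stop at the FOV centre, sampled at a voxel centre, peaks at the
calibration line's slope (kBq/ml per second of dwell).  The observed
0–6 s dwell / 0–14 kBq/ml correspondence is then reproduced by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grid import CalibrationLine
from .image import VoxelImage, _as_vec3
from .trajectory import StageModel, TrajectoryPlan

__all__ = [
    "ScannerModel",
    "SourceModel",
    "Profile",
    "simulate_noiseless",
    "simulate_acquisition",
    "line_profile",
    "plateau_cov",
    "resample_image",
    "preset_scanner",
    "PRESET_NAMES",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
NA22_HALF_LIFE_S = 2.602 * 365.25 * 24 * 3600.0  # 22Na, 2.602 years
_TRUNC_SD = 4.0  # kernel truncation radius in standard deviations


@dataclass
class SourceModel:
    """Sealed positron-emitting point source."""

    activity_kbq: float = 1100.0  # 1.1 MBq calibration source
    half_life_s: float = NA22_HALF_LIFE_S

    def __post_init__(self):
        if self.activity_kbq <= 0:
            raise ValueError("activity must be > 0")
        if self.half_life_s <= 0:
            raise ValueError("half_life must be > 0")

    def decay_factor(self, elapsed_s):
        return 2.0 ** (-np.asarray(elapsed_s, dtype=float) / self.half_life_s)


@dataclass
class ScannerModel:
    """Effective model of one PET device.

    psf_fwhm0 / psf_fwhm_axial0 : transaxial and axial FWHM (mm) on the
    scanner axis; psf_radial_slope : mm of extra transaxial FWHM per mm of
    radial distance; psf_correction_factor : multiplicative FWHM shrink
    applied when ``psf_correction`` is on; sensitivity : expected counts
    per (kBq·s) per ml of voxel volume, setting the Poisson noise level;
    calibration : dwell-to-concentration line.
    """

    name: str
    voxel_size: np.ndarray
    fov_extent: np.ndarray
    psf_fwhm0: float
    psf_fwhm_axial0: float
    psf_radial_slope: float = 0.0
    psf_correction_factor: float = 0.85
    psf_correction: bool = False
    sensitivity: float = 6.0
    calibration: CalibrationLine = field(default_factory=CalibrationLine)

    def __post_init__(self):
        self.voxel_size = _as_vec3(self.voxel_size, "voxel_size")
        self.fov_extent = _as_vec3(self.fov_extent, "fov_extent")
        if np.any(self.voxel_size <= 0) or np.any(self.fov_extent <= 0):
            raise ValueError("voxel_size and fov_extent must be positive")
        if self.psf_fwhm0 <= 0 or self.psf_fwhm_axial0 <= 0:
            raise ValueError("PSF FWHMs must be > 0")
        if self.psf_radial_slope < 0:
            raise ValueError("psf_radial_slope must be >= 0")
        if not (0 < self.psf_correction_factor <= 1):
            raise ValueError("psf_correction_factor must be in (0, 1]")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be > 0")
        if isinstance(self.calibration, dict):
            self.calibration = CalibrationLine(**self.calibration)

    @property
    def grid_shape(self) -> tuple:
        return tuple(int(round(e / v)) for e, v in zip(self.fov_extent, self.voxel_size))

    @property
    def grid_origin(self) -> np.ndarray:
        n = np.asarray(self.grid_shape)
        return -(n - 1) * self.voxel_size / 2.0

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) * 1e-3

    def effective_fwhm(self, radius_mm: float) -> tuple:
        """(transaxial, axial) FWHM in mm at a given radial distance."""
        corr = self.psf_correction_factor if self.psf_correction else 1.0
        trans = (self.psf_fwhm0 + self.psf_radial_slope * radius_mm) * corr
        axial = self.psf_fwhm_axial0 * corr
        if trans <= 0 or axial <= 0:
            raise ValueError("effective FWHM must be > 0 after correction")
        return trans, axial

    def empty_image(self, **meta) -> VoxelImage:
        return VoxelImage(
            values=np.zeros(self.grid_shape),
            voxel_size=self.voxel_size,
            origin=self.grid_origin,
            meta={"scanner": self.name, **meta},
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "voxel_size_mm": self.voxel_size.tolist(),
            "fov_extent_mm": self.fov_extent.tolist(),
            "psf_fwhm0_mm": self.psf_fwhm0,
            "psf_fwhm_axial0_mm": self.psf_fwhm_axial0,
            "psf_radial_slope": self.psf_radial_slope,
            "psf_correction_factor": self.psf_correction_factor,
            "psf_correction": self.psf_correction,
            "sensitivity": self.sensitivity,
            "calibration": {
                "dwell_max": self.calibration.dwell_max,
                "conc_max": self.calibration.conc_max,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScannerModel":
        return cls(
            name=d["name"],
            voxel_size=d["voxel_size_mm"],
            fov_extent=d["fov_extent_mm"],
            psf_fwhm0=d["psf_fwhm0_mm"],
            psf_fwhm_axial0=d["psf_fwhm_axial0_mm"],
            psf_radial_slope=d.get("psf_radial_slope", 0.0),
            psf_correction_factor=d.get("psf_correction_factor", 0.85),
            psf_correction=d.get("psf_correction", False),
            sensitivity=d.get("sensitivity", 6.0),
            calibration=CalibrationLine(**d.get("calibration", {})),
        )

    @classmethod
    def from_json(cls, path) -> "ScannerModel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def with_correction(self, on: bool) -> "ScannerModel":
        return replace(self, psf_correction=on)


# Bundled device presets.  Voxel sizes and on-axis FWHMs follow the three
# published device classes (4 mm PMT clinical, 2.73 mm SiPM-TOF clinical,
# 0.4 mm preclinical); radial slopes and sensitivities are effective-model
# parameters chosen to be representative and are documented as such.
def _presets() -> dict:
    cal = CalibrationLine(dwell_max=6.0, conc_max=14.0)
    return {
        # FOV extents are chosen to give an odd voxel count per axis so the
        # FOV centre is a voxel centre and centred painting grids align
        # with the voxel lattice
        "clinical_pmt_4mm": ScannerModel(
            name="clinical_pmt_4mm",
            voxel_size=4.0,
            fov_extent=(300.0, 300.0, 164.0),
            psf_fwhm0=4.58,
            psf_fwhm_axial0=4.58,
            psf_radial_slope=0.02,
            sensitivity=3.0,
            calibration=cal,
        ),
        "clinical_sipm_273mm": ScannerModel(
            name="clinical_sipm_273mm",
            voxel_size=2.73,
            fov_extent=(297.57, 297.57, 161.07),
            psf_fwhm0=4.57,
            psf_fwhm_axial0=4.57,
            psf_radial_slope=0.02,
            sensitivity=12.0,
            calibration=cal,
        ),
        "preclinical_04mm": ScannerModel(
            name="preclinical_04mm",
            voxel_size=0.4,
            fov_extent=(80.4, 80.4, 60.4),
            psf_fwhm0=0.91,
            psf_fwhm_axial0=0.91,
            psf_radial_slope=0.01,
            sensitivity=40.0,
            calibration=cal,
        ),
    }


PRESET_NAMES = tuple(_presets().keys())


def preset_scanner(name: str) -> ScannerModel:
    """One of the three bundled scanner presets (fresh copy)."""
    presets = _presets()
    if name not in presets:
        raise KeyError(f"unknown scanner preset {name!r}; available: {PRESET_NAMES}")
    return presets[name]


@dataclass
class Profile:
    """1-D line profile through an image."""

    positions: np.ndarray
    values: np.ndarray
    axis: str = "x"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape or self.positions.ndim != 1:
            raise ValueError("positions and values must be equal-length 1-D arrays")
        if len(self.positions) > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


def _gauss_1d(offsets: np.ndarray, sigma: float) -> np.ndarray:
    g = np.exp(-0.5 * (offsets / sigma) ** 2)
    return g


def _kernel_peak_on_axis(scanner: ScannerModel) -> float:
    """Peak (ml^-1) of a unit-dwell deposit for a source exactly at a voxel
    centre on the scanner axis — the calibration reference condition."""
    trans, axial = scanner.effective_fwhm(0.0)
    peak = 1.0
    for k, fwhm in enumerate((trans, trans, axial)):
        sigma = fwhm * FWHM_TO_SIGMA
        # same truncation rule as the deposit loop: voxel centres within 4 SD
        half = int(np.floor(_TRUNC_SD * sigma / scanner.voxel_size[k]))
        offs = np.arange(-half, half + 1) * scanner.voxel_size[k]
        g = _gauss_1d(offs, sigma)
        peak *= g.max() / g.sum()
    return peak / scanner.voxel_volume_ml


def _emission_points(
    plan: TrajectoryPlan, stage: StageModel | None, travel_emission: bool, voxel_size: np.ndarray
):
    """Positions (M,3), weights (M,) in seconds, elapsed times (M,) s.

    Stops contribute their dwell; with a stage, travel legs are subsampled
    at <= min(voxel)/4 spacing and weighted by traversal time.
    """
    seg_len = plan.segment_lengths()
    if stage is not None:
        travel_t = seg_len / stage.speed
    else:
        travel_t = np.zeros_like(seg_len)
    # elapsed time at the midpoint of each dwell
    arrival = np.concatenate([[0.0], np.cumsum(plan.dwells[:-1] + travel_t)])
    positions = [plan.positions]
    weights = [plan.dwells]
    times = [arrival + plan.dwells / 2.0]
    if travel_emission and stage is not None:
        spacing = float(np.min(voxel_size)) / 4.0
        for i in range(len(plan) - 1):
            if seg_len[i] <= 0:
                continue
            n_sub = max(int(np.ceil(seg_len[i] / spacing)), 1)
            frac = (np.arange(n_sub) + 0.5) / n_sub
            p0, p1 = plan.positions[i], plan.positions[i + 1]
            positions.append(p0 + frac[:, None] * (p1 - p0))
            weights.append(np.full(n_sub, travel_t[i] / n_sub))
            times.append(np.full(n_sub, arrival[i] + plan.dwells[i] + travel_t[i] / 2.0))
    return (
        np.concatenate(positions, axis=0),
        np.concatenate(weights),
        np.concatenate(times),
    )


def simulate_noiseless(
    plan: TrajectoryPlan,
    scanner: ScannerModel,
    source: SourceModel | None = None,
    radial_offset: float = 0.0,
    stage: StageModel | None = None,
    travel_emission: bool = True,
) -> VoxelImage:
    """Deterministic reconstructed-like image of a painted trajectory.

    Each emission point deposits a separable Gaussian PSF (truncated at
    4 SD and renormalized to unit spatial integral) weighted by its dwell
    time and the source decay factor at that moment.  The transaxial FWHM
    grows linearly with the point's radial distance.  ``radial_offset``
    rigidly translates the whole trajectory along +x.  Travel-leg emission
    requires a ``stage`` (for traversal times) and is then on by default.
    """
    if source is None:
        source = SourceModel()
    shape = scanner.grid_shape
    origin = scanner.grid_origin
    vox = scanner.voxel_size
    img = np.zeros(shape)

    offset = np.array([radial_offset, 0.0, 0.0])
    # FOV bounds check on the stop positions (named error per waypoint)
    hi = origin + (np.asarray(shape) - 1) * vox
    shifted = plan.positions + offset
    out = (shifted < origin - 1e-9) | (shifted > hi + 1e-9)
    if np.any(out):
        k = int(np.argmax(out.any(axis=1)))
        raise ValueError(
            f"waypoint {k} at {shifted[k]} mm falls outside the scanner FOV"
        )

    pts, wts, times = _emission_points(plan, stage, travel_emission, vox)
    pts = pts + offset
    wts = wts * source.decay_factor(times)

    slope = scanner.calibration.slope  # kBq/ml per dwell second
    kappa = slope / _kernel_peak_on_axis(scanner)

    axes_coords = [origin[k] + np.arange(shape[k]) * vox[k] for k in range(3)]
    for p, w in zip(pts, wts):
        if w <= 0:
            continue
        radius = float(np.hypot(p[0], p[1]))
        trans, axial = scanner.effective_fwhm(radius)
        kern1d = []
        windows = []
        for k, fwhm in enumerate((trans, trans, axial)):
            sigma = fwhm * FWHM_TO_SIGMA
            half = _TRUNC_SD * sigma
            lo_i = max(int(np.ceil((p[k] - half - origin[k]) / vox[k])), 0)
            hi_i = min(int(np.floor((p[k] + half - origin[k]) / vox[k])), shape[k] - 1)
            if hi_i < lo_i:  # support entirely between voxel centres / outside
                lo_i = hi_i = int(np.clip(round((p[k] - origin[k]) / vox[k]), 0, shape[k] - 1))
            offs = axes_coords[k][lo_i : hi_i + 1] - p[k]
            g = _gauss_1d(offs, sigma)
            kern1d.append(g / g.sum())
            windows.append(slice(lo_i, hi_i + 1))
        kern = kern1d[0][:, None, None] * kern1d[1][None, :, None] * kern1d[2][None, None, :]
        img[windows[0], windows[1], windows[2]] += (kappa * w / scanner.voxel_volume_ml) * kern

    return VoxelImage(
        values=img,
        voxel_size=vox,
        origin=origin,
        meta={
            "scanner": scanner.name,
            "noiseless": True,
            "radial_offset_mm": radial_offset,
            "psf_correction": scanner.psf_correction,
        },
    )


def simulate_acquisition(
    plan: TrajectoryPlan,
    scanner: ScannerModel,
    source: SourceModel | None = None,
    radial_offset: float = 0.0,
    seed: int = 0,
    stage: StageModel | None = None,
    travel_emission: bool = True,
) -> VoxelImage:
    """Noisy acquisition: Poisson counts on top of the noiseless image.

    Expected counts per voxel are ``sensitivity * concentration *
    voxel_volume_ml * total_plan_time``; a Poisson draw is rescaled back
    to concentration units.  Seeded and reproducible; the seed-averaged
    image converges to the noiseless one.
    """
    noiseless = simulate_noiseless(
        plan, scanner, source, radial_offset, stage=stage, travel_emission=travel_emission
    )
    if stage is not None:
        from .trajectory import total_time

        t_norm = total_time(plan, stage)
    else:
        t_norm = plan.total_dwell_s
    scale = scanner.sensitivity * scanner.voxel_volume_ml * t_norm
    lam = noiseless.values * scale
    if lam.max() > 1e15:
        raise OverflowError(
            "expected counts overflow; lower the scanner sensitivity or plan time"
        )
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam)
    noisy = counts / scale
    return VoxelImage(
        values=noisy,
        voxel_size=noiseless.voxel_size,
        origin=noiseless.origin,
        meta={**noiseless.meta, "noiseless": False, "seed": int(seed)},
    )


def expected_counts(img: VoxelImage, scanner: ScannerModel, t_norm: float) -> np.ndarray:
    """Expected Poisson counts per voxel for a noiseless image."""
    return img.values * scanner.sensitivity * scanner.voxel_volume_ml * t_norm


def line_profile(img: VoxelImage, axis: int | str, at_mm=(0.0, 0.0)) -> Profile:
    """Voxel values along one axis at fixed transverse mm coordinates
    (nearest-voxel selection on the transverse axes)."""
    axis_names = {"x": 0, "y": 1, "z": 2}
    ax = axis_names.get(axis, axis) if isinstance(axis, str) else int(axis)
    if ax not in (0, 1, 2):
        raise ValueError("axis must be one of x/y/z or 0/1/2")
    other = [k for k in range(3) if k != ax]
    at_mm = np.asarray(at_mm, dtype=float)
    sel = []
    for k, a in zip(other, at_mm):
        i = int(round((a - img.origin[k]) / img.voxel_size[k]))
        if not (0 <= i < img.shape[k]):
            raise ValueError(f"requested line at {a} mm is outside the image on axis {k}")
        sel.append(i)
    index = [slice(None)] * 3
    index[other[0]], index[other[1]] = sel
    return Profile(
        positions=img.voxel_centers(ax),
        values=img.values[tuple(index)],
        axis="xyz"[ax],
    )


def plateau_cov(profile: Profile, margin_mm: float = 0.0) -> float:
    """Percent coefficient of variation over the profile plateau.

    The plateau is the profile support (strictly positive samples) with
    ``margin_mm`` trimmed from both ends; population SD convention.
    """
    nz = np.nonzero(profile.values > 0)[0]
    if len(nz) == 0:
        raise ValueError("profile has empty support")
    lo = profile.positions[nz[0]] + margin_mm
    hi = profile.positions[nz[-1]] - margin_mm
    sel = (profile.positions >= lo - 1e-9) & (profile.positions <= hi + 1e-9)
    vals = profile.values[sel]
    if len(vals) < 3:
        raise ValueError("plateau contains fewer than 3 samples")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("plateau mean is zero")
    return float(100.0 * vals.std() / mean)


_RESAMPLE_ORDERS = {"spline": 3, "trilinear": 1, "nearest": 0}


def resample_image(img: VoxelImage, new_voxel, method: str = "spline") -> VoxelImage:
    """Resample onto a new voxel size covering the same physical extent.

    Cubic-spline interpolation by default (the voxel-harmonization
    convention); trilinear and nearest are available.  The new grid has
    ``round(extent/new_voxel)`` voxels per axis, centred on the old image
    centre; total activity is preserved to within about a percent for
    smooth images.
    """
    if method not in _RESAMPLE_ORDERS:
        raise ValueError(f"method must be one of {sorted(_RESAMPLE_ORDERS)}")
    new_voxel = _as_vec3(new_voxel, "new_voxel")
    if np.any(new_voxel <= 0):
        raise ValueError("new_voxel must be > 0")
    extent = img.extent_mm
    new_shape = np.maximum(np.round(extent / new_voxel).astype(int), 1)
    if np.any(new_shape < 2):
        raise ValueError("new grid would have fewer than 2 voxels on some axis")
    if np.array_equal(new_voxel, img.voxel_size):
        return VoxelImage(
            values=img.values.copy(),
            voxel_size=img.voxel_size,
            origin=img.origin,
            meta={**img.meta, "resampled": "identity"},
        )
    zoom = new_shape / np.asarray(img.shape)
    # edge mode "nearest": exact for constant images and equivalent to a
    # zero background for the compact-support phantom images made here
    values = ndimage.zoom(
        img.values,
        zoom,
        order=_RESAMPLE_ORDERS[method],
        grid_mode=True,
        mode="nearest",
    )
    assert values.shape == tuple(new_shape)
    new_origin = img.center_mm - (new_shape - 1) * new_voxel / 2.0
    return VoxelImage(
        values=values,
        voxel_size=new_voxel,
        origin=new_origin,
        meta={**img.meta, "resampled": method, "resampled_from_mm": img.voxel_size.tolist()},
    )
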