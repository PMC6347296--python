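# Methods

This note records the models behind `paintpet`, the parameter choices that
matter, and what the simulated studies can and cannot say about physical
acquisitions.

## Painting model

A painted distribution is a dwell-time matrix (DTM): one stop duration per
point of an isotropic cubic grid (`GridGeometry`: step size, extent,
FOV-centred origin; points per axis `floor(extent/step)+1`). Shapes are
rasterized with inclusive boundary comparisons — a grid point exactly on
the surface is inside — so results are deterministic and sphere volumes
are slightly biased upward by at most a voxel shell. The heart shape uses
the classic implicit sextic surface `(x² + (9/4)y² + z² − 1)³ − x²z³ −
(9/80)y²z³ ≤ 0`, scaled by `size/2.6` so the whole surface fits in the
declared `size` bounding cube. The gradient cube ramps dwell linearly in
Chebyshev distance from the centre (cubic isolevels; Euclidean available),
reaching 0 exactly on the surface.

DTMs extracted from images invert the calibration line
`concentration = (conc_max/dwell_max)·dwell` (defaults 14 kBq/ml at 6 s,
intercept fixed at zero) after trilinear sampling of the target at the
grid points; negative samples clamp to zero and super-range values either
clamp to `dwell_max` or extrapolate linearly (`clip_above`).

## Trajectory model

Plans are serpentine: x is the fastest axis and reverses on every
traversed row, y reverses on every plane, so consecutive waypoints always
differ by exactly one grid step — the stage never retraces and total
travel length is exactly `(N−1)·step`. `skip_empty` drops whole x-rows
with no positive dwell; the resulting non-adjacent legs are flagged as
jumps. Zero-dwell points on kept rows are traversed (pass-through at
constant speed), matching a continuous-pathway stage.

Total time = Σ dwell + Σ leg length / speed + settle time per positive
stop. Stage speed defaults to 10 mm/s (representative of the small
motorized-stage class; it only affects time accounting and optional
travel emission, not the default images). Jitter — zero-mean Gaussian on
dwells (truncated at 0) and isotropic Gaussian on positions — is seeded
and defaults to zero; physical stages of this class are specified around
20 µm positioning and millisecond timing, so the defaults treat the stage
as deterministic.

## Scanner model

The scanner is an effective linear system, not a reconstruction chain:

* Each emission point deposits a separable 3-D Gaussian sampled at voxel
  centres, truncated at 4 SD and renormalized to unit integral, so counts
  are conserved exactly whenever the support is inside the FOV.
* Transaxial FWHM grows linearly with radial distance:
  `FWHM(r) = FWHM₀ + slope·r` (defaults: 4.58/4.57/0.91 mm on-axis for
  the three presets; slope 0.02 mm/mm clinical, 0.01 preclinical — an
  effective-model parameter, since radial degradation profiles are
  device-specific). Axial FWHM is constant. "PSF correction on"
  multiplies both by `psf_correction_factor` (default 0.85); how vendor
  resolution modelling really reshapes the PSF and noise is not
  derivable from published tables, so this factor is deliberately a free
  parameter.
* Calibration closure: the global scale κ is fixed so that an isolated
  1 s stop at a voxel centre on the axis peaks at the calibration slope
  (14/6 kBq/ml per second). Inside a filled 4 mm grid, spill-in from
  neighbouring stops raises plateau values above the single-stop peak —
  that is physics, not an inconsistency (see
  `examples/03_gradient_cube_calibration.py`).
* Decay uses the dwell-midpoint elapsed time with the ²²Na half-life
  (2.602 y); over typical ≤2 h plans this is a ≤1e-4 effect. Travel-leg
  emission (segments subsampled at ≤ voxel/4 and weighted by traversal
  time) requires a stage model and is off by default — the default mode
  treats travel as instantaneous.
* Noise: expected counts per voxel `n(v) = sensitivity ·
  concentration(v) · voxel volume · total plan time`, one independent
  Poisson draw per voxel, rescaled back to concentration. Sensitivities
  are illustrative, set once so the painted homogeneous 48 mm cube shows
  a 20 ml-VOI COV in the low-percent range reported for such phantoms
  (~2.3 % at the 4 mm preset), and frozen.
* Preset FOV extents give an odd voxel count per axis so the FOV centre
  is a voxel centre and centred 4 mm painting grids align with the voxel
  lattice; this makes the calibration closure and round-trip recovery
  exact rather than phase-dependent.

`resample_image` (voxel harmonization) uses `scipy.ndimage.zoom` with
cell-edge alignment (`grid_mode=True`) and nearest-edge boundary
handling, which is exact for constant images and equivalent to a zero
background for compact-support phantom images; the default order-3
spline is the harmonization convention, with trilinear and nearest as
alternatives. When the new voxel does not divide the extent, the new
grid has `round(extent/new_voxel)` voxels centred on the old centre (the
coverage mismatch is sub-voxel).

## Radiomics protocol

Delineation: voxels ≥ 40 % of the global maximum, reduced to the largest
26-connected component containing the maximum (first index wins on
ties). Discretization: 64 fixed bins over the in-mask min–max range,
`level = min(⌊N_b (v−v_min)/(v_max−v_min)⌋+1, N_b)`, constant regions all
map to level 1 — features are therefore invariant under positive affine
intensity transforms.

Texture matrices use the 13 unique unit-displacement 3-D directions
(half the 26-neighbourhood; a direction and its negation index the same
pairs and runs). All directions are merged into a single matrix rather
than averaged per direction — with closed-source reference software the
aggregation rule is not observable, and merging is the convention most
compatible with a fully connected 3-D analysis; per-direction averaging
would change the run/zone count normalizations but not the GLCM
probabilities. The GLCM is symmetrized and normalized; GLRLM runs are
maximal in-mask equal-level segments per direction; GLSZM zones are
26-connected equal-level components.

Two definitional edge cases are fixed: GLCM correlation is 1 when a
marginal SD vanishes (the co-occurrence is perfectly predictable), and
RLNU defaults to the run-count-normalized variant (÷N_r², bounded in
(0,1], the variant consistent with reported sub-unity values); the raw
Galloway form (÷N_r) is available via `normalized_rlnu=False`. SD is
population SD (÷N) everywhere, entropy is in bits.

All three matrix builders are validated against independent brute-force
enumerations (explicit neighbour loops, run walks and flood fill in
`tests/_oracles.py`) to 1e-12 on ~50 random small volumes per run.

## Studies and the lesion fixture

The four study drivers are pure functions of (config, seeds); reports
carry full provenance and re-running from it is byte-identical.

The heterogeneous lesion is a seeded stand-in for a patient-derived
dwell pattern (synthetic by construction): a spheroidal envelope (flat
core to 0.42·size, smooth sine² rolloff to 0.55·size) modulated by a
Gaussian random field low-pass filtered at σ = 1.2 grid steps; values
below 20 % of the maximum are zeroed, the heterogeneity amplitude is set
by deterministic bisection so the nonzero-dwell COV is 0.32 (the
mid-range of lesion voxel COVs around 30 %), and the result is scaled to
peak at 6 s — the top of the linear calibration range. On the default
48 mm grid this yields a ~55 cm³ blob. What it emulates: smooth
multi-scale uptake heterogeneity at a fixed global COV. What it does
not: patient-specific spatial frequency content, necrotic cores, or any
specific reported lesion — cross-condition results with it are
qualitative orderings, never value matches to any physical acquisition.

Study-specific choices:

* *Uniformity*: painted lines are 80 mm long with 1 s dwell; the plateau
  is the strictly-positive profile support minus a margin of 3×FWHM per
  end. The line-profile part is simulated on a 1 mm analysis grid
  (same PSF) because on the native 4 mm grid the ripple — whose period
  is the step size — aliases with the voxel sampling; the
  homogeneous-cube COV part uses the native grid and a geometric
  centred 20 ml spherical VOI.
* *Reproducibility*: hot/background statistics use geometric masks
  (known 36 mm sphere inside the 48 mm cube), removing segmentation
  noise from the repeat COVs.
* *Position dependence*: the same lesion plan is rigidly offset along x;
  exact feature equality at zero radial slope holds for offsets that are
  multiples of the voxel pitch (other offsets change the sampling phase
  of the PSF, which is a real effect, not an artefact).
* *Scanner comparison*: percent differences use the symmetric convention
  `100·|a−b| / ((a+b)/2)`. A preclinical device is compared by scaling
  the DTM geometry (not its values) by 1/4, mirroring step-size
  translation between human and animal systems.

## Known limitations

* Region-mean repeatability follows pure counting statistics: the COV of
  a compartment mean is `1/√(total expected counts)` in that compartment.
  Physical scanners add reconstruction-correlated and low-count noise
  that makes background means relatively noisier than this model
  predicts; orderings that depend on that extra noise are outside the
  model.
* No attenuation, scatter, randoms, TOF, or iterative-reconstruction
  texture; noise is voxel-independent.
* The dwell→counts scaling uses the total plan time for every voxel (a
  global exposure normalization), not per-voxel source proximity.
* Isotropic grids only; shapes are axis-aligned (no rotations);
  single-source plans.
* Problem sizes default to the 48 mm / 4 mm-step configuration (13³
  grid, clinical images ≤ 75×75×41 voxels), which keeps every bundled
  study and the full test suite in the seconds-to-minutes range on one
  CPU.
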