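"""Motion planning for the 3-axis source-positioning stage.

A DTM is executed by moving the point source along a serpentine
(boustrophedon) path over the grid, stopping at each grid point for its
dwell time.  The fastest axis is x, then y, then z; the x direction
alternates on every traversed row and the y direction on every plane, so
consecutive waypoints always differ by exactly one grid step on one axis.

With ``skip_empty`` the planner drops whole grid lines (rows along x)
whose dwell values are all zero; the plan may then jump between line ends
and those legs are flagged.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grid import DwellTimeMatrix, GridGeometry

__all__ = [
    "StageModel",
    "TrajectoryPlan",
    "plan_path",
    "total_time",
    "apply_timing_jitter",
    "export_motion_script",
    "load_motion_script",
]


@dataclass
class StageModel:
    """Kinematic model of the linear-stage ensemble.

    speed : mm/s, common to all three axes (a common value minimizes
    timing artefacts between axes); jitter SDs model positioning and dwell
    timing noise; settle_time is added per stop with positive dwell.
    """

    speed: float = 10.0
    position_jitter_sd: float = 0.0
    dwell_jitter_sd: float = 0.0
    settle_time: float = 0.0

    def __post_init__(self):
        if self.speed <= 0:
            raise ValueError("stage speed must be > 0")
        if self.position_jitter_sd < 0 or self.dwell_jitter_sd < 0:
            raise ValueError("jitter SDs must be >= 0")
        if self.settle_time < 0:
            raise ValueError("settle_time must be >= 0")


@dataclass
class TrajectoryPlan:
    """Ordered waypoints with dwell times.

    positions : (N, 3) physical mm; dwells : (N,) seconds; jump_legs :
    (N,) bool, True where the leg *arriving* at waypoint i is a jump
    (non-adjacent move created by skip_empty); element 0 is always False.
    """

    positions: np.ndarray
    dwells: np.ndarray
    grid: GridGeometry
    ordering: str = "serpentine"
    skip_empty: bool = False
    jump_legs: np.ndarray = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.dwells = np.asarray(self.dwells, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if self.dwells.shape != (self.positions.shape[0],):
            raise ValueError("dwells must be (N,)")
        if np.any(self.dwells < 0):
            raise ValueError("dwell times must be >= 0")
        if self.jump_legs is None:
            self.jump_legs = np.zeros(len(self.dwells), dtype=bool)
        self.jump_legs = np.asarray(self.jump_legs, dtype=bool)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def total_dwell_s(self) -> float:
        return float(self.dwells.sum())

    def segment_lengths(self) -> np.ndarray:
        """Euclidean leg lengths between consecutive waypoints (mm)."""
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)


def _serpentine_indices(shape: tuple) -> np.ndarray:
    """(N, 3) integer indices in serpentine visit order."""
    nx, ny, nz = shape
    order = []
    row_parity = 0
    for iz in range(nz):
        ys = range(ny) if iz % 2 == 0 else range(ny - 1, -1, -1)
        for iy in ys:
            xs = range(nx) if row_parity == 0 else range(nx - 1, -1, -1)
            order.extend((ix, iy, iz) for ix in xs)
            row_parity ^= 1
    return np.asarray(order, dtype=int)


def plan_path(dtm: DwellTimeMatrix, skip_empty: bool = False) -> TrajectoryPlan:
    """Serpentine traversal of the DTM grid.

    With ``skip_empty`` off every grid point appears exactly once and
    consecutive waypoints are one grid step apart.  With it on, rows along
    x whose dwell values are all zero are dropped; the first waypoint after
    a dropped run is flagged as a jump leg.
    """
    idx = _serpentine_indices(dtm.grid.shape)
    if skip_empty:
        # keep rows (fixed y,z) containing at least one positive dwell
        row_has_signal = np.any(dtm.dwell > 0, axis=0)  # (ny, nz)
        keep = row_has_signal[idx[:, 1], idx[:, 2]]
        if not np.any(keep):
            raise ValueError("empty DTM: no rows with positive dwell")
        idx = idx[keep]
    dwells = dtm.dwell[idx[:, 0], idx[:, 1], idx[:, 2]]
    positions = dtm.grid.origin + idx * dtm.grid.step_size
    jump = np.zeros(len(idx), dtype=bool)
    if len(idx) > 1:
        step_counts = np.abs(np.diff(idx, axis=0)).sum(axis=1)
        jump[1:] = step_counts != 1
    return TrajectoryPlan(
        positions=positions,
        dwells=dwells,
        grid=dtm.grid,
        skip_empty=skip_empty,
        jump_legs=jump,
    )


def total_time(plan: TrajectoryPlan, stage: StageModel) -> float:
    """Total acquisition time in seconds.

    Sum of dwell times, travel time (leg length / speed, jumps included as
    straight-line moves), and one settle time per stop with positive dwell.
    """
    travel = plan.segment_lengths().sum() / stage.speed
    stops = int(np.count_nonzero(plan.dwells > 0))
    return float(plan.dwells.sum() + travel + stops * stage.settle_time)


def apply_timing_jitter(plan: TrajectoryPlan, stage: StageModel, seed: int) -> TrajectoryPlan:
    """Perturb dwell times and positions with seeded Gaussian noise.

    Dwells get zero-mean noise of SD ``dwell_jitter_sd`` truncated at 0;
    positions get isotropic noise of SD ``position_jitter_sd``.  The same
    seed always reproduces the same plan.
    """
    rng = np.random.default_rng(seed)
    dwells = plan.dwells.copy()
    if stage.dwell_jitter_sd > 0:
        dwells = np.clip(dwells + rng.normal(0.0, stage.dwell_jitter_sd, dwells.shape), 0.0, None)
    positions = plan.positions.copy()
    if stage.position_jitter_sd > 0:
        positions = positions + rng.normal(0.0, stage.position_jitter_sd, positions.shape)
    return TrajectoryPlan(
        positions=positions,
        dwells=dwells,
        grid=plan.grid,
        ordering=plan.ordering,
        skip_empty=plan.skip_empty,
        jump_legs=plan.jump_legs.copy(),
    )


def export_motion_script(plan: TrajectoryPlan, path) -> None:
    """Write the plan as CSV: one ``x_mm,y_mm,z_mm,dwell_s`` row per
    waypoint in execution order, dwell at ms precision, preceded by a
    ``#``-comment header carrying the grid metadata as JSON."""
    meta = plan.grid.to_dict()
    meta["ordering"] = plan.ordering
    meta["skip_empty"] = plan.skip_empty
    buf = io.StringIO()
    buf.write(f"# paintpet motion script {json.dumps(meta)}\n")
    buf.write("x_mm,y_mm,z_mm,dwell_s\n")
    for (x, y, z), t in zip(plan.positions, plan.dwells):
        buf.write(f"{x:.6f},{y:.6f},{z:.6f},{t:.3f}\n")
    Path(path).write_text(buf.getvalue())


def load_motion_script(path) -> TrajectoryPlan:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("# paintpet motion script "):
        raise ValueError("not a paintpet motion script")
    meta = json.loads(lines[0][len("# paintpet motion script "):])
    grid = GridGeometry.from_dict(meta)
    rows = [ln.split(",") for ln in lines[2:] if ln.strip()]
    positions = np.array([[float(v) for v in r[:3]] for r in rows])
    dwells = np.array([float(r[3]) for r in rows])
    return TrajectoryPlan(
        positions=positions,
        dwells=dwells,
        grid=grid,
        ordering=meta.get("ordering", "serpentine"),
        skip_empty=meta.get("skip_empty", False),
    )
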