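"""Simulation engine: initial conditions, dual-clock loop, replicates.

The spheroid starts as a hexagonally packed disc of cells at the centre of a
square domain, surrounded by a homogeneous matrix (density 1 outside the
spheroid footprint, 0 underneath it).  The loop advances mechanics
(voxel selection -> degradation -> direction resampling -> velocities ->
positions) every ``dt_mech`` and phenotype (volume growth, division) every
``dt_cell``, and records measurement snapshots every 60 simulated minutes.

Each replicate owns a single seeded PCG64 stream, consumed in a fixed,
documented order (per mechanics step: one uniform + one angle per cell for
the persistence resampling; per phenotype step: one uniform + one angle per
cell for division), so a (configuration, seed) pair reproduces bit-identical
trajectories.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels, metrics as _metrics
from .cycle import grow_volume, inhibition_factor, radius_from_volume
from .ecm import ECMGrid
from .params import ModelParams

__all__ = [
    "SimulationState",
    "SimulationResult",
    "SimulationError",
    "ConfigurationError",
    "calibrate_spacing",
    "hex_disc_points",
    "init_spheroid",
    "run",
    "run_replicates",
]

SNAPSHOT_INTERVAL_MIN = 60.0
TARGET_INITIAL_CELLS = 139  # 200 um spheroid at the default cell volume
CALIBRATION_RADIUS_UM = 100.0


class SimulationError(RuntimeError):
    """The simulation reached an invalid state (NaN / domain exit)."""


class ConfigurationError(ValueError):
    """The configuration cannot produce a valid initial condition."""


# --------------------------------------------------------------------------
# initial condition


def hex_disc_points(spacing: float, radius: float) -> np.ndarray:
    """Hexagonal lattice points (including the origin) within a disc.

    Rows are ``spacing * sqrt(3)/2`` apart with odd rows offset by half a
    spacing; a point is kept when its centre lies within ``radius`` of the
    origin.  A disc smaller than one spacing yields the single origin point.
    """
    if radius < 0:
        raise ConfigurationError("disc radius must be >= 0")
    row_h = spacing * math.sqrt(3.0) / 2.0
    n_rows = int(math.ceil(radius / row_h)) + 1
    n_cols = int(math.ceil(radius / spacing)) + 1
    pts = []
    r2 = radius * radius + 1e-9  # tolerate roundoff on the rim
    for j in range(-n_rows, n_rows + 1):
        y = j * row_h
        off = 0.5 * spacing if (j % 2) else 0.0
        for i in range(-n_cols - 1, n_cols + 2):
            x = i * spacing + off
            if x * x + y * y <= r2:
                pts.append((x, y))
    return np.array(pts, dtype=np.float64)


def calibrate_spacing(cell_radius: float,
                      target_count: int = TARGET_INITIAL_CELLS,
                      calibration_radius: float = CALIBRATION_RADIUS_UM,
                      n_scan: int = 2001) -> float:
    """Packing spacing such that a 100 um disc holds exactly 139 cells.

    The spacing is scanned over ``[1.8 R, 2.0 R]`` (slight overlap to exact
    contact); the returned value is the midpoint of the plateau of spacings
    that seed the target count, so the calibration is robust to roundoff.
    """
    scan = np.linspace(1.8 * cell_radius, 2.0 * cell_radius, n_scan)
    hits = [a for a in scan
            if len(hex_disc_points(a, calibration_radius)) == target_count]
    if not hits:
        raise ConfigurationError(
            f"no spacing in [1.8R, 2.0R] (R={cell_radius:.3f} um) seeds "
            f"exactly {target_count} cells in a {calibration_radius} um disc"
        )
    return float(0.5 * (hits[0] + hits[-1]))


@dataclass
class SimulationState:
    """Complete mutable simulation state (cells + field + clock + RNG)."""

    params: ModelParams
    grid: ECMGrid
    pos: np.ndarray            # (n, 2) um, z fixed at 0
    vol: np.ndarray            # (n,) um^3
    dirs: np.ndarray           # (n, 2) motility unit directions (or zero)
    ids: np.ndarray            # (n,) stable integer identities
    rng: np.random.Generator
    seed: int
    step: int = 0              # mechanics steps taken
    next_id: int = 0
    divisions: int = 0
    packing_spacing: float = 0.0

    @property
    def clock_min(self) -> float:
        return self.step * self.params.dt_mech

    @property
    def n_cells(self) -> int:
        return self.pos.shape[0]

    @property
    def radii(self) -> np.ndarray:
        return radius_from_volume(self.vol)

    def cell_table(self) -> pd.DataFrame:
        """Per-cell snapshot table (the engine's cell CSV schema)."""
        rad = self.radii
        rho = _position_voxel_density(self)
        speed = 4.0 * self.params.S_rib * rho * (1.0 - rho)
        speed[np.hypot(self.dirs[:, 0], self.dirs[:, 1]) == 0] = 0.0
        return pd.DataFrame({
            "id": self.ids,
            "x_um": self.pos[:, 0],
            "y_um": self.pos[:, 1],
            "radius_um": rad,
            "volume_um3": self.vol,
            "dir_x": self.dirs[:, 0],
            "dir_y": self.dirs[:, 1],
            "speed_um_min": speed,
        })


def init_spheroid(params: ModelParams, seed: int,
                  diameter: float | None = None) -> SimulationState:
    """Build the initial spheroid + matrix state.

    Cells are hexagonally packed (calibrated spacing, see
    :func:`calibrate_spacing`) in a disc of the given diameter centred at the
    origin, at full volume with zero motility direction.  The matrix starts
    at density 1 everywhere except voxels whose centres fall under the
    spheroid, where it is 0.
    """
    diameter = params.spheroid_diameter if diameter is None else diameter
    radius = diameter / 2.0
    if radius > params.domain_half_width:
        raise ConfigurationError("spheroid does not fit inside the domain")
    spacing = calibrate_spacing(params.cell_radius)
    pos = hex_disc_points(spacing, radius)
    n = pos.shape[0]
    grid = ECMGrid.homogeneous(params.domain_half_width, params.voxel_size)
    grid.clear_disc((0.0, 0.0), radius)
    return SimulationState(
        params=params,
        grid=grid,
        pos=pos,
        vol=np.full(n, params.cell_volume_max),
        dirs=np.zeros((n, 2)),
        ids=np.arange(n, dtype=np.int64),
        rng=np.random.Generator(np.random.PCG64(seed)),
        seed=seed,
        next_id=n,
        packing_spacing=spacing,
    )


# --------------------------------------------------------------------------
# stepping


def _position_voxel_density(state: SimulationState) -> np.ndarray:
    """Density of the voxel nearest each cell position (vectorised)."""
    grid = state.grid
    h = grid.voxel_size
    out = np.empty(state.n_cells)
    idx = np.empty((state.n_cells, 2), dtype=np.int64)
    for axis, (origin, nvox) in enumerate(
            [(grid.origin[0], grid.nx), (grid.origin[1], grid.ny)]):
        f = (state.pos[:, axis] - origin) / h
        i = np.floor(f).astype(np.int64)
        i[(f == i) & (i > 0)] -= 1
        np.clip(i, 0, nvox - 1, out=i)
        idx[:, axis] = i
    out[:] = grid.density[idx[:, 1], idx[:, 0]]
    return out


def _mechanics_step(state: SimulationState) -> None:
    p = state.params
    rad = state.radii
    rad_a = p.adhesion_radius_multiple * rad
    decay = math.exp(-p.rdeg_rib * p.dt_mech)
    vox, clamped = _kernels.select_and_degrade(
        state.pos, rad, state.dirs, state.grid.density,
        state.grid.origin[0], state.grid.origin[1], state.grid.voxel_size,
        decay)
    state.grid.clamped_front_count += int(clamped)

    # persistence: resample direction with probability dt/Tper; draws are
    # consumed for every cell in id order regardless of outcome
    n = state.n_cells
    resample = state.rng.random(n) < p.dt_mech / p.Tper
    theta = state.rng.random(n) * 2.0 * np.pi
    state.dirs[resample, 0] = np.cos(theta[resample])
    state.dirs[resample, 1] = np.sin(theta[resample])

    status = _kernels.move_cells(
        state.pos, rad, rad_a, state.dirs, state.grid.density.ravel(), vox,
        4.0 * p.S_rib, p.ccca, p.cccr, p.dt_mech, p.domain_half_width)
    if status:
        reason = "NaN position" if status == 2 else \
            "cell left the domain (domain_half_width too small)"
        raise SimulationError(
            f"{reason} at t={state.clock_min:.1f} min, seed={state.seed}")


def _phenotype_step(state: SimulationState) -> None:
    p = state.params
    # volume relaxation towards the target, then division attempts
    state.vol = grow_volume(state.vol, p.cell_volume_max, p.growth_rate_k,
                            p.dt_cell)
    rad = state.radii
    rad_a = p.adhesion_radius_multiple * rad
    nbr = _kernels.count_neighbours(state.pos, rad_a)
    rho = _position_voxel_density(state)
    fip = inhibition_factor(nbr, rho, p.Nmax)
    u = state.rng.random(state.n_cells)
    theta = state.rng.random(state.n_cells) * 2.0 * np.pi
    dividing = np.nonzero(u < p.rdiv * p.dt_cell * fip)[0]
    if len(dividing) == 0:
        return
    new_pos, new_vol, new_dirs, new_ids = [], [], [], []
    for i in dividing:  # cell-id order
        parent_r = float(rad[i])
        ux, uy = math.cos(theta[i]), math.sin(theta[i])
        off = 0.5 * parent_r
        state.vol[i] *= 0.5
        cx, cy = state.pos[i]
        state.pos[i, 0] = cx + off * ux
        state.pos[i, 1] = cy + off * uy
        new_pos.append((cx - off * ux, cy - off * uy))
        new_vol.append(state.vol[i])
        new_dirs.append(tuple(state.dirs[i]))
        new_ids.append(state.next_id)
        state.next_id += 1
        state.divisions += 1
    state.pos = np.vstack([state.pos, np.array(new_pos)])
    state.vol = np.concatenate([state.vol, np.array(new_vol)])
    state.dirs = np.vstack([state.dirs, np.array(new_dirs)])
    state.ids = np.concatenate([state.ids, np.array(new_ids, dtype=np.int64)])


@dataclass
class SimulationResult:
    """Final state, measurement snapshots and the per-run metrics table."""

    state: SimulationState
    snapshot_times: list = field(default_factory=list)   # min
    snapshots: list = field(default_factory=list)        # (pos, radii) copies
    metrics: pd.DataFrame | None = None


def run(state: SimulationState, t_end_min: float,
        compute_metrics: bool = True,
        snapshot_interval_min: float = SNAPSHOT_INTERVAL_MIN) -> SimulationResult:
    """Advance the state to ``t_end_min``, recording snapshots.

    ``t_end_min`` must be a multiple of the snapshot interval, which in turn
    must be a multiple of both clocks.  Returns the result with a tidy
    metrics table (cell count, rasterized area, relative growth, Delaunay
    mean distance at every snapshot).
    """
    p = state.params
    n_steps = int(round(t_end_min / p.dt_mech))
    if abs(n_steps * p.dt_mech - t_end_min) > 1e-9:
        raise ValueError("t_end must be a multiple of dt_mech")
    snap_every = int(round(snapshot_interval_min / p.dt_mech))
    if abs(snap_every * p.dt_mech - snapshot_interval_min) > 1e-9 or \
            n_steps % max(snap_every, 1) != 0:
        raise ValueError(
            "t_end must be a multiple of the snapshot interval, and the "
            "snapshot interval a multiple of dt_mech")
    pheno_every = int(round(p.dt_cell / p.dt_mech))

    result = SimulationResult(state=state)

    def record() -> None:
        result.snapshot_times.append(state.clock_min)
        result.snapshots.append((state.pos.copy(), state.radii.copy()))

    record()
    for _ in range(n_steps):
        _mechanics_step(state)
        state.step += 1
        if state.step % pheno_every == 0:
            _phenotype_step(state)
        if state.step % snap_every == 0:
            record()

    if compute_metrics:
        result.metrics = _metrics.snapshot_metrics(
            result.snapshot_times, result.snapshots,
            domain_half_width=p.domain_half_width, raster_n=p.raster_n)
    return result


def run_replicates(params: ModelParams, n_reps: int, base_seed: int,
                   t_end_min: float,
                   diameter: float | None = None) -> pd.DataFrame:
    """Run ``n_reps`` independent replicates (seeds ``base_seed + k``).

    Returns a tidy long-format table with a ``replicate`` column holding the
    per-snapshot metrics of every replicate.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    frames = []
    for k in range(n_reps):
        state = init_spheroid(params, seed=base_seed + k, diameter=diameter)
        res = run(state, t_end_min)
        df = res.metrics.copy()
        df.insert(0, "replicate", k)
        df.insert(0, "seed", base_seed + k)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# output


def save_run(result: SimulationResult, outdir: str | Path) -> None:
    """Dump metrics CSV, final cell table, ECM field and run metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if result.metrics is not None:
        result.metrics.to_csv(outdir / "metrics.csv", index=False)
    result.state.cell_table().to_csv(outdir / "cells_final.csv", index=False)
    result.state.grid.save(outdir / "ecm_final.txt")
    meta = {
        "seed": result.state.seed,
        "t_end_min": result.state.clock_min,
        "n_cells": result.state.n_cells,
        "divisions": result.state.divisions,
        "clamped_fronts": result.state.grid.clamped_front_count,
        "packing_spacing_um": result.state.packing_spacing,
        "params": result.state.params.to_dict(),
    }
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2))
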