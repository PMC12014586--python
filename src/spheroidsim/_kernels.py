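"""Numba kernels for the engine's hot loop.

These duplicate the vectorised reference implementations in
:mod:`spheroidsim.mechanics` with identical arithmetic (the test suite checks
step-for-step agreement); they exist only because the mechanics loop runs
~60k steps per simulated experiment.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["select_and_degrade", "move_cells", "count_neighbours"]


@njit(cache=True)
def _axis_index(coord: float, origin: float, h: float, n: int) -> int:
    f = (coord - origin) / h
    i = int(np.floor(f))
    if f == i and i > 0:
        i -= 1  # tie on a voxel face -> smaller index
    if i < 0:
        i = 0
    elif i > n - 1:
        i = n - 1
    return i


@njit(cache=True)
def select_and_degrade(pos, rad, dirs, density, x0, y0, h, decay_factor):
    """Select each cell's interaction voxel and degrade the selected set.

    Moving cells act through their front (surface point in the direction of
    motion); stationary cells through the voxel nearest their centre.  The
    density update ``rho *= exp(-r*dt)`` (``decay_factor``) is the exact
    one-step solution of ``drho/dt = -r*rho`` and is applied once per voxel
    that at least one cell selected: the field decays at the characteristic
    rate ``r`` while in contact with cells, independent of how many cells
    touch the voxel.

    Returns (voxel linear indices (n,), number of clamped fronts).
    """
    n = pos.shape[0]
    ny, nx = density.shape
    flat = density.ravel()
    vox = np.empty(n, dtype=np.int64)
    touched = np.zeros(nx * ny, dtype=np.uint8)
    clamped = 0
    xmax = x0 + nx * h
    ymax = y0 + ny * h
    for i in range(n):
        dx = dirs[i, 0]
        dy = dirs[i, 1]
        px = pos[i, 0]
        py = pos[i, 1]
        if dx != 0.0 or dy != 0.0:
            norm = np.sqrt(dx * dx + dy * dy)
            px += rad[i] * dx / norm
            py += rad[i] * dy / norm
        if px < x0 or px > xmax or py < y0 or py > ymax:
            clamped += 1
            px = min(max(px, x0), xmax)
            py = min(max(py, y0), ymax)
        ix = _axis_index(px, x0, h, nx)
        iy = _axis_index(py, y0, h, ny)
        k = iy * nx + ix
        vox[i] = k
        if touched[k] == 0:
            flat[k] *= decay_factor
            touched[k] = 1
    return vox, clamped


@njit(cache=True)
def move_cells(pos, rad, rad_a, dirs, density_flat, vox, four_srib,
               ccca, cccr, dt, half_width):
    """One synchronous velocity + position update.

    Velocities are computed from the pre-step positions:
      v_cc   pairwise adhesion/repulsion along centre lines,
      v_cma  = 4*S_rib*rho * d_cm,
      total  = (v_cc + v_cma) * (1 - rho)  with rho from the selected voxel.

    Returns a status code: 0 ok, 1 a position left the domain, 2 NaN.
    """
    n = pos.shape[0]
    vel = np.zeros((n, 2))
    # pairwise cell-cell contributions (antisymmetric)
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            d = np.sqrt(dx * dx + dy * dy)
            ra = rad_a[i] + rad_a[j]
            if d < ra:
                if d == 0.0:
                    ux = 1.0
                    uy = 0.0
                else:
                    ux = dx / d
                    uy = dy / d
                t = 1.0 - d / ra
                mag = -ccca * t * t
                rr = rad[i] + rad[j]
                if d < rr:
                    t = 1.0 - d / rr
                    mag += cccr * t * t
                vel[i, 0] += mag * ux
                vel[i, 1] += mag * uy
                vel[j, 0] -= mag * ux
                vel[j, 1] -= mag * uy
    status = 0
    for i in range(n):
        rho = density_flat[vox[i]]
        vx = (vel[i, 0] + four_srib * rho * dirs[i, 0]) * (1.0 - rho)
        vy = (vel[i, 1] + four_srib * rho * dirs[i, 1]) * (1.0 - rho)
        x = pos[i, 0] + vx * dt
        y = pos[i, 1] + vy * dt
        pos[i, 0] = x
        pos[i, 1] = y
        if np.isnan(x) or np.isnan(y):
            status = 2
        elif x < -half_width or x > half_width or y < -half_width or y > half_width:
            if status == 0:
                status = 1
    return status


@njit(cache=True)
def count_neighbours(pos, rad_a):
    """Neighbour counts under the interaction-distance relation."""
    n = pos.shape[0]
    counts = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            d = np.sqrt(dx * dx + dy * dy)
            if d < rad_a[i] + rad_a[j]:
                counts[i] += 1
                counts[j] += 1
    return counts
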