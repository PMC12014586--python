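"""Centre-based cell mechanics: velocities, persistence, position update.

Cells are overdamped spheres identified by their centres, constrained to the
z=0 plane (pseudo-2D: one layer of 3D voxels, in-plane motion only).  The
total velocity of cell i is

    v_i = v_cc + v_cma + v_cmr = (v_cc + v_cma) * (1 - rho)

where ``v_cc`` sums pairwise cell-cell adhesion/repulsion, ``v_cma`` is the
cell-matrix adhesion velocity ``4*S_rib*rho`` along a persistent random
direction, and ``v_cmr = -(v_cc + v_cma)*rho`` is the matrix repulsion: a
fully dense gel (rho=1) acts as a wall, an empty gel (rho=0) offers neither
traction nor resistance.

The functions here are the vectorised reference implementations; the engine's
hot loop uses numerically identical numba kernels (cross-checked in the test
suite).
"""

from __future__ import annotations

import numpy as np

from .params import InvalidParameterError

__all__ = [
    "neighbours",
    "neighbour_counts",
    "cell_cell_velocity",
    "cell_ecm_adhesion_velocity",
    "cell_ecm_repulsion_velocity",
    "total_cell_ecm_speed",
    "direction_update",
    "step_positions",
]

# fallback push axis for exactly coincident centres
_FALLBACK_AXIS = np.array([1.0, 0.0])


def _pairwise(positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(displacements x_i - x_j (n,n,2), distances (n,n))."""
    diff = positions[:, None, :] - positions[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    return diff, dist


def neighbours(i: int, positions: np.ndarray, radii_A: np.ndarray) -> np.ndarray:
    """Indices j != i with ``|x_j - x_i| < R_A,i + R_A,j``.

    ``radii_A`` are the interaction (adhesion) radii, a fixed multiple of the
    cell radii.  The relation is symmetric.
    """
    d = np.linalg.norm(positions - positions[i], axis=1)
    mask = d < radii_A[i] + radii_A
    mask[i] = False
    return np.nonzero(mask)[0]


def neighbour_counts(positions: np.ndarray, radii_A: np.ndarray) -> np.ndarray:
    """Number of neighbours of every cell (vectorised pairwise scan)."""
    _, dist = _pairwise(positions)
    mask = dist < radii_A[:, None] + radii_A[None, :]
    np.fill_diagonal(mask, False)
    return mask.sum(axis=1).astype(np.int64)


def cell_cell_velocity(positions: np.ndarray, radii: np.ndarray,
                       radii_A: np.ndarray, ccca: float,
                       cccr: float) -> np.ndarray:
    """Cell-cell interaction velocities (n, 2).

    Standard centre-based pair potential: adhesion pulls cells together once
    they are within interaction distance ``R_A,i + R_A,j``; repulsion
    (volume exclusion) pushes overlapping cells apart below contact distance
    ``R_i + R_j``.  Both contributions act along the centre line with
    quadratic ramps:

        adhesion:  -ccca * (1 - d/(R_A,i + R_A,j))^2 * u_ij
        repulsion: +cccr * (1 - d/(R_i + R_j))^2 * u_ij

    where ``u_ij`` points from cell j to cell i.  The pair sum is exactly
    antisymmetric.
    """
    n = len(positions)
    v = np.zeros((n, 2))
    if n < 2:
        return v
    diff, dist = _pairwise(positions)
    ra_sum = radii_A[:, None] + radii_A[None, :]
    r_sum = radii[:, None] + radii[None, :]

    with np.errstate(divide="ignore", invalid="ignore"):
        unit = diff / dist[:, :, None]
    coincident = dist == 0
    np.fill_diagonal(coincident, False)
    if coincident.any():
        # push the lower-id cell along +x, the higher-id one along -x
        ci, cj = np.nonzero(coincident)
        sign = np.where(ci < cj, 1.0, -1.0)
        unit[ci, cj] = sign[:, None] * _FALLBACK_AXIS
    unit[np.arange(n), np.arange(n)] = 0.0  # self term (0/0) never acts
    np.fill_diagonal(dist, np.inf)

    mag = np.zeros_like(dist)
    adh = dist < ra_sum
    mag[adh] -= ccca * (1.0 - dist[adh] / ra_sum[adh]) ** 2
    rep = dist < r_sum
    mag[rep] += cccr * (1.0 - dist[rep] / r_sum[rep]) ** 2
    np.fill_diagonal(mag, 0.0)
    return (mag[:, :, None] * unit).sum(axis=1)


def cell_ecm_adhesion_velocity(direction: np.ndarray, rho: np.ndarray,
                               S_rib: float) -> np.ndarray:
    """Cell-matrix adhesion velocity ``4 * S_rib * rho * d_cm``.

    The speed grows linearly with local matrix density (more fibres, more
    adhesion sites); the factor 4 normalises the *total* cell-matrix speed so
    its maximum over rho equals ``S_rib``.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0) or np.any(rho > 1):
        raise InvalidParameterError("ECM density must lie in [0, 1]")
    return 4.0 * S_rib * rho[..., None] * direction


def cell_ecm_repulsion_velocity(v_cc: np.ndarray, v_cma: np.ndarray,
                                rho: np.ndarray) -> np.ndarray:
    """Cell-matrix repulsion ``-(v_cc + v_cma) * rho``.

    Steric hindrance by the fibre network: at rho=1 it exactly cancels the
    other velocity contributions (the matrix is a wall), at rho=0 it vanishes.
    """
    rho = np.asarray(rho, dtype=float)
    return -(v_cc + v_cma) * rho[..., None]


def total_cell_ecm_speed(rho, S_rib: float):
    """Net cell-matrix speed of an isolated cell: ``4*S_rib*rho*(1-rho)``.

    Non-monotone in the density: zero in an empty gel (nothing to pull on)
    and in a fully dense gel (wall), maximal ``S_rib`` at rho = 0.5.
    """
    rho = np.asarray(rho, dtype=float)
    out = 4.0 * S_rib * rho * (1.0 - rho)
    return float(out) if out.ndim == 0 else out


def direction_update(directions: np.ndarray, Tper: float, dt: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Persistent random walk direction resampling.

    Each mechanics step, every cell's motility direction is replaced by a
    fresh uniform random in-plane unit vector with probability ``dt / Tper``,
    so a direction survives ``Tper`` minutes on average.

    One uniform and one angle are drawn per cell regardless of the outcome so
    the stream consumption is deterministic.
    """
    if dt > Tper:
        raise InvalidParameterError(
            f"dt ({dt}) exceeds persistence time Tper ({Tper})"
        )
    n = len(directions)
    resample = rng.random(n) < dt / Tper
    theta = rng.random(n) * 2.0 * np.pi
    out = directions.copy()
    out[resample, 0] = np.cos(theta[resample])
    out[resample, 1] = np.sin(theta[resample])
    return out


def step_positions(positions: np.ndarray, velocities: np.ndarray,
                   dt: float) -> np.ndarray:
    """Forward Euler position update ``x <- x + v*dt`` (in-plane)."""
    return positions + velocities * dt
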