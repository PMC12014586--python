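"""Stochastic proliferation gated by crowding and matrix density.

Cells follow a live-cycle model: in a phenotype step of length ``dt`` a cell
divides with probability ``rdiv * f_IP(N_i, rho) * dt`` where the inhibition
of proliferation factor is

    f_IP(N_i, rho) = 1 - rho  if 0 < N_i < Nmax   (matrix confinement)
                   = 0        otherwise

``N_i`` is the cell's neighbour count and ``rho`` the matrix density of the
voxel nearest the cell's *position*.  Cells divide only while they have at
least one neighbour and fewer than the overcrowding threshold: overcrowding
arrests the cycle, and a fully detached cell lacks the cell-cell contacts to
cycle.  There is no cell death, so the
population is non-decreasing.  On division the parent halves its volume and
the two daughters (each carrying the parent's state) are placed side by side
with centres at ``+-(R_parent/2)`` along a uniform random in-plane axis;
daughters then relax their volume back to the target exponentially.
"""

from __future__ import annotations

import math

import numpy as np

from .params import InvalidParameterError

__all__ = [
    "inhibition_factor",
    "division_mask",
    "daughter_offsets",
    "grow_volume",
    "radius_from_volume",
]


def radius_from_volume(volume):
    """Radius of a sphere of the given volume."""
    return (3.0 * np.asarray(volume, dtype=float) / (4.0 * math.pi)) ** (1.0 / 3.0)


def inhibition_factor(Ni, rho, Nmax: int):
    """Inhibition of proliferation factor ``f_IP`` in [0, 1].

    ``1 - rho`` for ``0 < Ni < Nmax``, zero otherwise: an overcrowded cell
    (``Ni >= Nmax``) is arrested, and so is a fully detached one
    (``Ni = 0``).
    """
    Ni = np.asarray(Ni)
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0) or np.any(rho > 1):
        raise InvalidParameterError("ECM density must lie in [0, 1]")
    if np.any(Ni < 0):
        raise InvalidParameterError("neighbour count must be >= 0")
    out = np.where((Ni > 0) & (Ni < Nmax), 1.0 - rho, 0.0)
    return float(out) if out.ndim == 0 else out


def division_mask(Ni: np.ndarray, rho: np.ndarray, rdiv: float, dt: float,
                  Nmax: int, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli division outcomes for every cell over one phenotype step.

    One uniform is drawn per cell in cell-id order regardless of outcome, so
    RNG stream consumption is deterministic.
    """
    p_max = rdiv * dt
    if p_max > 1:
        raise InvalidParameterError(
            f"rdiv*dt = {p_max} > 1 is not a valid probability"
        )
    p = p_max * inhibition_factor(Ni, rho, Nmax)
    return rng.random(len(np.atleast_1d(Ni))) < p


def daughter_offsets(parent_radius: float, theta: float) -> np.ndarray:
    """Centre offsets of the two daughters relative to the parent centre.

    ``+-(R_parent/2)`` along the unit axis at angle ``theta``, which keeps
    both centres inside the parent's original radius.
    """
    u = np.array([math.cos(theta), math.sin(theta)])
    return np.stack([0.5 * parent_radius * u, -0.5 * parent_radius * u])


def grow_volume(volume, target, k: float, dt: float):
    """Exponential relaxation of cell volume towards its target.

    ``V <- V_target - (V_target - V) * exp(-k*dt)``: monotone, never
    overshoots, fixed point at the target volume.
    """
    if k < 0:
        raise InvalidParameterError(f"growth rate k must be >= 0, got {k}")
    volume = np.asarray(volume, dtype=float)
    out = target - (target - volume) * math.exp(-k * dt)
    return float(out) if out.ndim == 0 else out
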