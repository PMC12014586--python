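"""Single-layer voxel lattice of ECM density.

The extracellular matrix is a continuum field discretised into one z-layer of
cubic voxels; each voxel stores a dimensionless local fibre density
``rho in [0, 1]``.  Cells degrade the matrix towards zero density (chemical
remodelling); no deposition is modelled, so the field is pointwise
non-increasing in time.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

__all__ = ["ECMGrid", "OutOfDomainError"]


class OutOfDomainError(ValueError):
    """A queried point lies outside the lattice."""


class ECMGrid:
    """Regular 2D lattice of ECM voxels.

    Voxel ``(iy, ix)`` is centred at ``origin + (ix + 0.5, iy + 0.5) * h``
    where ``h`` is the voxel edge length.  Indices are linearised row-major
    (``iy * nx + ix``); nearest-voxel ties are broken towards the smaller
    linear index so runs are bit-reproducible.
    """

    def __init__(self, origin: tuple[float, float], voxel_size: float,
                 nx: int, ny: int, density: np.ndarray | None = None):
        if voxel_size <= 0 or nx < 1 or ny < 1:
            raise ValueError("voxel_size must be > 0 and nx, ny >= 1")
        self.origin = (float(origin[0]), float(origin[1]))
        self.voxel_size = float(voxel_size)
        self.nx = int(nx)
        self.ny = int(ny)
        if density is None:
            self.density = np.ones((self.ny, self.nx), dtype=np.float64)
        else:
            density = np.asarray(density, dtype=np.float64)
            if density.shape != (self.ny, self.nx):
                raise ValueError(
                    f"density shape {density.shape} != {(self.ny, self.nx)}"
                )
            if density.min() < 0 or density.max() > 1:
                raise ValueError("ECM density must lie in [0, 1]")
            self.density = density.copy()
        self.clamped_front_count = 0  # cells whose front fell outside the lattice

    # -- constructors ---------------------------------------------------------

    @classmethod
    def homogeneous(cls, half_width: float, voxel_size: float,
                    rho: float = 1.0) -> "ECMGrid":
        """Square lattice covering ``[-half_width, half_width]^2``."""
        n = max(1, int(round(2.0 * half_width / voxel_size)))
        grid = cls((-half_width, -half_width), voxel_size, n, n)
        grid.density[:] = rho
        return grid

    def clear_disc(self, centre: tuple[float, float], radius: float) -> None:
        """Zero the density of voxels whose centres lie within a disc.

        Used for the initial condition: the spheroid displaces the gel, so
        the matrix density at the spheroid's location starts at zero.
        """
        xc, yc = self.voxel_centres()
        dx = xc[None, :] - centre[0]
        dy = yc[:, None] - centre[1]
        self.density[dx * dx + dy * dy <= radius * radius] = 0.0

    # -- geometry -------------------------------------------------------------

    def voxel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x-centres (nx,), y-centres (ny,))."""
        h = self.voxel_size
        x = self.origin[0] + (np.arange(self.nx) + 0.5) * h
        y = self.origin[1] + (np.arange(self.ny) + 0.5) * h
        return x, y

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) covered by the lattice."""
        x0, y0 = self.origin
        h = self.voxel_size
        return (x0, x0 + self.nx * h, y0, y0 + self.ny * h)

    def _axis_index(self, coord: float, origin: float, n: int) -> int:
        f = (coord - origin) / self.voxel_size
        i = math.floor(f)
        # a point on the shared face of two voxels is equidistant from both
        # centres; take the smaller index
        if f == i and i > 0:
            i -= 1
        return i

    def voxel_of_point(self, point: tuple[float, float]) -> tuple[int, int]:
        """Index ``(iy, ix)`` of the voxel whose centre is nearest ``point``."""
        xmin, xmax, ymin, ymax = self.extent
        x, y = point
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            raise OutOfDomainError(f"point {point} outside domain {self.extent}")
        ix = min(self._axis_index(x, self.origin[0], self.nx), self.nx - 1)
        iy = min(self._axis_index(y, self.origin[1], self.ny), self.ny - 1)
        return iy, ix

    def voxel_of_point_clamped(self, point: tuple[float, float]) -> tuple[int, int]:
        """Like :meth:`voxel_of_point` but clamping out-of-domain points.

        Cell fronts can protrude past the lattice edge; they are clamped to
        the nearest boundary voxel and counted.
        """
        xmin, xmax, ymin, ymax = self.extent
        x, y = point
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            self.clamped_front_count += 1
            x = min(max(x, xmin), xmax)
            y = min(max(y, ymin), ymax)
        return self.voxel_of_point((x, y))

    def select_interaction_voxel(self, position: np.ndarray,
                                 direction: np.ndarray,
                                 radius: float) -> tuple[int, int]:
        """Voxel a cell senses and degrades.

        A moving cell interacts through its *front*: the point on its surface
        in the direction of motion (protrusions reach ahead of the cell body).
        A stationary cell (zero direction) uses the voxel nearest its centre.
        """
        dx, dy = float(direction[0]), float(direction[1])
        if dx == 0.0 and dy == 0.0:
            return self.voxel_of_point_clamped((position[0], position[1]))
        norm = math.hypot(dx, dy)
        front = (position[0] + radius * dx / norm,
                 position[1] + radius * dy / norm)
        return self.voxel_of_point_clamped(front)

    # -- dynamics -------------------------------------------------------------

    def degrade(self, voxel: tuple[int, int], rate: float, dt: float) -> float:
        """Apply one degradation step ``rho <- rho * exp(-rate*dt)``.

        This is the exact solution of ``drho/dt = -rate * rho`` over the
        step: unconditionally stable and positivity-preserving.  Returns the
        updated density.
        """
        if rate < 0:
            raise ValueError(f"rate must be >= 0, got {rate}")
        if dt <= 0:
            raise ValueError(f"dt must be > 0, got {dt}")
        iy, ix = voxel
        self.density[iy, ix] *= math.exp(-rate * dt)
        return float(self.density[iy, ix])

    # -- I/O ------------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the density matrix as plain text with a header sidecar."""
        path = Path(path)
        np.savetxt(path, self.density, fmt="%.17g")
        sidecar = path.with_suffix(path.suffix + ".meta")
        sidecar.write_text(
            f"origin_x {self.origin[0]!r}\norigin_y {self.origin[1]!r}\n"
            f"voxel_size {self.voxel_size!r}\nnx {self.nx}\nny {self.ny}\n"
        )

    @classmethod
    def load(cls, path: str | Path) -> "ECMGrid":
        path = Path(path)
        meta = {}
        for line in (path.with_suffix(path.suffix + ".meta")).read_text().splitlines():
            key, value = line.split()
            meta[key] = float(value)
        density = np.loadtxt(path, ndmin=2)
        return cls((meta["origin_x"], meta["origin_y"]), meta["voxel_size"],
                   int(meta["nx"]), int(meta["ny"]), density=density)
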