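"""Model parameters and the two ribose scaling laws.

The simulator describes cells embedded in a collagen gel whose stiffness is
raised by non-enzymatic ribose glycation.  Cross-linking does not change the
gel architecture, so its effect is modelled purely as an exponential
attenuation of (a) the rate at which cells proteolytically degrade the matrix
and (b) the maximum speed cells can reach through cell-matrix adhesion:

    r_deg(rib) = rdeg0 * exp(-delta * rib)
    S(rib)     = S0    * exp(-sigma * rib)

with ``rib`` the ribose concentration in mM and ``delta``/``sigma`` the
sensitivities in 1/mM.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "ModelParams",
    "InvalidParameterError",
    "degradation_rate",
    "max_speed",
    "load_config",
]


class InvalidParameterError(ValueError):
    """A parameter value violates the model's preconditions."""


def _check_nonnegative(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value) or value < 0:
            raise InvalidParameterError(
                f"{name} must be finite and >= 0, got {value!r}"
            )


def degradation_rate(rdeg0: float, delta: float, rib: float) -> float:
    """ECM degradation rate at ribose concentration ``rib``.

    Parameters
    ----------
    rdeg0
        Base degradation rate at 0 mM ribose, 1/min.
    delta
        Ribose sensitivity of degradation, 1/mM.  ``delta=0`` makes the rate
        independent of ribose.
    rib
        Ribose concentration, mM.
    """
    _check_nonnegative(rdeg0=rdeg0, delta=delta, rib=rib)
    return rdeg0 * math.exp(-delta * rib)


def max_speed(S0: float, sigma: float, rib: float) -> float:
    """Maximum cell-ECM interaction speed at ribose concentration ``rib``.

    Parameters
    ----------
    S0
        Maximum speed at 0 mM ribose, um/min.
    sigma
        Ribose sensitivity of speed, 1/mM.
    rib
        Ribose concentration, mM.
    """
    _check_nonnegative(S0=S0, sigma=sigma, rib=rib)
    return S0 * math.exp(-sigma * rib)


@dataclass
class ModelParams:
    """All model constants.

    Rates are per minute, lengths in micrometres, volumes in cubic
    micrometres, concentrations in mM.  Defaults correspond to the invasive
    breast-cancer cell line scenario; scenario presets override the cell-ECM
    interaction parameters.
    """

    # ECM degradation (chemical remodelling by the cells)
    rdeg0: float = 0.0032       # base degradation rate at 0 mM ribose, 1/min
    delta: float = 0.02         # ribose sensitivity of degradation, 1/mM

    # cell-ECM motility
    S0: float = 0.7             # max cell-ECM interaction speed at 0 mM, um/min
    sigma: float = 0.035        # ribose sensitivity of speed, 1/mM
    rib: float = 0.0            # ribose concentration, mM
    Tper: float = 10.0          # persistence time of the motility direction, min

    # proliferation
    rdiv: float = 0.00072       # division rate, 1/min
    Nmax: int = 6               # overcrowding threshold (hexagonal packing)
    growth_rate_k: float = 0.01  # volume relaxation rate after division, 1/min

    # cell geometry and mechanics
    cell_volume_max: float = 2494.0        # um^3; radius ~8.41 um
    adhesion_radius_multiple: float = 1.25  # interaction radius / cell radius
    ccca: float = 0.4           # cell-cell adhesion strength, um/min
    cccr: float = 10.0          # cell-cell repulsion strength, um/min

    # clocks
    dt_mech: float = 0.1        # mechanics time step, min
    dt_cell: float = 6.0        # phenotype (cycle/volume) time step, min

    # geometry of the domain and measurements
    voxel_size: float = 20.0    # ECM voxel edge, um
    domain_half_width: float = 500.0  # domain is [-w, w]^2, um
    spheroid_diameter: float = 200.0  # initial spheroid diameter, um
    raster_n: int = 5000        # rasterization grid size per axis

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def cell_radius(self) -> float:
        """Radius of a cell at maximum volume, um."""
        return (3.0 * self.cell_volume_max / (4.0 * math.pi)) ** (1.0 / 3.0)

    @property
    def rdeg_rib(self) -> float:
        """Degradation rate at the configured ribose concentration."""
        return degradation_rate(self.rdeg0, self.delta, self.rib)

    @property
    def S_rib(self) -> float:
        """Maximum cell-ECM speed at the configured ribose concentration."""
        return max_speed(self.S0, self.sigma, self.rib)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        _check_nonnegative(
            rdeg0=self.rdeg0, delta=self.delta, S0=self.S0, sigma=self.sigma,
            rib=self.rib, rdiv=self.rdiv, growth_rate_k=self.growth_rate_k,
            ccca=self.ccca, cccr=self.cccr,
        )
        for name in ("Tper", "cell_volume_max", "adhesion_radius_multiple",
                     "dt_mech", "dt_cell", "voxel_size", "domain_half_width",
                     "spheroid_diameter"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {value!r}")
        if self.Nmax < 1:
            raise InvalidParameterError(f"Nmax must be >= 1, got {self.Nmax}")
        if self.raster_n < 1:
            raise InvalidParameterError(
                f"raster_n must be >= 1, got {self.raster_n}"
            )
        if self.dt_mech > self.dt_cell:
            raise InvalidParameterError("dt_mech must not exceed dt_cell")
        ratio = self.dt_cell / self.dt_mech
        if abs(ratio - round(ratio)) > 1e-9:
            raise InvalidParameterError(
                "dt_cell must be an integer multiple of dt_mech "
                f"(got {self.dt_cell}/{self.dt_mech})"
            )
        if self.dt_mech > self.Tper:
            raise InvalidParameterError(
                "dt_mech must not exceed the persistence time Tper "
                "(direction-change probability would exceed 1)"
            )
        if self.rdiv * self.dt_cell > 1:
            raise InvalidParameterError(
                "rdiv*dt_cell exceeds 1: division probability invalid"
            )
        if self.spheroid_diameter / 2.0 > self.domain_half_width:
            raise InvalidParameterError(
                "initial spheroid does not fit inside the domain"
            )

    # -- configuration round-trips -------------------------------------------

    def replace(self, **overrides: float) -> "ModelParams":
        """Return a copy with the given fields replaced (and re-validated)."""
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise InvalidParameterError(
                f"unknown parameter(s): {sorted(unknown)}"
            )
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path, **overrides: float) -> ModelParams:
    """Load a flat YAML/JSON mapping of parameter overrides.

    Unknown keys are rejected to catch typos; keys omitted from the file take
    their defaults.  Keyword overrides are applied on top of the file.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InvalidParameterError(
            f"config file {path} must contain a flat key/value mapping"
        )
    valid = {f.name: f.type for f in dataclasses.fields(ModelParams)}
    unknown = set(raw) - set(valid)
    if unknown:
        raise InvalidParameterError(
            f"unknown configuration key(s) in {path}: {sorted(unknown)}"
        )
    raw.update(overrides)
    if "Nmax" in raw:
        raw["Nmax"] = int(raw["Nmax"])
    if "raster_n" in raw:
        raw["raster_n"] = int(raw["raster_n"])
    return ModelParams(**raw)
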