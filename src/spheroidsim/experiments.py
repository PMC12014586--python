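"""Scenario presets and parameter-sweep drivers.

The presets encode the three experimental conditions the model reproduces,
differing only in the cell-ECM interaction parameters:

* ``noninvasive`` — weakly interacting cells (MCF7-like): low matrix
  degradation (``rdeg0 = 0.0001 /min``) and low maximum cell-ECM speed
  (``S0 = 0.1 um/min``); spheroids stay compact at every stiffness.
* ``invasive`` — strongly interacting cells (HCC1954-like):
  ``rdeg0 = 0.0032 /min``, ``S0 = 0.7 um/min``; spheroids grow and invade,
  and ribose-induced stiffening suppresses both.
* ``gm6001`` — the invasive cells under a pan-MMP inhibitor: proteolysis is
  blocked but mechanical remodelling persists, modelled as the invasive
  preset with the degradation rate lowered to ``0.0004 /min``.

All presets share the ribose sensitivities ``delta = 0.02 /mM`` and
``sigma = 0.035 /mM``, the division rate ``rdiv = 0.00072 /min``, a 200 um
initial spheroid and 10 replicates; the standard read-out horizon is 96 h
(72 h for the MMP-inhibition comparison).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .engine import run_replicates
from .metrics import aggregate
from .params import ModelParams

__all__ = ["Scenario", "PRESET_NAMES", "preset", "run_scenario", "sweep"]

PRESET_NAMES = ("noninvasive", "invasive", "gm6001")

_SHARED = dict(delta=0.02, sigma=0.035, rdiv=0.00072, spheroid_diameter=200.0)

_PRESET_OVERRIDES = {
    "noninvasive": dict(rdeg0=0.0001, S0=0.1, **_SHARED),
    "invasive": dict(rdeg0=0.0032, S0=0.7, **_SHARED),
    "gm6001": dict(rdeg0=0.0004, S0=0.7, **_SHARED),
}

_PRESET_T_END_H = {"noninvasive": 96.0, "invasive": 96.0, "gm6001": 72.0}


@dataclass
class Scenario:
    """A fully resolved experimental condition."""

    name: str
    params: ModelParams
    t_end_min: float
    ribose_levels: tuple = (0.0, 50.0, 200.0)
    n_replicates: int = 10

    def params_at(self, rib: float) -> ModelParams:
        return self.params.replace(rib=float(rib))


def preset(name: str, **overrides) -> Scenario:
    """Build one of the named scenarios; overrides go into the parameters."""
    if name not in _PRESET_OVERRIDES:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        )
    t_end_h = overrides.pop("t_end_hours", _PRESET_T_END_H[name])
    n_replicates = overrides.pop("n_replicates", 10)
    params = ModelParams().replace(**{**_PRESET_OVERRIDES[name], **overrides})
    return Scenario(name=name, params=params, t_end_min=60.0 * t_end_h,
                    n_replicates=n_replicates)


def run_scenario(scenario: Scenario, base_seed: int,
                 ribose_levels=None) -> pd.DataFrame:
    """Run every ribose level of a scenario; tidy per-replicate table."""
    levels = scenario.ribose_levels if ribose_levels is None else ribose_levels
    frames = []
    for rib in levels:
        df = run_replicates(scenario.params_at(rib), scenario.n_replicates,
                            base_seed, scenario.t_end_min)
        df.insert(0, "ribose_mM", float(rib))
        df.insert(0, "scenario", scenario.name)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def sweep(base_params: ModelParams, axes: dict, n_replicates: int,
          base_seed: int, t_end_min: float = 96 * 60.0) -> pd.DataFrame:
    """Full-factorial parameter sweep.

    ``axes`` maps parameter names (e.g. ``rdeg0``, ``S0``, ``rdiv``,
    ``delta``, ``sigma``, ``rib``) to value lists.  For every grid point the
    replicates are run and the endpoint means of relative growth and Delaunay
    distance are reported, one row per grid point — the tidy form behind
    growth/compactness heatmaps.
    """
    names = list(axes)
    rows = []
    for values in itertools.product(*(axes[k] for k in names)):
        point = dict(zip(names, values))
        params = base_params.replace(**point)
        df = run_replicates(params, n_replicates, base_seed, t_end_min)
        agg = aggregate(df)
        final = agg[agg["time_min"] == agg["time_min"].max()].iloc[0]
        rows.append({
            **point,
            "t_end_min": t_end_min,
            "relative_growth_mean": final["relative_growth_mean"],
            "delaunay_mean_um_mean": final["delaunay_mean_um_mean"],
            "cell_count_mean": final["cell_count_mean"],
        })
    return pd.DataFrame(rows)


def heatmap_matrix(sweep_df: pd.DataFrame, x: str, y: str,
                   value: str) -> pd.DataFrame:
    """Pivot a sweep table into a heatmap matrix (y rows, x columns)."""
    return sweep_df.pivot_table(index=y, columns=x, values=value)


def plot_heatmap(sweep_df: pd.DataFrame, x: str, y: str, value: str,
                 vmin: float | None = None, vmax: float | None = None,
                 ax=None):
    """Render a sweep heatmap (growth scale 1-8, Delaunay 10-30 um by
    convention) and return the matplotlib Axes."""
    import matplotlib.pyplot as plt

    mat = heatmap_matrix(sweep_df, x, y, value)
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(mat.to_numpy(), origin="lower", aspect="auto",
                   vmin=vmin, vmax=vmax, cmap="viridis")
    ax.set_xticks(range(mat.shape[1]), [f"{v:g}" for v in mat.columns])
    ax.set_yticks(range(mat.shape[0]), [f"{v:g}" for v in mat.index])
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.figure.colorbar(im, ax=ax, label=value)
    return ax


@dataclass
class _Fig34Defaults:
    """Default sweep ladders mirroring the published parameter analysis."""

    rdeg0: tuple = (0.0001, 0.0002, 0.0004, 0.0008, 0.0016, 0.0032, 0.0064,
                    0.0128)
    S0: tuple = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    rdiv: tuple = (0.0004, 0.0006, 0.0008)
    delta: tuple = (0.0, 0.005, 0.01, 0.02, 0.04)
    sigma: tuple = (0.0, 0.005, 0.015, 0.025, 0.035)
    rib: tuple = (50.0, 200.0)


SWEEP_DEFAULTS = _Fig34Defaults()
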