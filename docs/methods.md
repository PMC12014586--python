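# Methods

## Model overview

`spheroidsim` couples an off-lattice, centre-based agent model of cancer
cells to a continuum extracellular-matrix (ECM) density field. Cells are
overdamped spheres identified by their centres; velocity, not force, is the
primitive (friction is folded into the interaction strengths, which carry
units of µm/min). The ECM is a single z-layer of cubic voxels, each storing a
scalar fibre density ρ ∈ [0, 1]. Cells move only in the plane of that layer
(pseudo-2D / constrained 3D), mimicking a microscope z-slice through a
spheroid. Ribose-induced collagen glycation stiffens the gel without changing
its architecture; the model represents it purely as exponential attenuation
of the ECM degradation rate, r_deg,rib = r_deg,0·e^(−δ·rib), and of the
maximum cell–matrix speed, S_rib = S₀·e^(−σ·rib).

Two clocks drive the dynamics. Every mechanics step (Δt_mech, default
0.1 min): (1) each cell selects its interaction voxel — the one nearest its
front point x + R·d̂ when its motility direction d is nonzero, otherwise the
one nearest its centre; (2) every selected voxel decays by the exact
one-step solution ρ ← ρ·e^(−r_deg,rib·Δt); (3) motility directions are
resampled with probability Δt_mech/T_per to a uniform in-plane unit vector;
(4) velocities are computed synchronously from pre-step positions and
(5) positions advance by forward Euler. Every phenotype step (Δt_cell,
default 6 min, an integer multiple of Δt_mech) cell volumes relax towards
their target and cells attempt division.

## Key modelling choices

**Degradation is a property of the voxel, not a per-cell increment.** The
field obeys dρ/dt = −r_deg,rib·ρ while in contact with cells, so a voxel
selected by several cells in one step decays once, at the characteristic
rate — not at k-times the rate for k cells. This keeps the remodelling
kinetics independent of the local crowding of the invasion front. The
exponential update is unconditionally stable, positivity-preserving, and
agrees with forward Euler to first order at the small rates used.

**Inhibition of proliferation.** f_IP(N_i, ρ) = 1 − ρ when 0 < N_i < N_max
and 0 otherwise, with ρ sampled at the voxel nearest the cell *position*.
Both branches of the "otherwise" matter: overcrowded cells (N_i ≥ N_max = 6,
the in-plane hexagonal coordination number) are contact-arrested, and fully
detached cells (N_i = 0) do not cycle either — proliferation requires at
least one cell-cell contact. The gate means growth is driven by the spheroid
rim, where cells have few neighbours and sit on degraded voxels.

**Cell-cell potentials.** Adhesion −c_cca·(1 − d/(R_A,i+R_A,j))²·û and
repulsion +c_ccr·(1 − d/(R_i+R_j))²·û along the centre line, the standard
quadratic-ramp pair of centre-based frameworks, with strengths
c_cca = 0.4 µm/min, c_ccr = 10 µm/min and interaction radius
R_A = 1.25 R. Exactly coincident centres (possible only by construction) are
pushed apart along a fixed axis, lower id towards +x.

**Division.** With probability r_div·f_IP·Δt_cell the parent halves its
volume and two daughters carrying its state are placed at ±(R_parent/2)
along a uniform random in-plane axis, keeping both centres inside the
original cell. Daughters relax back to the target volume as
V ← V_t − (V_t − V)e^(−k·Δt) with k = 0.01 min⁻¹ (deficit half-life ≈ 69 min,
i.e. full size is regained well within one cycle); the rate law is a modelling
convenience — only "growth to the maximum volume" is biologically
constrained. There is no cell death, so counts are non-decreasing.

## Parameters

| name | meaning | default | unit |
| --- | --- | --- | --- |
| r_deg,0 | base ECM degradation rate | 0.0032 (invasive) / 0.0001 (non-invasive) / 0.0004 (MMP-inhibited) | min⁻¹ |
| δ | ribose sensitivity of degradation | 0.02 | mM⁻¹ |
| S₀ | max cell-ECM speed at 0 mM | 0.7 (invasive) / 0.1 (non-invasive) | µm·min⁻¹ |
| σ | ribose sensitivity of speed | 0.035 | mM⁻¹ |
| rib | ribose concentration | 0 / 50 / 200 | mM |
| r_div | division rate | 0.00072 | min⁻¹ |
| N_max | overcrowding threshold | 6 | cells |
| T_per | persistence time | 10 | min |
| V | target cell volume (R ≈ 8.41 µm) | 2494 | µm³ |
| c_cca / c_ccr | cell-cell adhesion / repulsion strength | 0.4 / 10 | µm·min⁻¹ |
| k | volume relaxation rate | 0.01 | min⁻¹ |
| Δt_mech / Δt_cell | mechanics / phenotype step | 0.1 / 6 | min |
| voxel size | ECM lattice spacing | 20 | µm |
| domain | square, half-width | 500 | µm |

T_per is not pinned by any measurement; 10 min is a mid-range persistence for
mesenchymal-like migration. Endpoint growth changes by under 1% between
T_per = 1 and 10 min in the scenarios shipped, so the choice is not
load-bearing. The domain half-width merely has to exceed the largest spheroid
plus invasion halo; cells reaching the boundary abort the run rather than
wrap or clip.

## Initial condition

Cells are hexagonally packed in a disc. The lattice spacing is calibrated
once per cell size by scanning [1.8 R, 2.0 R] for the plateau of spacings
that put exactly 139 cells in a 100 µm-radius disc (the plateau is
[16.01, 16.44] µm for the default radius; its midpoint ≈ 16.23 µm is used).
That reproduces the experimental seeding of a 200 µm spheroid containing 139
cells in cross-section; other diameters reuse the calibrated spacing. The
spacing is slightly below the contact distance 2R, so the packing carries a
small compression that relaxes over the first simulated hour, as a freshly
embedded spheroid would. The ECM starts at ρ = 1 except at voxels whose
centres lie under the spheroid, where ρ = 0.

## Measurements

Every 60 simulated minutes: cell count; spheroid area by rasterizing the
union of cell disks onto an n×n grid over the domain (n = 5000 by default; an
element counts when its centre lies in at least one disk, overlaps count
once) rescaled to µm²; relative growth = area(t)/area(0); and the mean edge
length of the Delaunay triangulation of cell centres (SciPy Qhull), a
compactness statistic. Degenerate point sets (< 3 points or collinear) yield
a missing value. Replicates are aggregated as mean and 25th/75th percentile
per timepoint (linear-interpolation percentiles).

## Stochasticity and reproducibility

Each replicate owns one PCG64 stream seeded with base_seed + replicate
index. Draws are consumed in a fixed order — per mechanics step one uniform
and one angle per cell (persistence), per phenotype step one uniform and one
angle per cell (division) — regardless of outcomes, so trajectories are
bit-reproducible for a given (configuration, seed) and insensitive to which
events fire. The mechanics inner loop runs as numba kernels that are
arithmetic-identical to the vectorised reference implementations in
`mechanics.py`; the test suite checks step-for-step agreement between the
two paths over a full simulated hour.

## Scale of the shipped experiments

The scenario presets, the test suite and `scripts/acceptance.py` all run 10
replicates per condition over the full 96 h (72 h for the MMP-inhibition
comparison) horizons, matching the replication of the study they reproduce;
the full condition set takes on the order of ten minutes on one CPU.
Endpoint means move by only a few percent between 3 and 10 replicates
because inter-replicate variability is small (the initial condition is
deterministic and identical across replicates).

## What the synthetic scenarios do and do not show

The scenarios regenerate the study conditions exactly (parameters, seeding
geometry, horizons); no biological data enter the package. Passing tests
therefore show that the implementation reproduces the *model's* published
behaviour, not that the model is a validated description of any particular
cell line: real spheroids have heterogeneous initial ECM, nutrient
gradients, cell death, and fibre-level anisotropy, all outside this model.
Known limitations, by construction: degradation targets zero density (no
deposition or re-cross-linking); no fibre orientation or contact guidance;
no chemotaxis; motion confined to one plane; the inter-replicate variability
is much smaller than in vitro because the initial condition is identical
across replicates.
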