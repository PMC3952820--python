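# Methods

`hepatoflow` simulates the first pass of a compound through an isolated,
single-pass-perfused liver: no recirculation, one supplying vascular tree
(standing in for portal vein + hepatic artery combined), one draining tree
(hepatic vein), and the tissue in between treated as a porous continuum — the
homogenized hepatic space (HHS).  This note documents the model, the numerical
choices, and what the synthetic test conditions do and do not establish.

## Model structure

**Subspaces.** Each tissue voxel holds four compound pools with concentrations
per subspace volume (µmol/L): red blood cells (rbc), plasma (pls),
interstitium (int) and liver cells (cell), plus a passive "rest" fraction
(resolved vessels, bile ducts) that carries no compound.  Default volume
fractions (f_rbc, f_pls, f_int, f_cell, f_rest) = (0.09, 0.13, 0.16, 0.55,
0.07); the sinusoidal (blood) fraction is f_sin = f_rbc + f_pls and the
hematocrit f_rbc/f_sin ≈ 0.41.  These are plausible mouse-scale values chosen
once for the synthetic conditions, not measurements.

**Vascular trees.** Directed bifurcative trees with cylindrical edges.  Flows
follow the equal-leaf-outflow assumption: every terminal edge carries
Q_liv/N_leaves and interior flows are leaf-descendant sums, making junction
conservation exact by construction.  Mean edge velocity is v_e = Q_e/(πr_e²).
Synthetic trees are grown by constrained constructive optimization (CCO):
terminal sites are sampled uniformly from the organ mask with
minimum-distance rejection and connected one at a time through a bifurcation
whose position minimizes total intravascular volume Σ πr²L, searched by
Nelder–Mead from the perpendicular foot point over the few nearest host
segments, subject to (i) all nodes and segment midpoints inside the mask and
(ii) a minimum edge length of one grid spacing.  Constraint (ii) makes grown
trees invariant under the sub-resolution pruning pass, so a requested leaf
count is delivered exactly.

**Radii.** Terminal radius is a config parameter (0.12 mm at 64 leaves,
0.25 mm at 8 leaves — fewer leaves mean each terminal drains a larger
territory); interior radii follow the Murray power law
r_parent^γ = Σ r_child^γ with γ = 3.  Given equal leaf flows and a fixed
terminal radius this determines every radius, so a viscosity-dependent
resistance rule would only rescale the terminal radius; the
Pries–Neuhaus–Gaehtgens (1992) in-vitro relative-viscosity law (the
Fåhræus–Lindqvist effect) is implemented and used for hydraulic-resistance
diagnostics rather than in the radius rule.

**Vascular advection.** Pure 1D advection per edge at the constant mean
velocity, two independent problems per compound (rbc and pls phases, same
velocity).  At supplying junctions concentrations pass unchanged to all
children; at draining junctions the merged value is the flow-weighted average
(instant mixing); both rules generalize to multifurcations.  Discretization:
conservative first-order upwind finite volumes on per-edge sub-grids
(spacing min(edge length, HHS spacing), ≥ 2 cells), with the macro step
divided into the smallest integer number of sub-steps giving Courant ≤ 1 on
the fastest edge.  All inter-cell, junction and boundary fluxes are drawn
from one donor snapshot per sub-step, so the mass ledger
(inflow − outflow = Δstored) closes to round-off.  The scheme is monotone and
positivity-preserving; its known cost is first-order numerical diffusion,
which shrinks under sub-grid refinement (tested).  Front *arrival times* are
unbiased: the median/mean transit of a plug equals L/v within one sub-grid
cell transit.

**Darcy perfusion of the HHS.** The supplying terminal edges inject blood
uniformly along their centerlines (+Q_leaf/L per mm), draining terminals
withdraw it (−Q_leaf/L); the balanced line sources drive the pure-Neumann
problem −∇·(K_eff ∇p) = q with zero normal flux on the organ boundary.
K_eff = 1 (only ∇p matters; p is a relative pressure).  Discretization:
trilinear (Q1) finite elements with nodes at foreground voxel centers;
elements exist where a full 2×2×2 voxel-center block is foreground.  The
right-hand side uses per-element line integrals of the basis functions
(segments split at element faces, 3-point Gauss per piece); portions of a
segment that leave the element mesh are deposited on the nearest element so
the Neumann compatibility condition holds to round-off.  The constant
nullspace is removed by a mean-zero Lagrange constraint per connected
component.  Velocity: face fluxes −K_eff Δp/h·h² between active voxels, zero
on boundary faces, giving v = u/f_sin per voxel; total discrete divergence is
exactly the net source (zero), while local divergence near line sources is
nonzero and is absorbed into the coupling bookkeeping.

**HHS transport.** Only rbc and pls advect (c_int, c_cell exchange-only), via
conservative upwind finite volumes on the Darcy face fluxes, phase-split in
proportion to f_rbc/f_sin and f_pls/f_sin, Courant-limited sub-steps.
Supplying coupling: the mass leaving each supplying terminal in a step is
deposited along the rasterized centerline (≈ 4 samples per voxel length,
out-of-mask samples remapped to the nearest foreground voxel; weights sum to
one so no mass is lost).  Draining coupling: each draining terminal withdraws
at rate Q_leaf,phase · c̄_phase, where c̄ is the uniform volume-weighted mean
over foreground voxels within 2 grid spacings of its centerline; withdrawal
is distributed proportionally to local phase mass and capped at what is
present (capping events are logged).  The draining tree's leaf boundary
concentration is set from the mass *actually* withdrawn, so the two modules'
ledgers agree identically.

**PBPK kinetics.** Passive, gradient-driven exchange across a configurable
interface list (default serial chain rbc↔pls, pls↔int, int↔cell; a fourth
slot exists but is off by default):

    dc_a/dt −= (P_ab/f_a)(c_a − K_ab·c_b),   dc_b/dt += (P_ab/f_b)(c_a − K_ab·c_b)

with partition coefficient K_ab (flux vanishes at c_a = K_ab c_b) and
volume-normalized permeability P_ab in 1/min.  The tissue mass Σ f_i c_i is
conserved exactly by exchange; metabolization is a pure sink on c_cell,
first-order (k_met·c) or Michaelis–Menten (V_max·c/(K_m+c)).  Integration:
classical Fehlberg RKF45, applied to the stacked state of all grid nodes with
a shared adaptive step controlled by the worst scaled local error
(tol·(1+max|y|) per step); the 5th-order solution is propagated (local
extrapolation), which keeps the global error of smooth test problems below
the tolerance.  Initial step min(0.1·span, 1 s).

**Operator splitting.** Per macro step Δt (default 0.5 s; 1 s on the coarse
calibration geometry): (1) supplying-tree advection, (2) HHS advection with
the step's sources and sinks, (3) pointwise exchange+metabolization, (4)
draining-tree advection fed by the withdrawn mass.  First-order splitting; a
Δt-halving self-convergence test guards the choice (peak time moves by less
than one original Δt).  Metabolized mass is accounted as the tissue-mass drop
across phase (3) (exchange conserves, so the drop is exactly the sink);
the run aborts if the global ledger inflow = outflow + stored + metabolized
drifts beyond 10⁻⁶ relative (observed closure ≈ 10⁻¹⁵).

**Well-stirred reference.** The same four subspaces and kinetics in a single
perfusion-limited compartment: dc_phase/dt += Q_liv/(V_liv·f_sin)(c_in − c)
for both blood phases, outflow = mixed venous blood concentration.  Used
head-to-head to exhibit the two first-pass signatures of the spatial model:
a later and wider (larger FWHM) outflow peak.

**Pathology.**
*Steatosis*: a lipid volume ratio ρ(x) ∈ [0,1) raises the cellular partition
coefficient via volume-weighted affinity mixing, K_cell(ρ) = K_cell(0)(1−ρ) +
k_lip·ρ (anchored at the healthy value; k_lip is compound-specific; the form
is pluggable).  Heterogeneous fields are uniform draws per lobe range on a
4×-coarser grid, multilinearly interpolated; one coarse field is drawn per
lobe and composited by lobe membership, so lobe means are unbiased right up
to lobe boundaries.  The draws are antithetically paired (every second draw
mirrors the previous one within the range): marginals stay uniform while the
lobe-mean estimate is pinned at the range midpoint — without this, a 10⁴-voxel
lobe at 4× coarsening has only ~150 effective draws and the lobe mean scatters
by ~2.4% (1σ), swamping the homogeneous-vs-heterogeneous mean-matching
property the model is meant to exhibit.  The homogeneous variant is the
volume-weighted mean of the per-lobe range midpoints.
*Necrosis* (CCl₄-like pericentral injury): the fraction γ (default 0.2) of
foreground closest to the draining terminal centerlines (exact point-to-
segment distances) has its cellular space converted to interstitium
(f_int += f_cell, f_cell = 0, Σf_i = 1 preserved voxel-wise), cellular
exchange deactivated and metabolization zeroed.  Perfusion is deliberately
unchanged — a known simplification of the minimal model.

**Observables.** Outflow blood concentration at the draining root per macro
step; per-subspace total amounts; c_total = Σ f_i c_i (the imaging-comparable
quantity); mass-balance report; outflow summaries (peak, FWHM by linear
interpolation of half-maximum crossings, trapezoidal AUC, mean transit time as
the first temporal moment of outflow minus the inflow centroid).

**Calibration.** Lin's concordance correlation coefficient with population
(1/n) moments, ρ_c = 2cov/(var_x+var_y+(Δmean)²) — the 1/(n−1) convention
would change values.  Clearance fitting drives the full spatial simulator as
the forward model and minimizes the squared outflow residual over k_met by a
log-spaced grid bracket plus golden-section refinement (derivative-free; one
parameter).

## Synthetic study conditions

The standard substrate is an ellipsoidal two-lobe "liver" (half axes
8×6×4 mm ≈ 804 mm³, 0.5 mm grid, ≈ 6.4k tissue voxels) with 64-leaf supplying
and draining trees entering from opposite poles, Q_liv = 30 mm³/s
(≈ 1.8 mL/min, mouse scale), a 100 µmol/L whole-blood bolus for 10 s
(phase-equilibrated via the rbc↔pls partition), 60 s simulated at Δt = 0.5 s.
Four synthetic compounds (labelled synthetic throughout; no literature-value
claims): an inert non-exchanging reference, a lipophilic passively
exchanging tracer, a linearly cleared drug (k_met = 0.05/min), and a
high-clearance Michaelis–Menten drug (V_max = 40 µmol/L/min, K_m =
100 µmol/L, i.e. intrinsic clearance 0.4/min; K_m is of the order of the
cellular concentrations reached, so the kinetics operate in the mixed regime
— in a deeply saturated regime the metabolization rate is V_max regardless of
retention and steatosis could not alter turnover).  Steatosis ranges: lobe 1
(left-lateral-like) ρ ∈ [0.30, 0.70], lobe 2 ρ ∈ [0.05, 0.25].

The calibration geometry is deliberately coarse and fast (6×5×4 mm ellipsoid
at 1 mm spacing, 8-leaf trees, Δt = 1 s) with a 120 s window so the observed
outflow covers both uptake and washout; the washout tail is what identifies
the clearance rate (k_true = 0.3/min for the synthetic truth).  A shorter
window or a much smaller k leaves the outflow nearly insensitive to k and
the recovery ill-posed under noise.

What these conditions do **not** establish: agreement with any animal
measurement; behavior at production resolution (the desk scale is ~10× fewer
leaves and ~30× fewer voxels than a fully resolved mouse liver, so absolute
transit times and dispersion are coarser); effects excluded by design
(intravascular flow profiles, molecular diffusion, bile, hepatic artery as a
separate inflow, recirculation, steatosis effects on perfusion or enzyme
expression).  Passing tests certify internal consistency (conservation,
convergence, orderings, recovery) under the stated synthetic conditions.

## Numerical choices and degenerate inputs

- Coordinates: voxel indices 0-based, cell-centered physical coordinates
  x = (i+0.5)h, all geometry in mm; mass in nmol so that nmol/mm³ ≡ µmol/L.
- Kinetics run in minutes (P, k_met, V_max per minute), transport in seconds;
  conversion happens only at the operator-split interface.
- Disconnected masks: accepted by the geometry layer (CCO grows in the
  component reachable from the seed); the Darcy solver constrains the mean
  per connected component and requires per-component source balance.
- Draining sinks are capped at locally available mass per sub-step
  (nonnegativity guard); capping is logged and the draining-tree inflow uses
  the actually withdrawn mass, so capping never breaks the ledger.
- All randomness (CCO site sampling, steatosis fields, noise in calibration
  experiments) flows through explicitly seeded NumPy generators; results are
  bit-reproducible for a fixed configuration.
- Degenerate guards: empty masks, anisotropic rasters, zero-radius or
  zero-flow edges, pruning that would remove the root, empty sink
  neighborhoods (error names the terminal edge), both-constant series in
  ρ_c, and RKF45 step underflow all raise with diagnostics.

## Known limitations

First-order upwind transport smears sharp fronts (arrival times are
unbiased; widths are overestimated at coarse sub-grids).  First-order
operator splitting couples transport and kinetics to O(Δt).  The CCO search
is a local heuristic: volumes are guaranteed no worse than unoptimized
nearest-segment attachment per insertion, not globally minimal.  The
line-source quadrature near the organ surface clamps to the nearest element,
which conserves mass but slightly blurs source positions at the boundary.
The necrosis model removes metabolic capacity only through lost cell volume,
not through enzyme depletion in surviving tissue.
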