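# Methods

This note documents the models implemented in `porekinetics`, the default
parameter values and why they were chosen, the numerical methods, and the
known limitations. Energies are in units of kT unless stated otherwise;
lengths in Å, times in ns, voltages in mV. The default temperature is
303.15 K (kT = 0.6024 kcal/mol), matching typical recording conditions for
the TMEM16A system the presets describe.

## 1. Pore free-energy landscapes (`synthetic_pore.PoreLandscape`)

A landscape is a 1D free-energy profile G(s) for a Cl⁻ ion along the pore
coordinate s, defined by seven control points — three binding sites
(C, B, A at s = −10, 0, +10) and four barriers (s = −15, −5, +5, +15) —
interpolated with a monotonicity-preserving PCHIP spline and clamped to 0
outside the pore region [−20, 20] (bulk reference). PCHIP was chosen over
a cubic spline because it cannot overshoot between control points, so
barrier heights and well depths are exactly the specified values.

Two presets encode the two Ca²⁺-occupancy states of the channel:

| preset     | G(C, B, A) kT      | barriers kT (in→out)   | behaviour |
|------------|--------------------|------------------------|-----------|
| `paper2Ca` | (−2.5, 0, 0)       | (3.5, 3.5, 2.0, 1.0)   | near-Ohmic |
| `paper1Ca` | (+1.5, 0, 0)       | (6.5, 6.5, 2.0, 1.0)   | outwardly rectifying |

`paper2Ca`: a −2.5 kT well at the inner site C behind ~3.5 kT entrance
barriers, a ~6 kT climb from C to the neck, and ~2 kT outer features.
`paper1Ca` models the loss of one Ca²⁺ as a local destabilization of site C
(+4 kT) with its flanking barriers raised accordingly and the outer sites
unchanged.

## 2. Brownian-dynamics generator (`synthetic_pore.simulate`)

Overdamped Langevin (Euler–Maruyama) dynamics:

    x(t+dt) = x(t) − β D ∇U dt + √(2 D dt) η,  η ~ N(0, 1)³

with U(z) = G(z) + q·ψ(z), where ψ is a linear voltage ramp across the pore
region (ψ = u at the intracellular edge, 0 at the extracellular edge,
u = eV/kT), so a positive voltage drives anions inward and carries outward
(positive) current by the electrophysiological convention.

Defaults and rationale:

- `diffusion = 200 Å²/ns` — bulk Cl⁻ diffusivity near 303 K.
- `dt = 2×10⁻⁴ ns` — RMS step √(2Ddt) = 0.28 Å, ~18× smaller than the 5 Å
  control-point spacing; configurations whose RMS step exceeds a quarter of
  that spacing are rejected at construction.
- `pore_radius = 8 Å`, `box_height = 60 Å` — the whole periodic box is a
  cylinder of the pore radius. Deliberate simplification: because the
  cross-section is constant in z, the analytic Boltzmann linear density
  ρ(z) ∝ exp(−G(z)) is exact with no cross-section correction, making the
  generator a clean oracle for the profiling code.
- `n_ions = 16`, `n_waters = 16` — waters are neutral tracers that feel no
  landscape or field; they exist so trajectory files carry a second species
  and so water-flux analysis has input.
- `exclusion_radius = 1 Å` — ion–ion hard-sphere contact, applied by move
  rejection.
- Noise is drawn per particle from independent `SeedSequence`-spawned
  streams, so a particle's path does not depend on how many other particles
  follow it in memory order; runs are exactly reproducible by seed.

Stability guard: if the deterministic drift of any step exceeds 3× the RMS
thermal step, the run aborts with `UnstableStepError` rather than silently
integrating an unresolved force.

What the generator emulates: equilibrium Boltzmann statistics in a
prescribed landscape (verified by Kolmogorov–Smirnov distance and
landmark-by-landmark Boltzmann inversion in the tests), voltage-driven
drift with the Einstein relation, rare-event barrier crossings, and
MD-like trajectory output (frames every 0.25 ns at default settings are
typical of the analysis cadence).

What it does not emulate: explicit water and protein dynamics, 3D
electrostatics and induced charges, ion–ion electrostatic repulsion
(hard-sphere contact only), position-dependent diffusivity, and any radial
structure of the landscape. Finite-step (Euler–Maruyama) bias is below the
statistical resolution at the default dt.

Sampling caveat: with the deep `paper2Ca` well, occupancy of site C
decorrelates on the ~10 ns barrier-escape timescale, so a 10⁶-step (200 ns)
run determines well depths only to ~0.1–0.3 kT. Tests compare against
window-averaged Boltzmann expectations with tolerances set by this noise
floor, measured across independent seeds.

## 3. Profiles (`pathway_profiles`)

Pathways are straight axes or cubic splines through ≥4 anchor points
(arc-length parameterized, ±1% node spacing). Trajectory positions within
a radial cutoff of the path (default 7 Å; 5.7 Å is used when comparing to
the cylinder generator so the cylinder is fully contained) are binned along
s (default 0.5 Å, matching the density-grid resolution used throughout).
Free-energy profiles are G(s) = −ln(ρ(s)/ρ_bulk), with the bulk taken as
the mean density over a configurable bulk region (default: the outermost
15 Å at each end); empty bins are masked, not interpolated.
`read_feature` reads a landmark value by a local quadratic fit (default
half-width 1.75 Å), which is robust to bin placement and to noise in the
individual bins. `radius_profile` reports the largest ion-accessible
radius per slice from protein heavy atoms (probe-corrected), and
`kink_angle` measures helix bending as the angle between the axes of the
Cα runs on either side of a pivot residue. Helix axes are estimated from
cross products of successive second differences of the Cα positions —
exact for an ideal helix regardless of how many turns the window covers,
where a principal-component fit is biased by several degrees when the
window spans a non-integer number of turns.

## 4. Permeation counting (`permeation_analysis`)

A complete permeation event is a passage from one bulk boundary (s_lo or
s_hi) to the other; an ion must touch one boundary and then the other, and
re-entries without full crossing count nothing. The detector is an
incremental per-ion state machine (O(frames) and streamable); an
independent brute-force whole-trace scanner with the same definition
(`count_crossings_bruteforce`) exists purely for cross-validation, and the
two are required to agree exactly on large ensembles of random walks.

Currents: I = N·e/t per observation block (one event per 200 ns =
0.801 pA). Event-count uncertainty uses Poisson intervals:
`poisson_ci(n, method="garwood")` (default) gives the exact
chi-square-based interval — guaranteed ≥95% coverage, hence conservative
(e.g. 97.96% at mean 5); `method="score"` gives the Wilson-type interval
whose coverage tracks the nominal level closely (96.1% at mean 5). The
exact interval is the default because its endpoints are the standard
frozen reference values (n = 0 → upper 3.689; n = 54 → 40.6–70.5); the
score interval is provided for calibration studies where near-nominal
coverage matters. Conductance from counts at a single voltage is
g = I/V; `fit_iv` fits g across voltages with propagated Poisson weights.

Contact analysis uses a 3.5 Å heavy-atom cutoff (first-shell contact
distance); gate metrics report minimum inter-residue heavy-atom distances.

## 5. Kinetic permeation model (`kinetic_model`)

Three binding sites with at most two ions in the pore give 7 occupancy
states (∅, C, B, A, CB, CA, BA). Transitions are single-ion hops between
adjacent sites or exchanges with the two bulks. Rates are Eyring-like:

    k = k₀ · exp(−[E(barrier) − E(origin)])

where every energy includes the voltage term z·ψ(d) with ψ(d) = u(1−d) and
d the electrical distance from the intracellular side (sites at
d = 0.25/0.5/0.75, barriers at d = 0.125/…/0.875: the field drops linearly
along the pore). Bulk states carry the chemical potential ln(c/c_ref)
(c_ref = 150 mM), so entry rates scale linearly with the adjacent bulk
concentration. Because forward and backward rates share the same
transition-state energy, detailed balance holds by construction, and at
V = 0 with symmetric salt the steady-state current is exactly zero for any
landscape — the tests assert < 10⁻¹² pA over random landscapes, enabled by
one step of long-double iterative refinement after the dense steady-state
solve. Current is computed as z·e·(outward flux) across any cut (flux
conservation across all four cuts is asserted internally).

`g_interaction` (default 0, i.e. independent sites) adds a pairwise energy
when two ions occupy the pore. The single free prefactor k₀ is calibrated
by `calibrate_prefactor` so the small-voltage slope conductance matches a
target (4.4 pS for the double-bound preset); currents are proportional to
k₀, so this is a one-dimensional exact calibration, not a fit.

Ca²⁺ gating: sequential binding of two Ca²⁺ with state weights

    w₁ = (ca/c_ref)·exp(−E₁ + 2δ₁u),  w₂ = w₁·(ca/c_ref)·exp(−E₂ + 2δ₂u)

with c_ref = 1 µM, defaults E₁ = E₂ = −1 kT, δ₁ = 0.05, δ₂ = 0.10. The
defaults are calibrated, not measured: they place the double-bound
probability above 0.8 at 10 µM Ca²⁺ across ±150 mV, with weak voltage
dependence such that depolarization favors binding. The ensemble current
is P₀·0 + P₁·I₁(V) + P₂·I₂(V); with voltage-dependent binding this
produces strong outward rectification at sub-micromolar Ca²⁺
(|I(+150)/I(−150)| ≈ 2.9 at 0.4 µM) and a near-Ohmic response at
saturating Ca²⁺ (slope asymmetry ≈ 3% at 1 mM). "Saturating" is taken as
1 mM, where P₂ > 0.999 across the voltage range.

## 6. Continuum electrostatics (`electrostatics`)

1D nonlinear Poisson–Boltzmann across a planar membrane:

    d/dz [ε(z) du/dz] = κ²·ε_s·sinh(u)   (electrolyte; no mobile charge in the slab)

with ε = 80 in solution and 2 in the 29.2 Å hydrophobic slab, 0.1 M 1:1
electrolyte (Debye length 9.71 Å), Dirichlet boundaries (reduced potential
u_int at z_min, u_ext at z_max), and an optional conductor-like vestibule
that extends the intracellular boundary potential up to a given z —
representing the wide aqueous vestibule that carries the intracellular
potential deep into the membrane. With the vestibule at the slab bottom,
half the transmembrane field drops by the slab midplane
(field fraction 0.50); without it the electrolyte screens the boundary
within a few Debye lengths and essentially the whole drop happens before
the slab.

Numerics: damped Newton iteration on a second-order finite-difference
discretization (default grid 0.2 Å, ≪ the Debye length) with a banded
Jacobian solved by `scipy.linalg.solve_banded`; ε discontinuities are
handled by harmonic averaging on half-grid interfaces. For |u| ≤ 0.1 the
solution matches the closed-form linearized (Debye–Hückel) slab solution to
better than 0.01% of the boundary value; grid refinement changes the answer
by < 10⁻³.

The effective mobile charge density available to screen a perturbing
charge is n_eff = 2×10⁻²⁷·N_A·I·sinh(u) per Å⁻³ (I in mol/L) — the local
net ion density of the 1:1 electrolyte at reduced potential u.
`ca_perturbation` gives the screened-Coulomb (Debye–Hückel) potential
change from a point divalent charge, used to reason about how a bound
Ca²⁺ reshapes the local potential an anion sees.

Limitations: strictly 1D (planar), mean-field (no ion correlations or
finite-size effects), fixed dielectric constants, and the vestibule is a
conductor idealization rather than a solved 3D geometry.

## 7. Electrophysiology (`ephys`)

Nernst potentials (default 298.15 K, the usual bath temperature for the
reversal-potential convention); chord conductance G(V) = I/(V − E_rev)
with points within 2 mV of E_rev masked as indeterminate; normalization to
a reference voltage (default +140 mV). Boltzmann fits
G/G_max = 1/(1 + exp(−(V − V½)/k)) use `scipy.optimize.curve_fit` with
data-driven initial values; degenerate inputs (no rise, < 4 points) are
rejected rather than fit. The synthetic G(V) generator adds Gaussian noise
of a chosen σ; at σ = 0.02 (2% of G_max) the V½ estimator bias over 500
replicates is well under 1 mV (the acceptance script reports it).

## 8. Reproducibility

All stochastic routines take explicit seeds; simulations use per-particle
`SeedSequence` streams. `scripts/acceptance.py --seed N --out file.json`
recomputes every headline quantity from scratch (fresh simulations and
Monte-Carlo studies, closed-form references inlined) and writes
`{"name": {"value": ..., "n": ...}}`. Child seeds are derived from the
master seed and kept below 2³¹ for portability.
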