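# Methods

This note records the models, conventions and numerical choices behind
`ilscale`, and what the built-in toy fixtures do and do not demonstrate.

## Uniform scaling of fixed-charge force fields

Fixed-charge IL force fields combine ab initio (RESP-style) atomic charges
with transferable bonded/vdW parameters.  Because gas-phase charges neglect
condensed-phase polarization and charge transfer, the package implements the
two standard uniform corrections as exact, composable topology transforms:

* `scale_charges(top, s_q, targets)` multiplies every atomic charge of the
  target molecules by `s_q` (bounds (0, 1.5]); net charges scale exactly
  linearly, and scaling composes multiplicatively.
* `scale_sigma(top, s_sigma, targets)` multiplies the LJ collision diameter
  of every atom type used by the target molecules by `s_sigma` (bounds
  [0.5, 1.5]); ε, charges, masses and bonded terms are untouched.

By default both transforms target only molecules tagged `solvent-ion`
(role inferred from the net charge: |q| > 0.5 e), because the tuning
corrects the ionic *solvent*; solutes keep their full fitted charges and
radii.  Whether solute radii should also be scaled in solvation runs is
genuinely open; the `targets` argument surfaces the choice instead of hiding
it.  Cross-interaction σ between scaled ions and unscaled solutes follows
from re-applying the combination rule to the scaled per-type σ — no pair
overrides are generated, so an atom type shared between a target and a
non-target molecule is an error (`duplicate_atom_type` resolves it by
cloning the type).

Topology I/O supports a documented subset of the GROMACS dialect.  Round
trips are semantic, not byte-exact, except for passthrough blocks (bonded
sections, `[ system ]`, …) which are preserved verbatim.  Charges are
written with 10 decimals and a post-write check warns if any molecule's
formatted net charge drifts by more than 1e-6 e.

## ESP charge quality

Charge quality is scored by how well the point charges reproduce a reference
electrostatic potential on a molecular grid:

    RRMSE = sqrt( Σ_k (V_model,k − V_ref,k)² / Σ_k V_ref,k² ).

This ratio-of-sums definition is the conventional one in the RESP-fitting
literature (the quantity is reported both as a fraction and as a percent).
Everything is internal atomic units; Å input converts at 1 Å = 1.889726
bohr.  Grid points closer than 1e-6 bohr to an atom raise a singularity
error rather than returning huge potentials.  The shell-grid builder lays
golden-spiral points on scaled vdW surfaces (default scales 1.4–2.0,
density in points/bohr²) and prunes points falling inside any other atom's
scaled sphere; a seed fixes the sphere orientations, making grids
reproducible.

## Fast-growth free energies

Works are stored dimensionless (units of kT at the work set's temperature;
k_B = 0.0019872041 kcal/mol/K for conversions).  The estimator is
exponential averaging over solute-creation works,

    ΔA = −ln (1/n Σ_i exp(−W_i)),

evaluated with log-sum-exp stabilization so |W| up to ~1e3 kT cannot
overflow.  Sign convention: works are accumulated in the creation
(decoupled → coupled) direction, so ΔA *is* the solvation free energy; no
sign flips occur downstream, and transfer free energies are plain
differences with SDs combined in quadrature.

The estimator is asymptotically unbiased but biased high at finite n
(Jensen: ΔA ≤ mean(W), with the bias decreasing in n and increasing in the
work variance), and its analytic error formula underestimates the true
uncertainty.  Uncertainty therefore comes from bootstrap resampling:
B = 1000 resamples with replacement by default, seeded generator, SD =
sample standard deviation (ddof 1) of the resample estimates.  A single
bootstrap SD is itself a noisy estimate for this heavy-tailed statistic;
averaged over independent work sets it tracks the replication SD to within
~10 % in the regimes tested.

Two-stage protocols (a slow vdW-coupling stage followed by a faster
charging stage) combine per realization by default — the stages of one
realization run sequentially, so their works add before averaging.  A
per-stage mode (EXP per stage, ΔA summed, SDs in quadrature) is provided
for outputs where realizations cannot be paired.  λ-series inputs are
integrated by the trapezoid rule over the recorded λ grid; an engine's own
accumulated-work column can be supplied directly as a work list instead.

## Density response and factor recommendation

Simulated IL density responds almost linearly to σ scaling over the narrow
ranges of practical interest, so a scan is summarized by unweighted OLS
(scan SDs are display-only; the points are typically equally precise).
Derived quantities:

* relative slope b/ρ_exp — dimensionless response, comparable across ILs.
  The two-decimal *reporting* helper truncates toward zero; truncation (not
  rounding) is the only convention consistent with the published pairs
  −1.82/1.358 → −1.34 and −1.73/1.295 → −1.33.  Full precision is always
  retained internally.
* density-matched factor s\* = (ρ_exp − a)/b, with warnings for
  extrapolation outside the scanned range, non-positive solutions, and
  anomalous positive slopes.
* balanced factor: density matching alone overfits solvent–solvent
  interactions and degrades solvation/partition accuracy, so the
  recommended production factor lies in the closed interval between the
  density-derived and solvation-derived factors, one `step` (default 0.01)
  from the density-derived end toward the solvation-derived one — slightly
  denser-than-experiment packing is preferred.  A step spanning the whole
  interval clamps to the midpoint with a warning.

Per-temperature scans are independent records; no thermal-expansion model
is fitted.

## Agreement metrics

Kendall's τ is the tie-corrected tau-b (the published analyses do not state
a variant; tau-b is the safe default for data with repeated values) and
Pearson's r the standard product-moment correlation, both delegated to
scipy.  Pearlman's predictive index is implemented directly from its
original weighted-pairs formulation, w_ij = |expt_j − expt_i| and
c_ij = sign((expt_j − expt_i)/(calc_j − calc_i)) with c_ij = 0 for tied
calculations; pairs that matter more experimentally weigh more.  All-tied
inputs raise `UndefinedMetricError` rather than returning a silent NaN.
Because PI reweights pairs, its sign can differ from τ's for weakly ranked
data; they agree on clearly ranked data.

## The toy ionic fluid

`toyfluid` provides a stand-in for the ~170-ion-pair MD cells used in
production IL work, at a size where every test runs in seconds: a periodic
1:1 soft-sphere electrolyte sampled by Metropolis NPT Monte Carlo
(single-particle displacements plus ln-V volume moves accepted with
min(1, exp(−β(ΔU + PΔV) + (N+1)Δln V))).  Electrostatics use damped
shifted-force (Wolf-type) truncation — adequate for qualitative packing
behaviour, *not* a substitute for particle-mesh Ewald.  Scaling factors
enter exactly as in the topology transforms: charges ±q·s_q, diameters
σ·s_sigma.

Default conditions (chosen once as a coarse room-temperature IL): 24 ion
pairs with NTF-like masses 150/280 amu, σ 0.45/0.55 nm, ε 2.5/3.0 kJ/mol,
charges ±0.6 e with s_q = 0.8 applied, 298 K, 1 bar, 0.75 nm cutoff with
α = 1.5 nm⁻¹, move half-widths 0.08 nm and 0.03 ln-units (≈25–30 % and
≈60 % acceptance; fixed sizes, no auto-tuning, so trajectories are
bit-reproducible for a seed).  Two deliberate departures from a naive
point-ion picture are worth recording.  First, the LJ wells are ~kT —
molecular-liquid-grade dispersion — and the effective charges are well
below ±1 e, reflecting the delocalization of charge over large molecular
ions: full point charges at 0.5 nm contact (tens of kT) make the
48-particle fluid glassy at 298 K, while much weaker charges cannot hold a
liquid together at 1 bar in a sampler that has no aggregation moves.  The
chosen window gives an ergodic, condensed ionic fluid.  Second, runs start
from a condensed lattice (number density ρσ³ ≈ 0.7) for the same reason:
the liquid cannot nucleate from vapour by single-particle moves.

Densities are sampled once per sweep during production and block-averaged
(10 blocks; the reported SD is the SE of the block means).  Energies are
tracked incrementally for displacement moves and recomputed from scratch
for volume moves; the final incremental total matches a from-scratch
recomputation to better than 1e-6 relative.  An accepted volume move that
would take the box edge below 2 × cutoff aborts the run with a diagnostic
(the minimum-image energies would otherwise be wrong); sub-16-pair boxes
need a cutoff of ≲0.6 nm for this reason.

`density_scan_toy` averages 3 independent replicas per scan point
(between-replica scatter dominates the single-run block SD in so small a
system) and, when no experimental stand-in is supplied, uses the scan mean
as ρ_exp so density matching lands inside the scanned range.  Typical
problem sizes used by the test suite and the acceptance script — 600–1500
equilibration and 800–4000 production sweeps, 16–64 particles — were chosen
so the whole pipeline runs in minutes on one CPU.

What the toy shows: the qualitative density responses the analysis modules
consume (monotone decrease with σ scaling, local linearity with R² > 0.9
over ±3 %, the exact NPT ideal-gas law ⟨V⟩ = (N+1)kT/P when interactions
are switched off).  What it does not show: absolute IL densities,
transport, molecular structure, or Ewald-quality electrostatics — passing
its tests says the *analysis chain* is correct, not that any production
force field is accurate.

The synthetic work generator draws W ~ N(ΔG + σ_w²/2, σ_w²), the Gaussian
family consistent with the Crooks fluctuation theorem, so EXP has the exact
truth ΔG in the large-n limit and a known positive finite-n bias — this is
what the estimator-recovery tests exploit.  The paired-data generator puts
experimental values on a fixed −12…0 kcal/mol grid with iid Gaussian
calculation noise; at zero noise every agreement metric is exactly perfect.

## Known limitations

* The topology dialect excludes CHARMM/AMBER formats, bonded-parameter
  editing and RESP fitting; pair-type overrides are never generated.
* Only the unidirectional EXP estimator is implemented (no BAR/Crooks,
  no thermodynamic integration).
* The ESP module consumes reference potentials; it computes none
  (no quantum chemistry, no cube files).
* The toy fluid's Wolf electrostatics and tiny cell make it a fixture, not
  a production engine.
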