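# Methods

## Scope and model structure

`microfit` couples per-species flux balance analysis (FBA) to a single,
community-wide pool of extracellular compounds. The package deliberately
models only one interaction channel — competition for, and cross-feeding
through, that shared pool. Quorum sensing, spatial structure, pH and
thermodynamic feedbacks are out of scope. All species experience the same
well-mixed concentrations; each species' exchange reactions are mapped to
pool compound ids through its `exchange_map`. Although pool compounds could
be tracked per producing species, the shared pool is the semantically
relevant object, and the per-producer decomposition is recoverable from the
recorded per-species fluxes.

## The inner linear program

For one species at one instant, fluxes solve
maximize *c*ᵀ*v* s.t. *S v* = 0, lb ≤ *v* ≤ ub, with +1 on the biomass
reaction. The steady-state right-hand side is identically zero
(quasi-steady-state for intracellular metabolites). Sign convention:
exchange flux < 0 is uptake, > 0 secretion. An infeasible program is
returned as a status with zero fluxes, never raised — during a simulation a
species may transiently be unable to grow, and the stepper must carry on.

FBA optima are frequently degenerate. `resolve_unique_flux` re-solves
minimizing Σ|*v*| with the objective pinned at its optimum (held as an
inequality a relative 1e-9 below the reported value; an exact equality is
routinely infeasible at solver precision). The simulator applies this
parsimonious pass by default so that trajectories are reproducible when
alternate optima exist.

Two solver routes exist on purpose. `solve_fba`/`resolve_unique_flux` build
a fresh `scipy.optimize.linprog` (HiGHS) problem per call and are the
reference implementation. The simulator's hot loop uses `IncrementalFBA`, a
persistent GLPK problem (via swiglpk) whose column bounds are updated in
place and warm-started — the same LP solved ~20x faster. A property test
pins the two routes together on random networks; an independent brute-force
vertex-enumeration oracle checks the reference route itself.

Tolerances: steady-state residual |*S v*| ≤ 1e-6, bound violations ≤ 1e-9,
parsimonious objective drift ≤ 1e-8 relative. These are our choices; they
comfortably envelope both solvers' defaults.

## Time stepping

Forward Euler with Δt = 0.1 h. Per step: (1) Monod uptake bounds
−*V*max·*C*/(*K*s+*C*) from the current pool (*K*s = 0.10 mM, one scalar for
every species/compound — the deliberately generic parameterization that the
fitting loop later compensates through *V*max); secretion bounds are never
modified, and a Monod bound never widens a reaction the model declares
irreversible. (2) Per-species FBA. (3) Euler update of biomass and pool
with chemostat terms (q/V; default batch, q = 0, V = 1 L). (4) Augmentation
for pool non-negativity, below. Biomass is clamped to [0, *X*ᵐᵃˣ], default
50 g/L per species. A `frozen_species` option pins a species' biomass
constant (it still exchanges metabolites), for communities containing
members known not to grow.

### Augmentation: proportional rationing

If the consumers of compound *i* together demand more than the step can
supply (current stock + inflow + concurrent production), every consumption
term of *i* is scaled by the common factor supply/demand, and each species'
growth increment is scaled by the fraction of its total requested uptake it
actually received. This is the continuum limit of iteratively dividing the
consumers' effective biomass by a fixed reduction factor: it reaches the
same non-negative pool exactly, but — crucially — leaves the realized
transfers a *continuous* function of the kinetic parameters. A stepwise
reduction factor makes end-of-run fractions jump discontinuously under ~1%
parameter changes (one scarce byproduct can rescale a species' uptake of
every other compound by 8x), which defeats gradient-style fitting; the
rationing scheme removes those jumps while preserving the same guarantees.
`biomass_reduction_factor` remains a `ReactorConfig` field for interface
compatibility with the named integration parameters, but the closure
supersedes the iteration it would parameterize.

One caveat is accepted knowingly: a rationed species still secretes at its
FBA rate while its uptake and growth are scaled, so its *internal* flux
vector is not exactly stoichiometric during such a step. Pool-level mass is
still conserved exactly — the recorded effective fluxes are defined so that
`dt · flux · X(start)` is the realized transfer, which makes the discrete
mass-balance audit close to machine precision on closed reactors.

When the over-demand on a *stocked* compound exceeds `max_deviation` (25x
supply), the step is instead retried at half the step size, recursively
down to Δt/2¹⁰, so that a badly under-resolved drawdown is integrated
finely. Pure flow-through deficits (stock ≈ 0, supply dominated by
concurrent production) keep the same demand/supply ratio at any Δt and are
rationed directly — sub-stepping them would recurse to the depth limit for
no accuracy gain.

### Termination

`simulate` stops at `t_end` (default 24 h) or earlier once the largest
relative rate of change of any biomass or pool entry stays below
`steady_state_accuracy` (default 1e-2) for five consecutive steps. Two
details differ from the naive reading of that threshold. First, the
criterion is a rate per hour, not per step, so it does not depend on Δt.
Second, the five-step window exists because cross-feeding pipelines
transiently stall for a single step (producer throttled → consumer idle),
and a one-step test turns that lull into a knife-edge early exit.

The fitting loop disables the early stop entirely and always evaluates at
the full horizon: a termination time that shifts with the parameters makes
the end-point fractions — and therefore J — discontinuous in *V*max.
Observed failure mode before this choice: stop times shifting by hours
under < 0.1% parameter changes.

## The fitting loop

Cycle: simulate → fractions *f*ˢⁱᵐ at `t_end` → *J* = Σ(*f*ʳᵉᶠ−*f*ˢⁱᵐ)² →
update. Stop on *J* ≤ `j_stop` (default 0.001), on a plateau (|ΔJ| < 1e-5
for 5 consecutive cycles — a formalized version of stopping by hand when a
local minimum is reached), or at `max_cycles` (default 100). The result
carries the full *J*/fraction/*V*max history, the stop reason, the best
cycle's parameters and trajectory, and flags species that have positive
reference fraction but never grew.

The default update is multiplicative in log space,

  *V*max,j ← *V*max,j · (*f*ⱼʳᵉᶠ / *f*ⱼˢⁱᵐ)^α,

applied uniformly to all uptake-capable exchanges of species *j* (nothing
in the data distinguishes individual reactions), clipped to a factor of 2
per cycle and floored at 1e-6. The ratio form matters: an additive-error
rule (step ∝ *f*ʳᵉᶠ−*f*ˢⁱᵐ) caps its step size at the fraction mismatch
(≤ 1) even when the parameter must move several-fold, and in our
experiments plateaued above the stop threshold on ~40% of seeded recovery
problems; the ratio rule corrects rare and dominant species on the same
relative scale and converged on 40/40 seeded problems in 11–45 cycles,
consistent with α ∈ {0.125, 0.25} acting as a relative step size. A
`finite_difference` mode (forward differences of J w.r.t. each species'
log-*V*max, step −α·∇) is provided for validation; it costs n+1 simulations
per cycle and its gradient signs are tested against a refined
central-difference oracle.

The "weighted error" reported alongside J is defined here as
|*f*ʳᵉᶠ−*f*ˢⁱᵐ|·100 per species (percentage points), with mean and
population SD; whether an abundance-weighted variant was ever intended is
not recoverable, so the plain definition is exposed and documented.

## Hierarchical fitting

Profiles spanning orders of magnitude defeat a joint fit for a structural
reason: every species starts from the same inoculum (0.1 g/L), so a species
that should end at ≪ inoculum/total-biomass cannot get there — washout is
impossible in batch. `fit_hierarchical` splits the species into disjoint
groups (user-supplied, or automatic binning by floor(log10 *f*ʳᵉᶠ)),
renormalizes each group's reference to sum to 1, fits each group as its own
community on a fresh copy of the medium, and merges the fitted fractions
weighted by each group's original share. Split∘merge is exactly the
identity on fractions. Cross-group interactions are dropped by
construction; the compounds exchanged by species in more than one group are
logged so the user can judge the cost. A failed group is reported and does
not abort the others.

## Synthetic communities

The generator builds the smallest networks that still exercise every code
path: per species, one uptake exchange per carbon source, a conversion
reaction source → yield·biomass (+0.3 byproduct when the species secretes),
a biomass sink, and a secretion-only exchange. With cross-feeding, species
*k* ≥ 2 can also consume the byproduct of species *k*−1, so its extra niche
only opens once the upstream species is active. All generators are pure
functions of their seed.

Fixed study conditions, chosen once: inoculum 0.1 g/L per species; medium
40 mM of the single shared carbon source (~7 g/L glucose); biomass yields
uniform in [0.04, 0.10] gDW/mmol, bracketing real heterotroph yields on
glucose (~0.09); hidden *V*max\* log-uniform in [1, 20] mmol/gDW/h, drawn
*per species* and shared across that species' uptake exchanges so that the
reference profile generated by forward simulation lies on the manifold the
fitter searches. The yield range is not only realism: together with the
*V*max range it keeps specific growth rates below ~2 h⁻¹, which Δt = 0.1 h
forward Euler resolves (halving Δt moves endpoints < 5%); a wider yield
range produced growth rates the scheme integrates with O(1) error.

What the fixtures do *not* emulate: realistic network topology (tens to
thousands of reactions, cofactor coupling, maintenance ATP), per-reaction
kinetic heterogeneity, inhibition, death/lysis, and measurement noise in
the reference profile (targets are exact simulator outputs). Passing the
recovery tests therefore demonstrates that the optimization machinery
inverts the simulator's own map from kinetics to composition — it does not
by itself validate biological parameter estimates on real communities,
where the reference composition contains error and may be unattainable for
the model (the plateau stop exists precisely for that case).

## Numerical and interface details

- Fractions: reference profiles must sum to 1 within 1e-9 (loader
  renormalizes percentages/counts and logs it); `performance_j` insists on
  1e-6. Zero simulated fractions are guarded at 1e-6 inside the update.
- Ties/degeneracy: parsimonious FBA canonicalizes alternate optima; with it
  disabled (`parsimonious=False`), results remain deterministic for a fixed
  environment but may depend on solver pivoting across versions.
- Trajectory TSVs print 12 significant digits; round trips preserve values
  to that precision. The flux companion table stores realized specific
  rates and a flag marking uptakes that sat on their Monod bound
  (within 1e-6).
- `q`, `V`, `t_end` were never pinned by the original description; defaults
  are batch (q = 0), 1 L, 24 h, all configurable.
- Problem sizes in the shipped tests (4–8 species, ≤ 100 cycles, 240 steps
  per simulation) are the package's chosen desk-scale study conditions;
  they keep the full suite in a few minutes while exercising every
  mechanism.

## Known limitations

- The Euler scheme is explicit: stiff media (very low *K*s together with
  very high *V*max·X) rely on the rationing/sub-stepping machinery rather
  than true stiff integration.
- Uptake-only Monod limits: whether secretion should also saturate is left
  open; secretion is unconstrained here.
- Per-species uniform *V*max is both the fitter's search space and its
  blind spot: data that require per-reaction kinetics cannot be matched.
- In batch, a species' fraction cannot fall below its inoculum share of
  final total biomass; targets below that floor need the hierarchical mode
  (or a chemostat configuration).
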