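# Methods

## Model

`tracekin` simulates compartmentalized metabolic networks as a system of
ordinary differential equations over metabolite concentrations coupled to
¹³C isotopomer bookkeeping, fits grouped enzyme activities to
multi-condition measurements by simulated annealing, and assesses
identifiability by profile likelihood.

### Concentration dynamics

For metabolite *i* located in a compartment of volume `vol_i` (litres),

    dc_i/dt = Σ_r N_{i,r} · j_r(c, p) · ncell / vol_i        [mM·min⁻¹]

where `N` is the stoichiometric matrix, `j` the vector of per-cell reaction
rates (mmol·cell⁻¹·min⁻¹) given by the kinetic laws, `p` the kinetic
parameter vector and `ncell` the cell number.  Constant (boundary) species
are excluded from the integrated state; their fixed concentrations are
substituted at rate evaluation.  Every reversible reaction evaluates a
forward and a reverse rate separately.  Reverse capacities are never free
parameters: they are derived from the forward capacity and the equilibrium
constant through the Haldane relationship (for the uni-uni reversible
Michaelis–Menten template, `Vmax_r = Vmax_f·Km_P/(Keq·Km_S)`; multi-
substrate templates use the product-of-Km generalization), so zero net flux
at the thermodynamic equilibrium ratio holds identically in the parameters.

Negative concentrations produced by trial integrator steps are clamped to
zero inside rate evaluation only; the state itself is not modified, which
keeps the right-hand side smooth enough for the stiff solvers while
preventing sign errors in rates.

### Label propagation

Isotopomers are indexed by bitmask — bit (position−1) set means ¹³C at
carbon `position` (1-based, C1 = carbonyl end of a sugar) — giving 2ⁿ
states for an n-carbon metabolite (n ≤ 7 throughout, so direct enumeration
is used; no cumomer/EMU reduction).  The joint state stores isotopomer
concentrations for label-reachable species and plain totals for everything
else; totals of labelled species are *defined* as isotopomer sums, so the
consistency invariant holds by construction and is checked only as a guard
against bookkeeping regressions.

Per reaction direction carrying flux J ≥ 0, a substrate isotopomer
combination (i₁,…,i_s) is consumed at rate J·Π_k fraction(i_k) (well-mixed
pools, independent draws) and its carbons are routed through the
atom-transition map to one product isotopomer per product slot; carbons
that leave to non-labelable species (e.g. CO₂) are dropped, and unmapped
product carbons enter unlabelled.  Reverse rates propagate label backwards
through the inverted map, which captures exchange labelling without net
flux; "invisible" reactions (zero net stoichiometry) contribute only these
exchange terms.  Rotationally symmetric molecules (fumarate, succinate)
enter and leave reactions in either orientation with probability ½,
implemented by symmetrizing substrate fractions before routing and
splitting product inflow 50/50 between orientations.  When a labelled
pool's total falls below 10⁻¹² mM its fractional abundances are defined as
pure m0 to avoid 0/0 at startup.

The joint totals+isotopomer system is integrated as one stiff system (not
operator-split).  The default solver is LSODA for small systems
(< 150 states) and BDF with a network-derived Jacobian sparsity pattern for
large ones, at relative tolerance 1e-8 and absolute tolerance 1e-10 mM for
plain simulation (1e-6/1e-8 inside the fitting loop, where thousands of
simulations are required and measurement noise dominates discretization
error).  Halving the tolerances changes endpoints by less than the coarser
tolerance (checked in the test suite).

### Observables

GC/MS measures isotopologue (mass-isotopomer) fractions of whole molecules
or fragments (contiguous carbon ranges, e.g. glucose C1-C4).  Predicted
isotopomer vectors are collapsed by counting set bits within the fragment's
carbon positions.  The sorbitol observable pools medium glucose and
fructose (borohydride reduction converts both hexoses to sorbitol), so its
MID is the concentration-weighted combination of the two isotopomer
vectors.  **No natural-abundance correction is applied to simulated MIDs**:
the pipeline assumes experimental spectra were already corrected for
natural ¹³C before comparison.

### Objective and fitting

All conditions share one parameter set (activities normalized per cell are
assumed condition-independent).  Enzyme activities in unbranched reaction
chains are fitted as one group factor each (the chain flux cannot separate
them); near-equilibrium steps (glucose phosphate isomerase, triose
phosphate isomerase, enolase, phosphoglucomutase in the demo) keep fixed
large capacities and are not fitted.  The objective is

    X² = Σ_i ((Y_i − Z_i(E₁…E_m)) / σ_i)²

with σ_i floored at 0.01, summed over concentration and MID measurements of
every condition.  Parameter sets driving any metabolite above 50 mM
anywhere along a simulated trajectory — evaluated on all dense-output
samples, not just measurement times — are rejected with an infinite
objective, as are failed integrations.

The estimator is a variant of basic simulated annealing: a geometric
temperature ladder (default T₀ = initial X², cooling 0.95, 50 moves per
temperature, stop at T < 10⁻³·T₀ or 2·10⁴ evaluations), Metropolis
acceptance, and multiplicative log-normal proposals on one randomly chosen
factor.  Two refinements beyond the textbook scheme, both exposed in the
schedule: the proposal width shrinks with √(T/T₀) so late moves refine
rather than re-explore, and with probability 0.2 all free factors are
rescaled jointly, which traverses the correlated valley that chain
groupings otherwise leave (single-factor moves stall there).  Factor search
is in log space with default bounds 10∓³ × the initial guess.  The
best-ever point is returned and runs are bit-reproducible given a seed.

### Identifiability

The profile of factor θᵢ is X²(θᵢ) = min over the other factors of X² with
θᵢ fixed; the (1−α) confidence interval is {θᵢ : X²(θᵢ) − X²_bf < Δα} with
Δα the upper-α quantile of χ²(1 df) (3.841 at α = 0.05).  The
implementation steps θᵢ on a multiplicative ×1.2 grid outward from the
best fit, re-optimizes the remaining factors at each point, brackets the
threshold crossing and refines it by geometric bisection to 2% width; a
side with no crossing before 10±³ × the best-fit value is declared
unbounded (non-identifiable).  Re-optimization is deterministic and
warm-started from the neighbouring accepted point: a bounded
golden-section search in log space when one factor remains free, a
Nelder–Mead simplex in log space otherwise, with the evaluation budget a
fraction (default 10%) of the full anneal budget.  A short stochastic
re-anneal was rejected for this role: it systematically under-minimizes
the inner problem, which inflates X²(θᵢ) and makes the reported intervals
too narrow (anti-conservative).

Prediction envelopes for dependent variables (concentrations, fluxes, MID
fractions over time) are pointwise min/max over simulations at *every*
accepted profile point plus the best fit.  This is a superset of the
two-extremes-per-parameter heuristic; the superset is used deliberately
because extreme parameter values can miss non-monotone responses of the
dependent variables.

## The hepatocyte demonstration model

The shipped demo is a reduced, re-parameterized hepatocyte network
(35 reactions, 31 metabolites, 3 compartments: 2 mL medium, 40 µL total
cytosol and 10 µL mitochondrial matrix for 10⁷ cells), not a port of the
published full model.  It covers glucose transport and phosphorylation
into two channelled hexose-phosphate pools (*a* glycolysis-oriented, *b*
glycogen-oriented), the three net aldolase reactions (FBP cleavage, Fru1P
cleavage, and the transfer reaction FBP + glyceraldehyde ↔ Fru1P + GAP,
sharing one capacity group with competitive cross-inhibition), the
fructose pathway (low-affinity GLUT2-like transport with Km 67 mM,
fructokinase, triokinase), lower glycolysis to lactate export, the
glycogen branch, and a closed energy subsystem.  Deliberate reductions:

- **Lumped mitochondrial ATP regeneration**: one saturable reaction
  cADP + mPi → cATP stands in for the respiratory chain plus adenine
  translocator block; NAD/NADH and NADP/NADPH are held constant and folded
  into rate constants.
- **Uridine nucleotides folded into the adenine pool**: UDP-glucose
  formation consumes ATP and glycogen synthase releases ADP, so the
  conserved adenine moiety is cATP+cADP+cAMP+UDPG and the phosphate ledger
  stays closed without a uracil subsystem.
- **Glycogen** is a pool of glucosyl units in the cytosolic volume (no
  polymer chain-position bookkeeping).
- **Excluded branches**: pentose phosphate pathway, Krebs cycle, fatty
  acid and glutamate metabolism.  Glutamate observables are therefore
  disabled rather than approximated; the supported fragments are glucose/
  glycogen C1-C6, C1-C4, C3-C6, lactate C1-C3 and sorbitol C1-C6.
- **Phosphate homeostasis**: a sodium-coupled import (effective
  equilibrium constant > 1) holds cytosolic Pi near 5 mM against ~1 mM
  medium phosphate; the mitochondrial carrier equilibrates mPi toward
  2 × cPi.  Without active import, cytosolic phosphate drains down its
  gradient and the energy state collapses even at low fructose.

Capacities are hand-tuned (in cytosolic mM·min⁻¹ converted to per-cell
units) so that with 20 mM glucose + 3 mM fructose the cell accumulates
glycogen at a roughly steady energy charge, while 20 mM fructose drives
unregulated fructokinase flux that accumulates fructose 1-phosphate
(peaking ~35 mM, below the 50 mM rejection ceiling), sequesters phosphate,
throttles the Pi-limited ATP regeneration and depletes cytosolic ATP and
Pi — suppressing glycogen synthesis and the transfer of glucose ¹³C to
lactate.  Only this *directional* phenotype is claimed, never quantitative
agreement with fitted fluxes of the full published model.  Affinity
constants come from typical literature ranges for the liver isoforms
(glucokinase S₀.₅ 8 mM, GLUT2 glucose Km 17 mM, fructose Km 67 mM);
intracellular initial concentrations are literature-scale assumptions, not
measurements.

A ±20% single-parameter robustness sweep over the influential capacities
(fructose transport and fructokinase, aldolase, ATP load, ATP regeneration,
phosphate import, glucokinase, glycogen-synthesis chain) preserves the
direction of all five phenotype contrasts (ATP↓, Pi↓, Fru1P↑, glycogen↓,
lactate-m2↓ under high fructose); the sweep script is not part of the test
suite for runtime reasons, but the phenotype checks themselves run on every
test invocation.

The three incubation conditions: A1 = 20 mM glucose (50% [1,2-¹³C₂]) +
3 mM fructose; A2 = 20 mM glucose + 3 mM fructose (50% [U-¹³C₆]); B =
20 mM glucose (50% [1,2-¹³C₂]) + 20 mM fructose; 120 min horizon.  A1 and
A2 differ only in tracer placement, so their totals and fluxes coincide
(checked in the suite).

## Synthetic data generator

The generator emulates the study design: each condition is simulated at
the true parameters, observables are sampled at the 2-hour endpoint
(medium glucose and lactate concentrations, glycogen content, MIDs of
medium glucose C1-C6, glycogen C1-C4 and C3-C6, lactate C1-C3, pooled
sorbitol C1-C6), Gaussian noise of a configurable standard deviation is
added, MID fractions are clipped to [0, 1], and σ is recorded as
max(noise, 0.01).  What it does **not** emulate: natural-abundance
contamination and its regression correction, derivatization chemistry and
fragment-specific mass interferences, biological replicate variation
beyond additive Gaussian noise, and cell-number uncertainty.  Passing
recovery tests on this generator therefore demonstrates correctness of the
estimation machinery under the model's own assumptions, not robustness to
real-instrument systematics.

## Verification strategy and problem sizes

- **Closed forms**: first-order label wash-in on the chain3 toy matches
  1−e^(−kt) to 1e-4 relative; symmetric A↔B equilibration; Haldane-derived
  reverse capacities give identically zero net flux at the equilibrium
  ratio.
- **Molecule-level Monte Carlo oracle**: an independent stochastic
  simulator (explicit molecule populations of 10⁵ molecules/mM, tau-leap
  events, random substrate draws, per-molecule carbon routing, random
  orientation for symmetric species) reproduces the ODE engine's
  isotopologue fractions within 3 binomial standard errors on all toy
  networks.
- **Recovery**: on chain3 (3 factors, 30 measurements, 1% noise) the
  annealer recovers the true factors within the 95% profile intervals and
  reaches X² < 10⁻³ on noise-free data; interval coverage over 20 seeded
  noise replicates is ≥ 80% (a loose bound acknowledging optimizer noise).
- **Degeneracy**: the degenerate_pair toy (fast quasi-steady intermediate)
  yields a one-sided profile, flat upward, confirmed both by the profiling
  code and by brute-force 1-D re-optimization.

Problem sizes were chosen for tight feedback loops: the demo's joint system
has ~860 states (14 hexoses × 64 isotopomers + 10 trioses × 8 + 6 totals)
and integrates a 2-hour course in seconds; recovery and coverage
experiments use the 27-state chain3 toy with ~10 ms objective evaluations.

## Known limitations

- Multi-substrate isotopomer fluxes assume well-mixed pools (product of
  independent fractional abundances); no channelling of label *within* a
  reaction sequence is represented beyond the explicit two-pool hexose
  phosphate structure.
- The SBML reader covers the structural subset (compartments, species,
  reactions, kinetic-law MathML with arithmetic operators); rules, events
  and function definitions are not supported.  Carbon counts and atom maps
  are not expressible in plain SBML and always come from sidecar tables.
- The 50 mM rejection ceiling is a hard global constant of the objective,
  matching the fitting protocol it implements; it is not configurable
  per-metabolite.
- Annealing schedules are heuristic; the defaults are standard
  Kirkpatrick-style settings and every constant is exposed in
  `AnnealSchedule`.
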