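# Methods

## Model

A gene locus is a continuous-time Markov chain over states `(n_c, n_w, m)`:
`n_c` cognate and `n_w` noncognate activators bound (`n_c + n_w ≤ N_B`
identical sites) and `m` of `N_A` activation steps engaged.  Transcription
occurs at rate `r0` only in fully engaged conformations (`m = N_A`): all
molecular components must be in place for initiation, so the ON set is
exactly `{m = N_A}`.

Rate laws, with `n = n_c + n_w` (all reduce to the conventional four-state
cycle at `N_B = N_A = 1`):

| transition | rate |
|---|---|
| cognate binding | `(N_B − n) k_b c`, × `η_ba` iff `m = N_A` |
| cognate unbinding | `n_c k_u η_ub^(n−1)`, × `η_ua` iff `m = N_A` |
| noncognate binding / unbinding | same laws with `w` and `α k_u` |
| activation `m → m+1` | `(N_A − m) k_a η_ab^n` |
| inactivation `m+1 → m` | `(m+1) k_i η_ib^n` |

Assumptions built into these laws: all binding sites are identical and
contribute multiplicatively (per-bound-activator factors `η_ab`, `η_ib`);
all conformational steps have identical kinetics; noncognate activators are
identical to cognate ones except for the `α`-fold faster unbinding; the
pairwise activator–activator cooperativity `η_ub` acts on unbinding.  The
last two choices are genuinely open design points of the multi-site /
multi-step generalization; they are validated empirically by the endpoint
behaviors the models must reproduce (equilibrium sharpness ceiling
`S ≤ N_B`, nonequilibrium ceiling `S ≤ N_A + 1`, specificity ceiling
`f ≤ α^(N_A+1)`), all of which the sweeps attain.

### Parameters and defaults

| symbol | meaning | default | units |
|---|---|---|---|
| `N_B`, `N_A` | binding sites, activation steps | 1, 1 | — |
| `α` | noncognate/cognate unbinding ratio | 100 | — |
| `r0` | ON transcription rate | 1 | mRNA/time |
| `c`, `w` | activator concentrations | 1, 0 | units of c* |
| `δc/c*` | hypothesis separation | 0.1 | — |
| `ε` | decision error tolerance | 0.32 | — |
| rate box | `k·τ_b` window for sweeps | `[1e−5, 1e5]` | burst-time units |
| `η` box | interaction-factor window | `[1e−5, 1e5]` (`η_ab ≥ 1 ≥ η_ib`) | — |

`α = 100` encodes the ~4.6 k\_BT specific/nonspecific binding free-energy
difference of short eukaryotic binding footprints; `δc/c* = 0.1` is the
morphogen spacing between neighboring fly-embryo nuclei; `ε = 0.32` is a
one-sigma error level.  All times are reported in burst cycles `τ_b` and
all dissipation in k\_BT per burst, which makes every reported quantity
invariant under a global rescaling of the rates (tested).

## Steady state and thermodynamics

The stationary law solves the bordered dense system (one balance row
replaced by normalization) with one iterative-refinement step; models here
have at most ~10² states, so dense linear algebra is exact enough
(residual guard 1e−10 relative).  Entropy production uses the Schnakenberg
edge sum; for the four-state single cycle it equals `J × ln(η_ab η_ua /
(η_ib η_ba))` identically, which the tests assert against random draws.

The burst cycle time is defined as the reciprocal of the stationary one-way
OFF→ON crossing flux.  For two-macrostate structures this equals the mean
ON→OFF→ON recurrence time (a first-passage cross-check via absorbing-chain
algebra lives in the tests); with intermediate conformations the two
definitions could differ, and the boundary-flux definition is fixed as the
package's convention — it is cheap, differentiable, and exact for the
two-state anchor `τ_b = 1/k_on + 1/k_off`.

## Response metrics and conventions

Sharpness is the analytic derivative `c* ∂π_a/∂c` obtained by
differentiating the balance equations (checked against central finite
differences at 1e−6 relative).  The output variance rate solves the Poisson
equation `Q g = −(1_ON − π_a)`, `v_abs = 2 Σ π_i (1_ON,i − π_a) g_i`, and
is nondimensionalized as `v = v_abs / τ_b`.

**Precision/information convention.**  The precision is `p = (2v)^{−1/2}`
(normalized `P = p·π_a(1−π_a)`), and the information rate is
`IR = (δc/c*)² s² p²` nats per burst.  This calibration is pinned by three
anchors simultaneously: the two-state telegraph gives `P = 1/2` exactly at
any rates; the equilibrium four-state IR optimum is 0.0036 bits/burst at
`(S, P) = (1, 1/2)`; the nonequilibrium optimum is 0.0144 bits/burst at
`(2, 1/2)`.  Under this convention the *nonequilibrium precision ceiling*
of the four-state model is `P = 1/√2` (attained by clock-like cycles at
`S ≈ 0.5`), i.e. a √2 gain over equilibrium rather than a factor 2; no
single global factor can move this ceiling to 1 without breaking the three
anchors, so alternative variance normalizations relabel the P axis but do
not change which tradeoffs exist.  The qualitative exclusion — maximally
sharp circuits are pinned to equilibrium precision, and the sharp/precise
corner of the S–P plane is empty — is what the tests assert.

Poisson shot noise of mRNA synthesis is excluded from `p` by default (it is
small relative to locus-switching noise at these parameters); an additive
term is available via `variance_rate(..., include_poisson=True)`.

Specificity generalizes the single-site bound-probability odds to
occupancy expectations `π_c = Σ n_c π`, `π_w = Σ n_w π`.  At `w = 0` the
ratio is taken in the analytic limit via `∂π/∂w`, not by division.
The sharpness envelope `S ≤ f/(w/c + f) · S0` is a boundary statement
about the achievable cloud: individual random circuits can violate the
pointwise inequality by a few percent because `S0` is normalized at the
`w = 0` occupancy, but sweep maxima respect and approach it (0.903 vs
0.909 at `w/c = 10³` away from equilibrium; 0.0903 vs 0.0909 at
equilibrium), which is the form the tests check.

## Parameter sweeps

Boundary tracing is evolutionary: `n_init` log-uniform draws inside the
box, then `n_generations` rounds of Gaussian log-space mutation of the
archive (per-bin elitist for metric pairs, top-k for scalar maximization)
with step size annealed geometrically from 0.8 to 0.02 decades.  Scalar
maximization optionally finishes with a deterministic Powell polish and
supports multi-restart (independent substreams, best kept) because the
higher-dimensional equilibrium landscapes occasionally trap a single run.
Everything is reproducible bit-for-bit from the config seed.  Only attained
boundaries are asserted anywhere — the algorithm makes no global-optimality
claim.

The equilibrium branch parameterizes state energies and symmetric edge
barriers (Arrhenius rates `k_ij = φ_ij e^{E_i − B_ij}`, with `φ` the
multiplicity/concentration prefactors), so every candidate satisfies
detailed balance by construction.  Two further constructions avoid
hopeless rejection rates: energies are supermodular in (occupancy,
conformation) with the activation enhancement sampled as a fraction of the
available binding free-energy drop, which enforces the activator
constraint (`η_ab ≥ 1`, `η_ib ≤ 1`) by construction; and barriers are
anchored at the midpoint of their edge's state energies, so the
scale-invariant `k·τ_b` window only rejects circuits whose rate *spread*
exceeds ten decades.  Energies/barriers are keyed by occupancy class
`(n, m)`, which is what pins equilibrium specificity at exactly `f = α`
for every draw.  The half-max constraint used in perturbation analyses is
a thin shell, so searches under it first hill-climb `|π_a − 1/2|` to seed
the archive.

## Simulation and sequential decisions

The Gillespie simulator is exact; trajectories start from the stationary
law by default and derive the ON/OFF telegraph and accumulated-mRNA traces
(deterministic integration of `r0` over ON time by default, matching the
precision convention; Poisson emission optional).  Empirical estimators
use time-weighted occupancy, ON-entry interval means, and batch-means
variance with bootstrap errors.

The SPRT experiment accumulates the Gaussian drift-diffusion log-likelihood
ratio `LLR(t) = (δμ/v_abs)(x(t) − μ̄t)` of the integrated ON time and stops
at `±ln((1−ε)/ε)`, locating crossings exactly within sojourns (LLR is
piecewise linear); replicates are simulated in segments so each stops
shortly after deciding, with a hard cap and reported cap-hit fraction.
Validation uses near-optimal circuits found inside a narrower rate window
(one decade around the burst timescale): the analytic bound is
rate-scale invariant, while exact simulation of the unconstrained optima is
impractical because their rate spreads approach ten decades.  At the tested
occupancies the empirical mean decision time lands within ~5–15% of the
bound and the realized error rate matches `ε`.

## Problem sizes used by the tests and the acceptance script

Sweep budgets are 3–6·10³ initial draws, 150–400 generations, 20–32 elites
(1–3 restarts for the 28-dimensional five-site equilibrium space) — about
10⁴–4·10⁴ circuit evaluations per sweep, which reproduces the four-state
optima to ~2% and the five-site and proofreading optima to ~3–7% of their
asymptotic values, stably across seeds.  Property suites use 10⁴
equilibrium draws (barriers), 10³ draws (specificity), five random circuits
× 6 trajectories × 1.5·10³ time units (simulation equivalence), and 200–400
SPRT replicates.  The full-scale analyses that need orders of magnitude
more evaluations (four activation steps, the five-site interference bound
near 1,100 bursts, the seventeen-site extrapolation, the 10³-fold gain at
`w/c = 10⁵`) ship as configurations under `examples/configs/`; the test
suite checks only their qualitative directions.

## What the synthetic data does and does not emulate

The generator produces exactly the observables the model family defines:
binary burst telegraphs, accumulated-mRNA trajectories under the two
hypothesis concentrations, and decision-time ensembles.  It does not
emulate extrinsic (cell-to-cell) variability, mRNA degradation, elongation
or pausing dynamics, spatial context, or measurement noise — so passing
tests certify the internal consistency and the stated limits of this model
class, not the behavior of any particular experimental system.

## Known limitations

- The multi-site/multi-step rate laws are one principled generalization of
  the minimal cycle; other η-placements (e.g. cooperativity on binding)
  would change interior boundary shapes, though not the endpoint ceilings
  used for validation.
- Sweep boundaries are attained, not certified: reported limits are lower
  bounds on the true achievable maxima (observed gap ≤ a few percent at the
  calibrated budgets).
- The SPRT uses the Gaussian drift-diffusion likelihood, not the exact path
  likelihood; circuits with extreme occupancies or few bursts per decision
  fall outside its validity (the estimator reports cap-hit fractions).
- Decision-time conversions assume the locus is at stationarity throughout;
  pre-steady-state transients are out of scope.
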