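# Methods

## Model

N cells occupy the vertices of an undirected k-regular graph; every cell is
type A (alternatively activated, pro-repair) or type C (classically
activated, pro-inflammatory). A 2×2 interaction matrix (a, b, c, d) assigns
the energy exchanged along each link: a type-A cell collects a per A-link
and b per C-link; a type-C cell collects c per A-link and d per C-link
(row-player payoff convention). Entries are dimensionless and may be
negative. A cell's energy ε is the sum over its k links and its fitness is
F = 1 − ω + ω·ε with selection intensity ω ∈ [0, 1); ω = 0 is neutral
drift, ω ≪ 1 the weak-selection regime all analytic results assume
(a warning is raised above ω = 0.1).

**Exit-entry update.** One event: a uniformly random cell exits; the vacant
vertex is refilled by type A with probability F_A/(F_A + F_C), where F_X
sums the fitness of the type-X neighbours of the vacancy, else by type C.
Population size is conserved; the homogeneous states are absorbing.
Negative entries can in principle drive a fitness non-positive; a
configuration is rejected up front unless (1 − ω) + ω·k·min(row) > 0 for
both payoff rows.

**Vacated-link convention.** When a neighbour's energy is evaluated, its
link to the vacated vertex contributes with the type of the cell that just
exited. The alternative (skip that link) is exposed as
`count_vacated_link=False`; the slow-manifold limit is insensitive to the
choice at ω ≪ 1, and the degree-sweep experiment was checked under both
conventions with indistinguishable direction of effects.

**Generations.** Two time units are supported: `event` (one exit-entry
event) and `sweep` (N events, the default). Published trajectory
timescales (fixation "within a few hundred generations" at N = 10⁴) are
only compatible with the sweep unit, which the simulator reproduces
(absorption generations are reported per run by `macronet reproduce` and
in every ensemble JSON).

## Pair approximation and slow manifold

The network state is summarised by the global frequency P_A and the
ordered-pair edge frequencies P_XY (each undirected edge counted once per
direction, so P_AC = P_CA exactly); conditionals are q_X|Y = P_XY / P_Y.
Under weak selection the pair frequencies equilibrate fast at

    q_A|A = p + (1 − p)/(k − 1),        p = P_A,

the standard local excess assortment of 1/(k − 1) generated by the birth
process. This closure is validated directly against the simulator: the
test suite compares the quasi-stationary q_A|A with the formula at
tolerance 0.03 for k ∈ {4, 5, 6} at ω = 0.01 (observed agreement is an
order of magnitude tighter).

The expected per-event change of P_A, expanded to first order in ω with
neighbour types drawn from the fast-manifold conditionals, is

    E[Δp] per event = ω · p(1 − p) · (c0 − c2·p) · (k − 2)/(k(k − 1)) + O(ω²),

with

    c0 = (k+1)a + (k²−k−1)b − c − (k²−1)d
    c2 = −(k+1)(k−2)(a − b − c + d)
    c1 = −c0 − c2 = (k+1)(k−3)a − (2k²−2k−3)b − (k²−k−3)c + (2k²−k−3)d.

The neutral (ω⁰) term vanishes identically. This derivation is replayed
symbolically (sympy) in the test suite and is the package's authority for
the coefficients. It has two properties worth stating:

* **Mirror symmetry.** Relabeling the types (a↔d, b↔c, p → 1 − p) negates
  the drift exactly, as it must for a model in which "A" and "C" are pure
  labels. Coefficient variants that break this symmetry also fail direct
  simulation checks: with payoff (0,0,0,1) — only C–C support — the
  simulator fixes C from p₀ = 0.5 in every replicate, and with the
  coordination matrix [1 0; 0 1] it is bistable around 0.5, both exactly as
  the symmetric coefficients predict.
* **Sign structure.** Because c0 + c1 + c2 = 0, the quadratic
  g(p) = c0 + c1 p + c2 p² factors as c2(p − 1)(p − c0/c2) =
  (1 − p)(c0 − c2 p), so g carries the same sign as the true drift
  everywhere on (0, 1). The ODE module integrates
  dp/dt = rate_scale·ω·p(1 − p)·g(p); relative to the derived drift this
  carries an extra positive factor (1 − p)·k(k − 1)/(k − 2)/rate_scale,
  which rescales time but moves no equilibrium and flips no sign. ODE time
  is therefore an arbitrary unit, not calibrated to sweeps; only
  equilibria, directions and stability are quantitative.

## Stability classification

Equilibria of p(1 − p)g(p) are 0, 1 and, when c0/c2 ∈ (0, 1), the interior
root p* = c0/c2. Labels follow the flow direction on each side (stable /
unstable / semi-stable; 'degenerate' when g ≡ 0, i.e. a payoff-indifferent
matrix, where the dynamics is pure drift). The classifier reports:

* **A dominates** — g > 0 throughout the relevant interval; limit 1.
* **C dominates** — g < 0; limit 0.
* **stable coexistence** — c2 > 0 with interior p*; limit p* from any
  interior start.
* **bistable threshold** — c2 < 0 with interior p*; limit 1 above p*,
  0 below, explicitly flagged undecided exactly at p* (never silently
  assigned to a basin).

p₀ ∈ {0, 1} is returned as its own absorbing limit. The classifier is
cross-validated two ways: against the deterministic integrator on 500
random (payoff, k, p₀) configurations, and against simulator majorities on
the six figure-scale settings.

## Numerical choices

* Integrator: adaptive RK45, rtol 1e−8, atol 1e−10, p clipped to [0, 1] at
  machine-epsilon excursions. k = 2 makes c2 = 0 (g linear) and pins
  q_A|A = 1; supported as a documented degenerate case.
* Sign analysis uses an absolute tolerance of 1e−12 on coefficients; exact
  ties (p₀ on a threshold, root at a boundary) are reported as boundary
  cases.
* Random-regular graphs come from the configuration model with rejection
  (networkx), retrying with derived seeds until connected; ring
  (circulant) and torus (periodic lattice) variants exist for sensitivity
  checks. One named RNG per run with a fixed draw order (exiting vertex,
  then replacement Bernoulli) makes trajectories bit-reproducible per seed.
* The compiled kernel maintains edge-type counts incrementally (O(k) per
  flip); kernel and pure-Python reference paths are proven equivalent in
  the tests vertex-by-vertex, and the incremental counters are checked
  against full recounts.

## Study conditions and problem sizes

The preset experiments fix the published conditions: N = 10⁴ cells, k = 4,
ω = 0.01, matrices [1 0; 0 1], [0 −0.5; 1 0], [0 1; 1 0], [0 −1; −2 0],
initial mixtures 9900/100, 4000/6000 and 2000/8000. Headline quantities
are recomputed with 20–50 replicates and horizons of 1200–1500 sweeps
(several times the observed relaxation time of ~120 sweeps); the
degree-sweep experiment uses 200 paired replicates per grid point with
common random numbers across payoff values, which makes grid comparisons
far more precise than the cross-sectional spread suggests.

**Quasi-stationarity is conditional on non-fixation.** With only 100 cells
of the rare type in the 9900/100 start, a minority of replicates loses
that type to demographic noise before it establishes and absorbs at the
homogeneous state (the acceptance script reports the surviving count
as n). Such runs have left the coexistence state being
measured and are excluded from the quasi-stationary average (the surviving
count is reported). This establishment lottery is a finite-population
effect the deterministic reduction cannot represent.

## What the generator emulates — and does not

Synthetic inputs are seeded regular graphs with uniformly random type
placement (a clustered-patch option exists for robustness checks only).
Real post-infarct tissue is none of these things: cell counts vary, the
contact network is spatial, irregular and remodels over time, interaction
strengths drift with the healing phase, and more than two phenotypes
coexist. Passing tests therefore demonstrate internal consistency of the
model triad (simulator ↔ reduction ↔ classifier) under the stated
conditions, not predictive accuracy for tissue data.

## Known limitations

* All analytic results are O(ω) truncations; strong selection (ω near 1)
  is out of scope and rejected or warned about.
* The pair approximation is least accurate near the absorbing boundaries,
  where rare-type clustering and establishment stochasticity dominate; the
  direction of slow parameter effects measured there at short horizons can
  even oppose naive slow-manifold intuition; the degree-sweep experiment
  (`macronet sweep`) probes exactly this regime.
* Alternative update rules (entry-exit, imitation, mutation) and rewiring
  networks are not implemented.
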