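# Methods

## The stochastic model

The simulator is a multi-species generalization of the basic contact
process on a periodic L × L square lattice. Each cell is empty or carries
one individual of one of N species. One Monte Carlo (MC) step consists of
L × L iterations; every iteration performs

1. a **death trial**: choose one cell uniformly; if it holds species *i*,
   empty it with probability m_i;
2. a **birth trial**: choose a source cell uniformly and a partner cell —
   one of the four von Neumann neighbors (periodic boundary) under local
   interaction, or a second uniform cell distinct from the source under
   global interaction; if the ordered pair is (occupied by *i*, empty),
   the empty cell becomes species *i* with probability b_i.

The two trials draw their cells independently. Because the number of
trials a given cell receives per MC step is Binomial(L², 1/L²) ≈
Poisson(1), the per-trial probabilities m_i and b_i act as per-step
*rates*: the process is, to excellent approximation, the continuous-time
contact process with death rate m_i and total birth rate b_i per
individual, and one MC step as the unit of time. Species never convert
directly into one another; all competition is mediated by empty space.

Consequences used throughout the tests:

- With births off, occupancy thins by exactly (1 − m/L²)^{L²} ≈ e^{−m}
  per step in expectation (the one-step survival oracle).
- Under global interaction the densities follow the mean-field ODE
  dx_i/dt = x_i(−m_i + b_i e), e = 1 − Σx_j, up to O(1/L) sampling noise.
- For a single species the local-interaction extinction threshold is the
  2D contact-process critical point, b_c = λ_c · m with λ_c ≈ 1.6488,
  i.e. b_c ≈ 0.495 at m = 0.3; the global threshold approaches the
  mean-field bound b_c = m from above on finite lattices.

## Birth-rate curves and the community generator

Each species' birth probability rises with the nutrient level P along a
three-parameter logistic anchored at (0, b_0):

b_i(P) = b_max(i)/(1 + C_i e^{−k_i P}), C_i = b_max(i)/b_0 − 1, b_0 = 10⁻⁶.

The generator receives the saturation levels b_max(i) and solves each k_i
in closed form so that **every curve passes through one common pivot
(P_pivot, b_pivot)**. This single construction enforces all qualitative
features the model needs: distinct b_max with a shared pivot forces the
ranking below the pivot to be the exact reverse of the ranking above it
(the oligotrophy tradeoff), makes the curves nearly coincide at low P, and
lets them fan out with enrichment.

Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| b_0 | 10⁻⁶ | birth is effectively impossible without nutrients |
| pivot | (14.2, 0.545) | places the common crossing just above the extinction thresholds, so the survival onset sits near P ≈ 13.5–14 and the interesting transition happens over a narrow nutrient band |
| b_max grid | [0.60, 0.90], evenly spaced, descending | keeps all probabilities valid (< 1) while making high-P differences large; the same interval is subdivided for N = 20 or 50 |
| mortality | 0.3 (local), 0.5 (global) | global reproduction is more efficient (no neighbor crowding), so a higher mortality approximately equalizes the two modes' extinction thresholds and makes their density profiles comparable |

With these defaults the ten curves at P = 14.0 all lie within 0.032 of
each other and below the pivot rate; at P = 16 they span ≈ 0.25. The exact
spread at low P is a consequence of the pivot construction, not a tuned
quantity.

## Experiments

**Nutrient sweep.** One full simulation per nutrient level on an ascending
grid (paper-style increment 0.1), each level seeded independently from a
base seed via `SeedSequence(base_seed, spawn_key=(level,))`. Reported per
level: final richness (≥ 1 individual at the last step) and the final
density vector. The richness profile is unimodal: zero below the survival
onset, peaked just above it, collapsing toward one as P rises, while total
density increases monotonically — the paradox of enrichment.

**Extinction thresholds.** Single-species runs with a constant birth
probability (bypassing the nutrient mapping) over an ascending grid; the
estimate is the smallest grid value whose final density is positive in a
majority of seeded replicates. The scan exits early once a majority is
settled (replicate seeds depend only on grid index and replicate index, so
early exit cannot change the estimate). Note that at a finite horizon this
majority-positive criterion counts slowly decaying subcritical populations
as alive, so the estimate can sit one grid step *below* the true critical
point; conversely, small quasi-stationary densities on small lattices push
the global estimate *above* the mean-field bound.

**Clumping comparison.** Local interaction grows monospecific patches;
global interaction keeps the arrangement exchangeable (spatially random
given the counts). The comparison takes a local snapshot and a
global-mode snapshot at matched total density (within 0.02), classifies
all 2L² von Neumann neighbor pairs, and reports the cross-species fraction
among occupied–occupied pairs plus a permutation z-score of the local
same-species fraction against 200 random shuffles of its own cell
multiset. The matched global snapshot is taken where the global run's
relaxation from the initial occupancy first crosses the target density;
because the global-mode pattern is exchangeable at every instant, the
stopping time does not bias its adjacency statistics.

**Sensitivity.** The same sweep machinery at N = 20 and N = 50 (same
pivot, same b_max interval subdivided more finely) preserves the unimodal
profile with the peak in the same low-P region.

## Mean-field integration

The ODE system is integrated with fixed-step classical Runge–Kutta
(default dt = 0.01 MC steps), densities clipped at zero after each step;
fixed stepping was chosen over adaptive integration for bit-reproducibility
(the system is not stiff at these rates). The N = 1 trajectory matches the
closed-form logistic solution to < 10⁻⁶ at dt = 0.01. The four-class
equilibrium classification (both extinct / species 1 only / species 2
only / degenerate tie) is derived from the Lotka–Volterra form R_i =
b_i − m_i, K_i = (b_i − m_i)/b_i; a tie K_1 = K_2 is reported as
`degenerate` rather than resolved, since it is structurally unstable.

## Numerical and implementation choices

- **Kernel.** The inner loop is a numba-compiled kernel with an inline
  PCG32 generator (a Mersenne-Twister-based loop was several times
  slower). One 64-bit seed per run; draws are consumed in a fixed
  documented order, so runs are bit-reproducible. Partner cells in global
  mode are redrawn until distinct from the source.
- **Seeding.** All derived seeds come from `numpy.random.SeedSequence`
  with explicit spawn keys (initial placement, kernel stream, sweep level,
  threshold replicate), so every experiment is reproducible from one base
  seed and sub-computations are statistically independent.
- **Early stopping.** Total extinction is absorbing, so runs stop once the
  lattice empties and the frozen record is carried forward; experiments
  may also stop once richness reaches a target (e.g. 1 for the exclusion
  run), in which case the series is truncated at the stopping step.
- **Problem sizes.** The package's default experiment scale is L = 200
  and 5000 MC steps (thresholds, sweeps, clumping) and L = 500 × 500 steps
  for the mean-field tracking check — a deliberate desk-scale choice that
  preserves the qualitative phase structure of the full-size configuration
  (L = 1000, 20,000 steps), which remains available through `SimConfig`.
- **Ties and degenerate inputs.** The sweep's peak detection breaks ties
  toward lower P; `tradeoff_check` returns False whenever either ranking
  contains ties; communities with duplicate b_max are rejected by the
  generator but representable as containers for diagnostic use.

## What the synthetic communities do and do not emulate

The generator emulates the *structure* of phytoplankton growth curves —
negligible growth differences in oligotrophic water, widening differences
with eutrophication, and a rank-reversing tradeoff — not any measured
species' kinetics. Real communities differ in ways the model ignores:
cells move (diffusion, mixing between the local and global extremes), may
be grazed, compete for several nutrients, and have size- and
temperature-dependent rates. Passing tests therefore demonstrate the
mechanism (enrichment → amplified birth-rate differences → faster
competitive exclusion in finite time), not a quantitative prediction for
any particular lake.

## Known limitations

- Local-interaction theory is simulation-only: no pair approximation or
  correlation dynamics are provided.
- Richness at a finite horizon depends on the per-species curve constants;
  only the qualitative unimodal profile is asserted, not specific counts
  at specific P.
- The logistic parameters of any *particular* empirical community must be
  supplied by the user (CSV serialization is provided); the built-in
  generator is a structured synthetic family, not a fit.
- Threshold estimates inherit the finite-horizon bias discussed above;
  they converge to the true critical point only as steps and L grow.
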