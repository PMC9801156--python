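# Methods

## The fuzzy model

The estimator is a first-order Takagi–Sugeno (TSK) fuzzy system evaluated
as the classic five-layer network: Gaussian fuzzification, product
implication, firing-strength normalization, linear defuzzification and
weighted combination. Only the Gaussian membership family is implemented;
the output is a convex combination of the rule consequents, so it is always
bounded by their span — a property the test suite pins.

**Rule-base layout.** The default is *scatter* partitioning: R rules, each
owning its own Gaussian per input, giving 3·R·D + R free parameters
(centers, widths, coefficients, biases). Grid partitioning (M shared
membership functions per input, M^D rules) is provided for low-dimensional
work via `grid_model`, but the trainer's flat encoding is defined over a
rule list and therefore works with either layout as long as the template's
rule count matches. Scatter is the default because a product grid over
seven inputs explodes combinatorially, while scatter keeps the parameter
count linear and supports the shared single (c, σ) initialization the
template exposes. The consequent generalizes the textbook two-input form
p·x + q·y + r to Σ_d p_d x_d + r for D inputs — the only consistent reading
for subsets of three to seven predictors.

**Degenerate firing.** If every rule fires with strength zero (possible in
the corners of the search box when widths shrink), normalization falls back
to the uniform vector 1/R instead of raising. This keeps the training
objective finite everywhere the optimizer can reach. Widths are bounded
below by σ_min = 1e-3 (configurable) because the membership formula divides
by σ².

**Rule count.** R defaults to 4 in the template; the recovery and scan
experiments use R = 2, matching the two-rule structure that the worked
examples assume and keeping the encoded vector short (20 parameters at
D = 3) and identifiable.

## The optimizer

ACVO is described in the literature at the level of its three operators'
intent; the update equations here are the package's own fully specified
choices, kept consistent with that description and exposed in
`AcvoConfig`:

- *social distancing*: x' = x + r₁⊙(x_best − x) + r₂⊙(x − x_w) with
  r₁, r₂ ~ U(0,1) per dimension and x_w a uniformly chosen weaker person
  (or a random in-bounds point if none exists), clipped to bounds, accepted
  only if fitness does not decrease;
- *quarantine*: the q weakest persons (default q = ⌈0.2N⌉) have
  ⌈mutation_fraction·D⌉ variables resampled uniformly within bounds
  (default fraction 0.3); a person whose fitness recovers to at least its
  entry value — the comparison is inclusive — returns healthy, otherwise it
  is infected;
- *isolation*: infected persons receive ⌈injection_fraction·D⌉ of the best
  person's variables (default fraction 0.5), accepted greedily.

Fitness is −cost, so "healthiest" means lowest cost; greedy acceptance plus
best-ever elitism make the convergence trace non-increasing by
construction, and the whole trajectory is a pure function of (objective,
config, seed). Quarantine deliberately keeps a worsened mutant when
isolation cannot repair it — that is the population's only source of
uphill moves and prevents total collapse around the incumbent.

Defaults N = 40 and 400 iterations were chosen so that runs on the 20–44
parameter encodings of this package approach their attainable floor; the
sphere benchmark converges to near machine precision well before that.
These budgets have no external reference values — the method's source
literature reports none — and are documented as package choices.

## Training protocol

Features and target are min–max normalized with statistics fitted on the
training split only (Eq.: x ← (x − min)/(max − min)); out-of-range test
values extrapolate outside [0, 1] unclipped, and a degenerate column maps
to zero. The split is a uniformly random partition of sizes ⌈0.8n⌉ and the
remainder, deterministic given its seed. The objective is the RMSE of the
decoded model on the normalized training split; the search box is centers
∈ [0, 1], widths ∈ [σ_min, 1], consequent coefficients and biases ∈
[−10, 10].

Metrics (RMSE, δ%, AICc with k = the encoded parameter count and
σ̂² = SSE/n) are reported on the normalized scale by default — the scale on
which fits of different targets are comparable — with an option to
re-express them in original units. δ% is recorded as NaN when the
observations sum to zero (e.g. a constant target normalized to zeros), and
AICc as −∞ for an exact fit and NaN when n ≤ k + 1.

Yield and WP are modeled by independent single-output runs; the network is
single-output and nothing in the protocol couples the two targets.
Categorical predictors need no bespoke encoding: the generator emits
numeric levels (I ∈ {0.75, 1.0, 1.25}, V ∈ {0, 1}) and min–max
normalization maps them onto equally spaced points of [0, 1].

## The synthetic generator

The generator emulates the *statistical shape* of a semi-arid irrigation
trial's feature table: seven predictors drawn independently within
plausible ranges (T ∈ [10, 45] °C, RHavg ∈ [15, 85] %, Rn ∈ [6, 12] h,
Umin ∈ [0, 4] m/s, Pe ∈ [0, 90] mm, I ∈ {0.75, 1.0, 1.25}, V ∈ {0, 1}),
with an optional negative T–RHavg Gaussian-copula coupling (off by
default). The ranges are synthetic defaults, not measurements.

Two ground truths are available. The *analytic* response is a smooth
deficit curve on the normalized scale, 0.15 + 0.35·(1 − 1.2(I − 0.75)²) +
0.12·V + 0.25·Pe/90: concave in the irrigation level with its peak at 75%
of requirement, so mild deficit out-yields over-irrigation by
construction, and it depends only on {I, V, Pe} so the φ8 subset is the
right answer in the feature scan. The *planted* response evaluates a fixed
two-rule, three-input scatter TSK model on range-normalized {I, V, Pe};
`planted_model(seed)` draws its parameters reproducibly from narrow
documented ranges strictly inside the trainer's search box, so "fixed"
means fixed given the seed. Yield is base 5500 kg/ha plus 3000 kg/ha per
unit response, with Gaussian noise of standard deviation `noise_sd`
(default 0.02) added on the normalized response scale; WP divides yield by
an irrigation-proportional water proxy (10 040 m³/ha at full requirement),
landing near 0.7 kg/m³ at I = 1.

What passing on this generator does **not** show: robustness to correlated
climate drivers, block/replication structure, tree-level sampling
variance, multi-year trends, or measurement error in the predictors — none
of which the generator emulates.

## Water accounting

WP = Y/ET with Y in kg/ha and ET unit-tagged in m³/ha; the volume↔depth
bridge is fixed at 10 m³/ha per mm. The full balance is ET = I + P + D_p +
R_off − ΔS with ΔS a storage *gain* (depletion adds to ET); the source
balance writes "± ΔS" without a convention, so this one is adopted,
documented and test-pinned. The P term is carried with its printed
wetted-area (%) labelling and deliberately not reinterpreted as
precipitation.

The packaged ledger and treatment summaries store the printed values
verbatim, including their internal rounding slack (monthly totals differ
from irrigation + 10·Pe by up to ±1 m³/ha; the 125% treatment's printed
seasonal depth differs from the recomputed one by ~10 mm). Consistency
checks therefore use tolerances and the water report prints the residuals
instead of correcting them. Crop coefficients (0.91–1.00 over
April–September) ship as a documentation fixture; no reference-ET
computation is performed.

## Experiment sizes

The recovery experiment uses n = 300 rows, a 2-rule/3-input template and
five seeds (optimizer N = 40, 600 iterations; the training-floor variant
N = 60, 800); the feature scan uses n = 300, eight subsets and five seeds
(N = 40, 400 iterations). These sizes put each run's optimizer at its
plateau while keeping a full scan in the low minutes on one CPU. The
optimizer occasionally (roughly one seed in five) stalls in a near-linear
local optimum around normalized RMSE 0.04–0.15; the experiment designs
treat that as expected metaheuristic behavior and assert majorities across
seeds rather than per-seed success.

## Known limitations

- The ACVO update equations are this package's concretization of a
  qualitatively described algorithm; other concretizations are possible.
- No hybrid gradient/least-squares ANFIS training, non-Gaussian membership
  families, cross-validation, rule-count search or early stopping.
- The feature scan's (c, σ) columns record the template's shared initial
  antecedent pair, whose semantics in the source tables are ambiguous;
  they are initialization metadata here, not fitted values.
- Box bounds are the only constraint handling; the population is evaluated
  serially.
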