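# Methods

## The model chain

The pipeline treats regional land-use change as three loosely coupled
processes.

**Demand (Markov chain).** The landscape's class composition evolves as a
first-order Markov chain: `S_{t+1} = S_t P`, with `P` estimated by
row-normalizing the cell-level transition crosstab of a calibration map
pair. The assumption is stationarity — the calibration-era transition
rates persist to the horizon. Classes absent at the first date receive
identity rows so `P` stays row-stochastic. When a scenario prescribes its
own demand areas, those override the Markov projection; the Markov path
is the business-as-usual default.

**Spatial suitability (neural network).** A single-hidden-layer network
(sigmoid hidden activation, cross-entropy objective, fixed epoch budget,
seeded weight initialization) learns the association between a cell's
driver vector and its land class. Raw class scores are converted into a
per-cell probability distribution by dividing by their sum, so the
per-cell probabilities sum to exactly 1. Drivers are min–max scaled to
[0, 1] on the calibration stack; the bounds are stored in the model and
prediction-time values outside them are clamped with a warning. A
training set containing a single class bypasses the network and returns a
constant predictor — a fit would be degenerate.

**Allocation (cellular automaton).** Each iteration scores every mutable
cell for every class as suitability × neighborhood effect × inertia ×
conversion allowance, then draws a proposal per cell by roulette wheel
over the positive scores of classes still under demand (argmax selection
is available as an option). A proposal is accepted only if the cell's
current class is over-allocated and the drawn class under-allocated, so
each accepted move shrinks two gaps at once and the maximum residual gap
never increases across iterations. If a full pass accepts no move while
the gap exceeds tolerance, donors exactly at demand are temporarily
admitted — this covers allowance structures where only an at-demand class
can supply a deficit class. Iteration stops when the largest per-class
gap is within tolerance or the iteration cap is reached.

The inertia coefficient is the self-correcting element: per class it
stays at 1 while the demand gap is not growing; when an under-allocation
worsens it is multiplied by the ratio of the last two gaps (> 1, pulling
cells in), and when an over-allocation worsens by the inverse ratio
(< 1, pushing cells out). Coefficients are clamped to [1e-3, 1e3] to
keep a pathological gap sequence from overflowing the scores.

**Habitat quality.** Quality is the half-saturation response
`Q = H_j (1 − D^z/(D^z + k^z))` with `z = 2.5` and half-saturation
constant `k = 0.5`: a cell at degradation `D = k` loses half of its
attainable quality. Degradation accumulates over threats and source
cells: normalized threat weight × 0/1 source indicator × distance decay ×
accessibility `β` × the class-by-threat sensitivity. Decay is linear
(`1 − d/d_max`) or exponential (`exp(−2.99 d/d_max)`, which reaches
≈ 0.05 at the maximum effective distance); both kernels are truncated to
zero beyond `d_max` so the spatial support is finite.

## Parameters that matter

| parameter | unit | default | rationale |
|---|---|---|---|
| cell size | m | 30 | common national land-survey raster resolution |
| CA window | cells | 3×3 | the standard Moore neighborhood; denominator N²−1 excludes the focal cell |
| neighborhood weights ω_p | – | per scenario (0.1–1) | packaged per-scenario expansion capacities |
| allocation tolerance | cells | 0.1% of mutable cells | sub-permille demand error, reached quickly by the swap rule |
| iteration cap | – | 300 | far above observed convergence; a hard stop for infeasible corners |
| hidden neurons | – | 12 | ≈ 0.75 × the 15 drivers; smallest layer that separates the class gradient |
| training epochs | – | 200 | fixed budget; the loss curve is stored for inspection |
| sampling | – | stratified, 5% | stratification protects rare classes (garden, grassland) |
| threat d_max | km | 1–10 per threat | packaged threat table |
| z, k | – | 2.5, 0.5 | conventional scale and half-saturation constants |
| calibration interval / horizon | years | 8 / 13 | default fractional projection step 13/8 |

## Degradation: literal sum vs normalized exposure

`degradation_index` implements the textbook double sum literally by
default, and the brute-force implementation (`degradation_brute_force`)
is kept as an independent oracle — the optimized kernel-convolution path
must match it to 1e-6 on every fixture. The literal sum is the right
object for worked examples and for single- or few-source configurations.
It is, however, *extensive*: with areal threats (a town, a saline flat)
hundreds of source cells fall inside a 10 km kernel, `D` reaches the
tens, and the half-saturation response pins quality to ≈ 0 everywhere —
the grade distribution collapses into the lowest band. Landscape-scale
scoring therefore uses `normalize=True`, which divides each threat's
exposure by its kernel's total mass. Exposure is then the kernel-weighted
*fraction* of threatened neighborhood in [0, 1], commensurate with
`k = 0.5`, and monotonicity in added sources is preserved (the kernel
mass does not depend on the sources). The scenario runner and pipeline
use the normalized variant; all oracle comparisons use the literal one.

## Numerical choices

- **Integer apportionment** everywhere counts must sum exactly (projected
  demands, hm²-to-cell conversion, synthetic class proportions, synthetic
  transitions) uses the largest-remainder method with stable tie-breaks.
- **Fractional matrix powers** use the principal eigendecomposition
  branch; if any entry is negative or non-real beyond 1e-9 the code falls
  back to linear interpolation between the bracketing integer powers and
  warns. With realistic sparse transition matrices the fallback is the
  common path.
- **Inertia update cases.** The printed three-case rule is resolved to
  "keep the coefficient when the absolute gap is not growing; scale by
  the gap ratio when it is", which makes the cases exhaustive and
  mutually exclusive; a zero gap falls into the unchanged branch so no
  division is ever taken by zero.
- **Neighborhood floor.** The literal neighborhood effect is zero where a
  class has no neighbors, which would make spatially absent classes
  unreachable (their score is a product). Inside the allocation loop the
  neighborhood raster is floored at 1e-3 so demanded classes can
  nucleate; the exported `neighborhood_effect` stays literal.
- **Window edges.** Neighbors outside the raster or in nodata count as
  absent while the denominator stays N²−1 — a small, documented downward
  bias of the neighborhood effect at edges.
- **FFT convolution** of decay kernels can produce tiny negative values
  (≈ −1e-15); exposure is clipped at 0 before use.
- **Kappa degeneracy.** When both maps are constant and equal the
  expected agreement is 1 and kappa is undefined; it is reported as NaN
  rather than 1.
- **Demand reconciliation.** Full-landscape demands have the frozen-cell
  composition subtracted; if a class's frozen count exceeds its demand
  the mutable demand is clipped at zero and re-apportioned. An all-frozen
  landscape with any demand change is rejected as infeasible, as is a
  deficit class with too few convertible donor cells (reported with a
  per-class diagnosis table).

## The synthetic landscape

The generator emulates the input bundle of a delta-coastal study region:
15 driver surfaces in the usual four families (terrain fields, Euclidean
distance-to-feature surfaces, smooth socioeconomic and climate fields), a
calibration land-use pair, threat subtypes and a restricted-area blob.
Class assignment at t0 cuts the rank order of a fixed development-
potential score (a weighted combination of accessibility, population and
elevation surfaces) into contiguous bands sized by the target
proportions, ordered water → wetland → unused → grassland → forest →
garden → cultivated → construction. The t0→t1 transition applies a known
matrix `P_true` with largest-remainder apportionment per class and
clusters converting cells by affinity to existing target-class patches.

This design makes three things true by construction, and the test suite
leans on each: the class is a deterministic function of the drivers (so
suitability recovery is measurable), realized transition frequencies
track `P_true` up to integer rounding (so Markov estimation is
checkable), and restricted cells never change (so the CA contract is
checkable). What the generator does *not* emulate: multi-date driver
dynamics, georeferencing beyond cell size, class patches that are not
level sets of a single score, measurement error in the maps, and real
spatial configurations of the Yellow River Delta. Passing tests
demonstrate internal correctness of the machinery, not predictive skill
on real landscapes.

Default composition (28.5% cultivated, 22.5% water, 15.7% construction,
15.3% unused, 14.1% wetland, small garden/forest/grassland shares)
mirrors a 2017-style delta mosaic; the default transition matrix is
persistence-dominated with unused land eroding into cultivated and
construction — the dynamic the scenario design responds to.

## Open design choices made here

- The scenario tables' "expansion capacity" is identified with the
  neighborhood weight ω_p: one parameter under two names (the packaged
  numbers coincide).
- The conversion cost of the CA score is binary, `1 − allow`, so a
  forbidden transition scores exactly 0 and an allowed one is not
  penalized.
- Restricted-area semantics: the ecological-redline mask freezes cells
  outright; the permanent-farmland mask freezes only cells currently
  cultivated — it protects cultivated land specifically rather than the
  polygon's other contents.
- Garden and grassland keep constant demanded areas across the packaged
  scenarios; they participate in competition like any class, but the
  demand-driven swap rule leaves them untouched when their demand equals
  their composition.
- Threat derivation without a subtype raster maps construction → urban
  threat, cultivated → cultivated threat, unused → saline-alkali threat,
  leaving the finer construction threats (rural residential,
  transportation, mining) empty; with a subtype raster the construction
  subtypes split accordingly, and simulated cells that gained
  construction (or unused) inherit the urban (or saline-alkali) subtype.
- Accessibility `β` multiplies degradation literally (smaller β = more
  protection) and defaults to 1 everywhere; protection-level semantics
  vary between studies, so the layer is left to the user with the
  formula fixed.

## Limitations

- Demand is aspatial; the Markov chain ignores economic drivers and
  policy feedback, and a stationary `P` is a strong assumption over a
  13-year horizon.
- The CA competes cell by cell; patch-level processes (road growth,
  planned developments) are represented only through the neighborhood
  term.
- Habitat quality is a relative index: it ranks cells and scenarios but
  is not calibrated to any species outcome, and its parameters
  (sensitivities, weights, d_max) are expert-set constants.
- Raster I/O carries cell size but no coordinate reference system;
  co-registration is assumed, not checked.
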