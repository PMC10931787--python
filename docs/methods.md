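# Methods

## Scope and model

`thioreact` implements a descriptor-based estimate of how fast a
thiophene-containing photosensitizer is oxidized by singlet oxygen,
relative to unmodified thiophene. The quantity of interest is
log₁₀(k/kH) — decades of rate constant — for the [2+4] cycloaddition of
¹O₂ across the 2- and 5-positions of the thiophene ring. The model's
premise is that this relative rate is a function of the reactant's
electronic structure alone, so that no transition-state search is
needed: the inputs are three single-point calculations per compound
(N, N−1, N+1 electrons, all at the N-electron geometry) yielding total
energies and per-atom Hirshfeld charges.

### Conceptual-DFT descriptors (`cdft_descriptors`)

All global descriptors use the vertical finite-difference definitions
(VIP = E(N−1) − E(N), VEA = E(N) − E(N+1), χM = (VIP+VEA)/2, μ = −χM,
η = VIP − VEA, S = 1/η, ω = μ²/2η); there is no orbital-energy
(Koopmans) fallback. Energies are stored in the unit they arrived in
(hartree or eV, tagged) and converted only at the descriptor boundary,
with the hartree→eV factor 27.211386245988 (CODATA 2018) kept in one
place. A negative VEA (unbound vertical anion) is legitimate and is
never clamped. When η ≤ 0 the softness-derived quantities are undefined:
they are reported as absent, and anything that needs them (the model's
feature bundle) raises a descriptor-domain error rather than guessing.

Condensed Fukui functions are charge differences, f⁺ₖ = qₖ(N) − qₖ(N+1)
and f⁻ₖ = qₖ(N−1) − qₖ(N); local softness is s±ₖ = S·f±ₖ. On
charge-conserving inputs Σₖf⁺ₖ is exactly one electron; the synthetic
generator is built so this holds to the last bit (below), which turns
normalization into a sharp test.

The nucleophilicity index is computed only on request and needs an
explicit reference energy (it is a relative index; the conventional
reference electrophile is tetracyanoethylene). It is not consumed by
the reactivity model.

### The fitted reactivity equation (`reactivity_model`)

    log₁₀(k/kH)_ideal = 8.61 (q2+q5) − 76.00 F + 53.25
    F = log₁₀( χM (S + α/σ) + β/σ ),   σ = s2⁺ + s5⁺

with α = 30.75 (eV²·e)⁻¹, β = 0.03822 eV⁻¹·e. Every logarithm in the
package's rate scales is base 10 — the scales are counted in orders of
magnitude — and F uses base 10 as well; with natural log the published
coefficients would not reproduce the worked values. The bracket grouping
(α inside the χM product, β outside) is fixed by the model's own
monotonicity structure: F increases with χM at fixed S and σ, and
decreases with σ whenever χM·α + β > 0, so higher local softness at the
alpha carbons always predicts faster oxidation. These monotonicities are
asserted as tests. Inside F there are no protected operators: σ ≤ 0 or a
non-positive logarithm argument is an error, because the fitted
constants presuppose physically sensible descriptor ranges.

The methanol calibration is a fixed affine map,
log₁₀(k/k2T)_Methanol = 0.525·ideal + 8.646, onto the experimental scale
(rates relative to 2-tert-butylthiophene in methanol).
`fit_linear_calibration` refits such a map by ordinary least squares and
reports the r² between scales; `fit_baseline_chiM` fits the
one-descriptor baseline (response vs log₁₀χM) with a caller-controlled
exclusion list for outliers.

Classification uses two inclusive thresholds: ideal ≤ −3 ⇒ efficient,
methanol ≤ −4 ⇒ efficient, else safer. The thresholds are independent
rules on their own scales — note that the affine calibration maps
ideal = −3 to +7.07, not to −4, so they are deliberately *not*
interconverted. When both scales are present and disagree, the
ideal-scale verdict wins and a warning is attached.

### Eyring kinetics (`tst_kinetics`)

k = γ·(kBT/h)·exp(−ΔG‡/RT), with kB, h, R at their exact SI values
(via scipy.constants), default T = 298.15 K and γ = 1. ΔG‡ is taken in
kJ/mol; kcal/mol only via an explicit flag. Relative rates are returned
directly as log₁₀(k/k_ref) = −ΔΔG‡/(RT·ln10), where prefactor and γ
cancel, so standard-state conventions for the bimolecular reaction do
not affect anything downstream. `pearson_r2` (for level-of-theory
benchmarking) requires ≥3 points and non-constant inputs and clips the
square to 1 against rounding.

### Genetic-programming symbolic regression (`symbolic_regression`)

A from-scratch tree GP over the function set
{add, sub, mul, div, sqrt, log, inv} with protected semantics
(div/inv → 1 when |denominator| < 1e−6; log = log₁₀|x| with log 0 = 0;
sqrt on |x|), making evaluation total on finite inputs. Terminals are
feature references and ephemeral constants drawn uniformly from
(−1, 1).

Raw fitness is the squared Pearson correlation between tree output and
response — the determination coefficient of the best affine rescaling of
the tree — defined as 0 for constant or non-finite output. This choice
makes fitness invariant to the affine gauge a regression tree can
always absorb, which is what a "monitoring R²" should measure during
evolution; penalized fitness subtracts `parsimony_coefficient × node
count`.

The generational loop: per generation a fresh subsample of
⌈max_samples·n⌉ rows (without replacement) scores the population;
parents are chosen by tournament (default size 20) on penalized
fitness; offspring come from subtree crossover (p = 0.7), subtree
mutation (p = 0.1) and reproduction (the remaining 0.2 mass — the
minimal-assumption reading since only the first two probabilities are
prescribed). Depth is capped (default 10) by rejection with bounded
retries, falling back to a copy of the first parent. The generation
champion is re-scored on the full data, and the best full-data
individual so far is recorded in the history and — with elitism (on by
default, switchable) — copied unchanged into the next generation, which
makes the best-so-far trace provably non-decreasing. All randomness
flows through one `numpy.random.Generator(seed)`, so runs are
bit-reproducible; selection scheme, elitism, depth limits and constant
range are design choices of this engine, not prescribed quantities.

Default configuration is the production scale (population 5000, 10000
generations); everything in the test suite and the acceptance script
runs at desk scale (population ≤ 1000, ≤ 200 generations, tables of
≤ 200 rows), which recovers planted formulas — a noiseless linear model
to R² ≥ 0.999 and a log₁₀(c₁x₀ + c₂/x₁) model to R² ≥ 0.98 — in well
under a minute.

### Synthetic fixtures (`synthetic_fixtures`)

The generators stand in for a real DFT campaign (nominally a ~90
compound derivative set) and are deterministic functions of a mandatory
seed.

* **Species triplets.** VIP is drawn uniformly in [6, 10] eV and VEA in
  [−0.5, 3] eV (disjoint by construction, so η > 0 always); energies are
  placed accordingly around a plausible hartree baseline. Charges live
  on a dyadic grid (multiples of 2⁻¹⁶ e ≈ 1.5·10⁻⁵ e) with integer
  bookkeeping: the neutral state sums to exactly 0 e and the electron
  gained/lost between states is split into non-negative grid fractions
  summing to exactly 2¹⁶ grid units. Every charge and every Fukui
  difference is then exactly representable in double precision, so
  Σf⁺ = 1 e holds *exactly*, not approximately. Atom 0 plays the
  sulfur, atoms 1 and 4 the alpha carbons.
* **ORCA-style text.** The writer emits the `FINAL SINGLE POINT ENERGY`
  line and `HIRSHFELD ANALYSIS` table the parser reads, printing numbers
  at repr precision so parse∘write is the identity for every state (a
  real ORCA file prints fewer digits; the parser accepts both).
* **Regression tables.** Features are drawn in model-plausible ranges
  (χM ∈ [2, 6] eV, S ∈ [0.1, 0.6] eV⁻¹, σ ∈ [0.05, 1.5] eV⁻¹·e split
  randomly between s2⁺ and s5⁺, q ∈ [−0.15, 0.15] e), chosen so the
  F-term argument stays positive. Planted responses: the fitted equation
  itself ("eq1"), a linear model 3.2x₀ − 1.5x₁ on standard-normal
  features ("linear"), or log₁₀(0.5x₀ + 0.2/x₁) over the χM and σ ranges
  ("fshape"), plus optional Gaussian noise. The noise level 1.096
  decades used in tests mirrors the fitted model's residual scale; at
  n = 90 the sample SD of such noise has sampling SD ≈ 0.082, so the
  test band of ±0.15 is applied to the mean over 100 replicates.

What the fixtures do **not** emulate: real thiophene electronic
structure, correlations between descriptors induced by chemistry
(substituent effects make χM, S and s⁺ covary in real sets), solvent
effects, or realistic magnitudes of the response (uniform descriptor
draws can push the planted equation to physically absurd log-rates).
Passing tests therefore demonstrate the correctness of the arithmetic,
the I/O, the fits and the search machinery — not the chemical accuracy
of the model on new compounds, which is fixed by its published
constants and can only be probed against real descriptor data.

## Numerical choices

* Hartree→eV conversion at CODATA 2018; kB, h, R exact SI.
* Softness/electrophilicity undefined (not clamped) at η ≤ 0.
* Protected-operator threshold 1e−6 in the GP only; the fitted model
  raises on domain violations instead.
* OLS fits use the closed-form centered normal equations; r² is the
  squared Pearson correlation, clipped to 1.
* Sample (ddof = 1) standard deviation for residual SDs.
* Classifier thresholds inclusive on the efficient side; ties in GP
  tournament selection resolved by `argmax` (first best).

## Known limitations

* Absolute Eyring rates ignore standard-state corrections for the
  bimolecular reaction; only ratios are meaningful downstream.
* The GP engine has no constant-optimization step and no Pareto front;
  constants must be assembled by the evolution itself.
* The descriptor module trusts its inputs' metadata (geometry
  consistency across the triplet cannot be checked numerically).
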