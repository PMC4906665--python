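# Methods

This note documents the statistical conventions implemented in
`tempoweb`, the design of the synthetic community generator, and the
numerical choices that matter when reproducing results.

## Interaction intensities

Interaction intensity is the estimated number of fruits eaten, assembled
from two observation sources: direct fruit counts (focal observations)
and fruit numbers extrapolated from fecal seed counts. A fecal sample
with `s` seeds of a plant whose mean seed load is `k` seeds/fruit
contributes `s/k` fruits, floored at 1 whenever `s > 0`: finding seeds
evidences at least one fruit eaten. The floor is configurable off
(`floor_minimum=None`) because the field convention is not universal;
intensities stay real-valued, since downstream analyses use them only
through network-level aggregates. Sources are merged cellwise
(commutative and associative); species whose row or column is all zero
are dropped — a species belongs to a period's network only if it
interacted in that period.

## Network-level parameters

**NODF.** Computed on the binarized matrix. For an ordered pair of rows
(or columns) with marginal totals `MT_i > MT_j > 0` the pair term is the
shared presences divided by `MT_j`; pairs with equal or increasing totals
contribute zero (the decreasing-fill condition). The score is 100 × the
sum over terms divided by `P(P−1)/2 + A(A−1)/2`. A perfect staircase
scores 100, an equal-fill checkerboard 0. Matrices produced by the
probabilistic null may contain empty rows/columns; their pairs simply
contribute zero and the denominator keeps the full dimensions. The
implementation is verified cell-for-cell against a brute-force pair
enumeration (≤ 8×8, tolerance 1e−12) and against vegan's `nestednodf`
on spot checks.

**H2′.** With `p_ij = w_ij/m`, `H2 = −Σ p_ij ln p_ij`. `H2max` is the
entropy of the continuous marginal-product expectation
`e_ij = r_i c_j / m` (equivalently the sum of the two marginal
entropies); `H2min` is the entropy of the maximally aggregated table
built by greedy packing — repeatedly place
`min(remaining row total, remaining column total)` into the cell of the
currently largest remaining row and column totals, ties broken by lowest
index. `H2′ = (H2max − H2)/(H2max − H2min)`, clamped to [0, 1]; if
`H2max − H2min < 1e−12` the network is structureless and H2′ is 0.
The continuous extremes differ slightly from integer-constrained ones on
very small integer matrices; the choice is deterministic and fully
specified, which we prioritized.

**Interaction strength asymmetry.** Signed by convention: per realized
link, `(d_bird − d_plant)/max(d_bird, d_plant)` with `d_bird = w_ij/c_j`
(bird's dependence on the plant) and `d_plant = w_ij/r_i`; averaged over
links. Positive values mean birds depend more on plants. Transposing the
matrix negates the value. The absolute-value variant is available via
`signed=False`.

**Niche overlap.** Horn's entropy overlap of two normalized profiles,
`[Σ(x+y)ln(x+y) − Σx ln x − Σy ln y] / (2 ln 2)` with `0·ln 0 = 0`,
averaged over unordered pairs at one level (birds by default).

**Core/periphery.** `Gc = (k_i − k̄)/σ_k` with `k_i` the bird's number
of plant partners and `σ_k` the sample (n−1) standard deviation. Core
iff `Gc > 1`; `Gc` exactly 1 falls in the periphery (strict inequality).
If all degrees are equal the scores are undefined: the result is flagged
degenerate and everything is periphery. Whenever defined, the scores
have mean 0 and sample SD 1 by construction.

## Nestedness null model

Null replicates fill each cell independently with
`q_ij = (f_i + g_j)/2`, `f_i` = row fill / A, `g_j` = column fill / P.
Replicates with empty rows/columns are kept (the classical probabilistic
null); a resampling mode exists for sensitivity analysis only. The
one-sided p-value uses the add-one estimator (never exactly 0); the raw
proportion is available behind a flag. "Significantly nested" means
p ≤ 0.05. Per-period runs in a series derive independent seeds from one
master seed via `SeedSequence.spawn`, so results do not depend on period
order.

A calibration subtlety: when the null probabilities are re-derived from
each observed matrix (the only option with field data), the test is
mildly conservative — on unstructured homogeneous matrices the mean
z-score sits near −0.5 and the 0.05-level rejection rate near 0.02,
because the null adapts to the observed heterogeneity. With the
generating probabilities supplied explicitly (`probabilities=`), observed
and null draws are exchangeable and the p-value is exactly uniform; the
type-I acceptance experiment uses this design. Consequently the
generator calibration test asserts *no positive signal* at nestedness
strength 0 (mean z < 0.5, rejections ≤ 10%) and a clear signal at
strength 3 (mean z > 2, evaluated on ~25×20 matrices — the statistic
loses power on very small networks).

## Turnover

Core and periphery are analyzed separately. Composition matrices are
binary period × species membership by default (species lists; a
quantitative option uses partner counts); a species core in one period
and peripheral in another appears in both matrices. Bray–Curtis
dissimilarity `1 − 2Σmin(x,y)/(Σx+Σy)` reduces to Sørensen on binary
rows. PERMANOVA partitions `SS_total = (1/n)Σ_{i<j} d²_ij` into within-
and among-group parts; `pseudo-F = (SS_among/df_among)/(SS_within/df_within)`,
p from random relabelings with the add-one estimator. With perfectly
separated groups `SS_within = 0` and F is reported as +inf; note the
permutation p can never fall below the combinatorial floor set by
relabelings that reproduce the partition. The default period grouping is
the a-priori high-migration set {Jan14, Mar14, Sep14, Oct14} versus the
remaining six periods. NMDS ordination is deliberately not implemented;
the labeled dissimilarity matrix is exported for external ordination
tools.

## Driver models

`fit_quasipoisson` is a log-link IRLS fitter with the Poisson variance
function: working weights `w = μ`, convergence when the relative
deviance change is below 1e−8 (max 100 iterations), step-halving so the
deviance is non-increasing at every accepted step (asserted). The linear
predictor is clipped to ±30 to avoid overflow on degenerate designs.
Dispersion is `φ = Pearson χ²/(n−p)`; standard errors
`sqrt(φ·diag((XᵀWX)⁻¹))`; p-values from the t distribution with `n−p`
degrees of freedom (quasi-likelihood convention, not normal). Fits agree
with `statsmodels` GLM (`scale="X2"`) to 1e−6.

The two model families are
`response ~ migrants + richness + migrants:richness` and
`response ~ abundance`. Quasi-likelihood needs only non-negative
responses, so the models apply to non-count responses (connectance,
NODF, H2′, overlap) as well — a warning is emitted, and a signed
response (ISA can be negative) is refused with a clear error rather than
transformed. The interaction column is built after optional centering
(`center=True`); centering is off by default but recommended when the
main effect's sign is of interest, since the uncentered product column
absorbs part of it. With fewer than 7 usable periods the 4-parameter
interaction model is refused unless forced. No multiple-testing
correction is applied. `spearman` is the Pearson correlation of
mid-ranks (scipy's implementation; ties handled by average ranks).

## Synthetic community generator

The generator emulates the statistical structure the analysis assumes,
not any particular site: ten within-year sampling periods; lognormal
latent plant attractiveness `a_p` and bird generality `g_b`
(σ = 0.6 in the study-scale preset); a fruiting schedule per period; a
migrant presence schedule concentrated in migration periods; link
probability `max(1 − exp(−c·(a_p g_b)^s / mean), p0)` where `s` tunes how
strongly links concentrate on high-trait species (s = 0 is the
homogeneous Bernoulli baseline used for null calibration) and
`p0 = 0.02` adds rare opportunistic links so low-trait species
occasionally appear; negative-binomial intensities (size 0.8) shifted by
one so every link has weight ≥ 1; and FAI categories derived from
lognormal crop sizes through the exact ordinal breakpoints
1–10 / 11–100 / 101–1,000 / 1,001–10,000 / >10,000.

The `paper_like` preset fixes the study-scale conditions: 42 plants,
27 resident + 17 migrant birds; migrant presence peaking in January and
October, absent in June; fruiting richness high in the migration season
while crop sizes (hence FAI abundance) peak mid-year — this built-in
trade-off produces the strongly negative migrant/abundance rank
correlation (about −0.8); seven residents and three migrants carry
boosted generality (×6 and ×3) so the generalist core accumulates on
the order of ten species over the year while staying compositionally
stable, and the remaining migrants churn the periphery between migration
regimes; five periods (the larger, migration-season networks) carry a
strong nested backbone (s = 2) and five a weak one (s = 0.5), so roughly
half the networks test significantly nested. Link density is calibrated
so the year accumulates ~320 distinct links. All randomness flows
through one seeded generator; identical configs produce byte-identical
serialized output.

What the generator does *not* emulate: observation error and sampling
effort differences between mist nets and transects, within-period
temporal structure, spatial habitat structure, phylogenetic signal in
traits, and bird abundances (intensity is modeled directly). Passing
tests on synthetic data therefore demonstrate that the estimators and
tests behave correctly under the assumed data-generating structure, not
that any particular field system satisfies those assumptions.

## Problem sizes used in the validation suite

Oracle equivalence uses random matrices up to 8×8 (200 draws). Error-rate
experiments use 500 simulations each: the nestedness test at 199
replicates on 8×8 matrices, PERMANOVA at 99 permutations on n = 12
points. The quasi-Poisson recovery experiment fits 200 datasets of
n = 200. The study-scale checks run the full pipeline (1,000 null
replicates, 999 permutations) on five generator seeds. These sizes keep
the whole suite within a few minutes on one CPU while leaving Monte-Carlo
standard errors well below the asserted margins.

## Known limitations

- With ten periods, GLM inference is fragile (n − p = 6 for the
  interaction family); the package refuses smaller fits rather than
  reporting unstable estimates.
- The H2′ extremes use the continuous marginal expectation and a greedy
  packing heuristic; on tiny integer matrices these can differ in the
  third decimal from integer-constrained extremes.
- The fill-conditioned nestedness null is mildly conservative (see
  above); this is a property of the procedure, shared with standard
  practice, not an implementation artifact.
- Temporal autocorrelation between consecutive periods is ignored by
  both the PERMANOVA relabeling scheme and the GLMs, as is standard for
  this design.
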