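# Methods

## Model

For each biomarker of aging the package fits a mean age trajectory
BM = f(CA) by least squares and inverts it to a partial biological age
BAp = f⁻¹(BM).  Three families are supported:

| family        | forward form            | inverse                         |
|---------------|--------------------------|---------------------------------|
| `linear`      | a + b·CA                 | (v − a)/b, printed as a′ + b′·v |
| `exponential` | a·exp(b·CA), a one sign  | ln(v/a)/b                       |
| `polynomial2` | a + b·CA + c·CA²         | quadratic root in/nearest the observed age range |

The exponential family is estimated by ordinary least squares on
log-transformed values; r² is always evaluated on the original scale so
families are comparable.  Family selection is linear-first: another family
must improve r² by more than `improvement_threshold` (default 0.02) to
displace the linear fit, and inside the pipeline only strictly monotone
(invertible) candidate fits compete, because step 4's product is an inverse
formula.  A quadratic whose vertex lies inside the observed age range, or a
slope that rounds to zero, cannot be inverted; a biomarker with no
invertible fit is rejected at step 4 with the candidate r² values logged.

Coefficients are kept raw and rounded (default 4 decimal places, matching
the precision of published panel formulas); **inversion uses the rounded
coefficients**, since published formulas are applied in printed form.  For
the linear family the rounding is applied to the inverse-form pair
(a′, b′) = (−a/b, 1/b) that the printed formulas carry.  On a 20–70-year
range with well-scaled markers the rounding perturbs BAp by well under 0.5
years (asserted in the tests; the acceptance script measures ~0.03 y worst
case).  BAp is never clamped to the observed age range; values outside it
carry an extrapolation flag.

The regression direction is BM-on-CA with algebraic inversion (not CA-on-BM
regression).  The two differ by the usual attenuation factor r²; the
BM-on-CA convention reproduces the inverse-form coefficients that published
panels print, and the choice is recorded in every report so results are
auditable.

## Aggregation

With weights wᵢ ∈ (0, 1] (default wᵢ = |r(BMᵢ, CA)| rounded to two
decimals, floored at 0.01; user overrides win),

    BA − CA = ( Σ over available members of wᵢ·(BApᵢ − CA) ) / D

The default divisor D is the **count** of available members — published
panel formulas divide by the member count (…)/5, (…)/6 — even though with
w < 1 this shrinks BA−CA toward zero; the statistically conventional
D = Σwᵢ is available as `divisor_convention="weight_sum"`.  Subjects with
fewer than `min_availability` (default 0.5) of the members measured get no
BA and are excluded, with a logged count, from cohort statistics.

Cohort quality is mean and sample (n−1) standard deviation of BA−CA and
Pearson r(BA, CA), computed after trimming the `n_trim_ba` largest and
smallest BA values (statistics only — subjects keep their individual BA).
Gates: σ < 10 years (the conventional acceptability bound) and r within
configurable limits.  No numeric default for the r limits is established in
the field; the package ships (0.5, 1.0) as an explicit configuration
default, flagged as such.

## Outlier handling

Biomarker values are masked (treated as missing) when they fall more than
k standard deviations from the mean of their 10-year age bin (bins are
half-open, anchored at multiples of 10 years; k defaults to 3 and can be
set per bin).  Bin statistics use the sample SD because bins are small, and
bins with fewer than 3 values are never filtered.  Exactly **one pass** is
applied: because bin statistics are recomputed from the surviving cells, an
iterated rule would not be order-independent or reproducible.  One
consequence worth knowing: a single planted outlier in a bin of n values
can reach at most z = (n−1)/√n recomputed standard deviations, so k = 3
cannot fire in bins smaller than ~12 — the rule is a guard against gross
errors in reasonably populated bins, not a small-sample test.

## Accuracy-in-years

A marker changing Δ units over T years with instrument resolution δ
resolves Δ/δ units, so its achievable BAp accuracy is T/(Δ/δ) years
(e.g. 40/5 = 8 units over 50 years → 6.25 y, displayed 6.2: display
*truncates* to one decimal, reproducing how such values are conventionally
printed, while screening always uses full precision).  Two task classes
share the algorithm and differ only in the default gate: 10 years for
cross-sectional population studies, 5 years for longitudinal follow-up of
one person, where interindividual dispersion cancels.  Accuracy metadata is
optional; markers without it pass the screen with a warning, and the
reference change can be taken from the fitted regression over the observed
age window when only the instrument resolution is known.

## Synthetic cohorts

The generator draws CA uniformly over the cohort age range and builds each
marker as family(true coefficients)(CA) + Gaussian noise — the simplest
distributions consistent with what the optimizer assumes.  Redundant
markers are noisy affine copies of a source (optionally with their own age
slope), missingness is uniform Bernoulli over biomarker cells, and planted
outliers are placed at a chosen offset in within-bin SD units.  Ground
truth (true coefficients, links, planted cells, expected rejections) is
emitted with every cohort so tests never re-derive expectations from the
generator internals.  Everything is deterministic under the seed.

`paper_like_preset` emulates the classical Soviet screening panel: 13
named markers, n = 160, ages 20–70.  Planted correlations with age follow
the values reported for that panel on real cohorts (flat breath-hold time
r ≈ −0.05, self-assessment r ≈ 0.23, pulse-wave velocity r ≈ 0.82,
cross-correlations APs/APd ≈ 0.80, APs/APp ≈ 0.80, PWVe/PWVm ≈ 0.99,
LC/BW ≈ 0.66, body-weight range ≈ 45–135 kg).  One structural compromise:
age is the only latent factor in the generator, so two markers with age
correlations r₁, r₂ are incidentally cross-correlated at r₁·r₂.  Real
markers share only part of the age signal, so the preset keeps one strong
marker (PWVe at the reported 0.82) and places the other survivors near
0.62–0.67, keeping every incidental pair clearly below the 0.7 pruning
gate.  Companion instrument metadata (`paper_like_metadata`) makes the
redundancy tie-breaks deterministic through the accuracy comparison.

What passing on this preset does and does not show: it shows that the
pipeline attributes each planted defect to the correct step and recovers
the planted panel; it does not show that real cohort statistics are
reproduced (the clinic data behind the published panels were never
deposited), and it does not exercise non-Gaussian noise, informative
missingness, or multi-factor physiology.  Two planted values sit close to
their screens *by construction*: the self-assessment marker's true r ≈ 0.23
is only 0.07 below the 0.3 threshold, so at n = 160 roughly one cohort in
ten yields a sample correlation that legitimately crosses it and the marker
survives.  Fixed-seed tests are deterministic; across arbitrary seeds the
planted-recovery indicator reflects this genuine sampling variability
rather than a defect.

## Pipeline semantics

Step order is fixed (correlation → redundancy → accuracy →
regression/outliers → BA statistics → researcher criteria → assembly);
reordering is deliberately unsupported for reproducibility.  The step-5
statistics are computed on the panel as of step 4; if step 6 removes
members, the final panel's BA, statistics and gates are recomputed at
step 7, and both are logged.  A panel failing the gates is reported as
*rejected* together with its best-found statistics — the pipeline never
searches alternative subsets (combinatorial panel search is out of scope).
BA trimming affects cohort statistics only, never the regression fits.
Redundancy pruning processes pairs in descending |r| with lexicographic
tie-breaks (the later name is dropped), so results are order-independent.

Stratified runs (`group_stratify` / `run_stratified`) execute the whole
pipeline independently per stratum; no statistic ever mixes subjects across
strata.  Interactive mode is a terminal prompt sequence over exactly the
same parameters; every session echoes a replayable configuration, and a
scripted interactive session produces a byte-identical panel and result to
the equivalent automatic run.

## Problem sizes

Tests and the acceptance script use n = 160 (the preset), n = 200–500 for
parameter-recovery and variance-propagation checks, and n = 5000 for the
correlation-calibration property; the full suite runs in seconds.

## Known limitations

- No robust or quantile regression, no confidence bands, no measurement-
  error propagation through the aggregation formula.
- Pairwise-complete correlations can be inconsistent as a matrix (not
  positive semi-definite) under heavy missingness; per-pair n is reported.
- The quadratic family is the only curvature option, and it is rejected
  rather than restricted when its vertex falls inside the age range.
- Units are opaque labels; no unit conversion or checking is attempted.
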