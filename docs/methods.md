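# Methods

## The analysis

The pipeline turns raw longitudinal lab observations into an information
decomposition per comparison:

1. **Daily aggregation.** Each (patient, ICU day, variable) group of raw
   measurements is collapsed to its sample median (middle value for odd
   counts, mean of the middle two for even). Medians rather than means, and
   the percentile trim below, blunt the recording and transcription errors
   endemic to raw clinical data. Groups with no measurements simply produce
   nothing; missingness propagates as absence, never as NaN.
2. **Outlier exclusion.** Per variable, daily values strictly below the 1st
   or strictly above the 99th percentile are discarded. Percentiles use the
   linear-interpolation quantile definition and are pooled across days by
   default (a `per_day` switch exists for sensitivity analysis). Values
   exactly equal to a percentile are retained. Discard counts are returned
   so that retained + discarded always reconciles with the input.
3. **Discretization.** Per variable, 20 equal-width bins spanning the
   post-filter min/max, pooled across days so that bin k means the same
   value range on every day and day-wise entropies are comparable. Bins are
   half-open `[e_k, e_{k+1})` with the final bin closed, so the maximum
   retained value falls in bin 19. The 20-bin ceiling is log₂ 20 = 4.32
   bits.
4. **Information measures.** Plug-in estimators on the bin indices:
   H(X) = −Σ p log₂ p (with 0·log 0 = 0), I(X;Y) from the empirical joint,
   H(X|Y) = H(X) − I(X;Y). All logs are base 2; everything is reported in
   bits.

Two study designs run on the binned values:

- **Consecutive days** (pairs (1,2) and (2,3) by default): each patient's
  day-d bin is paired with the same patient's day-(d+1) bin; the pooled
  joint gives the redundant portion (MI) of the later day and its novel
  remainder H(later | earlier). X is the later day throughout.
- **Same-day variable pairs** (creatinine–BUN, HCO₃–lactate,
  sodium–chloride, platelet–WBC by default): within-patient same-day
  pairing; both conditionals are reported because the shared MI is a
  different fraction of each variable's entropy.

Pairing is always within patient, then pooled into a single cohort-level
joint — per-patient joints are impossible with one median per day. Patients
missing either side of a pair are excluded from that pair set but still
count toward single-day entropies.

### The paired-subset choice

Under attrition, the set of patients with a day-2 value is smaller than the
day-1 set, and the decomposition's entropies could be computed on either.
We compute H(X), H(Y) and I on the *paired* subset (the joint's own
marginals): this is the only choice that makes H(X|Y) = H(X) − I ≥ 0 and
the chain identity hold exactly. The entropy over *all* patients with X
available is reported alongside as `h_x_all`, since that is what a
per-day "total information" bar naturally plots; the two differ slightly
whenever the paired subset is not a random draw of the available one.

## Estimator properties

The plug-in MI is positively biased by approximately
(Bx−1)(By−1)/(2N ln 2) bits at N pairs (≈ 0.08 bits at N ≈ 3300 with
20×20 bins) — visible as the nonzero MI a permutation null leaves behind.
The suite checks three calibrations:

- an independently coded brute-force MI (explicit double loop) agrees with
  the estimator to 1e-12 on random joint tables;
- shuffling patient identity on one side of a real pairing collapses mean
  MI (100 permutations) to within 3 SD of the first-order bias bound; the
  first-order formula slightly *under*states the true bias, which the SD
  slack absorbs;
- for bivariate Gaussian pairs, the binned plug-in MI at n = 10⁵ lands
  within 0.1 bits of the closed form −½ log₂(1−ρ²) for ρ ∈ {0.3, 0.6,
  0.9}. At ρ = 0.9 the dominant error is *discretization loss* (≈ −0.09
  bits with min/max-edge bins), not sampling bias; trimming the tails
  before binning widens the error by discarding tail dependence, which is
  why bin edges span the full retained range.

An optional Miller–Madow correction (`decompose(..., miller_madow=True)`)
subtracts the first-order bias from each entropy term; it is off by
default so the default output is the plain plug-in analysis.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes —
not ICU physiology. Per patient, a latent standard-normal vector over the
11 variables is drawn with cross-variable correlation R (Gaussian copula),
evolved across days as AR(1), z_d = ρ z_{d−1} + √(1−ρ²) ε_d with
ε_d ~ MVN(0, R), and mapped through each variable's marginal. Raw
within-day observations (1–4 per patient-day-variable) are median-centred
noise around the latent daily value, so the daily median recovers the
latent value exactly; noise is additive for normal marginals and
multiplicative (log-scale SD) for lognormal ones, preserving positivity.
Patients drop out monotonically between days (discharge) and, once gone,
emit nothing; an independent per patient-day-variable coin models tests not
ordered.

Defaults (all tunable, natural units):

| variable   | family    | mean [SD]      | ρ (day-to-day) | notes |
|------------|-----------|----------------|----------------|-------|
| hematocrit | normal    | 31.9 [5.0] %   | 0.85 | |
| platelet   | lognormal | 218.4 [112.2] K/µL | 0.92 | slow marrow kinetics |
| WBC        | lognormal | 12.3 [8.8] K/µL | 0.75 | |
| glucose    | lognormal | 139.3 [50.5] mg/dL | 0.40 | labile |
| HCO₃       | normal    | 24.4 [4.6] mEq/L | 0.70 | |
| potassium  | normal    | 4.1 [0.5] mEq/L | 0.55 | tightly regulated |
| sodium     | normal    | 138.6 [4.4] mEq/L | 0.80 | |
| chloride   | normal    | 105.5 [5.7] mEq/L | 0.78 | |
| BUN        | lognormal | 25.3 [20.9] mg/dL | 0.93 | renal |
| creatinine | lognormal | 1.4 [1.5] mg/dL | 0.94 | renal, most persistent |
| lactate    | lognormal | 2.5 [2.0] mmol/L | 0.50 | missing rate 0.59 |

Marginal means/SDs track typical adult-ICU day-1 summary statistics;
lognormal location/scale are solved from the target moments
(σ² = ln(1 + SD²/mean²), µ = ln mean − σ²/2). Cross-correlation defaults:
creatinine–BUN 0.80, sodium–chloride 0.75, HCO₃–lactate −0.40,
WBC–platelet 0.15, all other off-diagonals zero (the disjoint 2×2 blocks
keep the matrix positive definite). Attrition defaults (1.0, 0.68, 0.46)
reproduce the typical fall-off of ICU admissions with labs on days 2 and 3;
cohort-wide missingness is 2 % per patient-day-variable, with lactate at
59 % because it is ordered selectively rather than on routine panels.
Default cohort size for analyses and the acceptance script is 5000
patients, which puts the plug-in bias near 0.08 bits on paired comparisons
while keeping a full run under a few seconds.

What the generator does **not** model — and hence what passing tests do not
show about real data: treatment effects and feedback between tests and
ordering decisions, diurnal/within-day dynamics (timestamps are not
generated; the analysis only consumes daily medians), readmission within
the window, non-monotone attrition, heavy-tailed error artifacts beyond
what the percentile trim removes, and any dependence structure beyond a
Gaussian copula (e.g. tail dependence). Recovery results on synthetic
cohorts demonstrate correctness of the estimators and pipeline, not the
clinical magnitude of redundancy in any real ICU population.

With differing per-variable ρ, the AR(1) recoupling preserves each
variable's unit variance and autocorrelation exactly, while same-day
cross-correlation is exact on day 1 and attenuated by at most a few
percent on later days (exact when the two ρ are equal) — immaterial for
the qualitative orderings the tests assert.

## Numerical choices

- Quantile definition: linear interpolation (numpy default). On small n the
  1st/99th percentiles depend on this choice; it is stated so results are
  reproducible elsewhere.
- Strict inequalities in the outlier filter; ties with the percentile are
  retained.
- `discretize` rejects values outside the fitted range rather than clamping
  silently — an out-of-range value means the filter and binning were fit on
  different data.
- Distribution validation tolerance 1e-9 on probability sums; MI floored at
  0 and conditional entropies floored at 0 to absorb rounding; MI exceeding
  entropy beyond 1e-9 is an error, not a clamp.
- Determinism: one `numpy` Generator seeded from the config drives the
  whole simulation in a fixed draw order, so identical (config, specs)
  give byte-identical CSV output.
- A variable whose retained values are all identical cannot be binned and
  is rejected by name; a variable with fewer than two distinct values
  passes the percentile filter untouched (with a warning) since its
  percentiles are degenerate.

## Known limitations

- Plug-in estimates at the default cohort size carry ~0.05–0.1 bits of
  positive MI bias; comparisons between conditions at matched N are safe,
  absolute values should be read with the bias in mind (or with the
  Miller–Madow flag).
- Only pairwise redundancy is measured; redundancy among three or more
  tests is out of scope.
- No significance testing of MI values and no adjustment for clinical
  covariates; the output is descriptive.
- Figures and summaries describe whatever cohort they were computed on —
  by default a synthetic one — and carry no claim about real ICU data.
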