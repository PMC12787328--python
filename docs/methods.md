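# Methods

## Scoring model

Each Fried criterion is a deterministic rule on a measured quantity;
all units are SI internally (the 15-ft walk distance is 4.572 m at
1 ft = 0.3048 m; heights in cm and grip in kg follow clinical
convention).

* **Weight loss** — flag 1 if the participant answers "yes" to
  unintentional loss, or a reported loss exceeds 4.5 kg or 5% of body
  weight (strict inequalities; a loss of exactly 4.5 kg does not meet
  the criterion).
* **Exhaustion (standard)** — CES-D items 7 and 8 are frequency codes
  0–3; flag 1 if either is ≥ 2. **Exhaustion (sensor)** — the spoken
  dialogue yields a days-per-week category; "3–7" maps to 1, "0–2"
  to 0. Anything else is an input error, not a missing value.
* **Low activity (standard)** — weekly caloric expenditure over 28
  exercise-related questionnaire activities. Ordinal duration codes
  0–6 recode to (0, 0.5, 1.75, 3.75, 5.75, 7.75, 9.75) hours/week;
  each activity contributes `D·MET·3.5·60·(W/200)` kcal/week and the
  criterion is met strictly below 383 kcal/week (men) or 270 (women).
  MET assignments come from an external codebook; the bundled table
  (`data/champs_mets_synthetic.csv`) is a synthetic stand-in with 28
  plausible activities in the light-to-moderate range (1.5–6.0 MET)
  and should be replaced for real questionnaire data.
* **Low activity (sensor)** — total dwell time in the task zones
  across the two timed household tasks, compared against the cohort's
  80th percentile (linear interpolation between order statistics).
  The threshold is sample-relative by design — it flags the slowest
  fifth — so it is recomputed for every cohort; ties at the threshold
  are not frail (strict >).
* **Weakness** — maximum of the three dominant-hand dynamometer peaks
  against the sex- and BMI-band cutoff. The published bands leave gaps
  (24 vs 24.1 etc.); we close them as half-open intervals ≤24,
  (24, 26], (26, 28], >28 so every BMI maps to exactly one cutoff.
  Grip at exactly the cutoff meets the criterion (≤). A missing grip
  measurement propagates as a missing flag, an incomplete total, and
  pairwise exclusion from agreement statistics.
* **Slowness** — 15-ft walk time ≥ 6 s for the taller stratum
  (men > 173 cm, women > 159 cm) or ≥ 7 s otherwise. The standard
  route times the walk directly; the sensor route fits ordinary least
  squares of distance on elapsed time over the UWB trajectory and
  solves the fitted line at 4.572 m.

Totals, the four-level category and the not-frail/frail dichotomy
follow the 0 / 1–2 / 3–4 / 5 and ≤2 / ≥3 partitions. Score 5
dichotomizes to frail.

### The distance–time regression

`fit_distance_time` regresses, by default, **displacement from the
start point** on elapsed time. Cumulative summed step distance is
available (`distance="cumulative"`) and is the natural reading of
"distance traveled", but it is statistically fragile: with white
per-sample positioning noise of sd σ at sampling interval Δt, each
step acquires a positive-mean error of order σ, so the cumulative
slope estimates the speed plus a noise-rate term (≈ 3× the true speed
at σ = 0.2 m, 10 Hz, 1 m/s) rather than the speed. Displacement from
the start has zero-mean error at every sample, leaving the slope
unbiased under noise, and coincides with cumulative distance exactly
on noiseless straight walks. The zigzag-inflation property — lateral
wander makes cumulative path length exceed straight-line displacement,
so the cumulative estimator can only shorten the implied 15-ft time —
is asserted as an inequality in the tests using the cumulative mode
explicitly. Only relative time (t − t₀) enters the fit, so wall-clock
offsets and time zones are irrelevant. Fits require ≥ 3 samples and a
positive time span; a non-positive slope, or an intercept at or
beyond the target distance, raises an invalid-fit error (the pipeline
records a missing slowness flag in that case rather than a wrong one).

### Zone occupancy

A stay is a maximal run of consecutive samples inside an axis-aligned
rectangular zone, measured from its first to its last sample; runs
shorter than `min_dwell` (default 2 s, suppressing boundary chatter at
zone edges) are discarded. Zone boundaries are inclusive.

## Agreement statistics

Cohen's kappa is computed from the k×k confusion matrix (2×2 for the
criteria, 3×3 for the robust/pre-frail/frail totals) as
(p_o − p_e)/(1 − p_e); its two-sided p-value uses the large-sample
normal test with the Fleiss–Cohen–Everitt null-hypothesis standard
error, which reproduces the reference SPSS output. Spearman's rho is
the Pearson correlation of mid-ranks (average ranks for ties) with the
t-approximation p-value at df = n − 2; for paired binary data it
equals the phi coefficient, which the tests exploit as an exact oracle.
Degenerate tables (uniform marginals, zero variance) are reported as
undefined rather than coerced to a number. No multiple-testing
correction is applied, matching the reference analysis.

`reconstruct_table` enumerates every integer 2×2 table consistent with
two marginal splits and returns the unique one whose kappa is within
0.005 of a target (the tolerance implied by 3-decimal rounding);
ambiguity or a larger deviation is an error, not a guess. This is what
lets published summary statistics be recomputed when the underlying
table was never printed: the per-criterion tables are identified
uniquely, whereas the 3×3 total-score table and the weakness row
(whose standard margin mixes n = 19 complete cases with 2 missing) are
under-determined and are therefore only reproduced qualitatively on
synthetic cohorts.

## The synthetic cohort

The generator's defaults encode the reference study conditions: 21
participants, 11 male; a 7/11/3 robust/pre-frail/frail mix;
sex-stratified age, height, weight and grip distributions with the
reference means and SDs (e.g. dominant grip 38.87 ± 8.91 kg male,
27.04 ± 6.73 kg female); 10 Hz UWB sampling (a typical tag rate,
giving ≥ 38 samples on a 15-ft walk at frail speeds — the real rate is
not published); isotropic Gaussian positional noise of sd 0.20 m per
axis (the dynamic-accuracy scale reported for UWB walking motion); and
a sinusoidal lateral zigzag of amplitude 0.15 m and period 2 m
standing in for gait wander.

Profile-dependent parameters are a documented default table, not an
empirical claim: gait speed 1.2 m/s (0.55 m/s when the slowness
criterion is set, ±0.05 jitter — both sides clear the 6/7 s thresholds
with margin for every sex/height stratum), total task duration uniform
on 40–80 s (150–220 s for low-activity participants; the disjoint
ranges keep the clusters separable by a percentile rule), and grip
maxima pulled to the correct side of the participant's cutoff with a
3–10 kg (or 10–40%) margin.

Two structural choices matter for interpretation:

* **The low-activity flag is a cohort quota.** Because the criterion
  is defined relative to the sample (the slowest fifth), the generator
  assigns it to exactly ⌈0.2·(n−1)⌉ participants (weighted toward
  higher totals) rather than independently per participant. This makes
  the 80th-percentile scoring rule an exact inverse of the generator
  at zero noise for every cohort size; with an independent per-person
  rate, quota and percentile would disagree by sampling error and
  "perfect sensors" would still misclassify.
* **Task zone crossings are aligned to the sampling grid**, so the
  extracted dwell duration equals the generated one to within two
  sample intervals at zero noise.

Standard-instrument answers are always faithful to the profile;
sensor-channel answers (speaker dialogue, task-duration cluster)
contradict it with probability `response_noise` (default 0). Clinical
scale totals (EFS 0–17, CFS 1–9) are monotone affine functions of the
implied total score plus integer noise, clamped to their ranges.

What the simulator does **not** emulate: real UWB error structure
(multipath bias, autocorrelation, dropouts — our noise is white),
anything about speech audio (answers arrive already transcribed),
within-person variability over repeated visits, correlations between
criteria beyond the profile itself, and any floor plan beyond named
rectangles. Passing round-trip tests therefore show the pipeline is a
correct inverse of its own data model, not that the sensor route is
valid on real patients.

## Numerical choices and problem sizes

Percentiles use numpy's linear interpolation; ranks use scipy
mid-ranks; OLS uses `scipy.stats.linregress`. The round-trip and
acceptance checks use a 50-participant zero-noise cohort; the
noise-degradation property uses 200 participants at three noise
levels; the phi/Spearman equivalence property uses 10⁴ random tables
at 1e-12 and the kappa brute-force check enumerates all tables with
n ≤ 12. Seeds are fixed in tests; all simulation randomness flows from
`SimulationConfig.seed` through a single generator, and the seed plus
a config hash are recorded in every run's metadata.

## Known limitations

* The bundled MET table is synthetic; absolute kcal values are only
  meaningful relative to it.
* The sensor low-activity criterion is cohort-relative, so a
  participant's flag depends on who else is in the batch — as in the
  reference protocol, but worth remembering when scoring single
  participants.
* Kappa p-values rely on the large-sample normal approximation, which
  is optimistic at n ≈ 21; we keep it for comparability with the
  reference output.
* The simulator's white positional noise is the worst case for
  cumulative-distance estimators and milder than reality for
  displacement-based ones; conclusions about noise robustness should
  be re-examined with correlated-error models before being applied to
  hardware.
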