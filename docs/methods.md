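# Methods

This note documents the model and procedure each module implements, the
defaults that matter and why, what the synthetic cohorts emulate, and the
numerical and design choices made where more than one reasonable option
existed.

## Data model

Two telemetry products feed the analysis: *detections* (timestamp,
receiver, transmitter, optional depth), which establish daily
presence/absence, and *positions* (timestamp, planar x/y in meters, a
manufacturer error metric, a dialect tag `vps` or `pinpoint`), which carry
the fine-scale movement signal. All timestamps are normalized to UTC on
ingest; local solar events enter only through the day/night calendar.
Positions must arrive pre-projected to planar meters — an optional
lon/lat→UTM helper (hand-written Krüger series, sub-mm within a zone) is
provided, but the core never mixes geographic and planar math.

## Filtering

**Isolated detections.** A detection is kept iff another detection of the
same transmitter lies within a rolling ±24 h window. We read the 24-h rule
as a rolling neighborhood rather than calendar-day bins: calendar binning
would treat a midnight-straddling pair asymmetrically. The filter is
idempotent by construction.

**Positional error.** The published workflow chose an error-metric cutoff
by visually weighing estimated error against retained positions, targeting
a median error tolerance below 3.5 m. We replace the visual step with a
deterministic rule targeting the same statistic: per dialect, the cutoff is
the **largest** metric threshold c such that the median measured error of
reference-transmitter fixes with metric ≤ c stays strictly below the
target. If no threshold achieves the target the minimum-metric threshold is
returned with a warning flag. Retention is reported per dialect as count
and percentage.

**Exclusions.** Mortality removes records from the mortality date onward;
tag failure and death shortly after tagging remove the individual entirely.
Mortality *inference* (from depth/position inspection) is out of scope; the
exclusion table is an input.

## Philopatry classification

Daily presence is a calendar-date bin (UTC): a date is present iff it has
at least one retained detection. For consecutive presence days d_k < d_k+1
the internal absence is (d_k+1 − d_k − 1) empty days. With absence
threshold T (default 90 d) and residency span S (default 365 d):

* **SF** — some internal absence > T (the return is implied: the absence is
  internal);
* **CR** — otherwise, presence span (last − first presence day) > S;
* **SR** — otherwise.

Choices worth flagging: absences are *strictly* longer than T ("longer than
90 days"); the span runs from first to last **detection**, not from the
tagging date, because the detection record is the only universally
available observable; the terminal absence never triggers SF, encoding that
both residency patterns end with a dispersal and no return; a
single-presence-day series is SR (span 0). The classifier carries no
correction for tagging-date truncation (an individual tagged at the end of
its stay can only ever look seasonal); that bias is documented, not
modeled. The sensitivity analysis re-classifies every series at alternative
thresholds (default {60, 90, 120} d) and counts label changes against the
default.

## Activity

Per individual, the position series is cut into sub-trajectories wherever
the inter-fix gap exceeds `max_gap` (default 1800 s). The original
workflow's finer flow chart separating "present but undetected" from
"absent" is not public; a single configurable gap cut is the simplest rule
consistent with its description, and the default is deliberately
conservative (30 min against a ≤160 s transmission delay). Sub-trajectories
are linearly interpolated on the lattice t₀, t₀+80 s, … ≤ t_end (80 s is
the minimum transmission delay; linear interpolation is the standard choice
at steps this short; no extrapolation). Each consecutive pair gives
activity = dist/dt × 3600 in m/h. Steps are labeled by the day/night
calendar **at the step start** (an 80-s step makes the boundary choice
negligible) and averaged per individual × ISO year × ISO week × diel
period. The ISO year is carried in the key so that the same week-of-year in
different calendar years remains a distinct repeated measure; the model
covariate is the week number 1–53. The weekly aggregate is the mean (the
original summary statistic is unstated; the mean matches the step-level
averaging already implied by the activity definition).

Sunrise/sunset come from a NOAA solar-position implementation evaluated at
the array centroid (tested against an independent almanac-formula oracle to
within ±2 min; agreement in practice is ~30 s), or from a user-supplied
almanac table.

## Activity space

The utilization distribution for one individual-week-diel is an
equal-weight mixture of isotropic bivariate Gaussian kernels of sd h
(default 50 m — the "smoothing factor 50" convention for projected
coordinates) evaluated on a regular grid (default 5 m resolution, data
bounding box padded by 5·h) and renormalized. The activity-space size is
the area of the 95% highest-density region: cells sorted by probability,
accumulated to the isopleth mass including the crossing cell, count ×
resolution² in km². The grid-based HDR was chosen over contouring because
it is deterministic and directly checkable against the closed form for a
single kernel (disc of radius h·√χ²₀.₉₅,₂ ≈ 2.448·h, i.e. 0.04706 km² at
h = 50 m; the 5-m grid agrees within 2%, and halving the resolution moves
Gaussian-fixture areas by under 1%). A weekly UD requires > 4 distinct
position-days (≥ 5, successive or not). The grid extent/resolution of the
original analysis is unspecified; the defaults are package choices backed
by the convergence tests.

The model table inner-joins weekly activity and weekly space on
(individual, ISO year, week, diel), log-transforms both responses, and
keeps complete cases only, so the residual covariance is estimated from
co-observed pairs; software that tolerates partial missingness would keep
slightly more rows — a documented divergence.

## The bivariate mixed model

For row j of individual i, with y the (log space, log activity) pair:

y_j = B'x_j + u_i + e_j, u_i ~ N₂(0, G), e_j ~ N₂(0, R).

Fixed effects are trait-specific: intercept, philopatry contrasts
(reference CR; levels absent from the data drop their column with a
warning, and the reference re-bases to the first present level), disc
length (cm), sex (reference female), an **orthogonal** cubic polynomial of
week 1–53 (raw powers of 1..53 are severely collinear; coefficients are
reported in the orthogonal basis), and diel period (reference night).
Priors: N(0, 10¹⁰) per fixed-effect coefficient; inverse-Wishart on G and
R parameterized by scale V = I₂ and degrees of freedom ν = 1.002, with
prior scale matrix V·ν — so the full conditionals are
IW(ν + n_ind, V·ν + Σuuᵀ) and IW(ν + n_obs, V·ν + Σeeᵀ).

**Sampler.** All conditionals are conjugate. Fixed effects are drawn from
their *collapsed* conditional, with the random intercepts integrated out
via the Woodbury identity, followed by u | B, G, R — an exact joint (B, u)
block draw. This matters: individual-level covariates (size, sex,
philopatry) are partially confounded with the random intercepts, and
sequential B/u updates random-walk along that ridge badly enough to stall
chains at inflated G. Every per-individual cross-product the collapsed draw
needs is constant across iterations, so the cost is O(p²) per iteration.
2×2 inverses and Cholesky factors use closed forms; inverse-Wishart draws
use a Bartlett-decomposition kernel (checked against scipy's invwishart in
the tests). A near-singular scale matrix is jittered once (1e-8 × trace)
and then a hard error. Chains start from the least-squares fit plus
dispersal noise and are seeded independently from one spawned seed
sequence.

**MCMC settings.** Library defaults are desk-scale: 4 chains × 50,000
iterations, burn-in 10,000, thinning 20 (2,000 retained draws per chain,
~100 s per fit for 4,500 rows on one CPU). The CLI's `--paper-fidelity`
switch restores 4 × 1,000,000 / 50,000 / 200 for full-length runs.

**Derived quantities** are computed per retained draw and then summarized
(mean, median, central 95% interval): r_adj = V_ind/(V_ind + V_res) per
trait and R_ind = g₁₂/√(g₁₁g₂₂). Whether a published summary of such a
ratio is the mean or the median of the per-draw posterior is ambiguous in
general (Jensen-type ordering separates the ratio of posterior means from
the posterior mean of the ratio by ~0.01 here), so both are emitted. A
fixed effect is "significant" iff its central 95% credible interval
excludes zero. Convergence: classic split-chain Gelman–Rubin PSRF per
scalar parameter (the statistic the original workflow used; arviz's
rank-normalized version is the cross-check in the tests) plus lag-1..k
autocorrelations. Temporal autocorrelation of the weekly residuals is
**not** modeled — the weekly (rather than monthly) measurement scale is the
mitigation — and no random slopes, non-Gaussian families, or model-
comparison criteria are fitted.

## Synthetic cohorts

The generator produces the study conditions at two fidelity levels.

*Model-ready rows* are direct draws from the mixed model above: archetypes
from the observed cohort frequencies (24.3% CR, 59.3% SR, 16.4% SF over
n = 177), random intercepts from G_true, residuals from R_true, with
G_true = [[0.202, 0.087], [0.087, 0.285]] and R_true = [[0.706, 0.218],
[0.218, 0.533]] — the published posterior-mean magnitudes — as defaults.
Fixed-effect defaults: null philopatry and sex effects (the focal null
result), small positive disc-length effects, night-over-day offsets
(−0.40/−0.30 on the log scales), and a cubic seasonal week effect on a
scaled basis t = (week − 27)/26 whose span the fitted orthogonal basis
contains. Disc lengths are uniform on 24–59 cm; the sex ratio is 59.9%
male. Presence histories are archetype-consistent by construction: bouts of
presence separated by short gaps capped at 25 d (safely under every
threshold in the sensitivity set), SR arrivals in spring/summer with
permanent emigration September–January, SF with one long winter absence of
N(150, 25²) days clipped to (95, 210) — a November–April absence — followed
by a return block. The archetype labels therefore coincide with the
classifier's output at the 90-d threshold for 100% of individuals (a
property test), and the balanced variant (`simulate_balanced_rows`, 150
individuals × 15 weeks × day/night) is the parameter-recovery design.

*Raw telemetry* adds the geometry: a correlated random walk with a
per-individual home tether inside a ~0.9 km² array polygon (28 receivers),
per-individual speed exp(5.0 + u_activity) m/h and home radius
120·exp(u_space/2) m. The kinematic model is an explicit artifact choice —
nothing in the analysis depends on it beyond respecting per-individual
speed and range scales. Positions are perturbed with Gaussian noise of
per-fix sd drawn lognormal(median 3.5 m, σ_log 0.6); the reported error
metric is the true sd times lognormal noise times a per-dialect scale, so
it is monotone in the truth only in expectation — which is exactly what
makes the cutoff calibration non-trivial and leaves per-dialect retention
strictly inside (0, 100)%. Detections are emitted at position instants plus
a sparse 3-per-day background stream on every presence day (so presence
reconstruction is exact even when track simulation is capped to
`raw_days_per_individual` days), and isolated singleton detections can be
injected into ≥3-empty-day absences at a configurable rate to exercise the
24-h filter with exact bookkeeping. No depth, receiver collisions, or
hydrodynamics are simulated, and the raw-level walk has no diel speed
cycle — diel contrasts at the raw level are therefore near zero by design,
and diel-effect inference is tested on the model-ready level.

All randomness descends from a single integer seed through spawned
`numpy.random` streams; identical seeds give bit-identical outputs at every
level, which is what the pipeline's byte-level determinism check relies on.

**What passing tests do and do not show.** The synthetic cohorts share the
analysis's own generative assumptions (Gaussian log-responses, constant G
and R, no residual autocorrelation, error metric monotone in true error in
expectation). Passing recovery tests therefore demonstrates that the
implementation is faithful and internally consistent — not that those
assumptions hold for real skates; model misfit on field data (heavy tails,
serial dependence, detection-probability artifacts) is outside what these
tests can detect.

## Pipeline

`run_all` executes simulate → filter_detections → filter_positions →
classify → activity → kud → fit with content-addressed caching: a stage's
key hashes only the configuration slice it depends on plus its input files'
content, so changing the philopatry threshold re-runs classification (and
the fit only if the labels actually changed), while the MCMC stage survives
upstream no-ops. The default pipeline cohort is deliberately small (12
individuals, one-and-a-half seasons, 30 track days each, 2 × 2,000 MCMC) —
a smoke-scale configuration for end-to-end runs; scientific runs pass an
explicit `SimConfig` and MCMC settings. All CSV output uses a fixed 12-
significant-digit float format, making reruns byte-identical.

## Known limitations

* The sub-trajectory rule is a single gap threshold; behavior-aware
  segmentation would classify resting-versus-absent differently.
* Complete-case pairing discards weeks observed for only one response.
* The KUD uses a fixed bandwidth everywhere; no cross-validated or
  autocorrelation-aware bandwidth selection.
* r_adj/R_ind at small cohort sizes inherit the sampling spread of the
  realized among-individual covariance (~√(2/m) relative), which dominates
  sampler error in recovery experiments.
* The philopatry classifier is rule-based; no probabilistic state-space
  treatment of partial migration.
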