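# Methods

## Data model

Four tabular streams (CSV; timestamps are integer milliseconds since the Unix
epoch, UTC; dates ISO-8601):

- `subjects.csv` — subject_id, age (years), diagnosis (control/bipolar), gender.
- `keypresses.csv` — subject_id, timestamp_ms, category (alphanumeric,
  backspace, punctuation, space, autocorrection, suggestion, other). No text
  content exists anywhere in the pipeline.
- `dtmt.csv` — one digital Trail Making Test part B administration per row:
  subject_id, timestamp_ms, completion_time_s, wrong_moves, variant_id (1–12),
  slot (morning/evening).
- `mood.csv` — weekly ratings: subject_id, date, hdrs17 (0–52), ymrs (0–60,
  empty for controls).
- `ptmt.csv` (optional) — pencil-and-paper TMT-B: subject_id, occasion
  (first/last), time_s.

## Window assignment

Each administration owns a half-open interval `[start, end)`:

1. **Midpoint rule.** If the neighbouring administration on a side is ≤ 24 h
   away, the boundary on that side is the midpoint of the two timestamps.
2. **Date clip.** Otherwise the boundary is the start (or end) of the
   administration's calendar date.
3. **Two-test-day clip.** On a date with both administrations recorded, the
   morning window additionally starts at the morning test and the evening
   window ends at the evening test, so keypresses outside the pair are
   discarded.

Rule 1 outranks rule 2; rule 3 is applied last as an override. On a day with
only one recorded administration the test keeps only its own midpoint-bounded
half toward each in-range neighbour (the other half belongs to that
neighbour); nothing is merged across a missing test. A keypress exactly on a
shared boundary belongs to the later window (deterministic tie-break).
Calendar dates use a configurable timezone (default UTC); generated data use
a single timezone with no daylight-saving transitions, an assumption real
loaders must not make.

Windows of one subject are pairwise disjoint by construction; tests verify
exact agreement with a brute-force classifier that re-derives ownership
minute by minute from the rules above.

## Typing features

Inter-key delays (IKD) are the differences between consecutive keypress
timestamps within a window, across all key categories including backspaces
and autocorrect events (a switch restricts to character keys for sensitivity
analyses). Delays of 8 s or more mark typing-session boundaries and are
excluded; the per-window feature is the **median** of the surviving delays,
defined only when at least 20 survive (mean of the middle two for even
counts). Inclusion filters then drop windows with fewer than 20 keypresses or
no median, and subjects with fewer than 6 surviving administrations; the two
window filters are deliberately separate (keypress count, then valid
transitions) and both are reported in the run log.

## Model table

The response is ln(completion seconds). Covariates before scaling: age;
ln(wrong moves + 1) (the +1 keeps zero-error administrations finite); time of
day coded 0/1 (morning/evening); practice = ln(day within study period), with
day 1 at each period's start so the practice curve restarts after the 4-week
break; period coded 0/1; their interaction formed as the product of the coded
(pre-scaled) terms — the regression-discontinuity term; diagnosis coded 0/1
(control/bipolar). HDRS-17, median IKD (and YMRS within the bipolar group)
are split two-level: the between-subject level is the subject mean centred at
the unweighted grand mean of subject means; the within-subject level is the
deviation from the subject's own mean (sums to zero within subject). Weekly
ratings are backpropagated: a rating dated d covers administrations dated in
(previous rating, d], with end effects taking the nearest rating.

Every fixed term is z-scored over the final analysis table (sample SD,
ddof 1) so estimates are comparable effect sizes; dummy-coded terms are
z-scored too by default, with a switch to leave them 0/1. z-scoring happens
last, and the builder refuses input that already contains z-scored columns.
Practice can alternatively count administrations instead of calendar days
(option); calendar days is the default reading of "days since period start".

## Mixed models

Per subject i: `y_i = X_i β + Z_i b_i + ε_i`, `b_i ~ N(0, G)`,
`ε_i ~ N(0, σ² I)`; random design columns are the intercept and the same
z-scored practice, period and interaction columns used as fixed terms.
Estimation is maximum likelihood (not REML), so likelihood-ratio tests
between nested fixed-effect specifications are valid. The deviance is
profiled: G = σ² ΛΛᵀ with Λ lower-triangular (log-Cholesky: log diagonals,
free off-diagonals; or log-SDs for the diagonal structure), and for each Λ
both β and σ² have closed forms. Per-subject blocks enter through
cross-product sufficient statistics and the Woodbury identity, so one
deviance evaluation costs O(subjects × q³) regardless of rows per subject.

Optimization: bounded L-BFGS-B from a default start (Λ = 0.5 I) plus jittered
restarts (default 5), deviance tolerance 1e-8, seed-controlled; forward fits
warm-start each model from the previous model's optimum, which also makes the
fitted deviance sequence monotone by construction. The unstructured 4×4
covariance has 10 parameters against (by default) 19 subjects, so boundary
fits are expected; if every unstructured start fails outright the fit falls
back to a diagonal G and records that. Wald z tests use the fixed-effect
information matrix at the optimum (Satterthwaite/Kenward–Roger df are out of
scope). R² follows the variance-partition definition: marginal =
var(Xβ̂) / (var(Xβ̂) + mean diag(ZGZᵀ) + σ̂²); conditional adds the
random-effect variance to the numerator.

The forward sequence: Model 1 = age, log wrong moves, time of day, practice,
period, practice×period; Model 2 adds diagnosis and the two HDRS levels (3
df); Model 3 adds the two typing-speed levels (2 df). Models 4–5 are the
within-bipolar sequence (practice terms + HDRS levels, then + YMRS levels; no
diagnosis term since it is constant in the subset).

## Reliability

ICC form is fixed to ICC(3,1) — two-way mixed effects, consistency, single
measurement: (MS_rows − MS_err) / (MS_rows + MS_err) with mean squares from
the subjects × occasions ANOVA and an F-based 95% interval. Consistency is
invariant to a constant offset between modalities but not to rescaling one of
them (both are tested). The report compares first/first and last/last scores
across modalities and first/last within each modality, the latter also by
paired t-tests; "first" means first completed administration. Subjects
missing a score are dropped from that comparison only.

## Synthetic cohort generator

Defaults emulate the study design: 8 controls + 11 bipolar subjects, two
administrations per day (09:00/21:00 ± 30 min jitter) on study days 1–17 and
45–56, a 0.47 probability that a scheduled administration is skipped (giving
≈ 31 completed tests per subject, matching the reported cohort means of
32.0/30.6 out of 58 possible), weekly ratings on days 1, 8, …, 56. The
single skip probability is deliberately the only missingness mechanism; the
source cohort's true dropout process is unknown.

- **Mood.** HDRS-17 = subject trait (normal: control 1.02 ± 1.49, bipolar
  12.68 ± 7.80, truncated at 0) + stationary AR(1) weekly fluctuation
  (ρ = 0.6, innovation SD 0.8 control / 2.5 bipolar), rounded and clipped to
  0–52. YMRS analogous for bipolar subjects (6.0 ± 3.8, innovation SD 1.5).
- **Typing.** Per-subject trait median IKD lognormal around 0.25 s (log-SD
  0.25); a daily lognormal multiplier (log-SD 0.10); Poisson(8) sessions per
  day placed in 07:00–22:00 with inter-session gaps forced above the 8-s
  cutoff; session lengths 1 + Poisson(25) keys; within-session delays
  lognormal with median trait × daily multiplier (log-SD 0.5), clipped below
  8 s so session structure is exact by construction. Categories are a fixed
  multinomial; no content.
- **Wrong moves.** Poisson per administration with a lognormal per-subject
  rate (median 1.5, log-SD 0.5) — error propensity is a subject trait.
- **Completion times.** The generated streams are pushed through the very
  same windowing/filtering/assembly code the analysis uses; the default
  coefficient vector (the published full-model estimates: intercept 2.898 on
  the natural-log scale, typing 0.189/0.032, depression 0.189/0.038,
  diagnosis −0.180, wrong moves 0.220, practice −0.069, period −0.039,
  interaction 0.041, age 0.008) is applied to the resulting z-scored
  covariates, plus diagonal random effects (variances 0.010 / 0.0003 / 0.002 /
  0.002) and residual noise (variance 0.058). Natural logs throughout:
  exp(2.898) ≈ 18 s is a plausible 13-circle completion time, whereas base-10
  would imply ≈ 791 s. Administrations the pipeline would discard (no valid
  typing window) get intercept + random intercept + noise; they never enter
  the analysis table.
- **Paper tests.** pTMT-B scores share the subject-level latent (age,
  diagnosis, trait depression, trait typing speed, trait error propensity,
  random intercept) plus modality noise (log-SD 0.11) and have no practice
  term, so the digital modality improves first-to-last while the paper
  modality stays flat.

Sharing one code path between generation and analysis makes parameter
recovery a genuine inverse test: over replicated 200-subject cohorts every
fixed-effect estimate is unbiased to Monte-Carlo precision, and with typing
coefficients zeroed the Model 2→3 LRT rejects at the nominal 5% rate.

**What the generator does not emulate** — and hence what passing tests do not
establish about real data: circadian/weekend structure and burstiness of real
typing; autocorrelated or heavy-tailed residuals in test performance; mood-
or symptom-dependent missingness; timezone changes and daylight-saving
transitions; content-dependent typing speed; device effects. The generator's
between-subject variance in test performance is exactly what the full model's
covariates and random intercept imply (≈ 0.06 on the log scale against a
within-subject residual of 0.058), which caps attainable cross-modality
consistency near 0.65; single-cohort ICC estimates at n = 19 scatter widely
around that, so reliability statistics on synthetic cohorts should be read as
behaviour checks, not as reproductions of any particular published value.

## Problem sizes and numerical choices

The test suite exercises parameter recovery at 100 replicates of 200-subject
cohorts and LRT calibration at 500 replicates of 50-subject cohorts — sizes
chosen to give Monte-Carlo standard errors small enough for 3-SE bias checks
and an informative exact binomial band around the 5% level while keeping the
suite quick on a single CPU. Likelihood correctness is asserted to 1e-8
against a dense multivariate-normal oracle, ICC to 1e-10 against explicit
sums of squares, and the statsmodels mixed-model fit to 1e-3 on shared
instances. Degenerate inputs are defined, not crashed on: zero-variance
paired differences flag an infinite t; zero between-subject variance yields
ICC 0 with a warning; a residual sum of squares is floored at 1e-300 before
logging; duplicate (date, slot) records, unsorted streams, out-of-period
administrations and rank-deficient fixed designs raise named validation
errors.

## Known limitations

- Wald z p-values (no small-sample df correction); with 19 subjects,
  between-subject effects' p-values are approximate.
- ML variance components are biased low in small samples (no REML option).
- The unstructured random-effect covariance is weakly identified at the
  study's size; fits on real 19-subject data will often sit on the boundary.
- The windowing rules assume at most two administrations per subject-day.
- Reliability uses complete pairs only; no agreement (absolute) ICC form.
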