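# Methods

`ctdnamon` analyzes longitudinal tumor-informed ctDNA monitoring data from
patients with HR+/HER2− metastatic breast cancer on endocrine therapy plus a
CDK4/6 inhibitor. The observable per patient is a series of plasma assay
results — a detected flag and, when detected, an estimated variant allele
fraction (eVAF, percent scale) aggregated over a personalized multi-variant
panel — alongside restaging CT scans with a radiologist progression
adjudication and RECIST v1.1 categories, and treatment/outcome dates. This
note records the models, conventions, and design choices; every number it
mentions is computed by the test suite, the analysis scripts, or
`scripts/acceptance.py`, not asserted.

## Data model and conventions

- eVAF is stored on the percent scale (0.5 means 0.5%); fractions appear
  only inside arithmetic. Undetected samples carry **no** eVAF: "not
  detected" is a distinct state from "detected at a tiny eVAF", and only the
  classification rules decide when an undetected value is treated as zero.
- Dates are calendar dates; durations in months are days / 30.4375.
- The baseline draw is the latest non-failed sample within 42 days before
  treatment start (grace after start 0 days; both configurable). The source
  data dictionary gives no explicit window, so this is a package convention.
- Duplicate keyed rows in input tables are dropped keep-first with a logged
  warning rather than failing, to tolerate real-world exports.

## Molecular response and progression rules

With baseline eVAF `e_BL` and the current effective eVAF `e` (0 when
undetected), `r = e / e_BL`:

- clearance: not detected on treatment, baseline-positive patient;
- molecular response eVAF_<10%: `r < 0.10` (reduction of more than 90%);
- graded progression eVAF_X%: `r >= X/100` for X in {75, 50, 25, 10} —
  absence of decrease or a decrease of less than 25/50/75/90%;
- any rise: `e > e_prior` against the immediate prior non-failed sample;
  noise-controlled rise: `e − e_prior > 0.01` percentage points;
- combined: rise >0.01 and/or eVAF_50%.

Knife-edge convention: a reduction of exactly 90% is eVAF_10%-positive and
response-negative, making the two calls mutually exclusive and jointly
exhaustive. Undetected samples enter ratios and deltas as 0, so a
redetection after clearance registers as a rise. Failed assays are skipped
when locating the immediate prior sample. Early-kinetics windows are kept
distinct (decrease within 28 days — one treatment cycle — and rise within 29
days) because they describe different observations. Consecutive clearance
requires 2 successive cleared on-treatment samples by default.
Baseline-undetected patients are excluded from every baseline-relative
metric but retain clearance-free descriptive output. Whether clearance may
occur at *any* on-treatment sample (our choice) or only the first is a
convention; any-sample matches how trajectories are summarized here.

## Concordance and diagnostic performance

On-treatment plasma timepoints are matched one-to-one to on-treatment scans
within ±30 days by greedy ascending |gap| (ties toward the earlier scan,
then the earlier sample). Greedy rather than globally optimal assignment
was chosen for determinism and order-stability; with sparse schedules the
two rarely differ. Baseline staging scans are excluded. Bone
pseudoprogression scans (new osteoblastic findings reflecting healing) are
excluded only when the matched sample shows an eVAF decrease from baseline.
The reference standard defaults to the radiologist adjudication, with RECIST
PD as a switch. The C-index of a binary rule is balanced accuracy,
(Se + Sp)/2; undefined ratios (zero denominators) are reported as absent,
never as 0. Best-response correlation is Spearman's rho between the percent
change in eVAF (sample nearest the best-response scan) and the percent
change in target-lesion diameter sum from the baseline staging scan.

## Survival analyses

TTF is treatment start to discontinuation of *both* agents for any reason
(the failure flag is authoritative: a CDK4/6i-only stop with ET continued is
not an event); OS is start to death of any cause; otherwise censored at last
follow-up. Estimation is delegated to lifelines: Kaplan–Meier, Mantel
log-rank, and Cox partial likelihood with Efron tie handling and Wald
intervals (the interval method is unstated in the source analyses; Wald is
the common default). Baseline eVAF enters Cox in percent units,
untransformed. ctDNA clearance is analyzed as a time-varying covariate
switching 0→1 at the first cleared sample, so person-time before clearance
counts as unexposed; the 12-month landmark analysis (patients event-free at
the landmark, grouped by status as of the landmark, clock restarted)
guards the same immortal-time bias and is checked directionally in the
tests. Zero-length at-risk intervals are clamped to half a day for the
partial likelihood. No multiple-testing correction is applied anywhere,
matching the exploratory framing.

## Plasma-first policy simulation

The retrospective mode (default) walks the observed matched pairs: a scan is
avoided when its matched sample meets the response rule (clearance or
eVAF_<10% by default); a trigger rule (e.g. eVAF_75%) forces the scan;
missed progressions are reference-progressive scans that were skipped. The
retrospective mode is the default because its avoided fraction is directly
interpretable against an observed cohort. A forward-walking mode simulates
the calendar instead (scheduled scans skipped when any in-window sample
responds, trigger-positive samples without a nearby scan add one).
Detection delay for a skipped progression — time to the next performed
scan — has no observed counterpart and is labeled model-derived. Triggered
scans are assumed performed within one sampling interval. The simulator
counts scans only, not clinic visits.

## WES filter and panel design

Variant filtering applies, in a fixed first-failing order: depth < 100; VAF
≤ 5%; VAF in 40–60% or > 90% (presumed germline — the band is a *removal*
condition, matching its stated purpose of excluding germline variants);
non-whitelisted consequence; population allele frequency ≥ 1%; buffy-coat
germline flag; CHIP flag. TMB is kept variants per megabase with a
configurable capture size (default 35 Mb, a standard exome; the source
denominator is unstated, and the 162-variant / 1.8 mut-per-Mb medians imply
roughly 90 Mb, which appears in tests only as a division consistency
check). Panel design ranks kept variants by descending tumor VAF with a
genomic-coordinate tie-break — a deliberate stand-in, not a reproduction of
any proprietary prioritization — capped at 48 targets, and fails with
`too_few_variants` below 8. Whether only drivers enter panel QC is
configurable via the driver-gene list; all kept variants by default.

## Synthetic cohort generator

The kinetic mode draws, per patient: baseline eVAF from a log-normal with
cohort geometric median 0.5% and ln-sd 2.0, shifted multiplicatively for
liver metastases by the 2.92/0.32 ratio of group medians (complementary
powers keep the cohort median at 0.5%); a decline rate k (log-normal,
median 0.35/month), a resistance time (log-normal, median 13 months,
shortened for higher baseline eVAF via a −0.15 power — this builds in the
prognostic direction of baseline ctDNA), and a regrowth rate (median
0.35/month). The latent path is `e0·exp(−k·t)` then regrowth; measurements
carry multiplicative log-normal noise (ln-sd 0.25) and 3% assay failures;
detection is logistic in ln(eVAF) anchored at 95% at the 0.001% LoD95
(only that single point is specified by the assay, the slope 0.7 is a
modeling choice). Radiographic progression occurs at the first scheduled
scan (every 115 days, first at day 88, matching a ~3.8-month interval)
after the latent burden regrows past 1.2× nadir *and* past 20% of baseline;
deep molecular responders therefore regrow longer, which is what links
clearance to treatment benefit. Treatment failure follows the progressive
scan by 7 days; death times are exponential after failure; follow-up is
uniform on 18–48 months. Blood draws follow baseline (day −3), days 15 and
28, then every 91 days up to an 18-month sampling horizon plus a failure
draw; the horizon reflects that real sampling stopped well before last
follow-up, and without it lead times collapse toward zero. Bone
pseudoprogression is injected at roughly the 3-in-234-scans rate to
exercise the exclusion path. The defaults are tuning targets for the
study's printed summaries, not estimates: no quantitative kinetic rates
exist to calibrate against, and no biological fidelity is claimed (single
compartment, no clonal structure, no lesion-level shedding).

The hazard mode exists for clean statistical experiments: failure is
piecewise exponential (baseline hazard 0.05/month), ctDNA clearance is
assigned with probability 0.4 at a visit-aligned time and multiplies the
hazard thereafter. In `null_effect` the assignment occurs at the first
on-treatment visit with hazard ratio 1, so the clearance label is exactly
independent of outcome and log-rank type-I error can be measured cleanly;
in `strong_clearance_benefit` the ratio is 0.07 and clearance times sit on
the sampling grid so the observed first cleared sample coincides with the
latent switch (no misclassification attenuating the time-varying Cox
recovery). Both modes are bit-for-bit reproducible from (config, seed).

What passing tests on these cohorts do **not** show: correctness on real
data with informative sampling gaps, assay batch effects, CHIP
contamination, inter-radiologist variability, or non-exponential kinetics.
The generator emulates the *structure* the analyses assume, which is
exactly what makes oracle and parameter-recovery tests possible.

## Problem sizes and numerics

The analysis scripts use a 50-patient cohort (seed 7). The test suite and
acceptance script use: 500 patients for generator-calibration checks, 500
replicates of 60-patient null cohorts for the log-rank level, and 100
replicates of 300-patient cohorts for time-varying Cox coverage — sizes
chosen so Monte-Carlo error is small relative to the tolerances asserted.
Cox convergence failures (no events, complete separation — e.g. zero
failures among cleared patients, which genuinely happens in small cohorts)
raise a typed error that callers report rather than masking.

## Known limitations

- The C-index here is balanced accuracy of a binary rule; a
  patient-clustered concordance statistic could differ, and one published
  combined-rule value is not reproduced by (Se+Sp)/2 under any reading.
- One-to-one matching is enforced; denser-than-imaging sampling could
  justify many-to-one matching, which is not implemented.
- No cost-effectiveness, patient-preference, or quality-of-life modeling in
  the policy simulator; avoided "scans" proxy scans-plus-visits.
- No upstream bioinformatics: variant tables are inputs, and RECIST
  adjudication is an input, never computed.
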