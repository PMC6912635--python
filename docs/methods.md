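# Methods

## Data model and time conventions

A recording is a per-animal series of beam-cross counts at 1-minute
resolution, acquired in 32-channel DAM2 monitors, together with the light
protocol it experienced.  Protocols are sequences of LD p:q segments
(p hours light + q hours dark = 24 h per day, days starting at lights-on)
and DD segments (constant darkness).  Minute 0 of every record is lights-on
of the first day, so Zeitgeber time is ZT(t) = (t/60) mod 24 throughout; in
DD this is the conventional 24-h extrapolation of the last entrained cycle.

The dead-animal filter replaces manual actogram inspection: a terminal
all-zero run of at least 24 h (configurable) marks death at the start of the
run, and animals dead before completing two full days of the analysed
segment are excluded entirely.  The rule is idempotent and can only shorten
a record.  A healthy animal's chance of a silent final day is negligible at
realistic activity levels, but the filter cannot see death that occurs in
the final quiet hours of a recording — those animals keep their data.

## Activity simulation

The simulator exists to validate every downstream stage by planted-parameter
recovery; it is first-class, tested code.

**Waveform.**  Expected activity is a circular unimodal profile defined by
three phases (onset, peak, offset in ZT): baseline rate outside the active
window, a raised-cosine ramp baseline→peak over [onset, peak] and
peak→baseline over [peak, offset], evaluated circularly.  A smooth
parametric form was chosen over an empirical template so the planted phases
are analytically exact.  Arrhythmic animals move at the template's 24-h
time-average rate.

**Clock.**  During LD the internal phase equals ZT (entrained).  From the
LD→DD transition the phase is continuous and advances at 24/τ hours of
subjective time per real hour, so the rate trace in DD repeats with period
τ and its peak drifts by τ − 24 hours of clock time per cycle.

**Noise.**  Beam crosses are event counts, so minute counts are independent
Poisson draws at the minute's expected rate.  No overdispersion, no
lights-on masking/startle artifacts, no temperature effects, no bimodal
profiles: passing recovery tests therefore shows the estimators work for
clean unimodal Poisson rhythms of the planted shape, not that they are
robust to every pathology of real recordings.

**Rates.**  Defaults are baseline 0.05 and peak 6.0 crosses/min — a
near-quiescent night and a daytime maximum of a few crosses per minute, the
character of DAM recordings of active wasps.  They were fixed once from a
design calculation: at this signal-to-noise the 20-min night bins carry
≈1 count (so the onset/offset threshold b + 2s sits around 0.15 crosses/min)
and threshold-crossing delays stay a fraction of an hour.

**Cohorts.**  Individuals are assigned round-robin to isofemale lines; per
individual τ = clip(N(τ_mean, τ_sd) + line intercept, 18, 30) with the line
intercept N(0, σ_line) shared within a line, rhythmicity Bernoulli, optional
uniform death times.  Everything — including the emitted DAM2 files — is
byte-reproducible from one master seed.

**Presets.**  Named cohort specs plant the published population values:
free-running means 24.3 h (southern isogenic), 26.7 h (northern isogenic),
24.6 h (Corsica virgin females), 25.42 h (Oulu virgin females); long-day
phase templates onset/peak/offset ZT 0/5/13 (south) and 2/8/16 (north);
short-day templates 21.5/2.5/8 (south) and 0/4/10.5 (north).  Protocols are
4 d LD 16:8 + 10 d DD for τ experiments and 10 d LD for profile
experiments.  Within-cohort τ SD is not published (only standard errors of
means), so it is a design choice: 0.2 h, set so a 30-animal cohort mean's
sampling error (3·SD/√30 ≈ 0.11 h) stays inside the ±0.15 h band the planted
means are validated against — recovery checks then measure the estimator
rather than draw luck — and consistent with the genetic uniformity of
isogenic lines.  The isofemale presets add a between-line SD of 0.15 h on
the same argument.

## Chi-square periodogram

For an equally-binned series (default 10-min bins) and every candidate
period that is an integer number of bins within 18–30 h, the statistic

    Qp = N′·K · Σ_h (M_h − M̄)² / Σ_i (X_i − M̄)²

uses only the K complete cycles (N′ = K·P bins); the trailing incomplete
cycle is excluded by default because the χ²₍P−1₎ null calibration is exact
only for complete folds (a dialect switch admits it).  A zero-variance
series is defined to have Qp = 0 everywhere (arrhythmic); series shorter
than two cycles of the longest candidate are rejected.

Significance uses the pointwise α = 0.05 line per candidate by default —
the convention of interactive periodogram software — with a Bonferroni
option for calibrated family-wise type-I error (the mode used in the
calibration tests; the pointwise mode's family-wise false-positive rate over
~73 candidates is substantially above α, which matters when analysing
genuinely arrhythmic animals).  τ̂ is the candidate maximising Qp − threshold
among significant candidates, ties to the smaller period.  At 10-min bins
the grid step near 24 h is 1/6 h, which bounds the quantisation error of
single-animal estimates; cohort means are unbiased to well within one step.

Cohort estimation drops LD entrainment days, applies the dead filter, and
requires ≥ 5 days of usable DD per animal (records failing this are skipped
with a logged warning, mirroring the omission of dead animals).

## Phase markers

Onset/offset operate on 20-min bin sums, the peak on minute data smoothed by
a centered circular 30-min moving average (which preserves the daily mean
exactly).  The first four entrainment days are always excluded.  The night
baseline b, s is the mean/SD of the bins in a 4-h window centered on
mid-dark; scanning starts at mid-dark so onsets that precede lights-on
(southern short-day behaviour, ZT 21.5) are found without wrap artifacts.
Onset = start of the first bin > b + 2s whose successor is not lower;
offset = start of the first bin after the day's maximum that stays ≤ b + 2s
for two consecutive bins; peak = smoothed argmax, with exactly tied plateaus
resolved to the midpoint of the first plateau met from mid-dark.  Threshold
multiplier, run length, window width and bin widths are all configurable.
Flat or all-zero days yield missing markers; days whose maximum never
exceeds the threshold have no offset.

The window is centered on mid-dark rather than placed at the end of the
night because the short-day southern template is already active in the last
hours of the dark phase; a reference window must be quiescent under every
profile it is applied to, and the mid-dark hours are the span farthest from
both light transitions.

Averaging is circular at both levels (days within animal, then animals),
with circular SDs as dispersion.  Computing markers per animal per day and
then averaging is the default; pooled-profile markers can be obtained by
running the detectors on `daily_profile` output.

**Known bias.**  Threshold detectors on a smooth waveform are systematically
late at onset and early at offset: the rate leaves baseline with zero slope,
so the b + 2s crossing happens a fraction of an hour inside the ramp
(≈ +0.3 h for onsets, ≈ −0.4 to −0.6 h for offsets at the default SNR and
ramp lengths, partly offset/aggravated by reporting bin starts).  Peak
detection is unbiased for symmetric ramps but drifts slightly toward the
shallower side of asymmetric ones (≈ +0.2 h at the preset templates).
Recovered cohort means at the preset SNR stay within ±0.5 h of planted
phases, but offsets approach that band's edge; sharper waveforms or lower
thresholds would tighten both.

## Mixed models and group statistics

The τ models are Gaussian random-intercept models with isofemale line nested
in location encoded as line-unique groups (one variance component, as a
single random effect).  Fitting profiles the likelihood over λ = σ²_u/σ²:
for fixed λ the per-group covariance I + λ11′ has closed-form inverse and
determinant, β̂ is a GLS solve, and λ is found by bounded scalar optimisation
on log λ with the λ = 0 boundary always checked — deterministic given the
data.  ML is the default so likelihood-ratio tests on fixed effects are
valid; REML is available for variance reporting.  With a single group the
model degenerates to OLS with a warning.  The LRT validates nesting
(same n, ML, non-decreasing likelihood) and refers 2Δℓ to χ² with the
parameter-count difference.

Rhythmic proportions are compared with a binomial-logit GLM (IRLS via
statsmodels) and drop-one analysis-of-deviance χ² tests; complete separation
is detected from fitted probabilities and flags the tests unreliable.
The peak-phase-vs-τ regression unwraps the circular peak phase around the
cohort circular mean (deviations in (−12, 12]) before the linear mixed fit —
adequate while phases cluster within about half a cycle, which holds for
unimodal entrained cohorts; no full circular–linear model is attempted.
Cline summaries report per-population means ± SE ordered by latitude plus
the latitude slope from the nested mixed model, with latitude continuous and
location categorical in the respective models.  Rows lacking τ or markers
are dropped listwise per model.

## Pipeline

`run_pipeline` chains simulate/ingest → periodogram → markers → statistics →
figures from a single YAML config with one master seed; simulated cohorts
are written as DAM2 files and re-ingested through the real reader so the I/O
path is always exercised.  Outputs are CSVs with a config-hash header
(paths excluded from the hash), `stats.json`/`stats.txt`, static figures
(double-plotted actograms, profile panels), and a config copy; reruns with
the same config and seed are byte-identical.  Stage failures raise errors
naming the stage and offending file/line.

## Validation scale

Recovery checks use the study-sized cohorts the protocols define: 30
animals per free-running cohort (14-day records) and 25 per profile cohort
(10-day records); statistical calibration uses 1000 null replicates for the
LRT and GLM deviance tests and 500 replicates for slope-recovery bias.  The
full suite runs in about a minute on one core.

## Limitations

- The dead-animal filter is a surrogate for manual actogram inspection; the
  original screening criterion is unknown, so excluded-animal counts are not
  reconstructable.
- The periodogram grid is bin-quantised; sub-grid τ differences within one
  step (10 min) are not resolvable per animal.
- Marker detection assumes unimodal profiles with a quiescent mid-dark span;
  bimodal (morning+evening) patterns are out of scope.
- The simulator's clean Poisson world omits masking, overdispersion and
  inter-day drift of waveform shape; recovery results bound estimator
  behaviour under the stated model only.
- The phase-τ regression's unwrap approximation degrades if peak phases span
  more than about half the cycle.
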