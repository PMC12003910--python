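# Methods

## Task model

Each door is a Bernoulli payoff process: gain `g` with probability `p`,
loss `l` otherwise. Expected value is reported over a 10-trial horizon,
`EV = 10·(p·(g−l) + l)`, so the standard payoff sets print as +40 (RareG,
experimental), −40 (RareL, experimental) and 0 (both baseline doors); the
horizon is an explicit parameter and the factored form keeps the standard
integer payoffs exact in floating point. Outcomes are sampled i.i.d. per
trial by default; a permuted fixed-ratio schedule (exact gain counts) is
available for sensitivity checks. Blocks hold 40 trials; block order
alternates with subject index parity as a stand-in for counterbalancing.

## Synthetic cohort

Covariates are drawn per group from truncated normals (age, SES 0–9,
GAD7 0–21, PHQ9 0–27) and categorical distributions (gender, ethnicity,
recent trauma). Defaults qualitatively mirror a three-group wildfire-
exposure cohort of 27/21/27: matched age and gender, elevated anxiety,
depression and recent-trauma rates in the exposed groups, lower affluence
in the exposed groups. These shifts are configuration, not claims about
any real sample; `CovariateEffectConfig.null()` pools all groups.

Behavior comes from stochastic Win-Stay/Lose-Shift agents: after a RareG
win the agent stays with probability `p_stay_win_rareG` (the controlled
quantity), after a RareL win with `p_stay_win_rareL` (default 0.5), and
after any loss it shifts with `p_shift_loss` (default 0.5); the first
choice is uniform. The experimental-block `p_stay_win_rareG` mean is
0.65 for the indirectly/non-exposed groups and 0.45 for the directly
exposed group (a 0.2 deficit, between-subject SD 0.1 — a medium-to-large
standardized effect once estimator noise is added); the baseline block
uses a common mean of 0.65 for all groups, so the baseline control
analysis is null by construction. A delta-rule/softmax learner
(`V ← V + α(r − V)`, losses scalable by a loss-aversion weight) is
provided as an EV-sensitive alternative agent.

Because each subject contributes roughly six rewarded RareG trials per
40-trial block, the per-subject Win-Stay estimate carries binomial noise
(SD ≈ 0.19) on top of the between-subject SD of 0.1. The 0.2 deficit is
detected by the robust group model in ≈ 82% of replicates when covariates
are group-matched. With the default Table-1-like covariate shifts, the
group dummies are substantially collinear with GAD7/PHQ9/trauma and
detection drops to ≈ 50% — the realistic, confounded condition. The
power-recovery analyses therefore use the group-matched covariate
configuration, which isolates the injected behavioral effect; the
confounded configuration remains the pipeline default.

## Synthetic EEG

Epochs span −0.5…+1.5 s around choice onset at 250 Hz on a 24-channel
10–20 montage (positions from the standard template, adjacency by 2-D
Delaunay triangulation). Each epoch is 1/f-shaped background noise
(spectral exponent 1, broadband RMS 10 µV, independent across channels)
plus, on RareG-choice trials, a phase-consistent 10 Hz burst spanning
0–1.5 s on Pz/P3/P4/POz with 0.4× leakage to their neighbors. The burst
amplitude is drawn once per subject from the subject's group distribution:
2.6 µV (directly exposed) vs. 2.0 µV (others) at SD 0.8 µV — a configured
standardized difference of 0.75, in the range of the medium-to-large
parietal alpha effects such studies report. Blink-like frontal transients
(150 µV, 5% of trials) and forced >100 µV excursions (2%) are injected and
flagged in metadata so rejection can be scored against ground truth.

Features of real EEG deliberately not emulated: spatially correlated
background activity, induced (non-phase-locked) oscillations, channel
drift and impedance artifacts, volume-conducted cardiac/muscle sources,
and any cortical source geometry. Passing recovery tests therefore shows
the analysis chain is correct and calibrated under its own assumptions,
not that it would behave identically on recorded data.

## Preprocessing

Polyphase resampling to 250 Hz, then zero-phase band-pass filtering.
Filters are forward–backward 4th-order Butterworth by default; a
Hamming-window FIR design (transition bandwidth 25% of each band edge,
tap count capped at two-thirds of the signal length so 2-s epochs remain
filterable) is available via `design="fir"`. Measured responses for the
1–45 Hz filter: unity gain at 10 Hz, ≈113 dB attenuation at 0.2 Hz.

Trial rejection applies the absolute 100 µV criterion first, then the
iterative outlier rule: the per-trial deviation statistic (max absolute
amplitude by default, variance optional) is compared to the remaining
trials' mean ± 5 SD, recomputing after each pass, for at most 8 passes.
Every dropped trial appears exactly once in the rejection log with its
rule and iteration.

Band activity is *evoked*: trials are band-filtered then averaged, so only
phase-locked signal survives. Baseline correction subtracts each channel's
mean over −250…−50 ms. Period summaries over choice (0–500 ms), immediate
reward (500–1000 ms) and cumulative reward (1000–1500 ms) support two
measures: the signed window mean (`measure="mean"`) and the mean Hilbert
envelope of the trial-averaged waveform (`measure="envelope"`). The
pipeline default is the envelope: the signed mean of a band-limited
oscillation over a 500-ms window integrates to ≈0 regardless of amplitude,
so only the envelope carries oscillatory magnitude into the group
contrasts. The envelope is still an evoked quantity — phase-random alpha
cancels in the trial average before the envelope is taken. Finally, any
per-subject scalar further than 5 SD from the cross-subject mean is set
to NaN and excluded downstream.

## Group statistics

Scalp maps contrast directly exposed vs. everyone else. Per electrode a
pooled-variance two-sample t is computed (NaN subjects excluded per
electrode; zero-variance electrodes excluded with NaN t). Electrodes with
two-sided p < 0.05 form clusters of adjacency-connected, same-sign
neighbors; cluster mass is the sum of |t|; the null is the maximum cluster
mass over label permutations (default 10,000), giving family-wise control
within a map. Cluster p-values use the (1 + exceedances)/(n_perm + 1)
estimator. The cluster-forming threshold, the mark threshold for flagged
electrodes, and the permutation count are all configurable; mass and
max-statistic control are the conventional choices where the method family
leaves them open. Benjamini–Hochberg FDR is applied across the map family
(9 = 3 bands × 3 periods), and separately across the 12 electrode × period
neurobehavioral models. Measured calibration: family-wise cluster false
positives 4.5 ± 1.5% at nominal 5% (200 null replicates × 1,000
permutations); a 1.5-pooled-SD parietal effect at n = 20/36 is detected
with Pz in a significant cluster in 100% of replicates.

Parietal-cluster contrasts report pooled-variance t, degrees of freedom
and Cohen's d (mean difference / pooled SD). The neurobehavioral models
regress z-scored Win-Stay on group, a z-scored neural scalar, their
interaction, and covariates (age, ethnicity, anxiety), fit by the same
bisquare IRLS; within-group Spearman correlations follow up interactions.
Demographic tables use rank-sum tests for ordinal/continuous variables and
chi-square contingency tests for gender and ethnicity.

The default generators inject no coupling between alpha amplitude and
Win-Stay, so the interaction and Spearman outputs of a default run
estimate a true null; the recovery tests construct coupled data
explicitly.

## Robust regression details

IRLS with Tukey bisquare weights (tuning constant 4.685, ≈95% Gaussian
efficiency), per-term inference from the robust fit's asymptotic standard
errors, and model-level adjusted R², F and p from a weighted least-squares
fit at the converged robust weights. When the robust residual scale
collapses (perfect fit), the routine falls back to ordinary least squares,
which the IRLS solution equals when residuals vanish. Continuous outcome
and covariates are z-scored; categoricals are reference-coded
(non-exposed group, female, caucasian as references). Rank-deficient
designs raise an error naming the collinear columns; subjects with
undefined Win-Stay (no rewarded RareG trial with a follow-up) are dropped
with a logged count, never imputed. Final-trial wins are excluded from the
Win-Stay denominator because no follow-up choice exists.

## Numerical and design choices

- One run seed expands via `SeedSequence.spawn` into per-stage child
  seeds (cohort, behavior, EEG, statistics), so stages re-run in
  isolation reproduce exactly and a full re-run is checksum-identical.
- EDF export is a minimal single-record 16-bit writer with integer
  physical ranges (the 8-byte ASCII header fields) and fixed date fields
  for byte-reproducibility; round-trip error is bounded by the per-channel
  quantization step (range/65535), verified against an independent reader.
- Epoched data live in one HDF5 file (`/subjects/<id>/data` plus JSON
  metadata attributes); arrays round-trip bitwise.
- The 5 SD cross-subject mask is a single pass; the 5 SD trial-rejection
  rule is iterative (≤8 passes) with the SD recomputed after each pass.
- Degenerate inputs: zero-SD columns mask nothing; constant inputs yield
  NaN Spearman rho (reported, not raised); all-trials-rejected subjects
  raise a per-subject error and are skipped by the pipeline with a log
  entry.
- Analysis problem sizes: the pipeline's study scale is 75 subjects
  (57 with EEG after simulated technical loss of 8/7/3 per group),
  40 trials per block, 24 channels, 10,000 permutations. Replicate
  studies use 200 replicates (power, calibration) with 1,000-permutation
  cluster tests, sizes at which Monte-Carlo error is small relative to
  the effects under test.

## Known limitations

- Agents are deliberately minimal: no response times, learning curves, or
  within-block nonstationarity, so behavioral realism beyond the Win-Stay
  structure is out of scope.
- Artifact handling uses amplitude/deviation rules only; no ICA or
  Bayesian source-space decomposition, and no source localization — the
  analysis stops at the scalp.
- With the realistic confounded covariate configuration, group effects on
  behavior are harder to detect (see above); users comparing confounded
  groups should interpret group betas accordingly.
- Permutation p-values have resolution 1/(n_perm + 1); map-level FDR uses
  the minimum cluster p as the map p-value, a conservative summary when a
  map holds several clusters.
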