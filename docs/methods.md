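# Methods

This note documents the models, estimators and numerical choices behind
`cmconn`, the assumptions each one makes, and what the synthetic-data tests
do and do not establish about real recordings.

## 1. The synthetic session model

The generator produces trial-structured sessions mirroring a cued
reach–grasp–lift–replace paradigm: a 2 s rest baseline, a cue at t = 2 s,
object manipulation, and replacement at t = 8 s within a 10 s trial. EEG is
generated at 500 Hz (μV) and sEMG at 4 kHz (arbitrary units); sampling rates
must be integer multiples so that polyphase resampling is exact.

Per analysis channel (C3, Cz, C4) the EEG is a sum of independent Gaussian
components:

- **1/f background** — pink noise, default SD 0.4 μV, spectrum flattened
  below 1 Hz;
- **μ rhythm** — narrowband Gaussian noise at 8–12 Hz, amplitude 1.0 μV in
  sine convention (variance = amplitude²/2). From the cue onward its
  amplitude is multiplied by `erd_amplitude_factor` (default 0.5), which is
  the injected ERD: power drops by the factor squared, i.e. −75%;
- **β rhythm** — narrowband 16–24 Hz, amplitude 0.3 μV, stationary;
- **γ floor** — stationary broadband 30–50 Hz noise, SD 2.0 μV. Its job is
  numerical rather than physiological: it pins the effective bandwidth of
  short (100 ms) analysis windows so that the adaptive histogram bin rule
  (§5) sees nearly identical sample statistics before and after the cue.
  Without it, μ desynchronization alone changes window bin counts and
  imprints a spurious MI step at the cue even with zero coupling;
- **latent drive κ·h_c·D(t)** — the ground-truth coupling. D(t) is
  band-limited (14–30 Hz) Gaussian noise with a steep in-band power slope
  (∝ f⁻⁴), unit variance inside its gate, gated to [cue, replace] with
  100 ms cosine ramps. The steep slope concentrates the drive's power at
  the low band edge, a spectral signature that survives in both the EEG
  band features and the sEMG features and makes the rank correlation
  respond monotonically to κ. Channel mixing gains h default to 1.1 / 1.0 /
  0.9.

Five additional **reference-only channels** containing pure background are
generated (configurable). They take part in common-average referencing and
are then discarded. In a 3-channel montage a drive added identically to all
channels would be cancelled exactly by CAR; real recordings reference over a
full montage in which most channels do not carry the corticomuscular drive,
and the reference channels emulate that.

Each muscle m is `amp_m · env(t) · n_m(t) + κ · g_m · D̃(t)`, where n_m is
band-limited carrier noise, env(t) ramps from a tonic 0.1 to 1.0 during the
movement (cosine ramps; release at replace + 0.5 s), D̃ is D resampled to
4 kHz, and the activation scales follow the dominant-muscle ordering
AD 1.6 > CED 1.3 > B 1.1 > FDI 0.9 > FD 0.7. The drive gains g_m are
proportional to the activation scales with AD at twice the relative
coupling (3.2 vs amp-matched values for the rest): both connectivity
estimators respond to the drive's *share* of a muscle's variance, so flat
absolute gains would make the weakest muscle — not AD — look best connected.

The carrier n_m is pre-emphasized by the inverse of the default conditioning
response (20–150 Hz zero-phase Butterworth + 50 Hz notch), so that after
preprocessing its expected spectrum is flat across the whole 20–149 Hz
feature grid. This is the white-carrier assumption stated explicitly:
without it, the filters' edge roll-off imprints the same deterministic rank
pattern on every muscle's feature vector and biases the zero-coupling PBC
null by +0.2 to +0.4. The pre-emphasis is calibrated to the default
preprocessing configuration; strongly non-default filter settings will
reintroduce some spectral structure.

Per-subject κ values receive a ±10% uniform jitter so group statistics see
between-subject variance. Seeding uses a `SeedSequence` tree
(session → subject → trial); identical specs reproduce sessions bit for bit.

**What the generator does not emulate:** motor-unit EMG physiology, scalp
topography / volume conduction beyond the reference-channel device,
conduction delays (the MI estimator is zero-lag by design), movement-time
variability across trials, artifacts (ocular, cable, line noise), and
object weight as a second factor. Passing recovery tests therefore show the
estimators are correct and well-calibrated under the stated model — not that
they are robust to every property of real recordings.

## 2. Preprocessing

Fixed order: resample EEG to 4 kHz → CAR → band-pass (EEG 6–50 Hz, sEMG
20–150 Hz) → 50 Hz notch (Q = 25, ≈2 Hz width) → amplitude rejection →
baseline/task split at the cue (half-open, no shared sample).

- "Eighth-order zero-phase" is realized as a 4th-order Butterworth run
  forward–backward (8th-order zero-phase magnitude). `literal_order=True`
  applies the stated order twice instead.
- Resampling is polyphase with a sharp Kaiser (β = 14) anti-imaging filter;
  the resample-then-decimate round trip is accurate to better than 1e−6
  relative RMS on interior samples.
- Rejection (±350 μV, any channel ⇒ trial dropped from both modalities;
  >10% ⇒ subject flag) is applied to the referenced, filtered EEG by
  default; `reject_on_filtered=False` screens the raw EEG instead.
- Reference-only channels are dropped right after CAR; only analysis
  channels are filtered, screened and carried downstream.

## 3. Relative power and ERD maps

Relative power is (A − B)/B × 100 with B > 0 enforced; values are bounded
below by −100 because power is non-negative. ERD maps use
`mne.time_frequency.tfr_array_morlet` with 5 cycles at every frequency
(8–50 Hz, 1 Hz step), sampled at a 50 ms stride.

Two numerical choices matter:

- **Baseline statistic.** The default divides by the *trial-average*
  baseline power per frequency. A per-trial narrowband baseline over 2 s
  carries only ~8 power degrees of freedom, and dividing by such a noisy
  estimate biases the expected ratio upward by roughly its squared
  coefficient of variation (~+5 points on a −75% effect, measured). The
  per-trial variant remains available (`per_trial_baseline=True`).
- **Baseline edge trim.** The first 0.25 s is excluded from the baseline
  window (`edge_trim_s`): filter and wavelet supports crossing the trial
  boundary inflate the t ≈ 0 cells by up to 5× and would otherwise bias the
  whole map by −10 points or more.

Significance is a bootstrap-t (t-percentile) mask: trials are resampled with
replacement (default 1000 resamples), the studentized mean is bootstrapped
per cell, and a cell is marked when the two-sided 1 − α interval excludes
zero. The same resample indices serve every cell; because cells enter only
through their own data, each cell's marginal bootstrap distribution — and
the independence of decisions across independent cells — is unaffected,
while the map computation stays vectorized. No multiplicity correction is
applied to the mask. Type-I calibration at n = 50 trials is ~5% (checked
against 500 independent null cells).

## 4. Power-Based Connectivity

The sEMG feature grid is fixed at 20 : 3 : 149 Hz, MBL = 44 points — the
only grid consistent with the β-band matched resolution 16/43 ≈ 0.37 Hz.
EBL counts a band's integer frequencies inclusive; FR = (EBL − 1)/(MBL − 1);
the EEG grid spans [f_lo, f_lo + 43·FR]. A degenerate band (EBL = 1) has no
defined resolution and raises. The matched-resolution values for μ, γ and
All under their conventional edges are 5/43 ≈ 0.12, 20/43 ≈ 0.47 and
42/43 ≈ 0.98 Hz; they are whatever the formula yields for the configured
edges, and the implementation does not special-case any printed convention
that the formula cannot reproduce.

EEG PSDs are estimated natively at 1 Hz (Welch, 1 s Hamming, 50% overlap)
and re-gridded onto the fractional-resolution points by linear
interpolation; features are min–max normalized per vector (constant vectors
map to zeros with a warning). Connectivity per trial uses the movement
segment [cue, replace] only — rest-period corticomuscular coupling is
treated as negligible. Spearman's ρ is tested one-sided for ρ > 0; no
record-level multiplicity correction (correction happens at the group
stage). μ-band edges default to 8–13 Hz; the 30 Hz bin belongs to both β
and γ as conventionally printed.

Parameter recovery under the default generator: β-band mean ρ rises
strictly in κ (≈ 0.00 / 0.14 / 0.18 at κ = 0 / 0.5 / 1.0, single-subject
measurement), and the zero-coupling mean lies within ±0.02 of zero in every
band. The μ band is not coupled (the drive lives at 14–30 Hz) and responds
slightly negatively to κ through rank competition in the sEMG vector; the
All band saturates above κ ≈ 0.6. Surface comparisons and the monotonicity
property are therefore evaluated on the β band, where the drive is injected.

## 5. Windowed mutual information

Adjacent (non-overlapping) 100 ms windows, zero lag, broadband preprocessed
signals. The bin count per signal and window follows the printed std-based
rule bins = range/(3.5·std·n^(−1/3)) — a Scott-type width; a true IQR-based
Freedman–Diaconis variant sits behind `rule="fd"` — rounded to the nearest
integer, floored at 1 and capped at 256; degenerate windows get one bin.
Entropies are computed from the joint histogram (marginals from its
margins), which is algebraically identical to separate histograms on the
same edges and guarantees MI ≥ 0.

The plug-in MI estimator carries a positive bias that grows with bin counts
and with the serial correlation of the windowed samples (≈ (m−1)(n−1)/(2N
ln 2) for independent samples, larger for oversampled band-limited
signals). In the time-course readout this bias is common to all windows as
long as the signal's short-window statistics are stationary, which the
generator's γ floor ensures. A small residual state dependence remains:
after the cue, μ desynchronization shortens the EEG correlation time,
raises the effective sample count, and *lowers* the bias by ~0.01 bits.
The zero-coupling null is therefore stated and tested as the absence of
post-cue *elevation*; a genuine coupling effect (≈ +0.10 bits at κ = 1 for
the C3–AD pair) is an order of magnitude above the residual bias drift.

## 6. Group statistics

Two levels: two-sample t-test (paired on request). Three or more: one-way
ANOVA plus all pairwise t-tests, Bonferroni-corrected (p·k capped at 1).
Assumption checks are Shapiro–Wilk (or one-sample KS against a
moment-fitted normal, used where that convention applies) plus Levene; the
checks are reported, not used to switch tests automatically. The unit of
analysis is the subject-level aggregate (mean over trials), so ANOVA groups
contain one value per subject. The four studies aggregate as: (1) muscles
averaged per channel/band, (2) channels averaged per muscle/band, (3)
channel–muscle pairs in the All band, (4) channel-averaged MI per muscle,
restricted to movement windows (2–8 s default). One-way ANOVA per stratum
is used throughout; a repeated-measures structure is not modelled.

## 7. Pipeline and reproducibility

`run_pipeline` executes enabled stages in dependency order, writes tidy CSV
artifacts plus a JSON manifest (stage, path, parameters, seed, config
hash), and derives per-stage seeds from the single global seed, so any
stage rerun in isolation reproduces its output. Reruns with an identical
config are byte-identical. The CLI (`cmconn simulate|preprocess|erd|emg|
pbc|mi|stats|all`) resolves stage dependency closures automatically.

## 8. Problem sizes used in tests

Unit tests run on 1-subject sessions with 3–4 trials per surface. The
recovery checks use the scales their claims name: ERD, 50 trials; MI
gating, 100 trials; surface-ranking recovery, 20 replicates of 12 subjects
× 3 surfaces × 11 trials (396 trials each), chosen to match a realistic
two-series session per participant. The dominant-muscle MI study uses 8
subjects × 3 trials per surface.

## 9. Known limitations

- PBC correlates spectral *profiles* across grids indexed at different
  physical frequencies; its κ response rests on the drive's spectral
  signature appearing in both vectors, not on per-frequency phase or
  amplitude coupling. Coherence-style estimators are out of scope.
- The MI estimator is histogram plug-in with adaptive bins: absolute MI
  values are bias-dominated for 400-sample windows and should only be read
  comparatively (between windows, muscles or surfaces), never as absolute
  information rates.
- No conduction-delay modelling or lag scan anywhere; estimates are
  zero-lag by construction.
- The KS normality screen uses moment-fitted parameters (Lilliefors-style
  usage without the corrected critical values), matching common practice in
  the application domain rather than strict theory.
- Rejection thresholds are tuned for μV-scale EEG; the synthetic default
  never triggers them, so rejection logic is exercised by dedicated unit
  tests rather than by the default sessions.
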