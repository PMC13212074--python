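# Methods

`nirsgait` re-implements, as a tested pipeline, a walking-task fNIRS analysis
for freezing of gait (FOG) in Parkinson's disease: 48-channel dual-wavelength
(730/850 nm) intensity recordings at 11 Hz are converted to hemoglobin
concentration changes, cleaned, segmented by task condition, and summarized as
cortical activation and functional connectivity, with a group-statistics layer
on top. A synthetic cohort generator states the data-generating model
explicitly so that every stage is verifiable without patient data.

## Task paradigm and timing conventions

The protocol is 1 min quiet standing, 1 min freezing-induction walking (narrow
corridor), 30 s rest, 1 min normal walking, 1 min standing. t = 0 is the onset
of the first standing block; the 10-s preparatory period is excluded from the
recording clock. Analysis windows are the baseline rest (0-60 s), the
freezing-induction phase (62.5-120 s), and normal ambulation (152.5-210 s).

Windows are half-open `[start, end)` in seconds. A window selects exactly the
samples whose time lies inside it (`ceil(start*fs) .. ceil(end*fs)-1`), so the
62.5-120 s window holds 632 samples at 11 Hz.

Walk onsets are taken at the block boundaries (60 s and 150 s). The epoch
extraction rule — HbO2 from 3 to 60 s after walking onset, baseline the 5 s
immediately before onset — is applied relative to those onsets and intersected
with the stated analysis windows, giving extraction ranges [63, 120) and
[153, 210) s with baselines [55, 60) and [145, 150) s. The 2.5-s discrepancy
between the stated condition windows (62.5/152.5) and the 3-s extraction
offset is resolved in favour of the onset-relative rule; both windows are kept
in the `Paradigm` object so the alternative reading is one config edit away.

## Preprocessing

1. **Channel QC.** Coefficient of variation (100 x sample SD / mean) of raw
   intensity per channel and wavelength over the whole recording; a channel is
   excluded iff CV > 14% at either wavelength (equality retains). The window
   and wavelength rule are not standardized in the field; requiring both
   wavelengths to pass over the full recording is the strictest deterministic
   reading. Channels with non-positive mean intensity have undefined CV and
   are excluded with a reason code.
2. **Optical density.** dOD(t) = -log10(I(t)/mean(I)), per channel/wavelength.
3. **Motion artifacts** are detected and corrected in the OD domain (before
   the Beer-Lambert inversion): the amplitude criterion AMP-thresh = 0.5 is
   only dimensionally meaningful in OD units. Detection: within a sliding
   0.5-s window, flag when the signal range exceeds STDEV-thresh = 6 times the
   channel-global SD, or 0.5 OD outright; flags are dilated by +-1 s
   (`t_motion`/`t_mask` are pinned defaults; the exact windowing of the
   SD/amplitude method is not standardized). The per-channel mask is the OR
   over wavelengths.
4. **Spline correction.** Each flagged segment is fit with a natural cubic
   smoothing spline (penalized least squares, lam = (1-p)/p x 0.01 with
   p = 0.99 on a sample-index abscissa — near-interpolating, so the fit tracks
   even sub-sample discontinuities and subtracting it removes the artifact
   *shape*), then re-levelled to the mean of the preceding clean segment (the
   following one if the artifact opens the recording). Segments after an
   artifact are shifted to restore continuity at the boundary (1-s boundary
   means); without this cascade a sustained baseline *shift* would survive
   correction, because only the flagged transition samples would be touched.
   The dense Reinsch solve used for short segments is verified against
   `scipy.interpolate.make_smoothing_spline` to 1e-13.
5. **Beer-Lambert inversion.** Per sample, the 2x2 system
   dOD(lambda) = eps(lambda, chromophore) * d * DPF * dC is solved for
   (dHbO2, dHHb) in umol/L, with source-detector separation d = 3 cm and
   DPF = 6.0. Molar extinction coefficients at 730/850 nm are pinned
   compilation values (HbO2: 390 / 1058, HHb: 1102.2 / 691.32 cm^-1 M^-1) and
   are shared verbatim with the simulator's forward model, so forward/inverse
   round trips are exact (< 1e-9).
6. **Bandpass.** Zero-phase (forward-backward) Butterworth, 0.01-0.2 Hz,
   order 3 per pass (effective order 6) — common practice where only the band
   is standardized; the order is configurable. Single-pass attenuation at
   1 Hz already exceeds 40 dB.

Downstream analysis uses HbO2 only, as the more perfusion-sensitive
chromophore; HHb is carried through the conversion but not analysed.

## Activation and connectivity

Activation per channel = mean HbO2 over the extraction window minus mean over
the 5-s pre-onset baseline (invariant to constant offsets, linear in
amplitude). ROI values are unweighted means over retained member channels
(PFC 14, PMC 8, M1 2, S1 5, TLC 10 channels; 9 channels carry no ROI label
and enter only channel-level analyses). Excluded channels propagate as
missing, never as zeros.

Functional connectivity is the Pearson correlation matrix across the 48
channels over the same extraction windows, per condition. ROI-pair values are
means over member channel pairs (intra-ROI excludes the diagonal; intra-M1 is
the single pair r(37, 44)). Group summaries use raw r, not Fisher z (the
published group cells are plainly raw-r means); a Fisher option exists.
Negative correlations are retained.

## Group statistics

Two-group comparisons use the pooled-variance Student t (Welch by flag) with
Cohen's d = (mean_PD - mean_HC)/s_p; this reproduces the published
connectivity-table t and d values from their printed summary cells to within
rounding. Normality gating (Shapiro-Wilk per group, alpha = 0.05; n < 3 or
zero variance force the nonparametric route) switches to Mann-Whitney U /
Kruskal-Wallis H. The one-way repeated-measures ANOVA computes the
sums-of-squares decomposition with subject as blocking factor,
partial eta^2 = SS_cond/(SS_cond + SS_err), and Fisher-LSD post-hoc =
uncorrected pairwise paired t tests; it is cross-checked against a brute-force
oracle, the F = t^2 identity at k = 2, and `pingouin.rm_anova`.
Benjamini-Hochberg FDR (step-up with enforced monotonicity, q = 0.05) is
applied across channels within one comparison family. Gait contrasts are
paired (freeze-induction vs normal walking) and repeated-measures
(no-cue / beat / music / imagined-beat cueing) per parameter, normality-gated;
FOG counts (integer, zero-inflated) route nonparametric.

## Synthetic cohort generator

The generator is the stated world the tests operate in: 28 subjects per group
(healthy controls vs PD+FOG), 270-s sessions at 11 Hz.

**Task drive.** Each ROI receives a within-block neural drive convolved with a
double-gamma HRF (onset latency 1.5 s, peak 5.5 s — inside the physiological
4-7 s range). Two calibration choices matter:

* Block scales are solved (a 2x2 linear system per ROI) so that the *default
  analysis path* — including the 0.01-0.2 Hz zero-phase bandpass — recovers
  exactly the requested activation amplitude. The bandpass removes ~35-40% of
  a 57-s block's baseline-referenced amplitude, so calibrating against the
  unfiltered signal would make every published-scale group mean come out
  ~40% low from the real pipeline.
* The within-block drive is a boxcar plus a shape correction (cubic
  polynomial plus fast-decaying onset terms) solved once so the filtered
  response is as flat as possible over the extraction window (residual
  within-window SD ~ 0.12 of the activation amplitude, down from ~ 0.47 for a
  plain boxcar). Without this,
  the response variance inside the connectivity window acts as a shared
  within-ROI signal scaled by each subject's activation amplitude, and the
  (large) between-subject amplitude variance contaminates measured
  connectivity far beyond the scales the generator is calibrated to.

Group activation effects (mean, between-subject SD) are the published
freeze-period group cells; normal-walk patient effects (untested at desk
scale) are set to 0.6 x control means. Per-subject amplitudes are drawn at
ROI level and shared by member channels.

**Connectivity structure.** A latent-factor background gives channel pairs in
ROIs A, B correlation R[A, B] (within-A: R[A, A]); each channel adds
idiosyncratic noise so its background variance is 1. The background is
generated *white* — correlations are then exact at generation and the analysis
bandpass (one common linear filter) both band-limits it and preserves them,
maximizing the effective sample count in the 632-sample connectivity window.
`NoiseSpec.background` (0.05 umol/L) is the in-band SD after filtering. The
preset's latent matrices are solved numerically (fixed-point iteration with a
positive-semidefinite projection, offline) so that the *measured* group-mean
ROI connectivity from the full pipeline reproduces the published cells;
unprinted cells (adjacent sensorimotor pairs and S1/M1/PMC intra values) are
fixed once at plausible values and are not calibration targets. Per-subject
connectivity heterogeneity is a global additive coupling shift (every latent
cell moves by one Gaussian delta per subject; positive semidefiniteness
reduces to a single feasibility bound, so the subject distribution stays
near-Gaussian). Its group SDs are set so the group SDs of measured PFC-TLC
connectivity match the published scales, which also pins the true PFC-TLC
group effect size near d = 1.16.

**Nuisance and artifacts.** Cardiac (~1 Hz), respiratory (~0.3 Hz), and Mayer
(~0.1 Hz) oscillations with per-subject frequency jitter and per-channel
phases/gains; linear drift plus a random walk; HHb = -HbO2/3 plus independent
noise (HbO2 is the analysed chromophore; HHb realism is secondary).
Concentrations map through the same Beer-Lambert forward model as the
inverter to dual-wavelength intensity around per-channel baseline levels,
with multiplicative (log-normal) detector noise. Motion artifacts (80%
spikes <= 1 s, 20% sustained baseline shifts; magnitudes 6-15x / 3-8x the
channel OD SD) are injected at 1 event/min.

**Gait tables** are drawn summary distributions, not kinematic simulations: a
shared per-subject factor (loading 0.6) induces the within-subject correlation
paired tests rely on. Patient freeze-induction walking is slower, shorter-
strided, and wider-swinging than normal walking, with Poisson FOG counts
(lambda = 3.5 without cueing); beat and music cueing improve all parameters
more than imagined cueing. The study reports gait contrasts only graphically,
so the preset's numeric levels are typical published PD-FOG magnitudes, chosen
once.

**What a green test does not establish.** The generator emulates group
summary structure, not raw-data realism: no optical photon transport, no
superficial/systemic layer (the real study lacked short-separation channels),
no kinematic gait model, single-trial sessions (block averaging is exercised
but trivial end-to-end), and stationarity within blocks. Recovery tests
validate the pipeline's internal consistency against this stated world, not
clinical validity.

## Numerical choices and degenerate inputs

- Window slices select samples whose timestamps lie in the half-open window.
- Zero-variance channels in a connectivity window become missing rows/columns
  with a warning; a ROI with no retained channel is missing with a warning.
- Zero-variance groups: t = 0 / p = 1 when means agree, an infinite-t flag
  otherwise; all-tied nonparametric inputs return p = 1 with a warning.
- BH-FDR adjusted p-values are clipped to [0, 1] and forced monotone.
- Bandpass refuses series shorter than three startup lengths and advises
  padding.
- The latent connectivity matrices are validated positive semidefinite at
  spec construction; the per-subject coupling shift is clipped at its
  rank-one feasibility bound.
- Seeds: cohorts spawn per-subject child seeds via `numpy.random.SeedSequence`,
  so cohorts are pure functions of (spec, seed) and subjects are independent.

## Known limitations

- The repeated-measures layer is exercised on gait and channel-pair tables;
  the synthetic cohort does not simulate fNIRS recordings under cueing
  interventions (only gait responds to cueing), so intervention contrasts on
  hemodynamic data run on real inputs only.
- Measured group-mean connectivity reproduces published cells to ~0.02 (worst
  case ~0.04 in the patient group) rather than exactly: the published
  intra-/inter-ROI pattern is at the edge of what a latent-factor model can
  express once task-drive contamination is accounted for.
- CV-based QC almost never excludes channels under the preset noise levels;
  QC failure paths are exercised by constructed inputs.
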