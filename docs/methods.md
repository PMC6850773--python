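# Methods

## The phenomenon and the statistics computed

A session consists of three contiguous epochs on a 180 cm linear VR track:
7 min in a familiar environment (Fam), 14 min in a middle environment — a
visually novel track (New) or a static black screen with no task (No Task) —
and 7 min back in the familiar environment (Fam′). Behavior (ball forward and
rotational speed, VR position and speed, rewards, licks) is sampled at 1 kHz
and downsampled to the imaging frame rate (5.2–7.8 Hz; frame means for
continuous variables, containing-frame assignment for events).

Per-cell activity change is quantified as the suppression index

    S = 1 − μ_New / ((μ_Fam + μ_Fam′) / 2),     percent change = −100·S,

where μ is the mean ΔF/F in an epoch. ΔF/F uses a time-varying baseline
F₀(t), the 8th percentile of fluorescence in a 300 s window centered on t
(truncated at the trace edges; percentiles interpolate linearly between order
statistics). Cohort summaries are two-stage: cells are averaged within each
mouse, then mice averaged into a grand mean.

Encoding models are per-cell Gaussian identity-link GLMs (ordinary least
squares) on time-lagged behavioral regressors. Each regressor's lag
(0–2 s, behavior leading activity) maximizes the absolute normalized
cross-correlation with the cell's activity; within-epoch performance is
scored by 10-fold cross-validation on contiguous folds, and cross-epoch
transfer applies the trained weights and lags unchanged to a test epoch,
scoring RMS error and r² (squared Pearson correlation) over the whole
series.

## The synthetic-session generator

The generator is the package's validation instrument: it produces sessions
with the statistical structure the analysis assumes, plus the planted ground
truth needed to score recovery.

**Kinematics.** Forward running speed is a clipped Ornstein–Uhlenbeck
process (mean 22 cm/s, SD 6 cm/s, τ = 1 s) gated by alternating run/rest
bouts (means 4.5 s and 3.5 s, truncated-normal durations with CV 0.15,
~45% time at rest); the final goal-directed approach to a reward is not
interrupted by rest bouts, so pre-reward deceleration is negative and
scales with proficiency. Mice in head-fixed VR tasks are immobile for a large
fraction of each session; the rest bouts both reproduce that and anchor the
sliding-percentile baseline (F₀ is estimated from quiescent samples). Bout
durations are short and fairly regular so that epoch-level locomotion
statistics are stationary — the regime in which an epoch-ratio statistic
like S is well-posed; real sessions drift more (see Limitations). The
simulated mouse runs to alternating track ends; per-epoch proficiency
p ∈ [0, 1] controls failure (mid-track turn-around) probability
0.55·(1 − p), the depth of the pre-reward slowdown (linear ramp over the
final 30 cm, up to 70% at p = 1), and spurious licking (0.5 + 4·(1 − p) bouts/min;
every reward also elicits a 4–7-event bout within ±0.3 s). Rewards are
instantaneous events at correct end-zone entry followed by a 1.5 s
consumption dwell. In the No-Task variant the middle epoch freezes VR
position, delivers no rewards, and leaves ball speed untouched.

**Fluorescence.** For cell i with baseline brightness base_i (~U[50, 200] au),
gain g_i (~U[1.0, 2.0]), sign (+1 with probability 0.8), lag (~U[0, 1] s)
and suppression s_i (~U[−0.2, 0.8]), the noiseless latent in the default
`"activity"` mode is

    L_i(t) = base_i · B_i(t) · (1 + g_i · r_i(t − lag_i) · (1 − s_i·1[middle])),

where r_i is the cell's drive — normalized ball speed (95th-percentile
scaled, clipped to [0, 1]) for locomotion-activated cells, a rectified
immobility signal for sign −1 cells — and B_i(t) = exp(−t/τ_bleach) models
photobleaching (off by default). The drive is further multiplied by a
mean-one lognormal gain fluctuation (log-SD `excess_variability` = 0.3,
correlation time 0.5 s, independent across cells): interneuron activity is
not a deterministic function of speed, and this excess variability is what
gives ΔF/F its positive skew (median ~0.7 in the first familiar epoch, so
the skewness ≥ 0.3 responsiveness filter keeps most locomotion-coupled
cells) and caps encoding-model cross-validated R² near 0.8 rather than 1. Suppression scales only the behavior-driven
component: a suppressed interneuron fires less, but its quiescent
fluorescence (which F₀ tracks) is unchanged. This is what makes the ΔF/F
ratio statistic sensitive to s. An alternative `"total"` mode scales the
entire latent by (1 − s_i); it makes the latent's epoch-mean ratio exactly
1 − s (useful for exact algebraic checks) but is invisible to an adaptive
baseline, since F₀ scales identically inside the 840 s middle epoch.
Raw traces add per-frame Gaussian noise of SD `noise_sd`·base (default
0.02, a bright-soma SNR). A shared neuropil trace (0.5 × population-mean
latent plus noise) is returned; by default ROI traces are uncontaminated,
and setting `neuropil_coef = r` adds r·neuropil so the correction can be
exercised end-to-end (the pipeline subtracts only when contamination was
simulated).

**Movies.** Planted 2-D Gaussian somata (σ = 3 µm at 1 µm/px; ground-truth
mask the 2σ disc, ≈113 µm², above the 90 µm² detection floor) with ≥25 µm
centroid separation on a 256×256 px field; soma brightness follows the
latent, the diffuse background follows the neuropil trace, photon noise is
Poisson, and optional known integer rigid shifts are applied per frame.

## Numerical and design choices

- **Sliding percentile**: streaming sorted-window implementation (numba,
  falling back to a vectorized partition in pure numpy), truncated windows at
  the edges, linear interpolation between order statistics. It matches a
  materialized-window `np.percentile` brute force to ~1e−14.
- **ROI detection**: the temporal-SD map is z-scored robustly
  (median / 1.4826·MAD) before thresholding at 1.5; with mean/SD scaling a
  few very active somata inflate the scale and mask dimmer cells
  (mean/SD available via `robust=False`). Components are 8-connected and the
  area filter is strict (> 90 µm²). Overlapping ROIs are never split
  automatically; `apply_mask_edits` accepts externally supplied splits.
- **Motion correction**: FFT cross-correlation against the mean of the first
  100 frames, integer shifts only; frames whose normalized correlation peak
  falls below 0.3, or whose shift exceeds the configured maximum, are flagged
  unreliable and left unshifted.
- **Annuli**: 5–20 µm from the ROI boundary (distance transform), excluding
  all detected ROI pixels.
- **Skewness filter**: cells kept when first-Fam-epoch ΔF/F skewness ≥ 0.3
  (boundary kept); near-zero-variance traces are dropped with reason
  `"flat"`. On default synthetic cohorts ~80–85% of cells pass; the drops
  concentrate among immobility-activated cells, whose ΔF/F is less
  positively skewed.
- **Lag search** maximizes |r| rather than the signed maximum, so
  anti-correlated cells receive a meaningful lag; the signed peak is
  recorded. Lags are restricted to behavior-leading (≥ 0).
- **Cross-validation folds** are contiguous blocks (temporal data);
  interleaved folds are available by flag.
- **Reward regressor**: binary impulse at the reward frame.
- **Fam_Ave**: mean of the two familiar epoch means (the epochs have equal
  length); a concatenated-frames alternative is available by flag.
- **Bout-within-±500 ms-of-reward** is anchored at the bout start time,
  inclusive boundary; lick-bout gaps split at exactly 200 ms (strict <).
- **Turn-arounds** require a displacement-sign reversal sustained ≥ 0.5 s
  covering ≥ 2 cm, to reject jitter; rewards without a full 3 s pre-window
  are excluded from deceleration.
- **Hilbert-phase classification**: stop-triggered mean activity and speed
  (±5 s windows around run→rest transitions) are cross-correlated; the
  analytic-signal phase at zero lag classifies the cell (phase in
  (−π/2, π/2] → locomotion-correlated). Every element (window, threshold,
  boundary) is an argument.
- **Holm correction** is implemented directly (step-down, adjusted
  p = running max of (m−i+1)·p_(i), capped at 1) and cross-checked in tests
  against an independent enumeration oracle and statsmodels. Families mirror
  figure panels: days within one metric/context form a family.
- **Two-sided tests** throughout; zero-variance inputs return flagged NaN
  results rather than raising mid-pipeline.

## Validation experiments and problem sizes

The validation suite (`novelsupp.validation`, driven by
`tests/test_acceptance.py` and `scripts/acceptance.py`) uses full-size
sessions (7/14/7 min at 7.8 Hz, 1 kHz behavior) throughout. Parameter
recovery uses 8 mice × 20 cells (one session each) and a 5-day, 8-mouse
cohort for trajectory tracking; encoding-model experiments use 12-cell
sessions with suppression planted at 1 (coupling abolished) or 0 (control);
consistency uses 10 paired exposures of 20 shared cells; movies use 20
somata over 120 s. The ΔF/F brute-force oracle materializes every window on
5 of 50 traces and ~150 random frames on each of the rest, keeping the check
fast while still testing all traces; the implementation path is identical
for all frames.

Parameter-recovery experiments hold proficiency equal across epochs.  The
suppression index is a ratio of epoch means, so any systematic difference in
locomotion statistics between epochs is absorbed into S — that is a property
of the statistic, not an estimator error, and it is precisely the confound
the encoding-model analyses are designed to expose (they are validated under
epoch-dependent behavior). Recovery is therefore scored under the
statistic's own stationarity assumption.

## What the generator does and does not emulate

It emulates: the session/epoch structure, alternation task with
proficiency-dependent performance, run/rest locomotion with pre-reward
slowing, reward-locked and spurious licking, locomotion-coupled fluorescence
with per-cell gain/sign/lag, epoch-specific multiplicative suppression of the
activity component, photobleaching, frame-rate sampling, shared neuropil,
and planted imaging geometry with rigid motion.

It does not emulate: calcium-indicator kinetics (no rise/decay convolution —
fluorescence follows the drive instantaneously), spiking statistics,
behavioral drift at the epoch scale (rest-bout statistics are stationary by
design), visual-scene content, non-rigid motion, or slow network-state
changes that outlast the middle epoch. Consequently, passing recovery tests
shows the estimators are correct under their stated assumptions; it does not
show that real sessions satisfy those assumptions — on real data, epoch-scale
behavioral drift inflates the spread of S, and photobleaching (if
uncorrected) biases RMS-based model-fit comparisons, both directions the
original analyses had to argue around.

## Known limitations

- The area of ROIs detected from bright somata overshoots the planted 2σ
  mask (the Gaussian skirt exceeds threshold); centroid matching is the
  reliable planted-vs-detected criterion, and the 20%-area agreement holds
  for moderate-amplitude cells.
- `suppression_index` is undefined for cells with non-positive familiar-epoch
  mean ΔF/F; such cells are excluded and logged, matching the per-cell
  normalization's domain.
- The No-Task middle epoch ignores proficiency (there is no task); spurious
  licking in that epoch uses the baseline rate.
- With per-cell suppression drawn near −0.2 (facilitation), recovered S is
  the noisiest (the (1 − s) factor amplifies behavior-sampling error), which
  sets the ±0.05 recovery band's failure mode.
- The recovery error budget has two parts: a systematic attenuation of
  ~0.02·s (the 8th-percentile baseline sits ~1 noise-SD below the true
  quiescent level, inflating both epochs' mean ΔF/F additively), and a
  per-session wobble of ~0.02·(1 − s) from sampling fluctuations in the
  epoch-mean locomotion drive. Under the default conditions ~95% of cells
  land within ±0.05 of the planted value; sessions whose realized epoch
  drive ratio deviates by more than ~4% account for most of the remainder.
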