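# Methods

`mukin` implements a pipeline for proportional wrist control from
high-density surface EMG: joint angles of the three wrist degrees of
freedom (DoFs: flexion/extension, pronation/supination, ulnar/radial
deviation) are regressed either from classic time-domain (TD) features of
the interference EMG or from motor-unit discharge timings ("neural
features"), including a model-based dimensionality reduction that converts
a population of decomposed spike trains into one activation signal per
DoF. Because no public recordings accompany this problem, the package
ships a motor-neuron-pool/EMG simulator that generates complete sessions
with ground truth, and every claim the test suite makes is a claim about
that synthetic world.

## Signal model and simulator

**Cues and kinematics.** A session cues one DoF at a time with triangular
constant-speed ramps: each trial is neutral → +rom → neutral, rest,
neutral → −rom → neutral, three trials per DoF, at one of three ramp
durations (5, 2.5 or 1 s). Defaults: rom = 60° per direction (the
half-range of motion; a free parameter, as full wrist excursions differ by
DoF and subject), 2 s rests, 2048 Hz sampling.

**Motor neuron pools.** Each DoF direction has an agonist pool (six pools
total). Recruitment thresholds follow an exponential ladder spanning a
30-fold range, scaled so the highest threshold sits at 0.8 of maximal
drive; the common drive of a pool is the rectified normalized cue angle,
clip(±angle/rom, 0, 1). A unit fires when the drive exceeds its threshold,
at rate min(peak, min_rate + gain·(drive − threshold)) with min_rate = 8,
peak = 35 discharges/s and gain = 40 discharges/s per unit drive — the
standard size-principle pool parameterization. Inter-spike intervals are
Gaussian with CoV 0.15 (0 for deterministic tests) with intervals ≤ 1 ms
rejected; spike times accumulate in continuous time and are rounded to
samples, so long constant-drive runs recover the model rate to well within
2%. Five percent of units are driven by two pools of different DoFs
(multi-DoF units, matching the observation that a few units appear in more
than one DoF). Per-pool unit counts are drawn with ~27% relative spread
around the configured mean (default 30/pool): real decomposition yields
are strongly heterogeneous across muscles and sessions, and exactly equal
antagonist pools are a degenerate configuration the median-pooling model
is maximally sensitive to (see limitations).

**EMG.** Each unit's MUAP is a Gaussian-derivative biphasic waveform
(width 1.2–2.4 ms drawn per unit), identical across channels up to an
amplitude that decays exponentially (length constant 1.5 electrodes) with
grid distance from the unit's territory center; territories cluster
around six fixed loci on the 8×8 grid, one per pool, like distinct muscle
compartments. Peak amplitude is proportional to recruitment threshold
(later-recruited units are larger). EMG is the superposition of templates
at discharge times (a discharge places the template onset at the discharge
sample — a self-consistent convention shared by synthesis,
spike-triggered averaging and reconstruction) plus white Gaussian noise.
SNR is defined as the channel-mean of 10·log10(signal power/noise power)
during activity; the default 15 dB describes a good laboratory recording.

**Decomposition errors.** The corruption model keeps
ceil(detected_fraction·n) units drawn without replacement with weight
threshold^bias (decomposition preferentially finds large, high-threshold
units), deletes each retained spike independently with the miss rate, and
adds spurious discharges as a homogeneous process. Errors are therefore
*stationary*: training and testing ramps see the same corruption
statistics (a consequential property; see limitations).

## Feature sets

* **TD** — 20–500 Hz zero-phase band-pass (5th-order Butterworth
  prototype applied forward-backward), automatic noisy-channel exclusion
  (channel RMS beyond 5× either side of the median channel RMS), 100 ms
  windows with 90 ms step, per channel RMS, slope-sign changes, zero
  crossings and waveform length, z-scored and reduced by PCA to 98%
  variance. ZC/SSC thresholds are set per channel to 3·1.4826·MAD of the
  rest-period signal, clipped to 10% of full scale — an automated
  surrogate for manual threshold picking.
* **DSC** — per-unit discharge counts in the same windows.
* **AM1 / AM2** — DSC plus residual-EMG TD features (joint PCA), and DSC
  alone (PCA), both without the activation model.
* **PROPOSED** — the three per-DoF activation signals (below) plus
  residual-EMG TD features after PCA.

The residual EMG is the recording minus the superposition of
spike-triggered-average (STA) templates (25 ms, ≥ 10 full-support
discharges per unit, training ramps only) at the decomposed discharge
times; it retains whatever the decomposition missed.

## Model-based dimensionality reduction

Each unit j assigned to DoF i contributes a per-window synaptic-input
proxy α_ij = g_ij(x_ij), where x_ij is the unit's windowed spike count and
g_ij is a linear map fitted by iteratively reweighted least squares with
the Tukey bisquare weight (tuning constant 4.685, scale = MAD/0.6745 of
residuals about zero, ≤ 50 iterations, relative tolerance 1e-8; MAD about
zero rather than about the residual median keeps the weights alive when
gross outliers displace the initial OLS fit). Units are assigned to the
DoF whose windowed angle series has the largest |Pearson correlation| with
their count series; units with zero count variance or |r| < 0.2 are
excluded as uninformative. The pool activation is the recursive median

    a_i[r] = median(α_i1[r], …, α_in[r], a_i[r−1]),   a_i[0] = 0°,

with the even-cardinality median taken as the mean of the central pair
(keeps the operator continuous). The median bounds the influence of up to
⌊(n−1)/2⌋ grossly wrong unit estimates per window, and the a[r−1] term
never increases |a[r] − a[r−1]| relative to the same median without it.

## Regression and evaluation protocol

A single OLS regression (with intercept) maps any feature set to the
three joint angles; the window target is the mean angle over the window.
The final estimate is the median of three consecutive regression outputs,
applied per DoF within each contiguous evaluated segment. Performance is
per-DoF R² = 1 − SS_res/SS_tot about the test-trace mean, averaged over
DoFs with equal weight (zero-variance DoFs excluded).

Cross-validation is leave-one-ramp-per-DoF 3-fold, repeated with random
fold assignments (default 10 repeats). Every stage parameter — channel
mask, noise thresholds, STA templates, PCA bases, DoF assignments,
g-functions, regression weights — is fit on the training ramps only; the
no-leakage property is asserted by a test that tampers held-out targets
and requires bit-identical trained models. Rest segments belong to the
trial they precede and are included in both training and testing traces.

## Problem sizes and numerical choices

The test suite and the acceptance script scale the study down to keep a
desk-size footprint: the end-to-end recovery check runs the full design
(3 DoFs × 3 trials × 3 speeds, ~30 units/pool) with 2 CV repeats; the
feature-set ordering checks use ten seeded 1 s-ramp sessions with
~16 units/pool and 3 repeats; the acceptance script uses 24 units/pool and
2 repeats across all three speeds. Sample indexing is 0-based throughout;
EMG is stored as little-endian float32 channel-major with a plain-text
header; all randomness derives from one session seed via spawned
`SeedSequence` children (order: DoF shuffle, pools, templates, spikes,
sharing, noise, corruption), so sessions are bit-reproducible.

## What the simulator does and does not show

The synthetic world reproduces the structure the pipeline needs —
recruitment-ordered pools driven by kinematics, MUAP mixing on a grid,
configurable decomposition errors — but it is deliberately idealized: the
mixture is stationary (no electrode shift, posture-dependent waveform
change, fatigue or motion artifact), noise is white and Gaussian, and the
drive–kinematics link is exact. Three consequences matter when reading
the results:

1. **TD features are near ceiling.** With a stationary linear mixture and
   64 clean channels, interference-EMG amplitude decodes the cue almost
   perfectly (R² ≈ 0.94), far above what TD features achieve on real
   recordings. The real-world advantage of neural features over TD rests
   on nonstationarities this simulator excludes by design, so that
   ordering does not emerge here even at unrealistically low SNR.
2. **Stationary corruption is kind to count regression.** Because
   decomposition errors are statistically identical in training and
   testing ramps, an OLS regression on PCA-reduced spike counts (AM2)
   adapts to the corrupted units during training. The median model's
   protection against units that *change behavior* between training and
   testing — the regime real decomposition failures occupy — is therefore
   only partially exercised; the proposed set edges out AM2 in most but
   not all seeded sessions.
3. **Antagonist balance limits the median.** With both direction pools of
   a DoF merged, the activation can only track a direction while more than
   half of the pool (plus the recursion term) responds; silent antagonist
   units hold the median near their intercepts otherwise. Heterogeneous
   pool sizes and the recursion term mitigate this; with ground-truth
   spikes the full pipeline still recovers held-out kinematics at
   R² ≥ 0.85.

## Known limitations

No volume-conductor or anatomical realism, no force model, no fatigue or
electrode-shift effects; decomposition itself is out of scope (ground
truth plus the error model stands in); single-DoF cues only; the ANOVA
machinery of a subject study is replaced by descriptive per-condition
aggregates.
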