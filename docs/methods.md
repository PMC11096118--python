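# Methods

This note documents the models implemented in `hapticstim`, the defaults
chosen where the design was open, and what the synthetic data can and
cannot establish.

## Task and schedules (`trial_design`)

A session comprises 8 familiarization trials (A/B/B triplets with
f_A = 100 m^-1 and f_B = 164 m^-1, odd position fixed at position 1 —
configurable, since only the habituation matters, not its placement),
then 20 pre-intervention, 60 intervention (3 x 20) and 20 post-intervention
triangle-test trials. Each 20-trial block presents each of the four
comparison frequencies exactly five times in a randomized order drawn once
at pre-intervention and reused verbatim in all later blocks, mirroring the
constant-stimuli design the task uses. Triplet arrangements are drawn
uniformly from the six St/Co patterns.

The simulated participant is an equal-variance Thurstonian observer:
stimulus i evokes x_i ~ N(f_i, sigma^2) on a perceptual scale identified
with spatial frequency (only differences matter under this model), and the
response is the stimulus farthest from the midpoint of the other two — the
classical triangle-test decision rule, consistent with the power analysis
this design family relies on. The rule implies chance performance of
exactly 1/3 as sigma grows and perfect performance at sigma = 0.

`triangle_power` computes exact binomial power of the one-sided test of
H0: p = 1/3: the critical count is the smallest k with
P(X >= k | n, 1/3) <= alpha and power is P(X >= k | n, p_alt). The
discrimination probability p_alt is an explicit argument; no attempt is
made to reproduce any particular published sample-size figure, whose
underlying effect size is not public.

Behavioral group-by-phase effects are modeled as multiplicative sigma
factors (`pipeline.default_behavior_effects`). With sigma_base = 18 m^-1
the pre-intervention probability correct is ~0.56-0.61; the stimulation
group's post factor of 0.70 yields a ~+0.12 gain and the sham factors leave
post essentially flat with a small dip during the intervention. These
factors were derived from the triangle psychometric function to reproduce
the direction and rough magnitude of the group-level pattern the task is
designed to detect; they are design choices of the simulator, not measured
quantities.

## Haptic rendering and guided exploration (`haptic_sim`)

The scene is planar (y lateral, z vertical; no forces along x). Grating
force C sin(2 pi f y) with C = 3 N applies while the hand is in contact and
inside a texture; the virtual table is a penalty contact
K_z (z_tbl - z) - B_z vz below z_tbl = 1 mm with K_z = 1960 N/m,
B_z = 28 Ns/m; guidance is a PD controller (K_hg = 300 N/m, B_hg = 60 Ns/m)
tracking a cycloidal reference — the standard machine-design cycloid
y_R = y0 + h (t/T - sin(2 pi t/T)/(2 pi)), whose velocity and acceleration
vanish at both ends. The trajectory policy is replaceable; sweep duration
defaults to 1.2 s per texture with 0.3 s gap transitions.

The hand/end-effector is a 1 kg point mass with 5 Ns/m viscous damping
(passive arm impedance), a 3 N steady downward press maintaining table
contact, and small per-trial compliance noise (0.2 N RMS) as the only
stochastic element. Integration is fixed-step semi-implicit Euler at
1 kHz, the typical haptic control rate; the scheme is stable for the
printed stiffnesses, and the closed loop tracks the reference within
~7 mm at default gains. Texture layout (not specified by the task
definition) defaults to three equal-width bands spanning the 0.20 m table
with 0.01 m gaps; contact is defined as z < z_tbl, matching the table
force's branch condition.

Kinematic metrics use samples in texture contact with |vy| > 0.01 m/s:
scanning time and path length are averaged over the three textures,
scanning speed is the mean |vy| over qualifying samples; trials with no
qualifying samples report missing values rather than zeros. The simulator
does not model participant-driven speed changes, so kinematics carry no
group effect; they exist to exercise the metric definitions and the data
plumbing.

## Stimulation (`stimulation`)

The pulse train is rectangular charge-balanced biphasic, cathode-first,
300 us per phase with a 10 us interphase delay at 50 Hz; both phases use
the same sample count so net charge per pulse is zero to within one
sample's quantization. Sampling must resolve the interphase delay
(fs >= 1e5 Hz; 1e6 Hz in practice).

The staircase reproduces the bench procedure: 0.5 mA ascents from 0 until
first perceived, then descents of 0.2 mA until not perceived — started one
coarse step below the first-perceived intensity, since the procedure's
descending start point is otherwise unspecified — then 0.1 mA ascents
until perceived again; that value is the threshold estimate. For any
deterministic perceiver (perceives iff intensity >= true threshold) the
estimate overshoots the true threshold by at most one fine step; an
optional logistic perceiver models report variability. Intensities are
kept on the step grid by rounding after every update so thresholds lying
exactly on a grid point are recovered exactly. Simulated thresholds are
drawn from N(2.8, 0.74^2) mA truncated at 0.5 mA. Intervention intensity
is 95% of the estimate for the stimulation group and 0 mA for sham; sham
sessions keep identical event structure. Stimulation is gated to the union
of intervals in which the hand is in contact and inside a texture.

## Synthetic EEG (`synthetic_eeg`)

The montage is the 64-label extended 10-20 set with schematic 2-D positions
generated row-by-row (unique, unit head radius); the two channels flagged
bad in this recording setup (Fz, Oz) are excluded, leaving 62 usable
channels. Positions serve only the spatial computations below and make no
anatomical claims.

Each epoch is:

1. **Background**: per-channel Gaussian noise spectrally shaped to
   PSD ~ 1/f^1 (exponent configurable; log-log slope verified within 0.2
   over 1-40 Hz), spatially smoothed across electrodes with a Gaussian
   kernel (width 0.3 head radii) and rescaled to 5 uV RMS.
2. **Alpha**: one oscillation per trial at a frequency uniform in
   [8, 13] Hz with uniform random phase, amplitude
   alpha_base x factor(group, phase, trigger), weighted by a Gaussian
   centro-parietal topography centered between Cz and Pz (width 0.35) —
   a generic sensorimotor-ish alpha distribution, since no electrode-level
   localization is being modeled.
3. Average reference.

Defaults: alpha_base = 5 uV at the topography peak and 5 uV RMS noise —
resting-EEG scales at which ongoing alpha and broadband background are
comparable. The default effect map multiplies alpha *amplitude* (power
scales as the square): stimulation group 1.3 during / 1.5 after the
intervention, sham 1.2 during / 0.8 after, pre = 1.0 everywhere, for both
trigger types. The factors encode only the qualitative sign pattern and
ordering the analysis is meant to recover; no quantitative effect sizes
are claimed. Windows are [0, 1.4] s (trial start) and [-1.0, 0.4] s
(trial end) at 1200 Hz, 20/60/20 trials per phase, 13 participants per
group — the study-scale defaults.

The generator produces clean data; artifact removal is out of scope and an
optional artifact injector (line noise, blink-like transients) exists only
to exercise robustness paths. Because alpha phase is random per trial, the
synthetic alpha is non-phase-locked — an induced, not evoked, oscillation.

**What passing tests show**: that the pipeline recovers amplitude effects
of the configured size from data with realistic spectral and spatial
correlation structure, and that its error rates are calibrated under this
generator's null. Real recordings add non-stationarity, artifacts,
between-subject topography variation and non-Gaussian noise that this
generator deliberately omits; results here bound what the analysis can do
under ideal conditions, not what it will do on hardware data.

## Derived metrics (`efield`)

Evoked maps are trial means; paired contrasts are elementwise differences
(weights [1, -1]), e.g. intervention - pre. The Morlet transform uses
w(t) = exp(i 2 pi f t) exp(-t^2 / 2 sigma_t^2) with
sigma_t = n_cycles / (2 pi f), n_cycles = 1.5 (temporal precision
prioritized over frequency resolution), unit-energy normalization,
truncation at +-4 sigma_t, frequencies 8-13 Hz in 1 Hz steps. Amplitude is
the complex magnitude; samples within half a wavelet of either window edge
have incomplete support, are flagged, and are excluded from statistics.
With 1.5 cycles the wavelets are spectrally broad — adjacent alpha
frequencies overlap heavily, which is inherent to the chosen width, so the
transform is treated as a band-level, not line-level, measure. The alpha
band is taken as 8-13 Hz for computation (a narrower 8-12 Hz preset is
also provided, as both conventions circulate).

Two TFR modes exist because both conventions appear in practice: *evoked*
(transform the trial average; phase-locked content only) and *induced*
(transform each trial, average amplitudes). The pipeline uses induced mode:
the synthetic alpha is non-phase-locked, so the evoked-mode TFR is blind
to it by construction, and a pipeline meant to recover the generator's
amplitude effects must average single-trial amplitudes. A TFR computed on
an `EvokedMap` is always the evoked mode.

GFP is the per-sample standard deviation across channels with the
population (divide by N) convention, so under average reference it equals
the spatial RMS — the sample convention would shift every value by a
constant factor, hence the choice is documented. GMD divides each
re-average-referenced map by its GFP and takes the RMS difference: 0 for
proportional maps, 2 for antipodal ones; zero-GFP samples are undefined
and returned as NaN rather than 0. Both functions re-reference their
inputs (idempotent and cheap) rather than trusting input state.

In the full contrast grid, the per-participant GFP series is the GFP of
the paired-contrast evoked map and the GMD series compares each phase's
evoked map against pre-intervention. Both are non-negative by
construction, so their one-sample tests against zero are expected to fire
wherever any signal or noise difference exists — the grid reports them in
this conventional form rather than recalibrating them.

## Cluster-based permutation inference (`cluster_stats`)

Pointwise t statistics (one-sample on within-group contrasts; pooled-
variance independent-samples between groups) are thresholded at
t.ppf(1 - alpha/2, df). df is the per-group n - 1 by default (13 - 1 = 12
gives the conventional 2.17 after truncation to two decimals; the pooled
n1 + n2 - 2 reading is available). Suprathreshold points (strict
inequality; exactly-threshold points are excluded) form clusters under
4-connectivity in the frequency x time plane and simple contiguity in 1-D;
the channel dimension is averaged out beforehand, matching the 2-D
presentation of time-frequency clusters. Cluster mass is the sum of t.

The null is the permutation distribution of the maximum |cluster mass| per
permutation, pooled over both sign classes. Testing each sign class
against its own null at alpha would roughly double the familywise error of
a two-tailed test (both tails can fire independently), so the pooled
max-statistic convention — the one used by the standard EEG permutation
tools — is adopted; clusters are still reported with their signs.
Sampled permutations use the add-one convention
p = (1 + #{null >= |mass|}) / (1 + n_perm), so p > 0 always; when the full
permutation set (2^n sign flips, or all label partitions) is no larger
than the requested count it is enumerated exhaustively, the result is
seed-independent, and `exact_flag` is set. Default n_perm = 1024, which
auto-enumerates one-sample designs up to n = 10.

Calibration is tested empirically: the familywise false-positive rate of
the between-group test over 1,000 null-generator replicates lies within
Monte-Carlo error of alpha, and sampled p-values at n = 8 match the
256-pattern exact enumeration within 0.02.

## Pipeline and problem sizes (`pipeline`, CLI)

`run_study` chains schedules -> observer -> kinematics -> staircase ->
EEG -> derived metrics -> contrast grid. One master seed is split into
named, purpose-specific streams (schedule, observer, exploration noise,
EEG) via `numpy.random.SeedSequence` spawn keys, so each stage is
independently reproducible and two runs of the same config produce
byte-identical tables; the generator's own seed field is overridden by a
stream derived from the master seed. Epochs are reduced to derived
metrics participant-by-participant, keeping memory flat; raw traces and
epochs are not retained by default. Outputs are tidy CSVs (behavior,
thresholds, cluster results) plus an optional HDF5 container holding the
montage and derived arrays, every dataset annotated with the producing
config hash, with a YAML copy of the config alongside.

Statistical-calibration tests run at reduced problem sizes chosen as this
package's desk-scale study conditions: null familywise-error replicates
use 6 participants per group, 4 trials per phase, 300 Hz sampling and a
0.8 s window; effect-recovery replicates use the full 13 participants and
the default effect map at 600 Hz with 12/24 trials; the full contrast-grid
check runs 13 per group with the default 20/60/20 trials at 600 Hz. The
600 and 300 Hz rates sample the 8-13 Hz band far above Nyquist and leave
the analysis unchanged apart from time-axis resolution.

## Known limitations

- The observer has no lapses, bias, learning within a block, or
  stimulation-dependent perceptual mechanism; behavioral effects are
  injected directly as sigma factors.
- The hand model is a planar point mass; no 3-D robot dynamics, actuator
  saturation, or arm-weight-support mechanics.
- The EEG generator is statistical, not biophysical: no dipole forward
  model, no artifacts by default, a single fixed alpha topography shared
  by all participants.
- GFP/GMD one-sample grid cells are positively biased by construction (see
  above); between-group cells are unbiased and are the informative ones
  under this generator.
- Mixed-model fitting and multiple-comparison correction across the grid
  are out of scope; the behavior table is the hand-off point.
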