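# Methods

This note documents the models, numerical choices, and limitations behind
`odorcontrast`. Units are seconds, Hz, centimetres, and % ΔF/F throughout.

## Odor pulses and arena concentration

A valve-controlled pulse is modelled as a first-order rise toward the
PID plateau `peak` with time constant `rise_tau_s` (default 0.05 s)
during the pulse, and a first-order decay with `decay_tau_s` (default
0.1 s) after valve closure; the trace is zero before onset.

Inside the closed 10 cm arena the waveform a fly experiences depends on
its distance from the odor port. `arena_pid` rescales the pulse through a
distance profile `(peak_scale, tau_scale)`. The default profile is

- `peak_scale(d) = exp(−d/4 cm)` — smooth attenuation with distance;
- `tau_scale(d) = 1 + 9 / (1 + exp(−(d − 3.5)/0.35))` — a logistic step
  that leaves the decay plume-like (τ ≈ 0.1 s) within ~3 cm of the port
  and stretches it about tenfold beyond 3–4 cm.

The logistic step encodes the qualitative observation that the decay
time rises steeply beyond 3–4 cm from the port; its exact steepness and
plateau are not constrained by data and were fixed once at values that
preserve monotonicity of both peak and τ.

## OSN rate model

`osn_rate` integrates, on the stimulus grid,

r(t) = max(0, r_spont + gain·a(t)·c(t) + S(t) − I(t))

- **Adaptation** `a(t)` relaxes from 1 toward `1 − adapt_depth`
  (default depth 0.5) with `adapt_tau_s = 0.35 s` while the stimulus is
  on, and recovers toward 1 when it is off. The discrete update is the
  exact exponential step, so constant-stimulus segments match the
  closed-form solution to machine precision.
- **Sustained activity** `S(t)` charges instantaneously to
  `sustain_gain·(c − sustain_threshold)` while the concentration exceeds
  the threshold and decays with `sustain_decay_s = 2.5 s` afterwards.
  The threshold (0.5 PID units) sits between the default "1:25" (0.3)
  and "1:5" (0.8) stimulus amplitudes: only high-intensity pulses
  produce postpulse firing above the spontaneous rate. Whether sustained
  peripheral activity reflects lingering odor or intracellular cascades
  is unresolved; the threshold-gated slow component is an explicit
  modelling assumption.
- **Poststimulus inhibition** `I(t)` is triggered once at stimulus
  offset (concentration falling below 5% of its running maximum), only
  when no sustained component was charged, with depth 6 Hz and decay
  0.8 s. This reproduces the sub-threshold regime in which postpulse
  firing dips below the spontaneous rate.

Defaults (`r_spont` 8 Hz, `gain` 150 Hz per PID unit) put peak evoked
rates near 120 Hz, in the range typical of fruit-fly OSN responses.

## Presynaptic inhibition

The inhibition model is phenomenological: the rate is convolved with two
unit-area causal exponential kernels — fast (`gA_tau_s = 0.08 s`,
ionotropic-like) and slow (`gB_tau_s = 1.2 s`, metabotropic-like) — and
the weighted sum is subtracted, clamping at zero:

out = max(0, r − gA_w·(k_A∗r) − gB_w·(k_B∗r))

The slow kernel keeps subtracting after the pulse, which is what
truncates sustained activity and raises `sharpness_offset`; the fast
kernel mainly reduces the in-pulse amplitude. Each kernel can be toggled
to emulate pharmacology or cell-specific receptor knockdown; disabling
both raises the response peak and abolishes the extra sharpening, and
the joint effect on sharpness exceeds either kernel alone.

Default weights are `gA_w = 0.2`, `gB_w = 0.35`. They were chosen so the
standard sustained fixture stays in the non-saturating regime: with
substantially heavier weights the zero clamp pins the postpulse rate at
0 and `sharpness_offset` saturates at exactly 1 for both the slow-alone
and joint conditions, a degenerate tie that would mask the joint-versus-
single ordering the model exists to express. At the highest stimulus
intensities the inhibition capacity saturates in the same way, which is
the model's rendering of sharpening being achievable only up to a
certain odor intensity.

## Spikes and extracellular voltage

`sample_spikes` draws an inhomogeneous Poisson train by thinning a
homogeneous candidate stream at the rate ceiling, with an absolute
refractory period (default 2 ms) enforced by discarding candidates too
close to the last accepted spike. For refractory ≪ 1/rate the expected
count equals ∫r dt (verified by a 500-replicate Monte-Carlo test).

`render_extracellular` places a fixed biphasic template (~2 ms support,
sine lobe shape, extremum aligned to the spike time) scaled by a
per-unit amplitude (default ratio A:B = 2:1) and adds white Gaussian
noise at 10 kHz.

Detection thresholds at `k·MAD/0.6745` (k = 5) of the band-passed trace
(300–2000 Hz, zero-phase Butterworth). Spike times snap to the local
absolute extremum within ±1 ms of each crossing. Refractory suppression
keeps the **largest** candidate in each 2 ms conflict window: zero-phase
filtering pre-rings, so the earliest crossing of a large spike can sit
on a side lobe just before the true peak, and earliest-first suppression
would discard the peak itself.

Unit sorting is one-dimensional 2-means on absolute amplitude with
deterministic quantile initialization (25th/75th percentile), so the
result is independent of event order; the larger-amplitude cluster is
labelled "A". A caveat on the sortability bound: when the two amplitude
classes are exactly 4 noise-SD apart and the amplitude jitter equals the
noise SD, the Bayes-optimal boundary already misassigns ≈2.3% of events,
so ≥99% accuracy is only achievable at somewhat larger separations
(≥ ~5σ); the test suite uses 6σ and a rendered fixture at 10σ.

Rate estimation uses a centered sliding rectangular window (default
100 ms window, 8 ms step; Gaussian kernel optional). The peak of a
single windowed estimate is an upward-biased order statistic, so
recovery tests compare the across-trial mean profile.

## Fluorescence rendering and trace processing

`render_arclight` maps a normalized drive x(t) through an optional
soft-saturating nonlinearity `sat_level·tanh(x/sat_level)` and onto a
two-exponential-plus-offset bleaching baseline:
`F = b(t)·(1 + scale·sat(x))`. The default `scale = −0.05`: the voltage
indicator dims on depolarization, so raw responses point downward and
processed ΔF/F is sign-inverted on load (`invert=True`), a pure display
convention. `render_gcamp` first convolves the rate with a
double-exponential calcium kernel (rise 0.05 s, decay 1 s by default),
which is why calcium responses are far more sustained than the
underlying electrical activity.

Processing follows standard imaging practice: least-squares
two-exponential-plus-offset bleach fit with multi-start over tau decades
(amplitudes and offset solved linearly for each tau pair — variable
projection — then a bounded nonlinear refinement); detrending by
division (default; subtraction available) — division is consistent with
multiplicative bleach and ΔF/F; eight rounds of box-car smoothing
(default width 3 samples = 24 ms at 125 Hz, preserving ~100 ms response
features) with reflection padding to avoid endpoint droop; then
`100·(F − F0)/F0` with F0 from a pre-stimulus baseline window.

By default the bleach fit excludes the stimulus/response window
(onset − 0.2 s to offset + 4 s) so responses do not bias the baseline;
fitting the full trace is available. Note that because the drive
includes spontaneous firing, the fluorescence baseline already carries
`scale·x_spont`, and recovered ΔF/F peaks are measured relative to that
baseline, slightly below `100·|scale|`. Single-exponential inputs are
represented degenerately (one amplitude near zero, or both taus
coinciding); either form reproduces the baseline.

## Tracking and kinematics

Tracking is a constant-velocity Kalman filter (state x, y, vx, vy;
discrete white-noise-acceleration process covariance) with greedy
nearest-neighbor assignment within a gate (ties to the lower track id;
Hungarian assignment available). Track birth requires 3 consecutive
supporting detections; a track coasts through up to `max_missed = 2`
missed frames on its prediction before terminating. Reported `xy` are
the assigned detections (predictions on coasted frames), so clean input
is recovered exactly; `xy_filtered` carries the Kalman estimates used
for the static-target noise-reduction test.

Kinematics follow the study conventions: Δd_t = d_0 − d_t (positive =
toward the port); the 10 s-pulse timecourse samples mean distance every
15 frames (0.5 s) over 35 s → 70 bins; 1 s-pulse analyses track
individual flies at 30 fps, stratify by initial distance (≤ 3 cm vs
> 3 cm; 4 cm bins available for position-resolved analyses), and report
signed radial velocity (d(t1) − d(t0))/(t1 − t0), positive away from the
port — radial displacement, not path speed (path speed is exposed as an
option).

## Fly behavior generator

Each fly takes diffusive-heading steps (base speed 1 cm/s, heading
diffusion 2 rad²/s — a walking fly's speed scale) plus a radial drift
`drift_gain(c)` toward or away from the port, evaluated on the local
arena concentration sensed `sensing_latency_s = 0.1 s` earlier. An
engaged drift persists `persistence_s` after the local concentration
declines (peak-hold with timed expiry), which is what produces postpulse
avoidance that outlasts a brief pulse near the port. The boundary is
reflective. Saturating drives are provided:
attraction `+g·c/(c + c_mid)` and avoidance `−g·c/(c + c_mid)` with
g = 0.8/1.2 cm/s and `c_mid = 0.05/0.15`. The attraction midpoint was
calibrated once so that the low-intensity regime produces net
displacement clearly above motility noise at arena concentrations
(~2 cm toward the port over a 10 s pulse for 40 flies), as the
attraction condition requires; it was not revisited afterwards.

Simulated detections can be degraded (dropout probability, position
noise) for tracker testing.

## Scenario defaults and problem sizes

The dilution series maps labels 1:125, 1:25, 1:5, 1:1 to PID peaks 0.08,
0.3, 0.8, 1.5 — weak stimuli below, strong stimuli above the sustained-
activity threshold, with only the strongest driving saturation-range
inhibition. Genotypes toggle the inhibition kernels (`gA_off`, `gB_off`,
`both_off`); behavior scenarios additionally scale avoidance gain and
persistence per genotype. Physiology runs use 8 s recordings at 125 Hz;
behavior runs use 30–50 flies (default 40) in the 10 cm arena at 30 fps,
10 s pulses for net-displacement readouts and 1 s pulses for postpulse
kinetics. Monte-Carlo checks use 500 replicates for spike-count
conservation and 6–10 seeds × 40 flies for behavioral orderings; these
sizes give standard errors comfortably below the tested effects while
keeping the full suite fast.

## What the synthetic data does and does not show

The generator reproduces the statistical *structure* the analysis
assumes — bleach baselines, saturating indicator responses, two
amplitude classes of spikes, threshold-gated sustained firing,
concentration-dependent drift — with known ground truth, so tests
demonstrate that each estimator recovers what it claims to recover and
that the qualitative orderings (sharpness vs. intensity, joint-blockade
effects, attraction/avoidance) follow from the modelled mechanisms. It
does not emulate motion artifacts, focal drift, correlated pixel noise,
overlapping spike waveforms, fly–fly interactions, or true plume
turbulence; passing tests therefore validate the analysis chain, not
any biological claim about real recordings.

## Known limitations

- The inhibition and behavior models are deliberately minimal
  (linear kernels, peak-hold persistence); they are fixtures for the
  statistics, not biophysical models.
- `fit_bleach` extrapolates through the excluded response window; with
  short recordings relative to the slow tau the extrapolated baseline
  (and hence absolute ΔF/F) carries percent-level error, though
  sharpness coefficients, being ratios, are insensitive to it.
- The tracker's greedy assignment can swap identities when flies
  approach within the gate; the Hungarian option mitigates but cannot
  eliminate this.
- `decay_time` defines the peak as the first maximal sample; on
  plateaued traces whose rise saturates numerically the "peak time" is
  the plateau start, so the statistic is intended for decaying stimulus
  traces, its defined domain.
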