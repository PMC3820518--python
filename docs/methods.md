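# Methods

`mmnsim` simulates the auditory mismatch negativity (MMN) as the scalp
signature of precision-weighted prediction errors in a listener who inverts
a generative model of tones online.  This note documents the model, its
parameters, the numerical choices, and what the simulations do and do not
show.

## The generative model of a tone

A single trial is described by a three-level hierarchical dynamic model
(HDM).  Writing `v = (v_l, v_nu)` for the hidden causes (loudness envelope
and target log-frequency) and `x = (x_l, x_l', x_nu)` for the hidden states:

- **Sensory level (A1).**  The observation is a 50-channel spectrogram.
  Channel `i` has a Gaussian tuning curve in natural-log frequency,

      g_i(x) = x_l * exp(-(x_nu - nu_i)^2 / (2 w^2)),

  with preferred frequencies `nu_i` equally spaced over ±4 tuning widths
  around the standard tone and tuning width `w = 0.15` log-units.  The
  loudness readout is the first loudness state, `l(x) = x_l`, isolated in
  `AuditoryHDM.loudness_readout` so that alternatives (softplus,
  exponential) are one-line swaps.  The width was chosen so that the
  largest simulated deviant (32%, 0.278 log-units ≈ 1.9 tuning widths,
  ≈ 11 channels) moves the spectral peak by several channels while keeping
  enough tuning overlap for gradient-based inference to find it; the span
  then follows from the ±4 width rule.

- **Dynamics (Heschl's gyrus).**  The instantaneous log-frequency relaxes
  towards the target at rate `kappa`:  `dx_nu/dt = kappa (v_nu - x_nu)`,
  with `kappa = 12.7` per native time unit so that a step change reaches
  95% within one third of the stimulus duration.  The loudness pair follows
  a canonical damped oscillator

      d(x_l, x_l')/dt = [[0, 1], [-omega^2, -2 zeta omega]] (x_l, x_l')
                         + (0, omega^2) v_l,

  with `omega = 8`, `zeta = 0.6`: complex eigenvalues (-4.8 ± 6.4i), i.e. a
  decaying spiral with unit DC gain so `x_l` tracks the envelope; the
  impulse response falls below 1% of its peak within 1.0 native time units.

- **Causes (inferior frontal gyrus).**  The loudness cause is a Gaussian
  bump (peak at native time 1.0, SD 0.3, amplitude 1).  The target
  log-frequency is constant within a trial; its prior mean is the expected
  tone and its prior precision encodes the oddball context (below).

All noise streams are smooth (analytic): white Gaussian noise convolved with
a Gaussian kernel such that the autocorrelation falls to `exp(-1/2)` at a
lag equal to the smoothness parameter (0.04 native units, shared by
generation and recognition).  Marginal variance is the reciprocal of the
stream's precision.

## Stimulus generation (the synthetic-data generator)

Each trial draws the true target log-frequency from a Normal centred on
`log(standard)` (standard trials) or `log(standard * (1 + magnitude))`
(deviant trials) with SD `sigma_draw = 0.002` log-units — trial-to-trial
jitter small enough that standard and deviant distributions do not overlap
even at 2% deviance (10 sigma separation).  The HDM is then integrated
forward (Euler, 256 steps over 4 native time units) with generation-side
log-precisions of 16 on every stream, i.e. nearly deterministic stimuli.
The generator returns the spectrogram and the ground-truth trajectories.

What it emulates: single oddball trials of loudness-modulated pure tones
with a fixed envelope.  What it does not: multi-tone streams, trial-history
effects (each trial's context enters only through the prior precision),
cochlear/subcortical transduction, and realistic EEG background noise.
Passing tests therefore show that the *inference-to-ERP chain* behaves as
designed, not that the model fits any particular empirical dataset.

## Recognition: generalized filtering

The listener inverts the same HDM, with two differences: epistemic
(lower) precisions — log-precision 4 for sensory channels and state motion,
2 for the loudness cause — and a prior on the target frequency centred on
the *expected* tone with precision

    pi(p) = pi_floor + pi_scale * (-ln p),        pi_floor = 1, pi_scale = 32,

a monotone decreasing, continuous map from deviant probability `p`: rarer
deviants mean more confident predictions.  The floor keeps the prior proper
as `p -> 1`; the scale sets how strongly rarity amplifies the cause-level
prediction error (and hence the MMN's probability effect).

Posterior expectations evolve in generalized coordinates of motion (value
plus temporal derivatives): embedding order 4 for states and data, 2 for
causes — standard practice; higher orders add cost without changing
qualitative behaviour.  Sampled spectrograms are lifted into generalized
coordinates by local least-squares Taylor embedding (exact for polynomials
below the embedding order).  Precisions acquire the Kronecker structure
`inv(V) ⊗ Pi`, where `V` is the derivative covariance implied by the
Gaussian autocorrelation of the noise.

The update is a gradient flow on the sum of squared precision-weighted
errors plus the prior-prediction term `D mu~` (`D` = shift operator), with
three error streams: sensory (A1), state motion (Heschl), causes (IFG).
Integration is by local linearization — matrix exponential of the
Gauss-Newton Jacobian over one sample step — which remains stable at the
stiff flows implied by large precisions; an explicit Euler micro-step is the
fallback if the local system is numerically singular.  A `gradient_rate` of
0.15 scales the descent: it slows evidence accumulation to a biologically
sensible tempo (errors are resolved over tens of milliseconds of warped
time rather than instantaneously) without moving the flow's fixed points,
which is what the analytic posterior checks constrain.  Beliefs whose norm
exceeds 1e6 raise an explicit divergence error.

Conditional covariances are not propagated: only expectations and
precision-weighted errors are exposed, because only the errors feed the ERP
model.

## From prediction errors to the scalp

The value-order precision-weighted errors are the modelled error-unit
activities: 50 sensory units (A1), 3 state-motion units (Heschl's gyrus),
2 cause units (IFG).  The forward map has four stages:

1. **Time warp.**  Affine: native time is scaled so the stimulus lasts
   70 ms and shifted so its onset lands at the 10 ms conduction delay.
   "Stimulus duration" is the full width at half maximum of the loudness
   bump (FWHM = 2.355 SD, so the warped bump has SD ≈ 30 ms and peaks
   ≈ 70 ms post-onset).  The conduction delay trades off exactly against
   latency, so it is recorded alongside all latency outputs.
2. **Sigmoid activation.**  Each unit's signed error passes through a unit-
   amplitude logistic `s(lambda xi)` — firing is nonnegative and saturates —
   and units within a source sum into a local field potential.  Sigmoid
   amplitude is fixed at 1; the lead field carries all scale (resolving the
   amplitude degeneracy).  Per-unit sigmoid before summation treats each
   error unit as a neuronal population generating its own field.
3. **Lead field.**  Scalp potential = `sum_i w_i LFP_i + offset`.  Defaults:
   slopes (0.07, 0.05, 0.15) and lead field (-8, -4, -8) µV for (A1,
   Heschl, IFG).  These play the role of the subject-specific biophysical
   parameters that would be estimated from data; the defaults were chosen,
   once, so that the simulated MMN is a negative deflection of a few µV
   with IFG (cause-level) errors weighted most strongly and enough sigmoid
   saturation that the sustained cause error stops deepening at large
   deviance while the early sensory transient keeps growing — the regime in
   which the magnitude-latency effect expresses itself.
4. **Data processing.**  Linear-interpolation resampling to 200 Hz, then a
   single-pass 3rd-order Butterworth low-pass at 40 Hz initialized at the
   DC steady state (so constants pass with unit gain; the small group delay
   of the causal filter is accepted because latency is measured on the
   unfiltered waveform).  Both filtered and unfiltered 200 Hz waveforms are
   kept.  Simulated ERPs are baseline-corrected by the pre-stimulus mean so
   the offset does not leak into metrics; the fitting module works on
   uncorrected waveforms so the offset stays identifiable.

## MMN estimators

The MMN is the deviant-minus-standard difference wave.  Latency is the
fractional-area estimate on the *unfiltered* wave: find the trough minimum,
bound the window by the first and last crossings of half the trough depth
(linearly interpolated; "half the MMN amplitude" is read as half the most
negative value, the only self-contained definition available before the
amplitude estimator runs), rectify to the negative part, and return the
time splitting the trapezoidal area in two.  Amplitude is the mean of the
*filtered* wave within ±10 ms of that latency.  A wave with no negative
deflection raises an explicit no-MMN-detected error.

## Experiments

Each condition runs two simulations on independently sampled stimuli of the
same tone B: expected-A/presented-B (deviant) and expected-B/presented-B
(standard); the same precision rule applies to both priors (one precision
per condition).  With deviance magnitude 0 the two runs differ only in
their noise and jitter draws; the resulting |MMN| stays below 0.25 µV (the
documented null threshold, about five times the typical null peak and
below the smallest deviant response simulated).

The default sweep crosses magnitudes {2, 4, 12.7, 27, 32}% with deviant
probabilities {0.4, 0.3, 0.2, 0.1, 0.05} at a 1000 Hz standard, three seeds
per cell (≈ 20 s on one CPU).  On the condition means it reproduces the
qualitative oddball phenomenology:

- |peak MMN| increases strictly with deviance magnitude (at p = 0.05) —
  larger mismatch, larger errors;
- |peak MMN| increases strictly as deviants get rarer (at 12.7%) — higher
  prior precision multiplies the cause-level error;
- latency is much shorter at 32% than at 12.7% (≈ 59 ms difference):
  at large magnitude the early, quickly-resolved sensory transient comes to
  dominate the sustained cause error, so an early trough emerges;
- deviant probability barely moves latency at magnitudes ≤ 12.7% (spread
  ≈ 7 ms): precision scales the transient and sustained components together,
  and the fractional-area latency is invariant under uniform rescaling;
- the probability effect on amplitude grows with magnitude (precision and
  prediction error interact multiplicatively through the sigmoid).

In this parameterization the MMN trough sits earlier (≈ 85 ms latency at
12.7%) than typical empirical MMNs (~100-250 ms); absolute timing depends
on the observation parameters, which here are package defaults rather than
values fitted to empirical recordings.  The latency transition between
12.7% and 32% is sharp rather than gradual: the fractional-area window
jumps once the early trough outweighs the sustained one — a known
limitation of this model class.

## Parameter estimation

`fit_observation_params` estimates slopes, lead field and offset from
target standard/deviant waveforms given the error trajectories.  The scalp
model is linear in lead field and offset once the slopes are fixed, so the
fit uses variable projection: bounded linear least squares inside, and
multi-start (default 20 seeded starts, log-uniform in slope) bounded
nonlinear least squares over the three log-slopes outside.  Bounds: slopes
in [1e-3, 1e3] (keeps the logistic off pure-saturation plateaus where
gradients vanish), lead field and offset in ±100 µV.  Because slope and
lead-field weight trade off in the near-linear regime, results are also
reported as per-source gains `g_i = w_i lambda_i / 4`, and the condition
number of the full Gauss-Newton Hessian flags near-degenerate directions.
On noiseless synthetic targets the identifiable combinations (`w_i
lambda_i` products and the offset) are recovered to well under 1%; with
additive Gaussian noise the residual norm is chi-square consistent with the
injected noise.

Empirical ERP datasets are not bundled; the `fixtures` CLI command writes
synthetic targets produced by the package's own forward model, and the
`fit` command accepts user-supplied two-column (time_ms, voltage_uV) files.

## Problem sizes and defaults

Trials use 256 Euler steps over 4 native time units (≈ 30 samples per
envelope SD, native sampling ≈ 646 Hz after warping — comfortably above
the 400 Hz needed for the 200 Hz/40 Hz processing chain).  The default
sweep (25 conditions × 3 seeds × 2 trials) was sized to characterize the
phenomenology on condition means while staying cheap; single runs take
≈ 0.1 s.

## Known limitations

- Absolute MMN latency and amplitude depend on observation-parameter
  defaults, not on fits to empirical recordings.
- Trial history is summarized by one prior precision per condition; no
  learning across trials.
- The sigmoid's form (logistic) and per-unit aggregation are modelling
  choices; both are isolated behind `source_lfp`.
- A single electrode and a scalar lead field per source: no volume
  conduction or topography.
- The latency transition with deviance magnitude is abrupt (a window
  switch), not gradual.
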