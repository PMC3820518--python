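# mmnsim

Predictive-coding simulation of the auditory **mismatch negativity (MMN)** —
the negative event-related potential (ERP) deflection evoked when a rare
"deviant" tone violates the regularity established by repeated "standard"
tones.

The package is for computational neuroscientists who want to simulate
oddball experiments under the hypothesis that evoked responses reflect
precision-weighted prediction errors.  It provides, end to end:

1. **A hierarchical dynamic model (HDM) of tone generation** — a 50-channel
   tonotopic spectrogram (Gaussian tuning in log-frequency), driven by
   hidden loudness states (a damped oscillator) and an instantaneous
   frequency that relaxes towards a hidden target frequency at rate κ.
2. **Online Bayesian inversion by generalized filtering** (predictive
   coding): posterior expectations μ̃ over hidden states and causes evolve
   in generalized coordinates of motion by

       dμ̃/dt = Dμ̃ − ∂/∂μ̃ [ ½ Σ ε̃ᵀ Π̃ ε̃ ],

   a gradient flow on precision-weighted prediction errors ξ = Π̃ε̃ with
   three streams: sensory (primary auditory cortex), state motion (lateral
   Heschl's gyrus) and causes (inferior frontal gyrus).  The oddball
   context enters through the prior on the target frequency: its mean is
   the expected tone and its precision grows as deviants get rarer,
   π(p) = π₀ + s·(−ln p).
3. **An ERP forward model**: time warp (stimulus duration ↦ 70 ms, 10 ms
   conduction delay), per-unit logistic activation of the error units,
   linear lead-field superposition of the three source field potentials,
   then simulated data processing (200 Hz resampling, 3rd-order Butterworth
   low-pass at 40 Hz).
4. **MMN estimators**: the deviant-minus-standard difference wave, its
   50% fractional-area latency (on the unfiltered wave) and its mean
   amplitude in a ±10 ms window around that latency (on the filtered wave).
5. **Parameter fitting**: multi-start nonlinear least squares (with
   variable projection) for the sigmoid slopes, lead field and offset
   against target ERP waveforms.

See `docs/methods.md` for the model equations, parameter defaults and
limitations.

## Worked example

Simulate one oddball condition — a 1000 Hz standard with a 12.7% deviant
(1127 Hz) at deviant probability 0.05:

```sh
mmnsim simulate --standard-hz 1000 --magnitude 0.127 --probability 0.05 \
                --seed 1 --out-dir out/
```

which prints

```json
{
  "latency_ms": 85.4945616349923,
  "amplitude_uv": -2.619923598201204,
  "peak_uv": -2.7111375088828424,
  "conduction_shift_ms": 10.0
}
```

— the MMN difference wave has its fractional-area latency at ≈ 85 ms
post-stimulus-onset (reported alongside the 10 ms conduction delay it
includes), a mean amplitude of ≈ −2.6 µV in the ±10 ms window around that
latency, and a most-negative point of ≈ −2.7 µV.  The standard and deviant
ERPs and the filtered/unfiltered MMN waveforms are written to `out/` as
two-column text files (time_ms, voltage_uV), together with a JSON manifest
of the full configuration and seeds.

The same thing from Python:

```python
from mmnsim import OddballCondition, run_condition

res = run_condition(OddballCondition(1000.0, 0.127, 0.05), rng_seed=1)
print(res.latency_ms, res.amplitude_uv, res.peak_uv)
```

A full deviance-magnitude × deviant-probability sweep with the qualitative
contrasts (amplitude grows with magnitude and rarity; latency shortens with
magnitude but is insensitive to probability; the two factors interact):

```sh
mmnsim sweep --out-dir out/   # sweep.csv + summary.json
```

Fitting observation parameters to waveforms (synthetic targets can be
regenerated with `mmnsim fixtures`):

```sh
mmnsim fixtures --out-dir out/
mmnsim fit --standard out/synthetic_target_standard.tsv \
           --deviant out/synthetic_target_deviant.tsv --out-dir out/
```

Every model constant is a named key in a YAML config (`--config`); defaults
are documented in `docs/methods.md`.

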