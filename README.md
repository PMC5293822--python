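# limbdecode

Decoding lower-limb muscle activity and ankle kinematics from
motor-cortical spike trains during visually cued stand/squat behaviour.

Brain–machine interfaces for the lower limb need two things that this
package implements end to end: a way to find *where* in the leg area of
the primary motor cortex (M1) the muscle-related neurons cluster, and
decoders that reconstruct muscle activation and limb trajectory from the
spiking of those neurons. It is aimed at neural-engineering researchers
who want a tested, reproducible reference implementation of this analysis
chain — together with a synthetic-session generator that makes every stage
verifiable against ground truth without any animal data.

## What it computes

**Neuron–muscle association (SpTA).** For each (unit, muscle) pair the
spike-triggered average of the full-wave-rectified EMG is taken over a
window from 20 ms before to 60 ms after each spike. With baseline mean μ
and SD σ from the [−20, −10) ms pre-spike segment, a pair shows post-spike
facilitation when the SpTA crosses μ + 2σ at an onset latency in
[5, 15] ms with a peak width at half magnitude in [0.75, 9] ms. Accepted
units are mapped as identified/recorded densities on a 0.4 mm stereotaxic
grid, and the per-muscle maps are compared by hierarchical clustering of
their Euclidean distances.

**State-space decoding.** With x_k the 8-vector of normalised EMG
envelopes (or the 3-vector of ankle z-position, velocity, acceleration)
and y_k the vector of spike counts in 30 ms bins:

    x_k = A x_{k−1} + w_k,   w_k ~ N(0, W)
    y_k = H x_k + q_k,       q_k ~ N(0, Q)        (Kalman filter)
    y_k = net(x_k) + q_k                          (ANN-observation UKF)

A, H are least-squares fits on training folds; W, Q are residual
covariances; `net` is a single-hidden-layer sigmoid network trained by
back-propagation. The Kalman filter runs the classic predict/update
recursion with gain K = P⁻Hᵀ(HP⁻Hᵀ + Q)⁻¹; the unscented Kalman filter
propagates 2d+1 sigma points X_i = x̂⁻ ± √(d+λ)[√P⁻]_i through `net` and
updates with K = P_xy P_yy⁻¹, P₀ = I.

**Evaluation.** Per channel, Pearson's CC and SNR(dB) =
10·log₁₀(Σ(x−x̄)²/Σ(x̂−x)²) under 4-fold cross-validation over contiguous
trial blocks, plus a paired one-sided t-test of the UKF−KF differences and
convergence diagnostics on the spectral norms of P_k and K_k.

**Synthetic sessions.** `limbdecode.synth` generates the full recording a
session would produce — trial event sequences (0.4 s holds, 5–10 s
inter-trial intervals), logistic stand/squat z-trajectories at 15 ms,
phase-locked 8-channel EMG at 1 kHz, Poisson spike trains from a
saturating (logistic) tuning of the behavioural state, spatially clustered
unit coordinates, and optional spike-locked EMG transients as ground truth
for the SpTA stage. See `docs/methods.md` for every model and default.

## Worked example

```python
import limbdecode as ld

# one synthetic dataset: 12 stand/squat trials, 24 cortical units
session = ld.make_session(ld.SessionConfig(n_trials=12, n_units=24), seed=101)

# cross-validated EMG decoding with both filters
table = ld.cross_validate(session, ld.DecoderConfig(target="emg"), seed=1)
print(table.groupby("decoder")[["CC", "SNR"]].mean().round(3))

# paired comparison over the matched (fold, channel) observations
print(ld.compare_decoders(table, metric="CC"))
```

Output:

```
            CC    SNR
decoder
kf       0.921  6.789
ukf      0.933  8.851
{'n': 32, 't': 5.240952155767624, 'p': 5.381209428629662e-06,
 'mean_diff': 0.011453167133528504, 'metric': 'CC',
 'alpha': 0.05, 'significant': True}
```

The mean correlation between the true and reconstructed EMG envelopes is
0.92 for the Kalman filter and 0.93 for the ANN-UKF; the paired one-sided
t-test over the 32 matched (fold, channel) observations shows the UKF's
improvement is systematic (p < 1e−5), the qualitative signature of a
nonlinear neural tuning that a linear observation model cannot capture.

The same stages are available from the shell:

```bash
limbdecode simulate --seed 1 --out runs/data --n-trials 12 --n-units 24
limbdecode spta     --in runs/data --dataset ds00 --out runs/spta
limbdecode decode   --in runs/data --dataset ds00 --decoder both --out runs/dec
limbdecode run-all  --config config.yaml          # full pipeline + manifest
```

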