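# Methods

`limbdecode` implements a complete analysis chain for decoding lower-limb
muscle activity (EMG envelopes) and ankle kinematics from motor-cortical
spike trains recorded while a monkey performs visually cued stand/squat
trials, together with a synthetic-session generator that provides ground
truth for every stage. This note documents the models, the parameter
choices that matter, and the known limits of what the synthetic tests can
show.

## 1. Synthetic sessions

### Behavioural model

A trial is the event sequence CenterOn → CenterHit → TargetOn →
CenterRelease → TargetHit → TargetRelease → CenterHitAgain. The standing
hold (TargetHit → TargetRelease) is Gaussian around 0.4 s (SD 0.05 s,
truncated at 0.1 s) and inter-trial intervals are uniform on [5, 10] s.
The remaining phase durations are properties of the task apparatus that no
published source fixes; the defaults (squat-to-centre 0.8 s, cue delay
0.5 s, reaction 0.5 s, rise/fall 0.7 s, ±15% multiplicative jitter) were
chosen once as plausible for a trained macaque and are configurable. A
default *study* is 13 datasets of 40 ± 5 trials with 34 units each,
mirroring a two-week chronic recording campaign.

### Kinematics

The ankle-marker z-position is a sum of logistic ramps: up between
CenterRelease and TargetHit, down between TargetRelease and CenterHitAgain,
with time constant `duration/10` so the trajectory plateaus during the
hold. Velocity and acceleration are the generator's analytic derivatives,
sampled at the tracker interval of 15 ms; the preprocessing stage
independently recomputes difference-based estimates from z alone, so the
two routes can be compared. Only the z axis moves; x/y are not modelled.

### EMG

Each of the 8 right-leg channels (RS, RTA, RST, RRF, REDL, RFDL, RMG,
RFHL) is a white Gaussian carrier amplitude-modulated at 1 kHz by a
per-muscle activation envelope plus additive sensor noise. Activations are
a baseline plus, per trial, a pre-movement ramp (TargetOn → CenterRelease),
Gaussian bursts centred in the rise and fall phases, and a smoothed tonic
term through the hold; the per-muscle phase weights encode crude
physiology (anti-gravity extensors load the rise/hold, dorsiflexors and
toe extensors the descent). The envelope of |EMG| therefore tracks the
activation, which is exactly what the decoders are asked to reconstruct.

What this does *not* emulate: motor-unit structure, signal
cross-correlation between muscles beyond shared phase timing, electrode
artefacts, or fatigue/drift. Passing decoding tests on this generator
shows the estimators work when their statistical assumptions hold
approximately; it cannot certify performance on real intramuscular
recordings.

### Spike trains and tuning

The drive state for unit firing is the 9-vector of the 8 binned muscle
activations plus normalised z. Unit `c` fires at

    rate_c(x) = baseline + scale · f(offset_c + g_c · x)   [Hz]

with `f` the logistic sigmoid by default. Defaults: baseline 3 Hz, scale
50 Hz, offsets N(−3, 0.7), own-group gains N(6, 1), cross-gains N(0, 0.6).
At rest a unit fires ~5 Hz; at full drive it saturates towards ~50 Hz —
the classic sigmoidal recruitment of task-related M1 units, and
deliberately *saturating at both ends*. A softplus option exists, but in a
softplus parameterisation strong enough to produce realistic rates the
observable tuning is close to linear over the state's operating range, and
sessions generated that way are nearly optimally decoded by a plain linear
filter (cross-validated CC ≈ 0.96), which defeats the generator's purpose
of emulating recordings in which a nonlinear observation model
demonstrably helps. Under the logistic default the linear-filter CC is
≈ 0.92, in the range reported for comparable real recordings, with a
consistent margin left for the nonlinear decoder.

Counts per 30 ms bin are Poisson around `rate·Δt` (a Gaussian option
serves linear-Gaussian oracle tests); timestamps are uniform within their
bin, so binning the emitted spikes reproduces the drawn counts exactly.
Each unit belongs to one of four anatomically motivated muscle groups
(RRF+RMG, RFHL+RFDL, RTA+REDL, RS+RST) and its stereotaxic coordinates
(PA 8–22 mm, DL 0–16 mm, depth 0–5 mm) are drawn from a per-group Gaussian
cluster (SD 1.2 mm), so the group structure is recoverable from density
maps.

### Post-spike facilitation

For SpTA testing, half-sine transients (caller-chosen latency, width,
amplitude) are added to a muscle channel at `spike + latency`. The
`grouped` mode wires every unit to the two muscles of its own group with
latencies in [6, 12] ms and widths in [2, 4] ms — inside the physiological
acceptance windows — at amplitude 30 (≈1.5× the baseline carrier SD).

## 2. Preprocessing

* EMG envelope: full-wave rectification then a 4-pole 10 Hz low-pass
  Butterworth. The filter is causal (forward-only) by default — the
  conservative reading when no phase convention is stated — with a
  zero-phase option; the filter state is initialised at the signal's first
  value to suppress the onset transient. Negative excursions from filter
  ringing are below 1% of the signal maximum (tested).
* Spike counts: consecutive non-overlapping 30 ms bins, half-open
  `[start, end)`; a spike exactly on a boundary belongs to the later bin.
* Kinematics: v and a are successive differences of z divided by the 15 ms
  sampling step so they carry physical units (mm/s, mm/s²); a
  `raw_differences` flag reproduces plain undivided differences. First
  samples are zero-padded.
* Resampling to the bin grid: EMG envelopes are averaged within each bin;
  15 ms kinematics are linearly interpolated at bin centres (decimation
  would be equally defensible; interpolation was chosen and is flagged).
* Normalisation: per-channel min–max to [0, 1] with statistics computed on
  the training folds only; the same affine map is applied to test folds
  (values may leave [0, 1]) and is stored invertibly. This ordering
  prevents train→test leakage.

## 3. Spike-triggered averaging and density mapping

The SpTA of a (unit, muscle) pair is the mean of rectified-EMG windows
from 20 ms before to 60 ms after each spike — 81 samples at 1 kHz,
endpoints inclusive. Windows that leave the record are skipped and
counted. Averages over fewer than 100 spikes (configurable) are flagged
insufficient and never accepted.

Baseline mean and SD come from the [−20, −10) ms segment (10 samples).
Onset is the first strictly post-spike crossing of baseline + 2 SD;
offset the first dip below baseline − 2 SD. Two numerical choices matter
and both are deliberate:

* **Sustained crossing.** A crossing must hold for 2 consecutive samples.
  The SpTA's own baseline statistics put a single sample above the 2 SD
  threshold ~4% of the time per sample, so a one-sample rule contaminates
  ~25% of genuine onsets with spurious earlier crossings and pushes the
  shuffle-null acceptance rate to ~7%. With the 2-sample rule the null
  rate is ~1% and injected 8 ms transients are recovered within ±1 ms.
* **PWHM as sample span.** The peak width at half magnitude is
  `(last − first) × 1 ms` over the contiguous region around the peak at or
  above baseline + peak/2, nearest sample, no interpolation. A
  single-sample noise peak then has width 0 ms and is rejected by the
  0.75 ms lower bound — that bound is what makes the half-magnitude
  criterion selective at 1 kHz.

A pair is accepted iff onset ∈ [5, 15] ms and PWHM ∈ [0.75, 9] ms.

Density maps bin accepted/recorded unit ratios on a 0.4 mm grid
(horizontal DL×PA or coronal DL×depth view), min–max normalise to [0, 1]
and keep a 3×3 median-filtered copy (zero-padded borders). Per-muscle maps
are compared by Euclidean distance between the vectorised grids under
average-linkage agglomerative clustering. Clustering uses the *unfiltered*
normalised maps by default: with hundreds of units per map the filtered
and unfiltered versions cluster identically, but at tens of units nearly
every occupied 0.4 mm cell is isolated and a 3×3 median filter maps the
whole grid to zero, collapsing all pairwise distances.

## 4. Decoders

State-space model: `x_k = A x_{k−1} + w_k`, `y_k = H x_k + q_k` with
x the 8-vector of normalised EMG envelopes or the 3-vector (z, v, a), and
y the C-vector of bin counts (raw counts; a z-scoring flag exists). A and
H are least-squares fits on training data (no intercept, matching the
model as written); W and Q are the empirical residual covariances.
Transition pairs spanning the gap left by a held-out fold are excluded
from the fit of A.

The Kalman filter is the standard predict/update recursion; the update
uses gain `K = P⁻Hᵀ(HP⁻Hᵀ + Q)⁻¹`. P is re-symmetrised every step
(asymmetry < 1e−10, tested).

The nonlinear observation model is a single-hidden-layer feed-forward
network (sigmoid hidden units, identity output) trained by full-batch
gradient-descent back-propagation on mean squared error. Defaults: 20
hidden units, learning rate 0.2, 2000 epochs, fan-in-scaled seeded uniform
initialisation, output thresholds initialised at the target means. The
learning rate acts on the gradient of the per-sample-mean loss, so
training is invariant to duplicating the training set. Plain gradient
descent at a timid rate (e.g. 0.01 for 500 epochs) leaves the network
above the linear regression baseline and the UKF then inherits a worse
observation model than the KF's; the defaults train past that baseline.
Training much longer begins to overfit the Poisson count noise, which
degrades the filter again — the default is chosen at the elbow.

The unscented Kalman filter keeps the linear state prediction (A, W) and
propagates 2d+1 sigma points through the network:
`X₀ = x̂⁻`, `X_i = x̂⁻ ± √(d+λ)·[√P⁻]_i` with the rows of the
upper-triangular Cholesky factor, `λ = α²(d+κ) − d`, and the single
weight set `w₀ = λ/(d+λ)`, `w_i = 1/(2(d+λ))` used for both mean and
covariance. Q is added to the predicted observation covariance only (it
is dimensionally impossible on the d×C cross-covariance). The update is
`x̂ = x̂⁻ + K(y − ŷ)`, `P = P⁻ − K P_yy Kᵀ`, `K = P_xy P_yy⁻¹`; P₀ is the
identity. Numerical policy: Cholesky with an escalating diagonal jitter
ladder (1e−9·I ×10 up to 1e−3) before failing; P re-symmetrised per step.

Defaults α = 1, κ = 0, so λ = 0 and every weight is positive, which
makes the sigma-point joint covariance positive semi-definite for *any*
observation map and hence the filter provably stable. The classic
heuristic κ = 3 − d coincides with this for the 3-dim kinematic state but
gives w₀ = −5/3 for the 8-dim EMG state, and with the single weight set a
negative centre weight drove P_yy indefinite under the trained network
(observed as Cholesky failures beyond the jitter ladder). Both parameters
remain configurable.

The filter runs continuously across the concatenated trials of a decoded
block (datasets are treated as sequences); a per-trial reset flag exists.

## 5. Evaluation

Per channel, CC is Pearson's correlation between the actual and decoded
series, and SNR(dB) = 10·log₁₀(Σ(x−x̄)² / Σ(x̂−x)²) — 0 dB for an
estimator pinned at the signal mean, +∞ sentinel for a perfect estimate.
CC is invariant to positive affine rescaling of the estimate; SNR is not
(both properties are tested).

Cross-validation is 4-fold over *contiguous* trial blocks (temporal
leakage across the train/test boundary is limited to a single transition),
3 blocks for fitting (models, network, normalisation), 1 for decoding.
Decoder comparison is a paired one-sided t-test of UKF − KF differences on
matched (dataset, fold, channel) keys at α = 0.05, CC and SNR tested
separately; pairing matches the matched-fold design.

Stability is diagnosed from the per-bin spectral norms of P_k and K_k:
stabilisation is the first bin from which the relative change stays below
1% (configurable) for 3 consecutive bins, with a −1 sentinel if never.
For the KF these norms are data-independent given the model, the sequence
settles in 13–24 bins at default session sizes, and the 30-bin bound is
asserted. The UKF's P_k is state-dependent (the sigma points see the
local curvature of the network), so after its transient decays (~20 bins)
a 1–3% plateau wiggle remains and the sustained-tolerance rule fires
anywhere between ~24 and ~80 bins depending on the data; the acceptance
suite therefore asserts sustained stabilisation and transient decay for
the UKF rather than the 30-bin bound.

## 6. Problem sizes used in the test suite

Unit tests run on datasets of 5–12 trials and 4–32 units; the decoder
comparison uses 10 sessions of 12 trials × 24 units; the density-map
recovery uses 10 sessions of 10 trials × 32 units; the convergence check
runs one default-size dataset (40 trials, 34 units). The design-arithmetic
check runs the full 13-dataset × 4-fold × 8-channel bookkeeping on small
datasets, since the observation count depends only on the design. These
sizes are the package's choice of desk-scale defaults; every generator
parameter scales up by configuration.

## 7. Known limitations

* The generator's nonlinearity strength, noise levels and phase-weight
  matrix are stylised; the decoder ranking they produce is a structural
  property (nonlinear observation model + recursive Gaussian filter), not
  a quantitative prediction for any particular animal.
* The ANN is trained by plain full-batch gradient descent for fidelity to
  the classic back-propagation description; no momentum, mini-batching or
  adaptive rates. It under-uses large training sets.
* Acceleration decoding is poor (as expected for a twice-differenced
  signal); nothing in the package attempts to fix that.
* The SpTA stage assumes stationary baseline statistics within the
  averaging window; slow co-modulation of firing and EMG (common drive)
  can bias real-data SpTAs in ways the white-carrier generator does not
  reproduce.
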