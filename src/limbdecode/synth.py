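"""Synthetic stand/squat sessions with known ground truth.

Emulates the statistical structure of a visually cued stand/squat recording
session in a rhesus monkey: trial event sequences, z-axis ankle kinematics,
phase-locked EMG of eight right-leg muscles, motor-cortical spike trains
generated from a nonlinear tuning of the behavioural state, and stereotaxically
clustered unit coordinates.  Every generator is a pure function of
(config, seed), so downstream stages (preprocessing, spike-triggered averaging,
state-space decoding) can be validated against exact ground truth.

The default configuration mirrors the chronic recording design: 13 datasets of
40 +/- 5 successful trials with ~34 task-related units each, inter-trial
intervals drawn uniformly from [5, 10] s and a standing hold of about 400 ms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "MUSCLES",
    "MUSCLE_GROUPS",
    "COORD_BOX",
    "SessionConfig",
    "TrialEvents",
    "KinematicsTrace",
    "EMGRecord",
    "SpikeTrainSet",
    "TuningModel",
    "FacilitationEffect",
    "FacilitationSpec",
    "SyntheticSession",
    "generate_trial_events",
    "generate_kinematics",
    "muscle_activations",
    "generate_emg",
    "default_tuning",
    "generate_spikes",
    "inject_facilitation",
    "grouped_facilitation_spec",
    "make_session",
    "generate_study",
    "save_session",
    "load_session",
]

#: Right-leg muscles carrying intramuscular EMG electrodes, in channel order:
#: soleus, tibialis anterior, semitendinosus, rectus femoris, extensor
#: digitorum longus, flexor digitorum longus, adductor magnus, flexor
#: hallucis longus.
MUSCLES = ("RS", "RTA", "RST", "RRF", "REDL", "RFDL", "RMG", "RFHL")

#: Anatomically motivated muscle groupings (thigh muscles; tibial-nerve leg
#: muscles; deep-fibular-nerve leg muscles; triceps-surae/hamstring group).
#: Units are assigned to one group and their cortical coordinates cluster
#: per group, so the group structure is recoverable from density maps.
MUSCLE_GROUPS = (
    ("RRF", "RMG"),
    ("RFHL", "RFDL"),
    ("RTA", "REDL"),
    ("RS", "RST"),
)

#: Explored stereotaxic region (mm): posterior-anterior, dorsal-lateral, depth.
COORD_BOX = {"PA": (8.0, 22.0), "DL": (0.0, 16.0), "depth": (0.0, 5.0)}

# Gaussian cluster centres (PA, DL, depth) for the four muscle groups, spread
# inside the explored box; SD 1.2 mm, samples clipped to the box.
_GROUP_CENTERS = np.array(
    [
        [12.0, 4.0, 1.5],
        [14.0, 9.0, 1.5],
        [17.0, 5.0, 2.0],
        [19.0, 11.0, 1.5],
    ]
)
_COORD_SD = 1.2


class ConfigError(ValueError):
    """Invalid generator configuration."""


class GenerationError(RuntimeError):
    """Inconsistent inputs to a generator (e.g. overlapping trials)."""


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class SessionConfig:
    """Parameters of one synthetic dataset.

    Temporal structure follows the behavioural task: squat to the centre
    target, wait for the go cue, stand to the upper target, hold ~0.4 s,
    squat back; 5-10 s inter-trial intervals.  Movement-phase durations are
    free parameters of the task apparatus and are set to plausible values.
    """

    n_trials: int = 40
    n_units: int = 34

    emg_fs: float = 1000.0        # Hz
    kin_dt: float = 0.015         # s, optical tracker sampling interval
    bin_dt: float = 0.030         # s, spike-count bin width

    # behavioural epochs (s)
    center_on_to_hit: float = 0.8
    hit_to_target_on: float = 0.5
    target_on_to_release: float = 0.5   # pre-movement / reaction epoch
    rise_duration: float = 0.7          # CenterRelease -> TargetHit (stand up)
    hold_mean: float = 0.4              # TargetHit -> TargetRelease
    hold_sd: float = 0.05
    fall_duration: float = 0.7          # TargetRelease -> CenterHitAgain
    reward_delay: float = 0.1
    iti_range: tuple[float, float] = (5.0, 10.0)
    duration_jitter: float = 0.15       # +/- fraction on movement durations
    lead_in: float = 1.0                # s of baseline before first CenterOn
    lead_out: float = 1.0               # s of baseline after last event

    # kinematics (mm)
    z_squat: float = 0.0
    z_stand: float = 120.0

    # EMG
    emg_gain: float = 100.0             # arbitrary voltage units
    emg_noise_floor: float = 0.08       # baseline modulation level
    emg_sensor_noise: float = 2.0       # additive white noise SD (same units)

    # tuning model
    tuning_nonlinearity: str = "logistic"   # or "softplus"
    rate_scale: float = 50.0            # Hz, modulation depth of the tuning
    baseline_rate: float = 3.0          # Hz, additive floor
    tuning_offset_mean: float = -3.0    # nonlinearity argument at rest
    tuning_offset_sd: float = 0.7
    group_gain_mean: float = 6.0        # gain on the unit's own-group drive
    group_gain_sd: float = 1.0
    cross_gain_sd: float = 0.6
    z_gain_sd: float = 0.5
    spike_noise: str = "poisson"        # "poisson" or "gaussian"
    gaussian_count_sd: float = 0.3

    def validate(self) -> None:
        if self.n_trials <= 0:
            raise ConfigError(f"n_trials must be positive, got {self.n_trials}")
        if self.n_units <= 0:
            raise ConfigError(f"n_units must be positive, got {self.n_units}")
        lo, hi = self.iti_range
        if not 0 < lo <= hi:
            raise ConfigError(f"invalid iti_range {self.iti_range}")
        if self.spike_noise not in ("poisson", "gaussian"):
            raise ConfigError(f"unknown spike_noise {self.spike_noise!r}")
        if self.tuning_nonlinearity not in ("logistic", "softplus"):
            raise ConfigError(
                f"unknown tuning_nonlinearity {self.tuning_nonlinearity!r}"
            )


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

_EVENT_NAMES = (
    "center_on",
    "center_hit",
    "target_on",
    "center_release",
    "target_hit",
    "target_release",
    "center_hit_again",
)


@dataclass
class TrialEvents:
    """Behavioural event times (s) of one successful trial.

    Events occur in the fixed order CenterOn < CenterHit < TargetOn <
    CenterRelease < TargetHit < TargetRelease < CenterHitAgain.
    """

    center_on: float
    center_hit: float
    target_on: float
    center_release: float
    target_hit: float
    target_release: float
    center_hit_again: float
    reward_delay: float
    iti: float                      # interval preceding this trial's CenterOn

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, n) for n in _EVENT_NAMES)

    def validate(self) -> None:
        t = self.as_tuple()
        if not all(a < b for a, b in zip(t, t[1:])):
            raise GenerationError(f"event times not strictly increasing: {t}")

    @property
    def hold(self) -> float:
        return self.target_release - self.target_hit


@dataclass
class KinematicsTrace:
    """z-axis ankle-marker kinematics sampled every 15 ms.

    ``v`` and ``a`` are the generator's analytic derivatives (ground truth);
    the preprocessing stage recomputes difference-based estimates from ``z``
    the way the tracker data were treated.
    """

    t: np.ndarray
    z: np.ndarray       # mm
    v: np.ndarray       # mm/s
    a: np.ndarray       # mm/s^2

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.z) == len(self.v) == len(self.a)):
            raise GenerationError("kinematics series lengths differ")


@dataclass
class EMGRecord:
    """Multi-channel EMG at 1 kHz, channels in :data:`MUSCLES` order."""

    fs: float
    channels: tuple[str, ...]
    values: np.ndarray          # (n_samples, n_channels)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channels):
            raise GenerationError("EMG values must be (n_samples, n_channels)")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.shape[0]) / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.values[:, self.channels.index(name)]
        except ValueError:
            raise KeyError(f"unknown EMG channel {name!r}") from None

    def copy(self) -> "EMGRecord":
        return EMGRecord(self.fs, self.channels, self.values.copy(), self.t0)


@dataclass
class SpikeTrainSet:
    """Sorted spike timestamps and stereotaxic coordinates per unit."""

    spike_times: list[np.ndarray]
    unit_ids: list[str]
    coords: np.ndarray              # (C, 3): PA, DL, depth in mm
    counts: np.ndarray | None = None     # (K, C) ground-truth binned counts
    bin_t0: float = 0.0
    bin_dt: float = 0.030

    @property
    def n_units(self) -> int:
        return len(self.spike_times)

    def validate(self) -> None:
        for uid, st in zip(self.unit_ids, self.spike_times):
            if np.any(np.diff(st) < 0):
                raise GenerationError(f"spike times of unit {uid} not sorted")


@dataclass
class TuningModel:
    """Ground-truth mapping from behavioural state to expected counts/bin.

    Expected firing rate of unit ``c`` is a linear map of the state pushed
    through a saturating nonlinearity plus a baseline:
    ``baseline_rate + rate_scale * f(offset_c + gains_c . x)`` (Hz), with
    ``f`` the logistic sigmoid by default — near-silent below threshold and
    saturating at high drive, the classic sigmoidal recruitment curve of
    task-related motor-cortical units — or a softplus ramp.  Rates are
    non-negative by construction and genuinely nonlinear in the state, so a
    nonlinear observation model has something real to capture.
    ``unit_groups`` assigns each unit to a muscle group used for cortical
    coordinate clustering.
    """

    gains: np.ndarray               # (C, d_state)
    offsets: np.ndarray             # (C,)
    rate_scale: float
    baseline_rate: float
    unit_groups: np.ndarray         # (C,) int, index into MUSCLE_GROUPS
    noise: str = "poisson"
    gaussian_count_sd: float = 0.3
    nonlinearity: str = "logistic"
    state_labels: tuple[str, ...] = ()

    @property
    def n_units(self) -> int:
        return self.gains.shape[0]

    def expected_rate(self, states: np.ndarray) -> np.ndarray:
        """Expected firing rate (Hz) for states of shape (K, d_state)."""
        arg = self.offsets + np.asarray(states) @ self.gains.T
        f = _logistic if self.nonlinearity == "logistic" else _softplus
        return self.baseline_rate + self.rate_scale * f(arg)

    def expected_count(self, states: np.ndarray, bin_dt: float = 0.030) -> np.ndarray:
        lam = self.expected_rate(states) * bin_dt
        if np.any(lam < 0):
            raise GenerationError("negative expected spike count")
        return lam


def _softplus(x: np.ndarray) -> np.ndarray:
    # numerically stable log(1 + exp(x))
    return np.logaddexp(0.0, x)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


@dataclass
class FacilitationEffect:
    """One spike-locked EMG transient: half-sine of the given width added at
    ``spike_time + latency_ms`` on one muscle channel."""

    unit_id: str
    muscle: str
    latency_ms: float
    amplitude: float
    width_ms: float


@dataclass
class FacilitationSpec:
    """Ground-truth post-spike facilitation effects for SpTA testing."""

    effects: list[FacilitationEffect] = field(default_factory=list)


@dataclass
class SyntheticSession:
    """One dataset: everything the analysis consumes plus its ground truth."""

    config: SessionConfig
    seed: int
    dataset_id: str
    events: list[TrialEvents]
    kinematics: KinematicsTrace
    emg: EMGRecord
    spikes: SpikeTrainSet
    tuning: TuningModel
    activations: np.ndarray         # (n_emg_samples, 8) ground-truth envelopes
    drive_states: np.ndarray        # (K, d_state) states the spikes were drawn from
    drive_t: np.ndarray             # (K,) bin start times of drive_states
    facilitation: FacilitationSpec | None = None

    @property
    def duration(self) -> float:
        return self.emg.values.shape[0] / self.emg.fs


# --------------------------------------------------------------------------
# event generation
# --------------------------------------------------------------------------

def generate_trial_events(config: SessionConfig, seed: int) -> list[TrialEvents]:
    """Draw the event sequence of ``config.n_trials`` successful trials.

    Inter-trial intervals are uniform on ``config.iti_range``; the standing
    hold is Gaussian around ``hold_mean`` (truncated at 0.1 s); movement-phase
    durations get multiplicative jitter.  Deterministic for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    trials: list[TrialEvents] = []
    t = config.lead_in
    for _ in range(config.n_trials):
        iti = 0.0 if not trials else rng.uniform(*config.iti_range)
        t += iti

        def jit(dur: float) -> float:
            lo, hi = 1 - config.duration_jitter, 1 + config.duration_jitter
            return dur * rng.uniform(lo, hi)

        center_on = t
        center_hit = center_on + jit(config.center_on_to_hit)
        target_on = center_hit + jit(config.hit_to_target_on)
        center_release = target_on + jit(config.target_on_to_release)
        target_hit = center_release + jit(config.rise_duration)
        hold = max(0.1, rng.normal(config.hold_mean, config.hold_sd))
        target_release = target_hit + hold
        center_hit_again = target_release + jit(config.fall_duration)
        ev = TrialEvents(
            center_on, center_hit, target_on, center_release, target_hit,
            target_release, center_hit_again, config.reward_delay, iti,
        )
        ev.validate()
        trials.append(ev)
        t = center_hit_again + config.reward_delay
    return trials


def _session_end(events: list[TrialEvents], config: SessionConfig) -> float:
    return events[-1].center_hit_again + config.reward_delay + config.lead_out


# --------------------------------------------------------------------------
# kinematics
# --------------------------------------------------------------------------

def _logistic_terms(t: np.ndarray, center: float, tau: float):
    """Logistic sigmoid and its first two analytic derivatives."""
    u = (t - center) / tau
    # clip to avoid overflow; tails are exactly 0/1 at this range
    s = 1.0 / (1.0 + np.exp(-np.clip(u, -60, 60)))
    ds = s * (1 - s) / tau
    d2s = s * (1 - s) * (1 - 2 * s) / tau**2
    return s, ds, d2s


def generate_kinematics(events: list[TrialEvents], config: SessionConfig) -> KinematicsTrace:
    """Analytic z-trajectory: logistic rise CenterRelease->TargetHit, plateau
    through the hold, logistic fall TargetRelease->CenterHitAgain.

    Velocity and acceleration are exact derivatives of the generator, so the
    difference-based estimates of the preprocessing stage can be checked
    against ground truth.
    """
    if not events:
        raise GenerationError("no trials")
    for prev, nxt in zip(events, events[1:]):
        if nxt.center_on <= prev.center_hit_again:
            raise GenerationError("overlapping trials")
    t_end = _session_end(events, config)
    t = np.arange(0.0, t_end, config.kin_dt)
    dz = config.z_stand - config.z_squat
    z = np.full_like(t, config.z_squat)
    v = np.zeros_like(t)
    a = np.zeros_like(t)
    for ev in events:
        for center, tau, sign in (
            ((ev.center_release + ev.target_hit) / 2,
             (ev.target_hit - ev.center_release) / 10, +1),
            ((ev.target_release + ev.center_hit_again) / 2,
             (ev.center_hit_again - ev.target_release) / 10, -1),
        ):
            s, ds, d2s = _logistic_terms(t, center, tau)
            z += sign * dz * s
            v += sign * dz * ds
            a += sign * dz * d2s
    return KinematicsTrace(t=t, z=z, v=v, a=a)


# --------------------------------------------------------------------------
# EMG
# --------------------------------------------------------------------------

# Per-muscle weighting of the four activation components: pre-movement ramp,
# stand-up burst, hold tonus, squat-down burst.  Extensors/anti-gravity
# muscles load the rise and hold, dorsiflexors/toe extensors the descent.
_PHASE_WEIGHTS = {
    #          pre   rise  hold  fall
    "RS":   (0.30, 0.90, 0.50, 0.30),
    "RTA":  (0.30, 0.20, 0.10, 0.90),
    "RST":  (0.20, 0.60, 0.20, 0.40),
    "RRF":  (0.35, 1.00, 0.60, 0.20),
    "REDL": (0.25, 0.15, 0.10, 0.80),
    "RFDL": (0.20, 0.50, 0.40, 0.25),
    "RMG":  (0.30, 0.80, 0.50, 0.25),
    "RFHL": (0.25, 0.60, 0.40, 0.30),
}


def muscle_activations(
    events: list[TrialEvents], config: SessionConfig, t: np.ndarray
) -> np.ndarray:
    """Ground-truth activation envelope of each muscle on time grid ``t``.

    Each channel is a baseline plus, per trial, a linear ramp across the
    pre-movement epoch (TargetOn -> CenterRelease), Gaussian bursts centred
    in the stand-up and squat-down phases, and a smooth tonic component
    through the standing hold.  Values are clipped to [0, 1].
    """
    act = np.full((len(t), len(MUSCLES)), config.emg_noise_floor)
    for ev in events:
        ramp = np.clip(
            (t - ev.target_on) / (ev.center_release - ev.target_on), 0.0, 1.0
        )
        # ramp decays after the movement completes
        ramp *= np.clip(1 - (t - ev.center_hit_again) / 0.3, 0.0, 1.0)
        rise_c = (ev.center_release + ev.target_hit) / 2
        rise_s = (ev.target_hit - ev.center_release) / 4
        fall_c = (ev.target_release + ev.center_hit_again) / 2
        fall_s = (ev.center_hit_again - ev.target_release) / 4
        rise = np.exp(-0.5 * ((t - rise_c) / rise_s) ** 2)
        fall = np.exp(-0.5 * ((t - fall_c) / fall_s) ** 2)
        hold_lo, _, _ = _logistic_terms(t, ev.target_hit, 0.05)
        hold_hi, _, _ = _logistic_terms(t, ev.center_hit_again, 0.08)
        hold = hold_lo * (1 - hold_hi)
        for m, name in enumerate(MUSCLES):
            wp, wr, wh, wf = _PHASE_WEIGHTS[name]
            act[:, m] += 0.5 * wp * ramp + wr * rise + wh * hold * 0.6 + wf * fall
    return np.clip(act, 0.0, 1.0)


def generate_emg(
    events: list[TrialEvents], config: SessionConfig, rng: np.random.Generator
) -> tuple[EMGRecord, np.ndarray]:
    """Raw 1 kHz EMG: white broadband carrier amplitude-modulated by the
    activation envelope, plus additive sensor noise.

    Returns the record and the (n_samples, 8) ground-truth activation matrix.
    """
    t_end = _session_end(events, config)
    n = int(round(t_end * config.emg_fs))
    t = np.arange(n) / config.emg_fs
    act = muscle_activations(events, config, t)
    carrier = rng.standard_normal((n, len(MUSCLES)))
    sensor = rng.standard_normal((n, len(MUSCLES))) * config.emg_sensor_noise
    values = config.emg_gain * act * carrier + sensor
    return EMGRecord(config.emg_fs, MUSCLES, values), act


# --------------------------------------------------------------------------
# spikes
# --------------------------------------------------------------------------

def default_tuning(config: SessionConfig, rng: np.random.Generator) -> TuningModel:
    """Draw a tuning model over the 9-dim drive state (8 muscle activations
    plus normalised z).  Each unit is assigned to one muscle group and gains
    load mainly on that group's two muscles."""
    d = len(MUSCLES) + 1
    C = config.n_units
    groups = np.arange(C) % len(MUSCLE_GROUPS)
    gains = rng.normal(0.0, config.cross_gain_sd, size=(C, d))
    for c in range(C):
        for muscle in MUSCLE_GROUPS[groups[c]]:
            gains[c, MUSCLES.index(muscle)] = rng.normal(
                config.group_gain_mean, config.group_gain_sd
            )
        gains[c, -1] = rng.normal(0.0, config.z_gain_sd)
    offsets = rng.normal(config.tuning_offset_mean, config.tuning_offset_sd, size=C)
    return TuningModel(
        gains=gains,
        offsets=offsets,
        rate_scale=config.rate_scale,
        baseline_rate=config.baseline_rate,
        unit_groups=groups,
        noise=config.spike_noise,
        gaussian_count_sd=config.gaussian_count_sd,
        nonlinearity=config.tuning_nonlinearity,
        state_labels=MUSCLES + ("z",),
    )


def generate_spikes(
    states_binned: np.ndarray,
    tuning: TuningModel,
    rng: np.random.Generator,
    bin_dt: float = 0.030,
    t0: float = 0.0,
) -> SpikeTrainSet:
    """Draw per-bin spike counts around ``tuning(state)`` and place the
    corresponding timestamps uniformly within each bin.

    Unit stereotaxic coordinates are drawn from one Gaussian cluster per
    muscle group, clipped to the explored box.
    """
    states_binned = np.asarray(states_binned, dtype=float)
    lam = tuning.expected_count(states_binned, bin_dt)     # (K, C)
    K, C = lam.shape
    if tuning.noise == "poisson":
        counts = rng.poisson(lam)
    else:
        counts = np.maximum(
            0, np.rint(rng.normal(lam, tuning.gaussian_count_sd))
        ).astype(int)
    spike_times: list[np.ndarray] = []
    for c in range(C):
        per_bin = counts[:, c]
        total = int(per_bin.sum())
        offsets = rng.uniform(0.0, bin_dt, size=total)
        starts = t0 + np.repeat(np.arange(K) * bin_dt, per_bin)
        st = np.sort(starts + offsets)
        spike_times.append(st)
    coords = _GROUP_CENTERS[tuning.unit_groups] + rng.normal(
        0.0, _COORD_SD, size=(C, 3)
    )
    for j, key in enumerate(("PA", "DL", "depth")):
        coords[:, j] = np.clip(coords[:, j], *COORD_BOX[key])
    return SpikeTrainSet(
        spike_times=spike_times,
        unit_ids=[f"u{c:03d}" for c in range(C)],
        coords=coords,
        counts=counts,
        bin_t0=t0,
        bin_dt=bin_dt,
    )


# --------------------------------------------------------------------------
# post-spike facilitation injection
# --------------------------------------------------------------------------

def inject_facilitation(
    emg: EMGRecord, spikes: SpikeTrainSet, spec: FacilitationSpec
) -> EMGRecord:
    """Add a half-sine transient at ``spike + latency`` on the named muscle
    channel for every effect in ``spec``; all other channels untouched."""
    out = emg.copy()
    fs = emg.fs
    for eff in spec.effects:
        try:
            u = spikes.unit_ids.index(eff.unit_id)
        except ValueError:
            raise KeyError(f"unknown unit {eff.unit_id!r}") from None
        if eff.muscle not in emg.channels:
            raise KeyError(f"unknown muscle {eff.muscle!r}")
        ch = emg.channels.index(eff.muscle)
        width_n = max(2, int(round(eff.width_ms * fs / 1000.0)) + 1)
        kernel = eff.amplitude * np.sin(
            np.pi * np.arange(width_n) / (width_n - 1)
        )
        starts = np.round(
            (spikes.spike_times[u] - emg.t0 + eff.latency_ms / 1000.0) * fs
        ).astype(int)
        n = out.values.shape[0]
        for s in starts:
            if s < 0 or s + width_n > n:
                continue
            out.values[s : s + width_n, ch] += kernel
    return out


def grouped_facilitation_spec(
    spikes: SpikeTrainSet,
    tuning: TuningModel,
    rng: np.random.Generator,
    amplitude: float = 30.0,
    latency_range: tuple[float, float] = (6.0, 12.0),
    width_range: tuple[float, float] = (2.0, 4.0),
) -> FacilitationSpec:
    """Facilitation of each unit onto the two muscles of its own group, with
    latencies and widths inside the physiological acceptance windows."""
    effects = []
    for u, uid in enumerate(spikes.unit_ids):
        for muscle in MUSCLE_GROUPS[tuning.unit_groups[u]]:
            effects.append(
                FacilitationEffect(
                    unit_id=uid,
                    muscle=muscle,
                    latency_ms=rng.uniform(*latency_range),
                    amplitude=amplitude,
                    width_ms=rng.uniform(*width_range),
                )
            )
    return FacilitationSpec(effects)


# --------------------------------------------------------------------------
# session assembly
# --------------------------------------------------------------------------

def make_session(
    config: SessionConfig,
    seed: int,
    dataset_id: str = "ds00",
    facilitation: str | FacilitationSpec | None = None,
) -> SyntheticSession:
    """Assemble one dataset: events -> kinematics -> EMG -> tuning -> spikes.

    ``facilitation`` may be None, a :class:`FacilitationSpec`, or the string
    ``"grouped"`` to inject spike-locked transients of each unit onto its
    own muscle group (ground truth for SpTA/density-map recovery).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    events = generate_trial_events(config, seed)
    kin = generate_kinematics(events, config)
    emg, act = generate_emg(events, config, rng)

    # drive state at 30 ms bins: mean muscle activation + normalised z
    n_bins = int(emg.values.shape[0] / (config.bin_dt * config.emg_fs))
    per_bin = int(round(config.bin_dt * config.emg_fs))
    act_binned = act[: n_bins * per_bin].reshape(n_bins, per_bin, -1).mean(axis=1)
    bin_centers = (np.arange(n_bins) + 0.5) * config.bin_dt
    z_binned = np.interp(bin_centers, kin.t, kin.z)
    z_norm = (z_binned - config.z_squat) / max(config.z_stand - config.z_squat, 1e-12)
    drive = np.column_stack([act_binned, z_norm])

    tuning = default_tuning(config, rng)
    spikes = generate_spikes(drive, tuning, rng, bin_dt=config.bin_dt, t0=0.0)

    fac_spec: FacilitationSpec | None
    if facilitation == "grouped":
        fac_spec = grouped_facilitation_spec(spikes, tuning, rng)
    elif isinstance(facilitation, FacilitationSpec):
        fac_spec = facilitation
    elif facilitation is None:
        fac_spec = None
    else:
        raise ConfigError(f"unknown facilitation mode {facilitation!r}")
    if fac_spec is not None:
        emg = inject_facilitation(emg, spikes, fac_spec)

    return SyntheticSession(
        config=config,
        seed=seed,
        dataset_id=dataset_id,
        events=events,
        kinematics=kin,
        emg=emg,
        spikes=spikes,
        tuning=tuning,
        activations=act,
        drive_states=drive,
        drive_t=np.arange(n_bins) * config.bin_dt,
        facilitation=fac_spec,
    )


def generate_study(
    config: SessionConfig,
    seed: int,
    n_datasets: int = 13,
    trial_jitter: int = 5,
    facilitation: str | None = None,
) -> list[SyntheticSession]:
    """Generate a chronic-recording study: ``n_datasets`` independent
    datasets with trial counts drawn uniformly in ``n_trials +/- trial_jitter``."""
    rng = np.random.default_rng(seed)
    sessions = []
    for i in range(n_datasets):
        cfg = dataclasses.replace(
            config,
            n_trials=int(
                config.n_trials + rng.integers(-trial_jitter, trial_jitter + 1)
            )
            if trial_jitter
            else config.n_trials,
        )
        ds_seed = int(rng.integers(0, 2**31 - 1))
        sessions.append(
            make_session(cfg, ds_seed, dataset_id=f"ds{i:02d}", facilitation=facilitation)
        )
    return sessions


# --------------------------------------------------------------------------
# persistence: JSON metadata + CSV kinematics + HDF5 arrays
# --------------------------------------------------------------------------

def save_session(session: SyntheticSession, out_dir: str | Path) -> dict:
    """Write a session as JSON (config/events/seed), CSV (kinematics) and an
    HDF5 container (EMG, spikes, binned drive).  Returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "dataset_id": session.dataset_id,
        "seed": session.seed,
        "config": dataclasses.asdict(session.config),
        "events": [dataclasses.asdict(ev) for ev in session.events],
        "facilitation": (
            [dataclasses.asdict(e) for e in session.facilitation.effects]
            if session.facilitation
            else None
        ),
    }
    meta_path = out / f"{session.dataset_id}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=1))

    kin_path = out / f"{session.dataset_id}_kinematics.csv"
    kin = session.kinematics
    header = "t,z,v,a"
    np.savetxt(
        kin_path,
        np.column_stack([kin.t, kin.z, kin.v, kin.a]),
        delimiter=",",
        header=header,
        comments="",
    )

    h5_path = out / f"{session.dataset_id}_arrays.h5"
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("emg/values", data=session.emg.values, compression="gzip")
        f["emg"].attrs["fs"] = session.emg.fs
        f["emg"].attrs["channels"] = list(session.emg.channels)
        g = f.create_group("spikes")
        g.attrs["bin_dt"] = session.spikes.bin_dt
        g.attrs["bin_t0"] = session.spikes.bin_t0
        g.create_dataset("coords", data=session.spikes.coords)
        if session.spikes.counts is not None:
            g.create_dataset("counts", data=session.spikes.counts)
        for uid, st in zip(session.spikes.unit_ids, session.spikes.spike_times):
            g.create_dataset(f"times/{uid}", data=st)
        tg = f.create_group("tuning")
        tg.create_dataset("gains", data=session.tuning.gains)
        tg.create_dataset("offsets", data=session.tuning.offsets)
        tg.create_dataset("unit_groups", data=session.tuning.unit_groups)
        tg.attrs["rate_scale"] = session.tuning.rate_scale
        tg.attrs["baseline_rate"] = session.tuning.baseline_rate
        tg.attrs["noise"] = session.tuning.noise
        tg.attrs["nonlinearity"] = session.tuning.nonlinearity
        f.create_dataset("activations", data=session.activations, compression="gzip")
        f.create_dataset("drive/states", data=session.drive_states)
        f.create_dataset("drive/t", data=session.drive_t)
    return {"meta": str(meta_path), "kinematics": str(kin_path), "arrays": str(h5_path)}


def load_session(out_dir: str | Path, dataset_id: str) -> SyntheticSession:
    """Inverse of :func:`save_session`."""
    out = Path(out_dir)
    meta = json.loads((out / f"{dataset_id}_meta.json").read_text())
    cfg_dict = meta["config"]
    cfg_dict["iti_range"] = tuple(cfg_dict["iti_range"])
    config = SessionConfig(**cfg_dict)
    events = [TrialEvents(**ev) for ev in meta["events"]]
    kin_data = np.loadtxt(out / f"{dataset_id}_kinematics.csv", delimiter=",", skiprows=1)
    kin = KinematicsTrace(*(kin_data[:, j] for j in range(4)))
    with h5py.File(out / f"{dataset_id}_arrays.h5", "r") as f:
        emg = EMGRecord(
            fs=float(f["emg"].attrs["fs"]),
            channels=tuple(f["emg"].attrs["channels"]),
            values=f["emg/values"][()],
        )
        g = f["spikes"]
        uids = sorted(g["times"].keys())
        spikes = SpikeTrainSet(
            spike_times=[g[f"times/{u}"][()] for u in uids],
            unit_ids=uids,
            coords=g["coords"][()],
            counts=g["counts"][()] if "counts" in g else None,
            bin_t0=float(g.attrs["bin_t0"]),
            bin_dt=float(g.attrs["bin_dt"]),
        )
        tg = f["tuning"]
        tuning = TuningModel(
            gains=tg["gains"][()],
            offsets=tg["offsets"][()],
            rate_scale=float(tg.attrs["rate_scale"]),
            baseline_rate=float(tg.attrs["baseline_rate"]),
            unit_groups=tg["unit_groups"][()],
            noise=str(tg.attrs["noise"]),
            nonlinearity=str(tg.attrs.get("nonlinearity", "logistic")),
            state_labels=MUSCLES + ("z",),
        )
        activations = f["activations"][()]
        drive = f["drive/states"][()]
        drive_t = f["drive/t"][()]
    fac = None
    if meta.get("facilitation"):
        fac = FacilitationSpec(
            [FacilitationEffect(**e) for e in meta["facilitation"]]
        )
    return SyntheticSession(
        config=config,
        seed=meta["seed"],
        dataset_id=dataset_id,
        events=events,
        kinematics=kin,
        emg=emg,
        spikes=spikes,
        tuning=tuning,
        activations=activations,
        drive_states=drive,
        drive_t=drive_t,
        facilitation=fac,
    )
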