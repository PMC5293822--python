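"""Transform raw recordings into aligned 30 ms-binned series.

EMG is full-wave rectified and low-pass filtered (4-pole 10 Hz Butterworth)
into a non-negative envelope; spike timestamps become counts in consecutive
30 ms non-overlapping bins; ankle z-position at 15 ms becomes difference-based
velocity and acceleration; everything is resampled onto the common bin grid
and min-max normalised with statistics taken from training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .synth import EMGRecord, KinematicsTrace, SpikeTrainSet, SyntheticSession

__all__ = [
    "BinnedSeries",
    "MinMaxNormalizer",
    "rectify_and_envelope",
    "bin_spikes",
    "compute_kinematics_vector",
    "resample_to_bins",
    "normalize_unit",
    "preprocess_session",
    "PreprocessedSession",
]


class PreprocessError(ValueError):
    pass


@dataclass
class BinnedSeries:
    """Values on a uniform bin grid: ``values[k]`` belongs to the half-open
    bin [edges[k], edges[k+1])."""

    edges: np.ndarray               # (K+1,)
    values: np.ndarray              # (K, n_channels)
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] == 1 and len(self.edges) != 2:
            self.values = self.values.T
        if self.values.shape[0] != len(self.edges) - 1:
            raise PreprocessError(
                f"{self.values.shape[0]} bins but {len(self.edges)} edges"
            )

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def bin_dt(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2


# --------------------------------------------------------------------------
# EMG envelope
# --------------------------------------------------------------------------

def _lowpass_sos(fs: float, cutoff: float, order: int) -> np.ndarray:
    return signal.butter(order, cutoff, btype="low", fs=fs, output="sos")


def rectify_and_envelope(
    raw: EMGRecord,
    cutoff: float = 10.0,
    order: int = 4,
    zero_phase: bool = False,
    expected_fs: float = 1000.0,
) -> EMGRecord:
    """Full-wave rectify and low-pass filter each channel into an envelope.

    The filter is causal by default (forward pass only); ``zero_phase=True``
    applies it forward and backward instead.  The Butterworth DC gain is 1,
    so a constant input yields the same constant in steady state.
    """
    if abs(raw.fs - expected_fs) > 1e-9:
        raise PreprocessError(f"expected {expected_fs} Hz EMG, got {raw.fs} Hz")
    sos = _lowpass_sos(raw.fs, cutoff, order)
    rect = np.abs(raw.values)
    if zero_phase:
        env = signal.sosfiltfilt(sos, rect, axis=0)
    else:
        # start the filter from the rectified signal's initial value to
        # suppress the onset transient
        zi = signal.sosfilt_zi(sos)
        env = np.empty_like(rect)
        for c in range(rect.shape[1]):
            env[:, c], _ = signal.sosfilt(sos, rect[:, c], zi=zi * rect[0, c])
    return EMGRecord(raw.fs, raw.channels, env, raw.t0)


# --------------------------------------------------------------------------
# spike binning
# --------------------------------------------------------------------------

def bin_spikes(
    spikes: SpikeTrainSet, t0: float, t1: float, bin_dt: float = 0.030
) -> BinnedSeries:
    """Spike counts in consecutive half-open bins [t0+k*dt, t0+(k+1)*dt)
    covering [t0, t1); a spike exactly on a boundary goes to the later bin."""
    if t1 <= t0:
        raise PreprocessError("t1 must exceed t0")
    spikes.validate()
    n_bins = int(np.floor((t1 - t0) / bin_dt + 1e-9))
    edges = t0 + np.arange(n_bins + 1) * bin_dt
    counts = np.zeros((n_bins, spikes.n_units))
    for c, st in enumerate(spikes.spike_times):
        sel = st[(st >= edges[0]) & (st < edges[-1])]
        idx = np.floor((sel - t0) / bin_dt).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)
        np.add.at(counts[:, c], idx, 1.0)
    return BinnedSeries(edges, counts, tuple(spikes.unit_ids))


# --------------------------------------------------------------------------
# kinematics vector
# --------------------------------------------------------------------------

def compute_kinematics_vector(
    positions: np.ndarray,
    dt: float = 0.015,
    raw_differences: bool = False,
    t: np.ndarray | None = None,
) -> KinematicsTrace:
    """Difference-based velocity and acceleration from the z-position series.

    ``v[k] = (z[k] - z[k-1]) / dt`` and acceleration from the velocity the
    same way; the first sample of each difference is zero-padded.  With
    ``raw_differences=True`` the division by ``dt`` is skipped, reproducing
    plain sample-to-sample differences.
    """
    z = np.asarray(positions, dtype=float)
    if z.size < 3:
        raise PreprocessError("need at least 3 position samples")
    scale = 1.0 if raw_differences else 1.0 / dt
    v = np.zeros_like(z)
    v[1:] = np.diff(z) * scale
    a = np.zeros_like(z)
    a[1:] = np.diff(v) * scale
    if t is None:
        t = np.arange(z.size) * dt
    return KinematicsTrace(t=t, z=z, v=v, a=a)


# --------------------------------------------------------------------------
# resampling onto the bin grid
# --------------------------------------------------------------------------

def resample_to_bins(
    t: np.ndarray,
    values: np.ndarray,
    edges: np.ndarray,
    kind: str = "mean",
    names: tuple[str, ...] | None = None,
) -> BinnedSeries:
    """Down-sample a series onto the decoder bin grid.

    ``kind="mean"`` averages samples within each half-open bin (EMG
    envelopes); ``kind="interp"`` linearly interpolates at bin centers
    (15 ms kinematics).
    """
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    edges = np.asarray(edges, dtype=float)
    if t[0] > edges[0] + (edges[1] - edges[0]) or t[-1] < edges[-2]:
        raise PreprocessError(
            f"series [{t[0]}, {t[-1]}] does not cover bins [{edges[0]}, {edges[-1]}]"
        )
    K = len(edges) - 1
    if names is None:
        names = tuple(f"ch{j}" for j in range(values.shape[1]))
    if kind == "mean":
        idx = np.searchsorted(edges, t, side="right") - 1
        ok = (idx >= 0) & (idx < K)
        out = np.zeros((K, values.shape[1]))
        cnt = np.zeros(K)
        np.add.at(out, idx[ok], values[ok])
        np.add.at(cnt, idx[ok], 1.0)
        cnt[cnt == 0] = np.nan
        out /= cnt[:, None]
        # bins before the first/after the last sample: hold nearest value
        nan_rows = np.isnan(out[:, 0])
        if nan_rows.any():
            good = np.flatnonzero(~nan_rows)
            for k in np.flatnonzero(nan_rows):
                out[k] = out[good[np.argmin(np.abs(good - k))]]
    elif kind == "interp":
        centers = (edges[:-1] + edges[1:]) / 2
        out = np.column_stack(
            [np.interp(centers, t, values[:, j]) for j in range(values.shape[1])]
        )
    else:
        raise PreprocessError(f"unknown resampling kind {kind!r}")
    return BinnedSeries(edges, out, names)


# --------------------------------------------------------------------------
# normalisation
# --------------------------------------------------------------------------

@dataclass
class MinMaxNormalizer:
    """Per-channel affine map sending the training fold into [0, 1].

    The same map is applied unchanged to test folds (values may leave
    [0, 1]); the map is invertible via :meth:`inverse`.
    """

    lo: np.ndarray = field(default_factory=lambda: np.array([]))
    hi: np.ndarray = field(default_factory=lambda: np.array([]))

    def fit(self, train: np.ndarray) -> "MinMaxNormalizer":
        train = np.atleast_2d(np.asarray(train, dtype=float))
        self.lo = train.min(axis=0)
        self.hi = train.max(axis=0)
        if np.any(self.hi - self.lo <= 0):
            bad = np.flatnonzero(self.hi - self.lo <= 0)
            raise PreprocessError(f"constant training channel(s) {bad.tolist()}")
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.lo) / (self.hi - self.lo)

    def inverse(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=float) * (self.hi - self.lo) + self.lo


def normalize_unit(
    series: np.ndarray, stats_from_training: np.ndarray
) -> tuple[np.ndarray, MinMaxNormalizer]:
    """Min-max normalise ``series`` using statistics of the training data."""
    norm = MinMaxNormalizer().fit(stats_from_training)
    return norm.transform(series), norm


# --------------------------------------------------------------------------
# whole-session preprocessing
# --------------------------------------------------------------------------

@dataclass
class PreprocessedSession:
    """Aligned 30 ms-binned views of one dataset (un-normalised;
    normalisation happens per cross-validation fold)."""

    counts: BinnedSeries            # (K, C) spike counts
    emg: BinnedSeries               # (K, 8) envelope means
    kinematics: BinnedSeries        # (K, 3) z, v, a at bin centers
    trial_spans: np.ndarray         # (n_trials, 2) [start_bin, end_bin) per trial
    dataset_id: str = "ds00"


def preprocess_session(
    session: SyntheticSession,
    bin_dt: float | None = None,
    raw_differences: bool = False,
    zero_phase: bool = False,
) -> PreprocessedSession:
    """Run the full preprocessing chain on one synthetic dataset.

    All three output series share bin edges and length; per-trial bin spans
    (used for fold splitting) run from each trial's CenterOn to the midpoint
    of the following inter-trial interval.
    """
    cfg = session.config
    bin_dt = bin_dt or cfg.bin_dt
    t0 = 0.0
    t1 = session.emg.values.shape[0] / session.emg.fs
    counts = bin_spikes(session.spikes, t0, t1, bin_dt)
    edges = counts.edges

    env = rectify_and_envelope(session.emg, zero_phase=zero_phase)
    emg_binned = resample_to_bins(
        env.t, env.values, edges, kind="mean", names=env.channels
    )

    kin_diff = compute_kinematics_vector(
        session.kinematics.z,
        dt=cfg.kin_dt,
        raw_differences=raw_differences,
        t=session.kinematics.t,
    )
    kin_binned = resample_to_bins(
        kin_diff.t,
        np.column_stack([kin_diff.z, kin_diff.v, kin_diff.a]),
        edges,
        kind="interp",
        names=("z", "v", "a"),
    )

    ev = session.events
    starts = [e.center_on for e in ev]
    cuts = [t0] + [
        (a.center_hit_again + b.center_on) / 2 for a, b in zip(ev, ev[1:])
    ] + [t1]
    spans = np.zeros((len(ev), 2), dtype=int)
    K = counts.n_bins
    for i in range(len(ev)):
        spans[i, 0] = min(K, max(0, int(np.floor((cuts[i] - t0) / bin_dt))))
        spans[i, 1] = min(K, max(0, int(np.floor((cuts[i + 1] - t0) / bin_dt))))
    spans[-1, 1] = K
    del starts
    return PreprocessedSession(
        counts=counts,
        emg=emg_binned,
        kinematics=kin_binned,
        trial_spans=spans,
        dataset_id=session.dataset_id,
    )
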