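"""Decoder scoring and the cross-validated decoder comparison.

Per decoded channel, performance is Pearson's correlation coefficient and
the signal-to-noise ratio in dB, 10*log10 of the signal variance over the
mean squared estimation error (0 dB: an estimator equal to the signal mean).
Datasets are scored by 4-fold cross-validation over contiguous trial blocks
(3 folds fit the models and the normalisation, 1 fold is decoded), and the
UKF-vs-KF comparison is a paired one-sided t-test over the matched
(dataset, fold, channel) observations.  Filter stability is diagnosed from
the per-bin L2 norms of the error covariance P_k and the gain K_k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import decoders as dec
from .preprocess import MinMaxNormalizer, PreprocessedSession, preprocess_session
from .synth import SyntheticSession

__all__ = [
    "correlation_coefficient",
    "snr_db",
    "DecoderConfig",
    "cross_validate",
    "cross_validate_study",
    "compare_decoders",
    "ConvergenceTrace",
    "convergence_diagnostics",
]


class EvaluationError(ValueError):
    pass


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def correlation_coefficient(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Pearson correlation between the actual and the decoded series."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape or x.size < 2:
        raise EvaluationError("series must have equal length >= 2")
    if np.ptp(x) == 0 or np.ptp(x_hat) == 0:
        raise EvaluationError("correlation undefined for a constant series")
    xm = x - x.mean()
    ym = x_hat - x_hat.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))


def snr_db(x: np.ndarray, x_hat: np.ndarray) -> float:
    """10*log10(sum (x - mean(x))^2 / sum (x_hat - x)^2), in dB.

    A perfect estimate returns +inf; an estimate equal to the signal mean
    returns exactly 0 dB.
    """
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise EvaluationError("series must have equal length")
    sig = float(np.sum((x - x.mean()) ** 2))
    if sig == 0:
        raise EvaluationError("SNR undefined for a zero-variance signal")
    mse = float(np.sum((x_hat - x) ** 2))
    if mse == 0:
        return float("inf")
    return 10.0 * np.log10(sig / mse)


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

@dataclass
class DecoderConfig:
    """Everything the cross-validated decoding run needs."""

    target: str = "emg"                 # "emg" or "kinematics"
    decoders: tuple[str, ...] = ("kf", "ukf")
    folds: int = 4
    ann_hidden: int = 20
    ann_lr: float = 0.2
    ann_epochs: int = 2000
    ann_seed: int = 0
    ukf_alpha: float = 1.0
    ukf_kappa: float | None = None      # default 0
    raw_differences: bool = False
    zero_phase: bool = False
    reset_per_trial: bool = False


def _fold_blocks(n_trials: int, folds: int) -> list[np.ndarray]:
    """Contiguous, near-equal trial blocks (sizes differ by at most 1)."""
    if n_trials < folds:
        raise EvaluationError(f"{n_trials} trials cannot form {folds} folds")
    return [np.asarray(b) for b in np.array_split(np.arange(n_trials), folds)]


def _bins_of_trials(spans: np.ndarray, trials: np.ndarray) -> list[tuple[int, int]]:
    """Merge per-trial bin spans of consecutive trials into segments."""
    segs: list[tuple[int, int]] = []
    for t in trials:
        s0, s1 = int(spans[t, 0]), int(spans[t, 1])
        if segs and segs[-1][1] == s0:
            segs[-1] = (segs[-1][0], s1)
        else:
            segs.append((s0, s1))
    return segs


def _segment_indices(segs: list[tuple[int, int]]) -> np.ndarray:
    return np.concatenate([np.arange(s0, s1) for s0, s1 in segs])


def cross_validate(
    session: SyntheticSession | PreprocessedSession,
    config: DecoderConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """4-fold cross-validated decoding of one dataset.

    Trials are split into contiguous fold blocks.  For each fold the linear
    model (and the ANN for the UKF) plus the min-max normalisation are
    fitted on the training blocks only, the held-out block is decoded
    continuously, and CC/SNR are scored per channel.  Returns one row per
    (dataset, fold, channel, decoder).
    """
    config = config or DecoderConfig()
    if isinstance(session, PreprocessedSession):
        pre = session
    else:
        pre = preprocess_session(
            session,
            raw_differences=config.raw_differences,
            zero_phase=config.zero_phase,
        )
    if config.target == "emg":
        states_raw = pre.emg.values
        channel_names = pre.emg.names
    elif config.target == "kinematics":
        states_raw = pre.kinematics.values
        channel_names = pre.kinematics.names
    else:
        raise EvaluationError(f"unknown target {config.target!r}")
    counts = pre.counts.values
    spans = pre.trial_spans
    blocks = _fold_blocks(spans.shape[0], config.folds)

    rows = []
    for fold, test_trials in enumerate(blocks):
        train_trials = np.concatenate(
            [b for f, b in enumerate(blocks) if f != fold]
        )
        train_segs = _bins_of_trials(spans, np.sort(train_trials))
        test_segs = _bins_of_trials(spans, test_trials)
        train_idx = _segment_indices(train_segs)
        test_idx = _segment_indices(test_segs)

        norm = MinMaxNormalizer().fit(states_raw[train_idx])
        states = norm.transform(states_raw)
        X_train, Y_train = states[train_idx], counts[train_idx]
        Y_test = counts[test_idx]
        x_true = states[test_idx]

        # segment ranges rebased to positions inside train_idx
        offsets = np.cumsum([0] + [s1 - s0 for s0, s1 in train_segs])
        local_segs = list(zip(offsets[:-1], offsets[1:]))
        model = dec.fit_linear_models(X_train, Y_train, segments=local_segs)
        x0 = X_train.mean(axis=0)
        d = states.shape[1]

        preds: dict[str, np.ndarray] = {}
        if "kf" in config.decoders:
            preds["kf"] = _run_segments(
                lambda obs: dec.kf_run(model, obs, x0=x0, P0=np.eye(d)),
                Y_test, test_segs, config.reset_per_trial,
            )
        if "ukf" in config.decoders:
            net = dec.train_ann(
                X_train,
                Y_train,
                hidden_size=config.ann_hidden,
                learning_rate=config.ann_lr,
                epochs=config.ann_epochs,
                seed=config.ann_seed + seed,
            )
            resid = Y_train - net.predict(X_train)
            Q_ann = resid.T @ resid / max(resid.shape[0] - 1, 1)
            Q_ann = (Q_ann + Q_ann.T) / 2
            params = dec.UKFParams(
                d=d, alpha=config.ukf_alpha, kappa=config.ukf_kappa
            )
            preds["ukf"] = _run_segments(
                lambda obs: dec.ukf_run(
                    model.A, model.W, net, Q_ann, obs,
                    params=params, x0=x0, P0=np.eye(d),
                ),
                Y_test, test_segs, config.reset_per_trial,
            )

        for name, x_hat in preds.items():
            for ch, label in enumerate(channel_names):
                rows.append(
                    {
                        "dataset": pre.dataset_id,
                        "fold": fold,
                        "channel": label,
                        "decoder": name,
                        "CC": correlation_coefficient(x_true[:, ch], x_hat[:, ch]),
                        "SNR": snr_db(x_true[:, ch], x_hat[:, ch]),
                    }
                )
    return pd.DataFrame(rows)


def _run_segments(run, Y_test, test_segs, reset_per_trial: bool) -> np.ndarray:
    """Decode the held-out bins, continuously by default; with
    ``reset_per_trial`` the filter restarts on each test segment."""
    if not reset_per_trial:
        return run(Y_test).x_post
    out = []
    pos = 0
    for s0, s1 in test_segs:
        n = s1 - s0
        out.append(run(Y_test[pos : pos + n]).x_post)
        pos += n
    return np.vstack(out)


def cross_validate_study(
    sessions: list[SyntheticSession],
    config: DecoderConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Concatenated metric tables over all datasets of a study."""
    tables = [
        cross_validate(s, config, seed=seed + i) for i, s in enumerate(sessions)
    ]
    return pd.concat(tables, ignore_index=True)


# --------------------------------------------------------------------------
# decoder comparison
# --------------------------------------------------------------------------

def compare_decoders(
    table: pd.DataFrame,
    metric: str = "CC",
    direction: str = "greater",
    decoder_a: str = "ukf",
    decoder_b: str = "kf",
    channels=None,
) -> dict:
    """Paired one-sided t-test of decoder_a - decoder_b on matched
    (dataset, fold, channel) rows.  Returns n, t, p, mean difference."""
    tab = table if channels is None else table[table["channel"].isin(channels)]
    keys = ["dataset", "fold", "channel"]
    wide = tab.pivot_table(index=keys, columns="decoder", values=metric)
    if decoder_a not in wide or decoder_b not in wide:
        raise EvaluationError(f"table lacks decoder {decoder_a!r} or {decoder_b!r}")
    missing = wide[wide[[decoder_a, decoder_b]].isna().any(axis=1)]
    if len(missing):
        raise EvaluationError(
            f"unmatched rows for keys: {missing.index.tolist()[:5]}"
        )
    diff = (wide[decoder_a] - wide[decoder_b]).to_numpy()
    res = stats.ttest_1samp(diff, 0.0, alternative=direction)
    return {
        "n": int(diff.size),
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "mean_diff": float(diff.mean()),
        "metric": metric,
        "alpha": 0.05,
        "significant": bool(res.pvalue < 0.05),
    }


# --------------------------------------------------------------------------
# convergence diagnostics
# --------------------------------------------------------------------------

@dataclass
class ConvergenceTrace:
    """Stabilisation of the filter internals under a relative tolerance."""

    P_norms: np.ndarray
    K_norms: np.ndarray
    P_stable_at: int            # first stable bin index (-1: never)
    K_stable_at: int
    rel_tol: float
    stabilized: bool


def _stable_at(norms: np.ndarray, rel_tol: float, run: int = 3) -> int:
    """First index from which the relative change stays below ``rel_tol``
    for ``run`` consecutive bins."""
    prev = norms[:-1]
    denom = np.where(np.abs(prev) > 0, np.abs(prev), 1.0)
    rel = np.abs(np.diff(norms)) / denom
    ok = rel < rel_tol
    for k in range(len(ok) - run + 1):
        if ok[k : k + run].all():
            return k + 1
    return -1


def convergence_diagnostics(
    trace: dec.FilterTrace, rel_tol: float = 0.01
) -> ConvergenceTrace:
    """Iterations-to-stabilisation of ||P_k||_2 and ||K_k||_2.

    Stabilisation requires the relative change to stay below ``rel_tol``
    for 3 consecutive bins; -1 flags a sequence that never settles.
    """
    if trace.n_steps < 3:
        raise EvaluationError("need at least 3 filter steps")
    p_at = _stable_at(trace.P_norms, rel_tol)
    k_at = _stable_at(trace.K_norms, rel_tol)
    return ConvergenceTrace(
        P_norms=trace.P_norms.copy(),
        K_norms=trace.K_norms.copy(),
        P_stable_at=p_at,
        K_stable_at=k_at,
        rel_tol=rel_tol,
        stabilized=p_at >= 0 and k_at >= 0,
    )
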