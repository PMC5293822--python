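"""State-space decoders: linear Kalman filter and ANN-observation UKF.

The hidden state x_k is either the 8-vector of normalised EMG envelopes or
the 3-vector of ankle z-kinematics; the observation y_k is the C-vector of
30 ms spike counts.  The linear model

    x_k = A x_{k-1} + w_k,   w_k ~ N(0, W)
    y_k = H x_k     + q_k,   q_k ~ N(0, Q)

is fitted by least squares with W and Q taken as empirical residual
covariances.  The nonlinear variant replaces H by a single-hidden-layer
feed-forward network y_k = net(x_k) (sigmoid hidden units, identity output,
trained by full-batch gradient-descent back-propagation) and runs an
unscented Kalman filter: 2d+1 sigma points with scaling lambda =
alpha^2 (d + kappa) - d, a single weight set w_0 = lambda/(d+lambda),
w_i = 1/(2(d+lambda)) used for both mean and covariance, Q added to the
predicted observation covariance, and P_0 = I.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "LinearStateSpaceModel",
    "FilterTrace",
    "ANNModel",
    "UKFParams",
    "fit_linear_models",
    "kf_run",
    "train_ann",
    "sigma_points",
    "ukf_run",
]


class FitError(ValueError):
    pass


class FilterError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# model types
# --------------------------------------------------------------------------

@dataclass
class LinearStateSpaceModel:
    """A, W (state transition + process noise), H, Q (observation + noise)."""

    A: np.ndarray
    W: np.ndarray
    H: np.ndarray
    Q: np.ndarray

    def __post_init__(self) -> None:
        d = self.A.shape[0]
        if self.A.shape != (d, d) or self.W.shape != (d, d):
            raise FitError("A and W must be square with matching size")
        if self.H.shape[1] != d or self.Q.shape != (self.H.shape[0],) * 2:
            raise FitError("H/Q dimensions inconsistent with A")
        for M, name in ((self.W, "W"), (self.Q, "Q")):
            if not np.allclose(M, M.T, atol=1e-8):
                raise FitError(f"{name} must be symmetric")

    @property
    def state_dim(self) -> int:
        return self.A.shape[0]

    @property
    def obs_dim(self) -> int:
        return self.H.shape[0]


@dataclass
class FilterTrace:
    """Per-bin filter internals: a-priori/a-posteriori means, covariances,
    gains, and the L2 (spectral) norms of P_k and K_k."""

    x_prior: np.ndarray         # (K, d)
    x_post: np.ndarray          # (K, d)
    P_post: np.ndarray          # (K, d, d)
    K_gain: np.ndarray          # (K, d, C)
    P_norms: np.ndarray         # (K,)
    K_norms: np.ndarray         # (K,)

    @property
    def n_steps(self) -> int:
        return self.x_post.shape[0]


# --------------------------------------------------------------------------
# linear model fitting
# --------------------------------------------------------------------------

def _residual_cov(resid: np.ndarray) -> np.ndarray:
    n = resid.shape[0]
    C = resid.T @ resid / max(n - 1, 1)
    return (C + C.T) / 2


def _transition_pairs(X: np.ndarray, segments) -> tuple[np.ndarray, np.ndarray]:
    if segments is None:
        return X[:-1], X[1:]
    prev, curr = [], []
    for s0, s1 in segments:
        if s1 - s0 >= 2:
            prev.append(X[s0 : s1 - 1])
            curr.append(X[s0 + 1 : s1])
    if not prev:
        raise FitError("no usable transition pairs in the given segments")
    return np.vstack(prev), np.vstack(curr)


def fit_linear_models(
    states: np.ndarray, rates: np.ndarray, segments=None
) -> LinearStateSpaceModel:
    """Least-squares fit of A, H; W, Q as empirical residual covariances.

    ``segments`` is an optional list of [start, stop) index ranges; state
    transition pairs spanning a segment boundary (e.g. the gap left by a
    held-out cross-validation fold) are excluded from the fit of A.
    """
    X = np.atleast_2d(np.asarray(states, dtype=float))
    Y = np.atleast_2d(np.asarray(rates, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise FitError("states and rates must be aligned")
    if X.shape[0] < X.shape[1] + 1:
        raise FitError("need at least state_dim + 1 time bins")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        sv = np.linalg.svd(X, compute_uv=False)
        bad = int(np.argmin(sv))
        raise FitError(
            f"rank-deficient state regressors (rank {rank} < {X.shape[1]}, "
            f"weakest direction {bad})"
        )
    Xp, Xc = _transition_pairs(X, segments)
    A = np.linalg.lstsq(Xp, Xc, rcond=None)[0].T
    W = _residual_cov(Xc - Xp @ A.T)
    H = np.linalg.lstsq(X, Y, rcond=None)[0].T
    Q = _residual_cov(Y - X @ H.T)
    return LinearStateSpaceModel(A=A, W=W, H=H, Q=Q)


# --------------------------------------------------------------------------
# Kalman filter
# --------------------------------------------------------------------------

def kf_run(
    model: LinearStateSpaceModel,
    observations: np.ndarray,
    x0: np.ndarray | None = None,
    P0: np.ndarray | None = None,
) -> FilterTrace:
    """Standard Kalman filter over a (K, C) observation sequence.

    Per bin: predict x- = A x, P- = A P A' + W; gain
    K = P- H' (H P- H' + Q)^-1; update x = x- + K (y - H x-),
    P = (I - K H) P-.  P is re-symmetrised every step.
    """
    Y = np.atleast_2d(np.asarray(observations, dtype=float))
    d, C = model.state_dim, model.obs_dim
    if Y.shape[1] != C:
        raise FilterError(f"observations have {Y.shape[1]} channels, model {C}")
    x = np.zeros(d) if x0 is None else np.asarray(x0, dtype=float).copy()
    P = np.eye(d) if P0 is None else np.asarray(P0, dtype=float).copy()
    A, W, H, Q = model.A, model.W, model.H, model.Q
    K_steps = Y.shape[0]
    tr = FilterTrace(
        x_prior=np.zeros((K_steps, d)),
        x_post=np.zeros((K_steps, d)),
        P_post=np.zeros((K_steps, d, d)),
        K_gain=np.zeros((K_steps, d, C)),
        P_norms=np.zeros(K_steps),
        K_norms=np.zeros(K_steps),
    )
    I = np.eye(d)
    for k in range(K_steps):
        x_pr = A @ x
        P_pr = A @ P @ A.T + W
        S = H @ P_pr @ H.T + Q
        try:
            K_gain = np.linalg.solve(S.T, (P_pr @ H.T).T).T
        except np.linalg.LinAlgError as exc:
            raise FilterError(
                f"singular innovation covariance at bin {k}; "
                "consider adding diagonal jitter to Q"
            ) from exc
        x = x_pr + K_gain @ (Y[k] - H @ x_pr)
        P = (I - K_gain @ H) @ P_pr
        P = (P + P.T) / 2
        tr.x_prior[k] = x_pr
        tr.x_post[k] = x
        tr.P_post[k] = P
        tr.K_gain[k] = K_gain
        tr.P_norms[k] = np.linalg.norm(P, 2)
        tr.K_norms[k] = np.linalg.norm(K_gain, 2)
    return tr


# --------------------------------------------------------------------------
# ANN observation model
# --------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


@dataclass
class ANNModel:
    """Single-hidden-layer feed-forward network, sigmoid hidden units,
    identity output; trained by full-batch gradient descent."""

    W1: np.ndarray              # (hidden, in)
    b1: np.ndarray              # (hidden,)
    W2: np.ndarray              # (out, hidden)
    b2: np.ndarray              # (out,)
    loss_curve: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def hidden_size(self) -> int:
        return self.W1.shape[0]

    def hidden(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return _sigmoid(X @ self.W1.T + self.b1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Network output for inputs of shape (n, in) -> (n, out)."""
        return self.hidden(X) @ self.W2.T + self.b2

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.predict(X)


def train_ann(
    states: np.ndarray,
    rates: np.ndarray,
    hidden_size: int = 20,
    learning_rate: float = 0.2,
    epochs: int = 2000,
    seed: int = 0,
) -> ANNModel:
    """Back-propagation training of the tuning network on (state, count) pairs.

    Full-batch gradient descent on the mean squared error; weights
    initialised from a seeded uniform distribution scaled by fan-in, so the
    fit is exactly reproducible.  Raises on divergence (non-finite loss).
    """
    X = np.atleast_2d(np.asarray(states, dtype=float))
    Y = np.atleast_2d(np.asarray(rates, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise FitError("states and rates must be aligned")
    n, d_in = X.shape
    d_out = Y.shape[1]
    rng = np.random.default_rng(seed)
    W1 = rng.uniform(-1, 1, size=(hidden_size, d_in)) / np.sqrt(d_in)
    b1 = np.zeros(hidden_size)
    W2 = rng.uniform(-1, 1, size=(d_out, hidden_size)) / np.sqrt(hidden_size)
    b2 = Y.mean(axis=0).astype(float)
    losses = np.zeros(epochs)
    for ep in range(epochs):
        Hid = _sigmoid(X @ W1.T + b1)                  # (n, h)
        pred = Hid @ W2.T + b2                         # (n, out)
        err = pred - Y
        with np.errstate(over="ignore"):
            loss = float(np.mean(err**2))
        if not np.isfinite(loss):
            raise FitError(
                f"ANN training diverged at epoch {ep} "
                f"(learning_rate={learning_rate})"
            )
        losses[ep] = loss
        # gradient of the per-sample-mean loss: invariant under duplicating
        # the training set, so the step size does not depend on n
        g_pred = 2.0 * err / n
        gW2 = g_pred.T @ Hid
        gb2 = g_pred.sum(axis=0)
        g_hid = (g_pred @ W2) * Hid * (1 - Hid)
        gW1 = g_hid.T @ X
        gb1 = g_hid.sum(axis=0)
        W2 -= learning_rate * gW2
        b2 -= learning_rate * gb2
        W1 -= learning_rate * gW1
        b1 -= learning_rate * gb1
    return ANNModel(W1=W1, b1=b1, W2=W2, b2=b2, loss_curve=losses)


# --------------------------------------------------------------------------
# unscented transform
# --------------------------------------------------------------------------

@dataclass
class UKFParams:
    """Unscented-transform scaling: lambda = alpha^2 (d + kappa) - d with a
    single weight set w_0 = lambda/(d+lambda), w_i = 1/(2(d+lambda)) used
    for both mean and covariance.

    The default kappa = 0 makes lambda = 0 for alpha = 1, so every weight is
    positive and the sigma-point joint covariance stays positive
    semi-definite for any observation map; the classic kappa = 3 - d
    heuristic gives a negative centre weight for d > 3, which can drive the
    updated covariance indefinite under a nonlinear network."""

    d: int
    alpha: float = 1.0
    kappa: float | None = None          # default 0
    jitter_start: float = 1e-9
    jitter_max: float = 1e-3

    def __post_init__(self) -> None:
        if self.kappa is None:
            self.kappa = 0.0
        if self.d + self.lam <= 0:
            raise FitError(f"d + lambda must be positive, got {self.d + self.lam}")

    @property
    def lam(self) -> float:
        return self.alpha**2 * (self.d + self.kappa) - self.d

    @property
    def weights(self) -> np.ndarray:
        lam = self.lam
        w = np.full(2 * self.d + 1, 1.0 / (2 * (self.d + lam)))
        w[0] = lam / (self.d + lam)
        return w


def _cholesky_with_jitter(P: np.ndarray, params: UKFParams) -> np.ndarray:
    """Upper-triangular Cholesky factor, escalating diagonal jitter x10 from
    ``jitter_start`` to ``jitter_max`` before failing."""
    try:
        return linalg.cholesky(P, lower=False)
    except linalg.LinAlgError:
        pass
    eps = params.jitter_start
    I = np.eye(P.shape[0])
    while eps <= params.jitter_max:
        try:
            return linalg.cholesky(P + eps * I, lower=False)
        except linalg.LinAlgError:
            eps *= 10
    raise FilterError(
        f"covariance not decomposable even with jitter {params.jitter_max}"
    )


def sigma_points(
    x: np.ndarray, P: np.ndarray, params: UKFParams
) -> tuple[np.ndarray, np.ndarray]:
    """2d+1 sigma points and their weights.

    X(0) = x; X(i) = x + sqrt(d+lambda) * [sqrt(P)]_i;
    X(i+d) = x - sqrt(d+lambda) * [sqrt(P)]_i, where [.]_i are the rows of
    the upper-triangular Cholesky factor (so sum_i [.]_i' [.]_i = P and the
    weighted mean/scatter of the points reproduce x and P exactly).
    """
    x = np.asarray(x, dtype=float)
    d = params.d
    if x.size != d or P.shape != (d, d):
        raise FitError("sigma point dimensions inconsistent with params.d")
    U = _cholesky_with_jitter(np.asarray(P, dtype=float), params)
    scale = np.sqrt(d + params.lam)
    pts = np.empty((2 * d + 1, d))
    pts[0] = x
    pts[1 : d + 1] = x + scale * U
    pts[d + 1 :] = x - scale * U
    return pts, params.weights


# --------------------------------------------------------------------------
# unscented Kalman filter
# --------------------------------------------------------------------------

def ukf_run(
    A: np.ndarray,
    W: np.ndarray,
    net,
    Q: np.ndarray,
    observations: np.ndarray,
    params: UKFParams | None = None,
    x0: np.ndarray | None = None,
    P0: np.ndarray | None = None,
) -> FilterTrace:
    """UKF with a linear state transition and an arbitrary observation map.

    ``net`` is any callable mapping (n, d) state rows to (n, C) expected
    observations (typically a trained :class:`ANNModel`).  Per bin: linear
    predict with A, W; sigma points propagated through ``net``; predicted
    observation mean/covariance (Q added to P_yy only) and state-observation
    cross-covariance give the gain K = P_xy P_yy^-1; update
    x = x- + K (y - y^), P = P- - K P_yy K'.  P_0 defaults to the identity.
    """
    Y = np.atleast_2d(np.asarray(observations, dtype=float))
    A = np.asarray(A, dtype=float)
    W = np.asarray(W, dtype=float)
    Q = np.asarray(Q, dtype=float)
    d = A.shape[0]
    C = Q.shape[0]
    params = params or UKFParams(d=d)
    if params.d != d:
        raise FitError("params.d inconsistent with state dimension")
    x = np.zeros(d) if x0 is None else np.asarray(x0, dtype=float).copy()
    P = np.eye(d) if P0 is None else np.asarray(P0, dtype=float).copy()
    K_steps = Y.shape[0]
    tr = FilterTrace(
        x_prior=np.zeros((K_steps, d)),
        x_post=np.zeros((K_steps, d)),
        P_post=np.zeros((K_steps, d, d)),
        K_gain=np.zeros((K_steps, d, C)),
        P_norms=np.zeros(K_steps),
        K_norms=np.zeros(K_steps),
    )
    for k in range(K_steps):
        x_pr = A @ x
        P_pr = A @ P @ A.T + W
        P_pr = (P_pr + P_pr.T) / 2
        pts, w = sigma_points(x_pr, P_pr, params)
        Ypts = np.atleast_2d(net(pts))
        if Ypts.shape != (2 * d + 1, C):
            raise FilterError(
                f"net returned shape {Ypts.shape}, expected {(2 * d + 1, C)}"
            )
        y_hat = w @ Ypts
        dY = Ypts - y_hat
        dX = pts - x_pr
        P_yy = (dY * w[:, None]).T @ dY + Q
        P_xy = (dX * w[:, None]).T @ dY
        try:
            K_gain = np.linalg.solve(P_yy.T, P_xy.T).T
        except np.linalg.LinAlgError:
            eps = params.jitter_start
            K_gain = None
            while eps <= params.jitter_max:
                try:
                    K_gain = np.linalg.solve(
                        (P_yy + eps * np.eye(C)).T, P_xy.T
                    ).T
                    break
                except np.linalg.LinAlgError:
                    eps *= 10
            if K_gain is None:
                raise FilterError(f"singular predicted covariance at bin {k}")
        x = x_pr + K_gain @ (Y[k] - y_hat)
        P = P_pr - K_gain @ P_yy @ K_gain.T
        P = (P + P.T) / 2
        tr.x_prior[k] = x_pr
        tr.x_post[k] = x
        tr.P_post[k] = P
        tr.K_gain[k] = K_gain
        tr.P_norms[k] = np.linalg.norm(P, 2)
        tr.K_norms[k] = np.linalg.norm(K_gain, 2)
    return tr
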