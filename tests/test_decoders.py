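"""Model fitting, Kalman filter, ANN training, unscented transform, UKF."""

import numpy as np
import pytest

from limbdecode import decoders as dec


def _simulate_lgss(A, W, H, Q, n, rng, x0=None):
    d = A.shape[0]
    C = H.shape[0]
    Lw = np.linalg.cholesky(W) if np.any(W) else np.zeros((d, d))
    Lq = np.linalg.cholesky(Q) if np.any(Q) else np.zeros((C, C))
    X = np.zeros((n, d))
    x = np.zeros(d) if x0 is None else np.asarray(x0, dtype=float)
    for k in range(n):
        x = A @ x + Lw @ rng.standard_normal(d)
        X[k] = x
    Y = X @ H.T + (Lq @ rng.standard_normal((C, n))).T
    return X, Y


class TestFitLinearModels:
    def test_noiseless_system_recovered_exactly(self):
        X = (0.9 ** np.arange(50))[:, None]
        Y = 2.0 * X
        m = dec.fit_linear_models(X, Y)
        assert m.A[0, 0] == pytest.approx(0.9)
        assert m.H[0, 0] == pytest.approx(2.0)
        assert m.W[0, 0] == pytest.approx(0.0, abs=1e-20)
        assert m.Q[0, 0] == pytest.approx(0.0, abs=1e-20)

    def test_parameters_recovered_within_5_percent(self, rng):
        A = np.array([[0.9, 0.05, 0.0], [0.0, 0.85, 0.1], [0.05, 0.0, 0.8]])
        W = 0.1 * np.eye(3) + 0.02
        H = rng.normal(0, 1, (6, 3))
        Q = 0.5 * np.eye(6)
        X, Y = _simulate_lgss(A, W, H, Q, 5000, rng)
        m = dec.fit_linear_models(X, Y)
        for est, true in ((m.A, A), (m.W, W), (m.H, H), (m.Q, Q)):
            assert np.linalg.norm(est - true) <= 0.05 * np.linalg.norm(true)

    def test_order_free_over_transition_pairs(self, rng):
        X, Y = _simulate_lgss(
            np.array([[0.8]]), np.array([[0.2]]), np.array([[1.5]]),
            np.array([[0.3]]), 300, rng,
        )
        m1 = dec.fit_linear_models(X, Y)
        # feed the same pairs in permuted order via two segments swapped
        m2 = dec.fit_linear_models(
            np.vstack([X[150:], X[:150]]),
            np.vstack([Y[150:], Y[:150]]),
            segments=[(0, 150), (150, 300)],
        )
        # H/Q are pure per-sample regressions: identical; A/W only lose the
        # single pair that straddled the cut
        assert m2.H[0, 0] == pytest.approx(m1.H[0, 0])
        assert m2.Q[0, 0] == pytest.approx(m1.Q[0, 0], rel=1e-9)
        assert m2.A[0, 0] == pytest.approx(m1.A[0, 0], rel=0.05)

    def test_rank_deficient_states_rejected(self):
        X = np.zeros((50, 2))
        X[:, 0] = np.arange(50.0)
        with pytest.raises(dec.FitError, match="rank-deficient"):
            dec.fit_linear_models(X, X.copy())


class TestKalmanFilter:
    def test_scalar_riccati_first_step(self):
        # a=1, w=0, h=1, q=1, P0=1: P- = 1, K = 1/2, P = 1/2
        m = dec.LinearStateSpaceModel(
            A=np.eye(1), W=np.zeros((1, 1)), H=np.eye(1), Q=np.eye(1)
        )
        tr = dec.kf_run(m, np.array([[3.0]]), x0=np.zeros(1), P0=np.eye(1))
        assert tr.K_gain[0, 0, 0] == pytest.approx(0.5)
        assert tr.P_post[0, 0, 0] == pytest.approx(0.5)
        assert tr.x_post[0, 0] == pytest.approx(1.5)

    def test_exact_observation_limit_tracks_state(self, rng):
        # noise-free dynamics, invertible H, Q -> 0: the first update already
        # pins the estimate to the true state
        A = np.array([[0.95, 0.1], [0.0, 0.9]])
        H = np.array([[1.0, 0.5], [0.0, 1.0]])
        X, Y = _simulate_lgss(
            A, np.zeros((2, 2)), H, 1e-12 * np.eye(2), 40, rng,
            x0=np.array([3.0, -2.0]),
        )
        m = dec.LinearStateSpaceModel(A=A, W=np.zeros((2, 2)), H=H, Q=1e-12 * np.eye(2))
        tr = dec.kf_run(m, Y, x0=np.zeros(2), P0=np.eye(2))
        assert tr.x_post == pytest.approx(X, abs=1e-5)

    def test_posterior_matches_joint_gaussian_conditioning(self, rng):
        # brute-force oracle: condition the joint (states, observations)
        # Gaussian of a 4-step instance on the observations
        d, C, T = 2, 2, 4
        A = np.array([[0.9, 0.2], [-0.1, 0.8]])
        W = np.array([[0.3, 0.05], [0.05, 0.2]])
        H = np.array([[1.0, 0.5], [0.2, -1.0]])
        Q = np.array([[0.4, 0.0], [0.0, 0.3]])
        x0 = np.array([0.5, -0.3])
        P0 = np.array([[1.0, 0.1], [0.1, 0.8]])

        mu_x = np.zeros((T, d))
        mu_x[0] = A @ x0
        Cxx = np.zeros((T, T, d, d))
        Cxx[0, 0] = A @ P0 @ A.T + W
        for k in range(1, T):
            mu_x[k] = A @ mu_x[k - 1]
            Cxx[k, k] = A @ Cxx[k - 1, k - 1] @ A.T + W
            for l_ in range(k):
                Cxx[k, l_] = A @ Cxx[k - 1, l_]
                Cxx[l_, k] = Cxx[k, l_].T
        SX = np.block([[Cxx[i, j] for j in range(T)] for i in range(T)])
        mX = mu_x.ravel()
        Hb = np.kron(np.eye(T), H)
        SY = Hb @ SX @ Hb.T + np.kron(np.eye(T), Q)
        SXY = SX @ Hb.T
        mY = Hb @ mX

        Y = rng.normal(size=(T, C))
        y = Y.ravel()
        mean_post = mX + SXY @ np.linalg.solve(SY, y - mY)
        cov_post = SX - SXY @ np.linalg.solve(SY, SXY.T)

        m = dec.LinearStateSpaceModel(A=A, W=W, H=H, Q=Q)
        tr = dec.kf_run(m, Y, x0=x0, P0=P0)
        assert tr.x_post[-1] == pytest.approx(mean_post[-d:], abs=1e-8)
        assert tr.P_post[-1] == pytest.approx(
            cov_post[-d:, -d:], abs=1e-8
        )

    def test_covariance_trace_is_data_independent(self, rng):
        A = np.array([[0.9]])
        m = dec.LinearStateSpaceModel(
            A=A, W=np.array([[0.1]]), H=np.array([[1.0]]), Q=np.array([[0.5]])
        )
        t1 = dec.kf_run(m, rng.normal(size=(30, 1)))
        t2 = dec.kf_run(m, rng.normal(size=(30, 1)) + 5)
        assert np.array_equal(t1.P_norms, t2.P_norms)
        assert np.array_equal(t1.K_norms, t2.K_norms)

    def test_posterior_covariance_symmetric(self, rng):
        A = rng.normal(0, 0.3, (4, 4))
        m = dec.LinearStateSpaceModel(
            A=A, W=0.2 * np.eye(4), H=rng.normal(size=(6, 4)), Q=0.5 * np.eye(6)
        )
        tr = dec.kf_run(m, rng.normal(size=(50, 6)))
        asym = np.abs(tr.P_post - np.transpose(tr.P_post, (0, 2, 1))).max()
        assert asym < 1e-10


class TestANN:
    def test_zero_weights_output_equals_thresholds(self, rng):
        net = dec.ANNModel(
            W1=np.zeros((5, 3)), b1=np.zeros(5), W2=np.zeros((2, 5)),
            b2=np.array([1.5, -0.5]),
        )
        out = net.predict(rng.normal(size=(10, 3)))
        assert out == pytest.approx(np.tile([1.5, -0.5], (10, 1)))

    def test_beats_linear_fit_on_nonlinearly_tuned_data(self, rng):
        n, d, C = 3000, 4, 6
        B = rng.normal(0, 2.0, (C, d))
        X = rng.uniform(0, 1, (n, d))
        Y = np.logaddexp(0.0, X @ B.T - 2.0) + 0.05 * rng.standard_normal((n, C))
        Xtr, Ytr, Xte, Yte = X[:2000], Y[:2000], X[2000:], Y[2000:]
        net = dec.train_ann(Xtr, Ytr, seed=0)
        coef = np.linalg.lstsq(
            np.column_stack([Xtr, np.ones(len(Xtr))]), Ytr, rcond=None
        )[0]
        lin = np.column_stack([Xte, np.ones(len(Xte))]) @ coef
        mse_ann = np.mean((net.predict(Xte) - Yte) ** 2)
        mse_lin = np.mean((lin - Yte) ** 2)
        assert mse_ann < mse_lin

    def test_training_loss_monotone_at_stable_step_size(self, rng):
        # full-batch gradient descent at a small step is monotone on this
        # smooth loss; the faster default rate trades early monotonicity
        # for convergence speed
        X = rng.uniform(0, 1, (500, 3))
        Y = np.sin(3 * X[:, :1]) + 0.1 * rng.standard_normal((500, 1))
        net = dec.train_ann(X, Y, epochs=400, seed=1, learning_rate=0.05)
        lc = net.loss_curve
        assert lc[-1] < lc[0]
        assert np.all(np.diff(lc) < 1e-6 * lc[0])

    def test_duplicating_samples_leaves_fit_unchanged(self, rng):
        X = rng.uniform(0, 1, (200, 2))
        Y = X @ np.array([[1.0], [2.0]]) + 0.1 * rng.standard_normal((200, 1))
        n1 = dec.train_ann(X, Y, epochs=300, seed=3)
        n2 = dec.train_ann(np.vstack([X, X]), np.vstack([Y, Y]), epochs=300, seed=3)
        assert n1.predict(X) == pytest.approx(n2.predict(X), abs=1e-10)

    def test_divergence_raises_naming_learning_rate(self, rng):
        X = rng.uniform(0, 1, (100, 2)) * 100
        Y = rng.normal(size=(100, 2)) * 100
        with pytest.raises(dec.FitError, match="learning_rate"):
            dec.train_ann(X, Y, learning_rate=50.0, epochs=200, seed=0)

    def test_seed_reproducible(self, rng):
        X = rng.uniform(0, 1, (100, 2))
        Y = rng.normal(size=(100, 1))
        a = dec.train_ann(X, Y, epochs=50, seed=9)
        b = dec.train_ann(X, Y, epochs=50, seed=9)
        assert np.array_equal(a.W1, b.W1) and np.array_equal(a.W2, b.W2)


class TestSigmaPoints:
    def test_2d_plus_1_points(self):
        pts, w = dec.sigma_points(np.zeros(3), np.eye(3), dec.UKFParams(d=3))
        assert pts.shape == (7, 3)
        assert w.size == 7

    def test_weighted_moments_reproduce_mean_and_covariance(self, rng):
        d = 4
        Mrand = rng.normal(size=(d, d))
        P = Mrand @ Mrand.T + 0.5 * np.eye(d)
        x = rng.normal(size=d)
        pts, w = dec.sigma_points(x, P, dec.UKFParams(d=d))
        assert w.sum() == pytest.approx(1.0)
        assert w @ pts == pytest.approx(x, abs=1e-10)
        scatter = (pts - x).T @ np.diag(w) @ (pts - x)
        assert scatter == pytest.approx(P, abs=1e-10)

    def test_identity_covariance_lambda_zero_gives_sqrt2_offsets(self):
        params = dec.UKFParams(d=2, alpha=1.0, kappa=0.0)   # lambda = 0
        pts, w = dec.sigma_points(np.zeros(2), np.eye(2), params)
        assert w[0] == pytest.approx(0.0)
        expected = np.sqrt(2.0)
        assert sorted(np.abs(pts[1:]).max(axis=1)) == pytest.approx(
            [expected] * 4
        )

    def test_weight_normalisation_identity(self):
        for d, kappa in ((2, 1.0), (3, 0.0), (5, 3.0 - 5)):
            p = dec.UKFParams(d=d, kappa=kappa)
            w = p.weights
            assert w[0] + 2 * d * w[1] == pytest.approx(1.0)

    def test_non_decomposable_covariance_raises(self):
        P = -np.eye(2)
        with pytest.raises(dec.FilterError):
            dec.sigma_points(np.zeros(2), P, dec.UKFParams(d=2))


class TestUKF:
    def test_linear_net_reproduces_kalman_trace(self, rng):
        d, C = 3, 5
        A = np.diag([0.9, 0.85, 0.8]) + 0.02
        W = 0.1 * np.eye(d)
        H = rng.normal(size=(C, d))
        Q = 0.5 * np.eye(C)
        X, Y = _simulate_lgss(A, W, H, Q, 60, rng)
        m = dec.LinearStateSpaceModel(A=A, W=W, H=H, Q=Q)
        kf = dec.kf_run(m, Y, x0=np.zeros(d), P0=np.eye(d))
        ukf = dec.ukf_run(
            A, W, lambda pts: pts @ H.T, Q, Y, x0=np.zeros(d), P0=np.eye(d)
        )
        assert np.abs(ukf.x_post - kf.x_post).max() < 1e-8
        assert np.abs(ukf.P_post - kf.P_post).max() < 1e-8
        assert np.abs(ukf.K_gain - kf.K_gain).max() < 1e-8

    def test_default_initial_covariance_is_identity(self, rng):
        # first prediction must equal A P0 A' + W with P0 = I
        d = 2
        A = np.array([[0.9, 0.0], [0.0, 0.8]])
        W = 0.1 * np.eye(d)
        H = np.eye(d)
        seen = {}

        def probe(pts):
            if "P" not in seen:
                w = dec.UKFParams(d=d).weights
                x = w @ pts
                seen["P"] = (pts - x).T @ np.diag(w) @ (pts - x)
            return pts @ H.T

        dec.ukf_run(A, W, probe, 0.5 * np.eye(d), rng.normal(size=(3, d)))
        assert seen["P"] == pytest.approx(A @ np.eye(d) @ A.T + W, abs=1e-10)

    def test_posterior_covariance_symmetric_under_nonlinear_net(self, rng):
        d, C = 3, 4
        A = 0.9 * np.eye(d)
        W = 0.1 * np.eye(d)
        B = rng.normal(size=(d, C))
        net = lambda pts: np.tanh(pts @ B)
        tr = dec.ukf_run(A, W, net, 0.3 * np.eye(C), rng.normal(size=(40, C)))
        asym = np.abs(tr.P_post - np.transpose(tr.P_post, (0, 2, 1))).max()
        assert asym < 1e-10
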