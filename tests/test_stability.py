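"""PCA state space, nearest-neighbor divergence and LLE estimation."""
import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tapfatigue.core import ACCEL_CHANNELS
from tapfatigue.kinematics import NormalizedCycleSet
from tapfatigue.stability import (
    DivergenceCurve,
    build_state_space,
    divergence_curve,
    estimate_lle,
)


def _ncs(tensor):
    return NormalizedCycleSet(tensor, ACCEL_CHANNELS, np.arange(tensor.shape[0]))


class TestStateSpace:
    def test_planted_3d_subspace_fractions_sum_to_one(self, rng):
        latent = rng.standard_normal((20, 100, 3))
        mix = rng.standard_normal((9, 3))
        space = build_state_space(_ncs(latent @ mix.T))
        assert space.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(space.variance_fractions) <= 1e-12)

    def test_planted_variances_4_2_1(self, rng):
        # orthogonal mixing keeps component variances; fractions = (4,2,1)/7
        n = 6000
        latent = rng.standard_normal((n, 3)) * np.sqrt([4.0, 2.0, 1.0])
        q, _ = np.linalg.qr(rng.standard_normal((9, 9)))
        mix = q[:, :3]
        data = latent @ mix.T + 1e-6 * rng.standard_normal((n, 9))
        space = build_state_space(_ncs(data.reshape(60, 100, 9)))
        # eigen-decomposition oracle on the same data
        ev = np.linalg.eigvalsh(np.cov((data - data.mean(0)).T))[::-1][:3]
        oracle = ev / np.sum(np.linalg.eigvalsh(np.cov((data - data.mean(0)).T)))
        assert np.allclose(space.variance_fractions, oracle, atol=1e-6)
        assert np.allclose(space.variance_fractions, np.array([4, 2, 1]) / 7.0, atol=0.02)

    def test_rotation_invariant_fractions(self, rng):
        tensor = rng.standard_normal((10, 100, 9))
        q, _ = np.linalg.qr(rng.standard_normal((9, 9)))
        a = build_state_space(_ncs(tensor)).variance_fractions
        b = build_state_space(_ncs(tensor @ q.T)).variance_fractions
        assert np.allclose(a, b, atol=1e-9)

    def test_rank_deficient_rejected(self):
        tensor = np.zeros((10, 100, 9))
        tensor[..., 0] = np.random.default_rng(0).standard_normal((10, 100))
        with pytest.raises(ValueError, match="rank"):
            build_state_space(_ncs(tensor))


def _circle_scores(n_cycles=6, n_phase=100, radius=5.0):
    phase = np.linspace(0, 2 * np.pi, n_phase, endpoint=False)
    one = np.column_stack([radius * np.cos(phase), radius * np.sin(phase), 0 * phase])
    return np.tile(one, (n_cycles, 1))


class TestDivergenceCurve:
    def test_planted_exponential_pair_exact(self):
        # cycle 2 = cycle 1 + d0 * exp(gamma * phase) along a fixed direction
        gamma, d0 = 0.05, 1e-3
        base = _circle_scores(n_cycles=2)
        offset = d0 * np.exp(gamma * np.arange(100))
        base[100:, 2] += offset
        curve = divergence_curve(base, theiler=100, K=50, segment_len=100)
        expected = gamma * curve.k
        assert np.allclose(curve.y - curve.y[0], expected, atol=1e-9)

    def test_periodic_noiseless_flat(self):
        curve = divergence_curve(_circle_scores(8) +
                                 1e-9 * np.random.default_rng(0).standard_normal((800, 3)),
                                 theiler=100, K=50, segment_len=100)
        assert np.ptp(curve.y) < 0.5  # flat on the log scale

    def test_matches_brute_force_all_pairs(self, rng):
        scores = rng.standard_normal((500, 3)).cumsum(axis=0)
        theiler, K = 50, 30
        curve = divergence_curve(scores, theiler=theiler, K=K)
        # brute-force oracle: full distance matrix, per-k exclusion
        T = scores.shape[0]
        d2 = ((scores[:, None, :] - scores[None, :, :]) ** 2).sum(-1)
        ii = np.arange(T)
        d2[np.abs(ii[:, None] - ii[None, :]) < theiler] = np.inf
        nn = np.argmin(d2, axis=1)
        for k in range(K + 1):
            ok = (ii + k < T) & (nn + k < T)
            d = np.linalg.norm(scores[ii[ok] + k] - scores[nn[ok] + k], axis=1)
            assert curve.y[k] == pytest.approx(np.mean(np.log(d[d > 0])))

    def test_zero_distance_pairs_excluded(self):
        # cycles 0-2 are exact copies (zero neighbor distances, excluded);
        # cycle 3 is offset so the log mean stays finite
        scores = _circle_scores(4)
        scores[300:, 2] += 1e-3
        curve = divergence_curve(scores, theiler=100, K=10, segment_len=100)
        assert curve.n_zero_excluded > 0
        assert np.isfinite(curve.y).all()

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            divergence_curve(np.zeros((100, 3)), theiler=90, K=20)


class TestEstimateLle:
    def test_linear_curve_every_horizon_equal(self):
        k = np.arange(51)
        curve = DivergenceCurve(k, -3.0 + 0.05 * k, np.full(51, 10))
        lle = estimate_lle(curve)
        for h in (5, 10, 25, 50):
            assert lle[h] == pytest.approx(0.05, abs=1e-12)

    def test_flat_curve_zero(self):
        k = np.arange(51)
        lle = estimate_lle(DivergenceCurve(k, np.full(51, -2.0), np.full(51, 10)))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in lle.values())

    def test_exponential_then_saturating_monotone(self):
        # growth at 0.08/sample until k=10, then saturated: lambda5 >= lambdaH
        k = np.arange(51)
        y = np.minimum(0.08 * k, 0.8)
        lle = estimate_lle(DivergenceCurve(k, -1.0 + y, np.full(51, 10)))
        assert lle[5] >= lle[10] >= lle[25] >= lle[50]
        assert lle[5] == pytest.approx(0.08, rel=1e-9)

    def test_scale_invariant(self, rng):
        scores = rng.standard_normal((600, 3)).cumsum(axis=0)
        a = estimate_lle(divergence_curve(scores, theiler=50, K=50))
        b = estimate_lle(divergence_curve(10.0 * scores, theiler=50, K=50))
        for h in (5, 10, 25, 50):
            assert a[h] == pytest.approx(b[h], abs=1e-9)

    def test_short_curve_rejected(self):
        curve = DivergenceCurve(np.arange(11), np.zeros(11), np.full(11, 5))
        with pytest.raises(ValueError, match="horizon"):
            estimate_lle(curve, horizons=(5, 50))


def _lorenz_trajectory(dt=0.01, n=8000, discard=1000):
    def f(_, s):
        x, y, z = s
        return [10.0 * (y - x), x * (28.0 - z) - y, x * y - 8.0 / 3.0 * z]

    t_eval = np.arange(n + discard) * dt
    sol = solve_ivp(f, (0, t_eval[-1]), [1.0, 1.0, 20.0], t_eval=t_eval,
                    rtol=1e-9, atol=1e-9, method="RK45")
    return sol.y.T[discard:]


def _benettin_lle(traj, dt):
    """Tangent-propagation oracle along the same trajectory (per time unit)."""
    def jac(s):
        x, y, z = s
        return np.array([[-10.0, 10.0, 0.0], [28.0 - z, -1.0, -x], [y, x, -8.0 / 3.0]])

    v = np.array([1.0, 0.0, 0.0])
    total = 0.0
    for s in traj[:-1]:
        # one RK4 step of the variational equation
        def dv(vv, state=s):
            return jac(state) @ vv
        k1 = dv(v)
        k2 = dv(v + 0.5 * dt * k1)
        k3 = dv(v + 0.5 * dt * k2)
        k4 = dv(v + dt * k3)
        v = v + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        norm = np.linalg.norm(v)
        total += np.log(norm)
        v /= norm
    return total / ((len(traj) - 1) * dt)


class TestChaoticFixture:
    def test_lorenz_lle_matches_benettin_oracle(self):
        """Rosenstein estimate on a standard 3-D chaotic flow agrees with a
        Benettin-style tangent-propagation oracle computed on the same
        trajectory (within 15%)."""
        dt = 0.01
        traj = _lorenz_trajectory(dt=dt)
        oracle = _benettin_lle(traj, dt)  # ~0.90 per time unit
        # Theiler window of one mean orbit (~0.75 time units); the slope is
        # fitted on the exponential plateau after the neighbor-convergence
        # transient (one orbit) and before saturation
        curve = divergence_curve(traj, theiler=75, K=140)
        sel = (curve.k >= 75) & (curve.k <= 135)
        lam = np.polyfit(curve.k[sel], curve.y[sel], 1)[0] / dt
        assert lam == pytest.approx(oracle, rel=0.15)
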