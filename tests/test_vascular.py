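"""Vascular ring: geometry, coupling kernel, dynamics, deficit, synchrony."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurovasc.vascular import (
    ConstantTraceError,
    NumericalInstabilityError,
    RingNetwork,
    VascularParams,
    VascularState,
    build_coupling_matrix,
    build_ring_geometry,
    compute_apc,
    compute_supply,
    step_vascular,
    update_deficit,
)


def chord_distance_oracle(n, rho):
    """Direct scalar evaluation of the chord formula for every pair."""
    angles = [2 * np.pi * j / n for j in range(n)]
    d = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            d[j, k] = rho * np.sqrt(
                (np.cos(angles[j]) - np.cos(angles[k])) ** 2
                + (np.sin(angles[j]) - np.sin(angles[k])) ** 2
            )
    return d


class TestRingGeometry:
    def test_two_opposite_vessels(self):
        angles, d = build_ring_geometry(2, 1.0)
        assert np.allclose(angles, [0.0, np.pi])
        assert d[0, 1] == pytest.approx(2.0)  # diameter

    def test_zero_diagonal_and_symmetry(self):
        _, d = build_ring_geometry(7, 2.5)
        assert np.allclose(np.diag(d), 0.0)
        assert np.allclose(d, d.T)

    @pytest.mark.parametrize("n,rho", [(4, 1.0), (8, 1.0), (5, 3.0)])
    def test_matches_scalar_oracle(self, n, rho):
        _, d = build_ring_geometry(n, rho)
        assert np.allclose(d, chord_distance_oracle(n, rho), atol=1e-12)
        if n == 4:
            assert d[0, 1] == pytest.approx(np.sqrt(2.0))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            build_ring_geometry(1, 1.0)
        with pytest.raises(ValueError):
            build_ring_geometry(4, 0.0)


class TestCouplingMatrix:
    def test_beyond_cutoff_is_zero(self):
        d = np.array([[0.0, 4.0], [4.0, 0.0]])
        T = build_coupling_matrix(d, epsilon=1.0, sigma=1.0)
        assert T[0, 1] == 0.0 and T[1, 0] == 0.0

    def test_zero_distance_full_inhibition(self):
        # at d = 0 the kernel gives epsilon - 2; visible on the diagonal
        # when self-coupling is enabled
        d = np.zeros((2, 2))
        T = build_coupling_matrix(d, epsilon=0.0, sigma=1.0, self_coupling=True)
        assert np.allclose(T, -2.0)

    @pytest.mark.parametrize("kernel", ["gaussian", "printed"])
    def test_matches_scalar_oracle_on_ring(self, kernel):
        n, eps, sigma, rho = 8, 1.0, 1.0, 1.0
        _, d = build_ring_geometry(n, rho)
        T = build_coupling_matrix(d, eps, sigma, kernel=kernel, self_coupling=True)
        for j in range(n):
            for k in range(n):
                expo = d[j, k] ** 2 / sigma**2 if kernel == "gaussian" else d[j, k] / sigma**2
                expected = eps - 2 * np.exp(-expo) if d[j, k] < 3 * sigma else 0.0
                assert T[j, k] == pytest.approx(expected, abs=1e-12)

    def test_epsilon_extremes_sign_structure(self):
        _, d = build_ring_geometry(12, 1.0)
        sigma = 2 * np.pi / 12
        T0 = build_coupling_matrix(d, 0.0, sigma)
        T2 = build_coupling_matrix(d, 2.0, sigma)
        nz = T0 != 0
        assert np.all(T0[nz] < 0)  # mutual inhibition
        assert np.all(T2[T2 != 0] >= 0) or not np.any(T2 != 0)

    @settings(max_examples=25, deadline=None)
    @given(
        n=st.integers(3, 12),
        eps=st.floats(0.0, 2.0),
        sigma=st.floats(0.05, 3.0),
    )
    def test_symmetry_property(self, n, eps, sigma):
        _, d = build_ring_geometry(n, 1.0)
        T = build_coupling_matrix(d, eps, sigma)
        assert np.allclose(T, T.T)
        assert np.all(T[d >= 3 * sigma] == 0.0)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            build_coupling_matrix(np.zeros((2, 2)), 1.0, 0.0)


def _make_state(g, u, lambda_v, E=0.0, I=0.0):
    g = np.asarray(g, dtype=float)
    u = np.asarray(u, dtype=float)
    return VascularState(g=g, u=u, S=np.tanh(lambda_v * g), E=E, I=I)


class TestVesselDynamics:
    def test_origin_is_fixed_point(self):
        p = VascularParams(n=4)
        T = np.zeros((4, 4))
        st0 = _make_state(np.zeros(4), np.zeros(4), p.lambda_v)
        st1 = step_vascular(st0, p, T, I=0.0)
        assert np.allclose(st1.g, 0.0) and np.allclose(st1.u, 0.0) and np.allclose(st1.S, 0.0)

    def test_uncoupled_vessel_oscillates_while_relaxing(self):
        # with no coupling the deviation decays through a spiral: g changes
        # sign repeatedly along the way
        p = VascularParams(n=2, dt=0.001)
        T = np.zeros((2, 2))
        st_ = _make_state([0.1, 0.1], [0.0, 0.0], p.lambda_v)
        signs = []
        for _ in range(int(60.0 / p.dt)):
            st_ = step_vascular(st_, p, T, I=0.0)
            signs.append(np.sign(st_.g[0]))
        changes = np.sum(np.abs(np.diff([s for s in signs if s != 0])) > 0)
        assert changes >= 3

    def test_step_halving_convergence(self):
        # Euler trajectories at dt and dt/10 agree over 10 time units
        def integrate(dt):
            p = VascularParams(n=3, epsilon=0.0, dt=dt)
            _, d = build_ring_geometry(3, 1.0)
            T = build_coupling_matrix(d, p.epsilon, p.sigma_value)
            st_ = _make_state([0.05, -0.02, 0.01], [0.0, 0.01, -0.01], p.lambda_v)
            for _ in range(int(10.0 / dt)):
                st_ = step_vascular(st_, p, T, I=0.1)
            return st_.g

        g_coarse = integrate(0.01)
        g_fine = integrate(0.001)
        assert np.allclose(g_coarse, g_fine, atol=0.02)

    def test_state_stays_in_tanh_range(self):
        p = VascularParams(n=10, epsilon=0.0)
        ring = RingNetwork(p, rng=np.random.default_rng(0))
        _, S = ring.simulate(50.0, N_d=5.0)
        assert np.all(np.abs(S) < 1.0)

    def test_instability_raises(self):
        p = VascularParams(n=2, dt=1e6)
        T = np.full((2, 2), 1.0)
        st_ = _make_state([0.5, 0.5], [0.0, 0.0], p.lambda_v)
        with pytest.raises(NumericalInstabilityError):
            with np.errstate(over="ignore", invalid="ignore"):
                for _ in range(200):
                    st_ = step_vascular(st_, p, T, I=1.0)

    def test_fast_loop_matches_reference_step(self):
        # the compiled inner loop must agree with the stepwise reference
        p = VascularParams(n=6, epsilon=1.0)
        ring = RingNetwork(p, rng=np.random.default_rng(3))
        ref = ring.state.copy()
        ring.advance(200, N_d=3.0)
        st_ = ref
        E, I = st_.E, st_.I
        for _ in range(200):
            st_ = step_vascular(st_, p, ring.T, I)
            _, E, I = update_deficit(E, 3.0, compute_supply(st_.S), p)
            st_.E = E
        assert np.allclose(ring.state.g, st_.g, atol=1e-10)
        assert ring.state.E == pytest.approx(E, abs=1e-10)


class TestSupplyAndDeficit:
    def test_supply_is_sum(self, rng):
        S = rng.uniform(-1, 1, 17)
        assert compute_supply(S) == pytest.approx(sum(float(s) for s in S))
        assert compute_supply(np.array([0.9, -0.9])) == pytest.approx(0.0)

    def test_deficit_zero_when_balanced(self):
        p = VascularParams(n=4)
        e, E, I = update_deficit(1.0, N_d=2.0, N_s=2.0, params=p)
        assert e == 0.0
        assert E == pytest.approx(1.0)
        assert I == pytest.approx(1.0 - 2.0)

    def test_saturated_increment(self):
        p = VascularParams(n=4)
        _, E, _ = update_deficit(0.0, N_d=1e9, N_s=0.0, params=p)
        assert E == pytest.approx(p.dt / p.tau_e)

    def test_constant_deficit_linear_growth(self):
        # closed form E(t) = E0 + t * tanh(lambda_e * e) / tau_e
        p = VascularParams(n=4)
        e_const, E = 0.7, 0.2
        for _ in range(100):
            _, E, _ = update_deficit(E, N_d=e_const, N_s=0.0, params=p)
        t = 100 * p.dt
        assert E == pytest.approx(0.2 + t * np.tanh(p.lambda_e * e_const) / p.tau_e, rel=1e-12)


def apc_oracle(S):
    """Brute-force double loop over ordered pairs of Pearson correlations."""
    n = S.shape[0]
    total = 0.0
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            xj = S[j] - S[j].mean()
            xk = S[k] - S[k].mean()
            total += (xj * xk).sum() / np.sqrt((xj**2).sum() * (xk**2).sum())
    return total / (n * (n - 1))


class TestAPC:
    def test_identical_traces(self, rng):
        trace = rng.normal(size=40)
        S = np.tile(trace, (5, 1))
        assert compute_apc(S) == pytest.approx(1.0)

    def test_antiphase_pair(self, rng):
        trace = rng.normal(size=30)
        assert compute_apc(np.vstack([trace, -trace])) == pytest.approx(-1.0)

    def test_matches_pairwise_oracle(self, rng):
        S = rng.normal(size=(5, 50))
        assert compute_apc(S) == pytest.approx(apc_oracle(S), abs=1e-12)

    def test_constant_trace_reports_vessel(self, rng):
        S = rng.normal(size=(4, 20))
        S[2] = 0.42
        with pytest.raises(ConstantTraceError) as exc:
            compute_apc(S)
        assert exc.value.vessel == 2


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n=1),
            dict(epsilon=-0.1),
            dict(epsilon=2.5),
            dict(tau_v=0.0),
            dict(dt=-0.01),
            dict(kernel="nope"),
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            VascularParams(**kwargs)

    def test_default_sigma_is_1p5_spacings(self):
        p = VascularParams(n=100, rho=1.0)
        assert p.sigma_value == pytest.approx(1.5 * 2 * np.pi / 100)
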