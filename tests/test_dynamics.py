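import numpy as np
import pytest

from efgmep import (
    ActivationMap,
    DiffusionParams,
    FHNParams,
    SimTrace,
    Stimulus,
    activation_times,
    assemble,
    build_background_mesh,
    conduction_velocity,
    integrate_euler,
    integrate_rk4_adaptive,
    make_regular_grid,
    step_euler,
)
from efgmep.dynamics import (
    FHNSystem,
    HeatSystem,
    MassSolver,
    estimate_lambda_max,
    euler_diffusion_final,
    front_speed,
)
from efgmep.errors import (
    BlowUpError,
    InsufficientDataError,
    InvalidArgumentError,
    StiffnessError,
)


@pytest.fixture(scope="module")
def heat_2d_system():
    cloud, dom = make_regular_grid([(-10.0, 10.0)] * 2, [11, 11])
    mesh = build_background_mesh(dom, [10, 10])
    mats = assemble(cloud, None, dom, mesh, 4, 2.0, params=DiffusionParams(1.0, 1.0))
    return cloud, mats


class TestEuler:
    def test_scalar_decay_one_step(self):
        lam = 0.7
        y = step_euler(np.array([2.0]), 0.1, lambda t, v: -lam * v)
        assert y[0] == pytest.approx(2.0 * (1 - lam * 0.1), abs=1e-15)

    def test_constant_field_is_diffusion_equilibrium(self, heat_2d_system):
        _, mats = heat_2d_system
        sys_ = HeatSystem(mats)
        v = np.full(mats.n_nodes, 3.0)
        out = step_euler(v, 1e-3, sys_.rhs)
        assert np.allclose(out, v, atol=1e-10)

    def test_blowup_detected(self):
        with pytest.raises(BlowUpError) as exc:
            step_euler(np.array([1.0]), 1.0, lambda t, v: np.full_like(v, np.inf), step=7)
        assert exc.value.step == 7

    def test_stability_guard(self, heat_2d_system):
        _, mats = heat_2d_system
        lam = estimate_lambda_max(mats)
        sys_ = HeatSystem(mats)
        with pytest.raises(InvalidArgumentError):
            integrate_euler(
                np.ones(mats.n_nodes), 0.0, 10.0, 3, sys_.rhs, stability_limit=lam
            )

    def test_krylov_propagator_equals_direct_stepping(self, heat_2d_system):
        cloud, mats = heat_2d_system
        sys_ = HeatSystem(mats)
        rng = np.random.default_rng(1)
        v0 = rng.standard_normal(mats.n_nodes)
        trace = integrate_euler(v0, 0.0, 0.5, 5000, sys_.rhs, record_every=5000)
        vf = euler_diffusion_final(mats, v0, 0.5, 5000)
        assert np.allclose(vf, trace.v[-1], atol=1e-10 * np.abs(v0).max())

    def test_diffusion_conserves_weak_mass(self, heat_2d_system):
        cloud, mats = heat_2d_system
        sys_ = HeatSystem(mats)
        rng = np.random.default_rng(2)
        v0 = rng.random(mats.n_nodes)
        trace = integrate_euler(v0, 0.0, 1.0, 2000, sys_.rhs, record_every=400)
        total0 = (mats.M @ v0).sum()
        for v in trace.v:
            assert (mats.M @ v).sum() == pytest.approx(total0, rel=1e-6)


class TestMassSolver:
    def test_banded_and_lu_agree(self, heat_2d_system):
        import scipy.sparse as sp
        import scipy.sparse.linalg as spla

        _, mats = heat_2d_system
        ms = MassSolver(mats)
        b = np.random.default_rng(0).standard_normal(mats.n_nodes)
        ref = spla.spsolve(sp.csc_matrix(mats.M), b)
        assert np.allclose(ms.solve(b), ref, atol=1e-10)

    def test_lumped_mode(self, heat_2d_system):
        _, mats = heat_2d_system
        ms = MassSolver(mats, lumped=True)
        b = np.ones(mats.n_nodes)
        assert np.allclose(ms.solve(b) * mats.lumped_mass(), b)

    def test_lambda_max_close_to_dense_eigenvalue(self, heat_2d_system):
        import scipy.linalg as sla

        _, mats = heat_2d_system
        lam = estimate_lambda_max(mats)
        ref = np.max(sla.eigvalsh(mats.K.toarray(), mats.M.toarray()))
        assert lam == pytest.approx(ref, rel=0.05)


class TestRK4Adaptive:
    def test_zero_rhs_constant_state(self):
        y0 = np.array([1.0, -2.0])
        trace = integrate_rk4_adaptive(y0, (0.0, 5.0), lambda t, y: 0.0 * y)
        assert np.allclose(trace.v[-1], y0)
        assert trace.stats["rejected"] == 0

    def test_fhn_single_cell_matches_reference(self):
        from scipy.integrate import solve_ivp

        from efgmep.ionic import fhn_rhs

        p = FHNParams()

        def rhs(t, y):
            f, dw = fhn_rhs(y[:1], y[1:], p)
            return np.concatenate([f, dw])

        trace = integrate_rk4_adaptive(
            np.array([0.5, 0.0]), (0.0, 400.0), rhs, rtol=1e-7, atol=1e-9
        )
        ref = solve_ivp(
            rhs, (0.0, 400.0), [0.5, 0.0], rtol=1e-11, atol=1e-13, dense_output=True
        )
        err = np.abs(trace.v[:, 0] - ref.sol(trace.times)[0]).max()
        assert err <= 1e-4

    def test_snapshots_by_interpolation(self):
        trace = integrate_rk4_adaptive(
            np.array([1.0]), (0.0, 2.0), lambda t, y: -y,
            snapshot_times=[0.5, 1.5],
        )
        snaps = trace.stats["snapshots"]
        assert snaps[0.5][0] == pytest.approx(np.exp(-0.5), rel=1e-3)
        assert snaps[1.5][0] == pytest.approx(np.exp(-1.5), rel=1e-3)

    def test_determinism(self):
        rhs = lambda t, y: np.sin(y) - 0.3 * y
        a = integrate_rk4_adaptive(np.array([0.3]), (0.0, 10.0), rhs)
        b = integrate_rk4_adaptive(np.array([0.3]), (0.0, 10.0), rhs)
        assert np.array_equal(a.v, b.v) and np.array_equal(a.times, b.times)

    def test_step_underflow_raises(self):
        def nasty(t, y):
            return np.full_like(y, np.inf)

        with pytest.raises(StiffnessError):
            integrate_rk4_adaptive(np.array([1.0]), (0.0, 1.0), nasty, dt_min=1e-6)


class TestActivation:
    def _logistic_trace(self, t0_list, tau=1.0, t_end=40.0, nt=400):
        t = np.linspace(0.0, t_end, nt)
        v = np.stack(
            [1.0 / (1.0 + np.exp(-(t - t0) / tau)) for t0 in t0_list], axis=1
        )
        return SimTrace(times=t, v=v)

    def test_logistic_inflection(self):
        trace = self._logistic_trace([20.0])
        act = activation_times(trace, v_threshold_fallback=0.5)
        dt_sample = trace.times[1] - trace.times[0]
        assert abs(act.times[0] - 20.0) <= dt_sample
        assert not act.not_activated[0]

    def test_flat_trace_not_activated(self):
        t = np.linspace(0, 10, 50)
        trace = SimTrace(times=t, v=np.zeros((50, 3)))
        act = activation_times(trace, v_threshold_fallback=0.5)
        assert np.all(act.not_activated)

    def test_shift_equivariance(self):
        trace = self._logistic_trace([15.0, 21.5])
        act = activation_times(trace, v_threshold_fallback=0.5)
        dt_sample = trace.times[1] - trace.times[0]
        assert act.times[1] - act.times[0] == pytest.approx(6.5, abs=dt_sample)

    def test_requires_three_samples(self):
        trace = SimTrace(times=np.array([0.0, 1.0]), v=np.zeros((2, 1)))
        with pytest.raises(InvalidArgumentError):
            activation_times(trace, 0.5)


class TestConductionVelocity:
    def test_exact_linear_front(self):
        gamma = 0.6
        x = np.linspace(0, 20, 41)
        act = ActivationMap(times=x / gamma, not_activated=np.zeros(41, bool))
        vel, summary = conduction_velocity(act, x, reference=gamma)
        assert np.allclose(vel, gamma)
        assert summary["rms"] == pytest.approx(0.0, abs=1e-12)
        assert summary["mean"] == pytest.approx(gamma)

    def test_rms_hand_value(self):
        # RMS of exact (1,1) vs numerical (0,2) = sqrt(((1-0)^2+(1-2)^2)/2) = 1
        ref = np.array([1.0, 1.0])
        num = np.array([0.0, 2.0])
        assert np.sqrt(np.mean((ref - num) ** 2)) == pytest.approx(1.0)

    def test_insufficient_nodes(self):
        act = ActivationMap(times=np.array([0.0, 1.0]), not_activated=np.zeros(2, bool))
        with pytest.raises(InsufficientDataError):
            conduction_velocity(act, np.array([0.0, 1.0]))

    def test_front_speed_plane_fit(self):
        x = np.repeat(np.arange(11.0), 4)
        act = ActivationMap(times=5.0 + x / 0.25, not_activated=np.zeros(44, bool))
        speed = front_speed(act, x, exclude_below=0.0)
        assert speed == pytest.approx(0.25, rel=1e-9)


class TestStimulus:
    def test_initial_value_mode(self):
        s = Stimulus(node_indices=[1, 3], mode="initial_value", amplitude=2.0)
        v = s.initial_state(5)
        assert np.allclose(v, [0, 2, 0, 2, 0])

    def test_current_window(self):
        s = Stimulus(node_indices=[0], mode="current", amplitude=1.5, onset=2.0, duration=3.0)
        assert s.current(1.0, 2)[0] == 0.0
        assert s.current(4.0, 2)[0] == 1.5
        assert s.current(5.5, 2)[0] == 0.0

    def test_invalid_mode(self):
        with pytest.raises(InvalidArgumentError):
            Stimulus(node_indices=[0], mode="banana")
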