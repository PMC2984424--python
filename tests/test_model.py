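"""Unit and property tests for the oscillator model primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from segclock.model import (
    FrozenCellError,
    ModelParams,
    advect,
    cell_state,
    closed_form_freeze_phase,
    closed_form_freeze_time,
    domain_length,
    freeze_update,
    growth_rate,
    initial_state,
    oscillation_period,
    oscillation_period_age,
    phase_step,
    simulate,
)

P = ModelParams()  # published constants: A=0.5, B=5, T0=1, L0=2, t_end=50


class TestGrowthLaw:
    @pytest.mark.parametrize(
        "t, L0, expected",
        [(0.0, 2.0, 2.0), (48.0, 2.0, 50.0), (0.0, 5.0, 5.0)],
    )
    def test_linear_length(self, t, L0, expected):
        assert domain_length(t, ModelParams(L0=L0)) == expected

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            domain_length(-0.1, P)

    @pytest.mark.parametrize("t, expected", [(0.0, 0.5), (8.0, 0.1)])
    def test_uniform_relative_rate(self, t, expected):
        assert growth_rate(t, P) == pytest.approx(expected)

    def test_rate_decays_monotonically(self):
        t = np.linspace(0, 50, 200)
        r = growth_rate(t, P)
        assert np.all(np.diff(r) < 0)
        assert r[-1] < 0.02  # 1/(50+2)


class TestAdvection:
    def test_anterior_fixed_and_endpoints(self):
        st_ = initial_state(P)
        for _ in range(5):
            st_ = advect(st_, 10.0, P)
        assert st_.x[0] == 0.0
        assert st_.x[-1] == pytest.approx(52.0)  # rho=1 rides the posterior end

    def test_rho_conserved_to_machine_precision(self):
        st_ = initial_state(P)
        rho0 = st_.rho.copy()
        for _ in range(100):
            st_ = advect(st_, 0.5, P)
        np.testing.assert_array_equal(st_.rho, rho0)
        np.testing.assert_allclose(st_.x, rho0 * domain_length(st_.t, P), rtol=1e-14)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        rho=st.lists(st.floats(0, 1), min_size=2, max_size=20, unique=True),
        t=st.floats(0.01, 49.0),
    )
    def test_order_preserved(self, rho, t):
        """The uniform-growth map is monotone: cell order never changes."""
        state = initial_state(ModelParams(n_cells=50))
        r = np.sort(np.asarray(rho))
        state.rho = r
        state.x = r * P.L0
        state.frozen = np.zeros(r.size, bool)
        out = advect(state, t, P)
        assert np.all(np.diff(out.x) > 0)

    def test_localized_variant_rejected(self):
        p = ModelParams(variant="localized_age", n_cells=50)
        with pytest.raises(ValueError):
            advect(initial_state(p), 0.1, p)


class TestPeriodRules:
    @pytest.mark.parametrize("d, expected", [(0.0, 1.0), (2.0, 2.0), (8.0, 5.0)])
    def test_distance_period(self, d, expected):
        """T(d) = T0(1 + A d); reaches the critical period B at d* = 8."""
        state = initial_state(P)
        state.t = 10.0
        state.x[0] = domain_length(10.0, P) - d
        assert oscillation_period(state, 0, P) == pytest.approx(expected)

    def test_frozen_cell_has_no_period(self):
        state = initial_state(P)
        state.frozen[0] = True
        with pytest.raises(FrozenCellError):
            oscillation_period(state, 0, P)

    @pytest.mark.parametrize("a, expected", [(0.0, 1.0), (8.0, 5.0), (2.0, 2.0)])
    def test_age_period(self, a, expected):
        assert oscillation_period_age(a, P) == pytest.approx(expected)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            oscillation_period_age(-1.0, P)

    def test_gradient_fastest_at_posterior(self):
        """At fixed t the period rises monotonically toward the anterior."""
        state = initial_state(P)
        T = [oscillation_period(state, i, P) for i in range(0, P.n_cells, 400)]
        assert np.all(np.diff(T) < 0)  # anterior-to-posterior indexing
        assert oscillation_period(state, P.n_cells - 1, P) == pytest.approx(P.T0)


class TestPhaseAndFreezing:
    def test_posterior_cell_one_cycle_per_period(self):
        state = initial_state(P)
        out = phase_step(state, P.T0, P)
        assert out.phi[-1] - state.phi[-1] == pytest.approx(2 * np.pi)

    def test_frozen_phase_immutable(self):
        state = initial_state(P)
        state.frozen[:] = True
        out = phase_step(state, 1.0, P)
        np.testing.assert_array_equal(out.phi, state.phi)

    def test_no_freezing_at_start(self):
        """Initial tissue (max d = L0 = 2 < d* = 8): everything oscillates."""
        out = freeze_update(initial_state(P), P)
        assert not out.frozen.any()

    def test_freeze_beyond_critical_distance_and_idempotence(self):
        state = initial_state(P)
        state.t = 20.0
        state.x = state.rho * domain_length(20.0, P)
        out = freeze_update(state, P)
        d = domain_length(20.0, P) - out.x
        np.testing.assert_array_equal(out.frozen, d >= P.d_star)
        again = freeze_update(out, P)
        np.testing.assert_array_equal(again.z_frozen, out.z_frozen)
        np.testing.assert_array_equal(again.freeze_time, out.freeze_time)

    @pytest.mark.parametrize("phi, expected", [(0.0, 10.0), (np.pi, -10.0), (np.pi / 2, 0.0)])
    def test_cell_state_cosine(self, phi, expected):
        assert cell_state(phi, P) == pytest.approx(expected, abs=1e-12)


class TestClosedForms:
    @pytest.mark.parametrize("u, expected", [(1.0, 6.0), (0.5, 14.0)])
    def test_freeze_time(self, u, expected):
        assert closed_form_freeze_time(u, P) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "u, expected",
        [(1.0, 2 * np.log(2.5)), (0.5, 4 * np.log(10 / 3))],
    )
    def test_freeze_phase(self, u, expected):
        assert closed_form_freeze_phase(u, P) == pytest.approx(expected)

    @pytest.mark.parametrize("bad_u", [0.0, -0.5, 1.5])
    def test_domain_errors(self, bad_u):
        with pytest.raises(ValueError):
            closed_form_freeze_time(bad_u, P)
        with pytest.raises(ValueError):
            closed_form_freeze_phase(bad_u, P)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(u=st.floats(0.05, 1.0))
    def test_phase_matches_independent_quadrature(self, u):
        """N(u) equals the numerically integrated cycles along d(t) = u(t+L0)."""
        tf = closed_form_freeze_time(u, P)
        n_quad, _ = quad(lambda t: 1.0 / (P.T0 * (1 + P.A * u * (t + P.L0))), 0.0, tf)
        assert closed_form_freeze_phase(u, P) == pytest.approx(n_quad, abs=1e-9)

    def test_cycle_count_decreases_toward_anterior(self):
        u = np.linspace(0.02, 1.0, 300)
        assert np.all(np.diff(closed_form_freeze_phase(u, P)) < 0)


class TestSimulate:
    def test_short_horizon_freezes_nothing(self):
        """Anterior freeze time is t = d*/1 - L0 = 6, so t_end=5 stays fluid."""
        kymo = simulate(ModelParams(t_end=5.0, n_cells=200, sample_dt=0.5))
        assert np.all(np.isnan(kymo.cell_freeze_time))
        assert np.all(np.isnan(kymo.front_hi))

    def test_lengths_strictly_increase(self, fig_kymo):
        assert np.all(np.diff(fig_kymo.lengths) > 0)

    def test_frozen_front_monotone_prefix(self, fig_kymo):
        """Frozen region is an anterior prefix whose front never retreats."""
        fh = fig_kymo.front_hi
        seen = fh[~np.isnan(fh)]
        assert np.all(np.diff(seen) >= 0)
        # prefix in material coordinates: frozen cells are exactly those with
        # u = 1 - rho >= d*/L(t_end)
        u = 1.0 - fig_kymo.cell_rho
        frozen = ~np.isnan(fig_kymo.cell_freeze_time)
        u_star = P.d_star / domain_length(P.t_end, P)
        np.testing.assert_array_equal(frozen, u >= u_star - 1e-12)

    def test_cell_count_conserved(self, fig_kymo):
        assert fig_kymo.cell_rho.size == fig_kymo.params.n_cells

    def test_deterministic(self):
        p = ModelParams(t_end=8.0, n_cells=120, dt=0.02, sample_dt=0.5)
        a, b = simulate(p), simulate(p)
        np.testing.assert_array_equal(a.z_grid, b.z_grid)
        np.testing.assert_array_equal(a.cell_freeze_time, b.cell_freeze_time)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(A=-0.5),
            dict(B=0.5),  # violates B > T0
            dict(T0=0.0),
            dict(dt=0.2),  # violates dt <= T0/20
            dict(n_cells=10),
            dict(variant="nonsense"),
            dict(variant="localized_age", pz_width=-1.0),
            dict(L0=0.0),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)
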