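"""Well-mixed kinetics: closed-form eigenvalues, stationary states, time evolution."""

import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rtcycle import (
    CarryingCapacity,
    DensityTriple,
    KineticRates,
    ModelParams,
    ParameterError,
    Transport,
    build_rate_matrix,
    eigenvalues,
    evolve_linear,
    evolve_nonlinear,
    series_to_frame,
    stationary_state,
    unstable_eigenvalue_approx,
)

pos_rates = st.builds(
    KineticRates,
    lambda_s=st.floats(0.01, 20),
    lambda_d=st.floats(0.01, 20),
    lambda_e=st.floats(0.01, 20),
    mu=st.floats(0.01, 20),
)


def _rk4_reference(M, rho0, t_end, dt=1e-4):
    """Independent fixed-step RK4 integrator of d(rho)/dt = M rho."""
    rho = rho0.copy()
    n = int(round(t_end / dt))
    for _ in range(n):
        k1 = M @ rho
        k2 = M @ (rho + 0.5 * dt * k1)
        k3 = M @ (rho + 0.5 * dt * k2)
        k4 = M @ (rho + dt * k3)
        rho = rho + (dt / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
    return rho


class TestEigenvalues:
    @given(pos_rates)
    def test_matches_numerical_eigendecomposition(self, rates):
        e = eigenvalues(rates)
        expected = np.sort(np.linalg.eigvals(build_rate_matrix(rates)).real)
        got = np.sort([e.E1, np.real(e.E2), np.real(e.E3)])
        scale = max(1.0, np.abs(expected).max())
        npt.assert_allclose(got, expected, rtol=0, atol=1e-12 * scale)

    @given(pos_rates)
    def test_stable_pair_always_negative(self, rates):
        e = eigenvalues(rates)
        assert e.E1 <= 0
        assert np.real(e.E2) <= 1e-12

    def test_marginal_on_separating_line(self):
        e = eigenvalues(KineticRates(lambda_s=0.7, lambda_d=2.0, lambda_e=3.0, mu=0.7))
        assert e.E3 == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("lambda_s", [1.0, 5.0, 20.0])
    def test_instant_doubling_limit(self, lambda_s):
        # lambda_d -> infinity: growth decided purely by settling vs death
        e = eigenvalues(KineticRates(lambda_s=lambda_s, lambda_d=1e6, lambda_e=1.0, mu=10.0))
        assert np.real(e.E3) == pytest.approx(lambda_s - 10.0, rel=1e-3)

    def test_unit_rates_closed_form(self):
        e = eigenvalues(KineticRates(1, 1, 1, 1))
        assert (e.E1, e.E2, e.E3, e.Lambda) == (-4.0, -3.0, 0.0, 3.0)


class TestUnstableApprox:
    def test_zero_on_separating_line(self):
        assert unstable_eigenvalue_approx(KineticRates(1.0, 5.0, 1.0, 1.0)) == 0.0

    def test_zero_without_doubling(self):
        assert unstable_eigenvalue_approx(KineticRates(2.0, 0.0, 1.0, 1.0)) == 0.0

    def test_accurate_for_small_growth(self):
        rates = KineticRates(lambda_s=1.01, lambda_d=1.0, lambda_e=1.0, mu=1.0)
        approx = unstable_eigenvalue_approx(rates)
        exact = np.real(eigenvalues(rates).E3)
        assert approx == pytest.approx(exact, rel=0.01)


class TestStationaryState:
    def test_equal_populations_when_doubling_twice_death(self):
        s = stationary_state(KineticRates(lambda_s=1.0, lambda_d=2.0, lambda_e=1.0, mu=1.0), R0=4.0)
        npt.assert_allclose(s.as_array(), [1.0, 1.0, 1.0])

    def test_empty_system(self):
        s = stationary_state(KineticRates(1, 1, 1, 1), R0=0.0)
        npt.assert_array_equal(s.as_array(), np.zeros(3))

    @given(st.floats(0.01, 10), st.floats(0.01, 10), st.floats(0.0, 100))
    def test_conserves_weighted_density(self, mu, ld, R0):
        s = stationary_state(KineticRates(mu, ld, 1.0, mu), R0)
        assert s.R == pytest.approx(R0, rel=1e-12, abs=1e-12)

    def test_off_separatrix_rejected(self):
        with pytest.raises(ParameterError):
            stationary_state(KineticRates(lambda_s=1.0, lambda_d=1.0, lambda_e=1.0, mu=2.0), R0=1.0)


class TestEvolveLinear:
    def test_t_zero_identity(self):
        init = DensityTriple(0.3, 0.2, 0.1)
        out = evolve_linear(init, KineticRates(1, 1, 1, 1), [0.0])
        npt.assert_array_equal(out[0], init.as_array())

    def test_relaxes_to_stationary_state(self):
        rates = KineticRates(lambda_s=1.0, lambda_d=1.0, lambda_e=1.0, mu=1.0)
        init = DensityTriple(0.5, 0.1, 0.0)
        out = evolve_linear(init, rates, [50.0])[0]
        expected = stationary_state(rates, init.R).as_array()
        npt.assert_allclose(out, expected, atol=1e-8)

    def test_against_independent_rk4(self):
        rates = KineticRates(0.4, 1.3, 0.8, 0.9)
        init = np.array([0.2, 0.5, 0.3])
        got = evolve_linear(DensityTriple(*init), rates, [1.0])[0]
        ref = _rk4_reference(build_rate_matrix(rates), init, 1.0)
        npt.assert_allclose(got, ref, atol=1e-6)

    def test_weighted_density_conserved_on_separatrix(self):
        rates = KineticRates(lambda_s=0.9, lambda_d=1.7, lambda_e=1.1, mu=0.9)
        init = DensityTriple(0.2, 0.4, 0.3)
        ts = np.linspace(0, 100, 31)
        out = evolve_linear(init, rates, ts)
        R = out[:, 0] + out[:, 2] + 2 * out[:, 1]
        npt.assert_allclose(R, init.R, rtol=0, atol=1e-10)

    def test_mirror_symmetry_preserved(self):
        rates = KineticRates(0.5, 1.2, 2.0, 0.8)
        out = evolve_linear(DensityTriple(0.4, 0.1, 0.4), rates, np.linspace(0, 5, 11))
        npt.assert_allclose(out[:, 0], out[:, 2], rtol=1e-12)

    @pytest.mark.parametrize("ls,mu,sign", [(2.0, 1.0, 1), (1.0, 2.0, -1)])
    def test_long_time_growth_sign(self, ls, mu, sign):
        rates = KineticRates(ls, 1.0, 1.0, mu)
        out = evolve_linear(DensityTriple(0.1, 0.1, 0.1), rates, [50.0, 60.0])
        N = out.sum(axis=1)
        assert np.sign(np.log(N[1] / N[0])) == sign

    def test_series_frame_columns(self):
        rates = KineticRates(1, 1, 1, 1)
        ts = [0.0, 1.0]
        df = series_to_frame(ts, evolve_linear(DensityTriple(1, 1, 1), rates, ts))
        assert list(df.columns) == ["t", "rho_plus", "rho_0", "rho_minus", "N", "R"]


class TestEvolveNonlinear:
    def _params(self, ls=3.0, mu=1.0):
        return ModelParams(
            rates=KineticRates(lambda_s=ls, lambda_d=1.0, lambda_e=1.0, mu=mu),
            transport=Transport(0, 0, 0),
            carrying=CarryingCapacity(1, 1, 1),
            growth_mode="logistic",
        )

    def test_linear_limit_small_densities(self):
        p = self._params()
        init = DensityTriple(1e-4, 2e-4, 5e-5)
        t = [1.0]
        nl = evolve_nonlinear(init, p, t, dt=1e-3)[0]
        lin = evolve_linear(init, p.rates, t)[0]
        npt.assert_allclose(nl, lin, rtol=0.01)

    def test_matches_linear_model_stationary_state(self):
        # logistic run with lambda_s = 3 mu converges to the same plateau as
        # the linear model on the separating line with mu = 2.848 lambda_e
        p = self._params()
        init = DensityTriple(0.0, 0.1, 0.479)
        nl = evolve_nonlinear(init, p, [60.0], dt=1e-3)[0]
        lin_rates = KineticRates(lambda_s=2.848, lambda_d=1.0, lambda_e=1.0, mu=2.848)
        expected = stationary_state(lin_rates, init.R).as_array()
        npt.assert_allclose(nl, expected, atol=1e-3)

    def test_growth_rate_near_linear_for_huge_capacity(self):
        p = ModelParams(
            rates=KineticRates(lambda_s=2.0, lambda_d=1.0, lambda_e=1.0, mu=1.0),
            transport=Transport(0, 0, 0),
            carrying=CarryingCapacity(1e12, 1e12, 1e12),
            growth_mode="logistic",
        )
        out = evolve_nonlinear(DensityTriple(0.1, 0.1, 0.1), p, [20.0, 25.0], dt=1e-3)
        rate = np.log(out[1].sum() / out[0].sum()) / 5.0
        E3 = np.real(eigenvalues(p.rates).E3)
        assert rate == pytest.approx(E3, rel=1e-3)

    def test_bounded_for_aggressive_growth(self):
        p = self._params(ls=10.0, mu=0.1)
        out = evolve_nonlinear(DensityTriple(0.5, 0.5, 0.5), p, [200.0], dt=1e-3)[0]
        assert np.all(np.isfinite(out)) and np.all(out < 50.0)

    def test_requires_logistic_mode(self):
        p = ModelParams(rates=KineticRates(1, 1, 1, 1), transport=Transport(0, 0, 0))
        with pytest.raises(ParameterError):
            evolve_nonlinear(DensityTriple(1, 1, 1), p, [1.0])
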