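"""Linear stability: Jacobian, dispersion branches, limits, roots, separatrix."""

import math

import numpy as np
import numpy.testing as npt
import pytest

from rtcycle import (
    HomogeneousState,
    Interactions,
    KineticRates,
    ModelParams,
    ParameterError,
    Transport,
    dispersion_branches,
    eigenvalues,
    fourier_jacobian,
    get_preset,
    is_stable,
    largest_unstable_root,
    s1_limits,
    separatrix_fit,
)
from rtcycle.params import speeds_from_vm_vr


@pytest.fixture(scope="module")
def hs8(fig8):
    """Stationary homogeneous state with unit conserved density R0 = 1."""
    return HomogeneousState(1.0 / 6.0, 1.0 / 3.0, 1.0 / 6.0)


@pytest.fixture(scope="module")
def fig9_hs(fig9):
    return HomogeneousState(1.0 / 6.0, 1.0 / 3.0, 1.0 / 6.0)


class TestFourierJacobian:
    def test_k_zero_equals_rate_matrix(self, fig9, fig9_hs):
        npt.assert_allclose(fourier_jacobian(0.0, fig9, fig9_hs), fig9.M, atol=1e-15)

    def test_free_cells_reduce_to_transport_operator(self, fig4):
        hs = HomogeneousState.from_params(fig4)
        k = 2.3
        J = fourier_jacobian(k, fig4, hs)
        expected = fig4.M - k**2 * fig4.diffusion_matrix - 1j * k * fig4.velocity_matrix
        npt.assert_allclose(J, expected, atol=1e-15)

    def test_matches_symbolic_linearization(self, fig9, fig9_hs):
        # computer-algebra oracle: linearize the full spatial model about the
        # homogeneous state for a plane-wave perturbation and compare entries
        import sympy as sp

        x, k = sp.symbols("x k", real=True)
        eps = sp.symbols("eps_p eps_0 eps_m")
        hat = fig9_hs.as_array()
        wave = sp.exp(sp.I * k * x)
        rho = [sp.Float(hat[a]) + eps[a] * wave for a in range(3)]
        D, vp, vm = fig9.transport.D, fig9.transport.v_plus, fig9.transport.v_minus
        kap, kap0 = fig9.interactions.kappa, fig9.interactions.kappa_0
        M = fig9.M
        U = [-kap * rho[1], kap0 * rho[1], -kap * rho[1]]
        Dv = [D, 0, D]
        Vv = [vp, 0, -vm]
        rhs = []
        for a in range(3):
            expr = (
                Dv[a] * sp.diff(rho[a], x, 2)
                + sp.diff(sp.diff(U[a], x) * rho[a], x)
                - Vv[a] * sp.diff(rho[a], x)
                + sum(M[a, b] * rho[b] for b in range(3))
            )
            rhs.append(sp.expand(expr))
        k_val = 2.0 * 2 * math.pi
        J_sym = np.empty((3, 3), dtype=complex)
        for a in range(3):
            lin = rhs[a]
            for b in range(3):
                coeff = lin.coeff(eps[b]).subs(k, k_val) / wave.subs(k, k_val)
                # drop second-order pieces that still carry an eps factor
                coeff = sp.simplify(coeff.subs([(e, 0) for e in eps]))
                J_sym[a, b] = complex(coeff)
        npt.assert_allclose(fourier_jacobian(k_val, fig9, fig9_hs), J_sym, atol=1e-12)


class TestDispersionBranches:
    def test_s1_starts_at_unstable_eigenvalue(self, fig9, fig9_hs):
        db = dispersion_branches(np.array([0.0, 0.1]), fig9, fig9_hs)
        E3 = np.real(eigenvalues(fig9.rates).E3)
        assert abs(db.s1[0].real - E3) < 1e-10

    def test_roots_satisfy_characteristic_polynomial(self, fig9, fig9_hs):
        kgrid = np.linspace(0.0, 50.0, 40)
        db = dispersion_branches(kgrid, fig9, fig9_hs)
        for i, k in enumerate(kgrid):
            J = fourier_jacobian(k, fig9, fig9_hs)
            norm = np.linalg.norm(J)
            for s in db.s[i]:
                res = abs(np.linalg.det(J - s * np.eye(3)))
                assert res < 1e-10 * max(norm, 1.0) ** 3

    def test_conjugate_symmetry_under_k_reflection(self, fig9, fig9_hs):
        kgrid = np.array([0.7, 5.0, 20.0])
        sp_ = dispersion_branches(kgrid, fig9, fig9_hs).s
        sm = dispersion_branches(-kgrid, fig9, fig9_hs).s
        npt.assert_allclose(np.sort_complex(np.conj(sm[1])), np.sort_complex(sp_[1]), atol=1e-10)

    def test_free_large_k_behavior(self, fig4):
        # kappa = kappa_0 = 0 at large k: everything is damped, and the two
        # mover branches have Re ~ -D k^2 and |Im| ~ v k (transient waves)
        hs = HomogeneousState.from_params(fig4)
        k = 300.0
        s = np.linalg.eigvals(fourier_jacobian(k, fig4, hs))
        assert s.real.max() < 0
        movers = s[np.argsort(s.real)[:2]]
        npt.assert_allclose(movers.real, -fig4.transport.D * k**2, rtol=0.05)
        npt.assert_allclose(
            np.sort(np.abs(movers.imag)),
            np.array([fig4.transport.v_minus, fig4.transport.v_plus]) * k,
            rtol=0.05,
        )


class TestS1Limits:
    def test_attraction_only_marginal_case(self):
        # all rates lambda_e, kappa = 1/lambda_e, rho^+ = 1, D = 2 v+^2:
        # the short-wave limit 2*kappa*rho^+*lambda_s/D - lambda_d vanishes
        p = get_preset("fig7").params
        hs = HomogeneousState.from_params(p, rho_hat_plus=1.0)
        lims = s1_limits(p, hs)
        assert lims["s1_at_inf"] == pytest.approx(0.0, abs=1e-14)

    def test_marginal_growth_on_separating_line(self, fig9, fig9_hs):
        assert np.real(s1_limits(fig9, fig9_hs)["s1_at_0"]) == pytest.approx(0.0, abs=1e-12)

    def test_repulsion_dominates_short_waves(self, fig9, fig9_hs):
        # Re s1(k)/k^2 -> -kappa_0 rho^_0: the repulsion caps the unstable
        # band.  (As a statement about the largest eigenvalue this requires
        # kappa_0 rho^_0 < D, otherwise the free mover decay -D k^2 is
        # slower and takes over at short waves.)
        p = fig9.with_(transport=Transport(0.1, 0.05, 0.05))
        lims = s1_limits(p, fig9_hs)
        k = 1e3
        s1 = np.linalg.eigvals(fourier_jacobian(k, p, fig9_hs)).real.max()
        assert s1 / k**2 == pytest.approx(lims["large_k_quadratic_coeff"], rel=0.01)


class TestIsStable:
    def test_no_attraction_and_no_growth_is_stable(self):
        p = ModelParams(
            rates=KineticRates(lambda_s=1.0, lambda_d=1.0, lambda_e=1.0, mu=2.0),
            transport=Transport(1.0, 1.0, 0.5),
        )
        hs = HomogeneousState.from_params(p)
        assert is_stable(p, hs)["stable"]

    def test_population_growth_fails_first_condition(self):
        p = ModelParams(
            rates=KineticRates(lambda_s=2.0, lambda_d=1.0, lambda_e=1.0, mu=1.0),
            transport=Transport(1.0, 1.0, 0.5),
        )
        hs = HomogeneousState.from_params(p)
        verdict = is_stable(p, hs)
        assert not verdict["stable"]
        assert any("mu < lambda_s" in c for c in verdict["failed_conditions"])

    def test_endpoint_marginal_case_stable_under_full_scan(self):
        # D = 2 v+^2: conditions only narrowly fulfilled, but Re s1 < 0 for k > 0
        p = get_preset("fig7").params
        hs = HomogeneousState.from_params(p, rho_hat_plus=1.0)
        verdict = is_stable(p, hs, mode="full_scan")
        assert verdict["stable"]
        assert verdict["max_re_s1"] <= 1e-10


class TestLargestUnstableRoot:
    def test_agrees_with_dense_scan(self, fig9, fig9_hs):
        k_max = 100.0
        k_r = largest_unstable_root(fig9, fig9_hs, k_max=k_max)
        # brute-force oracle: very dense scan for the last sign change
        ks = np.linspace(1e-4, k_max, 100_000)
        re = np.array([
            np.linalg.eigvals(fourier_jacobian(k, fig9, fig9_hs)).real.max()
            for k in ks[:: 500]
        ])
        # refine around the coarse oracle bracket with a fine local scan
        idx = np.nonzero(re > 0)[0][-1]
        lo, hi = ks[::500][idx], ks[::500][idx + 1]
        ks_fine = np.linspace(lo, hi, 20_000)
        re_fine = np.array([
            np.linalg.eigvals(fourier_jacobian(k, fig9, fig9_hs)).real.max()
            for k in ks_fine
        ])
        k_oracle = ks_fine[np.nonzero(re_fine > 0)[0][-1]]
        assert k_r == pytest.approx(k_oracle, abs=1e-3)
        # just above the domain mode k0 = 2*pi: the fig9 point is wave-forming
        assert k_r > 2 * math.pi

    def test_stable_system_has_no_root(self):
        p = ModelParams(
            rates=KineticRates(lambda_s=0.1, lambda_d=0.1, lambda_e=1.0, mu=0.2),
            transport=Transport(0.0, 0.0, 0.01),
            interactions=Interactions(kappa=1e-4, kappa_0=0.05),
        )
        hs = HomogeneousState(1.0 / 6.0, 1.0 / 3.0, 1.0 / 6.0)
        assert largest_unstable_root(p, hs, k_max=100.0) is None

    def test_requires_repulsion(self, fig4):
        hs = HomogeneousState.from_params(fig4)
        with pytest.raises(ParameterError):
            largest_unstable_root(fig4, hs, k_max=10.0)


class TestSeparatrix:
    def test_mirror_symmetry_under_speed_exchange(self, fig8, hs8):
        # swapping v+ <-> v- flips the sign of v_r but not the physics
        vr = 0.4
        from rtcycle.stability import largest_unstable_root as lur

        for vm in (2.0, 3.5):
            vp, vmn = speeds_from_vm_vr(vm, vr, fig8.transport.D, fig8.rates.lambda_e)
            k_pos = lur(fig8.with_(transport=Transport(vp, vmn, fig8.transport.D)), hs8, k_max=150.0)
            k_neg = lur(fig8.with_(transport=Transport(vmn, vp, fig8.transport.D)), hs8, k_max=150.0)
            if k_pos is None:
                assert k_neg is None
            else:
                assert k_neg == pytest.approx(k_pos, rel=1e-9)

    def test_separatrix_spot_check(self, fig8, hs8):
        # separatrix points satisfy k_r = k0 when re-evaluated independently
        fit = separatrix_fit(np.linspace(0.0, 0.9, 5), fig8, hs=hs8)
        k0 = 2 * math.pi
        for vr, vm in list(zip(fit.v_r, fit.v_m))[::2]:
            vp, vmn = speeds_from_vm_vr(vm, vr, fig8.transport.D, fig8.rates.lambda_e)
            p = fig8.with_(transport=Transport(vp, vmn, fig8.transport.D))
            k_r = largest_unstable_root(p, hs8, k_max=150.0)
            assert k_r == pytest.approx(k0, rel=2e-3)
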