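"""Constitutive-law tests: energy closed forms, stress-energy consistency,
and the semi-analytic incompressible uniaxial solution."""

import math

import numpy as np
import pytest

from arterymech import (
    Direction,
    GHOParams,
    cauchy_stress,
    forward_curves,
    strain_energy,
    uniaxial_response,
)
from arterymech.gho_constitutive import uniaxial_sigma1


def neo_hookean(mu: float) -> GHOParams:
    # k1 = 0 switches the fiber terms off entirely
    return GHOParams(mu=mu, k1=0.0, k2=1.0, kappa=0.0, gamma=45.0)


class TestStrainEnergy:
    def test_reference_state_has_zero_energy(self, cn_params):
        assert strain_energy(cn_params, np.eye(3)) == pytest.approx(0.0, abs=1e-14)

    def test_neo_hookean_closed_form(self):
        # W = mu/2 (I1 - 3) with I1 = lam^2 + 2/lam for isochoric uniaxial C
        lam = 1.2
        C = np.diag([lam**2, 1 / lam, 1 / lam])
        expected = 35.0 / 2.0 * (lam**2 + 2.0 / lam - 3.0)  # = 1.8667 kPa
        assert strain_energy(neo_hookean(35.0), C) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.8667, abs=5e-5)

    def test_kappa_third_energy_is_in_plane_rotation_invariant(self):
        # at kappa = 1/3 the fiber term depends on C only through I1
        p = GHOParams(mu=20.0, k1=50.0, k2=0.5, kappa=1.0 / 3.0, gamma=30.0)
        C = np.diag([1.5, 0.9, 1.0 / 1.35])
        th = 0.7
        R = np.array(
            [
                [math.cos(th), -math.sin(th), 0.0],
                [math.sin(th), math.cos(th), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        assert strain_energy(p, R @ C @ R.T) == pytest.approx(
            strain_energy(p, C), rel=1e-12
        )

    @pytest.mark.parametrize(
        "bad_C",
        [
            np.array([[1.0, 0.5, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]),  # asymmetric
            np.diag([1.0, -0.5, 1.0]),  # not positive definite
        ],
    )
    def test_invalid_C_rejected(self, cn_params, bad_C):
        with pytest.raises(ValueError):
            strain_energy(cn_params, bad_C)


class TestCauchyStress:
    def test_reference_with_hydrostatic_balance_is_stress_free(self, cn_params):
        sigma = cauchy_stress(cn_params, np.eye(3), p=cn_params.mu)
        assert np.abs(sigma).max() == pytest.approx(0.0, abs=1e-12)

    def test_neo_hookean_uniaxial_closed_form(self):
        lam = 1.2
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        p = 35.0 / lam  # makes the lateral stress vanish: p = mu*lam2^2
        sigma = cauchy_stress(neo_hookean(35.0), F, p)
        assert sigma[0, 0] == pytest.approx(35.0 * (lam**2 - 1 / lam), rel=1e-12)
        assert sigma[0, 0] == pytest.approx(21.23, abs=5e-3)
        assert abs(sigma[1, 1]) < 1e-12 and abs(sigma[2, 2]) < 1e-12

    def test_singular_F_rejected(self, cn_params):
        with pytest.raises(ValueError):
            cauchy_stress(cn_params, np.diag([1.0, 1.0, 0.0]), 0.0)

    def test_matches_finite_difference_of_energy(self, cn_params, rng):
        """sigma = 2 J^-1 F dW/dC F^T - p I with dW/dC by central differences."""

        def fd_cauchy(params, F, p):
            C = F.T @ F
            h = 1e-6
            dWdC = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    dC = np.zeros((3, 3))
                    dC[i, j] = dC[j, i] = h
                    scale = 2 * h if i == j else 4 * h
                    dWdC[i, j] = (
                        strain_energy(params, C + dC) - strain_energy(params, C - dC)
                    ) / scale
            J = np.linalg.det(F)
            return 2.0 / J * F @ dWdC @ F.T - p * np.eye(3)

        for _ in range(100):
            A = np.eye(3) + 0.15 * rng.standard_normal((3, 3))
            F = A / np.linalg.det(A) ** (1 / 3)  # incompressible random state
            p = float(rng.uniform(0, 50))
            params = GHOParams(
                mu=float(rng.uniform(5, 100)),
                k1=float(rng.uniform(5, 200)),
                k2=float(rng.uniform(0.02, 2.0)),
                kappa=float(rng.uniform(0, 1 / 3)),
                gamma=float(rng.uniform(0, 90)),
            )
            s_exact = cauchy_stress(params, F, p)
            s_fd = fd_cauchy(params, F, p)
            denom = max(np.abs(s_exact).max(), 1.0)
            assert np.abs(s_exact - s_fd).max() / denom < 1e-6

    def test_tension_only_switch_zeroes_compressed_fibers(self):
        # uniaxial radial-plane compression puts both families below I4 = 1
        p_on = GHOParams(mu=10.0, k1=80.0, k2=0.5, kappa=0.0, gamma=45.0,
                         fiber_tension_only=True)
        p_off = GHOParams(mu=10.0, k1=80.0, k2=0.5, kappa=0.0, gamma=45.0)
        lam = 0.9
        F = np.diag([lam, lam, 1.0 / lam**2])
        s_on = cauchy_stress(p_on, F, 0.0)
        s_nh = cauchy_stress(neo_hookean(10.0), F, 0.0)
        assert np.allclose(s_on, s_nh, rtol=1e-12)
        assert not np.allclose(cauchy_stress(p_off, F, 0.0), s_nh)


class TestUniaxialResponse:
    def test_undeformed_state(self, cn_params):
        st = uniaxial_response(cn_params, "circumferential", 1.0)
        assert st.lambda2 == pytest.approx(1.0, abs=1e-10)
        assert st.lambda3 == pytest.approx(1.0, abs=1e-10)
        assert st.sigma1 == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("lam1", [1.1, 1.4, 1.8])
    def test_isotropic_lateral_symmetry(self, lam1):
        st = uniaxial_response(neo_hookean(35.0), "longitudinal", lam1)
        assert st.lambda2 == pytest.approx(lam1**-0.5, rel=1e-12)
        assert st.lambda3 == pytest.approx(lam1**-0.5, rel=1e-12)

    def test_incompressibility_and_zero_lateral_stress(self, cn_params):
        for direction in Direction:
            for lam1 in (1.2, 1.5, 1.9):
                st = uniaxial_response(cn_params, direction, lam1)
                assert abs(st.lambda1 * st.lambda2 * st.lambda3 - 1.0) <= 1e-10
                F = np.diag(
                    [st.lambda1, st.lambda2, st.lambda3]
                    if direction == Direction.CIRCUMFERENTIAL
                    else [st.lambda2, st.lambda1, st.lambda3]
                )
                sigma = cauchy_stress(cn_params, F, st.p)
                tol = 1e-8 * max(cn_params.mu, cn_params.k1)
                assert abs(sigma[1, 1]) <= tol or abs(sigma[0, 0]) <= tol
                assert abs(sigma[2, 2]) <= tol
                assert max(sigma[0, 0], sigma[1, 1]) == pytest.approx(st.sigma1, rel=1e-8)

    @pytest.mark.parametrize("direction", list(Direction))
    def test_energy_minimization_oracle(self, cn_params, direction):
        """sigma1 agrees to 4 significant digits with an oracle that builds
        the uniaxial energy by brute-force minimization over lambda2 and
        differentiates it numerically in lambda1."""
        from scipy.optimize import minimize_scalar

        def W_hat(lam1):
            def w(lam2):
                lam3 = 1.0 / (lam1 * lam2)
                if direction == Direction.CIRCUMFERENTIAL:
                    C = np.diag([lam1**2, lam2**2, lam3**2])
                else:
                    C = np.diag([lam2**2, lam1**2, lam3**2])
                return strain_energy(cn_params, C)

            # bracket by coarse grid scan, then refine
            grid = np.linspace(0.5, 1.2, 141)
            k = int(np.argmin([w(x) for x in grid]))
            lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
            res = minimize_scalar(w, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-12})
            return res.fun

        lam1 = 1.5
        h = 1e-5
        sigma_oracle = lam1 * (W_hat(lam1 + h) - W_hat(lam1 - h)) / (2 * h)
        st = uniaxial_response(cn_params, direction, lam1)
        assert st.sigma1 == pytest.approx(sigma_oracle, rel=1e-4)

    def test_stress_monotone_in_stretch_over_parameter_draws(self, rng):
        grid = np.linspace(1.0, 2.0, 40)
        for _ in range(20):
            params = GHOParams(
                mu=float(rng.uniform(1, 500)),
                k1=float(rng.uniform(1, 500)),
                k2=float(rng.uniform(0.01, 5)),
                kappa=float(rng.uniform(0, 1 / 3)),
                gamma=float(rng.uniform(0, 90)),
            )
            for direction in Direction:
                sigma, _, _, _ = uniaxial_sigma1(params, direction, grid)
                assert np.all(np.diff(sigma) > 0), params

    def test_direction_swap_equals_complementary_angle(self, cn_params):
        grid = np.linspace(1.0, 1.9, 25)
        flipped = GHOParams(
            mu=cn_params.mu, k1=cn_params.k1, k2=cn_params.k2,
            kappa=cn_params.kappa, gamma=90.0 - cn_params.gamma,
        )
        c0, l0 = forward_curves(cn_params, grid)
        c1, l1 = forward_curves(flipped, grid)
        assert np.allclose(c0.stress, l1.stress, rtol=1e-10)
        assert np.allclose(l0.stress, c1.stress, rtol=1e-10)


class TestForwardCurves:
    def test_single_point_grid(self, cn_params):
        cc, cl = forward_curves(cn_params, [1.0])
        for c in (cc, cl):
            assert len(c) == 1
            assert c.stress[0] == pytest.approx(0.0, abs=1e-8)

    def test_kappa_third_collapses_anisotropy(self):
        p = GHOParams(mu=35.0, k1=73.0, k2=0.07, kappa=1.0 / 3.0, gamma=74.5)
        grid = np.linspace(1.0, 1.9, 30)
        cc, cl = forward_curves(p, grid)
        assert np.abs(cc.stress - cl.stress).max() <= 1e-8 * cc.stress.max()

    def test_transverse_stretches_decay(self, cn_params):
        grid = np.linspace(1.0, 1.9, 60)
        for curve in forward_curves(cn_params, grid):
            assert np.all(np.diff(curve.lambda2) < 0)
            assert np.all(np.diff(curve.lambda3) < 0)

    @pytest.mark.parametrize("grid", [[], [1.1, 1.2], [1.0, 1.3, 1.2]])
    def test_invalid_grids_rejected(self, cn_params, grid):
        with pytest.raises(ValueError):
            forward_curves(cn_params, grid)
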