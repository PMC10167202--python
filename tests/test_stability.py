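import math

import numpy as np
import pytest

from osteodyn import (EigClass, ModelSpec, SIGMA_SWEEP, TumorParams, Variant,
                      characteristic_invariants, classify_eigenvalues,
                      fixture_generator, jacobian_at_point,
                      jacobian_at_steady, routh_hurwitz, stability_region_scan,
                      stability_report, steady_state)

ALL_SPECS = [ModelSpec(Variant.BASE),
             ModelSpec(Variant.MODEL1, scenario=3),
             ModelSpec(Variant.MODEL2, g31=-0.1, g32=0.05),
             ModelSpec(Variant.MODEL3, r11=0.1, r12=0.2, r21=-0.1, r22=0.1)]


def _fd_jacobian(f, y0, rel=6e-6):
    J = np.zeros((3, 3))
    for j in range(3):
        h = rel * abs(y0[j])
        e = np.zeros(3)
        e[j] = h
        J[:, j] = (np.asarray(f(y0 + e)) - np.asarray(f(y0 - e))) / (2 * h)
    return J


class TestJacobian:
    @pytest.mark.parametrize("spec", ALL_SPECS)
    def test_block_triangular_tumor_row(self, spec, params, tumor):
        J = jacobian_at_steady(spec, params, tumor)
        assert J[2, 0] == 0.0 and J[2, 1] == 0.0
        assert J[2, 2] == -tumor.mu / math.log(10.0)

    def test_base_cell_block_is_traceless(self, params, tumor):
        """The physiological parameter set sits exactly on the center
        manifold: the 2x2 cell block has zero trace, so the base model's
        eigenvalues carry no real part."""
        J = jacobian_at_steady(ModelSpec(Variant.BASE), params, tumor)
        scale = max(1.0, float(np.abs(J).max()))
        assert abs(J[0, 0] + J[1, 1]) < 1e-9 * scale

    @pytest.mark.parametrize("variant", list(Variant))
    def test_matches_finite_differences(self, variant):
        """Analytic Jacobian vs central differences of the implemented RHS
        (spot sample; the 100-set-per-variant sweep runs in acceptance)."""
        from osteodyn import cell_rates, gompertz_rate

        for spec, p, tu in fixture_generator(seed=5, n=20, variant=variant):
            ss = steady_state(spec, p, tu, self_consistent=True)
            D = tu.sigma if spec.variant is not Variant.BASE else tu.sigma

            def f(y):
                d1, d2 = cell_rates(spec, p, tu, y[0], y[1], y[2])
                return [d1, d2, gompertz_rate(y[2], tu.mu, tu.sigma)]

            y0 = np.array([ss.x1bar, ss.x2bar, D])
            J = jacobian_at_point(spec, p, tu, *y0)
            Jfd = _fd_jacobian(f, y0)
            scale = max(1.0, float(np.abs(J).max()),
                        p.beta1 * ss.x1bar, p.beta2 * ss.x2bar)
            assert np.all(np.abs(J - Jfd) < 1e-6 * scale)


class TestInvariants:
    def test_diagonal_matrix(self):
        a = characteristic_invariants(np.diag([-1.0, -2.0, -3.0]))
        assert a == pytest.approx((6.0, 11.0, 6.0))

    def test_block_triangular_determinant_identity(self, rng):
        for _ in range(50):
            J = rng.normal(size=(3, 3))
            J[2, 0] = J[2, 1] = 0.0
            _, _, a3 = characteristic_invariants(J)
            expect = -J[2, 2] * (J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0])
            assert a3 == pytest.approx(expect, rel=1e-9, abs=1e-12)

    def test_roots_reconstruct_spectrum(self, rng):
        for _ in range(50):
            J = rng.normal(size=(3, 3))
            a1, a2, a3 = characteristic_invariants(J)
            roots = np.roots([1.0, a1, a2, a3])
            eigs = np.linalg.eigvals(J)
            assert np.allclose(np.sort_complex(roots), np.sort_complex(eigs),
                               atol=1e-8)


class TestRouthHurwitz:
    def test_known_verdicts(self):
        assert routh_hurwitz(6.0, 11.0, 6.0) is True
        assert routh_hurwitz(1.0, 1.0, 2.0) is False  # a1*a2 - a3 = -1

    def test_matches_eigenvalue_signs_on_random_matrices(self, rng):
        agree = 0
        for _ in range(200):
            J = rng.normal(size=(3, 3))
            verdict = routh_hurwitz(*characteristic_invariants(J))
            stable = np.max(np.linalg.eigvals(J).real) < 0.0
            assert verdict == stable
            agree += 1
        assert agree == 200


class TestClassification:
    def test_taxonomy_on_plain_spectra(self):
        assert classify_eigenvalues([-1, -2, -3], 1e-9) is EigClass.STABLE_NODE
        assert classify_eigenvalues([-1 + 2j, -1 - 2j, -3],
                                    1e-9) is EigClass.STABLE_SPIRAL
        assert classify_eigenvalues([0.04j, -0.04j, -0.002],
                                    1e-9) is EigClass.CENTER_LIKE
        assert classify_eigenvalues([1e-3, -1, -2], 1e-9) is EigClass.UNSTABLE

    def test_base_model_is_center(self, params, tumor):
        rep = stability_report(ModelSpec(Variant.BASE), params, tumor)
        assert rep.eig_class is EigClass.CENTER_LIKE
        assert not rep.routh_hurwitz_stable

    def test_scenario2_damps_at_low_burden(self, params):
        rep = stability_report(ModelSpec(Variant.MODEL1, scenario=2),
                               params, TumorParams(sigma=0.05))
        assert rep.eig_class is EigClass.STABLE_SPIRAL
        assert rep.routh_hurwitz_stable

    @pytest.mark.parametrize("scenario", [2, 3, 6])
    def test_stabilized_scenarios(self, params, scenario):
        for sigma in (0.05, 0.10, 0.20, 0.40):
            rep = stability_report(ModelSpec(Variant.MODEL1,
                                             scenario=scenario),
                                   params, TumorParams(sigma=sigma))
            assert rep.routh_hurwitz_stable, (scenario, sigma)

    @pytest.mark.parametrize("scenario", [1, 4])
    def test_destabilized_scenarios(self, params, scenario):
        for sigma in SIGMA_SWEEP:
            rep = stability_report(ModelSpec(Variant.MODEL1,
                                             scenario=scenario),
                                   params, TumorParams(sigma=sigma))
            assert rep.eig_class is EigClass.UNSTABLE, (scenario, sigma)

    def test_scenario7_limit_cycle_and_scenario8_unstable(self, params):
        """Scenarios 7 and 8 share a steady state but not a verdict: 7 keeps
        a pure-imaginary pair (limit cycle), 8 is pushed unstable."""
        rep7 = stability_report(ModelSpec(Variant.MODEL1, scenario=7),
                                params, TumorParams(sigma=0.05))
        rep8 = stability_report(ModelSpec(Variant.MODEL1, scenario=8),
                                params, TumorParams(sigma=0.05))
        assert rep7.eig_class is EigClass.CENTER_LIKE
        assert rep8.eig_class is EigClass.UNSTABLE


class TestExactTumorEigenvalue:
    @pytest.mark.parametrize("variant", list(Variant))
    def test_minus_mu_over_ln10_is_always_an_eigenvalue(self, variant):
        for spec, p, tu in fixture_generator(seed=3, n=15, variant=variant):
            rep = stability_report(spec, p, tu)
            target = -tu.mu / math.log(10.0)
            assert np.min(np.abs(rep.eigenvalues - target)) < 1e-14


class TestRegionScan:
    def test_neutral_row_matches_base_class(self, params):
        table = stability_region_scan(
            Variant.MODEL2, params, g31_grid=[0.0], g32_grid=[0.0],
            sigma_grid=[0.05, 0.2, 0.8])
        assert set(table.eig_class) == {EigClass.CENTER_LIKE.value}

    def test_row_count_is_grid_product(self, params):
        table = stability_region_scan(
            Variant.MODEL2, params, g31_grid=np.linspace(-0.2, 0.2, 5),
            g32_grid=np.linspace(-0.2, 0.2, 7), sigma_grid=[0.05, 0.4])
        assert len(table) == 5 * 7 * 2

    def test_reference_point_is_stable(self, params):
        table = stability_region_scan(
            Variant.MODEL2, params, g31_grid=[-0.10], g32_grid=[0.0],
            sigma_grid=[0.05])
        row = table.iloc[0]
        assert row.routh_hurwitz_stable
        assert row.eig_class == EigClass.STABLE_SPIRAL.value

    def test_model3_scan_runs_and_is_complete(self, params):
        table = stability_region_scan(
            Variant.MODEL3, params,
            r_grids={"r11": np.linspace(-0.3, 0.3, 4),
                     "r12": np.linspace(-0.3, 0.3, 4),
                     "r21": [0.0],
                     "r22": np.linspace(-0.3, 0.3, 4)},
            sigma_grid=[0.05])
        assert len(table) == 4 * 4 * 1 * 4
        assert set(table.columns) >= {"r11", "r12", "r21", "r22", "sigma",
                                      "a1", "a2", "a3", "eig_class"}
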