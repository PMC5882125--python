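import numpy as np
import pytest

import phyllosim as ps
from phyllosim.stability import StabilityError

from conftest import a_params, b_params, o_params


def _random_o_params(rng):
    return ps.Params(
        A=rng.uniform(0.5, 2.0), Ep=10 ** rng.uniform(-1, 1),
        p=10 ** rng.uniform(-1, 1), Da=10 ** rng.uniform(-1, 1),
        Ga=rng.uniform(0.05, 1.0), Gp=1.0)


class TestCompartmentFree:
    def test_uniform_mode_decays_at_turnover_rate(self):
        # lambda(nu=1) = -Ga is an algebraic identity of the coefficients
        rng = np.random.default_rng(0)
        for _ in range(20):
            P = _random_o_params(rng)
            spec = ps.make_model("O", P, 2, n=rng.uniform(0.5, 4.0))
            res = ps.dispersion(spec, P, spec.reg, 16)
            scale = max(1.0, abs(res.coefficients["c1"]),
                        abs(res.coefficients["c2"]))
            assert abs(res.lambda_k[0] + P.Ga) < 1e-12 * scale

    def test_fastest_mode_matches_printed_ratio(self):
        # Ra = 0.2, n = 2 -> nu* = (1 + Ra)/(2n) = 0.3, L* ~ 4.96 cells
        P = o_params(Ep=1.0, p=1.0, Da=0.2)
        spec = ps.make_model("O", P, 2, n=2.0)
        cond = ps.pattern_condition(spec, P, spec.reg)
        assert cond.nu_star == pytest.approx(0.3, rel=1e-12)
        assert cond.L_star == pytest.approx(2 * np.pi / np.arccos(0.3),
                                            rel=1e-12)
        # and the grid argmax sits at the wavenumber whose nu is nearest 0.3
        res = ps.dispersion(spec, P, spec.reg, 200)
        k_grid = int(np.argmax(res.lambda_k[:101]))
        k_cont = 200 * np.arccos(0.3) / (2 * np.pi)
        assert abs(k_grid - k_cont) <= 0.5

    def test_maximizer_outside_range_means_stable(self):
        # n=2, p=1, Ep=1, Da=4: nu* = -c1/(4 c2) = 5/4 > 1 -> no pattern
        P = o_params(Ep=1.0, p=1.0, Da=4.0)
        spec = ps.make_model("O", P, 2, n=2.0)
        cond = ps.pattern_condition(spec, P, spec.reg)
        assert cond.nu_star == pytest.approx(1.25, rel=1e-12)
        assert not cond.unstable

    def test_dispersion_matches_jacobian_oracle(self):
        rng = np.random.default_rng(1)
        N = 32
        for _ in range(5):
            P = _random_o_params(rng)
            spec = ps.make_model("O_qss", P, 2, n=rng.uniform(0.5, 4.0))
            res = ps.dispersion(spec, P, spec.reg, N)
            orc = ps.reduced_jacobian_spectrum(spec, P, N)
            err = (np.max(np.abs(res.lambda_k - orc.leading))
                   / np.max(np.abs(res.lambda_k)))
            assert err < 1e-6

    def test_boundary_transect_agrees_with_oracle_sign(self):
        # crossing the re-derived instability boundary flips the sign of the
        # oracle's max growth rate at the same Da (within one grid step)
        P0 = o_params(Ep=1.0, p=40.0)
        Da_grid = np.linspace(80.0, 150.0, 15)
        N = 64
        analytic, oracle = [], []
        for Da in Da_grid:
            P = P0.replace(Da=Da)
            spec = ps.make_model("O_qss", P, 2, n=2.0)
            analytic.append(ps.pattern_condition(spec, P, spec.reg).unstable)
            orc = ps.reduced_jacobian_spectrum(spec, P, N)
            oracle.append(orc.leading[1:].max() > 0)
        flips_a = int(np.argmin(analytic))
        flips_o = int(np.argmin(oracle))
        assert analytic[0] and oracle[0]
        assert not analytic[-1] and not oracle[-1]
        assert abs(flips_a - flips_o) <= 1

    def test_rederived_boundary_closed_form(self):
        # boundary from lambda(nu*) = 0: Da = (2n-1) Ep p - sqrt(2 n Ga Ep p)
        Ep, p, Ga, n = 1.0, 40.0, 0.2, 2.0
        Da_b = (2 * n - 1) * Ep * p - np.sqrt(2 * n * Ga * Ep * p)
        for Da, expect in [(Da_b - 1.0, True), (Da_b + 1.0, False)]:
            P = o_params(Ep=Ep, p=p, Da=Da)
            spec = ps.make_model("O", P, 2, n=n)
            assert ps.pattern_condition(spec, P, spec.reg).unstable is expect


class TestApoplast:
    def test_growth_is_affine_in_nu(self):
        P = a_params()
        spec = ps.make_model("A", P, 2, n=4.0)
        res = ps.dispersion(spec, P, spec.reg, 40)
        co = res.coefficients
        np.testing.assert_allclose(
            res.lambda_k, 2 * co["c1"] * res.nu_grid + co["c0"], rtol=1e-13)

    def test_fastest_mode_is_always_the_alternating_one(self):
        # in the unstable region the argmax sits at nu = -1 (k = N/2)
        rng = np.random.default_rng(2)
        N = 40
        found = 0
        while found < 10:
            P = a_params(p=10 ** rng.uniform(0.8, 2.0),
                         Da=10 ** rng.uniform(-1, 1.5),
                         q=10 ** rng.uniform(0.5, 1.5))
            spec = ps.make_model("A", P, 2, n=4.0)
            cond = ps.pattern_condition(spec, P, spec.reg)
            if not cond.unstable:
                continue
            found += 1
            res = ps.dispersion(spec, P, spec.reg, N)
            assert int(np.argmax(res.lambda_k[1:N // 2 + 1])) + 1 == N // 2
            assert cond.L_star == 2.0
            assert cond.units_of_L == "apoplast spaces"

    def test_instability_threshold_matches_printed_inequality(self):
        # power-law polarization with exponent n: unstable iff Da < (n-1) Ep p
        for Da, expect in [(100.0, True), (200.0, False)]:
            P = a_params(Da=Da)  # threshold at (4-1)*1*50 = 150
            spec = ps.make_model("A", P, 2, n=4.0)
            assert ps.pattern_condition(spec, P, spec.reg).unstable is expect

    def test_adiabatic_reduction_reproduces_dispersion_exactly(self):
        rng = np.random.default_rng(3)
        N = 32
        for _ in range(5):
            P = a_params(p=10 ** rng.uniform(0.5, 2.0),
                         Da=10 ** rng.uniform(-1, 1.5),
                         q=10 ** rng.uniform(0.5, 1.5),
                         V=rng.uniform(0.5, 2.0))
            spec = ps.make_model("A", P, 2, n=rng.uniform(1.5, 5.0))
            res = ps.dispersion(spec, P, spec.reg, N)
            orc = ps.reduced_jacobian_spectrum(spec, P, N,
                                               reduction="adiabatic")
            err = (np.max(np.abs(res.lambda_k - orc.leading))
                   / np.max(np.abs(res.lambda_k)))
            assert err < 1e-6

    def test_full_system_shares_sign_and_argmax(self):
        P = a_params()
        spec = ps.make_model("A", P, 2, n=4.0)
        res = ps.dispersion(spec, P, spec.reg, 40)
        orc = ps.reduced_jacobian_spectrum(spec, P, 40, reduction="pin")
        assert (res.lambda_k.max() > 0) == (orc.leading.max() > 0)
        assert (int(np.argmax(res.lambda_k[:21]))
                == int(np.argmax(orc.leading[:21])))


class TestMediator:
    def test_printed_small_volume_limit(self):
        # nu* from the coefficients equals the printed closed form
        rng = np.random.default_rng(4)
        for _ in range(10):
            P = b_params(V=rng.uniform(0.01, 2.0),
                         Dx=10 ** rng.uniform(-1, 1.5),
                         Gx=10 ** rng.uniform(-0.5, 0.5),
                         p=10 ** rng.uniform(0, 1),
                         q=10 ** rng.uniform(0, 1),
                         Da=10 ** rng.uniform(-1, 1))
            r, m = rng.uniform(0.5, 4.0), rng.uniform(0.5, 8.0)
            spec = ps.make_model("B6", P, 2, m=m, r=r, phia_constant=True)
            co = ps.dispersion_coefficients(spec, P, spec.reg)
            nu_star = -co["c1"] / (4 * co["c2"])
            Ra, Rx = P.Da / (P.Ep * P.p), P.Dx / P.Gx
            printed = (2 * (1 + Ra) * (1 + 2 * Rx) * (P.V + 2 * Rx)
                       / (r * m * (P.V + 2 * (1 + P.V) * Rx)))
            assert nu_star == pytest.approx(printed, rel=1e-10)
            # and the V -> 0 limit of the printed form
            if P.V < 0.02:
                limit = 2 * (1 + Ra) * (1 + 2 * Rx) / (r * m)
                assert nu_star == pytest.approx(limit, rel=0.05)

    def test_two_quadrant_instability(self):
        # patterns need the synthesis and polarization regulations to pull
        # the same way: (r, m) both positive or both negative (evaluated in
        # the scale-separated regime where the approximate condition applies)
        P = b_params(V=0.1, Gx=5.0, Dx=5.0, p=2.0, q=5.0, Da=0.2)
        for r, m, expect in [(3.0, 4.0, True), (-3.0, -4.0, True),
                             (3.0, -4.0, False), (-3.0, 4.0, False)]:
            spec = ps.make_model("B6", P, 2, m=m, r=r, phia_constant=True)
            cond = ps.pattern_condition(spec, P, spec.reg)
            assert cond.unstable is expect, (r, m)

    def test_oracle_confirms_robust_analytic_instability(self):
        # where the approximate condition predicts clear instability (strong
        # time-scale separation: small V, fast mediator), the full QSS
        # linearization agrees in sign and peak location within one mode
        N = 100
        for P, r, m in [
            (b_params(V=0.1, Gx=5.0, Dx=5.0, p=2.0, q=5.0, Da=0.2), 3.0, 4.0),
            (b_params(V=0.1, Gx=2.0, Dx=2.0, p=2.0, q=2.0, Da=0.1), 2.0, 6.0),
        ]:
            spec = ps.make_model("B6", P, 2, m=m, r=r, phia_constant=True)
            res = ps.dispersion(spec, P, spec.reg, N)
            assert res.unstable and res.lambda_k.max() > 0.3
            orc = ps.reduced_jacobian_spectrum(spec, P, N)
            assert orc.leading.max() > 0
            half = N // 2 + 1
            assert abs(int(np.argmax(res.lambda_k[:half]))
                       - int(np.argmax(orc.leading[:half]))) <= 1

    def test_simple_diffusion_mode_required(self):
        P = b_params()
        spec = ps.make_model("B6", P, 2, m=3.0, r=2.0, x_mode="symplast",
                             phia_constant=True)
        with pytest.raises(StabilityError):
            ps.dispersion_coefficients(spec, P, spec.reg)


class TestOracleStructure:
    def test_spectrum_is_symmetric_in_k(self):
        P = o_params(p=2.0)
        spec = ps.make_model("O_qss", P, 2, n=2.0)
        orc = ps.reduced_jacobian_spectrum(spec, P, 24)
        np.testing.assert_allclose(orc.leading[1:],
                                   orc.leading[1:][::-1], rtol=1e-9)

    def test_uniform_mode_of_reduced_system_is_minus_Ga(self):
        P = o_params(p=3.0, Ga=0.37)
        spec = ps.make_model("O_qss", P, 2, n=2.0)
        orc = ps.reduced_jacobian_spectrum(spec, P, 16)
        assert orc.leading[0] == pytest.approx(-0.37, rel=1e-9)


class TestModeGrowth:
    def test_growth_rate_matches_dispersion_at_fastest_mode(self):
        # QSS model, k near nu*: measured slope within 5% of lambda(nu_k)
        N = 40
        P = o_params(Ep=1.0, p=1.0, Da=0.2)
        spec = ps.make_model("O_qss", P, 2, n=2.0)
        lat = ps.build_ring(N)
        res = ps.dispersion(spec, P, spec.reg, N)
        k = int(np.argmax(res.lambda_k[:N // 2 + 1]))
        rate = ps.measure_mode_growth(spec, P, lat, k)
        assert rate == pytest.approx(res.lambda_k[k], rel=0.05)

    def test_uniform_mode_decays_at_minus_Ga(self):
        N = 40
        P = o_params(Ep=1.0, p=1.0, Da=0.2)
        spec = ps.make_model("O_qss", P, 2, n=2.0)
        lat = ps.build_ring(N)
        rate = ps.measure_mode_growth(spec, P, lat, 0, t_max=5.0)
        assert rate == pytest.approx(-P.Ga, rel=0.05)

    def test_stable_regime_gives_negative_rates(self):
        N = 24
        P = o_params(Ep=1.0, p=1.0, Da=4.0)
        spec = ps.make_model("O_qss", P, 2, n=2.0)
        lat = ps.build_ring(N)
        for k in (1, 6, 12):
            assert ps.measure_mode_growth(spec, P, lat, k, t_max=5.0) < 0
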