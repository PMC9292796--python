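"""Rate physics: tunneling, TST, Marcus theory, diffusion, coupling."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from scavkin import (
    CONSTANTS,
    DiffusionInputs,
    MarcusRegion,
    collins_kimball,
    diffusion_rate,
    eyring_rate,
    infer_lambda,
    marcus_barrier,
    wigner_kappa,
)

finite_barriers = st.floats(min_value=0.0, max_value=60.0)
positive_rates = st.floats(min_value=1e-30, max_value=1e30)


class TestWigner:
    def test_no_frequency_means_no_tunneling(self):
        assert wigner_kappa(None) == 1.0
        assert wigner_kappa(0.0) == 1.0

    def test_typical_hat_frequency(self):
        # (2000 * 1.43877 / 298.15)^2 / 24 + 1
        assert wigner_kappa(2000.0, 298.15) == pytest.approx(4.88, abs=0.01)

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            wigner_kappa(-100.0)

    @given(
        nu=st.floats(min_value=1.0, max_value=4000.0),
        T=st.floats(min_value=100.0, max_value=1000.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_frequency_and_temperature(self, nu, T):
        assert wigner_kappa(nu * 1.01, T) > wigner_kappa(nu, T)
        assert wigner_kappa(nu, T * 1.01) < wigner_kappa(nu, T)


class TestEyring:
    def test_barrierless_rate_is_the_prefactor(self):
        assert eyring_rate(0.0, 1.0, 298.15) == pytest.approx(
            6.212e12, rel=1e-3
        )

    def test_tunneling_scales_linearly(self):
        assert eyring_rate(5.0, 3.0) == pytest.approx(
            3.0 * eyring_rate(5.0, 1.0), rel=1e-12
        )

    @given(g1=finite_barriers, g2=finite_barriers)
    @settings(max_examples=100, derandomize=True)
    def test_log_linear_with_slope_minus_one_over_RT(self, g1, g2):
        """ln k is linear in the barrier with slope exactly -1/RT."""
        if abs(g1 - g2) < 1e-6:
            return
        slope = (
            math.log(eyring_rate(g1)) - math.log(eyring_rate(g2))
        ) / (g1 - g2)
        assert slope == pytest.approx(-1.0 / CONSTANTS.RT(298.15), rel=1e-9)

    def test_negative_barrier_rejected(self):
        with pytest.raises(ValueError):
            eyring_rate(-1.0)


class TestMarcus:
    def test_thermoneutral_barrier_is_quarter_lambda(self):
        dG, region = marcus_barrier(0.0, 20.0)
        assert dG == pytest.approx(5.0)
        assert region is MarcusRegion.normal

    def test_activationless_point_is_normal(self):
        dG, region = marcus_barrier(-10.0, 10.0)
        assert dG == 0.0
        assert region is MarcusRegion.normal

    def test_inverted_region_case(self):
        # exergonicity 13.0 with lambda 10.91: small barrier, inverted
        dG, region = marcus_barrier(-13.0, 10.91)
        assert dG == pytest.approx(0.10, abs=5e-3)
        assert region is MarcusRegion.inverted

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            marcus_barrier(-5.0, 0.0)


class TestInferLambda:
    def test_two_admissible_roots_with_regions(self):
        roots = dict(
            (region, lam) for lam, region in infer_lambda(-13.0, 0.1)
        )
        assert roots[MarcusRegion.normal] == pytest.approx(15.49, abs=0.01)
        assert roots[MarcusRegion.inverted] == pytest.approx(10.91, abs=0.01)

    def test_thermoneutral_single_root(self):
        [(lam, region)] = infer_lambda(0.0, 5.0)
        assert lam == pytest.approx(20.0)
        assert region is MarcusRegion.normal

    def test_activationless_single_root(self):
        [(lam, _)] = infer_lambda(-10.0, 0.0)
        assert lam == pytest.approx(10.0)

    def test_barrier_below_endergonicity_has_no_root(self):
        assert infer_lambda(10.0, 5.0) == []

    @given(
        lam=st.floats(min_value=0.5, max_value=100.0),
        g=st.floats(min_value=-80.0, max_value=80.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_round_trip_through_marcus_barrier(self, lam, g):
        """Inverting the Marcus quadratic recovers the generating lambda."""
        dG, _ = marcus_barrier(g, lam)
        roots = infer_lambda(g, dG)
        assert any(
            abs(root - lam) < 1e-9 * max(1.0, lam) for root, _ in roots
        )
        # and every reported root reproduces the barrier
        for root, _ in roots:
            assert marcus_barrier(g, root)[0] == pytest.approx(
                dG, abs=1e-9
            )


class TestDiffusion:
    def test_equal_radii_closed_form_is_radius_independent(self):
        # 8 kB T N_A / (3 eta), in M^-1 s^-1
        expected = (
            8.0 * CONSTANTS.kB * 298.15 * CONSTANTS.N_A / (3.0 * 8.91e-4)
        ) * 1000.0
        for a in (1e-10, 3e-10, 8e-10):
            k = diffusion_rate(
                DiffusionInputs(radius_A=a, radius_B=a, viscosity=8.91e-4)
            )
            assert k == pytest.approx(expected, rel=1e-12)
            assert k == pytest.approx(7.42e9, rel=1e-3)

    def test_doubling_viscosity_halves_the_rate(self):
        base = DiffusionInputs(radius_A=2e-10, radius_B=4e-10, viscosity=8.91e-4)
        thick = DiffusionInputs(
            radius_A=2e-10, radius_B=4e-10, viscosity=2 * 8.91e-4
        )
        assert diffusion_rate(thick) == pytest.approx(
            diffusion_rate(base) / 2.0, rel=1e-12
        )

    def test_default_reaction_distance_is_contact(self):
        d = DiffusionInputs(radius_A=2e-10, radius_B=4e-10, viscosity=1e-3)
        assert d.R_AB == pytest.approx(6e-10)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(radius_A=0.0, radius_B=1e-10, viscosity=1e-3),
            dict(radius_A=1e-10, radius_B=1e-10, viscosity=-1e-3),
            dict(radius_A=1e-10, radius_B=1e-10, viscosity=1e-3,
                 reaction_distance=0.0),
        ],
    )
    def test_nonpositive_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DiffusionInputs(**kwargs)


class TestCollinsKimball:
    def test_diffusion_limit(self):
        assert collins_kimball(1e15, 1e9) == pytest.approx(1e9, rel=1e-5)

    def test_activation_limit(self):
        assert collins_kimball(1e3, 1e9) == pytest.approx(1e3, rel=1e-5)

    def test_equal_rates_give_half(self):
        assert collins_kimball(2e9, 2e9) == pytest.approx(1e9, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            collins_kimball(0.0, 1e9)

    @given(k=positive_rates, kD=positive_rates)
    @settings(max_examples=200, derandomize=True)
    def test_bounded_by_both_and_monotone(self, k, kD):
        kapp = collins_kimball(k, kD)
        assert kapp <= min(k, kD) * (1 + 1e-12)
        assert collins_kimball(k * 1.5, kD) >= kapp * (1 - 1e-12)
        assert collins_kimball(k, kD * 1.5) >= kapp * (1 - 1e-12)
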