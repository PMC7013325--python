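"""Singlet-oxygen dose model: closed forms, inversions, and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ipdtsim as ipdt
from ipdtsim.dose import UnreachableDoseError

P = ipdt.PhotophysicalParams()
P_NOBLEACH = P.with_(bleaching_enabled=False)

# Hand arithmetic: 1000 * 5000 * ln(10) * 635e-7 / (6.626e-34 * 3.0e10 * 6.0e23)
A_HAND = 1000 * 5000 * math.log(10) * 635e-7 / (6.626e-34 * 3.0e10 * 6.0e23)


class TestPrefactor:
    def test_default_value_matches_hand_arithmetic(self):
        assert ipdt.dose_prefactor(P) == pytest.approx(A_HAND, rel=1e-12)
        assert ipdt.dose_prefactor(P) == pytest.approx(61.3, rel=1e-3)

    def test_linear_in_epsilon(self):
        assert ipdt.dose_prefactor(P.with_(epsilon=10000.0)) == pytest.approx(
            2 * ipdt.dose_prefactor(P)
        )

    def test_vanishes_with_wavelength(self):
        assert ipdt.dose_prefactor(P.with_(wavelength=1e-12)) < 1e-4


class TestSingletOxygenDose:
    def test_bleached_dose_near_threshold_fluence(self):
        # 2.3 J/cm^2 at C0 = 5.8 uM should give ~0.56 mM (printed rounding)
        d = ipdt.singlet_oxygen_dose(2.3e-3, 1000.0, 5.8e-6, P)  # F = 2.3 J/cm^2
        assert d == pytest.approx(0.56e-3, rel=0.10)

    def test_zero_inputs_give_zero(self):
        assert ipdt.singlet_oxygen_dose(0.0, 3600.0, 5.8e-6, P) == 0.0
        assert ipdt.singlet_oxygen_dose(0.1, 3600.0, 0.0, P) == 0.0
        assert ipdt.singlet_oxygen_dose(0.1, 0.0, 5.8e-6, P) == 0.0

    def test_unbleached_exceeds_high_threshold_while_bleached_saturates(self):
        f_rate, t = 150.0 / 3600.0, 3600.0  # 150 J/cm^2
        unbleached = ipdt.singlet_oxygen_dose(f_rate, t, 5.8e-6, P_NOBLEACH)
        assert unbleached == pytest.approx(41e-3, rel=0.02)
        assert unbleached > 7.9e-3
        assert ipdt.saturation_dose(5.8e-6, P) < 7.9e-3

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            ipdt.singlet_oxygen_dose(-1.0, 1.0, 1e-6, P)


class TestNumericIntegralOracle:
    @pytest.mark.parametrize("f_rate,time,c0,beta", [
        (580e-3, 3600.0, 5.8e-6, 13.5),
        (0.01, 100.0, 1e-6, 4.5),
        (2.0, 10.0, 2.82e-5, 33.0),
    ])
    def test_converges_to_closed_form(self, f_rate, time, c0, beta):
        params = P.with_(beta=beta)
        closed = ipdt.singlet_oxygen_dose(f_rate, time, c0, params)
        numeric = ipdt.numeric_dose_integral(f_rate, time, c0, params, dt=time / 10_000)
        assert numeric == pytest.approx(closed, rel=1e-4)

    def test_single_step_overestimates_decreasing_integrand(self):
        closed = ipdt.singlet_oxygen_dose(580e-3, 3600.0, 5.8e-6, P)
        one_step = ipdt.numeric_dose_integral(580e-3, 3600.0, 5.8e-6, P, dt=3600.0)
        assert one_step > closed

    def test_exact_without_bleaching_for_any_dt(self):
        for dt in (3600.0, 100.0, 1.0):
            closed = ipdt.singlet_oxygen_dose(0.1, 3600.0, 5.8e-6, P_NOBLEACH)
            numeric = ipdt.numeric_dose_integral(0.1, 3600.0, 5.8e-6, P_NOBLEACH, dt=dt)
            assert numeric == pytest.approx(closed, rel=1e-12)


class TestSaturationDose:
    def test_default_parameters(self):
        assert ipdt.saturation_dose(5.8e-6, P) == pytest.approx(3.7e-3, rel=0.01)

    def test_zero_concentration(self):
        assert ipdt.saturation_dose(0.0, P) == 0.0

    def test_monotone_in_beta(self):
        vals = [ipdt.saturation_dose(5.8e-6, P.with_(beta=b)) for b in (4.5, 13.5, 33.0)]
        assert vals == sorted(vals)

    def test_requires_bleaching(self):
        with pytest.raises(ValueError):
            ipdt.saturation_dose(5.8e-6, P_NOBLEACH)


class TestRequiredFluence:
    @pytest.mark.parametrize("threshold_mM,expected", [(0.4, 1.6), (0.56, 2.3), (0.72, 3.0)])
    def test_reproduces_threshold_fluences(self, threshold_mM, expected):
        f = ipdt.required_fluence(threshold_mM * 1e-3, 5.8e-6, P)
        assert f == pytest.approx(expected, rel=0.10)

    def test_round_trip_inversion_identity(self):
        threshold = 0.56e-3
        f = ipdt.required_fluence(threshold, 5.8e-6, P)
        back = ipdt.singlet_oxygen_dose(f / 3600.0, 3600.0, 5.8e-6, P)
        assert back == pytest.approx(threshold, rel=1e-10)

    def test_saturation_threshold_unreachable(self):
        sat = ipdt.saturation_dose(5.8e-6, P)
        with pytest.raises(UnreachableDoseError):
            ipdt.required_fluence(sat, 5.8e-6, P)

    def test_no_bleaching_linear_inverse(self):
        f = ipdt.required_fluence(0.56e-3, 5.8e-6, P_NOBLEACH)
        a = ipdt.dose_prefactor(P)
        assert f == pytest.approx(0.56e-3 / (a * 0.77 * 5.8e-6), rel=1e-12)


class TestMinInitialConcentration:
    def test_saturation_limit(self):
        c0 = ipdt.min_initial_concentration(0.56e-3, math.inf, P)
        assert c0 == pytest.approx(0.9e-6, rel=0.10)

    def test_finite_fluence(self):
        c0 = ipdt.min_initial_concentration(0.56e-3, 2.0, P)
        assert 6.3e-6 <= c0 <= 6.4e-6

    def test_vanishing_threshold(self):
        assert ipdt.min_initial_concentration(1e-12, math.inf, P) < 1e-12

    def test_round_trip_with_required_fluence(self):
        c0 = ipdt.min_initial_concentration(0.56e-3, 2.0, P)
        assert ipdt.required_fluence(0.56e-3, c0, P) == pytest.approx(2.0, rel=1e-9)


class TestMinBleachingCoefficient:
    def test_threshold_case(self):
        beta = ipdt.min_bleaching_coefficient(0.56e-3, 3.0, 5.8e-6, P)
        assert beta == pytest.approx(3.52, rel=0.05)

    def test_forward_residual_small(self):
        beta = ipdt.min_bleaching_coefficient(0.56e-3, 3.0, 5.8e-6, P)
        d = ipdt.singlet_oxygen_dose(3.0 / 3600, 3600.0, 5.8e-6, P.with_(beta=beta))
        assert d == pytest.approx(0.56e-3, rel=1e-6)

    def test_effective_fluence_monotone_in_beta(self):
        f = 3.0
        vals = [b * -math.expm1(-f / b) for b in (0.5, 2.0, 5.0, 20.0, 100.0)]
        assert vals == sorted(vals)

    def test_unreachable_without_bleaching(self):
        # even the unbleached model cannot reach 0.56 mM at 1 J/cm^2 for tiny c0
        with pytest.raises(UnreachableDoseError):
            ipdt.min_bleaching_coefficient(0.56e-3, 1.0, 1e-8, P)


class TestDoseMap:
    def _uniform_fluence(self, model, phi_mw):
        phi = np.full(model.grid.dims, phi_mw)
        return ipdt.FluenceMap(model.grid, phi, n_photons=1, seed=0)

    def test_uniform_fluence_gives_uniform_dose(self):
        model = ipdt.build_uniform_phantom((4, 4, 4), (0.1, 0.1, 0.1))
        dmap = ipdt.dose_map(self._uniform_fluence(model, 580.0), 3600.0, model, P)
        assert np.ptp(dmap.d_so) == 0.0

    def test_linear_in_c0_field(self):
        m1 = ipdt.build_uniform_phantom((4, 4, 4), (0.1, 0.1, 0.1), c0=2e-6)
        m2 = ipdt.build_uniform_phantom((4, 4, 4), (0.1, 0.1, 0.1), c0=6e-6)
        f = self._uniform_fluence(m1, 580.0)
        d1 = ipdt.dose_map(f, 3600.0, m1, P)
        d2 = ipdt.dose_map(f, 3600.0, m2, P)
        np.testing.assert_allclose(d2.d_so, 3.0 * d1.d_so, rtol=1e-12)

    def test_voxel_matches_scalar_operation(self):
        model = ipdt.build_uniform_phantom((4, 4, 4), (0.1, 0.1, 0.1))
        dmap = ipdt.dose_map(self._uniform_fluence(model, 580.0), 3600.0, model, P)
        scalar = ipdt.singlet_oxygen_dose(0.580, 3600.0, 5.8e-6, P)
        assert dmap.d_so[2, 1, 3] == pytest.approx(scalar, rel=1e-12)

    def test_grid_mismatch_rejected(self):
        m1 = ipdt.build_uniform_phantom((4, 4, 4), (0.1, 0.1, 0.1))
        m2 = ipdt.build_uniform_phantom((5, 5, 5), (0.1, 0.1, 0.1))
        with pytest.raises(ValueError):
            ipdt.dose_map(self._uniform_fluence(m1, 1.0), 10.0, m2, P)


# ---------------------------------------------------------------------------
# property-based invariants (derandomized)
# ---------------------------------------------------------------------------

fluence_rates = st.floats(1e-6, 10.0)
times = st.floats(1.0, 1e5)
c0s = st.floats(1e-9, 3e-5)
betas = st.floats(0.5, 50.0)


@settings(derandomize=True, max_examples=50)
@given(f=fluence_rates, t=times, c0=c0s, beta=betas)
def test_bleached_dose_never_exceeds_unbleached(f, t, c0, beta):
    params = P.with_(beta=beta)
    bleached = ipdt.singlet_oxygen_dose(f, t, c0, params)
    unbleached = ipdt.singlet_oxygen_dose(f, t, c0, params.with_(bleaching_enabled=False))
    assert bleached <= unbleached * (1 + 1e-12)


@settings(derandomize=True, max_examples=50)
@given(f=fluence_rates, t=times, c0=c0s, beta=betas, factor=st.floats(1.01, 5.0))
@pytest.mark.parametrize("param", ["fluence", "c0", "phi_quantum", "epsilon", "beta"])
def test_dose_nondecreasing_in_each_parameter(param, f, t, c0, beta, factor):
    params = P.with_(beta=beta, phi_quantum=0.3, epsilon=3000.0)
    base = ipdt.singlet_oxygen_dose(f, t, c0, params)
    if param == "fluence":
        bumped = ipdt.singlet_oxygen_dose(f * factor, t, c0, params)
    elif param == "c0":
        bumped = ipdt.singlet_oxygen_dose(f, t, c0 * factor, params)
    elif param == "phi_quantum":
        bumped = ipdt.singlet_oxygen_dose(f, t, c0, params.with_(phi_quantum=min(1.0, 0.3 * factor)))
    elif param == "epsilon":
        bumped = ipdt.singlet_oxygen_dose(f, t, c0, params.with_(epsilon=3000.0 * factor))
    else:
        bumped = ipdt.singlet_oxygen_dose(f, t, c0, params.with_(beta=beta * factor))
    assert bumped >= base * (1 - 1e-12)


@settings(derandomize=True, max_examples=30)
@given(f=fluence_rates, t=times, c0=c0s)
def test_infinite_beta_limit_recovers_unbleached_model(f, t, c0):
    huge = ipdt.singlet_oxygen_dose(f, t, c0, P.with_(beta=1e6))
    linear = ipdt.singlet_oxygen_dose(f, t, c0, P_NOBLEACH)
    # leading-order relative deviation is F/(2 beta)
    assert huge == pytest.approx(linear, rel=1.1 * (f * t) / (2 * 1e6) + 1e-9)


@settings(derandomize=True, max_examples=30)
@given(fluence=st.floats(0.01, 300.0), c0=c0s, beta=betas, split=st.floats(0.05, 0.95))
def test_dose_depends_only_on_fluence_product(fluence, c0, beta, split):
    """Reciprocity: (phi, T) pairs with equal product phi*T give equal dose."""
    params = P.with_(beta=beta)
    t1, t2 = 3600.0, 3600.0 * split
    d1 = ipdt.singlet_oxygen_dose(fluence / t1, t1, c0, params)
    d2 = ipdt.singlet_oxygen_dose(fluence / t2, t2, c0, params)
    assert d1 == pytest.approx(d2, rel=1e-12)


@settings(derandomize=True, max_examples=25)
@given(f=st.floats(1e-4, 1.0), t=st.floats(10.0, 2e4), c0=c0s, beta=betas)
def test_closed_form_matches_integral_oracle_across_parameters(f, t, c0, beta):
    params = P.with_(beta=beta)
    closed = ipdt.singlet_oxygen_dose(f, t, c0, params)
    dt = t / 10_000
    numeric = ipdt.numeric_dose_integral(f, t, c0, params, dt=dt)
    # trapezoid truncation for the exponential integrand scales as (f*dt/beta)^2
    tol = 1e-4 + (f * dt / beta) ** 2
    assert numeric == pytest.approx(closed, rel=tol, abs=1e-300)
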