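"""Scalar solar/atmosphere chain: frozen examples, domains, oracle equivalence."""

import math

import numpy as np
import pytest

import oracles
from mptet.errors import DomainError
from mptet.solar import (
    MeteoSnapshot,
    atmosphere_at_overpass,
    atmospheric_emissivity,
    beam_transmissivity,
    broadband_transmissivity,
    cos_incidence,
    diffuse_transmissivity,
    inverse_relative_distance,
    precipitable_water,
    psychrometric_constant,
    svp_slope,
    vapour_pressure_from_dewpoint,
)


class TestExamples:
    def test_earth_sun_distance_annual_range(self):
        values = [inverse_relative_distance(d) for d in range(1, 366)]
        assert round(min(values), 2) == 0.97
        assert round(max(values), 2) == 1.03

    @pytest.mark.parametrize(
        "func, args, expected, tol",
        [
            (inverse_relative_distance, (1,), 1.0330, 1e-4),
            (cos_incidence, (90.0,), 1.0, 1e-12),
            (cos_incidence, (30.0,), 0.5, 1e-12),
            (cos_incidence, (45.0,), 0.70711, 1e-5),
            (vapour_pressure_from_dewpoint, (273.15,), 0.6108, 1e-12),
            (vapour_pressure_from_dewpoint, (298.15,), 3.168, 2e-3),
            (vapour_pressure_from_dewpoint, (283.15,), 1.228, 2e-3),
            (precipitable_water, (0.0, 100.0), 2.1, 1e-12),
            (precipitable_water, (1.0, 100.0), 16.1, 1e-12),
            (precipitable_water, (3.0, 95.0), 42.0, 1e-12),
            (beam_transmissivity, (100.0, 1.0, 1.0, 10.0), 0.7015, 1e-3),
            (diffuse_transmissivity, (0.15,), 0.296, 1e-12),
            (diffuse_transmissivity, (0.10,), 0.262, 1e-12),
            (diffuse_transmissivity, (0.70,), 0.098, 1e-12),
            (broadband_transmissivity, (0.15, 0.296), 0.446, 1e-12),
            (atmospheric_emissivity, (math.exp(-1),), 0.85, 1e-12),
            (atmospheric_emissivity, (0.799,), 0.7430, 1e-3),
            (psychrometric_constant, (101.325,), 0.0674, 2e-4),
            (psychrometric_constant, (0.0,), 0.0, 0.0),
            (svp_slope, (298.15,), 0.1887, 5e-4),
            (svp_slope, (273.15,), 0.0445, 2e-4),
        ],
    )
    def test_frozen_values(self, func, args, expected, tol):
        assert func(*args) == pytest.approx(expected, abs=tol)

    def test_broadband_sum_of_prior_examples(self):
        tb = beam_transmissivity(100.0, 1.0, 1.0, 10.0)
        td = diffuse_transmissivity(tb)
        assert broadband_transmissivity(tb, td) == pytest.approx(0.7990, abs=1e-3)

    def test_beam_transmissivity_clean_limit(self):
        # exponent -> 0 as Pair, W -> 0+: tau_B -> 0.98
        assert beam_transmissivity(1e-9, 1.0, 1.0, 1e-9) == pytest.approx(0.98, abs=1e-4)


class TestDomainsAndProperties:
    @pytest.mark.parametrize(
        "func, args",
        [
            (inverse_relative_distance, (0,)),
            (inverse_relative_distance, (367,)),
            (cos_incidence, (0.0,)),
            (cos_incidence, (-5.0,)),
            (vapour_pressure_from_dewpoint, (200.0,)),
            (precipitable_water, (-1.0, 100.0)),
            (beam_transmissivity, (100.0, 1.0, 0.0, 10.0)),
            (diffuse_transmissivity, (1.5,)),
            (atmospheric_emissivity, (1.0,)),
            (svp_slope, (200.0,)),
        ],
    )
    def test_out_of_domain_rejected(self, func, args):
        with pytest.raises(DomainError):
            func(*args)

    def test_dr_bounded_and_near_periodic(self):
        vals = np.array([inverse_relative_distance(d) for d in range(1, 367)])
        assert vals.min() >= 1 - 0.033 and vals.max() <= 1 + 0.033
        assert inverse_relative_distance(366) == pytest.approx(
            inverse_relative_distance(1), abs=2e-5
        )

    def test_diffuse_branch_selected_at_threshold(self):
        # both branches exist near 0.15; the >= branch wins at the threshold
        below = diffuse_transmissivity(0.15 - 1e-9)
        at = diffuse_transmissivity(0.15)
        assert at == pytest.approx(0.35 - 0.36 * 0.15)
        assert below == pytest.approx(0.18 + 0.82 * 0.15, abs=1e-6)
        assert abs(below - at) == pytest.approx(0.007, abs=1e-6)

    def test_beam_transmissivity_decreases_with_pressure(self):
        taus = [beam_transmissivity(p, 1.0, 0.8, 15.0) for p in (60, 80, 100)]
        assert taus[0] > taus[1] > taus[2]

    def test_svp_slope_strictly_increasing(self):
        t = np.linspace(245.0, 325.0, 50)
        d = np.array([svp_slope(x) for x in t])
        assert np.all(np.diff(d) > 0)

    def test_emissivity_decreasing_in_transmissivity(self):
        taus = np.linspace(0.05, 0.95, 30)
        eps = np.array([atmospheric_emissivity(t) for t in taus])
        assert np.all(np.diff(eps) < 0)

    def test_composed_emissivity_stays_physical(self):
        for pair in (60.0, 85.0, 101.0):
            for w in (2.5, 15.0, 45.0):
                for ct in (0.3, 0.7, 1.0):
                    tb = beam_transmissivity(pair, 1.0, ct, w)
                    tsw = broadband_transmissivity(tb, diffuse_transmissivity(tb))
                    assert 0.0 < atmospheric_emissivity(tsw) < 1.0

    def test_gamma_linear_in_pressure(self):
        assert psychrometric_constant(200.0) == pytest.approx(
            2 * psychrometric_constant(100.0)
        )


class TestOracleEquivalence:
    """Every scalar operation matches the independent evaluator to 1e-12 relative."""

    def test_thousand_random_valid_inputs(self, rng):
        for _ in range(1000):
            doy = int(rng.integers(1, 366))
            elev = float(rng.uniform(5.0, 90.0))
            tdew = float(rng.uniform(250.0, 310.0))
            pair = float(rng.uniform(55.0, 105.0))
            kt = float(rng.uniform(0.5, 1.0))
            ta = float(rng.uniform(250.0, 325.0))

            assert inverse_relative_distance(doy) == pytest.approx(
                oracles.dr_oracle(doy), rel=1e-12
            )
            ct = cos_incidence(elev)
            assert ct == pytest.approx(oracles.cos_theta_oracle(elev), rel=1e-12)
            ea = vapour_pressure_from_dewpoint(tdew)
            assert ea == pytest.approx(
                oracles.tetens_oracle(tdew - 273.15), rel=1e-12
            )
            w = precipitable_water(ea, pair)
            assert w == pytest.approx(oracles.w_oracle(ea, pair), rel=1e-12)
            tb = beam_transmissivity(pair, kt, ct, w)
            assert tb == pytest.approx(
                oracles.tau_b_oracle(pair, kt, ct, w), rel=1e-12
            )
            td = diffuse_transmissivity(tb)
            assert td == pytest.approx(oracles.tau_d_oracle(tb), rel=1e-12)
            tsw = broadband_transmissivity(tb, td)
            assert atmospheric_emissivity(tsw) == pytest.approx(
                oracles.eps_a_oracle(tsw), rel=1e-12
            )
            assert psychrometric_constant(pair) == pytest.approx(
                oracles.gamma_oracle(pair), rel=1e-12
            )
            assert svp_slope(ta) == pytest.approx(
                oracles.delta_oracle(ta - 273.15), rel=1e-12
            )


class TestMeteoSnapshot:
    def test_vapour_pressure_precedence(self):
        m = MeteoSnapshot(ta_K=300.0, pair_kPa=100.0, ea_kPa=2.0, tdew_K=290.0)
        assert m.vapour_pressure() == 2.0
        m2 = MeteoSnapshot(ta_K=300.0, pair_kPa=100.0, tdew_K=273.15)
        assert m2.vapour_pressure() == pytest.approx(0.6108)

    def test_missing_humidity_rejected(self):
        with pytest.raises(DomainError):
            MeteoSnapshot(ta_K=300.0, pair_kPa=100.0)

    def test_full_chain_state_is_consistent(self):
        m = MeteoSnapshot(ta_K=300.0, pair_kPa=100.0, ea_kPa=1.5)
        atm = atmosphere_at_overpass(m, doy=100, sun_elevation_deg=55.0)
        assert atm.tau_sw == pytest.approx(atm.tau_b + atm.tau_d)
        assert 0 < atm.eps_a < 1
        assert atm.gamma_kPa_per_C > 0 and atm.delta_kPa_per_C > 0
        assert atm.w_mm == pytest.approx(0.14 * 1.5 * 100.0 + 2.1)
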