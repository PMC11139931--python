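"""Unit and property tests for the meteorological primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from etobench.met_core import (
    MonthlyClimateRecord,
    SiteMetadata,
    actual_vapour_pressure,
    atmospheric_pressure,
    daylight_hours,
    daytime_percentage,
    derive_met,
    extraterrestrial_radiation,
    mean_relative_humidity,
    mean_temperature,
    mid_month_doy,
    net_radiation,
    psychrometric_constant,
    saturation_vapour_pressure,
    solar_radiation_angstrom,
    svp_slope,
    unit_convert_rs,
    wind_to_2m_ms,
)

DAYS_IN_MONTH = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]


class TestScalarPrimitives:
    @pytest.mark.parametrize(
        "tmax,tmin,expected",
        [(19.5, 7.3, 13.4), (0.0, 0.0, 0.0), (22.1, 12.0, 17.05)],
    )
    def test_mean_temperature(self, tmax, tmin, expected):
        assert mean_temperature(tmax, tmin) == pytest.approx(expected)

    def test_mean_temperature_rejects_inverted_extremes(self):
        with pytest.raises(ValueError):
            mean_temperature(5.0, 10.0)

    @pytest.mark.parametrize(
        "rhmax,rhmin,expected",
        [(95.0, 51.1, 73.05), (100.0, 100.0, 100.0), (96.2, 80.3, 88.25)],
    )
    def test_mean_relative_humidity(self, rhmax, rhmin, expected):
        assert mean_relative_humidity(rhmax, rhmin) == pytest.approx(expected)

    def test_mean_relative_humidity_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            mean_relative_humidity(101.0, 50.0)
        with pytest.raises(ValueError):
            mean_relative_humidity(50.0, 60.0)

    @pytest.mark.parametrize(
        "wind,height,expected",
        [(4.09, 2.0, 4.09 / 3.6), (0.0, 2.0, 0.0), (8.51, 2.0, 8.51 / 3.6)],
    )
    def test_wind_conversion_at_2m(self, wind, height, expected):
        assert wind_to_2m_ms(wind, height) == pytest.approx(expected, abs=1e-6)

    def test_wind_log_profile_reduces_higher_measurements(self):
        # wind measured at 10 m reduced by 4.87/ln(67.8*10 - 5.42) ~ 0.748
        u10 = wind_to_2m_ms(10.0, 10.0)
        assert u10 == pytest.approx(10.0 / 3.6 * 4.87 / math.log(67.8 * 10 - 5.42))
        assert u10 < wind_to_2m_ms(10.0, 2.0)

    @pytest.mark.parametrize("month,doy", [(1, 15), (2, 46), (12, 349)])
    def test_mid_month_doy(self, month, doy):
        assert mid_month_doy(month) == doy

    def test_mid_month_doy_rejects_invalid_month(self):
        with pytest.raises(ValueError):
            mid_month_doy(13)

    @pytest.mark.parametrize(
        "t,expected,tol",
        [(0.0, 0.6108, 1e-9), (13.4, 1.5374, 1e-3), (19.5, 2.2664, 1e-3)],
    )
    def test_saturation_vapour_pressure(self, t, expected, tol):
        assert saturation_vapour_pressure(t) == pytest.approx(expected, abs=tol)

    def test_svp_slope_values(self):
        assert svp_slope(13.4) == pytest.approx(0.1002, abs=2e-4)
        assert svp_slope(0.0) == pytest.approx(0.0445, abs=5e-4)
        assert svp_slope(20.0) > svp_slope(10.0)

    def test_atmospheric_pressure(self):
        assert atmospheric_pressure(0.0) == pytest.approx(101.3)
        assert atmospheric_pressure(2218.0) == pytest.approx(77.7, abs=0.2)
        z = np.linspace(0, 4000, 30)
        p = [atmospheric_pressure(zi) for zi in z]
        assert all(a > b for a, b in zip(p, p[1:]))

    def test_psychrometric_constant(self):
        sea = SiteMetadata(latitude=0.0, elevation=0.0)
        high = SiteMetadata(latitude=11.41, elevation=2218.0)
        override = SiteMetadata(latitude=11.41, elevation=2218.0, gamma_override=0.0677)
        assert psychrometric_constant(sea) == pytest.approx(0.0674, abs=2e-4)
        assert psychrometric_constant(high) == pytest.approx(0.0517, abs=2e-4)
        assert psychrometric_constant(override) == 0.0677

    @pytest.mark.parametrize(
        "rs,dialect,expected",
        [(19.29, "cal_cm2", 460.72), (1.0, "kJ_m2", 1000.0), (0.0, "MJ", 0.0)],
    )
    def test_unit_convert_rs(self, rs, dialect, expected):
        assert unit_convert_rs(rs, dialect) == pytest.approx(expected, abs=0.05)

    def test_unit_convert_rejects_unknown_dialect(self):
        with pytest.raises(ValueError):
            unit_convert_rs(1.0, "W_m2")


class TestRadiationAstronomy:
    def test_ra_at_study_site_mid_january(self):
        assert extraterrestrial_radiation(11.41, 15) == pytest.approx(31.2, abs=0.4)

    def test_polar_night_gives_zero(self):
        assert extraterrestrial_radiation(70.0, 355) == pytest.approx(0.0, abs=1e-9)
        assert daylight_hours(70.0, 355) == pytest.approx(0.0, abs=1e-9)

    def test_equator_beats_high_latitude_at_equinox(self):
        doy = 80  # ~equinox
        ra_eq = extraterrestrial_radiation(0.0, doy)
        assert ra_eq >= extraterrestrial_radiation(60.0, doy)
        assert ra_eq >= extraterrestrial_radiation(-60.0, doy)

    def test_daylight_hours(self):
        assert daylight_hours(0.0, 100) == pytest.approx(12.0, abs=0.1)
        assert daylight_hours(11.41, 15) == pytest.approx(11.4, abs=0.15)

    @pytest.mark.parametrize("lat", [0.0, 15.0, 35.0, 55.0])
    def test_hemispheric_symmetry_of_ra(self, lat):
        # Ra(phi, d) ~ Ra(-phi, d + half year) once the Sun-Earth distance
        # factor dr -- a seasonal, not hemispheric, asymmetry of up to ~3% --
        # is normalised out
        def dr(doy):
            return 1 + 0.033 * math.cos(2 * math.pi * doy / 365)

        for doy in (15, 105, 196, 288):
            mirrored = int((doy + 182.5) % 365) or 365
            a = extraterrestrial_radiation(lat, doy) / dr(doy)
            b = extraterrestrial_radiation(-lat, mirrored) / dr(mirrored)
            assert a == pytest.approx(b, abs=0.5)

    @pytest.mark.parametrize("lat", [0.0, 20.0, 40.0, 60.0])
    def test_daylight_averages_twelve_hours_over_year(self, lat):
        mean_n = np.mean([daylight_hours(lat, d) for d in range(1, 366)])
        assert mean_n == pytest.approx(12.0, abs=0.2)

    def test_angstrom_solar_radiation(self):
        assert solar_radiation_angstrom(8.5, 11.4, 31.2, 0.25, 0.50) == pytest.approx(
            19.4, abs=0.1
        )
        assert solar_radiation_angstrom(0.0, 11.4, 31.2) == pytest.approx(0.25 * 31.2)
        assert solar_radiation_angstrom(11.4, 11.4, 31.2) == pytest.approx(0.75 * 31.2)
        # sunshine marginally above N is clamped, not rejected
        assert solar_radiation_angstrom(11.6, 11.4, 31.2) == pytest.approx(0.75 * 31.2)


class TestDoorenbosPruitt:
    def test_study_site_january(self):
        assert daytime_percentage(11.41, 1) == pytest.approx(0.26, abs=0.005)

    def test_equator_is_flat(self):
        for m in range(1, 13):
            assert daytime_percentage(0.0, m) == pytest.approx(0.27, abs=0.005)

    @pytest.mark.parametrize("lat", [0.0, 11.41, 30.0, 60.0, -20.0])
    def test_annual_percentage_sums_to_hundred(self, lat):
        total = sum(daytime_percentage(lat, m) * d for m, d in zip(range(1, 13), DAYS_IN_MONTH))
        assert total == pytest.approx(100.0, abs=2.5)

    def test_southern_hemisphere_is_six_months_shifted(self):
        assert daytime_percentage(-40.0, 1) == daytime_percentage(40.0, 7)

    def test_rejects_latitude_outside_table(self):
        with pytest.raises(ValueError):
            daytime_percentage(65.0, 1)


class TestVapourPressureAndNetRadiation:
    def test_actual_vapour_pressure_conventions(self, january):
        assert actual_vapour_pressure(january, "dual_rh") == pytest.approx(1.065, abs=0.005)
        assert actual_vapour_pressure(january, "mean_rh") == pytest.approx(1.123, abs=0.005)

    def test_saturated_record_reaches_saturation(self):
        rec = MonthlyClimateRecord(1, 15.0, 10.0, 0.0, 100.0, 100.0, 4.0, 6.0, 3.0)
        es_mean = (saturation_vapour_pressure(15.0) + saturation_vapour_pressure(10.0)) / 2
        assert actual_vapour_pressure(rec, "dual_rh") == pytest.approx(es_mean)

    def test_net_radiation_january(self, january, site, conv):
        met = derive_met(january, site, conv)
        assert met.rn == pytest.approx(10.3, abs=0.3)

    def test_net_radiation_zero_when_no_sun(self, january, site):
        assert net_radiation(january, 0.0, 31.2, 1.06, site) == 0.0

    def test_net_radiation_below_net_shortwave(self, site, conv, climate):
        for rec in climate:
            met = derive_met(rec, site, conv)
            assert met.rn < (1 - site.albedo) * met.rs


class TestDerivedMet:
    def test_invariants_on_study_climate(self, climate, site, conv):
        for rec in climate:
            met = derive_met(rec, site, conv)
            assert 0.0 <= met.rs <= met.ra
            assert met.rn <= met.rs
            assert met.delta > 0 and met.gamma > 0
            assert 0.0 < met.ea <= met.es
            assert met.ema > 0 and met.td >= 0

    def test_record_validation(self):
        with pytest.raises(ValueError):
            MonthlyClimateRecord(1, 5.0, 10.0, 0.0, 90.0, 50.0, 4.0, 6.0, 3.0)
        with pytest.raises(ValueError):
            MonthlyClimateRecord(1, 15.0, 10.0, 0.0, 50.0, 90.0, 4.0, 6.0, 3.0)
        with pytest.raises(ValueError):
            MonthlyClimateRecord(0, 15.0, 10.0, 0.0, 90.0, 50.0, 4.0, 6.0, 3.0)

    def test_site_validation(self):
        with pytest.raises(ValueError):
            SiteMetadata(latitude=95.0, elevation=100.0)
        with pytest.raises(ValueError):
            SiteMetadata(latitude=10.0, elevation=100.0, pan_fetch=0.5)
        with pytest.raises(ValueError):
            SiteMetadata(latitude=10.0, elevation=100.0, angstrom_a=0.6, angstrom_b=0.6)


# --- oracle equivalence ------------------------------------------------------
# straightforward loop-free re-implementations, kept deliberately separate
# from the package code paths


def _oracle_es(t):
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def _oracle_delta(t):
    return 4098.0 * _oracle_es(t) / (t + 237.3) ** 2


def _oracle_pressure(z):
    return 101.3 * math.pow((293.0 - 0.0065 * z) / 293.0, 5.26)


def _oracle_ra(lat, doy):
    phi = lat * math.pi / 180.0
    dr = 1 + 0.033 * math.cos(2 * math.pi / 365 * doy)
    dec = 0.409 * math.sin(2 * math.pi / 365 * doy - 1.39)
    ws = math.acos(max(-1.0, min(1.0, -math.tan(phi) * math.tan(dec))))
    return (
        24 * 60 / math.pi * 0.082 * dr
        * (ws * math.sin(phi) * math.sin(dec) + math.cos(phi) * math.cos(dec) * math.sin(ws))
    )


def test_primitives_match_independent_oracle():
    rng = np.random.default_rng(20240915)
    for _ in range(1000):
        t = rng.uniform(-30.0, 50.0)
        z = rng.uniform(0.0, 4000.0)
        lat = rng.uniform(-65.0, 65.0)
        doy = int(rng.integers(1, 366))
        assert saturation_vapour_pressure(t) == pytest.approx(_oracle_es(t), abs=1e-9)
        assert svp_slope(t) == pytest.approx(_oracle_delta(t), abs=1e-9)
        assert atmospheric_pressure(z) == pytest.approx(_oracle_pressure(z), abs=1e-9)
        assert extraterrestrial_radiation(lat, doy) == pytest.approx(
            max(_oracle_ra(lat, doy), 0.0), abs=1e-9
        )


# --- hypothesis properties ---------------------------------------------------


@given(st.floats(min_value=-39.0, max_value=59.0))
@settings(deadline=None)
def test_es_strictly_increasing(t):
    assert saturation_vapour_pressure(t + 0.5) > saturation_vapour_pressure(t)


@given(st.floats(min_value=-38.0, max_value=56.0))
@settings(deadline=None)
def test_es_convex(t):
    h = 1.0
    mid = saturation_vapour_pressure(t + h)
    assert saturation_vapour_pressure(t) + saturation_vapour_pressure(t + 2 * h) >= 2 * mid


@given(
    st.floats(min_value=-60.0, max_value=60.0),
    st.integers(min_value=1, max_value=365),
    st.floats(min_value=0.0, max_value=24.0),
)
@settings(deadline=None)
def test_rs_bounded_by_ra(lat, doy, sunshine):
    ra = extraterrestrial_radiation(lat, doy)
    n = daylight_hours(lat, doy)
    rs = solar_radiation_angstrom(sunshine, n, ra)
    assert 0.0 <= rs <= ra + 1e-12
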