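import datetime as dt

import numpy as np
import pytest

from polcompass.geometry import sph_to_vec, vec_to_sph
from polcompass.skylight import (
    Sky,
    SkyConfig,
    SunPosition,
    dome_raster,
    sample_hemisphere,
    sample_sun_positions,
    sky_sample,
    solar_position,
)


def psa_solar_position(when, latitude, longitude, utc_offset=0.0):
    """Independent ephemeris oracle (PSA algorithm, Blanco-Muriel et al.)."""
    hour = when.hour + when.minute / 60.0 + when.second / 3600.0 - utc_offset
    jd = (
        (1461 * (when.year + 4800 + (when.month - 14) // 12)) // 4
        + (367 * (when.month - 2 - 12 * ((when.month - 14) // 12))) // 12
        - (3 * ((when.year + 4900 + (when.month - 14) // 12) // 100)) // 4
        + when.day
        - 32075
    ) - 0.5 + hour / 24.0
    n = jd - 2451545.0
    Omega = 2.1429 - 0.0010394594 * n
    L = 4.8950630 + 0.017202791698 * n
    g = 6.2400600 + 0.0172019699 * n
    l = (
        L
        + 0.03341607 * np.sin(g)
        + 0.00034894 * np.sin(2 * g)
        - 0.0001134
        - 0.0000203 * np.sin(Omega)
    )
    ep = 0.4090928 - 6.2140e-9 * n + 0.0000396 * np.cos(Omega)
    ra = np.arctan2(np.cos(ep) * np.sin(l), np.cos(l)) % (2 * np.pi)
    dec = np.arcsin(np.sin(ep) * np.sin(l))
    gmst = 6.6974243242 + 0.0657098283 * n + hour
    lmst = np.deg2rad(gmst * 15 + longitude)
    ha = lmst - ra
    lat = np.deg2rad(latitude)
    zen = np.arccos(np.cos(lat) * np.cos(ha) * np.cos(dec) + np.sin(dec) * np.sin(lat))
    az = np.arctan2(-np.sin(ha), np.tan(dec) * np.cos(lat) - np.sin(lat) * np.cos(ha))
    zen += 6371.01 / 149597890.0 * np.sin(zen)  # parallax
    return 90.0 - np.rad2deg(zen), np.rad2deg(az) % 360.0


class TestSolarPosition:
    def test_equator_equinox_noon_is_overhead(self):
        sun = solar_position(dt.datetime(2018, 3, 20, 12, 0), 0.0, 0.0)
        assert sun.elevation > 85.0
        assert sun.is_up

    def test_night_flagged_not_raised(self):
        sun = solar_position(dt.datetime(2018, 6, 21, 0, 0), 37.39, -5.88, 1.0)
        assert sun.elevation < 0
        assert not sun.is_up

    @pytest.mark.parametrize(
        "when",
        [
            dt.datetime(2018, 6, 28, 10, 0),
            dt.datetime(2018, 6, 28, 16, 30),
            dt.datetime(2018, 12, 21, 12, 0),
        ],
    )
    def test_agrees_with_independent_ephemeris(self, when):
        lat, lon = 37.392508, -5.883875
        ours = solar_position(when, lat, lon, 0.0)
        el, az = psa_solar_position(when, lat, lon, 0.0)
        assert abs(ours.elevation - el) < 0.5
        assert abs((ours.azimuth - az + 180) % 360 - 180) < 0.5

    def test_latitude_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            solar_position(dt.datetime(2018, 6, 1, 12, 0), 95.0, 0.0)


class TestSkyPattern:
    sun = SunPosition(30.0, 0.0)

    def test_dop_values_along_the_solar_meridian(self):
        # 90 degrees from the sun: maximal; towards the sun: zero
        s = sky_sample(self.sun, 30.0, 180.0)  # gamma = 120... use exact points
        sky = Sky(self.sun)
        assert sky.dop_at(90.0) == pytest.approx(0.75, abs=1e-12)
        assert sky.dop_at(0.0) == pytest.approx(0.0, abs=1e-12)
        assert sky.dop_at(45.0) == pytest.approx(0.25, abs=1e-12)
        assert 0.0 <= s.dop <= 0.75

    def test_dop_depends_only_on_sun_distance(self, rng):
        sky = Sky(self.sun)
        # random rotations about the sun direction leave d unchanged
        gammas = rng.uniform(5, 120, 50)
        d_ref = sky.dop_at(gammas)
        assert np.all(d_ref >= 0) and np.all(d_ref <= 0.75)
        # two different view directions at the same gamma
        v1 = sky.sample(30.0 + 40.0, 0.0)  # 40 deg above the sun, same azimuth
        el2, az2 = vec_to_sph(  # 40 deg from sun, rotated off-meridian
            _rotate_about(self.sun.vector, np.deg2rad(60.0))
            @ sph_to_vec(70.0, 0.0)
        )
        v2 = sky.sample(float(el2), float(az2))
        assert v1.dop == pytest.approx(v2.dop, abs=1e-9)

    def test_aop_perpendicular_to_sun_view_great_circle(self, rng):
        sky = Sky(self.sun)
        v = sample_hemisphere(1000, seed=5)
        _, _, e = sky.field(v)
        # e must be orthogonal to both the view and the in-plane tangent
        s = self.sun.vector
        dots = np.abs(np.einsum("nk,nk->n", e, v))
        in_plane = np.einsum("nk,k->n", e, s)
        assert dots.max() < 1e-9
        assert np.abs(in_plane).max() < 1e-9

    def test_luminance_positive_everywhere(self):
        sky = Sky(self.sun)
        Y, d, _ = sky.field(sample_hemisphere(500, seed=1))
        assert np.all(Y > 0)

    def test_view_at_sun_returns_zero_dop(self):
        s = sky_sample(self.sun, 30.0, 0.0)
        assert s.dop == pytest.approx(0.0, abs=1e-12)
        assert 0.0 <= s.aop < 180.0

    def test_below_horizon_view_rejected(self):
        with pytest.raises(ValueError):
            sky_sample(self.sun, -5.0, 0.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SkyConfig(d_max=0.0)
        with pytest.raises(ValueError):
            SkyConfig(latitude=99.0)

    def test_dome_raster_max_dop_on_cross_solar_circle(self):
        raster = dome_raster(Sky(SunPosition(30.0, 180.0)), 2.0, 5.0)
        assert raster["dop"].max() == pytest.approx(0.75, abs=1e-6)
        # the cross-solar point (90 deg from the sun on the solar meridian)
        # attains the maximum
        cross = raster[(raster["elevation"] == 60.0) & (raster["azimuth"] == 0.0)]
        assert cross["dop"].iloc[0] == pytest.approx(0.75, abs=1e-6)


def _rotate_about(axis, angle):
    x, y, z = axis
    c, s, C = np.cos(angle), np.sin(angle), 1 - np.cos(angle)
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


class TestHemisphereSampling:
    def test_single_point_is_on_upper_hemisphere(self):
        v = sample_hemisphere(1, seed=0)
        assert v.shape == (1, 3)
        assert v[0, 2] >= 0

    def test_horizontal_balance(self):
        v = sample_hemisphere(1000, seed=3)
        assert np.abs(v[:, :2].mean(axis=0)).max() < 1.0 / np.sqrt(1000)

    def test_quasi_uniform_spacing(self):
        v = sample_hemisphere(500, seed=0)
        d = np.arccos(np.clip(v @ v.T, -1, 1))
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        assert nn.std() / nn.mean() < 0.5

    def test_deterministic_and_seed_dependent(self):
        a = sample_hemisphere(100, seed=4)
        b = sample_hemisphere(100, seed=4)
        c = sample_hemisphere(100, seed=5)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_sun_positions_in_range(self):
        el, az = sample_sun_positions(200, seed=1)
        assert np.all((el >= 0) & (el <= 90))
        assert np.all((az >= 0) & (az < 360))
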