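"""Polarised sky-dome model and solar ephemeris.

The sky model is a single-scattering Rayleigh description of the celestial
polarisation pattern.  For a view direction at angular distance ``gamma``
from the sun it predicts

* degree of linear polarisation  ``d = d_max * sin^2(gamma) / (1 + cos^2(gamma))``,
  zero towards the sun and maximal (``d_max``, default 0.75) on the great
  circle 90 degrees away from it;
* angle of polarisation perpendicular to the great circle through the sun
  and the view point (the e-vectors form concentric rings around the sun);
* a smooth relative luminance ``Y = (1 + cos^2(gamma)) / 2``.  Downstream
  polarisation-opponent processing is luminance-invariant, so only the
  positivity and smoothness of ``Y`` matter.

Sun positions come either from a NOAA-style solar ephemeris (date, time and
geographic coordinates) or are sampled quasi-uniformly on the hemisphere
with a Fibonacci spiral lattice.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    azimuthal_tangent,
    meridian_tangent,
    sph_to_vec,
    vec_to_sph,
    wrap360,
)
from .rng import stream

__all__ = [
    "SunPosition",
    "SkySample",
    "SkyConfig",
    "Sky",
    "solar_position",
    "sky_sample",
    "sample_hemisphere",
    "sample_sun_positions",
    "dome_raster",
]

#: golden angle in degrees, used by the Fibonacci spiral lattice
_GOLDEN_ANGLE = 360.0 * (1.0 - 1.0 / ((1.0 + np.sqrt(5.0)) / 2.0))


@dataclass(frozen=True)
class SunPosition:
    """Sun elevation above the horizon and azimuth clockwise from north (deg)."""

    elevation: float
    azimuth: float

    @property
    def is_up(self) -> bool:
        """False during the night (sun below the horizon)."""
        return self.elevation >= 0.0

    @property
    def vector(self) -> np.ndarray:
        return sph_to_vec(self.elevation, self.azimuth)


@dataclass(frozen=True)
class SkySample:
    """Sky state at one view direction.

    ``luminance`` is a relative radiance (>= 0), ``dop`` the degree of
    linear polarisation in [0, 1] and ``aop`` the axial e-vector angle in
    degrees, measured in the local view frame from the meridian (towards
    the zenith) rotating towards increasing azimuth, wrapped to [0, 180).
    """

    luminance: float
    dop: float
    aop: float


@dataclass
class SkyConfig:
    """Sky model and ephemeris configuration.

    ``latitude``/``longitude`` default to a desert-ant field site near
    Seville, Spain; ``utc_offset`` is the local clock offset in hours.
    """

    d_max: float = 0.75
    latitude: float = 37.392508
    longitude: float = -5.883875
    date: _dt.date = field(default_factory=lambda: _dt.date(2018, 6, 28))
    time: _dt.time = field(default_factory=lambda: _dt.time(10, 0))
    utc_offset: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.d_max <= 1.0:
            raise ValueError(f"d_max must be in (0, 1], got {self.d_max}")
        if abs(self.latitude) > 90.0:
            raise ValueError(f"|latitude| must be <= 90, got {self.latitude}")

    def sun(self, when: _dt.datetime | None = None) -> SunPosition:
        """Ephemeris sun position at ``when`` (default: configured date/time)."""
        if when is None:
            when = _dt.datetime.combine(self.date, self.time)
        return solar_position(when, self.latitude, self.longitude, self.utc_offset)


def solar_position(
    when: _dt.datetime,
    latitude: float,
    longitude: float,
    utc_offset: float = 0.0,
) -> SunPosition:
    """Sun elevation/azimuth from a NOAA-style low-cost solar ephemeris.

    ``when`` is local clock time offset from UTC by ``utc_offset`` hours;
    ``longitude`` is positive east.  Accuracy is a small fraction of a
    degree, far below the compass error scale.  A sun below the horizon is
    returned with negative elevation (``SunPosition.is_up`` is False), not
    raised as an error.
    """
    if abs(latitude) > 90.0:
        raise ValueError("latitude out of range")
    doy = when.timetuple().tm_yday
    hours = when.hour + when.minute / 60.0 + when.second / 3600.0
    year_len = 366.0 if _is_leap(when.year) else 365.0
    g = 2.0 * np.pi / year_len * (doy - 1 + (hours - 12.0) / 24.0)

    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )

    time_offset = eqtime + 4.0 * longitude - 60.0 * utc_offset  # minutes
    tst = hours * 60.0 + time_offset  # true solar time, minutes
    ha = np.deg2rad(tst / 4.0 - 180.0)  # hour angle

    lat = np.deg2rad(latitude)
    sin_el = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(ha)
    elevation = np.rad2deg(np.arcsin(np.clip(sin_el, -1.0, 1.0)))
    # azimuth measured from south, westward positive, then shifted to
    # clockwise-from-north
    az_south = np.arctan2(
        np.sin(ha), np.cos(ha) * np.sin(lat) - np.tan(decl) * np.cos(lat)
    )
    azimuth = wrap360(180.0 + np.rad2deg(az_south))
    return SunPosition(float(elevation), float(azimuth))


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


class Sky:
    """Polarised sky dome for a fixed sun position.

    The vectorised :meth:`field` evaluates luminance, degree of
    polarisation and e-vector direction (as a 3-D tangent unit vector) at
    arbitrary view directions; :meth:`sample` provides the scalar
    elevation/azimuth interface.
    """

    def __init__(self, sun: SunPosition, config: SkyConfig | None = None):
        self.sun = sun
        self.config = config if config is not None else SkyConfig()
        self._sun_vec = sun.vector

    def dop_at(self, gamma_deg):
        """Degree of polarisation at angular distance ``gamma_deg`` from the sun."""
        g = np.deg2rad(np.asarray(gamma_deg, dtype=float))
        return self.config.d_max * np.sin(g) ** 2 / (1.0 + np.cos(g) ** 2)

    def field(self, view_vecs: np.ndarray):
        """Sky state at view direction unit vectors, shape (..., 3).

        Returns ``(Y, d, e)``: luminance (...,), degree of polarisation
        (...,) and e-vector unit tangents (..., 3).  At the sun direction
        the angle of polarisation is undefined: ``d`` is 0 there and a
        fixed arbitrary tangent is returned.
        """
        v = np.asarray(view_vecs, dtype=float)
        s = self._sun_vec
        cos_g = np.clip(v @ s, -1.0, 1.0)
        d = self.config.d_max * (1.0 - cos_g**2) / (1.0 + cos_g**2)
        Y = (1.0 + cos_g**2) / 2.0

        e = np.cross(np.broadcast_to(s, v.shape), v)
        norm = np.linalg.norm(e, axis=-1, keepdims=True)
        degen = norm[..., 0] < 1e-9
        if np.any(degen):
            # view parallel to sun: d = 0, pick the azimuthal ring tangent
            fallback = azimuthal_tangent(v)
            bad = ~np.isfinite(fallback).all(axis=-1)
            fallback[bad] = np.array([1.0, 0.0, 0.0])
            e = np.where(degen[..., None], fallback, e / np.maximum(norm, 1e-12))
        else:
            e = e / norm
        return Y, d, e

    def sample(self, view_elevation: float, view_azimuth: float) -> SkySample:
        """Scalar :class:`SkySample` at one view direction (degrees)."""
        if view_elevation < 0:
            raise ValueError("view direction must be on the upper hemisphere")
        v = sph_to_vec(view_elevation, view_azimuth)
        Y, d, e = self.field(v[None, :])
        t_up = meridian_tangent(v)
        t_az = azimuthal_tangent(v)
        if not np.isfinite(t_up).all():  # zenith view: use north as meridian ref
            t_up = np.array([0.0, 1.0, 0.0])
            t_az = np.array([1.0, 0.0, 0.0])
        chi = np.rad2deg(np.arctan2(e[0] @ t_az, e[0] @ t_up)) % 180.0
        return SkySample(float(Y[0]), float(d[0]), float(chi))


def sky_sample(sun: SunPosition, view_elevation, view_azimuth, config=None) -> SkySample:
    """Convenience wrapper: one :class:`SkySample` for a sun and view direction."""
    return Sky(sun, config).sample(view_elevation, view_azimuth)


def sample_hemisphere(n_points: int, seed: int = 0) -> np.ndarray:
    """Quasi-uniform unit vectors on the upper hemisphere, shape (n, 3).

    A Fibonacci spiral lattice, rotated about the zenith by a uniform
    random phase drawn from the seed, so different seeds give distinct but
    equally homogeneous point sets.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = stream(seed, "hemisphere")
    offset = rng.uniform(0.0, 360.0)
    i = np.arange(n_points)
    z = (i + 0.5) / n_points
    r = np.sqrt(1.0 - z**2)
    az = np.deg2rad(wrap360(i * _GOLDEN_ANGLE + offset))
    return np.stack([r * np.sin(az), r * np.cos(az), z], axis=-1)


def sample_sun_positions(n_points: int, seed: int = 0):
    """Elevation/azimuth arrays (degrees) of quasi-uniform sun positions."""
    el, az = vec_to_sph(sample_hemisphere(n_points, seed))
    return el, az


def dome_raster(sky: Sky, elevation_step: float = 1.0, azimuth_step: float = 1.0) -> pd.DataFrame:
    """Regular elevation x azimuth grid of (Y, d, chi) for map-style plots.

    Returns a tidy DataFrame with columns ``elevation, azimuth, luminance,
    dop, aop``; elevations span [0, 90], azimuths [0, 360).
    """
    els = np.arange(0.0, 90.0 + 1e-9, elevation_step)
    azs = np.arange(0.0, 360.0, azimuth_step)
    E, A = np.meshgrid(els, azs, indexing="ij")
    v = sph_to_vec(E.ravel(), A.ravel())
    Y, d, e = sky.field(v)
    t_up = meridian_tangent(v)
    t_az = azimuthal_tangent(v)
    zen = ~np.isfinite(t_up).all(axis=-1)
    t_up[zen] = [0.0, 1.0, 0.0]
    t_az[zen] = [1.0, 0.0, 0.0]
    chi = np.rad2deg(
        np.arctan2(np.sum(e * t_az, axis=-1), np.sum(e * t_up, axis=-1))
    ) % 180.0
    return pd.DataFrame(
        {
            "elevation": E.ravel(),
            "azimuth": A.ravel(),
            "luminance": Y,
            "dop": d,
            "aop": chi,
        }
    )
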