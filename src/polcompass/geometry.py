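"""Spherical geometry helpers shared across the package.

Conventions (used everywhere in the public API):

* azimuth: degrees clockwise from north, wrapped to [0, 360)
* elevation: degrees above the horizon, in [-90, 90]
* world frame unit vectors: x = east, y = north, z = up

A direction with azimuth ``a`` and elevation ``e`` is therefore
``(cos e sin a, cos e cos a, sin e)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap360",
    "wrap180_axial",
    "signed_angdiff",
    "sph_to_vec",
    "vec_to_sph",
    "azimuthal_tangent",
    "meridian_tangent",
    "rotation_zenith_to",
    "rotation_yaw",
]


def wrap360(angle):
    """Wrap an angle (degrees) to [0, 360)."""
    out = np.mod(angle, 360.0)
    # np.mod can round a tiny negative input up to exactly 360.0
    return np.where(out >= 360.0, out - 360.0, out) if np.ndim(out) else (
        out - 360.0 if out >= 360.0 else out
    )


def wrap180_axial(angle):
    """Wrap an axial angle (degrees, 180-periodic) to [0, 180)."""
    return np.mod(angle, 180.0)


def signed_angdiff(a, b):
    """Signed circular difference a - b in (-180, 180] degrees."""
    return 180.0 - np.mod(180.0 - (np.asarray(a, dtype=float) - b), 360.0)


def sph_to_vec(elevation, azimuth):
    """Unit vector(s) for elevation/azimuth in degrees.

    Broadcasts; returns array with trailing axis of size 3.
    """
    el = np.deg2rad(np.asarray(elevation, dtype=float))
    az = np.deg2rad(np.asarray(azimuth, dtype=float))
    ce = np.cos(el)
    return np.stack([ce * np.sin(az), ce * np.cos(az), np.sin(el)], axis=-1)


def vec_to_sph(v):
    """Inverse of :func:`sph_to_vec`: (elevation, azimuth) in degrees."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1)
    el = np.rad2deg(np.arcsin(np.clip(v[..., 2] / n, -1.0, 1.0)))
    az = wrap360(np.rad2deg(np.arctan2(v[..., 0], v[..., 1])))
    return el, az


def azimuthal_tangent(v, pole=None):
    """Unit tangent at ``v`` along increasing azimuth about ``pole`` (default: +z).

    This is the tangent of the circle of constant polar distance through
    ``v`` — for a sensor dome it is the direction of the concentric-ring
    polariser axis of a unit looking along ``v``.  Undefined when ``v`` is
    parallel to the pole; callers must handle that case.
    """
    v = np.asarray(v, dtype=float)
    if pole is None:
        pole = np.array([0.0, 0.0, 1.0])
    t = np.cross(v, pole)
    n = np.linalg.norm(t, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return t / n


def meridian_tangent(v, pole=None):
    """Unit tangent at ``v`` pointing towards the pole (local 'up' on the dome)."""
    v = np.asarray(v, dtype=float)
    t_az = azimuthal_tangent(v, pole)
    return np.cross(t_az, v)


def rotation_zenith_to(elevation, azimuth):
    """Rotation matrix taking +z to the direction (elevation, azimuth), zero roll.

    The rotation is the minimal (geodesic) rotation about the horizontal
    axis perpendicular to the target azimuth, so a sensor tilted this way
    keeps its azimuthal reference aligned with the world as far as possible.
    """
    target = sph_to_vec(elevation, azimuth)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(z, target)
    s = np.linalg.norm(axis)
    c = float(np.dot(z, target))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # zenith to nadir: degenerate, pick rotation about east axis
        axis, s = np.array([1.0, 0.0, 0.0]), 1.0
        return _axis_angle(axis, np.pi)
    return _axis_angle(axis / s, np.arctan2(s, c))


def rotation_yaw(heading):
    """Rotation about +z by ``heading`` degrees clockwise from north.

    Applied to a sensor-frame vector it yaws the sensor so that its
    north reference points along ``heading`` in the world.
    """
    h = np.deg2rad(heading)
    c, s = np.cos(h), np.sin(h)
    # a feature at sensor azimuth phi maps to world azimuth phi + heading
    return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])


def _axis_angle(axis, angle):
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )
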