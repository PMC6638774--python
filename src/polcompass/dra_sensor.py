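"""Cyclopic dorsal-rim sensor array and polarisation-opponent responses.

The sensor emulates the joint (cyclopic) dorsal rim area of a desert ant:
``n = 60`` ommatidia quasi-homogeneously placed in a spherical cap of
receptive field ``omega = 56 deg`` around the sensor zenith, each with a
polariser axis tangential to its concentric ring (the fan-like layout,
``alpha_j = phi_j - 90 deg``) and acceptance angle ``rho = 5.4 deg``
(retained as metadata; units point-sample the sky along their optical
axis, which is negligible blur at the sky-pattern length scale).

Each unit carries two orthogonal photoreceptor channels followed by
normalised opponent processing, giving a luminance-invariant POL-neuron
output in [-1, 1].  Two photoreceptor transforms are supported:

* ``"linear"`` (package default): r_POL = (s_par - s_perp) / (s_par + s_perp)
  = d * cos 2(chi - alpha) — the pure polarisation-opponent contrast.  The
  compass's printed population-level constants (confidence scale, the
  domain of the confidence-elevation inversion) are quantitatively
  consistent with this form.
* ``"sqrt"``: square-root photoreceptor activation before opponency,
  r_POL = (sqrt(s_par) - sqrt(s_perp)) / (sqrt(s_par) + sqrt(s_perp)),
  which compresses bright-sky responses (the micro-circuit reading of the
  POL unit); it rescales the response curve without changing its zeros
  or 180-degree periodicity.

A disturbance level ``eta`` masks a uniformly random subset of units
(standing in for clouds, occlusion or sensor failure); masked units
report 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import (
    azimuthal_tangent,
    rotation_yaw,
    rotation_zenith_to,
    sph_to_vec,
    wrap360,
)
from .skylight import Sky, SkyConfig, SunPosition

__all__ = [
    "SensorArray",
    "PolResponse",
    "build_dra",
    "photoreceptor_stimulus",
    "pol_unit_response",
    "sense",
    "pol_responses_batch",
    "layout_table",
    "array_from_table",
]

DEFAULT_N = 60
DEFAULT_OMEGA = 56.0
DEFAULT_RHO = 5.4
DEFAULT_TRANSFORM = "linear"


@dataclass
class SensorArray:
    """Rigid array of polarisation units with a world pose.

    ``elevations``/``azimuths`` are the unit optical axes in the sensor
    frame (degrees); ``alphas`` the polariser axes, ``alpha_j = phi_j - 90``
    (axial).  The pose places the sensor zenith at world direction
    (``tilt_elevation``, ``tilt_azimuth``) with yaw ``heading``; the tilt
    magnitude is ``delta = 90 - tilt_elevation``.
    """

    elevations: np.ndarray
    azimuths: np.ndarray
    omega: float = DEFAULT_OMEGA
    rho: float = DEFAULT_RHO
    tilt_elevation: float = 90.0
    tilt_azimuth: float = 0.0
    heading: float = 0.0

    def __post_init__(self):
        self.elevations = np.asarray(self.elevations, dtype=float)
        self.azimuths = np.asarray(self.azimuths, dtype=float)
        if self.elevations.size < 1:
            raise ValueError("sensor needs at least one unit")
        if not 0.0 <= self.tilt_delta <= 90.0:
            raise ValueError("tilt magnitude must be within [0, 90] degrees")

    @property
    def n(self) -> int:
        return self.elevations.size

    @property
    def alphas(self) -> np.ndarray:
        """Polariser axis angles (degrees, axial), fan-like rule phi - 90."""
        return wrap360(self.azimuths - 90.0)

    @property
    def tilt_delta(self) -> float:
        """Tilt magnitude delta = 90 - tilt_elevation, degrees."""
        return 90.0 - self.tilt_elevation

    def posed(self, tilt_elevation=90.0, tilt_azimuth=0.0, heading=0.0) -> "SensorArray":
        """Copy of the array with a new rigid-body pose."""
        return replace(
            self,
            tilt_elevation=tilt_elevation,
            tilt_azimuth=tilt_azimuth,
            heading=heading,
        )

    # -- geometry -----------------------------------------------------

    def sensor_views(self) -> np.ndarray:
        """Unit optical-axis vectors in the sensor frame, (n, 3)."""
        return sph_to_vec(self.elevations, self.azimuths)

    def sensor_axes(self) -> np.ndarray:
        """Polariser-axis tangent unit vectors in the sensor frame, (n, 3)."""
        v = self.sensor_views()
        p = azimuthal_tangent(v)
        # units on the sensor zenith have no ring tangent; use the alpha rule
        bad = ~np.isfinite(p).all(axis=-1)
        if np.any(bad):
            p[bad] = sph_to_vec(0.0, self.alphas[bad])
        return p

    def pose_matrix(self) -> np.ndarray:
        """World-from-sensor rotation: yaw about the sensor zenith, then tilt."""
        return rotation_zenith_to(self.tilt_elevation, self.tilt_azimuth) @ rotation_yaw(
            self.heading
        )

    def world_frame(self):
        """(views, axes) unit vectors in the world frame, each (n, 3)."""
        R = self.pose_matrix()
        return self.sensor_views() @ R.T, self.sensor_axes() @ R.T


@dataclass
class PolResponse:
    """POL-neuron population output.

    ``r`` is the length-n response vector in [-1, 1] (0 for failed units)
    and ``failed`` the per-unit failure mask.  When requested, the raw
    photoreceptor stimuli and transformed channel responses are retained
    for inspection.
    """

    r: np.ndarray
    failed: np.ndarray
    s_par: np.ndarray | None = None
    s_perp: np.ndarray | None = None


def build_dra(
    n: int = DEFAULT_N,
    omega: float = DEFAULT_OMEGA,
    rho: float = DEFAULT_RHO,
    jitter: float = 2.0,
) -> SensorArray:
    """Build the concentric-ring dorsal-rim layout.

    Places one unit on the sensor zenith and the rest on equally spaced
    concentric rings filling the spherical cap of radius ``omega / 2``,
    with per-ring counts proportional to ring circumference (largest
    remainder rounding) — a deterministic quasi-homogeneous cap layout
    with ring-tangential (fan-like) polariser axes.

    ``jitter`` perturbs the within-ring azimuths by a fixed (deterministic)
    irregularity of up to that many degrees.  A perfectly regular ring
    annihilates the odd azimuthal lattice sums, which erases the residual
    polariser-tuning fan that irregular biological lattices exhibit; a
    small jitter restores it without measurably affecting compass
    accuracy.  ``jitter=0`` gives the exactly mirror-symmetric layout.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < omega <= 180.0:
        raise ValueError("omega must be in (0, 180] degrees")
    cap = omega / 2.0
    if n == 1:
        return SensorArray(np.array([90.0]), np.array([0.0]), omega=omega, rho=rho)

    # ring count from the hexagonal-packing spacing for n units in the cap
    area = 2.0 * np.pi * (1.0 - np.cos(np.deg2rad(cap)))
    spacing = np.rad2deg(np.sqrt(2.0 * area / (np.sqrt(3.0) * n)))
    m = max(1, int(np.ceil(cap / spacing)))
    radii = cap * np.arange(1, m + 1) / m

    weights = np.sin(np.deg2rad(radii))
    quota = (n - 1) * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    for i in np.argsort(remainder)[::-1][: (n - 1) - counts.sum()]:
        counts[i] += 1

    els = [90.0]
    azs = [0.0]
    jitter_rng = np.random.default_rng(20190718)  # fixed: the layout is deterministic
    for r, c in zip(radii, counts):
        if c == 0:
            continue
        k = np.arange(c)
        jit = jitter_rng.uniform(-jitter, jitter, c) if jitter > 0 else 0.0
        els.extend(np.full(c, 90.0 - r))
        azs.extend(wrap360(k * 360.0 / c + jit))
    return SensorArray(np.array(els), np.array(azs), omega=omega, rho=rho)


def photoreceptor_stimulus(sample, alpha: float):
    """Stimuli (s_par, s_perp) of the two photoreceptor channels.

    Malus-type response to partially linearly polarised light: with
    luminance Y, degree of polarisation d and e-vector angle chi,

        s_par  = Y * (1 + d cos 2(chi - alpha)) / 2
        s_perp = Y * (1 - d cos 2(chi - alpha)) / 2

    so s_par + s_perp = Y always, and the modulation amplitude scales
    with d.  ``alpha`` is the polariser axis of the parallel channel,
    in the same angular frame as ``sample.aop``.
    """
    c = np.cos(np.deg2rad(2.0 * (sample.aop - alpha)))
    s_par = sample.luminance * (1.0 + sample.dop * c) / 2.0
    s_perp = sample.luminance * (1.0 - sample.dop * c) / 2.0
    return s_par, s_perp


def pol_unit_response(s_par, s_perp, transform: str = "sqrt"):
    """Opponent POL-neuron output for channel stimuli (scalars or arrays).

    Photoreceptor activation (square root by default for this unit-level
    function, matching the POL micro-circuit description; ``"linear"``
    for the raw opponent contrast) followed by normalised opponency
    (r_par - r_perp) / (r_par + r_perp), in [-1, 1] and invariant to
    scaling both stimuli by any positive constant.  Total darkness (both
    stimuli 0) yields 0 — callers should mark such units failed.
    """
    s_par = np.maximum(np.asarray(s_par, dtype=float), 0.0)
    s_perp = np.maximum(np.asarray(s_perp, dtype=float), 0.0)
    if transform == "sqrt":
        r_par, r_perp = np.sqrt(s_par), np.sqrt(s_perp)
    elif transform == "linear":
        r_par, r_perp = s_par, s_perp
    else:
        raise ValueError(f"unknown transform {transform!r}")
    total = r_par + r_perp
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(total > 0, (r_par - r_perp) / np.where(total > 0, total, 1.0), 0.0)
    return r if r.ndim else float(r)


def _disturbance_mask(n: int, eta: float, rng: np.random.Generator, batch: int = 1) -> np.ndarray:
    """(batch, n) boolean masks with exactly round(eta * n) failures each."""
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must be in [0, 1]")
    k = int(round(eta * n))
    mask = np.zeros((batch, n), dtype=bool)
    if k > 0:
        order = np.argsort(rng.random((batch, n)), axis=1)
        np.put_along_axis(mask, order[:, :k], True, axis=1)
    return mask


def pol_responses_batch(
    sun_vecs: np.ndarray,
    array: SensorArray,
    config: SkyConfig | None = None,
    eta: float = 0.0,
    rng: np.random.Generator | None = None,
    transform: str = DEFAULT_TRANSFORM,
):
    """POL responses of the posed array for many sun positions at once.

    ``sun_vecs`` has shape (S, 3); returns ``(r, failed)`` with shape
    (S, n).  Units looking below the horizon are marked failed, and a
    fresh uniformly random disturbance mask of round(eta * n) units is
    drawn per sun from ``rng``.
    """
    sun_vecs = np.atleast_2d(np.asarray(sun_vecs, dtype=float))
    cfg = config if config is not None else SkyConfig()
    views, axes = array.world_frame()

    # e-vector perpendicular to the sun-view great circle, per (sun, unit)
    e = np.cross(sun_vecs[:, None, :], views[None, :, :])
    norm = np.linalg.norm(e, axis=-1)
    degen = norm < 1e-9
    e = e / np.maximum(norm, 1e-12)[..., None]

    cos_g = np.clip(views @ sun_vecs.T, -1.0, 1.0).T  # (S, n)
    d = cfg.d_max * (1.0 - cos_g**2) / (1.0 + cos_g**2)
    d = np.where(degen, 0.0, d)
    Y = (1.0 + cos_g**2) / 2.0

    cos2 = 2.0 * np.einsum("snk,nk->sn", e, axes) ** 2 - 1.0
    cos2 = np.where(degen, 0.0, cos2)
    s_par = Y * (1.0 + d * cos2) / 2.0
    s_perp = Y * (1.0 - d * cos2) / 2.0
    r = pol_unit_response(s_par, s_perp, transform=transform)

    below = views[:, 2] < 0.0  # unit looks below the horizon
    failed = np.broadcast_to(below, r.shape).copy()
    failed |= (s_par + s_perp) <= 0.0
    if eta > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        failed |= _disturbance_mask(array.n, eta, rng, batch=r.shape[0])
    r = np.where(failed, 0.0, r)
    return r, failed


def sense(
    sky: Sky,
    array: SensorArray,
    eta: float = 0.0,
    rng: np.random.Generator | int | None = None,
    keep_internals: bool = False,
    transform: str = DEFAULT_TRANSFORM,
) -> PolResponse:
    """POL-neuron population response of the posed array under ``sky``."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    r, failed = pol_responses_batch(
        sky.sun.vector[None, :], array, sky.config, eta=eta, rng=rng, transform=transform
    )
    resp = PolResponse(r=r[0], failed=failed[0])
    if keep_internals:
        views, axes = array.world_frame()
        Y, d, e = sky.field(views)
        cos2 = 2.0 * np.sum(e * axes, axis=-1) ** 2 - 1.0
        resp.s_par = Y * (1.0 + d * cos2) / 2.0
        resp.s_perp = Y * (1.0 - d * cos2) / 2.0
    return resp


def layout_table(array: SensorArray) -> pd.DataFrame:
    """Layout as a table (j, elevation, azimuth, alpha, rho) for CSV export."""
    return pd.DataFrame(
        {
            "j": np.arange(array.n),
            "elevation": array.elevations,
            "azimuth": array.azimuths,
            "alpha": array.alphas,
            "rho": np.full(array.n, array.rho),
        }
    )


def array_from_table(table: pd.DataFrame, omega: float | None = None) -> SensorArray:
    """Rebuild a :class:`SensorArray` from a :func:`layout_table` frame.

    The polariser axes are implied by the fan rule, so only the view
    directions (and acceptance angle) are read back; ``omega`` defaults
    to twice the largest zenith distance in the table.
    """
    el = table["elevation"].to_numpy(dtype=float)
    az = table["azimuth"].to_numpy(dtype=float)
    rho = float(table["rho"].iloc[0]) if "rho" in table else DEFAULT_RHO
    if omega is None:
        omega = 2.0 * float((90.0 - el).max())
    return SensorArray(el, az, omega=max(omega, 1e-6), rho=rho)
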