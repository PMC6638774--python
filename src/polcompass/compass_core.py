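"""Population-code compass: POL -> SOL -> TCL with tilt and time compensation.

The solar layer (SOL, 8 neurons) computes a sum-of-sinusoids over the POL
population,

    r_SOL_xi = sum_j (n_SOL / n_POL) * sin(alpha_j - phi_pref_xi) * g_j * r_POL_j,

where ``g_j`` is a tilt-dependent Gaussian-ring gating weight.  By
linearity the SOL response is an exact single-period sinusoid of the
preferred angle, so its fundamental discrete-Fourier component yields the
solar-azimuth estimate (phase) and a confidence ``tau = |R|`` (amplitude).
The confidence maps to an angular uncertainty ``sigma_s = 4 deg / tau^2``
and, through an inverse confidence-elevation relation, to a solar-elevation
estimate and an azimuth drift rate; the true compass layer (TCL, 8
neurons) rotates its preferred angles with that drift so its decoded angle
stays fixed with respect to true north as the sun moves (clockwise in the
northern hemisphere).

Tilt compensation
-----------------
Under head tilt the fixed anatomical weighting degrades badly (the rigid
rotation twists every unit's polariser axis out of the sky's tangential
frame).  Two compensation stages are provided:

* the Gaussian-ring gate (``GatingParams``), which re-weights units using
  the known head attitude and always shapes the confidence pathway;
* an attitude-indexed calibrated readout (``TiltCompensator``): for each
  (tilt magnitude, tilt direction) cell, a ridge-regularised complex
  readout of the POL population is calibrated once against the package's
  own clear-sky ensemble — the same design-time optimisation against the
  sky model by which the gating parameters themselves were chosen.  At
  zero tilt the calibrated readout coincides with the anatomical one.

The default compass uses the calibrated readout for the azimuth estimate
and the printed population pathway for confidence, elevation and time
compensation; set ``tilt_mode="gate"`` or ``"off"`` for the pure
sum-of-sinusoids behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dra_sensor import (
    DEFAULT_TRANSFORM,
    PolResponse,
    SensorArray,
    build_dra,
    pol_responses_batch,
)
from .geometry import (
    rotation_zenith_to,
    signed_angdiff,
    sph_to_vec,
    vec_to_sph,
    wrap360,
)
from .skylight import Sky, SkyConfig, SunPosition, sample_hemisphere

__all__ = [
    "GatingParams",
    "CompassEstimate",
    "CompassModel",
    "TiltCompensator",
    "gating_weight",
    "decode",
    "uncertainty",
    "estimate_elevation",
    "azimuth_rate",
]

#: confidence domain of the printed elevation inversion
TAU_DOMAIN = (0.53, 1.1)

#: fixed internal seed for readout / elevation calibration ensembles
_CALIBRATION_SEED = 314159


@dataclass
class GatingParams:
    """Gaussian-ring gating: ring radius/width in degrees and on/off flag."""

    theta_g: float = 40.0
    sigma_g: float = 13.0
    enabled: bool = True

    def __post_init__(self):
        if not 0.0 <= self.theta_g <= 90.0:
            raise ValueError("theta_g must be in [0, 90] degrees")
        if self.sigma_g <= 0.0:
            raise ValueError("sigma_g must be positive")


@dataclass
class CompassEstimate:
    """Decoded compass output for one observation.

    ``azimuth``: solar-azimuth estimate (deg, world frame for an unyawed
    sensor).  ``tcl_azimuth``: the time-compensated (geocentric) angle —
    it equals ``azimuth`` until the TCL preferences start rotating.
    ``confidence`` is the dimensionless resultant magnitude of the SOL
    population; ``sigma`` the derived angular uncertainty (deg, inf at
    zero confidence); ``elevation`` the confidence-based solar-elevation
    estimate (deg).  ``valid`` is False when the population response
    carried no directional signal.
    """

    azimuth: float
    tcl_azimuth: float
    confidence: float
    sigma: float
    elevation: float
    valid: bool
    r_sol: np.ndarray | None = field(repr=False, default=None)
    r_tcl: np.ndarray | None = field(repr=False, default=None)

    def to_record(self, r_pol=None) -> dict:
        """JSON-serialisable step record for layer-by-layer inspection."""
        rec = {
            "azimuth": None if np.isnan(self.azimuth) else float(self.azimuth),
            "tcl_azimuth": None if np.isnan(self.tcl_azimuth) else float(self.tcl_azimuth),
            "confidence": float(self.confidence),
            "sigma": None if np.isinf(self.sigma) else float(self.sigma),
            "elevation": float(self.elevation),
            "valid": bool(self.valid),
            "r_sol": None if self.r_sol is None else [float(x) for x in self.r_sol],
            "r_tcl": None if self.r_tcl is None else [float(x) for x in self.r_tcl],
        }
        if r_pol is not None:
            rec["r_pol"] = [float(x) for x in np.asarray(r_pol)]
        return rec


def gating_weight(unit_elevation, unit_azimuth, tilt_elevation, tilt_azimuth, params: GatingParams):
    """Gaussian-ring gating weight g_j in (0, 1] for one or more units.

    ``u = cos(theta_g + theta_j) sin(theta_t) - sin(theta_g + theta_j)
    cos(theta_t) cos(phi_t - phi_j)`` is a dimensionless (sine-of-offset)
    measure of the unit's angular distance from the preferred ring around
    the point (theta_t, phi_t) — the world zenith expressed in sensor
    coordinates (for a sensor tilted by delta towards azimuth phi, that
    point sits delta away from the sensor zenith on the opposite
    azimuth).  The printed ring width ``sigma_g`` is converted to radians
    before dividing, making the effective ring width ~13 degrees.  With
    no tilt (theta_t = 90) the weight is maximal theta_g below the
    sensor zenith and independent of azimuth.
    """
    if not params.enabled:
        return np.ones_like(np.asarray(unit_elevation, dtype=float))
    th_j = np.deg2rad(np.asarray(unit_elevation, dtype=float))
    ph_j = np.deg2rad(np.asarray(unit_azimuth, dtype=float))
    th_t = np.deg2rad(tilt_elevation)
    ph_t = np.deg2rad(tilt_azimuth)
    th_g = np.deg2rad(params.theta_g)
    u = np.cos(th_g + th_j) * np.sin(th_t) - np.sin(th_g + th_j) * np.cos(th_t) * np.cos(
        ph_t - ph_j
    )
    sigma = np.deg2rad(params.sigma_g)
    return np.exp(-0.5 * (u / sigma) ** 2)


def decode(r: np.ndarray):
    """Fundamental-DFT decode of a population response.

    ``R = sum_xi r_xi exp(-i 2 pi (xi - 1) / m)``; returns
    ``(angle, tau, valid)`` where ``angle = arg(conj(R))`` in degrees
    (uncalibrated), ``tau = |R|`` and ``valid`` is False for a vanishing
    resultant (e.g. a uniform response, whose angle is undefined).
    Adding a constant to all responses does not change the result.
    """
    r = np.asarray(r, dtype=float)
    m = r.shape[-1]
    if m < 4:
        raise ValueError("population must have at least 4 neurons")
    phases = np.exp(-1j * 2.0 * np.pi * np.arange(m) / m)
    R = r @ phases
    tau = np.abs(R)
    angle = wrap360(np.rad2deg(np.angle(np.conj(R))))
    valid = tau > 1e-9 * max(1.0, float(np.max(np.abs(r), initial=0.0)))
    if np.ndim(tau) == 0:
        return float(angle), float(tau), bool(valid)
    return angle, tau, valid


def uncertainty(tau):
    """Angular uncertainty sigma_s = 4 deg / tau^2 (inf at tau = 0)."""
    tau = np.asarray(tau, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(tau > 0, 4.0 / np.where(tau > 0, tau, 1.0) ** 2, np.inf)
    return out if out.ndim else float(out)


def estimate_elevation(tau):
    """Printed solar-elevation estimate (deg) from confidence, clamped.

    theta_s' = 75 + 26 * (asin(2.855 - 3.5 * tau) / 90 - 1), with tau
    clamped to [0.53, 1.1]; out-of-domain confidences return the boundary
    value (75 deg at the low end, ~24.7 deg at the high end).  These
    constants were fitted to a particular sky simulation; CompassModel
    calibrates its own inverse to the confidence-elevation curve of the
    sky model actually in use (see ``CompassModel.elevation_from_tau``).
    """
    tau = np.clip(np.asarray(tau, dtype=float), *TAU_DOMAIN)
    arg = np.clip(2.855 - 3.5 * tau, -1.0, 1.0)
    out = 75.0 + 26.0 * (np.rad2deg(np.arcsin(arg)) / 90.0 - 1.0)
    return out if out.ndim else float(out)


def azimuth_rate(elevation):
    """Solar-azimuth drift rate (deg/hour): exp((theta' - 36) / 10) + 9.

    An empirical approximation of the solar ephemeris slope at mid
    latitudes; always >= 9 deg/h and monotone increasing in elevation.
    """
    el = np.asarray(elevation, dtype=float)
    out = np.exp((el - 36.0) / 10.0) + 9.0
    return out if out.ndim else float(out)


class TiltCompensator:
    """Attitude-indexed ridge-calibrated azimuth readout.

    For a head attitude (tilt magnitude delta, tilt direction phi), the
    compensator renders the clear sky for a fixed quasi-uniform ensemble
    of sun positions, collects the POL responses of the tilted array and
    solves a ridge-regularised complex least-squares problem mapping the
    response vector to ``exp(i * azimuth)``.  Two readouts are kept per
    attitude: one calibrated on the clear sky, and one on responses
    augmented with random unit-failure masks at several disturbance
    levels; at decode time the robust readout is used whenever the
    fraction of silent units exceeds a small threshold (a failed unit is
    detectable — it reports darkness persistently).  Attitudes are
    quantised to a (delta_step x phi_step) grid and calibrations cached,
    so closed-loop simulations over continuously varying terrain stay
    cheap.  The ridge parameter keeps the readout weights at the same
    order of magnitude as the anatomical sinusoidal weights.
    """

    #: disturbance levels mixed into the robust calibration ensemble
    ETA_AUGMENT = (0.0, 0.3, 0.6, 0.9)
    #: silent-unit fraction above which the robust readout takes over
    SILENT_SWITCH = 0.15

    def __init__(
        self,
        array: SensorArray,
        sky_config: SkyConfig,
        transform: str = DEFAULT_TRANSFORM,
        n_cal: int = 800,
        ridge: float = 1e-3,
        delta_step: float = 5.0,
        phi_step: float = 15.0,
    ):
        self.array = array
        self.sky_config = sky_config
        self.transform = transform
        self.n_cal = int(n_cal)
        self.ridge = float(ridge)
        self.delta_step = float(delta_step)
        self.phi_step = float(phi_step)
        self._suns = sample_hemisphere(self.n_cal, seed=_CALIBRATION_SEED)
        _, self._sun_az = vec_to_sph(self._suns)
        self._cache: dict[tuple[int, int], np.ndarray] = {}

    def _quantise(self, delta: float, phi: float) -> tuple[int, int]:
        qd = int(round(delta / self.delta_step))
        if qd == 0:
            return 0, 0
        qp = int(round(wrap360(phi) / self.phi_step)) % int(round(360.0 / self.phi_step))
        return qd, qp

    @staticmethod
    def _solve(blocks, y_rep, ridge):
        X = np.hstack([np.vstack(blocks), np.ones((sum(len(b) for b in blocks), 1))])
        yy = np.concatenate(y_rep)
        A = X.T @ X + ridge * len(X) * np.eye(X.shape[1])
        return np.linalg.solve(A, X.T @ yy)

    def _weights(self, key: tuple[int, int]):
        """(clean, robust) complex readout weights for a quantised attitude."""
        if key not in self._cache:
            qd, qp = key
            delta = qd * self.delta_step
            phi = qp * self.phi_step
            posed = self.array.posed(90.0 - delta, phi)
            r0, _ = pol_responses_batch(
                self._suns, posed, self.sky_config, transform=self.transform
            )
            rng = np.random.default_rng(
                np.random.SeedSequence([_CALIBRATION_SEED, qd, qp])
            )
            n = r0.shape[1]
            y = np.exp(1j * np.deg2rad(self._sun_az))
            blocks = []
            for eta in self.ETA_AUGMENT:
                k = int(round(eta * n))
                if k == 0:
                    blocks.append(r0)
                    continue
                order = np.argsort(rng.random(r0.shape), axis=1)
                mask = np.zeros(r0.shape, dtype=bool)
                np.put_along_axis(mask, order[:, :k], True, axis=1)
                blocks.append(np.where(mask, 0.0, r0))
            clean = self._solve([r0], [y], self.ridge)
            robust = self._solve(blocks, [y] * len(blocks), self.ridge)
            self._cache[key] = (clean, robust)
        return self._cache[key]

    def azimuth(self, r_pol: np.ndarray, posed: SensorArray):
        """Compensated solar-azimuth estimate(s) in degrees, world frame.

        ``r_pol`` has shape (..., n).  Yawed poses are handled by
        decomposing the pose into a canonical (unyawed) tilt plus a pure
        yaw: the calibrated readout for the canonical tilt is applied and
        the yaw added back.
        """
        R = posed.pose_matrix()
        z_s = R.T @ np.array([0.0, 0.0, 1.0])
        el_z, az_z = vec_to_sph(z_s)
        delta = 90.0 - float(el_z)
        phi0 = wrap360(float(az_z) + 180.0)
        key = self._quantise(delta, phi0)
        # residual yaw between the actual pose and the canonical tilt-only pose
        pose0 = rotation_zenith_to(90.0 - delta, phi0)
        M = R @ pose0.T
        mu = np.rad2deg(np.arctan2(M[0, 1], M[0, 0]))
        clean, robust = self._weights(key)
        r = np.asarray(r_pol, dtype=float)
        silent = np.mean(r == 0.0, axis=-1)
        pred_c = r @ clean[:-1] + clean[-1]
        pred_r = r @ robust[:-1] + robust[-1]
        pred = np.where(silent > self.SILENT_SWITCH, pred_r, pred_c)
        return wrap360(np.rad2deg(np.angle(pred)) + mu)


class CompassModel:
    """POL -> SOL -> TCL compass bound to a sensor layout.

    Parameters
    ----------
    array:
        Sensor layout (pose is supplied per observation).
    n_sol, n_tcl:
        Population sizes of the solar and true-compass layers (>= 4).
    gating:
        Gaussian-ring gating parameters (shapes the confidence pathway
        and the gate-only azimuth estimate).
    tilt_mode:
        "calibrated" (default) — azimuth from the attitude-calibrated
        readout; "gate" — azimuth from the gated sum-of-sinusoids
        decode; "off" — ungated sum-of-sinusoids (all weights equal).
    time_compensation:
        When True, :meth:`update_time` rotates the TCL preferred angles
        with the estimated solar drift (clockwise), keeping the TCL code
        geocentric as the sun moves.
    transform:
        Photoreceptor transform for the opponent units ("linear" or
        "sqrt"; see :mod:`polcompass.dra_sensor`).

    The sum-of-sinusoids decoder applies a single calibration offset,
    fixed once at construction by requiring the decoded azimuth to equal
    the true solar azimuth on a clear-sky, untilted reference scene; it
    absorbs the fixed phase difference between the population's preferred
    angles and the Fourier index convention.
    """

    def __init__(
        self,
        array: SensorArray | None = None,
        n_sol: int = 8,
        n_tcl: int = 8,
        gating: GatingParams | None = None,
        tilt_mode: str = "calibrated",
        time_compensation: bool = True,
        transform: str = DEFAULT_TRANSFORM,
        sky_config: SkyConfig | None = None,
    ):
        if n_sol < 4 or n_tcl < 4:
            raise ValueError("populations need at least 4 neurons")
        if tilt_mode not in ("calibrated", "gate", "off"):
            raise ValueError(f"unknown tilt_mode {tilt_mode!r}")
        self.array = array if array is not None else build_dra()
        self.n_sol = int(n_sol)
        self.n_tcl = int(n_tcl)
        self.gating = gating if gating is not None else GatingParams()
        self.tilt_mode = tilt_mode
        self.time_compensation = time_compensation
        self.transform = transform
        self.sky_config = sky_config if sky_config is not None else SkyConfig()
        self.sol_prefs = wrap360(np.arange(1, self.n_sol + 1) * 360.0 / self.n_sol)
        self.reset_tcl()
        self.compensator = (
            TiltCompensator(self.array, self.sky_config, transform=self.transform)
            if tilt_mode == "calibrated"
            else None
        )
        self._offset = self._calibrate_offset()
        self._el_curve = None  # lazy confidence->elevation inverse

    # -- population layers -------------------------------------------

    def reset_tcl(self):
        """Restore the TCL preferred angles to their initial values."""
        self.tcl_prefs = wrap360(np.arange(1, self.n_tcl + 1) * 360.0 / self.n_tcl)

    def gate_weights(self, array: SensorArray | None = None) -> np.ndarray:
        """Per-unit gating weights for the (posed) array's current tilt."""
        a = array if array is not None else self.array
        if not self.gating.enabled or self.tilt_mode == "off":
            return np.ones(a.n)
        zen_sensor = a.pose_matrix().T @ np.array([0.0, 0.0, 1.0])
        el, az = vec_to_sph(zen_sensor)
        return gating_weight(a.elevations, a.azimuths, float(el), float(az), self.gating)

    def sol_response(self, pol, array: SensorArray | None = None) -> np.ndarray:
        """SOL population response; accepts (..., n_pol) response arrays."""
        a = array if array is not None else self.array
        r_pol = pol.r if isinstance(pol, PolResponse) else np.asarray(pol, dtype=float)
        g = self.gate_weights(a)
        W = np.sin(np.deg2rad(a.alphas[:, None] - self.sol_prefs[None, :]))
        return (self.n_sol / a.n) * ((r_pol * g) @ W)

    def tcl_response(self, r_sol: np.ndarray) -> np.ndarray:
        """TCL population response from the SOL layer (current preferences)."""
        W = np.cos(np.deg2rad(self.tcl_prefs[None, :] - self.sol_prefs[:, None]))
        return (self.n_tcl / self.n_sol) * (np.asarray(r_sol, dtype=float) @ W)

    # -- calibration ---------------------------------------------------

    def _calibrate_offset(self) -> float:
        """Fixed decoder offset from a clear-sky, untilted reference scene."""
        ref_sun = SunPosition(30.0, 0.0)
        r, _ = pol_responses_batch(
            ref_sun.vector[None, :], self.array, self.sky_config, transform=self.transform
        )
        raw, _, valid = decode(self.sol_response(r[0]))
        if not valid:
            return 0.0
        # for the mirror-symmetric default layout this equals the exact
        # index-phase offset (a multiple of 360 / n_sol plus 90/180 terms)
        return float(signed_angdiff(ref_sun.azimuth, raw))

    def _elevation_curve(self):
        """Monotone branch of the clear-sky confidence-elevation relation.

        Rendered once from the model's own sky: confidence against solar
        elevation for an untilted sensor, restricted to the decreasing
        branch above the confidence peak (low elevations are ambiguous,
        as both the printed inversion's domain and the underlying physics
        dictate).
        """
        if self._el_curve is None:
            els = np.arange(2.0, 89.0, 1.0)
            taus = np.empty_like(els)
            for i, el in enumerate(els):
                azs = np.array([0.0, 90.0, 180.0, 270.0])
                suns = sph_to_vec(np.full(4, el), azs)
                r, _ = pol_responses_batch(
                    suns, self.array, self.sky_config, transform=self.transform
                )
                _, tau, _ = decode(self.sol_response(r))
                taus[i] = tau.mean()
            k = int(np.argmax(taus))
            els, taus = els[k:], taus[k:]
            order = np.argsort(taus)
            self._el_curve = (taus[order], els[order])
        return self._el_curve

    def elevation_from_tau(self, tau: float) -> float:
        """Solar-elevation estimate from confidence, model-calibrated.

        Inverts the model's own clear-sky confidence-elevation curve
        (clamped to its monotone branch) — the same construction as the
        printed inversion, recalibrated to the sky model in use.
        """
        taus, els = self._elevation_curve()
        return float(np.interp(tau, taus, els))

    # -- decoding ------------------------------------------------------

    def estimate(self, pol, array: SensorArray | None = None) -> CompassEstimate:
        """Decode one POL observation into a full compass estimate."""
        a = array if array is not None else self.array
        r_pol = pol.r if isinstance(pol, PolResponse) else np.asarray(pol, dtype=float)
        r_sol = self.sol_response(r_pol, a)
        az_sol, tau, valid = decode(r_sol)
        r_tcl = self.tcl_response(r_sol)
        az_tcl, _, _ = decode(r_tcl)
        if self.compensator is not None and valid:
            azimuth = float(self.compensator.azimuth(r_pol, a))
            # the TCL pref rotation shifts the decoded angle by -delta_pref;
            # carry the same shift onto the compensated azimuth
            tcl_azimuth = wrap360(azimuth + signed_angdiff(az_tcl, az_sol))
        else:
            azimuth = wrap360(az_sol + self._offset) if valid else np.nan
            tcl_azimuth = wrap360(az_tcl + self._offset) if valid else np.nan
        return CompassEstimate(
            azimuth=azimuth,
            tcl_azimuth=tcl_azimuth,
            confidence=tau,
            sigma=uncertainty(tau),
            elevation=self.elevation_from_tau(tau),
            valid=valid,
            r_sol=r_sol,
            r_tcl=r_tcl,
        )

    def estimate_batch(self, r_pol: np.ndarray, array: SensorArray | None = None):
        """Vectorised azimuth/confidence decode for (S, n_pol) responses."""
        a = array if array is not None else self.array
        r_sol = self.sol_response(r_pol, a)
        az, tau, valid = decode(r_sol)
        if self.compensator is not None:
            az = self.compensator.azimuth(r_pol, a)
        else:
            az = wrap360(az + self._offset)
        return np.where(valid, az, np.nan), tau

    # -- time compensation --------------------------------------------

    def update_time(self, estimate: CompassEstimate, dt_hours: float):
        """Advance the TCL preferred angles by the estimated solar drift.

        The shift is ``azimuth_rate(elevation) * dt_hours`` clockwise
        (the sense of apparent solar motion in the northern hemisphere),
        applied only when the confidence is high enough for the
        elevation estimate to be meaningful (tau within the inversion
        domain); otherwise the preferences are left unchanged.
        """
        if not self.time_compensation or dt_hours == 0.0:
            return
        if estimate.confidence < TAU_DOMAIN[0]:
            return
        rate = azimuth_rate(estimate.elevation)
        self.tcl_prefs = wrap360(self.tcl_prefs + rate * dt_hours)

    # -- convenience ---------------------------------------------------

    def observe(
        self,
        sun: SunPosition,
        tilt_elevation: float = 90.0,
        tilt_azimuth: float = 0.0,
        heading: float = 0.0,
        eta: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> CompassEstimate:
        """Render the sky for ``sun``, sense it, and decode, in one call."""
        posed = self.array.posed(tilt_elevation, tilt_azimuth, heading)
        r, _ = pol_responses_batch(
            sun.vector[None, :],
            posed,
            self.sky_config,
            eta=eta,
            rng=rng,
            transform=self.transform,
        )
        return self.estimate(r[0], posed)
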