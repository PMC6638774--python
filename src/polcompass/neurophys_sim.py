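"""Simulated electrophysiology of the compass output neurons.

Two classic stimulus paradigms are reproduced on the same model instance:

* a *rotating linear polariser* under a uniform light source (the bench
  condition of insect electrophysiology): every ommatidium receives fully
  polarised light with a common e-vector orientation, swept over a full
  turn.  The e-vector is axial, so every tuning curve is 180-degree
  periodic and each output neuron shows a double preference angle; across
  the population the preferred angles step by ~22.5 degrees per column.
* a *rotating natural sky*: the whole celestial pattern (sun azimuth)
  rotates around the sensor.  The sky's degree-of-polarisation gradient
  breaks the axial symmetry, the tuning curves become 360-degree
  periodic, and the preferred directions tile the full circle at ~45
  degrees per column.

The contrast between the two is the model's reconciliation of the
apparently conflicting 180-degree and 360-degree compass organisations
reported from insect recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pingouin as pg

from .compass_core import CompassModel
from .dra_sensor import pol_unit_response
from .geometry import sph_to_vec, wrap360
from .rng import stream

__all__ = [
    "TuningCurve",
    "rotating_polariser_experiment",
    "rotating_sky_experiment",
    "preferred_direction",
    "dominant_period",
    "preference_slope",
]


@dataclass
class TuningCurve:
    """Stimulus-angle response profile of one output (TCL) neuron.

    ``angles`` covers [0, 360) degrees; ``response`` is the mean response
    over trials, ``trial_pref`` the per-trial preferred directions (NaN
    where the Rayleigh test fails), ``axial`` whether the preference is
    180-degree periodic.  ``pref`` is the preferred direction of the mean
    curve (NaN if not significant).
    """

    neuron: int
    angles: np.ndarray
    response: np.ndarray
    axial: bool
    pref: float
    trial_pref: np.ndarray
    background: float = 0.0


def _tcl_responses(compass: CompassModel, r_pol: np.ndarray) -> np.ndarray:
    """(S, n_tcl) TCL responses for (S, n_pol) POL inputs."""
    return compass.tcl_response(compass.sol_response(r_pol))


def _trial_mask(rng, eta, n):
    """One fixed failure mask per trial (the preparation does not change
    while the stimulus rotates)."""
    k = int(round(eta * n))
    m = np.zeros(n, dtype=bool)
    if k > 0:
        m[rng.choice(n, size=k, replace=False)] = True
    return m


def rotating_polariser_experiment(
    compass: CompassModel | None = None,
    angle_step: float = 5.0,
    n_trials: int = 10,
    eta: float = 0.0,
    seed: int = 0,
):
    """Tuning curves under a uniform source seen through a rotating polariser.

    Every ommatidium receives the same fully polarised stimulus (d = 1,
    constant luminance) whose e-vector orientation — a horizontal axial
    angle — sweeps the full circle.  Per unit, the e-vector is projected
    onto the unit's tangent plane and compared with its polariser axis.
    Returns one :class:`TuningCurve` per TCL neuron (curves are
    180-degree periodic; any preference between the two lobes is decided
    by layout discreteness and disturbance noise).
    """
    compass = compass if compass is not None else CompassModel()
    rng = stream(seed, "polariser-trials")
    angles = np.arange(0.0, 360.0, angle_step)
    views, axes = compass.array.world_frame()
    n = compass.array.n

    # e-vector direction per stimulus angle (horizontal axial vector)
    evec = sph_to_vec(np.zeros_like(angles), angles)  # (S, 3)
    # project into each unit's tangent plane
    proj = evec[:, None, :] - (np.einsum("sk,nk->sn", evec, views))[..., None] * views[None, :, :]
    norm = np.linalg.norm(proj, axis=-1)
    cos2 = 2.0 * (np.einsum("snk,nk->sn", proj, axes) / np.maximum(norm, 1e-12)) ** 2 - 1.0
    s_par = (1.0 + cos2) / 2.0
    s_perp = (1.0 - cos2) / 2.0
    r_clean = pol_unit_response(s_par, s_perp, transform=compass.transform)

    trials = np.empty((n_trials, len(angles), compass.n_tcl))
    for t in range(n_trials):
        m = _trial_mask(rng, eta, n)
        trials[t] = _tcl_responses(compass, np.where(m[None, :], 0.0, r_clean))
    return _build_curves(angles, trials, axial=True)


def rotating_sky_experiment(
    compass: CompassModel | None = None,
    sun_elevation: float = 30.0,
    eta: float = 0.5,
    n_trials: int = 100,
    angle_step: float = 5.0,
    seed: int = 0,
):
    """Tuning curves under a rotating natural sky.

    The full celestial pattern rotates about the sensor (sun azimuth
    swept over 360 degrees at fixed elevation), with a fresh
    unit-failure mask of level ``eta`` per trial.
    Curves are 360-degree periodic and the preferred directions of the
    population span the circle at the TCL preference spacing.
    """
    from .dra_sensor import pol_responses_batch

    compass = compass if compass is not None else CompassModel()
    rng = stream(seed, "sky-trials")
    angles = np.arange(0.0, 360.0, angle_step)
    suns = sph_to_vec(np.full_like(angles, sun_elevation), angles)
    r_clean, _ = pol_responses_batch(
        suns, compass.array, compass.sky_config, transform=compass.transform
    )
    n = compass.array.n
    trials = np.empty((n_trials, len(angles), compass.n_tcl))
    for t in range(n_trials):
        m = _trial_mask(rng, eta, n)
        trials[t] = _tcl_responses(compass, np.where(m[None, :], 0.0, r_clean))
    return _build_curves(angles, trials, axial=False)


def _build_curves(angles, trials, axial):
    curves = []
    mean = trials.mean(axis=0)
    n_tcl = trials.shape[-1]
    for k in range(n_tcl):
        per_trial = np.array(
            [preferred_direction(angles, trials[t, :, k], axial=axial)[0] for t in range(len(trials))]
        )
        pref, _ = preferred_direction(angles, mean[:, k], axial=axial)
        curves.append(
            TuningCurve(
                neuron=k,
                angles=angles.copy(),
                response=mean[:, k],
                axial=axial,
                pref=pref,
                trial_pref=per_trial,
            )
        )
    return curves


def preferred_direction(angles, responses, axial: bool, background: float = 0.0, alpha: float = 0.05):
    """Response-weighted circular preferred direction with Rayleigh test.

    Responses below ``background`` are clipped to zero and used as
    weights of the stimulus angles (doubled first when ``axial``); the
    Rayleigh test on the weighted angles decides significance.  Returns
    ``(pref, p_value)``; ``pref`` is NaN when the distribution is not
    significantly directional (e.g. a flat curve).
    """
    angles = np.asarray(angles, dtype=float)
    w = np.clip(np.asarray(responses, dtype=float) - background, 0.0, None)
    if w.sum() <= 0:
        return np.nan, 1.0
    # weights act as observation counts in the Rayleigh statistic; scale
    # them to the number of bins so the test depends on curve shape, not
    # on response amplitude
    w = w / w.sum() * len(angles)
    theta = np.deg2rad(2.0 * angles if axial else angles)
    theta = np.angle(np.exp(1j * theta))  # wrap to (-pi, pi] for the test
    z, p = pg.circ_rayleigh(theta, w=w, d=np.deg2rad(np.diff(angles).mean()))
    mean = np.angle(np.sum(w * np.exp(1j * theta)))
    pref = wrap360(np.rad2deg(mean))
    if axial:
        pref = (pref / 2.0) % 180.0
    return (float(pref), float(p)) if p < alpha else (np.nan, float(p))


def dominant_period(angles, responses) -> float:
    """Dominant angular period (360 or 180 degrees) of a tuning curve.

    Compares the power of the first and second circular harmonics of the
    curve (uniform angle sampling over the full turn is assumed).
    """
    r = np.asarray(responses, dtype=float)
    theta = np.deg2rad(np.asarray(angles, dtype=float))
    h1 = np.abs(np.sum(r * np.exp(-1j * theta)))
    h2 = np.abs(np.sum(r * np.exp(-2j * theta)))
    return 360.0 if h1 > h2 else 180.0


def preference_slope(curves) -> float:
    """Mean signed preferred-direction step per neuron index (deg/column).

    Steps between consecutive significant preferences are wrapped to the
    curve's period (180 degrees for axial tuning, 360 otherwise) before
    averaging; the sign records the direction of progression around the
    columns.  Neurons without a significant preference are skipped.
    """
    prefs = [(c.neuron, c.pref) for c in curves if np.isfinite(c.pref)]
    if len(prefs) < 2:
        return np.nan
    period = 180.0 if curves[0].axial else 360.0
    steps = []
    for (k0, p0), (k1, p1) in zip(prefs[:-1], prefs[1:]):
        d = (p1 - p0 + period / 2.0) % period - period / 2.0
        steps.append(d / (k1 - k0))
    return float(np.mean(steps))
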