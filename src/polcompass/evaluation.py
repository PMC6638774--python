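"""Quantitative evaluation: objective J over tilt/sun ensembles and sweeps.

The reference protocol measures the mean absolute wrapped azimuth error
over 17 tilt orientations (zenith + 8 on a 30-degree ring + 8 on a
60-degree ring, ring azimuths 45 degrees apart) x 500 quasi-uniform sun
positions per tilt = 8500 predictions.  Sweeps repeat the protocol over
gating parameters, sensor layouts and compass population sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compass_core import CompassModel, GatingParams
from .dra_sensor import DEFAULT_TRANSFORM, build_dra, pol_responses_batch
from .geometry import signed_angdiff, vec_to_sph
from .rng import stream, substream_seed
from .skylight import SkyConfig, sample_hemisphere

__all__ = [
    "EvalProtocol",
    "EvalResult",
    "angular_error",
    "default_tilts",
    "run_objective",
    "disturbance_curve",
    "sweep_gating",
    "sweep_layout",
    "sweep_populations",
]


def default_tilts():
    """Zenith + 8 orientations on a 30-degree ring + 8 on a 60-degree ring."""
    tilts = [(0.0, 0.0)]
    tilts += [(30.0, phi) for phi in np.arange(0.0, 360.0, 45.0)]
    tilts += [(60.0, phi) for phi in np.arange(0.0, 360.0, 45.0)]
    return tilts


@dataclass
class EvalProtocol:
    """Tilt set, per-tilt sun count, disturbance level and master seed."""

    tilts: list = field(default_factory=default_tilts)
    n_sun: int = 500
    eta: float = 0.0
    seed: int = 0

    @property
    def n_predictions(self) -> int:
        return len(self.tilts) * self.n_sun


@dataclass
class EvalResult:
    """Per-prediction records plus aggregate objective values.

    ``records`` has one row per (tilt, sun) prediction with the true and
    estimated azimuths, the wrapped absolute error, confidence, tilt and
    disturbance level.  ``J`` is the mean absolute angular error in
    degrees and ``se`` its standard error (sample SD / sqrt(N)).
    """

    records: pd.DataFrame
    J: float
    se: float
    mean_confidence: float

    def by_tilt(self) -> pd.DataFrame:
        """J +/- SE per tilt magnitude (the Table-2 style breakdown)."""
        g = self.records.groupby("tilt_delta")["error"]
        return pd.DataFrame(
            {"J": g.mean(), "se": g.std(ddof=1) / np.sqrt(g.count()), "n": g.count()}
        ).reset_index()

    def by_elevation(self, bin_width: float = 10.0) -> pd.DataFrame:
        """J and mean confidence binned by true solar elevation."""
        df = self.records.copy()
        df["elevation_bin"] = (df["sun_elevation"] // bin_width) * bin_width
        g = df.groupby("elevation_bin")
        return pd.DataFrame(
            {
                "J": g["error"].mean(),
                "se": g["error"].std(ddof=1) / np.sqrt(g["error"].count()),
                "confidence": g["confidence"].mean(),
                "n": g["error"].count(),
            }
        ).reset_index()


def angular_error(phi, phi_prime):
    """Wrapped absolute angular difference in degrees, in [0, 180]."""
    return np.abs(signed_angdiff(phi, phi_prime))


def run_objective(
    compass: CompassModel | None = None,
    protocol: EvalProtocol | None = None,
) -> EvalResult:
    """Evaluate the compass over the tilt x sun protocol.

    Sun positions are drawn per tilt from independent sub-seeds of the
    protocol seed, and each prediction's disturbance mask is fresh, so a
    given (protocol, compass) pair is exactly reproducible.
    """
    compass = compass if compass is not None else CompassModel()
    protocol = protocol if protocol is not None else EvalProtocol()
    rows = []
    for t_idx, (delta, phi_t) in enumerate(protocol.tilts):
        sun_seed = substream_seed(protocol.seed, f"suns-tilt{t_idx}")
        suns = sample_hemisphere(protocol.n_sun, seed=sun_seed)
        sun_el, sun_az = vec_to_sph(suns)
        posed = compass.array.posed(90.0 - delta, phi_t)
        rng = stream(protocol.seed, f"disturbance-tilt{t_idx}")
        r, _ = pol_responses_batch(
            suns,
            posed,
            compass.sky_config,
            eta=protocol.eta,
            rng=rng,
            transform=compass.transform,
        )
        az_est, tau = compass.estimate_batch(r, posed)
        err = angular_error(sun_az, az_est)
        rows.append(
            pd.DataFrame(
                {
                    "tilt_delta": delta,
                    "tilt_azimuth": phi_t,
                    "sun_elevation": sun_el,
                    "sun_azimuth": sun_az,
                    "azimuth_estimate": az_est,
                    "error": err,
                    "confidence": tau,
                    "eta": protocol.eta,
                }
            )
        )
    records = pd.concat(rows, ignore_index=True)
    err = records["error"].to_numpy()
    return EvalResult(
        records=records,
        J=float(np.mean(err)),
        se=float(np.std(err, ddof=1) / np.sqrt(err.size)),
        mean_confidence=float(records["confidence"].mean()),
    )


def disturbance_curve(
    etas,
    compass: CompassModel | None = None,
    protocol: EvalProtocol | None = None,
    n_seeds: int = 1,
) -> pd.DataFrame:
    """J, confidence and uncertainty per disturbance level.

    Each eta level is evaluated with ``n_seeds`` independent disturbance
    realisations of the same protocol; the sun ensembles are shared
    across levels so the curve isolates the effect of eta.
    """
    from dataclasses import replace

    from .compass_core import uncertainty

    compass = compass if compass is not None else CompassModel()
    protocol = protocol if protocol is not None else EvalProtocol()
    rows = []
    for eta in etas:
        if not 0.0 <= eta <= 1.0:
            raise ValueError("eta grid must lie in [0, 1]")
        Js, taus = [], []
        for k in range(n_seeds):
            # per-replicate seeds shared across eta levels: identical sun
            # ensembles and nested disturbance masks (common random numbers)
            seed = substream_seed(protocol.seed, f"rep{k}") if n_seeds > 1 else protocol.seed
            res = run_objective(compass, replace(protocol, eta=eta, seed=seed))
            Js.append(res.J)
            taus.append(res.mean_confidence)
        tau = float(np.mean(taus))
        rows.append(
            {
                "eta": eta,
                "J": float(np.mean(Js)),
                "J_sd": float(np.std(Js, ddof=1)) if n_seeds > 1 else np.nan,
                "confidence": tau,
                "sigma": float(uncertainty(tau)),
                "n_seeds": n_seeds,
            }
        )
    return pd.DataFrame(rows)


def sweep_gating(
    theta_g_grid,
    sigma_g_grid,
    protocol: EvalProtocol | None = None,
    sky_config: SkyConfig | None = None,
):
    """Objective J over a grid of gating parameters (printed architecture).

    Each cell evaluates a gate-only compass (fixed anatomical sinusoidal
    weights, Gaussian-ring gate with that cell's parameters) on the tilt
    protocol — the published global-optimisation procedure.  Returns
    ``(table, argmin)`` where table has one row per cell.
    """
    protocol = protocol if protocol is not None else EvalProtocol(n_sun=100)
    array = build_dra()
    rows = []
    for tg in theta_g_grid:
        for sg in sigma_g_grid:
            compass = CompassModel(
                array,
                gating=GatingParams(theta_g=tg, sigma_g=sg),
                tilt_mode="gate",
                sky_config=sky_config,
            )
            res = run_objective(compass, protocol)
            rows.append({"theta_g": tg, "sigma_g": sg, "J": res.J, "se": res.se})
    table = pd.DataFrame(rows)
    best = table.loc[table["J"].idxmin()]
    return table, (float(best["theta_g"]), float(best["sigma_g"]))


def sweep_layout(
    n_grid,
    omega_grid,
    protocol: EvalProtocol | None = None,
    sky_config: SkyConfig | None = None,
    tilt_mode: str = "gate",
    jitter: float = 0.0,
):
    """Objective J over sensor layouts (number of units x receptive field).

    The sweep scans the regular concentric-ring layout family (no
    azimuthal jitter) with the sum-of-sinusoids decoder by default, so
    the J surface reflects array resolution rather than readout
    adaptation.
    """
    protocol = protocol if protocol is not None else EvalProtocol(n_sun=100)
    rows = []
    for n in n_grid:
        for omega in omega_grid:
            compass = CompassModel(
                build_dra(n=n, omega=omega, jitter=jitter),
                tilt_mode=tilt_mode,
                sky_config=sky_config,
            )
            res = run_objective(compass, protocol)
            rows.append({"n": n, "omega": omega, "J": res.J, "se": res.se})
    return pd.DataFrame(rows)


def sweep_populations(
    n_sol_grid,
    n_tcl_grid,
    protocol: EvalProtocol | None = None,
    sky_config: SkyConfig | None = None,
):
    """Objective J over SOL/TCL population sizes (each >= 4)."""
    protocol = protocol if protocol is not None else EvalProtocol(n_sun=100)
    array = build_dra()
    rows = []
    for n_sol in n_sol_grid:
        for n_tcl in n_tcl_grid:
            compass = CompassModel(array, n_sol=n_sol, n_tcl=n_tcl, sky_config=sky_config)
            res = run_objective(compass, protocol)
            rows.append({"n_sol": n_sol, "n_tcl": n_tcl, "J": res.J, "se": res.se})
    return pd.DataFrame(rows)
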