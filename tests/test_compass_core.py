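import numpy as np
import pytest

from polcompass.compass_core import (
    CompassModel,
    GatingParams,
    azimuth_rate,
    decode,
    estimate_elevation,
    gating_weight,
    uncertainty,
)
from polcompass.dra_sensor import SensorArray, build_dra, pol_responses_batch
from polcompass.geometry import signed_angdiff, vec_to_sph, wrap360
from polcompass.skylight import SunPosition, sample_hemisphere


class TestGatingWeight:
    params = GatingParams()

    def test_maximal_on_the_preferred_ring(self):
        # untilted: a unit 40 degrees below the zenith sits on the ring
        g = gating_weight(50.0, 123.0, 90.0, 0.0, self.params)
        assert g == pytest.approx(1.0, abs=1e-12)

    def test_zenith_unit_strongly_suppressed_untilted(self):
        u = np.cos(np.deg2rad(130.0))
        expected = np.exp(-0.5 * (u / np.deg2rad(13.0)) ** 2)
        g = gating_weight(90.0, 0.0, 90.0, 0.0, self.params)
        assert g == pytest.approx(expected, rel=1e-9)
        assert g == pytest.approx(0.018, abs=0.002)

    def test_disabled_gate_is_unity(self):
        off = GatingParams(enabled=False)
        g = gating_weight(np.array([62.0, 90.0]), np.array([0.0, 10.0]), 60.0, 45.0, off)
        assert np.all(g == 1.0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            GatingParams(theta_g=120.0)
        with pytest.raises(ValueError):
            GatingParams(sigma_g=0.0)


class TestDecode:
    def test_pure_sinusoid_recovers_phase_and_amplitude(self):
        prefs = np.arange(1, 9) * 45.0
        for phi0 in (0.0, 73.0, 211.5):
            r = np.cos(np.deg2rad(prefs - phi0))
            angle, tau, valid = decode(r)
            assert valid
            assert tau == pytest.approx(4.0, abs=1e-9)
            # the decoder's raw angle differs from phi0 by the fixed
            # index-phase offset (45 degrees for 8 neurons)
            assert signed_angdiff(angle + 45.0, phi0) == pytest.approx(0.0, abs=1e-9)

    def test_dc_component_ignored(self):
        prefs = np.arange(1, 9) * 45.0
        r = np.cos(np.deg2rad(prefs - 100.0))
        a1, t1, _ = decode(r)
        a2, t2, _ = decode(r + 5.0)
        assert a1 == pytest.approx(a2, abs=1e-9)
        assert t1 == pytest.approx(t2, abs=1e-9)

    def test_uniform_response_flagged_invalid(self):
        angle, tau, valid = decode(np.full(8, 0.7))
        assert not valid
        assert tau == pytest.approx(0.0, abs=1e-9)

    def test_too_small_population_rejected(self):
        with pytest.raises(ValueError):
            decode(np.ones(3))


class TestScalarRelations:
    def test_uncertainty_values_and_monotonicity(self):
        assert uncertainty(1.0) == pytest.approx(4.0)
        assert uncertainty(2.0) == pytest.approx(1.0)
        assert uncertainty(0.0) == np.inf
        taus = np.linspace(0.1, 3, 50)
        assert np.all(np.diff(uncertainty(taus)) < 0)

    def test_elevation_estimate_endpoints(self):
        assert estimate_elevation(0.53) == pytest.approx(75.0, abs=1e-9)
        assert estimate_elevation(2.855 / 3.5) == pytest.approx(49.0, abs=1e-9)
        # out-of-domain confidence clamps to the boundary value
        assert estimate_elevation(1.2) == pytest.approx(estimate_elevation(1.1))
        assert estimate_elevation(0.1) == pytest.approx(75.0)

    def test_azimuth_rate_values(self):
        assert azimuth_rate(36.0) == pytest.approx(10.0)
        assert azimuth_rate(59.0) == pytest.approx(np.exp(2.3) + 9.0)
        els = np.linspace(0, 90, 40)
        rates = azimuth_rate(els)
        assert np.all(np.diff(rates) > 0)
        assert np.all(rates >= 9.0)


class TestSolTclLayers:
    def test_zero_pol_input_gives_zero_populations(self, gate_compass):
        r_sol = gate_compass.sol_response(np.zeros(60))
        assert np.allclose(r_sol, 0)
        assert np.allclose(gate_compass.tcl_response(r_sol), 0)

    def test_sol_response_is_an_exact_sinusoid(self, gate_compass, rng):
        r_pol = rng.uniform(-1, 1, 60)
        r_sol = gate_compass.sol_response(r_pol)
        # a pure first harmonic: the residual after removing it vanishes
        prefs = np.deg2rad(gate_compass.sol_prefs)
        M = np.column_stack([np.cos(prefs), np.sin(prefs)])
        resid = r_sol - M @ np.linalg.lstsq(M, r_sol, rcond=None)[0]
        assert np.abs(resid).max() < 1e-12

    def test_tcl_initially_decodes_like_sol(self, gate_compass, rng):
        r_pol = rng.uniform(-1, 1, 60)
        r_sol = gate_compass.sol_response(r_pol)
        a_sol, _, _ = decode(r_sol)
        a_tcl, _, _ = decode(gate_compass.tcl_response(r_sol))
        assert signed_angdiff(a_sol, a_tcl) == pytest.approx(0.0, abs=1e-9)

    def test_pref_shift_rotates_the_decoded_angle_oppositely(self, array, rng):
        cm = CompassModel(array, tilt_mode="gate")
        r_pol = rng.uniform(-1, 1, 60)
        r_sol = cm.sol_response(r_pol)
        a0, _, _ = decode(cm.tcl_response(r_sol))
        cm.tcl_prefs = wrap360(cm.tcl_prefs + 30.0)
        a1, _, _ = decode(cm.tcl_response(r_sol))
        cm.reset_tcl()
        assert signed_angdiff(a0 - 30.0, a1) == pytest.approx(0.0, abs=1e-9)

    def test_unit_duplication_leaves_sol_unchanged(self, array, rng):
        doubled = SensorArray(
            np.concatenate([array.elevations] * 2),
            np.concatenate([array.azimuths] * 2),
            omega=array.omega,
        )
        cm1 = CompassModel(array, tilt_mode="gate")
        cm2 = CompassModel(doubled, tilt_mode="gate")
        sun = SunPosition(35.0, 200.0)
        r1, _ = pol_responses_batch(sun.vector[None], array)
        r2, _ = pol_responses_batch(sun.vector[None], doubled)
        assert np.allclose(
            cm1.sol_response(r1[0]), cm2.sol_response(r2[0]), atol=1e-12
        )


class TestEndToEnd:
    def test_clear_sky_untilted_azimuth_within_one_degree(self, gate_compass):
        for az in (0.0, 95.0, 222.2, 301.0):
            est = gate_compass.observe(SunPosition(30.0, az))
            assert est.valid
            assert abs(signed_angdiff(az, est.azimuth)) < 1.0

    def test_no_180_degree_aliasing_around_the_circle(self, gate_compass):
        azs = np.arange(0.0, 360.0, 10.0)
        errs = []
        for az in azs:
            est = gate_compass.observe(SunPosition(30.0, az))
            errs.append(abs(signed_angdiff(az, est.azimuth)))
        assert max(errs) < 10.0  # no flip anywhere near 180

    def test_decoded_angle_stable_across_sol_population_sizes(self, array):
        sun = SunPosition(40.0, 140.0)
        angles = []
        for n_sol in (8, 16, 64):
            cm = CompassModel(array, n_sol=n_sol, n_tcl=8, tilt_mode="gate")
            angles.append(cm.observe(sun).azimuth)
        spread = max(abs(signed_angdiff(a, angles[0])) for a in angles[1:])
        assert spread < 0.5

    def test_confidence_decreases_with_disturbance(self, compass):
        suns = sample_hemisphere(150, seed=6)
        taus = []
        for eta in (0.0, 0.33, 0.66, 0.99):
            level = []
            for rep in range(20):
                rng = np.random.default_rng(1000 + rep)
                r, _ = pol_responses_batch(suns, compass.array, eta=eta, rng=rng)
                _, tau = compass.estimate_batch(r)
                level.append(tau.mean())
            taus.append(np.mean(level))
        assert taus[0] > taus[1] > taus[2] > taus[3]

    def test_all_failed_input_collapses_confidence(self, compass):
        est = compass.estimate(np.zeros(60))
        assert not est.valid
        assert est.confidence == pytest.approx(0.0, abs=1e-12)
        assert np.isinf(est.sigma)

    def test_tilt_compensation_beats_gate_only_under_tilt(self, compass, gate_compass):
        suns = sample_hemisphere(200, seed=8)
        _, az_true = vec_to_sph(suns)
        errs = {}
        for name, cm in (("calibrated", compass), ("gate", gate_compass)):
            posed = cm.array.posed(30.0, 90.0)  # 60-degree tilt
            r, _ = pol_responses_batch(suns, posed)
            az, _ = cm.estimate_batch(r, posed)
            errs[name] = np.abs(signed_angdiff(az_true, az)).mean()
        assert errs["calibrated"] < errs["gate"] / 3


class TestTimeCompensation:
    def test_no_update_without_elapsed_time(self, array):
        cm = CompassModel(array, tilt_mode="gate")
        est = cm.observe(SunPosition(30.0, 0.0))
        before = cm.tcl_prefs.copy()
        cm.update_time(est, 0.0)
        assert np.array_equal(cm.tcl_prefs, before)

    def test_low_confidence_blocks_the_update(self, array):
        cm = CompassModel(array, tilt_mode="gate")
        est = cm.observe(SunPosition(30.0, 0.0))
        object.__setattr__(est, "confidence", 0.1)
        before = cm.tcl_prefs.copy()
        cm.update_time(est, 1.0)
        assert np.array_equal(cm.tcl_prefs, before)

    def test_prefs_advance_clockwise_at_the_estimated_rate(self, array):
        cm = CompassModel(array, tilt_mode="gate")
        est = cm.observe(SunPosition(30.0, 0.0))
        object.__setattr__(est, "confidence", 1.0)
        object.__setattr__(est, "elevation", 36.0)
        before = cm.tcl_prefs.copy()
        cm.update_time(est, 1.0)
        assert np.allclose(wrap360(cm.tcl_prefs - before), 10.0)
        cm.reset_tcl()

    def test_tcl_angle_tracks_the_moving_sun(self, compass):
        """Closed loop: as the sun azimuth advances at the model's own
        estimated rate, the TCL-decoded angle stays put."""
        compass.reset_tcl()
        sun_az = 103.7
        el = 50.0
        first = compass.observe(SunPosition(el, sun_az))
        start = first.tcl_azimuth
        est = first
        for _ in range(12):  # one hour in 5-minute steps
            rate = azimuth_rate(est.elevation)
            sun_az += rate * (5 / 60.0)
            compass.update_time(est, 5 / 60.0)
            est = compass.observe(SunPosition(el, sun_az))
        drift = abs(signed_angdiff(est.tcl_azimuth, start))
        compass.reset_tcl()
        assert drift < 5.0
        # while the sun itself moved by tens of degrees
        assert sun_az - 103.7 > 10.0
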