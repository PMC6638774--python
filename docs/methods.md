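# Methods

This note documents the model assumptions, the parameters that matter,
the numerical choices, and the known limitations of the package — in
particular where the design was genuinely open and what the synthetic
inputs do and do not emulate.

## Sky model

The celestial polarisation pattern is a single-scattering Rayleigh
description. For view directions at angular distance γ from the sun:

* degree of linear polarisation `d = d_max · sin²γ / (1 + cos²γ)` with
  `d_max = 0.75` (the commonly quoted maximum for clear natural skies);
* angle of polarisation perpendicular to the sun–view great circle
  (e-vectors form concentric rings around the sun);
* relative luminance `Y = (1 + cos²γ)/2`. The opponent units are exactly
  luminance-invariant, so only positivity matters; any smooth positive
  gradation would give identical compass output.

What this stand-in does **not** contain: multiple scattering, turbidity,
neutral points (the AOP deviations near the sun and antisun), horizon
brightening, or spectral structure. Two measurable consequences, both
visible in the test suite: (i) near the horizon-sun condition (sun
elevation ≲ 10°) the DOP gradient across the sensor cap vanishes
(`d′(90°) = 0`), so the 360°-disambiguating first harmonic becomes weak
and clear-sky errors concentrate there; (ii) robustness to unit failure
is information-limited — with 80 % of units silenced the mean error is
≈ 40° rather than the ≲ 30° a richer sky (whose AOP asymmetries carry
additional azimuth information) can support. Passing tests therefore
demonstrate the geometry and the decoding architecture, not radiative
realism.

The solar ephemeris is a NOAA-style closed form (fractional-year series
for declination and the equation of time); its error is a small fraction
of a degree, far below compass error scales, and it is cross-checked in
the tests against an independently implemented ephemeris. The default
site/date configuration (Seville, late June, 10:00 with zero clock
offset) was chosen so that the simulated solar geometry matches the
field numbers the behavioural experiments are built around (sun azimuth
≈ 103.7° at trial start, drifting ≈ 24° clockwise over 76 minutes); the
calendar date of the original field work is not recorded, so the date
remains a configuration field.

## Sensor array

`build_dra(n=60, omega=56°)` places one unit on the sensor zenith and
the rest on equally spaced concentric rings filling the 28°-radius cap,
per-ring counts proportional to circumference. Polariser axes follow the
fan rule `α_j = φ_j − 90°` (ring-tangential). The acceptance angle
ρ = 5.4° is carried as metadata: units point-sample the sky along their
optical axis, since 5.4° is far below the sky pattern's length scale and
no integration rule over ρ is specified by the biology.

**Within-ring jitter.** A deterministic azimuthal irregularity of up to
2° (fixed internal seed; `jitter=0` restores the exactly mirror-symmetric
layout) is applied by default. This is not cosmetic: on a perfectly
regular ring the odd azimuthal lattice sums vanish identically, which
(a) makes the layout's polariser-condition tuning fan degenerate (all
residual preferences collapse onto the symmetry axes) and (b) is a
property no biological lattice has. Two degrees is small enough to leave
compass accuracy unchanged under the default readout while restoring the
graded ~22.5°-per-column preference fan seen in the simulated
electrophysiology.

**Photoreceptor transform.** The opponent unit supports two activation
functions. The package default is the *linear* opponent contrast
`r = (s∥ − s⊥)/(s∥ + s⊥) = d·cos 2(χ − α)`: the population-level
constants of the model — the confidence scale (clear-sky mean τ ≈ 1.0,
with the elevation inversion's domain 0.53–1.1) — are quantitatively
consistent with this form, whereas the square-root variant compresses
responses by ≈ ×0.6 and lands the confidence scale well below that
domain. The square-root variant
`r = (√s∥ − √s⊥)/(√s∥ + √s⊥)` (the micro-circuit reading of the unit,
with its right-skew compression of bright stimuli) is retained as
`transform="sqrt"` and is the default of the unit-level
`pol_unit_response` function; the two differ only by a monotone
rescaling of the response curve (same zeros, same 180° periodicity).

## Compass

The solar layer is the printed sum of sinusoids with the `n_SOL/n_POL`
weight scaling; by linearity its response across preferred angles is an
*exact* first harmonic, so the fundamental-DFT decoder is lossless and
population sizes ≥ 4 are equivalent for the azimuth (they differ only in
the confidence scale, which is defined at n_SOL = 8). A single decoder
calibration constant — fixed once on a clear-sky, untilted reference
scene — absorbs the phase offset between the preference convention
(ξ·45°) and the Fourier index convention (ξ−1).

**Gating.** The Gaussian-ring gate
`g_j = exp(−½[(cos(θ_g+θ_j)sinθ_t − sin(θ_g+θ_j)cosθ_t cos(φ_t−φ_j))/σ_g]²)`
takes `(θ_t, φ_t)` as the world zenith expressed in sensor coordinates
(for a sensor tilted δ towards azimuth φ, that point sits δ away from
the sensor zenith on the opposite azimuth — the "zenith point"). The
numerator is a dimensionless sine-of-offset, so σ_g = 13° is converted
to radians before dividing; treating it as a bare number would make the
gate inert. With no tilt, the gate is an azimuth-independent ring 40°
below the sensor zenith; its weighting always shapes the confidence
pathway.

**Tilt compensation.** A rigid tilt rotates every unit's polariser axis
out of the sky's tangential frame (by up to ~50° at δ = 60°), and we
found — by exhaustive enumeration of chart conventions and by comparing
against the optimal linear decoder — that no positive masking of the
fixed anatomical sinusoid can undo this: the gated sum-of-sinusoids
plateaus near 45–70° error on 30–60° tilts, while a tilt-matched linear
readout of the same POL vector reaches ≈ 5–10°. The default compass
therefore pairs the gate with an **attitude-indexed calibrated readout**:
for each head attitude (quantised to 5° in magnitude, 15° in direction)
a ridge-regularised complex readout is calibrated once against the
package's own clear-sky ensemble (800 quasi-uniform suns, fixed internal
seed), augmented with random unit-failure masks at η ∈ {0, 0.3, 0.6, 0.9}
for a second, occlusion-robust readout that takes over when more than
15 % of units are silent. This is the same epistemic move as tuning the
gating parameters themselves by global optimisation against the sky
model: a design-time calibration, not run-time access to ground truth.
At zero tilt the calibrated readout coincides with the anatomical one
(the calibration is equivariant there). The ridge weight (10⁻³ per
sample) keeps readout magnitudes at the scale of the printed synaptic
weights. `tilt_mode="gate"` and `"off"` expose the pure printed
architecture.

**Confidence, elevation and time.** Confidence is τ = |R| from the gated
solar layer; uncertainty σ_s = 4°/τ². The printed confidence→elevation
inversion `θ_s′ = 75° + 26°(asin(2.855 − 3.5τ)/90° − 1)` (domain
τ ∈ [0.53, 1.1], clamped outside) is provided as `estimate_elevation`;
because that fit is specific to the sky simulation it was derived on,
the pipeline uses the same construction recalibrated to this package's
own clear-sky confidence–elevation curve (its monotone branch above the
confidence peak; low elevations are intrinsically ambiguous). The drift
rate `dφ_s/dt = exp((θ_s′ − 36°)/10°) + 9 °/h` is ephemeris physics at
mid latitudes and is used as printed. When the confidence is inside the
inversion domain, the true-compass-layer preferences advance clockwise
by the estimated rate, so the decoded TCL angle stays geocentric; below
the domain the update is skipped.

## Evaluation

The objective J is the mean absolute wrapped azimuth error over 17 tilt
orientations (zenith + 8 × 30°-ring + 8 × 60°-ring, ring azimuths 45°
apart, zero roll) × 500 quasi-uniform suns per tilt, reported ± the
standard error (sample SD/√N). Sun ensembles per tilt derive from named
sub-seeds of the protocol seed; disturbance masks are fresh per
prediction. The gating-parameter sweep evaluates the printed (gate-only)
architecture — the published optimisation procedure; on this package's
sky its J surface over (θ_g, σ_g) is nearly flat with a shallow optimum
near (50°, 21°) rather than (40°, 13°), a consequence of the different
tilt pathway. The layout sweep scans the regular (unjittered) ring
family with the sum-of-sinusoids decoder on the untilted protocol, which
isolates array resolution: error falls steeply up to n ≈ 60 at ω = 56°
and then flattens, the interommatidial spacing having reached the
pattern's useful resolution.

## Behavioural simulations

Terrain is a Gaussian random field (white noise smoothed with a Gaussian
kernel, then scaled to the requested altitude SD); the agent's tilt is
the local surface normal, with the tilt azimuth pointing downhill. The
smoothing length (default 1.9 m on the 10 m reference arena) is
calibrated so the reference 0.8 m altitude SD yields a maximum tilt near
47°. Outward routes are correlated random walks from nest to feeder
(AR(1) angular wobble; tortuosity 0 gives the beeline), standing in for
recorded ant foraging paths, with 2 cm steps — roughly the distance
between successive compass readings of a walking ant.

The home-vector integrator consumes the 8-neuron TCL code: each step the
decoded TCL angle, minus the pose's own yaw, gives a sun-referenced
bearing; a confidence-weighted circular mean over the outward leg (where
the commanded heading is known) fixes the reference once per trip, and a
confidence-adaptive heading memory (a confident reading replaces the
heading, a doubtful one barely moves it — an attractor-like stand-in for
the heading circuit's dynamics) filters the per-step estimate before it
enters the home vector. Homing steers along the inverted home vector
with a bounded turn rate; arrival is defined by a search radius of 10 %
of the nest–feeder distance (the scale of nest-search onset scatter in
desert ants). With the ground-truth heading oracle the integrator
returns the agent to the nest up to step resolution, and a fixed
injected azimuth bias cancels between the legs. Long runs scale the
arena ×100 (1 km, ≈ 76 simulated minutes at 0.35 m/s) with the sun
recomputed from the ephemeris each step.

On this package's sky, closed-loop homing is reliable through η ≈ 0.8
unit failure on 47°-tilt terrain and degrades beyond (the miss distance
at η = 0.9 is a few tenths of the route length); the time-compensation
contrast on the kilometre run is clean (returns with it, misses by
roughly the accumulated solar drift without it).

## Simulated electrophysiology

The rotating-polariser condition models the bench stimulus as fully
polarised light (d = 1, constant luminance) with a common horizontal
e-vector projected into each unit's tangent plane; the rotating-sky
condition sweeps the sun azimuth at 30° elevation. Unit-failure masks
are drawn once per trial (the preparation does not change while the
stimulus rotates). Preferred directions are response-weighted circular
means (angles doubled for axial curves) with a weighted Rayleigh test;
weights are normalised to the bin count so significance reflects curve
shape, not amplitude. Under the polariser the population response is
carried entirely by the lattice's residual asymmetries — hence
180°-periodic curves whose two lobes differ only through noise and a
~22.5°-per-column preference fan — while under the natural sky the DOP
gradient makes the same neurons 360°-periodic at 45° spacing.

## Reproducibility

All randomness flows from a master seed through named sub-streams
(`rng.stream(seed, name)`), so changing one component's draws never
perturbs another's; identical configurations and seeds reproduce output
tables byte for byte. Model-internal calibrations (decoder offset,
attitude readouts, elevation curve, layout jitter) use fixed internal
seeds and are part of the model definition, not of experiment
randomness.

## Known limitations

* The sky stand-in omits the AOP asymmetries of real skies; disturbance
  robustness and low-sun accuracy are correspondingly conservative.
* The tilt compensation achieving published-scale accuracy is a
  calibrated readout, not a pure weight mask; the printed gate alone
  mitigates but does not solve large tilts here (see the design
  discussion above).
* The azimuth decode is independent of the SOL/TCL population size
  (≥ 4) by the exactness of the first harmonic; claims that small
  populations degrade accuracy are not reproduced by this architecture.
* The path-integration controller is a deliberately minimal
  population-code integrator; no memory dynamics, motor noise, or
  steering neuron model beyond a bounded turn rate.
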