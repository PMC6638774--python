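"""Render the polarised sky dome for a morning sun over Seville.

Builds the sky model from the default field-site configuration (an
ephemeris sun position) and reports the polarisation pattern's headline
numbers: the maximum degree of polarisation and where it sits.
"""

from polcompass import Sky, SkyConfig, dome_raster

cfg = SkyConfig()  # Seville field site, late-June morning
sun = cfg.sun()
print(f"sun: elevation {sun.elevation:.1f} deg, azimuth {sun.azimuth:.2f} deg (clockwise from north)")

sky = Sky(sun, cfg)
raster = dome_raster(sky, elevation_step=1.0, azimuth_step=1.0)
top = raster.loc[raster["dop"].idxmax()]
print(f"max degree of polarisation: {raster['dop'].max():.3f}")
print(f"  at view elevation {top['elevation']:.0f} deg, azimuth {top['azimuth']:.0f} deg")
print("  (the cross-solar ring, 90 deg from the sun, carries the strongest polarisation)")

sample = sky.sample(89.9, 0.0)
print(
    f"near the zenith: dop {sample.dop:.3f}, e-vector angle {sample.aop:.1f} deg "
    "(perpendicular to the solar meridian)"
)
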