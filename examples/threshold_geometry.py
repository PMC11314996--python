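"""Degree/pixel geometry: where the 40 px/ms artifact threshold comes from.

A saccade cannot exceed about 0.9 degrees of visual angle per
millisecond, so any faster sample is a sensor artifact. This script
converts that ceiling into screen-pixel units for the default scanner
display (1680x1050 px, viewed at 1 m via the head-coil mirror).
"""

from gazemend import DEFAULT_GEOMETRY, angular_extent, deg_per_ms_to_px_per_ms, px_per_degree

ppd = px_per_degree(DEFAULT_GEOMETRY)
limit = deg_per_ms_to_px_per_ms(0.9, DEFAULT_GEOMETRY)
w_deg, h_deg = angular_extent(DEFAULT_GEOMETRY)

print(f"pixels per degree at screen centre : {ppd:.2f} px/deg")
print(f"saccade ceiling 0.9 deg/ms         : {limit:.2f} px/ms (threshold ~ {round(limit)})")
print(f"full screen subtends               : {w_deg:.1f} x {h_deg:.1f} deg")
print()
print("Any sample-to-sample speed above the threshold is flagged as a")
print("transient spike or spatial displacement by the detector.")
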