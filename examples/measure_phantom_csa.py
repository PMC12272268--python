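"""Measure cord cross-sectional area on a tilted phantom.

Creates a 30-degree-tilted cylinder of known radius, synthesizes a contrast,
segments the cord by thresholding, and compares raw vs angle-corrected CSA
against the analytic ground truth: an oblique cut is larger by 1/cos(tilt),
and the centerline-angle correction removes exactly that factor.
"""

import warnings

import numpy as np

from synt1w import (
    PhantomSpec,
    SequenceParams,
    make_cord_phantom,
    measure_csa,
    segment_cord,
    synthesize_volume,
)
from synt1w.phantom import PD_CONTRAST_TISSUES

RADIUS = 4.0  # mm
TILT = 30.0  # degrees

phantom = make_cord_phantom(
    PhantomSpec(
        grid_shape=(64, 64, 24),
        cord_radius=RADIUS,
        tilt_deg=TILT,
        tissue_params=dict(PD_CONTRAST_TISSUES),  # intensity linear in cord fraction
    )
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    params = SequenceParams.from_ms(14.0, 0.0, 1400.0, 900.0, 14.0, 176)
    volume = synthesize_volume(phantom.maps, params)

mask = segment_cord(volume, (1.0, 1.0, 1.0))
meas = measure_csa(mask)

true_perp = np.pi * RADIUS**2
true_cut = true_perp / np.cos(np.radians(TILT))
print(f"analytic perpendicular CSA : {true_perp:.2f} mm^2")
print(f"analytic oblique-cut CSA   : {true_cut:.2f} mm^2 (inflated by 1/cos {TILT} deg)")
print(f"measured raw CSA           : {np.nanmean(meas.slice_area_raw):.2f} mm^2")
print(f"measured corrected CSA     : {meas.overall_mean:.2f} mm^2")
print(f"mean centerline angle      : {np.nanmean(meas.slice_angle_deg[6:-6]):.1f} deg")
# The corrected value should sit within a few percent of pi*r^2 = 50.27 mm^2;
# the residual is voxel digitization at 1 mm resolution.
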