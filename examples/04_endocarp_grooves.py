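"""Endocarp vertical-view sculpture: convexity, circles and groove depths.

An endocarp cross-section is emulated as a disc with sinusoidal grooves
r(theta) = R + amp*sin(8*theta); roughness descriptors are printed next to
their closed-form truths.
"""

import numpy as np

import organmorph as om
from organmorph.endocarp import vertical_block
from organmorph.segmentation import clean_mask, threshold_hsb
from organmorph.synthetic import make_grooved_disc

R, amp = 1.0, 0.1
fx = make_grooved_disc(R, amp, n_grooves=8, pixels_per_cm=200.0)
mask = clean_mask(threshold_hsb(fx.image, fx.hsb_background, invert=True))
c = om.calibrate(om.smooth_resample(om.trace_boundary(mask)), 200.0)

v = vertical_block(c)
rows = [
    ("StArConv", v.st_ar_conv, fx.truth["st_ar_conv"]),
    ("MinCentCnt", v.min_cent_cnt, R - amp),
    ("MaxCentCnt", v.max_cent_cnt, R + amp),
    ("DiamInscrCir", v.diam_inscr_cir, 2 * (R - amp)),
    ("DiamMinBdCir", v.diam_min_bd_cir, 2 * (R + amp)),
    ("Area", c.area(), np.pi * (R**2 + amp**2 / 2)),
]
print(f"{'descriptor':<14}{'measured':>10}{'truth':>10}")
for name, got, truth in rows:
    print(f"{name:<14}{got:>10.4f}{truth:>10.4f}")
print(f"grooves: mean depth {v.groove_mean_depth:.4f} cm, "
      f"max {v.groove_max_depth:.4f} cm, count {v.groove_count}")
# StArConv < 1 measures surface roughness (area / convex hull area);
# groove depth is measured perpendicular to each convex-hull edge.
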