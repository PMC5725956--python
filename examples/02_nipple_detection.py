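"""Detect the apex nipple across a ladder of protrusion heights.

The nipple — a small apical protrusion diagnostic for cultivars like
Mastoidis — is found as a high-curvature apex peak set off from the fruit
body by curvature shoulders.  Prints detection and recovered geometry for
bump heights 0 to 0.5 cm.
"""

import numpy as np

import organmorph as om
from organmorph.segmentation import clean_mask, threshold_hsb
from organmorph.synthetic import make_nippled_fruit

print(f"{'bump cm':>8}{'detected':>10}{'height':>8}{'area':>8}{'arc len':>8}")
for h in np.linspace(0.0, 0.5, 6):
    fx = make_nippled_fruit(a=1.5, b=1.0, bump_height=h, pixels_per_cm=200.0)
    mask = clean_mask(threshold_hsb(fx.image, fx.hsb_background, invert=True))
    c = om.calibrate(om.smooth_resample(om.trace_boundary(mask)), 200.0)
    c = om.normalize_orientation(c)
    g = om.detect_nipple(c)
    print(f"{h:>8.2f}{str(g.present):>10}{g.height:>8.3f}{g.area:>8.3f}"
          f"{g.upper_length:>8.3f}")
# height = perpendicular distance from the apex to the shoulder chord E-F
# (tracks the generative bump height); area = region enclosed by the nipple
# arc and the chord.  A plain ellipse (bump 0) must report no nipple.
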