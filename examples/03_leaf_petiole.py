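"""Split a leaf into blade and petiole and report the 16-parameter profile.

The petiole is the narrow contiguous run at the base of the width profile;
blade shape descriptors are computed after removing it, so a long stalk
does not inflate the shape index.
"""

from organmorph.contour import flip_vertical
from organmorph.leaf import leaf_profile
from organmorph.segmentation import clean_mask, threshold_hsb
from organmorph.synthetic import make_leaf

import organmorph as om

fx = make_leaf(blade_a=2.0, blade_b=0.8, petiole_len=0.8, petiole_w=0.1,
               pixels_per_cm=150.0)
mask = clean_mask(threshold_hsb(fx.image, fx.hsb_background, invert=True))
c = om.calibrate(om.smooth_resample(om.trace_boundary(mask)), 150.0)
c = flip_vertical(om.normalize_orientation(c))  # petiole end up

traits = leaf_profile(c)
for key, val in traits.as_row().items():
    print(f"{key:<14}{val:>10.4f}")
print(f"\ntruth: petiole {fx.truth['petiole_hgt']} cm long, "
      f"{fx.truth['petiole_area']} cm^2; blade height {fx.truth['blade_hgt']} cm")
# BladeHgt + PetioleHgt = Hght; ShIdx uses the blade only; TipCur is the
# mean curvature (1/cm) of the arc around the blade tip.
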