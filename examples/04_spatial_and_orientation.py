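"""FA-nucleus distances and orientation statistics.

Compares the FA-to-nucleus centroid distance between all-peripheral and
all-perinuclear adhesion placement, and recovers the dominant fiber
orientation of a striped actin texture.
"""

import numpy as np

from fibromorph import (
    ChannelImage,
    SceneSpec,
    fa_nucleus_distances,
    fiber_orientation_map,
    generate_scene,
)

for placement, label in ((1.0, "peripheral"), (0.0, "perinuclear")):
    spec = SceneSpec(image_shape=(700, 700), pixel_size=0.25, n_cells=4,
                     fa_per_cell=(6.0, 0.0), fa_radial_placement=placement, seed=0)
    _, truth = generate_scene(spec)
    rep = fa_nucleus_distances(truth.level_table("fa"),
                               truth.level_table("nucleus"), spec.pixel_size)
    print(f"{label:12s} FA placement: mean FA-nucleus distance "
          f"{rep.mean_um:5.1f} um over {len(rep.per_fa)} FAs")

rr, cc = np.mgrid[0:256, 0:256]
th = np.deg2rad(30.0)
texture = (((rr * np.cos(th) + cc * np.sin(th)) % 12) < 3).astype(float)
rep = fiber_orientation_map(ChannelImage(texture, 1.0, "actin"))
print(f"\nfiber texture planted at 30 deg: dominant orientation "
      f"{rep.dominant_deg:.1f} deg, alignment index S = {rep.order_parameter:.3f}")
print("(peripheral adhesions sit farther from the nucleus by construction;")
print(" S = 1 would be perfect alignment, 0 an isotropic fiber field)")
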