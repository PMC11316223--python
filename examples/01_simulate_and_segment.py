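"""Simulate a micropatterned-fibroblast field of view and segment it.

Generates a small synthetic scene (elongated cells, elliptical nuclei,
focal-adhesion puncta) with known ground truth, runs the three-level
segmentation (nuclei -> cells -> FAs) and reports how well the recovered
objects match the truth.
"""

import numpy as np

from fibromorph import SceneSpec, generate_scene
from fibromorph.pipeline import process_image_set

spec = SceneSpec(image_shape=(700, 700), pixel_size=0.25, n_cells=5, seed=0)
image_set, truth = generate_scene(spec)
labels, tables = process_image_set(image_set)

print(f"scene: {spec.n_cells} cells on a "
      f"{spec.image_shape[0]*spec.pixel_size:.0f} um field, "
      f"{spec.pixel_size} um/px")
for level in ("nucleus", "cell", "fa"):
    true_n = len(truth.level_table(level))
    print(f"  {level:8s} true {true_n:3d}  recovered {labels[level].n_objects:3d}")

jaccards = []
for t in truth.level_table("cell")["label"]:
    tm = truth.label_maps["cell"] == t
    vals, cnts = np.unique(labels["cell"].labels[tm], return_counts=True)
    r = vals[vals > 0][np.argmax(cnts[vals > 0])]
    rm = labels["cell"].labels == r
    jaccards.append((tm & rm).sum() / (tm | rm).sum())
print(f"per-cell Jaccard overlap with truth: min {min(jaccards):.3f}")
print("(counts should match exactly and Jaccard approach 1: at SNR ~10 the")
print(" Otsu + seeded-growth segmentation recovers the rendered masks)")
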