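"""Shared fixtures: synthetic scenes reused across the suite.

The default scene (10 non-touching cells with 8 FAs each at the standard
noise level) is expensive enough to generate that it is built once per
session and shared by the segmentation, morphometry, spatial and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fibromorph import SceneSpec, generate_scene
from fibromorph.pipeline import process_image_set


@pytest.fixture(scope="session")
def default_scene():
    """Default-parameter scene: (spec, image_set, ground_truth)."""
    spec = SceneSpec(seed=1)
    image_set, gt = generate_scene(spec)
    return spec, image_set, gt


@pytest.fixture(scope="session")
def processed_scene(default_scene):
    """Default scene run through preprocess + segmentation + morphometry."""
    _, image_set, _ = default_scene
    labels, tables = process_image_set(image_set)
    return labels, tables


@pytest.fixture(scope="session")
def small_four_condition_dataset():
    """Feature matrices for four small simulated conditions (anchors first)."""
    from fibromorph.morphometry import assemble_feature_matrix

    presets = {
        "control": {},
        "myofibroblast": dict(
            cell_length_um=(48.0, 5.0),
            cell_width_um=(20.0, 2.0),
            fa_major_um=(5.2, 0.5),
            fa_minor_um=(2.2, 0.2),
            fa_per_cell=(10.0, 0.0),
            fa_radial_placement=0.3,
        ),
        "lines_20x20": dict(
            cell_length_um=(50.0, 4.0),
            cell_width_um=(11.0, 1.2),
            fa_minor_um=(1.4, 0.12),
        ),
        "lines_10x10": dict(
            cell_length_um=(46.0, 4.0),
            cell_width_um=(12.0, 1.5),
            fa_minor_um=(1.5, 0.12),
        ),
    }
    matrices = []
    for i, (name, kw) in enumerate(presets.items()):
        spec = SceneSpec(
            image_shape=(760, 760),
            pixel_size=0.25,
            n_cells=6,
            seed=100 + i,
            condition=name,
            **kw,
        )
        image_set, _ = generate_scene(spec)
        _, tables = process_image_set(image_set)
        matrices.append(
            assemble_feature_matrix(tables, image_id=name, condition=name, day=2)
        )
    return pd.concat(matrices, ignore_index=True)


def match_objects(true_lbl: np.ndarray, rec_lbl: np.ndarray, true_label: int) -> int:
    """Recovered label overlapping a true object the most (0 if none)."""
    vals, cnts = np.unique(rec_lbl[true_lbl == true_label], return_counts=True)
    keep = vals > 0
    vals, cnts = vals[keep], cnts[keep]
    return int(vals[np.argmax(cnts)]) if vals.size else 0
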