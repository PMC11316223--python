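"""Per-object shape descriptors, the 40-feature cell catalog, heat-map normalization.

Shape descriptors are computed per labelled object at each of the three
levels (cell, nucleus, focal adhesion).  Conventions, fixed here because
several descriptors depend on them:

* **moments**: second central moments of the pixel-centre point set in
  (x, y) = (col, -row) coordinates; eccentricity = sqrt(1 - lmin/lmax) of
  the covariance eigenvalues; axis lengths are the equivalent-ellipse
  lengths 4 sqrt(l) (so a filled ellipse recovers its generating axes);
  orientation in degrees CCW from the x axis, wrapped to (-90, 90].
* **perimeter**: chain-code length of the traced outer boundary, axial
  steps counting 1 pixel and diagonal steps sqrt(2).
* **Feret diameters**: rotating calipers on the convex hull of the pixel
  *corner* points, giving max and min caliper widths.
* form_factor = 4 pi A / P^2 (1 for an ideal disk), compactness = its
  reciprocal P^2 / (4 pi A).

The per-cell feature vector is a fixed, ordered catalog of 40 features: 13
descriptors for the cell and for its nucleus, 13 focal-adhesion aggregate
summaries, and the FA count.  Condition means are placed on the
fibroblast-to-myofibroblast (FMT) phenotype axis by a two-point affine
normalization sending the control (homogeneous-coating fibroblast) mean to
0 and the activated-myofibroblast mean to 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .core import LabelMap, ValidationError, wrap_axial_deg

#: the 13 scalar shape descriptors measured per object
DESCRIPTOR_NAMES = (
    "area_um2",
    "perimeter_um",
    "eccentricity",
    "major_axis_um",
    "minor_axis_um",
    "aspect_ratio",
    "orientation_deg",
    "solidity",
    "extent",
    "form_factor",
    "compactness",
    "feret_max_um",
    "feret_min_um",
)

#: focal-adhesion aggregate features (13) in the per-cell vector
FA_AGGREGATE_NAMES = (
    "fa_area_um2_mean",
    "fa_area_um2_sd",
    "fa_perimeter_um_mean",
    "fa_perimeter_um_sd",
    "fa_eccentricity_mean",
    "fa_eccentricity_sd",
    "fa_major_axis_um_mean",
    "fa_major_axis_um_sd",
    "fa_minor_axis_um_mean",
    "fa_aspect_ratio_mean",
    "fa_solidity_mean",
    "fa_form_factor_mean",
    "fa_total_area_um2",
)

#: the fixed, ordered 40-feature catalog of the per-cell vector
FEATURE_NAMES = (
    tuple(f"cell_{n}" for n in DESCRIPTOR_NAMES)
    + tuple(f"nuc_{n}" for n in DESCRIPTOR_NAMES)
    + FA_AGGREGATE_NAMES
    + ("fa_count",)
)
assert len(FEATURE_NAMES) == 40

_CLOCKWISE = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))


def boundary_chain_length(mask: np.ndarray) -> float:
    """Chain-code length of the outer boundary of a connected region.

    Moore-neighbour tracing over the 8-connected boundary; axial steps add
    1, diagonal steps sqrt(2).  A single-pixel region has no chain; its
    perimeter is defined as 4 (the pixel-square boundary).
    """
    mask = np.pad(np.asarray(mask, dtype=bool), 1)
    coords = np.argwhere(mask)
    if coords.size == 0:
        return 0.0
    if coords.shape[0] == 1:
        return 4.0
    start = tuple(coords[0])  # topmost-leftmost foreground pixel
    # entered from the west; begin the clockwise scan there
    prev_dir = 0
    cur = start
    length = 0.0
    first_move: tuple | None = None
    max_steps = 4 * mask.sum() + 8
    for _ in range(int(max_steps)):
        found = False
        for k in range(8):
            d = (prev_dir + k) % 8
            nr, nc = cur[0] + _CLOCKWISE[d][0], cur[1] + _CLOCKWISE[d][1]
            if mask[nr, nc]:
                step = np.sqrt(2.0) if (_CLOCKWISE[d][0] and _CLOCKWISE[d][1]) else 1.0
                move = (cur, (nr, nc))
                if first_move is None:
                    first_move = move
                elif move == first_move:
                    return length
                length += step
                cur = (nr, nc)
                # next scan starts from the neighbour after the backtrack
                prev_dir = (d + 5) % 8
                found = True
                break
        if not found:  # isolated pixel reached (should not happen for N > 1)
            return max(length, 4.0)
    return length


def _corner_points(coords: np.ndarray) -> np.ndarray:
    """Pixel corner points (each pixel contributes its 4 square corners)."""
    offs = np.array([(-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5)])
    return (coords[:, None, :] + offs[None, :, :]).reshape(-1, 2)


def _feret_and_hull_area(coords: np.ndarray) -> tuple[float, float, float]:
    """(max Feret, min Feret, hull area) from pixel-corner convex hull, in px."""
    pts = _corner_points(coords)
    try:
        hull = ConvexHull(pts)
    except QhullError:  # pragma: no cover - corners of squares are never collinear
        return 0.0, 0.0, float(len(coords))
    v = pts[hull.vertices]
    d2 = ((v[:, None, :] - v[None, :, :]) ** 2).sum(-1)
    feret_max = float(np.sqrt(d2.max()))
    edges = np.roll(v, -1, axis=0) - v
    norms = np.hypot(edges[:, 0], edges[:, 1])
    widths = []
    for i in range(len(v)):
        if norms[i] == 0:
            continue
        nvec = np.array([-edges[i, 1], edges[i, 0]]) / norms[i]
        proj = (v - v[i]) @ nvec
        widths.append(proj.max() - proj.min())
    feret_min = float(min(widths)) if widths else 0.0
    return feret_max, feret_min, float(hull.volume)


def _moments(coords: np.ndarray) -> tuple[float, float, float, float, float]:
    """(lmax, lmin, orientation_deg, centroid_row, centroid_col) in px units."""
    r = coords[:, 0].astype(float)
    c = coords[:, 1].astype(float)
    r0, c0 = r.mean(), c.mean()
    x = c - c0
    y = -(r - r0)
    cxx = np.mean(x * x)
    cyy = np.mean(y * y)
    cxy = np.mean(x * y)
    common = np.sqrt(((cxx - cyy) / 2.0) ** 2 + cxy**2)
    lmax = (cxx + cyy) / 2.0 + common
    lmin = max((cxx + cyy) / 2.0 - common, 0.0)
    theta = wrap_axial_deg(np.rad2deg(0.5 * np.arctan2(2.0 * cxy, cxx - cyy)))
    return lmax, lmin, float(theta), r0, c0


def measure_objects(labels: LabelMap, pixel_size: float | None = None) -> pd.DataFrame:
    """One row of shape descriptors per labelled object.

    Returns a table with columns ``level``, ``label``, ``parent``,
    ``centroid_row``, ``centroid_col`` and :data:`DESCRIPTOR_NAMES`
    (lengths in um, areas in um^2).  Nuclei are their cell's partner, so
    their parent is their own label; cells have parent 0; FA parents come
    from the label map.
    """
    px = labels.pixel_size if pixel_size is None else pixel_size
    if not (px > 0):
        raise ValidationError("pixel_size must be > 0")
    lbl = labels.labels
    objects = ndimage.find_objects(lbl)
    rows = []
    for idx, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        sub = lbl[slc] == idx
        coords = np.argwhere(sub)
        n = coords.shape[0]
        lmax, lmin, theta, r0, c0 = _moments(coords)
        perim_px = boundary_chain_length(sub)
        feret_max, feret_min, hull_area = _feret_and_hull_area(coords)
        area = n * px**2
        perim = perim_px * px
        major = 4.0 * np.sqrt(lmax) * px
        minor = 4.0 * np.sqrt(lmin) * px
        bbox_area = sub.shape[0] * sub.shape[1]
        if labels.level == "fa":
            parent = labels.parent[idx] if labels.parent else 0
        elif labels.level == "nucleus":
            parent = idx
        else:
            parent = 0
        rows.append(
            dict(
                level=labels.level,
                label=idx,
                parent=parent,
                centroid_row=r0 + slc[0].start,
                centroid_col=c0 + slc[1].start,
                area_um2=area,
                perimeter_um=perim,
                eccentricity=np.sqrt(1.0 - lmin / lmax) if lmax > 0 else 0.0,
                major_axis_um=major,
                minor_axis_um=minor,
                aspect_ratio=major / minor if minor > 0 else np.inf,
                orientation_deg=theta,
                solidity=min(n / hull_area, 1.0) if hull_area > 0 else 1.0,
                extent=n / bbox_area,
                form_factor=4.0 * np.pi * area / perim**2 if perim > 0 else np.nan,
                compactness=perim**2 / (4.0 * np.pi * area) if area > 0 else np.nan,
                feret_max_um=feret_max * px,
                feret_min_um=feret_min * px,
            )
        )
    cols = ["level", "label", "parent", "centroid_row", "centroid_col", *DESCRIPTOR_NAMES]
    return pd.DataFrame(rows, columns=cols)


def assemble_feature_matrix(
    tables: pd.DataFrame,
    image_id: str = "img0",
    condition: str = "unspecified",
    day: int | None = None,
) -> pd.DataFrame:
    """Assemble per-cell 40-feature vectors from the three-level tables.

    ``tables`` is the concatenation of :func:`measure_objects` outputs for
    the cell, nucleus and fa levels of one field of view.  Each cell row
    carries its own 13 descriptors, its nucleus's 13, 13 FA aggregates and
    the FA count (:data:`FEATURE_NAMES`, fixed order), plus metadata and a
    ``zero_fa`` flag (FA aggregates are 0 for cells without FAs).
    """
    cells = tables[tables["level"] == "cell"].set_index("label")
    nucs = tables[tables["level"] == "nucleus"].set_index("parent")
    fas = tables[tables["level"] == "fa"]
    missing = set(nucs.index) - set(cells.index)
    if missing:
        raise ValidationError(f"nuclei with no matching cell: {sorted(missing)}")
    rows = []
    for cell_id, cell in cells.iterrows():
        if cell_id not in nucs.index:
            continue  # a cell without nucleus cannot occur in the seeded pipeline
        nuc = nucs.loc[cell_id]
        row = dict(
            image_id=image_id, condition=condition, day=day, cell_id=int(cell_id)
        )
        for name in DESCRIPTOR_NAMES:
            row[f"cell_{name}"] = float(cell[name])
            row[f"nuc_{name}"] = float(nuc[name])
        sub = fas[fas["parent"] == cell_id]
        row["fa_count"] = float(len(sub))
        row["zero_fa"] = len(sub) == 0
        if len(sub) == 0:
            for name in FA_AGGREGATE_NAMES:
                row[name] = 0.0
        else:
            agg = {
                "fa_area_um2_mean": sub["area_um2"].mean(),
                "fa_area_um2_sd": sub["area_um2"].std(ddof=0),
                "fa_perimeter_um_mean": sub["perimeter_um"].mean(),
                "fa_perimeter_um_sd": sub["perimeter_um"].std(ddof=0),
                "fa_eccentricity_mean": sub["eccentricity"].mean(),
                "fa_eccentricity_sd": sub["eccentricity"].std(ddof=0),
                "fa_major_axis_um_mean": sub["major_axis_um"].mean(),
                "fa_major_axis_um_sd": sub["major_axis_um"].std(ddof=0),
                "fa_minor_axis_um_mean": sub["minor_axis_um"].mean(),
                "fa_aspect_ratio_mean": sub["aspect_ratio"].mean(),
                "fa_solidity_mean": sub["solidity"].mean(),
                "fa_form_factor_mean": sub["form_factor"].mean(),
                "fa_total_area_um2": sub["area_um2"].sum(),
            }
            row.update({k: float(v) for k, v in agg.items()})
        rows.append(row)
    meta = ["image_id", "condition", "day", "cell_id", "zero_fa"]
    return pd.DataFrame(rows, columns=[*meta, *FEATURE_NAMES])


def normalize_to_anchors(
    matrix: pd.DataFrame,
    control_condition: str,
    myo_condition: str,
    rel_tol: float = 1e-9,
) -> pd.DataFrame:
    """Two-point normalization of condition means onto the FMT phenotype axis.

    For every feature, the affine map sending the control-condition mean to
    0 and the myofibroblast-condition mean to 1 is applied to each
    (condition, day) group mean:  n = (xbar - xbar_ctrl) / (xbar_myo -
    xbar_ctrl).  Features whose anchor gap is below tolerance are flagged
    ``defined = False`` (value NaN) rather than dropped.

    Returns a long-format table (condition, day, feature, value, defined).
    """
    for cond in (control_condition, myo_condition):
        n = (matrix["condition"] == cond).sum()
        if n < 2:
            raise ValidationError(
                f"anchor condition {cond!r} needs >= 2 cells, found {n}"
            )
    feats = list(FEATURE_NAMES)
    ctrl = matrix.loc[matrix["condition"] == control_condition, feats].mean()
    myo = matrix.loc[matrix["condition"] == myo_condition, feats].mean()
    gap = myo - ctrl
    scale = np.maximum.reduce([np.ones(len(feats)), ctrl.abs().to_numpy(), myo.abs().to_numpy()])
    defined = gap.abs().to_numpy() > rel_tol * scale
    day_key = matrix["day"].fillna(-1)
    rows = []
    for (cond, day), grp in matrix.groupby(["condition", day_key], sort=True):
        gmean = grp[feats].mean()
        norm = (gmean - ctrl) / gap.where(gap != 0, np.nan)
        for j, f in enumerate(feats):
            rows.append(
                dict(
                    condition=cond,
                    day=None if day == -1 else int(day),
                    feature=f,
                    value=float(norm[f]) if defined[j] else np.nan,
                    defined=bool(defined[j]),
                )
            )
    return pd.DataFrame(rows, columns=["condition", "day", "feature", "value", "defined"])


def heatmap_pivot(normalized: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long normalized table into a (condition, day) x feature grid."""
    tbl = normalized.copy()
    tbl["group"] = tbl["condition"] + tbl["day"].map(
        lambda d: "" if pd.isna(d) else f"_d{int(d)}"
    )
    return tbl.pivot_table(index="group", columns="feature", values="value", sort=False)
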