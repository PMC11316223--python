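"""FA-nucleus distance statistics, contact-guidance orientation, fiber analysis.

Three spatial readouts of the micropatterned-fibroblast phenotype:

* the Euclidean distance between each focal adhesion's centroid and the
  nucleus centroid of its own parent cell (um) -- a measure of how
  peripherally vs perinuclearly the adhesions are positioned;
* per-cell orientation relative to the micropattern lines, with 0 deg =
  parallel and +/-90 deg = perpendicular (the exact perpendicular reports
  +90);
* actin fiber orientation from a multiscale vesselness (ridge) filter and
  the smoothed structure tensor, summarized as a response-weighted
  orientation histogram and the alignment order parameter
  S = \|<exp(2 i theta)>\| (1 = perfectly aligned, 0 = isotropic).

All orientation statistics are axial (180 deg-periodic) and therefore use
angle doubling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import feature, filters

from .core import ChannelImage, PatternSpec, ValidationError, wrap_axial_deg

DEFAULT_VESSELNESS_SCALES = (1.0, 2.0, 4.0)


@dataclass
class DistanceReport:
    """FA-to-own-nucleus centroid distances.

    ``per_fa`` has one row per FA (fa_label, cell, distance_um); ``per_cell``
    one row per cell with the mean/sd/count; ``mean_um`` is the pooled mean.
    """

    per_fa: pd.DataFrame
    per_cell: pd.DataFrame

    @property
    def mean_um(self) -> float:
        return float(self.per_fa["distance_um"].mean())


@dataclass
class OrientationReport:
    """Axial orientation summary (cells or fibers).

    ``angles_deg`` are the raw orientations in (-90, 90]; circular mean/SD
    are computed on doubled angles; ``order_parameter`` is
    S = \|<exp(2 i theta)>\| with optional weights; ``histogram`` (fiber
    analysis only) is a response-weighted orientation histogram with
    ``dominant_deg`` its mode.  ``defined`` is False when there was nothing
    to orient (blank image, empty table).
    """

    angles_deg: np.ndarray
    circular_mean_deg: float
    circular_sd_deg: float
    order_parameter: float
    defined: bool = True
    histogram: pd.DataFrame | None = None
    dominant_deg: float | None = None


def order_parameter(angles_deg: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Alignment index S = \|<exp(2 i theta)>\| over axial orientations."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        return np.nan
    z = np.exp(2j * a)
    if weights is None:
        return float(np.abs(z.mean()))
    w = np.asarray(weights, dtype=float)
    tot = w.sum()
    if tot <= 0:
        return np.nan
    return float(np.abs((w * z).sum() / tot))


def _circular_stats(angles_deg: np.ndarray, weights: np.ndarray | None = None):
    """(mean_deg, sd_deg, R) of axial angles via doubling; sd = sqrt(-2 ln R)/2."""
    a = 2.0 * np.deg2rad(np.asarray(angles_deg, dtype=float))
    z = np.exp(1j * a)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        zbar = (w * z).sum() / w.sum()
    else:
        zbar = z.mean()
    r = np.abs(zbar)
    mean = wrap_axial_deg(np.rad2deg(np.angle(zbar)) / 2.0)
    sd = np.rad2deg(np.sqrt(-2.0 * np.log(max(r, 1e-300)))) / 2.0
    return float(mean), float(sd), float(r)


def fa_nucleus_distances(
    fa_table: pd.DataFrame,
    nucleus_table: pd.DataFrame,
    pixel_size: float,
) -> DistanceReport:
    """Distance from each FA centroid to its parent cell's nucleus centroid.

    Both tables are :func:`fibromorph.morphometry.measure_objects` outputs;
    FAs are matched to nuclei through their ``parent`` cell label (the
    nucleus of a cell carries the same label).  Distances are in um.
    """
    if not (pixel_size > 0):
        raise ValidationError("pixel_size must be > 0")
    nuc = nucleus_table.set_index("label")
    rows = []
    for _, fa in fa_table.iterrows():
        parent = int(fa["parent"])
        if parent == 0 or parent not in nuc.index:
            raise ValidationError(f"FA {int(fa['label'])} has no valid parent nucleus")
        dr = fa["centroid_row"] - nuc.loc[parent, "centroid_row"]
        dc = fa["centroid_col"] - nuc.loc[parent, "centroid_col"]
        rows.append(
            dict(
                fa_label=int(fa["label"]),
                cell=parent,
                distance_um=float(np.hypot(dr, dc) * pixel_size),
            )
        )
    per_fa = pd.DataFrame(rows, columns=["fa_label", "cell", "distance_um"])
    if len(per_fa):
        per_cell = (
            per_fa.groupby("cell")["distance_um"]
            .agg(mean_um="mean", sd_um=lambda s: s.std(ddof=0), n_fa="count")
            .reset_index()
        )
    else:
        per_cell = pd.DataFrame(columns=["cell", "mean_um", "sd_um", "n_fa"])
    return DistanceReport(per_fa=per_fa, per_cell=per_cell)


def cell_orientation(
    cell_table: pd.DataFrame, pattern: PatternSpec | None = None
) -> OrientationReport:
    """Per-cell orientation relative to the micropattern direction.

    theta_rel = wrap(theta_cell - theta_pattern) into (-90, 90]; for the
    homogeneous control (no pattern) the reference angle is 0 and absolute
    orientations are reported.  Circular statistics use doubled angles.
    """
    ref = pattern.angle if pattern is not None else 0.0
    theta = cell_table["orientation_deg"].to_numpy(dtype=float)
    if theta.size == 0:
        return OrientationReport(np.array([]), np.nan, np.nan, np.nan, defined=False)
    rel = wrap_axial_deg(theta - ref)
    rel = np.atleast_1d(rel)
    mean, sd, _ = _circular_stats(rel)
    return OrientationReport(
        angles_deg=rel,
        circular_mean_deg=mean,
        circular_sd_deg=sd,
        order_parameter=order_parameter(rel),
    )


def fiber_orientation_map(
    actin_img: ChannelImage,
    vesselness_scales: tuple[float, ...] = DEFAULT_VESSELNESS_SCALES,
    tensor_sigma: float = 4.0,
    presmooth_sigma: float = 1.0,
    bin_width_deg: float = 1.0,
    weight_floor: float = 0.05,
) -> OrientationReport:
    """Fiber orientation from vesselness-weighted structure-tensor analysis.

    The actin image is ridge-enhanced with a multiscale Frangi vesselness
    filter at fixed scales; local orientation comes from the structure
    tensor of the lightly pre-smoothed image (``presmooth_sigma``
    suppresses pixel-grid aliasing of the derivatives; ridge direction =
    gradient direction + 90 deg).  The orientation histogram is weighted by
    the vesselness response (responses below ``weight_floor`` of the
    maximum are discarded), and the alignment index S is the weighted order
    parameter.  A blank image yields an empty histogram with
    ``defined = False``.
    """
    px = actin_img.pixels
    if px.ndim != 2:
        raise ValidationError("fiber analysis expects a single 2D plane")
    if float(px.max() - px.min()) == 0.0:
        return OrientationReport(
            np.array([]), np.nan, np.nan, np.nan, defined=False,
            histogram=pd.DataFrame(columns=["angle_deg", "weight"]), dominant_deg=None,
        )
    vess = filters.frangi(
        px, sigmas=vesselness_scales, black_ridges=False, mode="reflect"
    )
    smoothed = ndi.gaussian_filter(px, presmooth_sigma) if presmooth_sigma > 0 else px
    arr, arc, acc = feature.structure_tensor(smoothed, sigma=tensor_sigma, order="rc")
    # (x, y) = (col, -row): Jxx = Acc, Jyy = Arr, Jxy = -Arc
    theta_grad = 0.5 * np.arctan2(-2.0 * arc, acc - arr)
    theta_ridge = wrap_axial_deg(np.rad2deg(theta_grad) + 90.0)
    w = vess.ravel()
    mask = w >= weight_floor * w.max() if w.max() > 0 else np.zeros_like(w, dtype=bool)
    angles = np.asarray(theta_ridge).ravel()[mask]
    weights = w[mask]
    if angles.size == 0 or weights.sum() <= 0:
        return OrientationReport(
            np.array([]), np.nan, np.nan, np.nan, defined=False,
            histogram=pd.DataFrame(columns=["angle_deg", "weight"]), dominant_deg=None,
        )
    edges = np.arange(-90.0, 90.0 + bin_width_deg, bin_width_deg)
    hist, _ = np.histogram(angles, bins=edges, weights=weights)
    centers = 0.5 * (edges[:-1] + edges[1:])
    histogram = pd.DataFrame({"angle_deg": centers, "weight": hist})
    dominant = float(centers[int(np.argmax(hist))])
    mean, sd, _ = _circular_stats(angles, weights)
    return OrientationReport(
        angles_deg=angles,
        circular_mean_deg=mean,
        circular_sd_deg=sd,
        order_parameter=order_parameter(angles, weights),
        histogram=histogram,
        dominant_deg=dominant,
    )
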