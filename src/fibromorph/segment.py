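"""Three-level segmentation: nuclei (primary), cells (secondary), FAs (tertiary).

The segmentation mirrors a classic primary/secondary/tertiary object
workflow: nuclei are thresholded from the DAPI channel (two-class Otsu on
the intensity histogram), cell territories are grown from the nucleus seeds
over the thresholded actin foreground by geodesic nearest-seed assignment,
and focal adhesions are thresholded *within* the union of cell masks from
the top-hat-filtered FA channel, each punctum inheriting the cell that
covers the majority of its pixels.

Otsu's threshold is computed by an explicit scan of the inter-class
variance over all histogram bin boundaries, with ties broken toward the
smallest threshold; this fixes the convention exactly and is checked
against a brute-force oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra

from .core import ChannelImage, LabelMap, ValidationError

DEFAULT_NBINS = 256
#: default object-size filters (unstated upstream; exposed in config)
DEFAULT_MIN_NUCLEUS_AREA_UM2 = 50.0
DEFAULT_MAX_NUCLEUS_AREA_UM2 = 500.0
DEFAULT_MIN_FA_AREA_UM2 = 0.4

_EIGHT = ndimage.generate_binary_structure(2, 2)  # 8-connectivity


@dataclass(frozen=True)
class ThresholdResult:
    """Otsu threshold: value t, inter-class variance at t, degeneracy flag.

    Foreground is defined as intensity strictly greater than ``t``.
    """

    t: float
    sigma_b2: float
    degenerate: bool = False


def otsu_threshold(counts: np.ndarray, bin_values: np.ndarray | None = None) -> ThresholdResult:
    """Two-class Otsu threshold from a histogram.

    ``counts[i]`` is the number of pixels with intensity ``bin_values[i]``
    (defaults to ``0..K-1``).  The returned ``t`` is the bin value below or
    at which the background class ends: it maximizes the inter-class
    variance, the smallest maximizer winning ties.  A histogram with all
    mass in one bin is degenerate (t = that value, empty foreground).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size == 0:
        raise ValidationError("histogram must be a non-empty 1D array")
    if np.any(counts < 0) or counts.sum() <= 0:
        raise ValidationError("histogram counts must be non-negative with positive total")
    if bin_values is None:
        bin_values = np.arange(counts.size, dtype=float)
    bin_values = np.asarray(bin_values, dtype=float)

    nz = np.flatnonzero(counts)
    if nz.size == 1:
        return ThresholdResult(float(bin_values[nz[0]]), 0.0, degenerate=True)

    total = counts.sum()
    p = counts / total
    omega = np.cumsum(p)                       # class-0 weight for t at bin k
    mu = np.cumsum(p * bin_values)             # class-0 unnormalized mean
    mu_t = mu[-1]
    # sigma_b^2(k) = (mu_t * omega - mu)^2 / (omega (1 - omega)); valid for
    # boundaries with both classes non-empty
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma[~np.isfinite(sigma)] = -np.inf
    sigma[-1] = -np.inf                        # all-foreground split is not a split
    k = int(np.argmax(sigma))                  # argmax returns the first (smallest) maximizer
    return ThresholdResult(float(bin_values[k]), float(sigma[k]), degenerate=False)


def otsu_threshold_image(img: np.ndarray, nbins: int = DEFAULT_NBINS) -> ThresholdResult:
    """Otsu threshold of an intensity image via an ``nbins``-bin histogram."""
    px = np.asarray(img, dtype=float).ravel()
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        return ThresholdResult(lo, 0.0, degenerate=True)
    counts, edges = np.histogram(px, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    res = otsu_threshold(counts, centers)
    # foreground = pixels > t: place t just below the upper edge of the
    # winning bin so that pixels falling in later bins (including ones
    # exactly at the edge) are foreground and earlier bins background
    idx = int(np.searchsorted(centers, res.t))
    t = float(np.nextafter(edges[idx + 1], -np.inf))
    return ThresholdResult(t, res.sigma_b2, res.degenerate)


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Relabel objects to a contiguous 1..N preserving order."""
    vals = np.setdiff1d(np.unique(labels), [0])
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(vals, start=1):
        out[labels == old] = new
    return out


def segment_nuclei(
    nuclei_img: ChannelImage,
    min_area_um2: float = DEFAULT_MIN_NUCLEUS_AREA_UM2,
    max_area_um2: float = DEFAULT_MAX_NUCLEUS_AREA_UM2,
    exclude_border: bool = True,
) -> LabelMap:
    """Primary-object segmentation of nuclei.

    Otsu foreground -> fill holes -> 8-connected components -> area filter
    in [min, max] um^2 -> optional removal of border-touching objects ->
    contiguous relabel.
    """
    px = nuclei_img.pixels
    thr = otsu_threshold_image(px)
    if thr.degenerate:
        return LabelMap(np.zeros(px.shape, dtype=np.int32), "nucleus", nuclei_img.pixel_size)
    mask = px > thr.t
    mask = ndimage.binary_fill_holes(mask)
    labels, _ = ndimage.label(mask, structure=_EIGHT)
    area_px = nuclei_img.pixel_size**2
    counts = np.bincount(labels.ravel())
    keep = np.zeros(counts.size, dtype=bool)
    areas = counts * area_px
    keep[1:] = (areas[1:] >= min_area_um2) & (areas[1:] <= max_area_um2)
    if exclude_border:
        border = np.unique(
            np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
        )
        keep[border] = False
    labels[~keep[labels]] = 0
    return LabelMap(_relabel(labels), "nucleus", nuclei_img.pixel_size)


def segment_cells(actin_img: ChannelImage, nuclei: LabelMap) -> LabelMap:
    """Secondary-object segmentation: grow cell territories from nucleus seeds.

    Foreground is the Otsu threshold of the actin channel united with all
    nucleus pixels.  Every foreground pixel is assigned to the nucleus seed
    with the smallest geodesic distance *within* the foreground (8-connected
    lattice, axial step 1 and diagonal step sqrt(2)), yielding exactly one
    cell per nucleus, each containing its own nucleus.  Foreground regions
    unreachable from any seed remain background.
    """
    if actin_img.pixels.shape != nuclei.labels.shape:
        raise ValidationError("actin image and nucleus label map shapes differ")
    px = actin_img.pixels
    thr = otsu_threshold_image(px)
    fg = (px > thr.t) if not thr.degenerate else np.zeros(px.shape, dtype=bool)
    fg |= nuclei.labels > 0
    cells = np.zeros(px.shape, dtype=np.int32)
    if nuclei.n_objects == 0:
        return LabelMap(cells, "cell", actin_img.pixel_size)

    idx_img = np.full(px.shape, -1, dtype=np.int64)
    flat = np.flatnonzero(fg)
    idx_img.ravel()[flat] = np.arange(flat.size)
    n = flat.size
    rows_list, cols_list, w_list = [], [], []
    for dr, dc, w in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0))):
        a = idx_img[max(0, -dr) : idx_img.shape[0] - max(0, dr),
                    max(0, -dc) : idx_img.shape[1] - max(0, dc)]
        b = idx_img[max(0, dr) : idx_img.shape[0] - max(0, -dr),
                    max(0, dc) : idx_img.shape[1] - max(0, -dc)]
        ok = (a >= 0) & (b >= 0)
        rows_list.append(a[ok])
        cols_list.append(b[ok])
        w_list.append(np.full(int(ok.sum()), w))
    rows = np.concatenate(rows_list)
    cols = np.concatenate(cols_list)
    weights = np.concatenate(w_list)
    graph = sparse.csr_matrix((weights, (rows, cols)), shape=(n, n))

    seed_flat = np.flatnonzero(nuclei.labels.ravel() > 0)
    seed_nodes = idx_img.ravel()[seed_flat]
    seed_labels = nuclei.labels.ravel()[seed_flat]
    _, _, sources = dijkstra(
        graph, directed=False, indices=seed_nodes, min_only=True, return_predecessors=True
    )
    reached = sources >= 0
    node_label = np.zeros(n, dtype=np.int32)
    src_to_label = np.zeros(int(seed_nodes.max()) + 1, dtype=np.int32)
    src_to_label[seed_nodes] = seed_labels
    node_label[reached] = src_to_label[sources[reached]]
    cells.ravel()[flat] = node_label
    return LabelMap(cells, "cell", actin_img.pixel_size)


def segment_fas(
    fa_img_tophat: ChannelImage,
    cells: LabelMap,
    min_area_um2: float = DEFAULT_MIN_FA_AREA_UM2,
) -> LabelMap:
    """Tertiary-object segmentation of focal adhesions inside cell masks.

    The Otsu threshold is computed over within-cell pixels only; connected
    components (8-connectivity) restricted to the cell union are filtered
    by minimum area and assigned the parent cell covering the majority of
    their pixels.  Puncta outside all cells are discarded by construction.
    """
    if fa_img_tophat.pixels.shape != cells.labels.shape:
        raise ValidationError("FA image and cell label map shapes differ")
    px = fa_img_tophat.pixels
    inside = cells.labels > 0
    empty = LabelMap(
        np.zeros(px.shape, dtype=np.int32), "fa", fa_img_tophat.pixel_size, parent={}
    )
    if not np.any(inside):
        import logging

        logging.getLogger("fibromorph").warning("segment_fas: no cell pixels; empty result")
        return empty
    thr = otsu_threshold_image(px[inside])
    if thr.degenerate:
        return empty
    mask = (px > thr.t) & inside
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return empty
    area_px = fa_img_tophat.pixel_size**2
    counts = np.bincount(labels.ravel())
    keep = np.zeros(counts.size, dtype=bool)
    keep[1:] = counts[1:] * area_px >= min_area_um2
    labels[~keep[labels]] = 0
    labels = _relabel(labels)
    parent: dict[int, int] = {}
    for lab in np.setdiff1d(np.unique(labels), [0]):
        covering = cells.labels[labels == lab]
        vals, cnts = np.unique(covering[covering > 0], return_counts=True)
        parent[int(lab)] = int(vals[np.argmax(cnts)])
    return LabelMap(labels, "fa", fa_img_tophat.pixel_size, parent=parent)
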