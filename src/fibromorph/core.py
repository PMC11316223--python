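"""Shared domain types, image/table I/O, configuration and logging.

All downstream stages operate on the containers defined here:
:class:`ChannelImage` (one fluorescence channel with physical pixel size),
:class:`ImageSet` (one field of view), :class:`PatternSpec` (the adhesive
line micropattern geometry) and :class:`LabelMap` (an integer segmentation
mask at one object level).  The only operations that touch the filesystem
are :func:`read_image_set`, :func:`write_image_set`, :func:`write_table`
and :func:`read_table`.

Conventions
-----------
* pixel coordinates are 0-based ``(row, col)``; centroids may be fractional
* every physical quantity is in micrometres, derived via ``pixel_size``
* orientations are in degrees in ``(-90, 90]``, measured counterclockwise
  from the image x axis (columns increasing rightward, y pointing up, i.e.
  against the row axis)
* intensities are converted to ``float64`` on ingestion
"""

from __future__ import annotations

import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

log = logging.getLogger("fibromorph")

#: channel roles understood by the pipeline (nuclei/actin/fa are mandatory)
CHANNEL_ROLES = ("nuclei", "actin", "fa", "asma", "pattern")
REQUIRED_ROLES = ("nuclei", "actin", "fa")

#: object levels of the three-tier segmentation
LEVELS = ("nucleus", "cell", "fa")


class ValidationError(ValueError):
    """Raised when a domain-type invariant is violated."""


def wrap_axial_deg(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap an orientation (axial, 180 deg-periodic) into ``(-90, 90]``.

    The exact perpendicular maps to +90, matching the micropattern
    orientation convention (0 deg = parallel to the lines).
    """
    a = ((np.asarray(angle, dtype=float) + 90.0) % 180.0) - 90.0
    a = np.where(a == -90.0, 90.0, a)
    return float(a) if np.isscalar(angle) or np.ndim(angle) == 0 else a


@dataclass(frozen=True)
class ChannelImage:
    """A single fluorescence channel (2D plane or 3D z-stack).

    Parameters
    ----------
    pixels : ndarray
        Non-negative intensities, shape ``(rows, cols)`` or
        ``(planes, rows, cols)`` for a z-stack awaiting projection.
    pixel_size : float
        Micrometres per pixel (> 0), isotropic.
    role : str
        One of :data:`CHANNEL_ROLES`.
    meta : dict
        Free-form stage annotations (e.g. ``degenerate`` flags).
    """

    pixels: np.ndarray
    pixel_size: float
    role: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim not in (2, 3) or px.size == 0:
            raise ValidationError("pixels must be a non-empty 2D or 3D array")
        if not np.all(np.isfinite(px)):
            raise ValidationError("pixel intensities must be finite")
        if not (self.pixel_size > 0):
            raise ValidationError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.role not in CHANNEL_ROLES:
            raise ValidationError(
                f"unknown channel role {self.role!r}; expected one of {CHANNEL_ROLES}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def is_stack(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape[-2:]

    def with_pixels(self, pixels: np.ndarray, **meta) -> "ChannelImage":
        return ChannelImage(pixels, self.pixel_size, self.role, {**self.meta, **meta})


@dataclass(frozen=True)
class ImageSet:
    """One field of view: a named set of channels plus condition metadata."""

    channels: Mapping[str, ChannelImage]
    condition: str = "unspecified"
    day: int | None = None
    replicate: str = "r0"

    def __post_init__(self) -> None:
        for role in REQUIRED_ROLES:
            if role not in self.channels:
                raise ValidationError(f"missing required channel role {role!r}")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValidationError(f"channels disagree on plane shape: {shapes}")
        sizes = {ch.pixel_size for ch in self.channels.values()}
        if len(sizes) != 1:
            raise ValidationError(f"channels disagree on pixel_size: {sizes}")
        if self.day is not None and self.day not in (2, 4, 8):
            raise ValidationError(f"day must be one of 2, 4, 8 or None, got {self.day}")

    @property
    def pixel_size(self) -> float:
        return next(iter(self.channels.values())).pixel_size

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, role: str) -> ChannelImage:
        return self.channels[role]

    def with_channels(self, **channels: ChannelImage) -> "ImageSet":
        merged = dict(self.channels)
        merged.update(channels)
        return replace(self, channels=merged)


@dataclass(frozen=True)
class PatternSpec:
    """Geometry of the linear adhesive micropattern.

    ``width`` is the fibronectin line width w and ``spacing`` the gap s
    between lines, both in micrometres; patterns are referred to as
    "w x s lines" (e.g. 20x20, 10x10, 5x5).  ``angle`` is the direction of
    the lines in degrees, 0 = lines along the image x axis.
    """

    width: float
    spacing: float
    angle: float = 0.0

    def __post_init__(self) -> None:
        if not (self.width > 0):
            raise ValidationError(f"pattern width must be > 0, got {self.width}")
        if self.spacing < 0:
            raise ValidationError(f"pattern spacing must be >= 0, got {self.spacing}")
        if not (-90.0 < self.angle <= 90.0):
            raise ValidationError(f"pattern angle must be in (-90, 90], got {self.angle}")

    @property
    def period(self) -> float:
        return self.width + self.spacing


@dataclass
class LabelMap:
    """Integer-labelled segmentation mask at one object level.

    0 is background; labels 1..N are objects.  For the ``fa`` level,
    ``parent`` maps every FA label to the cell label that contains it.
    """

    labels: np.ndarray
    level: str
    pixel_size: float
    parent: dict[int, int] | None = None

    def __post_init__(self) -> None:
        lbl = np.asarray(self.labels)
        if not np.issubdtype(lbl.dtype, np.integer):
            raise ValidationError("labels must be an integer array")
        if lbl.ndim != 2 or lbl.size == 0:
            raise ValidationError("labels must be a non-empty 2D array")
        if lbl.min() < 0:
            raise ValidationError("labels must be >= 0")
        if self.level not in LEVELS:
            raise ValidationError(f"level must be one of {LEVELS}, got {self.level!r}")
        if not (self.pixel_size > 0):
            raise ValidationError("pixel_size must be > 0")
        if self.level == "fa":
            present = set(np.unique(lbl)) - {0}
            if self.parent is None or not present <= set(self.parent):
                missing = sorted(present - set(self.parent or {}))
                raise ValidationError(f"fa labels without parent assignment: {missing}")
        self.labels = lbl

    @property
    def n_objects(self) -> int:
        return int(len(np.setdiff1d(np.unique(self.labels), [0])))

    def object_labels(self) -> np.ndarray:
        return np.setdiff1d(np.unique(self.labels), [0])


# ---------------------------------------------------------------------------
# I/O


def read_image_set(
    path: str | Path,
    channel_map: Mapping[str, int],
    pixel_size: float,
    condition: str = "unspecified",
    day: int | None = None,
    replicate: str = "r0",
) -> ImageSet:
    """Read a multi-channel TIFF/OME-TIFF into an :class:`ImageSet`.

    ``channel_map`` maps channel roles to indices along the channel axis.
    Accepted array layouts are ``(C, Y, X)`` and ``(Z, C, Y, X)``; z-stacks
    are retained as stacks for later maximum projection.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    for role in REQUIRED_ROLES:
        if role not in channel_map:
            raise ValidationError(f"channel_map is missing required role {role!r}")
    if not (pixel_size > 0):
        raise ValidationError(f"pixel_size must be > 0, got {pixel_size}")
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 3:  # (C, Y, X)
        n_ch, take = arr.shape[0], lambda i: arr[i]
    elif arr.ndim == 4:  # (Z, C, Y, X)
        n_ch, take = arr.shape[1], lambda i: arr[:, i]
    else:
        raise ValidationError(f"unsupported TIFF dimensionality {arr.ndim}")
    channels = {}
    for role, idx in channel_map.items():
        if not (0 <= idx < n_ch):
            raise ValidationError(
                f"channel index {idx} for role {role!r} out of range (file has {n_ch})"
            )
        channels[role] = ChannelImage(take(idx), pixel_size, role)
    return ImageSet(channels, condition=condition, day=day, replicate=replicate)


def write_image_set(image_set: ImageSet, path: str | Path) -> Path:
    """Write an ImageSet as a (C, Y, X) float32 TIFF, role order fixed."""
    path = Path(path)
    roles = [r for r in CHANNEL_ROLES if r in image_set.channels]
    stack = np.stack([image_set[r].pixels.astype(np.float32) for r in roles])
    tifffile.imwrite(
        path, stack, photometric="minisblack", metadata={"axes": "CYX", "roles": roles}
    )
    return path


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as UTF-8 CSV with a stable column order.

    Values round-trip exactly through :func:`read_table` (floats are written
    with ``repr`` precision).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, encoding="utf-8", float_format=lambda x: repr(float(x)))
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


# ---------------------------------------------------------------------------
# configuration & logging


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("configuration file must contain a mapping")
    return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@contextmanager
def stage_timer(stage: str) -> Iterator[None]:
    """Log wall-clock duration of a pipeline stage."""
    t0 = time.perf_counter()
    log.info("stage %s: start", stage)
    try:
        yield
    finally:
        log.info("stage %s: done in %.2f s", stage, time.perf_counter() - t0)
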