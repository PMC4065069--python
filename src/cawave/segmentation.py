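"""Cell and nucleus detection by threshold + distance-map watershed.

The detection recipe is the classic one for separating touching nuclei in a
fluorescence image: binarise the image, fill holes, compute the Euclidean
distance transform of the foreground, seed a watershed at the regional maxima
of the distance map, then discard objects failing size/radius criteria.

Coordinates are 0-based ``(row, col)`` pixel indices; centroids are converted
to micrometres with the supplied pixel size.  ``x_um`` maps to the column
axis and ``y_um`` to the row axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

__all__ = ["SegParams", "segment", "reference_image", "CELLTABLE_COLUMNS"]

CELLTABLE_COLUMNS = [
    "label",
    "row_px",
    "col_px",
    "x_um",
    "y_um",
    "area_um2",
    "radius_um",
]


@dataclass(frozen=True)
class SegParams:
    """Object-detection criteria.

    intensity_threshold
        Either ``"auto"`` (Otsu on the image) or a fraction of the image
        dynamic range in ``[0, 1]``.
    min_area
        Minimum object area in µm².
    min_radius
        Minimum equivalent radius in µm (radius of the circle with the
        object's area).
    min_separation
        Minimum distance between watershed seeds in µm; closer seed pairs
        are merged, keeping the deeper distance-map maximum.
    """

    intensity_threshold: Union[str, float] = "auto"
    min_area: float = 20.0
    min_radius: float = 2.0
    min_separation: float = 8.0

    def __post_init__(self) -> None:
        if isinstance(self.intensity_threshold, str):
            if self.intensity_threshold != "auto":
                raise ValueError(
                    f"intensity_threshold must be 'auto' or a number in [0, 1], "
                    f"got {self.intensity_threshold!r}"
                )
        elif not 0.0 <= float(self.intensity_threshold) <= 1.0:
            raise ValueError(
                f"numeric intensity_threshold must lie in [0, 1], got "
                f"{self.intensity_threshold}"
            )
        if self.min_area < 0:
            raise ValueError(f"min_area must be >= 0, got {self.min_area}")
        if self.min_radius < 0:
            raise ValueError(f"min_radius must be >= 0, got {self.min_radius}")
        if self.min_separation < 0:
            raise ValueError(f"min_separation must be >= 0, got {self.min_separation}")


def reference_image(stack: np.ndarray, method: str = "temporal_mean") -> np.ndarray:
    """Reduce a T×H×W stack to a single 2-D image for segmentation.

    ``temporal_mean`` averages across frames (the default used for calcium
    movies, where every labelled cell is visible at baseline); ``temporal_max``
    takes the per-pixel maximum.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack.astype(float)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("stack must be a non-empty T x H x W array")
    if method == "temporal_mean":
        return stack.mean(axis=0)
    if method == "temporal_max":
        return stack.max(axis=0).astype(float)
    raise ValueError(f"unknown reference method {method!r}")


def _threshold_value(image: np.ndarray, params: SegParams) -> float:
    if params.intensity_threshold == "auto":
        if np.ptp(image) == 0:
            return np.inf  # flat image: nothing to segment
        return float(threshold_otsu(image))
    lo, hi = float(image.min()), float(image.max())
    return lo + float(params.intensity_threshold) * (hi - lo)


def _seed_points(dist: np.ndarray, min_sep_px: float) -> list[tuple[int, int, float]]:
    """Regional maxima of the distance map, h-maxima suppressed by 1 px.

    Each connected maximum region contributes one seed: its deepest pixel,
    ties broken by lowest (row, col).  Seed pairs closer than ``min_sep_px``
    are merged keeping the deeper seed (depth ties again broken by (row, col)).
    """
    peaks = h_maxima(dist, 1.0)
    lab, n = ndi.label(peaks)
    seeds: list[tuple[int, int, float]] = []
    for region in range(1, n + 1):
        rows, cols = np.nonzero(lab == region)
        depths = dist[rows, cols]
        best = np.lexsort((cols, rows, -depths))[0]
        seeds.append((int(rows[best]), int(cols[best]), float(depths[best])))
    # greedy merge: deepest first, deterministic tie-break
    seeds.sort(key=lambda s: (-s[2], s[0], s[1]))
    kept: list[tuple[int, int, float]] = []
    for r, c, d in seeds:
        if all((r - kr) ** 2 + (c - kc) ** 2 >= min_sep_px**2 for kr, kc, _ in kept):
            kept.append((r, c, d))
    return kept


def segment(
    image: np.ndarray, params: SegParams, pixel_size: float
) -> tuple[np.ndarray, pd.DataFrame]:
    """Detect objects in a single-channel image.

    Parameters
    ----------
    image
        2-D intensity array (finite values).
    params
        Detection criteria; see :class:`SegParams`.
    pixel_size
        Micrometres per pixel.

    Returns
    -------
    label_map : ndarray of int
        Background 0, objects labelled contiguously from 1.
    cells : DataFrame
        One row per object with columns ``label, row_px, col_px, x_um, y_um,
        area_um2, radius_um``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D single channel")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if pixel_size <= 0:
        raise ValueError(f"pixel_size must be > 0, got {pixel_size}")

    empty = pd.DataFrame(columns=CELLTABLE_COLUMNS)
    thr = _threshold_value(image, params)
    mask = image > thr
    if not mask.any():
        return np.zeros(image.shape, dtype=np.int32), empty

    mask = ndi.binary_fill_holes(mask)
    dist = ndi.distance_transform_edt(mask)
    seeds = _seed_points(dist, params.min_separation / pixel_size)
    if not seeds:
        return np.zeros(image.shape, dtype=np.int32), empty

    markers = np.zeros(image.shape, dtype=np.int32)
    for i, (r, c, _) in enumerate(seeds, start=1):
        markers[r, c] = i
    labels = watershed(-dist, markers=markers, mask=mask)

    # size / radius criteria, then contiguous relabelling
    keep = []
    for prop in regionprops(labels):
        area_um2 = prop.area * pixel_size**2
        radius_um = np.sqrt(area_um2 / np.pi)
        if area_um2 >= params.min_area and radius_um >= params.min_radius:
            keep.append((prop.label, prop.centroid, area_um2, radius_um))

    out = np.zeros(image.shape, dtype=np.int32)
    rows = []
    for new_label, (old_label, (cr, cc), area_um2, radius_um) in enumerate(keep, start=1):
        out[labels == old_label] = new_label
        rows.append(
            {
                "label": new_label,
                "row_px": cr,
                "col_px": cc,
                "x_um": cc * pixel_size,
                "y_um": cr * pixel_size,
                "area_um2": area_um2,
                "radius_um": radius_um,
            }
        )
    cells = pd.DataFrame(rows, columns=CELLTABLE_COLUMNS)
    return out, cells
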