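"""Cell and vesicle segmentation with classical, weight-free operators.

Vesicles (late endosomes/lysosomes) are detected as local intensity maxima
used as markers for a seeded watershed on a foreground mask; cell
territories come from a nucleus-seeded watershed.
All thresholds are relative (Otsu, relative peak heights), so label counts are
invariant under uniform intensity rescaling, and every tie-break is the
deterministic scan order of the underlying scikit-image routines.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a (z, y, x) stack onto (y, x)."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack.copy()
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("expected a (z, y, x) stack with at least one plane")
    return stack.max(axis=0)


def _relabel_sequential(mask: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mask, dtype=np.int32)
    for new, old in enumerate(np.unique(mask[mask > 0]), start=1):
        out[mask == old] = new
    return out


def segment_cells(nuclei_img: np.ndarray, cyto_img: np.ndarray | None = None,
                  supplied_mask: np.ndarray | None = None, *,
                  min_nucleus_area: int = 80,
                  smoothing_sigma: float = 2.0) -> np.ndarray:
    """Cell territories as a label mask, one label per detected nucleus.

    When ``supplied_mask`` is given it is validated and passed through
    unchanged (masks drawn elsewhere remain usable, mirroring a manual
    outlining workflow).  Otherwise nuclei are Otsu-thresholded, hole-filled
    and size-filtered, and territories are grown by watershed on the inverted
    smoothed cytoplasm image, or on the distance to the nearest nucleus when
    no cytoplasm channel exists.

    A blank image yields an all-zero mask with a warning, not an exception.
    """
    if supplied_mask is not None:
        supplied_mask = np.asarray(supplied_mask)
        if supplied_mask.shape != np.asarray(nuclei_img).shape:
            raise ValueError("supplied cell mask shape does not match image")
        if not np.issubdtype(supplied_mask.dtype, np.integer):
            raise ValueError("cell mask must be an integer label image")
        return supplied_mask

    nuclei_img = np.asarray(nuclei_img, dtype=np.float64)
    smooth = ndi.gaussian_filter(nuclei_img, smoothing_sigma)
    if smooth.max() <= smooth.min():
        warnings.warn("blank nuclei image: no cells detected", stacklevel=2)
        return np.zeros(nuclei_img.shape, dtype=np.int32)
    fg = smooth > threshold_otsu(smooth)
    fg = ndi.binary_fill_holes(fg)
    seeds = cc_label(fg, connectivity=2)
    areas = np.bincount(seeds.ravel())
    seeds[np.isin(seeds, np.flatnonzero(areas < min_nucleus_area))] = 0
    seeds = cc_label(seeds > 0, connectivity=2)
    if seeds.max() == 0:
        warnings.warn("no nucleus detected: empty cell mask", stacklevel=2)
        return np.zeros(nuclei_img.shape, dtype=np.int32)

    if cyto_img is not None:
        surface = -ndi.gaussian_filter(np.asarray(cyto_img, dtype=np.float64),
                                       smoothing_sigma)
    else:
        surface = ndi.distance_transform_edt(seeds == 0)
    return watershed(surface, markers=seeds).astype(np.int32)


def detect_vesicles(vesicle_img: np.ndarray, min_radius_px: float = 3.0,
                    max_radius_px: float = 6.0, *,
                    threshold_rel: float = 0.05,
                    marker_smooth_sigma: float = 1.0) -> np.ndarray:
    """Label mask of vesicles from one intensity channel.

    The foreground is Otsu on a background-subtracted image (large-scale
    Gaussian background estimate, scale ``4 * max_radius``).  Watershed
    markers are local intensity maxima of the lightly smoothed foreground
    signal, spaced at least ``min_radius - 1`` px apart — each vesicle keeps
    its own intensity peak even when touching a neighbor, so the
    marker-seeded watershed splits contacting vesicles at the intensity
    neck.  That splitting is essential: merged pairs would corrupt the
    downstream contact statistic.  Labels smaller than half the minimal
    disk area (pi * min_radius^2 / 2) are discarded.
    """
    if min_radius_px < 1 or max_radius_px < min_radius_px:
        raise ValueError("need max_radius_px >= min_radius_px >= 1")
    img = np.asarray(vesicle_img, dtype=np.float64)
    if img.max() <= img.min():
        return np.zeros(img.shape, dtype=np.int32)

    bg = ndi.gaussian_filter(img, 4.0 * max_radius_px)
    sub = np.clip(img - bg, 0.0, None)
    if sub.max() <= 0:
        return np.zeros(img.shape, dtype=np.int32)
    fg = sub > threshold_otsu(sub)
    fg = ndi.binary_fill_holes(fg)

    smooth = ndi.gaussian_filter(sub, marker_smooth_sigma)
    min_dist = max(2, int(round(min_radius_px)) - 1)
    coords = peak_local_max(smooth, min_distance=min_dist, labels=fg,
                            threshold_rel=threshold_rel)
    markers = np.zeros(img.shape, dtype=np.int32)
    if len(coords):
        order = np.lexsort((coords[:, 1], coords[:, 0]))  # scan order: stable
        for k, (y, x) in enumerate(coords[order], start=1):
            markers[y, x] = k
    if markers.max() == 0:
        return np.zeros(img.shape, dtype=np.int32)

    labels = watershed(-sub, markers=markers, mask=fg)
    min_area = np.pi * min_radius_px ** 2 / 2.0
    counts = np.bincount(labels.ravel())
    too_small = np.flatnonzero(counts < min_area)
    if len(too_small):
        labels[np.isin(labels, too_small)] = 0
    return _relabel_sequential(labels)
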