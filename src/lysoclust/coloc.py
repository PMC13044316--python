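"""Two-channel colocalization: masked Pearson and Costes-thresholded Pearson.

The plain Pearson product-moment coefficient over an ROI is always reported.
Alongside it, an automatic-threshold coefficient in the style of the Fiji
colocalization-threshold analysis is computed with the Costes procedure:
channel 2 is regressed on channel 1 by orthogonal (total least squares)
regression, a candidate threshold walks down from the channel-1 maximum, and
the search stops at the largest threshold for which the below-threshold
pixels are uncorrelated (Pearson <= 0); the coefficient is then computed
over pixels above threshold in either channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class UndefinedCorrelationError(ValueError):
    """A channel is constant on the ROI, so Pearson r does not exist."""


@dataclass(frozen=True)
class ColocResult:
    r_pearson: float
    r_above_threshold: float
    t1: float
    t2: float
    n_pixels_used: int
    mask_id: int | None = None
    #: True when the threshold walk exhausted all candidates without the
    #: below-threshold correlation dropping to <= 0 (e.g. perfect correlation)
    search_exhausted: bool = False


def _masked_pixels(ch1: np.ndarray, ch2: np.ndarray,
                   mask: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    ch1 = np.asarray(ch1, dtype=np.float64)
    ch2 = np.asarray(ch2, dtype=np.float64)
    if ch1.shape != ch2.shape:
        raise ValueError("channels must have the same shape")
    if mask is None:
        return ch1.ravel(), ch2.ravel()
    mask = np.asarray(mask)
    if mask.shape != ch1.shape:
        raise ValueError("mask shape does not match channels")
    keep = mask > 0
    return ch1[keep], ch2[keep]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2:
        raise ValueError("need at least 2 pixels for a correlation")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(np.dot(xd, xd))
    sy = np.sqrt(np.dot(yd, yd))
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("constant channel on the ROI")
    return float(np.clip(np.dot(xd, yd) / (sx * sy), -1.0, 1.0))


def pearson_r(ch1: np.ndarray, ch2: np.ndarray,
              mask: np.ndarray | None = None) -> float:
    """Pearson correlation of two channels over the masked pixels."""
    x, y = _masked_pixels(ch1, ch2, mask)
    return _pearson(x, y)


def _orthogonal_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Total-least-squares line y = a*x + b through the point cloud."""
    sxx = np.var(x)
    syy = np.var(y)
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    if sxx == 0 or syy == 0:
        raise UndefinedCorrelationError("degenerate regression: zero variance")
    if sxy == 0:
        a = np.sqrt(syy / sxx)  # slope sign ambiguous; pick positive
    else:
        a = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy ** 2)) / (2 * sxy)
    b = y.mean() - a * x.mean()
    return float(a), float(b)


def _threshold_step(x: np.ndarray) -> float:
    # one quantization level for integer-valued data, else 1/256 of the range
    if np.allclose(x, np.round(x)):
        return 1.0
    return float((x.max() - x.min()) / 256.0)


def costes_thresholded_pearson(ch1: np.ndarray, ch2: np.ndarray,
                               mask: np.ndarray | None = None, *,
                               mask_id: int | None = None) -> ColocResult:
    """Costes auto-thresholded Pearson coefficient over an ROI."""
    x, y = _masked_pixels(ch1, ch2, mask)
    r_plain = _pearson(x, y)
    a, b = _orthogonal_fit(x, y)

    step = _threshold_step(x)
    t1 = float(x.max())
    t_min = float(x.min())
    exhausted = True
    while t1 > t_min:
        t2 = a * t1 + b
        below = (x < t1) & (y < t2)
        if np.count_nonzero(below) >= 2:
            xb, yb = x[below], y[below]
            if np.ptp(xb) > 0 and np.ptp(yb) > 0:
                if _pearson(xb, yb) <= 0.0:
                    exhausted = False
                    break
        t1 -= step
    if exhausted:
        t1 = t_min
    t2 = a * t1 + b

    above = (x > t1) | (y > t2)
    n_above = int(np.count_nonzero(above))
    if n_above >= 2 and np.ptp(x[above]) > 0 and np.ptp(y[above]) > 0:
        r_thr = _pearson(x[above], y[above])
    else:
        r_thr = float("nan")
    return ColocResult(r_pearson=r_plain, r_above_threshold=r_thr,
                       t1=t1, t2=float(t2), n_pixels_used=n_above,
                       mask_id=mask_id, search_exhausted=exhausted)


def coloc_per_cell(ch1: np.ndarray, ch2: np.ndarray,
                   cell_mask: np.ndarray | None) -> pd.DataFrame:
    """Per-cell colocalization table (whole image if no mask is given)."""
    if cell_mask is None:
        cells = [None]
    else:
        cell_mask = np.asarray(cell_mask)
        cells = [int(c) for c in np.unique(cell_mask[cell_mask > 0])]
        if not cells:
            cells = [None]
    rows = []
    for c in cells:
        roi = None if c is None else (cell_mask == c).astype(np.uint8)
        res = costes_thresholded_pearson(ch1, ch2, roi, mask_id=c)
        rows.append({"cell": 0 if c is None else c, "r": res.r_pearson,
                     "r_thresh": res.r_above_threshold, "t1": res.t1,
                     "t2": res.t2, "n_pixels": res.n_pixels_used})
    return pd.DataFrame(rows)
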