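"""Local heterogeneity (LH): how rough an image layout is at small scales.

For a pixel (i, j), the neighborhood heterogeneity is the mean absolute
intensity difference between the pixel and the other p^2 - 1 pixels of the
p-by-p window centered on it.  LH averages this over every position where
the full window fits (no padding; partial windows are excluded by the
summation limits).  A layout that places similar features next to each
other yields smooth images and hence low LH; comparing the LH of two
layouts of the same data measures which one preserves feature
neighborhood structure better, summarized as the percentage reduction
(LH_other - LH_ref) / LH_other * 100.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .imaging import SampleImage

__all__ = [
    "local_heterogeneity",
    "lh_reduction_percentage",
    "layout_lh_summary",
]


def _as_image_array(image) -> np.ndarray:
    arr = image.intensities if isinstance(image, SampleImage) else np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError("image must be a 2-D array")
    return arr


def local_heterogeneity(image, p: int = 3) -> float:
    """Mean neighborhood heterogeneity over all full p-by-p windows.

    ``p`` must be odd and no larger than either image dimension.
    """
    y = _as_image_array(image)
    nr, nc = y.shape
    if p < 3 or p % 2 == 0:
        raise ValueError("neighborhood size p must be an odd integer >= 3")
    if p > nr or p > nc:
        raise ValueError(f"p={p} exceeds image dimensions {nr}x{nc}")
    half = (p - 1) // 2
    center = y[half:nr - half, half:nc - half]
    acc = np.zeros_like(center)
    for da in range(-half, half + 1):
        for db in range(-half, half + 1):
            if da == 0 and db == 0:
                continue
            neighbor = y[half + da:nr - half + da, half + db:nc - half + db]
            acc += np.abs(neighbor - center)
    per_window = acc / (p * p - 1)
    return float(per_window.mean())


def lh_reduction_percentage(lh_other: float, lh_ref: float) -> float:
    """Percentage by which ``lh_ref`` improves on ``lh_other``; negative if worse."""
    if lh_other <= 0:
        raise ValueError("reference LH must be positive for a relative comparison")
    return (lh_other - lh_ref) / lh_other * 100.0


def layout_lh_summary(images: list, p_values=(3, 5, 7, 9),
                      other_images: list | None = None) -> pd.DataFrame:
    """Per-neighborhood-size LH statistics across a set of images.

    With ``other_images`` (same samples rendered under a competing layout,
    matched by position), adds the competing statistics, the per-sample
    reduction percentages, and a paired two-tailed t-test p-value.  The
    t-test is a convenience wrapper around scipy, not a contribution of
    this package.
    """
    if len(images) == 0:
        raise ValueError("need at least one image")
    if other_images is not None and len(other_images) != len(images):
        raise ValueError("paired comparison needs equally many images in both sets")
    rows = []
    for p in p_values:
        lh = np.array([local_heterogeneity(img, p) for img in images])
        row = {"p": p, "lh_mean": lh.mean(), "lh_sd": lh.std(ddof=1) if lh.size > 1 else 0.0}
        if other_images is not None:
            lh_other = np.array([local_heterogeneity(img, p) for img in other_images])
            with np.errstate(divide="ignore", invalid="ignore"):
                reductions = (lh_other - lh) / lh_other * 100.0
            row.update({
                "lh_mean_other": lh_other.mean(),
                "lh_sd_other": lh_other.std(ddof=1) if lh_other.size > 1 else 0.0,
                "reduction_pct_mean": float(np.mean(reductions)),
                "reduction_pct_sd": float(np.std(reductions, ddof=1)) if lh.size > 1 else 0.0,
            })
            if lh.size > 1 and not np.allclose(lh, lh_other):
                row["p_value"] = float(stats.ttest_rel(lh, lh_other).pvalue)
            else:
                row["p_value"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
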