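"""Brain-wide microglial (Iba-1) image quantification.

Grayscale histology fields are binarized (fixed threshold or Otsu, with a
polarity flag because DAB staining is dark-on-light), connected components
are measured per region of interest (percent-positive area, object count,
mean object size in um^2), and ROI-level values roll up into
hemisphere/group/day tables.  The fold-reduction statistic compares the
day-2 -> day-7 decrease of one group against another.

Conventions: 8-connectivity, border-touching objects included, components
smaller than ``min_object_px`` removed before all statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label

logger = logging.getLogger(__name__)

__all__ = [
    "RoiQuant",
    "binarize",
    "quantify_roi",
    "summarize_groups",
    "fold_reduction",
]


@dataclass(frozen=True)
class RoiQuant:
    """Quantification of one ROI field."""

    percent_area: float
    n_objects: int
    mean_object_size_um2: float  # NaN when n_objects == 0


def binarize(image: np.ndarray, method: str = "otsu",
             threshold: float | None = None,
             polarity: str = "dark",
             min_contrast: float = 20.0) -> np.ndarray:
    """Binary positive-pixel mask of an 8-bit grayscale field.

    ``method='fixed'`` uses the supplied threshold: positive iff intensity
    >= t for ``polarity='bright'``, <= t for ``'dark'`` (DAB-like stain on
    a light background).  ``method='otsu'`` maximises between-class
    variance; on a constant image it returns an all-negative mask with a
    warning, and when the Otsu class means are separated by less than
    ``min_contrast`` intensity levels the field is treated as unstained
    (Otsu on a stain-free field would otherwise split the background noise
    itself and grossly overestimate the positive area).
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    if polarity not in ("dark", "bright"):
        raise ValueError("polarity must be 'dark' or 'bright'")
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        t = threshold
    elif method == "otsu":
        if img.min() == img.max():
            logger.warning("constant image under Otsu; returning empty mask")
            return np.zeros(img.shape, dtype=bool)
        t = threshold_otsu(img)
        lo, hi = img[img <= t], img[img > t]
        if lo.size and hi.size and hi.mean() - lo.mean() < min_contrast:
            logger.warning("Otsu class contrast %.1f below %.1f; treating "
                           "field as unstained", hi.mean() - lo.mean(),
                           min_contrast)
            return np.zeros(img.shape, dtype=bool)
        # skimage's Otsu convention: foreground strictly above the threshold
        return img <= t if polarity == "dark" else img > t
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return img <= t if polarity == "dark" else img >= t


def quantify_roi(mask: np.ndarray, um_per_px: float,
                 min_object_px: int = 3) -> RoiQuant:
    """Percent-positive area, object count and mean object size.

    8-connected components smaller than ``min_object_px`` pixels are
    treated as speckle and removed before every statistic.
    """
    m = np.asarray(mask)
    if m.dtype != bool:
        if not np.isin(m, (0, 1)).all():
            raise ValueError("mask must be binary")
        m = m.astype(bool)
    if um_per_px <= 0:
        raise ValueError("um_per_px must be positive")
    lab, n = _cc_label(m, connectivity=2, return_num=True)
    if n == 0:
        return RoiQuant(0.0, 0, math.nan)
    sizes = np.bincount(lab.ravel())[1:]  # pixel count per component
    keep = sizes >= min_object_px
    kept_sizes = sizes[keep]
    n_objects = int(keep.sum())
    kept_px = int(kept_sizes.sum())
    percent = 100.0 * kept_px / m.size
    if n_objects == 0:
        return RoiQuant(0.0, 0, math.nan)
    mean_size = float(kept_sizes.mean()) * um_per_px ** 2
    return RoiQuant(percent, n_objects, mean_size)


def summarize_groups(quants: pd.DataFrame) -> pd.DataFrame:
    """Group x day x hemisphere summary of ROI quantifications.

    ``quants`` needs columns subject_id, group, day, hemisphere,
    percent_area, mean_object_size_um2.  The animal-level value is the
    mean over that animal's ROIs within the hemisphere; the table reports
    the group mean +/- SD (ddof=1) of animal-level values and the animal
    count.  Empty cells are omitted with a warning.
    """
    required = {"subject_id", "group", "day", "hemisphere",
                "percent_area", "mean_object_size_um2"}
    if not required.issubset(quants.columns):
        raise ValueError(f"quants needs columns {sorted(required)}")
    animal = (quants
              .groupby(["group", "day", "hemisphere", "subject_id"], observed=True)
              [["percent_area", "mean_object_size_um2"]]
              .mean()
              .reset_index())
    rows = []
    for (group, day, hemi), sub in animal.groupby(["group", "day", "hemisphere"],
                                                  observed=True):
        if len(sub) == 0:  # pragma: no cover - groupby never yields empties
            logger.warning("empty cell (%s, %s, %s) omitted", group, day, hemi)
            continue
        pa = sub["percent_area"].to_numpy()
        sz = sub["mean_object_size_um2"].to_numpy()
        rows.append({
            "group": group, "day": day, "hemisphere": hemi,
            "percent_area_mean": float(pa.mean()),
            "percent_area_sd": float(pa.std(ddof=1)) if len(pa) > 1 else math.nan,
            "object_size_mean_um2": float(np.nanmean(sz)),
            "object_size_sd_um2": (float(np.nanstd(sz, ddof=1))
                                   if len(sz) > 1 else math.nan),
            "n_animals": int(len(sub)),
        })
    return pd.DataFrame(rows)


def fold_reduction(day2_a: float, day7_a: float,
                   day2_b: float, day7_b: float) -> float:
    """Ratio of day-2 -> day-7 decreases: (a2 - a7) / (b2 - b7).

    Signs are preserved (a negative "reduction" is an increase); a zero
    reference decrease is an error.
    """
    denom = day2_b - day7_b
    if denom == 0:
        raise ZeroDivisionError("reference group shows no day-2 to day-7 change")
    return (day2_a - day7_a) / denom
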