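"""Condensate partition coefficients and nuclear heterogeneity from images.

The nucleoplasmic reference intensity for each labeled nucleolus is taken
from a rim built with the Euclidean distance transform: pixels whose
distance to the nearest nucleolus lies in (inner - 1, outer] px, assigned
to the nearest label and excluding all nucleolus pixels.  K = (nucleolus
mean - background) / (rim mean - background), with the background measured
in a rectangular ROI outside the cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "LabeledImage",
    "PartitionResult",
    "make_rim",
    "measure_partition_coefficients",
    "normalize_k",
    "nuclear_cv",
    "px_to_physical",
    "naive_threshold_labels",
]

DEFAULT_MIN_AREA = 1000.0   # px^2
DEFAULT_FLOOR = 20.0        # nucleolus mean must exceed floor x background
DEFAULT_INNER = 1
DEFAULT_OUTER = 6


@dataclass
class LabeledImage:
    intensity: np.ndarray
    labels: np.ndarray
    pixel_size_nm: float
    background_roi: tuple[int, int, int, int]  # (row, col, height, width)
    nucleus_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.intensity.shape != self.labels.shape:
            raise ValueError("intensity and label mask shapes differ")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if (self.labels < 0).any():
            raise ValueError("labels must be non-negative integers")


def make_rim(
    mask: np.ndarray, inner: int = DEFAULT_INNER, outer: int = DEFAULT_OUTER
) -> tuple[np.ndarray, dict[int, bool]]:
    """Per-label rim mask from the Euclidean distance transform.

    Returns ``(rim_labels, clipped)``: rim pixels carry the label of the
    nearest nucleolus; a label is flagged clipped when its region touches
    the image border (its rim is truncated there).  Rim membership:
    background pixels with distance to the nearest labeled pixel in
    ``(inner - 1, outer]``.
    """
    if inner >= outer:
        raise ValueError("inner must be < outer")
    labs = np.unique(mask)
    labs = labs[labs > 0]
    if labs.size == 0:
        raise ValueError("label mask is empty")
    dist, (iy, ix) = ndimage.distance_transform_edt(
        mask == 0, return_indices=True
    )
    nearest = mask[iy, ix]
    rim_zone = (mask == 0) & (dist > inner - 1) & (dist <= outer)
    rim = np.where(rim_zone, nearest, 0).astype(mask.dtype)

    clipped = {}
    border = np.zeros_like(mask, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    for lab in labs:
        region = mask == lab
        near_border = ndimage.binary_dilation(
            region, iterations=int(np.ceil(outer))
        )
        clipped[int(lab)] = bool((near_border & border).any() or (region & border).any())
    return rim, clipped


@dataclass
class PartitionResult:
    label: int
    nucleolus_mean: float
    rim_mean: float
    background: float
    k: float | None
    area_px2: float
    area_um2: float
    passed_filters: bool
    reasons: list[str] = field(default_factory=list)


def _roi_mean(intensity: np.ndarray, roi: tuple[int, int, int, int]) -> float:
    r, c, h, w = roi
    if r < 0 or c < 0 or r + h > intensity.shape[0] or c + w > intensity.shape[1]:
        raise ValueError("background ROI extends outside the frame")
    return float(intensity[r:r + h, c:c + w].mean())


def measure_partition_coefficients(
    img: LabeledImage,
    min_area_px2: float = DEFAULT_MIN_AREA,
    intensity_floor: float = DEFAULT_FLOOR,
    inner: int = DEFAULT_INNER,
    outer: int = DEFAULT_OUTER,
) -> list[PartitionResult]:
    """Background-subtracted partition coefficient per labeled nucleolus.

    Filters: area strictly greater than ``min_area_px2`` and nucleolus mean
    above ``intensity_floor`` times the mean background.  A rim mean at or
    below background leaves K undefined with the reason recorded.
    """
    bg = _roi_mean(img.intensity, img.background_roi)
    r, c, h, w = img.background_roi
    if (img.labels[r:r + h, c:c + w] > 0).any():
        raise ValueError("background ROI overlaps a labeled region")
    rim, clipped = make_rim(img.labels, inner=inner, outer=outer)
    results = []
    for lab in np.unique(img.labels):
        if lab == 0:
            continue
        region = img.labels == lab
        rim_px = rim == lab
        nuc_mean = float(img.intensity[region].mean())
        rim_mean = float(img.intensity[rim_px].mean()) if rim_px.any() else np.nan
        area = float(region.sum())
        reasons = []
        if area <= min_area_px2:
            reasons.append(f"area {area:.0f} px2 <= {min_area_px2:.0f}")
        if bg > 0 and nuc_mean <= intensity_floor * bg:
            reasons.append(f"nucleolus mean <= {intensity_floor:g}x background")
        if clipped.get(int(lab)):
            reasons.append("rim clipped at image border")
        k: float | None
        if not np.isfinite(rim_mean) or rim_mean - bg <= 0:
            k = None
            reasons.append("rim mean <= background")
        elif nuc_mean - bg <= 0:
            k = None
            reasons.append("nucleolus mean <= background")
        else:
            k = (nuc_mean - bg) / (rim_mean - bg)
        results.append(
            PartitionResult(
                label=int(lab),
                nucleolus_mean=nuc_mean,
                rim_mean=rim_mean,
                background=bg,
                k=k,
                area_px2=area,
                area_um2=px_to_physical(area, img.pixel_size_nm, area=True),
                passed_filters=not reasons and k is not None,
                reasons=reasons,
            )
        )
    return results


def normalize_k(
    results: list[PartitionResult], reference: list[PartitionResult]
) -> pd.DataFrame:
    """K relative to the median K of the (filter-passing) reference set."""
    ref_ks = [r.k for r in reference if r.passed_filters and r.k is not None]
    if not ref_ks:
        raise ValueError("reference set empty after filters")
    ref_median = float(np.median(ref_ks))
    rows = [
        {
            "label": r.label,
            "k": r.k,
            "relative_k": (r.k / ref_median) if r.k is not None else np.nan,
            "passed_filters": r.passed_filters,
        }
        for r in results
    ]
    return pd.DataFrame(rows).set_index("label")


def nuclear_cv(
    img: LabeledImage,
    nucleus_mask: np.ndarray | None = None,
    subtract_background: bool = True,
    ddof: int = 1,
) -> float:
    """Coefficient of variation (s.d. / mean) of the nuclear signal.

    Sample standard deviation by default (``ddof=0`` for the population
    variant).  Returns NaN when the background-subtracted mean is <= 0.
    """
    mask = nucleus_mask if nucleus_mask is not None else img.nucleus_mask
    if mask is None or not mask.any():
        raise ValueError("nucleus mask is empty")
    vals = img.intensity[mask].astype(float)
    if subtract_background:
        vals = vals - _roi_mean(img.intensity, img.background_roi)
    mean = vals.mean()
    if mean <= 0:
        return float("nan")
    return float(vals.std(ddof=ddof) / mean)


def px_to_physical(value: float, pixel_size_nm: float, area: bool = False) -> float:
    """Pixels to micrometres (or px^2 to um^2 with ``area=True``)."""
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be positive")
    um_per_px = pixel_size_nm / 1000.0
    return value * (um_per_px**2 if area else um_per_px)


def naive_threshold_labels(intensity: np.ndarray, min_px: int = 9) -> np.ndarray:
    """Otsu threshold + connected components.

    Convenience plumbing only — NOT the segmentation used in the original
    workflow (which relied on an external local-adaptive-threshold tool);
    label masks should normally be supplied as inputs.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label as cc_label

    thr = threshold_otsu(intensity)
    lab = cc_label(intensity > thr)
    for l in np.unique(lab):
        if l and (lab == l).sum() < min_px:
            lab[lab == l] = 0
    return lab
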