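"""Per-sperm stain measurements: acrosome area and nuclear vacuoles.

The acrosome is quantified as the PNA-positive area inside (a slightly
dilated copy of) the head mask, in µm². Nuclear vacuoles are detected as
dark connected components in the nuclear-stain channel: pixels inside the
eroded head whose intensity falls below ``(1 - rel_intensity_drop)`` times
the median head intensity, size-filtered to exclude single-pixel noise and
whole-head dropouts. Group-level vacuole prevalence is reported with a
Wilson 95% binomial interval.

Both measurements use relative criteria (Otsu or a median-relative drop),
so they are invariant to image-wide affine intensity rescaling; absolute
staining units are not comparable across instruments anyway, and only
relative group contrasts are interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import filters, measure, morphology
from statsmodels.stats.proportion import proportion_confint

from ._exceptions import MeasurementError, ParameterError

__all__ = ["AcrosomeMeasure", "VacuoleMeasure", "acrosome_area", "detect_vacuoles", "prevalence"]


@dataclass(frozen=True)
class AcrosomeMeasure:
    """Acrosome (PNA-positive) area of one sperm head."""

    specimen_id: str
    positive_px: int
    area_um2: float
    head_area_um2: float

    @property
    def ratio(self) -> float:
        return self.area_um2 / self.head_area_um2


@dataclass(frozen=True)
class VacuoleMeasure:
    """Nuclear vacuoles of one sperm head: count, centroids, areas."""

    specimen_id: str
    count: int
    centroids: tuple        # (row, col) per vacuole
    areas_px: tuple

    @property
    def has_vacuole(self) -> bool:
        return self.count >= 1


def acrosome_area(
    pna_channel,
    head_mask,
    pixel_size: float,
    method: str = "otsu",
    threshold: float | None = None,
    specimen_id: str = "",
    margin_px: int = 2,
) -> AcrosomeMeasure:
    """Measure the PNA-positive area within the (dilated) head mask.

    The head mask is dilated by ``margin_px`` before thresholding so a
    crescent hugging the head boundary is not clipped by segmentation
    jitter. ``method='otsu'`` thresholds the within-region intensities;
    a constant region yields zero positive area.
    """
    pna = np.asarray(pna_channel)
    mask = np.asarray(head_mask).astype(bool)
    if pna.shape != mask.shape:
        raise ParameterError(f"channel {pna.shape} and mask {mask.shape} shapes differ")
    if pixel_size <= 0:
        raise ParameterError(f"pixel_size must be > 0, got {pixel_size}")
    if not mask.any():
        raise MeasurementError("empty head mask")

    region = morphology.dilation(mask, morphology.disk(margin_px))
    vals = pna[region]
    if method == "otsu":
        thr = filters.threshold_otsu(vals) if vals.max() > vals.min() else np.inf
    elif method == "fixed":
        if threshold is None:
            raise ParameterError("method='fixed' requires a threshold")
        thr = threshold
    else:
        raise ParameterError(f"unknown method {method!r}; use 'otsu' or 'fixed'")
    positive = int(np.count_nonzero((pna > thr) & region))
    px2 = pixel_size**2
    return AcrosomeMeasure(
        specimen_id=specimen_id,
        positive_px=positive,
        area_um2=positive * px2,
        head_area_um2=int(mask.sum()) * px2,
    )


def detect_vacuoles(
    nuclear_channel,
    head_mask,
    min_area: float = 4.0,
    max_area: float | None = None,
    rel_intensity_drop: float = 0.5,
    specimen_id: str = "",
) -> VacuoleMeasure:
    """Detect nuclear vacuoles as dark blobs inside the head.

    Candidate pixels lie inside the 1 px-eroded head mask with intensity
    below ``(1 - rel_intensity_drop) * median(head intensity)``; connected
    components are kept if their area is in ``[min_area, max_area]``
    (``max_area`` defaults to 25% of the head area). Centroids are
    (row, col).
    """
    img = np.asarray(nuclear_channel, dtype=float)
    mask = np.asarray(head_mask).astype(bool)
    if img.shape != mask.shape:
        raise ParameterError(f"channel {img.shape} and mask {mask.shape} shapes differ")
    if not mask.any():
        raise MeasurementError("empty head mask")
    if not 0.0 < rel_intensity_drop < 1.0:
        raise ParameterError(
            f"rel_intensity_drop must be in (0, 1), got {rel_intensity_drop}"
        )

    if max_area is None:
        max_area = 0.25 * float(mask.sum())
    eroded = morphology.erosion(mask, morphology.disk(1))
    med = float(np.median(img[mask]))
    dark = eroded & (img < (1.0 - rel_intensity_drop) * med)

    centroids, areas = [], []
    for region in measure.regionprops(measure.label(dark, connectivity=2)):
        if min_area <= region.area <= max_area:
            centroids.append(tuple(region.centroid))
            areas.append(int(region.area))
    return VacuoleMeasure(
        specimen_id=specimen_id,
        count=len(centroids),
        centroids=tuple(centroids),
        areas_px=tuple(areas),
    )


def prevalence(records) -> tuple[float, tuple[float, float]]:
    """Fraction of heads with >= 1 vacuole, with a Wilson 95% CI."""
    records = list(records)
    if not records:
        raise ParameterError("cannot compute prevalence of an empty group")
    k = sum(r.has_vacuole for r in records)
    n = len(records)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return k / n, (float(lo), float(hi))
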