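"""Ventilation-inhomogeneity indices on a ΔZ image restricted to an ROI.

Global inhomogeneity (GI) index::

    GI = Σ_ROI |ΔZ_xy − median(ΔZ_lung)| / Σ_ROI ΔZ_xy

Coefficient of variation (CV)::

    CV = SD(ΔZ_lung) / mean(ΔZ_lung)

with ΔZ_lung the ROI pixel values.  Both are dimensionless and invariant
under positive rescaling of the image.  Negative ΔZ pixels inside the ROI
enter the formulas exactly as written — no clipping — so the denominators
can in principle vanish; that case raises
:class:`~eitroi.errors.DegenerateDenominatorError` and is recorded by the
pipeline as a flagged (missing) cell rather than silently skipped.
"""

from __future__ import annotations

import numpy as np

from .errors import (
    DegenerateDenominatorError,
    EmptyRoiError,
    InsufficientPixelsError,
)
from .frames import DeltaZImage, ROIMask


def _roi_values(image: DeltaZImage, roi: ROIMask | np.ndarray) -> np.ndarray:
    included = roi.included if isinstance(roi, ROIMask) else np.asarray(roi, dtype=bool)
    return image.values[included & image.valid]


def gi_values(values: np.ndarray) -> float:
    """GI of a flat vector of ROI pixel values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EmptyRoiError("GI index requested on an empty ROI")
    denom = values.sum()
    if denom == 0.0:
        raise DegenerateDenominatorError("sum of ROI ΔZ values is zero; GI undefined")
    return float(np.abs(values - np.median(values)).sum() / denom)


def cv_values(values: np.ndarray, ddof: int = 1) -> float:
    """CV of a flat vector of ROI pixel values (sample SD by default)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientPixelsError(
            f"CV needs at least 2 ROI pixels, got {values.size}"
        )
    mean = values.mean()
    if mean == 0.0:
        raise DegenerateDenominatorError("mean of ROI ΔZ values is zero; CV undefined")
    return float(values.std(ddof=ddof) / mean)


def gi_index(image: DeltaZImage, roi: ROIMask | np.ndarray) -> float:
    """Global inhomogeneity index of ``image`` over ``roi``.

    The median of an even pixel count is the mean of the two central order
    statistics.  Zero for a constant-valued ROI.
    """
    return gi_values(_roi_values(image, roi))


def coefficient_of_variation(
    image: DeltaZImage, roi: ROIMask | np.ndarray, ddof: int = 1
) -> float:
    """SD-to-mean ratio of ``image`` over ``roi``.

    ``ddof=1`` (sample SD, the convention of common desktop statistics
    packages) by default; pass ``ddof=0`` for the population SD.
    """
    return cv_values(_roi_values(image, roi), ddof=ddof)
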