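"""Region-of-interest definitions: no-fROI, fROI, fROI-heart and LAEM.

The functional ROI (fROI) keeps pixels whose ΔZ exceeds a cutoff expressed
as a fraction *t* of the image's dynamic range::

    ΔZ_max  = max(ΔZ_lung) − min(ΔZ_lung)
    cutoff  = ΔZ_max · t + min(ΔZ_lung)

where ΔZ_lung is the set of valid-pixel values (minima may be negative;
anchoring the cutoff at the true minimum rather than at zero is essential
when out-of-phase pixels are present).

The lung area estimation method (LAEM) mirrors the fROI left–right with a
Boolean OR — lungs are roughly symmetric, so a defect that silences one
side is recovered from its mirror — and then subtracts the cardiac area,
detected in the frequency domain: each pixel trace is band-pass filtered
±20% around the subject's heart rate, and pixels whose cardiac-band
excursion exceeds 50% of the image-wide maximum are deemed cardiac.
fROI-heart is the fROI minus that same cardiac area, without mirroring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import EmptyImageError, InvalidParametersError
from .frames import DeltaZImage, FrameSequence, ROIMask

#: The study's threshold grid: 0.05 to 0.95 in steps of 0.05.
THRESHOLD_GRID: tuple[float, ...] = tuple(round(0.05 * k, 2) for k in range(1, 20))

#: ROI method names accepted throughout the package.
METHOD_NAMES: tuple[str, ...] = ("none", "froi", "froi_heart", "laem")


@dataclass(frozen=True)
class CardiacParams:
    """Cardiac-area detection parameters.

    band_fraction
        Relative half-width of the passband around the heart rate
        (0.20 → keep spectral content within ±20% of f_heart).
    amplitude_fraction
        A pixel is cardiac when its cardiac-band excursion exceeds this
        fraction of the maximum excursion over valid pixels (default 0.50).
    metric
        ``"ptp"`` — peak-to-peak of the filtered trace (default), or
        ``"rms"`` — root-mean-square, for sensitivity analyses.
    """

    band_fraction: float = 0.20
    amplitude_fraction: float = 0.50
    metric: str = "ptp"

    def __post_init__(self) -> None:
        if not 0.0 < self.band_fraction < 1.0:
            raise InvalidParametersError(
                f"band_fraction must be in (0, 1), got {self.band_fraction}"
            )
        if not 0.0 < self.amplitude_fraction <= 1.0:
            raise InvalidParametersError(
                f"amplitude_fraction must be in (0, 1], got {self.amplitude_fraction}"
            )
        if self.metric not in ("ptp", "rms"):
            raise InvalidParametersError(f"metric must be 'ptp' or 'rms', got {self.metric!r}")


def _check_threshold(t: float) -> float:
    t = float(t)
    if not 0.0 <= t <= 1.0:
        raise InvalidParametersError(f"threshold fraction must be in [0, 1], got {t}")
    return t


def froi_cutoff(image: DeltaZImage, t: float) -> float:
    """ΔZ cutoff for threshold fraction ``t``: ``(max − min)·t + min`` over valid pixels."""
    t = _check_threshold(t)
    vals = image.lung_values()
    if vals.size == 0:
        raise EmptyImageError("ΔZ image has no valid pixels")
    lo, hi = float(vals.min()), float(vals.max())
    return (hi - lo) * t + lo


def froi_mask(image: DeltaZImage, t: float) -> ROIMask:
    """Functional ROI: valid pixels with ΔZ strictly above the cutoff."""
    cutoff = froi_cutoff(image, t)
    with np.errstate(invalid="ignore"):
        included = image.valid & (np.nan_to_num(image.values, nan=-np.inf) > cutoff)
    return ROIMask(included)


def mirror_mask(mask: ROIMask, valid: np.ndarray | None = None) -> ROIMask:
    """Left–right symmetrisation by Boolean OR with the column-reflected mask.

    The result is a superset of the input, invariant under column
    reflection, and (when ``valid`` is given) intersected with the valid
    region, which is itself symmetric.
    """
    out = mask.included | mask.included[:, ::-1]
    if valid is not None:
        out = out & np.asarray(valid, dtype=bool)
    return ROIMask(out)


def cardiac_amplitudes(
    seq: FrameSequence,
    params: CardiacParams = CardiacParams(),
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pixel cardiac-band excursion of the impedance trace.

    Each pixel trace is detrended (the straight line through its first and
    last sample, then the mean, is removed) and ideally band-pass filtered
    by zeroing every discrete Fourier component outside
    ``[(1−b)·f_heart, (1+b)·f_heart]``; the returned grid holds the
    peak-to-peak excursion (or RMS, per ``params.metric``) of the filtered
    trace, zero outside the valid region.

    The detrend matters: a maneuver trace is a monotonic ramp, and the
    DFT's implicit periodic extension turns its end-to-start jump into
    broadband leakage (∝ 1/f) that would otherwise swamp the cardiac band
    in strongly ventilated pixels.  Removing the endpoint-anchored line
    cancels that jump exactly while perturbing an in-band oscillation by
    well under the 5% tolerance the detection is specified to.
    """
    f_c = seq.heart_rate / 60.0
    lo = (1.0 - params.band_fraction) * f_c
    hi = (1.0 + params.band_fraction) * f_c
    nyquist = seq.sample_rate / 2.0
    if hi >= nyquist:
        raise InvalidParametersError(
            f"cardiac passband upper edge {hi:.3f} Hz is at/above Nyquist {nyquist:.3f} Hz"
        )
    if seq.duration < 3.0 / f_c:
        warnings.warn(
            f"recording {seq.duration:.1f}s covers fewer than 3 cardiac periods; "
            "cardiac-area detection may be unreliable",
            stacklevel=2,
        )
    if valid is None:
        valid = np.ones(seq.shape, dtype=bool)
    valid = np.asarray(valid, dtype=bool)

    n = seq.n_frames
    ramp01 = (np.arange(n) / (n - 1))[:, None, None]
    line = seq.frames[0] + (seq.frames[-1] - seq.frames[0]) * ramp01
    x = seq.frames - line
    x = x - x.mean(axis=0)
    spectrum = np.fft.rfft(x, axis=0)
    freqs = np.fft.rfftfreq(seq.n_frames, d=1.0 / seq.sample_rate)
    spectrum[(freqs < lo) | (freqs > hi)] = 0.0
    filtered = np.fft.irfft(spectrum, n=seq.n_frames, axis=0)

    if params.metric == "ptp":
        amp = filtered.max(axis=0) - filtered.min(axis=0)
    else:
        amp = np.sqrt(np.mean(filtered**2, axis=0))
    return np.where(valid, amp, 0.0)


def cardiac_mask(
    seq: FrameSequence,
    params: CardiacParams = CardiacParams(),
    valid: np.ndarray | None = None,
) -> ROIMask:
    """Pixels whose cardiac-band excursion strictly exceeds the 50% rule.

    Included iff amplitude > ``amplitude_fraction`` × (maximum amplitude
    over valid pixels).  If nothing oscillates in the cardiac band the mask
    is empty.
    """
    amp = cardiac_amplitudes(seq, params, valid)
    peak = float(amp.max())
    if peak <= 0.0:
        return ROIMask(np.zeros(seq.shape, dtype=bool))
    return ROIMask(amp > params.amplitude_fraction * peak)


def no_froi_mask(image: DeltaZImage) -> ROIMask:
    """The whole valid region (912 pixels on the default 32×32 grid)."""
    return ROIMask(image.valid.copy())


def froi_heart_mask(
    image: DeltaZImage,
    seq: FrameSequence,
    t: float,
    params: CardiacParams = CardiacParams(),
) -> ROIMask:
    """fROI with the cardiac area removed (no mirroring)."""
    return froi_mask(image, t) - cardiac_mask(seq, params, image.valid)


def laem_mask(
    image: DeltaZImage,
    seq: FrameSequence,
    t: float,
    params: CardiacParams = CardiacParams(),
) -> ROIMask:
    """Lung area estimation method: mirror the fROI, then subtract the cardiac area."""
    sym = mirror_mask(froi_mask(image, t), image.valid)
    return sym - cardiac_mask(seq, params, image.valid)


def roi_for_method(
    method: str,
    image: DeltaZImage,
    seq: FrameSequence,
    t: float | None = None,
    params: CardiacParams = CardiacParams(),
    cardiac: ROIMask | None = None,
) -> ROIMask:
    """Dispatch on a method name; ``cardiac`` may be precomputed and reused."""
    if method == "none":
        return no_froi_mask(image)
    if t is None:
        raise InvalidParametersError(f"method {method!r} needs a threshold fraction")
    if method == "froi":
        return froi_mask(image, t)
    if cardiac is None:
        cardiac = cardiac_mask(seq, params, image.valid)
    if method == "froi_heart":
        return froi_mask(image, t) - cardiac
    if method == "laem":
        return mirror_mask(froi_mask(image, t), image.valid) - cardiac
    raise InvalidParametersError(f"unknown ROI method {method!r}; expected one of {METHOD_NAMES}")
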