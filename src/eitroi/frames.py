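"""Frame sequences, ΔZ images and the canonical valid-pixel region.

EIT (electrical impedance tomography) devices deliver a time series of
reconstructed 2-D grids of relative impedance change (ΔZ), here 32×32 at
25 frames/s.  During a low-flow inflation maneuver, regional ventilation
shows up as a per-pixel impedance excursion; the "max–min image" condenses
the maneuver into one ΔZ value per pixel.

Coordinate convention (fixed; required for left–right mirroring):
row 0 = ventral (anterior), column 0 = the subject's right side,
row-major, 0-based.  File writers record this convention as metadata.

The reconstruction algorithm only produces meaningful values inside a
quasi-circular region of 912 of the 1024 grid positions; the device's
exact pixel set is not public, so :func:`default_pixel_mask` builds a
deterministic radial stand-in with exactly that count, and device-specific
masks can be supplied from a CSV file instead.
"""

from __future__ import annotations

import enum
import functools
import math
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    FormatError,
    InvalidGeometryError,
    InvalidParametersError,
    MissingMetadataError,
)

#: Number of valid pixels in the device's reconstructed 32×32 image.
N_VALID_PIXELS = 912

#: Default acquisition rate, frames per second.
DEFAULT_SAMPLE_RATE = 25.0

_CONVENTION = "row0=ventral,col0=subject-right,row-major,0-based"


class Group(str, enum.Enum):
    """Subject group label: ARDS (positive class) or pulmonary-healthy control."""

    ARDS = "ARDS"
    CONTROL = "CONTROL"

    @classmethod
    def parse(cls, value: "Group | str") -> "Group":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().upper())
        except ValueError as exc:
            raise FormatError(f"unknown group label {value!r}") from exc


@dataclass
class FrameSequence:
    """A subject's time-ordered ΔZ frames plus the metadata the analysis needs.

    Parameters
    ----------
    frames
        Array of shape ``(T, rows, cols)``, dimensionless relative impedance
        change.  ``T >= 2``.
    sample_rate
        Frames per second (> 0).
    heart_rate
        Beats per minute.  Required: cardiac-area detection filters each
        pixel trace around this frequency, and the 20%-wide passband must
        stay below Nyquist (``1.2 * heart_rate / 60 < sample_rate / 2``).
    subject_id
        Opaque label.
    group
        :class:`Group` membership.
    """

    frames: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    heart_rate: float = 70.0
    subject_id: str = "anonymous"
    group: Group = Group.CONTROL

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise FormatError(
                f"frames must be a (T, rows, cols) array, got ndim={self.frames.ndim}"
            )
        if self.frames.shape[0] < 2:
            raise EmptyInputError(
                f"need at least 2 frames, got {self.frames.shape[0]}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise FormatError("frames contain non-finite values")
        if not self.sample_rate > 0:
            raise InvalidParametersError(f"sample_rate must be > 0, got {self.sample_rate}")
        if not self.heart_rate > 0:
            raise InvalidParametersError(f"heart_rate must be > 0, got {self.heart_rate}")
        if not 1.2 * self.heart_rate / 60.0 < self.sample_rate / 2.0:
            raise InvalidParametersError(
                f"cardiac passband (1.2 × {self.heart_rate}/60 Hz) reaches the "
                f"Nyquist frequency {self.sample_rate / 2.0} Hz"
            )
        self.group = Group.parse(self.group)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_frames / self.sample_rate


@dataclass
class DeltaZImage:
    """Per-pixel ΔZ over a maneuver, defined on the valid reconstruction region.

    ``values`` is a float grid; entries outside ``valid`` are NaN.  Negative
    values are legitimate: pixels whose impedance falls while the lung
    inflates (out-of-phase, e.g. mediastinal tissue) carry negative ΔZ.
    """

    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape or self.values.ndim != 2:
            raise FormatError(
                f"values {self.values.shape} and valid {self.valid.shape} must be "
                "equal-shape 2-D grids"
            )
        if not np.all(np.isfinite(self.values[self.valid])):
            raise FormatError("non-finite ΔZ on a valid pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def lung_values(self) -> np.ndarray:
        """The flat vector of ΔZ over the valid region (ΔZ_lung)."""
        return self.values[self.valid]


@dataclass
class ROIMask:
    """Boolean pixel set; always a subset of its image's valid region."""

    included: np.ndarray

    def __post_init__(self) -> None:
        self.included = np.asarray(self.included, dtype=bool)
        if self.included.ndim != 2:
            raise FormatError("ROI mask must be a 2-D boolean grid")

    @property
    def count(self) -> int:
        return int(self.included.sum())

    def __and__(self, other: "ROIMask") -> "ROIMask":
        return ROIMask(self.included & other.included)

    def __or__(self, other: "ROIMask") -> "ROIMask":
        return ROIMask(self.included | other.included)

    def __sub__(self, other: "ROIMask") -> "ROIMask":
        return ROIMask(self.included & ~other.included)

    def issubset(self, other: "ROIMask") -> bool:
        return bool(np.all(~self.included | other.included))


# ---------------------------------------------------------------------------
# Valid-region mask
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=32)
def _default_pixel_mask_cached(rows: int, cols: int, n_pixels: int) -> np.ndarray:
    cy, cx = rows / 2.0, cols / 2.0
    r = np.arange(rows)[:, None] + 0.5 - cy
    c = np.arange(cols)[None, :] + 0.5 - cx
    dist = np.hypot(r, c)

    flat = np.sort(dist.ravel())
    radius = flat[n_pixels - 1]  # smallest radius admitting >= n_pixels
    mask = dist <= radius
    excess = int(mask.sum()) - n_pixels
    if excess:
        # All trimmable pixels sit on the boundary ring at exactly `radius`
        # (mirror pairs share a distance bit-for-bit since the column offset
        # only changes sign).  Trim mirror pairs together, ordered by
        # ascending polar angle then row-major, midline pixels first when the
        # remainder is odd.
        ring = [
            (rr, cc)
            for rr in range(rows)
            for cc in range(cols)
            if dist[rr, cc] == radius
        ]
        angle = {
            (rr, cc): math.atan2(rr + 0.5 - cy, cc + 0.5 - cx) % (2 * math.pi)
            for rr, cc in ring
        }
        ring.sort(key=lambda p: (angle[p], p))
        if excess % 2:
            # a single pixel must go on the vertical midline to keep symmetry;
            # prefer a midline ring pixel, else the farthest included one
            midline = [p for p in ring if p[1] == cols - 1 - p[1]]
            if not midline:
                midline = sorted(
                    ((rr, cc) for rr, cc in np.argwhere(mask).tolist()
                     if cc == cols - 1 - cc),
                    key=lambda p: (-dist[p[0], p[1]], p),
                )
            if not midline:
                raise InvalidGeometryError(
                    f"cannot keep a left-right symmetric mask with {n_pixels} "
                    f"pixels on a {rows}x{cols} grid"
                )
            target = tuple(midline[0])
            mask[target] = False
            if target in ring:
                ring.remove(target)
            excess -= 1
        removed: set[tuple[int, int]] = set()
        for p in ring:
            if excess == 0:
                break
            if p in removed:
                continue
            mirror = (p[0], cols - 1 - p[1])
            if mirror == p:
                continue  # keep midline pixels once parity is fixed
            mask[p] = False
            mask[mirror] = False
            removed.update((p, mirror))
            excess -= 2
    mask.setflags(write=False)
    return mask


def default_pixel_mask(rows: int = 32, cols: int = 32, n_pixels: int | None = None) -> np.ndarray:
    """Deterministic quasi-circular valid-pixel mask.

    A pixel is included iff its center lies within the smallest radius (from
    the grid center) that admits at least ``n_pixels`` pixels; ties on the
    boundary ring are then trimmed — symmetric left/right pairs together —
    until exactly ``n_pixels`` remain, so the result is always left–right
    symmetric.

    Parameters
    ----------
    rows, cols
        Grid size; the device default is 32×32.
    n_pixels
        Target pixel count.  Defaults to 912 on the 32×32 grid and to the
        same area fraction (rounded to a symmetric-feasible count) elsewhere.
    """
    if rows < 2 or cols < 2:
        raise InvalidGeometryError(f"grid must be at least 2x2, got {rows}x{cols}")
    if n_pixels is None:
        if (rows, cols) == (32, 32):
            n_pixels = N_VALID_PIXELS
        else:
            n_pixels = int(round(rows * cols * N_VALID_PIXELS / 1024.0))
            if cols % 2 == 0 and n_pixels % 2:
                n_pixels -= 1
            n_pixels = max(n_pixels, 2 if cols % 2 == 0 else 1)
    if not 1 <= n_pixels <= rows * cols:
        raise InvalidGeometryError(
            f"n_pixels={n_pixels} not achievable on a {rows}x{cols} grid"
        )
    return _default_pixel_mask_cached(rows, cols, n_pixels).copy()


# ---------------------------------------------------------------------------
# Max–min image
# ---------------------------------------------------------------------------

def compute_max_min_image(
    seq: FrameSequence,
    valid: np.ndarray | None = None,
    *,
    signed: bool = True,
) -> DeltaZImage:
    """Condense a maneuver into a per-pixel ΔZ image.

    For every valid pixel the magnitude is the difference between the
    temporal maximum and minimum of that pixel's trace.  With
    ``signed=True`` (default) the value additionally carries a sign: pixels
    whose trace co-varies negatively with the global (valid-region mean)
    signal — impedance falling while the lung inflates — get negative ΔZ.
    This reproduces the negative out-of-phase pixels seen in clinical
    max–min images while leaving in-phase pixels at plain max − min.

    Both the magnitude and the sign are invariant to frame reordering and to
    adding a constant to every frame.
    """
    rows, cols = seq.shape
    if valid is None:
        if (rows, cols) == (32, 32):
            valid = default_pixel_mask(rows, cols)
        else:
            valid = np.ones((rows, cols), dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    if valid.shape != (rows, cols):
        raise FormatError(
            f"valid mask shape {valid.shape} does not match frames {rows, cols}"
        )

    magnitude = seq.frames.max(axis=0) - seq.frames.min(axis=0)
    if signed and valid.any():
        global_trace = seq.frames[:, valid].mean(axis=1)
        g = global_trace - global_trace.mean()
        x = seq.frames - seq.frames.mean(axis=0)
        cov = np.tensordot(g, x, axes=(0, 0))
        sign = np.where(cov < 0, -1.0, 1.0)
        values = sign * magnitude
    else:
        values = magnitude.astype(float)
    values = np.where(valid, values, np.nan)
    return DeltaZImage(values=values, valid=valid)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_HDF5_SUFFIXES = {".h5", ".hdf5", ".hdf"}
_CSV_HEADER = "eitroi-frames"


def write_frames(seq: FrameSequence, path: str | Path) -> Path:
    """Write a frame sequence; container chosen by suffix (.h5/.hdf5 or .csv).

    The HDF5 layout is one ``frames`` dataset of shape (T, rows, cols) with
    ``sample_rate``, ``heart_rate``, ``subject_id``, ``group`` and the
    coordinate convention as root attributes.  The CSV dialect (for small,
    hand-checkable fixtures) stores the same metadata in ``#``-prefixed
    header lines above ``frame,row,col,value`` records.
    """
    path = Path(path)
    if path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=seq.frames)
            f.attrs["sample_rate"] = seq.sample_rate
            f.attrs["heart_rate"] = seq.heart_rate
            f.attrs["subject_id"] = seq.subject_id
            f.attrs["group"] = seq.group.value
            f.attrs["convention"] = _CONVENTION
    elif path.suffix.lower() == ".csv":
        t, rows, cols = seq.frames.shape
        fr, rr, cc = np.meshgrid(
            np.arange(t), np.arange(rows), np.arange(cols), indexing="ij"
        )
        with open(path, "w", newline="") as fh:
            fh.write(f"# {_CSV_HEADER} 1\n")
            fh.write(f"# sample_rate: {seq.sample_rate!r}\n")
            fh.write(f"# heart_rate: {seq.heart_rate!r}\n")
            fh.write(f"# subject_id: {seq.subject_id}\n")
            fh.write(f"# group: {seq.group.value}\n")
            fh.write(f"# convention: {_CONVENTION}\n")
            fh.write("frame,row,col,value\n")
            for a, b, c, v in zip(
                fr.ravel(), rr.ravel(), cc.ravel(), seq.frames.ravel()
            ):
                fh.write(f"{a},{b},{c},{float(v)!r}\n")
    else:
        raise FormatError(f"unsupported frame container suffix: {path.suffix!r}")
    return path


def _read_frames_hdf5(path: Path) -> FrameSequence:
    with h5py.File(path, "r") as f:
        if "frames" not in f:
            raise FormatError(f"{path}: no 'frames' dataset")
        frames = np.asarray(f["frames"])
        if frames.ndim != 3:
            raise FormatError(f"{path}: 'frames' must be 3-D, got ndim={frames.ndim}")
        attrs = dict(f.attrs)
    for key in ("heart_rate", "sample_rate", "group"):
        if key not in attrs:
            raise MissingMetadataError(f"{path}: missing required metadata {key!r}")
    return FrameSequence(
        frames=frames,
        sample_rate=float(attrs["sample_rate"]),
        heart_rate=float(attrs["heart_rate"]),
        subject_id=str(attrs.get("subject_id", path.stem)),
        group=Group.parse(attrs["group"]),
    )


def _read_frames_csv(path: Path) -> FrameSequence:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    table = pd.read_csv(path, comment="#")
    required_cols = {"frame", "row", "col", "value"}
    if not required_cols.issubset(table.columns):
        raise FormatError(f"{path}: CSV must have columns {sorted(required_cols)}")
    for key in ("heart_rate", "sample_rate", "group"):
        if key not in meta:
            raise MissingMetadataError(f"{path}: missing required metadata {key!r}")

    frame_ids = np.sort(table["frame"].unique())
    if not np.array_equal(frame_ids, np.arange(len(frame_ids))):
        raise FormatError(f"{path}: frame indices must be contiguous from 0")
    rows = int(table["row"].max()) + 1
    cols = int(table["col"].max()) + 1
    frames = np.empty((len(frame_ids), rows, cols), dtype=float)
    expected = {(r, c) for r in range(rows) for c in range(cols)}
    for fid, sub in table.groupby("frame", sort=True):
        cells = set(zip(sub["row"].astype(int), sub["col"].astype(int)))
        if cells != expected or len(sub) != rows * cols:
            raise FormatError(
                f"{path}: frame {int(fid)} does not cover the {rows}x{cols} grid"
            )
        frames[int(fid), sub["row"].to_numpy(), sub["col"].to_numpy()] = (
            sub["value"].to_numpy()
        )
    return FrameSequence(
        frames=frames,
        sample_rate=float(meta["sample_rate"]),
        heart_rate=float(meta["heart_rate"]),
        subject_id=meta.get("subject_id", path.stem),
        group=Group.parse(meta["group"]),
    )


def read_frames(path: str | Path) -> FrameSequence:
    """Read a frame sequence written by :func:`write_frames`."""
    path = Path(path)
    if path.suffix.lower() in _HDF5_SUFFIXES:
        return _read_frames_hdf5(path)
    if path.suffix.lower() == ".csv":
        return _read_frames_csv(path)
    raise FormatError(f"unsupported frame container suffix: {path.suffix!r}")


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean grid as a CSV of 0/1 integers."""
    path = Path(path)
    np.savetxt(path, np.asarray(mask, dtype=int), fmt="%d", delimiter=",")
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 0/1 CSV grid as a boolean mask (e.g. a device-specific valid region)."""
    arr = np.atleast_2d(np.loadtxt(path, delimiter=",", dtype=float))
    if not np.isin(arr, (0.0, 1.0)).all():
        raise FormatError(f"{path}: mask entries must be 0 or 1")
    return arr.astype(bool)
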