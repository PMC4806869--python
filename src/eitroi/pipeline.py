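"""Study orchestration: threshold sweep, group statistics and report tables.

For every subject the maneuver is condensed to one ΔZ image; each ROI
method (no-fROI, fROI, fROI-heart, LAEM) is evaluated on the 19-point
threshold grid (0.05 … 0.95) and the GI index and CV are recorded per
cell.  Group discrimination (AUC with 95% CI and p, ARDS = positive
class), group means ± 95% CI, and per-threshold ROI pixel-count t-tests
are then computed over subjects, and everything is written as CSV tables
with a run manifest for provenance.

Degenerate cells (empty ROI at high thresholds, zero GI/CV denominators
from negative pixels) are flagged and excluded cell-wise, with the
exclusion count carried into every downstream table.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import EitRoiError, InsufficientDataError, InvalidParametersError
from .frames import FrameSequence, Group, default_pixel_mask
from .indices import coefficient_of_variation, gi_index
from .roi import (
    METHOD_NAMES,
    THRESHOLD_GRID,
    CardiacParams,
    cardiac_mask,
    roi_for_method,
)
from .stats import (
    auc,
    auc_ci,
    auc_p_value,
    bootstrap_auc_ci,
    group_mean_ci,
    unpaired_t_test,
)
from .frames import compute_max_min_image

logger = logging.getLogger("eitroi")

#: Columns of the long-format sweep table, in emission order.
SWEEP_COLUMNS = (
    "subject_id",
    "group",
    "method",
    "threshold",
    "index",
    "value",
    "n_pixels",
    "flag",
)

AUC_COLUMNS = (
    "threshold",
    "auc",
    "ci_low",
    "ci_high",
    "p",
    "n_ards",
    "n_control",
    "n_excluded",
)


@dataclass(frozen=True)
class StudyConfig:
    """Everything that parameterises the analysis (not the phantom)."""

    methods: tuple[str, ...] = METHOD_NAMES
    thresholds: tuple[float, ...] = THRESHOLD_GRID
    cardiac: CardiacParams = CardiacParams()
    sd_ddof: int = 1            # 1 = sample SD (default), 0 = population SD
    ci_method: str = "hanley"   # "hanley" or "bootstrap"
    n_bootstrap: int = 2000
    bootstrap_seed: int = 0
    signed_delta_z: bool = True

    def __post_init__(self) -> None:
        for m in self.methods:
            if m not in METHOD_NAMES:
                raise InvalidParametersError(
                    f"unknown method {m!r}; expected subset of {METHOD_NAMES}"
                )
        if self.ci_method not in ("hanley", "bootstrap"):
            raise InvalidParametersError(
                f"ci_method must be 'hanley' or 'bootstrap', got {self.ci_method!r}"
            )
        for t in self.thresholds:
            if not 0.0 <= t <= 1.0:
                raise InvalidParametersError(f"threshold {t} outside [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        d["thresholds"] = list(self.thresholds)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        data = dict(data)
        if "cardiac" in data and isinstance(data["cardiac"], dict):
            data["cardiac"] = CardiacParams(**data["cardiac"])
        for key in ("methods", "thresholds"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _threshold_key(t: float | str | None) -> str:
    return "none" if t in (None, "none") else f"{float(t):.2f}"


@dataclass
class ReportBundle:
    """All study outputs: sweep table, AUC tables, summaries, pixel counts."""

    sweep: pd.DataFrame
    auc_tables: dict[tuple[str, str], pd.DataFrame]
    group_summary: pd.DataFrame
    pixel_counts: pd.DataFrame
    config: StudyConfig


# ---------------------------------------------------------------------------
# Per-subject sweep
# ---------------------------------------------------------------------------

def analyze_subject(
    seq: FrameSequence,
    config: StudyConfig = StudyConfig(),
    valid: np.ndarray | None = None,
) -> pd.DataFrame:
    """One subject's sweep rows: (method × threshold × index) → value, pixel count.

    The ΔZ image and the cardiac area are computed once and reused across
    thresholds.  Cells whose index is undefined are emitted with
    ``value = NaN`` and the error class name in ``flag``.
    """
    image = compute_max_min_image(seq, valid, signed=config.signed_delta_z)
    cardiac = None
    if any(m in config.methods for m in ("froi_heart", "laem")):
        cardiac = cardiac_mask(seq, config.cardiac, image.valid)

    records: list[tuple] = []
    for method in config.methods:
        thresholds: tuple = ("none",) if method == "none" else config.thresholds
        for t in thresholds:
            t_arg = None if t == "none" else t
            try:
                roi = roi_for_method(
                    method, image, seq, t_arg, config.cardiac, cardiac
                )
                n_pixels = roi.count
            except EitRoiError as exc:
                logger.info(
                    "%s: ROI %s@%s failed: %s", seq.subject_id, method, t, exc
                )
                for index in ("GI", "CV"):
                    records.append(
                        (seq.subject_id, seq.group.value, method, _threshold_key(t),
                         index, np.nan, 0, type(exc).__name__)
                    )
                continue
            for index in ("GI", "CV"):
                try:
                    if index == "GI":
                        value = gi_index(image, roi)
                    else:
                        value = coefficient_of_variation(image, roi, ddof=config.sd_ddof)
                    flag = ""
                except EitRoiError as exc:
                    logger.info(
                        "%s: %s %s@%s degenerate: %s",
                        seq.subject_id, index, method, t, exc,
                    )
                    value, flag = np.nan, type(exc).__name__
                records.append(
                    (seq.subject_id, seq.group.value, method, _threshold_key(t),
                     index, value, n_pixels, flag)
                )
    return pd.DataFrame.from_records(records, columns=SWEEP_COLUMNS)


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------

def _cell_auc_row(
    cell: pd.DataFrame, threshold: str, config: StudyConfig, cell_tag: str
) -> tuple:
    ok = cell[(cell["flag"] == "") & cell["value"].notna()]
    pos = ok.loc[ok["group"] == Group.ARDS.value, "value"].to_numpy()
    neg = ok.loc[ok["group"] == Group.CONTROL.value, "value"].to_numpy()
    n_excluded = len(cell) - len(ok)
    if pos.size == 0 or neg.size == 0:
        return (threshold, np.nan, np.nan, np.nan, np.nan, pos.size, neg.size, n_excluded)
    a = auc(pos, neg)
    if config.ci_method == "bootstrap":
        seed = np.random.SeedSequence(
            [config.bootstrap_seed, zlib.crc32(cell_tag.encode())]
        )
        lo, hi = bootstrap_auc_ci(pos, neg, n_boot=config.n_bootstrap, seed=seed)
    else:
        lo, hi = auc_ci(a, pos.size, neg.size)
    p = auc_p_value(pos, neg)
    return (threshold, a, lo, hi, p, pos.size, neg.size, n_excluded)


def summarize_sweep(sweep: pd.DataFrame, config: StudyConfig = StudyConfig()) -> ReportBundle:
    """Aggregate a sweep table over subjects into the full report bundle."""
    sweep = sweep.copy()
    sweep["flag"] = sweep["flag"].fillna("")
    groups_present = set(sweep["group"].unique())
    for g in (Group.ARDS.value, Group.CONTROL.value):
        if g not in groups_present:
            raise InsufficientDataError(f"no subjects in group {g}")

    auc_tables: dict[tuple[str, str], pd.DataFrame] = {}
    summary_rows: list[tuple] = []
    count_rows: list[tuple] = []
    for method in config.methods:
        sub = sweep[sweep["method"] == method]
        thresholds = ("none",) if method == "none" else tuple(
            _threshold_key(t) for t in config.thresholds
        )
        for index in ("GI", "CV"):
            rows = []
            for t in thresholds:
                cell = sub[(sub["threshold"] == t) & (sub["index"] == index)]
                rows.append(
                    _cell_auc_row(cell, t, config, f"{method}|{t}|{index}")
                )
                ok = cell[(cell["flag"] == "") & cell["value"].notna()]
                for g in (Group.ARDS.value, Group.CONTROL.value):
                    vals = ok.loc[ok["group"] == g, "value"].to_numpy()
                    n_total = int((cell["group"] == g).sum())
                    if vals.size >= 2:
                        mean, lo, hi = group_mean_ci(vals)
                    elif vals.size == 1:
                        mean, lo, hi = float(vals[0]), np.nan, np.nan
                    else:
                        mean = lo = hi = np.nan
                    summary_rows.append(
                        (method, t, index, g, vals.size, n_total - vals.size, mean, lo, hi)
                    )
            auc_tables[(method, index)] = pd.DataFrame.from_records(
                rows, columns=AUC_COLUMNS
            )
        # pixel counts are index-independent; take them from the GI rows
        for t in thresholds:
            cell = sub[(sub["threshold"] == t) & (sub["index"] == "GI")]
            a = cell.loc[cell["group"] == Group.ARDS.value, "n_pixels"].to_numpy(float)
            c = cell.loc[cell["group"] == Group.CONTROL.value, "n_pixels"].to_numpy(float)
            try:
                p = unpaired_t_test(a, c)
            except EitRoiError:
                p = np.nan
            count_rows.append(
                (method, t, a.mean() if a.size else np.nan,
                 c.mean() if c.size else np.nan, p, a.size, c.size)
            )

    group_summary = pd.DataFrame.from_records(
        summary_rows,
        columns=("method", "threshold", "index", "group", "n", "n_excluded",
                 "mean", "ci_low", "ci_high"),
    )
    pixel_counts = pd.DataFrame.from_records(
        count_rows,
        columns=("method", "threshold", "mean_ards", "mean_control", "p_ttest",
                 "n_ards", "n_control"),
    )
    return ReportBundle(
        sweep=sweep.reset_index(drop=True),
        auc_tables=auc_tables,
        group_summary=group_summary,
        pixel_counts=pixel_counts,
        config=config,
    )


def run_study(
    cohort: list[FrameSequence],
    config: StudyConfig = StudyConfig(),
    valid: np.ndarray | None = None,
) -> ReportBundle:
    """Full study on a cohort: per-subject sweeps, then group statistics.

    Deterministic given the cohort, config and valid mask.
    """
    if not cohort:
        raise InsufficientDataError("empty cohort")
    if valid is None:
        rows, cols = cohort[0].shape
        valid = (
            default_pixel_mask(rows, cols) if (rows, cols) == (32, 32)
            else np.ones((rows, cols), dtype=bool)
        )
    tables = []
    for i, seq in enumerate(cohort):
        logger.info("analysing subject %s (%d/%d)", seq.subject_id, i + 1, len(cohort))
        tables.append(analyze_subject(seq, config, valid))
    sweep = pd.concat(tables, ignore_index=True)
    return summarize_sweep(sweep, config)


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def write_report(bundle: ReportBundle, outdir: str | Path) -> list[Path]:
    """Write the bundle as CSV tables plus a YAML run manifest; returns the paths.

    Per thresholded method and index: ``auc_<method>_<index>.csv`` with
    columns ``threshold,auc,ci_low,ci_high,p,n_ards,n_control,n_excluded``
    (the machine layout of the printed per-method AUC tables); plus
    ``no_froi_summary.csv``, ``pixel_counts.csv``, ``group_summary.csv``,
    ``sweep_table.csv`` and ``manifest.yaml``.  Re-running on identical
    inputs reproduces these files byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    no_froi_rows = []
    for (method, index), table in sorted(bundle.auc_tables.items()):
        if method == "none":
            row = table.iloc[0].to_dict()
            row = {"index": index, **{k: row[k] for k in AUC_COLUMNS if k != "threshold"}}
            no_froi_rows.append(row)
            continue
        path = outdir / f"auc_{method}_{index.lower()}.csv"
        _write_csv(table, path)
        written.append(path)
    if no_froi_rows:
        path = outdir / "no_froi_summary.csv"
        _write_csv(pd.DataFrame(no_froi_rows), path)
        written.append(path)

    for name, df in (
        ("pixel_counts.csv", bundle.pixel_counts),
        ("group_summary.csv", bundle.group_summary),
        ("sweep_table.csv", bundle.sweep),
    ):
        path = outdir / name
        _write_csv(df, path)
        written.append(path)

    n_ards = bundle.sweep.loc[bundle.sweep["group"] == Group.ARDS.value, "subject_id"].nunique()
    n_ctrl = bundle.sweep.loc[bundle.sweep["group"] == Group.CONTROL.value, "subject_id"].nunique()
    manifest = {
        "eitroi_version": __version__,
        "config": bundle.config.to_dict(),
        "n_subjects": {"ARDS": int(n_ards), "CONTROL": int(n_ctrl)},
    }
    path = outdir / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    written.append(path)
    return written
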