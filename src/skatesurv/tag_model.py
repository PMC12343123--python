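"""Domain types and the miniPAT sensor/transmission observation model.

A pop-up satellite archival tag (miniPAT) records depth, temperature and
acceleration at 1 Hz, then transmits lossy summaries once it detaches and
surfaces: depth time series at 150 s cadence, quantized to 16 bins per 2 h
summary window, and per-window means of a unit-less "tag mobility" metric
together with the fraction of time the tag stood upright (vertical
acceleration Az at or below -0.75 g).

This module holds the per-deployment record types, the sensor accuracy and
depth-binning model, summarization of recovered 1 Hz archives into the
transmitted products, and plain-CSV readers/writers for all of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SEX_CODES = ("F", "M")
DETACHMENT_TYPES = ("scheduled", "early", "pin_intact")
REGIONS = ("canyon", "plateau_north", "plateau_south")

#: programmed pop-up day by deployment class
PROGRAMMED_DAYS = {"standard": 30, "pilot": 5}


@dataclass(frozen=True)
class SensorModel:
    """miniPAT sensor characteristics.

    depth accuracy degrades linearly with the reading (+/- 1% of reading);
    depth resolution is 0.5 m.  Tag mobility is the mean standard deviation
    of summed 3-axis acceleration over a 3 s window sampled every second,
    reported on a unit-less 5-63 scale.  Orientation is classified each
    second against a -0.75 g threshold on Az: a vertically floating tag
    reads about -1 g, so upright means Az <= -0.75 g.
    """

    depth_resolution: float = 0.5
    accuracy_fraction: float = 0.01
    mobility_min: float = 5.0
    mobility_max: float = 63.0
    upright_threshold: float = -0.75
    mobility_window_s: float = 3.0
    sample_rate_hz: float = 1.0

    def accuracy(self, depth_reading: float | np.ndarray) -> float | np.ndarray:
        return sensor_accuracy(depth_reading, self.accuracy_fraction)


DEFAULT_SENSOR = SensorModel()


def sensor_accuracy(
    depth_reading: float | np.ndarray, accuracy_fraction: float = 0.01
) -> float | np.ndarray:
    """Half-width (m) of the depth accuracy band at a given reading.

    Accuracy is +/-1% of reading: a 1700 m reading carries a +/-17 m band.
    """
    reading = np.asarray(depth_reading, dtype=float)
    if np.any(reading < 0):
        raise ValueError("depth_reading must be >= 0 (negative depth reading)")
    out = accuracy_fraction * reading
    return float(out) if np.isscalar(depth_reading) or out.ndim == 0 else out


@dataclass
class TagDeployment:
    """One tagged animal: covariates and the detachment record."""

    tag_id: str
    capture_depth_m: float
    total_length_mm: float
    sex: str
    time_out_water_min: float
    soak_time_h: float
    region: str
    detachment_type: str
    days_at_liberty: float
    is_control: bool = False
    programmed_days: float = 30.0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.capture_depth_m <= 0:
            raise ValueError(f"capture_depth_m must be > 0 for tag {self.tag_id}")
        if self.sex not in SEX_CODES:
            raise ValueError(f"sex must be one of {SEX_CODES}, got {self.sex!r}")
        if self.detachment_type not in DETACHMENT_TYPES:
            raise ValueError(
                f"detachment_type must be one of {DETACHMENT_TYPES}, "
                f"got {self.detachment_type!r}"
            )
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        if self.days_at_liberty <= 0:
            raise ValueError(f"days_at_liberty must be > 0 for tag {self.tag_id}")
        if self.days_at_liberty > self.programmed_days + 1e-9:
            raise ValueError(
                f"days_at_liberty ({self.days_at_liberty}) exceeds programmed "
                f"deployment length ({self.programmed_days}) for tag {self.tag_id}"
            )


@dataclass
class DepthSeries:
    """Transmitted depth time series (150 s cadence, bin-decoded).

    ``time_s`` is seconds since release (release = 0); calendar alignment is
    metadata carried elsewhere.  ``window_id`` indexes the 2 h summary window
    each sample was encoded in; ``phase`` labels, when present, come from the
    simulator ground truth (descent / benthic / ascent / surface).
    """

    tag_id: str
    time_s: np.ndarray
    depth_m: np.ndarray
    window_id: np.ndarray
    bin_width_m: dict[int, float] = field(default_factory=dict)
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        self.window_id = np.asarray(self.window_id, dtype=int)
        if not (len(self.time_s) == len(self.depth_m) == len(self.window_id)):
            raise ValueError("time_s, depth_m and window_id must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            bad = int(np.argmax(np.diff(self.time_s) <= 0)) + 1
            raise ValueError(f"non-monotone timestamps in depth series at row {bad}")


@dataclass
class MobilitySeries:
    """Per-window transmitted activity summaries.

    Windows are contiguous 2 h (1 h on pilot tags) periods; windows lost in
    transmission are simply absent, so ``window_start_s`` may have gaps.
    """

    tag_id: str
    window_start_s: np.ndarray
    window_hours: float
    mean_mobility: np.ndarray
    pct_upright: np.ndarray

    def __post_init__(self) -> None:
        self.window_start_s = np.asarray(self.window_start_s, dtype=float)
        self.mean_mobility = np.asarray(self.mean_mobility, dtype=float)
        self.pct_upright = np.asarray(self.pct_upright, dtype=float)
        n = len(self.window_start_s)
        if not (len(self.mean_mobility) == len(self.pct_upright) == n):
            raise ValueError("mobility series arrays must have equal length")
        if n and np.any(np.diff(self.window_start_s) <= 0):
            bad = int(np.argmax(np.diff(self.window_start_s) <= 0)) + 1
            raise ValueError(f"non-monotone window_start_s at row {bad}")

    @property
    def n_windows(self) -> int:
        return len(self.window_start_s)


@dataclass
class ArchivalRecord:
    """Full 1 Hz record, available only for physically recovered tags."""

    tag_id: str
    time_s: np.ndarray
    depth_m: np.ndarray
    temperature_c: np.ndarray
    az_g: np.ndarray
    mobility: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        n = len(self.time_s)
        for name in ("depth_m", "temperature_c", "az_g", "mobility"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise ValueError(f"{name} length does not match time_s")
            setattr(self, name, arr)
        if n > 1:
            dt = np.diff(self.time_s)
            if not np.allclose(dt, 1.0):
                raise ValueError("archival record must have exactly 1 Hz cadence")


class BinnedWindow(NamedTuple):
    """Result of 16-step depth encoding of one summary window."""

    bin_indices: np.ndarray
    bin_width: float
    window_min: float


def encode_window(
    raw_depths: Sequence[float] | np.ndarray, n_steps: int = 16
) -> BinnedWindow:
    """Quantize one summary window's depths into ``n_steps`` equal bins.

    The transmitted bin width is (max - min) / n_steps of the depths seen in
    the window, so a window spanning 160 m yields 10 m bins while a
    motionless window loses almost nothing.  Samples on a bin boundary go to
    the upper bin; the window maximum goes to the top bin.  A zero-range
    window has bin width 0 and all indices 0.
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    d = np.asarray(raw_depths, dtype=float)
    if d.size == 0:
        raise ValueError("raw_depths must be non-empty")
    lo = float(d.min())
    hi = float(d.max())
    width = (hi - lo) / n_steps
    if width == 0.0:
        return BinnedWindow(np.zeros(d.shape, dtype=int), 0.0, lo)
    idx = np.floor((d - lo) / width).astype(int)
    idx = np.clip(idx, 0, n_steps - 1)
    return BinnedWindow(idx, width, lo)


def decode_window(bw: BinnedWindow) -> np.ndarray:
    """Decode binned depths to bin centres (the minimum-worst-error choice)."""
    if bw.bin_width == 0.0:
        return np.full(bw.bin_indices.shape, bw.window_min, dtype=float)
    return bw.window_min + (bw.bin_indices + 0.5) * bw.bin_width


def encode_depth_series(
    tag_id: str,
    time_s: np.ndarray,
    depth_m: np.ndarray,
    window_hours: float = 2.0,
    n_steps: int = 16,
    phase: np.ndarray | None = None,
) -> DepthSeries:
    """Apply per-window 16-step binning to a sampled depth trace.

    Windows are assigned by ``floor(time / window_hours)``; each window is
    encoded and decoded independently, emulating the transmitted product.
    """
    time_s = np.asarray(time_s, dtype=float)
    depth_m = np.asarray(depth_m, dtype=float)
    win = np.floor(time_s / (window_hours * 3600.0)).astype(int)
    decoded = np.empty_like(depth_m)
    widths: dict[int, float] = {}
    for w in np.unique(win):
        m = win == w
        bw = encode_window(depth_m[m], n_steps=n_steps)
        decoded[m] = decode_window(bw)
        widths[int(w)] = bw.bin_width
    return DepthSeries(
        tag_id=tag_id,
        time_s=time_s,
        depth_m=decoded,
        window_id=win,
        bin_width_m=widths,
        phase=phase,
    )


def summarize_archival(
    rec: ArchivalRecord,
    window_hours: float = 2.0,
    sensor: SensorModel = DEFAULT_SENSOR,
) -> MobilitySeries:
    """Summarize a 1 Hz archive into per-window transmitted activity values.

    mean_mobility is the plain mean of the 1 Hz mobility metric per window;
    pct_upright is the fraction of seconds with Az at or below the upright
    threshold (-0.75 g).  A trailing window with no full complement of
    samples is still summarized; an empty window is dropped and logged.
    """
    if window_hours not in (1.0, 2.0, 1, 2):
        raise ValueError(f"window_hours must be 1 or 2, got {window_hours}")
    n_per = int(round(window_hours * 3600))
    t0 = float(rec.time_s[0])
    n = len(rec.time_s)
    n_full = n // n_per
    upright = rec.az_g <= sensor.upright_threshold
    # contiguous 1 Hz record: full windows summarize by reshape
    starts = list(t0 + np.arange(n_full) * float(n_per))
    means = list(rec.mobility[: n_full * n_per].reshape(n_full, n_per).mean(axis=1))
    uprights = list(
        upright[: n_full * n_per].reshape(n_full, n_per).mean(axis=1).astype(float)
    )
    if n > n_full * n_per:  # trailing partial window
        starts.append(t0 + n_full * float(n_per))
        means.append(float(rec.mobility[n_full * n_per :].mean()))
        uprights.append(float(upright[n_full * n_per :].mean()))
    return MobilitySeries(
        tag_id=rec.tag_id,
        window_start_s=np.asarray(starts),
        window_hours=float(window_hours),
        mean_mobility=np.asarray(means),
        pct_upright=np.asarray(uprights),
    )


# ---------------------------------------------------------------------------
# CSV I/O
#
# deployments.csv   one row per tag (covariates + detachment record)
# series_<tag>.csv  time_s, depth_m, window_id [, phase]
# summaries_<tag>.csv  window_start_s, window_hours, mean_mobility, pct_upright
# ---------------------------------------------------------------------------

_DEPLOYMENT_COLUMNS = [
    "tag_id",
    "capture_depth_m",
    "total_length_mm",
    "sex",
    "time_out_water_min",
    "soak_time_h",
    "region",
    "detachment_type",
    "days_at_liberty",
    "is_control",
    "programmed_days",
]


def write_deployments(deployments: Iterable[TagDeployment], path: str | Path) -> None:
    rows = []
    for d in deployments:
        row = {c: getattr(d, c) for c in _DEPLOYMENT_COLUMNS}
        row.update(d.extras)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_deployments(path: str | Path) -> list[TagDeployment]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _DEPLOYMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"deployments file missing mandatory column(s): {missing}")
    out = []
    for _, row in df.iterrows():
        extras = {
            c: row[c] for c in df.columns if c not in _DEPLOYMENT_COLUMNS
        }
        out.append(
            TagDeployment(
                tag_id=str(row["tag_id"]),
                capture_depth_m=float(row["capture_depth_m"]),
                total_length_mm=float(row["total_length_mm"]),
                sex=str(row["sex"]),
                time_out_water_min=float(row["time_out_water_min"]),
                soak_time_h=float(row["soak_time_h"]),
                region=str(row["region"]),
                detachment_type=str(row["detachment_type"]),
                days_at_liberty=float(row["days_at_liberty"]),
                is_control=bool(row["is_control"]),
                programmed_days=float(row["programmed_days"]),
                extras=extras,
            )
        )
    return out


def write_depth_series(ds: DepthSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        {"time_s": ds.time_s, "depth_m": ds.depth_m, "window_id": ds.window_id}
    )
    if ds.phase is not None:
        df["phase"] = ds.phase
    df.to_csv(path, index=False)


def read_depth_series(path: str | Path, tag_id: str | None = None) -> DepthSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "depth_m", "window_id"):
        if col not in df.columns:
            raise ValueError(f"depth series file missing mandatory column: {col}")
    tag = tag_id if tag_id is not None else Path(path).stem.replace("series_", "")
    phase = df["phase"].to_numpy() if "phase" in df.columns else None
    return DepthSeries(
        tag_id=tag,
        time_s=df["time_s"].to_numpy(float),
        depth_m=df["depth_m"].to_numpy(float),
        window_id=df["window_id"].to_numpy(int),
        phase=phase,
    )


def write_mobility_series(ms: MobilitySeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "window_start_s": ms.window_start_s,
            "window_hours": np.full(ms.n_windows, ms.window_hours),
            "mean_mobility": ms.mean_mobility,
            "pct_upright": ms.pct_upright,
        }
    ).to_csv(path, index=False)


def read_mobility_series(path: str | Path, tag_id: str | None = None) -> MobilitySeries:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("window_start_s", "window_hours", "mean_mobility", "pct_upright"):
        if col not in df.columns:
            raise ValueError(f"summaries file missing mandatory column: {col}")
    tag = tag_id if tag_id is not None else Path(path).stem.replace("summaries_", "")
    hours = float(df["window_hours"].iloc[0]) if len(df) else 2.0
    return MobilitySeries(
        tag_id=tag,
        window_start_s=df["window_start_s"].to_numpy(float),
        window_hours=hours,
        mean_mobility=df["mean_mobility"].to_numpy(float),
        pct_upright=df["pct_upright"].to_numpy(float),
    )
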