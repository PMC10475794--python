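"""Domain types for multimodal wearable records, CSV readers/writers and
basic quality metrics.

Timestamps are stored internally as float hours elapsed since local
midnight of study day 1, so wall-clock phase is recovered with ``t % 24``
while dynamics use elapsed time directly.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HOURS_PER_DAY = 24.0


class FormatError(ValueError):
    """A mandatory column or file-level convention is violated."""


class DataError(ValueError):
    """File parses but the contents are inconsistent."""


class Channel(str, enum.Enum):
    GLUCOSE = "glucose"
    ACTIVITY = "activity"
    HR = "hr"
    HRV = "hrv"


#: units of the stored values per channel (HRV is stored as RMSSD in ms in
#: device files; the modeled variable RMSSD^-1 is produced by preprocess).
CHANNEL_UNITS = {
    Channel.GLUCOSE: "mmol/L",
    Channel.ACTIVITY: "counts",
    Channel.HR: "bpm",
    Channel.HRV: "ms",
}


@dataclasses.dataclass
class SensorSeries:
    """One channel's timestamped values with units and missingness mask."""

    channel: Channel
    times: np.ndarray
    values: np.ndarray
    missing: np.ndarray | None = None
    units: str | None = None

    def __post_init__(self) -> None:
        self.channel = Channel(self.channel)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.units is None:
            self.units = CHANNEL_UNITS[self.channel]
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise DataError("times and values must be 1-D and aligned")
        if self.missing.shape != self.times.shape:
            raise DataError("missing mask must align with times")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                bad = self.times[1:][dt <= 0][0]
                raise DataError(
                    f"timestamps not strictly increasing (around t={bad:.6g} h)"
                )
        obs = ~self.missing
        if not np.all(np.isfinite(self.values[obs])):
            raise DataError("non-finite value marked as observed")
        if self.channel is Channel.GLUCOSE and np.any(self.values[obs] <= 0):
            raise DataError("observed glucose values must be positive")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def observed(self) -> np.ndarray:
        return ~self.missing

    @property
    def n_observed(self) -> int:
        return int(np.count_nonzero(self.observed))

    def observed_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) restricted to observed samples."""
        m = self.observed
        return self.times[m], self.values[m]

    def replace(self, **kw) -> "SensorSeries":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass(frozen=True)
class MealEvent:
    """A timestamped ingestion event with a normalized annotation label."""

    time: float
    label: str


@dataclasses.dataclass
class ParticipantRecord:
    participant_id: str
    series: dict[Channel, SensorSeries]
    meals: list[MealEvent]
    window: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not hi > lo:
            raise DataError("recording window must have positive length")
        for ch, s in self.series.items():
            if s.times.size and (s.times[0] < lo - 1e-9 or s.times[-1] > hi + 1e-9):
                raise DataError(f"{ch.value} series extends outside the window")
        for ev in self.meals:
            if not lo - 1e-9 <= ev.time <= hi + 1e-9:
                raise DataError(f"meal at t={ev.time:.3f} h outside the window")

    @property
    def glucose(self) -> SensorSeries:
        return self.series[Channel.GLUCOSE]

    @property
    def n_days(self) -> int:
        lo, hi = self.window
        return int(np.ceil((hi - lo) / HOURS_PER_DAY))


def normalize_label(label: str, *, enabled: bool = True) -> str:
    """Lowercase and collapse whitespace (configurable off)."""
    if not enabled:
        return label
    return re.sub(r"\s+", " ", label.strip().lower())


def adherence(meals: Sequence[MealEvent], days: int) -> float:
    """Fraction of calendar days with >= 2 meals spanning >= 5 h.

    A day qualifies when it contains at least two logged meals whose
    maximum pairwise time gap is at least 5 hours; day boundaries are
    local midnights.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    qualifying = 0
    by_day: dict[int, list[float]] = {}
    for ev in meals:
        by_day.setdefault(int(np.floor(ev.time / HOURS_PER_DAY)), []).append(ev.time)
    for ts in by_day.values():
        if len(ts) >= 2 and (max(ts) - min(ts)) >= 5.0:
            qualifying += 1
    return qualifying / days


def unique_meal_labels(meals: Sequence[MealEvent]) -> dict[str, int]:
    """Ordered (first-occurrence) label -> event count mapping."""
    counts: dict[str, int] = {}
    for ev in meals:
        counts[ev.label] = counts.get(ev.label, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

DEFAULT_DIALECT: dict = {
    "timestamp_format": "%Y-%m-%d %H:%M:%S",
    "cgm": {"timestamp": "timestamp", "glucose": "glucose_mmol_L"},
    "actiheart": {
        "timestamp": "timestamp",
        "activity": "activity_counts",
        "hr": "hr_bpm",
        "hrv": "rmssd_ms",
    },
    "meals": {"timestamp": "timestamp", "annotation": "annotation"},
    "normalize_labels": True,
    # optional: "start" (ISO datetime of study day 1 local midnight),
    # "window_hours" (float) to clip the record.
}


def _merge_dialect(config: Mapping | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_DIALECT))  # deep copy
    if config:
        for k, v in config.items():
            if isinstance(v, Mapping) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def _parse_times(raw: pd.Series, fmt: str, start: pd.Timestamp) -> np.ndarray:
    ts = pd.to_datetime(raw, format=fmt)
    return ((ts - start).dt.total_seconds() / 3600.0).to_numpy()


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")


def _check_monotone(times: np.ndarray, path: Path) -> None:
    if times.size > 1:
        d = np.diff(times)
        if np.any(d == 0):
            t = times[1:][d == 0][0]
            raise DataError(f"{path}: duplicated timestamp at t={t:.6g} h")
        if np.any(d < 0):
            raise DataError(f"{path}: timestamps not monotone after sorting")


def read_participant(
    cgm_file: str | Path,
    actiheart_file: str | Path,
    meal_file: str | Path,
    config: Mapping | None = None,
    participant_id: str = "synthetic",
) -> ParticipantRecord:
    """Read one participant's CGM, Actiheart and meal-log CSV files.

    Timestamps are converted to hours since local midnight of study day 1
    (taken from ``config['start']`` or the midnight preceding the first
    CGM sample). Rows outside the recording window are dropped with a
    logged count; duplicate timestamps raise :class:`DataError`.
    """
    cfg = _merge_dialect(config)
    fmt = cfg["timestamp_format"]
    cgm_path, act_path, meal_path = Path(cgm_file), Path(actiheart_file), Path(meal_file)

    cgm = pd.read_csv(cgm_path, float_precision="round_trip")
    cmap = cfg["cgm"]
    _require_columns(cgm, [cmap["timestamp"], cmap["glucose"]], cgm_path)
    first = pd.to_datetime(cgm[cmap["timestamp"]].iloc[0], format=fmt)
    start = pd.Timestamp(cfg["start"]) if "start" in cfg else first.normalize()

    t_g = _parse_times(cgm[cmap["timestamp"]], fmt, start)
    order = np.argsort(t_g, kind="stable")
    t_g, v_g = t_g[order], cgm[cmap["glucose"]].to_numpy(dtype=float)[order]
    _check_monotone(t_g, cgm_path)

    act = pd.read_csv(act_path, float_precision="round_trip")
    amap = cfg["actiheart"]
    _require_columns(
        act, [amap["timestamp"], amap["activity"], amap["hr"], amap["hrv"]], act_path
    )
    t_a = _parse_times(act[amap["timestamp"]], fmt, start)
    order = np.argsort(t_a, kind="stable")
    t_a = t_a[order]
    _check_monotone(t_a, act_path)

    meals_df = pd.read_csv(meal_path, float_precision="round_trip")
    mmap = cfg["meals"]
    if len(meals_df):
        _require_columns(meals_df, [mmap["timestamp"], mmap["annotation"]], meal_path)
        t_m = _parse_times(meals_df[mmap["timestamp"]], fmt, start)
        labels = [
            normalize_label(str(a), enabled=cfg["normalize_labels"])
            for a in meals_df[mmap["annotation"]]
        ]
    else:
        t_m, labels = np.empty(0), []

    lo = 0.0
    hi = cfg.get("window_hours")
    if hi is None:
        hi = float(max(t_g[-1] if t_g.size else 0.0, t_a[-1] if t_a.size else 0.0))
        hi = max(hi, float(t_m.max()) if t_m.size else 0.0) + 1e-9

    def _clip(t: np.ndarray, *arrs: np.ndarray):
        keep = (t >= lo) & (t <= hi)
        dropped = int(np.count_nonzero(~keep))
        if dropped:
            logger.info("dropped %d out-of-window rows", dropped)
        return (t[keep], *(a[keep] for a in arrs))

    t_g, v_g = _clip(t_g, v_g)
    t_a, v_act, v_hr, v_hrv = _clip(
        t_a,
        act[amap["activity"]].to_numpy(dtype=float)[order],
        act[amap["hr"]].to_numpy(dtype=float)[order],
        act[amap["hrv"]].to_numpy(dtype=float)[order],
    )

    series = {
        Channel.GLUCOSE: SensorSeries(Channel.GLUCOSE, t_g, v_g),
        Channel.ACTIVITY: SensorSeries(Channel.ACTIVITY, t_a, v_act),
        Channel.HR: SensorSeries(Channel.HR, t_a, v_hr),
        Channel.HRV: SensorSeries(Channel.HRV, t_a, v_hrv),
    }
    meals = [
        MealEvent(float(t), lab)
        for t, lab in sorted(zip(t_m, labels), key=lambda p: p[0])
        if lo <= t <= hi
    ]
    return ParticipantRecord(participant_id, series, meals, (lo, hi))


def write_participant(
    record: ParticipantRecord,
    out_dir: str | Path,
    config: Mapping | None = None,
    start: str = "2024-01-01 00:00:00",
) -> dict[str, Path]:
    """Write CSV files in the dialect that :func:`read_participant` reads.

    Missing samples are written with empty value cells (NaN round-trips as
    a missing entry).
    """
    cfg = _merge_dialect(config)
    fmt = cfg["timestamp_format"]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = pd.Timestamp(start)

    def _stamps(t: np.ndarray) -> list[str]:
        # round to the nearest second so the round-trip error is <= 0.5 s
        return [
            (t0 + pd.to_timedelta(round(ti * 3600.0), unit="s")).strftime(fmt)
            for ti in t
        ]

    def _masked(s: SensorSeries) -> np.ndarray:
        v = s.values.astype(float).copy()
        v[s.missing] = np.nan
        return v

    paths = {}
    g = record.series[Channel.GLUCOSE]
    cmap = cfg["cgm"]
    paths["cgm"] = out / "cgm.csv"
    pd.DataFrame(
        {cmap["timestamp"]: _stamps(g.times), cmap["glucose"]: _masked(g)}
    ).to_csv(paths["cgm"], index=False)

    amap = cfg["actiheart"]
    a = record.series[Channel.ACTIVITY]
    paths["actiheart"] = out / "actiheart.csv"
    pd.DataFrame(
        {
            amap["timestamp"]: _stamps(a.times),
            amap["activity"]: _masked(a),
            amap["hr"]: _masked(record.series[Channel.HR]),
            amap["hrv"]: _masked(record.series[Channel.HRV]),
        }
    ).to_csv(paths["actiheart"], index=False)

    mmap = cfg["meals"]
    paths["meals"] = out / "meals.csv"
    pd.DataFrame(
        {
            mmap["timestamp"]: _stamps(np.array([m.time for m in record.meals])),
            mmap["annotation"]: [m.label for m in record.meals],
        }
    ).to_csv(paths["meals"], index=False)
    return paths


def record_summary(record: ParticipantRecord) -> dict:
    """JSON-able summary: counts, coverage, adherence."""
    lo, hi = record.window
    out: dict = {
        "participant_id": record.participant_id,
        "window_hours": [lo, hi],
        "n_days": record.n_days,
        "n_meals": len(record.meals),
        "meal_labels": unique_meal_labels(record.meals),
        "adherence": adherence(record.meals, record.n_days),
        "channels": {},
    }
    for ch, s in record.series.items():
        out["channels"][ch.value] = {
            "n": len(s),
            "n_observed": s.n_observed,
            "coverage": s.n_observed / len(s) if len(s) else 0.0,
            "units": s.units,
        }
    return out
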