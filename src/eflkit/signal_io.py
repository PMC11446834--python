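"""Waveform and manifest I/O for exercise flow-volume recordings.

Conventions used throughout the package:

* **Flow sign**: expiration positive, inspiration negative (L·s⁻¹).
  Recordings with the opposite polarity are handled by ``invert_flow``.
* **Volume**: the time-integral of *minus* flow, so the tidal volume trace
  rises with inspiration.  The additive offset is arbitrary (analog volume
  channels are zeroed at an unknown lung volume); all analyses work on
  differences or on the "litres above residual volume" axis.
* **Sampling**: a uniform grid at ``fs`` Hz (200 Hz by default, the rate of
  typical pneumotachograph acquisition systems).  Other rates are accepted
  if declared; a non-uniform time base is rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

__all__ = [
    "FlowVolumeSignal",
    "SessionManifest",
    "StageWindow",
    "ICWindow",
    "FVCWindow",
    "StageMetabolics",
    "StageRecord",
    "MalformedInputError",
    "integrate_flow",
    "read_waveform",
    "write_waveform",
    "write_stage_table",
    "read_stage_table",
]

#: Default acquisition rate in Hz.
DEFAULT_FS = 200.0

#: Tolerance on the uniformity of the time grid, in seconds.
TIME_STEP_TOL = 1e-9


class MalformedInputError(ValueError):
    """A waveform file or manifest violates the format contract."""


def integrate_flow(flow: np.ndarray, fs: float) -> np.ndarray:
    """Integrate a flow trace (L·s⁻¹) into a volume trace (L).

    Trapezoidal integration of ``-flow``: with expiration positive,
    inspiration (negative flow) raises volume.  ``volume[0] == 0``.

    Parameters
    ----------
    flow:
        Airflow samples, expiration positive.
    fs:
        Sampling rate in Hz; must be positive.
    """
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    flow = np.asarray(flow, dtype=float)
    if flow.ndim != 1:
        raise ValueError("flow must be one-dimensional")
    if flow.size == 0:
        return np.zeros(0)
    if not np.all(np.isfinite(flow)):
        bad = int(np.flatnonzero(~np.isfinite(flow))[0])
        raise MalformedInputError(f"non-finite flow value at sample {bad}")
    vol = np.empty_like(flow)
    vol[0] = 0.0
    # trapezoid of -flow over each step
    np.cumsum(-(flow[1:] + flow[:-1]) / (2.0 * fs), out=vol[1:])
    return vol


@dataclass
class FlowVolumeSignal:
    """A sampled airflow + volume trace on a uniform time grid.

    Attributes
    ----------
    time:
        Seconds, strictly increasing with constant step ``1/fs``.
    flow:
        L·s⁻¹, expiration positive.
    volume:
        L, arbitrary additive offset; rises with inspiration.
    fs:
        Sampling rate, Hz.
    """

    time: np.ndarray
    flow: np.ndarray
    volume: np.ndarray
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        n = self.time.size
        if self.flow.size != n or self.volume.size != n:
            raise MalformedInputError(
                "time, flow and volume must have equal length "
                f"(got {n}, {self.flow.size}, {self.volume.size})"
            )
        if n >= 2:
            steps = np.diff(self.time)
            if np.any(np.abs(steps - 1.0 / self.fs) > TIME_STEP_TOL + 1e-12 * self.time[-1]):
                k = int(np.argmax(np.abs(steps - 1.0 / self.fs)))
                raise MalformedInputError(
                    f"non-uniform time step at sample {k}: {steps[k]:.9f} s "
                    f"vs declared {1.0 / self.fs:.9f} s"
                )
        if not np.all(np.isfinite(self.flow)):
            bad = int(np.flatnonzero(~np.isfinite(self.flow))[0])
            raise MalformedInputError(f"NaN/inf flow at row {bad}")

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.n else 0.0

    def index_of(self, t: float, side: Literal["left", "right"] = "left") -> int:
        """Sample index of time ``t`` (clipped to the record)."""
        i = int(np.searchsorted(self.time, t, side=side))
        return int(np.clip(i, 0, self.n - 1))

    def slice_window(self, t_start: float, t_end: float) -> "FlowVolumeSignal":
        """Return the sub-signal with ``t_start <= time <= t_end``."""
        if t_end <= t_start:
            raise ValueError("window end must exceed window start")
        i0 = int(np.searchsorted(self.time, t_start - 1e-12))
        i1 = int(np.searchsorted(self.time, t_end + 1e-12))
        if i1 - i0 < 2:
            raise MalformedInputError(
                f"window [{t_start}, {t_end}] s contains fewer than 2 samples"
            )
        return FlowVolumeSignal(
            self.time[i0:i1], self.flow[i0:i1], self.volume[i0:i1], self.fs
        )

    def with_volume(self, volume: np.ndarray) -> "FlowVolumeSignal":
        return FlowVolumeSignal(self.time, self.flow, volume, self.fs)


def read_waveform(
    path: str | Path, fs: float = DEFAULT_FS, invert_flow: bool = False
) -> FlowVolumeSignal:
    """Read a delimited-text waveform file into a :class:`FlowVolumeSignal`.

    The file must be a comma-separated table with a header and columns
    ``time``, ``flow`` and optionally ``volume``.  If the volume column is
    absent it is computed with :func:`integrate_flow` (starting at 0 L).

    Raises
    ------
    MalformedInputError
        On a non-uniform time step (beyond 1 ns tolerance), a NaN flow
        value (the message names the first offending row), or missing
        columns.
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "time" not in cols or "flow" not in cols:
        raise MalformedInputError(
            f"{path}: expected columns 'time' and 'flow', found {list(df.columns)}"
        )
    time = df[cols["time"]].to_numpy(float)
    flow = df[cols["flow"]].to_numpy(float)
    if invert_flow:
        flow = -flow
    if not np.all(np.isfinite(flow)):
        bad = int(np.flatnonzero(~np.isfinite(flow))[0])
        raise MalformedInputError(f"{path}: NaN flow at data row {bad}")
    if "volume" in cols:
        volume = df[cols["volume"]].to_numpy(float)
        if invert_flow:
            volume = -volume
    else:
        volume = integrate_flow(flow, fs)
    return FlowVolumeSignal(time, flow, volume, fs)


def write_waveform(signal: FlowVolumeSignal, path: str | Path) -> None:
    """Write a signal as CSV (time, flow, volume) with full float precision."""
    df = pd.DataFrame(
        {"time": signal.time, "flow": signal.flow, "volume": signal.volume}
    )
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Session manifest
# ---------------------------------------------------------------------------


class StageWindow(BaseModel):
    """Analysis window (~30 s at the end of a stage, before the IC maneuver)."""

    model_config = ConfigDict(extra="forbid")
    label: str
    t_start: float
    t_end: float
    work_W: float

    @field_validator("t_end")
    @classmethod
    def _ordered(cls, v, info):
        if "t_start" in info.data and v <= info.data["t_start"]:
            raise ValueError("t_end must exceed t_start")
        return v


class ICWindow(BaseModel):
    model_config = ConfigDict(extra="forbid")
    stage_label: str
    t_start: float
    t_end: float


class FVCWindow(BaseModel):
    model_config = ConfigDict(extra="forbid")
    phase: Literal["pre", "post"]
    effort_pct: float
    t_start: float
    t_end: float


class StageMetabolics(BaseModel):
    model_config = ConfigDict(extra="forbid")
    stage_label: str
    VO2: float  # L·min⁻¹
    VCO2: float  # L·min⁻¹


class SessionManifest(BaseModel):
    """Annotations for one recording session (one participant, one visit)."""

    model_config = ConfigDict(extra="forbid")
    participant_id: str
    visit: Literal[1, 2]
    stage_windows: list[StageWindow]
    ic_windows: list[ICWindow]
    fvc_windows: list[FVCWindow]
    stage_metabolics: list[StageMetabolics] = []
    #: Per-stage list of breath ordinals (0-based, within the analysis
    #: window) excluded by the analyst as aberrant.
    excluded_breaths: dict[str, list[int]] = {}

    @field_validator("stage_windows")
    @classmethod
    def _unique_labels(cls, v):
        labels = [w.label for w in v]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate stage labels in manifest")
        return v

    def ic_window_for(self, stage_label: str) -> ICWindow:
        for w in self.ic_windows:
            if w.stage_label == stage_label:
                return w
        raise KeyError(f"no IC window for stage {stage_label!r}")

    def metabolics_for(self, stage_label: str) -> StageMetabolics | None:
        for m in self.stage_metabolics:
            if m.stage_label == stage_label:
                return m
        return None

    def validate_against(self, signal: FlowVolumeSignal) -> None:
        """Check every window lies inside the recording."""
        t0, t1 = float(signal.time[0]), float(signal.time[-1])
        for group in (self.stage_windows, self.ic_windows, self.fvc_windows):
            for w in group:
                if w.t_start < t0 - 1e-9 or w.t_end > t1 + 1e-9:
                    raise MalformedInputError(
                        f"window [{w.t_start}, {w.t_end}] s outside recording "
                        f"[{t0}, {t1}] s"
                    )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SessionManifest":
        return cls.model_validate_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# Per-stage results
# ---------------------------------------------------------------------------


@dataclass
class StageRecord:
    """Ventilatory, volume and flow-limitation summary for one stage."""

    stage_label: str
    work_W: float
    VT: float  # L
    fB: float  # breaths·min⁻¹
    VE: float  # L·min⁻¹
    TI: float  # s
    TE: float  # s
    VT_over_TE: float  # L·s⁻¹
    IC: float  # L
    ERV: float  # L
    IRV: float  # L, = ERV + VT (end-inspiratory lung volume above RV)
    EFL_present: bool
    EFL_pct_VT: float  # %
    VE_cap: float  # L·min⁻¹
    VE_frac_cap: float  # %, 100·VE/VE_cap
    VO2: float = np.nan  # L·min⁻¹
    VCO2: float = np.nan  # L·min⁻¹


_STAGE_COLUMNS = [f.name for f in fields(StageRecord)]


def write_stage_table(records: list[StageRecord], path: str | Path) -> None:
    """Write stage records as a CSV table (one row per stage).

    Round-tripping through :func:`read_stage_table` preserves values to
    better than 1e-9.
    """
    if not records:
        raise ValueError("cannot write an empty stage table")
    labels = [r.stage_label for r in records]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate stage_label in records: {labels}")
    df = pd.DataFrame([{c: getattr(r, c) for c in _STAGE_COLUMNS} for r in records])
    df.to_csv(path, index=False, float_format="%.12g")


def read_stage_table(path: str | Path) -> list[StageRecord]:
    df = pd.read_csv(path)
    missing = set(_STAGE_COLUMNS) - set(df.columns)
    if missing:
        raise MalformedInputError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        kw = {c: row[c] for c in _STAGE_COLUMNS}
        kw["stage_label"] = str(kw["stage_label"])
        kw["EFL_present"] = bool(kw["EFL_present"])
        out.append(StageRecord(**kw))
    return out
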