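"""Breath segmentation, volume-drift correction and tidal-loop compositing.

The tidal analysis window (~30 s at the end of each stage) is processed in
three steps:

1. :func:`correct_drift` — pneumotachograph volume channels drift slowly;
   an ordinary-least-squares line through the end-expiratory volumes is
   removed from the volume trace (flow is untouched).
2. :func:`segment_breaths` — breaths are delimited at flow zero crossings
   into inspiration, with a hysteresis band to suppress noise chatter;
   incomplete edge breaths and sub-threshold "breaths" (swallows, coughs)
   are discarded.
3. :func:`composite_average` — each breath's limbs are resampled onto a
   common relative-volume grid and averaged into one representative tidal
   flow-volume loop, the object that is later placed inside the maximal
   envelope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .signal_io import FlowVolumeSignal

__all__ = [
    "Breath",
    "BreathTable",
    "TidalFVCurve",
    "InsufficientDataError",
    "correct_drift",
    "segment_breaths",
    "ventilatory_params",
    "composite_average",
]

log = logging.getLogger(__name__)

#: Hysteresis half-band on flow for phase detection, L·s⁻¹.
DEFAULT_HYSTERESIS = 0.05
#: Minimum inspired volume for a deflection to count as a breath, L.
DEFAULT_MIN_VT = 0.10


class InsufficientDataError(ValueError):
    """Too few breaths/points in the window for the requested analysis."""


@dataclass
class Breath:
    """One tidal breath: inspiration then expiration."""

    i_insp_start: int
    i_exp_start: int
    i_end: int
    VT_insp: float
    VT_exp: float
    TI: float
    TE: float
    EEV_start: float
    EEV_end: float


@dataclass
class BreathTable:
    breaths: list[Breath]
    window: tuple[float, float]
    drift_slope: float  # L·s⁻¹ removed before segmentation

    @property
    def n(self) -> int:
        return len(self.breaths)


@dataclass
class TidalFVCurve:
    """Composite-averaged tidal flow-volume loop on a relative-volume grid.

    ``rel_volume_grid`` runs from 0 (end-expiration) to VT (end-inspiration);
    ``exp_flow``/``insp_flow`` are mean flows (both stored positive-valued
    magnitudes for the respective phase).
    """

    rel_volume_grid: np.ndarray  # L, 0 .. VT
    exp_flow: np.ndarray  # L·s⁻¹, expiratory flow (positive)
    insp_flow: np.ndarray  # L·s⁻¹, inspiratory flow magnitude
    VT: float
    fB: float
    n_breaths: int


# ---------------------------------------------------------------------------
# Phase detection
# ---------------------------------------------------------------------------


def _inspiratory_onsets(flow: np.ndarray, hysteresis: float) -> np.ndarray:
    """Indices where flow crosses from expiration into inspiration.

    A sample enters the "expiratory" state when flow > +h and the
    "inspiratory" state when flow < −h; samples inside the band keep the
    previous state.  An onset is the first sub-band sample of each
    expiration→inspiration transition.
    """
    above = flow > hysteresis
    below = flow < -hysteresis
    state = np.where(above, 1, np.where(below, -1, 0))
    idx = np.flatnonzero(state != 0)
    if idx.size < 2:
        return np.empty(0, dtype=int)
    s = state[idx]
    trans = np.flatnonzero((s[:-1] == 1) & (s[1:] == -1))
    return idx[trans + 1]


def _expiratory_onsets(flow: np.ndarray, hysteresis: float) -> np.ndarray:
    return _inspiratory_onsets(-flow, hysteresis)


# ---------------------------------------------------------------------------
# Drift correction
# ---------------------------------------------------------------------------


def correct_drift(
    signal: FlowVolumeSignal,
    window: tuple[float, float] | None = None,
    hysteresis: float = DEFAULT_HYSTERESIS,
) -> tuple[FlowVolumeSignal, float]:
    """Remove linear volume drift estimated from end-expiratory volumes.

    End-expiratory points are the volume samples at inspiratory-onset zero
    crossings inside ``window`` (whole record if None).  An OLS line fitted
    to (time, EEV) pairs, anchored to zero at the window start, is
    subtracted from the entire volume trace; flow is unchanged.

    Returns the corrected signal and the fitted drift slope (L·s⁻¹).

    Raises
    ------
    InsufficientDataError
        If fewer than 3 end-expiratory points are detectable.
    """
    if window is None:
        window = (float(signal.time[0]), float(signal.time[-1]))
    sub = signal.slice_window(*window)
    onsets = _inspiratory_onsets(sub.flow, hysteresis)
    if onsets.size < 3:
        raise InsufficientDataError(
            f"only {onsets.size} end-expiratory points in window {window}; need >=3"
        )
    t_eev = sub.time[onsets]
    v_eev = sub.volume[onsets]
    slope, intercept = np.polyfit(t_eev, v_eev, 1)
    corrected = signal.volume - slope * (signal.time - window[0])
    return signal.with_volume(corrected), float(slope)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def segment_breaths(
    signal: FlowVolumeSignal,
    window: tuple[float, float],
    min_VT: float = DEFAULT_MIN_VT,
    hysteresis: float = DEFAULT_HYSTERESIS,
    drift_slope: float = 0.0,
    exclude: list[int] | None = None,
) -> BreathTable:
    """Segment tidal breathing in ``window`` into complete breaths.

    The signal is expected to be drift-corrected already (pass the slope
    from :func:`correct_drift` for bookkeeping).  Breaths are delimited at
    successive inspiratory onsets; deflections with inspired volume below
    ``min_VT`` are discarded as artifacts.  ``exclude`` lists 0-based
    ordinals of additional breaths to drop (the analyst's aberrant-breath
    list from the manifest).

    Raises
    ------
    InsufficientDataError
        If fewer than 2 complete breaths remain.
    """
    sub = signal.slice_window(*window)
    onsets = _inspiratory_onsets(sub.flow, hysteresis)
    if onsets.size < 2:
        raise InsufficientDataError(
            f"fewer than 2 breaths detected in window {window}"
        )
    breaths: list[Breath] = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        exp_on = _expiratory_onsets(sub.flow[a:b], hysteresis)
        if exp_on.size == 0:
            continue  # no expiratory phase: not a complete breath
        i_exp = int(a + exp_on[0])
        vt_insp = float(sub.volume[i_exp] - sub.volume[a])
        vt_exp = float(sub.volume[i_exp] - sub.volume[b])
        if vt_insp < min_VT:
            log.debug("discarding sub-threshold breath (VT_insp=%.3f L)", vt_insp)
            continue
        if vt_exp <= 0:
            continue
        ti = float(sub.time[i_exp] - sub.time[a])
        te = float(sub.time[b] - sub.time[i_exp])
        breaths.append(
            Breath(
                i_insp_start=int(a),
                i_exp_start=i_exp,
                i_end=int(b),
                VT_insp=vt_insp,
                VT_exp=vt_exp,
                TI=ti,
                TE=te,
                EEV_start=float(sub.volume[a]),
                EEV_end=float(sub.volume[b]),
            )
        )
    if exclude:
        breaths = [br for k, br in enumerate(breaths) if k not in set(exclude)]
    if len(breaths) < 2:
        raise InsufficientDataError(
            f"only {len(breaths)} complete breaths in window {window}; need >=2"
        )
    return BreathTable(breaths=breaths, window=window, drift_slope=drift_slope)


def ventilatory_params(table: BreathTable) -> dict[str, float]:
    """Average ventilatory parameters over a breath table.

    Returns a dict with keys ``VT`` (L, mean expired), ``fB``
    (breaths·min⁻¹), ``VE`` (L·min⁻¹, = VT·fB), ``TI``, ``TE`` (s) and
    ``VT_over_TE`` (L·s⁻¹, mean tidal expiratory flow).
    """
    if table.n < 2:
        raise InsufficientDataError("need >=2 breaths for ventilatory parameters")
    vt = float(np.mean([b.VT_exp for b in table.breaths]))
    span = float(np.sum([b.TI + b.TE for b in table.breaths]))
    fb = 60.0 * table.n / span
    ti = float(np.mean([b.TI for b in table.breaths]))
    te = float(np.mean([b.TE for b in table.breaths]))
    return {
        "VT": vt,
        "fB": fb,
        "VE": vt * fb,
        "TI": ti,
        "TE": te,
        "VT_over_TE": vt / te,
    }


# ---------------------------------------------------------------------------
# Composite averaging
# ---------------------------------------------------------------------------


def _limb_on_grid(
    rel_vol: np.ndarray, flow: np.ndarray, grid01: np.ndarray, vt: float
) -> np.ndarray | None:
    """Interpolate one limb's flow onto the 0..1 relative-volume grid.

    ``rel_vol`` is volume above the limb's end-expiratory level.  Returns
    None when the limb's volume excursion is too non-monotonic to resample
    (total reversal beyond 5% of VT).
    """
    x = rel_vol / vt
    # monotonicity check: reversals against the limb's net direction
    increments = np.diff(x)
    reversal = float(np.sum(np.clip(increments, 0, None)))
    forward = float(-np.sum(np.clip(increments, None, 0)))
    if min(reversal, forward) > 0.05 * max(reversal, forward, 1e-12) and min(
        reversal, forward
    ) > 0.05:
        return None
    order = np.argsort(x, kind="stable")
    xs, fs_ = x[order], flow[order]
    # collapse duplicate abscissae introduced by noise
    xs, uniq = np.unique(xs, return_index=True)
    fs_ = fs_[uniq]
    if xs.size < 2:
        return None
    return np.interp(grid01, xs, fs_)


def composite_average(
    table: BreathTable,
    signal: FlowVolumeSignal,
    n_bins: int = 101,
    smoothing: int = 0,
) -> TidalFVCurve:
    """Composite-average the breaths of a window into one tidal loop.

    Each breath's expiratory and inspiratory limb is linearly resampled
    onto a common relative-volume grid spanning 0..1 of that breath's own
    tidal volume; flows are then averaged across breaths per bin and the
    grid is rescaled to 0..mean(VT).  ``smoothing`` > 0 applies a moving
    average of that many samples to flow before resampling (off by
    default).

    Breaths whose volume excursion is badly non-monotonic are excluded
    with a warning; if all breaths are excluded an error is raised.
    """
    if table.n < 2:
        raise InsufficientDataError("need >=2 breaths to composite")
    sub = signal.slice_window(*table.window)
    flow = sub.flow
    if smoothing and smoothing > 1:
        kernel = np.ones(smoothing) / smoothing
        flow = np.convolve(flow, kernel, mode="same")
    grid01 = np.linspace(0.0, 1.0, n_bins)
    exp_rows, insp_rows, vts = [], [], []
    n_excluded = 0
    for br in table.breaths:
        # expiratory limb: volume falls from EEV+VT_exp to EEV_end
        ev = sub.volume[br.i_exp_start : br.i_end + 1] - br.EEV_end
        ef = flow[br.i_exp_start : br.i_end + 1]
        iv = sub.volume[br.i_insp_start : br.i_exp_start + 1] - br.EEV_start
        if_ = -flow[br.i_insp_start : br.i_exp_start + 1]
        e = _limb_on_grid(ev, ef, grid01, br.VT_exp)
        i = _limb_on_grid(iv, if_, grid01, br.VT_insp)
        if e is None or i is None:
            n_excluded += 1
            continue
        exp_rows.append(e)
        insp_rows.append(i)
        vts.append(br.VT_exp)
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} breath(s) with non-monotonic volume",
            stacklevel=2,
        )
    if not exp_rows:
        raise InsufficientDataError("all breaths excluded from composite")
    vt_mean = float(np.mean(vts))
    params_fb = 60.0 * table.n / float(
        np.sum([b.TI + b.TE for b in table.breaths])
    )
    return TidalFVCurve(
        rel_volume_grid=grid01 * vt_mean,
        exp_flow=np.clip(np.mean(exp_rows, axis=0), 0.0, None),
        insp_flow=np.clip(np.mean(insp_rows, axis=0), 0.0, None),
        VT=vt_mean,
        fB=params_fb,
        n_breaths=len(exp_rows),
    )
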