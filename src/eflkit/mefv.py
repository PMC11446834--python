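"""Maximal expiratory flow-volume (MEFV) envelope construction.

A single maximal forced expiration underestimates attainable flows at low
lung volumes because of thoracic gas compression.  The envelope is
therefore built from a series of *graded* forced vital capacity (FVC)
maneuvers at roughly 20–100% of maximal effort, all anchored at total lung
capacity: on a 0.01 L lung-volume grid (litres above residual volume) the
envelope takes, at each volume, the highest flow achieved by any maneuver.

The module also computes standard spirometry indices (FVC, FEV₁, PEF,
FEF₂₅₋₇₅) from the best single maneuver, and the slope-ratio index (SR)
describing the curvilinearity of the envelope's effort-independent
descending limb.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .signal_io import FlowVolumeSignal

__all__ = [
    "FVCManeuver",
    "MEFVCurve",
    "extract_fvc_maneuver",
    "build_mefv",
    "spirometry_indices",
    "slope_ratio",
]

log = logging.getLogger(__name__)

#: Lung-volume grid step for the envelope, L.
GRID_STEP = 0.01


@dataclass
class FVCManeuver:
    """One graded forced expiration, anchored at total lung capacity.

    ``expired_volume`` is the cumulative expired volume from the onset of
    expiration (0 at TLC, rising to ``FVC_this``); ``time`` is seconds from
    the same onset.  On the litres-above-RV axis the maneuver occupies
    ``FVC_session − expired_volume`` once anchored by :func:`build_mefv`.
    """

    phase: str  # 'pre' or 'post' exercise
    effort_pct: float  # nominal effort label
    time: np.ndarray  # s from expiratory onset
    exp_flow: np.ndarray  # L·s⁻¹, >= 0 after onset
    expired_volume: np.ndarray  # L, 0 .. FVC_this

    @property
    def FVC_this(self) -> float:
        return float(np.max(self.expired_volume))

    def volume_above_RV(self, fvc_session: float) -> np.ndarray:
        """Anchor at TLC: the maneuver's start maps to the session FVC."""
        return fvc_session - self.expired_volume


@dataclass
class MEFVCurve:
    """The maximal envelope on a uniform 0.01 L above-RV volume grid."""

    vol_grid: np.ndarray  # L above RV, 0 .. FVC, step 0.01
    max_flow: np.ndarray  # L·s⁻¹
    FVC: float
    PEF: float
    FEV1: float = np.nan
    FEF25_75: float = np.nan
    SR_mean: float = np.nan

    def flow_at(self, vol_above_rv: np.ndarray | float) -> np.ndarray:
        """Envelope flow at arbitrary volumes (linear interpolation)."""
        return np.interp(vol_above_rv, self.vol_grid, self.max_flow, left=0.0)


def extract_fvc_maneuver(
    signal: FlowVolumeSignal,
    window: tuple[float, float],
    phase: str,
    effort_pct: float,
) -> FVCManeuver:
    """Extract a graded FVC maneuver from a recording window.

    The expiratory portion starts at the volume maximum (TLC, reached by
    the preceding deep inspiration) and ends at the volume minimum of the
    window.  Expired volume is measured downward from TLC.
    """
    sub = signal.slice_window(*window)
    i_tlc = int(np.argmax(sub.volume))
    tail = sub.volume[i_tlc:]
    i_rv = i_tlc + int(np.argmin(tail))
    if i_rv - i_tlc < 2:
        raise ValueError(f"no expiration found in FVC window {window}")
    vol = sub.volume[i_tlc : i_rv + 1]
    flow = np.clip(sub.flow[i_tlc : i_rv + 1], 0.0, None)
    t = sub.time[i_tlc : i_rv + 1] - sub.time[i_tlc]
    return FVCManeuver(
        phase=phase,
        effort_pct=effort_pct,
        time=t,
        exp_flow=flow,
        expired_volume=vol[0] - vol,
    )


def build_mefv(
    maneuvers: list[FVCManeuver],
    smooth: int = 0,
    min_maneuvers_warn: int = 8,
) -> MEFVCurve:
    """Pointwise-maximum envelope over a set of graded FVC maneuvers.

    Each maneuver is anchored at TLC (its start maps to the session FVC,
    the largest FVC over the set), linearly interpolated onto the 0.01 L
    above-RV grid, and the envelope takes the per-volume maximum.  Volumes
    covered by no maneuver get flow 0 (the RV endpoint).  ``smooth`` > 0
    applies a moving average of that many grid points to the envelope
    (recommended ~5 for measured data; leave 0 for analytic inputs).

    Maneuvers with no expiration (non-increasing expired volume) are
    excluded with a warning.  Fewer than ``min_maneuvers_warn`` usable
    maneuvers logs a warning (graded-effort sets are normally >=8 per
    phase) but is not an error.
    """
    if not maneuvers:
        raise ValueError("need at least one FVC maneuver")
    usable = []
    for m in maneuvers:
        if np.max(m.expired_volume) <= 0:
            warnings.warn(
                f"excluding maneuver (phase={m.phase}, effort={m.effort_pct}%) "
                "with no expiration",
                stacklevel=2,
            )
            continue
        usable.append(m)
    if not usable:
        raise ValueError("no usable FVC maneuver (none shows expiration)")
    if len(usable) < min_maneuvers_warn:
        log.warning(
            "only %d usable FVC maneuvers (graded sets normally have >=%d)",
            len(usable),
            min_maneuvers_warn,
        )
    fvc = max(m.FVC_this for m in usable)
    # the grid stays inside [0, FVC] so every point has maneuver coverage
    n = int(np.floor(fvc / GRID_STEP + 1e-9)) + 1
    grid = np.arange(n) * GRID_STEP
    envelope = np.zeros(n)
    for m in usable:
        v = m.volume_above_RV(fvc)
        f = m.exp_flow
        # expired volume may be locally non-monotone on measured data; sort
        order = np.argsort(v, kind="stable")
        vs, fs = v[order], f[order]
        vs, uniq = np.unique(vs, return_index=True)
        fs = fs[uniq]
        interp = np.interp(grid, vs, fs, left=-np.inf, right=-np.inf)
        envelope = np.maximum(envelope, interp)
    envelope = np.clip(envelope, 0.0, None)
    if smooth and smooth > 1:
        kernel = np.ones(smooth) / smooth
        pad = smooth // 2
        padded = np.pad(envelope, pad, mode="edge")
        envelope = np.convolve(padded, kernel, mode="same")[pad : pad + n]
    return MEFVCurve(
        vol_grid=grid, max_flow=envelope, FVC=fvc, PEF=float(np.max(envelope))
    )


def spirometry_indices(maneuver: FVCManeuver) -> dict[str, float]:
    """FVC, FEV₁, PEF and FEF₂₅₋₇₅ from a (maximal) FVC maneuver.

    FEV₁ is the expired volume at t = 1.000 s (linear interpolation);
    FEF₂₅₋₇₅ is the mean flow over the middle half of the FVC, computed as
    0.5·FVC divided by the time to go from 25% to 75% of FVC expired.

    Raises
    ------
    ValueError
        If the maneuver lasts less than 1 s (FEV₁ undefined).
    """
    t = maneuver.time
    ev = maneuver.expired_volume
    if t.size < 2 or t[-1] <= 0:
        raise ValueError("zero-duration maneuver")
    if t[-1] < 1.0:
        raise ValueError(
            f"maneuver lasts {t[-1]:.3f} s < 1 s: FEV1 undefined"
        )
    fvc = float(np.max(ev))
    # expired volume is non-decreasing in a clean maneuver; enforce for interp
    ev_mono = np.maximum.accumulate(ev)
    fev1 = float(np.interp(1.0, t, ev_mono))
    t25 = float(np.interp(0.25 * fvc, ev_mono, t))
    t75 = float(np.interp(0.75 * fvc, ev_mono, t))
    if t75 <= t25:
        raise ValueError("degenerate maneuver: t(75% FVC) <= t(25% FVC)")
    return {
        "FVC": fvc,
        "FEV1": fev1,
        "PEF": float(np.max(maneuver.exp_flow)),
        "FEF25_75": 0.5 * fvc / (t75 - t25),
    }


def slope_ratio(
    curve: MEFVCurve,
    lo_frac: float = 0.20,
    hi_frac: float = 0.80,
    min_chord: float = 0.01,
) -> float:
    """Mean slope ratio over the effort-independent portion of the envelope.

    At each grid point with volume v (above RV) in [0.2·FVC, 0.8·FVC] the
    tangent slope dV̇/dV is estimated by central finite differences (one-
    sided at the boundary points) and the chord slope is V̇(v)/v — the
    slope of the line from the point to the RV intercept where flow is 0.
    SR(v) = tangent/chord; points with chord below ``min_chord``
    (L·s⁻¹·L⁻¹) are skipped.  Returns the arithmetic mean.

    SR = 1 for a linear descending limb through RV, > 1 for a concave
    (curvilinear) limb.

    Raises
    ------
    ValueError
        If fewer than 10 usable grid points fall in the volume range.
    """
    v = curve.vol_grid
    mask = (v >= lo_frac * curve.FVC - 1e-12) & (v <= hi_frac * curve.FVC + 1e-12)
    if np.count_nonzero(mask) < 10:
        raise ValueError("envelope does not cover 20-80% of FVC finely enough")
    vs = v[mask]
    fs = curve.max_flow[mask]
    tangent = np.gradient(fs, vs)
    chord = fs / vs
    ok = chord >= min_chord
    if np.count_nonzero(ok) < 10:
        raise ValueError("fewer than 10 usable points for slope ratio")
    return float(np.mean(tangent[ok] / chord[ok]))
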