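"""Expiratory flow limitation (EFL) assessment and ventilatory capacity.

The composite tidal flow-volume loop is placed on the absolute
(litres-above-RV) axis using the ERV from the stage's IC maneuver and
compared point-for-point against the maximal envelope.  A stage is
flow-limited when the tidal expiratory limb meets or exceeds the envelope
over at least ``threshold_pct`` (default 5%) of the tidal volume.

The same placement yields the theoretical ventilatory capacity V̇E,CAP:
the minute ventilation that would result if every expiration ran along
the envelope over the current tidal-volume placement, keeping the
measured inspiratory time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np

from .breaths import TidalFVCurve
from .mefv import MEFVCurve
from .signal_io import StageRecord
from .volumes import OperatingVolumes

__all__ = [
    "PlacedTidalCurve",
    "EFLResult",
    "place_tidal_curve",
    "assess_efl",
    "ve_cap",
    "match_ve_stages",
]

#: Flow floor (L·s⁻¹) when integrating 1/flow for the minimal expiratory time.
VECAP_FLOW_FLOOR = 0.05
#: Tolerated EILV overshoot above FVC before placement is an error, L.
EILV_SLACK = 0.05


@dataclass
class PlacedTidalCurve:
    """A tidal loop on the above-RV axis, with envelope flows alongside."""

    abs_vol_grid: np.ndarray  # L above RV (= ERV + relative volume)
    exp_flow: np.ndarray  # L·s⁻¹ tidal expiratory flow
    envelope_flow: np.ndarray  # L·s⁻¹ envelope flow at the same volumes
    VT: float
    TI: float
    TE: float


@dataclass
class EFLResult:
    EFL_present: bool
    EFL_pct_VT: float  # % of VT over which tidal flow meets the envelope
    overlap_volume: float  # L


def place_tidal_curve(
    tidal: TidalFVCurve,
    vols: OperatingVolumes,
    curve: MEFVCurve,
    TI: float = np.nan,
    TE: float = np.nan,
) -> PlacedTidalCurve:
    """Place the composite tidal curve inside the maximal envelope.

    Absolute volume = ERV + relative volume.  If the end-inspiratory
    volume exceeds FVC by up to 0.05 L (measurement noise) the grid is
    clipped at FVC with a warning; a larger overshoot is an error, as is
    a negative ERV.
    """
    erv = vols.ERV
    if erv < 0:
        raise ValueError(f"negative ERV ({erv:.3f} L): placement impossible")
    abs_grid = erv + tidal.rel_volume_grid
    overshoot = abs_grid[-1] - curve.FVC
    if overshoot > EILV_SLACK:
        raise ValueError(
            f"EILV exceeds FVC by {overshoot:.3f} L (> {EILV_SLACK} L slack)"
        )
    if overshoot > 0:
        warnings.warn(
            f"EILV exceeds FVC by {overshoot * 1e3:.0f} mL; clipping at TLC",
            stacklevel=2,
        )
        abs_grid = np.minimum(abs_grid, curve.FVC)
    return PlacedTidalCurve(
        abs_vol_grid=abs_grid,
        exp_flow=np.asarray(tidal.exp_flow, float),
        envelope_flow=curve.flow_at(abs_grid),
        VT=tidal.VT,
        TI=TI,
        TE=TE,
    )


def assess_efl(
    placed: PlacedTidalCurve,
    threshold_pct: float = 5.0,
    flow_tol: float = 0.0,
) -> EFLResult:
    """Detect and quantify expiratory flow limitation on a placed curve.

    A grid point is flow-limited when tidal expiratory flow >= envelope
    flow − ``flow_tol``.  The overlap volume is the sum of the volume-bin
    widths of flow-limited points (half-width bins at the grid ends);
    EFL is present when the overlap reaches ``threshold_pct`` % of VT.
    """
    v = placed.abs_vol_grid
    limited = placed.exp_flow >= placed.envelope_flow - flow_tol
    if v.size < 2:
        raise ValueError("placed curve needs at least 2 grid points")
    widths = np.empty_like(v)
    widths[1:-1] = (v[2:] - v[:-2]) / 2.0
    widths[0] = (v[1] - v[0]) / 2.0
    widths[-1] = (v[-1] - v[-2]) / 2.0
    overlap = float(np.sum(widths[limited]))
    pct = 100.0 * overlap / placed.VT if placed.VT > 0 else 0.0
    pct = float(np.clip(pct, 0.0, 100.0))
    return EFLResult(
        EFL_present=pct >= threshold_pct, EFL_pct_VT=pct, overlap_volume=overlap
    )


def ve_cap(
    curve: MEFVCurve,
    VT: float,
    ERV: float,
    TI: float,
    flow_floor: float = VECAP_FLOW_FLOOR,
) -> float:
    """Theoretical maximum minute ventilation for the current placement.

    The minimal expiratory time is the time to expire VT along the
    envelope: TE_min = ∫ dv / V̇max(v) over v in [ERV, ERV + VT]
    (trapezoidal on a fine grid; envelope flows below ``flow_floor`` are
    floored there to avoid divergence near RV).  Then
    V̇E,CAP = 60·VT / (TI + TE_min) with the stage's measured TI.

    Raises
    ------
    ValueError
        If the envelope is (essentially) zero across more than 20% of the
        tidal range — the placement is inconsistent with the envelope.
    """
    if VT <= 0 or TI <= 0:
        raise ValueError(f"VT and TI must be positive (VT={VT}, TI={TI})")
    if ERV < 0:
        raise ValueError(f"negative ERV ({ERV})")
    v = np.linspace(ERV, ERV + VT, 501)
    env = curve.flow_at(v)
    if np.mean(env < flow_floor) > 0.20:
        raise ValueError(
            "envelope is zero/near-zero across >20% of the tidal range; "
            "placement inconsistent with the MEFV curve"
        )
    te_min = float(np.trapezoid(1.0 / np.maximum(env, flow_floor), v))
    return 60.0 * VT / (TI + te_min)


def match_ve_stages(
    visit1: list[StageRecord],
    visit2: list[StageRecord],
    peak_VO2_1: float,
    peak_VO2_2: float,
    frac: float = 0.75,
) -> tuple[StageRecord, StageRecord]:
    """Pick the matched-ventilation stage pair across two visits.

    Eligible stages are those with V̇O₂ above ``frac`` of that visit's
    peak V̇O₂.  Over the Cartesian product of eligible stages the pair
    minimizing |V̇E₁ − V̇E₂| is returned; ties break toward the higher
    combined work rate, then toward visit-1 stage order.
    """
    elig1 = [r for r in visit1 if r.VO2 > frac * peak_VO2_1]
    elig2 = [r for r in visit2 if r.VO2 > frac * peak_VO2_2]
    if not elig1 or not elig2:
        raise ValueError(
            f"no stage above {100 * frac:.0f}% of peak VO2 on one of the visits"
        )
    best = None
    for k1, r1 in enumerate(elig1):
        for r2 in elig2:
            key = (abs(r1.VE - r2.VE), -(r1.work_W + r2.work_W), k1)
            if best is None or key < best[0]:
                best = (key, r1, r2)
    return best[1], best[2]
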