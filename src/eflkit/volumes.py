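"""Inspiratory capacity and operating lung volumes.

During exercise, absolute lung volume is not measurable from flow alone;
the inspiratory capacity (IC) maneuver — a maximal inspiration to total
lung capacity from tidal breathing — anchors the tidal loop within the
maximal envelope: with TLC fixed, IC locates the end-expiratory lung
volume as ERV = FVC − IC litres above residual volume.

Note on naming: the derived quantity ``IRV`` = ERV + VT is the
end-inspiratory lung volume above RV (EILV), not the conventional
inspiratory reserve IC − VT; both EELV/EILV aliases are exposed so
downstream code is unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .breaths import BreathTable, InsufficientDataError
from .signal_io import FlowVolumeSignal

__all__ = ["OperatingVolumes", "measure_ic", "derive_volumes"]


@dataclass
class OperatingVolumes:
    IC: float  # L
    ERV: float  # L, = FVC − IC
    IRV: float  # L, = ERV + VT (= EILV above RV)
    EELV_above_RV: float  # L, alias of ERV
    EILV_above_RV: float  # L, alias of ERV + VT


def measure_ic(
    signal: FlowVolumeSignal,
    ic_window: tuple[float, float],
    baseline_breaths: BreathTable,
    nadir_convention: bool = False,
) -> float:
    """Inspiratory capacity from an IC-maneuver window.

    The baseline end-expiratory volume is the mean of the end-expiratory
    volumes of the complete breaths preceding the maneuver (>=3 required);
    IC is the excursion from that baseline to the extreme volume reached
    during the maneuver.  With this package's polarity (volume rises with
    inspiration) the extreme is the window maximum; set
    ``nadir_convention=True`` for traces recorded with the inverted
    polarity, where the maneuver reaches a volume nadir.

    The signal must already be drift-corrected over the combined
    tidal + IC window.  A maneuver excursion smaller than the last tidal
    volume triggers a "submaximal IC?" warning (returned, not fatal).
    """
    if baseline_breaths.n < 3:
        raise InsufficientDataError(
            f"need >=3 baseline breaths for IC, got {baseline_breaths.n}"
        )
    eev = float(np.mean([b.EEV_end for b in baseline_breaths.breaths]))
    sub = signal.slice_window(*ic_window)
    if nadir_convention:
        ic = eev - float(np.min(sub.volume))
    else:
        ic = float(np.max(sub.volume)) - eev
    if ic <= 0:
        raise ValueError(
            f"IC maneuver shows no inspiratory excursion above baseline ({ic:.3f} L)"
        )
    last_vt = baseline_breaths.breaths[-1].VT_insp
    if ic < last_vt:
        warnings.warn(
            f"submaximal IC? maneuver excursion {ic:.2f} L is below the last "
            f"tidal volume {last_vt:.2f} L",
            stacklevel=2,
        )
    return ic


def derive_volumes(IC: float, FVC: float, VT: float) -> OperatingVolumes:
    """Operating lung volumes from IC, FVC and tidal volume.

    ERV = FVC − IC; IRV = ERV + VT (end-inspiratory lung volume
    above RV).  Raises if IC exceeds FVC (inconsistent calibration) or if
    IC or VT is non-positive.  EILV above FVC (VT > IC) is allowed with a
    warning — it indicates measurement inconsistency, handled downstream
    by clipping at placement.
    """
    if IC <= 0 or VT <= 0:
        raise ValueError(f"IC and VT must be positive (IC={IC}, VT={VT})")
    if IC > FVC + 1e-9:
        raise ValueError(
            f"IC ({IC:.3f} L) exceeds FVC ({FVC:.3f} L): inconsistent calibration"
        )
    erv = FVC - IC
    eilv = erv + VT
    if VT > IC:
        warnings.warn(
            f"EILV {eilv:.2f} L exceeds FVC {FVC:.2f} L (VT > IC)", stacklevel=2
        )
    return OperatingVolumes(
        IC=IC, ERV=erv, IRV=eilv, EELV_above_RV=erv, EILV_above_RV=eilv
    )
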