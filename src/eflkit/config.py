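"""Run configuration: every tunable of the analysis pipeline in one place."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict


class RunConfig(BaseModel):
    """Pipeline tunables.  Unknown keys are rejected.

    ``flow_tol`` deserves a note: flow limitation is decided as
    tidal flow >= envelope flow − flow_tol.  For analytic inputs the
    strict comparison (0) is exact, but on sampled data the tidal
    composite and the envelope each pass through interpolation, so a
    small slack comparable to the flow-noise level is the working
    default.
    """

    model_config = ConfigDict(extra="forbid")

    #: EFL-presence threshold, % of tidal volume overlapping the envelope.
    threshold_pct: float = 5.0
    #: Slack on the flow comparison, L·s⁻¹ (of the order of the flow
    #: noise; 0 gives the strict comparison for analytic inputs).
    flow_tol: float = 0.02
    #: Bins of the composite tidal flow-volume curve.
    n_bins: int = 101
    #: Minimum inspired volume for a breath, L.
    min_VT: float = 0.10
    #: Hysteresis half-band for breath-phase detection, L·s⁻¹.
    hysteresis_flow: float = 0.05
    #: Moving-average width (samples) on flow before compositing; 0 = off.
    smoothing: int = 0
    #: Moving-average width (grid points) on the measured envelope; 0 = off.
    envelope_smooth: int = 5
    #: ICC model: ICC(2,1) absolute agreement or ICC(3,1) consistency.
    icc_form: Literal["ICC2", "ICC3"] = "ICC2"
    #: Inspiratory-time source for ventilatory capacity.
    vecap_ti_mode: Literal["measured", "fixed_fraction"] = "measured"
    #: TI/Ttot used when ``vecap_ti_mode == "fixed_fraction"``.
    vecap_ti_fraction: float = 0.45
    #: Flip input flow polarity (for recordings with inspiration positive).
    invert_flow: bool = False
    #: Fraction of peak V̇O₂ above which stages are matched across visits.
    match_vo2_frac: float = 0.75
    seed: int = 0

    def echo(self) -> str:
        return " ".join(f"{k}={v}" for k, v in self.model_dump().items())
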