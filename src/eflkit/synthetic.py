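"""Synthetic two-visit incremental-exercise studies with known ground truth.

The generator emulates the raw material of an exercise flow-limitation
study so that every step of the analysis pipeline can be validated
against known truth:

* an analytic maximal envelope ``V̇max(v) = PEF·(v/FVC)^s`` on the
  litres-above-RV axis (the shape exponent ``s`` is exactly the
  slope-ratio index of the descending limb);
* graded FVC maneuvers (25/50/75/100% effort) whose attainment of the
  envelope varies with lung volume the way thoracic gas compression
  does — submaximal efforts fall short near TLC but are the best efforts
  at low lung volumes — and whose pointwise maximum reproduces the
  envelope;
* quasi-periodic tidal breathing (half-sine inspiration, early-peaking
  expiration) with per-breath variability, Gaussian flow noise and a
  linear volume-channel drift, ending in an IC maneuver to TLC;
* an induced-EFL mechanism: the expiratory limb is generated as
  ``min(desired flow, envelope flow at the placed volume)`` with the
  demand amplitude solved so the volume fraction where clipping binds
  matches a requested overlap percentage;
* two visits per participant, visit-2 parameters perturbed from visit-1
  by configurable between-day coefficients of variation.

Default parameter ranges are physiologic for healthy adults of average
fitness (FVC 4.88 ± 0.99 L, PEF 9.68 ± 2.16 L·s⁻¹, peak VT
2.41 ± 0.56 L, peak fB 46 ± 8 min⁻¹, peak work 211 ± 51 W in 20 W
steps).  These are generator priors, not asserted outputs.

Randomness follows a single hierarchical stream contract: the study seed
spawns one child sequence per participant, each of which spawns one per
visit, which spawns one per stage — so adding a participant never
perturbs earlier participants' data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .mefv import FVCManeuver
from .signal_io import (
    FlowVolumeSignal,
    FVCWindow,
    ICWindow,
    SessionManifest,
    StageMetabolics,
    StageWindow,
    write_waveform,
)

__all__ = [
    "ParticipantParams",
    "StudyConfig",
    "SyntheticSession",
    "SyntheticStudy",
    "envelope_flow",
    "gen_mefv",
    "gen_stage_waveform",
    "gen_session",
    "gen_two_visit_study",
    "write_dataset",
]

#: Default between-day coefficients of variation, % (multiplicative
#: perturbation of visit-1 parameters), in the range reported for
#: repeated exercise testing.
DEFAULT_BETWEEN_DAY_CV: dict[str, float] = {
    "FVC": 3.5,
    "PEF": 4.0,
    "SR": 5.0,
    "VT": 3.2,
    "fB": 6.0,
    "IC": 3.5,
    "EELV": 9.0,
    "EFL": 30.0,
    "W": 3.0,
    "VO2": 5.0,
}


@dataclass
class ParticipantParams:
    """Ground-truth physiology for one participant-visit."""

    FVC_true: float  # L
    PEF_true: float  # L·s⁻¹
    sr_shape: float  # envelope exponent = slope ratio of the limb
    W_max: float  # peak work rate, W (20 W multiple)
    VT_by_stage: dict[str, float] = field(default_factory=dict)  # L
    fB_by_stage: dict[str, float] = field(default_factory=dict)  # min⁻¹
    EELV_above_RV_by_stage: dict[str, float] = field(default_factory=dict)  # L
    efl_target_by_stage: dict[str, float] = field(default_factory=dict)  # %VT
    VO2_by_stage: dict[str, float] = field(default_factory=dict)  # L·min⁻¹
    VCO2_by_stage: dict[str, float] = field(default_factory=dict)  # L·min⁻¹
    drift_rate: float = 0.0  # L·s⁻¹ volume-channel drift
    noise_sd_flow: float = 0.02  # L·s⁻¹ white flow noise
    efl_target_pct: float = 0.0  # intended %VT overlap at peak
    TI_fraction: float = 0.45  # TI / Ttot

    @property
    def stage_labels(self) -> list[str]:
        return list(self.VT_by_stage)


@dataclass
class StudyConfig:
    n_participants: int = 32
    seed: int = 0
    between_day_cv: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETWEEN_DAY_CV)
    )
    work_step_W: float = 20.0
    fs: float = 200.0
    tidal_seconds: float = 31.0  # tidal window length before the IC maneuver
    #: fraction of participants carrying an EFL propensity, and the
    #: normal prior (mean, sd, clipped to [0.5, 75] %VT) of its magnitude
    #: at peak.  Means near the 5% detection threshold produce borderline,
    #: day-to-day-unstable flow limitation.
    efl_propensity: float = 0.42
    efl_target_mean: float = 26.0
    efl_target_sd: float = 18.0


@dataclass
class SyntheticSession:
    signal: FlowVolumeSignal
    manifest: SessionManifest
    maneuvers: list[FVCManeuver]  # noiseless ground-truth maneuvers
    truth: pd.DataFrame  # per-stage ground truth
    params: ParticipantParams


@dataclass
class SyntheticStudy:
    config: StudyConfig
    sessions: dict[tuple[str, int], SyntheticSession]  # (participant, visit)
    truth: pd.DataFrame

    @property
    def participant_ids(self) -> list[str]:
        return sorted({pid for pid, _ in self.sessions})


# ---------------------------------------------------------------------------
# Envelope and graded maneuvers
# ---------------------------------------------------------------------------


def envelope_flow(
    v_above_rv: np.ndarray | float, params: ParticipantParams
) -> np.ndarray:
    """True maximal expiratory flow at a lung volume (L above RV)."""
    v = np.clip(np.asarray(v_above_rv, float), 0.0, None)
    return params.PEF_true * (v / params.FVC_true) ** params.sr_shape


#: (effort %, volume window as fractions of FVC where the effort attains
#: the true envelope).  Windows overlap and cover [0, 1]: the 100% effort
#: wins near TLC, lower efforts win toward RV (gas-compression emulation).
_EFFORT_WINDOWS = [
    (100.0, 0.55, 1.00),
    (75.0, 0.35, 0.60),
    (50.0, 0.15, 0.40),
    (25.0, 0.00, 0.20),
]

_MANEUVER_FLOW_FLOOR = 0.05  # L·s⁻¹, stop expiring below this flow


def _attainment(u: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fraction of the true envelope an effort achieves at volume fraction u."""
    dist = np.where(u < lo, lo - u, np.where(u > hi, u - hi, 0.0))
    return np.maximum(1.0 - 1.6 * dist, 0.25)


def _maneuver_flow_of_volume(
    v: np.ndarray, params: ParticipantParams, lo: float, hi: float
) -> np.ndarray:
    return envelope_flow(v, params) * _attainment(v / params.FVC_true, lo, hi)


def _maneuver_timeseries(
    params: ParticipantParams, lo: float, hi: float, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """(exp_flow, volume_above_RV) of one graded expiration sampled at fs."""
    fvc = params.FVC_true
    v_grid = np.linspace(fvc, 0.0, 2001)
    f_grid = _maneuver_flow_of_volume(v_grid, params, lo, hi)
    # expiration continues to RV at a floored trickle flow, so every
    # maneuver empties the full vital capacity
    f_grid = np.maximum(f_grid, _MANEUVER_FLOW_FLOOR)
    # time to reach each volume: dt = -dv / flow  (v decreasing)
    dt = -np.diff(v_grid) / (0.5 * (f_grid[1:] + f_grid[:-1]))
    t_of_v = np.concatenate([[0.0], np.cumsum(dt)])
    t = np.arange(0.0, t_of_v[-1], 1.0 / fs)
    v_t = np.interp(t, t_of_v, v_grid)
    f_t = np.interp(t, t_of_v, f_grid)
    return f_t, v_t


def gen_mefv(
    params: ParticipantParams, rng: np.random.Generator, fs: float = 200.0
) -> tuple[np.ndarray, np.ndarray, list[FVCManeuver]]:
    """Generate the analytic envelope and its graded FVC maneuver set.

    Returns ``(vol_grid, true_envelope, maneuvers)`` where the eight
    maneuvers (4 pre-, 4 post-exercise efforts at 25/50/75/100%) are
    noiseless and their pointwise maximum reproduces the true envelope
    (to interpolation accuracy) wherever expiratory flow exceeds the
    0.05 L·s⁻¹ termination floor.
    """
    fvc = params.FVC_true
    grid = np.arange(int(np.floor(fvc / 0.01 + 1e-9)) + 1) * 0.01
    true_env = envelope_flow(grid, params)
    maneuvers = []
    for phase in ("pre", "post"):
        for effort, lo, hi in _EFFORT_WINDOWS:
            f_t, v_t = _maneuver_timeseries(params, lo, hi, fs)
            t = np.arange(f_t.size) / fs
            maneuvers.append(
                FVCManeuver(
                    phase=phase,
                    effort_pct=effort,
                    time=t,
                    exp_flow=f_t,
                    expired_volume=fvc - v_t,
                )
            )
    return grid, true_env, maneuvers


# ---------------------------------------------------------------------------
# Tidal breathing and the IC maneuver
# ---------------------------------------------------------------------------

_X = np.linspace(0.0, 1.0, 801)  # expired volume fraction within a breath


def _exp_shape(x: np.ndarray) -> np.ndarray:
    """Early-peaking expiratory flow profile over expired fraction x.

    Peaks near one third of expired volume so flow limitation engages at
    the low-lung-volume end of the breath first.
    """
    s = x**0.6 * (1.0 - x) ** 1.1
    s /= s.max()
    return np.maximum(s, 0.06)


def _overlap_fraction(
    amp: float, shape: np.ndarray, env_at_x: np.ndarray
) -> float:
    """Volume fraction of the breath where demand meets the envelope."""
    return float(np.trapezoid((amp * shape >= env_at_x).astype(float), _X))


def _solve_breath_amplitude(
    VT: float,
    TE_nom: float,
    EELV: float,
    params: ParticipantParams,
    target_pct: float,
) -> float:
    """Demand amplitude for one expiration.

    Without flow limitation the amplitude reproduces the nominal
    expiratory time.  With a requested overlap target the amplitude is
    found by bisection so that clipping binds over ``target_pct`` % of
    the expired volume; without a target the amplitude is capped just
    below the envelope so the breath is guaranteed free of limitation.
    """
    shape = _exp_shape(_X)
    env_at_x = envelope_flow(EELV + VT * (1.0 - _X), params)
    amp_nom = VT * float(np.trapezoid(1.0 / shape, _X)) / TE_nom
    amp_touch = float(np.min(env_at_x / shape))
    # targets under 2% of VT are below the generator's resolution: the
    # breath stays clearly below the envelope (no tangential graze), so
    # near-threshold physiology genuinely disengages between days
    if target_pct < 2.0:
        return min(amp_nom, 0.92 * amp_touch)
    lo, hi = amp_touch, amp_touch * 50.0
    goal = target_pct / 100.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _overlap_fraction(mid, shape, env_at_x) < goal:
            lo = mid
        else:
            hi = mid
    return hi


def _gen_expiration(
    VT: float,
    TE_nom: float,
    EELV: float,
    params: ParticipantParams,
    target_pct: float,
    fs: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One expiratory limb sampled at fs.

    Returns ``(flow, volume_above_RV, true_overlap_pct)``; flow is the
    demand profile clipped at the envelope, so the realized expiratory
    time may exceed the nominal one.
    """
    shape = _exp_shape(_X)
    env_at_x = envelope_flow(EELV + VT * (1.0 - _X), params)
    amp = _solve_breath_amplitude(VT, TE_nom, EELV, params, target_pct)
    f_x = np.minimum(amp * shape, env_at_x)
    overlap = _overlap_fraction(amp, shape, env_at_x)
    # time as a function of expired fraction: dt = VT dx / flow
    dt = VT * np.diff(_X) / (0.5 * (f_x[1:] + f_x[:-1]))
    t_of_x = np.concatenate([[0.0], np.cumsum(dt)])
    te = t_of_x[-1]
    t = np.arange(1, int(te * fs) + 1) / fs
    x_t = np.interp(t, t_of_x, _X)
    flow = np.interp(x_t, _X, f_x)
    vol = EELV + VT * (1.0 - x_t)
    return flow, vol, 100.0 * overlap


def _gen_inspiration(
    VT: float, TI: float, start_vol: float, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Half-sine inspiratory limb (negative flow), sampled at fs."""
    t = np.arange(1, int(TI * fs) + 1) / fs
    flow = -(np.pi * VT / (2.0 * TI)) * np.sin(np.pi * t / TI)
    vol = start_vol + VT * (1.0 - np.cos(np.pi * t / TI)) / 2.0
    return flow, vol


def gen_stage_waveform(
    params: ParticipantParams,
    stage_label: str,
    rng: np.random.Generator,
    fs: float = 200.0,
    tidal_seconds: float = 31.0,
) -> tuple[np.ndarray, np.ndarray, float, dict]:
    """Tidal breathing plus an end-stage IC maneuver for one stage.

    Returns ``(flow, volume_above_RV, t_ic_start, truth)`` where the
    truth dict carries the realized mean VT, fB, TI, TE, the IC and EELV,
    and the volume-weighted mean of the per-breath true overlap
    percentages.  The flow trace carries Gaussian noise; the volume trace
    is the noiseless lung volume (the deterministic channel drift is
    added at session assembly).

    Raises
    ------
    ValueError
        If the requested EELV + VT exceeds FVC.
    """
    VT = params.VT_by_stage[stage_label]
    fB = params.fB_by_stage[stage_label]
    EELV = params.EELV_above_RV_by_stage[stage_label]
    target = params.efl_target_by_stage.get(stage_label, 0.0)
    if EELV + VT > params.FVC_true:
        raise ValueError(
            f"stage {stage_label}: EELV + VT = {EELV + VT:.2f} L exceeds "
            f"FVC {params.FVC_true:.2f} L"
        )
    ttot = 60.0 / fB
    flows, vols = [], []
    breath_truth = []
    elapsed = 0.0
    while elapsed < tidal_seconds:
        vt_b = VT * (1.0 + 0.03 * rng.standard_normal())
        ti_b = params.TI_fraction * ttot * (1.0 + 0.02 * rng.standard_normal())
        te_nom = (1.0 - params.TI_fraction) * ttot
        fi, vi = _gen_inspiration(vt_b, ti_b, EELV, fs)
        fe, ve, ov = _gen_expiration(vt_b, te_nom, EELV, params, target, fs)
        flows += [fi, fe]
        vols += [vi, ve]
        dur = (fi.size + fe.size) / fs
        breath_truth.append((vt_b, ti_b, fe.size / fs, ov))
        elapsed += dur
    t_ic_start = elapsed
    # IC maneuver: maximal inspiration from EEV to TLC, brief hold, return
    ic_true = params.FVC_true - EELV
    fi, vi = _gen_inspiration(ic_true, 2.2, EELV, fs)
    hold_n = int(0.25 * fs)
    fh = np.zeros(hold_n)
    vh = np.full(hold_n, vi[-1] if vi.size else EELV + ic_true)
    fe, ve, _ = _gen_expiration(ic_true, 2.2, EELV, params, 0.0, fs)
    flows += [fi, fh, fe]
    vols += [vi, vh, ve]
    flow = np.concatenate(flows)
    vol = np.concatenate(vols)
    flow = flow + rng.normal(0.0, params.noise_sd_flow, flow.size)
    vts = np.array([b[0] for b in breath_truth])
    tis = np.array([b[1] for b in breath_truth])
    tes = np.array([b[2] for b in breath_truth])
    ovs = np.array([b[3] for b in breath_truth])
    truth = {
        "VT": float(vts.mean()),
        "fB": 60.0 * vts.size / float((tis + tes).sum()),
        "TI": float(tis.mean()),
        "TE": float(tes.mean()),
        "IC": ic_true,
        "EELV_above_RV": EELV,
        "EFL_pct_VT": float(np.average(ovs, weights=vts)),
        "efl_target_pct": target,
        "drift_rate": params.drift_rate,
        "n_breaths": int(vts.size),
    }
    return flow, vol, t_ic_start, truth


# ---------------------------------------------------------------------------
# Session and study assembly
# ---------------------------------------------------------------------------


def _stage_schedule(
    rng: np.random.Generator,
    fvc: float,
    ic_rest: float,
    erv_peak: float,
    vt_peak: float,
    fb_peak: float,
    w_max: float,
    efl_target_peak: float,
    vo2_slope: float,
    work_step: float,
) -> dict[str, dict[str, float]]:
    """Per-stage (rest + 20 W steps) ventilatory / metabolic targets."""
    works = [0.0] + list(np.arange(work_step, w_max + 1e-9, work_step))
    eelv_rest = fvc - ic_rest
    vt_rest = min(0.75 * (1.0 + 0.1 * rng.standard_normal()), 0.9 * ic_rest)
    fb_rest = 14.0 + 2.0 * rng.standard_normal()
    out: dict[str, dict[str, float]] = {}
    for w in works:
        u = w / w_max
        vt = vt_rest + (vt_peak - vt_rest) * np.tanh(2.2 * u) / np.tanh(2.2)
        fb = fb_rest + (fb_peak - fb_rest) * u**1.6
        eelv = eelv_rest + (erv_peak - eelv_rest) * u
        vt = min(vt, fvc - eelv - 0.15)  # leave inspiratory headroom
        if efl_target_peak > 0 and u >= 0.999:
            target = efl_target_peak
        elif efl_target_peak > 25 and u >= 1.0 - work_step / w_max - 1e-9:
            target = 0.4 * efl_target_peak
        else:
            target = 0.0
        vo2 = (0.35 + vo2_slope * w) * (1.0 + 0.02 * rng.standard_normal())
        rer = 0.82 + 0.33 * u**1.5
        label = "rest" if w == 0 else f"{int(w)}W"
        out[label] = {
            "work_W": w,
            "VT": float(vt),
            "fB": float(fb),
            "EELV": float(eelv),
            "target": float(target),
            "VO2": float(vo2),
            "VCO2": float(vo2 * rer),
        }
    return out


def _draw_visit1_params(
    rng: np.random.Generator,
    work_step: float,
    efl_propensity: float = 0.42,
    efl_target_mean: float = 26.0,
    efl_target_sd: float = 18.0,
) -> ParticipantParams:
    def tnorm(mean, sd, lo, hi):
        return float(np.clip(mean + sd * rng.standard_normal(), lo, hi))

    fvc = tnorm(4.88, 0.99, 3.2, 7.5)
    pef = tnorm(9.68, 2.16, 6.0, 15.0)
    sr = tnorm(1.13, 0.22, 0.65, 1.8)
    ic_rest = tnorm(2.78, 0.63, 1.6, fvc - 0.8)
    erv_peak = tnorm(1.79, 0.52, 0.8, min(3.0, fvc - 1.8))
    vt_peak = tnorm(2.41, 0.56, 1.4, fvc - erv_peak - 0.2)
    fb_peak = tnorm(46.0, 8.0, 30.0, 65.0)
    w_max = float(np.clip(round((211.0 + 51.0 * rng.standard_normal()) / work_step), 6, 16) * work_step)
    vo2_slope = tnorm(0.0135, 0.0015, 0.010, 0.018)
    # a minority of participants carry an EFL propensity; the magnitude
    # prior is broad and allowed to fall under the 5%-of-VT detection
    # threshold, so a default study has a flow-limited fraction near 40%
    # with a tail of borderline, day-to-day-unstable cases.
    if rng.uniform() < efl_propensity:
        efl_target = tnorm(efl_target_mean, efl_target_sd, 0.5, 75.0)
    else:
        efl_target = 0.0
    p = ParticipantParams(
        FVC_true=fvc,
        PEF_true=pef,
        sr_shape=sr,
        W_max=w_max,
        drift_rate=float(rng.uniform(-0.005, 0.005)),
        noise_sd_flow=0.02,
        efl_target_pct=efl_target,
        TI_fraction=tnorm(0.45, 0.03, 0.38, 0.52),
    )
    sched = _stage_schedule(
        rng, fvc, ic_rest, erv_peak, vt_peak, fb_peak, w_max, efl_target,
        vo2_slope, work_step,
    )
    _apply_schedule(p, sched)
    return p


def _apply_schedule(p: ParticipantParams, sched: dict[str, dict[str, float]]) -> None:
    p.VT_by_stage = {k: v["VT"] for k, v in sched.items()}
    p.fB_by_stage = {k: v["fB"] for k, v in sched.items()}
    p.EELV_above_RV_by_stage = {k: v["EELV"] for k, v in sched.items()}
    p.efl_target_by_stage = {k: v["target"] for k, v in sched.items()}
    p.VO2_by_stage = {k: v["VO2"] for k, v in sched.items()}
    p.VCO2_by_stage = {k: v["VCO2"] for k, v in sched.items()}
    p._works = {k: v["work_W"] for k, v in sched.items()}  # type: ignore[attr-defined]


def _perturb_for_visit2(
    p1: ParticipantParams,
    cv: dict[str, float],
    rng: np.random.Generator,
    work_step: float,
) -> ParticipantParams:
    """Visit-2 parameters: visit-1 × (1 + CV·z), z ~ N(0,1) per parameter."""

    def jig(value, key, lo=None, hi=None):
        v = value * (1.0 + cv.get(key, 0.0) / 100.0 * rng.standard_normal())
        if lo is not None:
            v = max(v, lo)
        if hi is not None:
            v = min(v, hi)
        return float(v)

    fvc = jig(p1.FVC_true, "FVC", lo=3.0)
    pef = jig(p1.PEF_true, "PEF", lo=5.0)
    sr = jig(p1.sr_shape, "SR", lo=0.6, hi=2.0)
    works1: dict[str, float] = p1._works  # type: ignore[attr-defined]
    ic_rest1 = p1.FVC_true - p1.EELV_above_RV_by_stage["rest"]
    peak1 = list(works1)[-1]
    erv_peak1 = p1.EELV_above_RV_by_stage[peak1]
    vt_peak1 = p1.VT_by_stage[peak1]
    fb_peak1 = p1.fB_by_stage[peak1]
    ic_rest = jig(ic_rest1, "IC", lo=1.4, hi=fvc - 0.6)
    erv_peak = jig(erv_peak1, "EELV", lo=0.7, hi=fvc - 1.6)
    vt_peak = jig(vt_peak1, "VT", lo=1.2, hi=fvc - erv_peak - 0.2)
    fb_peak = jig(fb_peak1, "fB", lo=28.0, hi=70.0)
    w_max = float(
        np.clip(round(jig(p1.W_max, "W") / work_step), 6, 16) * work_step
    )
    efl_target = (
        jig(p1.efl_target_pct, "EFL", lo=0.0, hi=85.0)
        if p1.efl_target_pct > 0
        else 0.0
    )
    vo2_peak1 = p1.VO2_by_stage[peak1]
    vo2_slope = max((jig(vo2_peak1, "VO2") - 0.35) / max(w_max, 1.0), 0.008)
    p2 = ParticipantParams(
        FVC_true=fvc,
        PEF_true=pef,
        sr_shape=sr,
        W_max=w_max,
        drift_rate=float(rng.uniform(-0.005, 0.005)),
        noise_sd_flow=p1.noise_sd_flow,
        efl_target_pct=efl_target,
        TI_fraction=p1.TI_fraction,
    )
    sched = _stage_schedule(
        rng, fvc, ic_rest, erv_peak, vt_peak, fb_peak, w_max, efl_target,
        vo2_slope, work_step,
    )
    _apply_schedule(p2, sched)
    return p2


def single_stage_params(
    FVC_true: float = 4.9,
    PEF_true: float = 9.7,
    sr_shape: float = 1.13,
    VT: float = 2.4,
    fB: float = 45.0,
    EELV_above_RV: float = 1.8,
    efl_target_pct: float = 0.0,
    work_W: float = 200.0,
    VO2: float = 3.3,
    **kwargs,
) -> ParticipantParams:
    """A participant with a single exercise stage — convenient for
    exercising the pipeline under one controlled breathing condition."""
    p = ParticipantParams(
        FVC_true=FVC_true, PEF_true=PEF_true, sr_shape=sr_shape,
        W_max=work_W, efl_target_pct=efl_target_pct, **kwargs,
    )
    label = f"{int(work_W)}W"
    sched = {
        label: {
            "work_W": work_W, "VT": VT, "fB": fB, "EELV": EELV_above_RV,
            "target": efl_target_pct, "VO2": VO2, "VCO2": VO2 * 1.1,
        }
    }
    _apply_schedule(p, sched)
    return p


_GAP_SECONDS = 1.0  # quiet-flow padding between recorded segments


def gen_session(
    params: ParticipantParams,
    participant_id: str,
    visit: int,
    rng: np.random.Generator,
    fs: float = 200.0,
    tidal_seconds: float = 31.0,
) -> SyntheticSession:
    """Assemble one continuous recording: pre-exercise graded FVC
    maneuvers, every exercise stage (tidal breathing + IC maneuver), and
    post-exercise maneuvers, with the manifest annotating every window.
    """
    _, _, maneuvers = gen_mefv(params, rng, fs)
    seg_flow: list[np.ndarray] = []
    seg_vol: list[np.ndarray] = []
    fvc_windows: list[FVCWindow] = []
    stage_windows: list[StageWindow] = []
    ic_windows: list[ICWindow] = []
    metabolics: list[StageMetabolics] = []
    truth_rows = []
    t_cursor = 0.0
    gap_n = int(_GAP_SECONDS * fs)

    def push(flow: np.ndarray, vol: np.ndarray) -> tuple[float, float]:
        nonlocal t_cursor
        t0 = t_cursor
        seg_flow.append(flow)
        seg_vol.append(vol)
        t_cursor += flow.size / fs
        # quiet gap: zero flow, constant volume
        seg_flow.append(np.zeros(gap_n))
        seg_vol.append(np.full(gap_n, vol[-1]))
        t_cursor += _GAP_SECONDS
        return t0, t0 + flow.size / fs

    def push_maneuver(m: FVCManeuver, phase: str) -> None:
        # deep breath from a mid lung volume to TLC, then the graded expiration
        eelv0 = max(params.FVC_true - 2.8, 0.5)
        fi, vi = _gen_inspiration(params.FVC_true - eelv0, 1.6, eelv0, fs)
        flow = np.concatenate([fi, m.exp_flow])
        vol = np.concatenate([vi, params.FVC_true - m.expired_volume])
        t0, t1 = push(flow, vol)
        fvc_windows.append(
            FVCWindow(phase=phase, effort_pct=m.effort_pct, t_start=t0, t_end=t1)
        )

    for m in maneuvers:
        if m.phase == "pre":
            push_maneuver(m, "pre")
    for label in params.stage_labels:
        flow, vol, t_ic, truth = gen_stage_waveform(
            params, label, rng, fs, tidal_seconds
        )
        t0, t1 = push(flow, vol)
        stage_windows.append(
            StageWindow(
                label=label,
                t_start=t0,
                t_end=t0 + t_ic,
                work_W=params._works[label],  # type: ignore[attr-defined]
            )
        )
        ic_windows.append(
            ICWindow(stage_label=label, t_start=t0 + t_ic, t_end=t1)
        )
        metabolics.append(
            StageMetabolics(
                stage_label=label,
                VO2=params.VO2_by_stage[label],
                VCO2=params.VCO2_by_stage[label],
            )
        )
        truth_rows.append(
            {"participant_id": participant_id, "visit": visit, "stage_label": label,
             "work_W": params._works[label], **truth}  # type: ignore[attr-defined]
        )
    for m in maneuvers:
        if m.phase == "post":
            push_maneuver(m, "post")

    flow = np.concatenate(seg_flow)
    vol = np.concatenate(seg_vol)
    time = np.arange(flow.size) / fs
    vol = vol + params.drift_rate * time  # volume-channel drift
    signal = FlowVolumeSignal(time=time, flow=flow, volume=vol, fs=fs)
    manifest = SessionManifest(
        participant_id=participant_id,
        visit=visit,
        stage_windows=stage_windows,
        ic_windows=ic_windows,
        fvc_windows=fvc_windows,
        stage_metabolics=metabolics,
    )
    manifest.validate_against(signal)
    truth = pd.DataFrame(truth_rows)
    truth["FVC_true"] = params.FVC_true
    truth["PEF_true"] = params.PEF_true
    truth["SR_true"] = params.sr_shape
    return SyntheticSession(
        signal=signal, manifest=manifest, maneuvers=maneuvers, truth=truth,
        params=params,
    )


def gen_two_visit_study(cfg: StudyConfig) -> SyntheticStudy:
    """Generate a complete two-visit study in memory.

    Deterministic for a fixed ``cfg.seed``; participants draw from
    independent child streams so the first k participants are identical
    across study sizes >= k.
    """
    root = np.random.SeedSequence(cfg.seed)
    sessions: dict[tuple[str, int], SyntheticSession] = {}
    truths = []
    for i, pseq in enumerate(root.spawn(cfg.n_participants)):
        pid = f"P{i + 1:02d}"
        sub = pseq.spawn(3)
        p1 = _draw_visit1_params(
            np.random.default_rng(sub[0]), cfg.work_step_W,
            cfg.efl_propensity, cfg.efl_target_mean, cfg.efl_target_sd,
        )
        p2 = _perturb_for_visit2(
            p1, cfg.between_day_cv, np.random.default_rng(sub[1]), cfg.work_step_W
        )
        for visit, params, vseq in ((1, p1, sub[0]), (2, p2, sub[1])):
            rng = np.random.default_rng(vseq.spawn(1)[0])
            s = gen_session(
                params, pid, visit, rng, cfg.fs, cfg.tidal_seconds
            )
            sessions[(pid, visit)] = s
            truths.append(s.truth)
    return SyntheticStudy(
        config=cfg, sessions=sessions, truth=pd.concat(truths, ignore_index=True)
    )


def write_dataset(study: SyntheticStudy, out_dir: str | Path) -> None:
    """Persist a study as waveform CSVs, manifest JSONs and truth.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (pid, visit), s in study.sessions.items():
        stem = out / f"{pid}_v{visit}"
        write_waveform(s.signal, f"{stem}_waveform.csv")
        s.manifest.to_json(f"{stem}_manifest.json")
    study.truth.to_csv(out / "truth.csv", index=False)
    (out / "study_config.json").write_text(
        json.dumps(
            {
                "n_participants": study.config.n_participants,
                "seed": study.config.seed,
                "between_day_cv": study.config.between_day_cv,
                "fs": study.config.fs,
            },
            indent=2,
        )
    )
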