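"""End-to-end session analysis and two-visit repeatability.

Per session (one participant, one visit): build the maximal envelope
from the graded FVC maneuvers, then for each stage drift-correct the
combined tidal + IC window, segment the breaths, composite-average the
tidal loop, measure IC, derive the operating lung volumes, place the
loop inside the envelope, assess flow limitation and compute the
ventilatory capacity.  Across visits: peak-exercise and matched-
ventilation repeatability (Cohen's κ, ICC, between-day CV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import breaths as br
from . import efl as efl_mod
from . import mefv as mefv_mod
from . import repeatability as rep
from .config import RunConfig
from .signal_io import FlowVolumeSignal, SessionManifest, StageRecord
from .volumes import derive_volumes, measure_ic

__all__ = [
    "SessionResult",
    "analyze_session",
    "analyze_study",
    "peak_stage",
    "repeatability_report",
    "study_repeatability",
]

log = logging.getLogger(__name__)


@dataclass
class SessionResult:
    participant_id: str
    visit: int
    mefv: mefv_mod.MEFVCurve | None
    spirometry: dict[str, float]
    records: list[StageRecord]
    drift_slopes: dict[str, float] = field(default_factory=dict)

    @property
    def peak_VO2(self) -> float:
        vals = [r.VO2 for r in self.records if np.isfinite(r.VO2)]
        return max(vals) if vals else np.nan

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"participant_id": self.participant_id, "visit": self.visit,
             **r.__dict__}
            for r in self.records
        ]
        return pd.DataFrame(rows)


def analyze_session(
    signal: FlowVolumeSignal,
    manifest: SessionManifest,
    config: RunConfig | None = None,
) -> SessionResult:
    """Run the full per-session pipeline; returns one record per stage."""
    cfg = config or RunConfig()
    manifest.validate_against(signal)
    if cfg.invert_flow:
        signal = FlowVolumeSignal(
            signal.time, -signal.flow, -signal.volume, signal.fs
        )
    maneuvers = [
        mefv_mod.extract_fvc_maneuver(
            signal, (w.t_start, w.t_end), w.phase, w.effort_pct
        )
        for w in manifest.fvc_windows
    ]
    curve = mefv_mod.build_mefv(maneuvers, smooth=cfg.envelope_smooth)
    # spirometry comes from the maximal-effort maneuver: among the graded
    # set, the one with the highest peak flow (ties toward larger FVC)
    best = max(maneuvers, key=lambda m: (float(np.max(m.exp_flow)), m.FVC_this))
    spiro = mefv_mod.spirometry_indices(best)
    curve.FEV1 = spiro["FEV1"]
    curve.FEF25_75 = spiro["FEF25_75"]
    curve.SR_mean = mefv_mod.slope_ratio(curve)
    spiro["SR_mean"] = curve.SR_mean

    records: list[StageRecord] = []
    drift_slopes: dict[str, float] = {}
    for sw in manifest.stage_windows:
        icw = manifest.ic_window_for(sw.label)
        # the EEV regression uses the tidal breaths only (the maneuver
        # itself has no tidal end-expiratory points); the fitted line is
        # subtracted over the whole trace, so the IC window is corrected
        # by the same drift estimate
        corrected, slope = br.correct_drift(
            signal, (sw.t_start, sw.t_end), hysteresis=cfg.hysteresis_flow
        )
        drift_slopes[sw.label] = slope
        table = br.segment_breaths(
            corrected,
            (sw.t_start, sw.t_end),
            min_VT=cfg.min_VT,
            hysteresis=cfg.hysteresis_flow,
            drift_slope=slope,
            exclude=manifest.excluded_breaths.get(sw.label),
        )
        params = br.ventilatory_params(table)
        tidal = br.composite_average(
            table, corrected, n_bins=cfg.n_bins, smoothing=cfg.smoothing
        )
        ic = measure_ic(corrected, (icw.t_start, icw.t_end), table)
        vols = derive_volumes(ic, curve.FVC, tidal.VT)
        placed = efl_mod.place_tidal_curve(
            tidal, vols, curve, TI=params["TI"], TE=params["TE"]
        )
        result = efl_mod.assess_efl(
            placed, threshold_pct=cfg.threshold_pct, flow_tol=cfg.flow_tol
        )
        if cfg.vecap_ti_mode == "measured":
            ti_for_cap = params["TI"]
        else:
            ti_for_cap = cfg.vecap_ti_fraction * (params["TI"] + params["TE"])
        vecap = efl_mod.ve_cap(curve, tidal.VT, vols.ERV, ti_for_cap)
        met = manifest.metabolics_for(sw.label)
        rec = StageRecord(
            stage_label=sw.label,
            work_W=sw.work_W,
            VT=params["VT"],
            fB=params["fB"],
            VE=params["VE"],
            TI=params["TI"],
            TE=params["TE"],
            VT_over_TE=params["VT_over_TE"],
            IC=ic,
            ERV=vols.ERV,
            IRV=vols.IRV,
            EFL_present=result.EFL_present,
            EFL_pct_VT=result.EFL_pct_VT,
            VE_cap=vecap,
            VE_frac_cap=100.0 * params["VE"] / vecap,
            VO2=met.VO2 if met else np.nan,
            VCO2=met.VCO2 if met else np.nan,
        )
        log.info(
            "%s v%d %s: VT=%.2f fB=%.1f IC=%.2f EFL%%=%.1f",
            manifest.participant_id, manifest.visit, sw.label,
            rec.VT, rec.fB, rec.IC, rec.EFL_pct_VT,
        )
        records.append(rec)
    return SessionResult(
        participant_id=manifest.participant_id,
        visit=manifest.visit,
        mefv=curve,
        spirometry=spiro,
        records=records,
        drift_slopes=drift_slopes,
    )


def peak_stage(result: SessionResult) -> StageRecord:
    """Peak stage = last completed stage of the incremental protocol."""
    return result.records[-1]


def analyze_study(study, config: RunConfig | None = None) -> dict[tuple[str, int], SessionResult]:
    """Analyze every session of a (synthetic or loaded) two-visit study."""
    cfg = config or RunConfig()
    out = {}
    for key, sess in study.sessions.items():
        out[key] = analyze_session(sess.signal, sess.manifest, cfg)
    return out


def repeatability_report(
    results_v1: list[SessionResult],
    results_v2: list[SessionResult],
    config: RunConfig | None = None,
) -> dict:
    """Two-visit repeatability of EFL and of ventilatory parameters.

    Returns a dict with ``peak`` and ``matched_ve`` sections (each with
    κ for binary EFL, ICC + CV for the continuous EFL magnitude) and a
    ``parameters`` section (ICC + CV per ventilatory parameter at peak),
    plus the between-visit Fisher exact p for EFL counts at peak.
    """
    cfg = config or RunConfig()
    by_id1 = {r.participant_id: r for r in results_v1}
    by_id2 = {r.participant_id: r for r in results_v2}
    ids = sorted(set(by_id1) & set(by_id2))
    if not ids:
        raise ValueError("no participant present on both visits")

    def section(rec_pairs: list[tuple[StageRecord, StageRecord]]) -> dict:
        flags = [(a.EFL_present, b.EFL_present) for a, b in rec_pairs]
        table = rep.AgreementTable2x2.from_pairs(flags)
        kr = rep.cohens_kappa(table)
        pairs_pct = [(a.EFL_pct_VT, b.EFL_pct_VT) for a, b in rec_pairs]
        ir = rep.icc(pairs_pct, form=cfg.icc_form)
        report = rep.RepeatabilityReport(
            n_pairs=len(rec_pairs),
            kappa=kr.kappa,
            kappa_p=kr.p,
            kappa_class=None if kr.undefined else rep.kappa_class(kr.kappa),
            icc=ir.icc,
            icc_ci95=ir.ci95,
            icc_p=ir.p,
            icc_class=None if ir.undefined else rep.icc_class(ir.icc),
            icc_form=ir.form,
            extras={
                "agreement_table": [table.a, table.b, table.c, table.d],
                "n_efl_visit1": table.a + table.b,
                "n_efl_visit2": table.a + table.c,
            },
        )
        return report.to_dict()

    peak_pairs = [(peak_stage(by_id1[i]), peak_stage(by_id2[i])) for i in ids]
    matched_pairs = []
    for i in ids:
        r1, r2 = by_id1[i], by_id2[i]
        s1, s2 = efl_mod.match_ve_stages(
            r1.records, r2.records, r1.peak_VO2, r2.peak_VO2, cfg.match_vo2_frac
        )
        matched_pairs.append((s1, s2))

    out = {
        "n_participants": len(ids),
        "peak": section(peak_pairs),
        "matched_ve": section(matched_pairs),
    }
    out["peak"]["fisher_p_efl_counts"] = rep.fisher_exact(
        out["peak"]["n_efl_visit1"], len(ids) - out["peak"]["n_efl_visit1"],
        out["peak"]["n_efl_visit2"], len(ids) - out["peak"]["n_efl_visit2"],
    )
    union = sum(
        1 for a, b in peak_pairs if a.EFL_present or b.EFL_present
    )
    any_stage_union = sum(
        1 for i in ids
        if any(r.EFL_present for r in by_id1[i].records)
        or any(r.EFL_present for r in by_id2[i].records)
    )
    out["efl_prevalence_peak_pct"] = 100.0 * union / len(ids)
    out["efl_prevalence_any_stage_pct"] = 100.0 * any_stage_union / len(ids)

    params = {}
    for name in ("VT", "fB", "VE", "IC", "ERV", "IRV", "VT_over_TE",
                 "VE_cap", "VE_frac_cap"):
        pairs = [
            (getattr(a, name), getattr(b, name)) for a, b in peak_pairs
        ]
        ir = rep.icc(pairs, form=cfg.icc_form)
        t, tp = rep.paired_t(pairs)
        params[name] = {
            "cv_pct": rep.between_day_cv(pairs),
            "icc": ir.icc,
            "icc_ci95": list(ir.ci95),
            "icc_p": ir.p,
            "icc_class": None if ir.undefined else rep.icc_class(ir.icc),
            "paired_t": t,
            "paired_t_p": tp,
        }
    out["parameters_peak"] = params
    return out


def study_repeatability(
    session_results: dict[tuple[str, int], SessionResult],
    config: RunConfig | None = None,
) -> dict:
    v1 = [r for (pid, v), r in session_results.items() if v == 1]
    v2 = [r for (pid, v), r in session_results.items() if v == 2]
    return repeatability_report(v1, v2, config)


def repeatability_from_stage_tables(
    tables: dict[tuple[str, int], list[StageRecord]],
    config: RunConfig | None = None,
) -> dict:
    """Repeatability report from already-computed per-stage tables
    (as written by ``write_stage_table``), without re-analyzing waveforms."""
    results = {
        (pid, visit): SessionResult(
            participant_id=pid, visit=visit, mefv=None, spirometry={},
            records=records,
        )
        for (pid, visit), records in tables.items()
    }
    return study_repeatability(results, config)
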