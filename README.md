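# eflkit

Assessment of expiratory flow limitation (EFL) from exercise
flow–volume recordings, with a ground-truth synthetic study generator
and between-day repeatability statistics.

## The problem

During incremental exercise, ventilatory demand can reach the
mechanical ceiling of expiratory flow.  The standard non-invasive
assessment overlays the averaged tidal flow–volume loop on the maximal
expiratory flow–volume (MEFV) envelope: the subject is flow-limited
when the tidal expiratory limb meets the envelope over ≥ 5% of tidal
volume (V_T).  Getting there takes a chain of signal processing —
graded-effort FVC maneuvers merged into an envelope, volume-drift
correction, breath segmentation, composite averaging, inspiratory
capacity (IC) to place the loop absolutely via ERV = FVC − IC — and the
repeatability of the final call across test days is a question in its
own right.  `eflkit` implements the full chain for researchers in
exercise respiratory physiology, plus the agreement statistics (Cohen's
κ, ICC, within-subject CV) used to quantify test–retest repeatability,
and a synthetic two-visit study generator so every step can be validated
against known truth.

Core quantities, in the field's notation:

* MEFV envelope: V̇max(v) = max over graded maneuvers of V̇(v), on a
  0.01 L grid of volume above residual volume.
* Slope ratio: SR(v) = (dV̇/dV) / (V̇/v), averaged over 20–80% of FVC.
* Operating volumes: ERV = FVC − IC; EILV = ERV + V_T.
* EFL magnitude: %V_T over which tidal V̇(v) ≥ V̇max(v);
  present when ≥ 5%.
* Ventilatory capacity: V̇E,CAP = 60·V_T / (T_I + ∫ dv/V̇max(v)).
* Repeatability: Cohen's κ (binary), ICC(2,1) (continuous),
  CV = 100·√(mean within-pair variance)/grand mean.

## Worked example

```python
from eflkit import RunConfig, analyze_session
from eflkit.synthetic import single_stage_params, gen_session
import numpy as np

# a participant with FVC 4.9 L, PEF 9.7 L/s, breathing at VT 2.4 L,
# 45 breaths/min, whose expiratory demand overlaps the envelope over
# 40% of VT
params = single_stage_params(efl_target_pct=40.0)
session = gen_session(params, "demo", visit=1, rng=np.random.default_rng(21))
result = analyze_session(session.signal, session.manifest, RunConfig())

rec = result.records[0]
print(f"FVC {result.mefv.FVC:.2f} L  SR {result.mefv.SR_mean:.2f}")
print(f"VT {rec.VT:.2f} L  fB {rec.fB:.1f} /min  VE {rec.VE:.1f} L/min")
print(f"IC {rec.IC:.2f} L  ERV {rec.ERV:.2f} L")
print(f"EFL {rec.EFL_present}  ({rec.EFL_pct_VT:.0f}% of VT)  "
      f"VE/VE_cap {rec.VE_frac_cap:.0f}%")
```

prints

```
FVC 4.90 L  SR 1.13
VT 2.39 L  fB 40.0 /min  VE 95.5 L/min
IC 3.10 L  ERV 1.80 L
EFL True  (40% of VT)  VE/VE_cap 71%
```

i.e. the pipeline recovers the generator's ground truth: the envelope
(FVC 4.9 L, slope ratio 1.13), the breathing pattern (the realized rate
is below the nominal 45 min⁻¹ because flow limitation stretches
expiration), the IC-derived placement (ERV 1.8 L), and the constructed
40% overlap, with ventilation at 71% of the envelope-limited capacity.

## Command line

```sh
efl-kit simulate --n 32 --seed 1 --out dataset/       # waveforms + manifests
efl-kit analyze --waveform dataset/P01_v1_waveform.csv \
    --manifest dataset/P01_v1_manifest.json --out P01_v1_stages.csv
efl-kit repeatability --stages-dir outdir/ --out report.json
efl-kit run-all --n 32 --seed 1 --out outdir/          # all of the above
```

## Analysis scripts

The `analysis/` directory holds the narrative drivers, each writing its
tables under `results/`:

1. `01_simulate.py` — generate the 32-participant two-visit study
   (ground-truth tables; raw waveforms optional, under `scratch/`).
2. `02_analyze_sessions.py` — run the pipeline over all 64 sessions;
   stage tables, spirometry, truth-recovery errors.
3. `03_repeatability.py` — κ/ICC/CV at peak exercise and at matched
   ventilation, from the stage tables.
4. `04_worked_agreement.py` — the worked 2×2 agreement example from
   published per-visit flow-limitation counts.

## Layout

```
src/eflkit/
  signal_io.py      waveform/manifest I/O, flow integration, stage tables
  breaths.py        drift correction, segmentation, composite tidal loop
  mefv.py           envelope construction, spirometry indices, slope ratio
  volumes.py        inspiratory capacity, operating lung volumes
  efl.py            placement, overlap/EFL, V̇E,CAP, matched-V̇E pairing
  repeatability.py  κ, ICC, CV, paired t, Fisher exact, band labels
  synthetic.py      two-visit study generator with ground truth
  pipeline.py       per-session and study-level orchestration
  cli.py, config.py
```

See `docs/methods.md` for the model, parameter defaults, numerical
choices and known limitations.
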