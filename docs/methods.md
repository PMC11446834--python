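# Methods

## The measurement problem

During heavy exercise, some adults reach the mechanical limit of
expiratory flow: at a given lung volume, no additional effort can raise
flow any further.  This *expiratory flow limitation* (EFL) is commonly
assessed non-invasively by superimposing the averaged tidal
flow–volume loop on the subject's maximal expiratory flow–volume (MEFV)
envelope and asking how much of the tidal breath touches the envelope.
Every ingredient of that comparison — the envelope, the tidal loop, the
placement of the loop on the absolute volume axis — is itself a derived
measurement, so the package implements the whole chain and quantifies
how repeatable the final call is across days.

## Pipeline

### MEFV envelope from graded maneuvers (`eflkit.mefv`)

A single maximal forced expiration underestimates attainable flow at mid
and low lung volumes because thoracic gas compression shifts the
measured volume axis.  The envelope is therefore assembled from forced
vital capacity (FVC) maneuvers performed at graded efforts (~20–100% of
maximal), before and after exercise, all anchored at total lung
capacity.  On a 0.01 L volume grid (litres above residual volume, RV)
the envelope is the pointwise maximum of the interpolated maneuver
flows; grid points no maneuver covers get flow 0 (the RV endpoint).
Spirometry indices (FVC, FEV₁, PEF, FEF₂₅₋₇₅) come from the
maximal-effort maneuver of the set — the one with the highest peak flow.

The *slope ratio* (SR) summarises the curvature of the descending limb:
at each grid point in the effort-independent 20–80% of FVC, SR is the
tangent slope (central finite difference; one-sided at the range ends)
divided by the chord slope to the RV intercept (where flow is zero, so
the chord is simply V̇(v)/v).  SR = 1 for a straight limb through RV,
2 for a quadratic limb, 0.5 for a square-root limb; the mean over the
range is reported.  The chord's anchor at RV is this implementation's
definition; points with chord slope under 0.01 s⁻¹ are skipped.  No
smoothing is applied before differentiation by default, which keeps the
analytic cases exact; for measured envelopes the pipeline applies a
5-grid-point (0.05 L) moving average before SR and placement, which
suppresses interpolation corners without visibly biasing the limb.

### Tidal analysis (`eflkit.breaths`)

Each exercise stage contributes a ~30 s analysis window of tidal
breathing that ends in an inspiratory-capacity maneuver.  Processing
order:

1. **Drift correction.**  Integrated pneumotach volume drifts; an
   ordinary-least-squares line through the end-expiratory volumes of the
   window's tidal breaths (anchored to zero at the window start) is
   subtracted from the volume channel.  The regression deliberately uses
   only the tidal portion — the IC maneuver itself has no tidal
   end-expiratory points and flow noise during its zero-flow hold can
   otherwise fabricate one at total lung capacity — but the fitted line
   is subtracted over the whole trace, so the IC window is corrected by
   the same estimate.
2. **Segmentation.**  Breath boundaries are flow zero crossings into
   inspiration with a ±0.05 L·s⁻¹ hysteresis band (a standard debounce
   against noise chatter).  Incomplete edge breaths are discarded, as
   are deflections with inspired volume under 0.10 L (swallows, coughs).
   Additional aberrant breaths can be excluded by ordinal through the
   session manifest; no automatic outlier statistics are applied, so the
   exclusion rule stays auditable.
3. **Compositing.**  Each breath's expiratory and inspiratory limb is
   linearly resampled onto a common relative-volume grid (101 bins over
   0..1 of that breath's own tidal volume), flows are averaged across
   breaths per bin, and the grid is rescaled to 0..mean VT.  Compositing
   on relative volume rather than time is deliberate: the flow-limitation
   comparison is a flow-at-volume comparison.  Breaths whose volume
   excursion is badly non-monotonic (reversals beyond ~5% of VT) are
   excluded with a warning.

### Operating lung volumes (`eflkit.volumes`)

The IC maneuver anchors the loop: baseline end-expiratory volume is the
mean over the window's tidal breaths, and IC is the excursion from that
baseline to the maneuver extreme (with this package's polarity the
maximum; a flag handles inverted recordings where it is a nadir).  Then
ERV = FVC − IC is the end-expiratory lung volume above RV.  The quantity
ERV + VT is exposed both as `IRV` and as `EILV_above_RV`: it is
the end-inspiratory lung volume above RV, not the conventional
inspiratory reserve IC − VT; both names are kept so downstream use is
unambiguous.

### EFL and ventilatory capacity (`eflkit.efl`)

The composite expiratory limb, shifted to start at ERV on the above-RV
axis, is compared point-for-point with the envelope: a grid point is
flow-limited when tidal flow ≥ envelope flow − `flow_tol`, and the
overlap is the summed volume-bin width of limited points.  EFL is
present when the overlap reaches 5% of VT (threshold configurable).
`flow_tol` defaults to 0 in the low-level function (exact for analytic
curves) and to 0.02 L·s⁻¹ in the pipeline configuration: both the
composite and the envelope pass through interpolation and carry flow
noise, so a strict comparison systematically undercounts bins that are
genuinely on the envelope, while slack much larger than the noise floor
inflates grazing contact; 0.02 L·s⁻¹ matches the generator's flow-noise
scale and recovers constructed overlaps of 20–60% of VT to within about
a bin.  An end-inspiratory volume exceeding FVC by up to 0.05 L
(measurement noise) is clipped with a warning; more is an error.

Ventilatory capacity V̇E,CAP asks what minute ventilation the envelope
would allow over the current tidal placement: the minimal expiratory
time is TE_min = ∫ dv / V̇max(v) over [ERV, ERV + VT] (trapezoidal;
envelope flows under 0.05 L·s⁻¹ are floored there so the integral cannot
diverge at the RV corner), and V̇E,CAP = 60·VT/(TI + TE_min) with the
stage's measured inspiratory time (a fixed-TI/Ttot mode is available as
configuration, since conventions differ between laboratories).
V̇E/V̇E,CAP is the fractional use of capacity; on sessions without flow
limitation V̇E ≤ V̇E,CAP holds by construction, and the test suite
asserts it.

### Matched-ventilation pairing

Peak exercise is the last completed stage of each incremental test, but
peak V̇E rarely matches across days.  For the matched comparison, among
the stages above 75% of that visit's peak V̇O₂ the pair minimising
|V̇E₁ − V̇E₂| is selected (ties toward higher work, then visit-1 order).

### Repeatability statistics (`eflkit.repeatability`)

* **Cohen's κ** for the binary call, from the 2×2 both/one/neither
  table; p-value from the large-sample normal test of κ = 0 using
  SE₀ = √(pe/(n(1−pe))).  Bands: none ≤ 0.20 < minimal ≤ 0.39 < weak
  ≤ 0.59 < moderate ≤ 0.79 < strong ≤ 0.90 < almost perfect (exact
  shared endpoints go to the lower band).
* **ICC** for continuous quantities, single-measure, from the two-way
  ANOVA mean squares via pingouin; the default form is ICC(2,1)
  (absolute agreement, visit as a random factor — the natural choice
  for a repeatability design), with ICC(3,1) (consistency) selectable.
  Bands: poor < 0.50 ≤ moderate ≤ 0.75 < good ≤ 0.90 < excellent.
* **Between-day CV**: per pair the within-subject SD is |x₁−x₂|/√2 and
  CV = 100·√(mean within-pair variance)/grand mean — one of several
  conventions in use; this one is stated explicitly because results
  differ across definitions.
* Paired Student's t (group shifts) and Fisher's exact test
  (per-visit positive counts) via scipy.

## The synthetic study generator (`eflkit.synthetic`)

The generator produces complete two-visit studies with known truth so
every pipeline stage is testable end to end.

* **Envelope**: V̇max(v) = PEF·(v/FVC)^s on the above-RV axis.  The
  exponent s *is* the slope ratio of the limb (tangent/chord = s for a
  power law), so SR recovery is exact by construction.
* **Graded maneuvers**: eight per session (pre/post × 25/50/75/100%
  effort).  Each effort attains the true envelope over a volume window
  and falls below it elsewhere — the 100% effort wins near TLC, lower
  efforts win toward RV — emulating the effect thoracic gas compression
  has on real graded sets.  The windows cover the whole volume range, so
  the pointwise maximum reproduces the true envelope (to within ~0.5%,
  the interpolation error at 200 Hz sampling); expiration finishes to RV
  at a floored 0.05 L·s⁻¹ trickle, like an end-of-test criterion.
* **Tidal breathing**: half-sine inspiration; the expiratory demand
  profile peaks at about one third of expired volume and is clipped at
  the envelope flow for the breath's placed volume,
  flow = min(demand, V̇max), so limitation engages at the low-volume end
  first.  The demand amplitude is solved by bisection so the clipped
  fraction of expired volume matches the stage's overlap target; targets
  under 2% of VT are below the generator's resolution and produce a
  clearly sub-envelope breath instead of a tangential graze (without
  this, borderline cases would never disengage between days, because a
  graze measures as a few percent of overlap under any finite flow
  tolerance).  Breaths carry 3% VT and 2% timing jitter and 0.02 L·s⁻¹
  Gaussian flow noise; the volume channel carries a linear drift
  (±0.005 L·s⁻¹) but not integrated flow noise.
* **Protocol**: rest plus 20 W increments to a participant-specific
  peak; each stage is ~31 s of tidal breathing ending in an IC maneuver
  to TLC.  Stage schedules ramp VT (saturating), fB (accelerating) and
  end-expiratory volume (linear) between resting and peak values.
* **Population priors** are group statistics typical of healthy adults
  of average fitness: FVC 4.88 ± 0.99 L, PEF 9.68 ± 2.16 L·s⁻¹,
  SR 1.13 ± 0.22, resting IC 2.78 ± 0.63 L, peak VT 2.41 ± 0.56 L, peak
  fB 46 ± 8 min⁻¹, peak ERV 1.79 ± 0.52 L, peak work 211 ± 51 W.  About
  42% of participants carry an EFL propensity whose magnitude prior
  (normal, mean 26, SD 18, clipped to [0.5, 75] %VT) leaves a tail of
  borderline cases; the realized flow-limited fraction of an n = 32
  study fluctuates around ~40% (roughly 30–55% across seeds).
* **Two visits**: visit-2 parameters are visit-1 values times
  (1 + CV·z) with independent standard-normal z per parameter, at
  default between-day CVs of a few percent (FVC 3.5, PEF 4, VT 3.2,
  fB 6, EELV 9, EFL magnitude 30, all %) — magnitudes typical of
  repeated exercise testing.
* **Randomness**: one hierarchical stream (study → participant → visit
  → stage) from a single seed; adding participants never perturbs
  earlier ones, and a fixed seed reproduces the dataset byte for byte.

### What the generator does and does not emulate

It reproduces the *structure* the analysis assumes: quasi-periodic
breathing with drift and noise, graded maneuvers with effort-dependent
attainment, IC maneuvers, controlled overlap, parameter-level day-to-day
variation.  It does not model airway mechanics (the envelope is a power
law, not a physiological pressure–flow solution), cardiogenic flow
oscillations, irregular breathing, glottal artifacts, submaximal IC
efforts, or within-session fatigue drift of the envelope.  Passing tests
therefore demonstrate that the pipeline recovers what it claims to
measure under realistic signal structure — not that any physiological
conclusion transfers to real recordings.

A consequence worth stating: with purely multiplicative parameter-level
day-to-day variation, the binary EFL call at default priors is *more*
repeatable (κ near 1 at n = 32) than in real two-visit data, where κ
around 0.3–0.5 is observed.  Borderline overlap magnitudes are the
destabilising mechanism — the test suite shows κ degrading when the
magnitude prior concentrates near the 5% threshold — but the generator's
default conditions do not attempt to reproduce any particular observed
κ.

## Numerical choices and degenerate inputs

* Linear interpolation throughout; no splines.
* Envelope grid step exactly 0.01 L; the grid stays inside [0, FVC].
* Overlap bin widths: half-width at the composite grid ends.
* κ undefined (constant rater, pe = 1) and ICC undefined (zero total
  variance) are returned as flagged results, not exceptions.
* Band boundaries are closed on both ends as printed; exact shared
  endpoints go to the lower-named band.
* Breath-phase detection needs ≥ 2 complete breaths; drift correction
  and IC need ≥ 3 end-expiratory points; SR needs ≥ 10 usable grid
  points — each violation raises a specific error.
* Sampling other than the declared rate is rejected rather than
  resampled.

## Problem sizes

The bundled study is 32 participants × 2 visits × (rest + up to 16
stages) at 200 Hz — about 45 minutes of signal per session — generated
and fully analyzed in well under a minute on one core.  Test-suite
simulations use 3–12 participants; the acceptance script runs the full
32.

## Known limitations

* The κ p-value convention (H₀ standard error) is one of several in the
  literature; the Fleiss-corrected variance gives smaller p on the same
  table.
* ICC confidence intervals follow the F-based approximation; they are
  unreliable below ~10 pairs.
* The within-subject CV assumes homoscedastic within-pair variance on
  the measurement scale (not log-normal).
* The matched-V̇E pairing minimises |ΔV̇E| only; it does not enforce a
  maximum acceptable ΔV̇E.
* `IRV` deliberately reproduces the ERV + VT definition described
  above; users wanting conventional IRV should compute IC − VT.
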