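# Methods

`manodrift` models and analyzes the measurement chain of solid-state
high-resolution esophageal manometry (HRM): a 36-sensor catheter at 1-cm
spacing records a space–time pressure topography; the sensors drift as they
warm from room to body temperature; and a post-hoc *thermal compensation*
step estimates each sensor's residual baseline after the catheter leaves the
body and subtracts it from the recording. The package exists to study how
the *timing* of that estimate — at the end of the "waterfall image", or 1,
5, 10 s later, or never — propagates into the Chicago-style metric panel and
the final motility diagnosis.

## Coordinate and unit conventions

Pressures are mmHg relative to atmospheric at calibration, so drift appears
as a nonzero post-removal baseline. Sensor 0 is the most proximal
(pharyngeal) sensor; indices increase distally, matching the top-down
reading order of a Clouse plot. Time is seconds from recording start;
samples are left-closed intervals of width `1/fs`, and every analysis window
is half-open `[t0, t0 + w)`, which makes all sample counts unambiguous
integers. The default sampling rate is 50 Hz — enough to resolve the 4-s
relaxation span of the IRP into 200 samples; all rates are configurable.

## Drift model

Each sensor *i* carries an amplitude `D_i ≥ 0` (mmHg), drawn from a normal
distribution with mean `mu_d = 6`, sd `sigma_d = 3`, floored at zero.
Amplitudes are spatially correlated along the catheter (exponential
correlation, length 4 sensors): adjacent sensors share a thermal
environment, and the correlation keeps the drift *differential* between the
EGJ sensors and the gastric reference sensors roughly symmetric around zero,
so a borderline IRP can be pushed across its threshold in either direction —
the behavior observed clinically.

In-body, drift accrues as `D_i · (1 − exp(−t/tau_warm))` with
`tau_warm = 120 s` (a warm-up on the scale of minutes); a linear warm-up
option exists for closed-form checks. After catheter exit at `t_exit`, the
saturated level is multiplied by a bounded shape

    g_i(Δt) = (1 + gain_i · (Δt/4) · exp(1 − Δt/4)) · exp(−Δt/52),

with `g_i(0) = 1`, a mild overshoot peaking a few seconds after removal
(`g(1), g(5) > 1`) and a slow decay (`g(10) ≈ 0.9`). The true post-removal
kinetics of these sensors are not characterized in the literature beyond the
fact that offsets measured at different instants differ; the shape above is
the package's declared assumption, fully configurable. The overshoot gain is
per-sensor (`gain_i ~ N(0.16, 0.06)`, clipped to [0, 0.3]) because each
sensor is its own transducer: this is what makes the *anchored* conditions
(1/5/10 s) differ from formal compensation by more than a uniform — and
therefore referencing-invisible — scale factor. When `sigma_d = 0` all
sensors share a single drift curve (amplitudes *and* gains), which is the
"uniform drift" configuration used to verify that gastric referencing
nullifies spatially uniform error.

## Compensation model

Offsets are measured as the mean reading over `[anchor, anchor + 0.5 s)` —
a short window rather than a point sample, to suppress noise. The correction
subtracts `o_i · r(t)` with `r(t) = min(t, t_exit)/t_exit`: zero at
recording start, the full measured offset at catheter exit, and `r = 1`
afterwards so re-detecting the waterfall end on a corrected study is stable.
The vendor's accrual shape is proprietary; the linear ramp is the simplest
model consistent with a warming process, and it is exact when the in-body
accrual is itself linear (a property verified in the tests). The end of the
waterfall image is detected as the earliest post-swallow time at which the
spatial range of 0.25-s-smoothed pressures stays below 15 mmHg for 0.5 s;
the pipeline prefers an annotated `t_exit` when one exists (the simulator
always annotates) so anchor offsets are exact relative to ground truth.

## Metric panel

All metrics are referenced to intragastric pressure, computed per sample as
the mean of 3 sensors distal to the LES band. Consistent referencing is what
makes uniform drift provably null and isolates inter-sensor heterogeneity as
the error mechanism.

- **IRP** — eSleeve signal = min across the LES/EGJ band at each sample over
  the 10-s window from UES-relaxation onset; IRP = mean of the lowest 4 s of
  samples, *noncontiguous* (the wording of the clinical definition does not
  require contiguity; the noncontiguous form is the platform convention).
  Median over the 10 swallows; > 15 mmHg (strict) = impaired EGJ relaxation
  for this platform, supine.
- **DCI** — Σ max(P − gastric − 20, 0) · dt · dx over the esophageal body
  span and a fixed 15-s post-onset window (clipped at `t_exit`). A fixed box
  window is simpler than contour-tracking the contraction offset and is
  adequate for the simulated waves.
- **DL / CDP** — per body sensor, the front arrival is the first crossing of
  the 30-mmHg referenced contour; a continuous two-segment line is fitted to
  (distance, arrival) by exhaustive least-squares breakpoint search (ties →
  first minimum); the knot is the contractile deceleration point and DL is
  the measured arrival there minus onset. DL is undefined (excluded from
  medians) when fewer than 4 sensors cross or the front stops short of the
  distal body.
- **Break length** — longest gap in the 20-mmHg per-sensor peak contour
  along the body span, in cm.
- **Panesophageal pressurization** — a ≥ 30 mmHg referenced column spanning
  the entire body span at any instant of the contraction window.
- **Swallow labels** — failed (DCI < 100 mmHg·s·cm), weak (< 450), else
  normal; premature (DL < 4.5 s, DCI > 450), fragmented (break > 5 cm,
  DCI > 450), else intact; failed swallows carry only the failed label. Weak
  swallows still receive a pattern label, so weak% and intact% can overlap —
  this matches how the clinical percentages are reported independently.
- **UESP/LESP** — band-maximum pressure averaged over a 5-s quiet window
  ending 0.5 s before the first swallow, gastric-referenced.

Thresholds not fixed by the platform literature (100/450/8000 mmHg·s·cm,
4.5 s, 5 cm, 20/30 mmHg) follow the Chicago conventions and live in
`AnalysisParams`, all configurable. Whether per-study DCI should be a median
or a mean over swallows is not settled; the median was chosen to match the
IRP convention.

## Decision tree

The classifier first splits on median IRP (strictly > 15 mmHg), then works
through the disorder definitions in listing order, which fixes precedence:
achalasia types before outflow obstruction on the elevated branch; absent
contractility / achalasia-cannot-rule-out before the body disorders, then
spasm, hypercontractile esophagus (≥ 2 swallows with DCI > 8000),
ineffective motility (> 50% ineffective), fragmented peristalsis (> 50%
fragmented) on the normal branch; the only composite label is DES+IEM.
Open points resolved as package choices: "borderline" IRP for
achalasia-cannot-rule-out is (10, 15] with pressurization in ≥ 20% of
swallows as the "evidence"; "no normal peristalsis" for type 3 achalasia is
`pct_intact == 0`; spasm outranks hypercontractile esophagus when both fire
(no guidance exists; listing order wins). Every evaluated predicate is
recorded in `rule_trace`.

## Synthetic cohorts

The generator emulates the clinical protocol: supine position, ten
sequential 5-mL water swallows at 20-s intervals after an 18-s quiet
baseline, catheter withdrawal 15 s after the last swallow, and a 12-s
post-removal tail. Anatomy is stylized: Gaussian UES band (sensor 3,
~80 mmHg), a flat-topped LES band (sensors 29–31) whose plateau guarantees
the eSleeve minimum reads the programmed relaxation level, gastric baseline
8 mmHg (sensors 32–35), a peristaltic contraction as a Gaussian ridge
(sd 0.9 s) whose front runs at ~4 cm/s to a deceleration point 3 cm above
the LES and at ~1 cm/s below it, a 2-mmHg respiratory sinusoid on the
sphincter zones, and white measurement noise (sd 1 mmHg) while the catheter
is in the body. Post-removal readings equal the drift term exactly — the
residual baseline *is* the quantity compensation estimates, and a drift-free
study reads identically zero after exit.

Archetypes set per-swallow mixtures (intact/weak/failed/premature/
fragmented/hypercontractile), a relaxation depth targeting the archetype's
nominal median IRP, and sphincter pressures. Two deliberate stylizations:

- The programmed relaxation level includes a +1.55 mmHg calibration constant
  so the *measured* IRP equals the nominal target at default noise (the
  eSleeve minimum over three noisy sensors plus lowest-4-s averaging biases
  the raw measurement low by that amount; the constant was fitted once
  against ground truth and is independent of archetype).
- Panesophageal pressurization is a brief (0.3 s) 32-mmHg common-cavity
  column. Real common-cavity pressurization lasts seconds, but under the
  fixed box-window DCI a seconds-long column would add > 450 mmHg·s·cm and
  contradict the "100% failed" requirement of the type-2-achalasia
  definition; the brief column keeps the vigor and pressurization axes
  independent (a pressurized failed swallow stays below DCI 100).

Near-threshold variants (`nem_borderline`, IRP ≈ 13.8; `egjoo_borderline`,
IRP ≈ 16.3) exist to study drift-induced diagnosis flips; by construction
they occasionally self-misclassify even drift-free, which is their purpose.

What the generator does **not** emulate: real inter-patient anatomical
variability (hiatal hernia, EGJ morphology subtypes), catheter movement and
swallow-to-swallow landmark shifts, vendor-software peculiarities (ManoView's
actual accrual shape and eSleeve placement), transit of the rapid-swallow
test, or fold/applied-pressure pressure patterns (folds are annotation
flags). Passing tests therefore demonstrate the *internal consistency* of
the measurement-error mechanism — referencing invariances, recovery of known
offsets, threshold-crossing behavior — not clinical accuracy on real
tracings.

## Statistics

Continuous metrics are compared across the five conditions as independent
groups, mirroring the clinical convention even though the groups are the
same studies re-analyzed (an unpaired analysis is conservative here; a
paired alternative would be stronger but is not the default). Summaries are
median (IQR) unless a two-test normality gate — one-sample KS against the
fitted normal *and* Lilliefors, both p > 0.05 — declares every group normal.
Omnibus differences use tie-corrected Kruskal–Wallis; when p < 0.05,
pairwise two-sided Mann–Whitney U (asymptotic, tie-corrected) feeds a
compact letter display (letters k, l, m, …) built from the maximal cliques
of the not-significantly-different graph. Diagnosis distributions use
Pearson chi-square per diagnosis with adjusted standardized residuals
`(O − E)/√(E(1 − row share)(1 − col share))`, |r| > 1.96 flagged. No
multiple-testing correction is applied by default, matching the reporting
convention the package mirrors. Scipy/statsmodels provide the underlying
tests; the residuals and letter display are implemented here and verified
against brute-force oracles in the test suite.

The flip cross-tabulation stratifies studies by the *reference* (formal
compensation) IRP category and counts diagnoses — grouped as NEM / IEM /
EGJ-OO / achalasia / other — per condition within each stratum; row sums per
stratum are invariant across conditions (a partition), and flips are counted
in both directions. A verbatim transcription of the published
cross-tabulation is packaged for arithmetic checks; its known internal
inconsistencies (a reference-row NEM count that disagrees with the diagnosis
table by one) are preserved as printed.

## Numerical choices and problem sizes

Exhaustive breakpoint search (≤ 24 candidates) rather than an analytic
two-phase fit; `np.partition` for the lowest-4-s average (equal to a full
sort to ~1e-15); offsets and metrics in float64 throughout; study bundles
are CSV at full repr precision and round-trip bit-exactly
(`float_precision="round_trip"` on read). The anchor-window mean of a curved
post-exit shape differs from the point value by up to ≈ 0.5 mmHg for
amplitudes ~4 sd above the mean; with the default kinetics the observed
worst recovery error is ≈ 0.3–0.5 mmHg.

The test suite and the acceptance script run cohorts of 40 studies for the
invariance checks, 40 near-threshold studies for the flip experiment, 20
seeds for offset recovery and a 136-study review-flow cohort — sizes chosen
to keep the full suite around a minute while leaving every statistic far
from its decision boundary.

## Known limitations

- The linear-ramp correction model and the post-exit kinetics are
  assumptions; only the existence of anchor-time sensitivity is established
  externally. Conclusions about *which* anchor is least biased depend on
  those assumptions.
- Landmarks are located once from the resting profile and held fixed;
  real EGJ landmarks move with respiration and swallowing.
- DL's fixed 30-mmHg contour and box-window DCI are simplifications; they
  are exact for the simulated waves but coarser than vendor implementations.
- Cohort comparisons treat re-analyses as independent groups (by design, to
  mirror the convention); the optional paired interpretation is left to the
  user.
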