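# Methods

## The Mxa index

The mean flow index treats cerebral autoregulation as a correlation
phenomenon on slow time scales. Paired arterial blood pressure (ABP,
mmHg) and middle-cerebral-artery flow velocity (FV, cm/s) are recorded
simultaneously for several minutes at 50–100 Hz. Both signals are averaged
on a moving window of `window_s` = 10 s advancing by
`window_s * (1 − overlap_frac)` = 5 s (50% overlap), which suppresses
pulsatile and respiratory components and leaves the slow (< ~0.05 Hz)
fluctuations that autoregulation acts on. Mxa is the Pearson correlation
of the two window-mean series. Classification uses a strict inequality:
`impaired` iff Mxa > `impaired_threshold` (default 0.3); the threshold
value itself classifies intact.

Assumptions inherited from the method: FV changes are proportional to
cerebral-blood-flow changes (constant insonated-vessel diameter), and the
recording is long enough — `min_duration_s` = 360 s by default — that the
correlation is estimated from a few dozen effectively independent slow
fluctuations. That last point matters for interpretation: even a 480-s
recording yields 95 windows but only ~25–50 independent slow-wave degrees
of freedom, so a single Mxa estimate carries a sampling SD of roughly
0.1–0.2. The index is reported per recording with the window series and QC
detail preserved.

Processing chain (`compute_mxa`): crop both signals to their common time
span; flag artifacts; if sampling rates differ, linearly interpolate both
onto the lower rate (samples falling in a flagged stretch stay missing);
window-average each side; drop any window pair with a missing side;
correlate; classify. Fewer than two usable window pairs raises an
unusable-recording error carrying the QC counts rather than returning a
number.

### Artifact handling

Published Mxa studies typically state that artifacts were removed without
giving criteria, so the rules here are explicit, configurable and
conservative defaults rather than a reconstruction of any specific lab's
practice:

* physiologic range gates — ABP outside 20–250 mmHg, FV outside
  0–300 cm/s;
* one-sample jumps larger than `jump_sd` = 5 robust SDs
  (1.4826 × MAD of the first differences);
* runs of identical values longer than `flat_run_s` = 2 s (frozen
  sensor/dropout).

Flagged samples become missing; original values are never edited. A window
whose missing fraction exceeds `max_missing_frac` = 0.25 is dropped to
avoid biased partial means. Raw pressure (not beat-averaged MAP) enters
the windowing: the 10-s means suppress pulsatility either way, and this
avoids committing to a beat detector.

## Pupillometry aggregation

Each eye contributes NPi (device-computed 0–5 score), baseline pupil size
(mm), constriction (% of baseline), constriction velocity (mm/s) and
latency (s). Patient-level values are the median across both eyes — for
two eyes, the arithmetic midpoint — with a single measured eye used
verbatim. "Worst NPi" is the minimum across available eyes (the standard
clinical usage; the term is otherwise ambiguous and this interpretation is
deliberate). NPi status uses the conventional cut-off: normal iff
NPi > 3, so the boundary value 3 is abnormal. NPi is always consumed as a
measured input; the device's internal algorithm is out of scope.

## Statistical toolkit

* **Rank-sum comparison** — Mann–Whitney with midranks. For pooled
  n ≤ 12 the two-sided p is computed by exhaustive enumeration of group
  assignments, defined symmetrically as P(|T − E T| ≥ |t − E T|); this
  coincides with the classical doubled-tail exact p for tie-free data and
  extends cleanly to ties (identical multisets give p = 1). Larger
  samples use the normal approximation with tie and continuity
  correction.
* **Pearson correlation** — r with the two-sided t-test on n − 2 df;
  r² is reported alongside because weak associations are the object of
  interest here.
* **ROC analysis** — AUC via the Mann–Whitney identity U/(n₁n₀) with
  midrank ties; orientation flipped if needed so AUC ≥ 0.5 (and
  reported); 95% CI by DeLong's placement-value variance (validated
  against R's pROC); operating point maximizing Youden's J, ties resolved
  to the highest threshold.
* **Descriptives** — median and 25th–75th percentiles with the
  linear-interpolation convention (numpy default), documented because
  these values are report-facing.

Tests are two-sided with α = 0.05. No multivariable adjustment and no
multiple-testing correction are applied — the study design this package
serves performed none — and the report JSON carries an explicit caveat
flag saying so.

## Synthetic data

The generator's purpose is ground truth for the pipeline, not hemodynamic
realism: no pulse-wave morphology, PaCO₂ dynamics or ICP.

**ABP** = mean (77 mmHg) + slow-wave component + cardiac sinusoid
(~1 Hz, 2 mmHg) + white noise (0.5 mmHg SD). The slow-wave component is a
sum of 24 sinusoids with random phases and frequencies drawn one per
equal-width sub-band of 0.005–0.05 Hz, plus a 0.1 Hz component, normalized
to 5 mmHg RMS. The stratified draw guarantees every realization covers the
whole band; a purely uniform draw occasionally concentrates all power
below 0.02 Hz, leaving too few independent fluctuations in an 8-min
recording. The 0.1 Hz component is deliberately cancelled by the 10-s
window mean (one full period), mimicking how Mxa-type indices ignore
Mayer-wave-band activity above the averaging scale.

**FV** (mixture generator, the default ground-truth mechanism)
= baseline (60 cm/s) + 3 cm/s × [w·Z + (1−w)·E] + measurement noise
(0.5 cm/s SD), where Z is the standardized slow-wave component extracted
from the ABP by brick-wall Fourier low-pass at 0.15 Hz, E an independent
phase-randomized surrogate with Z's amplitude spectrum, and w ∈ [0, 1] the
pressure-passivity weight. w = 1 gives downstream Mxa ≈ 1; w = 0 gives
Mxa scattered about 0. The scatter at w = 0 is wide (SD ≈ 0.19) for the
degrees-of-freedom reason above; the test suite asserts the
simulation-measured bound (|Mxa| < 0.2 in ≥ 50–60% of seeds), since no
generator respecting this band structure can make 8-min null recordings
much tighter.

A **Tiecks–Lassen** second-order state model (per-ARI parameters T, D, K
from Tiecks et al., Stroke 1995; critical closing pressure 12 mmHg) is
provided as an optional physiological alternative; ARI 0 (K = 0) reduces
to a pressure-passive FV. The mixture generator is the default because it
is self-contained and analytically tractable.

**Pupillometry.** Patient-level NPi is
`npi_center + b·(Mxa − mean Mxa) + ε` with b solved from
r² = b²Var(Mxa)/(b²Var(Mxa) + σ²_ε) at fixed total variance
(SD 0.53, i.e. IQR ≈ 0.7 on the NPi scale), slope negative by default
(impaired autoregulation trends to lower NPi), and per-eye values adding
0.1-SD eye noise, truncated to the device's 0–5 scale. The other four
variables are drawn independently of Mxa from truncated normals matching
published ICU medians/IQRs (size 3.67 mm, constriction 32.5%, velocity
3.61 mm/s, latency 0.24 s), because no association was observed for them.
Defaults: r² = 0.04 per group, NPi center 4.33.

**Cohorts.** 52 septic + 40 non-septic patients, 480-s recordings at
50 Hz. Intended per-patient Mxa is drawn from a normal(0.33, 0.356)
truncated to [−1, 1] — matching a 0.33 [0.09–0.57] median/IQR target —
and mapped to w through the inverse of a pilot-simulated, monotonized
w → E[Mxa] curve (21 grid points × 24 pilot seeds, fixed internal pilot
seed, cached per waveform setting; targets outside the achievable range
clamp to w ∈ {0, 1}). Pupillometry is generated per group from the
*computed* Mxa values so that the targeted r² refers to the association
the analysis actually measures; a group with zero Mxa variance falls back
to the null association. Measured behavior at these defaults: impaired
fraction averages ≈ 0.55 across cohorts, realized median Mxa ≈ 0.35
(a +0.02 offset intrinsic to the left skew of bounded correlation
estimates), realized IQR ≈ [0.10, 0.58].

All generators are pure functions of (config, seed); a fixed seed yields
byte-identical cohort directories.

### What the generator does and does not emulate

It reproduces the statistical structure the pipeline consumes: shared slow
waves with tunable coupling, realistic Mxa dispersion, weak and noisy
pupillometry associations, group labels. It does not emulate pulse
morphology, beat-to-beat variability, non-stationarity within a
recording, asymmetric eyes, or any causal link between sepsis and
autoregulation (group labels are assigned, not mechanistic). Passing
tests therefore demonstrate that the pipeline measures what it claims on
data with known structure — not that the clinical findings themselves
generalize.

## Numerical choices

* Window starts are sample-index based (`round(k · step · rate)`), final
  partial window dropped; a 480-s recording at defaults yields exactly
  floor((480 − 10)/5) + 1 = 95 windows.
* Pearson r clipped into [−1, 1] against rounding overshoot; constant
  series raise an undefined-correlation error distinct from numeric 0.
* Signal CSVs are written with 6 significant digits (stated in the file
  header); missing samples round-trip as empty fields.
* Rate mismatch between ABP and FV is resolved by linear interpolation to
  the lower rate before windowing.
* The w → E[Mxa] pilot curve is forced monotone with a running maximum
  before inversion.
* Test problem sizes (cohort counts, seed counts, 2-min recordings in
  fixtures) are chosen so the full suite completes in a few minutes while
  keeping every assertion's Monte-Carlo error well below its margin.

## Known limitations

* Mxa estimation noise at realistic recording lengths is large (SD ~0.15);
  single-recording classifications near the 0.3 threshold are fragile.
  This is a property of the index, faithfully reproduced.
* The exact rank-sum path enumerates C(n, n_x) assignments and is
  restricted to pooled n ≤ 12.
* DeLong CIs are asymptotic; for very small strata the bootstrap
  alternative (not enabled by default) may be preferable.
* The cohort generator's Mxa median carries the +0.02 skew offset noted
  above; calibrating it away would require distorting the intended-Mxa
  distribution and is deliberately not done.
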