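# Methods

This note records the models and procedures the package implements, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data generators do and do not establish about real data.

## 1. Screen normalization model

A screening *run* is one physical 96-well plate read once: identified by
(plate, concentration pass, replicate). All normalization is strictly
within-run, against the run's own DMSO vehicle wells:

* `Vi = 100 · fluo / mean(fluo_vehicle)` — the viability index. It is not
  clamped; values above 100 occur whenever a well out-fluoresces the
  vehicle mean and are flagged (`vi_over_100`) rather than truncated,
  because truncation would silently hide pipetting or growth anomalies.
* `N = lum / fluo` — reporter activity per viable-cell signal. Wells with
  `fluo = 0` cannot be normalized; they are retained, flagged invalid and
  excluded downstream. A dead well never aborts a run.
* `E = 100 · N / mean(N_vehicle)` — the effect on the percent-of-vehicle
  scale.

Two exact consequences, asserted by tests on every dataset: vehicle wells
average to `Vi = E = 100` per run, and any multiplicative rescaling of a
plate's luminescence channel (a "plate effect": reagent lot, detector gain,
time drift) leaves every `E` unchanged.

A note on the measurement table: `concentration_uM` labels the screening
pass a run belongs to, for every well including controls (controls are
physically present on every pass). Vehicle wells contain no drug by role;
the drug content of the control wells is fixed assay metadata, not a
per-row variable.

## 2. Z′-factor quality control

Per plate, `Z′ = 1 − 3(σ_s + σ_c)/|µ_s − µ_c|` is computed on the E scale
between each control class and the vehicle, with sample standard deviations
(n − 1). Z′ is scale-invariant, so the E and N scales give identical values
(asserted by test). Equal means make Z′ undefined; the implementation
returns a flagged NaN sentinel and fails the plate instead of raising.

Grouping: the default pools a plate's control wells across its four runs
(2 concentrations × 2 replicates: 16 wells per control class, 32 vehicle).
Pooling is legitimate because E is already per-run normalized, and it
matters: with only 4 control wells per class per run, the per-run Z′
estimator has a standard deviation near 0.10, so a run of a genuinely
excellent assay (true Z′ ≈ 0.64) still dips below 0.5 about one time in
ten. Pooling shrinks the estimator sd to ≈ 0.05. Even then, roughly 1% of
plates of such an assay fall under the 0.5 bar by estimation noise alone —
an irreducible property of small-n Z′ estimation, visible in the package's
own simulations, and the reason a small fraction of true modulators can be
lost to QC gating (their plates are excluded, which is the conservative and
intended behavior). Per-run QC is available via `qc_screen(...,
group_keys=RUN_KEYS)`.

A plate missing a control class (e.g. a screen's first plate before an
inhibitor control compound was identified) is QC'd on the available pair
with a warning; a plate with no computable pair fails.

Defaults: `qc_threshold = 0.5`, the conventional excellent-assay bound for
the screening-window coefficient.

## 3. Hit calling

A compound-well observation is a candidate inhibitor iff `E ≤ 40` and
`Vi ≥ 70`, candidate activator iff `E ≥ 240` and `Vi ≥ 70`, on a
QC-passing plate. Thresholds encode "at least a 0.4-fold reduction or a
2.4-fold upregulation" on the DMSO = 100 scale; the boundary is inclusive
("at least"). The replicate rule (`all`, default) requires every replicate
at a concentration to agree — conservative, favoring reproducibility over
sensitivity; `any` is available. A hit needs to satisfy the rule at one or
more concentrations; opposite directions at different concentrations
cancel to `none` with a conflict flag. Compounds with no valid observation
on any passing plate carry a no-data flag.

The viability gate (`viability_min = 70`, configurable) is a conventional
cytotoxicity cut: a well that has lost a third of its cells cannot be
trusted to report transcription rather than death. It is a gate, not a
correction — no attempt is made to rescale E in partially toxic wells.

Out of scope by design: B-score/median-polish spatial correction,
dose-response (EC50) fitting, and multiple-testing control — the hit
calling is threshold-based, not p-value-based.

## 4. Validation statistics

**Relative expression.** `ΔCt = Ct_target − Ct_reference` on per-gene mean
Cts; multiple reference genes combine as the arithmetic mean of their mean
Cts, i.e. the geometric mean of their abundances (configurable to a single
reference). Because the orientation of `2^ΔCt` ratios is the dominant
failure mode of comparative-Ct analyses, both orientations are always
emitted (`ratio_target_over_reference = 2^(−ΔCt)` and its reciprocal).
Fold versus a calibrator sample is `2^(−ΔΔCt)`; the calibrator's own fold
is exactly 1 by construction. PCR-efficiency correction and standard
curves are out of scope.

**Group tests.** Both tests are computed side by side wherever conditions
are compared. The Mann–Whitney test is exact by full enumeration of all
C(n, n_x) group assignments when total n ≤ 12 (C(12,6) = 924 assignments):
the two-sided p is the proportion of assignments whose rank-sum deviates
from its null mean at least as much as observed, computed on midranks so it
remains exact under ties (the usual exact algorithms assume no ties). Above
n = 12 the tie-corrected normal approximation takes over; the cutoff keeps
triplicate-scale data exact at negligible cost. Note an inherent
small-sample fact: with 3 vs 3 observations the smallest achievable
two-sided exact p is 0.1, so triplicates can never reach the `*` tier under
this test — the t-test carries the significance assessment at that scale.
The t-test is the pooled-variance Student form (Welch by flag); zero pooled
variance returns p = 1 (equal means) or a flagged p = 0 (unequal means)
instead of raising. Tiers: `§` p<0.001, `#` p<0.01, `*` p<0.05, `ns`
otherwise, strict inequalities.

**Condition summaries.** Dose series and time courses are reported on the
vehicle = 100 scale per stratum, with both tests against the vehicle
group attached. No multiple-testing correction across panels is applied.

## 5. Imaging quantification

**µCT.** `V = N · v` for N voxels at or above the HU threshold and voxel
volume `v`; density is `Σ HU_i / V` over the mask. Segmentation is a
single global threshold with no morphology; an optional minimum-component
filter exists but is off by default. "75 µm voxels" is read as an
isotropic 75 µm edge (voxel volume 0.075³ mm³) — the standard µCT usage —
and spacing is always explicit so the reading is overridable. There is no
principled universal HU cut for "mineralized": the threshold is a required
explicit parameter in the CLI (no silent default); 400–600 HU are
conventional soft-tissue/bone cuts used in the examples. Registration
between time points and anatomical masking of the normal skeleton are out
of scope; longitudinal comparison is by volume difference of
equal-spacing scans only.

**Stained area.** Color thresholding in HSV space: positive = inside a
hue window (wrapping around red for Alizarin-type stains) with saturation
and value floors; denominator = tissue pixels (saturated or dark enough
not to be blank slide). The default window values are artifact choices
documented in `StainConfig`, not measured constants; real slides need the
window set against stained/unstained references.

**Nuclei.** Intensity threshold, 8-connected components, minimum size,
centroid per retained component. No watershed/declumping: touching nuclei
merge into one component. Adequacy is guaranteed only for well-separated
nuclei (as on the synthetic fixtures); dense cultures would need a
declumping step this package deliberately does not include.

## 6. Synthetic-data generators

Every generator is a deterministic function of (config, seed) and emits
its ground truth. The screen generator's default structure is the screen
it emulates: 16 plates × 80 compounds, 8 vehicle + 4 + 4 control wells in
columns 1/12, duplicates at 20 and 2 µM, control multipliers 2.4×/0.4×,
5% coefficients of variation, a lognormal per-plate scale effect on
luminescence (sd 0.15), and 5% cytotoxic compounds at 30% viability.

Generative model per well: the fluorescence draw (cell-number variation,
cv 5%) enters the luminescence proportionally — dead cells emit neither
signal, which is also how toxicity is modeled (one factor scaling both
channels) — while an independent 5% multiplicative measurement noise on
luminescence survives into N = lum/fluo. Consequences: the viability gate,
not the effect threshold, is what flags toxic compounds (their E stays
near 100); the plate effect cancels from E exactly; and the per-plate Z′
lands at 0.62–0.66 for the default control multipliers, a realistic
excellent-assay window. Toxic compounds are drawn among the inactive ones
so that recovery tests have an unambiguous truth set. Potency at the lower
concentration is attenuated as `multiplier^0.5`, so the
either-concentration hit logic is genuinely exercised (actives typically
qualify only at 20 µM).

What the generators do *not* emulate: spatial plate artifacts (edge
effects, drift), correlated well failures, PCR efficiency differences, CT
noise physics (beam hardening, rings), stain anti-aliasing, overlapping
nuclei. Passing recovery tests therefore shows the analysis is correct
under the stated generative model, not that it is robust to artifacts the
model excludes.

Problem sizes used in the test suite and acceptance script — 100 simulated
screens for QC statistics, 20 for hit recovery, 100 Ct-table seeds,
phantom grids up to 96³ — were chosen as the smallest sizes at which the
measured quantities are stable to well within the asserted tolerances.

## 7. Numerical and degenerate-input policy

* Division anchors (vehicle means, calibrator ΔCt) must be strictly
  positive; violations raise plate-level errors naming the run.
* Z′ with equal means, density of an empty mask, percent change from a
  zero baseline: flagged NaN results, never exceptions, so one degenerate
  record cannot abort a batch run.
* Standard deviations use n − 1 throughout; n ≥ 2 is required wherever an
  sd is reported.
* Exact test p-values are compared with a 1e-9 rank-sum slack when
  classifying "at least as extreme", guarding against float noise in
  midranks; enumeration itself is exact.
* Well labels are letter-row/1-based-column ("A01"), plate-reader
  convention; all CSVs are UTF-8 with '.' decimals.

## 8. Known limitations

* Z′-based plate gating at small control counts discards ~1% of plates of
  a genuinely good assay (section 2); re-screening excluded plates is the
  real-world remedy and is outside this package.
* The hit rule treats concentrations independently; no monotonic
  dose-response consistency check is applied.
* The exact Mann–Whitney becomes the asymptotic test above n = 12 without
  a continuity-matched blend; p-values are not continuous across the
  switch (documented, conventional).
* Image quantification assumes 8-bit RGB/grayscale inputs and makes no
  attempt at illumination correction or stain deconvolution.
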