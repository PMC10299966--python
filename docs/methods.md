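# Methods

## The transition model

The package classifies country-years into five mortality-transition phases
from two indicators: the maternal mortality ratio (MMR, deaths per 100 000
livebirths) and combined stillbirth plus neonatal mortality (SBN, deaths per
1000 total births).  The default knots are MMR 700/300/100/20 and SBN
80/55/30/15; the SBN knots correspond to neonatal-mortality thresholds of
45/30/15/5 per 1000 livebirths plus a stillbirth contribution of roughly
equal magnitude.  An NMR-only knot vector (45/30/15/5) ships as
`NMR_ONLY_KNOTS` for analyses of empirical data without stillbirth counts,
and arbitrary custom knots are accepted (validated as four strictly
decreasing positive values).

**Dual-threshold (min) rule.**  A country reaches phase *k* only when both
indicators are below all knots separating phases 1..k; the combined phase is
the minimum of the per-indicator phases.

**Boundary convention.**  A value exactly at a knot has *not* passed it and
stays in the higher-mortality phase.  This follows the printed phase
definitions ("≥ 700" for phase 1, "< 20" for phase 5); the convention at
intermediate knots is not documented in the source material, so the same
half-open rule is applied uniformly and is exercised explicitly by the
tests (a zero-margin generator run samples knot values exactly).

**Combining SBR and NMR.**  The stillbirth rate is per 1000 total births but
neonatal mortality is per 1000 livebirths.  Two conventions are available:

* `approximate` (default): `sbn = sbr + nmr`.  The model's knot arithmetic
  behaves as a simple sum (neonatal 45 + stillbirth 35 → 80), so this is the
  convention under which the published knots are self-consistent.
* `exact`: `sbn = sbr + nmr * (1 − sbr/1000)`, rescaling neonatal deaths to
  the total-births denominator.  Always ≤ the approximate value; the
  difference is < 2 per 1000 at realistic rates.

**Knot ratios.**  `sbn_to_mmr_ratio = 100 * sbn / mmr` treats total births
as approximately equal to livebirths (error < 4% even at a stillbirth rate
of 35 per 1000); an optional livebirth-fraction correction applies when
counts are known.  Under this convention the default knots give ratios
(80/7, 55/3, 30, 75) → rounded (11, 18, 30, 75), reported both ways because
the printed integers come from non-integer arithmetic.  Rounding is
half-away-from-zero.

**Uncertainty sensitivity.**  Classifying the lower estimate bound (lower
mortality) can only give an equal-or-later phase than the point estimate,
and the upper bound an equal-or-earlier one; this ordering is a theorem of
the monotone classifier and is property-tested.  `uncertainty_phase_span`
reports the per-country difference phase(lower) − phase(upper) and its mean;
countries missing any bound are excluded and counted rather than imputed.

## Transition dynamics

Transition matrices are 5×5 counts of (phase at t0, phase at t1) over
countries classified at both time points; countries present at only one time
point are excluded and logged, never imputed, so the matrix total equals the
matched-country count by construction.  The progression summary counts
Δ ≥ +1, Δ = +2 (exactly; with a Δ ≥ +2 variant also reported) and Δ < 0
among eligible countries.  Default eligibility is countries below phase 5 at
t0 — phase-5 countries cannot progress further — with an `all_phases_at_t0`
switch for the inclusive denominator.  Proportions are kept exact internally
and rounded to whole percent only for display.

## Phase profiles and benchmarking

Phase-conditional reference distributions are unweighted country medians
with quartiles (the underlying multicountry analyses report country
medians, not population-weighted ones).  The quartile convention is numpy's
linear-interpolation method, the common statistical default; it is a
parameter, so alternative conventions can be compared.  Phases with no
contributing country are absent from the result rather than zero-filled.
Benchmarking flags a country value as `typical` when it lies within the
phase IQR, widened multiplicatively by an optional tolerance.  Profiles are
computed per reference year; on synthetic data the 2000 and 2020 profiles
agree because covariates are generated conditionally on the current phase,
mirroring the time-invariance of phase characteristics in observed data.

Cause-of-death tables are aggregated into three broad groups — infectious
causes (including abortion complications), causes related to the health and
nutritional status of the woman or baby (indirect causes, prematurity,
growth restriction), and peripartum complications — plus `other`, and
renormalised to sum to 100 (guarded to 1e−6).  Default cause→group mappings
for maternal, stillbirth and neonatal deaths ship as editable two-column CSV
files; strict mode rejects unmapped causes, lenient mode routes them to
`other` with a logged count.

The abortion-policy score counts permitted legal grounds out of five
(save the woman's life; physical health; mental health; rape/incest or
fetal impairment; on request) on a 0–100 scale with equal weights.  The
exact grounds and any ordinal weighting used in published scores are not
reproducible from the available material, so equal-weight binary counting is
the documented stand-in; both the ground names and the weight vector are
configurable.

## Equity statistics

For coverage by wealth quintile (q1 poorest … q5 richest) the package
computes the absolute gap `q5 − q1` (percentage points, negative when the
gradient reverses) and the inequality patterns index

    IPI = (q5 − mean) − (mean − q1) = q5 + q1 − 2·mean.

The source describes this index in one sentence (the difference in the gap
between the bottom and top quintiles compared with the national mean)
without a functional form or threshold; the signed formula above is a
faithful reading, with a ±5 percentage-point tolerance for the `linear`
label.  Both the formula's tolerance and the label rule are configurable.
A consequence worth noting: once the overall gap shrinks below about 7
points, |IPI| cannot exceed 5, so very late-transition countries are
necessarily `linear` — the index is a pattern detector for material
inequality, not a high-precision measure at near-universal coverage.  The
national mean defaults to the unweighted quintile mean (with a warning)
when absent; livebirth weights are honoured when provided.

## The synthetic-data generator

The generator emulates the statistical structure of the real inputs, not
any particular country:

* **Mortality.**  Each country gets an intended baseline phase; its
  (MMR, SBN) pair is drawn uniformly inside that phase's threshold box
  shrunk by a 10% interior margin, so classification recovers the intended
  phase exactly (margin 0 stress-tests the boundary convention).  The open
  phase-1 and phase-5 boxes are capped at MMR 1400 / SBN 130 and floored at
  3, generous relative to the highest national estimates.  Between years a
  country advances one phase with probability 0.63 (phases 1–4) or regresses
  one with probability 0.03, matching the observed share of countries
  progressing (≈63%) and regressing (≈3%) over a 20-year interval; otherwise
  its rates decline at 2%/year with lognormal noise (sd 0.05 on the decline
  factor), clipped into the phase box so the truth table stays exact.
* **Indicator split.**  SBN is split into SBR and NMR by drawing a target
  stillbirth:neonatal ratio uniformly in (0.7, 1.1) — the band observed in
  historical and estimate data — and solving the resulting quadratic
  exactly, so every generated country-year's ratio lies in the band.
* **Uncertainty.**  Bounds are point × (1 ± half-width) with half-widths
  0.30 (MMR), 0.20 (SBR) and 0.10 (NMR), reflecting the relative widths of
  the published uncertainty intervals (maternal mortality much less
  precisely estimated than neonatal mortality).
* **Covariates.**  Ten covariates are drawn per country-year from normal
  distributions centred on the phase-specific medians, with sd = IQR/1.349
  and clipping to natural bounds (clipping preserves the median).  The
  reference medians equal the printed phase medians where available (TFR
  6.1/5.4/2.8/2.2/1.5 with the printed IQRs; ANC1 66→98; ANC4 44→94;
  institutional birth 36→99; caesarean 2→25; abortion score 51→86;
  workforce and financing gradients); IQRs not printed in the source are
  set to plausible widths of roughly 30–50% of the median.
* **Quintiles.**  Institutional-birth quintile centres implement the
  configured inequality regime per phase — top inequality in phases 1–2
  (richest quintile ~25–30 points above the gradient, gap ≈50), bottom
  inequality in phase 3 (poorest ~25 points below, gap ≈47), linear in
  phases 4–5 (gaps 7 and 2).  Phase 4 is configured `linear` rather than
  `bottom`: with the published gap of 7 points the IPI is bounded by ±4.2,
  below the 5-point tolerance, so a `bottom` label is unattainable there by
  construction.  Additive noise sd is 1.5 points, giving ≥95% pattern
  recovery with margin.  Caesarean quintile centres rise from (0.5, 5) in
  phase 1 to (22, 33) in phase 5, passing the characteristic accelerations
  (richest 10→28 across phase 2|3, poorest 4→15 across phase 3|4), with 15%
  relative noise.
* **Randomness.**  A single seed spawns one named stream per output table
  (mortality, covariates, quintiles), so adding a table never perturbs
  existing ones; a fixed seed yields bit-identical output.

**What the generator does not emulate:** the UN estimation models'
uncertainty propagation or shared-covariate correlations, real country
trajectories, reporting artefacts (stillbirth under-reporting,
neonatal/stillbirth misclassification), or multi-phase jumps within one
interval (two-phase advances arise only over multiple intervals).  Passing
recovery tests therefore demonstrates the pipeline's internal correctness
and statistical calibration under clean conditions, not robustness to
real-data pathologies.

## Problem sizes and numerical choices

The parameter-recovery checks run on 400 countries per intended phase
(2000 countries, two years), which makes the sampling error of each
phase-median ≲ 2.5% relative and keeps the whole suite and the acceptance
script within seconds.  Classifier correctness is checked by exact
agreement with a brute-force highest-passed-phase scan on a 200×200 grid
that includes every knot exactly.  Cause-group shares are clamped at 100
after renormalisation to absorb float round-off in single-group tables.
Undefined ratios (zero denominators) raise in scalar calls and propagate as
NaN with a logged count in batch calls, so one degenerate row cannot abort
a multi-country run.  All analysis stages are deterministic; randomness is
confined to the generator.

## Known limitations

* The intermediate-knot boundary convention and the IPI functional form are
  documented package choices where the source material is silent; both are
  configurable.
* The abortion-policy score is an equal-weight stand-in for a published
  score whose exact construction is unavailable.
* The package consumes mortality *estimates*; it does not estimate rates
  from survey microdata, smooth trajectories between estimate years, or
  compute onset years of transitions.
* Phase counts and progression shares computed on synthetic data
  characterise the generator's conditions, not any real country set.
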