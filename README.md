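# msnt — a five-phase maternal, stillbirth and neonatal mortality transition model

Maternal deaths, stillbirths and neonatal deaths share causes, interventions
and service-delivery platforms, yet are usually analysed separately.  `msnt`
implements an integrated five-phase mortality-transition model for
country-level analysis: it classifies countries into transition phases from
two mortality indicators, quantifies movement between phases over time,
profiles the covariates (fertility, health workforce and financing, service
coverage, abortion policy, causes of death) that characterise each phase,
benchmarks individual countries against phase norms, and analyses
wealth-quintile inequality in coverage.  A bundled synthetic country-panel
generator with known ground truth makes the whole pipeline testable without
any external data downloads.

The intended users are epidemiologists and global-health analysts working
with national mortality estimates and household-survey coverage data.

## The model

Two indicators drive the classification:

* **MMR** — maternal mortality ratio, maternal deaths per 100 000 livebirths;
* **SBN** — stillbirths plus neonatal deaths per 1000 total births
  (livebirths + stillbirths), combining the stillbirth rate (per 1000 total
  births) and the neonatal mortality rate (per 1000 livebirths) onto one
  denominator.

Phases are separated by four threshold knots per indicator:

| knot | MMR (per 100 000) | SBN (per 1000) | SBN:MMR ratio |
|------|-------------------|----------------|---------------|
| 1→2  | 700               | 80             | 11            |
| 2→3  | 300               | 55             | 18            |
| 3→4  | 100               | 30             | 30            |
| 4→5  | 20                | 15             | 75            |

Phase 1 has the highest mortality (MMR ≥ 700 *and* SBN ≥ 80), phase 5 the
lowest (MMR < 20 and SBN < 15).  A country advances to the next phase only
when **both** indicators have passed the knot — the combined phase is
`min(phase_MMR, phase_SBN)`.  Values exactly at a knot remain in the
higher-mortality phase.  The rising SBN:MMR knot ratio encodes the
structural feature of the transition: maternal deaths fall faster than
stillbirths and neonatal deaths, so their ratio climbs from about 11 to 75
as countries progress.

On top of the classification the package provides: uncertainty-bound
sensitivity (re-classifying on the lower/upper estimate bounds), 5×5
transition matrices and progression summaries between two years,
phase-conditional median/IQR profiles for any covariate with IQR-based
country benchmarking, three-group cause-of-death aggregation, a five-ground
abortion-policy score, and the wealth-quintile gap and inequality patterns
index (IPI = q5 + q1 − 2·mean, positive = top inequality, negative = bottom
inequality).

## Worked example

```python
import msnt

est = msnt.CountryYearEstimate(
    "BGD", 2000, mmr=434, sbr=32.8, nmr=42.4,
    mmr_lower=350, mmr_upper=540, sbr_lower=26.0, sbr_upper=40.0,
    nmr_lower=38.0, nmr_upper=47.0)

print(msnt.classify_country(est))
print(msnt.CombinedRates.from_estimate(est))
```

```
PhaseAssignment(country_id='BGD', year=2000, phase_mmr=2, phase_sbn=2, phase=2, variant='point')
CombinedRates(sbn=75.19999999999999, sbn_to_mmr_ratio=17.327188940092164, sb_to_nn_ratio=0.7998189678043602)
```

MMR 434 sits between the 700 and 300 knots and the combined SBN rate
(32.8 + 42.4 = 75.2 per 1000 births, simple-sum convention) between 80 and
55, so both indicators — and the country — are in phase 2.  Stillbirths and
neonatal deaths together outnumber maternal deaths about 17:1, and the
stillbirth:neonatal ratio of 0.80 is in the usual 0.7–1.1 band.

End to end on a synthetic panel (300 countries, 60 per intended phase,
years 2000 and 2020):

```python
panel = msnt.generate_panel(msnt.reference_config(), seed=42)
cls = msnt.classify_panel(panel.estimates)
t0, t1 = cls[cls.year == 2000], cls[cls.year == 2020]
print(msnt.progression_summary(msnt.match_assignments(t0, t1)).as_dict())
```

```
{'n_eligible': 240, 'n_progressed_ge1': 149, 'n_progressed_eq2': 0, 'n_progressed_ge2': 0,
 'n_regressed': 7, 'pct_progressed_ge1': 62, 'pct_progressed_eq2': 0, 'pct_regressed': 3}
```

Of the 240 countries below phase 5 at baseline, 62% progressed at least one
phase over the 20-year interval and 3% regressed, matching the generator's
configured progression (0.63) and regression (0.03) probabilities.

The same pipeline is scriptable from the shell:

```sh
msnt simulate --seed 42 --outdir synth/
msnt classify --input synth/panel.csv --year 2020 --output phases2020.csv
msnt report --panel synth/panel.csv --covariates synth/covariates.csv \
            --quintiles synth/quintiles.csv --outdir report/
```

## Layout

- `src/msnt/core.py` — validated estimates; SBN combination and ratios
- `src/msnt/phases.py` — thresholds, classification, knot ratios, bound spans
- `src/msnt/transitions.py` — transition matrices, progression summaries
- `src/msnt/profiles.py` — phase profiles, benchmarking, causes of death, abortion score
- `src/msnt/equity.py` — quintile gap, inequality patterns index
- `src/msnt/synthetic.py` — synthetic country-panel generator
- `src/msnt/io.py`, `cli.py` — readers/writers, report pipeline, CLI

See `docs/methods.md` for the modelling choices, generator design and known
limitations.
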