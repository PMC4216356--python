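# edemascore

Standardized scoring of pulmonary edema on bedside chest radiographs,
plus the complete multi-reader diagnostic-accuracy evaluation machinery
needed to compare a score-based reading approach against unaided reading.

## The problem

Bedside (portable, supine AP) chest radiographs of ventilated ICU
patients are hard to read, and unaided judgments of whether a patient
has pulmonary edema agree poorly between radiologists and with objective
measures of lung water. A structured alternative is to grade nine
characteristic radiographic findings on ordinal scales, weight them, and
classify the film by the total score:

| finding | points by severity |
|---|---|
| hilar vessels enlarged | 1 / 2 / 3 |
| hilar vessels increased in density | 2 / 4 / 6 |
| hilar vessels blurred | 3 / 6 / 9 |
| Kerley B lines | 4 / 8 |
| micronoduli | 4 / 8 |
| widening of interlobular fissure | 4 / 8 / 12 |
| peribronchial and perivascular cuffs | 4 / 8 / 12 |
| extensive perihilar haze | 5 / 10 / 15 |
| diffuse increase in density | 5 / 10 / 15 |

An absent finding always scores 0. The total `S = Σᵢ wᵢ(ℓᵢ)` ranges over
0–88; `S > 15` is read as pulmonary edema, `S ≤ 15` as no edema.
Findings that directly represent extravascular lung water (perihilar
haze, diffuse density) carry the largest weights.

The reference standard is extravascular lung water (EVLW, mL/kg,
transpulmonary thermodilution): ≤ 8 means no edema, ≥ 15 means edema,
and 9–14 is borderline and excluded from accuracy computations.

The evaluation layer implements, for a paired readers × cases design:

- pooled and per-reader confusion counts against the EVLW reference;
- sensitivity, specificity, PPV, NPV with Clopper–Pearson (default) or
  Wilson binomial confidence intervals;
- mean per-case proportion of concordant reader pairs (observed
  agreement P̄₀) and the free-marginal multirater kappa
  `κ_free = (P̄₀ − 1/k)/(1 − 1/k)`, which for two categories is `2P̄₀ − 1`;
- the paired binary net reclassification index
  `NRI = (up_ev − down_ev)/n_ev + (down_ne − up_ne)/n_ne = ΔSens + ΔSpec`,
  with an asymptotic standard error, normal CI and p-value, pooled and
  per reader.

A synthetic-study module (`edemascore.simulate`) generates complete
reader studies — EVLW cohorts, latent per-case finding severities,
per-reader rating sheets and unaided calls — so the whole pipeline is
testable without a single radiograph. This tool scores human-entered
ratings; it does no image analysis.

## Worked example

Score one reader's ratings for one film (`level` is the ordinal grade,
0 = finding absent):

```
$ edemascore score ratings.csv
[
  {
    "case_id": "case_07",
    "reader_id": "reader_1",
    "per_item_points": {
      "hilar_enlarged": 2, "hilar_density": 4, "hilar_blurred": 6,
      "kerley_b": 4, "micronoduli": 4, "fissure_widening": 4,
      "cuffs": 0, "perihilar_haze": 0, "diffuse_density": 0
    },
    "total": 24,
    "classification": "edema",
    "threshold": 15,
    "rubric_checksum": "ba8bc7a5ddb4"
  }
]
```

Moderate hilar findings (2+4+6) plus mild Kerley B lines, micronoduli
and fissure widening (4+4+4) total 24 points, above the threshold of 15,
so the film is classified as showing pulmonary edema.

Compare two reading approaches on the packaged seven-reader study
reconstruction (`edemascore.fixtures`):

```
$ edemascore evaluate --old calls_standard.csv --new calls_score_based.csv \
      --reference reference.csv --format tsv-summary
metric              standard   score_based
sensitivity_percent    57.14         77.14
specificity_percent    90.00        100.00
ppv_percent            85.11        100.00
npv_percent            67.74         81.40
nri_pooled              0.30
nri_reader_1            0.30
nri_reader_3            0.60
...
```

Reading with the score raised pooled sensitivity from 57.14% to 77.14%
and specificity from 90.00% to 100%; the pooled NRI of 0.30 means the
score-based approach corrected a net 20% of edema readings plus a net
10% of no-edema readings. (Agreement and kappa in this fixture's output
describe the reconstructed per-case assignment, which is synthetic — see
`edemascore/fixtures.py`.)

Generate a full synthetic study from a YAML config:

```
$ edemascore simulate --config sim.yaml --out-dir study/
```

writes the reference, rating sheets, both call matrices, and the
evaluation report (JSON + TSV).

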