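# Methods

## Scoring model

Nine radiographic indicators are graded ordinally; level 0 always means
the finding is absent and scores 0 points. Seven indicators use four
levels (absent / mild / moderate / severe); Kerley B lines and
micronoduli use three. Because the published grade names for the
three-level scales are ambiguous, levels are stored **positionally**
(0 = absent, then ascending severity) and display names are cosmetic;
the point values are unambiguous either way. The three hilar-vessel
findings (enlarged, increased density, blurred) are modelled as three
independent indicators since each carries its own point vector.

The total is the sum of the per-indicator points (0–88 for the default
weights). The decision rule is strict: total > 15 → edema,
total ≤ 15 → no edema. It is encoded at a single comparison site
(`classify_score`) so the boundary convention is auditable. Weights and
threshold are loadable from YAML for sensitivity-to-weights experiments;
the default rubric is frozen in code and identified in every report by a
SHA-256-derived checksum.

Rating sheets are all-or-nothing: every indicator must be graded. No
"not assessable" state is modelled, because the scoring procedure being
reproduced has none.

## Reference standard

EVLW (mL/kg) maps to no edema (≤ 8), borderline (9–14, excluded from
accuracy computations), or edema (≥ 15). Non-integer values are rounded
half-up before banding — EVLW is reported clinically in integer mL/kg,
and rounding makes the three bands tile the positive axis with no
undefined gaps at (8, 9) and (14, 15). Borderline cases are excluded
explicitly by the evaluation stage and listed in the report; they are
never dropped silently and never enter confusion counts.

## Diagnostic metrics and confidence intervals

Readings are pooled over readers × cases. Sensitivity = tp/(tp+fn),
specificity = tn/(tn+fp), PPV = tp/(tp+fp), NPV = tn/(tn+fn), reported
as percentages. A PPV or NPV with a zero denominator is reported as
undefined with an explicit flag, never coerced to 0 or 100.

CIs are two-sided binomial intervals: Clopper–Pearson (beta-quantile
exact, the default) or Wilson, both via statsmodels, with the method
name recorded in every report. The source study does not name its CI
method and its printed bounds match neither method at the pooled
denominators (e.g. a lower bound of 93.52 for 70/70, where
Clopper–Pearson gives 94.87), so CI bounds are treated as
non-reproducible; only point estimates are asserted in tests.
Clopper–Pearson is guaranteed conservative, which the suite confirms by
simulation (coverage ≥ 95% at n = 70 over 10,000 binomial draws at
p ∈ {0.5, 0.77, 0.9, 1.0}).

## Agreement

"Overall agreement" is computed as the mean over cases of the
proportion of concordant reader pairs (the observed-agreement component
of Fleiss-style statistics) — the standard companion of the
free-marginal multirater kappa, and consistent with the published
κ = 2P̄₀ − 1 pairing for both arms (0.84 ↔ 0.68, 0.67 ↔ 0.34).
κ_free = (P̄₀ − 1/k)/(1 − 1/k) assumes readers are not constrained to
category quotas, which matches a free binary edema call.

## Net reclassification index

For paired binary calls on the same readings, up-moves are
no-edema → edema reclassifications and down-moves the reverse. The
point estimate is the net proportion of event readings reclassified
correctly plus the net proportion of nonevent readings reclassified
correctly; algebraically this equals ΔSensitivity + ΔSpecificity, and a
property test asserts the identity against independently computed
confusion matrices. The standard error uses the asymptotic
variance of each net-move proportion,

    var = [(p_up + p_down) − (p_up − p_down)²]/n,

summed over the event and nonevent strata; the CI is nri ± z·se and the
p-value is a two-sided normal approximation. When nothing is
reclassified, se = 0 and the p-value is reported as undefined rather
than fabricated. Raw up/down counts are always exposed in the report so
alternative variance estimators can be applied downstream. The source
study's per-reader NRI CIs/p-values are under-determined (its up/down
splits were never published); with all-zero down-counts this estimator
reproduces its pooled CI 0.18–0.42 to the printed rounding, which the
suite asserts.

Per-reader readings of a common case set are balanced, so pooled
sensitivity equals the unweighted mean of per-reader sensitivities; this
is asserted as a property.

## The published-study fixture

`edemascore.fixtures` reconstructs the seven-reader, twenty-case study
from its per-reader correct counts by marking the first k cases of each
group correct for each reader (a nested construction, so all
reclassification is upward). The per-case assignment is a modelling
choice: all pooled and per-reader point metrics and the NRI point
estimates are invariant to it, and only those are asserted. Pairwise
agreement, kappa and the NRI up/down split computed *from this fixture*
reflect the synthetic assignment, not the original reading sessions, and
are documented as such. Fixture EVLW values are synthetic integers
spanning the reported 4–8 and 15–21 mL/kg ranges, anchored to the two
published worked examples (7 and 21 mL/kg).

## Synthetic studies

`simulate_cohort` draws integer EVLW values uniformly within each
group's band (defaults 4–8, 15–21, 9–14 mL/kg; default composition 10
edema + 10 no-edema cases, the study design being emulated).
`simulate_ratings` draws latent per-indicator severities once per case
from a severity model conditional on true status, then perturbs them
per reader by ±1 level with probability `rating_noise` (symmetric, the
simplest noise respecting the ordinal scale; default 0.05). Unaided
calls are Bernoulli draws from each reader's configured operating point
(defaults 57% sensitivity / 90% specificity, the pooled unaided
operating point of the study being emulated). All randomness flows
through numpy generators seeded from one `SeedSequence`; reruns are
bit-identical.

Two severity presets ship. `separable` is degenerate (edema → all
findings severe, no edema → none) and makes the score arm a perfect
classifier, for contract tests. `paper_like` was calibrated once, by
exact convolution of the level distributions (no simulation in the
loop), so that noise-free P(total > 15 | edema) = 0.776 and
P(total > 15 | no edema) = 0.004 — a score arm operating near 77%
sensitivity / 100% specificity. The individual level probabilities
carry no biological claim; no generative link between EVLW and finding
severities exists to fit. Consequently the simulator reproduces the
*operating points* of a reading study, not the correlation structure of
real radiographs (indicator severities are conditionally independent
given status; real findings co-occur), so passing tests demonstrate the
statistical machinery, not radiographic realism.

The Monte-Carlo checks use 2,000 cases × 7 readers, large enough that
binomial error on a pooled proportion is ~0.6% while the full study
simulates and evaluates in under a second.

## Numerical and design notes

- Percentages, kappa and NRI are display-rounded to 2 decimals in the
  TSV summary; JSON reports keep full precision and round-trip
  losslessly through `report_from_dict`.
- Reports serialize with deterministic field ordering; identical
  reports produce byte-identical files.
- CSV schemas are comma-separated UTF-8 with required headers. Strict
  mode (default) rejects duplicate rating rows and unknown indicators;
  lenient mode keeps the last duplicate and drops unknowns with a
  warning.
- Exit codes: 0 success, 2 validation errors, 3 pairing errors, 4 I/O
  errors.
- Known limitations: binary calls only (no ROC, no multi-category NRI);
  no correction for clustering of readings within readers beyond the
  pooled/per-reader split; no image handling of any kind.
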