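# Methods

## The pipeline

`ehrphewas` implements a phenome-wide association scan over coded EHR
data, organized as five stages that mirror how such a study is actually
run: phenotype the index disease with a deterministic rule, assemble a
matched control series, classify every subject for every phecode, fit
one adjusted logistic regression per testable phecode with FDR control,
and fit a conditional logistic model over the matched sets for selected
codes.

### Phecode mapping and "related diseases"

ICD-9-CM codes are collapsed to phecodes through a v1.2-layout map. Two
structures on the phecode space drive the case/control logic:

* **Hierarchy** — positional: `q` is a descendant of `p` iff `q`'s
  string extends `p`'s at a decimal position (`401.22` ⊂ `401.2` ⊂
  `401`). Case counting for a phecode includes descendant-mapped events,
  the convention of the standard PheWAS tooling. A consequence worth
  knowing: a parent code inherits its children's signals, so effects
  planted (or present) on a child propagate upward. The bundled
  scenario's planted effects are placed on hierarchy leaves so that each
  planted odds ratio is estimated from its own phecode's events.
* **Exclusion range** — each map row may carry an inclusive numeric
  range of phecodes denoting related diseases. A subject with any code
  in a phecode's related set (itself, descendants, range members) is
  ineligible as that phecode's control.

The shipped fixture map has 30 rows / 30 phecodes across six
organ-system categories, chosen to cover the hierarchy and range
structures above; the full public v1.2 map loads through the same
reader (headers matched case-insensitively with aliases, because
published exports vary in spelling).

### Phenotype status

For target phecode `p`, a subject is:

* **case** — events mapping into `p`'s descendant closure on ≥2
  distinct calendar days ("two instances on different days, at least a
  day apart" coincides with 2 distinct dates at date granularity);
* **control** — zero events mapping into `p`'s related set;
* **excluded** — otherwise: a single-instance code (possible rule-out
  or billing error) or related-range codes without two target dates.

Excluded subjects are dropped from that phecode's regression, not
folded into controls: the control definition demands *no* related
instances.

### Index-disease algorithm and cohort

SLE cases: ICD-9 710.0 on ≥4 distinct dates, maximum recorded ANA titer
≥1:160 (any qualifying result ever — the rule asks for "a positive
ANA"), and zero 710.1/710.3 events. Distinct dates rather than raw row
counts make the rule robust to same-day duplicate billing.

Control pool: no ICD-9 codes under the 710.*/714.* headings, no ICD-10
codes under M05/M06/M32–M36, and "medical home" care density — ≥3
distinct outpatient dates within some 1826-day window (5 years
including a leap day; the window is evaluated over every
anchored-at-a-visit span, i.e. any three consecutive distinct dates
spanning <1826 days qualify).

Matching: cases visited in seeded random order; per case, pool members
of identical sex and race within ±`age_window` years (default 5) are
ranked by absolute age difference, ties broken uniformly at random
under the run seed, and the nearest `ratio` (default 5) taken without
replacement. Age is age at a common index date (the dataset's last
event date), since de-identified sources have no enrollment date.
Achieved ratios are reported rather than forced: with a finite pool
some cases match fewer than `ratio` controls, and a case with none
yields an empty stratum that downstream conditional regression drops.

### Unconditional logistic regression

`fit_logistic` is straight IRLS/Newton with step-halving: convergence
when max |score| < 1e-8 or the relative log-likelihood change is below
1e-10, at most 50 iterations. Wald covariance comes from the inverse
observed information at the optimum. Separation is *flagged*
(`converged=False`, via runaway coefficients or solver failure), never
silently penalized; non-converged fits are excluded from the FDR family.
A Firth-type penalty would be a reasonable extension point but is
deliberately not applied by default — transparency over silent
correction. Covariates enter on their natural scales (age in years,
unstandardized); factor covariates are coded against the first sorted
level, and columns constant in the analysis sample (e.g. sex in a
single-sex stratum) are dropped with a log note.

The FDR family for a scan is exactly the set of phecodes fitted in that
run (those with ≥ `min_cases` cases, default 20, and a converged fit).
`bh_adjust` implements the Benjamini–Hochberg step-up rule
`adj(i) = min_{j≥i} p(j)·m/j`, capped at 1, returned in input order.

### Conditional logistic regression

With exactly one case per matched set, conditioning on the set's case
count gives the softmax likelihood
`Σ_s [x_case·β − log Σ_j exp(x_j·β)]`, which is exact for this design —
no approximation to a more general conditional likelihood is involved.
Newton–Raphson with analytic gradient/Hessian and step-halving, ≤100
iterations, gradient tolerance 1e-8. Two numerical details:

* Covariates constant within *every* stratum (exactly-matched sex/race)
  are unidentified and dropped with a warning; age retains residual
  within-stratum variation under a ±5-year caliper and so stays
  estimable, which is why "adjusting for age, sex, race" on matched
  data is accepted but may reduce to adjusting for age.
* With covariates on natural scales the gradient's floating-point floor
  can sit above the absolute tolerance; when the likelihood stops
  improving at its precision floor, convergence is declared iff the
  gradient is small relative to |log L|. Perfect within-stratum
  prediction (log L → 0) or runaway coefficients are flagged
  non-converged.

The conditional OR for a binary phenotype is symmetric in
outcome/exposure; the implementation parameterizes outcome = case
status.

## The synthetic-EHR generator

The generator emulates, at desk scale, the statistical structure the
analysis assumes. Default study conditions:

| parameter | default | rationale |
|---|---|---|
| n_subjects | 20,000 | large enough for stable per-phecode fits at 1 CPU |
| P(African American) | 0.19 | source-EHR mix (81% Caucasian) |
| P(female) | 0.5 | source-EHR mix |
| age | uniform 18–85 y | adult tertiary-care range |
| follow-up | uniform 1–19 y | mean ≈10 y of EHR follow-up |
| SLE prevalence | AA 0.071, C 0.044 | yields ≈270 AA / ≈715 C cases at n=20,000, the cohort sizes a study of this design reports, with the expected ≈1.6× AA excess |
| P(ANA ≥1:160 \| SLE) | 0.95 | dominant driver of algorithm sensitivity |
| planted SLE ORs | 4.0 (401.1), 8.0 (585.31), 3.5 (480.1) | tiered hypertension / dialysis / pneumonia-like signals among 27 nulls |
| comorbidity baseline | 4% at age 50, +0.01/y log-odds | common-comorbidity prevalence |
| event_rate | Poisson mean 2 extra dates | diseased subjects emit 1+Poisson(2) distinct dates |
| rule_out_prob | 0.05 | non-diseased single-instance codes → excluded stratum |
| phenotyping noise | 2% SLE with 710.1; 0.4% lupus-like non-SLE meeting the full algorithm; 2% non-SLE with 1–3 710.0 dates | gives realistic PPV/sensitivity ≈93% rather than a vacuously perfect algorithm |
| sparse_visit_frac | 0.02 | subjects failing the medical-home rule |

Disease indicators are drawn per phecode from
`logit P = α + β_sle·SLE + β_race·AA + β_age·(age−50) + β_sex·female`;
diseased subjects emit distinct-date coded events (distinctness enforced
by resampling collisions), non-diseased subjects a single rule-out date
with small probability. All sampling flows from one seeded generator, so
a config reproduces its CSVs byte-for-byte.

Named scenarios: `default_scenario` (planted effects), `null_scenario`
(all β_sle = 0; FDR calibration), `confounded_scenario` (β_sle = 0,
race OR 4 on an 8% baseline, strongly race-dependent SLE prevalence —
sized so the crude SLE–phenotype association is reliably detectable at
n=5,000 while race-adjusted and matched-conditional estimates are
null), and `age_confounded_scenario` (effect flows only through age).

**Reduced-form sampler.** `simulate_statuses` draws per-phecode
case/control/excluded statuses directly from the same probabilistic
model (same disease logistic, same 1+Poisson date-count rule, same
rule-out exclusions) without materializing event tables; replicate-heavy
experiments use it so Monte-Carlo runs of 100–1,000 replicates complete
in minutes on one CPU. It does not model cross-phecode exclusion-range
interactions or the phecode hierarchy; a rule-concordance test verifies
on small populations that the event-level path and the scan's rules
agree, and the event-level path is what the acceptance script runs.

**What the generator does not emulate** — and hence what passing tests
do not establish about real EHRs: realistic ICD co-occurrence and
coding-practice drift, informative observation (visit intensity
correlated with disease), care fragmentation across systems,
socioeconomic structure, and chart-review ground truth. Tests establish
that the *pipeline* is correct and calibrated under its assumed model,
not that the model is true of any particular health system.

## Verification strategy

* **Oracles** — BH against an explicit min-over-suffix evaluation; the
  conditional likelihood against per-stratum enumeration; the logistic
  fit against the closed-form 2×2 cross-product OR (≥6 significant
  digits) and statsmodels on random designs; the conditional fit
  against statsmodels' ConditionalLogit and the exact discordant-pair
  ratio n10/n01 on 1:1 binary pairs.
* **Calibration** — planted-OR Wald CIs cover at their nominal rate
  across 200 seeded replicates of the default scenario; the all-null
  scenario's familywise any-hit rate stays at the FDR level across
  1,000 replicates at n=5,000.
* **Confounding** — the race-confounded scenario shows a crude
  association that race adjustment and matched conditional analysis
  both remove, the motivating phenomenon for matched/adjusted designs.
* **Determinism** — every pipeline stage rerun with the same seed
  produces byte-identical CSVs and marker manifests (floats serialized
  at 17 significant digits; readers use round-trip parsing).

## Known limitations

* Wald intervals only; no score/likelihood-ratio or exact conditional
  inference, and no Firth correction for separation (flagged instead).
* One case per stratum is assumed by the conditional likelihood (true
  by construction here).
* ICD-10 appears only in control-pool exclusions; no ICD-10 → phecode
  mapping.
* The Manhattan plot's y-axis uses unadjusted p with an FDR-derived
  threshold line (the largest unadjusted p whose BH-adjusted p passes),
  the convention of standard PheWAS tooling; the threshold is omitted,
  with a log note, when nothing passes.
* Parent-phecode results are not independent of their descendants'
  (descendant case counting); interpret hierarchy-adjacent hits jointly.
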