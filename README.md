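# oralsim

A multistate, multifactorial natural-history model of oral squamous cell
carcinoma and a Markov microsimulation of risk-stratified screening
programs, for epidemiologists and screening-policy modellers.

Oral cancer develops through a progressive continuum

```
normal mucosa → leukoplakia → erythroleukoplakia → oral cancer
```

with per-year transition intensities in proportional-hazards form

```
λ_k(x) = λ_k0 · exp(β_kᵀ x),   k ∈ {12, 23, 34}
```

where `x` is an individual's risk-factor profile (betel-quid and cigarette
dose categories, HPV status, 19 risk genotypes, 8 miRNA aberration
indicators) and `λ_k0` are the literature-derived baseline rates of the
reference group (0.0014, 0.01917 and 0.1428 per year). All coefficients are
natural logs of published rate/odds ratios, shipped as auditable delimited
text under `src/oralsim/data/`. A composite risk score combines the three
linear predictors with weights proportional to `−ln λ_k0`
(w = 0.527, 0.317, 0.156), and the cohort is stratified into deciles of that
score.

On top of the natural history, the package simulates screening programs —
inter-screening interval, attendance (0.60), treatment compliance upon
detection (0.80), cure probability of treated pre-malignant lesions (0.50) —
optionally combined with a betel-quid/smoking cessation education arm, and
reports the percentage reduction in cumulative oral-cancer incidence versus
a no-intervention arm simulated with common random numbers.

## Worked example

```python
import oralsim as o
from oralsim.nathist import SimConfig
from oralsim.screening import ScreeningConfig

cohort = o.generate_cohort(100_000, seed=7)           # synthetic high-risk cohort
coeffs = o.CoefficientSet.printed()                   # published equation coefficients
scores = o.linear_predictors(cohort.profiles, coeffs)
composite = o.composite_scores(scores)
deciles = o.assign_deciles(composite)

nat = o.simulate_lifetime_risk(cohort.profiles, coeffs,
                               config=SimConfig(horizon_years=60.0, seed=8),
                               deciles=deciles)
lam34 = o.transition_intensities(cohort.profiles, coeffs)["lambda34"].to_numpy()
print(o.decile_summary(composite, lam34, nat.cancer, deciles).round(3))

annual = o.run_program(cohort.profiles, ScreeningConfig(interval_years=1.0),
                       SimConfig(horizon_years=40.0, seed=9),
                       coeffs=coeffs, deciles=deciles)
print(f"overall reduction, annual: {annual.reduction_pct:.1f}%")
```

prints (abridged)

```
 decile      mean_risk_score  lifetime_risk_per_1e5  relative_risk  mst_years
      1                5.459                 5260.0          0.162      0.840
      5                6.781                32430.0          1.000      0.090
     10                8.415                90400.0          2.788      0.006
overall reduction, annual: 64.8%
```

Reading the output: the composite score spans ~5.5 → 8.4 across deciles; the
60-year cumulative incidence ("lifetime risk") rises 17-fold from the lowest
to the highest decile (5,260 → 90,400 per 100,000); the mean sojourn time in
erythroleukoplakia falls from ~0.8 years to days; and annual screening at
the default operating parameters cuts 40-year cumulative incidence by about
65% overall. Relative risks are expressed against decile 5, the
average-risk group.

The same pipeline is available from the shell:

```
oralsim generate --n 100000 --seed 7 --out cohort.csv
oralsim score    --cohort cohort.csv --out-scores scores.csv --out-distribution dist.tsv
oralsim simulate --cohort cohort.csv --horizon 60 --seed 8 --out decile_summary.tsv
oralsim screen   --cohort cohort.csv --interval 1 --interval 10 --horizon 40 --seed 9 --out reductions.tsv
```

Every output table starts with `#`-prefixed provenance headers (package
version, seeds, config hash); rerunning a command with the same
configuration reproduces its output byte for byte.

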