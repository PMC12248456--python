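# Methods

## Model

The natural history of oral squamous cell carcinoma is represented as a
progressive four-state continuous-time Markov chain — normal mucosa (1),
leukoplakia (2), erythroleukoplakia (3), oral cancer (4) — with no
regression outside treatment, no state skipping, no competing mortality and
no age structure: individuals enter in state 1 and are followed for a fixed
horizon. Sojourn times are exponential, so the time to cancer is the sum of
three independent exponentials (hypoexponential).

Each transition intensity has proportional-hazards form
`λ_k(x) = λ_k0 · exp(β_kᵀ x)`. The baseline rates, per year, are those of
the reference group (occasional betel use, no other risk factors):

| transition | λ_k0 | implied baseline sojourn |
|---|---|---|
| normal → leukoplakia | 0.0014 | ~714 y |
| leukoplakia → erythroleukoplakia | 0.01917 | ~52 y |
| erythroleukoplakia → cancer | 0.1428 | ~7 y |

Coefficients are natural logarithms of published rate/odds ratios. Odds
ratios are exponentiated into hazards as if they were rate ratios, with no
rare-disease correction — the scale on which the transition equations were
originally written. Two coefficient modes are provided: `printed_equation`
(the equation literals, the default) and `derived_from_evidence`
(ln of the published effect sizes). The two differ on a handful of terms;
`evidence.consistency_report` lists them (at the default absolute tolerance
of 5×10⁻³: the λ23 smoking terms and the ACE, MALAT1, RYR2 and miR-431
terms of λ34). Neither variant is silently "corrected": the default
reproduces the equations as printed, the alternative the effect-size tables.
The miRNA markers appearing in both λ12 and λ34 (miR-3614, miR-10b,
miR-215, miR-182) are one flag per individual entering both equations.

## Composite risk score and deciles

Only the weighting principle — weights from the logarithms of the baseline
rates — is fixed by the source analysis; the exact formula is not. The
package uses

```
score(x) = Σ_k w_k·s_k(x) + offset,   w_k = −ln λ_k0 / Σ_j −ln λ_j0,
offset   = −Σ_k w_k·ln λ_k0  (≈ 5.02 at the default baselines)
```

so that the reference profile anchors near the low end of the published
decile mean-score scale (a cohort at default prevalences averages ≈ 6.9,
matching the published decile-5 mean). Weights and offset are
config-exposed. Deciles are empirical quantiles with stable-order
tie-breaking: group sizes differ by at most one even with tied scores.

## Synthetic cohort generator

The generator emulates a high-risk screening population: betel (0.240,
0.302, 0.330, 0.128) and smoking (0.769, 0.141, 0.062, 0.029, renormalised
from rounded percentages) category probabilities and HPV positivity (0.17)
are the published decile-table row averages; the 19 genotype prevalences are
the published control-group frequencies (e.g. NOTCH1 0.034, TIMP-2 0.054,
P53 0.310). miRNA aberration prevalences are not published anywhere in the
source tables (which report expression means, not categorical frequencies);
the dichotomised flags default to 0.25, config-exposed.

All factors are sampled independently. Real exposures are correlated
(betel and smoking co-occur; genotypes show linkage structure), and real
cohorts have age structure; none of that is modelled. Consequently the
decile gradients in exposure (heavy betel/smoking and HPV enriched in upper
deciles) are *emergent* from the composite score, and passing tests show
that the scoring and simulation machinery orders risk correctly — not that
the generator reproduces the joint distribution of any real population.

## Simulation engines and numerics

The primary engine samples exact event times (inverse-CDF exponentials);
with the printed λ34 coefficients some individuals have sojourn times of
days, which a one-year cycle model cannot represent. The retained
`annual_cycle` cross-check engine uses per-cycle transition probabilities
`1 − exp(−λ)` with a half-cycle correction and agrees with the event-time
engine within 1% absolute cumulative incidence when all rates are ≤ 0.2/yr.

The closed-form cumulative incidence is evaluated as the state-4 entry of
the matrix exponential of the generator, which is stable for equal or
near-equal rates (the partial-fraction hypoexponential CDF is not). Tests
check it against an independent Kolmogorov-forward ODE integration and
against Monte-Carlo estimates (3 standard errors on five rate triples,
including equal and near-equal rates). Zero intensities are treated as
"never" in vectorised sampling; the scalar sampler rejects them. A zero
exit intensity makes the mean sojourn time infinite and is flagged with a
warning rather than an exception.

Horizons are config-exposed and default to 60 years for "lifetime" risk and
40 years for screening comparisons; the source analysis states no horizon
or entry age, so published lifetime risks are treated as soft calibration
references, not targets. Acceptance-scale runs use cohorts of 200,000
(screening targets) and 1,000,000 (decile-monotonicity and marginal
properties); all randomness flows through explicit integer seeds and
`numpy.random.default_rng`.

## Screening overlay

Screens occur at `offset + k·interval` (offset 0, so the round at entry is
included — it matters only for the education arm, since everyone starts in
state 1). Defaults: attendance 0.60 drawn independently per round;
sensitivity 1.0 for both pre-malignant states; on detection, treatment with
probability 0.80 (compliance) cures with probability 0.50 (efficacy); a
cured individual returns to state 1 and progression is re-sampled at their
current intensities, so relapse is possible; unlimited re-treatment.
Screen-detected cancer still counts as incident. The education arm applies
cessation (probability 1.0, config-exposed) at the first attended screen:
betel and smoking categories drop to the reference level, λ12/λ23 are
recomputed, and — by memorylessness — the residual sojourn in the current
state is re-drawn at the new rate.

The control arm shares the natural-history random numbers with the screened
arm (common random numbers); screening-specific draws use a separate
stream, so attendance 0 reproduces the control arm exactly and reduction
estimates are stable at moderate cohort sizes. The delta-method standard
error of the percentage reduction treats the arms as independent and is
therefore conservative.

Two structural choices are genuinely open and config-exposed rather than
hidden: `attendance_model="persistent"` replaces the per-round draw with a
fixed attender subset, and `max_treatment_courses` caps how often one
individual can be treated. Both alternatives lower projected effectiveness
of frequent screening (fewer distinct attendees, or fewer second chances);
neither changes any monotonicity property.

## Known limitations

* With the printed λ34 coefficients and the published control-group
  prevalences, the mean λ34 linear predictor is ≈ 2.9, so simulated
  erythroleukoplakia sojourns are days to months for most of the cohort.
  The published per-decile summaries imply a far slower scale (average-risk
  MST 4.5 years, lowest decile 45.5 years — below even the baseline exit
  rate for an entire decile). These two published parameterisations are
  mutually inconsistent; this package follows the printed equations and the
  reference-group baseline identity, and reports the resulting decile
  summaries as computed. Simulated lifetime risks therefore sit well above
  the published decile table while reproducing its orderings.
* For the same reason, projected screening effectiveness differs from the
  published program estimates: lesion windows shorter than the screening
  interval make long-interval programs much weaker, and repeated annual
  detection of long-lived leukoplakia makes annual programs much stronger,
  than the published 46%/40% (annual/decennial, average-risk) figures.
  `scripts/acceptance.py` recomputes the package's own projections under
  the documented defaults; sweeping the horizon across 30–60 years and
  cessation across 0.5–1.0 does not bridge the gap under any of the
  config-exposed attendance/treatment variants.
* No competing mortality, ageing, cancer staging, post-diagnosis survival,
  cost-effectiveness, self-selection adjustment or gene–environment
  correlation; effect sizes come from single studies, not pooled estimates.
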