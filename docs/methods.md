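# Methods

## Model

The diagnostic model is a two-class naive Bayes classifier over
categorical clinical-history predictors. Each predictor j has 2–3
levels and a conditional probability table (CPT) P(level | class) for
class ∈ {cardiac, noncardiac}; each patient population s has a prior
π_s = P(cardiac). The posterior for a patient is the normalized product
of the prior and the class-conditional probabilities of the observed
predictor values. Predictors are assumed conditionally independent
given the diagnosis; dependence between predictors (e.g. between
prodrome and its component symptoms nausea/diaphoresis/blurred vision)
is deliberately not modelled.

**Missing data.** A missing predictor value is marginalized by omission
from the product. Under conditional independence this is exact
marginalization, and it is applied identically whether a centre never
collected the variable or an individual patient lacks it. Missingness
is therefore implicitly assumed non-informative (MCAR given class).

**Numerics.** Products are accumulated in log space
(posterior = expit(logit(π) + Σ log P(x|cardiac) − Σ log P(x|noncardiac))),
which agrees with the direct product to well below 1e-12 at the model's
scale (≤ 10 factors) and cannot underflow. CPT cells are raw pooled
frequencies with no smoothing, so zero cells occur (e.g. a centre-fitted
table in which no cardiac patient fainted during effort) and propagate
as genuine zeros: a zero cardiac likelihood yields posterior 0, a zero
non-cardiac likelihood yields 1, and a record whose likelihood is zero
under *both* classes raises an error instead of guessing. A posterior
exactly at the decision cutoff is classified cardiac (the cutoff, 0.02,
exists to favour sensitivity, and the boundary convention follows it).

## Derivation from pooled literature counts

CPTs are estimated by summing the per-study predictor-by-diagnosis
frequencies of seven derivation studies and dividing by the pooled class
totals. A study that did not report a predictor (or reported it for one
class only) contributes zero to the missing cells. Association is
assessed with the Pearson χ² test on the pooled 2×K table **without**
continuity correction — the published pooled statistics are reproduced
only without Yates' correction — and, for binary predictors, a
diagnostic likelihood ratio P(level|cardiac)/P(level|noncardiac)
computed from the exact pooled counts (rounding percentages first gives
visibly different ratios) and reported at the cardiac-pointing level:
presence of supine syncope, effort syncope, male sex, ≤2 spells;
absence of nausea, diaphoresis, prodrome, blurred vision.

**Selection rule.** A candidate enters the model if the source
literature reports a significant association in ≥3 studies *and* the
pooled association has p < 0.05. The per-study significance sets are
fixture metadata, not recomputed: several source studies reported
multivariable significance without publishing a cross-tabulation. The
bundled metadata file is labelled synthetic (reconstructed) for this
reason. On the bundled fixtures the rule retains exactly ten predictors
and excludes palpitations (pooled p = 0.064). Bystander-observed signs
are excluded upstream by never entering the candidate list.

**Age bins.** Age is categorical with bins <40, [40, 60), ≥60 years; a
value of exactly 60 falls in the upper bin (configurable through the
bin edges). Where a source study reported only mean ± SD,
`counts_from_mean_sd` allocates its n patients to bins by the normal
CDF, rounds each bin to the nearest integer and reconciles the rounding
residual into the largest bin so the total is always n; with SD 0 the
whole mass falls in the bin containing the mean. The rounding rule is
our choice; the source of the published reconstruction does not state
one.

### Inconsistencies in the published pooled table

The published pooled table contains internal inconsistencies. The
bundled fixtures resolve each in favour of the arithmetic that
reproduces the published summary statistics, and the package never
silently "corrects" a statistic:

* **Age** — the per-study cells sum to (2, 65, 227 | 323, 427, 363) but
  the printed totals are (3, 65, 226 | 234, 427, 363); only the printed
  totals give the published χ² = 171.7 (df 2). The fixture carries the
  printed totals as a single pooled entry (`table_totals`). The
  non-cardiac <40 total (234 vs cell-sum 323) looks like a digit
  transposition.
* **Diaphoresis** — the per-study yes/no rows are swapped relative to
  the printed totals; the totals (86/382 cardiac, 753/1015 non-cardiac)
  are self-consistent and reproduce χ² = 92.6 and LR = 1.42, so the
  fixture carries them.
* **Palpitations** — one study's non-cardiac "no" cell (printed 372) is
  inconsistent with both the study's class size and the printed total
  1568; the fixture carries the reconciled 672, which reproduces
  χ² = 3.4, p = 0.06. The published LR 1.03 corresponds to the
  *absence* level.
* **Structural heart disease** — the published χ² (283.7) and LR (3.00)
  are **not reproducible** from the published counts, which are
  internally consistent and give χ² ≈ 144.7 and LR ≈ 3.35. The fixtures
  carry the counts; the association report shows the recomputed values.
  No test asserts the published pair.

## Evaluation

The c-statistic is computed from midranks (U/(n₁n₀) with
U = R₁ − n₁(n₁+1)/2), which counts tied cross-class pairs one half and
equals both exhaustive pair counting and the trapezoidal area under the
empirical ROC. ROC thresholds are the unique observed scores plus a
sentinel above the maximum, so the curve always spans (0,0)–(1,1). The
rank-sum test is the two-sided Mann–Whitney U with normal approximation
and tie correction (no continuity correction); its statistic satisfies
U = c·n₁·n₀ exactly.

## Standardized resampling

To mitigate accrual bias, a cohort is redrawn with replacement within
age-category × spells-category strata so each replicate matches a
target distribution; 1000 replicates of the source-cohort size is the
default. Integer stratum sizes come from the largest-remainder method
(counts always sum exactly to the replicate size), and every replicate
matches them exactly. All replicates of a run flow from a single seed.
The *joint* literature distribution of age × spells is not published;
the default plan uses the product of the pooled both-class marginals
(age ≈ 18%/37%/45%, spells ≤2 ≈ 48%) — this gap is real, and any other
target can be supplied as a JSON/YAML plan file. A plan targeting a
stratum that is empty in the source cohort fails loudly rather than
renormalizing.

## Synthetic cohorts

The generator draws each patient's class from the centre prior, then
each collected predictor independently from its class-conditional
distribution — i.e. exactly the model's data-generating assumptions.
Centre parameterizations come from the published per-centre
class-conditional counts of four test cohorts (Calgary n=663, prior
0.208; Amsterdam n=463, 0.095; Milan n=689, 0.054; Rochester n=3877,
0.109). Reporting shortfalls relative to the class sizes become
class-independent per-predictor missing rates (class-dependent
missingness would leak the label through the missing-value pattern,
which the model never uses). Predictors a centre did not survey are
entirely missing: supine/effort for Calgary, blurred vision and supine
for Amsterdam, the autonomic prodrome components for Milan. Rochester's
blurred-vision variable was mined from free text rather than asked and
is excluded by default (`include_rochester_blurred_vision=True`
restores it). Milan's number of spells was recorded as "one spell" vs
"more than one" and is used, as published, as a proxy for the ≤2/>2
coding; the `PopulationSpec.notes` field records this. The published Milan
spells "Total" column is internally swapped relative to the class
cells; the fixtures carry the self-consistent class cells.

`exact_cohort` builds a deterministic cohort whose per-predictor,
per-class level counts equal the published cells exactly (columns are
filled independently, so the joint distribution across predictors is
arbitrary — sufficient for frequency checks, not for joint ones).

**What passing synthetic tests shows.** Because the generator satisfies
conditional independence by construction, discrimination measured on
synthetic cohorts is an upper bound on real-data performance, and
parameter recovery only validates the estimation machinery. The
published real-data c-statistics (0.87/0.84/0.72/0.71 and the
resampled 0.80/0.78/0.73/0.69) depend on patient-level datasets that
were never deposited and are therefore not reproduction targets here.

## Problem sizes in the test suite

The suite exercises parameter recovery at 100 000 synthetic patients,
the posterior-vs-enumeration oracle on all 3·2⁹ complete predictor
states for each of the four populations, exhaustive pair-counting
oracles at ≤500 patients, 1000 resampling replicates of size 1000, and
end-to-end class-separation checks at 5000–10 000 patients per centre —
sizes at which binomial/Monte-Carlo error is far below the asserted
tolerances while the whole suite stays fast.

## Known limitations

* Conditional independence is assumed and is known to be violated in
  real syncope cohorts; no interaction terms are modelled.
* CPTs are unsmoothed frequencies; a zero cell makes the corresponding
  level decisive evidence, which is faithful to the construction but
  fragile for small derivation samples.
* The selection rule depends on reconstructed per-study significance
  metadata (see above).
* The default standardization target is a product of marginals, not the
  (unpublished) joint distribution.
* Priors are treated as known constants per population; no uncertainty
  in priors or CPT cells is propagated to the posterior.
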