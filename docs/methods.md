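# Methods

This package implements a genetics-first pipeline for identifying and
characterizing gain-of-function (GoF) variants in the calcium-sensing
receptor gene *CASR* — the cause of autosomal-dominant hypocalcemia type 1
(ADH1) — in population biobanks, together with a synthetic biobank
generator that makes every stage testable end to end without access to
controlled genotype data.

## The ADH1 score

For each rare protein-altering variant (MAF < 0.01 in the stratum,
missense/nonsense/frameshift) and each ancestry stratum, the score is a
weighted sum of direction-constrained sub-scores:

| component | weight | fires when |
|---|---|---|
| serum calcium | 3 | carrier OLS beta < 0 and p ≤ α |
| serum phosphate | 1 | carrier OLS beta > 0 and p ≤ α |
| each of 5 dx categories | 1 | ≥1 carrier with a category phecode and Fisher p ≤ α |
| ADH1 medication | 1 | ≥1 carrier on a relevant medication and Fisher p ≤ α |
| GoF hotspot | 0.5 | protein residue in 116–136 or 819–837 |
| in-silico ensemble | 0.2 | majority of predictors call deleterious |

with nominal α = 0.05.  Calcium dominates because hypocalcemia is the
defining phenotype; phosphate gets less weight because only about half of
strongly affected carriers are hyperphosphatemic.  Quantitative
associations adjust for age, sex, and 10 genetic principal components; the
two-sided Fisher p uses the sum-of-probabilities-≤-observed convention
(pinned by an enumeration oracle in the tests).  Binary phenotypes always
feed Fisher p-values into the score; a Firth-penalized logistic regression
(Jeffreys-prior penalty, profile penalized LRT) is additionally reported
when there are ≥10 events per model variable, since with 1–4 carriers
ordinary logistic regression diverges under the separation that is the
norm here.  The variant-level score is the maximum across strata, and
per-stratum results can be pooled by inverse-variance fixed-effect
meta-analysis (weighted-Z fallback when odds ratios are infinite).

### Binary versus graded sub-scores

Two grading modes exist.  **Binary** (the reporting default) is the
auditable weight-times-indicator rule above.  **Graded** replaces the
indicator with a continuous factor that ramps on the log-p scale from 0 at
p = 5α to full credit at p = α (direction gating unchanged) and grades the
in-silico component by the ensemble fraction itself.

The graded mode exists for threshold calibration.  The binary score's null
distribution is purely atomic — under the null the calcium component alone
puts ~2.3% mass at exactly 3.0 — so an empirical 98th-percentile threshold
necessarily lands on an atom, and held-out specificity is forced to
whichever side of 0.98 the atom boundary falls (≈0.975 or ≈0.996,
depending on the realization).  The graded score's null is continuous near
its upper quantiles, so the percentile threshold attains its nominal
specificity as the synonymous set grows.  The ramp window matters: a ramp
anchored at p = 1 hands substantial partial credit to chance-level
associations (a p = 0.36 enrichment would earn a third of its weight),
inflating the null and destroying sensitivity; anchoring at 5α keeps the
continuity without rewarding noise.  The calibration stage, the analysis
drivers, and the operating-characteristic studies therefore use graded
scores, while variant reports remain binary.

## Empirical-null threshold calibration

Synonymous variants cannot alter CaSR function, so their sub-scores
reflect chance.  The null is built by resampling sub-scores of synonymous
variants: B = 10,000 draws, each the sum of one value per component
sampled independently with replacement from that component's empirical
distribution across the synonymous set (a joint mode resampling whole
vectors, preserving inter-component correlation, is available behind
config; independent is the default and measured slightly better
sensitivity at equal specificity).  The threshold is the lower empirical
order statistic at the 98th percentile — no interpolation, so the
at-or-below mass among draws is exactly ⌈0.98·B⌉/B regardless of the
numeric stack.  A fixed-threshold mode returns the published operating
point (1.5 score units, appropriate to binary grading) and records its
provenance in the run manifest.

Classifier performance uses strict `score > threshold` as the positive
call; sensitivity/specificity are undefined (not zero) when the relevant
class is absent.

## Synthetic biobank generator

The generator emulates the architecture that matters for this analysis and
nothing more (no LD, imputation, read-level simulation, or pedigrees):

* **Individuals** per stratum: age ~ U(40, 70), sex (54% female), 10 PCs ~
  N(0,1), cystatin C ~ logN(log 0.9, 0.15); baseline serum calcium ~
  N(2.385, 0.09) mM and phosphate ~ N(1.16, 0.16) mM plus small age/sex/PC
  effects, which puts ~2% of non-carriers below the 2.2 mM calcium LLN —
  the background rate in unselected biobank participants.
* **Lab coverage**: calcium/phosphate are missing at random for 7%/15% of
  individuals, emulating biobank biochemistry coverage.  This matters: a
  single-carrier variant is unscoreable for a lab when its one carrier
  lacks the measurement.
* **Variants**: each class specifies carrier-count range and distribution
  (default ∝ 1/k, the neutral site-frequency spectrum), calcium shift,
  diagnosis penetrance, hotspot fraction, and in-silico ensemble behavior
  (a Beta mixture leaning deleterious or benign).  Carriers are
  heterozygous, drawn without replacement, so realized MAF is exactly
  carriers/(2n).  The established-GoF class defaults to the 13 reported
  per-variant (calcium shift, carrier count) pairs for known ADH1 variants
  (−0.65 to +0.12 mM, 1–4 carriers), deliberately including the
  weak-effect members — sensitivity estimates are only honest when the
  positive class reflects them.  Phosphate shifts are coupled opposite in
  sign and proportional to the calcium shift (scaled so a −0.30 mM calcium
  shift gives a +0.30 mM phosphate shift, putting ~half of strongly
  affected carriers above the 1.45 mM ULN).  Synonymous and neutral
  classes have effects that are exactly zero by construction.
* **Diagnoses** are conditioned on the realized lab, not the genotype:
  anyone whose biological calcium is below the LLN receives an
  ADH1-suggestive ICD-10 code with probability 0.5 (plus a symptom code —
  tetany/paresthesia/epilepsy — with probability 0.4), on top of small
  per-category background code rates (0.1–1.6%) and unrelated background
  codes.  Diagnosed individuals receive free-text ADH1 medication strings
  with probability 0.6 (0.5% background).  This reproduces the
  underdiagnosis gap: code-based penetrance lags lab-based penetrance.
* One lab measurement per individual by default (repeat measurements with
  within-person SD 0.05 mM — an assumption, as real within-person repeat
  variability is not well characterized — are available to exercise
  averaging policies).

What passing tests on this generator do **not** show: robustness to
non-Gaussian lab distributions, albumin confounding, EHR coding drift,
population structure beyond linear PC effects, or relatedness (handled
upstream by exclusion).  Conclusions about real cohorts inherit those
caveats.

## Burden and allelic series

Count-based quantities (carrier frequency per 100,000, lab/diagnosis
penetrance, excess burden) are computed in exact rational arithmetic
before float conversion.  Lab penetrance uses strict comparisons against
LLN 2.2 mM / ULN 1.45 mM.  Diagnosis penetrance counts only carriers with
full record coverage as evaluable, over the two directly ADH1-suggestive
phecode categories.  Excess burden is max(0, observed − carriers ×
baseline), with the baseline phenotype rate taken among non-carriers of
any scored variant; negative excess is surfaced only in a diagnostics
field.  The allelic-series summary reports per-class variant counts,
median calcium beta, and MAF range — the boxplot-ready table for effect
size versus allele frequency.

## Numerical and design choices

* ICD-10 codes are normalized (uppercase, dots stripped) and mapped to
  phecodes by longest-prefix match (4 then 3 characters), so truncated
  codes resolve deterministically.  The epilepsy phecodes are collapsed
  into one category.  The bundled phecode map is a small synthetic subset
  covering the ADH1-relevant and common background codes.
* Medication matching is case-insensitive substring matching; "PTH"
  matches only as a whole word.
* The Haldane–Anscombe 0.5 correction applies to displayed odds ratios
  only, never to p-values.
* Relatedness exclusion is greedy maximum-degree removal on the
  above-cutoff kinship graph (KING cutoff 0.0884), ties broken by
  lexicographic id — deterministic, and star-family hubs go first.
* eGFR uses the 2012 CKD-EPI cystatin C equation.
* Pipeline outputs are a pure function of (inputs, config, seed); the run
  manifest records a config hash and per-file SHA-256 checksums.

## Problem sizes

The operating-characteristic studies simulate 50,000-person strata: the
specificity study uses 1,000 synonymous variants to build the null and 500
held out; the sensitivity study pools 50 replicates (650 positives) in the
acceptance script and 12 replicates (156 positives) in the test suite.
Unit tests run on 2,000–20,000-person cohorts.  These sizes were chosen so
Monte-Carlo error is small relative to the quantities checked (binomial SE
≈ 0.006 for specificity at n = 500, ≈ 0.017 for sensitivity at n = 650).

## Known limitations

* The in-silico pathogenicity ensemble is abstracted to a numeric input
  (fraction of predictors calling deleterious); no live predictor service
  is queried.
* Set-based tests (SKAT-O), fine-mapping, and colocalization are out of
  scope, as are albumin correction and SNOMED mapping machinery.
* The per-category composition of the diagnosis sub-scores (five phecode
  categories plus one medication component) is an interpretation of the
  ADH1-associated phenotype list; the config exposes the categories.
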