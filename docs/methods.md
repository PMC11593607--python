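# Methods

## Scope and data model

The pipeline consumes an already-curated occurrence table: one row per
study-level measurement of one contaminant in one food, with the reported
central statistic (mean or median), the sample size behind it, the reporting
unit, the wet/dry basis and the censoring status. Literature mining,
country/year stratification and nutrient profiling beyond per-item energy
bookkeeping are out of scope. Controlled vocabularies cover 16 foods
(4 animal-based, 12 plant-based including beans) and 73 analytes in five
classes; name resolution is case-insensitive and alias-aware by default
(`strict=True` disables both), because mined tables drift in nomenclature.

## Harmonisation

Records are excluded when they cannot inform dietary estimation: artificially
spiked samples, samples intended for animal feed, animal-model studies,
records reporting only a minimum or maximum, and dry-basis records for
non-cereal foods. Dry-basis records for wheat, maize and rice are retained
as-is, with no moisture correction — the cereal occurrence literature
largely reports dry weight and a correction factor would be speculative.
Units are standardised to µg of contaminant per kg of food by exact scalar
factors (mg/kg ×1000, ng/g ×1, ng/kg ×0.001, µg/g ×1000, µg/100g ×10).
Left-censored values are substituted by LOD/√2 or LOQ/√2, the conventional
mid-bound substitution for low-to-moderate censoring; no parametric
censored-likelihood fitting is attempted. Cooking-state variants of a food
are pooled under one food key (the record model retains the state for
stratified reanalysis).

## Weighted estimation

Weights are record-level sample sizes (absent *n* ⇒ weight 1); records from
the same study are not merged, but a study's median records are ignored for
a food×contaminant pair whenever that same study also reports a mean for it
(medians are a fallback central statistic, not an extra datum).

The weighted percentile needs a convention, and the natural reading of
"weight = sample size" fixes it: a record with *n* = 8 should behave exactly
like eight unit records. The default (`convention="expansion"`) therefore
defines Q(q) as the Hazen (midpoint) percentile of the weight-expanded
multiset, computed in closed form: on the cumulative-weight line of total
mass W, record *i* occupies (S₍ᵢ₋₁₎, Sᵢ] and contributes knots at
S₍ᵢ₋₁₎+½ and Sᵢ−½ (a plateau; a single midpoint knot if wᵢ < 1); Q(q)
linearly interpolates this knot sequence at qW, clamping in the tails. For
integer weights this equals `numpy.quantile(repeat(v, w), q, method="hazen")`
identically, which the test suite verifies on thousands of random instances
against exactly that brute-force oracle. The price of expansion semantics is
that uniform weight rescaling changes the answer (doubling every sample size
legitimately sharpens the tails); users who want rescaling invariance can
select `convention="midpoint"` (interpolation through cumulative-weight
midpoints (c₍ᵢ₋₁₎+cᵢ)/2 — the textbook weighted Hazen, which is invariant
but does not reproduce the expansion) or `convention="inverted_cdf"` (the
step-function weighted quantile, delegated to numpy). The three coincide for
a single record and agree with their unweighted analogues for equal unit
weights.

Congener families are reported as single cumulative estimates — enniatins
(A, B, A1, B1), ergot alkaloids (the nine classical epimer pairs) and
alternaria toxins (alternariol + its methyl ether) — by summing the mean and
each percentile member-wise, absent members contributing zero. Summing
percentiles assumes comonotonic members; it is the conservative choice
consistent with the scenario construction below, and is exact for the mean.
Foods without direct data borrow a proxy's full estimate set (bread ← maize,
pasta ← wheat) with provenance recorded; direct estimates are never
overwritten.

## Diet models

The two built-in models follow the EAT-Lancet reference diet with
representative foods per food group; both total 1580 g/day. Group masses are
validated against the reference ranges with *inclusive* bounds, because the
models intentionally sit on bounds (600 g whole grains). Two bookkeeping
caveats are inherent to the published tables and surface in
`validate_ranges`/`total_energy`:

* the vegetarian model's "other protein sources" group (beans 200 g +
  peanuts 80 g = 280 g) exceeds the 25–250 g reference range, and is
  reported as `above`;
* per-item energies sum to 2339 kcal (omnivorous) and 2305 kcal
  (vegetarian) versus published totals of 2338 and 2304 — subtotal-rounding
  artefacts; checks against the published totals should allow ±1 kcal.

## Exposure scenarios

A percentile scenario takes the chosen percentile of *every* food ×
contaminant simultaneously and sums over the diet:
B꜀ = Σ_f Q_{f,c}(q)·m_f/1000 µg/day. This comonotonic stacking is a
deliberate conservative co-exposure assumption — real foods' contamination
levels are not perfectly rank-correlated — so p75 scenarios are worst-case
screens, not central estimates. Class totals partition the global burden
exactly by construction, and the global burden is normalised by total diet
mass (kg/day) for cross-diet comparison. Indicator sums follow the
regulatory definitions: PAH4 (benzo[a]pyrene, benz[a]anthracene, chrysene,
benzo[b]fluoranthene), PAH8 (PAH4 + benzo[k]fluoranthene,
dibenz[a,h]anthracene, benzo[g,h,i]perylene, indeno[1,2,3-cd]pyrene) and
β-carbolines (harman + norharman). Report tables round for display (1
decimal ≥100 µg, 2 decimals 1–100, 3 below 1) while full-precision values
are always written alongside.

## Guidance-value screening

The packaged registry carries EFSA values per kg body weight: TWIs for
cadmium (2.5 µg/kg bw/week) and mercury (4), BMDLs for arsenic (BMDL05
0.06 µg/kg bw/day) and lead (BMDL01 0.5 and 1.5; BMDL10 0.63), nine
pesticide ADIs, five mycotoxin TDIs, and ochratoxin A BMDL10 values (4.73
non-neoplastic, 14.5 neoplastic) with MOE thresholds 200 and 10 000.
Conversions are exact: daily amount = value × bw, ÷7 for weekly values
(note 4 µg/kg bw/week at 70 kg is 40 µg/day). Intake-type entries and
BMDLs without an MOE threshold are compared directly (exposure equal to
the reference is `within`; exceedance is strict); BMDLs with a threshold
use MOE = BMDL/(exposure/bw), with MOE equal to the threshold counting as
low concern and zero exposure reported as not computable. Entries are
keyed by (contaminant, guidance type, endpoint) so that e.g. two lead
BMDL01 endpoints coexist; same-key duplicates are rejected. Arsenic is
screened at an MOE threshold of 1, i.e. concern whenever exposure exceeds
BMDL×bw. The registry also encodes the ochratoxin A per-person bound
14.5 × 70 = 1015 µg/day as informational context, not a tolerable intake.
Screening is contaminant-by-contaminant; no mixture indices (hazard index,
combined MOE) are computed.

## Synthetic data generator

The generator emulates the statistical structure the estimator assumes:
study-level mean concentrations per food × contaminant drawn from a
lognormal (occurrence data are non-negative and right-skewed; defaults
GM = 10 µg/kg, GSD = 2), sample sizes uniform on 5–50, 3–8 studies per pair,
a unit mix dominated by µg/kg and mg/kg, and 30% of cereal records flagged
dry-basis. Censoring is imposed by thresholding at quantiles of the
generating distribution — LOQ at the target censored fraction (default 0.2),
LOD at half of it — so the expected censored fraction is controlled exactly
and split between <LOD and <LOQ; censored rows store value 0 and their
thresholds. Everything derives from one integer seed; identical seeds give
byte-identical tables.

What the generator does *not* emulate: between-study heterogeneity beyond
the lognormal (no publication bias, no country or era effects), correlation
between contaminants within a food, reported medians versus means, and
analytical measurement error. Passing recovery tests therefore shows the
estimator is correct under its stated sampling model, not that literature
data meet that model.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately small problems — tables of a few
hundred to ten thousand records, 200–1000 studies per pair for recovery
checks — which keep the whole suite within seconds while giving the
Monte-Carlo checks adequate power (the weighted median of a 200-study table
has ≈6% relative sd, so unbiasedness checks average several independent
tables). Percentile ties are handled by stable sorting; zero-weight records
are dropped before quantile computation; empty record groups, zero-mass
diets and zero exposures raise explicit errors or report "not computable"
rather than propagating NaNs.

## Known limitations

Substitution at threshold/√2 biases percentiles when censoring is heavy
(>50%); a censored-likelihood estimator would be preferable there but is out
of scope. Percentile-summing for congeners and the comonotonic scenario
stack both overstate joint tails by construction. Guidance values evolve;
the packaged registry reflects one snapshot of EFSA opinions and is
trivially replaceable via `read_registry`. Exposure is deterministic
per-person at a fixed body weight; no probabilistic (2-D Monte-Carlo)
body-weight or consumption variability is modelled.
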