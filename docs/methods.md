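# Methods

This note documents the models, rules and defaults behind `allernova`, the
choices made where the design was genuinely open, and what the tests do and
do not demonstrate.

## Record model and exclusion filter

A record is one packaged product: taxonomy position (category,
subcategory), free-text ingredient list, a list of free-text precautionary
statements, and two completeness flags. The analyzable set is defined by a
sequential filter: records without a readable ingredient list are excluded
first, then records without images of all package sides (precautionary
statements have no regulated position on the packaging, so partial imaging
means allergen data may be incomplete). A record failing both criteria is
counted once, under the unreadable-list reason. The filter is idempotent
and partitions the input by product id; both properties are tested.

The shipped taxonomy (13 categories, 41 subcategories) mirrors a branded
food composition database for the Greek market. It is data, not code: any
two-level scheme loads from a JSON file. Note the published subcategory
sizes for that market sum to 4590 while the stated analyzable total is
4587 (and the NOVA1 present-count row sum is 524 vs the printed 523); the
package validates its own bookkeeping strictly and carries the published
numbers as-printed in its fixture rather than reconciling them.

## Allergen detection

Text is normalized by lower-casing, NFKD accent folding (Greek tonos marks
and final-sigma normalization included), punctuation unification and
whitespace collapse. Ingredient lists are split on top-level commas and
semicolons; parenthetical sub-ingredients stay inside their parent phrase
and are also exposed as child phrases; percentage annotations are stripped
for matching but preserved.

Detection is exact whole-word/phrase matching against a JSON lexicon with,
per allergen: canonical terms, derivative terms (whey/casein/lactose →
milk; wheat/rye/barley/oats/spelt/kamut → gluten cereals; named tree nuts →
tree nuts; E220–E228 and sulphite salts → sulphites), and exclusion
patterns. Design choices:

* **Scopes.** An allergen named in the ingredient list or in a post-list
  "contains …" statement is an *ingredient* declaration; one named in a
  statement carrying a precautionary trigger phrase ("may contain traces
  of", "manufactured in a facility that also processes", "may be present",
  …) is a *trace*. All precautionary variants collapse to one trace status.
  An allergen declared both ways counts once, as ingredient — the higher
  exposure risk — so per-record counts satisfy n_any = n_ingredient +
  n_trace and the three scopes never double-count.
* **Claims.** Allergen-free claims ("gluten-free") are excised before term
  matching and logged; excision suppresses the claimed term only, never
  other matches in the phrase, so "gluten-free oat flakes" still maps to
  gluten cereals through the oat term. This is deliberately conservative
  for allergic consumers: a claim does not override an explicit derivative.
  Multi-word exclusions also handle non-claim collisions (cocoa/peanut/shea
  butter are not milk).
* **Implicit sources.** Only explicit terms match. Compound ingredients
  that merely *may* carry an allergen ("flavouring") are not inferred;
  this understates true prevalence on real labels.
* **Fuzzy matching is off.** Matching is exact on normalized text for
  reproducibility; misspelled or out-of-vocabulary synonyms are misses (the
  generator's adversarial mode quantifies this).

The shipped lexicon is English; Greek or other vocabularies load from the
same JSON schema.

## NOVA classification

The classifier operationalizes the four NOVA groups as a decision cascade
over the parsed ingredient list:

1. any ultra-processing marker → NOVA4. Marker classes (terms plus
   E-number ranges): sweeteners beyond plain sugar, flavourings/flavour
   enhancers, emulsifiers, thickeners/stabilizers, bulking agents,
   antioxidants, protein isolates/concentrates, added vitamins/minerals,
   hydrolyzed/extruded ingredients, food extracts;
2. else a single-ingredient product (water tolerated) whose sole
   ingredient is culinary (salt, sugar, oils, starch, butter, honey) →
   NOVA2;
3. else a multi-ingredient list containing ≥ 1 culinary term → NOVA3;
4. else → NOVA1 (this includes single non-culinary ingredients such as
   plain almonds).

Open design points, resolved as follows:

* A literal reading that treats *any* added sodium/oil/sugar as an
  ultra-processing marker would leave NOVA3 empty (every cheese — milk,
  salt, rennet — would be NOVA4), contradicting how processed foods are
  defined (multiple ingredients, at least one culinary). Default routing
  therefore sends plain culinary ingredients in a recipe to NOVA3 and
  reserves NOVA4 for industrial substances; the literal mode is available
  as `strict_culinary_markers=True`.
* "Five or more ingredients" is descriptive of UPFs, not decisive:
  ingredient count is recorded in the classification trace but never fires
  a rule by itself.
* Subcategories that are by construction industrially formulated (meat
  analogues, dairy imitations, prepared foods) can be forced to a minimum
  grade through a taxonomy-level override table in the marker lexicon.
  The default is overrides off, i.e. classification purely from label
  text; both modes are supported because survey practice varies.

Every classification carries a trace (rule fired, matched markers and
culinary terms, ingredient count) sufficient to re-derive the grade.

## Statistics

Within each subcategory, foods are cross-tabulated as NOVA grade ×
allergen presence for a scope (any / ingredient / trace; presence = count
≥ 1). Differences between grades are tested with Pearson's chi-square
without continuity correction, df = (number of grades present) − 1,
α = 0.01 by default with no multiple-testing correction (a Bonferroni
option exists but is off, matching survey practice for per-subcategory
reporting). A subcategory is not testable when only one grade is present
or when prevalence is uniformly 100% or uniformly 0% — the degeneracy that
would produce zero expected counts; the rule is evaluated on the table
being tested (the published convention applies it to the either-scope
table). The engine delegates to `scipy.stats.chi2_contingency`; tests pin
it to the independent 2 × 2 closed form to 1e-10 and to a null-simulation
type-I error within the 99% binomial band around 0.01 (1000 replicates of
two groups of 250 at 30% prevalence).

Rendering follows label-survey conventions: percentages at one decimal,
half-up (100% prints as "100"); p-values at three decimals, with values
rounding below 0.005 printed as "<0.01" (so 0.009 prints as itself). Note
the stated significance level in the source survey ("0.01%") is treated as
a typo for 0.01, consistent with its own "99% confidence" footnote and
reported significant-subcategory count.

Per-grade allergen-count summaries always compute both mean conventions —
over all foods in the grade and over declaring foods only — because survey
reports mix them: headline means for the any/ingredient scopes are
consistent only with the all-foods denominator, while trace means are
consistent only with the declaring-foods denominator (a mean of 2.3 traces
over all foods would exceed the observed maximum share). The reporting
layer applies exactly that per-scope default and labels the convention.

Diversity analysis collects the set of distinct allergens per
(subcategory, grade, scope) cell; grades 1–3 can be pooled into one
comparator, and the report flags subcategories where the NOVA4 set is
strictly larger.

## Synthetic-label generator

The generator emulates the structure of a branded-food market survey with
known ground truth. Defaults are the study conditions of the published
survey: per-subcategory sizes and NOVA mixtures taken from the published
table (4590 records before exclusion), exclusion rates 27/4851 (unreadable)
and 237/4824 (incomplete imaging), and per-(grade, allergen) rates
calibrated to the published per-grade statistics:

* **Ingredient allergens** are drawn independently per allergen with rates
  summing to the published per-grade means (0.4 / 0.5 / 0.8 / 1.3),
  allocated across allergens by fixed market-realistic weights (milk and
  gluten dominant). Independence is a simplification: it fixes the mean
  exactly but gives a slightly lower any-ingredient prevalence than
  published (the published NOVA1 pair — 41.7% prevalence, 0.4 mean — is
  unattainable jointly, since prevalence cannot exceed the mean).
* **Trace allergens** are drawn comonotonically: one cross-contamination
  severity uniform per record, an allergen tracing iff its rate exceeds
  it. Under this coupling the trace prevalence equals the maximum rate and
  the per-declarer mean equals sum/max, so both published quantities
  (prevalences 28.7 / 1.4 / 10.2 / 45.4%, declarer means 2.3 / 2.0 / 1.8 /
  2.8) are hit by construction, and statements naturally cluster several
  allergens — as real shared-facility labels do. Removing the overlap with
  ingredient declarations dilutes both slightly.
* **Text is rendered from truth, never the reverse.** Grade-4 records
  embed markers, grade-3 records a culinary term in a multi-ingredient
  list, grade-2 records a single culinary ingredient (the only grade-2
  ingredient-allergen rendering is butter → milk; other draws are dropped
  there and the stored truth reflects the rendered text), grade-1 records
  neither. Allergens render as canonical or derivative terms
  (`synonym_rate`, default 0.3); the adversarial `out_of_lexicon_rate`
  (default 0) substitutes renderings absent from the lexicon to measure
  recall degradation.
* **Determinism.** Per-record random substreams are seeded by a stable
  hash of the product id, so output is byte-identical for a given seed and
  unaffected by record order.

What passing recovery tests show: the detector and classifier are exact on
vocabulary the lexicon knows, and degrade only through misses (never false
alarms) on vocabulary it does not. What they do not show: performance on
real labels, whose vocabulary, spelling, languages and compound-ingredient
ambiguity exceed any fixed lexicon; real-label prevalence will be
underestimated in proportion to lexicon coverage.

## Problem sizes and numerical notes

Default test and demonstration runs use proportionally scaled-down record
sets (scale 0.03–0.15 of the 4590-record default, i.e. a few hundred to
~700 records), which the generator supports natively; recovery and
calibration results are scale-free. The chi-square golden suite runs on
the published counts directly. The null-simulation calibration uses 1000
replicates. Percent/percentage rounding uses decimal half-up arithmetic to
match printed tables; chi-square values are asserted to 3 printed decimals
against the published table, and one published row ("Starchy root or
potato", printed p = 0.058) is internally inconsistent with its own counts
(which give 0.093) — the engine's value from the printed counts is the one
asserted, and the discrepancy does not affect the significant-subcategory
count.

## Known limitations

* Rule-based detection cannot resolve implicit or ambiguous allergen
  sources and does not quantify amounts or allergenicity.
* NOVA grading from label text inherits NOVA's own ambiguities; borderline
  NOVA3/NOVA4 products hinge on lexicon coverage of marker vocabulary.
* The shipped lexicons are English-first; accent folding supports Greek
  text, but the Greek vocabulary pack is left to the user.
* The generator's subcategory-level realism is structural (sizes,
  mixtures, rates), not culinary: ingredient lists are plausible, not
  marketing copy.
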