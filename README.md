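# allernova

Rule-based analysis of allergen declarations and food-processing grade on
branded (packaged) food labels.

Packaged foods carry two kinds of allergen information: the 14 substances
regulated in the EU (gluten-containing cereals, crustaceans, eggs, fish,
peanuts, soybeans, milk, tree nuts, celery, mustard, sesame, sulphites,
lupin, mollusks) must be declared when used as ingredients, and voluntary
precautionary statements ("may contain traces of …") warn of possible
cross-contamination. Independently, the NOVA system grades foods 1–4 by the
extent and purpose of processing, with grade 4 ("ultra-processed foods",
UPFs) marked by industrial substances such as emulsifiers, flavourings,
bulking agents and protein isolates. `allernova` is for researchers in food
science and nutritional epidemiology who want to ask, at the level of a
branded-food composition database: *are more processed foods more likely to
carry allergens, and does that hold within comparable foods?*

The package provides:

* **Record handling** — a documented CSV/JSON schema for branded-food
  records, a 13-category / 41-subcategory market taxonomy (shipped as data,
  swappable), and the exclusion filter that removes records without a
  readable ingredient list or complete package imaging.
* **`AllergenDetector`** — a scikit-learn-style transformer that parses the
  ingredient list (parenthetical sub-ingredients, percentage annotations)
  and the precautionary statements, and assigns each of the 14 allergens a
  status in `{ingredient, trace, absent}` with precedence
  ingredient > trace. Matching is whole-word lookup on normalized
  (lower-cased, accent-folded) text against a JSON lexicon of canonical
  terms, derivatives (whey → milk, spelt → gluten cereals, E220–E228 →
  sulphites) and allergen-free-claim exclusions.
* **`NovaClassifier`** — a rule-based classifier implementing the cascade:
  any ultra-processing marker (term or E-number) ⇒ NOVA4; single culinary
  ingredient ⇒ NOVA2; multi-ingredient list with a culinary term ⇒ NOVA3;
  else NOVA1. Every decision comes with a trace (rule fired, matched
  markers, ingredient count).
* **Prevalence statistics** — per-subcategory NOVA-group × allergen-presence
  contingency tables with Pearson's chi-square (no continuity correction,
  df = groups − 1, α = 0.01), the not-applicable rules for single-group or
  uniformly 100%/0% subcategories, per-grade allergen-count histograms and
  means, and distinct-allergen diversity sets with a pooled NOVA1–3
  comparator. For a grades × {present, absent} table the statistic is the
  usual Σ (O − E)²/E; for 2 × 2 tables this equals
  n(ad − bc)²/((a+b)(c+d)(a+c)(b+d)).
* **A synthetic-label generator** — seeded, ground-truth-first: grades and
  allergen sets are drawn, then label text is rendered to satisfy them, so
  detector and classifier can be validated by exact recovery
  (F1 = 1.0 / accuracy = 1.0 on lexicon-conformant output), with an
  adversarial out-of-lexicon mode to measure degradation.
* **A CLI** (`allernova`) with `validate`, `detect`, `classify`, `analyze`,
  `simulate`, `report` and `run` subcommands, exporting plain CSV/JSON
  artifacts with a reproducibility manifest.

## Worked example

Simulate a market survey at one tenth of the default scale, run the full
pipeline, and print the headline summary:

```bash
allernova simulate --seed 42 --scale 0.1 --out records.csv
# wrote records.csv (461 records) and records.csv.truth.json
allernova run --records records.csv --out results
```

which prints (abridged):

```json
{
 "alpha": 0.01,
 "n_retained": 428,
 "n_significant_subcategories": 1,
 "n_subcategories": 41,
 "n_testable_subcategories": 15,
 "overall_any_prevalence_pct": 79.0,
 "per_grade": {
  "1": {"any_prevalence_pct": 58.9, "mean_any": 1.22, "mean_ingredient": 0.49,
        "mean_trace": 2.36, "n": 90},
  "4": {"any_prevalence_pct": 89.3, "mean_any": 2.15, "mean_ingredient": 1.27,
        "mean_trace": 2.23, "n": 299}
 }
}
```

Reading this: of 461 simulated products, 428 survive the exclusion filter
(unreadable ingredient list, incomplete package imaging). 79.0% declare at
least one allergen as ingredient or trace. Minimally processed foods
(NOVA1, n = 90) have a 58.9% allergen prevalence and 0.49 allergenic
ingredients per food on average, ultra-processed foods (NOVA4, n = 299)
89.3% and 1.27 — the UPF excess the analysis is designed to quantify — yet
only 1 of the 15 testable subcategories shows a significant
prevalence difference between grades at α = 0.01: between comparable foods,
processing grade alone separates allergen exposure far less than the
market-level contrast suggests. `results/` also contains the per-record
profiles and grades, the nested prevalence table with rendered p-values,
histogram and diversity CSVs, and a run manifest.

The same analysis from Python:

```python
from allernova import (AllergenDetector, NovaClassifier, apply_exclusions,
                       default_config, generate, prevalence_report)

records, truth = generate(default_config(seed=42, scale=0.1))
retained, log = apply_exclusions(records)
profiles = AllergenDetector().fit().profiles(retained)
grades = {pid: t.grade for pid, t in NovaClassifier().fit().classify_all(retained).items()}
report = prevalence_report(retained, profiles, grades, alpha=0.01)
print(report.n_testable, report.n_significant)   # 15 1
```

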