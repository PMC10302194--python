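"""Seeded generator of branded-food label records with known ground truth.

The real record source for this kind of analysis is an access-gated branded
food composition database, so every pipeline stage here is exercised on
synthetic record sets instead.  The generator assigns ground truth FIRST
(NOVA grade, allergen sets, exclusion flags) and then renders label text to
satisfy it: grade-4 records embed at least one ultra-processing marker
phrase, grade-3 records put a culinary ingredient in a multi-ingredient
list, grade-2 records are single culinary ingredients, grade-1 records
contain neither markers nor added culinary terms; allergens render as
canonical or derivative terms, traces as precautionary statements with
weighted trigger phrases.

The default configuration reproduces the study conditions of the published
branded-food market survey: the 41-subcategory taxonomy with the published
per-subcategory sizes and NOVA mixtures (4590 records), per-grade allergen
rates calibrated to the published per-grade means (0.4/0.5/0.8/1.3
ingredient allergens and trace prevalences 28.7/1.4/10.2/45.4%), and
exclusion rates matching the published sampling funnel (27/4851 unreadable,
237/4824 incomplete imaging).

Randomness: one integer seed; per-record substreams are derived by stable
hashing of the product id, so record order never shifts draws.  Same seed,
same config -> byte-identical output.

The module also ships the published per-subcategory contingency counts as a
fixture (:func:`table1_fixture`) for testing the statistics engine against
printed values.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .allergens import ALLERGENS
from .records import FoodRecord, RecordSet, Taxonomy, load_default_taxonomy
from .stats import ContingencyTable

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "default_config",
    "generate",
    "table1_fixture",
    "table1_all_tables",
    "headline_counts",
]

# --- rendering vocabulary (aligned with the shipped lexicons) ---------------

# allergen-free, culinary-free, marker-free filler ingredients
_NEUTRAL_BASES = [
    "tomatoes", "lentils", "carrots", "chickpeas", "green peas", "apples",
    "apricots", "grapes", "mushrooms", "olives", "beef", "chicken",
    "potatoes", "brown rice", "quinoa", "cucumber", "spinach", "onions",
]

# per-allergen ingredient renderings; first entry is the canonical choice,
# the rest are derivative synonyms.  Terms that would collide with culinary
# or marker vocabulary (peanut butter, sesame oil, celery salt, soy
# lecithin) are deliberately not used here so the rendered grade is never
# perturbed by an allergen term.
_ALLERGEN_RENDER = {
    "gluten_cereals": ["wheat flour", "barley malt", "rye flour", "oat flakes", "spelt"],
    "crustaceans": ["shrimp", "crab", "prawns"],
    "eggs": ["egg", "egg white", "whole egg"],
    "fish": ["fish", "cod", "tuna", "anchovies"],
    "peanuts": ["peanuts", "groundnuts"],
    "soybeans": ["soy", "soya flour", "tofu", "soybeans"],
    "milk": ["milk", "skimmed milk powder", "whey powder", "cream", "casein"],
    "tree_nuts": ["hazelnuts", "almonds", "walnuts", "cashews", "pistachios"],
    "celery": ["celery", "celeriac"],
    "mustard": ["mustard", "mustard seeds"],
    "sesame": ["sesame seeds", "sesame", "tahini"],
    "sulphites": ["sulphites", "sodium metabisulphite", "e220"],
    "lupin": ["lupin", "lupin flour"],
    "mollusks": ["squid", "mussels", "octopus"],
}

# precautionary-statement wording per allergen
_TRACE_RENDER = {
    "gluten_cereals": "gluten", "crustaceans": "crustaceans", "eggs": "eggs",
    "fish": "fish", "peanuts": "peanuts", "soybeans": "soy", "milk": "milk",
    "tree_nuts": "nuts", "celery": "celery", "mustard": "mustard",
    "sesame": "sesame", "sulphites": "sulphites", "lupin": "lupin",
    "mollusks": "molluscs",
}

# adversarial renderings absent from the shipped lexicon (out_of_lexicon_rate)
_OUT_OF_LEXICON_RENDER = {
    "gluten_cereals": "triticale", "crustaceans": "langoustine",
    "eggs": "meringue powder", "fish": "pollock", "peanuts": "goober peas",
    "soybeans": "okara", "milk": "lactalbumin", "tree_nuts": "filberts",
    "celery": "smallage", "mustard": "brassica juncea",
    "sesame": "benne seeds", "sulphites": "pyrosulphite",
    "lupin": "altramuz", "mollusks": "calamari",
}

_CULINARY_SINGLE = ["sugar", "sea salt", "olive oil", "sunflower oil", "corn starch", "honey"]
_CULINARY_ADDED = ["salt", "sugar", "olive oil", "sunflower oil"]

# allergen-neutral ultra-processing marker phrases
_MARKER_RENDER = [
    "flavourings",
    "emulsifier: mono- and diglycerides of fatty acids (e471)",
    "thickener: xanthan gum",
    "antioxidant: ascorbic acid (e300)",
    "glucose syrup",
    "maltodextrin",
    "yeast extract",
    "monosodium glutamate (e621)",
    "stabiliser: carrageenan (e407)",
]
_MARKER_RENDER_SOY = "emulsifier: lecithins (soy)"
# a genuinely unlisted additive (preservatives are not a marker class)
_OUT_OF_LEXICON_MARKER = "preservative: potassium sorbate (e202)"

# per-grade allocation weights of the ingredient-allergen budget
_INGREDIENT_WEIGHTS = {
    "milk": 0.25, "gluten_cereals": 0.25, "soybeans": 0.12, "eggs": 0.08,
    "tree_nuts": 0.08, "sesame": 0.05, "sulphites": 0.05, "celery": 0.03,
    "mustard": 0.03, "fish": 0.02, "peanuts": 0.02, "crustaceans": 0.01,
    "lupin": 0.005, "mollusks": 0.005,
}
_TRACE_WEIGHTS = {
    "tree_nuts": 0.20, "milk": 0.15, "gluten_cereals": 0.15, "soybeans": 0.12,
    "sesame": 0.10, "peanuts": 0.10, "eggs": 0.08, "mustard": 0.03,
    "celery": 0.02, "lupin": 0.02, "sulphites": 0.01, "fish": 0.01,
    "crustaceans": 0.005, "mollusks": 0.005,
}
# published per-grade expectations: mean ingredient allergens per food,
# trace prevalence and mean trace allergens per declaring food
_INGREDIENT_MEANS = {1: 0.4, 2: 0.5, 3: 0.8, 4: 1.3}
_TRACE_PREVALENCE = {1: 0.287, 2: 0.014, 3: 0.102, 4: 0.454}
_TRACE_DECLARING_MEANS = {1: 2.3, 2: 2.0, 3: 1.8, 4: 2.8}


@dataclass
class SyntheticConfig:
    """Generator parameters; the seed fully determines the output."""

    seed: int = 0
    n_per_subcategory: dict[str, int] = field(default_factory=dict)
    grade_mixture: dict[str, list[float]] = field(default_factory=dict)  # p(grade 1..4)
    ingredient_allergen_rates: dict[int, dict[str, float]] = field(default_factory=dict)
    trace_rates: dict[int, dict[str, float]] = field(default_factory=dict)
    synonym_rate: float = 0.3
    out_of_lexicon_rate: float = 0.0
    trigger_phrase_weights: dict[str, float] = field(default_factory=lambda: {
        "may contain traces of": 0.6,
        "manufactured in a facility that also processes": 0.2,
        "may be present": 0.2,
    })
    exclusion_rates: tuple[float, float] = (27 / 4851, 237 / 4824)  # (unreadable, incomplete)

    def validate(self, taxonomy: Taxonomy) -> None:
        known = set(taxonomy.subcategory_names)
        unknown = sorted(set(self.n_per_subcategory) - known)
        if unknown:
            raise ValueError(f"subcategories not in taxonomy: {unknown}")
        for sub, mix in self.grade_mixture.items():
            if sub not in known:
                raise ValueError(f"grade_mixture subcategory not in taxonomy: {sub!r}")
            if len(mix) != 4 or any(p < 0 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"{sub!r}: grade mixture must be 4 probabilities summing to 1")
        for rates in (self.ingredient_allergen_rates, self.trace_rates):
            for g, per_a in rates.items():
                for a, p in per_a.items():
                    if a not in ALLERGENS:
                        raise ValueError(f"unknown allergen {a!r}")
                    if not 0.0 <= p <= 1.0:
                        raise ValueError(f"rate out of [0,1]: grade {g} {a} = {p}")
        for p in (self.synonym_rate, self.out_of_lexicon_rate, *self.exclusion_rates):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if not self.trigger_phrase_weights:
            raise ValueError("empty trigger_phrase_weights")


@dataclass
class GroundTruth:
    """True labels per product id, for recovery testing."""

    grades: dict[str, int]
    ingredient_allergens: dict[str, set[str]]
    trace_allergens: dict[str, set[str]]
    exclusion_reason: dict[str, str | None]

    def to_json(self, path: str | Path) -> None:
        obj = {
            pid: {
                "grade": self.grades[pid],
                "ingredient_allergens": sorted(self.ingredient_allergens[pid]),
                "trace_allergens": sorted(self.trace_allergens[pid]),
                "exclusion_reason": self.exclusion_reason[pid],
            }
            for pid in self.grades
        }
        Path(path).write_text(json.dumps(obj, indent=1) + "\n", encoding="utf-8")


def _load_table1() -> dict:
    text = resources.files("allernova.data").joinpath("table1_counts.json").read_text("utf-8")
    return json.loads(text)


def default_rates() -> tuple[dict[int, dict[str, float]], dict[int, dict[str, float]]]:
    """Per-(grade, allergen) ingredient and trace rates calibrated to the
    published per-grade statistics.

    Ingredient rates are sized so their sum equals the published mean count
    (draws are independent: recipe allergens are roughly independent).
    Trace rates are sized so the top rate equals the published trace
    prevalence and the sum equals prevalence x declarer mean; the generator
    draws traces comonotonically (one shared-facility uniform per record),
    under which prevalence = max rate and the per-declarer mean = sum/max,
    so both published quantities are hit by construction."""
    ing = {
        g: {a: min(0.95, mean * w) for a, w in _INGREDIENT_WEIGHTS.items()}
        for g, mean in _INGREDIENT_MEANS.items()
    }
    top = max(_TRACE_WEIGHTS, key=_TRACE_WEIGHTS.get)
    w_rest = sum(w for a, w in _TRACE_WEIGHTS.items() if a != top)
    trace = {}
    for g, prev in _TRACE_PREVALENCE.items():
        extra = _TRACE_DECLARING_MEANS[g] - 1.0  # allergens beyond the first
        trace[g] = {
            a: prev if a == top else min(prev, prev * extra * w / w_rest)
            for a, w in _TRACE_WEIGHTS.items()
        }
    return ing, trace


def default_config(seed: int = 0, scale: float = 1.0) -> SyntheticConfig:
    """Study-condition configuration: published subcategory sizes and NOVA
    mixtures, calibrated allergen rates, published exclusion rates.

    ``scale`` shrinks every subcategory size proportionally (minimum 1) for
    fast test runs without changing the mixture structure."""
    t1 = _load_table1()
    n_per = {}
    mixture = {}
    for entry in t1["subcategories"]:
        sub = entry["subcategory"]
        n = sum(r["n"] for r in entry["rows"])
        n_per[sub] = max(1, int(round(n * scale)))
        mix = [0.0, 0.0, 0.0, 0.0]
        for r in entry["rows"]:
            mix[r["grade"] - 1] = r["n"] / n
        mixture[sub] = mix
    ing, trace = default_rates()
    return SyntheticConfig(
        seed=seed,
        n_per_subcategory=n_per,
        grade_mixture=mixture,
        ingredient_allergen_rates=ing,
        trace_rates=trace,
    )


def _record_rng(seed: int, product_id: str) -> np.random.Generator:
    # stable per-record substream: draws never depend on record order
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(product_id.encode("utf-8"))])
    )


def _slug(text: str) -> str:
    return "".join(ch if ch.isalnum() else "-" for ch in text.lower()).strip("-")[:24]


def _pick(rng: np.random.Generator, options: list[str]) -> str:
    return options[int(rng.integers(len(options)))]


def _render_allergen(rng: np.random.Generator, allergen: str,
                     synonym_rate: float, out_rate: float) -> str:
    if out_rate > 0 and rng.random() < out_rate:
        return _OUT_OF_LEXICON_RENDER[allergen]
    options = _ALLERGEN_RENDER[allergen]
    if len(options) > 1 and rng.random() < synonym_rate:
        return _pick(rng, options[1:])
    return options[0]


def generate(config: SyntheticConfig,
             taxonomy: Taxonomy | None = None) -> tuple[RecordSet, GroundTruth]:
    """Generate a record set realizing a drawn ground truth.

    Ground truth is drawn first (grade from the subcategory mixture,
    allergen sets from per-grade Bernoulli rates, exclusion flags), then the
    label text is rendered to satisfy it.  Grade-2 records are constrained
    to a single culinary ingredient, so their ingredient-allergen truth is
    restricted to what a culinary single can carry (butter for milk); other
    draws are dropped there and the stored truth reflects the rendered text.
    """
    taxonomy = taxonomy or load_default_taxonomy()
    config.validate(taxonomy)
    triggers = list(config.trigger_phrase_weights.items())
    trig_names = [t for t, _ in triggers]
    trig_w = np.array([w for _, w in triggers], dtype=float)
    trig_w = trig_w / trig_w.sum()

    records: list[FoodRecord] = []
    grades: dict[str, int] = {}
    ing_truth: dict[str, set[str]] = {}
    trace_truth: dict[str, set[str]] = {}
    excl: dict[str, str | None] = {}

    for sub in taxonomy.subcategory_names:
        n = config.n_per_subcategory.get(sub, 0)
        if n == 0:
            continue
        category = taxonomy.parent_of(sub)
        mix = np.array(config.grade_mixture.get(sub, [1.0, 0.0, 0.0, 0.0]))
        slug = _slug(sub)
        for i in range(n):
            pid = f"SYN-{slug}-{i:05d}"
            rng = _record_rng(config.seed, pid)
            grade = int(rng.choice([1, 2, 3, 4], p=mix))
            ing_rates = config.ingredient_allergen_rates.get(grade, {})
            trace_rates = config.trace_rates.get(grade, {})
            ing_set = {a for a in ALLERGENS if rng.random() < ing_rates.get(a, 0.0)}
            # comonotone trace draw: one cross-contamination severity uniform
            # per record, so statements cluster several allergens together
            # while each allergen keeps its configured marginal rate
            u_trace = rng.random()
            trace_set = {a for a in ALLERGENS if u_trace < trace_rates.get(a, 0.0)}
            # an allergen present as ingredient outranks a trace declaration
            trace_set -= ing_set

            # --- render ingredient list to satisfy the drawn grade ---------
            phrases: list[str] = []
            if grade == 2:
                ing_set &= {"milk"}  # only a culinary single can carry milk (butter)
                phrases = ["butter"] if "milk" in ing_set else [_pick(rng, _CULINARY_SINGLE)]
            else:
                n_bases = 1 + int(rng.integers(3)) if grade != 1 else 1 + int(rng.integers(2))
                bases = [
                    _pick(rng, _NEUTRAL_BASES)
                    for _ in range(n_bases)
                ]
                phrases.extend(dict.fromkeys(bases))  # dedupe, keep order
                for a in [x for x in ALLERGENS if x in ing_set]:
                    phrases.append(_render_allergen(rng, a, config.synonym_rate,
                                                    config.out_of_lexicon_rate))
                if grade in (3, 4):
                    n_cul = 1 + int(rng.integers(2))
                    culs = {_pick(rng, _CULINARY_ADDED) for _ in range(n_cul)}
                    phrases.extend(sorted(culs))
                if grade == 4:
                    n_mark = 1 + int(rng.integers(2))
                    marks = []
                    if "soybeans" in ing_set and rng.random() < 0.5:
                        marks.append(_MARKER_RENDER_SOY)
                    while len(marks) < n_mark:
                        m = _pick(rng, _MARKER_RENDER)
                        if m not in marks:
                            marks.append(m)
                    if config.out_of_lexicon_rate > 0 and rng.random() < config.out_of_lexicon_rate:
                        marks = [_OUT_OF_LEXICON_MARKER]
                    phrases.extend(marks)
                if rng.random() < 0.25 and phrases:
                    pct = int(rng.integers(5, 90))
                    phrases[0] = f"{phrases[0]} ({pct}%)"
            ingredient_text = ", ".join(phrases)

            # --- precautionary statement ----------------------------------
            precautions: list[str] = []
            if trace_set:
                trigger = trig_names[int(rng.choice(len(trig_names), p=trig_w))]
                terms = [_TRACE_RENDER[a] for a in ALLERGENS if a in trace_set]
                if config.out_of_lexicon_rate > 0:
                    terms = [
                        _OUT_OF_LEXICON_RENDER[a] if rng.random() < config.out_of_lexicon_rate
                        else _TRACE_RENDER[a]
                        for a, _t in zip([x for x in ALLERGENS if x in trace_set], terms)
                    ]
                joined = ", ".join(terms[:-1]) + " and " + terms[-1] if len(terms) > 1 else terms[0]
                if trigger == "may be present":
                    precautions.append(f"{joined} may be present")
                else:
                    precautions.append(f"{trigger} {joined}")

            # --- exclusion flags ------------------------------------------
            r_unread, r_incomplete = config.exclusion_rates
            reason: str | None = None
            readable, complete = True, True
            text: str | None = ingredient_text
            if rng.random() < r_unread:
                reason, readable, text = "unreadable_ingredient_list", False, None
            elif rng.random() < r_incomplete:
                reason, complete = "incomplete_package_imaging", False

            records.append(FoodRecord(
                product_id=pid,
                name=f"synthetic {sub.lower()} #{i}",
                category=category,
                subcategory=sub,
                ingredient_text=text,
                precaution_texts=precautions,
                ingredient_list_readable=readable,
                all_package_sides_available=complete,
            ))
            grades[pid] = grade
            ing_truth[pid] = ing_set
            trace_truth[pid] = trace_set
            excl[pid] = reason

    rs = RecordSet(records=records, provenance=f"synthetic(seed={config.seed})")
    gt = GroundTruth(grades=grades, ingredient_allergens=ing_truth,
                     trace_allergens=trace_truth, exclusion_reason=excl)
    return rs, gt


# --- published-count fixtures ------------------------------------------------


def table1_all_tables() -> list[ContingencyTable]:
    """All 41 published subcategory contingency tables (either scope)."""
    t1 = _load_table1()
    return [
        ContingencyTable(
            subcategory=e["subcategory"],
            rows=[(r["grade"], r["n_present"], r["n"] - r["n_present"]) for r in e["rows"]],
            category=e["category"],
        )
        for e in t1["subcategories"]
    ]


def _is_testable(t: ContingencyTable) -> bool:
    if len(t.rows) < 2:
        return False
    all_present = all(a == 0 for _, _, a in t.rows)
    all_absent = all(p == 0 for _, p, _ in t.rows)
    return not (all_present or all_absent)


def table1_fixture() -> list[ContingencyTable]:
    """The 13 testable published subcategory tables (>=2 NOVA groups and
    non-degenerate prevalence)."""
    return [t for t in table1_all_tables() if _is_testable(t)]


def headline_counts() -> dict:
    """Published headline counts: retained n, overall/any-scope and
    per-grade present counts and denominators, per-grade means."""
    return _load_table1()["headline"]
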