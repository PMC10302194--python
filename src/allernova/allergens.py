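"""Detection of the 14 EU-regulated allergens on food labels.

EU law (Annex II of Regulation 1169/2011) singles out 14 substances whose
presence as an ingredient must be declared: gluten-containing cereals,
crustaceans, eggs, fish, peanuts, soybeans, milk, tree nuts, celery,
mustard, sesame, sulphites, lupin and mollusks.  On a label an allergen can
appear two ways, ranked by exposure risk:

* as an **ingredient** — named in the ingredient list (directly or through a
  derivative such as whey for milk or spelt for gluten cereals), or in a
  "contains ..." statement printed after the list;
* as a **trace** — named in a voluntary precautionary statement ("may
  contain traces of ...", "manufactured in a facility that also processes
  ..."); all precautionary variants collapse to a single trace status.

Matching is exact whole-word/phrase lookup on normalized text against a
lexicon shipped as data (English by default; other vocabularies load from
JSON).  Allergen-free claims ("gluten-free") suppress the claimed term only
and are logged.  An allergen declared both ways counts once, as an
ingredient, so the any-scope count is the sum of the two scopes.

The scikit-learn-style :class:`AllergenDetector` is the primary surface;
the module-level functions are thin wrappers kept for direct use.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .records import FoodRecord
from .text import IngredientPhrase, normalize_text, split_ingredient_list

__all__ = [
    "ALLERGENS",
    "STATUS_ORDER",
    "AllergenLexicon",
    "AllergenProfile",
    "AllergenDetector",
    "load_default_lexicon",
    "detect_ingredient_allergens",
    "detect_precautionary_allergens",
    "build_profile",
]

# Annex II order; identifiers are stable across releases.
ALLERGENS: tuple[str, ...] = (
    "gluten_cereals",
    "crustaceans",
    "eggs",
    "fish",
    "peanuts",
    "soybeans",
    "milk",
    "tree_nuts",
    "celery",
    "mustard",
    "sesame",
    "sulphites",
    "lupin",
    "mollusks",
)

# precedence: ingredient > trace > absent
STATUS_ORDER = {"absent": 0, "trace": 1, "ingredient": 2}

_ENUM_RE = re.compile(r"(?<![a-z0-9])e[\s.-]?(\d{3,4})[a-z]?(?![a-z0-9])")


def _term_pattern(term: str) -> re.Pattern:
    # whole-word/phrase match on normalized text
    return re.compile(r"(?<!\w)" + re.escape(term) + r"(?!\w)")


@dataclass
class AllergenLexicon:
    """Validated term lists for allergen matching.

    ``terms`` maps allergen -> list of (normalized term, kind) where kind is
    "canonical" or "derivative"; ``exclusions`` maps allergen -> claim
    patterns excised before matching; ``e_ranges`` maps allergen -> inclusive
    E-number ranges (sulphites: E220-E228)."""

    name: str
    terms: dict[str, list[tuple[str, str]]]
    exclusions: dict[str, list[str]]
    e_ranges: dict[str, list[tuple[int, int]]]
    trigger_phrases: list[str]
    contains_statement_phrases: list[str]

    def __post_init__(self):
        missing = [a for a in ALLERGENS if a not in self.terms]
        extra = [a for a in self.terms if a not in ALLERGENS]
        if missing or extra:
            raise ValueError(f"lexicon allergen set mismatch: missing={missing} extra={extra}")
        for a in ALLERGENS:
            if not any(kind == "canonical" for _, kind in self.terms[a]):
                raise ValueError(f"allergen {a!r} has no canonical term")
        if not self.trigger_phrases:
            raise ValueError("lexicon has no precautionary trigger phrases")
        self._compiled = {
            a: [(_term_pattern(t), t, kind) for t, kind in self.terms[a]]
            for a in ALLERGENS
        }
        self._compiled_exclusions = {
            a: [(_term_pattern(p), p) for p in self.exclusions.get(a, [])]
            for a in ALLERGENS
        }
        self._triggers = sorted((normalize_text(t) for t in self.trigger_phrases),
                                key=len, reverse=True)
        self._contains = [normalize_text(t) for t in self.contains_statement_phrases]

    @classmethod
    def from_dict(cls, obj: dict, name: str | None = None) -> "AllergenLexicon":
        terms: dict[str, list[tuple[str, str]]] = {}
        exclusions: dict[str, list[str]] = {}
        e_ranges: dict[str, list[tuple[int, int]]] = {}
        for allergen, entry in obj["allergens"].items():
            terms[allergen] = (
                [(normalize_text(t), "canonical") for t in entry.get("canonical_terms", [])]
                + [(normalize_text(t), "derivative") for t in entry.get("derivative_terms", [])]
            )
            exclusions[allergen] = [normalize_text(p) for p in entry.get("exclusion_patterns", [])]
            e_ranges[allergen] = [tuple(r) for r in entry.get("e_number_ranges", [])]
        return cls(
            name=name or obj.get("name", "custom"),
            terms=terms,
            exclusions=exclusions,
            e_ranges=e_ranges,
            trigger_phrases=list(obj.get("trigger_phrases", [])),
            contains_statement_phrases=list(obj.get("contains_statement_phrases", ["contains"])),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "AllergenLexicon":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    # -- matching primitives -------------------------------------------------

    def apply_exclusions(self, allergen: str, text: str, claims: list | None = None) -> str:
        """Excise allergen-free-claim spans for one allergen from ``text``.

        Excision suppresses the claimed term only ("gluten-free oat flakes"
        loses "gluten-free" but "oat flakes" still matches); other allergens'
        matches in the phrase are never affected."""
        for pat, raw in self._compiled_exclusions.get(allergen, []):
            if pat.search(text):
                text = pat.sub(" ", text)
                if claims is not None:
                    claims.append((allergen, raw))
        return text

    def match_allergens(self, text: str, claims: list | None = None,
                        audit: list | None = None,
                        fuzzy_threshold: float | None = None) -> set[str]:
        """Return allergens whose terms (or E-numbers) match ``text``.

        With ``fuzzy_threshold`` set (similarity ratio in (0, 1]), word
        tokens that miss every exact term are additionally compared against
        single-word terms by edit-distance ratio; off by default for
        reproducibility."""
        found: set[str] = set()
        enums = [int(m.group(1)) for m in _ENUM_RE.finditer(text)]
        for allergen in ALLERGENS:
            scrubbed = self.apply_exclusions(allergen, text, claims)
            for pat, term, kind in self._compiled[allergen]:
                if pat.search(scrubbed):
                    found.add(allergen)
                    if audit is not None:
                        audit.append({"term": term, "kind": kind, "allergen": allergen})
                    break
            else:
                for lo, hi in self.e_ranges.get(allergen, []):
                    if any(lo <= n <= hi for n in enums):
                        found.add(allergen)
                        if audit is not None:
                            audit.append({"term": f"E{lo}-E{hi}", "kind": "e_number",
                                          "allergen": allergen})
                        break
                else:
                    if fuzzy_threshold is not None:
                        hit = self._fuzzy_match(allergen, scrubbed, fuzzy_threshold)
                        if hit is not None:
                            found.add(allergen)
                            if audit is not None:
                                audit.append({"term": hit, "kind": "fuzzy",
                                              "allergen": allergen})
        return found

    def _fuzzy_match(self, allergen: str, text: str, threshold: float) -> str | None:
        from difflib import SequenceMatcher

        single_word_terms = [t for t, _ in self.terms[allergen] if " " not in t]
        for token in re.findall(r"[^\W\d_]+", text):
            for term in single_word_terms:
                if SequenceMatcher(None, token, term).ratio() >= threshold:
                    return f"{token}~{term}"
        return None

    def has_trigger(self, statement: str) -> bool:
        return any(t in statement for t in self._triggers)

    def is_contains_statement(self, statement: str) -> bool:
        s = statement.strip()
        return any(s.startswith(c) for c in self._contains)


def load_default_lexicon() -> AllergenLexicon:
    """Load the shipped English Annex-II lexicon."""
    text = resources.files("allernova.data").joinpath("allergen_lexicon_en.json").read_text("utf-8")
    return AllergenLexicon.from_dict(json.loads(text))


@dataclass
class AllergenProfile:
    """Per-record allergen status for all 14 allergens plus scope counts."""

    product_id: str
    statuses: dict[str, str]
    claims: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if set(self.statuses) != set(ALLERGENS):
            raise ValueError("profile must cover exactly the 14 allergens")
        for v in self.statuses.values():
            if v not in STATUS_ORDER:
                raise ValueError(f"invalid status {v!r}")

    @property
    def n_ingredient(self) -> int:
        return sum(1 for v in self.statuses.values() if v == "ingredient")

    @property
    def n_trace(self) -> int:
        return sum(1 for v in self.statuses.values() if v == "trace")

    @property
    def n_any(self) -> int:
        return sum(1 for v in self.statuses.values() if v != "absent")

    @property
    def contains_any(self) -> bool:
        return self.n_any >= 1

    def allergens(self, scope: str = "any") -> set[str]:
        """Allergen set for a scope: any (!= absent), ingredient, or trace."""
        if scope == "any":
            return {a for a, v in self.statuses.items() if v != "absent"}
        return {a for a, v in self.statuses.items() if v == scope}

    def count(self, scope: str) -> int:
        return {"any": self.n_any, "ingredient": self.n_ingredient,
                "trace": self.n_trace}[scope]


def detect_ingredient_allergens(
    phrases: Sequence[IngredientPhrase],
    contains_statements: Iterable[str],
    lex: AllergenLexicon,
    claims: list | None = None,
    audit: list | None = None,
    fuzzy_threshold: float | None = None,
) -> set[str]:
    """Allergens declared as an ingredient: matched in an ingredient phrase
    (or a parenthetical sub-phrase) or named in a post-list "contains"
    statement."""
    found: set[str] = set()
    for phrase in phrases:
        for p in phrase.iter_all():
            found |= lex.match_allergens(p.text, claims=claims, audit=audit,
                                         fuzzy_threshold=fuzzy_threshold)
    for stmt in contains_statements:
        found |= lex.match_allergens(normalize_text(stmt), claims=claims, audit=audit,
                                     fuzzy_threshold=fuzzy_threshold)
    return found


def detect_precautionary_allergens(
    precaution_texts: Iterable[str],
    lex: AllergenLexicon,
    audit: list | None = None,
) -> set[str]:
    """Allergens named in a precautionary statement carrying a recognized
    trigger phrase.  All trigger variants (traces, shared facility,
    adventitious presence) map to the single trace status."""
    found: set[str] = set()
    for stmt in precaution_texts:
        norm = normalize_text(stmt)
        if not lex.has_trigger(norm):
            continue
        hits = lex.match_allergens(norm, audit=audit)
        if not hits:
            import warnings

            warnings.warn(f"precautionary statement with no recognizable allergen: {stmt!r}",
                          stacklevel=2)
        found |= hits
    return found


def _split_statements(record: FoodRecord, lex: AllergenLexicon) -> tuple[list[str], list[str]]:
    """Partition a record's precaution_texts into post-list "contains"
    statements (ingredient scope) and true precautionary statements."""
    contains, precautionary = [], []
    for stmt in record.precaution_texts:
        norm = normalize_text(stmt)
        if lex.has_trigger(norm):
            precautionary.append(stmt)
        elif lex.is_contains_statement(norm):
            contains.append(stmt)
        else:
            precautionary.append(stmt)  # no trigger: ignored downstream
    return contains, precautionary


def build_profile(record: FoodRecord, lex: AllergenLexicon,
                  audit: list | None = None,
                  fuzzy_threshold: float | None = None) -> AllergenProfile:
    """Build the per-record allergen profile.

    Status precedence per allergen: ingredient > trace > absent; an allergen
    declared both as ingredient and as trace counts once, as ingredient."""
    phrases = split_ingredient_list(normalize_text(record.ingredient_text or ""))
    contains, precautionary = _split_statements(record, lex)
    claims: list[tuple[str, str]] = []
    ing_audit: list | None = [] if audit is not None else None
    trace_audit: list | None = [] if audit is not None else None
    ing = detect_ingredient_allergens(phrases, contains, lex, claims=claims,
                                      audit=ing_audit, fuzzy_threshold=fuzzy_threshold)
    trace = detect_precautionary_allergens(precautionary, lex, audit=trace_audit)
    statuses = {}
    for a in ALLERGENS:
        if a in ing:
            statuses[a] = "ingredient"
        elif a in trace:
            statuses[a] = "trace"
        else:
            statuses[a] = "absent"
    if audit is not None:
        for ev in ing_audit or []:
            audit.append({"product_id": record.product_id, "scope": "ingredient", **ev})
        for ev in trace_audit or []:
            audit.append({"product_id": record.product_id, "scope": "trace", **ev})
        for allergen, pattern in claims:
            audit.append({"product_id": record.product_id, "scope": "claim",
                          "allergen": allergen, "term": pattern, "kind": "exclusion"})
    return AllergenProfile(product_id=record.product_id, statuses=statuses, claims=claims)


class AllergenDetector(BaseEstimator, TransformerMixin):
    """Stateless transformer mapping label text to allergen profiles.

    Parameters
    ----------
    lexicon : None, str, Path or dict
        ``None`` loads the shipped English Annex-II lexicon; a path loads a
        JSON lexicon file; a dict is parsed in place.
    fuzzy_threshold : float or None, default None
        When set, ingredient tokens missing every exact term are also
        matched by edit-distance similarity at this ratio; off by default
        for reproducibility.

    The transformer has no learned state: ``fit`` only loads and validates
    the lexicon (exposed as ``lexicon_``).  ``transform`` accepts a
    RecordSet, a sequence of FoodRecord, or a DataFrame with the record
    column contract, and returns one row per record with the 14 per-allergen
    statuses and the scope counts.
    """

    def __init__(self, lexicon=None, fuzzy_threshold: float | None = None):
        self.lexicon = lexicon
        self.fuzzy_threshold = fuzzy_threshold

    def fit(self, X=None, y=None) -> "AllergenDetector":
        if self.lexicon is None:
            self.lexicon_ = load_default_lexicon()
        elif isinstance(self.lexicon, AllergenLexicon):
            self.lexicon_ = self.lexicon
        elif isinstance(self.lexicon, dict):
            self.lexicon_ = AllergenLexicon.from_dict(self.lexicon)
        else:
            self.lexicon_ = AllergenLexicon.from_json(self.lexicon)
        return self

    def _check_fitted(self):
        if not hasattr(self, "lexicon_"):
            raise RuntimeError("AllergenDetector is not fitted; call fit() first")

    def profile(self, record: FoodRecord, audit: list | None = None) -> AllergenProfile:
        self._check_fitted()
        return build_profile(record, self.lexicon_, audit=audit,
                             fuzzy_threshold=self.fuzzy_threshold)

    def profiles(self, records, audit: list | None = None) -> dict[str, AllergenProfile]:
        self._check_fitted()
        return {r.product_id: self.profile(r, audit=audit)
                for r in _as_records(records)}

    def transform(self, X) -> pd.DataFrame:
        self._check_fitted()
        rows = []
        for rec in _as_records(X):
            prof = self.profile(rec)
            row = {"product_id": rec.product_id}
            row.update(prof.statuses)
            row.update(
                n_ingredient=prof.n_ingredient,
                n_trace=prof.n_trace,
                n_any=prof.n_any,
                contains_any=prof.contains_any,
            )
            rows.append(row)
        cols = ["product_id", *ALLERGENS, "n_ingredient", "n_trace", "n_any", "contains_any"]
        return pd.DataFrame(rows, columns=cols).set_index("product_id")


def _as_records(X) -> list[FoodRecord]:
    if isinstance(X, pd.DataFrame):
        out = []
        for _, row in X.iterrows():
            pre = row.get("precaution_texts", [])
            if isinstance(pre, str):
                pre = json.loads(pre) if pre else []
            out.append(FoodRecord(
                product_id=str(row["product_id"]),
                name=str(row.get("name", "")),
                category=str(row.get("category", "")),
                subcategory=str(row.get("subcategory", "")),
                ingredient_text=row.get("ingredient_text") or None,
                precaution_texts=list(pre),
                ingredient_list_readable=bool(row.get("ingredient_list_readable", True)),
                all_package_sides_available=bool(row.get("all_package_sides_available", True)),
            ))
        return out
    return list(X)
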