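"""Rule-based NOVA processing-grade classification from ingredient lists.

NOVA sorts foods into four groups by the extent and purpose of processing:

* **NOVA1** — unprocessed or minimally processed foods (edible plant or
  animal parts with no or minimal preservation);
* **NOVA2** — culinary ingredients (salt, sugar, oils, starch, butter,
  honey) obtained from NOVA1 foods and sold as such;
* **NOVA3** — processed foods combining multiple ingredients, at least one
  of which is a culinary (NOVA2) ingredient;
* **NOVA4** — ultra-processed foods (UPFs): industrially formulated
  products marked by substances rarely used in kitchens — sweeteners beyond
  plain sugar, flavourings and flavour enhancers, emulsifiers, bulking
  agents, thickeners, antioxidants, protein isolates/concentrates, added
  vitamins/minerals, hydrolyzed or extruded ingredients, and food extracts.

The classifier applies a decision cascade over the parsed ingredient list:

1. any ultra-processing marker (term or E-number) or, when enabled, a
   taxonomy-level industrial-formulation override -> grade 4;
2. else a single-ingredient product (water tolerated alongside) whose sole
   ingredient is culinary -> grade 2;
3. else a multi-ingredient list containing at least one culinary term ->
   grade 3;
4. else -> grade 1.

Ingredient count is recorded in the trace but never decides a grade by
itself.  Plain salt/sugar/oil/starch inside a multi-ingredient recipe route
to NOVA3, not NOVA4; a strict mode (``strict_culinary_markers=True``)
instead treats any added culinary ingredient as an ultra-processing marker,
which collapses NOVA3 into NOVA4.

:class:`NovaClassifier` is the scikit-learn-style surface; module functions
wrap it for one-off use.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .records import FoodRecord, RecordSet
from .text import IngredientPhrase, normalize_text, split_ingredient_list

__all__ = [
    "NOVA_GRADES",
    "MarkerLexicon",
    "ClassificationTrace",
    "ClassificationError",
    "NovaClassifier",
    "load_default_markers",
    "classify_nova",
    "classify_all",
]

NOVA_GRADES = (1, 2, 3, 4)

_ENUM_RE = re.compile(r"(?<![a-z0-9])e[\s.-]?(\d{3,4})[a-z]?(?![a-z0-9])")


class ClassificationError(ValueError):
    """Record cannot be graded (e.g. empty ingredient list after parsing)."""


def _term_pattern(term: str) -> re.Pattern:
    return re.compile(r"(?<!\w)" + re.escape(term) + r"(?!\w)")


@dataclass
class MarkerLexicon:
    """Ultra-processing marker classes, culinary terms and overrides.

    ``marker_classes`` maps class name -> (terms, E-number ranges).
    ``culinary_terms`` are the NOVA2 vocabulary; validated disjoint from
    every marker class.  ``subcategory_overrides`` maps taxonomy subcategory
    -> minimum grade for by-construction formulated subcategories (meat
    analogues, dairy imitations); empty by default and only consulted when
    the classifier enables overrides."""

    name: str
    marker_classes: dict[str, tuple[list[str], list[tuple[int, int]]]]
    culinary_terms: list[str]
    industrial_formulation_cues: list[str] = field(default_factory=list)
    subcategory_overrides: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        culinary = set(self.culinary_terms)
        for cls_name, (terms, _) in self.marker_classes.items():
            overlap = culinary & set(terms)
            if overlap:
                raise ValueError(
                    f"marker class {cls_name!r} overlaps culinary terms: {sorted(overlap)}"
                )
        self._compiled_markers = {
            cls_name: [(_term_pattern(t), t) for t in terms]
            for cls_name, (terms, _) in self.marker_classes.items()
        }
        self._e_ranges = {
            cls_name: ranges for cls_name, (_, ranges) in self.marker_classes.items()
        }
        self._compiled_culinary = [(_term_pattern(t), t) for t in self.culinary_terms]

    @classmethod
    def from_dict(cls, obj: dict, name: str | None = None) -> "MarkerLexicon":
        classes = {
            cname: (
                [normalize_text(t) for t in entry.get("terms", [])],
                [tuple(r) for r in entry.get("e_number_ranges", [])],
            )
            for cname, entry in obj["marker_classes"].items()
        }
        return cls(
            name=name or obj.get("name", "custom"),
            marker_classes=classes,
            culinary_terms=[normalize_text(t) for t in obj.get("culinary_terms", [])],
            industrial_formulation_cues=[normalize_text(t) for t in
                                         obj.get("industrial_formulation_cues", [])],
            subcategory_overrides={k: int(v) for k, v in
                                   obj.get("subcategory_overrides", {}).items()},
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkerLexicon":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def markers_in(self, text: str) -> list[tuple[str, str]]:
        """(matched term, marker class) pairs found in a phrase."""
        hits = []
        enums = [int(m.group(1)) for m in _ENUM_RE.finditer(text)]
        for cls_name, patterns in self._compiled_markers.items():
            for pat, term in patterns:
                if pat.search(text):
                    hits.append((term, cls_name))
                    break
            else:
                for lo, hi in self._e_ranges.get(cls_name, []):
                    matched = [n for n in enums if lo <= n <= hi]
                    if matched:
                        hits.append((f"e{matched[0]}", cls_name))
                        break
        return hits

    def is_culinary(self, text: str) -> bool:
        return any(pat.search(text) for pat, _ in self._compiled_culinary)


def load_default_markers() -> MarkerLexicon:
    """Load the shipped English ultra-processing marker lexicon."""
    text = resources.files("allernova.data").joinpath("nova_markers_en.json").read_text("utf-8")
    return MarkerLexicon.from_dict(json.loads(text))


@dataclass
class ClassificationTrace:
    """Grade plus the evidence that produced it; sufficient to re-derive the
    grade without re-running the cascade."""

    product_id: str
    grade: int
    rule_fired: str
    matched_markers: list[tuple[str, str]] = field(default_factory=list)
    matched_culinary: list[str] = field(default_factory=list)
    n_ingredients: int = 0

    def __post_init__(self):
        if self.grade not in NOVA_GRADES:
            raise ValueError(f"invalid grade {self.grade!r}")
        if (self.grade == 4) != (bool(self.matched_markers)
                                 or self.rule_fired == "nova4_override"):
            raise ValueError("grade 4 iff markers matched or override fired")


class NovaClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based NOVA grade classifier.

    Parameters
    ----------
    markers : None, str, Path, dict or MarkerLexicon
        ``None`` loads the shipped marker lexicon.
    strict_culinary_markers : bool, default False
        Treat plain added salt/sugar/oil/starch as ultra-processing markers
        (the literal reading of the marker list).  Off by default: culinary
        ingredients in a multi-ingredient recipe route to NOVA3.
    use_subcategory_overrides : bool, default False
        Force by-construction formulated subcategories to a minimum grade
        via the lexicon's override table.

    ``fit`` loads/validates the lexicon (``markers_``) and sets
    ``classes_``; ``predict`` maps records to grades 1-4.
    """

    def __init__(self, markers=None, strict_culinary_markers: bool = False,
                 use_subcategory_overrides: bool = False):
        self.markers = markers
        self.strict_culinary_markers = strict_culinary_markers
        self.use_subcategory_overrides = use_subcategory_overrides

    def fit(self, X=None, y=None) -> "NovaClassifier":
        if self.markers is None:
            self.markers_ = load_default_markers()
        elif isinstance(self.markers, MarkerLexicon):
            self.markers_ = self.markers
        elif isinstance(self.markers, dict):
            self.markers_ = MarkerLexicon.from_dict(self.markers)
        else:
            self.markers_ = MarkerLexicon.from_json(self.markers)
        self.classes_ = np.array(NOVA_GRADES)
        return self

    def _check_fitted(self):
        if not hasattr(self, "markers_"):
            raise RuntimeError("NovaClassifier is not fitted; call fit() first")

    def classify(self, record: FoodRecord) -> ClassificationTrace:
        """Run the decision cascade on one record."""
        self._check_fitted()
        lex = self.markers_
        phrases = split_ingredient_list(normalize_text(record.ingredient_text or ""))
        if not phrases:
            raise ClassificationError(
                f"{record.product_id}: empty ingredient list after parsing "
                "(record should have been excluded)"
            )
        matched_markers: list[tuple[str, str]] = []
        matched_culinary: list[str] = []
        for phrase in phrases:
            for p in phrase.iter_all():
                matched_markers.extend(lex.markers_in(p.text))
            if lex.is_culinary(phrase.text):
                matched_culinary.append(phrase.text)

        if self.strict_culinary_markers and len(phrases) > 1:
            # literal mode: any added culinary ingredient is itself a marker
            matched_markers.extend((c, "added_culinary") for c in matched_culinary)

        n = len(phrases)
        if matched_markers:
            return ClassificationTrace(record.product_id, 4, "nova4_marker",
                                       matched_markers, matched_culinary, n)
        if self.use_subcategory_overrides:
            floor = lex.subcategory_overrides.get(record.subcategory)
            if floor == 4:
                return ClassificationTrace(record.product_id, 4, "nova4_override",
                                           [], matched_culinary, n)
        non_water = [p for p in phrases if p.text != "water"]
        if len(non_water) == 1 and lex.is_culinary(non_water[0].text):
            return ClassificationTrace(record.product_id, 2, "culinary_single",
                                       [], matched_culinary, n)
        if len(phrases) > 1 and matched_culinary:
            return ClassificationTrace(record.product_id, 3, "processed_multi",
                                       [], matched_culinary, n)
        return ClassificationTrace(record.product_id, 1, "minimally_processed",
                                   [], matched_culinary, n)

    def classify_all(self, records) -> dict[str, ClassificationTrace]:
        """Classify every record; per-record errors propagate with the id."""
        self._check_fitted()
        return {r.product_id: self.classify(r) for r in records}

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        records = X.records if isinstance(X, RecordSet) else list(X)
        return np.array([self.classify(r).grade for r in records])

    def trace_frame(self, records) -> pd.DataFrame:
        """Per-record grade + rule table (CLI export shape)."""
        traces = self.classify_all(records)
        return pd.DataFrame(
            [
                {
                    "product_id": t.product_id,
                    "nova_grade": t.grade,
                    "rule_fired": t.rule_fired,
                    "n_ingredients": t.n_ingredients,
                    "matched_markers": ";".join(f"{m}:{c}" for m, c in t.matched_markers),
                }
                for t in traces.values()
            ]
        )


def classify_nova(record: FoodRecord, markers: MarkerLexicon | None = None,
                  **kwargs) -> ClassificationTrace:
    """Classify one record (convenience wrapper over NovaClassifier)."""
    return NovaClassifier(markers=markers, **kwargs).fit().classify(record)


def classify_all(rs, markers: MarkerLexicon | None = None,
                 **kwargs) -> dict[str, ClassificationTrace]:
    """Classify a record set (convenience wrapper over NovaClassifier)."""
    return NovaClassifier(markers=markers, **kwargs).fit().classify_all(rs)
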