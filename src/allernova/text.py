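"""Text normalization and ingredient-list parsing for packaged-food labels.

Label text arrives as free text in mixed case, with accents (Greek labels in
particular), percentage annotations ("hazelnuts (13%)") and nested
parenthetical sub-ingredients ("emulsifier: lecithins (soy)").  Everything
downstream (allergen matching, processing-grade rules) operates on the
normalized, tokenized form produced here.
"""

from __future__ import annotations

import re
import unicodedata
import warnings
from dataclasses import dataclass, field

__all__ = ["IngredientPhrase", "normalize_text", "split_ingredient_list"]

_WS_RE = re.compile(r"\s+")
_PCT_RE = re.compile(r"\(?\s*(\d+(?:[.,]\d+)?)\s*%\s*\)?")
# unify typographic punctuation to ASCII before folding
_PUNCT_MAP = str.maketrans({
    "\u2019": "'", "\u2018": "'", "\u201c": '"', "\u201d": '"',
    "\u2013": "-", "\u2014": "-", "\u2022": " ",
    "\uff0c": ",", "\uff1b": ";",
})


def normalize_text(raw: str) -> str:
    """Normalize free label text for matching.

    Lowercases, folds accents/diacritics (NFKD decomposition with combining
    marks stripped, so Greek tonos marks fold too), unifies typographic
    punctuation to ASCII and collapses whitespace.  Deterministic and
    idempotent.
    """
    if not raw:
        return ""
    text = raw.translate(_PUNCT_MAP)
    text = unicodedata.normalize("NFKD", text)
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    # Greek final sigma normalizes to sigma so word forms compare equal
    text = text.lower().replace("ς", "σ")
    text = _WS_RE.sub(" ", text).strip()
    # no space before list punctuation
    text = re.sub(r"\s+([,;:)])", r"\1", text)
    return text


@dataclass
class IngredientPhrase:
    """One ingredient phrase from a label's ingredient list.

    ``text`` is the full normalized phrase (percentages stripped),
    ``children`` are parenthetical sub-ingredients exposed as phrases of
    their own, and ``percentage`` keeps any stripped "x%" annotation.
    """

    text: str
    children: list["IngredientPhrase"] = field(default_factory=list)
    percentage: float | None = None
    raw: str = ""

    def iter_all(self):
        """Yield this phrase and all nested sub-phrases, depth first."""
        yield self
        for child in self.children:
            yield from child.iter_all()


def _strip_percentage(text: str) -> tuple[str, float | None]:
    m = _PCT_RE.search(text)
    pct = None
    if m:
        pct = float(m.group(1).replace(",", "."))
        text = (text[: m.start()] + " " + text[m.end():]).strip()
        text = _WS_RE.sub(" ", text)
    return text.strip(" ,;"), pct


def _split_top_level(text: str, seps: str = ",;") -> list[str]:
    """Split on separators not enclosed in parentheses or brackets."""
    parts, depth, buf = [], 0, []
    for ch in text:
        if ch in "([":
            depth += 1
        elif ch in ")]":
            depth = max(0, depth - 1)
        if ch in seps and depth == 0:
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    parts.append("".join(buf))
    return [p.strip() for p in parts if p.strip()]


_PAREN_RE = re.compile(r"[(\[]([^()\[\]]*)[)\]]")


def split_ingredient_list(text: str) -> list[IngredientPhrase]:
    """Split a normalized ingredient list into ordered phrases.

    Splits on top-level commas and semicolons.  Parenthetical
    sub-ingredients stay inside the parent phrase text and are additionally
    exposed as ``children`` (recursively split on commas).  Additive-function
    prefixes ("emulsifier: lecithins") remain part of the phrase.
    Percentage annotations are stripped from the matching text but preserved
    on the phrase.  Unbalanced parentheses trigger a warning and a
    best-effort split.
    """
    if not text:
        return []
    if text.count("(") != text.count(")"):
        warnings.warn("unbalanced parentheses in ingredient list; best-effort split",
                      stacklevel=2)
    phrases: list[IngredientPhrase] = []
    for part in _split_top_level(text):
        raw = part
        stripped, pct = _strip_percentage(part)
        if not stripped:
            continue
        children: list[IngredientPhrase] = []
        for m in _PAREN_RE.finditer(stripped):
            inner = m.group(1).strip()
            if not inner or _PCT_RE.fullmatch("(" + inner + ")"):
                continue
            for sub in _split_top_level(inner):
                sub_clean, sub_pct = _strip_percentage(sub)
                if sub_clean:
                    children.append(
                        IngredientPhrase(text=sub_clean, percentage=sub_pct, raw=sub)
                    )
        phrases.append(
            IngredientPhrase(text=stripped, children=children, percentage=pct, raw=raw)
        )
    return phrases
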