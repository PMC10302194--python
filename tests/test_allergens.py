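import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from allernova import ALLERGENS, AllergenDetector, AllergenLexicon, build_profile
from allernova.allergens import (
    STATUS_ORDER,
    detect_ingredient_allergens,
    detect_precautionary_allergens,
)
from allernova.text import normalize_text, split_ingredient_list


def _phrases(text):
    return split_ingredient_list(normalize_text(text))


class TestLexicon:
    def test_default_lexicon_covers_all_14(self, detector):
        lex = detector.lexicon_
        assert set(lex.terms) == set(ALLERGENS)
        for a in ALLERGENS:
            assert any(kind == "canonical" for _, kind in lex.terms[a])

    def test_lexicon_missing_allergen_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            AllergenLexicon.from_dict({
                "allergens": {"milk": {"canonical_terms": ["milk"]}},
                "trigger_phrases": ["may contain"],
            })

    def test_lexicon_without_canonical_term_rejected(self, detector):
        obj = {
            "allergens": {a: {"canonical_terms": [a]} for a in ALLERGENS},
            "trigger_phrases": ["may contain"],
        }
        obj["allergens"]["milk"] = {"canonical_terms": [], "derivative_terms": ["whey"]}
        with pytest.raises(ValueError, match="canonical"):
            AllergenLexicon.from_dict(obj)


class TestIngredientDetection:
    @pytest.mark.parametrize(
        "text, expected",
        [
            (
                "wheat flour, sugar, hazelnuts, skimmed milk powder, whey powder, "
                "emulsifier: lecithins (soy)",
                {"gluten_cereals", "tree_nuts", "milk", "soybeans"},
            ),
            ("water, salt", set()),
            ("spelt, tahini", {"gluten_cereals", "sesame"}),  # derivative terms
            ("preservative: E223, apricots", {"sulphites"}),  # E-number range
            ("coconut, nutmeg", set()),  # no whole-word match on "nut"
            ("peanuts, almonds", {"peanuts", "tree_nuts"}),
        ],
    )
    def test_detects_terms_and_derivatives(self, detector, text, expected):
        found = detect_ingredient_allergens(_phrases(text), [], detector.lexicon_)
        assert found == expected

    def test_contains_statement_counts_as_ingredient(self, detector, make_record):
        rec = make_record("cocoa mass, sugar", ["Contains milk and soy"])
        prof = detector.profile(rec)
        assert prof.statuses["milk"] == "ingredient"
        assert prof.statuses["soybeans"] == "ingredient"

    def test_allergen_free_claim_suppresses_claimed_term_only(self, detector):
        claims = []
        found = detect_ingredient_allergens(
            _phrases("gluten-free oat flakes"), [], detector.lexicon_, claims=claims)
        # the oat term still maps to gluten cereals; the claim is logged
        assert found == {"gluten_cereals"}
        assert ("gluten_cereals", "gluten-free") in claims

    def test_claim_never_suppresses_other_allergens(self, detector):
        found = detect_ingredient_allergens(
            _phrases("gluten-free biscuit mix, milk"), [], detector.lexicon_)
        assert "milk" in found

    def test_cocoa_butter_is_not_milk(self, detector):
        found = detect_ingredient_allergens(
            _phrases("cocoa butter, cocoa mass"), [], detector.lexicon_)
        assert "milk" not in found

    def test_butter_is_milk(self, detector):
        found = detect_ingredient_allergens(_phrases("butter"), [], detector.lexicon_)
        assert found == {"milk"}


class TestPrecautionaryDetection:
    @pytest.mark.parametrize(
        "statements, expected",
        [
            (["may contain traces of nuts and sesame"], {"tree_nuts", "sesame"}),
            ([], set()),
            (["manufactured in a facility that also processes peanuts"], {"peanuts"}),
            (["milk may be present"], {"milk"}),
            (["store in a cool dry place"], set()),  # no trigger
        ],
    )
    def test_trigger_variants(self, detector, statements, expected):
        assert detect_precautionary_allergens(statements, detector.lexicon_) == expected

    def test_trigger_without_recognizable_allergen_warns(self, detector):
        with pytest.warns(UserWarning, match="no recognizable allergen"):
            found = detect_precautionary_allergens(
                ["may contain traces of happiness"], detector.lexicon_)
        assert found == set()


class TestProfile:
    def test_ingredient_precedence_over_trace(self, detector, make_record):
        rec = make_record("milk, cocoa", ["may contain traces of milk and nuts"])
        prof = detector.profile(rec)
        assert prof.statuses["milk"] == "ingredient"
        assert prof.statuses["tree_nuts"] == "trace"
        assert prof.n_ingredient == 1 and prof.n_trace == 1 and prof.n_any == 2

    def test_no_matches_all_absent(self, detector, make_record):
        prof = detector.profile(make_record("water, salt"))
        assert prof.n_any == 0
        assert not prof.contains_any

    def test_saturation_all_14_as_ingredients(self, detector, make_record):
        text = ("wheat, shrimp, egg, cod, peanuts, soy, milk, almonds, celery, "
                "mustard, sesame, sulphites, lupin, mussels")
        prof = detector.profile(make_record(text))
        assert prof.n_ingredient == 14
        assert prof.n_trace == 0

    def test_counts_identity(self, detector, make_record):
        prof = detector.profile(
            make_record("milk, wheat flour", ["may contain traces of soy"]))
        assert prof.n_any == prof.n_ingredient + prof.n_trace
        assert prof.contains_any == (prof.n_any >= 1)

    def test_determinism(self, detector, make_record):
        rec = make_record("milk, hazelnuts (10%)", ["may contain traces of soy"])
        p1, p2 = detector.profile(rec), detector.profile(rec)
        assert p1.statuses == p2.statuses


ALLERGEN_TERMS = ["milk", "wheat flour", "hazelnuts", "soy", "egg", "tahini",
                  "water", "salt", "tomatoes", "cod", "mustard"]


class TestMonotonicity:
    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        base=st.lists(st.sampled_from(ALLERGEN_TERMS), min_size=1, max_size=6),
        extra=st.sampled_from(ALLERGEN_TERMS),
    )
    def test_adding_a_phrase_never_removes_an_allergen(self, detector, base, extra):
        lex = detector.lexicon_
        before = detect_ingredient_allergens(_phrases(", ".join(base)), [], lex)
        after = detect_ingredient_allergens(_phrases(", ".join(base + [extra])), [], lex)
        assert before <= after

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(base=st.lists(st.sampled_from(ALLERGEN_TERMS), min_size=1, max_size=6))
    def test_status_is_max_under_precedence_order(self, detector, base):
        from allernova import FoodRecord

        rec = FoodRecord("P1", "x", "Grain or grain product", "Fine bakery ware",
                         ", ".join(base), ["may contain traces of nuts"])
        lex = detector.lexicon_
        ing = detect_ingredient_allergens(_phrases(normalize_text(rec.ingredient_text)), [], lex)
        trace = detect_precautionary_allergens(rec.precaution_texts, lex)
        prof = build_profile(rec, lex)
        for a in ALLERGENS:
            candidates = ["absent"]
            if a in trace:
                candidates.append("trace")
            if a in ing:
                candidates.append("ingredient")
            assert prof.statuses[a] == max(candidates, key=STATUS_ORDER.get)


class TestSklearnSurface:
    def test_get_set_params_and_clone(self):
        det = AllergenDetector(lexicon=None)
        assert det.get_params() == {"lexicon": None, "fuzzy_threshold": None}
        cloned = clone(det)
        assert cloned.get_params() == det.get_params()

    def test_fuzzy_matching_off_by_default_and_opt_in(self, make_record):
        rec = make_record("hazlenuts, water")  # misspelled hazelnuts
        exact = AllergenDetector().fit()
        assert exact.profile(rec).statuses["tree_nuts"] == "absent"
        fuzzy = AllergenDetector(fuzzy_threshold=0.85).fit()
        assert fuzzy.profile(rec).statuses["tree_nuts"] == "ingredient"

    def test_transform_frame_shape(self, detector, make_record):
        recs = [make_record("milk", product_id="A"),
                make_record("water", product_id="B")]
        frame = detector.transform(recs)
        assert list(frame.index) == ["A", "B"]
        assert frame.loc["A", "milk"] == "ingredient"
        assert frame.loc["B", "n_any"] == 0
        assert set(ALLERGENS) <= set(frame.columns)

    def test_unfitted_raises(self, make_record):
        with pytest.raises(RuntimeError, match="not fitted"):
            AllergenDetector().profile(make_record("milk"))
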