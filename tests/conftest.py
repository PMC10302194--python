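import pytest

from allernova import AllergenDetector, FoodRecord, NovaClassifier


@pytest.fixture(scope="session")
def detector():
    return AllergenDetector().fit()


@pytest.fixture(scope="session")
def classifier():
    return NovaClassifier().fit()


@pytest.fixture
def make_record():
    def _make(ingredients, precautions=(), subcategory="Fine bakery ware",
              category="Grain or grain product", product_id="P1", **kwargs):
        return FoodRecord(
            product_id=product_id,
            name="test product",
            category=category,
            subcategory=subcategory,
            ingredient_text=ingredients,
            precaution_texts=list(precautions),
            **kwargs,
        )

    return _make
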