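"""Branded-food record model, market taxonomy, readers/writers and the
exclusion filter that defines the analyzable record set.

A record is one packaged product as captured from its label: its position in
a category/subcategory taxonomy, the free-text ingredient list, any
precautionary ("may contain") statements, and two completeness flags that
drive the exclusion step — whether an image with a readable ingredient list
existed, and whether all sides of the package were imaged (precautionary
statements can sit on any side, so partial imaging means allergen data may
be incomplete).
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Taxonomy",
    "FoodRecord",
    "RecordSet",
    "ExclusionLog",
    "SchemaError",
    "TaxonomyError",
    "RecordValidationError",
    "load_default_taxonomy",
    "read_records",
    "write_records",
    "apply_exclusions",
]

CSV_COLUMNS = [
    "product_id",
    "name",
    "category",
    "subcategory",
    "ingredient_text",
    "precaution_texts",
    "ingredient_list_readable",
    "all_package_sides_available",
]


class SchemaError(ValueError):
    """Input file does not conform to the documented column/key schema."""


class TaxonomyError(ValueError):
    """A record references a category/subcategory unknown to the taxonomy."""


class RecordValidationError(ValueError):
    """A record is internally contradictory (e.g. readable list but no text)."""


@dataclass(frozen=True)
class Taxonomy:
    """Two-level market taxonomy: ordered categories, each with ordered
    subcategories.  Shipped default is a 13-category / 41-subcategory
    branded-food scheme; alternative market taxonomies load from JSON."""

    name: str
    categories: tuple[str, ...]
    subcategories: tuple[tuple[str, str], ...]  # (subcategory, parent category)

    def __post_init__(self):
        if len(set(self.categories)) != len(self.categories):
            raise TaxonomyError("duplicate category names")
        subs = [s for s, _ in self.subcategories]
        if len(set(subs)) != len(subs):
            raise TaxonomyError("duplicate subcategory names")
        for sub, parent in self.subcategories:
            if parent not in self.categories:
                raise TaxonomyError(f"subcategory {sub!r} has unknown parent {parent!r}")

    @property
    def subcategory_names(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.subcategories)

    def parent_of(self, subcategory: str) -> str:
        for sub, parent in self.subcategories:
            if sub == subcategory:
                return parent
        raise TaxonomyError(f"unknown subcategory: {subcategory!r}")

    def subcategories_of(self, category: str) -> tuple[str, ...]:
        if category not in self.categories:
            raise TaxonomyError(f"unknown category: {category!r}")
        return tuple(s for s, p in self.subcategories if p == category)

    @classmethod
    def from_mapping(cls, mapping: dict[str, list[str]], name: str = "custom") -> "Taxonomy":
        cats = tuple(mapping.keys())
        subs = tuple((s, c) for c, ss in mapping.items() for s in ss)
        return cls(name=name, categories=cats, subcategories=subs)

    @classmethod
    def from_json(cls, path: str | Path) -> "Taxonomy":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls.from_mapping(obj["categories"], name=obj.get("name", Path(path).stem))


def load_default_taxonomy() -> Taxonomy:
    """Load the shipped 13-category / 41-subcategory branded-food taxonomy."""
    text = resources.files("allernova.data").joinpath("taxonomy_branded_gr.json").read_text("utf-8")
    obj = json.loads(text)
    return Taxonomy.from_mapping(obj["categories"], name=obj.get("name", "default"))


@dataclass
class FoodRecord:
    """One packaged product as read from its label."""

    product_id: str
    name: str
    category: str
    subcategory: str
    ingredient_text: str | None
    precaution_texts: list[str] = field(default_factory=list)
    ingredient_list_readable: bool = True
    all_package_sides_available: bool = True

    def validate(self, taxonomy: Taxonomy | None = None) -> None:
        if not self.product_id:
            raise RecordValidationError("empty product_id")
        if self.ingredient_list_readable and not self.ingredient_text:
            raise RecordValidationError(
                f"{self.product_id}: ingredient list flagged readable but no ingredient_text"
            )
        if taxonomy is not None:
            parent = taxonomy.parent_of(self.subcategory)
            if parent != self.category:
                raise TaxonomyError(
                    f"{self.product_id}: subcategory {self.subcategory!r} belongs to "
                    f"{parent!r}, not {self.category!r}"
                )


@dataclass
class RecordSet:
    """Ordered collection of food records with stable iteration order."""

    records: list[FoodRecord]
    provenance: str = ""

    def __post_init__(self):
        ids = [r.product_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise RecordValidationError(f"duplicate product_id(s): {dup[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[FoodRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def by_id(self, product_id: str) -> FoodRecord:
        for r in self.records:
            if r.product_id == product_id:
                return r
        raise KeyError(product_id)


@dataclass
class ExclusionLog:
    """Bookkeeping for the exclusion filter.

    A record failing both criteria is counted once, under the unreadable
    ingredient list (exclusions are applied sequentially: readability first,
    then complete package imaging)."""

    n_input: int
    n_unreadable_excluded: int
    n_incomplete_package_excluded: int
    n_retained: int
    excluded_ids: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        expected = self.n_input - self.n_unreadable_excluded - self.n_incomplete_package_excluded
        if self.n_retained != expected:
            raise ValueError(
                f"inconsistent exclusion log: {self.n_input} - "
                f"{self.n_unreadable_excluded} - {self.n_incomplete_package_excluded} "
                f"!= {self.n_retained}"
            )


def apply_exclusions(rs: RecordSet) -> tuple[RecordSet, ExclusionLog]:
    """Retain records with a readable ingredient list AND complete package
    imaging; log the rest with one reason each (unreadable takes precedence).

    Idempotent: applying it to its own output excludes nothing."""
    retained: list[FoodRecord] = []
    excluded: list[tuple[str, str]] = []
    n_unreadable = n_incomplete = 0
    for rec in rs.records:
        if not rec.ingredient_list_readable:
            excluded.append((rec.product_id, "unreadable_ingredient_list"))
            n_unreadable += 1
        elif not rec.all_package_sides_available:
            excluded.append((rec.product_id, "incomplete_package_imaging"))
            n_incomplete += 1
        else:
            retained.append(rec)
    log = ExclusionLog(
        n_input=len(rs),
        n_unreadable_excluded=n_unreadable,
        n_incomplete_package_excluded=n_incomplete,
        n_retained=len(retained),
        excluded_ids=excluded,
    )
    out = RecordSet(records=retained, provenance=f"{rs.provenance} [exclusions applied]".strip())
    return out, log


# ---------------------------------------------------------------------------
# readers / writers


def _parse_bool(value: str, column: str, row: int) -> bool:
    v = value.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise SchemaError(f"row {row}: column {column!r} is not a boolean: {value!r}")


def _encode_precautions(texts: list[str], dialect: str) -> str:
    if dialect == "json":
        return json.dumps(texts, ensure_ascii=False)
    return "|".join(texts)


def _decode_precautions(raw: str, dialect: str) -> list[str]:
    if not raw:
        return []
    if dialect == "json":
        out = json.loads(raw)
        if not isinstance(out, list):
            raise SchemaError("precaution_texts must be a JSON array")
        return [str(x) for x in out]
    return [p for p in raw.split("|") if p]


def read_records(
    path: str | Path,
    format: str | None = None,
    taxonomy: Taxonomy | None = None,
    precaution_dialect: str = "json",
    permissive_taxonomy: bool = False,
) -> RecordSet:
    """Read a record set from CSV or JSON.

    ``format`` defaults from the file extension.  With a taxonomy given,
    unknown subcategories raise :class:`TaxonomyError` unless
    ``permissive_taxonomy`` is set, in which case offending records are
    dropped to ``rs.quarantined``-style bookkeeping in provenance.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt not in ("csv", "json"):
        raise ValueError(f"unsupported format: {fmt!r}")
    rows: list[dict]
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            missing = [c for c in CSV_COLUMNS if c not in (reader.fieldnames or [])]
            if missing:
                raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
            rows = list(reader)
    else:
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise SchemaError("JSON record file must be an array of objects")
        rows = []
        for i, obj in enumerate(data):
            missing = [c for c in CSV_COLUMNS if c not in obj]
            if missing:
                raise SchemaError(f"object {i}: missing key(s): {', '.join(missing)}")
            rows.append(obj)

    records: list[FoodRecord] = []
    offenders: list[str] = []
    for i, row in enumerate(rows):
        if fmt == "csv":
            precautions = _decode_precautions(row["precaution_texts"], precaution_dialect)
            readable = _parse_bool(row["ingredient_list_readable"], "ingredient_list_readable", i)
            complete = _parse_bool(row["all_package_sides_available"], "all_package_sides_available", i)
            ingredient_text = row["ingredient_text"] or None
        else:
            precautions = [str(x) for x in (row["precaution_texts"] or [])]
            readable = bool(row["ingredient_list_readable"])
            complete = bool(row["all_package_sides_available"])
            ingredient_text = row["ingredient_text"] or None
        rec = FoodRecord(
            product_id=str(row["product_id"]),
            name=str(row["name"]),
            category=str(row["category"]),
            subcategory=str(row["subcategory"]),
            ingredient_text=ingredient_text,
            precaution_texts=precautions,
            ingredient_list_readable=readable,
            all_package_sides_available=complete,
        )
        if taxonomy is not None:
            try:
                rec.validate(taxonomy)
            except TaxonomyError as err:
                if permissive_taxonomy:
                    offenders.append(rec.product_id)
                    continue
                offenders.append(f"{rec.product_id} ({rec.subcategory})")
                continue
        else:
            rec.validate()
        records.append(rec)
    if offenders and not permissive_taxonomy:
        raise TaxonomyError(f"records off taxonomy: {offenders}")
    prov = str(path)
    if offenders:
        prov += f" [quarantined {len(offenders)} off-taxonomy records]"
    return RecordSet(records=records, provenance=prov)


def write_records(
    rs: RecordSet,
    path: str | Path,
    format: str | None = None,
    precaution_dialect: str = "json",
) -> None:
    """Write a record set to CSV or JSON so that reading it back reproduces
    the set exactly (text fields byte-preserved, UTF-8)."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=CSV_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for r in rs.records:
            writer.writerow({
                "product_id": r.product_id,
                "name": r.name,
                "category": r.category,
                "subcategory": r.subcategory,
                "ingredient_text": r.ingredient_text or "",
                "precaution_texts": _encode_precautions(r.precaution_texts, precaution_dialect),
                "ingredient_list_readable": str(r.ingredient_list_readable).lower(),
                "all_package_sides_available": str(r.all_package_sides_available).lower(),
            })
        path.write_text(buf.getvalue(), encoding="utf-8")
    elif fmt == "json":
        objs = [
            {
                "product_id": r.product_id,
                "name": r.name,
                "category": r.category,
                "subcategory": r.subcategory,
                "ingredient_text": r.ingredient_text,
                "precaution_texts": r.precaution_texts,
                "ingredient_list_readable": r.ingredient_list_readable,
                "all_package_sides_available": r.all_package_sides_available,
            }
            for r in rs.records
        ]
        path.write_text(
            json.dumps(objs, ensure_ascii=False, indent=1) + "\n", encoding="utf-8"
        )
    else:
        raise ValueError(f"unsupported format: {fmt!r}")
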