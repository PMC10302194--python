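"""Prevalence statistics for allergens across NOVA processing grades.

The analysis layer is nested: within every food subcategory, foods are split
by NOVA grade and allergen presence (for a scope: ingredient, trace, or
either) is tabulated as a grades x {present, absent} contingency table.
Differences between grades are tested with Pearson's chi-square (no
continuity correction; df = number of grades - 1) at a 0.01 significance
level.  A subcategory is not testable ("n.a.") when it holds a single NOVA
grade, or when prevalence is uniformly 100% or uniformly 0% across its
grades; the degeneracy rule is evaluated on the either-scope table.

Besides the per-subcategory table the module computes per-grade
allergen-count histograms and means (over all foods, and over declaring
foods only — both conventions are always computed; reports use the
all-foods mean for the either/ingredient scopes and the declaring-foods
mean for the trace scope), and distinct-allergen diversity sets per
(subcategory, grade) cell with a pooled NOVA1-3 comparator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .allergens import ALLERGENS, AllergenProfile
from .records import TaxonomyError

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "GroupCountSummary",
    "PrevalenceReport",
    "build_contingency",
    "pearson_chi_square",
    "analyze_tables",
    "prevalence_report",
    "count_summary",
    "diversity_report",
    "round_half_up",
    "format_pct",
    "format_p",
]

SCOPES = ("any", "ingredient", "trace")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (label-table convention, unlike banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_pct(n_present: int, n: int) -> str:
    """Percentage at one decimal, half-up; exact 100 prints as "100"."""
    if n == 0:
        return "n.a."
    pct = round_half_up(100.0 * n_present / n, 1)
    if pct == int(pct) and pct in (0.0, 100.0) and n_present in (0, n):
        return f"{pct:.1f}" if pct == 0.0 else "100"
    return f"{pct:.1f}"


def format_p(p: float, threshold: float = 0.005) -> str:
    """Render a p-value at 3 d.p.; values rounding below ``threshold``
    render as "<0.01" (so 0.009 prints as 0.009, 0.004 as "<0.01")."""
    if not math.isfinite(p):
        return "n.a."
    r = round_half_up(p, 3)
    if r < threshold:
        return "<0.01"
    return f"{r:.3f}"


@dataclass
class ContingencyTable:
    """NOVA-grade x allergen-presence counts for one subcategory."""

    subcategory: str
    rows: list[tuple[int, int, int]]  # (grade, n_present, n_absent), grade order
    category: str = ""
    scope: str = "any"

    def __post_init__(self):
        if not self.rows:
            raise ValueError(f"{self.subcategory}: contingency table needs >=1 row")
        for g, p, a in self.rows:
            if p < 0 or a < 0:
                raise ValueError("negative cell count")
            if p + a == 0:
                raise ValueError(f"grade {g}: empty group row")
        grades = [g for g, _, _ in self.rows]
        if grades != sorted(grades) or len(set(grades)) != len(grades):
            raise ValueError("rows must be unique and in grade order")

    @property
    def n(self) -> int:
        return sum(p + a for _, p, a in self.rows)

    def group_size(self, grade: int) -> int:
        for g, p, a in self.rows:
            if g == grade:
                return p + a
        raise KeyError(grade)


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    applicable: bool
    na_reason: str = "none"  # single_group | degenerate_prevalence | none

    def __post_init__(self):
        if self.applicable != (self.na_reason == "none"):
            raise ValueError("applicable flag inconsistent with na_reason")


def pearson_chi_square(t: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square on a grades x presence table, no continuity
    correction, df = rows - 1.

    Not applicable when the table has one grade row (``single_group``) or
    when every row is at 100% or every row at 0% prevalence
    (``degenerate_prevalence``; also covers any zero expected count)."""
    r = len(t.rows)
    if r == 1:
        return ChiSquareResult(math.nan, 0, math.nan, False, "single_group")
    if all(a == 0 for _, _, a in t.rows) or all(p == 0 for _, p, _ in t.rows):
        return ChiSquareResult(math.nan, 0, math.nan, False, "degenerate_prevalence")
    obs = np.array([[p, a] for _, p, a in t.rows], dtype=float)
    if (obs.sum(axis=0) == 0).any():  # defensive; unreachable given the guards
        return ChiSquareResult(math.nan, 0, math.nan, False, "degenerate_prevalence")
    stat, p_value, df, _ = chi2_contingency(obs, correction=False)
    return ChiSquareResult(float(stat), int(df), float(p_value), True, "none")


def _presence(profile: AllergenProfile, scope: str) -> bool:
    return profile.count(scope) >= 1


def build_contingency(records, profiles: dict[str, AllergenProfile],
                      grades: dict[str, int], subcategory: str,
                      scope: str = "any", strict: bool = True) -> ContingencyTable:
    """Tabulate one subcategory's grades x presence counts for a scope.

    ``grades`` maps product_id to NOVA grade (ints or objects with a
    ``grade`` attribute).  With ``strict``, an unknown/empty subcategory
    raises; otherwise an empty table error is converted to a single
    empty-row error upstream."""
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}")
    cells: dict[int, list[int]] = {}
    category = ""
    n_seen = 0
    for rec in records:
        if rec.subcategory != subcategory:
            continue
        n_seen += 1
        category = rec.category
        g = grades[rec.product_id]
        g = getattr(g, "grade", g)
        present = _presence(profiles[rec.product_id], scope)
        cell = cells.setdefault(g, [0, 0])
        cell[0 if present else 1] += 1
    if n_seen == 0:
        if strict:
            raise TaxonomyError(f"no records in subcategory {subcategory!r}")
        return ContingencyTable(subcategory, [], scope=scope)  # raises: documented
    rows = [(g, cells[g][0], cells[g][1]) for g in sorted(cells)]
    return ContingencyTable(subcategory, rows, category=category, scope=scope)


def analyze_tables(tables: list[ContingencyTable],
                   alpha: float = 0.01) -> list[tuple[ContingencyTable, ChiSquareResult]]:
    """Run the chi-square test with n.a. rules over a list of tables."""
    out = []
    for t in tables:
        out.append((t, pearson_chi_square(t)))
    return out


@dataclass
class PrevalenceReport:
    """Nested prevalence table plus the significance summary."""

    frame: pd.DataFrame
    alpha: float
    n_subcategories: int
    n_testable: int
    n_significant: int
    significant_subcategories: list[str] = field(default_factory=list)


def prevalence_report_from_tables(tables: list[ContingencyTable],
                                  alpha: float = 0.01,
                                  bonferroni: bool = False) -> PrevalenceReport:
    """Build the published-table-shaped report from prepared tables."""
    results = analyze_tables(tables, alpha=alpha)
    n_testable = sum(1 for _, r in results if r.applicable)
    threshold = alpha / n_testable if (bonferroni and n_testable) else alpha
    rows = []
    significant = []
    for t, r in results:
        if r.applicable and r.p_value < threshold:
            significant.append(t.subcategory)
        for i, (g, p, a) in enumerate(t.rows):
            rows.append({
                "category": t.category,
                "subcategory": t.subcategory,
                "nova_group": g,
                "n": p + a,
                "n_present": p,
                "pct": format_pct(p, p + a),
                "p_value": (format_p(r.p_value) if r.applicable else "n.a.") if i == 0 else "",
            })
    frame = pd.DataFrame(rows, columns=["category", "subcategory", "nova_group",
                                        "n", "n_present", "pct", "p_value"])
    return PrevalenceReport(
        frame=frame,
        alpha=alpha,
        n_subcategories=len(tables),
        n_testable=n_testable,
        n_significant=len(significant),
        significant_subcategories=significant,
    )


def prevalence_report(records, profiles: dict[str, AllergenProfile],
                      grades: dict[str, int], alpha: float = 0.01,
                      scope: str = "any", taxonomy=None,
                      bonferroni: bool = False) -> PrevalenceReport:
    """Per-subcategory prevalence report from record-level inputs.

    Subcategories appear in taxonomy order when a taxonomy is given, else in
    first-appearance order.  No multiple-testing correction by default (the
    per-subcategory tests are reported at ``alpha`` as-is); ``bonferroni``
    divides alpha by the number of testable subcategories."""
    if taxonomy is not None:
        order = [s for s in taxonomy.subcategory_names
                 if any(r.subcategory == s for r in records)]
    else:
        seen = set()
        order = []
        for r in records:
            if r.subcategory not in seen:
                seen.add(r.subcategory)
                order.append(r.subcategory)
    tables = [build_contingency(records, profiles, grades, s, scope=scope)
              for s in order]
    return prevalence_report_from_tables(tables, alpha=alpha, bonferroni=bonferroni)


@dataclass
class GroupCountSummary:
    """Allergen-count distribution for one NOVA grade and scope."""

    scope: str
    grade: int
    n_foods: int
    histogram: dict[int, int]  # allergen count k -> number of foods
    prevalence_pct: float
    mean_over_all: float
    mean_over_declaring: float  # nan when no food declares

    def __post_init__(self):
        if sum(self.histogram.values()) != self.n_foods:
            raise ValueError("histogram does not sum to group size")


def count_summary(profiles: dict[str, AllergenProfile], grades: dict[str, int],
                  scope: str = "any") -> dict[int, GroupCountSummary]:
    """Histogram and both mean conventions of per-food allergen counts, per
    NOVA grade.  Reports conventionally use mean_over_all for the any and
    ingredient scopes and mean_over_declaring for the trace scope."""
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}")
    by_grade: dict[int, list[int]] = {}
    for pid, prof in profiles.items():
        g = grades[pid]
        g = getattr(g, "grade", g)
        by_grade.setdefault(g, []).append(prof.count(scope))
    out = {}
    for g, counts in sorted(by_grade.items()):
        n = len(counts)
        hist: dict[int, int] = {}
        for k in counts:
            hist[k] = hist.get(k, 0) + 1
        declaring = [k for k in counts if k >= 1]
        out[g] = GroupCountSummary(
            scope=scope,
            grade=g,
            n_foods=n,
            histogram=dict(sorted(hist.items())),
            prevalence_pct=100.0 * len(declaring) / n if n else math.nan,
            mean_over_all=float(np.mean(counts)) if n else math.nan,
            mean_over_declaring=float(np.mean(declaring)) if declaring else math.nan,
        )
    return out


def diversity_report(records, profiles: dict[str, AllergenProfile],
                     grades: dict[str, int], scope: str = "any",
                     pool_nova123: bool = False) -> pd.DataFrame:
    """Distinct-allergen sets per (subcategory, NOVA grade) cell.

    With ``pool_nova123`` grades 1-3 merge into one "1-3" comparator and a
    ``nova4_strictly_larger`` column marks subcategories where the NOVA4 set
    strictly contains more distinct allergens than the pooled comparator
    (only evaluated where both cells exist)."""
    sets: dict[tuple[str, object], set[str]] = {}
    for rec in records:
        g = grades[rec.product_id]
        g = getattr(g, "grade", g)
        key_grade: object = "1-3" if (pool_nova123 and g in (1, 2, 3)) else g
        key = (rec.subcategory, key_grade)
        sets.setdefault(key, set()).update(profiles[rec.product_id].allergens(scope))
    rows = []
    for (sub, g), allergens in sorted(sets.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
        row = {
            "subcategory": sub,
            "nova_group": g,
            "scope": scope,
            "n_distinct": len(allergens),
            "allergens": ";".join(a for a in ALLERGENS if a in allergens),
        }
        if pool_nova123:
            comparator = sets.get((sub, "1-3"))
            nova4 = sets.get((sub, 4))
            row["nova4_strictly_larger"] = (
                len(nova4) > len(comparator)
                if (comparator is not None and nova4 is not None)
                else None
            )
        rows.append(row)
    return pd.DataFrame(rows)
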