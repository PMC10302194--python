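"""End-to-end pipeline: read -> exclude -> detect -> classify -> analyze ->
export, with a run manifest for byte-reproducible outputs.

Artifacts are plain CSV/JSON with documented columns so spreadsheet and R
users can consume them directly:

* ``exclusion_log.json`` — sampling funnel counts and per-record reasons;
* ``profiles_grades.csv`` — one row per retained record: 14 allergen
  statuses, scope counts, NOVA grade and the rule that fired;
* ``prevalence_report.csv`` — nested subcategory x NOVA-grade prevalence
  with rendered percentages and chi-square p-values;
* ``counts_<scope>.csv`` — per-grade allergen-count histograms and means
  for the any/ingredient/trace scopes;
* ``diversity_<scope>.csv`` — distinct-allergen sets per subcategory and
  grade with the pooled NOVA1-3 comparator;
* ``headline.json`` — the summary comparators (overall prevalence, UPF
  share, per-grade prevalence and means, significant subcategories);
* ``manifest.json`` — config hash, lexicon names, package version, seed.

Identical config and inputs produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .allergens import ALLERGENS, AllergenDetector
from .nova import NovaClassifier
from .records import RecordSet, Taxonomy, apply_exclusions, load_default_taxonomy, read_records
from .stats import (
    SCOPES,
    count_summary,
    diversity_report,
    format_p,
    format_pct,
    prevalence_report,
    round_half_up,
)

__all__ = ["PipelineConfig", "run_pipeline", "summarize_headlines"]

log = logging.getLogger("allernova")

#: which mean convention each scope's headline uses
DEFAULT_MEAN_CONVENTIONS = {
    "any": "over_all",
    "ingredient": "over_all",
    "trace": "over_declaring",
}


@dataclass
class PipelineConfig:
    records_path: str
    output_dir: str
    taxonomy_path: str | None = None
    allergen_lexicon_path: str | None = None
    marker_lexicon_path: str | None = None
    alpha: float = 0.01
    strict_nova4_markers: bool = False
    subcategory_overrides_enabled: bool = False
    mean_conventions: dict = field(default_factory=lambda: dict(DEFAULT_MEAN_CONVENTIONS))
    precaution_dialect: str = "json"
    audit: bool = False
    log_level: str = "INFO"
    seed: int | None = None  # recorded in the manifest for synthetic inputs

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix in (".yaml", ".yml"):
            import yaml

            obj = yaml.safe_load(text)
        else:
            obj = json.loads(text)
        return cls(**obj)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode("utf-8")
        return hashlib.sha256(blob).hexdigest()[:16]


def _mean_for(summary, convention: str) -> float | None:
    """Selected mean convention, rounded; None when undefined (no declarer)."""
    import math

    x = summary.mean_over_all if convention == "over_all" else summary.mean_over_declaring
    return round(x, 2) if math.isfinite(x) else None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the headline summary dict.

    Any stage error propagates as an exception tagged with the stage name in
    its message; the CLI maps that to a nonzero exit status."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    taxonomy = (Taxonomy.from_json(config.taxonomy_path)
                if config.taxonomy_path else load_default_taxonomy())

    log.info("stage=read path=%s", config.records_path)
    rs = read_records(config.records_path, taxonomy=taxonomy,
                      precaution_dialect=config.precaution_dialect)

    log.info("stage=exclude n_input=%d", len(rs))
    retained, excl_log = apply_exclusions(rs)
    (outdir / "exclusion_log.json").write_text(json.dumps({
        "n_input": excl_log.n_input,
        "n_unreadable_excluded": excl_log.n_unreadable_excluded,
        "n_incomplete_package_excluded": excl_log.n_incomplete_package_excluded,
        "n_retained": excl_log.n_retained,
        "excluded_ids": excl_log.excluded_ids,
    }, indent=1) + "\n", encoding="utf-8")

    log.info("stage=detect n=%d", len(retained))
    detector = AllergenDetector(lexicon=config.allergen_lexicon_path).fit()
    audit_events: list | None = [] if config.audit else None
    profiles = detector.profiles(retained, audit=audit_events)
    if audit_events is not None:
        with open(outdir / "audit.jsonl", "w", encoding="utf-8") as fh:
            for ev in audit_events:
                fh.write(json.dumps(ev, sort_keys=True) + "\n")

    log.info("stage=classify")
    clf = NovaClassifier(
        markers=config.marker_lexicon_path,
        strict_culinary_markers=config.strict_nova4_markers,
        use_subcategory_overrides=config.subcategory_overrides_enabled,
    ).fit()
    traces = clf.classify_all(retained)
    grades = {pid: t.grade for pid, t in traces.items()}

    rows = []
    for rec in retained:
        prof, tr = profiles[rec.product_id], traces[rec.product_id]
        row = {"product_id": rec.product_id, "category": rec.category,
               "subcategory": rec.subcategory}
        row.update(prof.statuses)
        row.update(n_ingredient=prof.n_ingredient, n_trace=prof.n_trace,
                   n_any=prof.n_any, contains_any=prof.contains_any,
                   nova_grade=tr.grade, rule_fired=tr.rule_fired,
                   n_ingredients=tr.n_ingredients)
        rows.append(row)
    import pandas as pd

    pd.DataFrame(rows).to_csv(outdir / "profiles_grades.csv", index=False,
                              lineterminator="\n")

    log.info("stage=analyze alpha=%s", config.alpha)
    report = prevalence_report(retained, profiles, grades, alpha=config.alpha,
                               taxonomy=taxonomy)
    report.frame.to_csv(outdir / "prevalence_report.csv", index=False,
                        lineterminator="\n")

    summaries = {}
    for scope in SCOPES:
        summary = count_summary(profiles, grades, scope=scope)
        summaries[scope] = summary
        pd.DataFrame([
            {
                "scope": scope,
                "nova_group": g,
                "n_foods": s.n_foods,
                "prevalence_pct": round_half_up(s.prevalence_pct, 1),
                "mean_over_all": round(s.mean_over_all, 4),
                "mean_over_declaring": round(s.mean_over_declaring, 4),
                "histogram": json.dumps(s.histogram),
            }
            for g, s in summary.items()
        ]).to_csv(outdir / f"counts_{scope}.csv", index=False, lineterminator="\n")
        div = diversity_report(retained, profiles, grades, scope=scope,
                               pool_nova123=True)
        div.to_csv(outdir / f"diversity_{scope}.csv", index=False, lineterminator="\n")

    n_total = len(retained)
    n_any = sum(1 for p in profiles.values() if p.contains_any)
    n_nova4 = sum(1 for g in grades.values() if g == 4)
    headline = {
        "n_retained": n_total,
        "overall_any_prevalence_pct": round_half_up(100.0 * n_any / n_total, 1) if n_total else None,
        "upf_share_pct": round_half_up(100.0 * n_nova4 / n_total, 1) if n_total else None,
        "per_grade": {
            str(g): {
                "n": s.n_foods,
                "any_prevalence_pct": round_half_up(s.prevalence_pct, 1),
                "mean_any": _mean_for(s, config.mean_conventions["any"]),
                "mean_ingredient": _mean_for(
                    summaries["ingredient"][g], config.mean_conventions["ingredient"])
                if g in summaries["ingredient"] else None,
                "mean_trace": _mean_for(
                    summaries["trace"][g], config.mean_conventions["trace"])
                if g in summaries["trace"] else None,
            }
            for g, s in summaries["any"].items()
        },
        "n_subcategories": report.n_subcategories,
        "n_testable_subcategories": report.n_testable,
        "n_significant_subcategories": report.n_significant,
        "significant_subcategories": report.significant_subcategories,
        "alpha": config.alpha,
    }
    (outdir / "headline.json").write_text(
        json.dumps(headline, indent=1, sort_keys=True, allow_nan=True) + "\n",
        encoding="utf-8")

    manifest = {
        "package": "allernova",
        "version": __version__,
        "config_hash": config.content_hash(),
        "config": asdict(config),
        "taxonomy": taxonomy.name,
        "allergen_lexicon": detector.lexicon_.name,
        "marker_lexicon": clf.markers_.name,
        "seed": config.seed,
        "n_input": excl_log.n_input,
        "n_retained": excl_log.n_retained,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8")
    log.info("stage=done retained=%d significant=%d", n_total, report.n_significant)
    return headline


def summarize_headlines(output_dir: str | Path) -> dict:
    """Re-read a run's artifacts and return the headline summary.

    Raises FileNotFoundError naming the first missing artifact."""
    outdir = Path(output_dir)
    for name in ("headline.json", "manifest.json", "prevalence_report.csv"):
        if not (outdir / name).exists():
            raise FileNotFoundError(f"missing artifact: {outdir / name}")
    return json.loads((outdir / "headline.json").read_text(encoding="utf-8"))
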