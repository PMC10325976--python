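"""End-to-end analysis pipeline: filter -> fit -> classify -> compare.

Ties the modules together into one reproducible run over a variant table and
a patient cohort, producing an :class:`AnalysisReport` that is written
atomically as ``report.json`` plus flat companion tables (``tier_calls.tsv``,
``tests.tsv``, ``fits.json``) in the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .cohort import (
    Patient, compare_age_at_onset, compare_involvement, compare_laterality,
    ischemic_burden_comparison, read_cohort_table,
)
from .exact_tests import Table2x2, fisher_exact
from .mixture import classify_variants, compare_score_groups, fit_score_model, tier_counts
from .variants import (
    GenePanel, default_mma_panel, filter_by_maf, filter_by_panel,
    read_variant_table, summarize_inheritance,
)

logger = logging.getLogger("moyastrat")

__all__ = ["RunConfig", "AnalysisReport", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    variants_path: Optional[str] = None
    cohort_path: Optional[str] = None
    panel_path: Optional[str] = None
    literature_variants_path: Optional[str] = None
    variant_format: str = "tsv"
    maf_max: float = 0.02
    alpha: float = 0.05
    out_dir: str = "moyastrat_report"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.maf_max <= 1.0:
            raise ValueError("maf_max must be in (0, 1]")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class AnalysisReport:
    config: dict
    provenance: dict
    fits: dict
    tier_calls: list
    tier_counts: dict
    inheritance: Optional[dict]
    tests: list
    cohort_summary: Optional[dict]
    score_group_comparisons: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _stage(stage: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", stage)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(stage, str(exc)) from exc
        return wrapped
    return deco


@_stage("load")
def _load(config: RunConfig):
    variants = read_variant_table(config.variants_path, format=config.variant_format)
    cohort = read_cohort_table(config.cohort_path) if config.cohort_path else None
    panel = (GenePanel.from_file(config.panel_path)
             if config.panel_path else default_mma_panel())
    literature = (read_variant_table(config.literature_variants_path)
                  if config.literature_variants_path else [])
    return variants, cohort, panel, literature


@_stage("filter")
def _filter(variants, panel, maf_max):
    variants = filter_by_maf(variants, maf_max)
    variants = filter_by_panel(variants, panel)
    if not variants:
        raise ValueError("no variants left after MAF/panel filtering")
    return variants


@_stage("stratify")
def _stratify(variants):
    cadd_scores = [v.cadd for v in variants if v.cadd is not None]
    vipur_scores = [v.vipur for v in variants if v.vipur is not None]
    cadd_fit = fit_score_model(cadd_scores)
    vipur_fit = fit_score_model(vipur_scores)
    calls = classify_variants(variants, cadd_fit, vipur_fit)
    return cadd_fit, vipur_fit, calls


@_stage("compare")
def _compare(cohort: list[Patient]):
    grouping = lambda p: p.rnf213_carrier  # noqa: E731
    tests = []

    n_mmd = sum(p.diagnosis == "MMD" for p in cohort)
    n_mms = len(cohort) - n_mmd
    car_mmd = sum(p.rnf213_carrier and p.diagnosis == "MMD" for p in cohort)
    car_mms = sum(p.rnf213_carrier and p.diagnosis == "MMS" for p in cohort)
    if min(n_mmd, n_mms) > 0:
        fet = fisher_exact(Table2x2(car_mmd, n_mmd - car_mmd, car_mms, n_mms - car_mms))
        fet.label = "carrier_by_diagnosis"
        tests.append(fet)

    tests.append(compare_age_at_onset(cohort, grouping, context="rnf213"))
    tests.extend(compare_involvement(cohort, grouping))
    tests.append(compare_laterality(cohort, grouping, "PCA"))
    tests.append(ischemic_burden_comparison(cohort, grouping))

    summary = {
        "n_patients": len(cohort),
        "n_mmd": n_mmd,
        "n_mms": n_mms,
        "n_carriers": car_mmd + car_mms,
        "carriers_mmd": car_mmd,
        "carriers_mms": car_mms,
        "n_incidental": sum(p.incidental_diagnosis for p in cohort),
    }
    return tests, summary


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Run filter -> fit -> classify -> compare and write the report directory."""
    if not config.variants_path:
        raise PipelineError("load", "variants_path is required")

    variants, cohort, panel, literature = _load(config)
    variants = _filter(variants, panel, config.maf_max)
    cadd_fit, vipur_fit, calls = _stratify(variants)

    tier_by_id = {c.variant_id: c.tier for c in calls}
    flagged = [
        v for v in variants
        if tier_by_id[v.variant_id] in ("deleterious", "possibly_deleterious")
    ]
    inheritance = summarize_inheritance(flagged)

    score_comparisons = []
    if literature:
        pool = literature + [
            v for v in variants if v.phenotype_label is not None
        ]
        for score in ("CADD", "VIPUR"):
            try:
                score_comparisons.extend(
                    c.__dict__ for c in compare_score_groups(pool, score)
                )
            except ValueError as exc:
                logger.warning("score group comparison skipped: %s", exc)

    tests: list = []
    cohort_summary = None
    if cohort:
        tests, cohort_summary = _compare(cohort)

    report = AnalysisReport(
        config=asdict(config),
        provenance={
            "package": "moyastrat",
            "version": __version__,
            "config_hash": config.digest(),
            "seed": config.seed,
        },
        fits={"cadd": cadd_fit.to_dict(), "vipur": vipur_fit.to_dict()},
        tier_calls=[c.__dict__ for c in calls],
        tier_counts=tier_counts(calls),
        inheritance={
            "n_occurrences": inheritance.n_occurrences,
            "n_established": inheritance.n_established,
            "n_de_novo": inheritance.n_de_novo,
            "de_novo_fraction_pct": inheritance.de_novo_fraction,
        },
        tests=[t.to_dict() for t in tests],
        cohort_summary=cohort_summary,
        score_group_comparisons=score_comparisons,
    )
    _write_report(report, variants, calls, Path(config.out_dir))
    return report


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _write_report(report: AnalysisReport, variants, calls, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    _atomic_write(out_dir / "report.json",
                  json.dumps(report.to_dict(), indent=2, default=float))
    _atomic_write(out_dir / "fits.json", json.dumps(report.fits, indent=2))

    score_by_id = {v.variant_id: v for v in variants}
    rows = []
    for c in calls:
        v = score_by_id[c.variant_id]
        rows.append({
            "variant_id": c.variant_id,
            "cadd": v.cadd if v.cadd is not None else ".",
            "vipur": v.vipur if v.vipur is not None else ".",
            "cadd_flag": c.cadd_flag,
            "vipur_flag": c.vipur_flag,
            "tier": c.tier,
        })
    _atomic_write(out_dir / "tier_calls.tsv",
                  pd.DataFrame(rows).to_csv(sep="\t", index=False))
    _atomic_write(out_dir / "tests.tsv",
                  pd.DataFrame(report.tests).to_csv(sep="\t", index=False))
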