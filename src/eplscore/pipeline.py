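"""End-to-end derivation pipeline on a synthetic cohort.

Mirrors the study design: simulate a cohort, split it into a training
and a verification set by a simulated enrolment year (sizes proportional
to the 7261 / 6716 temporal split), fit the logistic model with stepwise
screening on the training set, derive the integer point system from the
fitted coefficients, and evaluate the derived score on both splits.

Every artifact is JSON with provenance (seed, configuration hash,
package version); two runs with the same configuration and seed produce
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .cohort import (
    DEFAULT_PREVALENCE,
    DEFAULT_SEED,
    CohortConfig,
    GenerativeModel,
    cohort_to_csv,
    generate_cohort,
)
from .evaluation import performance_table
from .fit import (
    FitResult,
    calibrate_risk_intercept,
    derive_point_system,
    estimate_risk_curve,
    fit_logistic,
    stepwise_select,
)
from .scoring import (
    DEFAULT_CUTOFF,
    published_category_templates,
    published_system,
    score_cohort,
    system_to_dict,
)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

#: Training / verification split of the study cohort (year 2016 vs 2017).
TRAIN_FRACTION = 7261 / 13977

DEFAULT_CANDIDATES = ("ma", "bmi", "duration", "hcg", "em", "gsd", "ysd", "el", "ehr", "iuh")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``stages`` toggles the three phases; a later stage requires the
    earlier ones.  The cohort defaults to the logistic generative mode
    with the published coefficients as truth, so the derived point table
    is directly comparable with the published one.
    """

    n: int = 13977
    prevalence: float = DEFAULT_PREVALENCE
    mode: str = "logistic_generative"
    seed: int = DEFAULT_SEED
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    alpha_stay: float = 0.10
    cutoff: int = DEFAULT_CUTOFF
    stages: tuple[str, ...] = ("simulate", "fit", "evaluate")
    write_cohort: bool = False

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["candidates"] = list(self.candidates)
        doc["stages"] = list(self.stages)
        return doc

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(config: PipelineConfig) -> dict:
    return {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash,
        "config": config.to_dict(),
    }


def _write_json(path: Path, doc: dict) -> None:
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def _rows_to_doc(rows) -> list[dict]:
    return [dataclasses.asdict(r) for r in rows]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the configured stages, writing a report bundle to ``outdir``.

    Returns the report dictionary (also written to ``report.json``).
    Unknown stage names raise; an empty stage tuple yields an empty
    bundle and a report containing provenance only.
    """
    unknown = set(config.stages) - {"simulate", "fit", "evaluate"}
    if unknown:
        raise ValueError(f"unknown pipeline stages: {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": _provenance(config), "stages": list(config.stages)}

    cohort = train = verify = None
    if "simulate" in config.stages:
        cohort_config = CohortConfig(
            n=config.n, prevalence=config.prevalence, mode=config.mode, seed=config.seed
        )
        model = (
            GenerativeModel.published(config.prevalence)
            if config.mode == "logistic_generative"
            else None
        )
        cohort = generate_cohort(cohort_config, model)
        n_train = int(round(config.n * TRAIN_FRACTION))
        year = np.where(np.arange(config.n) < n_train, 2016, 2017)
        cohort = cohort.assign(year=year)
        train = cohort[cohort["year"] == 2016]
        verify = cohort[cohort["year"] == 2017]
        logger.info(
            "simulate: %d records (%d training, %d verification, %d losses)",
            len(cohort), len(train), len(verify), int((cohort["outcome"] == "epl").sum()),
        )
        report["simulate"] = {
            "n": len(cohort),
            "n_train": len(train),
            "n_verify": len(verify),
            "n_epl": int((cohort["outcome"] == "epl").sum()),
        }
        if config.write_cohort:
            cohort_to_csv(cohort, outdir / "cohort.csv")

    fit_res: FitResult | None = None
    system = None
    if "fit" in config.stages:
        if train is None:
            raise ValueError("fit stage needs the simulate stage (no cohort available)")
        candidates = [c for c in config.candidates if c in train.columns]
        selected, fit_res = stepwise_select(
            train, candidates, alpha_stay=config.alpha_stay
        )
        logger.info("fit: stepwise retained %s", selected)
        templates = published_category_templates()
        scorable = [v for v in selected if v in {t.name for t in templates}]
        if scorable != selected:
            dropped = sorted(set(selected) - set(scorable))
            logger.info("fit: no clinical categories for %s; excluded from points", dropped)
            fit_res = fit_logistic(train, scorable)
        system = derive_point_system(fit_res, templates)
        _write_json(
            outdir / "fit.json",
            {"provenance": _provenance(config), "selected": scorable, "fit": fit_res.to_dict()},
        )
        published, _ = published_system()
        comparison = _compare_systems(system, published)
        report["fit"] = {
            "selected": scorable,
            "B": system.B,
            "score_range": [system.score_min, system.score_max],
            "points_matching_published": comparison["n_matching"],
            "points_total": comparison["n_categories"],
        }
        _write_json(outdir / "system.json", {
            "provenance": _provenance(config),
            "system": system_to_dict(system),
            "comparison_with_published": comparison,
        })

    if "evaluate" in config.stages:
        if system is None or train is None:
            raise ValueError("evaluate stage needs the simulate and fit stages")
        _, published_table = published_system()
        c = calibrate_risk_intercept(published_table, 0.46)
        risk_table = estimate_risk_curve(
            c, system.B, range(system.score_min, system.score_max + 1)
        )
        for split_name, split in (("train", train), ("verify", verify)):
            scores = score_cohort(split, system)
            rows = performance_table(scores, split["outcome"].to_numpy(), risk_table)
            _write_json(
                outdir / f"performance_{split_name}.json",
                {
                    "provenance": _provenance(config),
                    "risk_model": "analytic approximation expit(c + B*total)",
                    "rows": _rows_to_doc(rows),
                },
            )
            at_cut = next(r for r in rows if r.cutoff == config.cutoff)
            report[f"evaluate_{split_name}"] = {
                "cutoff": config.cutoff,
                "sensitivity": at_cut.sensitivity,
                "specificity": at_cut.specificity,
                "ppv": at_cut.ppv,
                "npv": at_cut.npv,
                "accuracy": at_cut.accuracy,
            }
            logger.info(
                "evaluate[%s]: accuracy %.2f%% at cutoff %d",
                split_name, at_cut.accuracy, config.cutoff,
            )

    _write_json(outdir / "report.json", report)
    return report


def _compare_systems(derived, published) -> dict:
    """Category-by-category point comparison of two systems."""
    rows = []
    n_match = 0
    for pf in published.factors:
        try:
            df_factor = derived.factor(pf.name)
        except KeyError:
            for c in pf.categories:
                rows.append(
                    {"factor": pf.name, "label": c.label,
                     "published": c.points, "derived": None, "match": False}
                )
            continue
        for pc, dc in zip(pf.categories, df_factor.categories):
            match = pc.points == dc.points
            n_match += match
            rows.append(
                {"factor": pf.name, "label": pc.label,
                 "published": pc.points, "derived": dc.points, "match": match}
            )
    return {
        "n_categories": sum(len(f.categories) for f in published.factors),
        "n_matching": n_match,
        "rows": rows,
    }
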