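"""End-to-end pipeline chain: simulate -> align -> extract -> train -> evaluate.

One global seed drives every stage through derived per-stage seeds, so a
full run is reproducible bit for bit from its configuration alone.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from paco2est import io
from paco2est.align import STATUS_ALIGNED, EventPoint, align_events, events_frame
from paco2est.config import PipelineConfig
from paco2est.evaluate import (
    bland_altman_tables,
    build_report,
    config_hash,
    report_json,
)
from paco2est.features import assemble_feature_table
from paco2est.model import NestedCVResult, make_folds, run_nested_cv
from paco2est.synth import generate_cohort
from paco2est.types import Cohort

_SEED_MOD = 2 ** 31


def derive_seed(seed: int, stage: int) -> int:
    """Per-stage seed derived from the single global seed."""
    return (seed * 7919 + stage) % _SEED_MOD


@dataclass
class RunResult:
    """Everything a full run produced, for inspection and testing."""

    config: PipelineConfig
    cohort: Cohort
    events: list[EventPoint]
    features: pd.DataFrame
    exclusions: pd.DataFrame
    cv: NestedCVResult
    report: dict


def run_all(config: PipelineConfig, out_dir: Optional[str] = None,
            write_signals: bool = False,
            cohort: Optional[Cohort] = None) -> RunResult:
    """Execute the full chain and (optionally) write all stage outputs.

    ``write_signals`` controls whether the large long-format signals table
    is materialized on disk; every other artifact (events, features,
    predictions, report, manifest) is always written when ``out_dir`` is
    given.  A pre-built cohort can be injected for testing.
    """
    config.validate()
    if cohort is None:
        gen_cfg = dataclasses.replace(config.generator,
                                      seed=derive_seed(config.seed, 1))
        cohort = generate_cohort(gen_cfg)
    else:
        gen_cfg = config.generator

    events = align_events(cohort, config.alignment)
    features, exclusions = assemble_feature_table(events, cohort,
                                                  config.features)
    if features.empty:
        raise ValueError("no events survived alignment and feature "
                         "extraction; nothing to model")
    folds = make_folds(features["case_id"].unique(),
                       k_outer=config.folds.k_outer,
                       k_inner=config.folds.k_inner,
                       seed=derive_seed(config.seed, 2))
    cv = run_nested_cv(features, folds, config.search,
                       include_co=config.features.include_co)
    n_aligned = sum(1 for e in events if e.status == STATUS_ALIGNED)
    provenance = {
        "seed": config.seed,
        "config_hash": config_hash(config.to_dict()),
        "n_abga_events": len(events),
        "n_aligned": n_aligned,
        "n_modeled": int(len(features)),
        "exclusions": exclusions["reason"].str.split(":").str[0]
        .value_counts().to_dict() if not exclusions.empty else {},
    }
    report = build_report(cv, config.evaluation, provenance=provenance)

    if out_dir is not None:
        _write_outputs(config, cohort, events, features, exclusions, cv,
                       report, out_dir, write_signals)
    return RunResult(config=config, cohort=cohort, events=events,
                     features=features, exclusions=exclusions, cv=cv,
                     report=report)


def _write_outputs(config, cohort, events, features, exclusions, cv, report,
                   out_dir: str, write_signals: bool) -> None:
    os.makedirs(out_dir, exist_ok=True)
    paths = []

    def p(name: str) -> str:
        path = os.path.join(out_dir, name)
        paths.append(path)
        return path

    io.write_table(cohort.clinical_frame(), p("clinical.csv"))
    io.write_table(cohort.abga_frame(), p("abga.csv"))
    if write_signals:
        io.write_table(cohort.signals_frame(), p("signals.csv"))
    io.write_table(events_frame(events), p("events.csv"))
    io.write_table(features, p("features.csv"))
    io.write_table(exclusions, p("exclusions.csv"))
    io.write_table(cv.predictions, p("predictions.csv"))
    io.write_json({"outer": cv.folds.outer,
                   "inner": {str(k): v for k, v in cv.folds.inner.items()},
                   "seed": cv.folds.seed}, p("folds.json"))
    io.write_json({str(k): v for k, v in cv.tuning_log.items()},
                  p("tuning_log.json"))
    io._atomic_write(p("report.json"), lambda fh: fh.write(report_json(report)))
    _write_report_tables(report, cv, out_dir, p)
    io.write_manifest(os.path.join(out_dir, "manifest.json"),
                      config.to_dict(), config.seed, files=paths,
                      counts=report["provenance"])


def _write_report_tables(report: dict, cv: NestedCVResult, out_dir: str,
                         p) -> None:
    rows = []
    for model, blocks in report["models"].items():
        for sg, b in blocks["metrics"].items():
            row = {"model": model, "subgroup": sg, "n_events": b["n_events"]}
            for m in ("mae", "mse", "rmse"):
                row[m] = b[m]["mean"]
                row[f"{m}_ci_low"] = b[m]["ci_low"]
                row[f"{m}_ci_high"] = b[m]["ci_high"]
            rows.append(row)
    io.write_table(pd.DataFrame(rows), p("metrics.csv"))

    rows = [{"model": m, **report["models"][m]["agreement"]}
            for m in report["models"]]
    io.write_table(pd.DataFrame(rows), p("agreement.csv"))

    rows = [{"model": m, **report["models"][m]["utility"]}
            for m in report["models"]]
    io.write_table(pd.DataFrame(rows), p("utility.csv"))

    io.write_table(pd.DataFrame(report["attribution"]["features"]),
                   p("attribution.csv"))
    for model, table in bland_altman_tables(cv).items():
        io.write_table(table, p(f"bland_altman_{model}.csv"))
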