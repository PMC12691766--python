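"""End-to-end assessment pipeline driven by one configuration document.

Stages run in a fixed order: read (or generate) inputs → exclude incomplete
individuals → trim implausible intakes → substitute censored concentrations
→ fit input distributions → Monte Carlo simulation → margin-of-exposure
risk table → contribution-to-variance sensitivity → write artifacts. Any
stage failure aborts the run with the stage name and removes partial
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from collections.abc import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .data import (
    AnalyteSpec,
    ConcentrationRecord,
    ConsumptionRecord,
    censoring_rate,
    exclude_incomplete,
    read_concentration_csv,
    read_consumption_csv,
    substitute_censored,
    summarize,
    trim_implausible,
    write_concentration_csv,
    write_consumption_csv,
)
from .model import ExposureConfig, ExposureModel, ExposureResults
from .risk import round_sig
from .synthetic import (
    ConcentrationGeneratorParams,
    SurveyGeneratorParams,
    generate_concentrations,
    generate_survey,
)

log = logging.getLogger("cpexposure.pipeline")


@dataclass
class PipelineConfig:
    """Configuration for one assessment run.

    Either ``consumption_csv``/``concentration_csv`` point at input tables,
    or ``synthetic=True`` generates the demo dataset (sizes set by
    ``synthetic_individuals``/``synthetic_samples``).
    """

    outdir: str = "assessment_out"
    seed: int = 0
    n_iterations: int = 10_000
    mode: str = "fitted_independent"
    percentiles_reported: tuple[float, ...] = (50.0, 95.0)

    consumption_csv: str | None = None
    concentration_csv: str | None = None
    synthetic: bool = True
    synthetic_individuals: int = 5_000
    synthetic_samples: int = 50

    # analyte registry: name -> {lod (ng/g), bmdl10 (mg/kg bw/d)}
    analytes: dict = field(
        default_factory=lambda: {
            "SCCP": {"lod": 32.0, "bmdl10": 2.3},
            "MCCP": {"lod": 16.0, "bmdl10": 36.0},
        }
    )

    trim_low_pct: float = 1.0
    trim_high_pct: float = 99.0
    substitution_fraction: float = 0.5
    anchor_percentiles: tuple[float, ...] | None = None  # default: deciles

    def registry(self) -> dict[str, AnalyteSpec]:
        return {
            name: AnalyteSpec(name, lod=float(v["lod"]), bmdl10=float(v["bmdl10"]))
            for name, v in self.analytes.items()
        }

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["percentiles_reported"] = list(self.percentiles_reported)
        if self.anchor_percentiles is not None:
            doc["anchor_percentiles"] = list(self.anchor_percentiles)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        if unknown := set(doc) - known:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "percentiles_reported" in doc:
            doc["percentiles_reported"] = tuple(doc["percentiles_reported"])
        if doc.get("anchor_percentiles") is not None:
            doc["anchor_percentiles"] = tuple(doc["anchor_percentiles"])
        return cls(**doc)


@dataclass
class AssessmentReport:
    """Complete, provenance-stamped result of one pipeline run."""

    config: dict
    seed: int
    version: str
    counts: dict
    consumption_summary: list[dict]
    concentration_summary: list[dict]
    edi_summary: list[dict]
    risk: list[dict]
    sensitivity: list[dict]

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "AssessmentReport":
        return cls(**json.loads(text))


def _summary_dict(group: str, values: Sequence[float], extra: Mapping | None = None) -> dict:
    s = summarize(values, percentiles=(50.0, 95.0), group=group)
    row = {
        "group": group,
        "n": s.n,
        "mean": s.mean,
        "median": s.median,
        "p95": s.p95,
        "min": s.min,
        "max": s.max,
    }
    if extra:
        row.update(extra)
    return row


def _load_inputs(
    config: PipelineConfig,
) -> tuple[list[ConsumptionRecord], list[ConcentrationRecord]]:
    if config.consumption_csv and config.concentration_csv:
        log.info("reading inputs from %s and %s", config.consumption_csv, config.concentration_csv)
        return (
            read_consumption_csv(config.consumption_csv),
            read_concentration_csv(config.concentration_csv),
        )
    if not config.synthetic:
        raise ValueError("config provides neither input CSVs nor synthetic=True")
    log.info(
        "generating synthetic inputs (%d individuals, %d samples/oil)",
        config.synthetic_individuals,
        config.synthetic_samples,
    )
    survey = generate_survey(
        SurveyGeneratorParams.demo(config.synthetic_individuals, seed=config.seed)
    )
    conc_params = ConcentrationGeneratorParams.demo(
        n_samples=config.synthetic_samples, seed=config.seed
    )
    lods = {name: spec["lod"] for name, spec in config.analytes.items()}
    conc_params = dataclasses.replace(conc_params, lods=lods)
    concentrations = generate_concentrations(conc_params)
    return survey, concentrations


def run_assessment(config: PipelineConfig) -> AssessmentReport:
    """Execute the full pipeline and write all artifacts to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "load"
        survey, concentrations = _load_inputs(config)
        n_read = len(survey)

        stage = "exclude_incomplete"
        survey = exclude_incomplete(survey)
        n_after_exclude = len(survey)
        log.info("excluded incomplete individuals: %d -> %d rows", n_read, n_after_exclude)

        stage = "trim_implausible"
        survey = trim_implausible(survey, config.trim_low_pct, config.trim_high_pct)
        log.info("trimmed implausible intakes: %d -> %d rows", n_after_exclude, len(survey))

        stage = "substitute_censored"
        n_censored = sum(r.censored for r in concentrations)
        concentrations = substitute_censored(concentrations, config.substitution_fraction)
        log.info("substituted %d censored concentration records", n_censored)

        stage = "fit"
        registry = config.registry()
        model = ExposureModel.from_records(
            survey,
            concentrations,
            analytes=registry,
            anchor_percentiles=config.anchor_percentiles,
        )

        stage = "simulate"
        results = model.fit(
            ExposureConfig(
                n_iterations=config.n_iterations,
                seed=config.seed,
                mode=config.mode,
                percentiles_reported=tuple(config.percentiles_reported),
            )
        )

        stage = "summaries"
        consumption_summary = _consumption_summaries(survey)
        concentration_summary = _concentration_summaries(concentrations)
        edi_summary = [
            _summary_dict(analyte, results[analyte].draws)
            for analyte in results.analytes
        ]

        stage = "risk"
        risk_rows = [
            {
                "analyte": r.analyte,
                "statistic": r.statistic,
                "edi_ng_per_kg_bw_day": r.edi,
                "bmdl10_mg_per_kg_bw_day": r.bmdl10,
                "moe": round_sig(r.moe, 3),
                "concern": r.concern,
            }
            for r in results.moe()
        ]

        stage = "sensitivity"
        sens_rows = []
        for analyte in results.analytes:
            sens = results.sensitivity(analyte)
            for name, contrib in sens.contributions.items():
                sens_rows.append(
                    {"output": sens.output, "input": name, "contribution_pct": contrib}
                )
            sens_rows.append(
                {"output": sens.output, "input": "residual", "contribution_pct": sens.residual}
            )

        report = AssessmentReport(
            config=_config_echo(config),
            seed=config.seed,
            version=__version__,
            counts={
                "survey_rows_read": n_read,
                "survey_rows_after_exclusion": n_after_exclude,
                "survey_rows_after_trimming": len(survey),
                "concentration_records": len(concentrations),
                "censored_substituted": n_censored,
                "bodyweight_resampled": sum(
                    results[a].n_bodyweight_resampled for a in results.analytes
                ),
            },
            consumption_summary=consumption_summary,
            concentration_summary=concentration_summary,
            edi_summary=edi_summary,
            risk=risk_rows,
            sensitivity=sens_rows,
        )

        stage = "write"
        _write_artifacts(outdir, report, results, survey, concentrations, written)
        return report
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _config_echo(config: PipelineConfig) -> dict:
    doc = dataclasses.asdict(config)
    doc["percentiles_reported"] = list(config.percentiles_reported)
    if config.anchor_percentiles is not None:
        doc["anchor_percentiles"] = list(config.anchor_percentiles)
    return doc


def _consumption_summaries(survey: Sequence[ConsumptionRecord]) -> list[dict]:
    rows = []
    by_oil: dict[str, list[float]] = {}
    totals: dict[str, float] = {}
    weights: dict[str, float] = {}
    for rec in survey:
        if rec.intake is None:
            continue
        by_oil.setdefault(rec.oil_type, []).append(rec.intake)
        totals[rec.individual_id] = totals.get(rec.individual_id, 0.0) + rec.intake
        if rec.body_weight is not None:
            weights[rec.individual_id] = rec.body_weight
    for oil in sorted(by_oil):
        rows.append(_summary_dict(f"intake:{oil}", by_oil[oil]))
    if totals:
        rows.append(_summary_dict("intake:total", list(totals.values())))
    if weights:
        rows.append(_summary_dict("body_weight", list(weights.values())))
    return rows


def _concentration_summaries(records: Sequence[ConcentrationRecord]) -> list[dict]:
    groups: dict[tuple[str, str], list[ConcentrationRecord]] = {}
    for rec in records:
        groups.setdefault((rec.analyte, rec.oil_type), []).append(rec)
    rows = []
    for (analyte, oil) in sorted(groups):
        recs = groups[(analyte, oil)]
        values = [r.value for r in recs if r.value is not None]
        rows.append(
            _summary_dict(
                f"{analyte}:{oil}", values, extra={"censoring_rate": censoring_rate(recs)}
            )
        )
    return rows


def _write_artifacts(
    outdir: Path,
    report: AssessmentReport,
    results: ExposureResults,
    survey: Sequence[ConsumptionRecord],
    concentrations: Sequence[ConcentrationRecord],
    written: list[Path],
) -> None:
    import pandas as pd

    def _write(name: str, writer) -> None:
        path = outdir / name
        written.append(path)
        writer(path)

    _write("report.json", lambda p: p.write_text(report.to_json()))
    _write(
        "risk.csv", lambda p: pd.DataFrame(report.risk).to_csv(p, index=False)
    )
    _write(
        "sensitivity.csv",
        lambda p: pd.DataFrame(report.sensitivity).to_csv(p, index=False),
    )
    _write(
        "consumption_summary.csv",
        lambda p: pd.DataFrame(report.consumption_summary).to_csv(p, index=False),
    )
    _write(
        "concentration_summary.csv",
        lambda p: pd.DataFrame(report.concentration_summary).to_csv(p, index=False),
    )
    _write("prepared_consumption.csv", lambda p: write_consumption_csv(survey, p))
    _write("prepared_concentration.csv", lambda p: write_concentration_csv(concentrations, p))
    for analyte in results.analytes:
        _write(
            f"edi_draws_{analyte}.csv",
            lambda p, a=analyte: pd.Series(results[a].draws, name="edi_ng_per_kg_bw_day").to_csv(
                p, index=False
            ),
        )
    fits = {
        "consumption": {o: d.to_dict() for o, d in results.model.consumption_models.items()},
        "concentration": {
            a: {o: d.to_dict() for o, d in per_oil.items()}
            for a, per_oil in results.model.concentration_models.items()
        },
        "bodyweight": (
            results.model.bodyweight_model.to_dict() if results.model.bodyweight_model else None
        ),
    }
    _write("fitted_distributions.json", lambda p: p.write_text(json.dumps(fits, indent=2)))
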