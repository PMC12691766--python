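"""Monte Carlo simulation of the estimated daily intake (EDI).

The population EDI of an analyte is simulated as

    EDI = sum_i  P_i * C_i / Bw      [ng/kg bw/d]

where, per iteration, ``P_i`` is the consumption of the i-th oil type (g/d),
``C_i`` the analyte concentration in that oil (ng/g) and ``Bw`` the body
weight (kg). Units compose with no hidden factors: ng/g × g/d ÷ kg =
ng/kg bw/d.

The interface follows the model/results idiom: :class:`ExposureModel` is
built from per-variable fitted distributions (or from prepared record
tables), ``fit()`` runs the simulation, and :class:`ExposureResults` carries
the draws, their summaries, margin-of-exposure tables, sensitivity
attribution and a printable ``summary()``.

Two sampling modes are provided. ``fitted_independent`` (default) draws all
input variables independently from their fitted distributions.
``bootstrap_paired`` resamples whole survey individuals, preserving the
empirical pairing between a person's oil intakes and body weight, and is
available when record-level survey data are at hand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    DEFAULT_ANALYTES,
    AnalyteSpec,
    ConcentrationRecord,
    ConsumptionRecord,
    SummaryRow,
    summarize,
)
from .distributions import FittedDistribution, fit_cumulative, sample_with_rng, stream_rng
from .risk import RiskResult, SensitivityResult, contribution_to_variance, round_sig

MODES = ("fitted_independent", "bootstrap_paired")


@dataclass(frozen=True)
class ExposureConfig:
    """Simulation settings.

    ``n_iterations`` defaults to 10,000 Monte Carlo iterations.
    """

    n_iterations: int = 10_000
    seed: int = 0
    mode: str = "fitted_independent"
    percentiles_reported: tuple[float, ...] = (50.0, 95.0)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


@dataclass(frozen=True)
class ExposureResult:
    """Simulated EDI draws for one analyte with summary statistics.

    ``input_draws`` retains the per-variable draw matrix (one vector per
    named stochastic input) for sensitivity analysis.
    """

    analyte: str
    draws: np.ndarray = field(repr=False)
    mean: float
    median: float
    p95: float
    input_draws: dict[str, np.ndarray] = field(repr=False)
    n_bodyweight_resampled: int = 0

    @classmethod
    def from_draws(
        cls,
        analyte: str,
        draws: np.ndarray,
        input_draws: dict[str, np.ndarray],
        n_bodyweight_resampled: int = 0,
    ) -> "ExposureResult":
        return cls(
            analyte=analyte,
            draws=draws,
            mean=float(draws.mean()),
            median=float(np.percentile(draws, 50)),
            p95=float(np.percentile(draws, 95)),
            input_draws=input_draws,
            n_bodyweight_resampled=n_bodyweight_resampled,
        )


def summarize_exposure(
    result: ExposureResult, percentiles: Sequence[float] = (50.0, 95.0)
) -> SummaryRow:
    """Descriptive summary of the EDI draw vector."""
    if result.draws.size == 0:
        raise ValueError("empty draw vector")
    return summarize(result.draws, percentiles=percentiles, group=result.analyte)


def _draw_bodyweights(
    model: FittedDistribution, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Draw body weights, resampling non-positive values (counted)."""
    bw = sample_with_rng(model, n, rng)
    resampled = 0
    for _ in range(100):
        bad = bw <= 0
        n_bad = int(bad.sum())
        if n_bad == 0:
            return bw, resampled
        resampled += n_bad
        bw[bad] = sample_with_rng(model, n_bad, rng)
    raise RuntimeError("body-weight model keeps producing non-positive draws")


def simulate_edi(
    consumption_models: Mapping[str, FittedDistribution],
    concentration_models: Mapping[str, FittedDistribution],
    bodyweight_model: FittedDistribution | Sequence[ConsumptionRecord],
    config: ExposureConfig,
    analyte: str = "analyte",
) -> ExposureResult:
    """Simulate the EDI distribution for one analyte.

    ``consumption_models`` and ``concentration_models`` are keyed by oil
    type and must cover the same oils. ``bodyweight_model`` is either a
    fitted distribution (``fitted_independent`` mode) or the survey records
    themselves (``bootstrap_paired`` mode, which resamples individuals and
    keeps each person's intakes paired with their body weight).

    Every variable draws from its own named random stream derived from
    ``config.seed``, so the draws for one oil are unaffected by which other
    oils are present.
    """
    oils = sorted(consumption_models)
    missing = set(oils) - set(concentration_models)
    if missing:
        raise ValueError(f"no concentration model for oils: {sorted(missing)}")

    n = config.n_iterations
    input_draws: dict[str, np.ndarray] = {}
    resampled = 0

    if config.mode == "fitted_independent":
        if not isinstance(bodyweight_model, FittedDistribution):
            raise TypeError("fitted_independent mode requires a body-weight distribution")
        for oil in oils:
            rng = stream_rng(config.seed, f"consumption:{oil}")
            input_draws[f"consumption:{oil}"] = sample_with_rng(
                consumption_models[oil], n, rng
            )
        bw, resampled = _draw_bodyweights(
            bodyweight_model, n, stream_rng(config.seed, "bodyweight")
        )
        input_draws["bodyweight"] = bw
        intake = {oil: input_draws[f"consumption:{oil}"] for oil in oils}
    elif config.mode == "bootstrap_paired":
        records = list(bodyweight_model)  # type: ignore[arg-type]
        if not records or isinstance(records[0], FittedDistribution):
            raise TypeError("bootstrap_paired mode requires survey records")
        table = _individual_table(records, oils)
        rng = stream_rng(config.seed, "individuals")
        idx = rng.integers(0, len(table.index), size=n)
        bw = table["body_weight"].to_numpy(dtype=float)[idx]
        if np.any(bw <= 0):
            raise ValueError("survey records contain non-positive body weights")
        input_draws["bodyweight"] = bw
        intake = {}
        for oil in oils:
            vec = table[oil].to_numpy(dtype=float)[idx]
            intake[oil] = vec
            input_draws[f"consumption:{oil}"] = vec
    else:  # pragma: no cover - config validates
        raise ValueError(config.mode)

    edi = np.zeros(n)
    for oil in oils:
        rng = stream_rng(config.seed, f"concentration:{analyte}:{oil}")
        conc = sample_with_rng(concentration_models[oil], n, rng)
        input_draws[f"concentration:{analyte}:{oil}"] = conc
        edi += intake[oil] * conc
    edi /= input_draws["bodyweight"]

    if np.any(edi < 0):
        raise ValueError("negative EDI draw; check input supports")
    return ExposureResult.from_draws(analyte, edi, input_draws, resampled)


def _individual_table(
    records: Sequence[ConsumptionRecord], oils: Sequence[str]
) -> pd.DataFrame:
    """Wide per-individual table: body weight plus intake per oil (0 if absent)."""
    rows: dict[str, dict[str, float]] = {}
    for rec in records:
        entry = rows.setdefault(rec.individual_id, {"body_weight": float(rec.body_weight or 0)})
        if rec.oil_type in oils and rec.intake is not None:
            entry[rec.oil_type] = entry.get(rec.oil_type, 0.0) + float(rec.intake)
    table = pd.DataFrame.from_dict(rows, orient="index")
    for oil in oils:
        if oil not in table.columns:
            table[oil] = 0.0
    return table.fillna(0.0)


class ExposureModel:
    """Probabilistic dietary exposure model for one or more analytes.

    Parameters
    ----------
    consumption_models : mapping oil type -> FittedDistribution
        Per-oil daily intake models, g/d (zeros represent non-consumers).
    concentration_models : mapping analyte -> (mapping oil type -> FittedDistribution)
        Per-analyte, per-oil concentration models, ng/g.
    bodyweight_model : FittedDistribution
        Body-weight model, kg (``fitted_independent`` mode).
    survey_records : sequence of ConsumptionRecord, optional
        Record-level survey data enabling ``bootstrap_paired`` mode.
    analytes : mapping name -> AnalyteSpec
        Registry carrying the LOD and BMDL10 per analyte.
    """

    def __init__(
        self,
        consumption_models: Mapping[str, FittedDistribution],
        concentration_models: Mapping[str, Mapping[str, FittedDistribution]],
        bodyweight_model: FittedDistribution | None = None,
        survey_records: Sequence[ConsumptionRecord] | None = None,
        analytes: Mapping[str, AnalyteSpec] | None = None,
    ) -> None:
        self.consumption_models = dict(consumption_models)
        self.concentration_models = {a: dict(m) for a, m in concentration_models.items()}
        self.bodyweight_model = bodyweight_model
        self.survey_records = list(survey_records) if survey_records is not None else None
        self.analytes = dict(analytes) if analytes is not None else dict(DEFAULT_ANALYTES)
        for analyte in self.concentration_models:
            if analyte not in self.analytes:
                raise ValueError(f"analyte {analyte!r} not in registry")
        oils = set(self.consumption_models)
        for analyte, models in self.concentration_models.items():
            if missing := oils - set(models):
                raise ValueError(
                    f"analyte {analyte!r} lacks concentration models for {sorted(missing)}"
                )

    @classmethod
    def from_records(
        cls,
        consumption_records: Sequence[ConsumptionRecord],
        concentration_records: Sequence[ConcentrationRecord],
        analytes: Mapping[str, AnalyteSpec] | None = None,
        anchor_percentiles: Sequence[float] | None = None,
    ) -> "ExposureModel":
        """Fit cumulative-anchor models from *prepared* record tables.

        Records are assumed already cleaned: incomplete individuals excluded,
        implausible intakes trimmed, and censored concentrations substituted
        (censored records must carry their substitution value).
        """
        registry = dict(analytes) if analytes is not None else dict(DEFAULT_ANALYTES)
        kw = {} if anchor_percentiles is None else {"anchor_percentiles": anchor_percentiles}

        intake_by_oil: dict[str, list[float]] = {}
        bodyweights: dict[str, float] = {}
        for rec in consumption_records:
            if rec.intake is not None:
                intake_by_oil.setdefault(rec.oil_type, []).append(rec.intake)
            if rec.body_weight is not None:
                bodyweights[rec.individual_id] = rec.body_weight
        consumption_models = {
            oil: fit_cumulative(vals, **kw) for oil, vals in intake_by_oil.items()
        }
        bw_model = fit_cumulative(list(bodyweights.values()), **kw)

        conc_by: dict[str, dict[str, list[float]]] = {}
        for rec in concentration_records:
            if rec.value is None:
                raise ValueError(
                    f"sample {rec.sample_id!r} is censored without a substituted value; "
                    "run substitute_censored first"
                )
            conc_by.setdefault(rec.analyte, {}).setdefault(rec.oil_type, []).append(rec.value)
        concentration_models = {
            analyte: {oil: fit_cumulative(vals, **kw) for oil, vals in per_oil.items()}
            for analyte, per_oil in conc_by.items()
        }
        # keep only oils covered by every analyte's concentration panel
        common = set(consumption_models)
        for per_oil in concentration_models.values():
            common &= set(per_oil)
        consumption_models = {o: m for o, m in consumption_models.items() if o in common}
        concentration_models = {
            a: {o: m for o, m in per_oil.items() if o in common}
            for a, per_oil in concentration_models.items()
        }
        return cls(
            consumption_models,
            concentration_models,
            bodyweight_model=bw_model,
            survey_records=list(consumption_records),
            analytes=registry,
        )

    def fit(self, config: ExposureConfig | None = None, **kwargs) -> "ExposureResults":
        """Run the Monte Carlo simulation and return the results object."""
        config = replace(config or ExposureConfig(), **kwargs) if kwargs else (
            config or ExposureConfig()
        )
        results: dict[str, ExposureResult] = {}
        for analyte, conc_models in sorted(self.concentration_models.items()):
            if config.mode == "bootstrap_paired":
                if self.survey_records is None:
                    raise ValueError("bootstrap_paired mode requires survey_records")
                bw_source: object = self.survey_records
            else:
                if self.bodyweight_model is None:
                    raise ValueError("fitted_independent mode requires a bodyweight_model")
                bw_source = self.bodyweight_model
            results[analyte] = simulate_edi(
                self.consumption_models,
                conc_models,
                bw_source,  # type: ignore[arg-type]
                config,
                analyte=analyte,
            )
        return ExposureResults(self, config, results)

    # alias familiar to simulation users
    simulate = fit


class ExposureResults:
    """Results of a fitted exposure simulation.

    Provides per-analyte EDI summaries, margin-of-exposure tables against
    the registry BMDL10 values, and contribution-to-variance sensitivity.
    """

    def __init__(
        self,
        model: ExposureModel,
        config: ExposureConfig,
        results: Mapping[str, ExposureResult],
    ) -> None:
        self.model = model
        self.config = config
        self.results = dict(results)

    def __getitem__(self, analyte: str) -> ExposureResult:
        return self.results[analyte]

    @property
    def analytes(self) -> list[str]:
        return sorted(self.results)

    def summary_frame(self) -> pd.DataFrame:
        """EDI statistics (ng/kg bw/d) per analyte."""
        rows = []
        for analyte in self.analytes:
            r = self.results[analyte]
            row = {"analyte": analyte, "mean": r.mean, "median": r.median}
            for p in self.config.percentiles_reported:
                row[f"p{p:g}"] = float(np.percentile(r.draws, p))
            rows.append(row)
        return pd.DataFrame(rows).set_index("analyte")

    def moe(self, statistics: Sequence[str] = ("mean", "median", "p95")) -> list[RiskResult]:
        """Margin of exposure at the requested EDI statistics."""
        out = []
        for analyte in self.analytes:
            r = self.results[analyte]
            spec = self.model.analytes[analyte]
            for stat in statistics:
                out.append(
                    RiskResult.from_edi(analyte, stat, getattr(r, stat), spec.bmdl10)
                )
        return out

    def moe_frame(self, statistics: Sequence[str] = ("mean", "median", "p95")) -> pd.DataFrame:
        rows = [
            {
                "analyte": r.analyte,
                "statistic": r.statistic,
                "edi_ng_per_kg_bw_day": r.edi,
                "bmdl10_mg_per_kg_bw_day": r.bmdl10,
                "moe": round_sig(r.moe, 3),
                "concern": r.concern,
            }
            for r in self.moe(statistics)
        ]
        return pd.DataFrame(rows)

    def sensitivity(self, analyte: str, grouped: bool = True) -> SensitivityResult:
        """Contribution to variance of the analyte's EDI.

        With ``grouped=True`` the stochastic inputs are pooled into the
        natural question the assessment asks — consumption vs concentration
        vs body weight — by summing squared rank correlations per group.
        """
        r = self.results[analyte]
        groups = None
        if grouped:
            groups = {
                "consumption": [k for k in r.input_draws if k.startswith("consumption:")],
                "concentration": [k for k in r.input_draws if k.startswith("concentration:")],
                "bodyweight": ["bodyweight"],
            }
            groups = {k: v for k, v in groups.items() if v}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant inputs (e.g. point masses) report 0
            return contribution_to_variance(
                r.input_draws, r.draws, groups=groups, output_name=f"EDI:{analyte}"
            )

    def summary(self) -> str:
        """Printable report: EDI statistics, MOEs, and sensitivity."""
        lines = [
            "Probabilistic dietary exposure assessment",
            "=" * 57,
            f"iterations: {self.config.n_iterations}   seed: {self.config.seed}   "
            f"mode: {self.config.mode}",
            "",
            "EDI (ng/kg bw/d)",
            f"{'analyte':<10}{'mean':>10}{'median':>10}{'P95':>10}",
        ]
        for analyte in self.analytes:
            r = self.results[analyte]
            lines.append(f"{analyte:<10}{r.mean:>10.2f}{r.median:>10.2f}{r.p95:>10.2f}")
        lines += ["", "Margin of exposure (concern if MOE < 1000)"]
        lines.append(f"{'analyte':<10}{'statistic':<10}{'EDI':>10}{'MOE':>12}{'concern':>9}")
        for rr in self.moe():
            lines.append(
                f"{rr.analyte:<10}{rr.statistic:<10}{rr.edi:>10.2f}"
                f"{round_sig(rr.moe, 3):>12.3g}{str(rr.concern):>9}"
            )
        lines += ["", "Contribution to variance (%)"]
        for analyte in self.analytes:
            sens = self.sensitivity(analyte)
            parts = ", ".join(f"{k}: {v:.1f}" for k, v in sens.contributions.items())
            lines.append(f"{analyte:<10}{parts}, residual: {sens.residual:.1f}")
        return "\n".join(lines)

    def plot_distribution(self, analyte: str, ax=None, bins: int = 60):
        """Histogram of the simulated EDI distribution for one analyte."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        r = self.results[analyte]
        ax.hist(r.draws, bins=bins, color="steelblue", edgecolor="none")
        ax.axvline(r.mean, color="firebrick", label=f"mean {r.mean:.1f}")
        ax.axvline(r.p95, color="darkorange", linestyle="--", label=f"P95 {r.p95:.1f}")
        ax.set_xlabel("EDI (ng/kg bw/d)")
        ax.set_ylabel("frequency")
        ax.set_title(f"Simulated dietary exposure: {analyte}")
        ax.legend()
        return ax
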