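"""Core records, tabular IO and data-preparation rules.

This module holds the two record types the assessment consumes — laboratory
concentration measurements (possibly left-censored) and survey consumption
records — together with the preparation steps applied before any modelling:

* half-LOD substitution for concentrations below the limit of detection,
* per-oil percentile trimming of implausible intakes,
* exclusion of individuals with incomplete survey information,
* descriptive summaries (n, mean, median, percentiles, min, max).

Percentile convention: linear interpolation between order statistics
(``numpy.percentile`` with the default ``"linear"`` method, the classical
"type 7" definition). The same convention is used throughout the package.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OIL_TYPES: tuple[str, ...] = (
    "peanut",
    "corn",
    "soybean",
    "sunflower",
    "rapeseed",
    "sesame",
)

#: Markers accepted as "censored / non-detect" in the concentration value column.
ND_MARKERS = frozenset({"ND", "nd", "n.d.", "<LOD", "<lod"})


@dataclass(frozen=True)
class AnalyteSpec:
    """An analyte with its detection limit and toxicological reference point.

    Parameters
    ----------
    name : str
        Analyte label, e.g. ``"SCCP"`` or ``"MCCP"``.
    lod : float
        Limit of detection, ng/g.
    bmdl10 : float
        Benchmark dose lower confidence limit (10% response), mg/kg bw/d.
    """

    name: str
    lod: float
    bmdl10: float

    def __post_init__(self) -> None:
        if not self.lod > 0:
            raise ValueError(f"LOD must be positive, got {self.lod}")
        if not self.bmdl10 > 0:
            raise ValueError(f"BMDL10 must be positive, got {self.bmdl10}")


#: Default analyte registry: short- and medium-chain chlorinated paraffins.
#: LODs are the analytical method's detection limits (ng/g); BMDL10 values are
#: the EFSA reference points (mg/kg bw/d) used for margin-of-exposure work.
DEFAULT_ANALYTES: dict[str, AnalyteSpec] = {
    "SCCP": AnalyteSpec("SCCP", lod=32.0, bmdl10=2.3),
    "MCCP": AnalyteSpec("MCCP", lod=16.0, bmdl10=36.0),
}


def make_registry(specs: Iterable[AnalyteSpec]) -> dict[str, AnalyteSpec]:
    """Build an analyte registry, enforcing unique names."""
    registry: dict[str, AnalyteSpec] = {}
    for spec in specs:
        if spec.name in registry:
            raise ValueError(f"duplicate analyte name {spec.name!r}")
        registry[spec.name] = spec
    return registry


@dataclass(frozen=True)
class ConcentrationRecord:
    """One measurement of one analyte in one oil sample.

    ``value`` is ``None`` for a censored (below-LOD) record that has not yet
    been substituted. After half-LOD substitution the record carries the
    substituted value but keeps ``censored=True`` so that censoring rates
    remain reportable downstream.
    """

    sample_id: str
    oil_type: str
    analyte: str
    value: float | None
    censored: bool
    lod: float

    def __post_init__(self) -> None:
        if not self.lod > 0:
            raise ValueError(
                f"sample {self.sample_id!r}: LOD must be positive, got {self.lod}"
            )
        if not self.censored:
            if self.value is None or not self.value >= 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: uncensored record requires a "
                    f"non-negative value, got {self.value!r}"
                )


@dataclass(frozen=True)
class ConsumptionRecord:
    """One individual's daily intake of one oil type, with body weight.

    Demographic fields may be ``None`` (missing); such individuals are removed
    by :func:`exclude_incomplete` before analysis.
    """

    individual_id: str
    oil_type: str
    intake: float | None  # g/d
    body_weight: float | None  # kg
    sex: str | None = None
    age: float | None = None

    def is_complete(self) -> bool:
        def _missing(x) -> bool:
            if x is None:
                return True
            if isinstance(x, float) and math.isnan(x):
                return True
            if isinstance(x, str) and not x.strip():
                return True
            return False

        return not (
            _missing(self.intake)
            or _missing(self.body_weight)
            or _missing(self.sex)
            or _missing(self.age)
        )


@dataclass(frozen=True)
class SummaryRow:
    """Descriptive statistics for one group of values."""

    group: str
    n: int
    mean: float
    median: float
    min: float
    max: float
    percentiles: dict[float, float] = field(default_factory=dict)

    @property
    def p95(self) -> float:
        return self.percentiles[95.0]


# ---------------------------------------------------------------------------
# Preparation operations
# ---------------------------------------------------------------------------


def substitute_censored(
    records: Sequence[ConcentrationRecord], fraction: float = 0.5
) -> list[ConcentrationRecord]:
    """Replace below-LOD concentrations with ``fraction × LOD``.

    Censored records receive ``value = fraction * lod`` and keep
    ``censored=True``; uncensored records pass through unchanged. The
    operation is idempotent: a censored record already holding the
    substitution value is left as is.
    """
    out: list[ConcentrationRecord] = []
    for rec in records:
        if not rec.censored:
            out.append(rec)
            continue
        if not rec.lod > 0:  # defensive: dataclass already validates
            raise ValueError(f"sample {rec.sample_id!r}: censored record without a positive LOD")
        out.append(dataclasses.replace(rec, value=fraction * rec.lod))
    return out


def trim_implausible(
    records: Sequence[ConsumptionRecord],
    low_pct: float = 1.0,
    high_pct: float = 99.0,
) -> list[ConsumptionRecord]:
    """Drop implausible intakes: strictly below P(low) or above P(high).

    Percentile bounds are computed per oil type on the *input* set, before any
    removal, with the package-wide linear-interpolation convention. Records
    with missing intake are passed through untouched (completeness is the job
    of :func:`exclude_incomplete`).
    """
    if not records:
        raise ValueError("trim_implausible requires at least one record")
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError(f"invalid percentile bounds ({low_pct}, {high_pct})")

    bounds: dict[str, tuple[float, float]] = {}
    by_oil: dict[str, list[float]] = {}
    for rec in records:
        if rec.intake is not None and not math.isnan(rec.intake):
            by_oil.setdefault(rec.oil_type, []).append(rec.intake)
    for oil, vals in by_oil.items():
        arr = np.asarray(vals, dtype=float)
        bounds[oil] = (
            float(np.percentile(arr, low_pct)),
            float(np.percentile(arr, high_pct)),
        )

    out: list[ConsumptionRecord] = []
    for rec in records:
        if rec.intake is None or math.isnan(rec.intake) or rec.oil_type not in bounds:
            out.append(rec)
            continue
        lo, hi = bounds[rec.oil_type]
        if rec.intake < lo or rec.intake > hi:
            continue
        out.append(rec)
    if records and not out:
        warnings.warn("trimming removed every record", stacklevel=2)
    return out


def exclude_incomplete(
    records: Sequence[ConsumptionRecord],
) -> list[ConsumptionRecord]:
    """Drop all rows of any individual with a missing field.

    Removal is per individual: if any of an individual's rows lacks intake,
    body weight, sex or age, every row of that individual is removed.
    """
    bad = {rec.individual_id for rec in records if not rec.is_complete()}
    return [rec for rec in records if rec.individual_id not in bad]


def summarize(
    values: Sequence[float],
    percentiles: Sequence[float] = (50.0, 95.0),
    group: str = "",
) -> SummaryRow:
    """Descriptive summary of a non-empty list of values."""
    if len(values) == 0:
        raise ValueError("summarize requires a non-empty list")
    arr = np.asarray(values, dtype=float)
    pct = {float(p): float(np.percentile(arr, p)) for p in percentiles}
    return SummaryRow(
        group=group,
        n=int(arr.size),
        mean=float(arr.mean()),
        median=float(np.percentile(arr, 50.0)),
        min=float(arr.min()),
        max=float(arr.max()),
        percentiles=pct,
    )


def censoring_rate(records: Sequence[ConcentrationRecord]) -> float:
    """Fraction of records flagged censored (substitution preserves the flag)."""
    if not records:
        raise ValueError("no records")
    return sum(r.censored for r in records) / len(records)


# ---------------------------------------------------------------------------
# CSV IO
# ---------------------------------------------------------------------------

CONCENTRATION_COLUMNS = ["sample_id", "oil_type", "analyte", "value", "censored", "lod"]
CONSUMPTION_COLUMNS = [
    "individual_id",
    "oil_type",
    "intake_g_per_day",
    "body_weight_kg",
    "sex",
    "age",
]


def concentration_to_frame(records: Sequence[ConcentrationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "oil_type": [r.oil_type for r in records],
            "analyte": [r.analyte for r in records],
            "value": [r.value for r in records],
            "censored": [r.censored for r in records],
            "lod": [r.lod for r in records],
        }
    )


def frame_to_concentration(df: pd.DataFrame) -> list[ConcentrationRecord]:
    records = []
    for row in df.itertuples(index=False):
        raw = row.value
        censored = bool(row.censored)
        if isinstance(raw, str):
            if raw.strip() in ND_MARKERS or not raw.strip():
                value, censored = None, True
            else:
                value = float(raw)
        elif raw is None or (isinstance(raw, float) and math.isnan(raw)):
            value = None
        else:
            value = float(raw)
        records.append(
            ConcentrationRecord(
                sample_id=str(row.sample_id),
                oil_type=str(row.oil_type),
                analyte=str(row.analyte),
                value=value,
                censored=censored,
                lod=float(row.lod),
            )
        )
    return records


def read_concentration_csv(path) -> list[ConcentrationRecord]:
    """Read a concentration table; empty cells and "ND" mark censored values."""
    df = pd.read_csv(path, dtype={"sample_id": str, "value": object})
    missing = set(CONCENTRATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"concentration CSV missing columns: {sorted(missing)}")
    return frame_to_concentration(df)


def write_concentration_csv(records: Sequence[ConcentrationRecord], path) -> None:
    concentration_to_frame(records).to_csv(path, index=False)


def consumption_to_frame(records: Sequence[ConsumptionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "oil_type": [r.oil_type for r in records],
            "intake_g_per_day": [r.intake for r in records],
            "body_weight_kg": [r.body_weight for r in records],
            "sex": [r.sex for r in records],
            "age": [r.age for r in records],
        }
    )


def frame_to_consumption(df: pd.DataFrame) -> list[ConsumptionRecord]:
    def _opt_float(x) -> float | None:
        if x is None or (isinstance(x, float) and math.isnan(x)):
            return None
        if isinstance(x, str) and not x.strip():
            return None
        return float(x)

    def _opt_str(x) -> str | None:
        if x is None or (isinstance(x, float) and math.isnan(x)):
            return None
        s = str(x)
        return s if s.strip() else None

    return [
        ConsumptionRecord(
            individual_id=str(row.individual_id),
            oil_type=str(row.oil_type),
            intake=_opt_float(row.intake_g_per_day),
            body_weight=_opt_float(row.body_weight_kg),
            sex=_opt_str(row.sex),
            age=_opt_float(row.age),
        )
        for row in df.itertuples(index=False)
    ]


def read_consumption_csv(path) -> list[ConsumptionRecord]:
    df = pd.read_csv(path, dtype={"individual_id": str})
    missing = set(CONSUMPTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"consumption CSV missing columns: {sorted(missing)}")
    return frame_to_consumption(df)


def write_consumption_csv(records: Sequence[ConsumptionRecord], path) -> None:
    consumption_to_frame(records).to_csv(path, index=False)
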