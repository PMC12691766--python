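"""Margin-of-exposure risk characterization and sensitivity analysis.

The margin of exposure (MOE) is the ratio of a toxicological reference point
— here the BMDL10, the lower confidence limit of the benchmark dose for a
10% response — to an exposure estimate:

    MOE = BMDL10 / EDI

with BMDL10 in mg/kg bw/d converted to ng/kg bw/d (× 10^6) so the ratio is
dimensionless. An MOE below 1000 flags a potential health concern.

Sensitivity uses a contribution-to-variance metric: each stochastic input's
squared Spearman rank correlation with the simulated output, expressed as a
percentage (normalized only when the squared correlations sum above 1, so
independent-input contributions are not inflated). The unattributed
remainder is reported as an explicit residual rather than folded into the
inputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
from scipy import stats

CONCERN_THRESHOLD = 1000.0

#: mg -> ng
MG_TO_NG = 1e6


def compute_moe(edi: float, bmdl10: float) -> float:
    """Margin of exposure for an EDI (ng/kg bw/d) against a BMDL10 (mg/kg bw/d)."""
    if not edi > 0:
        raise ValueError(f"EDI must be positive, got {edi}")
    if not bmdl10 > 0:
        raise ValueError(f"BMDL10 must be positive, got {bmdl10}")
    return bmdl10 * MG_TO_NG / edi


def flag_concern(moe: float, threshold: float = CONCERN_THRESHOLD) -> bool:
    """True iff the MOE falls strictly below the concern threshold."""
    if moe < 0:
        raise ValueError(f"MOE must be non-negative, got {moe}")
    return moe < threshold


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (display precision for MOEs)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass(frozen=True)
class RiskResult:
    """MOE at one exposure statistic for one analyte."""

    analyte: str
    statistic: str  # mean | median | p95
    edi: float  # ng/kg bw/d
    bmdl10: float  # mg/kg bw/d
    moe: float
    concern: bool

    @classmethod
    def from_edi(
        cls,
        analyte: str,
        statistic: str,
        edi: float,
        bmdl10: float,
        threshold: float = CONCERN_THRESHOLD,
    ) -> "RiskResult":
        moe = compute_moe(edi, bmdl10)
        return cls(analyte, statistic, edi, bmdl10, moe, flag_concern(moe, threshold))


@dataclass(frozen=True)
class SensitivityResult:
    """Per-input contribution-to-variance percentages for one output."""

    output: str
    contributions: dict[str, float]
    method: str = "normalized squared Spearman rank correlation"
    residual: float = field(default=0.0)

    def __post_init__(self) -> None:
        for name, c in self.contributions.items():
            if not (-1e-9 <= c <= 100 + 1e-9):
                raise ValueError(f"contribution for {name!r} out of [0, 100]: {c}")
        total = sum(self.contributions.values())
        if total > 100 + 1e-6:
            raise ValueError(f"contributions sum above 100%: {total}")


def contribution_to_variance(
    input_draws: Mapping[str, Sequence[float]],
    output_draws: Sequence[float],
    groups: Mapping[str, Sequence[str]] | None = None,
    output_name: str = "output",
) -> SensitivityResult:
    """Attribute output variance to stochastic inputs via rank correlations.

    For each input, the squared Spearman correlation with the output gives
    its contribution; contributions are scaled to percentages and normalized
    by the total squared correlation only when that total exceeds 1 (as
    happens with strongly dependent inputs). ``groups`` maps a group label to
    input names; group members' squared correlations are summed before
    normalization. Constant inputs (or a constant output) contribute 0, with
    a warning.
    """
    out = np.asarray(output_draws, dtype=float)
    if out.size < 100:
        raise ValueError("need at least 100 draws for a stable sensitivity estimate")
    out_constant = np.ptp(out) == 0
    if out_constant:
        warnings.warn("output is constant; all contributions are 0", stacklevel=2)

    rho_sq: dict[str, float] = {}
    for name, draws in input_draws.items():
        arr = np.asarray(draws, dtype=float)
        if arr.size != out.size:
            raise ValueError(f"input {name!r} length {arr.size} != output length {out.size}")
        if out_constant or np.ptp(arr) == 0:
            if not out_constant:
                warnings.warn(f"input {name!r} is constant; contribution set to 0", stacklevel=2)
            rho_sq[name] = 0.0
        else:
            rho = float(stats.spearmanr(arr, out).statistic)
            rho_sq[name] = rho * rho

    if groups is not None:
        grouped: dict[str, float] = {}
        for label, members in groups.items():
            grouped[label] = sum(rho_sq[m] for m in members)
        rho_sq = grouped

    denom = max(1.0, sum(rho_sq.values()))
    contributions = {name: 100.0 * v / denom for name, v in rho_sq.items()}
    residual = max(0.0, 100.0 - sum(contributions.values()))
    return SensitivityResult(
        output=output_name, contributions=contributions, residual=residual
    )
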