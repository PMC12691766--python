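"""Synthetic survey, concentration and congener data generators.

No record-level data accompany the study conditions this package targets, so
every pipeline stage is exercised on generated data with the documented
statistical structure:

* right-skewed (lognormal) per-oil consumption with an optional non-consumer
  fraction per oil, plus lognormal body weights;
* per-oil, per-analyte lognormal concentrations moment-matched to target
  (mean, CV) pairs, paired across analytes through a Gaussian copula hitting
  a target Spearman correlation, and left-censored below the analyte LOD;
* congener-group matrices built as the outer product of chain-length and
  chlorination marginals with multiplicative lognormal noise.

Every generator is a pure function of its parameters and seed.

The ``demo_*`` constructors encode the calibration used throughout the
package's examples: pooled daily oil intake with median 23.91 g/d and P95
67.23 g/d, per-oil mean concentrations of tens to hundreds of ng/g with
LODs of 32 (SCCP) and 16 (MCCP) ng/g, and an SCCP–MCCP rank correlation of
0.411.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .congeners import CongenerMatrix
from .data import ConcentrationRecord, ConsumptionRecord
from .distributions import stream_rng

# ---------------------------------------------------------------------------
# lognormal helpers
# ---------------------------------------------------------------------------


def lognormal_from_mean_cv(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given arithmetic mean and CV."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    sigma2 = math.log1p(cv * cv)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def lognormal_from_median_p95(median: float, p95: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given median and 95th percentile."""
    if not 0 < median < p95:
        raise ValueError("need 0 < median < p95")
    z95 = stats.norm.ppf(0.95)
    return math.log(median), math.log(p95 / median) / z95


# ---------------------------------------------------------------------------
# consumption survey
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OilIntakeParams:
    """Lognormal intake model for one oil type.

    ``consumer_fraction`` is the probability an individual consumes the oil
    at all; non-consumers get intake 0.
    """

    mu: float
    sigma: float
    consumer_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0 <= self.consumer_fraction <= 1:
            raise ValueError("consumer_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SurveyGeneratorParams:
    n_individuals: int
    oils: Mapping[str, OilIntakeParams]
    body_weight_mu: float = math.log(60.0)  # median 60 kg
    body_weight_sigma: float = 0.15
    female_fraction: float = 0.516
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be at least 1")
        if self.body_weight_sigma < 0:
            raise ValueError("body_weight_sigma must be non-negative")
        if not self.oils:
            raise ValueError("at least one oil required")

    @classmethod
    def pooled(cls, n_individuals: int, seed: int = 0, oil_type: str = "pooled") -> "SurveyGeneratorParams":
        """Single pooled-oil survey with median 23.91 g/d and P95 67.23 g/d."""
        mu, sigma = lognormal_from_median_p95(23.91, 67.23)
        return cls(n_individuals, {oil_type: OilIntakeParams(mu, sigma)}, seed=seed)

    @classmethod
    def demo(cls, n_individuals: int, seed: int = 0) -> "SurveyGeneratorParams":
        """Six-oil demo survey.

        Per-oil medians/P95s and consumer fractions are chosen so that
        rapeseed, peanut and corn dominate (medians above 25 g/d), sesame is
        a low-volume condiment oil (population mean about 2.7 g/d among a
        long-tailed distribution), and the population-wide mean total intake
        lands near 27 g/d.
        """
        def mp(median, p95, frac):
            mu, sigma = lognormal_from_median_p95(median, p95)
            return OilIntakeParams(mu, sigma, frac)

        oils = {
            "peanut": mp(26.0, 65.0, 0.25),
            "rapeseed": mp(27.0, 68.0, 0.30),
            "corn": mp(25.5, 63.0, 0.15),
            "soybean": mp(20.0, 55.0, 0.20),
            "sunflower": mp(15.0, 45.0, 0.08),
            "sesame": OilIntakeParams(math.log(1.5), 1.098, 0.30),
        }
        return cls(n_individuals, oils, seed=seed)


def generate_survey(params: SurveyGeneratorParams) -> list[ConsumptionRecord]:
    """Generate one consumption row per individual per oil (zeros included)."""
    n = params.n_individuals
    bw = np.exp(
        params.body_weight_mu
        + params.body_weight_sigma * stream_rng(params.seed, "survey:bodyweight").standard_normal(n)
    )
    sex = np.where(
        stream_rng(params.seed, "survey:sex").random(n) < params.female_fraction, "F", "M"
    )
    age = stream_rng(params.seed, "survey:age").uniform(18.0, 80.0, n).round(0)

    records: list[ConsumptionRecord] = []
    intake_by_oil: dict[str, np.ndarray] = {}
    for oil, p in sorted(params.oils.items()):
        rng = stream_rng(params.seed, f"survey:intake:{oil}")
        consumes = rng.random(n) < p.consumer_fraction
        draws = np.exp(p.mu + p.sigma * rng.standard_normal(n))
        intake_by_oil[oil] = np.where(consumes, draws, 0.0)

    for i in range(n):
        ind = f"ind-{i:06d}"
        for oil in sorted(params.oils):
            records.append(
                ConsumptionRecord(
                    individual_id=ind,
                    oil_type=oil,
                    intake=float(intake_by_oil[oil][i]),
                    body_weight=float(bw[i]),
                    sex=str(sex[i]),
                    age=float(age[i]),
                )
            )
    return records


# ---------------------------------------------------------------------------
# concentration panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcentrationGeneratorParams:
    """Paired SCCP/MCCP lognormal concentrations per oil.

    ``means`` maps oil type -> {analyte: mean ng/g}. Values are paired
    across the two analytes through a Gaussian copula calibrated to
    ``rank_correlation`` (Spearman); values below the analyte LOD are
    flagged censored.
    """

    means: Mapping[str, Mapping[str, float]]
    lods: Mapping[str, float]
    n_samples: int = 50
    cv: float = 0.6
    rank_correlation: float = 0.411
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be at least 1")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if not -1 <= self.rank_correlation <= 1:
            raise ValueError("rank_correlation must be in [-1, 1]")
        if abs(self.rank_correlation) > 0.999 and self.cv > 0:
            raise ValueError(
                "rank correlation magnitude above 0.999 is not attainable with the "
                "Gaussian copula; feasible range is (-0.999, 0.999)"
            )
        for oil, per_analyte in self.means.items():
            for analyte, m in per_analyte.items():
                if m < 0:
                    raise ValueError(f"negative mean for {oil}/{analyte}")
                if analyte not in self.lods:
                    raise ValueError(f"no LOD for analyte {analyte!r}")

    @classmethod
    def demo(cls, n_samples: int = 50, seed: int = 0) -> "ConcentrationGeneratorParams":
        """Six-oil panel with mean SCCP/MCCP levels typical of market oils."""
        means = {
            "sunflower": {"SCCP": 54.0, "MCCP": 47.0},
            "peanut": {"SCCP": 121.0, "MCCP": 211.0},
            "soybean": {"SCCP": 119.0, "MCCP": 187.0},
            "sesame": {"SCCP": 165.0, "MCCP": 82.0},
            "rapeseed": {"SCCP": 125.0, "MCCP": 170.0},
            "corn": {"SCCP": 79.0, "MCCP": 132.0},
        }
        return cls(means=means, lods={"SCCP": 32.0, "MCCP": 16.0}, n_samples=n_samples, seed=seed)


def spearman_to_pearson_copula(rho_s: float) -> float:
    """Gaussian-copula correlation reproducing a target Spearman rho."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def generate_concentrations(
    params: ConcentrationGeneratorParams, return_truth: bool = False
) -> list[ConcentrationRecord] | tuple[list[ConcentrationRecord], pd.DataFrame]:
    """Generate a censored concentration panel.

    With ``return_truth=True`` a second value is returned: the uncensored
    draw table (one row per sample, one column per analyte), the generator's
    internal bookkeeping for oracle tests.
    """
    r = spearman_to_pearson_copula(params.rank_correlation)
    records: list[ConcentrationRecord] = []
    truth_rows = []
    for oil in sorted(params.means):
        per_analyte = params.means[oil]
        analytes = sorted(per_analyte)
        rng = stream_rng(params.seed, f"concentration:{oil}")
        k = len(analytes)
        if k == 2:
            cov = np.array([[1.0, r], [r, 1.0]])
            z = rng.multivariate_normal(np.zeros(2), cov, size=params.n_samples, method="cholesky")
        else:
            z = rng.standard_normal((params.n_samples, k))
        for j, analyte in enumerate(analytes):
            mean = per_analyte[analyte]
            lod = params.lods[analyte]
            if params.cv == 0 or mean == 0:
                values = np.full(params.n_samples, mean)
            else:
                mu, sigma = lognormal_from_mean_cv(mean, params.cv)
                values = np.exp(mu + sigma * z[:, j])
            for i, v in enumerate(values):
                sample_id = f"{oil}-{i:04d}"
                censored = bool(v < lod)
                records.append(
                    ConcentrationRecord(
                        sample_id=sample_id,
                        oil_type=oil,
                        analyte=analyte,
                        value=None if censored else float(v),
                        censored=censored,
                        lod=lod,
                    )
                )
                truth_rows.append((sample_id, oil, analyte, float(v)))
    if return_truth:
        truth = pd.DataFrame(
            truth_rows, columns=["sample_id", "oil_type", "analyte", "true_value"]
        )
        return records, truth
    return records


# ---------------------------------------------------------------------------
# congener matrices
# ---------------------------------------------------------------------------

#: Chain-length profiles: printed average percentages, renormalized to sum to 1.
DEMO_CHAIN_FRACTIONS = {
    "SCCP": {10: 0.34 / 0.99, 11: 0.25 / 0.99, 12: 0.19 / 0.99, 13: 0.21 / 0.99},
    "MCCP": {14: 0.36, 15: 0.42, 16: 0.16, 17: 0.06},
}

#: Chlorination profiles: Cl6–Cl8 carry about 65% of SCCPs (Cl7 leading);
#: Cl5, Cl6 and Cl8 carry about 65% of MCCPs (Cl8 leading).
DEMO_CHLORINE_FRACTIONS = {
    "SCCP": {5: 0.12, 6: 0.20, 7: 0.25, 8: 0.20, 9: 0.13, 10: 0.10},
    "MCCP": {5: 0.22, 6: 0.18, 7: 0.14, 8: 0.25, 9: 0.12, 10: 0.09},
}


def generate_congener_matrix(
    chain_fractions: Mapping[int, float],
    chlorine_fractions: Mapping[int, float],
    noise_cv: float = 0.0,
    seed: int = 0,
    analyte: str = "SCCP",
    total: float = 100.0,
) -> CongenerMatrix:
    """Congener matrix from marginal profiles with multiplicative noise.

    The noise is mean-one lognormal per cell; the matrix is renormalized to
    ``total``, so expected marginals equal the input fractions (exactly when
    ``noise_cv=0``).
    """
    chain = np.array([chain_fractions[c] for c in sorted(chain_fractions)], dtype=float)
    chlor = np.array([chlorine_fractions[c] for c in sorted(chlorine_fractions)], dtype=float)
    for name, vec in (("chain", chain), ("chlorine", chlor)):
        if abs(vec.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} fractions must sum to 1 (±1e-6), got {vec.sum():.8f}")
    base = total * np.outer(chain, chlor)
    if noise_cv > 0:
        sigma2 = math.log1p(noise_cv * noise_cv)
        z = stream_rng(seed, f"congener:{analyte}").standard_normal(base.shape)
        base = base * np.exp(math.sqrt(sigma2) * z - sigma2 / 2.0)
        base *= total / base.sum()
    return CongenerMatrix(
        analyte=analyte,
        carbons=tuple(sorted(chain_fractions)),
        chlorines=tuple(sorted(chlorine_fractions)),
        abundance=base,
    )
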