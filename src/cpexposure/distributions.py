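"""Sampleable probability models for exposure inputs.

The workhorse family is the *cumulative anchor* distribution: a bounded
distribution specified by its minimum, maximum and a set of ordered
(percentile, value) anchor points, with the CDF linearly interpolated between
anchors (piecewise-uniform density). This mirrors the cumulative-fit
construct used in spreadsheet risk software, where an input variable is
described by its observed extremes plus percentile points. Parametric
alternatives (lognormal, gamma), a point mass, and an empirical bootstrap
complete the set.

Random streams: every stochastic variable in a pipeline run draws from its
own generator, derived from the run seed and the variable's *name* via a
stable hash. Adding or removing a variable therefore never perturbs the
draws of the others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
from scipy import stats

FAMILIES = ("cumulative_anchor", "lognormal", "gamma", "point_mass", "empirical_bootstrap")

DEFAULT_ANCHOR_PERCENTILES: tuple[float, ...] = tuple(float(p) for p in range(10, 100, 10))


def stable_hash(name: str) -> int:
    """Deterministic 32-bit hash of a variable name (stable across runs)."""
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big")


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Generator for one named variable stream under a run seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), stable_hash(name)]))


@dataclass(frozen=True)
class FittedDistribution:
    """A fitted 1-D probability model.

    ``params`` is family-specific:

    * ``cumulative_anchor`` — ``percentiles`` and ``values`` arrays including
      the 0th and 100th percentiles (support bounds);
    * ``lognormal`` — ``mu``, ``sigma`` of the underlying normal;
    * ``gamma`` — shape ``k`` and scale ``theta``;
    * ``point_mass`` — ``value``;
    * ``empirical_bootstrap`` — the ``values`` resampled from.
    """

    family: str
    params: dict = field(repr=False)
    support: tuple[float, float]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "cumulative_anchor":
            ps = np.asarray(self.params["percentiles"], dtype=float)
            vs = np.asarray(self.params["values"], dtype=float)
            if np.any(np.diff(ps) < 0) or np.any(np.diff(vs) < 0):
                raise ValueError("anchors must be non-decreasing in percentile and value")
            if not (np.isfinite(self.support[0]) and np.isfinite(self.support[1])):
                raise ValueError("cumulative_anchor requires finite support bounds")
        if self.family == "lognormal" and not self.params["sigma"] > 0:
            raise ValueError("lognormal sigma must be positive")
        if self.family == "gamma" and not (self.params["k"] > 0 and self.params["theta"] > 0):
            raise ValueError("gamma parameters must be positive")

    # -- quantile / cdf / moments -------------------------------------------

    def quantile(self, u):
        """Quantile function at probabilities ``u`` in [0, 1]."""
        u = np.asarray(u, dtype=float)
        if self.family == "cumulative_anchor":
            ps = np.asarray(self.params["percentiles"], dtype=float) / 100.0
            vs = np.asarray(self.params["values"], dtype=float)
            return np.interp(u, ps, vs)
        if self.family == "lognormal":
            return stats.lognorm.ppf(u, s=self.params["sigma"], scale=np.exp(self.params["mu"]))
        if self.family == "gamma":
            return stats.gamma.ppf(u, a=self.params["k"], scale=self.params["theta"])
        if self.family == "point_mass":
            return np.full_like(u, self.params["value"], dtype=float)
        raise ValueError(f"quantile not defined for {self.family}")

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        if self.family == "cumulative_anchor":
            ps = np.asarray(self.params["percentiles"], dtype=float) / 100.0
            vs = np.asarray(self.params["values"], dtype=float)
            return np.interp(x, vs, ps)
        if self.family == "lognormal":
            return stats.lognorm.cdf(x, s=self.params["sigma"], scale=np.exp(self.params["mu"]))
        if self.family == "gamma":
            return stats.gamma.cdf(x, a=self.params["k"], scale=self.params["theta"])
        if self.family == "point_mass":
            return (x >= self.params["value"]).astype(float)
        if self.family == "empirical_bootstrap":
            vals = np.sort(np.asarray(self.params["values"], dtype=float))
            return np.searchsorted(vals, x, side="right") / vals.size
        raise ValueError(f"cdf not defined for {self.family}")

    def mean(self) -> float:
        """Analytic mean of the fitted model."""
        if self.family == "cumulative_anchor":
            # piecewise-uniform: each CDF segment contributes its probability
            # mass times the segment midpoint
            ps = np.asarray(self.params["percentiles"], dtype=float) / 100.0
            vs = np.asarray(self.params["values"], dtype=float)
            w = np.diff(ps)
            mid = (vs[:-1] + vs[1:]) / 2.0
            return float(np.sum(w * mid))
        if self.family == "lognormal":
            return float(np.exp(self.params["mu"] + self.params["sigma"] ** 2 / 2.0))
        if self.family == "gamma":
            return float(self.params["k"] * self.params["theta"])
        if self.family == "point_mass":
            return float(self.params["value"])
        if self.family == "empirical_bootstrap":
            return float(np.mean(self.params["values"]))
        raise ValueError(self.family)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        params = {
            k: (np.asarray(v).tolist() if isinstance(v, (np.ndarray, list, tuple)) else float(v))
            for k, v in self.params.items()
        }
        return {"family": self.family, "params": params, "support": list(self.support)}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, doc: dict) -> "FittedDistribution":
        return cls(
            family=doc["family"],
            params=dict(doc["params"]),
            support=(float(doc["support"][0]), float(doc["support"][1])),
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedDistribution":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class FitDiagnostics:
    family: str
    n: int
    log_likelihood: float | None = None
    anchor_residual: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")


def point_mass(value: float) -> FittedDistribution:
    return FittedDistribution("point_mass", {"value": float(value)}, (float(value), float(value)))


def fit_cumulative(
    samples: Sequence[float],
    anchor_percentiles: Sequence[float] = DEFAULT_ANCHOR_PERCENTILES,
    bounds: tuple[float, float] | None = None,
) -> FittedDistribution:
    """Fit a cumulative-anchor distribution to a sample.

    The quantile function linearly interpolates between the sample minimum,
    the anchor quantiles (default: deciles, linear-interpolation convention)
    and the sample maximum; ``bounds`` overrides the observed extremes.
    Constant samples degenerate to a point mass. Requires n ≥ 10 — below
    that, anchor quantiles are not meaningful and ``empirical_bootstrap`` is
    the recommended fallback.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.size < 10:
        raise ValueError(
            f"cumulative fit requires at least 10 samples (got {arr.size}); "
            "use an empirical_bootstrap distribution instead"
        )
    ps = np.asarray(anchor_percentiles, dtype=float)
    if np.any(np.diff(ps) <= 0) or np.any(ps <= 0) or np.any(ps >= 100):
        raise ValueError("anchor percentiles must be strictly increasing within (0, 100)")
    lo, hi = (float(arr.min()), float(arr.max())) if bounds is None else map(float, bounds)
    if np.ptp(arr) == 0 and bounds is None:
        return point_mass(arr[0])
    anchor_vals = np.percentile(arr, ps)
    all_ps = np.concatenate([[0.0], ps, [100.0]])
    all_vs = np.concatenate([[lo], np.clip(anchor_vals, lo, hi), [hi]])
    all_vs = np.maximum.accumulate(all_vs)  # guard monotonicity under bounds override
    return FittedDistribution(
        "cumulative_anchor",
        {"percentiles": all_ps, "values": all_vs},
        (lo, hi),
    )


def fit_parametric(
    samples: Sequence[float], family: str
) -> tuple[FittedDistribution, FitDiagnostics]:
    """Maximum-likelihood lognormal or gamma fit with diagnostics."""
    arr = np.asarray(samples, dtype=float)
    if arr.size < 10:
        raise ValueError(f"parametric fit requires at least 10 samples (got {arr.size})")
    if family == "lognormal":
        if np.any(arr <= 0):
            raise ValueError("lognormal fit requires strictly positive values")
        logs = np.log(arr)
        mu = float(logs.mean())
        sigma = float(logs.std(ddof=0))
        if sigma == 0:
            dist = point_mass(arr[0])
            return dist, FitDiagnostics("point_mass", n=arr.size)
        ll = float(np.sum(stats.lognorm.logpdf(arr, s=sigma, scale=np.exp(mu))))
        dist = FittedDistribution("lognormal", {"mu": mu, "sigma": sigma}, (0.0, np.inf))
        return dist, FitDiagnostics("lognormal", n=arr.size, log_likelihood=ll)
    if family == "gamma":
        if np.any(arr <= 0):
            raise ValueError("gamma fit requires strictly positive values")
        if np.ptp(arr) == 0:
            dist = point_mass(arr[0])
            return dist, FitDiagnostics("point_mass", n=arr.size)
        k, _, theta = stats.gamma.fit(arr, floc=0)
        ll = float(np.sum(stats.gamma.logpdf(arr, a=k, scale=theta)))
        dist = FittedDistribution("gamma", {"k": float(k), "theta": float(theta)}, (0.0, np.inf))
        return dist, FitDiagnostics("gamma", n=arr.size, log_likelihood=ll)
    raise ValueError(f"unsupported parametric family {family!r}")


def fit_bootstrap(samples: Sequence[float]) -> FittedDistribution:
    """Empirical bootstrap model: draws resample the observed values."""
    arr = np.asarray(samples, dtype=float)
    if arr.size < 1:
        raise ValueError("bootstrap fit requires at least one sample")
    return FittedDistribution(
        "empirical_bootstrap",
        {"values": arr.copy()},
        (float(arr.min()), float(arr.max())),
    )


def sample_with_rng(dist: FittedDistribution, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` values using an externally managed generator."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if dist.family == "empirical_bootstrap":
        vals = np.asarray(dist.params["values"], dtype=float)
        return rng.choice(vals, size=n, replace=True)
    if dist.family == "point_mass":
        return np.full(n, float(dist.params["value"]))
    # inverse-CDF sampling keeps every family on one uniform stream
    return np.asarray(dist.quantile(rng.random(n)), dtype=float)


def sample_from(dist: FittedDistribution, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` values; identical seed gives identical draws."""
    return sample_with_rng(dist, n, np.random.default_rng(seed))
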