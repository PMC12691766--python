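"""Congener-group (homologue) profiles of chlorinated paraffins.

A chlorinated-paraffin measurement resolves into congener groups indexed by
carbon chain length (C10–C13 for SCCPs, C14–C17 for MCCPs) and chlorine
substitution count. This module computes the two marginal profiles (chain
length and chlorination degree), ranks dominant congener groups, and provides
the Spearman rank association used to compare paired SCCP/MCCP levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

CARBON_RANGES = {"SCCP": range(10, 14), "MCCP": range(14, 18)}


@dataclass(frozen=True)
class CongenerMatrix:
    """Abundances per (carbon chain length, chlorine number) cell.

    ``abundance[i, j]`` corresponds to ``carbons[i]`` and ``chlorines[j]``.
    Units may be absolute (ng/g) or relative; marginals are scale-invariant.
    """

    analyte: str
    carbons: tuple[int, ...]
    chlorines: tuple[int, ...]
    abundance: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.abundance, dtype=float)
        object.__setattr__(self, "abundance", arr)
        if arr.shape != (len(self.carbons), len(self.chlorines)):
            raise ValueError(
                f"abundance shape {arr.shape} does not match "
                f"({len(self.carbons)}, {len(self.chlorines)})"
            )
        if np.any(arr < 0):
            raise ValueError("abundances must be non-negative")
        if not np.any(arr > 0):
            raise ValueError("congener matrix must have at least one positive cell")
        if self.analyte in CARBON_RANGES:
            expected = tuple(CARBON_RANGES[self.analyte])
            if tuple(self.carbons) != expected:
                raise ValueError(
                    f"{self.analyte} carbon range must be {expected}, got {self.carbons}"
                )

    @property
    def total(self) -> float:
        return float(self.abundance.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.abundance, index=list(self.carbons), columns=list(self.chlorines))


def chain_length_marginal(m: CongenerMatrix) -> dict[int, float]:
    """Fraction of total abundance per carbon chain length (sums to 1)."""
    sums = m.abundance.sum(axis=1)
    return {c: float(s / m.total) for c, s in zip(m.carbons, sums)}


def chlorination_marginal(m: CongenerMatrix) -> dict[int, float]:
    """Fraction of total abundance per chlorine number (sums to 1)."""
    sums = m.abundance.sum(axis=0)
    return {cl: float(s / m.total) for cl, s in zip(m.chlorines, sums)}


def dominant_congeners(m: CongenerMatrix, k: int) -> list[tuple[int, int, float]]:
    """Top-``k`` congener groups by abundance.

    Ties are broken deterministically: lower carbon first, then lower chlorine.
    If ``k`` exceeds the number of cells the full ranking is returned.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    cells = [
        (c, cl, float(m.abundance[i, j]))
        for i, c in enumerate(m.carbons)
        for j, cl in enumerate(m.chlorines)
    ]
    cells.sort(key=lambda t: (-t[2], t[0], t[1]))
    return cells[:k]


def mean_profile(matrices: Sequence[CongenerMatrix], axis: str = "carbon") -> dict[int, float]:
    """Equal-weight average of per-sample marginal profiles.

    Each sample's matrix is normalized before averaging, so every sample
    contributes equally regardless of its absolute abundance. Pass
    ``axis="chlorine"`` for the chlorination-degree profile.
    """
    if not matrices:
        raise ValueError("no matrices")
    marginal = chain_length_marginal if axis == "carbon" else chlorination_marginal
    acc: dict[int, float] = {}
    for m in matrices:
        for key, frac in marginal(m).items():
            acc[key] = acc.get(key, 0.0) + frac
    return {key: val / len(matrices) for key, val in sorted(acc.items())}


def rank_association(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    Returns ``(rho, p)``; the p-value uses the standard t-distribution
    approximation for the null of no association. Raises if either vector is
    constant (the rank correlation is undefined).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    res = stats.spearmanr(xa, ya)
    return float(res.statistic), float(res.pvalue)


# Long-format congener CSV: sample_id, analyte, carbon, chlorine, abundance


def matrices_from_frame(df: pd.DataFrame) -> dict[str, CongenerMatrix]:
    """Build per-sample congener matrices from a long-format table."""
    required = {"sample_id", "analyte", "carbon", "chlorine", "abundance"}
    if missing := required - set(df.columns):
        raise ValueError(f"congener table missing columns: {sorted(missing)}")
    out: dict[str, CongenerMatrix] = {}
    for (sample_id, analyte), grp in df.groupby(["sample_id", "analyte"], sort=True):
        pivot = grp.pivot_table(
            index="carbon", columns="chlorine", values="abundance", aggfunc="sum", fill_value=0.0
        ).sort_index()
        out[f"{sample_id}:{analyte}"] = CongenerMatrix(
            analyte=str(analyte),
            carbons=tuple(int(c) for c in pivot.index),
            chlorines=tuple(int(c) for c in pivot.columns),
            abundance=pivot.to_numpy(dtype=float),
        )
    return out


def read_congener_csv(path) -> dict[str, CongenerMatrix]:
    return matrices_from_frame(pd.read_csv(path))


def write_congener_csv(matrices: dict[str, CongenerMatrix], path) -> None:
    rows = []
    for key, m in matrices.items():
        sample_id, _, analyte = key.rpartition(":")
        for i, c in enumerate(m.carbons):
            for j, cl in enumerate(m.chlorines):
                rows.append((sample_id, analyte, c, cl, m.abundance[i, j]))
    pd.DataFrame(
        rows, columns=["sample_id", "analyte", "carbon", "chlorine", "abundance"]
    ).to_csv(path, index=False)
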