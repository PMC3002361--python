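"""Correlation of dynamic and energetic descriptors with dissociation constants.

Binding affinity is summarized by the dissociation constant Kd (nM; lower Kd
means tighter binding).  Descriptors computed per complex — RMSF flexibility
sums, Schlitter entropy, intra-protein stabilization energy — are correlated
against log10(Kd) with the Pearson product-moment coefficient; the log
transform puts Kd on a free-energy-like scale.  With a handful of complexes
these are descriptive statistics, not hypothesis tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AffinityRecord:
    """One complex: its Kd (nM) and any named scalar descriptors."""

    complex_id: str
    kd_nm: float
    descriptors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kd_nm <= 0:
            raise ValueError(f"{self.complex_id}: Kd must be positive")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r plus the least-squares line for one descriptor vs log10(Kd)."""

    descriptor: str
    r: float
    n: int
    slope: float
    intercept: float


def log_kd(kd_nm: float | np.ndarray) -> float | np.ndarray:
    """Base-10 log of Kd expressed in nM (1 nM → 0)."""
    kd_nm = np.asarray(kd_nm, dtype=float)
    if np.any(kd_nm <= 0):
        raise ValueError("Kd must be positive")
    out = np.log10(kd_nm)
    return float(out) if out.ndim == 0 else out


def pearson(
    xs: Sequence[float], ys: Sequence[float], descriptor: str = ""
) -> CorrelationResult:
    """Product-moment correlation with least-squares slope and intercept."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape:
        raise ValueError("sequences must have equal length")
    n = len(xs)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("correlation undefined for a constant sequence")
    fit = stats.linregress(xs, ys)
    return CorrelationResult(
        descriptor=descriptor,
        r=float(fit.rvalue),
        n=n,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def correlate_descriptor(
    records: Sequence[AffinityRecord],
    descriptor: str,
    transform: str = "log10",
) -> CorrelationResult:
    """Correlate a named descriptor with log10(Kd) across complexes.

    ``transform="linear"`` correlates against untransformed Kd instead (the
    two typically give comparable coefficients for these systems; log10 is
    the reporting convention).
    """
    for rec in records:
        if descriptor not in rec.descriptors:
            raise KeyError(
                f"descriptor {descriptor!r} missing for complex {rec.complex_id}"
            )
    kd = np.array([rec.kd_nm for rec in records])
    xs = log_kd(kd) if transform == "log10" else kd
    ys = np.array([rec.descriptors[descriptor] for rec in records])
    return pearson(xs, ys, descriptor=descriptor)


def descriptor_table(records: Sequence[AffinityRecord]) -> pd.DataFrame:
    """One row per complex: Kd, log10(Kd), then descriptors in sorted order."""
    names = sorted({name for rec in records for name in rec.descriptors})
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "complex_id": rec.complex_id,
            "kd_nM": rec.kd_nm,
            "log10_kd": math.log10(rec.kd_nm),
        }
        for name in names:
            row[name] = rec.descriptors.get(name, float("nan"))
        rows.append(row)
    columns = ["complex_id", "kd_nM", "log10_kd", *names]
    return pd.DataFrame(rows, columns=columns)


def records_from_table(df: pd.DataFrame) -> list[AffinityRecord]:
    """Inverse of :func:`descriptor_table` (derived columns are recomputed)."""
    skip = {"complex_id", "kd_nM", "log10_kd"}
    names = [c for c in df.columns if c not in skip]
    return [
        AffinityRecord(
            complex_id=str(row["complex_id"]),
            kd_nm=float(row["kd_nM"]),
            descriptors={
                n: float(row[n]) for n in names if not pd.isna(row[n])
            },
        )
        for _, row in df.iterrows()
    ]
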