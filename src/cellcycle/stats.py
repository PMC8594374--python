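"""Pearson correlation machinery and the diagnostic correlation suite.

The suite computes the four model-discriminating correlations
rho(S_b, Delta_d), rho(s_i, delta_ii), rho(s_i, delta_id), rho(s_i, tau_cyc)
plus the three homeostasis correlations rho_i, rho_d, rho_id.  Pairs with a
missing member (e.g. boundary generations without a delta_ii) are dropped
pairwise, never imputed.  Standard errors are reported on the Fisher-z scale
(1/sqrt(n-3)), the repo-wide convention for 3-SE stochastic tolerance checks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedCorrelationError
from .lineage import normalize_by_mean

#: Names of the suite coefficients in report order.
SUITE_COEFFICIENTS = (
    "rho_Sb_Dd", "rho_si_dii", "rho_si_did", "rho_si_taucyc",
    "rho_i", "rho_d", "rho_id",
)

_SUITE_PAIRS = {
    "rho_Sb_Dd": ("S_b", "Delta_d"),
    "rho_si_dii": ("s_i", "delta_ii"),
    "rho_si_did": ("s_i", "delta_id"),
    "rho_si_taucyc": ("s_i", "tau_cyc"),
    "rho_id": ("s_i", "S_d"),
}


def _paired(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def pearson(x, y) -> float:
    """Product-moment correlation coefficient with strict error handling.

    NaN pairs are dropped pairwise; at least 4 complete pairs are required,
    and a zero-variance input raises
    :class:`~cellcycle.errors.UndefinedCorrelationError` rather than
    silently returning 0.
    """
    x, y = _paired(x, y)
    if len(x) < 4:
        raise ValueError(f"need at least 4 complete pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined for a zero-variance series")
    return float(sps.pearsonr(x, y).statistic)


def mother_daughter_corr(series) -> float:
    """Lag-1 Pearson coefficient, rho(x(n), x(n+1))."""
    series = np.asarray(series, dtype=float)
    if len(series) < 5:
        raise ValueError(f"need at least 5 points, got {len(series)}")
    return pearson(series[:-1], series[1:])


def fisher_z_se(n: int) -> float:
    """Standard error of a Pearson coefficient on the Fisher-z scale."""
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher-z standard error")
    return 1.0 / math.sqrt(n - 3)


def z_distance(r1: float, r2: float) -> float:
    """|atanh(r1) - atanh(r2)|, the Fisher-z distance between coefficients."""
    return abs(math.atanh(r1) - math.atanh(r2))


def within_se(measured: float, predicted: float, n: int, k: float = 3.0) -> bool:
    """Whether two coefficients agree within k Fisher-z standard errors."""
    return z_distance(measured, predicted) <= k * fisher_z_se(n)


@dataclass(frozen=True)
class CorrelationEntry:
    value: float
    n: int
    se: float  # Fisher-z scale


@dataclass
class CorrelationReport:
    """Named Pearson coefficients with sample sizes and z-scale SEs."""

    coefficients: dict[str, CorrelationEntry] = field(default_factory=dict)

    def __getitem__(self, name: str) -> CorrelationEntry:
        return self.coefficients[name]

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {name: {"value": e.value, "n": e.n, "se": e.se}
                for name, e in self.coefficients.items()}


def correlation_suite(table: pd.DataFrame) -> CorrelationReport:
    """Compute the diagnostic quartet plus (rho_i, rho_d, rho_id).

    ``table`` is an observable panel from
    :func:`cellcycle.lineage.extract_observables`.  All series are
    mean-normalized first (a no-op for Pearson, applied for parity with how
    these correlations are conventionally reported).
    """
    norm = normalize_by_mean(table)
    report = CorrelationReport()
    for name in SUITE_COEFFICIENTS:
        if name in _SUITE_PAIRS:
            a, b = _SUITE_PAIRS[name]
            x, y = _paired(norm[a], norm[b])
            r = pearson(x, y)
            n = len(x)
        else:  # lag-1 coefficients
            col = "s_i" if name == "rho_i" else "S_d"
            x = norm[col].to_numpy(dtype=float)
            x0, x1 = _paired(x[:-1], x[1:])
            r = pearson(x0, x1)
            n = len(x0)
        report.coefficients[name] = CorrelationEntry(r, n, fisher_z_se(n))
    return report
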