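"""The I-value statistic: determinant of a correlation matrix as a measure
of mutual statistical independence of candidate cell-cycle control variables.

For a set of variables with pairwise Pearson matrix R (unit diagonal),
``I = det(R)`` satisfies 0 <= I <= 1 for any positive semi-definite sample
matrix, with I = 1 iff all off-diagonal correlations vanish.  The module
also provides the per-model variable quadruples, model ranking by I, and
the exhaustive enumeration of all C(18,4) = 3060 quadruples from the fixed
18-variable panel used to probe the method's discriminative power.
"""
from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedCorrelationError
from .lineage import PANEL_VARIABLES

logger = logging.getLogger(__name__)

_DET_CLIP = 1e-12

#: Variable quadruples whose mutual independence defines each model.  The
#: RDA and IDA sets are canonical; the sHC and IA sets follow the same rule
#: (control parameters plus the extra variables entering the defining
#: correlations) and are a documented interpretation.
MODEL_VARIABLE_SETS = {
    "RDA": ("lambda", "delta_id", "delta_ii", "s_i"),
    "IDA": ("lambda", "Delta_d", "delta_ii", "S_b"),
    "sHC": ("lambda", "tau_cyc", "s_i", "S_b"),
    "IA": ("lambda", "tau_cyc", "delta_ii", "s_i"),
}


@dataclass
class IValueResult:
    """A variable set, its sample correlation matrix and determinant."""

    variable_names: tuple[str, ...]
    correlation_matrix: np.ndarray
    i_value: float
    n: int


def model_variable_set(model: str) -> tuple[str, ...]:
    """Ordered variable quadruple characterizing the named model."""
    key = {"rda": "RDA", "ida": "IDA", "shc": "sHC", "ia": "IA"}.get(
        model.strip().lower())
    if key is None:
        raise ConfigurationError(
            f"no I-value variable set for model {model!r}; "
            f"choose one of {sorted(MODEL_VARIABLE_SETS)}")
    return MODEL_VARIABLE_SETS[key]


def _complete_cases(table: pd.DataFrame, variables) -> np.ndarray:
    for v in variables:
        if v not in table.columns:
            raise ConfigurationError(f"unknown variable {v!r}")
    block = table.loc[:, list(variables)].to_numpy(dtype=float)
    return block[np.isfinite(block).all(axis=1)]


def _clip_det(det: float) -> float:
    if abs(det) < _DET_CLIP:
        if det < 0:
            logger.info("clipped tiny negative determinant %.3g to 0", det)
        return 0.0
    if det < 0:
        logger.warning("negative determinant %.3g clipped to 0 "
                       "(non-PSD sample matrix)", det)
        return 0.0
    return min(float(det), 1.0)


def i_value(table: pd.DataFrame, variables) -> IValueResult:
    """Determinant of the pairwise Pearson matrix over ``variables``.

    Rows with a missing value in any of the chosen variables are dropped
    (complete cases), guaranteeing a positive semi-definite sample matrix
    and hence 0 <= I <= 1.  Tiny negative determinants from floating-point
    round-off are clipped to 0 (threshold 1e-12, logged).
    """
    variables = tuple(variables)
    if not 3 <= len(variables) <= 6:
        raise ConfigurationError(
            f"need between 3 and 6 variables, got {len(variables)}")
    data = _complete_cases(table, variables)
    n = len(data)
    if n < 10:
        raise ConfigurationError(
            f"need at least 10 complete samples, got {n}")
    sds = data.std(axis=0, ddof=1)
    zero = [v for v, s in zip(variables, sds) if s == 0]
    if zero:
        raise UndefinedCorrelationError(
            f"zero-variance variable(s) {zero} make the correlation "
            "matrix undefined")
    mat = np.corrcoef(data, rowvar=False)
    det = _clip_det(float(np.linalg.det(mat)))
    return IValueResult(variables, mat, det, n)


def rank_models(table: pd.DataFrame, models) -> list[tuple[str, IValueResult]]:
    """Rank models by the I-value of their variable sets, descending.

    All requested models must use variable sets of the same size:
    determinants of correlation matrices of different sizes are not
    comparable, so mixing them is a hard error.  Ties (exact equality)
    break lexicographically by model name.
    """
    models = list(models)
    if len(models) < 2:
        if len(models) == 1:
            return [(models[0], i_value(table, model_variable_set(models[0])))]
        raise ConfigurationError("need at least one model to rank")
    sets = {m: model_variable_set(m) for m in models}
    sizes = {len(s) for s in sets.values()}
    if len(sizes) != 1:
        raise ConfigurationError(
            "cannot compare I-values across variable sets of different "
            f"sizes: {sorted((m, len(s)) for m, s in sets.items())}")
    results = [(m, i_value(table, sets[m])) for m in models]
    return sorted(results, key=lambda pair: (-pair[1].i_value, pair[0]))


@dataclass
class EnumerationResult:
    """All C(18,4) quadruple I-values, sorted descending."""

    results: list[IValueResult]
    model_ranks: dict[str, int]  # 1-based rank of each named model quadruple


def enumerate_quadruples(table: pd.DataFrame) -> EnumerationResult:
    """I-values of every 4-subset of the fixed 18-variable panel.

    Uses a single complete-case correlation matrix over the full panel so
    all 3060 determinants come from one positive semi-definite estimate.
    Results are sorted by descending I; the returned ``model_ranks`` give
    the 1-based position of each named model's quadruple.
    """
    missing = [v for v in PANEL_VARIABLES if v not in table.columns]
    if missing:
        raise ConfigurationError(f"panel incomplete, missing {missing}")
    data = _complete_cases(table, PANEL_VARIABLES)
    n = len(data)
    if n < 10:
        raise ConfigurationError(f"need at least 10 complete samples, got {n}")
    sds = data.std(axis=0, ddof=1)
    zero = [v for v, s in zip(PANEL_VARIABLES, sds) if s == 0]
    if zero:
        raise UndefinedCorrelationError(
            f"zero-variance panel variable(s) {zero}")
    full = np.corrcoef(data, rowvar=False)
    combos = list(itertools.combinations(range(len(PANEL_VARIABLES)), 4))
    idx = np.array(combos)
    sub = full[idx[:, :, None], idx[:, None, :]]
    dets = np.linalg.det(sub)
    results = []
    for combo, det in zip(combos, dets):
        names = tuple(PANEL_VARIABLES[i] for i in combo)
        results.append(IValueResult(names, sub[len(results)], _clip_det(det), n))
    results.sort(key=lambda r: -r.i_value)
    ranks = {}
    for model, want in MODEL_VARIABLE_SETS.items():
        target = frozenset(want)
        for pos, res in enumerate(results, start=1):
            if frozenset(res.variable_names) == target:
                ranks[model] = pos
                break
    return EnumerationResult(results, ranks)


def warn_if_overlapping(table: pd.DataFrame) -> int | None:
    """Warn when the data indicate overlapping cell cycles (p >= 1).

    The I-value analysis was introduced for non-overlapping cycles; the
    statistic is still computed, but a warning flags the regime.  Returns
    the estimated p, or None when tau_cyc is unavailable.
    """
    if "tau_cyc" not in table.columns or "tau" not in table.columns:
        return None
    tc = table["tau_cyc"].mean(skipna=True)
    tau = table["tau"].mean(skipna=True)
    if not np.isfinite(tc) or not np.isfinite(tau) or tau <= 0:
        return None
    p = int(tc // tau)
    if p >= 1:
        warnings.warn(
            f"data indicate {p + 1} overlapping cell cycles (p={p}); the "
            "I-value analysis was designed for non-overlapping cycles",
            UserWarning, stacklevel=2)
    return p
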