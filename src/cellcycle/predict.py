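"""Closed-form steady-state predictions for the cell-cycle models.

These formulas are the independent oracles against which the simulators are
validated: the three homeostasis correlations (rho_i, rho_d, rho_id) per
model, the overlapping-cycle count, the CCCP cell-cycle duration, and the
RDA sizer-skew curve.

Moment inputs follow the usual conventions: ``eta_i`` is the CV of the
per-origin initiation size s_i, ``eta_alpha`` the CV of
``alpha = exp(lambda tau_cyc)``, ``sigma_ii``/``sigma_id`` the SDs of the
two RDA adder increments.  The CCCP entries are expressed in log-size
moments (``mu_H``, ``sigma_H``, ... are mean/SD of ln S_H etc., and
``sigma_i`` the SD of ln s_i), measured from simulation since the candidate
division sizes are emergent quantities.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .params import ModelParams, canonical_model_name


@dataclass(frozen=True)
class CorrelationPrediction:
    """The three steady-state homeostasis correlations of a model."""

    rho_i: float   # consecutive initiation sizes, rho(s_i(n), s_i(n+1))
    rho_d: float   # mother-daughter division sizes, rho(S_d(n), S_d(n+1))
    rho_id: float  # initiation size vs division size, rho(s_i(n), S_d(n))

    def __post_init__(self):
        for name in ("rho_i", "rho_d", "rho_id"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0 + 1e-12:
                raise ConfigurationError(f"{name}={v} outside [-1, 1]")

    def as_dict(self) -> dict[str, float]:
        return {"rho_i": self.rho_i, "rho_d": self.rho_d, "rho_id": self.rho_id}


def _check_nonneg(**kw):
    for name, val in kw.items():
        if val < 0:
            raise ConfigurationError(f"{name} must be >= 0, got {val}")


def predict_correlations(model: str, **stats) -> CorrelationPrediction:
    """Closed-form (rho_i, rho_d, rho_id) for the named model.

    Required ``stats`` per model:

    * ``sHC``:  eta_i, eta_alpha, rho_i, rho_alpha
    * ``IA``:   eta_i, eta_alpha
    * ``RDA``:  sigma_ii, sigma_id
    * ``IDA``:  none (returns (1/2, 1/2, 0) unconditionally)
    * ``CCCP``: f, mu_H, mu_R, sigma_H, sigma_R, sigma_i  (log-size moments)
    """
    name = canonical_model_name(model)
    if name == "IDA":
        return CorrelationPrediction(0.5, 0.5, 0.0)
    if name in ("sHC", "IA"):
        eta_i = stats.pop("eta_i")
        eta_a = stats.pop("eta_alpha")
        _check_nonneg(eta_i=eta_i, eta_alpha=eta_a)
        denom = eta_i**2 + eta_a**2 + eta_i**2 * eta_a**2
        if name == "IA":
            rho_i, rho_a = 0.5, 0.0
            rho_d = 0.0 if denom == 0 else 0.5 * eta_i**2 / denom
        else:
            rho_i = stats.pop("rho_i")
            rho_a = stats.pop("rho_alpha")
            for nm, v in (("rho_i", rho_i), ("rho_alpha", rho_a)):
                if not -1.0 <= v <= 1.0:
                    raise ConfigurationError(f"{nm}={v} outside [-1, 1]")
            rho_d = 0.0 if denom == 0 else (
                rho_i * eta_i**2 + rho_a * eta_a**2
                + rho_i * rho_a * eta_i**2 * eta_a**2) / denom
        rho_id = 0.0 if denom == 0 else eta_i / math.sqrt(denom)
        _reject_extras(name, stats)
        return CorrelationPrediction(rho_i, rho_d, rho_id)
    if name == "RDA":
        s_ii = stats.pop("sigma_ii")
        s_id = stats.pop("sigma_id")
        _check_nonneg(sigma_ii=s_ii, sigma_id=s_id)
        if s_ii == 0:
            raise ConfigurationError("RDA prediction requires sigma_ii > 0")
        ratio2 = (s_id / s_ii) ** 2
        _reject_extras(name, stats)
        return CorrelationPrediction(
            0.5, 0.5 / (1.0 + 3.0 * ratio2), 1.0 / math.sqrt(1.0 + 3.0 * ratio2))
    if name == "CCCP":
        f = stats.pop("f")
        mu_H, mu_R = stats.pop("mu_H"), stats.pop("mu_R")
        s_H, s_R = stats.pop("sigma_H"), stats.pop("sigma_R")
        s_i = stats.pop("sigma_i")
        _check_nonneg(sigma_H=s_H, sigma_R=s_R, sigma_i=s_i)
        if not 0.0 <= f <= 1.0:
            raise ConfigurationError(f"f={f} outside [0, 1]")
        denom = s_H**2 * f + s_R**2 * (1 - f) + f * (1 - f) * (mu_H - mu_R) ** 2
        if denom == 0:
            rho_d = rho_id = 0.0
        else:
            rho_d = (s_H**2 * f**2 / 2.0 + s_i**2 * (1 - f) ** 2 / 2.0) / denom
            rho_id = (1 - f) * s_i / math.sqrt(denom)
        _reject_extras(name, stats)
        return CorrelationPrediction(0.5, min(rho_d, 1.0), min(rho_id, 1.0))
    raise ConfigurationError(f"no correlation prediction for model {model!r}")


def _reject_extras(model, stats):
    if stats:
        raise ConfigurationError(
            f"unexpected stats for model {model}: {sorted(stats)}")


def predict_overlap(model: str, **means) -> int:
    """Number of extra concurrent cycles p (p+1 cycles overlap).

    * sHC/IA: ``p = floor(mean_tau_cyc / mean_tau)`` (``mean_tau`` may be
      given directly or as ``mean_lambda`` via tau = ln2/lambda);
    * RDA: ``p = floor(log2(1 + mean_did / mean_dii))``;
    * IDA: ``p = floor(log2(mean_Dd / mean_dii))``.
    """
    name = canonical_model_name(model)
    if name in ("sHC", "IA", "CCCP"):
        tau_cyc = means.pop("mean_tau_cyc")
        if "mean_tau" in means:
            tau = means.pop("mean_tau")
        else:
            tau = math.log(2.0) / means.pop("mean_lambda")
        _require_positive(mean_tau_cyc=tau_cyc, mean_tau=tau)
        p = math.floor(tau_cyc / tau)
    elif name == "RDA":
        dii, did = means.pop("mean_dii"), means.pop("mean_did")
        _require_positive(mean_dii=dii, mean_did=did)
        p = math.floor(math.log2(1.0 + did / dii))
    elif name == "IDA":
        dii, Dd = means.pop("mean_dii"), means.pop("mean_Dd")
        _require_positive(mean_dii=dii, mean_Dd=Dd)
        p = math.floor(math.log2(Dd / dii))
    else:
        raise ConfigurationError(f"no overlap prediction for model {model!r}")
    if means:
        raise ConfigurationError(f"unexpected means: {sorted(means)}")
    return max(int(p), 0)


def _require_positive(**kw):
    for name, val in kw.items():
        if val is None or val <= 0:
            raise ConfigurationError(f"{name} must be > 0, got {val}")


def predict_tau_cyc_cccp(f: float, A: float, B: float, C: float,
                         lam: float) -> float:
    """Mean initiation-to-division time in the CCCP model.

    ``tau_cyc = (1-f) C + f 2(B-A)/lambda``, an approximation that replaces
    means of logs by logs of means; accurate to a few percent at 10% CVs.
    """
    if not 0.0 <= f <= 1.0:
        raise ConfigurationError(f"f={f} outside [0, 1]")
    if lam <= 0:
        raise ConfigurationError(f"lambda must be > 0, got {lam}")
    return (1.0 - f) * C + f * 2.0 * (B - A) / lam


def rda_sizer_curve(sigma_ratio_grid) -> np.ndarray:
    """RDA mother-daughter division-size correlation vs sigma_id/sigma_ii.

    Element-wise ``rho_d = (1/2) (1 + 3 r^2)^-1``: equal to 1/2 at r = 0
    (deterministic initiation-to-division adder, i.e. the adder limit) and
    strictly decreasing toward the sizer as the ratio grows.
    """
    grid = np.asarray(sigma_ratio_grid, dtype=float)
    if np.any(grid < 0):
        raise ConfigurationError("sigma ratios must be >= 0")
    return 0.5 / (1.0 + 3.0 * grid**2)


def moments_from_params(model: str, params: ModelParams) -> dict[str, float]:
    """Moment inputs for :func:`predict_correlations` derived from parameters.

    For IA the initiation-size CV follows from the adder recursion
    (``sigma_si^2 = (4/3) sigma_ii^2``, ``mu_si = 2 mu_ii``); for sHC and IA
    the CV of alpha = exp(lambda tau_cyc) uses the exact log-moments of the
    product of two independent Gaussians with a lognormal closure.  CCCP
    moments are emergent and must be measured from simulation instead.
    """
    name = canonical_model_name(model)
    params.validate(name)
    if name == "RDA":
        return {"sigma_ii": params.sd_dii, "sigma_id": params.sd_did}
    if name == "IDA":
        return {}
    if name in ("sHC", "IA"):
        mu_l = params.mean_lambda
        sd_l = params.cv_lambda * mu_l
        mu_t = params.mean_tau_cyc
        sd_t = params.cv_tau_cyc * mu_t
        v_ln = (mu_l * sd_t) ** 2 + (mu_t * sd_l) ** 2 + (sd_l * sd_t) ** 2
        eta_alpha = math.sqrt(math.expm1(v_ln))
        if name == "sHC":
            return {"eta_i": params.cv_si, "eta_alpha": eta_alpha,
                    "rho_i": params.rho_i_md, "rho_alpha": params.rho_alpha_md}
        eta_i = (params.sd_dii / params.mean_dii) / math.sqrt(3.0)
        return {"eta_i": eta_i, "eta_alpha": eta_alpha}
    raise ConfigurationError(
        f"moments for model {model!r} must be measured from simulation")
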