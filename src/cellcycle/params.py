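"""Model parameter container shared by all simulators.

A single :class:`ModelParams` dataclass carries the union of the per-model
distributional parameters; fields that a given model does not use are simply
left at ``None``/0 and :meth:`ModelParams.validate` checks the subset that the
chosen model requires.

Conventions
-----------
* Sizes are in arbitrary length units (think µm), times in arbitrary time
  units (think minutes); the models are scale-free.
* ``cv_*`` are coefficients of variation, ``sd_*`` absolute standard
  deviations, matching how each quantity is usually reported.
* ``cross_corr`` holds within-generation Pearson correlations between the
  sHC control variables, keyed ``"lambda:tau_cyc"``, ``"lambda:s_i"``,
  ``"tau_cyc:s_i"``.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from .errors import ConfigurationError

#: Canonical model names.
MODELS = ("sHC", "IA", "RDA", "IDA", "CCCP", "threshold-IDA")

_ALIASES = {
    "shc": "sHC",
    "ia": "IA",
    "rda": "RDA",
    "ida": "IDA",
    "cccp": "CCCP",
    "threshold": "threshold-IDA",
    "threshold-ida": "threshold-IDA",
    "threshold_ida": "threshold-IDA",
    "imported": "imported",
}

_SHC_VARS = ("lambda", "tau_cyc", "s_i")


def canonical_model_name(name: str) -> str:
    """Map a case-insensitive alias to the canonical model name."""
    key = name.strip().lower()
    if key not in _ALIASES:
        raise ConfigurationError(
            f"unknown model {name!r}; expected one of {sorted(set(_ALIASES))}"
        )
    return _ALIASES[key]


@dataclass
class ModelParams:
    """Distributional parameters for the stochastic cell-cycle models.

    Only the subset relevant to a given model needs to be set; see
    :meth:`validate` for the per-model requirements.
    """

    # growth rate (all models)
    mean_lambda: float | None = None
    cv_lambda: float = 0.0
    # initiation-to-division duration tau_cyc = C+D (sHC, IA)
    mean_tau_cyc: float | None = None
    cv_tau_cyc: float = 0.0
    # initiation size per origin s_i (sHC)
    mean_si: float | None = None
    cv_si: float = 0.0
    # mother-daughter auto-correlations (sHC): rho_i on s_i,
    # rho_alpha on alpha = exp(lambda * tau_cyc)
    rho_i_md: float = 0.0
    rho_alpha_md: float = 0.0
    # within-generation cross correlations among (lambda, tau_cyc, s_i) (sHC)
    cross_corr: dict[str, float] | None = None
    # initiation adder increment per origin delta_ii (IA, RDA, IDA)
    mean_dii: float | None = None
    sd_dii: float = 0.0
    # initiation-to-division adder increment per origin delta_id (RDA)
    mean_did: float | None = None
    sd_did: float = 0.0
    # birth-to-division adder increment Delta_d (IDA)
    mean_Dd: float | None = None
    sd_Dd: float = 0.0
    # CCCP log-adder increments A (initiation), B (division) and the
    # replication-to-division duration C
    mean_A: float | None = None
    sd_A: float = 0.0
    mean_B: float | None = None
    sd_B: float = 0.0
    mean_C: float | None = None
    sd_C: float = 0.0
    # initiator-threshold mechanistic model
    N0: float | None = None          # division-initiator threshold (copies)
    c_star: float | None = None      # steady-state concentration (copies/vol)
    N0_init: float | None = None     # initiation threshold per origin;
    #                                  defaults to 0.35*N0 (see docs/methods)
    production_noise: float = 0.0    # scale of counting noise on dN
    partition: str = "deterministic"  # protein partitioning at division
    # septum placement noise (all models); 0 = perfectly symmetric division
    septum_sd: float = 0.0

    # ------------------------------------------------------------------
    def cross_corr_matrix(self) -> np.ndarray:
        """3x3 correlation matrix over (lambda, tau_cyc, s_i).

        Raises :class:`ConfigurationError` if any entry is out of range or
        the matrix is not positive semi-definite.
        """
        mat = np.eye(3)
        cc = self.cross_corr or {}
        for key, val in cc.items():
            try:
                a, b = (part.strip() for part in key.split(":"))
                ia, ib = _SHC_VARS.index(a), _SHC_VARS.index(b)
            except ValueError as exc:
                raise ConfigurationError(
                    f"cross_corr key {key!r} must pair two of {_SHC_VARS}"
                ) from exc
            if not -1.0 <= val <= 1.0:
                raise ConfigurationError(f"cross_corr[{key!r}]={val} out of [-1, 1]")
            mat[ia, ib] = mat[ib, ia] = val
        eigmin = float(np.linalg.eigvalsh(mat).min())
        if eigmin < -1e-10:
            raise ConfigurationError(
                f"cross_corr matrix is not positive semi-definite (min eig {eigmin:.3g})"
            )
        return mat

    # ------------------------------------------------------------------
    def validate(self, model: str) -> None:
        model = canonical_model_name(model)
        self._check_common()
        need = {
            "sHC": ("mean_lambda", "mean_tau_cyc", "mean_si"),
            "IA": ("mean_lambda", "mean_tau_cyc", "mean_dii"),
            "RDA": ("mean_lambda", "mean_dii", "mean_did"),
            "IDA": ("mean_lambda", "mean_dii", "mean_Dd"),
            "CCCP": ("mean_lambda", "mean_A", "mean_B", "mean_C"),
            "threshold-IDA": ("mean_lambda", "N0", "c_star"),
        }[model]
        for name in need:
            val = getattr(self, name)
            if val is None:
                raise ConfigurationError(f"model {model} requires parameter {name!r}")
            # log-adder increments may legitimately be <= 0
            if name not in ("mean_A", "mean_B") and val <= 0:
                raise ConfigurationError(f"parameter {name!r} must be > 0, got {val}")
        if model == "sHC":
            self.cross_corr_matrix()
            if self.cross_corr and (self.rho_i_md or self.rho_alpha_md):
                raise ConfigurationError(
                    "cross_corr cannot be combined with mother-daughter "
                    "correlations rho_i_md/rho_alpha_md"
                )
        if model == "threshold-IDA":
            if self.N0_init is not None and self.N0_init <= 0:
                raise ConfigurationError("N0_init must be > 0")
            if self.partition not in ("deterministic", "binomial"):
                raise ConfigurationError(
                    f"partition must be 'deterministic' or 'binomial', got {self.partition!r}"
                )

    def _check_common(self) -> None:
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            if val is None or not f.name.startswith(("cv_", "sd_")):
                continue
            if val < 0:
                raise ConfigurationError(f"{f.name} must be >= 0, got {val}")
        for name in ("rho_i_md", "rho_alpha_md"):
            val = getattr(self, name)
            if not -1.0 <= val <= 1.0:
                raise ConfigurationError(f"{name}={val} out of [-1, 1]")
        if self.septum_sd < 0:
            raise ConfigurationError("septum_sd must be >= 0")
        if self.production_noise < 0:
            raise ConfigurationError("production_noise must be >= 0")

    # ------------------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        """Dictionary with unset (None / default-zero) fields dropped."""
        out: dict[str, Any] = {}
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            if val is None:
                continue
            if val == f.default and f.name != "partition":
                continue
            out[f.name] = val
        return out

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**dict(data))


def default_params(model: str) -> ModelParams:
    """Reference parameter set for each model.

    Means are of order one length unit and tens of time units (a 30-minute
    doubling time); all noise levels are 10% CVs, the regime the steady-state
    correlation formulas are derived for.
    """
    model = canonical_model_name(model)
    lam = math.log(2.0) / 30.0
    base = dict(mean_lambda=lam, cv_lambda=0.1)
    if model == "sHC":
        return ModelParams(**base, mean_tau_cyc=45.0, cv_tau_cyc=0.1,
                           mean_si=1.0, cv_si=0.1)
    if model == "IA":
        return ModelParams(**base, mean_tau_cyc=45.0, cv_tau_cyc=0.1,
                           mean_dii=0.5, sd_dii=0.05)
    if model == "RDA":
        return ModelParams(**base, mean_dii=0.5, sd_dii=0.05,
                           mean_did=0.5, sd_did=0.05)
    if model == "IDA":
        return ModelParams(**base, mean_dii=0.5, sd_dii=0.05,
                           mean_Dd=1.0, sd_Dd=0.1)
    if model == "CCCP":
        return ModelParams(**base, mean_A=0.0, sd_A=0.07,
                           mean_B=0.52, sd_B=0.07, mean_C=45.0, sd_C=4.5)
    # threshold-IDA
    return ModelParams(mean_lambda=lam, cv_lambda=0.05, N0=1000.0,
                       c_star=2000.0, production_noise=1.0)
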