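"""Delimited-text lineage serialization, fixtures and config loading.

Lineage tables are written as TSV (default) or CSV with a header row using
the exact :data:`~cellcycle.lineage.RECORD_COLUMNS` names; missing values
are empty fields.  Provenance travels in ``#`` comment lines::

    # model=IA; seed=3; burn_in=100
    # params={"mean_lambda": 0.0231, ...}
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, SchemaError
from .lineage import LineageTable, MANDATORY_COLUMNS, RECORD_COLUMNS
from .params import ModelParams, canonical_model_name
from . import simulate as sim

FIXTURE_PRESETS = ("nonoverlap", "overlap", "deterministic", "high-noise")
_FIXTURE_NGEN = 2000


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def write_lineage(lineage: LineageTable, path) -> None:
    """Serialize a lineage with its provenance comment header."""
    path = Path(path)
    sep = _sep_for(path)
    with path.open("w") as fh:
        fh.write(f"# model={lineage.model_name}; seed={lineage.seed}; "
                 f"burn_in={lineage.burn_in}\n")
        if lineage.params is not None:
            fh.write(f"# params={json.dumps(lineage.params.to_dict())}\n")
        lineage.data.to_csv(fh, sep=sep, index=False, na_rep="")


def read_lineage(path) -> LineageTable:
    """Parse a lineage table, recovering provenance when present.

    Extra columns are ignored with a warning; missing mandatory columns or
    non-numeric cells raise :class:`~cellcycle.errors.SchemaError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict[str, str] = {}
    params = None
    with path.open() as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("params="):
                try:
                    params = ModelParams.from_dict(json.loads(body[len("params="):]))
                except (json.JSONDecodeError, ConfigurationError) as exc:
                    warnings.warn(f"ignoring unparsable params header: {exc}")
            else:
                for item in body.split(";"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        if not line.strip():
            raise SchemaError(f"{path} is empty")
        fh.seek(pos)
        sep = _sep_for(path)
        try:
            df = pd.read_csv(fh, sep=sep)
        except Exception as exc:
            raise SchemaError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} missing mandatory column(s) {missing}")
    extras = [c for c in df.columns if c not in RECORD_COLUMNS]
    if extras:
        warnings.warn(f"ignoring extra column(s) {extras} in {path}")
        df = df.drop(columns=extras)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise SchemaError(f"column {col!r} in {path} contains "
                              "non-numeric cells")
    model = meta.get("model", "imported")
    seed = meta.get("seed")
    seed = int(seed) if seed not in (None, "None", "") else None
    burn_in = int(meta.get("burn_in", 0))
    return LineageTable(data=df, model_name=model, params=params,
                        seed=seed, burn_in=burn_in)


def load_params(path) -> ModelParams:
    """Read a ModelParams mapping from a YAML or JSON file."""
    path = Path(path)
    with path.open() as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path} must contain a mapping of parameters")
    return ModelParams.from_dict(data)


def _preset_params(model: str, preset: str) -> ModelParams:
    """Parameter sets emulating the experimentally relevant regimes:

    slow growth without overlapping cycles (p=0), fast growth with one extra
    concurrent cycle (p=1), the noise-free deterministic limit, and a
    high-noise (20% CV) variant of the overlap regime.
    """
    import math
    lam = math.log(2.0) / 30.0
    grow = dict(mean_lambda=lam, cv_lambda=0.1)
    tables = {
        "sHC": {
            "nonoverlap": dict(**grow, mean_tau_cyc=25.0, cv_tau_cyc=0.1,
                               mean_si=1.0, cv_si=0.1),
            "overlap": dict(**grow, mean_tau_cyc=45.0, cv_tau_cyc=0.1,
                            mean_si=1.0, cv_si=0.1),
        },
        "IA": {
            "nonoverlap": dict(**grow, mean_tau_cyc=25.0, cv_tau_cyc=0.1,
                               mean_dii=0.5, sd_dii=0.05),
            "overlap": dict(**grow, mean_tau_cyc=45.0, cv_tau_cyc=0.1,
                            mean_dii=0.5, sd_dii=0.05),
        },
        "RDA": {
            "nonoverlap": dict(**grow, mean_dii=0.5, sd_dii=0.05,
                               mean_did=0.35, sd_did=0.035),
            "overlap": dict(**grow, mean_dii=0.4, sd_dii=0.04,
                            mean_did=0.6, sd_did=0.06),
        },
        "IDA": {
            "nonoverlap": dict(**grow, mean_dii=0.5, sd_dii=0.05,
                               mean_Dd=0.75, sd_Dd=0.075),
            "overlap": dict(**grow, mean_dii=0.4, sd_dii=0.04,
                            mean_Dd=1.2, sd_Dd=0.12),
        },
        "CCCP": {
            "nonoverlap": dict(**grow, mean_A=0.0, sd_A=0.07, mean_B=0.3,
                               sd_B=0.07, mean_C=25.0, sd_C=2.5),
            "overlap": dict(**grow, mean_A=0.0, sd_A=0.07, mean_B=0.52,
                            sd_B=0.07, mean_C=45.0, sd_C=4.5),
        },
        "threshold-IDA": {
            "nonoverlap": dict(mean_lambda=lam, cv_lambda=0.05, N0=1000.0,
                               c_star=2000.0, production_noise=1.0),
            "overlap": dict(mean_lambda=lam, cv_lambda=0.05, N0=1000.0,
                            c_star=2000.0, N0_init=700.0,
                            production_noise=1.0),
        },
    }
    model_table = tables[model]
    if preset in model_table:
        return ModelParams(**model_table[preset])
    base = dict(model_table["overlap"])
    if preset == "deterministic":
        for key in list(base):
            if key.startswith(("cv_", "sd_")) or key == "production_noise":
                base[key] = 0.0
    elif preset == "high-noise":
        for key in list(base):
            if key.startswith(("cv_", "sd_")):
                base[key] *= 2.0
    else:
        raise ConfigurationError(
            f"unknown preset {preset!r}; choose from {FIXTURE_PRESETS}")
    return ModelParams(**base)


def generate_fixture(model: str, preset: str, seed: int) -> LineageTable:
    """Small (2,000-generation) reproducible lineage for tests and docs."""
    model = canonical_model_name(model)
    params = _preset_params(model, preset)
    return sim.simulate(model, params, _FIXTURE_NGEN, seed)
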