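"""Generation-by-generation stochastic simulators for the five cell-cycle
models plus the mechanistic initiator-threshold model.

All simulators share the same bookkeeping conventions:

* a single mother-machine-style lineage (one daughter followed per division);
* ``S_b(n+1) = division_ratio(n) * S_d(n)`` exactly;
* cells elongate exponentially, so ``tau = ln(S_d/S_b)/lambda``;
* the replication initiation attributed to division ``n`` (backward tracing
  by ``tau_cyc`` or by initiation size, depending on what the model draws)
  may fall in an ancestor generation; the per-origin initiation size ``s_i``
  is attributed to generation ``n`` while the in-generation timing ``a_i`` is
  attributed to the generation whose wall-clock span contains the event;
* the total size at initiation is ``S_i = 2**g * s_i`` where ``g`` counts
  generations between the initiation event and the division it triggers;
* one integer seed spawns a named independent RNG substream per stochastic
  variable, so adding a variable never perturbs another's draws;
* Gaussian draws are rejection-resampled into their physical domain with a
  cap of 100 attempts per draw, after which a
  :class:`~cellcycle.errors.RejectionSamplingError` names the variable.
"""
from __future__ import annotations

import math
import zlib

import numpy as np
import pandas as pd

from .errors import ConfigurationError, RejectionSamplingError
from .lineage import DEFAULT_BURN_IN, LineageTable
from .params import ModelParams, canonical_model_name

_MAX_REJECT = 100
_MIN_EXTRA_GEN = 100  # required generations beyond the burn-in


# ----------------------------------------------------------------------
# RNG plumbing
# ----------------------------------------------------------------------

def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent, named, reproducible RNG substream."""
    key = zlib.crc32(name.encode("ascii"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _positive_normal(rng, mean, sd, n, name, low=0.0):
    """Gaussian draws rejection-resampled to be strictly greater than low."""
    x = rng.normal(mean, sd, size=n)
    if sd == 0:
        if mean <= low:
            raise ConfigurationError(f"mean of {name!r} must exceed {low}")
        return x
    for _ in range(_MAX_REJECT):
        bad = x <= low
        if not bad.any():
            return x
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise RejectionSamplingError(name)


def _division_ratios(rng, n, septum_sd):
    """Division ratios: 0.5, or Gaussian(0.5, sd) truncated to [0.35, 0.65]."""
    if septum_sd == 0:
        return np.full(n, 0.5)
    r = rng.normal(0.5, septum_sd, size=n)
    for _ in range(_MAX_REJECT):
        bad = (r < 0.35) | (r > 0.65)
        if not bad.any():
            return r
        r[bad] = rng.normal(0.5, septum_sd, size=int(bad.sum()))
    raise RejectionSamplingError("division_ratio")


def _ar1_positive(rng, mean, sd, rho, n, name):
    """Stationary Gaussian AR(1) chain, rejection-kept strictly positive.

    The standardized variable follows x(n+1) = rho x(n) + sqrt(1-rho^2) eps,
    which makes the lag-1 Pearson correlation exactly ``rho``.
    """
    x = np.empty(n)
    c = math.sqrt(max(0.0, 1.0 - rho * rho))
    eps = rng.standard_normal(n)
    z_prev = 0.0
    for i in range(n):
        for _ in range(_MAX_REJECT + 1):
            z = eps[i] if i == 0 else rho * z_prev + c * eps[i]
            val = mean + sd * z
            if val > 0:
                break
            eps[i] = rng.standard_normal()
        else:
            raise RejectionSamplingError(name)
        x[i] = val
        z_prev = z
    return x


# ----------------------------------------------------------------------
# Initiation attribution (Fig.-style backward tracing, run forward)
# ----------------------------------------------------------------------

def _times_from_tau(tau):
    t_d = np.cumsum(tau)
    return t_d - tau, t_d


def _tau_from_sizes(S_b, S_d, lam, mean_lambda):
    """Realized doubling times ``ln(S_d/S_b)/lambda`` with a tiny floor.

    The sHC-family recursions draw division sizes directly, so in deep
    noise tails a generation can realize ``S_d <= S_b``; conditioning the
    draws away from those events would distort the models' defining
    independence structure (e.g. bias the sHC sizer correlation upward), so
    sizes are left exactly as drawn and only the wall clock is floored at
    0.1% of the mean doubling time for such generations.  The count of
    floored generations is reported in ``lineage.info["n_tau_floored"]``.
    """
    tau = np.log(S_d / S_b) / lam
    floor = 1e-3 * math.log(2.0) / mean_lambda
    n_floored = int((tau < floor).sum())
    if n_floored:
        tau = np.maximum(tau, floor)
    return tau, n_floored


def _attribute_by_time(s_i, tau_cyc, t_b, t_d):
    """Locate the initiation event a drawn tau_cyc before each division.

    Returns (a_i, S_i, g); generations whose initiation precedes the start of
    the recorded lineage get NaN/-1 entries.
    """
    n = len(t_d)
    a_i = np.full(n, np.nan)
    S_i = np.full(n, np.nan)
    g = np.full(n, -1, dtype=int)
    t_init = t_d - tau_cyc
    m = np.searchsorted(t_d, t_init, side="right")
    valid = t_init >= -1e-9
    idx = np.nonzero(valid)[0]
    mm = m[idx]
    a_i[mm] = np.clip(t_init[idx] - t_b[mm], 0.0, None)
    g[idx] = idx - mm
    S_i[idx] = np.ldexp(s_i[idx], idx - mm)
    return a_i, S_i, g


def _attribute_by_size(s_i, S_b, S_d, lam, t_b, t_d):
    """Locate initiation events by size for models where timing is emergent.

    The initiation attributed to division ``n`` occurred when the ancestor
    cell reached total size ``2**g * s_i(n)``; walk backward until that size
    falls inside an ancestor generation's [S_b, S_d] span.
    Returns (tau_cyc, a_i, S_i, g).
    """
    n = len(S_d)
    tau_cyc = np.full(n, np.nan)
    a_i = np.full(n, np.nan)
    S_i = np.full(n, np.nan)
    g = np.full(n, -1, dtype=int)
    rtol = 1e-9
    for nn in range(n):
        target = s_i[nn]
        m = nn
        found = False
        while m >= 0:
            if target > S_d[m] * (1.0 + rtol):
                break  # inconsistent placement (possible at high noise)
            if target >= S_b[m] * (1.0 - rtol):
                found = True
                break
            m -= 1
            target *= 2.0
        if not found:
            continue
        target = min(max(target, S_b[m]), S_d[m])
        t0 = t_b[m] + math.log(target / S_b[m]) / lam[m]
        tau_cyc[nn] = t_d[nn] - t0
        a_i[m] = t0 - t_b[m]
        S_i[nn] = target
        g[nn] = nn - m
    return tau_cyc, a_i, S_i, g


# ----------------------------------------------------------------------
# Table assembly
# ----------------------------------------------------------------------

def _make_lineage(model, params, seed, burn_in, *, lam, tau, S_b, S_d,
                  s_i=None, S_i=None, tau_cyc=None, a_i=None,
                  delta_ii=None, delta_id=None, ratios=None, info=None):
    n = len(S_d)
    nancol = np.full(n, np.nan)
    data = pd.DataFrame({
        "index": np.arange(n),
        "growth_rate": lam,
        "doubling_time": tau,
        "birth_size": S_b,
        "division_size": S_d,
        "init_size_per_ori": nancol if s_i is None else s_i,
        "total_init_size": nancol if S_i is None else S_i,
        "tau_cyc": nancol if tau_cyc is None else tau_cyc,
        "a_i": nancol if a_i is None else a_i,
        "delta_ii": nancol if delta_ii is None else delta_ii,
        "delta_id": nancol if delta_id is None else delta_id,
        "delta_d": S_d - S_b,
        "division_ratio": np.full(n, 0.5) if ratios is None else ratios,
    })
    return LineageTable(data=data, model_name=model, params=params,
                        seed=seed, burn_in=burn_in, info=info or {})


def _check_run(params: ModelParams, model: str, n_gen: int, seed: int,
               burn_in: int) -> None:
    params.validate(model)
    if seed < 0 or int(seed) != seed:
        raise ConfigurationError(f"seed must be a non-negative integer, got {seed}")
    if n_gen < burn_in + _MIN_EXTRA_GEN:
        raise ConfigurationError(
            f"n_gen={n_gen} too small: need at least burn_in + "
            f"{_MIN_EXTRA_GEN} = {burn_in + _MIN_EXTRA_GEN} generations"
        )


def _emergent_dii(s_i, ratios):
    """delta_ii(n) = s_i(n+1) - r(n) * s_i(n); trailing entry undefined."""
    out = np.full(len(s_i), np.nan)
    out[:-1] = s_i[1:] - ratios[:-1] * s_i[:-1]
    return out


# ----------------------------------------------------------------------
# stochastic Helmstetter-Cooper
# ----------------------------------------------------------------------

def simulate_shc(params: ModelParams, n_gen: int, seed: int,
                 burn_in: int = DEFAULT_BURN_IN) -> LineageTable:
    """Simulate the stochastic Helmstetter-Cooper model.

    Each generation draws (lambda, tau_cyc, s_i); the division size is
    ``S_d = s_i * exp(lambda * tau_cyc)`` and division occurs ``tau_cyc``
    after the attributed initiation.  Optional mother-daughter correlations
    ``rho_i_md`` (on s_i) and ``rho_alpha_md`` (on alpha = exp(lambda *
    tau_cyc)) are imposed through stationary AR(1) chains; optional
    within-generation ``cross_corr`` draws the triple from a joint Gaussian.
    """
    _check_run(params, "sHC", n_gen, seed, burn_in)
    n = n_gen
    mu_l, sd_l = params.mean_lambda, params.cv_lambda * params.mean_lambda
    mu_t, sd_t = params.mean_tau_cyc, params.cv_tau_cyc * params.mean_tau_cyc
    mu_s, sd_s = params.mean_si, params.cv_si * params.mean_si
    rng_l = _substream(seed, "lambda")
    rng_t = _substream(seed, "tau_cyc")
    rng_s = _substream(seed, "s_i")
    rng_r = _substream(seed, "septum")

    md_mode = bool(params.rho_i_md or params.rho_alpha_md)
    if md_mode:
        lam = _positive_normal(rng_l, mu_l, sd_l, n, "lambda")
        s_i = _ar1_positive(rng_s, mu_s, sd_s, params.rho_i_md, n, "s_i")
        # ln(alpha) = lambda * tau_cyc: exact moments of a product of
        # independent Gaussians, simulated as a lognormal AR(1) whose
        # coefficient is corrected so the Pearson lag-1 correlation of alpha
        # itself equals rho_alpha_md.
        m_ln = mu_l * mu_t
        v_ln = (mu_l * sd_t) ** 2 + (mu_t * sd_l) ** 2 + (sd_l * sd_t) ** 2
        if v_ln > 0:
            rho_ln = math.log1p(params.rho_alpha_md * math.expm1(v_ln)) / v_ln
        else:
            rho_ln = 0.0
        ln_alpha = _ar1_positive(rng_t, m_ln, math.sqrt(v_ln), rho_ln, n,
                                 "alpha")
        alpha = np.exp(ln_alpha)
        tau_cyc = ln_alpha / lam
    elif params.cross_corr:
        corr = params.cross_corr_matrix()
        mean_vec = np.array([mu_l, mu_t, mu_s])
        sds = np.array([sd_l, sd_t, sd_s])
        cov = corr * np.outer(sds, sds)
        rng_j = _substream(seed, "joint")
        draws = rng_j.multivariate_normal(mean_vec, cov, size=n,
                                          check_valid="ignore")
        for _ in range(_MAX_REJECT):
            bad = (draws <= 0).any(axis=1)
            if not bad.any():
                break
            draws[bad] = rng_j.multivariate_normal(
                mean_vec, cov, size=int(bad.sum()), check_valid="ignore")
        else:
            raise RejectionSamplingError("(lambda, tau_cyc, s_i) joint draw")
        lam, tau_cyc, s_i = draws.T.copy()
        alpha = np.exp(lam * tau_cyc)
    else:
        lam = _positive_normal(rng_l, mu_l, sd_l, n, "lambda")
        tau_cyc = _positive_normal(rng_t, mu_t, sd_t, n, "tau_cyc")
        s_i = _positive_normal(rng_s, mu_s, sd_s, n, "s_i")
        alpha = np.exp(lam * tau_cyc)

    S_d = s_i * alpha
    ratios = _division_ratios(rng_r, n, params.septum_sd)
    S_b = np.empty(n)
    S_b[0] = 0.5 * mu_s * math.exp(mu_l * mu_t)
    S_b[1:] = ratios[:-1] * S_d[:-1]
    tau, n_floored = _tau_from_sizes(S_b, S_d, lam, mu_l)
    t_b, t_d = _times_from_tau(tau)
    a_i, S_i, g = _attribute_by_time(s_i, tau_cyc, t_b, t_d)
    return _make_lineage(
        "sHC", params, seed, burn_in, lam=lam, tau=tau, S_b=S_b, S_d=S_d,
        s_i=s_i, S_i=S_i, tau_cyc=tau_cyc, a_i=a_i,
        delta_ii=_emergent_dii(s_i, ratios), delta_id=(S_d - s_i) / 2.0,
        ratios=ratios, info={"overlap_g": g, "n_tau_floored": n_floored})


# ----------------------------------------------------------------------
# Initiation Adder
# ----------------------------------------------------------------------

def simulate_ia(params: ModelParams, n_gen: int, seed: int,
                burn_in: int = DEFAULT_BURN_IN) -> LineageTable:
    """Simulate the Initiation Adder model.

    The per-origin initiation size follows the adder recursion
    ``s_i(n+1) = s_i(n)/2 + delta_ii(n)`` (ratio-generalized under septum
    noise) while division still fires a drawn ``tau_cyc`` after initiation,
    with ``S_d = s_i * exp(lambda * tau_cyc)``.
    """
    _check_run(params, "IA", n_gen, seed, burn_in)
    n = n_gen
    mu_l, sd_l = params.mean_lambda, params.cv_lambda * params.mean_lambda
    mu_t, sd_t = params.mean_tau_cyc, params.cv_tau_cyc * params.mean_tau_cyc
    rng_l = _substream(seed, "lambda")
    rng_t = _substream(seed, "tau_cyc")
    rng_d = _substream(seed, "delta_ii")
    rng_r = _substream(seed, "septum")

    lam = _positive_normal(rng_l, mu_l, sd_l, n, "lambda")
    tau_cyc = _positive_normal(rng_t, mu_t, sd_t, n, "tau_cyc")
    dii = _positive_normal(rng_d, params.mean_dii, params.sd_dii, n, "delta_ii")
    ratios = _division_ratios(rng_r, n, params.septum_sd)

    s_i = np.empty(n)
    s_i[0] = 2.0 * params.mean_dii
    for i in range(n - 1):
        s_i[i + 1] = ratios[i] * s_i[i] + dii[i]

    S_d = s_i * np.exp(lam * tau_cyc)
    S_b = np.empty(n)
    S_b[0] = params.mean_dii * math.exp(mu_l * mu_t)
    S_b[1:] = ratios[:-1] * S_d[:-1]
    tau, n_floored = _tau_from_sizes(S_b, S_d, lam, mu_l)
    t_b, t_d = _times_from_tau(tau)
    a_i, S_i, g = _attribute_by_time(s_i, tau_cyc, t_b, t_d)
    return _make_lineage(
        "IA", params, seed, burn_in, lam=lam, tau=tau, S_b=S_b, S_d=S_d,
        s_i=s_i, S_i=S_i, tau_cyc=tau_cyc, a_i=a_i, delta_ii=dii,
        delta_id=(S_d - s_i) / 2.0, ratios=ratios,
        info={"overlap_g": g, "n_tau_floored": n_floored})


# ----------------------------------------------------------------------
# Replication Double Adder
# ----------------------------------------------------------------------

def simulate_rda(params: ModelParams, n_gen: int, seed: int,
                 burn_in: int = DEFAULT_BURN_IN) -> LineageTable:
    """Simulate the Replication Double Adder model.

    Initiation sizes follow the initiation adder; the division size is set
    by the second adder ``S_d = s_i + 2 delta_id`` in per-origin coordinates
    (valid for any number of overlapping cycles).  tau_cyc is emergent and
    measured from the realized timing, not drawn.
    """
    _check_run(params, "RDA", n_gen, seed, burn_in)
    n = n_gen
    rng_l = _substream(seed, "lambda")
    rng_i = _substream(seed, "delta_ii")
    rng_d = _substream(seed, "delta_id")
    rng_r = _substream(seed, "septum")

    lam = _positive_normal(rng_l, params.mean_lambda,
                           params.cv_lambda * params.mean_lambda, n, "lambda")
    dii = _positive_normal(rng_i, params.mean_dii, params.sd_dii, n, "delta_ii")
    did = _positive_normal(rng_d, params.mean_did, params.sd_did, n, "delta_id")
    ratios = _division_ratios(rng_r, n, params.septum_sd)

    s_i = np.empty(n)
    s_i[0] = 2.0 * params.mean_dii
    for i in range(n - 1):
        s_i[i + 1] = ratios[i] * s_i[i] + dii[i]

    S_d = s_i + 2.0 * did
    S_b = np.empty(n)
    S_b[0] = params.mean_dii + params.mean_did
    S_b[1:] = ratios[:-1] * S_d[:-1]
    tau, n_floored = _tau_from_sizes(S_b, S_d, lam, params.mean_lambda)
    t_b, t_d = _times_from_tau(tau)
    tau_cyc, a_i, S_i, g = _attribute_by_size(s_i, S_b, S_d, lam, t_b, t_d)
    return _make_lineage(
        "RDA", params, seed, burn_in, lam=lam, tau=tau, S_b=S_b, S_d=S_d,
        s_i=s_i, S_i=S_i, tau_cyc=tau_cyc, a_i=a_i, delta_ii=dii,
        delta_id=did, ratios=ratios,
        info={"overlap_g": g, "n_tau_floored": n_floored})


# ----------------------------------------------------------------------
# Independent Double Adder
# ----------------------------------------------------------------------

def simulate_ida(params: ModelParams, n_gen: int, seed: int,
                 burn_in: int = DEFAULT_BURN_IN) -> LineageTable:
    """Simulate the Independent Double Adder model.

    Division sizes follow their own adder ``S_d(n+1) = S_d(n)/2 + Delta_d``
    while initiation sizes independently follow the initiation adder; the
    two processes use independent RNG substreams.  Initiation events are
    paired 1:1 with divisions in order, and delta_id / tau_cyc are emergent.
    """
    _check_run(params, "IDA", n_gen, seed, burn_in)
    n = n_gen
    rng_l = _substream(seed, "lambda")
    rng_i = _substream(seed, "delta_ii")
    rng_d = _substream(seed, "Delta_d")
    rng_r = _substream(seed, "septum")

    lam = _positive_normal(rng_l, params.mean_lambda,
                           params.cv_lambda * params.mean_lambda, n, "lambda")
    dii = _positive_normal(rng_i, params.mean_dii, params.sd_dii, n, "delta_ii")
    Dd = _positive_normal(rng_d, params.mean_Dd, params.sd_Dd, n, "Delta_d")
    ratios = _division_ratios(rng_r, n, params.septum_sd)

    s_i = np.empty(n)
    s_i[0] = 2.0 * params.mean_dii
    S_b = np.empty(n)
    S_d = np.empty(n)
    S_b[0] = params.mean_Dd
    for i in range(n):
        S_d[i] = S_b[i] + Dd[i]
        if i < n - 1:
            S_b[i + 1] = ratios[i] * S_d[i]
            s_i[i + 1] = ratios[i] * s_i[i] + dii[i]

    tau = np.log(S_d / S_b) / lam
    t_b, t_d = _times_from_tau(tau)
    tau_cyc, a_i, S_i, g = _attribute_by_size(s_i, S_b, S_d, lam, t_b, t_d)
    return _make_lineage(
        "IDA", params, seed, burn_in, lam=lam, tau=tau, S_b=S_b, S_d=S_d,
        s_i=s_i, S_i=S_i, tau_cyc=tau_cyc, a_i=a_i, delta_ii=dii,
        delta_id=(S_d - s_i) / 2.0, ratios=ratios, info={"overlap_g": g})


# ----------------------------------------------------------------------
# Concurrent Cell-Cycle Processes
# ----------------------------------------------------------------------

def simulate_cccp(params: ModelParams, n_gen: int, seed: int,
                  burn_in: int = DEFAULT_BURN_IN) -> LineageTable:
    """Simulate the Concurrent Cell-Cycle Processes model.

    Log initiation sizes follow a log-adder; two candidate division sizes
    compete each generation — the replication-limited ``ln S_R = ln s_i +
    lambda C`` and the division-adder ``ln S_H(n) = ln S_H(n-1)/2 + B`` —
    and the larger wins.  The realized limiting fraction ``f`` (strict
    ``S_H`` wins) is reported in ``lineage.info["f"]`` together with the
    measured log-moments of both candidates.
    """
    _check_run(params, "CCCP", n_gen, seed, burn_in)
    n = n_gen
    rng_l = _substream(seed, "lambda")
    rng_a = _substream(seed, "A")
    rng_b = _substream(seed, "B")
    rng_c = _substream(seed, "C")
    rng_r = _substream(seed, "septum")

    lam = _positive_normal(rng_l, params.mean_lambda,
                           params.cv_lambda * params.mean_lambda, n, "lambda")
    A = rng_a.normal(params.mean_A, params.sd_A, size=n)
    B = rng_b.normal(params.mean_B, params.sd_B, size=n)
    C = _positive_normal(rng_c, params.mean_C, params.sd_C, n, "C")
    ratios = _division_ratios(rng_r, n, params.septum_sd)

    ln_si = np.empty(n)
    ln_SR = np.empty(n)
    ln_SH = np.empty(n)
    ln_Sd = np.empty(n)
    S_b = np.empty(n)
    h_wins = np.zeros(n, dtype=bool)
    ln_si[0] = 2.0 * params.mean_A
    ln_SH_prev = 2.0 * params.mean_B
    S_b[0] = 0.5 * math.exp(max(2.0 * params.mean_B,
                                2.0 * params.mean_A + params.mean_lambda * params.mean_C))
    for i in range(n):
        lnH = 0.5 * ln_SH_prev + B[i]
        lnR = ln_si[i] + lam[i] * C[i]
        ln_SH[i] = lnH
        ln_SR[i] = lnR
        ln_Sd[i] = max(lnR, lnH)
        h_wins[i] = lnR < lnH  # ties (probability zero) go to S_R
        ln_SH_prev = lnH
        if i < n - 1:
            S_b[i + 1] = ratios[i] * math.exp(ln_Sd[i])
            ln_si[i + 1] = 0.5 * ln_si[i] + A[i]

    S_d = np.exp(ln_Sd)
    s_i = np.exp(ln_si)
    tau, n_floored = _tau_from_sizes(S_b, S_d, lam, params.mean_lambda)
    t_b, t_d = _times_from_tau(tau)
    tau_cyc, a_i, S_i, g = _attribute_by_size(s_i, S_b, S_d, lam, t_b, t_d)

    keep = slice(burn_in, None)
    info = {
        "f": float(h_wins[keep].mean()),
        "mu_H": float(ln_SH[keep].mean()),
        "sigma_H": float(ln_SH[keep].std(ddof=1)),
        "mu_R": float(ln_SR[keep].mean()),
        "sigma_R": float(ln_SR[keep].std(ddof=1)),
        "sigma_lnsi": float(ln_si[keep].std(ddof=1)),
        "h_wins": h_wins,
        "overlap_g": g,
        "n_tau_floored": n_floored,
    }
    dii = np.full(n, np.nan)
    dii[:-1] = s_i[1:] - 0.5 * s_i[:-1]  # the model's adder acts on log sizes
    return _make_lineage(
        "CCCP", params, seed, burn_in, lam=lam, tau=tau, S_b=S_b, S_d=S_d,
        s_i=s_i, S_i=S_i, tau_cyc=tau_cyc, a_i=a_i, delta_ii=dii,
        delta_id=(S_d - s_i) / 2.0, ratios=ratios, info=info)


# ----------------------------------------------------------------------
# Mechanistic initiator-threshold model
# ----------------------------------------------------------------------

def simulate_threshold_ida(params: ModelParams, n_gen: int, seed: int,
                           dt: float | None = None,
                           burn_in: int = DEFAULT_BURN_IN) -> LineageTable:
    """Simulate the initiator-threshold mechanism behind the IDA model.

    Two initiator pools are produced in proportion to volume growth
    (balanced biosynthesis, dN = c* dV, optionally with counting noise).
    Division fires when the division pool reaches ``N0``; replication
    initiation fires all origins when the initiation pool reaches
    ``(#oriC) * N0_init``.  The initiation pool resets on firing; both pools
    are partitioned at division (deterministic halving by default, binomial
    optionally), as is the origin count.
    """
    _check_run(params, "threshold-IDA", n_gen, seed, burn_in)
    tau_mean = math.log(2.0) / params.mean_lambda
    if dt is None:
        dt = tau_mean / 250.0
    if dt > tau_mean / 200.0:
        raise ConfigurationError(
            f"dt={dt} too coarse: must be <= mean doubling time / 200 "
            f"= {tau_mean / 200.0:.4g}")
    N0 = params.N0
    N0_init = params.N0_init if params.N0_init is not None else 0.35 * N0
    cst = params.c_star
    xi = params.production_noise
    binom = params.partition == "binomial"

    rng_l = _substream(seed, "lambda")
    rng_p = _substream(seed, "production")
    rng_r = _substream(seed, "septum")
    rng_part = _substream(seed, "partition")

    # steady-state-ish initial condition
    V = N0 / (2.0 * cst)
    n_ori = 1
    pool_div = N0 / 2.0
    pool_ini = 0.0
    t = 0.0
    lam = _draw_lambda(rng_l, params)
    birth_t, birth_V, birth_lam = t, V, lam

    div_t: list[float] = []
    rows: list[tuple] = []          # (t_b, t_d, S_b, S_d, lam, ratio)
    init_t: list[float] = []
    init_si: list[float] = []
    init_V: list[float] = []

    growth = math.exp(lam * dt)
    max_steps = int(n_gen * (tau_mean / dt) * 20)
    noise_buf = rng_p.standard_normal(1 << 14) if xi > 0 else None
    buf_i = 0
    for _ in range(max_steps):
        if len(rows) >= n_gen:
            break
        V_new = V * growth
        dV = V_new - V
        V = V_new
        t += dt
        inc = cst * dV
        if xi > 0:
            if buf_i + 2 > len(noise_buf):
                noise_buf = rng_p.standard_normal(1 << 14)
                buf_i = 0
            sd = xi * math.sqrt(inc)
            pool_div += inc + sd * noise_buf[buf_i]
            pool_ini += inc + sd * noise_buf[buf_i + 1]
            buf_i += 2
        else:
            pool_div += inc
            pool_ini += inc
        if pool_ini >= n_ori * N0_init:
            init_t.append(t)
            init_si.append(V / n_ori)
            init_V.append(V)
            n_ori *= 2
            pool_ini = 0.0
        if pool_div >= N0:
            r = 0.5 if params.septum_sd == 0 else float(
                _division_ratios(rng_r, 1, params.septum_sd)[0])
            rows.append((birth_t, t, birth_V, V, birth_lam, r))
            div_t.append(t)
            if binom:
                pool_div = float(rng_part.binomial(max(int(round(pool_div)), 0), r))
                pool_ini = float(rng_part.binomial(max(int(round(pool_ini)), 0), r))
            else:
                pool_div *= r
                pool_ini *= r
            V *= r
            n_ori = max(n_ori // 2, 1)
            lam = _draw_lambda(rng_l, params)
            growth = math.exp(lam * dt)
            birth_t, birth_V, birth_lam = t, V, lam
    if len(rows) < n_gen:
        raise RejectionSamplingError("threshold-IDA divisions (step budget)")

    t_b_arr = np.array([r[0] for r in rows])
    t_d_arr = np.array([r[1] for r in rows])
    S_b = np.array([r[2] for r in rows])
    S_d = np.array([r[3] for r in rows])
    lam_arr = np.array([r[4] for r in rows])
    ratios = np.array([r[5] for r in rows])
    tau = t_d_arr - t_b_arr

    n = len(rows)
    s_i = np.full(n, np.nan)
    S_i = np.full(n, np.nan)
    tau_cyc = np.full(n, np.nan)
    a_i = np.full(n, np.nan)
    if init_t:
        # pair the k-th initiation with the k-th division after it
        offset = int(np.searchsorted(t_d_arr, init_t[0]))
        for k in range(len(init_t)):
            nn = k + offset
            if nn >= n:
                break
            s_i[nn] = init_si[k]
            S_i[nn] = init_V[k]
            tau_cyc[nn] = t_d_arr[nn] - init_t[k]
            m = int(np.searchsorted(t_d_arr, init_t[k], side="right"))
            if m < n:
                a_i[m] = init_t[k] - t_b_arr[m]
    dii = np.full(n, np.nan)
    dii[:-1] = s_i[1:] - 0.5 * s_i[:-1]
    return _make_lineage(
        "threshold-IDA", params, seed, burn_in, lam=lam_arr, tau=tau,
        S_b=S_b, S_d=S_d, s_i=s_i, S_i=S_i, tau_cyc=tau_cyc, a_i=a_i,
        delta_ii=dii, delta_id=(S_d - s_i) / 2.0, ratios=ratios,
        info={"dt": dt, "N0_init": N0_init, "n_initiations": len(init_t)})


def _draw_lambda(rng, params):
    sd = params.cv_lambda * params.mean_lambda
    if sd == 0:
        return params.mean_lambda
    for _ in range(_MAX_REJECT):
        val = rng.normal(params.mean_lambda, sd)
        if val > 0:
            return val
    raise RejectionSamplingError("lambda")


# ----------------------------------------------------------------------

_SIMULATORS = {
    "sHC": simulate_shc,
    "IA": simulate_ia,
    "RDA": simulate_rda,
    "IDA": simulate_ida,
    "CCCP": simulate_cccp,
    "threshold-IDA": simulate_threshold_ida,
}


def simulate(model: str, params: ModelParams, n_gen: int, seed: int,
             burn_in: int = DEFAULT_BURN_IN, **kwargs) -> LineageTable:
    """Dispatch to the named model's simulator."""
    name = canonical_model_name(model)
    return _SIMULATORS[name](params, n_gen, seed, burn_in=burn_in, **kwargs)
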