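"""Convergence and model-comparison diagnostics.

* Gelman-Rubin potential scale reduction factor (PSRF), the classic
  between/within-chain variance ratio; values near 1 indicate the chains
  agree, and the conventional cutoff used here is 1.1.
* Conditional predictive ordinate (CPO): the leave-one-out predictive density
  of each site's detection history, estimated as the harmonic mean of the
  per-draw site likelihoods.  Models are ranked by the sum of negative log
  CPO values (lower = better predictive support).
* Effect probability eta = Pr(coefficient > 0): >= 0.90 is read as strong
  evidence of a positive effect, <= 0.10 strong evidence of a negative one.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import logsumexp

PSRF_THRESHOLD = 1.1


def gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """PSRF per parameter from draws of shape (n_chains, n_draws[, n_params]).

    Uses the between/within variance decomposition: with C chains of length
    N, W = mean within-chain variance, B/N = between-chain variance of the
    chain means, pooled variance (N-1)/N * W + B/N, and PSRF = sqrt(pooled/W).
    """
    chains = np.asarray(chains, dtype=float)
    squeeze = chains.ndim == 2
    if squeeze:
        chains = chains[..., None]
    C, N, _ = chains.shape
    if C < 2:
        raise ValueError("Gelman-Rubin diagnostic requires at least 2 chains")
    chain_means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean(axis=0)
    B = N * chain_means.var(axis=0, ddof=1)
    pooled = (N - 1) / N * W + B / N
    with np.errstate(divide="ignore", invalid="ignore"):
        psrf = np.sqrt(pooled / W)
    psrf = np.where((W == 0) & (B == 0), 1.0, psrf)  # identical constant chains
    psrf = np.maximum(psrf, 1.0)  # sampling noise can push the ratio below 1
    return float(psrf[0]) if squeeze else psrf


def effect_probability(draws: np.ndarray) -> float:
    """eta = fraction of posterior draws strictly greater than zero."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("effect_probability requires at least one draw")
    return float(np.mean(draws > 0))


def classify_effect(eta: float, strong: float = 0.90) -> str:
    if eta >= strong:
        return "strong positive"
    if eta <= 1 - strong:
        return "strong negative"
    return "equivocal"


def cpo_from_logliks(loglik: np.ndarray):
    """Per-site CPO and the model score from a (draws, sites) log-lik matrix.

    CPO_i = [ M^-1 sum_m 1 / L_i(theta_m) ]^-1  (harmonic mean of the per-draw
    site likelihoods); score = -sum_i log CPO_i.  A site whose likelihood is
    zero for any draw has an undefined CPO; it is reported as NaN and the
    score becomes +inf with a warning.
    """
    loglik = np.asarray(loglik, dtype=float)
    M = loglik.shape[0]
    log_cpo = np.log(M) - logsumexp(-loglik, axis=0)
    bad = ~np.isfinite(log_cpo) | np.any(~np.isfinite(loglik), axis=0)
    cpo = np.exp(log_cpo)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} site(s) have zero likelihood for some draw; "
            "CPO undefined, model score set to +inf"
        )
        cpo = np.where(bad, np.nan, cpo)
        return cpo, np.inf
    return cpo, float(-log_cpo.sum())
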