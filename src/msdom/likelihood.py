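"""Core probability machinery for the multi-state diel occupancy model (MSDOM).

A site-season is in one of four mutually exclusive latent diel-use states:

    1 -- no use
    2 -- day use only
    3 -- night use only
    4 -- day-and-night use

Occupancy is the probability vector ``psi = (psi1, psi2, psi3, psi4)`` over
these states.  Two parameterizations are supported:

* **full** -- a multinomial-logit link with state 1 as the reference, so the
  day-and-night state is estimated freely;
* **reduced** -- two independent latent use propensities, ``theta_D`` for day
  use and ``theta_N`` for night use, combined as independent Bernoullis so
  that ``psi4`` equals the product of the *marginal* day-use and night-use
  probabilities.

Observation is imperfect: each 24-h occasion yields an observed state drawn
from a row-stochastic 4x4 matrix ``Theta[s, o] = Pr(observe o | true state s)``
with the structural zeros implied by the state definitions (an unused site is
never detected; a day-only site never yields a night observation, and vice
versa).  Everything here is computed in log space; with ~42 occasions per
season the raw products underflow double precision.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, log_expit, logsumexp

N_STATES = 4
STATE_LABELS = {1: "none", 2: "day", 3: "night", 4: "daynight"}

# Tiny floor used when taking logs of structurally-zero observation
# probabilities: a history that requires an impossible cell then contributes
# ~ -690 per occasion, which vanishes inside logsumexp without producing NaN.
_LOG_FLOOR = 1e-300


def occupancy_logprobs_full(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Log state probabilities under the multinomial-logit (full) link.

    Parameters
    ----------
    beta : array, shape (3, k) or sequence of three length-k_s vectors
        Coefficient vectors for states 2, 3, 4 (state 1 is the reference).
    X : array, shape (n, k) or sequence of three (n, k_s) matrices
        Design rows.  A sequence allows state-specific design columns
        (used for the diel-matched prey index).

    Returns
    -------
    array, shape (n, 4) of log psi; rows log-sum to 0.
    """
    if isinstance(X, (list, tuple)):
        eta = np.column_stack([np.asarray(Xs) @ np.asarray(bs) for Xs, bs in zip(X, beta)])
    else:
        eta = np.asarray(X) @ np.asarray(beta).T
    z = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
    return z - logsumexp(z, axis=1, keepdims=True)


def occupancy_probs_full(beta, X) -> np.ndarray:
    """State probabilities (psi1..psi4) under the full parameterization."""
    return np.exp(occupancy_logprobs_full(beta, X))


def occupancy_logprobs_reduced(beta_day, beta_night, X_day, X_night=None) -> np.ndarray:
    """Log state probabilities under the reduced (independent day/night) link.

    theta_D = logit^-1(x . beta_day) and theta_N = logit^-1(x . beta_night)
    are latent day-use and night-use propensities; the four exclusive states
    are their independent-Bernoulli products:

        psi1 = (1-theta_D)(1-theta_N)   psi2 = theta_D (1-theta_N)
        psi3 = (1-theta_D) theta_N      psi4 = theta_D theta_N
    """
    if X_night is None:
        X_night = X_day
    eta_d = np.asarray(X_day) @ np.asarray(beta_day)
    eta_n = np.asarray(X_night) @ np.asarray(beta_night)
    ld, lmd = log_expit(eta_d), log_expit(-eta_d)
    ln, lmn = log_expit(eta_n), log_expit(-eta_n)
    return np.column_stack([lmd + lmn, ld + lmn, lmd + ln, ld + ln])


def occupancy_probs_reduced(beta_day, beta_night, X_day, X_night=None) -> np.ndarray:
    return np.exp(occupancy_logprobs_reduced(beta_day, beta_night, X_day, X_night))


def observation_matrix(
    p_day: float,
    p_night: float,
    state4_logits: np.ndarray | None = None,
) -> np.ndarray:
    """Row-stochastic observation matrix Theta[s, o] for one season.

    Rows are the true state, columns the observed state (1..4).  ``p_day`` and
    ``p_night`` are the per-occasion detection probabilities given true state
    2 and 3 respectively.

    ``state4_logits`` -- length-3 logits (observed day, night, day-and-night;
    reference = observed state 1) for the full parameterization's free
    state-4 observation distribution.  If None (reduced parameterization),
    row 4 composes independent day and night detection from ``p_day`` and
    ``p_night``.
    """
    Theta = np.zeros((4, 4))
    Theta[0, 0] = 1.0
    Theta[1] = [1.0 - p_day, p_day, 0.0, 0.0]
    Theta[2] = [1.0 - p_night, 0.0, p_night, 0.0]
    if state4_logits is None:
        qd, qn = 1.0 - p_day, 1.0 - p_night
        Theta[3] = [qd * qn, p_day * qn, qd * p_night, p_day * p_night]
    else:
        z = np.concatenate([[0.0], np.asarray(state4_logits, dtype=float)])
        e = np.exp(z - z.max())
        Theta[3] = e / e.sum()
    return Theta


def history_counts(history: np.ndarray) -> np.ndarray:
    """Per-row counts of observed states 1..4, ignoring missing occasions.

    ``history`` is (n_rows, n_occasions) with entries in {1,2,3,4} or NaN.
    Returns an (n_rows, 4) integer matrix.  Because the observation matrix is
    constant within a row (it depends only on the row's season), these counts
    are a sufficient summary of the history for the likelihood.
    """
    H = np.asarray(history, dtype=float)
    counts = np.empty((H.shape[0], 4), dtype=np.int64)
    for k in range(4):
        counts[:, k] = np.nansum(H == k + 1, axis=1)
    return counts


def loglik_rows(counts: np.ndarray, logpsi: np.ndarray, logTheta: np.ndarray) -> np.ndarray:
    """Marginal log-likelihood of each row given its state counts.

    log L_i = logsumexp_s [ log psi_is + sum_k counts_ik * log Theta[s, k] ]

    ``logTheta`` may be (4, 4) shared across rows or (n, 4, 4) per row.
    """
    counts = np.asarray(counts, dtype=float)
    if logTheta.ndim == 2:
        per_state = counts @ logTheta.T  # (n, 4)
    else:
        per_state = np.einsum("nk,nsk->ns", counts, logTheta)
    return logsumexp(logpsi + per_state, axis=1)


def log_observation_matrix(Theta: np.ndarray) -> np.ndarray:
    return np.log(np.clip(Theta, _LOG_FLOOR, None))


def site_loglik(y, psi, thetas) -> float:
    """Marginal log-likelihood of one detection history.

    Parameters
    ----------
    y : sequence of observed states in {1,2,3,4}, with None/NaN for missing
        occasions (which contribute a factor of 1).
    psi : length-4 state-occupancy vector.
    thetas : one 4x4 observation matrix, or a list with one per occasion.

    Returns ``-inf`` when the history is impossible under the parameters.
    """
    y = list(y)
    thetas = np.asarray(thetas, dtype=float)
    if thetas.ndim == 2:
        thetas = np.broadcast_to(thetas, (len(y), 4, 4))
    with np.errstate(divide="ignore"):
        logpsi = np.log(np.asarray(psi, dtype=float))
        per_state = np.zeros(4)
        for j, obs in enumerate(y):
            if obs is None or (isinstance(obs, float) and np.isnan(obs)):
                continue
            per_state = per_state + np.log(thetas[j][:, int(obs) - 1])
    out = logsumexp(logpsi + per_state)
    return float(out) if np.isfinite(out) else -np.inf
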