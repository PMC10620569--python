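"""Metropolis samplers: adaptive random walk + Laplace independence proposals.

The kernel mixes two proposal types:

* a Gaussian random walk whose covariance adapts during warmup to the
  empirical posterior covariance (Haario-style) with a Robbins-Monro
  adjustment of the global step size toward the canonical 0.234 acceptance
  rate; adaptation freezes after warmup so kept draws target the exact
  posterior;
* an independence proposal from a multivariate Student-t centered at the
  posterior mode with the Laplace (inverse-Hessian) covariance.  The
  posteriors fitted here are low-dimensional and close to Gaussian, so these
  moves are accepted often and decorrelate the chain; the random-walk
  component guarantees local exploration where the Laplace approximation is
  poor.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import gammaln

TARGET_ACCEPT = 0.234
INDEP_PROB = 0.5
INDEP_DF = 4.0


class _StudentT:
    """Multivariate Student-t proposal (frozen location/scale)."""

    def __init__(self, mean: np.ndarray, cov: np.ndarray, df: float = INDEP_DF):
        self.mean = np.asarray(mean, dtype=float)
        self.df = float(df)
        self.d = self.mean.size
        cov = np.asarray(cov, dtype=float)
        self.chol = np.linalg.cholesky(cov + 1e-10 * np.eye(self.d))
        self._logdet = 2 * np.log(np.diag(self.chol)).sum()
        self._lognorm = (gammaln((self.df + self.d) / 2) - gammaln(self.df / 2)
                         - self.d / 2 * np.log(self.df * np.pi) - self._logdet / 2)

    def rvs(self, rng: np.random.Generator) -> np.ndarray:
        z = self.chol @ rng.standard_normal(self.d)
        u = rng.chisquare(self.df)
        return self.mean + z * np.sqrt(self.df / u)

    def logpdf(self, x: np.ndarray) -> float:
        y = solve_triangular(self.chol, x - self.mean, lower=True)
        m = float(y @ y)
        return float(self._lognorm - (self.df + self.d) / 2 * np.log1p(m / self.df))


def adaptive_metropolis(
    log_post,
    x0: np.ndarray,
    warmup: int,
    draws: int,
    rng: np.random.Generator,
    target_accept: float = TARGET_ACCEPT,
    cov_update_every: int = 25,
    cov0: np.ndarray | None = None,
    indep: "_StudentT | None" = None,
    indep_prob: float = INDEP_PROB,
):
    """Sample ``draws`` points from ``log_post`` after ``warmup`` adaptation steps.

    ``cov0`` seeds the random-walk proposal covariance (e.g. a Laplace
    approximation at the posterior mode); adaptation refines it during
    warmup.  ``indep`` adds Metropolized independence proposals drawn from
    that Student-t with probability ``indep_prob`` per iteration.
    Returns (samples (draws, d), acceptance_rate_after_warmup).
    """
    x = np.asarray(x0, dtype=float).copy()
    d = x.size
    lp = log_post(x)
    if not np.isfinite(lp):
        raise ValueError("log posterior is not finite at the initial point")

    mean = x.copy()
    cov = np.eye(d) if cov0 is None else np.asarray(cov0, dtype=float).copy()
    log_scale = np.log(2.38**2 / d) / 2.0  # scale on the sd, not variance
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(d))
    logq_x = indep.logpdf(x) if indep is not None else 0.0

    samples = np.empty((draws, d))
    n_acc_post = 0

    total = warmup + draws
    for t in range(total):
        adapting = t < warmup
        indep_move = indep is not None and rng.random() < indep_prob
        if indep_move:
            prop = indep.rvs(rng)
            logq_prop = indep.logpdf(prop)
            lp_prop = log_post(prop)
            log_alpha = (lp_prop - logq_prop) - (lp - logq_x)
        else:
            prop = x + np.exp(log_scale) * (chol @ rng.standard_normal(d))
            lp_prop = log_post(prop)
            log_alpha = lp_prop - lp
        accept_prob = 1.0 if log_alpha >= 0 else float(np.exp(log_alpha))
        if rng.random() < accept_prob:
            x, lp = prop, lp_prop
            if indep is not None:
                logq_x = logq_prop if indep_move else indep.logpdf(x)
            if not adapting:
                n_acc_post += 1

        if adapting:
            # running mean / covariance of the chain
            w = 1.0 / (t + 2)
            delta = x - mean
            mean = mean + w * delta
            cov = (1 - w) * cov + w * np.outer(delta, delta)
            if not indep_move:
                # step-size adaptation toward the target acceptance rate
                log_scale += (accept_prob - target_accept) / (t + 1) ** 0.6
            if (t + 1) % cov_update_every == 0:
                chol = np.linalg.cholesky(cov + 1e-8 * np.eye(d))
        else:
            samples[t - warmup] = x

    return samples, n_acc_post / max(draws, 1)


def run_chains(
    log_post,
    init_points: np.ndarray,
    warmup: int,
    draws: int,
    seed: int,
    cov0: np.ndarray | None = None,
    mode: np.ndarray | None = None,
) -> np.ndarray:
    """Run one chain per initial point; returns draws of shape (C, draws, d).

    When ``mode`` and ``cov0`` are given, a Student-t independence proposal
    centered there (covariance inflated 1.3x) is mixed into the kernel.
    """
    init_points = np.atleast_2d(init_points)
    indep = None
    if mode is not None and cov0 is not None:
        indep = _StudentT(mode, 1.3 * cov0)
    chains = []
    for c, x0 in enumerate(init_points):
        rng = np.random.default_rng(np.random.SeedSequence([seed, c]))
        s, _ = adaptive_metropolis(log_post, x0, warmup, draws, rng,
                                   cov0=cov0, indep=indep)
        chains.append(s)
    return np.stack(chains)


def laplace_approximation(log_post, d: int, x0: np.ndarray | None = None):
    """Posterior mode and inverse-Hessian covariance (Laplace approximation).

    Used to initialize the chains and seed the proposal covariance.  Falls
    back to (x0, identity) if optimization or the Hessian inversion fails.
    """
    from scipy.optimize import minimize

    x0 = np.zeros(d) if x0 is None else np.asarray(x0, dtype=float)
    neg = lambda v: -log_post(v)
    try:
        opt = minimize(neg, x0, method="L-BFGS-B")
        xhat = opt.x
    except Exception:
        return x0, np.eye(d)
    # central-difference Hessian of -log posterior
    h = 1e-4 * np.maximum(1.0, np.abs(xhat))
    H = np.empty((d, d))
    f0 = neg(xhat)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h[i]
        H[i, i] = (neg(xhat + ei) - 2 * f0 + neg(xhat - ei)) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(d); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                neg(xhat + ei + ej) - neg(xhat + ei - ej)
                - neg(xhat - ei + ej) + neg(xhat - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        # guard against a non-PD numerical Hessian
        w, V = np.linalg.eigh((cov + cov.T) / 2)
        w = np.clip(w, 1e-8, None)
        cov = V @ np.diag(w) @ V.T
    except np.linalg.LinAlgError:
        cov = np.eye(d)
    return xhat, cov
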