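"""Bayesian multi-state diel occupancy model (MSDOM).

The model treats each stacked site-season row as closed within its season:
a latent diel-use state s in {1: none, 2: day, 3: night, 4: day-and-night}
is drawn once per row from the occupancy vector psi(x), and each 24-h
occasion independently yields an observed state from the row-stochastic
observation matrix Theta[s, .], whose detection probabilities differ by
state and by season.  The marginal likelihood of a row sums the latent state
out; missing occasions contribute nothing.

Priors follow standard practice for this model family: every regression
coefficient (occupancy and detection, on the logit / multinomial-logit
scale) has a diffuse Logistic(0, 1) prior.  For the intercept-only models
this is exactly a Beta(1, 1) prior on each plain probability, and the
full model's intercept-only occupancy simplex instead receives a flat
Dirichlet(1, 1, 1, 1) via the softmax change of variables.

Usage::

    model = MSDOM(history, design, parameterization="full")
    res = model.fit(draws=2000, warmup=2000, chains=3, seed=1)
    res.summary()
    res.predict_states(season="winter")
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit, logsumexp

from . import likelihood as lk
from .covariates import SiteDesign
from .diagnostics import (PSRF_THRESHOLD, classify_effect, cpo_from_logliks,
                          effect_probability, gelman_rubin)
from .params import FULL_STATES, REDUCED_STATES, MSDOMParams
from .sampler import laplace_approximation, run_chains


def _logistic_logpdf(x: np.ndarray) -> np.ndarray:
    # standard logistic density: e^-x / (1 + e^-x)^2
    return log_expit(x) + log_expit(-x)


def _lse_rows(a: np.ndarray) -> np.ndarray:
    # row-wise log-sum-exp for finite inputs; much cheaper than the scipy
    # general-purpose version, which dominates the sampling cost otherwise
    m = a.max(axis=1, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=1, keepdims=True)))[:, 0]


class MSDOM:
    """Multi-state diel occupancy model for one species.

    Parameters
    ----------
    history : DataFrame or array, shape (n_rows, n_occasions)
        Observed states 1-4 with NaN for unobserved occasions; rows are
        stacked site-seasons aligned with ``design``.
    design : SiteDesign
        Occupancy design (always carries the winter indicator for the
        detection model, which varies by state and season in every model).
    parameterization : {"full", "reduced"}
        Full estimates the day-and-night state freely via a multinomial
        logit; reduced derives it from independent day-use and night-use
        propensities.
    shared_state4_season : bool
        Collapse the three state-4 observation winter effects to one shared
        coefficient (full parameterization only).
    """

    def __init__(
        self,
        history,
        design: SiteDesign,
        parameterization: str = "full",
        shared_state4_season: bool = False,
    ):
        H = history.to_numpy(dtype=float) if isinstance(history, pd.DataFrame) else np.asarray(history, dtype=float)
        if isinstance(history, pd.DataFrame) and not history.index.equals(design.frame.index):
            raise ValueError("history rows do not align with the design rows")
        if H.shape[0] != len(design.frame):
            raise ValueError("history and design have different numbers of rows")
        obs = H[~np.isnan(H)]
        if obs.size and not np.isin(obs, [1, 2, 3, 4]).all():
            raise ValueError("history entries must be in {1,2,3,4} or missing")
        self.history = H
        self.design = design
        self.parameterization = parameterization
        self.shared_state4_season = shared_state4_season

        states = FULL_STATES if parameterization == "full" else REDUCED_STATES
        self._X = {s: design.matrix(s) for s in states}
        self.template = MSDOMParams(
            parameterization=parameterization,
            occ_coefs={s: np.zeros(self._X[s].shape[1]) for s in states},
            occ_columns={s: list(design.state_columns[s]) for s in states},
            shared_state4_season=shared_state4_season,
        )
        self.param_names = self.template.param_names()
        self.n_params = len(self.param_names)

        self._counts = lk.history_counts(H).astype(float)
        w = design.winter
        self._rows_by_season = {0: np.flatnonzero(w == 0), 1: np.flatnonzero(w == 1)}
        # flat Dirichlet on the occupancy simplex only for the full null model
        self._dirichlet_occ = (
            parameterization == "full"
            and all(design.state_columns[s] == ["intercept"] for s in states)
        )
        self._n_occ = sum(len(v) for v in self.template.occ_coefs.values())

    # -- posterior ----------------------------------------------------------

    def unpack(self, vec) -> MSDOMParams:
        return MSDOMParams.from_vector(vec, self.template)

    def _occ_logprobs(self, vec: np.ndarray) -> np.ndarray:
        """(n, 4) log state probabilities; hot path, works on vector slices."""
        states = self.template.states
        pos = 0
        etas = []
        for s in states:
            k = self._X[s].shape[1]
            etas.append(self._X[s] @ vec[pos:pos + k])
            pos += k
        if self.parameterization == "full":
            z = np.column_stack([np.zeros(len(etas[0])), *etas])
            return z - _lse_rows(z)[:, None]
        ld, lmd = log_expit(etas[0]), log_expit(-etas[0])
        ln, lmn = log_expit(etas[1]), log_expit(-etas[1])
        return np.column_stack([lmd + lmn, ld + lmn, lmd + ln, ld + ln])

    def _obs_logmatrix(self, vec: np.ndarray, winter: float) -> np.ndarray:
        pos = self._n_occ
        p_day = expit(vec[pos] + vec[pos + 1] * winter)
        p_night = expit(vec[pos + 2] + vec[pos + 3] * winter)
        s4 = None
        if self.parameterization == "full":
            tail = vec[pos + 4:]
            if self.shared_state4_season:
                a_d, al, a_n, a_dn = tail
                s4 = np.array([a_d, a_n, a_dn]) + al * winter
            else:
                s4 = tail[0::2] + tail[1::2] * winter
        return lk.log_observation_matrix(lk.observation_matrix(p_day, p_night, s4))

    def loglike_rows(self, vec) -> np.ndarray:
        """Per-row marginal log-likelihood at a flat parameter vector."""
        vec = np.asarray(vec, dtype=float)
        logpsi = self._occ_logprobs(vec)
        out = np.empty(self.history.shape[0])
        for w, rows in self._rows_by_season.items():
            if rows.size == 0:
                continue
            logT = self._obs_logmatrix(vec, w)
            out[rows] = _lse_rows(logpsi[rows] + self._counts[rows] @ logT.T)
        return out

    def loglike(self, vec) -> float:
        return float(self.loglike_rows(vec).sum())

    def logprior(self, vec) -> float:
        vec = np.asarray(vec, dtype=float)
        if self._dirichlet_occ:
            b = vec[: self._n_occ]
            z = np.concatenate([[0.0], b])
            occ_prior = float((z - logsumexp(z)).sum())  # sum_s log psi_s
            rest = vec[self._n_occ:]
            return occ_prior + float(_logistic_logpdf(rest).sum())
        return float(_logistic_logpdf(vec).sum())

    def logpost(self, vec) -> float:
        return self.loglike(vec) + self.logprior(vec)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        draws: int = 2000,
        warmup: int = 2000,
        chains: int = 3,
        seed: int = 0,
        cpo_draws: int = 1000,
        label: str | None = None,
    ) -> "MSDOMResults":
        """Sample the posterior and return a results object.

        ``cpo_draws`` caps the number of (evenly thinned) posterior draws used
        for the conditional-predictive-ordinate computation.
        """
        if chains < 2:
            raise ValueError("at least 2 chains are required for convergence checks")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 987]))
        xhat, cov0 = laplace_approximation(self.logpost, self.n_params)
        chol = np.linalg.cholesky(cov0 + 1e-10 * np.eye(self.n_params))
        init = xhat + rng.standard_normal((chains, self.n_params)) @ chol.T
        chain_draws = run_chains(self.logpost, init, warmup, draws, seed,
                                 cov0=cov0, mode=xhat)
        return MSDOMResults(self, chain_draws, seed=seed, cpo_draws=cpo_draws,
                            label=label)


@dataclass
class _PredRow:
    season: str
    state: str


class MSDOMResults:
    """Posterior draws, diagnostics and derived summaries for a fitted MSDOM."""

    def __init__(self, model: MSDOM, chain_draws: np.ndarray, seed: int,
                 cpo_draws: int = 1000, label: str | None = None):
        self.model = model
        self.chain_draws = chain_draws  # (chains, draws, d)
        self.param_names = model.param_names
        self.seed = seed
        self.label = label or f"{model.parameterization}:{model.design.form}"
        self.rhat = gelman_rubin(chain_draws)
        self.flat_draws = chain_draws.reshape(-1, chain_draws.shape[-1])
        self._site_logliks = self._compute_site_logliks(cpo_draws)
        self.cpo_sites, self.cpo_score = cpo_from_logliks(self._site_logliks)
        if not self.converged:
            warnings.warn(
                f"model {self.label}: PSRF >= {PSRF_THRESHOLD} for some parameters; "
                "treat estimates and CPO score with caution"
            )

    # -- diagnostics --------------------------------------------------------

    @property
    def converged(self) -> bool:
        return bool(np.all(self.rhat < PSRF_THRESHOLD))

    def _thin_indices(self, n: int) -> np.ndarray:
        total = self.flat_draws.shape[0]
        n = min(n, total)
        return np.linspace(0, total - 1, n).astype(int)

    def _compute_site_logliks(self, cpo_draws: int) -> np.ndarray:
        idx = self._thin_indices(cpo_draws)
        return np.stack([self.model.loglike_rows(self.flat_draws[i]) for i in idx])

    def eta(self, name: str) -> float:
        return effect_probability(self.flat_draws[:, self.param_names.index(name)])

    # -- summaries ----------------------------------------------------------

    def summary(self) -> pd.DataFrame:
        d = self.flat_draws
        q = np.percentile(d, [2.5, 50, 97.5], axis=0)
        return pd.DataFrame(
            {
                "mean": d.mean(axis=0),
                "sd": d.std(axis=0, ddof=1),
                "lo95": q[0],
                "median": q[1],
                "hi95": q[2],
                "eta": (d > 0).mean(axis=0),
                "rhat": self.rhat,
            },
            index=self.param_names,
        )

    def detection_summary(self) -> pd.DataFrame:
        """Winter effect on detection per diel state (mean, 95% CrI, eta).

        Reduced-model fits have no separate day-and-night observation
        process, so no day/night row is reported for them.
        """
        rows = [("day", "det[day]:winter"), ("night", "det[night]:winter")]
        if self.model.parameterization == "full":
            name = ("det4[daynight]:winter(shared)"
                    if self.model.shared_state4_season else "det4[daynight]:winter")
            rows.append(("daynight", name))
        out = []
        for state, name in rows:
            d = self.flat_draws[:, self.param_names.index(name)]
            eta = effect_probability(d)
            out.append({
                "state": state, "mean": d.mean(),
                "lo95": np.percentile(d, 2.5), "hi95": np.percentile(d, 97.5),
                "eta": eta, "evidence": classify_effect(eta),
            })
        return pd.DataFrame(out).set_index("state")

    # -- prediction ---------------------------------------------------------

    def _grid_default(self, n: int = 100) -> np.ndarray:
        frame = self.model.design.frame
        if "pca" in frame.columns and "pca" in {
            c for v in self.model.design.state_columns.values() for c in v
        }:
            lo, hi = np.percentile(frame["pca"], [1, 99])
            return np.linspace(lo, hi, n)
        return np.array([0.0])

    def _design_rows(self, pca: np.ndarray, winter: float) -> dict:
        value = {
            "intercept": np.ones_like(pca),
            "winter": np.full_like(pca, winter),
            "pca": pca,
            "winter:pca": winter * pca,
            "prey_day": np.zeros_like(pca),
            "prey_night": np.zeros_like(pca),
            "prey_mean": np.zeros_like(pca),
        }
        return {
            s: np.column_stack([value[c] for c in cols])
            for s, cols in self.model.design.state_columns.items()
        }

    def predict_states(
        self,
        season: str = "summer",
        grid: np.ndarray | None = None,
        max_draws: int = 1000,
    ) -> pd.DataFrame:
        """Posterior state-occupancy curves along the development-forest axis.

        Returns a long DataFrame (season, state, pca, median, lo95, hi95) for
        states day, night, daynight and the marginal occupancy psi2+psi3+psi4.
        """
        grid = self._grid_default() if grid is None else np.asarray(grid, dtype=float)
        winter = 1.0 if season == "winter" else 0.0
        X = self._design_rows(grid, winter)
        idx = self._thin_indices(max_draws)
        psis = np.stack([
            self.model.unpack(self.flat_draws[i]).occupancy_probs(X) for i in idx
        ])  # (draws, grid, 4)
        marginal = 1.0 - psis[..., 0]
        out = []
        for state_name, vals in (
            ("day", psis[..., 1]), ("night", psis[..., 2]),
            ("daynight", psis[..., 3]), ("marginal", marginal),
        ):
            q = np.percentile(vals, [2.5, 50, 97.5], axis=0)
            out.append(pd.DataFrame({
                "season": season, "state": state_name, "pca": grid,
                "lo95": q[0], "median": q[1], "hi95": q[2],
            }))
        return pd.concat(out, ignore_index=True)
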