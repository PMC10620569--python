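"""Forward simulation of the MSDOM study design.

Generates (a) stacked site-season detection-state histories with known
ground-truth parameters, and (b) raw timestamped camera-trap detection
records whose processing through the independence filter, day/night
classification and occasion coding reproduces the generated history exactly
(a round-trip oracle for the processing chain).

Defaults emulate the study design this package targets: 240 camera sites
surveyed over two ~6-week seasons (42 daily occasions each), a standardized
development-forest score per site, state- and season-dependent detection,
and a small fraction of unobserved occasions from camera downtime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .covariates import SiteDesign, assemble_design
from .params import MSDOMParams

SEASONS = ("summer", "winter")

#: season start dates and constant day windows (decimal hours, local time)
DEFAULT_SEASON_STARTS = {"summer": date(2021, 5, 26), "winter": date(2021, 10, 28)}
DEFAULT_DAY_WINDOWS = {"summer": (5.5, 19.5), "winter": (7.0, 16.75)}


class ConfigError(ValueError):
    """Invalid simulation scenario."""


def default_truth(form: str = "season+pca", parameterization: str = "full",
                  seed: int = 0) -> MSDOMParams:
    """Ground-truth parameters with effect sizes at realistic magnitudes.

    Coefficients are drawn with |beta| in [0.3, 1.5] (the magnitude range of
    effects this model family typically recovers from ~240-site designs) with
    random signs; intercepts are kept moderate so all four states occur.
    """
    rng = np.random.default_rng(seed)
    columns = {
        "null": ["intercept"],
        "season": ["intercept", "winter"],
        "pca": ["intercept", "pca"],
        "season+pca": ["intercept", "winter", "pca"],
        "season*pca": ["intercept", "winter", "pca", "winter:pca"],
    }[form]
    states = ("day", "night", "daynight") if parameterization == "full" else ("day", "night")

    def draw(k):
        mag = rng.uniform(0.3, 1.5, k)
        sign = rng.choice([-1.0, 1.0], k)
        out = mag * sign
        out[0] = rng.uniform(-1.0, 0.0)  # intercept: keep states reasonably common
        return out

    occ = {s: draw(len(columns)) for s in states}
    det_day = np.array([0.5, -0.5])
    det_night = np.array([0.3, 0.5])
    det_state4 = None
    if parameterization == "full":
        det_state4 = np.array([[0.2, -0.4], [0.0, 0.4], [-0.3, 0.3]])
    return MSDOMParams(parameterization, occ, {s: columns for s in states},
                       det_day, det_night, det_state4)


@dataclass
class ScenarioConfig:
    """Study-design scenario for the generator."""

    n_sites: int = 240
    n_occasions: int = 42
    seasons: tuple = SEASONS
    truth: MSDOMParams = field(default_factory=default_truth)
    missingness_rate: float = 0.05
    pca_sd: float = 1.0
    day_windows: dict = field(default_factory=lambda: dict(DEFAULT_DAY_WINDOWS))
    season_starts: dict = field(default_factory=lambda: dict(DEFAULT_SEASON_STARTS))
    species: str = "simulated_species"
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1 or self.n_occasions < 1:
            raise ConfigError("n_sites and n_occasions must be positive")
        if not self.seasons:
            raise ConfigError("at least one season is required")
        if not 0 <= self.missingness_rate <= 1:
            raise ConfigError("missingness_rate must be in [0, 1]")
        for season in self.seasons:
            rise, set_ = self.day_windows[season]
            if not rise < set_:
                raise ConfigError(f"{season}: sunrise must precede sunset")
            if set_ - rise <= 0 or (24 - (set_ - rise)) <= 0:
                raise ConfigError(f"{season}: day and night windows must have width")
        for arrs in (self.truth.det_day, self.truth.det_night):
            if not np.all(np.isfinite(arrs)):
                raise ConfigError("truth detection parameters must be finite")


def _design_for(cfg: ScenarioConfig, rng: np.random.Generator) -> SiteDesign:
    sites = [f"site_{i:03d}" for i in range(cfg.n_sites)]
    index = pd.MultiIndex.from_product([sites, list(cfg.seasons)],
                                       names=["site_id", "season"])
    pca = pd.Series(rng.normal(0.0, cfg.pca_sd, cfg.n_sites), index=pd.Index(sites, name="site_id"))
    needed = {c for cols in cfg.truth.occ_columns.values() for c in cols}
    form = "season*pca" if "winter:pca" in needed else (
        "season+pca" if {"winter", "pca"} <= needed else
        "pca" if "pca" in needed else
        "season" if "winter" in needed else "null")
    return assemble_design(index, pca=pca, form=form)


def simulate_state_history(cfg: ScenarioConfig, rng: np.random.Generator | None = None):
    """Draw latent states and observed occasion states under the truth.

    Returns (history DataFrame, latent state Series (1..4), SiteDesign).
    Latent state is fixed per site-season row (closure within a season);
    a site's summer and winter rows are independent stacked rows.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    design = _design_for(cfg, rng)
    X = {s: design.matrix(s) for s in cfg.truth.states}
    psi = cfg.truth.occupancy_probs(X)
    if not (np.all(psi >= -1e-12) & np.all(psi <= 1 + 1e-12)):
        raise ConfigError("truth implies state probabilities outside [0, 1]")
    n = len(design.frame)
    u = rng.random(n)
    latent = 1 + (u[:, None] > np.cumsum(psi, axis=1)[:, :3]).sum(axis=1)

    thetas = {w: cfg.truth.observation_matrix(w) for w in (0.0, 1.0)}
    H = np.empty((n, cfg.n_occasions), dtype=float)
    winter = design.winter
    for w, theta in thetas.items():
        rows = np.flatnonzero(winter == w)
        if rows.size == 0:
            continue
        cum = np.cumsum(theta, axis=1)
        uu = rng.random((rows.size, cfg.n_occasions))
        H[rows] = 1 + (uu[..., None] > cum[latent[rows] - 1][:, None, :3]).sum(axis=2)
    miss = rng.random(H.shape) < cfg.missingness_rate
    H[miss] = np.nan

    history = pd.DataFrame(H, index=design.frame.index,
                           columns=[f"occ_{j + 1}" for j in range(cfg.n_occasions)])
    latent = pd.Series(latent, index=design.frame.index, name="latent_state")
    return history, latent, design


def _window_times(rise: float, set_: float, diel: str, k: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Pick k event hours >= 0.5 h apart inside the requested diel window.

    Windows are shrunk 15 min from every boundary so classification is
    unambiguous; night events stay within the same calendar day (after
    sunset or before sunrise of that date).
    """
    pad = 0.25
    if diel == "day":
        windows = [(rise + pad, set_ - pad)]
    else:
        windows = [(pad, rise - pad), (set_ + pad, 24.0 - pad)]
    slots = []
    for lo, hi in windows:
        slots.extend(np.arange(lo, hi, 0.5).tolist())
    chosen = rng.choice(len(slots), size=min(k, len(slots)), replace=False)
    return np.sort(np.asarray(slots)[chosen])


def simulate_timestamped_records(cfg: ScenarioConfig, rng: np.random.Generator | None = None):
    """Emit raw detection records consistent with a simulated history.

    Returns (records DataFrame, history, latent, design).  Event times are
    spaced >= 30 min apart so the >20-min independence filter keeps all of
    them, making the round trip through the processing chain exact.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    history, latent, design = simulate_state_history(cfg, rng=rng)
    rows = []
    H = history.to_numpy()
    idx = history.index
    for i in range(H.shape[0]):
        site, season = idx[i]
        rise, set_ = cfg.day_windows[season]
        start = cfg.season_starts[season]
        for j in range(H.shape[1]):
            state = H[i, j]
            if np.isnan(state) or state == 1:
                continue
            day = start + timedelta(days=j)
            need = {2: [("day", 1 + rng.poisson(0.7))],
                    3: [("night", 1 + rng.poisson(0.7))],
                    4: [("day", 1 + rng.poisson(0.4)), ("night", 1 + rng.poisson(0.4))]}[int(state)]
            for diel, k in need:
                for h in _window_times(rise, set_, diel, k, rng):
                    minutes = int(round(h * 60))
                    ts = datetime(day.year, day.month, day.day) + timedelta(minutes=minutes)
                    rows.append((site, cfg.species, ts, 1))
    records = pd.DataFrame(rows, columns=["site_id", "species", "timestamp", "n_individuals"])
    records = records.sort_values(["site_id", "timestamp"], kind="stable").reset_index(drop=True)
    return records, history, latent, design


def sun_table_for(cfg: ScenarioConfig) -> pd.DataFrame:
    """Constant per-season sun table covering every simulated date."""
    rows = []
    for season in cfg.seasons:
        rise, set_ = cfg.day_windows[season]
        start = cfg.season_starts[season]
        for j in range(cfg.n_occasions + 1):
            d = start + timedelta(days=j)
            rows.append((d, rise, set_))
    return pd.DataFrame(rows, columns=["date", "sunrise_hour", "sunset_hour"])


def deployment_from_history(history: pd.DataFrame, cfg: ScenarioConfig) -> pd.DataFrame:
    """Camera active-date ranges implied by a simulated history.

    Missing occasions in the simulated history represent camera downtime, so
    each contiguous run of non-missing occasions becomes one deployment
    interval (site_id, start_date, end_date, inclusive dates).  Feeding this
    table to the processing chain reproduces the missingness pattern exactly.
    """
    rows = []
    H = history.to_numpy()
    for i, (site, season) in enumerate(history.index):
        start = cfg.season_starts[season]
        active = ~np.isnan(H[i])
        j = 0
        while j < len(active):
            if active[j]:
                k = j
                while k + 1 < len(active) and active[k + 1]:
                    k += 1
                rows.append((site, start + timedelta(days=j), start + timedelta(days=k)))
                j = k + 1
            else:
                j += 1
    return pd.DataFrame(rows, columns=["site_id", "start_date", "end_date"])


# -- disk round-trip --------------------------------------------------------

def write_records_csv(records: pd.DataFrame, path):
    out = records.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_records_csv(path) -> pd.DataFrame:
    rec = pd.read_csv(path)
    rec["timestamp"] = pd.to_datetime(rec["timestamp"])
    return rec


def write_history_csv(history: pd.DataFrame, path):
    history.to_csv(path)


def read_history_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=[0, 1])


def write_truth(truth: MSDOMParams, path):
    Path(path).write_text(yaml.safe_dump(truth.to_dict(), sort_keys=False))


def read_truth(path) -> MSDOMParams:
    return MSDOMParams.from_dict(yaml.safe_load(Path(path).read_text()))
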