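"""Site covariates: development-forest PCA score, prey index, design assembly.

Four landscape variables summarized in a 1-km buffer around each camera site
(forest cover, residential cover, road density, housing-unit density) are
strongly pairwise correlated, so they are collapsed to the first principal
component of their standardized values.  The score is oriented so that
positive values mean more forest and negative values more anthropogenic
development.

Detection histories for the two survey seasons are stacked, so the design has
one row per site-season with a winter indicator (summer is the reference
category).  For mesocarnivore models a prey-availability index (independent
prey detections per trap-night, split by diel period) can enter the occupancy
predictor matched to the diel state: the day-use state uses the day index,
the night-use state the night index, and the day-and-night state their mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

LANDSCAPE_VARS = ["forest_cover", "residential", "road_density", "housing"]

MODEL_FORMS = ("null", "season", "pca", "season+pca", "season*pca", "prey", "prey+season")

#: prey species pooled into the availability index
PREY_SPECIES = frozenset({
    "flying_squirrel", "gray_squirrel", "eastern_cottontail",
    "eastern_chipmunk", "red_squirrel", "small_rodent",
})


def correlation_screen(tab: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Pearson correlation matrix of the landscape variables and max |r|.

    Zero-variance columns yield undefined correlations (NaN) and a warning.
    """
    if len(tab) < 3:
        raise ValueError("correlation screen needs at least 3 sites")
    if tab.isna().any().any():
        raise ValueError("landscape table contains missing values")
    zero_var = tab.columns[tab.std(ddof=1) == 0]
    if len(zero_var):
        warnings.warn(f"zero-variance column(s) {list(zero_var)}: correlation undefined")
    corr = tab.corr()
    off = corr.values[~np.eye(len(corr), dtype=bool)]
    max_abs = float(np.nanmax(np.abs(off))) if np.isfinite(off).any() else float("nan")
    return corr, max_abs


def compute_pca_score(tab: pd.DataFrame, forest_col: str = "forest_cover"):
    """First-principal-component score per site and its variance-explained.

    Variables are centered and scaled to unit variance before the PCA.  The
    sign of PC1 is chosen so the forest-cover loading is positive (positive
    score = more forest, negative = more development).
    """
    if len(tab) < 4:
        raise ValueError("PCA needs at least 4 sites")
    if (tab.std(ddof=0) == 0).any():
        raise ValueError("constant column: cannot scale to unit variance")
    Z = StandardScaler().fit_transform(tab.values)
    pca = PCA(n_components=tab.shape[1]).fit(Z)
    scores = pca.transform(Z)[:, 0]
    loadings = pca.components_[0]
    if loadings[list(tab.columns).index(forest_col)] < 0:
        scores = -scores
        loadings = -loadings
    var_explained = float(pca.explained_variance_ratio_[0])
    return pd.Series(scores, index=tab.index, name="pca"), var_explained


def compute_prey_index(
    records: pd.DataFrame,
    effort: pd.DataFrame,
    prey_species=PREY_SPECIES,
) -> pd.DataFrame:
    """Prey detections per trap-night, by site, season and diel period.

    ``records`` must be independence-filtered and carry ``site_id``,
    ``species``, ``season`` and ``diel`` ("day"/"night") columns.  ``effort``
    has columns site_id, season, trap_nights.  Sites with zero trap-nights get
    a missing index and a warning.
    """
    if not prey_species:
        raise ValueError("prey species set is empty")
    prey = records[records["species"].isin(prey_species)]
    counts = (
        prey.groupby(["site_id", "season", "diel"], observed=True).size().unstack("diel")
        .reindex(columns=["day", "night"], fill_value=0)
    )
    out = effort.set_index(["site_id", "season"]).copy()
    counts = counts.reindex(out.index, fill_value=0).fillna(0)
    zero = out["trap_nights"] <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} site-season(s) with zero trap-nights: prey index missing")
    with np.errstate(divide="ignore", invalid="ignore"):
        out["prey_day"] = np.where(zero, np.nan, counts["day"] / out["trap_nights"])
        out["prey_night"] = np.where(zero, np.nan, counts["night"] / out["trap_nights"])
    return out[["prey_day", "prey_night"]].reset_index()


@dataclass
class SiteDesign:
    """Occupancy design for stacked site-season rows.

    ``frame`` holds all covariate columns (always including ``intercept`` and
    the ``winter`` indicator, even for the null occupancy form, because
    detection probability always varies by season).  ``state_columns`` maps
    each diel-use state to the subset of columns in its linear predictor,
    which differ between states only for prey forms.
    """

    frame: pd.DataFrame
    state_columns: dict = field(default_factory=dict)
    form: str = "null"

    @property
    def winter(self) -> np.ndarray:
        return self.frame["winter"].to_numpy(dtype=float)

    def matrix(self, state: str) -> np.ndarray:
        return self.frame[self.state_columns[state]].to_numpy(dtype=float)


def assemble_design(
    index: pd.MultiIndex,
    pca: pd.Series | None = None,
    prey: pd.DataFrame | None = None,
    form: str = "null",
    winter_label: str = "winter",
) -> SiteDesign:
    """Build the occupancy design for a (site_id, season) row index.

    ``pca`` is indexed by site_id; ``prey`` is the output of
    :func:`compute_prey_index`.  Prey columns are standardized to mean 0,
    sd 1 across rows (jointly over day and night values, so their contrast is
    preserved); the PCA score is already unit-scale by construction.
    """
    if form not in MODEL_FORMS:
        raise ValueError(f"unknown model form {form!r}; expected one of {MODEL_FORMS}")
    df = pd.DataFrame(index=index)
    df["intercept"] = 1.0
    seasons = index.get_level_values("season")
    df["winter"] = (seasons == winter_label).astype(float)

    cols = ["intercept"]
    if form in ("season", "season+pca", "season*pca", "prey+season"):
        cols.append("winter")
    if form in ("pca", "season+pca", "season*pca"):
        sites = index.get_level_values("site_id")
        df["pca"] = pca.reindex(sites).to_numpy()
        cols.append("pca")
    if form == "season*pca":
        df["winter:pca"] = df["winter"] * df["pca"]
        cols.append("winter:pca")

    state_cols = {s: list(cols) for s in ("day", "night", "daynight")}
    if form in ("prey", "prey+season"):
        p = prey.set_index(["site_id", "season"]).reindex(index)
        vals = np.concatenate([p["prey_day"].to_numpy(), p["prey_night"].to_numpy()])
        mu, sd = np.nanmean(vals), np.nanstd(vals)
        if sd == 0:
            raise ValueError("prey index is constant: cannot standardize")
        df["prey_day"] = (p["prey_day"].to_numpy() - mu) / sd
        df["prey_night"] = (p["prey_night"].to_numpy() - mu) / sd
        df["prey_mean"] = (df["prey_day"] + df["prey_night"]) / 2
        state_cols = {
            "day": cols + ["prey_day"],
            "night": cols + ["prey_night"],
            "daynight": cols + ["prey_mean"],
        }
    keep = sorted({c for v in state_cols.values() for c in v} | {"intercept", "winter"},
                  key=list(df.columns).index)
    return SiteDesign(frame=df[keep], state_columns=state_cols, form=form)
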