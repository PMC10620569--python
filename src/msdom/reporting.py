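"""Tables and figures: detection-count summaries and occupancy predictions.

Also bundles the published independent-detection counts from the Rhode
Island camera-trap mammal survey (2021-2022) that this package's study
design emulates: per-species day/night counts for the summer and winter
seasons, with season effort of 20,219 (summer) and 23,277 (winter) trap
nights.
"""

from __future__ import annotations

from importlib import resources

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

TRAP_NIGHTS = {"summer": 20219, "winter": 23277}


def load_study_detection_counts() -> pd.DataFrame:
    """Per-species independent detection counts from the RI survey."""
    with resources.files("msdom.data").joinpath("ri_survey_detections.csv").open() as fh:
        return pd.read_csv(fh)


def season_detection_totals(counts: pd.DataFrame | None = None) -> dict:
    """Total independent detections per season (day + night over species)."""
    counts = load_study_detection_counts() if counts is None else counts
    return {
        "summer": int(counts["summer_day"].sum() + counts["summer_night"].sum()),
        "winter": int(counts["winter_day"].sum() + counts["winter_night"].sum()),
    }


def detection_table_summary(records: pd.DataFrame,
                            trap_nights: dict | None = None) -> pd.DataFrame:
    """Species x season day/night counts from classified independent records.

    ``records`` must carry ``species``, ``season`` and ``diel`` columns
    (independence-filtered).  Returns a wide table with one row per species
    plus a ``total`` row; ``trap_nights`` (season -> effort) adds an effort
    row when given.
    """
    cols = ["summer_day", "summer_night", "winter_day", "winter_night"]
    if records.empty:
        tab = pd.DataFrame(columns=cols)
    else:
        counts = (records.groupby(["species", "season", "diel"], observed=True)
                  .size().unstack(["season", "diel"], fill_value=0))
        counts.columns = [f"{s}_{d}" for s, d in counts.columns]
        tab = counts.reindex(columns=cols, fill_value=0)
    tab.loc["total"] = tab.sum()
    if trap_nights:
        tab.loc["trap_nights"] = [trap_nights.get("summer", np.nan)] * 2 + \
                                 [trap_nights.get("winter", np.nan)] * 2
    return tab


def write_prediction_csv(grids: list[pd.DataFrame], path, species: str = "") -> pd.DataFrame:
    out = pd.concat(grids, ignore_index=True)
    if species:
        out.insert(0, "species", species)
    out.to_csv(path, index=False)
    return out


def plot_predictions(grids: list[pd.DataFrame], species: str = "", path=None):
    """One panel per diel state, prediction curves with 95% envelopes."""
    states = ["day", "night", "daynight", "marginal"]
    fig, axes = plt.subplots(1, len(states), figsize=(4 * len(states), 3.2), sharey=True)
    colors = {"summer": "tab:orange", "winter": "tab:blue"}
    allg = pd.concat(grids, ignore_index=True)
    for ax, state in zip(axes, states):
        for season, g in allg[allg["state"] == state].groupby("season"):
            ax.plot(g["pca"], g["median"], color=colors.get(season, "k"), label=season)
            ax.fill_between(g["pca"], g["lo95"], g["hi95"],
                            color=colors.get(season, "k"), alpha=0.25)
        ax.set_title(state)
        ax.set_xlabel("development-forest score (PC1)")
        ax.set_ylim(0, 1)
    axes[0].set_ylabel("occupancy probability")
    axes[0].legend(frameon=False)
    fig.suptitle(species)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
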