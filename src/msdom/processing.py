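"""Raw camera-trap detections -> 4-state detection histories.

The chain:

1. merge the two co-located cameras of each survey site into one site;
2. keep independent detections only: a record counts as independent when it
   shows more than one individual, is the first for its site and species, or
   falls strictly more than 20 minutes after the immediately preceding raw
   record of that site and species;
3. classify each independent detection as day (strictly after sunrise and
   strictly before sunset; boundary timestamps count as night) or night;
4. anchor the 24-h occasion grid at the clock hour with the fewest
   detections for the species-season (smallest hour on ties);
5. code each site-occasion as state 1 (no detection), 2 (day only),
   3 (night only) or 4 (both), with missing where no camera operated at any
   point of the occasion.
"""

from __future__ import annotations

import logging
from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["site_id", "species", "timestamp", "n_individuals"]


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records are missing columns {missing}")
    rec = records.copy()
    rec["timestamp"] = pd.to_datetime(rec["timestamp"])
    if (rec["n_individuals"] < 1).any():
        raise ValueError("n_individuals must be >= 1")
    return rec


def merge_paired_cameras(records: pd.DataFrame, camera_to_site: dict) -> pd.DataFrame:
    """Relabel per-camera records to the site level (two cameras = one site)."""
    rec = _check_records(records)
    unmapped = set(rec["site_id"]) - set(camera_to_site)
    if unmapped:
        raise ValueError(f"cameras with no site mapping: {sorted(unmapped)}")
    rec["site_id"] = rec["site_id"].map(camera_to_site)
    return rec.sort_values(["site_id", "species", "timestamp"], kind="stable").reset_index(drop=True)


def filter_independent(records: pd.DataFrame, gap_minutes: float = 20.0) -> pd.DataFrame:
    """Keep independent detections per site and species.

    The gap is measured from the immediately preceding *raw* detection of
    that site x species (chained gaps), with a strict > comparison; records
    with more than one individual in frame are always kept.  The operation is
    idempotent: kept records only gain larger gaps when their predecessors
    are removed.
    """
    if gap_minutes < 0:
        raise ValueError("gap_minutes must be non-negative")
    rec = _check_records(records).sort_values(
        ["site_id", "species", "timestamp"], kind="stable").reset_index(drop=True)
    if rec.empty:
        return rec
    prev = rec.groupby(["site_id", "species"], observed=True)["timestamp"].shift()
    gap = (rec["timestamp"] - prev).dt.total_seconds() / 60.0
    keep = (rec["n_individuals"] > 1) | prev.isna() | (gap > gap_minutes)
    return rec[keep].reset_index(drop=True)


def _sun_lookup(sun: pd.DataFrame) -> dict:
    tab = sun.copy()
    tab["date"] = pd.to_datetime(tab["date"]).dt.date
    bad = tab["sunrise_hour"] >= tab["sunset_hour"]
    if bad.any():
        raise ValueError("sun table has sunrise >= sunset")
    return {r.date: (r.sunrise_hour, r.sunset_hour) for r in tab.itertuples()}


def classify_diel(records: pd.DataFrame, sun: pd.DataFrame) -> pd.Series:
    """"day" or "night" per record.

    Day is the open interval (sunrise, sunset); a timestamp exactly at
    sunrise or sunset is classified night.
    """
    rec = _check_records(records)
    lut = _sun_lookup(sun)
    out = []
    for ts in rec["timestamp"]:
        d = ts.date()
        if d not in lut:
            raise ValueError(f"sun table does not cover date {d}")
        rise, set_ = lut[d]
        hour = ts.hour + ts.minute / 60 + ts.second / 3600
        out.append("day" if rise < hour < set_ else "night")
    return pd.Series(out, index=rec.index, name="diel")


def choose_occasion_start(records: pd.DataFrame) -> int:
    """Clock hour (0-23) with the fewest independent detections.

    Ties break to the smallest hour; with no detections at all the start
    defaults to hour 0 with a warning.
    """
    if records.empty:
        logger.warning("no detections: occasion start defaults to hour 0")
        return 0
    rec = _check_records(records)
    counts = rec["timestamp"].dt.hour.value_counts().reindex(range(24), fill_value=0)
    return int(counts.idxmin())  # idxmin takes the first (smallest) hour on ties


def build_state_history(
    records: pd.DataFrame,
    sun: pd.DataFrame,
    start_hour: int,
    season_windows: dict,
    deployment: pd.DataFrame,
    season_of: dict | None = None,
) -> pd.DataFrame:
    """Code one species' independent detections into a 4-state history.

    Parameters
    ----------
    records : independence-filtered detections of one species.
    sun : per-date sunrise/sunset table (decimal hours).
    start_hour : occasion anchor hour from :func:`choose_occasion_start`.
    season_windows : season -> (first_date, last_date) inclusive; occasions
        tile each window in 24-h blocks from ``first_date`` at ``start_hour``.
    deployment : DataFrame (site_id, start_date, end_date) of camera active
        ranges; an occasion is missing when no range overlaps any part of it
        (partial overlap counts as observed).

    Returns a DataFrame indexed by (site_id, season) with occasion columns,
    entries in {1, 2, 3, 4} or NaN.  Records outside every season window are
    ignored with a logged count.
    """
    rec = _check_records(records)
    rec["diel"] = classify_diel(rec, sun)
    dep = deployment.copy()
    dep["start"] = pd.to_datetime(dep["start_date"])
    dep["end"] = pd.to_datetime(dep["end_date"]) + pd.Timedelta(days=1)  # inclusive end date
    sites = sorted(dep["site_id"].unique())

    n_seasons_J = {}
    frames = []
    for season, (d0, d1) in season_windows.items():
        t0 = pd.Timestamp(datetime.combine(pd.Timestamp(d0).date(), time(start_hour)))
        t_end = pd.Timestamp(datetime.combine(pd.Timestamp(d1).date(), time(0))) + pd.Timedelta(days=1)
        J = int(np.ceil((t_end - t0) / pd.Timedelta(days=1)))
        n_seasons_J[season] = (t0, J)
        day_flag = np.zeros((len(sites), J), dtype=bool)
        night_flag = np.zeros((len(sites), J), dtype=bool)
        site_pos = {s: i for i, s in enumerate(sites)}
        in_season = (rec["timestamp"] >= t0) & (rec["timestamp"] < t0 + pd.Timedelta(days=J))
        for r in rec[in_season].itertuples():
            if r.site_id not in site_pos:
                continue
            j = int((r.timestamp - t0) / pd.Timedelta(days=1))
            if r.diel == "day":
                day_flag[site_pos[r.site_id], j] = True
            else:
                night_flag[site_pos[r.site_id], j] = True
        H = np.ones((len(sites), J), dtype=float)
        H[day_flag & ~night_flag] = 2
        H[~day_flag & night_flag] = 3
        H[day_flag & night_flag] = 4
        # occasions with no camera active at any moment -> missing
        for s, i in site_pos.items():
            ranges = dep[dep["site_id"] == s]
            occ_starts = t0 + pd.to_timedelta(np.arange(J), unit="D")
            occ_ends = occ_starts + pd.Timedelta(days=1)
            active = np.zeros(J, dtype=bool)
            for rr in ranges.itertuples():
                active |= (occ_starts < rr.end) & (occ_ends > rr.start)
            H[i, ~active] = np.nan
        frames.append(pd.DataFrame(
            H, index=pd.MultiIndex.from_product([sites, [season]], names=["site_id", "season"]),
            columns=[f"occ_{j + 1}" for j in range(J)]))

    total_window = sum(
        ((rec["timestamp"] >= t0) & (rec["timestamp"] < t0 + pd.Timedelta(days=J))).sum()
        for t0, J in n_seasons_J.values())
    outside = len(rec) - int(total_window)
    if outside:
        logger.info("%d record(s) fell outside every season window and were ignored", outside)

    J_max = max(f.shape[1] for f in frames)
    frames = [f.reindex(columns=[f"occ_{j + 1}" for j in range(J_max)]) for f in frames]
    out = pd.concat(frames)
    return out.sort_index(level=["site_id", "season"], sort_remaining=False)


def process_species(
    records: pd.DataFrame,
    sun: pd.DataFrame,
    season_windows: dict,
    deployment: pd.DataFrame,
    species: str,
    gap_minutes: float = 20.0,
    start_hour: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full chain for one species; returns (history, log dict of counts)."""
    rec = records[records["species"] == species]
    info = {"raw": len(rec)}
    ind = filter_independent(rec, gap_minutes)
    info["independent"] = len(ind)
    if start_hour is None:
        start_hour = choose_occasion_start(ind)
    info["start_hour"] = start_hour
    history = build_state_history(ind, sun, start_hour, season_windows, deployment)
    info["rows"] = len(history)
    logger.info("species %s: %s", species, info)
    return history, info
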