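"""Pressure-session detection and exposure summaries.

A *pressure session* is a bout of at least five scan samples with human
activity (boats and/or swimmers within ~300 m), never interrupted by more
than 10 min without activity.  *Exposure* of a focal group in a diel time
category is the proportion of its scans in that category that carry human
activity.  The daily *cumulative duration* of human activity is the number
of pressure scans times the scan interval.

The interruption rule is made exact on the scan grid: two successive
pressure scans belong to the same session when the pressure-free time
between them — elapsed time minus one scan interval — is at most the
maximum gap (so at a 150 s interval, up to four missing scans merge).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import TIME_CATEGORIES, FocalFollow
from .errors import AggregationError, UndefinedExposureError


@dataclass(frozen=True)
class PressureSession:
    site: str
    date: dt.date
    follow_id: str
    start_s: float
    end_s: float
    n_pressure_scans: int
    duration_min: float
    median_boats: float
    median_swimmers: float
    time_category: str  # diel category of the scan nearest the session midpoint


@dataclass(frozen=True)
class ExposureSummary:
    follow_id: str
    site: str
    season: str
    time_category: str
    n_samples: int
    n_pressure_samples: int

    @property
    def exposure(self) -> float:
        return self.n_pressure_samples / self.n_samples


def detect_sessions(
    follow: FocalFollow,
    min_samples: int = 5,
    max_gap_min: float = 10.0,
    purpose: str | None = None,
) -> list[PressureSession]:
    """Maximal pressure sessions of a follow, time-ordered and disjoint.

    Runs of pressure-present scans are merged across pressure-free gaps of
    at most ``max_gap_min`` minutes (measured net of one scan interval, see
    module docstring); merged runs with fewer than ``min_samples`` pressure
    scans are discarded.  Session duration is first to last pressure scan;
    boat/swimmer medians are over the pressure scans only.  Research and
    tourism activity are pooled unless ``purpose`` restricts to one.
    """
    scans = follow.scans
    mask = scans["pressure"].to_numpy(dtype=bool)
    if purpose is not None:
        mask &= scans["purpose"].str.contains(purpose, regex=False).to_numpy()
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    t = scans["t_s"].to_numpy(dtype=float)
    max_gap_s = max_gap_min * 60.0

    groups: list[list[int]] = [[int(idx[0])]]
    for i in idx[1:]:
        gap = t[i] - t[groups[-1][-1]] - follow.nominal_interval
        if gap <= max_gap_s + 1e-9:
            groups[-1].append(int(i))
        else:
            groups.append([int(i)])

    sessions = []
    for g in groups:
        if len(g) < min_samples:
            continue
        sub = scans.iloc[g]
        mid = (t[g[0]] + t[g[-1]]) / 2.0
        mid_scan = g[int(np.argmin(np.abs(t[g] - mid)))]
        sessions.append(
            PressureSession(
                site=follow.site,
                date=follow.date,
                follow_id=follow.follow_id,
                start_s=float(t[g[0]]),
                end_s=float(t[g[-1]]),
                n_pressure_scans=len(g),
                duration_min=(t[g[-1]] - t[g[0]]) / 60.0,
                median_boats=float(sub["n_boats"].median()),
                median_swimmers=float(sub["n_swimmers"].median()),
                time_category=str(scans["time_category"].iloc[mid_scan]),
            )
        )
    return sessions


def exposure(follow: FocalFollow, time_cat: str) -> ExposureSummary:
    """Exposure of one focal group in one time category.

    Raises :class:`UndefinedExposureError` when the follow has no scans in
    the category — an undefined exposure is distinct from an exposure of 0.
    """
    sub = follow.scans[follow.scans["time_category"] == time_cat]
    if len(sub) == 0:
        raise UndefinedExposureError(
            f"follow {follow.follow_id}: no samples in {time_cat!r}"
        )
    return ExposureSummary(
        follow_id=follow.follow_id,
        site=follow.site,
        season=follow.season,
        time_category=time_cat,
        n_samples=len(sub),
        n_pressure_samples=int(sub["pressure"].sum()),
    )


def exposure_table(follows: list[FocalFollow]) -> pd.DataFrame:
    """Tidy per-(follow, time category) exposure rows, skipping empty cells."""
    rows = []
    for f in follows:
        for tc in TIME_CATEGORIES:
            try:
                e = exposure(f, tc)
            except UndefinedExposureError:
                continue
            rows.append(
                {
                    "follow_id": e.follow_id,
                    "site": e.site,
                    "season": e.season,
                    "time_category": e.time_category,
                    "n_samples": e.n_samples,
                    "n_pressure_samples": e.n_pressure_samples,
                    "exposure": e.exposure,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "follow_id",
            "site",
            "season",
            "time_category",
            "n_samples",
            "n_pressure_samples",
            "exposure",
        ],
    )


def daily_cumulative(
    follows: list[FocalFollow], scan_interval: float | None = None
) -> float:
    """Estimated daily cumulative duration of human activity, in hours.

    All follows must come from one site-date; the estimate is (number of
    pressure scans) x (scan interval).  Invariant to how the day's scans
    are partitioned into follows.
    """
    if not follows:
        return 0.0
    keys = {(f.site, f.date) for f in follows}
    if len(keys) > 1:
        raise AggregationError(f"follows span multiple site-dates: {sorted(keys)}")
    interval = scan_interval if scan_interval is not None else follows[0].nominal_interval
    n = sum(f.n_pressure_scans for f in follows)
    return n * interval / 3600.0


def sessions_table(sessions: list[PressureSession]) -> pd.DataFrame:
    rows = [
        {
            "site": s.site,
            "date": s.date.isoformat(),
            "follow_id": s.follow_id,
            "start_s": s.start_s,
            "end_s": s.end_s,
            "n_pressure_scans": s.n_pressure_scans,
            "duration_min": s.duration_min,
            "median_boats": s.median_boats,
            "median_swimmers": s.median_swimmers,
            "time_category": s.time_category,
        }
        for s in sessions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "site",
            "date",
            "follow_id",
            "start_s",
            "end_s",
            "n_pressure_scans",
            "duration_min",
            "median_boats",
            "median_swimmers",
            "time_category",
        ],
    )


def _sd(x: pd.Series) -> float:
    """Sample s.d. (n-1); degenerate single-observation groups report 0."""
    if len(x) <= 1:
        return 0.0
    return float(x.std(ddof=1))


def summarize_site(
    sessions: list[PressureSession],
    exposures: pd.DataFrame,
) -> pd.DataFrame:
    """Site x time-category summary shaped like a field exposure table.

    Per group: number of follows, mean and s.d. of exposure; session
    duration mean/s.d./min/max; medians of boats and swimmers; earliest and
    latest session start.  Sessions carry the diel category of their
    midpoint scan.  Single-observation groups carry ``degenerate_sd=True``.
    """
    sess_df = sessions_table(sessions)
    rows = []
    groups = exposures.groupby(["site", "time_category"], sort=True)
    for (site, tc), grp in groups:
        s_grp = sess_df[(sess_df["site"] == site) & (sess_df["time_category"] == tc)]
        row = {
            "site": site,
            "time_category": tc,
            "n_follows": grp["follow_id"].nunique(),
            "exposure_mean": float(grp["exposure"].mean()),
            "exposure_sd": _sd(grp["exposure"]),
            "degenerate_sd": len(grp) <= 1,
            "n_sessions": len(s_grp),
            "duration_mean_min": float(s_grp["duration_min"].mean()) if len(s_grp) else np.nan,
            "duration_sd_min": _sd(s_grp["duration_min"]) if len(s_grp) else np.nan,
            "duration_min_min": float(s_grp["duration_min"].min()) if len(s_grp) else np.nan,
            "duration_max_min": float(s_grp["duration_min"].max()) if len(s_grp) else np.nan,
            "median_swimmers": float(s_grp["median_swimmers"].median()) if len(s_grp) else np.nan,
            "median_boats": float(s_grp["median_boats"].median()) if len(s_grp) else np.nan,
            "earliest_start_s": float(s_grp["start_s"].min()) if len(s_grp) else np.nan,
            "latest_start_s": float(s_grp["start_s"].max()) if len(s_grp) else np.nan,
        }
        rows.append(row)
    return pd.DataFrame(rows)
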