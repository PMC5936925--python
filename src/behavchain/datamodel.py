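"""Scan-record data model, CSV ingest and diel-time normalization.

The field protocol observes a focal dolphin group continuously and records
an *instantaneous scan* every 150 s: three binary behavioural indicators
(group cohesion tight/loose, school formation single/multiple, aerial
activity inactive/active, any of which may be blank when the group was not
visible), plus the number of boats and swimmers within ~300 m and the
purpose of that human activity.  Clock times are normalized to the fraction
of daylight elapsed (0 = sunrise, 1 = sunset) and binned into three equal
diel categories: morning, midday, afternoon.

In-memory containers: a :class:`FocalFollow` carries its scans as a pandas
DataFrame (one row per scan, columns as in the CSV dictionary below plus
the derived ``t_s``, ``rel_time``, ``time_category`` and ``pressure``).

CSV column dictionary (one row per scan)::

    follow_id, site, season, date (ISO 8601), time (HH:MM:SS),
    cohesion {tight,loose,''}, formation {single,multiple,''},
    aerial {inactive,active,''}, n_boats, n_swimmers,
    purpose (subset of {research,tourism}, '+'-joined, may be empty)

Sun-times CSV: ``site, date, sunrise (HH:MM:SS), sunset (HH:MM:SS)``.
Blank behavioural states are encoded as empty fields.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    OutOfRangeError,
    ResolutionError,
    StandardizationError,
    ValidationError,
)

MORNING, MIDDAY, AFTERNOON = "morning", "midday", "afternoon"
TIME_CATEGORIES = (MORNING, MIDDAY, AFTERNOON)

#: indicator name -> (state coded 0, state coded 1); the 0-state is the
#: rest-indicative one (tight cohesion, single school, no aerial activity).
INDICATORS: dict[str, tuple[str, str]] = {
    "cohesion": ("tight", "loose"),
    "formation": ("single", "multiple"),
    "aerial": ("inactive", "active"),
}

BLANK = ""

SCAN_COLUMNS = [
    "follow_id",
    "site",
    "season",
    "date",
    "time",
    "cohesion",
    "formation",
    "aerial",
    "n_boats",
    "n_swimmers",
    "purpose",
]


def _parse_time(value: str) -> dt.time:
    try:
        return dt.time.fromisoformat(str(value))
    except ValueError as exc:
        raise ValidationError(f"unparseable time {value!r}") from exc


def _time_to_seconds(t: dt.time) -> float:
    return t.hour * 3600.0 + t.minute * 60.0 + t.second + t.microsecond / 1e6


@dataclass(frozen=True)
class SunTimes:
    """Local sunrise and sunset for one site and date (naive local time)."""

    site: str
    date: dt.date
    sunrise: dt.time
    sunset: dt.time

    def __post_init__(self) -> None:
        if _time_to_seconds(self.sunset) <= _time_to_seconds(self.sunrise):
            raise ValidationError(
                f"sunset {self.sunset} not after sunrise {self.sunrise} "
                f"for {self.site} {self.date}"
            )

    @property
    def daylight_seconds(self) -> float:
        return _time_to_seconds(self.sunset) - _time_to_seconds(self.sunrise)


class SunTimesTable:
    """Lookup of :class:`SunTimes` keyed by (site, date)."""

    def __init__(self, entries: list[SunTimes]):
        self._by_key = {(e.site, e.date): e for e in entries}

    def lookup(self, site: str, date: dt.date) -> SunTimes:
        try:
            return self._by_key[(site, date)]
        except KeyError:
            raise ResolutionError(
                f"no sunrise/sunset entry for site {site!r} on {date}"
            ) from None

    def __iter__(self):
        return iter(self._by_key.values())

    def __len__(self) -> int:
        return len(self._by_key)

    @classmethod
    def from_csv(cls, path) -> "SunTimesTable":
        df = pd.read_csv(path, dtype=str)
        required = {"site", "date", "sunrise", "sunset"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"sun-times file missing columns {sorted(missing)}")
        entries = [
            SunTimes(
                site=row["site"],
                date=dt.date.fromisoformat(row["date"]),
                sunrise=_parse_time(row["sunrise"]),
                sunset=_parse_time(row["sunset"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(entries)

    def to_csv(self, path) -> None:
        rows = [
            {
                "site": e.site,
                "date": e.date.isoformat(),
                "sunrise": e.sunrise.isoformat(),
                "sunset": e.sunset.isoformat(),
            }
            for e in sorted(self, key=lambda e: (e.site, e.date))
        ]
        pd.DataFrame(rows, columns=["site", "date", "sunrise", "sunset"]).to_csv(
            path, index=False
        )


def relative_time(clock_time: dt.time, sun: SunTimes) -> float:
    """Fraction of daylight elapsed at ``clock_time``: 0 at sunrise, 1 at sunset."""
    t = _time_to_seconds(clock_time)
    t0 = _time_to_seconds(sun.sunrise)
    t1 = _time_to_seconds(sun.sunset)
    if not (t0 <= t <= t1):
        raise OutOfRangeError(
            f"clock time {clock_time} outside daylight "
            f"[{sun.sunrise}, {sun.sunset}] for {sun.site} {sun.date}"
        )
    return (t - t0) / (t1 - t0)


def time_category(rel_time: float) -> str:
    """Diel category of a daylight fraction.

    The day is split into three equal periods: morning [0, 1/3), midday
    [1/3, 2/3), afternoon [2/3, 1].  The commonly quoted 0.33/0.34
    boundaries are the two-decimal rendering of exact thirds.
    """
    if not (0.0 <= rel_time <= 1.0):
        raise OutOfRangeError(f"relative time {rel_time} outside [0, 1]")
    if rel_time < 1.0 / 3.0:
        return MORNING
    if rel_time < 2.0 / 3.0:
        return MIDDAY
    return AFTERNOON


@dataclass
class FocalFollow:
    """One focal-group follow: ordered scans from a single site and date.

    ``scans`` is a DataFrame with one row per scan carrying the CSV columns
    plus ``t_s`` (seconds since local midnight), ``rel_time``,
    ``time_category`` and the derived boolean ``pressure``
    (``n_boats + n_swimmers > 0`` — derived, never stored, so the two can
    never disagree).
    """

    follow_id: str
    site: str
    season: str
    date: dt.date
    scans: pd.DataFrame
    nominal_interval: float = 150.0
    interval_tolerance: float = 1.0
    gap_flags: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        t = self.scans["t_s"].to_numpy(dtype=float)
        if len(t) == 0:
            raise ValidationError(f"follow {self.follow_id}: no scans")
        if not np.all(np.diff(t) > 0):
            raise ValidationError(
                f"follow {self.follow_id}: scan times not strictly increasing"
            )
        dtv = np.diff(t)
        # a step is a "gap" when it is not one nominal interval (within tol)
        self.gap_flags = np.abs(dtv - self.nominal_interval) > self.interval_tolerance
        self.scans = self.scans.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.scans)

    @property
    def n_pressure_scans(self) -> int:
        return int(self.scans["pressure"].sum())


def _derive_columns(df: pd.DataFrame, sun: SunTimes) -> pd.DataFrame:
    df = df.copy()
    times = [_parse_time(v) for v in df["time"]]
    df["t_s"] = [_time_to_seconds(t) for t in times]
    df["rel_time"] = [relative_time(t, sun) for t in times]
    df["time_category"] = [time_category(r) for r in df["rel_time"]]
    df["n_boats"] = df["n_boats"].astype(int)
    df["n_swimmers"] = df["n_swimmers"].astype(int)
    if (df["n_boats"] < 0).any() or (df["n_swimmers"] < 0).any():
        raise ValidationError("negative boat or swimmer count")
    df["pressure"] = (df["n_boats"] + df["n_swimmers"]) > 0
    return df


def _validate_states(df: pd.DataFrame) -> list[tuple[int, str]]:
    problems = []
    for ind, states in INDICATORS.items():
        allowed = set(states) | {BLANK}
        bad = ~df[ind].isin(allowed)
        for idx in df.index[bad]:
            problems.append(
                (
                    int(idx),
                    f"unknown {ind} label {df.loc[idx, ind]!r} "
                    f"(allowed: {sorted(allowed - {BLANK})} or blank)",
                )
            )
    return problems


def read_scans(
    path,
    sun_times: SunTimesTable,
    nominal_interval: float = 150.0,
    strict: bool = True,
) -> tuple[list[FocalFollow], pd.DataFrame]:
    """Read a scan CSV into validated follows.

    Returns ``(follows, rejects)`` where ``rejects`` collects malformed rows
    with a ``reason`` column.  With ``strict=True`` an unknown behavioural
    state label raises :class:`ValidationError` naming the row instead of
    rejecting it silently; missing sun times always raise
    :class:`ResolutionError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(SCAN_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"scan file missing columns {sorted(missing)}")
    if df.empty:
        return [], df.assign(reason=pd.Series(dtype=str))

    problems = _validate_states(df)
    if problems and strict:
        raise ValidationError(
            "; ".join(f"row {idx}: {msg}" for idx, msg in problems)
        )
    reasons: dict[int, str] = {}
    for idx, msg in problems:
        reasons.setdefault(idx, msg)
    reject_idx = sorted(reasons)
    rejects = df.loc[reject_idx].copy()
    rejects["reason"] = [reasons[i] for i in reject_idx]
    df = df.drop(index=reject_idx)

    follows = []
    for follow_id, grp in df.groupby("follow_id", sort=True):
        sites = grp["site"].unique()
        dates = grp["date"].unique()
        if len(sites) > 1 or len(dates) > 1:
            raise ValidationError(
                f"follow {follow_id!r} spans multiple sites/dates"
            )
        date = dt.date.fromisoformat(dates[0])
        sun = sun_times.lookup(sites[0], date)
        grp = _derive_columns(grp, sun)
        grp = grp.sort_values("t_s")
        follows.append(
            FocalFollow(
                follow_id=str(follow_id),
                site=sites[0],
                season=grp["season"].iloc[0],
                date=date,
                scans=grp,
                nominal_interval=nominal_interval,
            )
        )
    return follows, rejects


def write_scans(follows: list[FocalFollow], path) -> None:
    """Write follows back to the documented scan CSV format."""
    frames = []
    for f in sorted(follows, key=lambda f: (f.site, f.date, f.follow_id)):
        frames.append(f.scans[SCAN_COLUMNS])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def standardize_interval(
    follow: FocalFollow, target_interval: float, tolerance: float = 1.0
) -> FocalFollow:
    """Map a follow sampled at another regular interval onto a target grid.

    If the source interval divides the target, every k-th scan is kept.
    Otherwise grid points are placed every ``target_interval`` from the
    first scan and matched to the nearest scan within half the target
    interval; unmatched grid points become gaps.  The original follow is
    never mutated.
    """
    t = follow.scans["t_s"].to_numpy(dtype=float)
    if len(t) < 2:
        return follow
    steps = np.diff(t)
    source = np.median(steps)
    if np.any(np.abs(steps - source) > tolerance):
        raise StandardizationError(
            f"follow {follow.follow_id}: irregular source spacing "
            f"(median {source:.1f} s, max deviation "
            f"{np.max(np.abs(steps - source)):.1f} s)"
        )
    ratio = target_interval / source
    if abs(ratio - round(ratio)) * source <= tolerance and round(ratio) >= 1:
        keep = np.arange(0, len(t), int(round(ratio)))
    else:
        grid = t[0] + target_interval * np.arange(
            0, int(np.floor((t[-1] - t[0]) / target_interval)) + 1
        )
        keep = []
        for g in grid:
            j = int(np.argmin(np.abs(t - g)))
            if abs(t[j] - g) <= target_interval / 2 and (
                not keep or j != keep[-1]
            ):
                keep.append(j)
        keep = np.asarray(keep, dtype=int)
    scans = follow.scans.iloc[keep].reset_index(drop=True)
    return FocalFollow(
        follow_id=follow.follow_id,
        site=follow.site,
        season=follow.season,
        date=follow.date,
        scans=scans,
        nominal_interval=target_interval,
        interval_tolerance=max(tolerance, follow.interval_tolerance),
    )
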