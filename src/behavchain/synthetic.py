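"""Synthetic focal-follow generator with known Markov ground truth.

The generator emulates the scan-sampling study design: for each site and
survey date a focal follow spans the daylight hours, scanned at a fixed
interval (150 s by default).  Each binary behavioural indicator evolves as
a first-order Markov chain whose 2x2 transition matrix depends on the diel
time category (morning/midday/afternoon) and on whether human pressure is
present.  Pressure is generated first as sessions — intervals with a start
time drawn as a fraction of daylight, a right-skewed (log-normal) duration
in minutes, and per-session boat and swimmer counts — and scans are then
labelled by membership, mirroring how pressure is recorded per scan in the
field.  Scans are blanked (all indicators unobserved) independently with a
configurable probability; the underlying behavioural chain keeps evolving
through blanks, as the animals do.

Because every transition matrix is configured, the exact stationary
distribution of any (indicator, time category, condition) cell is available
in closed form via :func:`true_stationary`, giving downstream estimators a
ground truth to recover.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    BLANK,
    INDICATORS,
    TIME_CATEGORIES,
    FocalFollow,
    SunTimes,
    SunTimesTable,
    time_category,
    write_scans,
)
from .errors import ConfigurationError, DegeneracyError

CONTROL, PRESSURE = "control", "pressure"
CONDITIONS = (CONTROL, PRESSURE)


@dataclass
class PressureProcess:
    """Per-site generative model of pressure sessions.

    Session start times are drawn as a fraction of daylight from a normal
    truncated to [0, 1]; durations are log-normal (parameterized by mean
    and s.d. in minutes, matching the right-skewed field distributions);
    boat and swimmer counts are Poisson draws held constant within a
    session (so session medians equal the drawn values).
    """

    sessions_per_day: float = 2.0
    start_frac_mean: float = 0.5
    start_frac_sd: float = 0.2
    duration_mean_min: float = 75.0
    duration_sd_min: float = 75.1
    boats_mean: float = 1.0
    swimmers_mean: float = 4.0
    purpose: str = "tourism"


@dataclass
class SiteSpec:
    """One study site: its survey dates, sun times and pressure regime."""

    name: str
    season: str
    dates: list[dt.date]
    sunrise: dt.time = dt.time(6, 0)
    sunset: dt.time = dt.time(18, 0)
    presence_prob: float = 0.9
    pressure: PressureProcess = field(default_factory=PressureProcess)


@dataclass
class SimulationConfig:
    sites: list[SiteSpec]
    transition_params: dict[tuple[str, str, str], np.ndarray]
    scan_interval: float = 150.0
    indicators: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(INDICATORS)
    )
    blank_prob: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.scan_interval <= 0:
            raise ConfigurationError("scan_interval must be > 0")
        if not (0.0 <= self.blank_prob < 1.0):
            raise ConfigurationError("blank_prob must be in [0, 1)")
        if not self.sites:
            raise ConfigurationError("sites must be non-empty")
        for ind in self.indicators:
            for tc in TIME_CATEGORIES:
                for cond in CONDITIONS:
                    key = (ind, tc, cond)
                    if key not in self.transition_params:
                        raise ConfigurationError(
                            f"transition_params missing entry for {key}"
                        )
                    m = np.asarray(self.transition_params[key], dtype=float)
                    if m.shape != (2, 2):
                        raise ConfigurationError(
                            f"transition_params[{key}] is not 2x2"
                        )
                    if np.any(m < 0) or np.any(m > 1):
                        raise ConfigurationError(
                            f"transition_params[{key}] has entries outside [0, 1]"
                        )
                    if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-12):
                        raise ConfigurationError(
                            f"transition_params[{key}] rows do not sum to 1"
                        )
        for s in self.sites:
            if not (0.0 <= s.presence_prob <= 1.0):
                raise ConfigurationError(
                    f"site {s.name}: presence_prob outside [0, 1]"
                )


def uniform_transition_params(
    control: dict[str, np.ndarray],
    pressure: dict[str, np.ndarray] | None = None,
    overrides: dict[tuple[str, str, str], np.ndarray] | None = None,
) -> dict[tuple[str, str, str], np.ndarray]:
    """Expand per-indicator matrices to all (time category, condition) cells.

    ``pressure`` defaults to ``control`` (a null, no-effect configuration);
    ``overrides`` patches individual (indicator, time_category, condition)
    cells, e.g. to localize a pressure effect to midday only.
    """
    pressure = pressure if pressure is not None else control
    params: dict[tuple[str, str, str], np.ndarray] = {}
    for ind, m in control.items():
        for tc in TIME_CATEGORIES:
            params[(ind, tc, CONTROL)] = np.asarray(m, dtype=float)
            params[(ind, tc, PRESSURE)] = np.asarray(pressure[ind], dtype=float)
    if overrides:
        for key, m in overrides.items():
            params[key] = np.asarray(m, dtype=float)
    return params


#: Default study conditions: three sites patterned on a Red Sea resting
#: lagoon design — one research-only control site surveyed a handful of
#: days and two tourism sites with multi-week seasons.  Control dynamics
#: are sticky in the rest-indicative state; pressure halves persistence.
DEFAULT_CONTROL = {
    "cohesion": np.array([[0.90, 0.10], [0.40, 0.60]]),
    "formation": np.array([[0.85, 0.15], [0.35, 0.65]]),
    "aerial": np.array([[0.92, 0.08], [0.50, 0.50]]),
}
DEFAULT_PRESSURE = {
    "cohesion": np.array([[0.75, 0.25], [0.55, 0.45]]),
    "formation": np.array([[0.70, 0.30], [0.50, 0.50]]),
    "aerial": np.array([[0.80, 0.20], [0.60, 0.40]]),
}


def _dates(year: int, month: int, day0: int, n: int) -> list[dt.date]:
    d0 = dt.date(year, month, day0)
    return [d0 + dt.timedelta(days=i) for i in range(n)]


def default_config(seed: int = 0, n_days: int = 10) -> SimulationConfig:
    """A realistic three-site study: control site plus two tourism sites."""
    sites = [
        SiteSpec(
            name="control_reef",
            season="C11",
            dates=_dates(2011, 7, 1, max(3, n_days // 2)),
            presence_prob=1.0,
            pressure=PressureProcess(
                sessions_per_day=1.0,
                duration_mean_min=42.0,
                duration_sd_min=13.2,
                boats_mean=1.0,
                swimmers_mean=0.1,
                purpose="research",
            ),
        ),
        SiteSpec(
            name="lagoon_a",
            season="A13",
            dates=_dates(2013, 7, 1, n_days),
            presence_prob=0.73,
            pressure=PressureProcess(
                sessions_per_day=2.0,
                duration_mean_min=73.0,
                duration_sd_min=61.8,
                boats_mean=0.5,
                swimmers_mean=11.0,
            ),
        ),
        SiteSpec(
            name="lagoon_b",
            season="B13",
            dates=_dates(2013, 8, 1, n_days),
            presence_prob=0.93,
            pressure=PressureProcess(
                sessions_per_day=2.5,
                duration_mean_min=75.0,
                duration_sd_min=75.1,
                boats_mean=1.0,
                swimmers_mean=4.0,
            ),
        ),
    ]
    return SimulationConfig(
        sites=sites,
        transition_params=uniform_transition_params(
            DEFAULT_CONTROL, DEFAULT_PRESSURE
        ),
        seed=seed,
    )


def true_stationary(
    config: SimulationConfig, indicator: str, time_cat: str, condition: str
) -> np.ndarray:
    """Exact stationary distribution of one configured transition matrix.

    For a two-state chain with off-diagonal rates p01 and p10 the unique
    stationary distribution is (p10, p01) / (p01 + p10); it exists only
    when both off-diagonals are positive (irreducible) and the chain is
    aperiodic (not the pure swap matrix).
    """
    key = (indicator, time_cat, condition)
    if key not in config.transition_params:
        raise ConfigurationError(f"no transition matrix configured for {key}")
    m = np.asarray(config.transition_params[key], dtype=float)
    p01, p10 = m[0, 1], m[1, 0]
    if p01 <= 0.0 or p10 <= 0.0:
        raise DegeneracyError(
            f"matrix for {key} is reducible: no unique stationary distribution"
        )
    if p01 == 1.0 and p10 == 1.0:
        raise DegeneracyError(f"matrix for {key} is periodic (pure swap)")
    return np.array([p10, p01]) / (p01 + p10)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _draw_sessions(
    rng: np.random.Generator, proc: PressureProcess, daylight_s: float
) -> list[tuple[float, float, int, int]]:
    """Sessions for one day as (start_s, end_s, n_boats, n_swimmers)."""
    n = rng.poisson(proc.sessions_per_day)
    raw = []
    mu, sigma = _lognormal_params(proc.duration_mean_min, proc.duration_sd_min)
    for _ in range(n):
        frac = rng.normal(proc.start_frac_mean, proc.start_frac_sd)
        frac = float(np.clip(frac, 0.0, 1.0))
        dur_s = float(rng.lognormal(mu, sigma)) * 60.0
        start = frac * daylight_s
        end = min(start + dur_s, daylight_s)
        boats = int(rng.poisson(proc.boats_mean))
        swimmers = int(rng.poisson(proc.swimmers_mean))
        if boats + swimmers == 0:
            boats = 1
        raw.append((start, end, boats, swimmers))
    raw.sort()
    merged: list[tuple[float, float, int, int]] = []
    for s in raw:
        if merged and s[0] <= merged[-1][1]:
            prev = merged[-1]
            merged[-1] = (prev[0], max(prev[1], s[1]), prev[2], prev[3])
        else:
            merged.append(s)
    return merged


def _closed_form_stationary(m: np.ndarray) -> np.ndarray:
    p01, p10 = m[0, 1], m[1, 0]
    if p01 + p10 == 0.0:
        return np.array([0.5, 0.5])
    return np.array([p10, p01]) / (p01 + p10)


def simulate_study(config: SimulationConfig) -> tuple[list[FocalFollow], SunTimesTable]:
    """Generate the full synthetic study: one focal follow per present day.

    Identical configuration (including seed) produces identical output.
    Returns the follows together with the sun-times table they were
    generated under.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sun_entries = []
    follows: list[FocalFollow] = []
    for site in config.sites:
        for date in site.dates:
            sun = SunTimes(site.name, date, site.sunrise, site.sunset)
            sun_entries.append(sun)
            if rng.random() >= site.presence_prob:
                continue
            follows.append(_simulate_follow(config, site, sun, rng))
    return follows, SunTimesTable(sun_entries)


def _simulate_follow(
    config: SimulationConfig,
    site: SiteSpec,
    sun: SunTimes,
    rng: np.random.Generator,
) -> FocalFollow:
    t0 = sun.sunrise.hour * 3600.0 + sun.sunrise.minute * 60.0 + sun.sunrise.second
    daylight = sun.daylight_seconds
    n_scans = int(np.floor(daylight / config.scan_interval)) + 1
    rel = np.arange(n_scans) * config.scan_interval / daylight
    t_s = t0 + np.arange(n_scans) * config.scan_interval
    cats = [time_category(r) for r in rel]

    sessions = _draw_sessions(rng, site.pressure, daylight)
    n_boats = np.zeros(n_scans, dtype=int)
    n_swimmers = np.zeros(n_scans, dtype=int)
    pressure = np.zeros(n_scans, dtype=bool)
    rel_s = rel * daylight
    for start, end, boats, swimmers in sessions:
        inside = (rel_s >= start) & (rel_s <= end)
        pressure |= inside
        n_boats[inside] = boats
        n_swimmers[inside] = swimmers

    # condition used for the step into scan t: pressure at either endpoint,
    # matching the default chain-labelling convention downstream
    cond = [
        PRESSURE if (pressure[t] or (t > 0 and pressure[t - 1])) else CONTROL
        for t in range(n_scans)
    ]

    states: dict[str, list[str]] = {}
    for ind, labels in config.indicators.items():
        seq = np.empty(n_scans, dtype=int)
        m0 = np.asarray(
            config.transition_params[(ind, cats[0], cond[0])], dtype=float
        )
        seq[0] = rng.choice(2, p=_closed_form_stationary(m0))
        for t in range(1, n_scans):
            m = np.asarray(
                config.transition_params[(ind, cats[t], cond[t])], dtype=float
            )
            seq[t] = rng.choice(2, p=m[seq[t - 1]])
        states[ind] = [labels[s] for s in seq]

    blank = rng.random(n_scans) < config.blank_prob
    for ind in config.indicators:
        states[ind] = [
            BLANK if blank[t] else states[ind][t] for t in range(n_scans)
        ]

    hh = (t_s // 3600).astype(int)
    mm = ((t_s % 3600) // 60).astype(int)
    ss = (t_s % 60).astype(int)
    scans = pd.DataFrame(
        {
            "follow_id": f"{site.name}-{sun.date.isoformat()}",
            "site": site.name,
            "season": site.season,
            "date": sun.date.isoformat(),
            "time": [f"{h:02d}:{m:02d}:{s:02d}" for h, m, s in zip(hh, mm, ss)],
            "cohesion": states.get("cohesion", [BLANK] * n_scans),
            "formation": states.get("formation", [BLANK] * n_scans),
            "aerial": states.get("aerial", [BLANK] * n_scans),
            "n_boats": n_boats,
            "n_swimmers": n_swimmers,
            "purpose": [
                site.pressure.purpose if p else "" for p in pressure
            ],
            "t_s": t_s.astype(float),
            "rel_time": rel,
            "time_category": cats,
            "pressure": pressure,
        }
    )
    return FocalFollow(
        follow_id=scans["follow_id"].iloc[0],
        site=site.name,
        season=site.season,
        date=sun.date,
        scans=scans,
        nominal_interval=config.scan_interval,
    )


def write_study(
    follows: list[FocalFollow],
    sun_times: SunTimesTable,
    out_dir,
    config: SimulationConfig | None = None,
) -> None:
    """Write scans.csv, suntimes.csv and a metadata.yaml recording the seed."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_scans(follows, out / "scans.csv")
    sun_times.to_csv(out / "suntimes.csv")
    meta = {"n_follows": len(follows)}
    if config is not None:
        meta["seed"] = int(config.seed)
        meta["scan_interval"] = float(config.scan_interval)
        meta["blank_prob"] = float(config.blank_prob)
    with open(out / "metadata.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def simulate_transition_records(
    transition_params: dict[tuple[str, str, str], np.ndarray],
    indicator: str,
    n_per_cell: int,
    rng: np.random.Generator,
    time_categories: tuple[str, ...] = TIME_CATEGORIES,
    conditions: tuple[str, ...] = CONDITIONS,
    site: str = "sim",
    season: str = "S1",
) -> pd.DataFrame:
    """Labelled transition records at a controlled per-cell sample size.

    For every (time category, condition) cell one stationary-start Markov
    sequence of ``n_per_cell`` transitions is generated from the configured
    matrix, bypassing the scan/session layer.  This is the surface for
    recovery and calibration studies where the number of transitions per
    chain — not the field sampling design — is the controlled quantity.
    """
    labels = INDICATORS[indicator]
    frames = []
    for tc in time_categories:
        for cond in conditions:
            m = np.asarray(transition_params[(indicator, tc, cond)], dtype=float)
            pi = _closed_form_stationary(m)
            seq = np.empty(n_per_cell + 1, dtype=int)
            u = rng.random(n_per_cell + 1)
            seq[0] = int(u[0] < pi[1])
            for t in range(1, n_per_cell + 1):
                seq[t] = int(u[t] < m[seq[t - 1], 1])
            frames.append(
                pd.DataFrame(
                    {
                        "indicator": indicator,
                        "preceding": [labels[s] for s in seq[:-1]],
                        "succeeding": [labels[s] for s in seq[1:]],
                        "chain": cond,
                        "site": site,
                        "season": season,
                        "time_category": tc,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def config_from_yaml(path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML document.

    Expected layout::

        seed: 1
        scan_interval: 150
        blank_prob: 0.05
        control:   {cohesion: [[0.9, 0.1], [0.4, 0.6]], ...}
        pressure:  {cohesion: [[0.75, 0.25], [0.55, 0.45]], ...}
        overrides: {"cohesion/midday/pressure": [[...], [...]]}   # optional
        sites:
          - name: lagoon_a
            season: A13
            dates: ["2013-07-01", ...]
            sunrise: "06:00:00"
            sunset:  "18:00:00"
            presence_prob: 0.9
            pressure: {sessions_per_day: 2.0, duration_mean_min: 75, ...}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    control = {k: np.asarray(v, float) for k, v in doc["control"].items()}
    pressure = {
        k: np.asarray(v, float) for k, v in doc.get("pressure", doc["control"]).items()
    }
    overrides = {}
    for key, m in (doc.get("overrides") or {}).items():
        ind, tc, cond = key.split("/")
        overrides[(ind, tc, cond)] = np.asarray(m, float)
    sites = []
    for s in doc["sites"]:
        proc = PressureProcess(**(s.get("pressure") or {}))
        sites.append(
            SiteSpec(
                name=s["name"],
                season=s["season"],
                dates=[dt.date.fromisoformat(d) for d in s["dates"]],
                sunrise=dt.time.fromisoformat(s.get("sunrise", "06:00:00")),
                sunset=dt.time.fromisoformat(s.get("sunset", "18:00:00")),
                presence_prob=float(s.get("presence_prob", 0.9)),
                pressure=proc,
            )
        )
    return SimulationConfig(
        sites=sites,
        transition_params=uniform_transition_params(control, pressure, overrides),
        scan_interval=float(doc.get("scan_interval", 150.0)),
        blank_prob=float(doc.get("blank_prob", 0.05)),
        seed=int(doc.get("seed", 0)),
    )


def config_to_dict(config: SimulationConfig) -> dict:
    """JSON/YAML-serializable snapshot of a configuration (for manifests)."""
    d = dataclasses.asdict(config)
    d["transition_params"] = {
        "/".join(k): np.asarray(v, float).tolist()
        for k, v in config.transition_params.items()
    }
    for s in d["sites"]:
        s["dates"] = [x.isoformat() for x in s["dates"]]
        s["sunrise"] = s["sunrise"].isoformat()
        s["sunset"] = s["sunset"].isoformat()
    return d
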