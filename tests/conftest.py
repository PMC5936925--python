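"""Shared fixtures: hand-built follows and a seeded synthetic study."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from behavchain.datamodel import BLANK, FocalFollow
from behavchain.synthetic import default_config, simulate_study


def make_follow(
    n_scans: int | None = None,
    t_s: list[float] | None = None,
    pressure_idx: list[int] = (),
    cohesion: list[str] | None = None,
    formation: list[str] | None = None,
    aerial: list[str] | None = None,
    time_cat: str | list[str] = "midday",
    interval: float = 150.0,
    site: str = "siteA",
    season: str = "S1",
    t0: float = 6 * 3600.0,
) -> FocalFollow:
    """Construct a follow from explicit scan attributes for hand enumeration."""
    if t_s is None:
        t_s = [t0 + i * interval for i in range(n_scans)]
    n = len(t_s)
    pressure = np.zeros(n, dtype=bool)
    pressure[list(pressure_idx)] = True
    cats = [time_cat] * n if isinstance(time_cat, str) else list(time_cat)
    scans = pd.DataFrame(
        {
            "follow_id": "F1",
            "site": site,
            "season": season,
            "date": "2013-07-01",
            "time": ["" for _ in range(n)],
            "cohesion": cohesion if cohesion is not None else ["tight"] * n,
            "formation": formation if formation is not None else ["single"] * n,
            "aerial": aerial if aerial is not None else ["inactive"] * n,
            "n_boats": pressure.astype(int),
            "n_swimmers": 0,
            "purpose": ["tourism" if p else "" for p in pressure],
            "t_s": np.asarray(t_s, dtype=float),
            "rel_time": np.linspace(0.4, 0.6, n),
            "time_category": cats,
            "pressure": pressure,
        }
    )
    return FocalFollow(
        follow_id="F1",
        site=site,
        season=season,
        date=dt.date(2013, 7, 1),
        scans=scans,
        nominal_interval=interval,
    )


@pytest.fixture(scope="session")
def small_study():
    """One seeded synthetic study reused across read-only tests."""
    cfg = default_config(seed=42, n_days=4)
    follows, sun = simulate_study(cfg)
    return cfg, follows, sun


BLANK_ = BLANK
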