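"""Control vs pressure comparison of rest-indicative stationary proportions.

For each behavioural indicator the state characteristic of rest (tight
cohesion, single school, no aerial activity) is compared between the
control and pressure chains: a two-proportion z-test on the stationary
proportions and a directional Cohen's h

    h = 2 arcsin(sqrt(p_pressure)) - 2 arcsin(sqrt(p_control))

so that h > 0 means the rest-indicative state is *more* frequent under
pressure.  Two designs are supported: *inter-site* (control chain from the
designated control site vs pressure chain from a tourism site, matched on
time of day) and *intra-site* (control vs pressure chain from the same
site, season and time of day).  Effect sizes are banded |h| < 0.2 small,
0.2-0.65 medium, >= 0.65 large (anchors 0.2 / ~0.5 / >0.8 with declared
midpoint cuts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .errors import DegenerateTestError, OutOfRangeError, PairingError, ValidationError

#: per-indicator rest-indicative state (the state whose persistence marks rest)
REST_STATES = {"cohesion": "tight", "formation": "single", "aerial": "inactive"}

INTER_SITE, INTRA_SITE = "inter_site", "intra_site"


def cohens_h(p_pressure: float, p_control: float) -> float:
    """Directional Cohen's h between two proportions (pressure minus control)."""
    for name, p in (("p_pressure", p_pressure), ("p_control", p_control)):
        if not (0.0 <= p <= 1.0):
            raise OutOfRangeError(f"{name}={p} outside [0, 1]")
    return 2.0 * math.asin(math.sqrt(p_pressure)) - 2.0 * math.asin(
        math.sqrt(p_control)
    )


def size_class(h: float) -> str:
    """Effect-size band of |h|: small / medium / large (none for h = 0)."""
    a = abs(h)
    if a == 0.0:
        return "none"
    if a < 0.2:
        return "small"
    if a < 0.65:
        return "medium"
    return "large"


def two_proportion_z(
    p1: float, n1: int, p2: float, n2: int, variance: str = "pooled"
) -> tuple[float, float]:
    """Two-sided two-proportion z-test; returns (z, p_value).

    Default is the pooled-variance form: with pooled proportion
    p = (p1 n1 + p2 n2)/(n1 + n2), z = (p1 - p2)/sqrt(p(1-p)(1/n1 + 1/n2)).
    ``variance='unpooled'`` uses p1(1-p1)/n1 + p2(1-p2)/n2 instead.
    A pooled (or unpooled) variance of zero leaves z undefined and raises
    :class:`DegenerateTestError`.
    """
    if n1 < 1 or n2 < 1:
        raise ValidationError("sample sizes must be >= 1")
    for name, p in (("p1", p1), ("p2", p2)):
        if not (0.0 <= p <= 1.0):
            raise OutOfRangeError(f"{name}={p} outside [0, 1]")
    if variance == "pooled":
        pool = (p1 * n1 + p2 * n2) / (n1 + n2)
        var = pool * (1.0 - pool) * (1.0 / n1 + 1.0 / n2)
    elif variance == "unpooled":
        var = p1 * (1.0 - p1) / n1 + p2 * (1.0 - p2) / n2
    else:
        raise ValidationError(f"unknown variance convention {variance!r}")
    if var <= 0.0:
        raise DegenerateTestError("degenerate test: zero variance (p-hat 0 or 1)")
    z = (p1 - p2) / math.sqrt(var)
    p_value = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p_value)


@dataclass(frozen=True)
class EffectResult:
    indicator: str
    rest_state: str
    design: str
    control_site: str
    control_season: str
    pressure_site: str
    pressure_season: str
    time_category: str
    p_control: float
    p_pressure: float
    n_control: int
    n_pressure: int
    z: float
    p_value: float
    h: float
    size_class: str


def _stars(p: float) -> str:
    return "**" if p < 0.01 else "*" if p < 0.05 else ""


def compare(
    design: str,
    stationary: pd.DataFrame,
    control_site: str | None = None,
    rest_states: dict[str, str] | None = None,
    variance: str = "pooled",
    holm: bool = False,
) -> list[EffectResult]:
    """Pair control and pressure stationary distributions and test them.

    ``stationary`` is the tidy table from
    :func:`behavchain.chains.stationary_table` (columns indicator, chain,
    site, season, time_category, state0/state1, p_state0/p_state1,
    n_transitions).

    inter_site: the control side is always the control chain of
    ``control_site``; the pressure side is the pressure chain of every
    *other* (tourism) site, matched on indicator and time category.
    Pressure rows of the control site and control rows of tourism sites are
    never consumed.

    intra_site: control and pressure chains from the same (site, season,
    time category).

    Raises :class:`PairingError` listing gaps if a control counterpart is
    missing for a pressure cell that the design requires.  ``holm=True``
    applies a Holm correction across the returned p-values (off by default).
    """
    rest_states = rest_states or REST_STATES
    if design not in (INTER_SITE, INTRA_SITE):
        raise ValidationError(f"unknown design {design!r}")
    if design == INTER_SITE and control_site is None:
        raise ValidationError("inter_site design requires control_site")

    def _p_rest(row: pd.Series, indicator: str) -> float:
        rest = rest_states[indicator]
        if row["state0"] == rest:
            return float(row["p_state0"])
        if row["state1"] == rest:
            return float(row["p_state1"])
        raise ValidationError(
            f"rest state {rest!r} not among states of {indicator}"
        )

    press = stationary[stationary["chain"] == "pressure"]
    ctrl = stationary[stationary["chain"] == "control"]
    if design == INTER_SITE:
        press = press[press["site"] != control_site]
        ctrl = ctrl[ctrl["site"] == control_site]

    results: list[EffectResult] = []
    gaps: list[str] = []
    for _, prow in press.sort_values(
        ["indicator", "site", "season", "time_category"]
    ).iterrows():
        ind, tc = prow["indicator"], prow["time_category"]
        if ind not in rest_states:
            continue
        if design == INTER_SITE:
            match = ctrl[(ctrl["indicator"] == ind) & (ctrl["time_category"] == tc)]
        else:
            match = ctrl[
                (ctrl["indicator"] == ind)
                & (ctrl["time_category"] == tc)
                & (ctrl["site"] == prow["site"])
                & (ctrl["season"] == prow["season"])
            ]
        if len(match) == 0:
            gaps.append(f"{ind}/{prow['site']}/{prow['season']}/{tc}")
            continue
        crow = match.iloc[0]
        p_c, p_p = _p_rest(crow, ind), _p_rest(prow, ind)
        n_c, n_p = int(crow["n_transitions"]), int(prow["n_transitions"])
        try:
            z, p_value = two_proportion_z(p_p, n_p, p_c, n_c, variance=variance)
        except DegenerateTestError:
            z, p_value = float("nan"), float("nan")
        h = cohens_h(p_p, p_c)
        results.append(
            EffectResult(
                indicator=ind,
                rest_state=rest_states[ind],
                design=design,
                control_site=str(crow["site"]),
                control_season=str(crow["season"]),
                pressure_site=str(prow["site"]),
                pressure_season=str(prow["season"]),
                time_category=tc,
                p_control=p_c,
                p_pressure=p_p,
                n_control=n_c,
                n_pressure=n_p,
                z=z,
                p_value=p_value,
                h=h,
                size_class=size_class(h),
            )
        )
    if gaps and not results:
        raise PairingError("no control counterpart for: " + ", ".join(gaps))
    if holm and results:
        order = sorted(range(len(results)), key=lambda i: results[i].p_value)
        m = len(results)
        adjusted = {}
        running = 0.0
        for rank, i in enumerate(order):
            adj = min(1.0, (m - rank) * results[i].p_value)
            running = max(running, adj)
            adjusted[i] = running
        results = [
            EffectResult(**{**r.__dict__, "p_value": adjusted[i]})
            for i, r in enumerate(results)
        ]
    return results


def effect_report(results: list[EffectResult]) -> pd.DataFrame:
    """Tidy effect table shaped like the data behind the paper-style figures."""
    rows = [
        {
            "design": r.design,
            "indicator": r.indicator,
            "rest_state": r.rest_state,
            "control_site": r.control_site,
            "control_season": r.control_season,
            "pressure_site": r.pressure_site,
            "pressure_season": r.pressure_season,
            "time_category": r.time_category,
            "p_control": r.p_control,
            "p_pressure": r.p_pressure,
            "n_control": r.n_control,
            "n_pressure": r.n_pressure,
            "h": r.h,
            "size_class": r.size_class,
            "z": r.z,
            "p_value": r.p_value,
            "stars": _stars(r.p_value) if r.p_value == r.p_value else "",
        }
        for r in results
    ]
    return pd.DataFrame(rows)
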