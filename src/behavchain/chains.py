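"""Behavioural transitions, chain-order selection, contingency tables,
transition matrices and stationary distributions.

Consecutive scans one nominal interval apart with both indicator states
observed define a transition (preceding state -> succeeding state).  Each
transition is assigned to the *pressure* chain when human activity is
present at either endpoint scan (endpoint convention configurable), to the
*control* chain when activity is absent at both endpoints and at every
recorded scan in the washout window (default 15 min) before the succeeding
scan — a window the follow must actually cover, since unobserved absence
cannot be certified — and is otherwise excluded.  Transitions never cross
follow boundaries, gaps or blank states.  The diel time category of a
transition is that of its succeeding scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import INDICATORS, FocalFollow
from .errors import DegeneracyError, EstimationError, ValidationError

CONTROL, PRESSURE = "control", "pressure"

TRANSITION_COLUMNS = [
    "indicator",
    "preceding",
    "succeeding",
    "chain",
    "site",
    "season",
    "time_category",
    "follow_id",
    "date",
]


def extract_transitions(
    follow: FocalFollow,
    indicator: str,
    washout_minutes: float = 15.0,
    pressure_endpoint: str = "either",
) -> pd.DataFrame:
    """Labelled transitions of one indicator from one follow.

    ``pressure_endpoint`` selects the pressure-labelling convention:
    ``either`` (default), ``both`` or ``succeeding``.  Pairs that are
    neither pressure (by the convention) nor certifiable control are
    excluded.  Returns a DataFrame with :data:`TRANSITION_COLUMNS`.
    """
    if indicator not in INDICATORS:
        raise ValidationError(f"unknown indicator {indicator!r}")
    if pressure_endpoint not in ("either", "both", "succeeding"):
        raise ValidationError(
            f"unknown pressure_endpoint convention {pressure_endpoint!r}"
        )
    scans = follow.scans
    t = scans["t_s"].to_numpy(dtype=float)
    states = scans[indicator].to_numpy(dtype=object)
    pres = scans["pressure"].to_numpy(dtype=bool)
    washout_s = washout_minutes * 60.0
    t_first = t[0]

    rows = []
    for i in range(len(t) - 1):
        j = i + 1
        if abs(t[j] - t[i] - follow.nominal_interval) > follow.interval_tolerance:
            continue  # gap: no adjacency
        if states[i] == "" or states[j] == "":
            continue  # blank endpoint
        if pressure_endpoint == "either":
            is_pressure = pres[i] or pres[j]
        elif pressure_endpoint == "both":
            is_pressure = pres[i] and pres[j]
        else:
            is_pressure = pres[j]
        if is_pressure:
            chain = PRESSURE
        else:
            window = (t >= t[j] - washout_s) & (t <= t[j])
            covered = t_first <= t[j] - washout_s
            if covered and not pres[window].any() and not pres[i] and not pres[j]:
                chain = CONTROL
            else:
                continue  # washout not certified, or recent pressure
        rows.append(
            {
                "indicator": indicator,
                "preceding": states[i],
                "succeeding": states[j],
                "chain": chain,
                "site": follow.site,
                "season": follow.season,
                "time_category": scans["time_category"].iloc[j],
                "follow_id": follow.follow_id,
                "date": follow.date.isoformat(),
            }
        )
    return pd.DataFrame(rows, columns=TRANSITION_COLUMNS)


def extract_all_transitions(
    follows: list[FocalFollow],
    indicators: list[str] | None = None,
    washout_minutes: float = 15.0,
    pressure_endpoint: str = "either",
) -> pd.DataFrame:
    """All transitions across follows and indicators, one long DataFrame."""
    indicators = indicators or list(INDICATORS)
    frames = [
        extract_transitions(f, ind, washout_minutes, pressure_endpoint)
        for f in follows
        for ind in indicators
    ]
    if not frames:
        return pd.DataFrame(columns=TRANSITION_COLUMNS)
    return pd.concat(frames, ignore_index=True)


@dataclass
class OrderSelection:
    bic0: float
    bic1: float
    order: int
    loglik0: float
    loglik1: float
    degenerate: bool = False


def select_order(records: pd.DataFrame) -> OrderSelection:
    """BIC comparison of zero-order vs first-order chains for one indicator.

    Zero order: the succeeding state is i.i.d. Bernoulli (1 free
    probability).  First order: succeeding depends on preceding (2 free
    probabilities).  BIC = -2 logL + k ln n; the smaller wins.  If every
    record has the same succeeding state the likelihoods are degenerate and
    order 0 is returned with a flag.
    """
    n = len(records)
    if n < 2:
        raise ValidationError("order selection needs at least 2 transitions")
    succ = records["succeeding"].to_numpy(dtype=object)
    prec = records["preceding"].to_numpy(dtype=object)

    def _bernoulli_ll(x: np.ndarray) -> float:
        k = np.sum(x)
        m = len(x)
        ll = 0.0
        if 0 < k < m:
            p = k / m
            ll = k * np.log(p) + (m - k) * np.log(1 - p)
        return float(ll)

    levels = sorted(set(succ) | set(prec))
    x = np.array([s == levels[-1] for s in succ])
    ll0 = _bernoulli_ll(x)
    ll1 = sum(
        _bernoulli_ll(x[prec == lv]) for lv in levels if np.any(prec == lv)
    )
    if len(set(succ)) == 1:
        return OrderSelection(
            bic0=-2 * ll0 + 1 * np.log(n),
            bic1=-2 * ll1 + 2 * np.log(n),
            order=0,
            loglik0=ll0,
            loglik1=ll1,
            degenerate=True,
        )
    bic0 = -2 * ll0 + 1 * np.log(n)
    bic1 = -2 * ll1 + 2 * np.log(n)
    return OrderSelection(
        bic0=float(bic0),
        bic1=float(bic1),
        order=0 if bic0 <= bic1 else 1,
        loglik0=float(ll0),
        loglik1=float(ll1),
    )


@dataclass
class ContingencyTable:
    """Cross-classified transition counts over ordered factors.

    ``counts[i, j, ...]`` indexes levels in the order given by ``levels``;
    the first two factors are always ``preceding`` and ``succeeding``.
    """

    factors: list[str]
    levels: dict[str, list[str]]
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def margin(self, factors: tuple[str, ...]) -> np.ndarray:
        axes = tuple(
            i for i, f in enumerate(self.factors) if f not in factors
        )
        return self.counts.sum(axis=axes)

    def to_long(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_product(
            [self.levels[f] for f in self.factors], names=self.factors
        )
        return (
            pd.Series(self.counts.ravel(), index=idx, name="count")
            .reset_index()
        )


def build_table(records: pd.DataFrame, factors: list[str]) -> ContingencyTable:
    """Cross-classify transition records over the requested factors.

    ``factors`` must include ``preceding`` and ``succeeding``; any other
    factor must be a column of ``records``.  Cells with no records are 0.
    """
    if "preceding" not in factors or "succeeding" not in factors:
        raise ValidationError("factors must include preceding and succeeding")
    for f in factors:
        if f not in records.columns:
            raise ValidationError(f"factor {f!r} absent from records")
    inds = records["indicator"].unique() if "indicator" in records.columns else []
    if len(inds) == 1:
        s0, s1 = INDICATORS.get(inds[0], (None, None))
        state_levels = [s0, s1] if s0 else sorted(
            set(records["preceding"]) | set(records["succeeding"])
        )
    else:
        state_levels = sorted(set(records["preceding"]) | set(records["succeeding"]))
    levels = {}
    for f in factors:
        if f in ("preceding", "succeeding"):
            levels[f] = list(state_levels)
        else:
            levels[f] = sorted(records[f].unique())
    shape = tuple(len(levels[f]) for f in factors)
    counts = np.zeros(shape, dtype=int)
    index = {f: {lv: i for i, lv in enumerate(levels[f])} for f in factors}
    for _, row in records.iterrows():
        pos = tuple(index[f][row[f]] for f in factors)
        counts[pos] += 1
    return ContingencyTable(factors=list(factors), levels=levels, counts=counts)


@dataclass
class TransitionMatrix:
    indicator: str
    labels: dict[str, str]  # conditioning labels: chain, site, season, time_category
    states: tuple[str, str]
    probabilities: np.ndarray  # 2x2 row-stochastic
    row_counts: np.ndarray  # transitions observed per preceding state
    reducible: bool = False


def estimate_matrix(records: pd.DataFrame) -> TransitionMatrix:
    """Maximum-likelihood transition matrix from a homogeneous record subset.

    The subset must share indicator and conditioning labels; rows are the
    normalized transition counts.  A preceding state with no observations
    raises :class:`EstimationError` naming the row.  An estimated matrix
    with a zero off-diagonal is flagged ``reducible`` (its stationary
    distribution would not be unique).
    """
    inds = records["indicator"].unique()
    if len(inds) != 1:
        raise ValidationError(f"records mix indicators {sorted(inds)}")
    indicator = inds[0]
    states = INDICATORS[indicator]
    counts = np.zeros((2, 2))
    for i, s_from in enumerate(states):
        for j, s_to in enumerate(states):
            counts[i, j] = np.sum(
                (records["preceding"] == s_from) & (records["succeeding"] == s_to)
            )
    row_counts = counts.sum(axis=1)
    for i, s_from in enumerate(states):
        if row_counts[i] == 0:
            raise EstimationError(
                f"{indicator}: preceding state {s_from!r} never observed"
            )
    probs = counts / row_counts[:, None]
    labels = {}
    for key in ("chain", "site", "season", "time_category"):
        if key in records.columns:
            vals = records[key].unique()
            labels[key] = vals[0] if len(vals) == 1 else "*"
    return TransitionMatrix(
        indicator=indicator,
        labels=labels,
        states=states,
        probabilities=probs,
        row_counts=row_counts.astype(int),
        reducible=bool(probs[0, 1] == 0.0 or probs[1, 0] == 0.0),
    )


def stationary(matrix: TransitionMatrix | np.ndarray) -> np.ndarray:
    """Unique stationary distribution pi with pi = pi P, sum(pi) = 1.

    Solved as the linear fixed-point system (P' - I) pi = 0 with the
    normalization row appended — not by matrix powering — so reducible or
    periodic chains fail loudly with :class:`DegeneracyError` instead of
    returning a start-dependent answer.
    """
    P = matrix.probabilities if isinstance(matrix, TransitionMatrix) else np.asarray(matrix, float)
    k = P.shape[0]
    if P.shape != (k, k):
        raise ValidationError("transition matrix must be square")
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
        raise ValidationError("transition matrix rows must sum to 1")
    _check_ergodic(P)
    A = np.vstack([P.T - np.eye(k), np.ones((1, k))])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return pi / pi.sum()


def _check_ergodic(P: np.ndarray) -> None:
    k = P.shape[0]
    if k == 2:
        p01, p10 = P[0, 1], P[1, 0]
        if p01 <= 0.0 or p10 <= 0.0:
            raise DegeneracyError("reducible chain: zero off-diagonal rate")
        if p01 == 1.0 and p10 == 1.0:
            raise DegeneracyError("periodic chain: pure swap matrix")
        return
    # general case: strong connectivity of the positive-entry digraph,
    # aperiodicity via a positive diagonal somewhere on the support
    reach = (P > 0).astype(int)
    closure = np.linalg.matrix_power(reach + np.eye(k, dtype=int), k) > 0
    if not closure.all():
        raise DegeneracyError("reducible chain")
    eigvals = np.linalg.eigvals(P)
    on_circle = np.sum(np.isclose(np.abs(eigvals), 1.0, atol=1e-10))
    if on_circle > 1:
        raise DegeneracyError("periodic chain")


def stationary_table(
    transitions: pd.DataFrame,
    by: list[str] = ("indicator", "chain", "site", "season", "time_category"),
    min_transitions: int = 1,
) -> pd.DataFrame:
    """Stationary distributions per conditioning cell, as a tidy table.

    One row per group with the stationary probability of each of the
    indicator's two states (``p_state0`` refers to the rest-indicative
    state listed first in the data model) and the number of supporting
    transitions.  Cells whose estimated chain is degenerate (reducible or
    missing a preceding state) or under-supported are skipped.
    """
    rows = []
    for key, grp in transitions.groupby(list(by), sort=True):
        if len(grp) < max(min_transitions, 2):
            continue
        try:
            tm = estimate_matrix(grp)
            pi = stationary(tm)
        except (EstimationError, DegeneracyError):
            continue
        row = dict(zip(by, key))
        row["state0"] = tm.states[0]
        row["state1"] = tm.states[1]
        row["p_state0"] = float(pi[0])
        row["p_state1"] = float(pi[1])
        row["n_transitions"] = int(len(grp))
        rows.append(row)
    return pd.DataFrame(rows)
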