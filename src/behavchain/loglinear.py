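"""Hierarchical log-linear models for transition contingency tables.

The modelling question is conditional: does the probability of a
*succeeding* behavioural state, given the *preceding* state, depend on the
diel time category, the location (or field season) and the control/pressure
chain?  Every model therefore always contains two base generators:

* the full interaction among the preceding state and all conditioning
  factors — so the sampling distribution of conditions is fitted exactly
  and never contributes to model comparison; and
* the preceding-succeeding association — the first-order chain itself.

An *effect term* is a subset of conditioning factors whose interaction with
the transition is added, i.e. the term ``Time x Chain`` contributes the
generator {preceding, succeeding, time, chain}: the transition probabilities
then vary freely over time-by-chain cells.  The null model has no effect
terms: the transition is homogeneous across all conditions.

Models are fitted by iterative proportional scaling (IPF) to the generator
margins, scored by the likelihood-ratio statistic G-squared = 2 sum
obs*ln(obs/fitted) penalized by twice the residual degrees of freedom
(AIC = G2 - 2 df, so the saturated model scores 0 and good parsimonious
models go negative), and models within 2 AIC units of the minimum are
reported as having substantial support.

Degrees of freedom count free cells minus free parameters of the
hierarchical parametrization (the downward closure of the generators);
sampling zeros are kept as zeros, and df is reduced by the number of cells
whose fitted value is forced to zero by a zero sufficient margin.  A
flattening constant (default off) is available for sensitivity analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chains import ContingencyTable
from .errors import SelectionError, ValidationError

#: display names for conditioning factors, in canonical label order
FACTOR_NAMES = {
    "time_category": "Time",
    "site": "Location",
    "season": "Season",
    "chain": "Chain",
}
_FACTOR_ORDER = {f: i for i, f in enumerate(FACTOR_NAMES)}


@dataclass(frozen=True)
class ModelSpec:
    """One hierarchical model: its conditioning factors and effect terms.

    ``effect_terms`` is a tuple of factor tuples; each term E adds the
    generator {preceding, succeeding} | E.  Terms form an antichain (no
    term contains another), which together with generator-implied margins
    keeps the family hierarchical.
    """

    conditioning: tuple[str, ...]
    effect_terms: tuple[tuple[str, ...], ...] = ()

    @property
    def label(self) -> str:
        if not self.effect_terms:
            return "Null"
        parts = []
        terms = sorted(
            self.effect_terms,
            key=lambda t: (
                -len(t),
                0 if len(t) > 1 and "chain" in t else 1,
                tuple(_FACTOR_ORDER.get(f, 99) for f in t),
            ),
        )
        for t in terms:
            parts.append(
                " × ".join(FACTOR_NAMES.get(f, f.title()) for f in t)
            )
        return " + ".join(parts)

    def generators(self) -> list[tuple[str, ...]]:
        gens = [("preceding",) + tuple(self.conditioning), ("preceding", "succeeding")]
        for term in self.effect_terms:
            gens.append(("preceding", "succeeding") + tuple(term))
        return gens


def enumerate_models(factors: list[str]) -> list[ModelSpec]:
    """The hierarchical model family over the given conditioning factors.

    Candidate effect terms are all singletons and pairs of conditioning
    factors; a model is any antichain of terms (the empty antichain is the
    null model).  For factors {time, chain} this yields Null, Time, Chain,
    Time + Chain and Time x Chain.
    """
    if "chain" not in factors or len(factors) < 2:
        raise ValidationError(
            "need the chain factor plus at least one of time/location/season"
        )
    conditioning = tuple(factors)
    terms = [
        tuple(sorted(c, key=lambda f: _FACTOR_ORDER.get(f, 99)))
        for r in (1, 2)
        for c in itertools.combinations(conditioning, r)
    ]
    specs = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            ok = all(
                not (set(a) < set(b) or set(b) < set(a))
                for a, b in itertools.combinations(combo, 2)
            )
            if ok:
                specs.append(ModelSpec(conditioning=conditioning, effect_terms=combo))
    return specs


@dataclass
class ModelFit:
    label: str
    spec: ModelSpec | None
    fitted: np.ndarray
    g_squared: float
    df: int
    converged: bool
    iterations: int
    n_forced_zero: int = 0
    generators: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def aic(self) -> float:
        return self.g_squared - 2.0 * self.df


def _margin_axes(factors: list[str], generator: tuple[str, ...]) -> tuple[int, ...]:
    return tuple(i for i, f in enumerate(factors) if f not in generator)


def ipf_fit(
    counts: np.ndarray,
    factors: list[str],
    generators: list[tuple[str, ...]],
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, bool, int]:
    """Iterative proportional scaling of a table to generator margins.

    Returns (fitted, converged, iterations).  Convergence is max absolute
    discrepancy between fitted and observed generator margins below
    ``tol``.  Cells under a zero sufficient margin are driven to exact 0.
    """
    obs = np.asarray(counts, dtype=float)
    for g in generators:
        unknown = set(g) - set(factors)
        if unknown:
            raise ValidationError(f"generator factor(s) {sorted(unknown)} not in table")
    fitted = np.ones_like(obs)
    targets = []
    for g in generators:
        axes = _margin_axes(factors, g)
        targets.append((axes, obs.sum(axis=axes, keepdims=True)))
    it = 0
    for it in range(1, max_iter + 1):
        for axes, target in targets:
            cur = fitted.sum(axis=axes, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(cur > 0, target / np.where(cur > 0, cur, 1.0), 0.0)
            fitted = fitted * ratio
        disc = max(
            float(np.max(np.abs(fitted.sum(axis=axes, keepdims=True) - target)))
            for axes, target in targets
        )
        if disc < tol:
            return fitted, True, it
    return fitted, False, it


def _n_parameters(factors: list[str], levels: dict[str, list[str]],
                  generators: list[tuple[str, ...]]) -> int:
    closure: set[tuple[str, ...]] = set()
    for g in generators:
        for r in range(len(g) + 1):
            for sub in itertools.combinations(sorted(g), r):
                closure.add(sub)
    n = 0
    for sub in closure:
        prod = 1
        for f in sub:
            prod *= len(levels[f]) - 1
        n += prod
    return n


def g_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    obs = np.asarray(observed, dtype=float)
    mask = obs > 0
    return float(2.0 * np.sum(obs[mask] * np.log(obs[mask] / fitted[mask])))


def fit_loglinear(
    table: ContingencyTable,
    generators: list[tuple[str, ...]],
    label: str = "",
    spec: ModelSpec | None = None,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    flatten: float = 0.0,
) -> ModelFit:
    """Fit an arbitrary generator set to a table (the generic engine)."""
    counts = table.counts.astype(float) + flatten
    fitted, converged, its = ipf_fit(counts, table.factors, generators, tol, max_iter)
    n_cells = int(np.prod(counts.shape))
    n_par = _n_parameters(table.factors, table.levels, generators)
    forced_zero = int(np.sum((fitted <= tol) & (counts == 0)))
    df = max(n_cells - n_par - forced_zero, 0)
    return ModelFit(
        label=label,
        spec=spec,
        fitted=fitted,
        g_squared=g_squared(counts, fitted),
        df=df,
        converged=converged,
        iterations=its,
        n_forced_zero=forced_zero,
        generators=list(generators),
    )


def fit_model(
    table: ContingencyTable,
    spec: ModelSpec,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    flatten: float = 0.0,
) -> ModelFit:
    """Fit one hierarchical transition model to a contingency table."""
    missing = set(spec.conditioning) - set(table.factors)
    if missing:
        raise ValidationError(f"spec factors {sorted(missing)} absent from table")
    return fit_loglinear(
        table, spec.generators(), label=spec.label, spec=spec,
        tol=tol, max_iter=max_iter, flatten=flatten,
    )


def aic(fit: ModelFit) -> float:
    """AIC score: G-squared penalized by twice the residual df."""
    return fit.g_squared - 2.0 * fit.df


@dataclass
class SelectionResult:
    best: ModelFit
    supported: list[tuple[ModelFit, float]]  # (fit, delta AIC), best first


def select_models(fits: list[ModelFit], support_window: float = 2.0) -> SelectionResult:
    """Best (minimum-AIC) model and all models with substantial support.

    Ties break toward fewer effect terms, then lexicographic label.
    """
    converged = [f for f in fits if f.converged]
    if not converged:
        raise SelectionError("no converged fits to select among")

    def _key(f: ModelFit):
        n_terms = len(f.spec.effect_terms) if f.spec is not None else 0
        return (f.aic, n_terms, f.label)

    ranked = sorted(converged, key=_key)
    best = ranked[0]
    supported = [
        (f, f.aic - best.aic) for f in ranked if f.aic - best.aic <= support_window
    ]
    return SelectionResult(best=best, supported=supported)


def selection_report(fits: list[ModelFit], support_window: float = 2.0) -> pd.DataFrame:
    """Model-comparison table: label, G2, df, AIC, delta AIC, support flag."""
    sel = select_models(fits, support_window)
    best_aic = sel.best.aic
    rows = []
    for f in sorted(fits, key=lambda f: f.aic):
        rows.append(
            {
                "model": f.label,
                "g_squared": f.g_squared,
                "df": f.df,
                "aic": f.aic,
                "delta_aic": f.aic - best_aic,
                "supported": f.converged and (f.aic - best_aic) <= support_window,
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows)
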