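"""Simulation studies that validate the pipeline against known ground truth.

Each study generates data with the synthetic module, runs the estimation
machinery exactly as the pipeline does, and reports a scalar summary:

* :func:`stationary_solver_agreement` — worst-case disagreement between the
  linear-system stationary solver and the two-state closed form
  (p10, p01)/(p01 + p10) over random row-stochastic matrices.
* :func:`model_recovery_study` — how often the generating log-linear model
  lands in the AIC-supported set over replicate synthetic datasets.
* :func:`ztest_type1_study` — empirical size of the two-proportion z-test on
  stationary proportions under a no-effect, no-persistence null (both
  transition-matrix rows equal, so supporting transitions are independent
  draws and the test's binomial variance is exact).
* :func:`midday_localization_study` — whether a pressure effect configured
  at midday only is recovered at midday with the correct sign and nowhere
  else.

Default scenario dynamics mirror the package-wide defaults: sticky
rest-indicative control dynamics, with pressure halving the persistence of
the rest state where an effect is present.
"""

from __future__ import annotations

import numpy as np

from .chains import build_table, estimate_matrix, stationary, stationary_table
from .effects import INTRA_SITE, compare
from .loglinear import enumerate_models, fit_model, select_models
from .synthetic import simulate_transition_records, uniform_transition_params

CONTROL_MATRIX = np.array([[0.9, 0.1], [0.4, 0.6]])
PRESSURE_MATRIX = np.array([[0.75, 0.25], [0.55, 0.45]])


def scenario_params(name: str) -> tuple[dict, str]:
    """Transition parameters and generating-model label for a named scenario.

    ``null``: pressure dynamics identical to control (generating model Null).
    ``midday_time_chain``: pressure differs from control at midday only
    (generating model Time x Chain).
    ``additive_chain``: pressure differs identically in all time categories
    (generating model Chain).
    """
    control = {"cohesion": CONTROL_MATRIX}
    if name == "null":
        return uniform_transition_params(control), "Null"
    if name == "additive_chain":
        return (
            uniform_transition_params(control, {"cohesion": PRESSURE_MATRIX}),
            "Chain",
        )
    if name == "midday_time_chain":
        return (
            uniform_transition_params(
                control,
                overrides={("cohesion", "midday", "pressure"): PRESSURE_MATRIX},
            ),
            "Time × Chain",
        )
    raise ValueError(f"unknown scenario {name!r}")


def stationary_solver_agreement(
    n_matrices: int, rng: np.random.Generator
) -> float:
    """Max |solver - closed form| over random irreducible 2-state matrices."""
    worst = 0.0
    for _ in range(n_matrices):
        p01, p10 = rng.uniform(0.001, 0.999, size=2)
        P = np.array([[1 - p01, p01], [p10, 1 - p10]])
        pi = stationary(P)
        closed = np.array([p10, p01]) / (p01 + p10)
        worst = max(worst, float(np.max(np.abs(pi - closed))))
    return worst


def model_recovery_study(
    scenario: str,
    n_replicates: int,
    transitions_per_chain: int,
    rng: np.random.Generator,
) -> float:
    """Fraction of replicates whose supported set contains the generator.

    Each replicate draws ``transitions_per_chain`` transitions per chain
    (split over the three time categories), builds the 4-way table
    (preceding, succeeding, chain, time), fits the full hierarchical family
    over {time, chain} and applies the delta-AIC <= 2 support rule.
    """
    params, truth = scenario_params(scenario)
    n_per_cell = max(transitions_per_chain // 3, 1)
    specs = enumerate_models(["chain", "time_category"])
    hits = 0
    for _ in range(n_replicates):
        recs = simulate_transition_records(params, "cohesion", n_per_cell, rng)
        tab = build_table(recs, ["preceding", "succeeding", "chain", "time_category"])
        fits = [fit_model(tab, s) for s in specs]
        sel = select_models(fits)
        if truth in {f.label for f, _ in sel.supported}:
            hits += 1
    return hits / n_replicates


def ztest_type1_study(
    n_replicates: int,
    transitions_per_chain: int,
    rng: np.random.Generator,
    alpha: float = 0.05,
) -> float:
    """Empirical rejection rate of the z-test under the no-effect null.

    Both chains share the memoryless matrix [[0.7, 0.3], [0.7, 0.3]]; each
    replicate estimates both stationary proportions and runs the pooled
    z-test with n = supporting transitions.
    """
    from .effects import two_proportion_z
    from .errors import DegenerateTestError

    params = uniform_transition_params(
        {"cohesion": np.array([[0.7, 0.3], [0.7, 0.3]])}
    )
    rejections = 0
    for _ in range(n_replicates):
        recs = simulate_transition_records(
            params, "cohesion", transitions_per_chain, rng,
            time_categories=("midday",),
        )
        pis = {}
        for chain, grp in recs.groupby("chain"):
            pis[chain] = (float(stationary(estimate_matrix(grp))[0]), len(grp))
        try:
            _, p = two_proportion_z(
                pis["pressure"][0], pis["pressure"][1],
                pis["control"][0], pis["control"][1],
            )
        except DegenerateTestError:
            continue
        rejections += p < alpha
    return rejections / n_replicates


def midday_localization_study(
    transitions_per_cell: int, rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    """Effect recovery for a midday-only pressure effect on tight cohesion.

    Returns per time category the Cohen's h, p-value and true h implied by
    the configured matrices.
    """
    params, _ = scenario_params("midday_time_chain")
    recs = simulate_transition_records(params, "cohesion", transitions_per_cell, rng)
    stat = stationary_table(recs)
    out = {}
    from .effects import cohens_h

    for r in compare(INTRA_SITE, stat):
        key = (
            "cohesion",
            r.time_category,
        )
        m_c = params[("cohesion", r.time_category, "control")]
        m_p = params[("cohesion", r.time_category, "pressure")]
        pi_c = m_c[1, 0] / (m_c[0, 1] + m_c[1, 0])
        pi_p = m_p[1, 0] / (m_p[0, 1] + m_p[1, 0])
        out[r.time_category] = {
            "h": r.h,
            "p_value": r.p_value,
            "true_h": cohens_h(pi_p, pi_c),
        }
    return out
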