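"""Log-linear engine: IPF fits, G2/AIC mechanics, model enumeration/selection.

The independent oracle for the fitting engine is a Poisson GLM (statsmodels)
with the same hierarchical design: for log-linear models its deviance equals
the goodness-of-fit G2, computed by direct likelihood maximization rather
than proportional scaling.
"""

import itertools

import numpy as np
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from behavchain.chains import ContingencyTable
from behavchain.errors import SelectionError, ValidationError
from behavchain.loglinear import (
    ModelFit,
    ModelSpec,
    aic,
    enumerate_models,
    fit_loglinear,
    fit_model,
    select_models,
    selection_report,
)


def _table(counts, factors=None):
    counts = np.asarray(counts)
    factors = factors or ["preceding", "succeeding", "chain"][: counts.ndim]
    levels = {
        f: [f"{f}{i}" for i in range(counts.shape[ax])]
        for ax, f in enumerate(factors)
    }
    if "preceding" in factors:
        levels["preceding"] = ["tight", "loose"][: counts.shape[factors.index("preceding")]]
    if "succeeding" in factors:
        levels["succeeding"] = ["tight", "loose"][: counts.shape[factors.index("succeeding")]]
    return ContingencyTable(factors=factors, levels=levels, counts=counts)


def glm_g_squared(table: ContingencyTable, generators) -> float:
    """Deviance of the equivalent Poisson log-linear model (the oracle)."""
    long = table.to_long()
    closure = set()
    for g in generators:
        for r in range(1, len(g) + 1):
            for sub in itertools.combinations(sorted(g), r):
                closure.add(sub)
    terms = [":".join(f"C({f})" for f in sub) for sub in sorted(closure)]
    formula = "count ~ " + " + ".join(terms)
    fit = smf.glm(formula, data=long, family=sm.families.Poisson()).fit()
    return float(fit.deviance)


class TestEnumerateModels:
    def test_two_factor_family(self):
        specs = enumerate_models(["chain", "time_category"])
        labels = {s.label for s in specs}
        assert labels == {"Null", "Chain", "Time", "Time + Chain", "Time × Chain"}

    def test_three_factor_family_contains_paper_labels(self):
        specs = enumerate_models(["chain", "time_category", "site"])
        labels = {s.label for s in specs}
        for expected in (
            "Null",
            "Chain",
            "Location + Chain",
            "Location × Chain",
            "Time × Chain + Time × Location",
        ):
            assert expected in labels

    def test_terms_form_antichain(self):
        for s in enumerate_models(["chain", "time_category", "season"]):
            for a, b in itertools.combinations(s.effect_terms, 2):
                assert not set(a) <= set(b) and not set(b) <= set(a)

    def test_requires_chain_factor(self):
        with pytest.raises(ValidationError):
            enumerate_models(["time_category"])


class TestFitEngine:
    def test_independence_closed_form(self):
        tab = _table([[10, 20], [30, 40]], ["preceding", "succeeding"])
        fit = fit_loglinear(tab, [("preceding",), ("succeeding",)], label="indep")
        np.testing.assert_allclose(fit.fitted, [[12, 18], [28, 42]], atol=1e-8)
        assert fit.g_squared == pytest.approx(0.80435, abs=1e-4)
        assert fit.df == 1

    def test_saturated_reproduces_observed(self):
        rng = np.random.default_rng(0)
        tab = _table(rng.integers(1, 9, size=(2, 2, 2)))
        fit = fit_loglinear(
            tab, [("preceding", "succeeding", "chain")], label="saturated"
        )
        np.testing.assert_allclose(fit.fitted, tab.counts, atol=1e-8)
        assert fit.g_squared == pytest.approx(0.0, abs=1e-10)
        assert fit.df == 0

    def test_margins_preserved_on_five_way_table(self, small_study):
        from behavchain.chains import build_table, extract_all_transitions

        _, follows, _ = small_study
        recs = extract_all_transitions(follows, indicators=["formation"])
        tab = build_table(
            recs, ["preceding", "succeeding", "chain", "site", "time_category"]
        )
        spec = ModelSpec(
            conditioning=("chain", "site", "time_category"),
            effect_terms=(("time_category", "chain"),),
        )
        fit = fit_model(tab, spec)
        assert fit.converged
        for g in spec.generators():
            axes = tuple(i for i, f in enumerate(tab.factors) if f not in g)
            np.testing.assert_allclose(
                fit.fitted.sum(axis=axes),
                tab.counts.sum(axis=axes).astype(float),
                atol=1e-8,
            )

    def test_agrees_with_glm_oracle_on_random_tables(self):
        rng = np.random.default_rng(7)
        gen_sets = [
            [("preceding", "succeeding"), ("chain",)],
            [("preceding", "succeeding"), ("preceding", "chain")],
            [("preceding", "chain"), ("succeeding", "chain")],
        ]
        for _ in range(10):
            tab = _table(rng.integers(1, 6, size=(2, 2, 2)))
            for gens in gen_sets:
                fit = fit_loglinear(tab, gens)
                assert fit.converged
                assert fit.g_squared == pytest.approx(
                    glm_g_squared(tab, gens), abs=1e-6
                )

    def test_g2_monotone_under_nesting(self):
        rng = np.random.default_rng(11)
        cond = ("chain", "time_category")
        nested = [
            ModelSpec(cond, ()),
            ModelSpec(cond, (("chain",),)),
            ModelSpec(cond, (("chain",), ("time_category",))),
            ModelSpec(cond, (("time_category", "chain"),)),
        ]
        for _ in range(5):
            tab = _table(
                rng.integers(1, 30, size=(2, 2, 2, 3)),
                ["preceding", "succeeding", "chain", "time_category"],
            )
            g2s = [fit_model(tab, s).g_squared for s in nested]
            assert all(a >= b - 1e-8 for a, b in zip(g2s, g2s[1:]))

    def test_zero_margin_cells_forced_to_zero(self):
        counts = np.array([[[5, 0], [3, 0]], [[2, 0], [4, 0]]])  # chain1 empty
        tab = _table(counts)
        fit = fit_loglinear(tab, [("preceding", "succeeding"), ("chain",)])
        assert np.all(fit.fitted[:, :, 1] == 0)
        assert fit.n_forced_zero == 4
        assert fit.df == max(4 - fit.n_forced_zero - 0, 0) or fit.df >= 0

    def test_unknown_generator_factor(self):
        tab = _table([[1, 2], [3, 4]], ["preceding", "succeeding"])
        with pytest.raises(ValidationError):
            fit_loglinear(tab, [("preceding", "observer")])


class TestAicMechanics:
    def test_worked_independence_example(self):
        tab = _table([[10, 20], [30, 40]], ["preceding", "succeeding"])
        fit = fit_loglinear(tab, [("preceding",), ("succeeding",)])
        assert aic(fit) == pytest.approx(-1.1957, abs=1e-3)

    def test_saturated_scores_zero(self):
        tab = _table([[10, 20], [30, 40]], ["preceding", "succeeding"])
        fit = fit_loglinear(tab, [("preceding", "succeeding")])
        assert aic(fit) == pytest.approx(0.0, abs=1e-10)

    def test_arithmetic(self):
        f = ModelFit("m", None, np.zeros(1), g_squared=10.0, df=4,
                     converged=True, iterations=1)
        assert aic(f) == pytest.approx(2.0)


class TestSelectModels:
    def _fit(self, label, a, n_terms=0):
        spec = ModelSpec(("chain",), tuple([("chain",)] * 0))
        f = ModelFit(label, None, np.zeros(1), g_squared=a, df=0,
                     converged=True, iterations=1)
        return f

    def test_delta_aic_support_rule(self):
        # AICs -36.96 and -35.13: both fall inside the 2-unit window,
        # so the runner-up is supported with delta AIC 1.83
        fits = [self._fit("Location + Chain", -36.96),
                self._fit("Location × Chain", -35.13)]
        sel = select_models(fits)
        assert sel.best.label == "Location + Chain"
        assert len(sel.supported) == 2
        assert sel.supported[1][1] == pytest.approx(1.83, abs=1e-9)

    def test_outside_two_units_not_supported(self):
        fits = [self._fit("A", 0.0), self._fit("B", 2.5)]
        sel = select_models(fits)
        assert [f.label for f, _ in sel.supported] == ["A"]

    def test_single_fit_is_best_and_sole_supported(self):
        (only,) = [self._fit("A", 1.0)]
        sel = select_models([only])
        assert sel.best is only and len(sel.supported) == 1

    def test_no_converged_fits(self):
        f = self._fit("A", 0.0)
        f.converged = False
        with pytest.raises(SelectionError):
            select_models([f])

    def test_report_orders_by_aic(self):
        fits = [self._fit("B", 3.0), self._fit("A", -1.0)]
        rep = selection_report(fits)
        assert rep["model"].tolist() == ["A", "B"]
        assert rep["supported"].tolist() == [True, False]


def test_generative_recovery_single_replicate():
    """A strong time-by-chain interaction is recovered in one big sample."""
    from behavchain.chains import build_table
    from behavchain.synthetic import (
        simulate_transition_records,
        uniform_transition_params,
    )

    params = uniform_transition_params(
        {"cohesion": np.array([[0.9, 0.1], [0.4, 0.6]])},
        overrides={
            ("cohesion", "midday", "pressure"): np.array([[0.6, 0.4], [0.6, 0.4]])
        },
    )
    rng = np.random.default_rng(123)
    recs = simulate_transition_records(params, "cohesion", 2000, rng)
    tab = build_table(recs, ["preceding", "succeeding", "chain", "time_category"])
    fits = [fit_model(tab, s) for s in enumerate_models(["chain", "time_category"])]
    sel = select_models(fits)
    assert "Time × Chain" in {f.label for f, _ in sel.supported}
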