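"""Transition extraction, chain-order BIC, tables, matrices, stationary laws."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from behavchain.chains import (
    build_table,
    estimate_matrix,
    extract_transitions,
    select_order,
    stationary,
    stationary_table,
)
from behavchain.errors import DegeneracyError, EstimationError, ValidationError
from conftest import make_follow


def _records(pairs, indicator="cohesion", **labels):
    states = {"cohesion": ("tight", "loose")}[indicator]
    rows = []
    for a, b in pairs:
        rows.append(
            {
                "indicator": indicator,
                "preceding": states[a],
                "succeeding": states[b],
                "chain": labels.get("chain", "control"),
                "site": labels.get("site", "siteA"),
                "season": labels.get("season", "S1"),
                "time_category": labels.get("time_category", "midday"),
            }
        )
    return pd.DataFrame(rows)


class TestExtractTransitions:
    def test_strict_washout_censors_follow_start(self):
        # 7 pressure-free scans span 0-15 min: only the transition whose
        # succeeding scan is >= 15 min after the follow start can certify the
        # washout -> exactly 1 control transition; with 8 scans, 2.
        for n_scans, expected in [(7, 1), (8, 2)]:
            f = make_follow(n_scans=n_scans)
            out = extract_transitions(f, "cohesion")
            assert len(out) == expected
            assert (out["chain"] == "control").all()

    def test_all_pressure_all_in_pressure_chain(self):
        f = make_follow(n_scans=7, pressure_idx=list(range(7)))
        out = extract_transitions(f, "cohesion")
        assert len(out) == 6
        assert (out["chain"] == "pressure").all()

    def test_recent_pressure_excluded_from_both_chains(self):
        # pressure ends at scan 2; the transition 5 min later is inside the
        # washout -> excluded from both chains
        f = make_follow(n_scans=30, pressure_idx=[0, 1, 2])
        out = extract_transitions(f, "cohesion")
        t = f.scans["t_s"].to_numpy()
        washout_end = t[2] + 15 * 60
        # control only where the whole washout window is past the last
        # pressure scan; pairs touching pressure (into scans 1,2,3) are the
        # pressure chain; the 5 pairs in between are excluded entirely
        assert len(out[out["chain"] == "control"]) == np.sum(t > washout_end)
        assert len(out[out["chain"] == "pressure"]) == 3
        assert len(out) == 24 and len(f) - 1 == 29

    def test_partition_property(self, small_study):
        # every eligible pair is pressure, control, or excluded - no overlap
        _, follows, _ = small_study
        for f in follows[:3]:
            scans = f.scans
            eligible = 0
            for i in range(len(scans) - 1):
                if scans["cohesion"].iloc[i] != "" and scans["cohesion"].iloc[i + 1] != "":
                    eligible += 1
            out = extract_transitions(f, "cohesion")
            assert len(out) <= eligible
            assert set(out["chain"]) <= {"control", "pressure"}

    def test_blank_endpoint_breaks_adjacency(self):
        f = make_follow(n_scans=20, cohesion=["tight"] * 10 + [""] + ["tight"] * 9)
        out = extract_transitions(f, "cohesion", washout_minutes=0)
        # 19 pairs, 2 touch the blank scan
        assert len(out) == 17

    def test_unknown_indicator(self):
        with pytest.raises(ValidationError):
            extract_transitions(make_follow(n_scans=5), "posture")

    def test_pressure_endpoint_conventions(self):
        f = make_follow(n_scans=12, pressure_idx=[5])
        either = extract_transitions(f, "cohesion", pressure_endpoint="either")
        both = extract_transitions(f, "cohesion", pressure_endpoint="both")
        succ = extract_transitions(f, "cohesion", pressure_endpoint="succeeding")
        assert (either["chain"] == "pressure").sum() == 2  # into and out of scan 5
        assert (both["chain"] == "pressure").sum() == 0
        assert (succ["chain"] == "pressure").sum() == 1

    def test_time_category_follows_succeeding_scan(self):
        cats = ["morning"] * 6 + ["midday"] * 6
        f = make_follow(n_scans=12, time_cat=cats, pressure_idx=list(range(12)))
        out = extract_transitions(f, "cohesion")
        # the transition straddling the boundary takes the succeeding category
        straddle = out.iloc[5]
        assert straddle["time_category"] == "midday"


class TestSelectOrder:
    def test_iid_sequence_prefers_order_zero(self):
        rng = np.random.default_rng(0)
        seq = rng.integers(0, 2, size=1001)
        recs = _records(list(zip(seq[:-1], seq[1:])))
        sel = select_order(recs)
        assert sel.order == 0
        assert sel.bic0 < sel.bic1

    def test_sticky_sequence_prefers_order_one(self):
        rng = np.random.default_rng(1)
        seq = [0]
        for _ in range(1000):
            seq.append(seq[-1] if rng.random() < 0.95 else 1 - seq[-1])
        recs = _records(list(zip(seq[:-1], seq[1:])))
        sel = select_order(recs)
        assert sel.order == 1
        assert sel.bic1 < sel.bic0

    def test_minimal_two_records(self):
        recs = _records([(0, 1), (1, 0)])
        sel = select_order(recs)
        assert np.isfinite(sel.bic0) and np.isfinite(sel.bic1)

    def test_constant_succeeding_degenerate(self):
        recs = _records([(0, 0)] * 10)
        sel = select_order(recs)
        assert sel.degenerate and sel.order == 0


class TestBuildTable:
    def test_two_way_sums_to_n(self):
        recs = _records([(0, 0)] * 4 + [(0, 1)] * 3 + [(1, 0)] * 2 + [(1, 1)])
        tab = build_table(recs, ["preceding", "succeeding"])
        assert tab.total == 10
        assert tab.counts.tolist() == [[4, 3], [2, 1]]

    def test_full_factor_table_conserves_total(self, small_study):
        from behavchain.chains import extract_all_transitions

        _, follows, _ = small_study
        recs = extract_all_transitions(follows, indicators=["cohesion"])
        tab = build_table(
            recs, ["preceding", "succeeding", "chain", "site", "time_category"]
        )
        assert tab.total == len(recs)

    def test_cell_matches_brute_force_filter(self, small_study):
        from behavchain.chains import extract_all_transitions

        _, follows, _ = small_study
        recs = extract_all_transitions(follows, indicators=["cohesion"])
        factors = ["preceding", "succeeding", "chain", "site", "time_category"]
        tab = build_table(recs, factors)
        cell = {
            "preceding": "tight",
            "succeeding": "tight",
            "chain": "pressure",
            "site": "lagoon_a",
            "time_category": "midday",
        }
        idx = tuple(tab.levels[f].index(cell[f]) for f in factors)
        brute = len(
            recs[np.logical_and.reduce([recs[f] == v for f, v in cell.items()])]
        )
        assert tab.counts[idx] == brute

    def test_missing_factor_rejected(self):
        recs = _records([(0, 1)] * 3)
        with pytest.raises(ValidationError):
            build_table(recs, ["preceding", "succeeding", "observer"])
        with pytest.raises(ValidationError):
            build_table(recs, ["succeeding", "chain"])


class TestEstimateMatrix:
    def test_row_normalization(self):
        recs = _records([(0, 0)] * 9 + [(0, 1)] + [(1, 0)] * 5 + [(1, 1)] * 5)
        tm = estimate_matrix(recs)
        np.testing.assert_allclose(tm.probabilities, [[0.9, 0.1], [0.5, 0.5]])
        assert tm.row_counts.tolist() == [10, 10]

    def test_identity_counts_flagged_reducible(self):
        recs = _records([(0, 0)] * 3 + [(1, 1)] * 3)
        tm = estimate_matrix(recs)
        np.testing.assert_allclose(tm.probabilities, np.eye(2))
        assert tm.reducible

    def test_unobserved_preceding_state_raises(self):
        recs = _records([(0, 0)] * 5)
        with pytest.raises(EstimationError, match="loose"):
            estimate_matrix(recs)


class TestStationary:
    @pytest.mark.parametrize(
        "matrix, expected",
        [
            ([[0.9, 0.1], [0.5, 0.5]], [5 / 6, 1 / 6]),
            ([[0.5, 0.5], [0.5, 0.5]], [0.5, 0.5]),
            ([[0.3, 0.7], [0.2, 0.8]], [2 / 9, 7 / 9]),
        ],
    )
    def test_closed_form_two_state(self, matrix, expected):
        np.testing.assert_allclose(stationary(np.array(matrix)), expected, atol=1e-12)

    @pytest.mark.parametrize(
        "matrix", [np.eye(2), [[1.0, 0.0], [0.5, 0.5]], [[0.0, 1.0], [1.0, 0.0]]]
    )
    def test_degenerate_matrices_raise(self, matrix):
        with pytest.raises(DegeneracyError):
            stationary(np.array(matrix))

    def test_fixed_point_property_random(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            p = rng.uniform(0.01, 0.99, size=2)
            P = np.array([[1 - p[0], p[0]], [p[1], 1 - p[1]]])
            pi = stationary(P)
            np.testing.assert_allclose(pi @ P, pi, atol=1e-12)
            closed = np.array([p[1], p[0]]) / (p[0] + p[1])
            np.testing.assert_allclose(pi, closed, atol=1e-12)

    def test_three_state_chain(self):
        P = np.array([[0.5, 0.25, 0.25], [0.2, 0.6, 0.2], [0.3, 0.3, 0.4]])
        pi = stationary(P)
        np.testing.assert_allclose(pi @ P, pi, atol=1e-12)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    @given(
        st.floats(min_value=0.01, max_value=0.99),
        st.floats(min_value=0.01, max_value=0.99),
    )
    @settings(deadline=None, max_examples=50)
    def test_matches_closed_form_property(self, p01, p10):
        P = np.array([[1 - p01, p01], [p10, 1 - p10]])
        pi = stationary(P)
        np.testing.assert_allclose(pi, [p10 / (p01 + p10), p01 / (p01 + p10)], atol=1e-12)


def test_estimated_stationary_converges_to_truth():
    """Error of the estimated stationary distribution shrinks like 1/sqrt(n)."""
    from behavchain.synthetic import simulate_transition_records, uniform_transition_params

    params = uniform_transition_params(
        {"cohesion": np.array([[0.9, 0.1], [0.4, 0.6]])}
    )
    errs = []
    for n, seed in [(500, 3), (50000, 4)]:
        rng = np.random.default_rng(seed)
        recs = simulate_transition_records(
            params, "cohesion", n, rng, time_categories=("midday",),
            conditions=("control",),
        )
        pi = stationary(estimate_matrix(recs))
        errs.append(abs(pi[0] - 0.8))
    assert errs[1] < errs[0]
    assert errs[1] < 0.01


def test_stationary_table_shape(small_study):
    from behavchain.chains import extract_all_transitions

    _, follows, _ = small_study
    recs = extract_all_transitions(follows)
    stat = stationary_table(recs)
    assert {"indicator", "chain", "site", "p_state0", "n_transitions"} <= set(
        stat.columns
    )
    np.testing.assert_allclose(
        stat["p_state0"] + stat["p_state1"], 1.0, atol=1e-12
    )
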