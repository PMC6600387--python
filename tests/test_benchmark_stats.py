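"""Selection criteria: precision, generality, robustness, profiling, tests."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from covbench import benchmark_stats as bs
from covbench.reference import load_reference_medians


def _frame(rows):
    return pd.DataFrame(rows, columns=[
        "tool_id", "entry_id", "warhead_class", "receptor_type",
        "uniprot_id", "s1", "s2"])


class TestPrecision:
    @pytest.mark.parametrize("axis,column,expected", [
        ("warhead_class", "best_scored_MOE", 1.94),
        ("warhead_class", "best_sampled_CovDock", 1.33),
        ("receptor_type", "best_scored_CovDock", 1.71),
        ("receptor_type", "best_sampled_GOLD", 1.17),
    ])
    def test_reference_outer_medians(self, axis, column, expected):
        """The published per-class medians reproduce the published overall
        precision for each tool/measurement."""
        table = load_reference_medians(axis)
        assert bs.outer_median(table[column]) == pytest.approx(expected)

    def test_singleton_class(self):
        frame = _frame([("A", "e1", "Nitrile(cys)", "Hydrolase", "P1",
                         1.7, 1.1)])
        medians, p = bs.precision(frame, bs.GroupingSpec(), "best_scored")
        assert p == pytest.approx(1.7)
        assert medians.to_dict() == {"Nitrile(cys)": 1.7}

    def test_even_class_count_uses_midpoint(self):
        rows = [("A", f"e{i}", c, "Hydrolase", "P1", v, v)
                for i, (c, v) in enumerate(
                    [("w1", 1.0), ("w2", 2.0), ("w3", 4.0), ("w4", 8.0)])]
        _, p = bs.precision(_frame(rows), bs.GroupingSpec(), "best_scored")
        assert p == pytest.approx(3.0)

    def test_best_sampled_never_exceeds_best_scored(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(60):
            s2 = rng.uniform(0.3, 3.0)
            s1 = s2 + rng.uniform(0, 2.0)
            rows.append(("A", f"e{i}", f"w{i % 5}", "Hydrolase", "P1",
                         s1, s2))
        frame = _frame(rows)
        _, p_scored = bs.precision(frame, bs.GroupingSpec(), "best_scored")
        _, p_sampled = bs.precision(frame, bs.GroupingSpec(), "best_sampled")
        assert p_sampled <= p_scored


class TestGenerality:
    def _two_tool_frame(self, winners):
        # 3 subgroups within one class; `winners` plants the per-subgroup
        # minimum
        rows = []
        for g, winner in enumerate(winners):
            for tool in ("A", "B"):
                val = 1.0 if tool == winner else 2.0
                for k in range(2):
                    rows.append((tool, f"e{g}{k}", "w", "Hydrolase",
                                 f"P{g}", val, val))
        return _frame(rows)

    def test_planted_winner_marks(self):
        out = bs.generality(self._two_tool_frame("AAB"), bs.GroupingSpec())
        marks = dict(zip(out.tool_id, out.marks))
        assert marks == {"A": 2, "B": 1}

    def test_single_tool_wins_every_subgroup(self):
        frame = self._two_tool_frame("AAA")
        frame = frame[frame.tool_id == "A"]
        out = bs.generality(frame, bs.GroupingSpec())
        assert out.marks.tolist() == [3]

    def test_exact_tie_marks_both(self):
        rows = []
        for tool in ("A", "B"):
            rows.append((tool, "e1", "w", "Hydrolase", "P1", 1.5, 1.5))
        out = bs.generality(_frame(rows), bs.GroupingSpec())
        assert out.marks.sum() >= 1
        assert out.marks.tolist() == [1, 1]

    def test_disjoint_entry_sets_rejected(self):
        rows = [("A", "e1", "w", "Hydrolase", "P1", 1.0, 1.0),
                ("B", "e2", "w", "Hydrolase", "P1", 2.0, 2.0)]
        with pytest.raises(ValueError, match="different entry sets"):
            bs.generality(_frame(rows), bs.GroupingSpec())

    def test_every_subgroup_awards_a_mark(self):
        rng = np.random.default_rng(0)
        rows = []
        for g in range(6):
            for tool in ("A", "B", "C"):
                rows.append((tool, f"e{g}", f"w{g % 2}", "Hydrolase",
                             f"P{g}", rng.uniform(0.5, 4), 1.0))
        out = bs.generality(_frame(rows), bs.GroupingSpec())
        assert out.marks.sum() >= 6


class TestRobustness:
    def test_constant_values(self):
        frame = _frame([("A", f"e{i}", "w", "H", "P", 2.0, 1.0)
                        for i in range(5)])
        assert bs.robustness(frame) == pytest.approx(0.0)

    def test_two_point_closed_form(self):
        frame = _frame([("A", "e1", "w", "H", "P", 1.0, 1.0),
                        ("A", "e2", "w", "H", "P", 3.0, 1.0)])
        assert bs.robustness(frame) == pytest.approx(np.sqrt(2.0))

    def test_gaussian_recovery(self):
        rng = np.random.default_rng(123)
        vals = rng.normal(2.0, 0.5, size=500)
        frame = _frame([("A", f"e{i}", "w", "H", "P", abs(v), 0.5)
                        for i, v in enumerate(vals)])
        assert bs.robustness(frame) == pytest.approx(0.5, rel=0.10)

    def test_single_result_rejected(self):
        frame = _frame([("A", "e1", "w", "H", "P", 1.0, 1.0)])
        with pytest.raises(ValueError):
            bs.robustness(frame)


class TestProfile:
    def test_exclusive_and_shared_successes(self):
        tau = 2.0
        rows = [
            # e1: only A succeeds; e2: both succeed; e3: both fail
            ("A", "e1", "w", "H", "P", 1.0, 1.0),
            ("B", "e1", "w", "H", "P", 3.0, 2.5),
            ("A", "e2", "w", "H", "P", 1.5, 1.0),
            ("B", "e2", "w", "H", "P", 1.8, 1.2),
            ("A", "e3", "w", "H", "P", 4.0, 3.0),
            ("B", "e3", "w", "H", "P", 5.0, 4.0),
        ]
        out = bs.profile(_frame(rows), tau).set_index("tool_id")
        assert out.loc["A", "s_only"] == 1
        assert out.loc["A", "s_ge2"] == 1
        assert out.loc["B", "s_only"] == 0
        assert out.loc["B", "s_ge2"] == 1
        assert out.loc["A", "f_ge2"] == 1 and out.loc["B", "f_ge2"] == 1
        assert out.loc["B", "f_only"] == 1   # e1: only B fails

    def test_random_matrix_matches_brute_force(self):
        rng = np.random.default_rng(77)
        tools = ["A", "B", "C", "D"]
        n_entries = 50
        succ = rng.random((4, n_entries)) < 0.5
        fail = (~succ) & (rng.random((4, n_entries)) < 0.7)
        rows = []
        for t, tool in enumerate(tools):
            for e in range(n_entries):
                if succ[t, e]:
                    s1 = 1.0
                    s2 = 0.5
                elif fail[t, e]:
                    s1, s2 = 4.0, 3.0
                else:
                    s1, s2 = 4.0, 1.0    # scored miss, sampler hit
                rows.append((tool, f"e{e}", "w", "H", "P", s1, s2))
        out = bs.profile(_frame(rows), 2.0).set_index("tool_id")
        for t, tool in enumerate(tools):
            others = [o for o in range(4) if o != t]
            s_only = sum(succ[t, e] and not any(succ[o, e] for o in others)
                         for e in range(n_entries))
            s_ge2 = sum(succ[t, e] and any(succ[o, e] for o in others)
                        for e in range(n_entries))
            f_only = sum(fail[t, e] and not any(fail[o, e] for o in others)
                         for e in range(n_entries))
            f_ge2 = sum(fail[t, e] and any(fail[o, e] for o in others)
                        for e in range(n_entries))
            assert out.loc[tool, "s_only"] == s_only
            assert out.loc[tool, "s_ge2"] == s_ge2
            assert out.loc[tool, "f_only"] == f_only
            assert out.loc[tool, "f_ge2"] == f_ge2
            assert out.loc[tool, "s_count"] == succ[t].sum()
            assert out.loc[tool, "f_count"] == fail[t].sum()

    def test_s_only_charged_to_at_most_one_tool(self):
        rng = np.random.default_rng(5)
        rows = []
        for e in range(30):
            for tool in ("A", "B", "C"):
                s1 = rng.choice([1.0, 4.0])
                rows.append((tool, f"e{e}", "w", "H", "P", s1, s1 - 0.5))
        out = bs.profile(_frame(rows), 2.0)
        assert out["s_only"].sum() <= 30

    def test_single_tool_rejected(self):
        rows = [("A", "e1", "w", "H", "P", 1.0, 1.0)]
        with pytest.raises(ValueError, match="2 tools"):
            bs.profile(_frame(rows), 2.0)


class TestPDeviation:
    def test_zero_deviations_spike_at_zero(self):
        frame = pd.DataFrame({
            "tool_id": ["A"] * 5, "entry_id": [f"e{i}" for i in range(5)],
            "p_deviation": [0.0] * 5})
        hist = bs.p_deviation_distribution(frame)
        assert hist["count"].sum() == 5
        assert hist.loc[hist["count"] > 0, "bin_low"].tolist() == [0.0]

    def test_bimodal_modes_recovered(self):
        rng = np.random.default_rng(10)
        dev = np.concatenate([rng.normal(2.0, 0.1, 100),
                              rng.normal(4.5, 0.1, 100)])
        frame = pd.DataFrame({
            "tool_id": ["A"] * 200,
            "entry_id": [f"e{i}" for i in range(200)],
            "p_deviation": np.abs(dev)})
        hist = bs.p_deviation_distribution(frame, bin_width=0.5)
        top2 = hist.nlargest(2, "count")["bin_low"].tolist()
        assert sorted(top2) == [1.5, 4.0] or sorted(top2) == [2.0, 4.5] \
            or (1.5 <= min(top2) <= 2.0 and 4.0 <= max(top2) <= 4.5)
        assert hist["count"].sum() == 200


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        with pytest.warns(UserWarning):
            u, p = bs.compare_tools([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0

    def test_fully_separated_samples(self):
        u, p = bs.compare_tools([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        # exact two-sided minimum for n=m=3: 2 / C(6,3) = 0.1
        assert p == pytest.approx(0.1, abs=1e-9)

    def test_power_under_two_sigma_shift(self):
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.normal(2.0, 0.5, 100)
            b = rng.normal(3.0, 0.5, 100)     # 2 sigma shift
            _, p = bs.compare_tools(a, b)
            hits += p < 0.05
        assert hits / n_rep >= 0.95

    def test_holm_adjustment_monotone(self):
        p = [0.01, 0.04, 0.03, 0.20]
        adj = bs.holm_adjust(p)
        assert all(a >= raw for a, raw in zip(adj, p))
        assert adj[0] == pytest.approx(0.04)


class TestHeatmap:
    def test_clamping_and_midpoint(self):
        medians = pd.DataFrame({"T": [0.5, 6.0, 3.0]},
                               index=["w1", "w2", "w3"])
        matrix, colors = bs.heatmap_table(medians)
        deep_green, deep_red = "#006400", "#8B0000"
        assert colors.loc["w1", "T"] == deep_green
        assert colors.loc["w2", "T"] == deep_red
        mid = colors.loc["w3", "T"]
        r, g, b = (int(mid[i:i + 2], 16) for i in (1, 3, 5))
        assert r == round((0 + 139) / 2) and g == round((100 + 0) / 2)
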