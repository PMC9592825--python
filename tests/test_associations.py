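"""Correlations, two-group tests and PC causal discovery oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sstmon.associations import (
    compare_groups,
    correlate_settings,
    pc_causal_graph,
    structural_hamming_distance,
)
from sstmon.errors import InsufficientDataError


def _frame(n=50, seed=0, link=0.0):
    rng = np.random.default_rng(seed)
    idx = [f"run{i}" for i in range(n)]
    ind = pd.Series(rng.standard_normal(n), index=idx, name="s2n")
    settings = pd.DataFrame(
        {
            "linked": link * ind.to_numpy() + 0.3 * rng.standard_normal(n),
            "noise": rng.standard_normal(n),
            "flat": np.full(n, 3.0),
        },
        index=idx,
    )
    return settings, ind


class TestCorrelateSettings:
    def test_planted_link_significant_after_bonferroni(self):
        settings, ind = _frame(n=50, seed=1, link=1.0)  # r ~ 0.95
        table = correlate_settings(settings, ind)
        row = table[table.setting == "linked"].iloc[0]
        assert abs(row.pearson_r) > 0.8
        assert row.p_bonferroni < 0.05 and row.significant

    def test_independent_setting_not_significant(self):
        settings, ind = _frame(n=50, seed=2)
        row = correlate_settings(settings, ind).set_index("setting").loc["noise"]
        assert abs(row.pearson_r) < 0.35
        assert not row.significant

    def test_constant_setting_excluded(self):
        settings, ind = _frame()
        table = correlate_settings(settings, ind)
        assert "flat" not in set(table.setting)
        assert table.attrs["excluded"] == ["flat"]

    def test_bonferroni_never_decreases_p(self):
        settings, ind = _frame(n=30, seed=3, link=0.4)
        table = correlate_settings(settings, ind)
        assert (table.p_bonferroni >= table.p_raw - 1e-15).all()

    def test_too_few_runs_rejected(self):
        settings, ind = _frame(n=4)
        with pytest.raises(InsufficientDataError):
            correlate_settings(settings, ind)


class TestCompareGroups:
    def _groups(self, delta=3.0, n=50, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"run{i}" for i in range(n)]
        ind = pd.Series(np.arange(n, dtype=float), index=idx)  # top 20% = last 10
        high = ind >= np.percentile(ind, 80)
        setting = rng.standard_normal(n)
        setting[high.to_numpy()] += delta
        settings = pd.DataFrame(
            {"shifted": setting, "noise": rng.standard_normal(n)}, index=idx
        )
        return settings, ind

    def test_separated_setting_significant_with_positive_sign(self):
        settings, ind = self._groups(delta=3.0)
        table = compare_groups(settings, ind).set_index("setting")
        row = table.loc["shifted"]
        assert row.significant and row.sign == "+"
        assert row.reported_p == pytest.approx(
            max(row.p_ks, row.p_mwu, row.p_kw)
        )

    def test_identical_distributions_not_significant(self):
        settings, ind = self._groups(delta=0.0, seed=5)
        table = compare_groups(settings, ind).set_index("setting")
        assert not table.loc["shifted"].significant
        assert np.isnan(table.loc["shifted"].reported_p)

    def test_negated_setting_flips_sign_only(self):
        settings, ind = self._groups(delta=3.0)
        a = compare_groups(settings, ind).set_index("setting").loc["shifted"]
        settings["shifted"] = -settings["shifted"]
        b = compare_groups(settings, ind).set_index("setting").loc["shifted"]
        assert a.significant == b.significant
        assert {a.sign, b.sign} == {"+", "-"}
        assert a.p_ks == pytest.approx(b.p_ks)

    def test_equal_medians_give_blank_sign(self):
        idx = [f"run{i}" for i in range(50)]
        ind = pd.Series(np.arange(50, dtype=float), index=idx)
        high = (ind >= np.percentile(ind, 80)).to_numpy()
        # symmetric around 0 in both groups (equal medians), very
        # different spread: KS can fire while the sign stays blank
        vals = np.zeros(50)
        vals[high] = np.resize([-30.0, 30.0], high.sum())
        vals[~high] = np.resize([-0.1, 0.1], (~high).sum())
        settings = pd.DataFrame({"spread": vals}, index=idx)
        table = compare_groups(settings, ind).set_index("setting")
        assert table.loc["spread"].sign == ""

    def test_small_group_rejected(self):
        idx = [f"run{i}" for i in range(8)]
        ind = pd.Series(np.arange(8, dtype=float), index=idx)
        settings = pd.DataFrame({"x": np.ones(8)}, index=idx)
        with pytest.raises(InsufficientDataError):
            compare_groups(settings, ind)


class TestPCAlgorithm:
    def test_chain_skeleton_and_no_shortcut(self):
        """X -> Y -> Z: X and Z separate given Y; no X-Z edge."""
        rng = np.random.default_rng(0)
        n = 2000
        x = rng.standard_normal(n)
        y = 0.8 * x + rng.standard_normal(n)
        z = 0.8 * y + rng.standard_normal(n)
        g = pc_causal_graph(pd.DataFrame({"X": x, "Y": y, "Z": z}), alpha=0.15)
        assert g.skeleton == {frozenset(("X", "Y")), frozenset(("Y", "Z"))}
        assert g.sepsets.get(frozenset(("X", "Z"))) == ("Y",)

    def test_collider_oriented_into_sink(self):
        rng = np.random.default_rng(1)
        n = 2000
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        z = 0.8 * x + 0.8 * y + rng.standard_normal(n)
        g = pc_causal_graph(pd.DataFrame({"X": x, "Y": y, "Z": z}), alpha=0.15)
        assert g.skeleton == {frozenset(("X", "Z")), frozenset(("Y", "Z"))}
        assert g.directed == {("X", "Z"), ("Y", "Z")}

    def test_independent_variables_give_empty_skeleton(self):
        """Null data keeps no edges at a strict alpha; at the liberal
        working alpha of 0.15 the per-pair false-edge rate stays small."""
        rng = np.random.default_rng(0)
        data = pd.DataFrame(
            rng.standard_normal((2000, 4)), columns=list("ABCD")
        )
        g = pc_causal_graph(data, alpha=0.01)
        assert g.skeleton == set()
        edges = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            d = pd.DataFrame(rng.standard_normal((2000, 4)), columns=list("ABCD"))
            edges += len(pc_causal_graph(d, alpha=0.15).skeleton)
        assert edges / 10 < 2.0  # 6 possible pairs per draw

    def test_directed_portion_is_acyclic(self):
        rng = np.random.default_rng(3)
        n = 1000
        a = rng.standard_normal(n)
        b = 0.7 * a + rng.standard_normal(n)
        c = 0.7 * a + 0.7 * b + rng.standard_normal(n)
        d = 0.7 * c + rng.standard_normal(n)
        g = pc_causal_graph(pd.DataFrame({"A": a, "B": b, "C": c, "D": d}))
        import networkx as nx

        dg = nx.DiGraph(list(g.directed))
        assert nx.is_directed_acyclic_graph(dg)
        for a_, b_ in g.directed:
            assert frozenset((a_, b_)) in g.skeleton

    def test_reduced_view_keeps_indicator_edges_only(self):
        rng = np.random.default_rng(4)
        n = 1500
        s1 = rng.standard_normal(n)
        s2 = 0.9 * s1 + rng.standard_normal(n)  # setting-setting edge
        ind = 0.8 * s2 + rng.standard_normal(n)
        g = pc_causal_graph(pd.DataFrame({"s1": s1, "s2": s2, "ind": ind}))
        red = g.reduced({"ind"})
        assert all("ind" in e for e in red.skeleton)

    def test_zero_variance_column_dropped(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(
            {"a": rng.standard_normal(100), "b": rng.standard_normal(100),
             "const": np.ones(100)}
        )
        g = pc_causal_graph(data)
        assert "const" not in g.nodes

    def test_non_finite_data_rejected(self):
        data = pd.DataFrame(np.ones((40, 3)), columns=list("abc"))
        data.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            pc_causal_graph(data)

    def test_too_few_rows_rejected(self):
        data = pd.DataFrame(np.random.default_rng(0).standard_normal((10, 3)))
        with pytest.raises(InsufficientDataError):
            pc_causal_graph(data)

    def test_shd_counts_symmetric_difference(self):
        skel = {frozenset(("a", "b")), frozenset(("b", "c"))}
        true = {frozenset(("a", "b")), frozenset(("c", "d"))}
        assert structural_hamming_distance(skel, true) == 2
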