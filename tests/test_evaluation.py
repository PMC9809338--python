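import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hns.evaluation import (
    degree_lgc_correlation,
    degree_ratio_chisq,
    essentiality_filter,
    f_measure,
    incremental_removal,
    single_node_removal_scan,
)
from hns.graph import degree_profile
from hns.synthetic import generate_score_table

from _oracles import chisq_statistic, precision_recall_f


class TestSingleNodeScan:
    def test_star_leaf_removal_keeps_connectivity(self):
        net = nx.DiGraph((f"H", f"L{i}") for i in range(5))
        scan = single_node_removal_scan(net, {"L1"})
        assert scan.at["L1", "gc_fraction"] == 1.0

    def test_star_hub_removal_fragments(self):
        n = 6
        net = nx.DiGraph(("H", f"L{i}") for i in range(n - 1))
        scan = single_node_removal_scan(net, {"H"})
        assert scan.at["H", "gc_fraction"] == pytest.approx(1 / (n - 1))

    def test_cycle_chord_removal_lengthens_paths(self):
        c6 = nx.cycle_graph(6, create_using=nx.DiGraph)
        scan = single_node_removal_scan(c6, {0})
        # C6: L = (1+2+3+2+1)/5 = 1.8; removing a node leaves a 5-path, L = 2
        assert scan.at["__baseline__", "L"] == pytest.approx(1.8)
        assert scan.at[0, "L"] == pytest.approx(2.0)
        assert scan.at[0, "L"] > scan.at["__baseline__", "L"]

    def test_unknown_node_rejected(self):
        with pytest.raises(ValueError):
            single_node_removal_scan(nx.DiGraph([("A", "B")]), {"Z"})


class TestIncrementalRemoval:
    def test_same_seed_identical(self, disease_net_mini):
        nodes = set(sorted(disease_net_mini.nodes)[:40])
        t1 = incremental_removal(disease_net_mini, nodes, step=5, iterations=8, seed=4)
        t2 = incremental_removal(disease_net_mini, nodes, step=5, iterations=8, seed=4)
        pd.testing.assert_frame_equal(t1.steps, t2.steps)
        assert t1.removed == t2.removed

    def test_final_step_removes_entire_set(self, disease_net_mini):
        nodes = set(sorted(disease_net_mini.nodes)[:20])
        tr = incremental_removal(disease_net_mini, nodes, step=5, iterations=4, seed=1)
        assert tr.steps["n_removed"].iloc[-1] == 20
        assert set(tr.removed) == nodes

    def test_truncation_warns(self, disease_net_mini):
        nodes = set(sorted(disease_net_mini.nodes)[:12])
        with pytest.warns(UserWarning, match="truncating"):
            tr = incremental_removal(disease_net_mini, nodes, step=5, iterations=10, seed=1)
        assert len(tr.steps) == 3  # baseline + 2 feasible steps

    def test_gc_monotone_along_nested_trace(self, disease_net_mini):
        rng = np.random.default_rng(9)
        nodes = sorted(disease_net_mini.nodes)
        for rep in range(5):
            subset = set(rng.choice(nodes, size=50, replace=False))
            tr = incremental_removal(
                disease_net_mini, subset, step=5, iterations=10, seed=rep, compute_l=False
            )
            gc = tr.steps["gc_fraction"].to_numpy()
            assert (np.diff(gc) <= 1e-12).all()

    def test_step_zero_is_baseline(self, disease_net_mini):
        nodes = set(sorted(disease_net_mini.nodes)[:20])
        tr = incremental_removal(disease_net_mini, nodes, step=5, iterations=2, seed=0)
        assert tr.steps["n_removed"].iloc[0] == 0


def test_articulation_hub_removal_beats_random_single_nodes(truth_default):
    """Deleting the highest-degree articulation hub shrinks the giant
    component more than deleting any of 100 random single genes."""
    import networkx as nx

    from hns.graph import giant_component_fraction, induce_disease_network, undirected_view
    from hns.synthetic import generate_all

    net = induce_disease_network(truth_default.reference_network, set(truth_default.deg_list))
    und = undirected_view(net)
    giant = max(nx.connected_components(und), key=len)
    arts = set(nx.articulation_points(und.subgraph(giant)))
    hub = max(arts, key=lambda v: (und.degree(v), v))

    def gc_after(drop):
        res = net.subgraph(set(net.nodes) - {drop})
        return giant_component_fraction(res) * res.number_of_nodes() / net.number_of_nodes()

    g_hub = gc_after(hub)
    rng = np.random.default_rng(0)
    sample = rng.choice(sorted(net.nodes), 100, replace=False)
    wins = sum(1 for v in sample if g_hub < gc_after(v))
    assert wins >= 95


class TestFMeasure:
    def test_perfect_prediction(self):
        assert f_measure({"A", "B"}, {"A", "B"}).f == 1.0

    def test_disjoint(self):
        assert f_measure({"A"}, {"B"}).f == 0.0

    def test_worked_example(self):
        pred = {f"P{i}" for i in range(30)} | {f"T{i}" for i in range(20)}
        ref = {f"T{i}" for i in range(100)}
        res = f_measure(pred, ref)
        assert res.precision == pytest.approx(0.4)
        assert res.recall == pytest.approx(0.2)
        assert res.f == pytest.approx(2 * 0.4 * 0.2 / 0.6)
        assert res.f == pytest.approx(0.2667, abs=1e-4)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            f_measure({"A"}, set())

    def test_against_second_implementation(self):
        rng = np.random.default_rng(55)
        universe = [f"G{i}" for i in range(40)]
        for _ in range(1000):
            pred = set(rng.choice(universe, size=rng.integers(0, 20)))
            ref = set(rng.choice(universe, size=rng.integers(1, 20)))
            res = f_measure(pred, ref)
            p, r, f = precision_recall_f(pred, ref)
            assert (res.precision, res.recall, res.f) == pytest.approx((p, r, f))


class TestChisq:
    def _summary(self, net):
        return degree_profile(net)

    def test_identical_sets_statistic_zero(self, disease_net_mini):
        summary = self._summary(disease_net_mini)
        genes = set(sorted(disease_net_mini.nodes)[:30])
        res = degree_ratio_chisq({"X": genes, "Y": genes}, summary, "in")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_separation_closed_form(self):
        # 2x2 table [[10,0],[0,10]]: chi-square = 20
        obs = [[10, 0], [0, 10]]
        assert chisq_statistic(obs) == pytest.approx(20.0)
        stat, p, _, _ = stats.chi2_contingency(obs, correction=False)
        assert stat == pytest.approx(20.0) and p < 0.001

    def test_matches_textbook_formula(self, disease_net_mini):
        summary = self._summary(disease_net_mini)
        rng = np.random.default_rng(12)
        nodes = sorted(disease_net_mini.nodes)
        sets = {
            "A": set(rng.choice(nodes, 40, replace=False)),
            "B": set(rng.choice(nodes, 40, replace=False)),
            "C": set(rng.choice(nodes, 40, replace=False)),
        }
        res = degree_ratio_chisq(sets, summary, "out")
        assert res.statistic == pytest.approx(chisq_statistic(res.table.to_numpy().tolist()))

    def test_row_permutation_invariance(self, disease_net_mini):
        summary = self._summary(disease_net_mini)
        rng = np.random.default_rng(13)
        nodes = sorted(disease_net_mini.nodes)
        sets = {k: set(rng.choice(nodes, 30, replace=False)) for k in "ABC"}
        r1 = degree_ratio_chisq(sets, summary, "in")
        r2 = degree_ratio_chisq(dict(reversed(list(sets.items()))), summary, "in")
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_needs_two_sets(self, disease_net_mini):
        with pytest.raises(ValueError):
            degree_ratio_chisq({"X": {"A"}}, self._summary(disease_net_mini), "in")


class TestCorrelation:
    def _scan_frame(self, rows):
        df = pd.DataFrame(rows, columns=["L", "gc_fraction"])
        df.index = [f"G{i}" for i in range(len(rows))]
        df.index.name = "gene"
        return df

    def _summary_frame(self, in_deg, out_deg):
        table = pd.DataFrame(
            {"in_degree": in_deg, "out_degree": out_deg},
            index=pd.Index([f"G{i}" for i in range(len(in_deg))], name="gene"),
        )

        class S:
            pass

        s = S()
        s.table = table
        return s

    def test_perfect_linear_relation(self):
        scan = self._scan_frame([(1.0, 0.9), (2.0, 0.8), (3.0, 0.7), (4.0, 0.6)])
        summary = self._summary_frame([1, 2, 3, 4], [4, 3, 2, 1])
        res = degree_lgc_correlation(scan, summary)
        r_in_l = res[(res.degree == "in_degree") & (res.outcome == "L")].r.iloc[0]
        r_out_l = res[(res.degree == "out_degree") & (res.outcome == "L")].r.iloc[0]
        assert r_in_l == pytest.approx(1.0)
        assert r_out_l == pytest.approx(-1.0)

    def test_zero_variance_marker(self):
        scan = self._scan_frame([(1.0, 0.5), (2.0, 0.5), (3.0, 0.5)])
        summary = self._summary_frame([2, 2, 2], [1, 2, 3])
        res = degree_lgc_correlation(scan, summary)
        undefined = res[(res.degree == "in_degree")]
        assert undefined.r.isna().all()

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(14)
        l_vals = rng.random(10)
        scan1 = self._scan_frame(list(zip(l_vals, rng.random(10))))
        scan2 = scan1.copy()
        scan2["L"] = 3.0 * scan2["L"] + 7.0
        summary = self._summary_frame(list(rng.integers(0, 9, 10)), list(rng.integers(0, 9, 10)))
        r1 = degree_lgc_correlation(scan1, summary)
        r2 = degree_lgc_correlation(scan2, summary)
        sel = lambda df: df[df.outcome == "L"].r.to_numpy(dtype=float)
        assert np.allclose(sel(r1), sel(r2))


class TestEssentialityFilter:
    def test_constant_scores(self):
        scores = pd.DataFrame(
            {"CL1": [-1.2, 0.0], "CL2": [-1.2, 0.0]},
            index=pd.Index(["ESS", "NEUT"], name="gene"),
        )
        assert essentiality_filter(scores) == ["ESS"]

    def test_planted_thirteen_recovered(self, truth_default):
        hits = essentiality_filter(
            truth_default.score_table, query_genes=set(truth_default.deg_list)
        )
        assert sorted(hits) == sorted(truth_default.essential_genes)
        assert len(hits) == 13

    def test_all_missing_gene_warns(self):
        scores = pd.DataFrame(
            {"CL1": [-1.5, np.nan], "CL2": [-1.5, np.nan]},
            index=pd.Index(["A", "B"], name="gene"),
        )
        with pytest.warns(UserWarning, match="no scores"):
            assert essentiality_filter(scores) == ["A"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            essentiality_filter(pd.DataFrame())
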