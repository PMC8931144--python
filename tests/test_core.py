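"""Core extraction, ego networks, reachability, support and path lengths."""

import pytest

from biocnet.core import (
    average_path_length,
    direct_biophysical_support,
    ego_network,
    ego_table,
    extract_core,
    reachable_values,
)
from biocnet.errors import AnalysisError
from biocnet.network import BiculturalNetwork, build_network, standardize_weights


def _net(edges, classes):
    return BiculturalNetwork.from_edges(edges, classes)


@pytest.fixture
def chain_core():
    """SEA -> PTP -> STE as an extracted (fraction 1.0) core."""
    net = standardize_weights(
        _net([("SEA", "PTP", 2), ("PTP", "STE", 1)],
             {"SEA": "biophysical", "PTP": "value", "STE": "value"})
    )
    return extract_core(net, fraction=1.0)


class TestExtractCore:
    def test_toy_five_percent_keeps_strongest_edge(self, toy_corpus):
        net = standardize_weights(build_network(toy_corpus))
        core = extract_core(net, fraction=0.05)
        assert set(core.graph.edges()) == {("SEA", "PTP")}
        assert set(core.graph.nodes()) == {"SEA", "PTP"}
        assert core.n_edges_kept == 1
        assert core.cutoff_weight == 1.0

    def test_fraction_one_is_identity_minus_isolates(self, toy_corpus):
        net = standardize_weights(build_network(toy_corpus, keep_isolated=True))
        core = extract_core(net, fraction=1.0)
        assert set(core.graph.edges()) == set(net.graph.edges())
        assert "ROCKS" not in core.graph  # isolated node dropped

    def test_boundary_tie_policies(self):
        # 40 edges; ranks 2-4 are a 3-way tie straddling the k=2 boundary
        classes = {"B": "biophysical"} | {f"V{i}": "value" for i in range(40)}
        weights = [50, 40, 40, 40] + list(range(36, 0, -1))
        edges = [("B", f"V{i}", w) for i, w in enumerate(weights)]
        net = standardize_weights(_net(edges, classes))
        inc = extract_core(net, fraction=0.05, tie_policy="include_ties")
        strict = extract_core(net, fraction=0.05, tie_policy="strict_count")
        assert inc.n_edges_kept == 4
        assert strict.n_edges_kept == 2

    def test_threshold_separates_kept_from_dropped(self, toy_corpus):
        net = standardize_weights(build_network(toy_corpus))
        core = extract_core(net, fraction=0.4)
        kept = {d["std_weight"] for _, _, d in core.graph.edges(data=True)}
        dropped = {
            d["std_weight"]
            for u, v, d in net.graph.edges(data=True)
            if (u, v) not in set(core.graph.edges())
        }
        assert not dropped or min(kept) >= max(dropped)

    @pytest.mark.parametrize("fraction", [0.0, -0.2, 1.5])
    def test_bad_fraction_rejected(self, toy_corpus, fraction):
        net = standardize_weights(build_network(toy_corpus))
        with pytest.raises(ValueError):
            extract_core(net, fraction=fraction)

    def test_works_on_raw_weights_too(self, toy_corpus):
        core = extract_core(build_network(toy_corpus), fraction=0.05)
        assert set(core.graph.edges()) == {("SEA", "PTP")}


class TestEgoNetwork:
    def test_chain_k1_and_k2(self, chain_core):
        assert ego_network(chain_core, "SEA", k=1).nodes == {"SEA", "PTP"}
        assert ego_network(chain_core, "SEA", k=2).nodes == {"SEA", "PTP", "STE"}

    def test_isolated_ego_is_alone(self):
        net = _net(
            [("PTP", "STE", 1)],
            {"SEA": "biophysical", "PTP": "value", "STE": "value"},
        )
        net.graph.add_node("SEA", cls="biophysical")
        ego = ego_network(net, "SEA", k=1)
        assert ego.nodes == {"SEA"}
        assert ego.graph.number_of_edges() == 0

    def test_value_ego_rejected(self, chain_core):
        with pytest.raises(AnalysisError, match="must be biophysical"):
            ego_network(chain_core, "PTP", k=1)

    def test_absent_ego_rejected(self, chain_core):
        with pytest.raises(AnalysisError, match="not present"):
            ego_network(chain_core, "MOON", k=1)

    def test_induced_subgraph_keeps_internal_edges(self):
        # SEA reaches PTP and STE at k=1; the PTP->STE edge must be included
        net = _net(
            [("SEA", "PTP", 1), ("SEA", "STE", 1), ("PTP", "STE", 1)],
            {"SEA": "biophysical", "PTP": "value", "STE": "value"},
        )
        ego = ego_network(net, "SEA", k=1)
        assert ("PTP", "STE") in ego.graph.edges()

    def test_strong_edge_flags(self, toy_corpus):
        net = standardize_weights(build_network(toy_corpus))
        ego = ego_network(net, "SEA", k=1)
        flags = {(u, v): d["strong"] for u, v, d in ego.graph.edges(data=True)}
        assert flags[("SEA", "PTP")] is True  # std_weight 1.0 > 0.5
        assert flags[("SEA", "PTL")] is False  # 1/3


class TestReachableValues:
    def test_chain(self, chain_core):
        assert reachable_values(chain_core, "SEA", 1) == {"PTP"}
        assert reachable_values(chain_core, "SEA", 2) == {"PTP", "STE"}

    def test_k_zero_is_empty(self, chain_core):
        assert reachable_values(chain_core, "SEA", 0) == set()

    def test_parallel_branches_union(self):
        net = _net(
            [("B", "V1", 1), ("V1", "V2", 1), ("B", "V3", 1), ("V3", "V4", 1)],
            {"B": "biophysical", "V1": "value", "V2": "value", "V3": "value",
             "V4": "value"},
        )
        assert reachable_values(net, "B", 2) == {"V1", "V2", "V3", "V4"}

    def test_monotone_in_k(self, chain_core):
        for k in (0, 1):
            assert reachable_values(chain_core, "SEA", k) <= reachable_values(
                chain_core, "SEA", k + 1
            )


class TestSupportTable:
    def test_counts_distinct_biophysical_in_neighbours(self):
        net = standardize_weights(
            _net(
                [("SEA", "PTP", 3), ("ROCKS", "PTP", 2), ("SEA", "STE", 2)],
                {"SEA": "biophysical", "ROCKS": "biophysical", "PTP": "value",
                 "STE": "value"},
            )
        )
        table = direct_biophysical_support(extract_core(net, fraction=1.0))
        assert list(table["value"]) == ["PTP", "STE"]
        assert list(table["n_biophysical"]) == [2, 1]

    def test_values_without_support_listed_as_zero(self, chain_core):
        table = direct_biophysical_support(chain_core)
        assert dict(zip(table["value"], table["n_biophysical"])) == {
            "PTP": 1, "STE": 0,
        }

    def test_value_to_value_edges_do_not_count(self):
        net = standardize_weights(
            _net([("PTP", "STE", 1)], {"PTP": "value", "STE": "value"})
        )
        table = direct_biophysical_support(extract_core(net, fraction=1.0))
        assert set(table["n_biophysical"]) == {0}


class TestAveragePathLength:
    def test_directed_chain(self):
        net = _net(
            [("B", "V1", 1), ("V1", "V2", 1)],
            {"B": "biophysical", "V1": "value", "V2": "value"},
        )
        out = average_path_length(net, "directed")
        assert out.mean == pytest.approx(4 / 3)
        assert out.n_finite_pairs == 3
        assert out.n_unreachable_pairs == 3

    def test_complete_digraph_mean_one(self):
        names = [f"V{i}" for i in range(4)]
        edges = [(u, v, 1) for u in names for v in names if u != v]
        net = _net(edges, {n: "value" for n in names})
        assert average_path_length(net).mean == 1.0

    def test_undirected_chain(self):
        net = _net(
            [("B", "V1", 1), ("V1", "V2", 1)],
            {"B": "biophysical", "V1": "value", "V2": "value"},
        )
        out = average_path_length(net, "undirected")
        assert out.mean == pytest.approx(4 / 3)
        assert out.n_unreachable_pairs == 0

    def test_too_small_network_rejected(self):
        net = _net([("B", "V1", 1)], {"B": "biophysical", "V1": "value"})
        net.graph.remove_node("V1")
        with pytest.raises(AnalysisError):
            average_path_length(net)


class TestEgoTable:
    def test_chain_counts_include_ego(self, chain_core):
        table = ego_table(chain_core, include_ego=True)
        row = table.iloc[0]
        assert row["element"] == "SEA"
        assert (row["k1_nodes"], row["k2_nodes"]) == (2, 3)
        assert (row["k1_values"], row["k2_values"]) == (1, 2)

    def test_exclude_ego_shifts_node_counts_by_one(self, chain_core):
        with_ego = ego_table(chain_core, include_ego=True)
        without = ego_table(chain_core, include_ego=False)
        assert (with_ego["k1_nodes"] - without["k1_nodes"]).eq(1).all()
        assert (with_ego["k2_nodes"] - without["k2_nodes"]).eq(1).all()
        # values-reached columns are unaffected by the convention
        assert (with_ego["k1_values"] == without["k1_values"]).all()

    def test_no_biophysical_nodes_is_an_error(self):
        net = standardize_weights(
            _net([("PTP", "STE", 1)], {"PTP": "value", "STE": "value"})
        )
        with pytest.raises(AnalysisError, match="no biophysical"):
            ego_table(extract_core(net, fraction=1.0))

    def test_k2_counts_never_below_k1(self, toy_corpus):
        net = standardize_weights(build_network(toy_corpus))
        table = ego_table(extract_core(net, fraction=1.0))
        assert (table["k2_nodes"] >= table["k1_nodes"]).all()
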