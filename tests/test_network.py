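import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from oracles import dijkstra
from ctpdn.config import RunConfig
from ctpdn.network import (
    build_network,
    classify_shape,
    cti_score,
    edge_length,
    edge_weight,
    floyd_warshall,
    node_usage_counts,
    rank_compounds,
    reconstruct_path,
    ShortestPathResult,
)
from ctpdn.simulate import SimSpec, gen_network


def _tables(docking_rows, ppi_rows, pathway_rows):
    docking = pd.DataFrame(docking_rows,
                           columns=["compound_id", "target_id", "s_i", "s_m", "success"])
    ppi = pd.DataFrame(ppi_rows, columns=["target_a", "target_b", "combined_score"])
    pathways = pd.DataFrame(pathway_rows,
                            columns=["pathway_id", "name", "p_value", "q_value",
                                     "member_targets", "diseases"])
    return docking, ppi, pathways


# ---------------------------------------------------------------------------
# edge arithmetic


def test_cti_score_is_docking_ratio():
    assert cti_score(45.2, 40.0) == pytest.approx(1.13)
    assert cti_score(38.0, 38.0) == 1.0
    with pytest.raises(ValueError):
        cti_score(45.2, 0.0)
    with pytest.raises(ValueError):
        cti_score(float("inf"), 40.0)


def test_edge_length_reciprocal_and_no_interaction():
    assert edge_length(2.0) == 0.5
    assert edge_length(1.0) == 1.0
    assert edge_length(0.0, interacts=False) == math.inf
    with pytest.raises(ValueError):
        edge_length(-1.0, interacts=True)


def test_edge_weight_pdi_is_one_and_sigmoid_elsewhere():
    assert edge_weight(123.0, "PDI") == 1.0
    assert edge_weight(1.0, "CTI") == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-9)
    assert edge_weight(1e-12, "TTI") == pytest.approx(0.5, abs=1e-9)
    with pytest.raises(ValueError):
        edge_weight(math.inf, "CTI")
    with pytest.raises(ValueError):
        edge_weight(1.0, "XXX")


# beyond L ~ 37 the logistic saturates to 1.0 in double precision, so the
# strict upper bound is only representable below that
@given(st.floats(min_value=1e-9, max_value=30.0, allow_nan=False))
def test_finite_non_pdi_weights_lie_in_open_half_unit(L):
    w = edge_weight(L, "CTI")
    assert 0.5 < w < 1.0


# ---------------------------------------------------------------------------
# construction


def test_minimal_network_counts_and_symmetry():
    docking, ppi, pathways = _tables(
        [("c1", "t1", 40.0, 40.0, True)],
        [],
        [("p1", "one", 1e-9, 1e-8, "t1", "d1")],
    )
    net = build_network(["c1"], docking, ppi, pathways)
    assert len(net.nodes) == 4 and len(net.edges) == 3
    finite = np.isfinite(net.matrix) & ~np.eye(4, dtype=bool)
    assert finite.sum() == 6  # three undirected edges, symmetric
    assert np.array_equal(net.matrix, net.matrix.T)
    assert np.all(np.diag(net.matrix) == 0)


def test_tti_weight_from_combined_score():
    docking, ppi, pathways = _tables(
        [], [("t1", "t2", 0.9)], [("p1", "one", 1e-9, 1e-8, "t1;t2", "d1")]
    )
    net = build_network([], docking, ppi, pathways)
    tti = [e for e in net.edges if e.edge_type == "TTI"][0]
    assert tti.W == pytest.approx(1 / (1 + math.exp(-1 / 0.9)), abs=1e-6)


def test_tti_reciprocal_mode_flips_score():
    docking, ppi, pathways = _tables(
        [], [("t1", "t2", 0.5)], [("p1", "one", 1e-9, 1e-8, "t1;t2", "d1")]
    )
    net = build_network([], docking, ppi, pathways,
                        config=RunConfig(tti_mode="reciprocal"))
    tti = [e for e in net.edges if e.edge_type == "TTI"][0]
    assert tti.S == 2.0 and tti.L == 0.5


def test_failed_docking_leaves_compound_isolated():
    docking, ppi, pathways = _tables(
        [("c1", "t1", float("nan"), 40.0, False)],
        [],
        [("p1", "one", 1e-9, 1e-8, "t1", "d1")],
    )
    net = build_network(["c1"], docking, ppi, pathways)
    assert all(e.edge_type != "CTI" for e in net.edges)
    ranking, _ = rank_compounds(net)
    assert math.isinf(ranking.mean_length.iloc[0]) and pd.isna(ranking["rank"].iloc[0])


def test_duplicate_docking_keeps_strongest(caplog):
    docking, ppi, pathways = _tables(
        [("c1", "t1", 20.0, 40.0, True), ("c1", "t1", 60.0, 40.0, True)],
        [],
        [("p1", "one", 1e-9, 1e-8, "t1", "d1")],
    )
    net = build_network(["c1"], docking, ppi, pathways)
    cti = [e for e in net.edges if e.edge_type == "CTI"][0]
    assert cti.S == pytest.approx(1.5)


def test_dangling_endpoint_raises_with_id():
    docking, ppi, pathways = _tables(
        [("ghost", "t1", 40.0, 40.0, True)],
        [],
        [("p1", "one", 1e-9, 1e-8, "t1", "d1")],
    )
    with pytest.raises(ValueError, match="ghost"):
        build_network(["c1"], docking, ppi, pathways)


# ---------------------------------------------------------------------------
# shortest paths


def test_floyd_warshall_prefers_relay():
    A = np.array([[0, 1, 3], [1, 0, 1], [3, 1, 0]], dtype=float)
    dist, succ = floyd_warshall(A)
    assert dist[0, 2] == 2.0
    assert reconstruct_path(succ, 0, 2) == [0, 1, 2]


def test_floyd_warshall_disconnected_and_domain_errors():
    A = np.array([[0, np.inf], [np.inf, 0]])
    dist, succ = floyd_warshall(A)
    assert math.isinf(dist[0, 1]) and reconstruct_path(succ, 0, 1) == []
    with pytest.raises(ValueError):
        floyd_warshall(np.array([[0, -1.0], [-1.0, 0]]))
    with pytest.raises(ValueError):
        floyd_warshall(np.array([[1.0, 2.0], [2.0, 1.0]]))


def test_floyd_warshall_matches_dijkstra_on_random_graphs():
    for seed in range(100):
        rng = np.random.default_rng(seed)
        n = 12
        A = np.full((n, n), np.inf)
        np.fill_diagonal(A, 0.0)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.35:
                    A[i, j] = A[j, i] = rng.uniform(0.5, 1.0)
        dist, succ = floyd_warshall(A)
        oracle = np.array([dijkstra(A, s) for s in range(n)])
        assert np.allclose(dist, oracle, atol=1e-9, equal_nan=False)
        assert np.allclose(dist, dist.T, atol=1e-12)
        # reconstructed path lengths agree with the distance matrix
        for i in range(n):
            for j in range(n):
                path = reconstruct_path(succ, i, j)
                if path:
                    total = sum(A[a, b] for a, b in zip(path, path[1:]))
                    assert total == pytest.approx(dist[i, j], abs=1e-9)


def test_rank_compounds_on_single_chain():
    docking, ppi, pathways = _tables(
        [("c1", "t1", 40.0, 40.0, True)],
        [],
        [("p1", "one", 1e-9, 1e-8, "t1", "d1;d2")],
    )
    net = build_network(["c1"], docking, ppi, pathways)
    ranking, paths = rank_compounds(net)
    w = 1 / (1 + math.exp(-1))
    expected = 2 * w + 1.0  # CTI and TPI at S=1 plus the unit PDI edge
    assert ranking.mean_length.iloc[0] == pytest.approx(expected, abs=1e-9)
    assert {p.disease_id for p in paths} == {"d1", "d2"}
    for p in paths:
        assert p.shape == "C-T-P-D"
        assert p.node_sequence[0] == "c1" and p.node_sequence[-1] in ("d1", "d2")
        assert p.length == pytest.approx(expected, abs=1e-9)


def test_rank_ties_break_lexicographically():
    docking, ppi, pathways = _tables(
        [("cB", "t1", 40.0, 40.0, True), ("cA", "t1", 40.0, 40.0, True)],
        [],
        [("p1", "one", 1e-9, 1e-8, "t1", "d1")],
    )
    ranking, _ = rank_compounds(build_network(["cB", "cA"], docking, ppi, pathways))
    assert list(ranking.compound_id) == ["cA", "cB"]
    assert list(ranking["rank"]) == [1, 2]


def test_shape_classification():
    assert classify_shape(["compound", "target", "pathway", "disease"]) == "C-T-P-D"
    assert classify_shape(
        ["compound", "target", "target", "pathway", "disease"]) == "C-T-T-P-D"
    assert classify_shape(
        ["compound", "target", "target", "target", "pathway", "disease"]) == "C-T-T-P-D"
    assert classify_shape(["compound", "pathway", "disease"]) == "other"
    assert classify_shape(
        ["compound", "target", "pathway", "target", "pathway", "disease"]) == "other"


def test_canonical_path_lengths_bounded(network_fixture):
    """With all finite non-PDI weights in (0.5, 1) and PDI = 1, any
    compound-target-pathway-disease path must be strictly between 2 and 3."""
    net = build_network(
        network_fixture["compounds"], network_fixture["docking"],
        network_fixture["ppi"], network_fixture["pathways"],
    )
    _, paths = rank_compounds(net)
    ctpd = [p for p in paths if p.shape == "C-T-P-D"]
    assert ctpd, "fixture should produce canonical-shape paths"
    for p in ctpd:
        assert 2.0 < p.length < 3.0


def test_raising_docking_score_never_hurts(network_fixture):
    base_net = build_network(
        network_fixture["compounds"], network_fixture["docking"],
        network_fixture["ppi"], network_fixture["pathways"],
    )
    base_rank, base_paths = rank_compounds(base_net)
    target_compound = base_rank.compound_id.iloc[-1]
    base_mean = float(base_rank.set_index("compound_id").mean_length[target_compound])

    docking = network_fixture["docking"].copy()
    on_path_edges = {
        (p.node_sequence[0], p.node_sequence[1])
        for p in base_paths if p.compound_id == target_compound and p.node_sequence
    }
    mask = docking.success & (docking.compound_id == target_compound)
    for idx in docking.index[mask]:
        bumped = docking.copy()
        bumped.loc[idx, "s_i"] *= 1.5
        net = build_network(
            network_fixture["compounds"], bumped,
            network_fixture["ppi"], network_fixture["pathways"],
        )
        ranking, _ = rank_compounds(net)
        new_mean = float(ranking.set_index("compound_id").mean_length[target_compound])
        assert new_mean <= base_mean + 1e-12
        pair = (docking.loc[idx, "compound_id"], docking.loc[idx, "target_id"])
        if pair in on_path_edges:
            assert new_mean < base_mean - 1e-12


def test_node_usage_counts_by_type():
    def spr(seq):
        return ShortestPathResult(seq[0], seq[-1], 0.0, seq, "C-T-P-D")

    docking, ppi, pathways = _tables(
        [("c1", "AKT1", 40, 40, True), ("c2", "AKT1", 40, 40, True),
         ("c3", "CAT", 40, 40, True)],
        [],
        [("p1", "one", 1e-9, 1e-8, "AKT1;CAT", "d"),
         ("p2", "two", 1e-9, 1e-8, "AKT1", "d")],
    )
    net = build_network(["c1", "c2", "c3"], docking, ppi, pathways)
    paths = [spr(["c1", "AKT1", "p1", "d"]), spr(["c2", "AKT1", "p2", "d"]),
             spr(["c3", "CAT", "p1", "d"])]
    targets = node_usage_counts(paths, "target", net)
    assert targets.set_index("node_id")["count"].to_dict() == {"AKT1": 2, "CAT": 1}
    pathways_count = node_usage_counts(paths, "pathway", net)
    assert pathways_count.set_index("node_id")["count"].to_dict() == {"p1": 2, "p2": 1}
    assert node_usage_counts([], "target", net).empty
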