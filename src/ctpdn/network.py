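"""Weighted compound-target-pathway-disease network (CTPDN) construction and
shortest-path compound ranking.

The network has four node layers (compound, target, pathway, disease) and four
edge classes: compound-target interactions (CTI) scored by a docking-score
ratio, target-target interactions (TTI) scored by protein-protein combined
scores, target-pathway interactions (TPI) scored by membership, and
pathway-disease interactions (PDI).  Every edge score S is turned into a
length L = 1/S (+inf for no interaction) and then normalized to a weight
W = 1/(1 + e^(-L)), except PDI edges whose weight is exactly 1.  Compounds are
ranked by the mean Floyd-Warshall shortest-path weight to each disease node:
the smaller the mean path length, the more valuable the compound.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import split_ids

logger = logging.getLogger("ctpdn")

NODE_TYPES = ("compound", "target", "pathway", "disease")
EDGE_TYPES = ("CTI", "TTI", "TPI", "PDI")

#: which (sorted) node-type pair each edge class may join
_EDGE_ENDPOINT_TYPES = {
    "CTI": {"compound", "target"},
    "TTI": {"target"},
    "TPI": {"target", "pathway"},
    "PDI": {"pathway", "disease"},
}


@dataclass(frozen=True)
class Node:
    node_id: str
    node_type: str

    def __post_init__(self) -> None:
        if self.node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type {self.node_type!r}")


@dataclass(frozen=True)
class Edge:
    """An undirected, typed, weighted edge.

    ``S`` is the raw interaction score, ``L`` the derived length (1/S, or +inf
    for no interaction), ``W`` the normalized weight actually written into the
    adjacency matrix.
    """

    u: str
    v: str
    edge_type: str
    S: float
    L: float
    W: float


@dataclass
class ShortestPathResult:
    compound_id: str
    disease_id: str
    length: float
    node_sequence: list[str]
    shape: str  # "C-T-P-D", "C-T-T-P-D" or "other"


@dataclass
class CtpdnNetwork:
    nodes: list[Node]
    edges: list[Edge]
    node_index: dict[str, int] = field(repr=False)
    matrix: np.ndarray = field(repr=False)

    @property
    def node_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes]

    def nodes_of_type(self, node_type: str) -> list[str]:
        return [n.node_id for n in self.nodes if n.node_type == node_type]

    def to_jsonable(self) -> dict:
        return {
            "nodes": [{"id": n.node_id, "type": n.node_type} for n in self.nodes],
            "edges": [
                {"u": e.u, "v": e.v, "type": e.edge_type, "S": e.S,
                 "L": "inf" if math.isinf(e.L) else e.L, "W": e.W}
                for e in self.edges
            ],
        }


# ---------------------------------------------------------------------------
# edge arithmetic


def cti_score(s_i: float, s_m: float) -> float:
    """Docking-score ratio S = s_i / s_m.

    ``s_i`` is the docking interaction score of the candidate compound against
    the target, ``s_m`` that of the target's original (reference) ligand; the
    ratio expresses binding capacity relative to the native ligand, so S = 1
    means the compound binds as well as the reference.
    """
    if not math.isfinite(s_i):
        raise ValueError("docking score s_i must be finite")
    if not s_m > 0:
        raise ValueError(f"reference docking score s_m must be positive, got {s_m}")
    return s_i / s_m


def edge_length(S: float, interacts: bool = True) -> float:
    """Length L = 1/S for an interacting pair; +inf when there is no
    interaction (a failed docking, an absent PPI link)."""
    if not interacts:
        return math.inf
    if not S > 0:
        raise ValueError(f"interacting edge requires S > 0, got {S}")
    return 1.0 / S


def edge_weight(L: float, edge_type: str, sigmoid_sign: int = 1) -> float:
    """Normalized weight W: exactly 1 for pathway-disease edges, else the
    logistic map W = 1/(1 + e^(-L)).

    With the default sign, any finite positive length maps into (0.5, 1), so
    all edge classes become commensurable before shortest-path analysis.
    A non-PDI edge of infinite length has no weight (the adjacency entry
    stays +inf); callers should omit it.
    """
    if edge_type not in EDGE_TYPES:
        raise ValueError(f"unknown edge type {edge_type!r}")
    if edge_type == "PDI":
        return 1.0
    if math.isinf(L):
        raise ValueError("infinite length: edge must be omitted, not weighted")
    if not L > 0:
        raise ValueError(f"edge length must be positive, got {L}")
    return 1.0 / (1.0 + math.exp(-sigmoid_sign * L))


# ---------------------------------------------------------------------------
# network construction


def _compound_ids(compounds) -> list[str]:
    if isinstance(compounds, pd.DataFrame):
        return compounds["compound_id"].astype(str).tolist()
    return [str(c) for c in compounds]


def build_network(
    compounds,
    docking: pd.DataFrame,
    ppi: pd.DataFrame,
    pathways: pd.DataFrame,
    diseases=None,
    targets=None,
    config: RunConfig | None = None,
) -> CtpdnNetwork:
    """Assemble the CTPDN and its symmetric adjacency matrix.

    Parameters
    ----------
    compounds:
        Compound table (or iterable of compound ids) — already filtered.
    docking:
        Docking table with columns compound_id, target_id, s_i, s_m, success.
        Failed dockings contribute no edge.
    ppi:
        Protein-protein interaction table (target_a, target_b, combined_score).
    pathways:
        Pathway table with ';'-joined ``member_targets`` and ``diseases``.
    diseases, targets:
        Explicit node rosters; derived from the edge tables when omitted.
    """
    cfg = config or RunConfig()
    compound_ids = _compound_ids(compounds)

    if targets is None:
        target_set = set(docking["target_id"].astype(str))
        target_set |= set(ppi["target_a"].astype(str)) | set(ppi["target_b"].astype(str))
        for m in pathways["member_targets"]:
            target_set |= set(split_ids(m))
        target_ids = sorted(target_set)
    else:
        target_ids = sorted(str(t) for t in targets)

    pathway_ids = pathways["pathway_id"].astype(str).tolist()
    if diseases is None:
        disease_set: set[str] = set()
        for d in pathways["diseases"]:
            disease_set |= set(split_ids(d))
        disease_ids = sorted(disease_set)
    else:
        disease_ids = sorted(str(d) for d in diseases)

    nodes = (
        [Node(c, "compound") for c in compound_ids]
        + [Node(t, "target") for t in target_ids]
        + [Node(p, "pathway") for p in pathway_ids]
        + [Node(d, "disease") for d in disease_ids]
    )
    seen: set[str] = set()
    for n in nodes:
        if n.node_id in seen:
            raise ValueError(f"duplicate node id across layers: {n.node_id}")
        seen.add(n.node_id)
    node_index = {n.node_id: i for i, n in enumerate(nodes)}

    # raw scores per unordered pair; duplicates keep the strongest binding
    raw: dict[tuple[str, str], tuple[str, float]] = {}

    def _add(u: str, v: str, edge_type: str, S: float) -> None:
        for endpoint in (u, v):
            if endpoint not in node_index:
                raise ValueError(f"{edge_type} edge endpoint not a declared node: {endpoint}")
        key = (u, v) if u <= v else (v, u)
        if key in raw:
            old_type, old_S = raw[key]
            logger.warning("duplicate %s edge %s-%s: keeping max S", edge_type, u, v)
            if S <= old_S:
                return
        raw[key] = (edge_type, S)

    for row in docking.itertuples(index=False):
        if not bool(row.success):
            continue  # docking failure: no interaction, length stays +inf
        if str(row.compound_id) not in node_index:
            raise ValueError(f"CTI edge endpoint not a declared node: {row.compound_id}")
        _add(str(row.compound_id), str(row.target_id), "CTI", cti_score(row.s_i, row.s_m))

    for row in ppi.itertuples(index=False):
        score = float(row.combined_score)
        S = score if cfg.tti_mode == "combined" else 1.0 / score
        _add(str(row.target_a), str(row.target_b), "TTI", S)

    for row in pathways.itertuples(index=False):
        pid = str(row.pathway_id)
        if cfg.tpi_mode == "qweight":
            S_tpi = float(np.clip(-math.log10(max(row.q_value, 1e-300)), 1e-3, 1e3))
        else:
            S_tpi = 1.0
        for t in split_ids(row.member_targets):
            _add(t, pid, "TPI", S_tpi)
        for d in split_ids(row.diseases):
            _add(pid, d, "PDI", 1.0)

    n = len(nodes)
    matrix = np.full((n, n), np.inf)
    np.fill_diagonal(matrix, 0.0)
    edges: list[Edge] = []
    node_type = {nd.node_id: nd.node_type for nd in nodes}
    for (u, v), (edge_type, S) in sorted(raw.items()):
        if {node_type[u], node_type[v]} != _EDGE_ENDPOINT_TYPES[edge_type]:
            raise ValueError(
                f"{edge_type} edge {u}-{v} joins incompatible node types "
                f"{node_type[u]}/{node_type[v]}"
            )
        L = edge_length(S, interacts=True)
        W = edge_weight(L, edge_type, cfg.sigmoid_sign)
        edges.append(Edge(u, v, edge_type, S, L, W))
        i, j = node_index[u], node_index[v]
        matrix[i, j] = matrix[j, i] = W

    return CtpdnNetwork(nodes=nodes, edges=edges, node_index=node_index, matrix=matrix)


# ---------------------------------------------------------------------------
# shortest paths


def floyd_warshall(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest paths by the Floyd-Warshall recurrence.

    Returns ``(dist, successor)`` where ``successor[i, j]`` is the next node
    index after ``i`` on one optimal i->j path (-1 if unreachable).  Updates
    are strict improvements only, so the result is deterministic for a given
    node ordering; ties between equal-length paths resolve to the path relayed
    through the earliest intermediate index.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency matrix must be square")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency diagonal must be exactly 0")
    if np.any(A < 0):
        raise ValueError("negative edge weight: weights must be non-negative")

    n = A.shape[0]
    dist = A.copy()
    successor = np.where(np.isfinite(A), np.arange(n)[None, :], -1)
    np.fill_diagonal(successor, np.arange(n))
    for k in range(n):
        with np.errstate(invalid="ignore"):
            alt = dist[:, k, None] + dist[None, k, :]
        better = alt < dist
        dist = np.where(better, alt, dist)
        successor = np.where(better, successor[:, k, None], successor)
    return dist, successor


def reconstruct_path(successor: np.ndarray, i: int, j: int) -> list[int]:
    """Node-index sequence of one optimal i->j path, [] if unreachable."""
    if successor[i, j] < 0:
        return []
    path = [i]
    while i != j:
        i = int(successor[i, j])
        path.append(i)
    return path


def classify_shape(node_types: list[str]) -> str:
    """Classify a path's layer sequence.

    ``C-T-P-D`` is compound, single target, pathway, disease; ``C-T-T-P-D``
    is compound, a group of two or more targets, pathway, disease.  Anything
    else — including layer zigzags — is ``other``.
    """
    if len(node_types) < 4 or node_types[0] != "compound" or node_types[-1] != "disease":
        return "other"
    inner = node_types[1:-1]
    n_targets = 0
    while n_targets < len(inner) and inner[n_targets] == "target":
        n_targets += 1
    if n_targets >= 1 and inner[n_targets:] == ["pathway"]:
        return "C-T-P-D" if n_targets == 1 else "C-T-T-P-D"
    return "other"


def rank_compounds(
    network: CtpdnNetwork,
) -> tuple[pd.DataFrame, list[ShortestPathResult]]:
    """Rank compounds by mean shortest-path length to the disease nodes.

    Returns the ranking table (compound_id, mean_length, rank; rank ascending
    by mean_length, ties broken lexicographically by compound id) and the
    per-pair shortest-path records.  Compounds that cannot reach every
    disease get mean_length +inf and no rank.
    """
    compound_ids = network.nodes_of_type("compound")
    disease_ids = network.nodes_of_type("disease")
    if not compound_ids or not disease_ids:
        raise ValueError("ranking needs at least one compound and one disease node")

    dist, successor = floyd_warshall(network.matrix)
    type_of = {n.node_id: n.node_type for n in network.nodes}
    ids = network.node_ids

    results: list[ShortestPathResult] = []
    means: list[float] = []
    for c in compound_ids:
        lengths = []
        for d in disease_ids:
            i, j = network.node_index[c], network.node_index[d]
            length = float(dist[i, j])
            seq = [ids[k] for k in reconstruct_path(successor, i, j)]
            shape = classify_shape([type_of[x] for x in seq]) if seq else "other"
            results.append(ShortestPathResult(c, d, length, seq, shape))
            lengths.append(length)
        means.append(float(np.mean(lengths)))

    ranking = pd.DataFrame({"compound_id": compound_ids, "mean_length": means})
    reachable = ranking[np.isfinite(ranking["mean_length"])].copy()
    unreachable = ranking[~np.isfinite(ranking["mean_length"])].copy()
    if not unreachable.empty:
        logger.warning(
            "compound(s) cannot reach every disease, excluded from ranking: %s",
            ", ".join(unreachable["compound_id"]),
        )
    reachable = reachable.sort_values(
        ["mean_length", "compound_id"], kind="stable"
    ).reset_index(drop=True)
    reachable["rank"] = np.arange(1, len(reachable) + 1)
    unreachable["rank"] = pd.NA
    ranking = pd.concat([reachable, unreachable], ignore_index=True)
    return ranking, results


def node_usage_counts(
    paths: list[ShortestPathResult], node_type: str, network: CtpdnNetwork
) -> pd.DataFrame:
    """Count, per node of ``node_type``, the shortest paths passing through it.

    Sorted by descending count, then node id; nodes on no path are omitted.
    """
    if node_type not in NODE_TYPES:
        raise ValueError(f"unknown node type {node_type!r}")
    wanted = set(network.nodes_of_type(node_type))
    counts: dict[str, int] = {}
    for p in paths:
        for node_id in set(p.node_sequence) & wanted:
            counts[node_id] = counts.get(node_id, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["node_id", "count"])
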