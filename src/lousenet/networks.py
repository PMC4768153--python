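"""Seasonal weighted social networks and their descriptive statistics.

Two networks per season are built from focal minute-scan records of adult
females:

* an **undirected contact network**, where the weight of edge A-B is the
  dyadic total number of scans of general body contact (grooming included)
  between A and B, pooling rows where either female was the focal;
* a **directed grooming-received network**, with an edge groomer -> groomee
  weighted by the number of grooming scans, again pooling focal-as-groomer
  (``groom_given``) and focal-as-groomee (``groom_received``) rows.

Self-grooming never forms an edge.  Females with no qualifying interactions
remain in the node set as isolates with zero centrality.

Centralities follow the epidemiological risk-of-exposure reading: *degree*
(number of distinct partners) and *strength* (total interaction scans) on the
contact network; *in-degree* (number of distinct groomers) and *in-strength*
(total grooming scans received) on the grooming network.

Community structure is summarized by modularity Q, maximized with Newman's
leading-eigenvector spectral bisection on the weighted modularity matrix
``B = A - k k^T / (2m)``, with a Kernighan-Lin style single-node sweep
refining each split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

from .io import CONTACT_BEHAVIORS, SEASONS, logger


@dataclass
class WeightedNetwork:
    """Node set plus weighted edge list for one season.

    Undirected networks store each dyad once with ``u < v``; weights are
    positive integer scan counts; no self-loops.
    """
    nodes: tuple[str, ...]
    edges: list[tuple[str, str, int]]
    directed: bool
    season: str

    def __post_init__(self) -> None:
        self.nodes = tuple(sorted(self.nodes))
        norm = []
        for u, v, w in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if w <= 0 or int(w) != w:
                raise ValueError(f"edge weight must be a positive integer, got {w}")
            if not self.directed and u > v:
                u, v = v, u
            norm.append((u, v, int(w)))
        if len({(u, v) for u, v, _ in norm}) != len(norm):
            raise ValueError("duplicate edges")
        self.edges = sorted(norm)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges)

    def adjacency(self) -> np.ndarray:
        """Weighted adjacency matrix in node sort order (symmetric if undirected)."""
        idx = {n: i for i, n in enumerate(self.nodes)}
        A = np.zeros((self.n_nodes, self.n_nodes))
        for u, v, w in self.edges:
            A[idx[u], idx[v]] += w
            if not self.directed:
                A[idx[v], idx[u]] += w
        return A

    def to_networkx(self) -> nx.Graph | nx.DiGraph:
        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges)
        return g

    def to_edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["source", "target", "weight"])


def _season_scans(scans: pd.DataFrame, season: str) -> pd.DataFrame:
    if season not in SEASONS:
        raise ValueError(f"unknown season label {season!r}")
    return scans[scans["season"] == season]


def build_contact_network(scans: pd.DataFrame, season: str,
                          females: list[str] | None = None) -> WeightedNetwork:
    """Undirected body-contact network (grooming counts as contact).

    ``weight(A, B)`` = number of scans with behavior in ``contact``,
    ``groom_given`` or ``groom_received`` between A and B in the season,
    pooling rows from both females' focal follows.
    """
    sub = _season_scans(scans, season)
    sub = sub[sub["behavior"].isin(CONTACT_BEHAVIORS)]
    nodes = set(females) if females is not None else (
        set(scans["focal_id"]) | set(scans["partner_id"].dropna()))
    counts: dict[tuple[str, str], int] = {}
    for focal, partner in zip(sub["focal_id"], sub["partner_id"]):
        if females is not None and (focal not in nodes or partner not in nodes):
            continue
        key = (focal, partner) if focal < partner else (partner, focal)
        counts[key] = counts.get(key, 0) + 1
    edges = [(u, v, w) for (u, v), w in counts.items()]
    return WeightedNetwork(tuple(nodes), edges, directed=False, season=season)


def build_grooming_network(scans: pd.DataFrame, season: str,
                           females: list[str] | None = None) -> WeightedNetwork:
    """Directed grooming-received network: edge groomer -> groomee.

    ``groom_given`` rows contribute focal -> partner; ``groom_received`` rows
    partner -> focal.  Self-grooming is excluded.
    """
    sub = _season_scans(scans, season)
    sub = sub[sub["behavior"].isin(["groom_given", "groom_received"])]
    nodes = set(females) if females is not None else (
        set(scans["focal_id"]) | set(scans["partner_id"].dropna()))
    counts: dict[tuple[str, str], int] = {}
    for focal, partner, behavior in zip(sub["focal_id"], sub["partner_id"],
                                        sub["behavior"]):
        if females is not None and (focal not in nodes or partner not in nodes):
            continue
        key = (focal, partner) if behavior == "groom_given" else (partner, focal)
        counts[key] = counts.get(key, 0) + 1
    edges = [(u, v, w) for (u, v), w in counts.items()]
    return WeightedNetwork(tuple(nodes), edges, directed=True, season=season)


def centralities(network: WeightedNetwork) -> pd.DataFrame:
    """Per-node centrality table.

    Undirected: columns ``degree`` and ``strength``.  Directed: ``in_degree``
    and ``in_strength`` (the grooming-received reading).  Isolates get zeros.
    """
    deg = {n: 0 for n in network.nodes}
    stren = {n: 0 for n in network.nodes}
    for u, v, w in network.edges:
        if network.directed:
            deg[v] += 1
            stren[v] += w
        else:
            deg[u] += 1
            deg[v] += 1
            stren[u] += w
            stren[v] += w
    prefix = "in_" if network.directed else ""
    return pd.DataFrame({
        "id": list(network.nodes),
        "season": network.season,
        f"{prefix}degree": [deg[n] for n in network.nodes],
        f"{prefix}strength": [stren[n] for n in network.nodes],
    })


def centrality_table(scans: pd.DataFrame, females: list[str],
                     seasons: tuple[str, ...] = SEASONS) -> pd.DataFrame:
    """Long table of all four centrality measures per female x season."""
    parts = []
    for season in seasons:
        contact = centralities(build_contact_network(scans, season, females))
        groom = centralities(build_grooming_network(scans, season, females))
        parts.append(contact.merge(groom, on=["id", "season"]))
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# modularity


@dataclass
class ModularityResult:
    partition: dict[str, int]
    Q: float
    n_communities: int
    season: str = ""


def modularity_q(A: np.ndarray, labels: np.ndarray) -> float:
    """Weighted Newman modularity of a labelling, from a symmetric adjacency."""
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    k = A.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    return float(((A - np.outer(k, k) / two_m) * same).sum() / two_m)


def _refine_split(Bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin style sweep: greedily move single nodes between the two
    halves while any move increases s^T B s; each node moves at most once
    per pass."""
    n = len(s)
    improved = True
    while improved:
        improved = False
        moved = np.zeros(n, dtype=bool)
        for _ in range(n):
            # gain of flipping node i: -4 s_i (Bg s)_i + 4 Bg_ii
            gains = -4 * s * (Bg @ s) + 4 * np.diag(Bg)
            gains[moved] = -np.inf
            i = int(np.argmax(gains))
            if gains[i] <= 1e-12:
                break
            s[i] = -s[i]
            moved[i] = True
            improved = True
    return s


def leading_eigenvector_partition(network: WeightedNetwork,
                                  tol: float = 1e-8,
                                  binarize: bool = False) -> ModularityResult:
    """Community detection by recursive leading-eigenvector bisection.

    Operates on the weighted modularity matrix ``B = A - k k^T / (2m)``;
    directed networks are symmetrized first (reciprocal weights summed)
    because this modularity is defined on undirected graphs.  A subgraph is
    split along the sign pattern of the leading eigenvector of the
    generalized modularity matrix, refined by a single-node sweep; splitting
    stops when the leading eigenvalue is ≤ ``tol`` or the split does not
    increase Q.  A zero-weight network yields one community with Q = 0.
    """
    A = network.adjacency()
    if network.directed:
        A = A + A.T
    if binarize:
        A = (A > 0).astype(float)
    n = network.n_nodes
    if n == 0:
        return ModularityResult({}, 0.0, 0, network.season)
    two_m = A.sum()
    if two_m == 0:
        return ModularityResult({node: 0 for node in network.nodes}, 0.0, 1,
                                network.season)
    k = A.sum(axis=1)
    B = A - np.outer(k, k) / two_m

    labels = np.zeros(n, dtype=int)
    next_label = [1]

    def split(members: np.ndarray) -> None:
        if len(members) < 2:
            return
        Bsub = B[np.ix_(members, members)]
        # generalized modularity matrix: zero row sums within the subgraph
        Bg = Bsub - np.diag(Bsub.sum(axis=1))
        vals, vecs = np.linalg.eigh(Bg)
        if vals[-1] <= tol:
            return
        s = np.where(vecs[:, -1] >= 0, 1.0, -1.0)
        if np.all(s == s[0]):
            return
        s = _refine_split(Bg, s)
        dQ = float(s @ Bg @ s) / (2 * two_m)
        if dQ <= 1e-12 or np.all(s == s[0]):
            return
        group2 = members[s < 0]
        labels[group2] = next_label[0]
        next_label[0] += 1
        split(members[s > 0])
        split(group2)

    split(np.arange(n))
    Q = modularity_q(A, labels)
    partition = {node: int(labels[i]) for i, node in enumerate(network.nodes)}
    n_comm = len(set(labels.tolist()))
    logger.info("season %s: %d communities, Q = %.4f",
                network.season, n_comm, Q)
    return ModularityResult(partition, Q, n_comm, network.season)


def export_graphml(network: WeightedNetwork, path) -> None:
    nx.write_graphml(network.to_networkx(), path)
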