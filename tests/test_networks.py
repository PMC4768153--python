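"""Network construction, centralities and their structural identities."""

import numpy as np
import pandas as pd
import pytest

from lousenet import (build_contact_network, build_grooming_network,
                      centralities, centrality_table)
from lousenet.io import CONTACT_BEHAVIORS
from lousenet.networks import WeightedNetwork


def _scans(rows):
    df = pd.DataFrame(rows, columns=["focal_id", "partner_id", "season",
                                     "behavior"])
    df["egg_picks"] = 0
    df["egg_pick_target"] = None
    return df


def test_single_dyad_contact_counts():
    scans = _scans([("A", "B", "winter", "contact")] * 3)
    net = build_contact_network(scans, "winter", ["A", "B", "C"])
    assert net.edges == [("A", "B", 3)]
    c = centralities(net).set_index("id")
    assert c.loc["A", "degree"] == 1 and c.loc["A", "strength"] == 3
    assert c.loc["C", "degree"] == 0 and c.loc["C", "strength"] == 0


def test_star_graph_degrees():
    scans = _scans([("A", p, "winter", "contact") for p in "BCD"])
    c = centralities(build_contact_network(scans, "winter", list("ABCD")))
    c = c.set_index("id")
    assert c.loc["A", "degree"] == 3 and c.loc["A", "strength"] == 3
    assert c.loc["B", "degree"] == 1


def test_symmetric_pooling_of_focal_rows():
    # A-focal contact with B plus B-focal contact with A pool into one edge
    scans = _scans([("A", "B", "winter", "contact"),
                    ("B", "A", "winter", "groom_given")])
    net = build_contact_network(scans, "winter", ["A", "B"])
    assert net.edges == [("A", "B", 2)]


def test_grooming_network_directed_weights_and_isolate():
    rows = [("A", "B", "winter", "groom_given")] * 5 + \
           [("B", "A", "winter", "groom_given")] * 2 + \
           [("A", None, "winter", "self_groom")]
    net = build_grooming_network(_scans(rows), "winter", ["A", "B", "C"])
    assert sorted(net.edges) == [("A", "B", 5), ("B", "A", 2)]
    c = centralities(net).set_index("id")
    assert c.loc["B", "in_strength"] == 5 and c.loc["B", "in_degree"] == 1
    # female groomed by no one stays in the node set with zeros
    assert c.loc["C", "in_degree"] == 0 and c.loc["C", "in_strength"] == 0


def test_groom_received_rows_reverse_direction():
    net = build_grooming_network(
        _scans([("A", "B", "winter", "groom_received")] * 4), "winter",
        ["A", "B"])
    assert net.edges == [("B", "A", 4)]   # partner grooms the focal


def test_edge_weights_equal_brute_force_recount(dataset):
    """Row-filter oracle: independently recount qualifying rows per dyad."""
    season = "spring"
    net = build_contact_network(dataset.scans, season, dataset.females)
    tally = {}
    for row in dataset.scans.itertuples(index=False):
        if row.season == season and row.behavior in CONTACT_BEHAVIORS \
                and row.partner_id is not None:
            key = tuple(sorted((row.focal_id, row.partner_id)))
            tally[key] = tally.get(key, 0) + 1
    assert {(u, v): w for u, v, w in net.edges} == tally

    gnet = build_grooming_network(dataset.scans, season, dataset.females)
    gtally = {}
    for row in dataset.scans.itertuples(index=False):
        if row.season != season or row.partner_id is None:
            continue
        if row.behavior == "groom_given":
            key = (row.focal_id, row.partner_id)
        elif row.behavior == "groom_received":
            key = (row.partner_id, row.focal_id)
        else:
            continue
        gtally[key] = gtally.get(key, 0) + 1
    assert {(u, v): w for u, v, w in gnet.edges} == gtally


def test_centralities_match_adjacency_row_sums():
    """Matrix oracle on a random weighted 10-node graph."""
    rng = np.random.default_rng(5)
    nodes = tuple(f"n{i}" for i in range(10))
    edges = []
    for i in range(10):
        for j in range(i + 1, 10):
            if rng.random() < 0.4:
                edges.append((nodes[i], nodes[j], int(rng.integers(1, 9))))
    net = WeightedNetwork(nodes, edges, directed=False, season="fall")
    A = net.adjacency()
    c = centralities(net).set_index("id").loc[list(net.nodes)]
    np.testing.assert_array_equal(c["strength"].to_numpy(), A.sum(axis=1))
    np.testing.assert_array_equal(c["degree"].to_numpy(), (A > 0).sum(axis=1))


def test_complete_graph_uniform_centrality():
    nodes = tuple("ABCD")
    edges = [(u, v, 1) for i, u in enumerate(nodes)
             for v in nodes[i + 1:]]
    c = centralities(WeightedNetwork(nodes, edges, False, "winter"))
    assert (c["degree"] == 3).all() and (c["strength"] == 3).all()


def test_strength_sum_identities(dataset):
    for season in ("winter", "summer"):
        net = build_contact_network(dataset.scans, season, dataset.females)
        c = centralities(net)
        assert c["strength"].sum() == 2 * net.total_weight
        gnet = build_grooming_network(dataset.scans, season, dataset.females)
        gc = centralities(gnet)
        assert gc["in_strength"].sum() == gnet.total_weight


def test_label_permutation_equivariance(dataset):
    season = "winter"
    base = centralities(build_contact_network(dataset.scans, season,
                                              dataset.females))
    mapping = {f: f"x{f[::-1]}" for f in dataset.females}
    renamed = dataset.scans.copy()
    renamed["focal_id"] = renamed["focal_id"].map(mapping)
    renamed["partner_id"] = renamed["partner_id"].map(
        lambda v: mapping.get(v) if v is not None else None)
    permuted = centralities(build_contact_network(
        renamed, season, [mapping[f] for f in dataset.females]))
    merged = base.assign(id=base["id"].map(mapping)).merge(
        permuted, on="id", suffixes=("_a", "_b"))
    assert (merged["degree_a"] == merged["degree_b"]).all()
    assert (merged["strength_a"] == merged["strength_b"]).all()


def test_centrality_table_covers_grid(dataset):
    t = centrality_table(dataset.scans, dataset.females)
    assert len(t) == len(dataset.females) * 4
    assert set(t.columns) >= {"degree", "strength", "in_degree", "in_strength"}
    assert (t["strength"] >= t["degree"]).all()       # integer weights >= 1
    assert (t["degree"] <= len(dataset.females) - 1).all()


def test_self_loops_and_bad_weights_rejected():
    with pytest.raises(ValueError, match="self-loop"):
        WeightedNetwork(("A",), [("A", "A", 1)], False, "winter")
    with pytest.raises(ValueError, match="positive integer"):
        WeightedNetwork(("A", "B"), [("A", "B", 0)], False, "winter")


def test_unknown_season_rejected(dataset):
    with pytest.raises(ValueError, match="unknown season"):
        build_contact_network(dataset.scans, "monsoon", dataset.females)
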