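"""Network-randomization significance test for centrality coefficients.

Because network metrics are not independent across individuals, observed
model coefficients are located within a null distribution obtained by
randomizing the seasonal networks themselves: for each of ``R`` runs a
rewiring intensity ``p`` is drawn (Uniform(0, 1) by default), every seasonal
network is rewired with that intensity, the centrality measure is
recomputed, the modelling frame is rebuilt (centrality re-transformed and
re-standardized), the final fixed-effects specification is refit, and the
coefficient of the term of interest is recorded.  The empirical p-value uses
the add-one rule

    p = (1 + #{runs with beta_rand in the rejection tail}) / (R + 1)

with ties counted toward the tail (conservative); the ``lower`` tail asks
whether the observed coefficient is more negative than expected by chance.

Two rewiring modes are provided:

``endpoint`` (default)
    Edge rearrangement: each edge, independently with probability ``p``, has
    one randomly chosen endpoint replaced by a node drawn uniformly at
    random, rejecting self-loops and duplicate edges.  This randomizes which
    individuals hold many connections and is the mode used for inference.

``swap``
    Degree-preserving double-edge swaps applied to ``ceil(p * |E|)`` edge
    pairs.  Each node keeps its exact degree (the degree sequence is
    conserved by construction), which makes this mode a structural null for
    strength-style measures and a sensitivity check — a degree-based test
    under this mode is vacuous, since degree centrality itself is invariant.

Weights always travel with edges, so total edge weight is conserved in both
modes.  Per-run random streams are spawned from the master seed by run
index, so results do not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SEASONS, logger
from .models import ModelFit, ModelFrame, fit_lmm, replace_centrality
from .networks import WeightedNetwork, build_contact_network, \
    build_grooming_network, centralities

_MAX_RETRIES = 10


@dataclass
class PermutationConfig:
    R: int = 2000
    seed: int = 0
    tail: str = "auto"             # lower | upper | auto (sign of beta_obs)
    criterion_level: float = 0.95
    mode: str = "endpoint"         # endpoint | swap
    max_dropped_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.tail not in ("lower", "upper", "auto"):
            raise ValueError(f"unknown tail {self.tail!r}")
        if self.mode not in ("endpoint", "swap"):
            raise ValueError(f"unknown rewiring mode {self.mode!r}")


@dataclass
class PermutationResult:
    term: str
    measure: str
    beta_obs: float
    beta_rand: np.ndarray
    p_empirical: float
    tail: str
    n_dropped: int
    config: PermutationConfig

    @property
    def significant(self) -> bool:
        return self.p_empirical <= 1.0 - self.config.criterion_level

    def to_dict(self) -> dict:
        return {"term": self.term, "measure": self.measure,
                "beta_obs": self.beta_obs, "p_empirical": self.p_empirical,
                "tail": self.tail, "R": int(self.config.R),
                "mode": self.config.mode, "n_dropped": int(self.n_dropped)}


def rewire(network: WeightedNetwork, p: float, rng: np.random.Generator,
           mode: str = "swap") -> WeightedNetwork:
    """Randomize a network's edges at intensity ``p`` (see module docstring).

    Degenerate networks (fewer than two edges) are returned unchanged with a
    log note.  Proposals creating self-loops or duplicate edges are redrawn
    a bounded number of times, then skipped, so graphs with no admissible
    move (e.g. a triangle under ``swap``) pass through unchanged.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("rewiring intensity p must lie in [0, 1]")
    edges = list(network.edges)
    if len(edges) < 2:
        logger.info("season %s: %d edge(s); rewiring skipped",
                    network.season, len(edges))
        return network
    if mode == "swap":
        edges = _rewire_swap(edges, network.directed, p, rng)
    elif mode == "endpoint":
        edges = _rewire_endpoint(edges, list(network.nodes),
                                 network.directed, p, rng)
    else:
        raise ValueError(f"unknown rewiring mode {mode!r}")
    return WeightedNetwork(network.nodes, edges, network.directed,
                           network.season)


def _key(u: str, v: str, directed: bool) -> tuple[str, str]:
    return (u, v) if directed or u < v else (v, u)


def _rewire_swap(edges, directed, p, rng):
    present = {_key(u, v, directed) for u, v, _ in edges}
    n_pairs = int(np.ceil(p * len(edges)))
    for _ in range(n_pairs):
        for _ in range(_MAX_RETRIES):
            i, j = rng.choice(len(edges), size=2, replace=False)
            (a, b, w1), (c, d, w2) = edges[i], edges[j]
            # (a-b), (c-d) -> (a-d), (c-b); preserves every node's degree
            if a == d or c == b:
                continue
            new1, new2 = _key(a, d, directed), _key(c, b, directed)
            if new1 in present or new2 in present or new1 == new2:
                continue
            present.discard(_key(a, b, directed))
            present.discard(_key(c, d, directed))
            present.add(new1)
            present.add(new2)
            edges[i] = (*new1, w1) if directed else (new1[0], new1[1], w1)
            edges[j] = (*new2, w2) if directed else (new2[0], new2[1], w2)
            break
    return edges


def _rewire_endpoint(edges, nodes, directed, p, rng):
    present = {_key(u, v, directed) for u, v, _ in edges}
    n = len(nodes)
    which = rng.random(len(edges)) < p
    for i in np.flatnonzero(which):
        u, v, w = edges[i]
        for _ in range(_MAX_RETRIES):
            end = rng.integers(2)            # which endpoint to move
            repl = nodes[rng.integers(n)]
            nu, nv = (repl, v) if end == 0 else (u, repl)
            if nu == nv:
                continue
            new = _key(nu, nv, directed)
            if new in present:
                continue
            present.discard(_key(u, v, directed))
            present.add(new)
            edges[i] = (new[0], new[1], w) if directed else (new[0], new[1], w)
            break
    return edges


def empirical_p(beta_obs: float, beta_rand: np.ndarray, tail: str = "auto"
                ) -> tuple[float, str]:
    """Add-one empirical p-value; ties count toward the tail."""
    beta_rand = np.asarray(beta_rand, float)
    if beta_rand.size == 0:
        raise ValueError("beta_rand is empty")
    if tail == "auto":
        tail = "lower" if beta_obs < 0 else "upper"
    if tail == "lower":
        k = int((beta_rand <= beta_obs).sum())
    elif tail == "upper":
        k = int((beta_rand >= beta_obs).sum())
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + k) / (beta_rand.size + 1), tail


def _measure_networks(scans: pd.DataFrame, females: list[str], measure: str,
                      seasons=SEASONS) -> dict[str, WeightedNetwork]:
    build = (build_contact_network if measure in ("degree", "strength")
             else build_grooming_network)
    return {s: build(scans, s, females) for s in seasons}


def _centrality_vector(networks: dict[str, WeightedNetwork],
                       frame: ModelFrame, measure: str) -> np.ndarray:
    tables = {s: centralities(net).set_index("id")[measure]
              for s, net in networks.items()}
    return np.array([tables[s].loc[i] for i, s in
                     zip(frame.data["id"], frame.data["season"])], float)


def permutation_test(scans: pd.DataFrame, females: list[str],
                     frame: ModelFrame, final_fit: ModelFit, term: str,
                     config: PermutationConfig) -> PermutationResult:
    """Locate an observed coefficient in its network-randomization null.

    ``frame`` and ``final_fit`` are the observed modelling frame and the
    pruned final model; ``term`` names a fixed-effect design column (e.g.
    ``centrality`` for the winter slope, or ``centrality:season[summer]``).
    Runs whose refit fails to converge are dropped and counted; more than
    ``max_dropped_fraction`` dropped runs is an error.
    """
    if not final_fit.converged:
        raise RuntimeError("observed final model did not converge")
    beta_obs = final_fit.coef(term)
    networks = _measure_networks(scans, females, frame.measure)
    children = np.random.SeedSequence(config.seed).spawn(config.R)
    beta_rand, dropped = [], 0
    for child in children:
        rng = np.random.default_rng(child)
        p = rng.uniform()
        rewired = {s: rewire(net, p, rng, config.mode)
                   for s, net in networks.items()}
        raw = _centrality_vector(rewired, frame, frame.measure)
        if np.std(np.sqrt(raw)) < 1e-12:
            dropped += 1
            continue
        fit = fit_lmm(replace_centrality(frame, raw), final_fit.terms)
        if not fit.converged:
            dropped += 1
            continue
        beta_rand.append(fit.coef(term))
    if dropped > config.max_dropped_fraction * config.R:
        raise RuntimeError(f"{dropped}/{config.R} randomization runs dropped")
    beta_rand = np.asarray(beta_rand)
    p_emp, tail = empirical_p(beta_obs, beta_rand, config.tail)
    logger.info("permutation %s/%s: beta_obs=%.4f p=%.4f (%s tail, R=%d, "
                "%d dropped)", frame.measure, term, beta_obs, p_emp, tail,
                config.R, dropped)
    return PermutationResult(term, frame.measure, beta_obs, beta_rand,
                             p_emp, tail, dropped, config)
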