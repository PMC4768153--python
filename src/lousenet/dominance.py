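"""Dominance hierarchy from decided agonistic interactions via David's scores.

David's score credits each individual with its dyadic win proportions,
weighted by the success of its opponents:

    w_i  = sum_j P_ij          (direct wins)
    w2_i = sum_j P_ij * w_j    (wins weighted by opponents' wins)
    l_i  = sum_j P_ji          (direct losses)
    l2_i = sum_j P_ji * l_j    (losses weighted by opponents' losses)
    DS_i = w_i + w2_i - l_i - l2_i

where ``P_ij`` is the proportion of the dyad's decided interactions won by
``i``.  Dyads that never interacted contribute zero to every sum.  The
normalized score ``normDS = (DS + N(N-1)/2) / N`` lies in ``[0, N-1]``;
ordinal ranks are assigned by descending normDS with rank 1 the highest.

Agonistic records are pooled across the whole study into one global
hierarchy (female macaque hierarchies are stable within a year), and that
rank is attached to every season row downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import logger


@dataclass
class DominanceResult:
    ids: list[str]
    P: np.ndarray            # dyadic win proportions; NaN where undefined
    n_interactions: np.ndarray
    w: np.ndarray
    w2: np.ndarray
    l: np.ndarray
    l2: np.ndarray
    DS: np.ndarray
    normDS: np.ndarray
    rank: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids, "w": self.w, "w2": self.w2, "l": self.l,
            "l2": self.l2, "DS": self.DS, "normDS": self.normDS,
            "rank": [self.rank[i] for i in self.ids],
        })


def win_proportions(agonistic: pd.DataFrame, ids: list[str],
                    chance_corrected: bool = False
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Dyadic win-proportion matrix ``P`` and interaction-count matrix ``n``.

    ``P[i, j]`` is the share of the dyad's decided interactions won by ``i``;
    entries for dyads that never interacted are NaN (they contribute nothing
    to the score sums).  With ``chance_corrected`` the proportions are
    replaced by ``Dij = P_ij - (P_ij - 0.5) / (n_ij + 1)``, which shrinks
    sparse dyads toward chance.
    """
    ids = list(ids)
    index = {f: i for i, f in enumerate(ids)}
    unknown = (set(agonistic["winner"]) | set(agonistic["loser"])) - set(ids)
    if unknown:
        raise ValueError(f"agonistic records name unknown ids: {sorted(unknown)}")
    n = len(ids)
    wins = np.zeros((n, n))
    for winner, loser in zip(agonistic["winner"], agonistic["loser"]):
        wins[index[winner], index[loser]] += 1
    totals = wins + wins.T
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(totals > 0, wins / np.where(totals > 0, totals, 1), np.nan)
    if chance_corrected:
        P = np.where(totals > 0, P - (P - 0.5) / (totals + 1), np.nan)
    np.fill_diagonal(P, np.nan)
    return P, totals


def davids_scores(P: np.ndarray, ids: list[str],
                  n_interactions: np.ndarray | None = None) -> DominanceResult:
    """Compute w, w2, l, l2, DS and normDS from a win-proportion matrix."""
    N = len(ids)
    Pz = np.nan_to_num(P, nan=0.0)
    w = Pz.sum(axis=1)
    l = Pz.sum(axis=0)
    w2 = Pz @ w
    l2 = Pz.T @ l
    DS = w + w2 - l - l2
    normDS = (DS + N * (N - 1) / 2) / N if N else DS
    result = DominanceResult(
        ids=list(ids), P=P,
        n_interactions=(n_interactions if n_interactions is not None
                        else np.zeros((N, N))),
        w=w, w2=w2, l=l, l2=l2, DS=DS, normDS=normDS, rank={})
    result.rank = ordinal_ranks(normDS, ids)
    return result


def ordinal_ranks(normDS: np.ndarray, ids: list[str]) -> dict[str, int]:
    """Ordinal rank from descending normDS; rank 1 = highest score.

    Ties are broken by identifier sort order and logged.
    """
    order = sorted(range(len(ids)), key=lambda i: (-normDS[i], ids[i]))
    scores = np.asarray(normDS, dtype=float)
    if len(np.unique(scores)) < len(scores):
        tied = [ids[i] for i in range(len(ids))
                if (scores == scores[i]).sum() > 1]
        logger.warning("normDS ties broken by id order among %s", sorted(set(tied)))
    return {ids[i]: r + 1 for r, i in enumerate(order)}


def dominance_from_records(agonistic: pd.DataFrame, ids: list[str],
                           chance_corrected: bool = False) -> DominanceResult:
    """Pool all agonistic records into one global hierarchy."""
    P, totals = win_proportions(agonistic, ids, chance_corrected)
    return davids_scores(P, ids, totals)
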