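"""Per-female, per-season lice-load estimation from egg-picking counts.

Louse burden is estimated non-invasively from the conspicuous louse
egg-picking gesture macaques perform while grooming.  Every pick count is
attributed to the female being groomed (the focal herself on
``groom_received`` and ``self_groom`` rows, the partner on ``groom_given``
rows); the load statistic normalizes the total by observation effort:

    lice_load(id) = egg_pick_total(id)
                    / (grooming_received_scans(id) + self_groom_scans(id))

in picks per grooming minute-scan.  Grooming-received scans pool rows where
the female was groomed during her own focal follow (``groom_received``) and
rows where the focal groomed her (``groom_given`` with her as partner).
Self-grooming picks enter the numerator by default (they are removals of the
female's own eggs); ``include_self_picks=False`` restricts the numerator to
social grooming.

Rows with a zero denominator and zero picks are flagged missing and excluded
from modelling with a logged warning; a zero denominator with positive picks
is a data inconsistency and raises.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import SEASONS, logger


class LiceLoadError(ValueError):
    """Egg picks recorded for a female with no qualifying grooming scans."""


def lice_load_table(scans: pd.DataFrame, females: list[str],
                    seasons: tuple[str, ...] = SEASONS,
                    include_self_picks: bool = True) -> pd.DataFrame:
    """Lice-load table per female x season with all audit components.

    Columns: ``egg_pick_total``, ``grooming_received_scans``,
    ``self_groom_scans``, ``lice_load`` (NaN where undefined).
    """
    females = list(females)
    dropped = scans[scans["egg_pick_target"].notna()
                    & ~scans["egg_pick_target"].isin(females)]
    if len(dropped):
        logger.info("dropping %d egg-pick rows attributed to non-study groomees",
                    int((dropped["egg_picks"] > 0).sum()))

    rows = []
    for season in seasons:
        sub = scans[scans["season"] == season]
        received = sub[sub["behavior"] == "groom_received"].groupby("focal_id").size()
        given = sub[sub["behavior"] == "groom_given"].groupby("partner_id").size()
        self_g = sub[sub["behavior"] == "self_groom"].groupby("focal_id").size()
        pick_rows = sub if include_self_picks else sub[sub["behavior"] != "self_groom"]
        picks = (pick_rows[pick_rows["egg_pick_target"].isin(females)]
                 .groupby("egg_pick_target")["egg_picks"].sum())
        for f in females:
            recv = int(received.get(f, 0)) + int(given.get(f, 0))
            selfg = int(self_g.get(f, 0))
            total = int(picks.get(f, 0))
            denom = recv + selfg
            if denom == 0 and total > 0:
                raise LiceLoadError(
                    f"{f}/{season}: {total} egg picks but no grooming scans")
            if denom == 0:
                logger.warning("%s/%s: no grooming observations; lice load "
                               "undefined, row excluded from models", f, season)
                load = np.nan
            else:
                load = total / denom
            rows.append({"id": f, "season": season, "egg_pick_total": total,
                         "grooming_received_scans": recv,
                         "self_groom_scans": selfg, "lice_load": load})
    return pd.DataFrame(rows)
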