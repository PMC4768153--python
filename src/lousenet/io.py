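"""Tabular input/output for behavioral-scan, agonistic and attribute data.

Three CSV schemas (UTF-8, comma delimiter, ``.`` decimal, identifiers are
opaque strings):

``scans.csv``
    One row per focal minute-scan in a social or self-directed grooming /
    contact state: ``focal_id, partner_id, season, behavior, egg_picks,
    egg_pick_target``.  ``behavior`` is one of ``contact``, ``groom_given``,
    ``groom_received``, ``self_groom``.  Louse-egg-pick counts belong to the
    groomee: the focal herself for ``groom_received`` and ``self_groom`` rows,
    the partner for ``groom_given`` rows.

``agonistic.csv``
    One row per decided agonistic interaction: ``winner, loser, season``.

``attributes.csv``
    One row per female x season: ``id, season, reproductive_state, treated``.

All loaders validate every row and raise :class:`SchemaError` naming the
offending line.  Writing then reading any table is the identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Sequence

import pandas as pd

logger = logging.getLogger("lousenet")

SEASONS = ("winter", "spring", "summer", "fall")

BEHAVIORS = ("contact", "groom_given", "groom_received", "self_groom")
#: behaviors on which egg-pick counts may occur
GROOMING_BEHAVIORS = ("groom_given", "groom_received", "self_groom")
#: behaviors counted as body contact (grooming is contact)
CONTACT_BEHAVIORS = ("contact", "groom_given", "groom_received")

SCAN_COLUMNS = ["focal_id", "partner_id", "season", "behavior",
                "egg_picks", "egg_pick_target"]
AGONISTIC_COLUMNS = ["winner", "loser", "season"]
ATTRIBUTE_COLUMNS = ["id", "season", "reproductive_state", "treated"]

REPRO_STATES = ("active", "not_active")
TREATED_STATES = ("yes", "no")

# study-specific season bins (month -> season); Dec is outside the window
# but mapped to winter for robustness of the date helper.
_MONTH_TO_SEASON = {1: "winter", 2: "winter", 3: "winter",
                    4: "spring", 5: "spring", 6: "spring",
                    7: "summer", 8: "summer", 9: "summer",
                    10: "fall", 11: "fall", 12: "winter"}


class SchemaError(ValueError):
    """A tabular input violated its documented schema."""


@dataclass(frozen=True)
class ScanRecord:
    focal_id: str
    partner_id: str | None
    season: str
    behavior: str
    egg_picks: int
    egg_pick_target: str | None


@dataclass(frozen=True)
class AgonisticRecord:
    winner: str
    loser: str
    season: str


@dataclass(frozen=True)
class AttributeRecord:
    id: str
    season: str
    reproductive_state: str
    treated: str


def season_of_date(d: date | str) -> str:
    """Map an ISO date to the study's season bins.

    Jan-Mar winter (mating season), Apr-Jun spring, Jul-Sep summer,
    Oct-Nov fall.
    """
    if isinstance(d, str):
        d = date.fromisoformat(d)
    return _MONTH_TO_SEASON[d.month]


def _require_columns(df: pd.DataFrame, expected: Sequence[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; "
                          f"found {list(df.columns)}")


def _read_csv(path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    _require_columns(df, columns, path)
    return df


def validate_scans(df: pd.DataFrame, source: str = "<scans>") -> pd.DataFrame:
    """Validate a scan table in place and return it with typed columns.

    Line numbers in error messages are 1-based data-row numbers
    (header = line 1).
    """
    _require_columns(df, SCAN_COLUMNS, source)
    df = df.copy()
    df["partner_id"] = df["partner_id"].replace({"": None}).astype(object)
    df["egg_pick_target"] = df["egg_pick_target"].replace({"": None}).astype(object)
    try:
        df["egg_picks"] = pd.to_numeric(df["egg_picks"], errors="raise").astype(int)
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{source}: non-integer egg_picks column ({exc})")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        line = f"{source}:{i}"
        if row.behavior not in BEHAVIORS:
            raise SchemaError(f"{line}: unknown behavior code {row.behavior!r}")
        if row.season not in SEASONS:
            raise SchemaError(f"{line}: unknown season label {row.season!r}")
        if row.egg_picks < 0:
            raise SchemaError(f"{line}: negative egg_picks {row.egg_picks}")
        if row.behavior == "self_groom":
            if row.partner_id is not None:
                raise SchemaError(f"{line}: self_groom row has a partner")
        else:
            if row.partner_id is None:
                raise SchemaError(f"{line}: social row lacks a partner")
            if row.partner_id == row.focal_id:
                raise SchemaError(f"{line}: partner equals focal")
        if row.egg_picks > 0 and row.behavior not in GROOMING_BEHAVIORS:
            raise SchemaError(f"{line}: egg_picks on non-grooming behavior "
                              f"{row.behavior!r}")
        if row.behavior in GROOMING_BEHAVIORS:
            expected_target = (row.focal_id
                               if row.behavior in ("groom_received", "self_groom")
                               else row.partner_id)
            if row.egg_pick_target is not None and row.egg_pick_target != expected_target:
                raise SchemaError(
                    f"{line}: egg_pick_target {row.egg_pick_target!r} does not "
                    f"match the groomee {expected_target!r}")
    # fill in attribution where omitted
    groomee = df["focal_id"].where(
        df["behavior"].isin(["groom_received", "self_groom"]), df["partner_id"])
    df["egg_pick_target"] = df["egg_pick_target"].where(
        df["egg_pick_target"].notna() & df["behavior"].isin(GROOMING_BEHAVIORS),
        groomee.where(df["behavior"].isin(GROOMING_BEHAVIORS), None))
    return df[SCAN_COLUMNS]


def load_scans(path) -> pd.DataFrame:
    """Load and validate a scan table; returns a typed DataFrame."""
    df = _read_csv(path, SCAN_COLUMNS)
    df = validate_scans(df, source=str(path))
    logger.info("loaded %d scan rows from %s", len(df), path)
    return df


def validate_agonistic(df: pd.DataFrame, source: str = "<agonistic>") -> pd.DataFrame:
    _require_columns(df, AGONISTIC_COLUMNS, source)
    df = df.copy()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.winner == row.loser:
            raise SchemaError(f"{source}:{i}: winner equals loser ({row.winner!r})")
        if row.season not in SEASONS:
            raise SchemaError(f"{source}:{i}: unknown season label {row.season!r}")
    return df[AGONISTIC_COLUMNS]


def load_agonistic(path) -> pd.DataFrame:
    df = _read_csv(path, AGONISTIC_COLUMNS)
    df = validate_agonistic(df, source=str(path))
    logger.info("loaded %d agonistic rows from %s", len(df), path)
    return df


def validate_attributes(df: pd.DataFrame, source: str = "<attributes>") -> pd.DataFrame:
    _require_columns(df, ATTRIBUTE_COLUMNS, source)
    df = df.copy()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.season not in SEASONS:
            raise SchemaError(f"{source}:{i}: unknown season label {row.season!r}")
        if row.reproductive_state not in REPRO_STATES:
            raise SchemaError(f"{source}:{i}: unknown reproductive_state "
                              f"{row.reproductive_state!r}")
        if row.treated not in TREATED_STATES:
            raise SchemaError(f"{source}:{i}: unknown treated flag {row.treated!r}")
    dupes = df.duplicated(subset=["id", "season"])
    if dupes.any():
        raise SchemaError(f"{source}: duplicate id x season rows at data rows "
                          f"{[i + 2 for i in df.index[dupes]]}")
    return df[ATTRIBUTE_COLUMNS]


def load_attributes(path) -> pd.DataFrame:
    df = _read_csv(path, ATTRIBUTE_COLUMNS)
    df = validate_attributes(df, source=str(path))
    logger.info("loaded %d attribute rows from %s", len(df), path)
    return df


def check_coverage(scans: pd.DataFrame, attributes: pd.DataFrame) -> list[tuple[str, str]]:
    """Report (id, season) cells present in scans but absent from attributes.

    Missing cells are logged as warnings; downstream model assembly treats
    them as errors.
    """
    have = set(zip(attributes["id"], attributes["season"]))
    need = set(zip(scans["focal_id"], scans["season"]))
    missing = sorted(need - have)
    for cell in missing:
        logger.warning("attributes missing id x season cell %s", cell)
    return missing


def write_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a DataFrame as CSV, optionally with a leading ``#`` comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def write_scans(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    out = df.copy()
    out["partner_id"] = out["partner_id"].fillna("")
    out["egg_pick_target"] = out["egg_pick_target"].fillna("")
    write_table(out[SCAN_COLUMNS], path, header_comment)


def write_agonistic(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    write_table(df[AGONISTIC_COLUMNS], path, header_comment)


def write_attributes(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    write_table(df[ATTRIBUTE_COLUMNS], path, header_comment)


def records_from_scans(df: pd.DataFrame) -> list[ScanRecord]:
    """Materialize a validated scan table as frozen records."""
    return [ScanRecord(r.focal_id, r.partner_id, r.season, r.behavior,
                       int(r.egg_picks), r.egg_pick_target)
            for r in df.itertuples(index=False)]
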