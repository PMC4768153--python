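"""Synthetic focal-observation datasets with known ground truth.

The generator emulates the design of a year-long focal study of ~20 adult
female Japanese macaques observed over four seasons (winter = mating season,
spring, summer = birth season, fall): per-female minute-scan budgets,
female-female dyadic contact and grooming driven by individual
gregariousness and heavy-tailed dyadic affinities, up-hierarchy grooming, a
stable linear dominance hierarchy with occasional upsets, seasonal
reproductive-state assignment (10 females in oestrus in winter, 7 mothers in
the other seasons), anthelminthic treatment of 11 females, and a latent
per-female per-season lice intensity

    lambda = exp(intercept + season_offset
                 + beta_degree[season] * z(degree)
                 + beta_repro * active + beta_treatment * treated + noise)

realized as negative-binomial louse-egg-pick counts on every scan in which
the female is groomed (or grooms herself).  ``z(degree)`` is the within-
season z-score of the female's realized contact-network degree, so seeded
coefficients live on (approximately) the scale downstream models estimate.

Seasons are generated independently; there is no carry-over of lice
intensity and no male/juvenile agents.  All randomness flows from the
config seed, so a config generates byte-identical datasets on every call.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .io import SEASONS
from .networks import build_contact_network


class ConfigError(ValueError):
    """Invalid synthetic-study configuration."""


def _default_sociality() -> dict:
    return {
        "gregariousness_shape": 4.0,   # Gamma shape, mean 1
        "affinity_shape": 0.4,         # heavy-tailed dyadic affinities, mean 1
        "w_contact": 0.05,             # plain body contact weight per dyad
        "w_groom": 0.11,               # grooming weight per dyad
        "w_self": 1.0,                 # self-grooming weight per focal
        "up_hierarchy_bias": 0.6,      # P(groom up the hierarchy)
        # seasonal sociality multiplier: fewer partners in summer/fall
        "season_factor": {"winter": 1.0, "spring": 1.0,
                          "summer": 0.6, "fall": 0.7},
    }


def _default_lice_model() -> dict:
    return {
        "intercept": np.log(0.7),      # ~0.7 picks per grooming minute-scan
        "season_offsets": {"winter": 0.0, "spring": 0.1,
                           "summer": 0.5, "fall": 0.4},
        # negative degree effect in the two reproductive seasons
        "beta_degree_by_season": {"winter": -0.5, "spring": 0.0,
                                  "summer": -0.5, "fall": 0.0},
        "beta_repro": 0.15,
        "beta_treatment": -0.1,
        "noise_sd": 0.3,
        "overdispersion": 1.5,         # NB size k; var = m + m^2/k
    }


@dataclass
class SynthConfig:
    n_females: int = 20
    seasons: tuple[str, ...] = SEASONS
    scans_per_female_per_season: int = 96
    n_active_winter: int = 10
    n_mothers: int = 7
    n_treated: int = 11
    n_agonistic_per_season: int = 150
    upset_probability: float = 0.1
    sociality_params: dict = field(default_factory=_default_sociality)
    lice_model: dict = field(default_factory=_default_lice_model)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_females", "scans_per_female_per_season",
                     "n_active_winter", "n_mothers", "n_treated",
                     "n_agonistic_per_season"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_active_winter > self.n_females:
            raise ConfigError("n_active_winter exceeds n_females")
        if self.n_mothers > self.n_females:
            raise ConfigError("n_mothers exceeds n_females")
        if self.n_treated > self.n_females:
            raise ConfigError("n_treated exceeds n_females")
        if tuple(self.seasons) != SEASONS:
            raise ConfigError(f"seasons must be {SEASONS}, got {self.seasons}")
        for s in self.lice_model["beta_degree_by_season"]:
            if s not in SEASONS:
                raise ConfigError(f"unknown season label {s!r} in lice model")

    def null(self) -> "SynthConfig":
        """Copy with every centrality coefficient forced to zero."""
        lice = {**self.lice_model,
                "beta_degree_by_season": {s: 0.0 for s in SEASONS}}
        return dataclasses.replace(self, lice_model=lice)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["seasons"] = list(d["seasons"])
        return json.dumps(d, indent=2, default=float)


@dataclass
class StudyDataset:
    scans: pd.DataFrame
    agonistic: pd.DataFrame
    attributes: pd.DataFrame
    truth: SynthConfig
    females: list[str]
    latent: dict = field(default_factory=dict)   # strengths, lambdas, z(degree)

    def write(self, outdir, comment: str | None = None) -> None:
        outdir = Path(outdir)
        lio.write_scans(self.scans, outdir / "scans.csv", comment)
        lio.write_agonistic(self.agonistic, outdir / "agonistic.csv", comment)
        lio.write_attributes(self.attributes, outdir / "attributes.csv", comment)
        (outdir / "truth.json").write_text(self.truth.to_json())


def _female_ids(n: int) -> list[str]:
    return [f"f{i + 1:02d}" for i in range(n)]


def _assign_attributes(config: SynthConfig, rng: np.random.Generator,
                       females: list[str]) -> pd.DataFrame:
    n = config.n_females
    oestrus = rng.choice(n, size=config.n_active_winter, replace=False)
    # mothers are drawn from the winter-oestrous females where possible
    # (females that conceived in the mating season give birth in summer)
    pool = oestrus if config.n_mothers <= config.n_active_winter else np.arange(n)
    mothers = rng.choice(pool, size=config.n_mothers, replace=False)
    treated = rng.choice(n, size=config.n_treated, replace=False)
    rows = []
    for season in config.seasons:
        active = set(oestrus) if season == "winter" else set(mothers)
        for i, f in enumerate(females):
            rows.append({"id": f, "season": season,
                         "reproductive_state": ("active" if i in active
                                                else "not_active"),
                         "treated": "yes" if i in set(treated) else "no"})
    return pd.DataFrame(rows)


def _generate_scans(config: SynthConfig, rng: np.random.Generator,
                    females: list[str]) -> pd.DataFrame:
    """Minute-scan rows for all focals and seasons, egg_picks still zero."""
    n = config.n_females
    soc = config.sociality_params
    greg = rng.gamma(soc["gregariousness_shape"],
                     1.0 / soc["gregariousness_shape"], size=n)
    S = config.scans_per_female_per_season
    cols = {c: [] for c in ("focal_id", "partner_id", "season", "behavior")}

    for season in config.seasons:
        factor = soc["season_factor"].get(season, 1.0)
        aff = rng.gamma(soc["affinity_shape"], 1.0 / soc["affinity_shape"],
                        size=(n, n))
        aff = np.triu(aff, 1) + np.triu(aff, 1).T      # symmetric dyads
        for i in range(n):
            dyad = greg[i] * greg * aff[i] * factor
            dyad[i] = 0.0
            weights = np.concatenate([
                soc["w_contact"] * dyad,               # contact with each j
                soc["w_groom"] * dyad,                 # grooming with each j
                [soc["w_self"]],
            ])
            counts = rng.multinomial(S, weights / weights.sum())
            contact_c, groom_c, self_c = counts[:n], counts[n:2 * n], counts[-1]
            for j in range(n):
                for _ in range(contact_c[j]):
                    cols["focal_id"].append(females[i])
                    cols["partner_id"].append(females[j])
                    cols["season"].append(season)
                    cols["behavior"].append("contact")
                if groom_c[j]:
                    # lower-index females are higher ranking; grooming tends
                    # to flow up the hierarchy
                    p_up = (soc["up_hierarchy_bias"] if j < i
                            else 1.0 - soc["up_hierarchy_bias"])
                    n_given = rng.binomial(groom_c[j], p_up)
                    for behavior, count in (("groom_given", n_given),
                                            ("groom_received",
                                             groom_c[j] - n_given)):
                        for _ in range(count):
                            cols["focal_id"].append(females[i])
                            cols["partner_id"].append(females[j])
                            cols["season"].append(season)
                            cols["behavior"].append(behavior)
            for _ in range(self_c):
                cols["focal_id"].append(females[i])
                cols["partner_id"].append(None)
                cols["season"].append(season)
                cols["behavior"].append("self_groom")

    scans = pd.DataFrame(cols)
    scans["egg_picks"] = 0
    groomee = scans["focal_id"].where(
        scans["behavior"].isin(["groom_received", "self_groom"]),
        scans["partner_id"])
    scans["egg_pick_target"] = groomee.where(
        scans["behavior"].isin(lio.GROOMING_BEHAVIORS), None)
    return scans


def _seed_lice(config: SynthConfig, rng: np.random.Generator,
               scans: pd.DataFrame, attributes: pd.DataFrame,
               females: list[str]) -> tuple[pd.DataFrame, dict]:
    """Draw egg-pick counts on grooming rows from the latent intensity model."""
    lice = config.lice_model
    k = float(lice["overdispersion"])
    attr = attributes.set_index(["id", "season"])
    lambdas: dict[tuple[str, str], float] = {}
    zdeg_map: dict[tuple[str, str], float] = {}
    for season in config.seasons:
        net = build_contact_network(scans, season, females)
        deg = {f: 0 for f in females}
        for u, v, _ in net.edges:
            deg[u] += 1
            deg[v] += 1
        degrees = np.array([deg[f] for f in females], float)
        sd = degrees.std()
        z = (degrees - degrees.mean()) / sd if sd > 0 else np.zeros_like(degrees)
        for f, zd in zip(females, z):
            zdeg_map[(f, season)] = float(zd)
            a = attr.loc[(f, season)]
            eta = (lice["intercept"] + lice["season_offsets"][season]
                   + lice["beta_degree_by_season"][season] * zd
                   + lice["beta_repro"] * (a["reproductive_state"] == "active")
                   + lice["beta_treatment"] * (a["treated"] == "yes")
                   + rng.normal(0.0, lice["noise_sd"]))
            lambdas[(f, season)] = float(np.exp(eta))

    scans = scans.copy()
    target_rows = scans["egg_pick_target"].notna()
    idx = scans.index[target_rows]
    lam = np.array([lambdas[(t, s)] for t, s in
                    zip(scans.loc[idx, "egg_pick_target"],
                        scans.loc[idx, "season"])])
    # negative binomial as a gamma-poisson mixture, mean lam, size k
    rates = rng.gamma(k, lam / k)
    scans.loc[idx, "egg_picks"] = rng.poisson(rates)
    return scans, {"lambda": lambdas, "z_degree": zdeg_map}


def _generate_agonistic(config: SynthConfig, rng: np.random.Generator,
                        females: list[str]) -> pd.DataFrame:
    """Decided agonistic interactions from a transitive latent order.

    Latent strength decreases with female index (f01 strongest); the
    stronger female wins with probability 1 - upset_probability.
    """
    n = config.n_females
    rows = []
    for season in config.seasons:
        for _ in range(config.n_agonistic_per_season):
            i, j = rng.choice(n, size=2, replace=False)
            hi, lo = (i, j) if i < j else (j, i)
            if rng.random() < config.upset_probability:
                hi, lo = lo, hi
            rows.append({"winner": females[hi], "loser": females[lo],
                         "season": season})
    return pd.DataFrame(rows)


def generate_dataset(config: SynthConfig) -> StudyDataset:
    """Generate one complete study dataset; deterministic given config.seed."""
    rng = np.random.default_rng(config.seed)
    females = _female_ids(config.n_females)
    attributes = _assign_attributes(config, rng, females)
    scans = _generate_scans(config, rng, females)
    scans, latent = _seed_lice(config, rng, scans, attributes, females)
    agonistic = _generate_agonistic(config, rng, females)
    latent["strength_order"] = list(females)   # f01 highest latent strength
    return StudyDataset(scans=scans, agonistic=agonistic,
                        attributes=attributes, truth=config,
                        females=females, latent=latent)


def generate_null_dataset(config: SynthConfig) -> StudyDataset:
    """As :func:`generate_dataset` with all centrality coefficients zeroed."""
    return generate_dataset(config.null())
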