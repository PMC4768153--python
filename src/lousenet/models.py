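"""Gaussian mixed models linking centrality to lice load, with LRT pruning.

The modelling frame has one row per female x season.  The response is
log-transformed, z-standardized lice load; the centrality predictor is
square-root-transformed and z-standardized; rank enters as standardized
ordinal.  Season (reference winter), reproductive state (reference
not_active) and anthelminthic treatment (reference not treated) are fixed
control factors, and female identity is a random intercept.

The full specification contains the three-way interaction
centrality x season x reproductive-state and its three two-way children.
Interactions are pruned backward by likelihood-ratio tests, highest order
first: an interaction is dropped when its LRT p exceeds 0.100, kept as
"marginal" for p in (0.050, 0.100], and kept otherwise.  Main effects and
control factors are never pruned.  The final model is compared by LRT with a
null model containing only control factors not involved in any retained
interaction, plus the random effect.

All fits maximize the full likelihood (ML, not REML) so that every nested
LRT in the procedure is valid.  For a single random intercept the ML
problem reduces to a one-dimensional profiled likelihood in the variance
ratio ``lambda = sigma^2_id / sigma^2_res``: for fixed lambda the GLS
estimates and both variances have closed forms through the Woodbury
identity, so the optimizer only searches lambda.  This makes a fit cheap
and exactly deterministic, which the network-randomization test (thousands
of refits per dataset) relies on; agreement with a general-purpose mixed
-model implementation is enforced in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import SEASONS, logger

MEASURES = ("degree", "strength", "in_degree", "in_strength")

MAIN_TERMS = ("centrality", "season", "repro", "rank", "treated")
TWO_WAY_TERMS = ("centrality:season", "centrality:repro", "season:repro")
THREE_WAY_TERM = "centrality:season:repro"
FULL_TERMS = MAIN_TERMS + TWO_WAY_TERMS + (THREE_WAY_TERM,)
CONTROL_FACTORS = ("season", "repro", "rank", "treated")

_SEASON_LEVELS = ("spring", "summer", "fall")  # winter is the reference


class DegenerateColumnError(ValueError):
    """A column to be standardized is constant."""


@dataclass
class ModelFrame:
    """Assembled, transformed modelling table plus its bookkeeping."""
    data: pd.DataFrame          # response, centrality, season, repro_active,
                                # treated_yes, rank, id
    measure: str
    offset: float               # constant added inside log(lice_load + c)
    centrality_raw: np.ndarray  # untransformed centrality, for permutation reuse
    n_excluded: int = 0

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ModelFit:
    terms: tuple[str, ...]
    names: list[str]
    params: np.ndarray
    bse: np.ndarray
    group_var: float
    resid_var: float
    loglik: float
    converged: bool
    n_obs: int

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.names, "estimate": self.params,
                             "se": self.bse})


@dataclass
class PruneStep:
    term: str
    chi2: float
    df: int
    p: float
    decision: str               # dropped | kept | kept_marginal | protected


@dataclass
class LRTResult:
    chi2: float
    df: int
    p: float
    skipped: bool = False
    note: str = ""


def _standardize(x: np.ndarray, name: str) -> np.ndarray:
    sd = float(np.std(x))
    if sd < 1e-12:
        raise DegenerateColumnError(
            f"column {name!r} is constant; cannot standardize")
    return (x - float(np.mean(x))) / sd


def build_frame(lice: pd.DataFrame, centrality: pd.DataFrame,
                rank: dict[str, int], attributes: pd.DataFrame,
                measure: str, offset: float | None = None) -> ModelFrame:
    """Merge stage tables into one standardized modelling frame.

    ``offset`` defaults to half the smallest positive lice load among
    included rows (used as ``log(lice_load + offset)``); rows with undefined
    lice load are excluded and logged.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown centrality measure {measure!r}")
    df = lice.merge(centrality[["id", "season", measure]], on=["id", "season"],
                    how="left")
    df = df.merge(attributes.rename(columns={"id": "id"}), on=["id", "season"],
                  how="left")
    if df[measure].isna().any() or df["reproductive_state"].isna().any():
        missing = df.loc[df[measure].isna() | df["reproductive_state"].isna(),
                         ["id", "season"]]
        raise ValueError(f"frame tables do not cover the same id x season "
                         f"grid; missing cells:\n{missing}")
    undefined = df["lice_load"].isna()
    if undefined.any():
        logger.warning("excluding %d rows with undefined lice load",
                       int(undefined.sum()))
    df = df[~undefined].reset_index(drop=True)
    if df.empty:
        raise ValueError("empty modelling frame")

    load = df["lice_load"].to_numpy(float)
    if offset is None:
        positive = load[load > 0]
        if len(positive) == 0:
            raise DegenerateColumnError("all lice loads are zero")
        offset = float(positive.min()) / 2.0
    raw = df[measure].to_numpy(float)
    out = pd.DataFrame({
        "id": df["id"],
        "season": pd.Categorical(df["season"], categories=SEASONS),
        "response": _standardize(np.log(load + offset), "response"),
        "centrality": _standardize(np.sqrt(raw), "centrality"),
        "rank": _standardize(df["id"].map(rank).to_numpy(float), "rank"),
        "repro_active": (df["reproductive_state"] == "active").astype(float),
        "treated_yes": (df["treated"] == "yes").astype(float),
    })
    return ModelFrame(out, measure, offset, centrality_raw=raw,
                      n_excluded=int(undefined.sum()))


def replace_centrality(frame: ModelFrame, raw: np.ndarray) -> ModelFrame:
    """New frame with a different raw centrality vector (re-standardized).

    Used by the network-randomization test, where rewiring changes the
    centrality distribution every run.
    """
    data = frame.data.copy()
    data["centrality"] = _standardize(np.sqrt(np.asarray(raw, float)),
                                      "centrality")
    return ModelFrame(data, frame.measure, frame.offset, np.asarray(raw, float),
                      frame.n_excluded)


def design_matrix(frame: ModelFrame, terms: tuple[str, ...]
                  ) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects design matrix for a term list, intercept always first.

    Factor codings: season has reference level winter; reproductive state
    reference not_active; treatment reference not treated.
    """
    df = frame.data
    n = len(df)
    season_d = {lvl: (df["season"] == lvl).to_numpy(float)
                for lvl in _SEASON_LEVELS}
    cent = df["centrality"].to_numpy(float)
    active = df["repro_active"].to_numpy(float)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]

    def add(name: str, col: np.ndarray) -> None:
        cols.append(col)
        names.append(name)

    for term in terms:
        if term == "centrality":
            add("centrality", cent)
        elif term == "season":
            for lvl in _SEASON_LEVELS:
                add(f"season[{lvl}]", season_d[lvl])
        elif term == "repro":
            add("repro[active]", active)
        elif term == "rank":
            add("rank", df["rank"].to_numpy(float))
        elif term == "treated":
            add("treated[yes]", df["treated_yes"].to_numpy(float))
        elif term == "centrality:season":
            for lvl in _SEASON_LEVELS:
                add(f"centrality:season[{lvl}]", cent * season_d[lvl])
        elif term == "centrality:repro":
            add("centrality:repro[active]", cent * active)
        elif term == "season:repro":
            for lvl in _SEASON_LEVELS:
                add(f"season[{lvl}]:repro[active]", season_d[lvl] * active)
        elif term == THREE_WAY_TERM:
            for lvl in _SEASON_LEVELS:
                add(f"centrality:season[{lvl}]:repro[active]",
                    cent * season_d[lvl] * active)
        else:
            raise ValueError(f"unknown model term {term!r}")
    return np.column_stack(cols), names


def _profile_loglik(lam: float, XtX, Xty, yty, Gx, Gy, sizes, n):
    """Profiled ML log-likelihood at variance ratio lam (beta, sigma profiled
    out).  Returns (loglik, beta, sigma2, XtVX)."""
    c = lam / (1.0 + lam * sizes)                     # per-group shrinkage
    XtVX = XtX - (Gx * c[:, None]).T @ Gx
    XtVy = Xty - (Gx * c[:, None]).T @ Gy
    beta = np.linalg.solve(XtVX, XtVy)
    # r' V^-1 r = y'V^-1 y - 2 b'X'V^-1 y + b'X'V^-1 X b
    yVy = yty - float(Gy @ (c * Gy))
    rss = yVy - 2 * float(beta @ XtVy) + float(beta @ (XtVX @ beta))
    rss = max(rss, 1e-300)
    sigma2 = rss / n
    ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2)
                 + float(np.log1p(lam * sizes).sum()) + n)
    return ll, beta, sigma2, XtVX


def fit_lmm(frame: ModelFrame, terms: tuple[str, ...],
            lam_max: float = 200.0) -> ModelFit:
    """ML fit of a Gaussian random-intercept model for the given fixed terms.

    The variance ratio is found by bounded one-dimensional optimization of
    the profiled likelihood; the zero boundary (no individual variance,
    i.e. ordinary least squares) is checked explicitly.
    """
    X, names = design_matrix(frame, terms)
    y = frame.data["response"].to_numpy(float)
    codes, _ = pd.factorize(frame.data["id"], sort=True)
    n, p = X.shape
    n_groups = codes.max() + 1
    sizes = np.bincount(codes, minlength=n_groups).astype(float)
    Gx = np.zeros((n_groups, p))
    np.add.at(Gx, codes, X)
    Gy = np.bincount(codes, weights=y, minlength=n_groups)
    XtX, Xty, yty = X.T @ X, X.T @ y, float(y @ y)

    def negll(lam: float) -> float:
        return -_profile_loglik(lam, XtX, Xty, yty, Gx, Gy, sizes, n)[0]

    try:
        res = optimize.minimize_scalar(negll, bounds=(0.0, lam_max),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        lam = float(res.x)
        if negll(0.0) <= res.fun:       # boundary: OLS beats interior optimum
            lam = 0.0
        ll, beta, sigma2, XtVX = _profile_loglik(lam, XtX, Xty, yty,
                                                 Gx, Gy, sizes, n)
        cov = sigma2 * np.linalg.inv(XtVX)
        bse = np.sqrt(np.diag(cov))
        converged = bool(np.isfinite(ll))
    except np.linalg.LinAlgError:
        logger.warning("singular design for terms %s; fit flagged "
                       "non-converged", terms)
        return ModelFit(terms, names, np.full(p, np.nan), np.full(p, np.nan),
                        np.nan, np.nan, -np.inf, False, n)
    return ModelFit(terms, names, beta, bse, group_var=lam * sigma2,
                    resid_var=sigma2, loglik=float(ll), converged=converged,
                    n_obs=n)


def lrt(full: ModelFit, reduced: ModelFit) -> LRTResult:
    """Likelihood-ratio test of nested ML fits; chi2 clipped at 0."""
    if not (full.converged and reduced.converged):
        raise RuntimeError("LRT on a non-converged fit")
    df = len(full.names) - len(reduced.names)
    chi2 = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    if df == 0:
        return LRTResult(chi2, 0, 1.0, skipped=True, note="identical df")
    return LRTResult(chi2, df, float(stats.chi2.sf(chi2, df)))


def _decision(p: float, drop_at: float = 0.100, marginal_at: float = 0.050) -> str:
    if p > drop_at:
        return "dropped"
    if p > marginal_at:
        return "kept_marginal"
    return "kept"


def prune_interactions(frame: ModelFrame,
                       drop_at: float = 0.100, marginal_at: float = 0.050
                       ) -> tuple[ModelFit, list[PruneStep]]:
    """Backward LRT elimination of interactions, highest order first.

    The three-way interaction is tested against the model without it; if it
    survives, its two-way children are protected and pruning stops.  If it
    is dropped, the two-way interactions are eliminated one at a time
    (always the currently least informative, i.e. largest LRT p) until every
    remaining one improves fit at the stated thresholds.  Main effects and
    control factors are never candidates.
    """
    trace: list[PruneStep] = []
    terms = list(FULL_TERMS)
    full = fit_lmm(frame, tuple(terms))
    reduced = fit_lmm(frame, tuple(t for t in terms if t != THREE_WAY_TERM))
    test = lrt(full, reduced)
    decision = _decision(test.p, drop_at, marginal_at)
    trace.append(PruneStep(THREE_WAY_TERM, test.chi2, test.df, test.p, decision))
    if decision == "dropped":
        terms.remove(THREE_WAY_TERM)
        current = reduced
        candidates = [t for t in terms if t in TWO_WAY_TERMS]
        while candidates:
            tests = {}
            for t in candidates:
                red = fit_lmm(frame, tuple(x for x in terms if x != t))
                tests[t] = (lrt(current, red), red)
            worst = max(candidates, key=lambda t: tests[t][0].p)
            wtest, wred = tests[worst]
            decision = _decision(wtest.p, drop_at, marginal_at)
            trace.append(PruneStep(worst, wtest.chi2, wtest.df, wtest.p,
                                   decision))
            if decision != "dropped":
                # remaining interactions all improve fit at least marginally
                for t in candidates:
                    if t != worst:
                        ttest, _ = tests[t]
                        trace.append(PruneStep(t, ttest.chi2, ttest.df, ttest.p,
                                               _decision(ttest.p, drop_at,
                                                         marginal_at)))
                break
            terms.remove(worst)
            candidates.remove(worst)
            current = wred
        final = current
    else:
        for t in TWO_WAY_TERMS:
            trace.append(PruneStep(t, np.nan, 0, np.nan, "protected"))
        final = full
    return final, trace


def null_terms_for(final_terms: tuple[str, ...]) -> tuple[str, ...]:
    """Control factors not involved in any retained interaction."""
    involved: set[str] = set()
    for t in final_terms:
        if ":" in t:
            involved.update(t.split(":"))
    return tuple(t for t in CONTROL_FACTORS if t not in involved)


def null_comparison(final: ModelFit, frame: ModelFrame) -> LRTResult:
    """LRT of the final model against the control-factors-only null model."""
    null_fit = fit_lmm(frame, null_terms_for(final.terms))
    result = lrt(final, null_fit)
    if result.df == 0:
        logger.info("final model equals null model; test skipped")
        return LRTResult(result.chi2, 0, 1.0, skipped=True,
                         note="final model identical to null model")
    return result


def variance_inflation(frame: ModelFrame, terms: tuple[str, ...]) -> pd.Series:
    """VIFs of the non-intercept design columns; values above 5 are logged."""
    X, names = design_matrix(frame, terms)
    vifs = {}
    for j in range(1, X.shape[1]):
        others = np.delete(X, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ beta
        tss = float(((X[:, j] - X[:, j].mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
        vifs[names[j]] = np.inf if r2 >= 1 else 1.0 / (1.0 - r2)
    out = pd.Series(vifs)
    high = out[out > 5]
    if len(high):
        logger.warning("variance inflation above 5 for: %s",
                       ", ".join(high.index))
    return out
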