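"""Variance partitioning, randomization tests and distance models.

The population repeatability of a timing trait is

    R = s_a^2 / (s_a^2 + s_eps^2),

with the among-individual variance s_a^2 and residual variance s_eps^2
estimated by a REML linear mixed model with migration distance as a fixed
effect and colony and individual as random intercepts (individuals are
nested in colonies). Year is deliberately NOT a random effect, so
year-to-year behavioural adjustment contributes to the residual
(within-individual) variance. Individual-level repeatability substitutes
individual i's own residual variance: R_i = s_a^2 / (s_a^2 + s_i^2).

Within- vs between-individual variation is compared with a one-sided
randomization test on the difference of group medians, and the effect of
migration distance with OLS models compared against an intercept-only
null (F test, with the equivalent likelihood-ratio test also reported).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .geo import great_circle_km

PAIR_CONSTRAINT_KM = 250.0
N_PERMUTATIONS = 10_000
N_BOOTSTRAPS = 1_000


@dataclass
class PairSet:
    """Between-individual pairs under the 250-km colony/winter constraint."""

    pairs: pd.DataFrame   # columns: id_a, id_b, season_a, season_b, pair_distance_km
    constraint_km: float
    seed: int


def build_pairs(individuals: pd.DataFrame, constraint_km=PAIR_CONSTRAINT_KM,
                seed=0) -> PairSet:
    """All unordered pairs whose colonies AND winter centroids lie within
    ``constraint_km`` of each other.

    ``individuals`` needs columns: individual_id, colony_lon, colony_lat,
    winter_lon, winter_lat, seasons (list of season labels),
    median_distance_km. One season per individual is selected uniformly at
    random per pair (pairs need not share years); deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    recs = individuals.to_dict("records")
    for a, b in itertools.combinations(recs, 2):
        d_col = great_circle_km(a["colony_lon"], a["colony_lat"],
                                b["colony_lon"], b["colony_lat"])
        d_win = great_circle_km(a["winter_lon"], a["winter_lat"],
                                b["winter_lon"], b["winter_lat"])
        if d_col <= constraint_km and d_win <= constraint_km:
            rows.append({
                "id_a": a["individual_id"], "id_b": b["individual_id"],
                "season_a": a["seasons"][rng.integers(len(a["seasons"]))],
                "season_b": b["seasons"][rng.integers(len(b["seasons"]))],
                "pair_distance_km": 0.5 * (a["median_distance_km"] + b["median_distance_km"]),
            })
    if not rows:
        warnings.warn("no valid pairs under the distance constraints")
    cols = ["id_a", "id_b", "season_a", "season_b", "pair_distance_km"]
    return PairSet(pairs=pd.DataFrame(rows, columns=cols),
                   constraint_km=constraint_km, seed=seed)


def randomization_test(within, between, n_perm=N_PERMUTATIONS, seed=0):
    """One-sided randomization test of median(between) - median(within).

    Group labels are shuffled preserving group sizes; the p-value is the
    add-one estimate (1 + #{perm >= observed}) / (n_perm + 1), the
    probability of a random grouping producing a median difference at
    least as large as observed.
    """
    within = np.asarray(within, dtype=float)
    between = np.asarray(between, dtype=float)
    if len(within) == 0 or len(between) == 0:
        raise ValueError("both groups must be non-empty")
    observed = float(np.median(between) - np.median(within))
    pooled = np.concatenate([between, within])
    nb = len(between)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.broadcast_to(pooled, (n_perm, len(pooled))).copy(), axis=1)
    delta = np.median(perms[:, :nb], axis=1) - np.median(perms[:, nb:], axis=1)
    p = (1.0 + np.count_nonzero(delta >= observed)) / (n_perm + 1.0)
    return p, observed


def randomization_test_exhaustive(within, between):
    """Exact enumeration counterpart of ``randomization_test`` (small n)."""
    within = np.asarray(within, dtype=float)
    between = np.asarray(between, dtype=float)
    observed = float(np.median(between) - np.median(within))
    pooled = np.concatenate([between, within])
    nb = len(between)
    idx = np.arange(len(pooled))
    count, total = 0, 0
    for comb in itertools.combinations(idx, nb):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(comb)] = True
        d = np.median(pooled[sel]) - np.median(pooled[~sel])
        count += d >= observed - 1e-12
        total += 1
    return count / total, observed


@dataclass
class RepeatabilityResult:
    trait: str
    s_a2: float                 # among-individual variance
    s_eps2: float               # residual (within-individual) variance
    s_colony2: float
    R: float
    ci95: Optional[tuple] = None
    fixed_effects: dict = field(default_factory=dict)
    per_individual: Optional[pd.DataFrame] = None   # n_i, s_i2, R_i
    include_distance: bool = True
    singular: bool = False
    n_boot_failures: int = 0
    _data: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self):
        if not 0.0 <= self.R <= 1.0:
            raise ValueError("R outside [0, 1]")


def _fit_mixed(data, include_distance):
    fixed = "value ~ distance" if include_distance else "value ~ 1"
    multi_colony = data["colony_id"].nunique() > 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if multi_colony:
            md = smf.mixedlm(fixed, data, groups="colony_id", re_formula="1",
                             vc_formula={"individual": "0 + C(individual_id)"})
        else:
            md = smf.mixedlm(fixed, data, groups="individual_id", re_formula="1")
        fit = md.fit(reml=True)
    if multi_colony:
        s_colony2 = float(fit.cov_re.iloc[0, 0])
        s_a2 = float(fit.vcomp[0])
    else:
        s_colony2 = 0.0
        s_a2 = float(fit.cov_re.iloc[0, 0])
    s_eps2 = float(fit.scale)
    singular = not getattr(fit, "converged", True) or min(s_a2, s_eps2) < 1e-10
    return fit, s_a2, s_eps2, s_colony2, singular


def _conditional_residuals(data, beta, s_a2, s_eps2, s_colony2):
    """Residuals after removing fixed effects and the BLUPs of both random
    intercepts: e_cond = s_eps2 * V^-1 (y - X beta), computed per colony."""
    X = _design(data, beta)
    r = data["value"].to_numpy(dtype=float) - X @ np.asarray(list(beta.values()))
    out = np.empty(len(data))
    for _, idx in data.groupby("colony_id", sort=False).indices.items():
        ind = pd.factorize(data["individual_id"].to_numpy()[idx])[0]
        n = len(idx)
        Z = np.zeros((n, ind.max() + 1))
        Z[np.arange(n), ind] = 1.0
        V = s_colony2 + s_a2 * (Z @ Z.T) + s_eps2 * np.eye(n)
        out[idx] = s_eps2 * np.linalg.solve(V, r[idx])
    return out


def _design(data, beta):
    cols = []
    for name in beta:
        if name == "Intercept":
            cols.append(np.ones(len(data)))
        else:
            cols.append(data[name].to_numpy(dtype=float))
    return np.column_stack(cols)


def fit_variance_components(values, individual_ids, colony_ids, distances,
                            trait="trait", include_distance=True) -> RepeatabilityResult:
    """REML variance partition of a trait into colony, individual and
    residual components, and the repeatability R.

    ``include_distance=False`` drops the migration-distance fixed effect
    (used for the winter-arrival trait, where it impedes convergence).
    """
    data = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "individual_id": np.asarray(individual_ids).astype(str),
        "colony_id": np.asarray(colony_ids).astype(str),
        "distance": np.asarray(distances, dtype=float),
    }).dropna(subset=["value"]).reset_index(drop=True)
    counts = data["individual_id"].value_counts()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 individuals with >= 2 seasons each")
    fit, s_a2, s_eps2, s_colony2, singular = _fit_mixed(data, include_distance)
    denom = s_a2 + s_eps2
    R = s_a2 / denom if denom > 0 else 0.0
    beta = {k: float(v) for k, v in fit.fe_params.items()}
    res = RepeatabilityResult(
        trait=trait, s_a2=s_a2, s_eps2=s_eps2, s_colony2=s_colony2,
        R=float(np.clip(R, 0.0, 1.0)), fixed_effects=beta,
        include_distance=include_distance, singular=singular, _data=data,
    )
    res.per_individual = individual_repeatability(res)
    return res


def individual_repeatability(result: RepeatabilityResult,
                             exclude=()) -> pd.DataFrame:
    """Per-individual residual variance s_i^2 and R_i = s_a2/(s_a2+s_i2).

    Individuals with fewer than two observations are skipped; ``exclude``
    removes wintering-area switchers.
    """
    data = result._data
    cond = _conditional_residuals(data, result.fixed_effects, result.s_a2,
                                  result.s_eps2, result.s_colony2)
    rows = []
    for ind, idx in data.groupby("individual_id", sort=True).indices.items():
        if ind in exclude or len(idx) < 2:
            continue
        s_i2 = float((cond[idx] ** 2).sum() / (len(idx) - 1))
        denom = result.s_a2 + s_i2
        r_i = result.s_a2 / denom if denom > 0 else 1.0
        rows.append({"individual_id": ind, "n_i": len(idx), "s_i2": s_i2,
                     "R_i": float(np.clip(r_i, 0.0, 1.0)),
                     "distance": float(data["distance"].to_numpy()[idx].mean())})
    return pd.DataFrame(rows, columns=["individual_id", "n_i", "s_i2", "R_i", "distance"])


def bootstrap_ci(result: RepeatabilityResult, n_boot=N_BOOTSTRAPS, seed=0):
    """Parametric bootstrap 95% CI for R.

    Responses are simulated from the fitted model (fixed effects plus
    normal colony, individual and residual draws), the model is refitted
    and R collected; the CI is the 2.5/97.5 percentile interval.
    """
    data = result._data
    rng = np.random.default_rng(seed)
    X = _design(data, result.fixed_effects)
    mu = X @ np.asarray(list(result.fixed_effects.values()))
    colonies, col_idx = np.unique(data["colony_id"], return_inverse=True)
    inds, ind_idx = np.unique(data["individual_id"], return_inverse=True)
    Rs = []
    failures = 0
    for _ in range(n_boot):
        y = (mu
             + np.sqrt(result.s_colony2) * rng.standard_normal(len(colonies))[col_idx]
             + np.sqrt(result.s_a2) * rng.standard_normal(len(inds))[ind_idx]
             + np.sqrt(result.s_eps2) * rng.standard_normal(len(data)))
        sim = data.assign(value=y)
        try:
            _, s_a2, s_eps2, _, _ = _fit_mixed(sim, result.include_distance)
            denom = s_a2 + s_eps2
            if not np.isfinite(denom) or denom <= 0:
                raise ValueError("degenerate refit")
            Rs.append(s_a2 / denom)
        except Exception:
            failures += 1
    if not Rs:
        raise RuntimeError("all bootstrap refits failed")
    lo, hi = np.percentile(Rs, [2.5, 97.5])
    result.ci95 = (float(lo), float(hi))
    result.n_boot_failures = failures
    return result.ci95


@dataclass
class DistanceModel:
    response: str
    intercept: float
    slope_per_km: float
    f_stat: float
    df: tuple
    p_value: float
    lrt_stat: float
    lrt_p: float
    r_squared: float


def distance_model(values, distances, response="response") -> DistanceModel:
    """OLS of a variation metric on migration distance, tested against an
    intercept-only null (F test; the equivalent LRT is also reported)."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(distances, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if len(y) < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in migration distance")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    null = sm.OLS(y, np.ones((len(y), 1))).fit()
    lrt = 2.0 * (fit.llf - null.llf)
    return DistanceModel(
        response=response,
        intercept=float(fit.params[0]),
        slope_per_km=float(fit.params[1]),
        f_stat=float(fit.fvalue),
        df=(1, len(y) - 2),
        p_value=float(fit.f_pvalue),
        lrt_stat=float(lrt),
        lrt_p=float(sps.chi2.sf(lrt, 1)),
        r_squared=float(fit.rsquared),
    )


def residual_variation(observed, distances, between_model: DistanceModel):
    """Subtract the between-individual null expectation at each distance.

    corrected_i = observed_i - (intercept + slope * distance_i), using the
    model fitted on between-individual pair values; regressing the
    corrected values on distance tests whether within-individual variation
    changes more or less than the spatial constraint alone predicts.
    """
    observed = np.asarray(observed, dtype=float)
    distances = np.asarray(distances, dtype=float)
    predicted = between_model.intercept + between_model.slope_per_km * distances
    corrected = observed - predicted
    model = distance_model(corrected, distances,
                           response=f"residual {between_model.response}")
    return corrected, model
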