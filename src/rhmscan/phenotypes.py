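"""From repeated count records to the standardized per-animal analysis trait.

Pipeline order is fixed: log transform, repeatability-model REML per
population (and per trait), per-population standardization to mean 0 / sd 1
(population-sd convention, denominator n), then assembly of one value per
genotyped animal with an optional population-to-trait mapping so a different
trait can stand in for one population without code changes.

The repeatability model is ``y = Xb + Z a + e`` with an i.i.d. random animal
effect ``a`` and i.i.d. residuals; the per-animal analysis phenotype is the
BLUP of ``a``. REML is profiled down to a one-dimensional optimization over
the variance ratio ``lambda = sigma2_a / sigma2_e`` — with ``Z'Z`` diagonal
the restricted likelihood, GLS solves and BLUPs all have closed forms given
``lambda``, so each evaluation is O(n records).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator


@dataclass
class AnimalEffects:
    """Per-animal effects for one or more populations plus fitted components."""

    table: pd.DataFrame  # animal_id, population, effect, n_records
    components: dict     # population -> dict(sigma2_a, sigma2_e, repeatability, loglik)
    standardized: bool = False
    sd_convention: str = "population"  # divide by n, not n-1


def log_transform(records: pd.DataFrame, offset: float = 1.0,
                  value_col: str = "value") -> pd.DataFrame:
    """value <- ln(value + offset); all other columns untouched."""
    if offset <= 0:
        raise ValueError("offset must be > 0")
    vals = records[value_col].to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("raw trait values must be non-negative")
    out = records.copy()
    out[value_col] = np.log(vals + offset)
    return out


class RepeatabilityModel(BaseEstimator):
    """REML fit of a single-random-effect repeated-records mixed model.

    Parameters
    ----------
    max_log_lambda:
        Bound for the profiled search over ``log(sigma2_a / sigma2_e)``.

    Attributes (after ``fit``)
    --------------------------
    sigma2_animal_, sigma2_resid_ : float
        Variance components (``sigma2_animal_`` may sit at the 0 boundary).
    repeatability_ : float
        ``sigma2_animal_ / (sigma2_animal_ + sigma2_resid_)``.
    loglik_ : float
        Restricted log-likelihood at the optimum.
    blup_ : pandas.Series
        BLUP of the animal effect, indexed by animal id.
    n_records_ : pandas.Series
        Records used per animal.
    """

    def __init__(self, max_log_lambda: float = 14.0, xatol: float = 1e-10):
        self.max_log_lambda = max_log_lambda
        self.xatol = xatol

    # restricted log-likelihood profiled over sigma2_e for a fixed ratio
    def _profile(self, lam, X, y, group_idx, counts):
        n, p = X.shape
        d = lam / (1.0 + lam * counts)  # per-animal Woodbury weight
        ZtX = np.zeros((len(counts), p))
        np.add.at(ZtX, group_idx, X)
        Zty = np.bincount(group_idx, weights=y, minlength=len(counts))
        XtWiX = X.T @ X - ZtX.T @ (d[:, None] * ZtX)
        XtWiy = X.T @ y - ZtX.T @ (d * Zty)
        ytWiy = y @ y - Zty @ (d * Zty)
        beta = np.linalg.solve(XtWiX, XtWiy)
        q = ytWiy - 2 * beta @ XtWiy + beta @ XtWiX @ beta
        q = max(q, 1e-300)
        sigma2_e = q / (n - p)
        _, logdet_W = 0.0, np.sum(np.log1p(lam * counts))
        sign, logdet_XtWiX = np.linalg.slogdet(XtWiX)
        sign0, logdet_XtX = np.linalg.slogdet(X.T @ X)
        ll = -0.5 * ((n - p) * (np.log(2 * np.pi) + np.log(sigma2_e) + 1.0)
                     + logdet_W + logdet_XtWiX - logdet_XtX)
        return ll, sigma2_e, beta, d, Zty, ZtX

    def fit(self, X, y, groups):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        if X.ndim != 2 or len(X) != len(y) or len(groups) != len(y):
            raise ValueError("X, y and groups must have matching lengths")
        if np.var(y) == 0:
            raise ValueError("zero phenotypic variance: trait is constant")
        n, p = X.shape
        if np.linalg.matrix_rank(X) < p:
            raise ValueError(self._name_confounded(X))
        uniq, group_idx = np.unique(groups, return_inverse=True)
        counts = np.bincount(group_idx).astype(float)

        def nll(t):
            return -self._profile(np.exp(t), X, y, group_idx, counts)[0]

        res = minimize_scalar(nll, bounds=(-self.max_log_lambda, self.max_log_lambda),
                              method="bounded", options={"xatol": self.xatol})
        ll_hat, lam_hat = -res.fun, float(np.exp(res.x))
        ll0 = self._profile(0.0, X, y, group_idx, counts)[0]
        if ll0 >= ll_hat:  # boundary: no between-animal variance
            lam_hat, ll_hat = 0.0, ll0
        ll, sigma2_e, beta, d, _, _ = self._profile(lam_hat, X, y, group_idx, counts)
        resid_sums = np.bincount(group_idx, weights=y - X @ beta,
                                 minlength=len(counts))
        blup = lam_hat * sigma2_e * resid_sums / (sigma2_e * (1.0 + lam_hat * counts))
        self.lambda_ = lam_hat
        self.sigma2_animal_ = lam_hat * sigma2_e
        self.sigma2_resid_ = sigma2_e
        self.repeatability_ = self.sigma2_animal_ / (self.sigma2_animal_ + sigma2_e)
        self.loglik_ = ll
        self.beta_ = beta
        self.blup_ = pd.Series(blup, index=uniq)
        self.n_records_ = pd.Series(counts.astype(int), index=uniq)
        return self

    @staticmethod
    def _name_confounded(X) -> str:
        full = np.linalg.matrix_rank(X)
        for j in range(X.shape[1]):
            rest = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(rest) == full:
                return (f"fixed-effect design is rank deficient; column {j} is "
                        "confounded with the others")
        return "fixed-effect design is rank deficient"


def build_design(records: pd.DataFrame, fixed_factors=(), covariates=()) -> tuple:
    """Intercept + dummy-coded factors (first level dropped) + raw covariates.

    Returns (design matrix, column names).
    """
    n = len(records)
    cols, names = [np.ones(n)], ["intercept"]
    for f in fixed_factors:
        if f not in records.columns:
            raise ValueError(f"fixed-effect column {f!r} not present in records")
        dummies = pd.get_dummies(records[f].astype("category"), prefix=f,
                                 drop_first=True, dtype=float)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy())
            names.append(c)
    for c in covariates:
        if c not in records.columns:
            raise ValueError(f"covariate column {c!r} not present in records")
        cols.append(records[c].to_numpy(dtype=float))
        names.append(c)
    return np.column_stack(cols), names


def fit_repeatability(records: pd.DataFrame, fixed_factors=("time_point",),
                      covariates=(), value_col: str = "value",
                      estimator: str = "blup") -> AnimalEffects:
    """Fit the repeatability model separately within each population.

    ``records`` must hold a single trait per population (filter first when a
    population has several). ``estimator="blup"`` (default) returns the mixed-
    model prediction of the animal effect; ``estimator="adjusted_mean"`` is a
    sensitivity alternative: the within-animal mean of fixed-effect-adjusted
    records, without shrinkage (variance components are still REML-fitted and
    reported).
    """
    if estimator not in ("blup", "adjusted_mean"):
        raise ValueError("estimator must be 'blup' or 'adjusted_mean'")
    tables, components = [], {}
    for pop, sub in records.groupby("population", sort=False):
        if sub.groupby("animal_id")[value_col].count().min() < 1:
            raise ValueError("every retained animal needs at least one record")
        X, _ = build_design(sub, fixed_factors, covariates)
        y = sub[value_col].to_numpy()
        animals = sub["animal_id"].to_numpy()
        model = RepeatabilityModel().fit(X, y, animals)
        if estimator == "blup":
            effect = model.blup_
        else:
            resid = y - X @ model.beta_
            effect = pd.Series(resid).groupby(animals).mean()
        tables.append(pd.DataFrame({
            "animal_id": effect.index,
            "population": pop,
            "effect": effect.to_numpy(),
            "n_records": model.n_records_.loc[effect.index].to_numpy(),
        }))
        components[pop] = {
            "sigma2_a": model.sigma2_animal_,
            "sigma2_e": model.sigma2_resid_,
            "repeatability": model.repeatability_,
            "loglik": model.loglik_,
        }
    return AnimalEffects(table=pd.concat(tables, ignore_index=True),
                         components=components, standardized=False)


def standardize(effects: AnimalEffects) -> AnimalEffects:
    """Within each population: subtract the mean, divide by the population sd."""
    table = effects.table.copy()
    table["effect"] = table["effect"].astype(float)
    for pop, idx in table.groupby("population", sort=False).groups.items():
        vals = table.loc[idx, "effect"].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 animals")
        sd = vals.std()  # population convention (ddof=0)
        if sd == 0:
            raise ValueError(f"population {pop!r} has zero spread in effects")
        table.loc[idx, "effect"] = (vals - vals.mean()) / sd
    return AnimalEffects(table=table, components=effects.components,
                         standardized=True)


def assemble_trait(effects_by_trait: dict, population_trait_map: dict,
                   animal_order) -> pd.Series:
    """One analysis value per genotyped animal, drawn from the trait mapped to
    its population.

    ``effects_by_trait`` maps trait name -> AnimalEffects (standardized);
    ``population_trait_map`` maps population -> trait name.
    """
    lookup = {}
    for trait, eff in effects_by_trait.items():
        for _, row in eff.table.iterrows():
            lookup[(row["population"], trait, row["animal_id"])] = row["effect"]
    pop_of = {}
    for eff in effects_by_trait.values():
        for _, row in eff.table.iterrows():
            pop_of[row["animal_id"]] = row["population"]
    out = []
    for aid in animal_order:
        if aid not in pop_of:
            raise KeyError(f"animal {aid!r} has no fitted effect in any trait")
        pop = pop_of[aid]
        if pop not in population_trait_map:
            raise KeyError(f"population {pop!r} is not mapped to a trait")
        trait = population_trait_map[pop]
        key = (pop, trait, aid)
        if key not in lookup:
            raise KeyError(f"no {trait!r} effect for animal {aid!r} "
                           f"in population {pop!r}")
        out.append(lookup[key])
    return pd.Series(out, index=list(animal_order), name="animal_effect")


def animal_effect_pipeline(records: pd.DataFrame, animal_order,
                           population_trait_map: dict | None = None,
                           fixed_factors=("time_point",), covariates=(),
                           offset: float = 1.0) -> pd.Series:
    """Full preparation: log transform -> per-(population, trait) repeatability
    REML -> per-population standardization -> assembly into one vector aligned
    with ``animal_order``."""
    logged = log_transform(records, offset=offset)
    pops = list(pd.unique(logged["population"]))
    if population_trait_map is None:
        traits = list(pd.unique(logged["trait"]))
        if len(traits) != 1:
            raise ValueError("multiple traits present: provide population_trait_map")
        population_trait_map = {p: traits[0] for p in pops}
    effects_by_trait: dict = {}
    for trait in set(population_trait_map.values()):
        sub = logged[logged["trait"] == trait]
        sub = sub[sub["population"].isin(
            [p for p, t in population_trait_map.items() if t == trait])]
        eff = fit_repeatability(sub, fixed_factors=fixed_factors,
                                covariates=covariates)
        effects_by_trait[trait] = standardize(eff)
    return assemble_trait(effects_by_trait, population_trait_map, animal_order)
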