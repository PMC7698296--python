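"""Carcass-abandonment model: fitting, selection, and imputation.

Interviewed farms state whether they abandon carcasses (1) or not (0).
A binomial-logit GLM on those farms, with distance and herd-size
predictors, is selected by AICc over all admissible predictor subsets
(collinear pairs never co-occur; models with uninformative parameters are
discarded) and used to impute an abandonment probability for farms whose
answer is unknown.  Observed farms always keep their hard 0/1 answer.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .glmm import aicc, collinear_pairs, prune_uninformative

__all__ = [
    "DISPOSAL_PREDICTORS",
    "DISPOSAL_CATEGORIES",
    "GLMFit",
    "fit_disposal_glm",
    "select_disposal_model",
    "impute_carcass",
    "tabulate_disposal",
    "load_interview_table",
]

log = logging.getLogger(__name__)

DISPOSAL_PREDICTORS = ("dist_dump", "dist_afs", "dist_road", "goat_sheep", "dist_urb")

#: what non-abandoning farmers do with carcasses, plus "abandon"
DISPOSAL_CATEGORIES = (
    "abandon",
    "dump",
    "feeding_station",
    "collection_service",
    "buried",
    "mortuary",
    "never",
)


@dataclass
class GLMFit:
    terms: tuple[str, ...]
    coefficients: pd.Series
    std_errors: pd.Series
    loglik: float
    k: int
    n: int
    aicc: float
    null_deviance: float
    deviance: float
    separable: bool = False
    scaler: dict | None = None  # per-term (mean, sd) used at fit time

    @property
    def term_names(self) -> tuple[str, ...]:
        return self.terms

    @property
    def adjusted_explained_deviance(self) -> float:
        """Explained deviance 1 - D/D0, penalized for the parameter count
        (the usual adjustment (n-1)/(n-k) on the unexplained fraction)."""
        d2 = 1.0 - self.deviance / self.null_deviance
        return 1.0 - (1.0 - d2) * (self.n - 1) / (self.n - self.k)

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(records), self.coefficients["(Intercept)"])
        for t in self.terms:
            mean, sd = self.scaler[t] if self.scaler else (0.0, 1.0)
            eta = eta + self.coefficients[t] * (records[t].to_numpy(float) - mean) / sd
        return 1.0 / (1.0 + np.exp(-eta))


def fit_disposal_glm(
    records: pd.DataFrame,
    term_set: tuple[str, ...],
    answer: str = "answer",
    standardize: bool = True,
) -> GLMFit:
    """Maximum-likelihood binomial-logit GLM of the abandonment answer.

    Predictors are z-scored within the fitting set by default (scaling
    constants are stored so prediction accepts raw units).  Perfectly
    separated fits are flagged and excluded from ranking upstream.
    """
    missing = [t for t in term_set if t not in records.columns]
    if missing:
        raise ValueError(f"missing predictor column(s): {missing}")
    y = records[answer].to_numpy(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("answers must be 0/1 in the fitting set")
    n = len(records)
    if n < len(term_set) + 2:
        raise ValueError("too few records for this term set")
    scaler = {}
    cols = [np.ones(n)]
    for t in term_set:
        v = records[t].to_numpy(float)
        if standardize:
            mean, sd = float(v.mean()), float(v.std())
            sd = sd if sd > 0 else 1.0
        else:
            mean, sd = 0.0, 1.0
        scaler[t] = (mean, sd)
        cols.append((v - mean) / sd)
    X = np.column_stack(cols)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=200)
    fitted = res.fittedvalues
    separable = bool(np.min(np.abs(fitted - 0.5)) > 0.5 - 1e-6) or not np.all(
        np.isfinite(res.bse)
    )
    names = ["(Intercept)", *term_set]
    k = len(names)
    return GLMFit(
        terms=tuple(term_set),
        coefficients=pd.Series(res.params, index=names),
        std_errors=pd.Series(res.bse, index=names),
        loglik=float(res.llf),
        k=k,
        n=n,
        aicc=aicc(float(res.llf), k, n),
        null_deviance=float(res.null_deviance),
        deviance=float(res.deviance),
        separable=separable,
        scaler=scaler,
    )


def select_disposal_model(
    records: pd.DataFrame,
    predictors: tuple[str, ...] = DISPOSAL_PREDICTORS,
    max_abs_rho: float = 0.5,
) -> GLMFit:
    """AICc selection over all admissible predictor subsets.

    Subsets containing a pair with |Spearman rho| above the threshold are
    never fitted; after ranking, models with uninformative parameters
    (a nested submodel within 2 AICc units) are discarded and the top
    remaining model is returned.
    """
    forbidden = collinear_pairs(records, predictors, max_abs_rho)
    fits: list[GLMFit] = []
    for r in range(len(predictors) + 1):
        for subset in itertools.combinations(predictors, r):
            if any(pair <= set(subset) for pair in forbidden):
                continue
            fit = fit_disposal_glm(records, subset)
            if fit.separable:
                log.warning("separated fit excluded from ranking: %s", subset)
                continue
            fits.append(fit)
    if not fits:
        raise ValueError("no admissible candidate models")
    retained = prune_uninformative(fits)
    best = min(retained, key=lambda f: (f.aicc, f.k, f.terms))
    log.info(
        "disposal model selected on n=%d farms: %s (AICc=%.2f, adjD2=%.3f)",
        best.n,
        " + ".join(best.terms) or "1",
        best.aicc,
        best.adjusted_explained_deviance,
    )
    return best


def impute_carcass(farm_table: pd.DataFrame, fit: GLMFit, answer: str = "answer") -> pd.Series:
    """Carcass covariate per farm: the observed 0/1 answer where known,
    the model's predicted abandonment probability elsewhere."""
    known = farm_table[answer].notna()
    out = pd.Series(np.nan, index=farm_table.index, dtype=float)
    out[known] = farm_table.loc[known, answer].astype(float)
    unknown = ~known
    if unknown.any():
        sub = farm_table.loc[unknown]
        for t in fit.terms:
            if t not in sub.columns or sub[t].isna().any():
                raise ValueError(f"predictor {t!r} missing for an uninterviewed farm")
        out[unknown] = fit.predict(sub)
    return out


def load_interview_table() -> pd.DataFrame:
    """The packaged farmer-interview disposal breakdown (one row per
    respondent, columns farm_id and category)."""
    with resources.files("farmvisits.data").joinpath("interviews.csv").open() as fh:
        return pd.read_csv(fh)


def tabulate_disposal(interviews: pd.DataFrame, category: str = "category") -> dict:
    """Counts per disposal category plus the abandon / not-abandon split."""
    counts = {c: 0 for c in DISPOSAL_CATEGORIES}
    for c in interviews[category]:
        if c not in counts:
            raise ValueError(f"unknown disposal category: {c!r}")
        counts[c] += 1
    total = int(len(interviews))
    abandoners = counts["abandon"]
    return {
        "counts": counts,
        "n_respondents": total,
        "n_abandon": abandoners,
        "n_not_abandon": total - abandoners,
    }
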