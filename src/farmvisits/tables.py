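"""Response tables and analysis orchestration.

Two complementary response variables are modelled as binomial
proportions:

* FARM — per active farm area and semester, the number of distinct
  eligible birds with at least one visit day, out of all eligible
  tracked birds that semester (random intercepts: farm, semester);
* VULTURE — per eligible bird-semester and candidate farm (a farm whose
  centroid lies in the bird's 95% kernel home range), the number of visit
  days out of the days tracked, split into territorial and
  non-territorial analyses (random intercepts: farm, semester, bird).

Continuous covariates are z-scored within each analysis table before
model fitting; factors (sex, breeding, success) are left on their 0/1
coding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glmm
from .geometry import BirdContext, FarmArea, Landscape, farm_covariates
from .homerange import HomeRange
from .periods import Semester

__all__ = [
    "FARM_TERMS",
    "TERRITORIAL_TERMS",
    "NONTERRITORIAL_TERMS",
    "DEFAULT_INTERACTIONS",
    "AnalysisResult",
    "build_farm_table",
    "build_vulture_tables",
    "standardize",
    "back_transform",
    "run_analysis",
    "descriptive_comparisons",
]

log = logging.getLogger(__name__)

FARM_TERMS = ("dist_hpfp", "dist_urb", "dist_road", "goat_sheep", "carcass", "breeding")
TERRITORIAL_TERMS = FARM_TERMS + (
    "dist_terr",
    "dist_k50",
    "dist_nest",
    "area_k95",
    "sex",
    "age",
    "success",
)
NONTERRITORIAL_TERMS = FARM_TERMS + ("dist_terr", "dist_k50", "area_k95", "sex", "age")

#: two-way interactions of biological interest considered one at a time
DEFAULT_INTERACTIONS = (
    ("breeding", "dist_hpfp"),
    ("age", "dist_k50"),
    ("breeding", "dist_terr"),
)

FACTOR_TERMS = {"breeding", "sex", "success"}


def _covariate_dict(row) -> dict:
    out = {
        "dist_hpfp": row.dist_hpfp,
        "dist_urb": row.dist_urb,
        "dist_road": row.dist_road,
        "goat_sheep": row.goat_sheep,
        "carcass": row.carcass,
        "breeding": row.breeding,
    }
    if row.dist_terr is not None:
        out["dist_terr"] = row.dist_terr
    if row.dist_k50 is not None:
        out["dist_k50"] = row.dist_k50
    if row.dist_nest is not None:
        out["dist_nest"] = row.dist_nest
    if row.area_k95 is not None:
        out["area_k95"] = row.area_k95
    if row.sex is not None:
        out["sex"] = 1 if row.sex == "M" else 0
    if row.age is not None:
        out["age"] = row.age
    if row.success is not None:
        out["success"] = row.success
    return out


def build_farm_table(
    visit_days: pd.DataFrame,
    eligibility: pd.DataFrame,
    farm_areas: list[FarmArea],
    landscape: Landscape,
    semesters: list[Semester],
    farms_by_id=None,
) -> pd.DataFrame:
    """One row per active farm area and semester.

    Numerator: distinct eligible birds with a visit day there; denominator:
    number of eligible birds that semester.  Semesters without eligible
    birds are skipped with a log entry.
    """
    vd = visit_days.copy()
    if len(vd):
        vd["semester"] = [
            Semester(d.year, 1 if d.month <= 6 else 2).label for d in vd["date"]
        ]
    elig = eligibility[eligibility["eligible"]]
    rows = []
    for sem in semesters:
        birds = set(elig.loc[elig["semester"] == sem.label, "bird_id"])
        if not birds:
            log.info("semester %s skipped: no eligible birds", sem.label)
            continue
        if len(vd):
            sub = vd[(vd["semester"] == sem.label) & vd["bird_id"].isin(birds)]
            per_area = sub.groupby("area_id")["bird_id"].nunique()
        else:
            per_area = pd.Series(dtype=int)
        for area in farm_areas:
            if not area.is_active(sem.label, farms_by_id):
                continue
            cov = farm_covariates(area, landscape, sem.label, breeding=sem.breeding)
            rows.append(
                {
                    "area_id": area.area_id,
                    "semester": sem.label,
                    "numerator": int(per_area.get(area.area_id, 0)),
                    "denominator": len(birds),
                    **_covariate_dict(cov),
                }
            )
    return pd.DataFrame(rows)


def build_vulture_tables(
    visit_days: pd.DataFrame,
    eligibility: pd.DataFrame,
    bird_contexts: dict,
    home_ranges: dict,
    farm_areas: list[FarmArea],
    landscape: Landscape,
    semesters: list[Semester],
    farms_by_id=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(territorial, non-territorial) response tables.

    ``bird_contexts`` maps (bird_id, semester label) to
    :class:`BirdContext`; ``home_ranges`` maps the same key to
    :class:`HomeRange`.  Visits to farms outside the 95% home range are
    excluded from the numerator and logged.
    """
    areas_by_id = {a.area_id: a for a in farm_areas}
    vd = visit_days.copy()
    if len(vd):
        vd["semester"] = [
            Semester(d.year, 1 if d.month <= 6 else 2).label for d in vd["date"]
        ]
    elig = eligibility[eligibility["eligible"]]
    terr_rows, nonterr_rows = [], []
    n_out_of_range = 0
    for rec in elig.itertuples():
        key = (rec.bird_id, rec.semester)
        if key not in home_ranges or key not in bird_contexts:
            continue
        hr: HomeRange = home_ranges[key]
        ctx: BirdContext = bird_contexts[key]
        sem = Semester.from_label(rec.semester)
        if len(vd):
            sub = vd[(vd["bird_id"] == rec.bird_id) & (vd["semester"] == rec.semester)]
            counts = sub.groupby("area_id").size()
        else:
            counts = pd.Series(dtype=int)
        out_of_range = set(counts.index) - set(hr.candidate_areas)
        if out_of_range:
            n_out_of_range += int(counts[list(out_of_range)].sum())
        for area_id in hr.candidate_areas:
            area = areas_by_id[area_id]
            if not area.is_active(rec.semester, farms_by_id):
                continue
            cov = farm_covariates(
                area, landscape, rec.semester, breeding=sem.breeding, bird=ctx
            )
            row = {
                "bird_id": rec.bird_id,
                "area_id": area_id,
                "semester": rec.semester,
                "numerator": int(counts.get(area_id, 0)),
                "denominator": int(rec.n_days),
                **_covariate_dict(cov),
            }
            (terr_rows if ctx.territorial else nonterr_rows).append(row)
    if n_out_of_range:
        log.info("%d visit days to farms outside home ranges excluded", n_out_of_range)
    return pd.DataFrame(terr_rows), pd.DataFrame(nonterr_rows)


def standardize(
    rows: pd.DataFrame, terms: tuple[str, ...]
) -> tuple[pd.DataFrame, dict]:
    """Z-score continuous covariates within the analysis table.

    Factors are untouched; zero-variance covariates are dropped with a
    warning.  Returns the scaled table and the per-term (mean, sd) map
    for back-transformation.
    """
    out = rows.copy()
    scaler: dict[str, tuple[float, float]] = {}
    for t in terms:
        if t in FACTOR_TERMS or t not in out.columns:
            continue
        v = out[t].to_numpy(float)
        sd = float(v.std())
        if sd == 0.0:
            log.warning("covariate %s has zero variance and was dropped", t)
            out = out.drop(columns=[t])
            continue
        mean = float(v.mean())
        scaler[t] = (mean, sd)
        out[t] = (v - mean) / sd
    return out, scaler


def back_transform(values, term: str, scaler: dict):
    mean, sd = scaler[term]
    return np.asarray(values, float) * sd + mean


@dataclass
class AnalysisResult:
    analysis: str
    ranking: pd.DataFrame
    averaged: glmm.AveragedModel
    best_fit: glmm.FitResult
    diagnostics: dict
    scaler: dict = field(default_factory=dict)


def run_analysis(
    analysis: str,
    rows: pd.DataFrame,
    terms: tuple[str, ...] | None = None,
    interactions: tuple[tuple[str, str], ...] = DEFAULT_INTERACTIONS,
    random_intercepts: tuple[str, ...] | None = None,
    coordinates: pd.DataFrame | None = None,
    seed: int = 0,
    moran_k: int = 15,
) -> AnalysisResult:
    """Enumerate, fit, rank, prune, and average candidate mixed models,
    then attach diagnostics.

    ``analysis`` is ``"farm"``, ``"vulture-territorial"`` or
    ``"vulture-nonterritorial"`` (used to pick default menus and random
    structures).  ``coordinates`` (area_id, x, y) enables the Moran's I
    residual diagnostic on per-farm mean residuals.
    """
    if not len(rows):
        raise ValueError("empty response table")
    if terms is None:
        terms = {
            "farm": FARM_TERMS,
            "vulture-territorial": TERRITORIAL_TERMS,
            "vulture-nonterritorial": NONTERRITORIAL_TERMS,
        }[analysis]
    if random_intercepts is None:
        random_intercepts = (
            ("area_id", "semester")
            if analysis == "farm"
            else ("area_id", "semester", "bird_id")
        )
    degenerate = [f for f in random_intercepts if rows[f].nunique() < 2]
    if degenerate:
        log.warning("random factor(s) with a single level dropped: %s", degenerate)
        random_intercepts = tuple(f for f in random_intercepts if f not in degenerate)
    terms = tuple(t for t in terms if t in rows.columns)
    scaled, scaler = standardize(rows, terms)
    terms = tuple(t for t in terms if t in scaled.columns)
    interactions = tuple(
        (a, b) for a, b in interactions if a in terms and b in terms
    )

    specs = glmm.enumerate_candidates(
        terms, scaled, interactions, random_intercepts
    )
    fits = []
    theta0 = None
    for spec in specs:
        try:
            fit = glmm.fit_binomial_glmm(scaled, spec, theta0=theta0)
        except Exception as exc:  # noqa: BLE001 - flagged, not fatal
            log.warning("fit failed for %s: %s", spec.describe(), exc)
            continue
        if not fit.converged:
            log.warning("non-convergence for %s; excluded from ranking", spec.describe())
            continue
        theta0 = np.array([fit.random_sd[f] for f in random_intercepts])
        fits.append(fit)
    if not fits:
        raise RuntimeError("all candidate models failed to converge")

    weights_all = glmm.akaike_weights([f.aicc for f in fits])
    order = np.argsort([f.aicc for f in fits])
    ranking = pd.DataFrame(
        {
            "model": [fits[i].spec.describe() for i in order],
            "k": [fits[i].k for i in order],
            "aicc": [fits[i].aicc for i in order],
            "delta_aicc": [fits[i].aicc - fits[order[0]].aicc for i in order],
            "weight": weights_all[order],
        }
    )
    retained = glmm.prune_uninformative(fits)
    averaged = glmm.model_average(retained)
    best = min(retained, key=lambda f: f.aicc)

    diagnostics: dict = {
        "n_rows": int(len(scaled)),
        "n_candidates": len(specs),
        "n_converged": len(fits),
        "n_retained": len(retained),
        "overdispersion": glmm.overdispersion_ratio(best),
        "random_sd": best.random_sd,
    }
    marg, cond = glmm.pseudo_r2(best)
    diagnostics["pseudo_r2_marginal"] = marg
    diagnostics["pseudo_r2_conditional"] = cond
    if len(best.spec.term_names) >= 2:
        design = scaled[[t for t in best.spec.fixed_terms]]
        try:
            diagnostics["vif"] = glmm.vif(design).to_dict()
        except ValueError as exc:
            diagnostics["vif_error"] = str(exc)
    if coordinates is not None and "area_id" in rows.columns:
        st = best._state
        resid = (st["y"] - st["m"] * st["fitted_p"]) / np.sqrt(
            np.clip(st["m"] * st["fitted_p"] * (1 - st["fitted_p"]), 1e-12, None)
        )
        per_farm = (
            pd.DataFrame({"area_id": scaled["area_id"].to_numpy(), "resid": resid})
            .groupby("area_id")["resid"]
            .mean()
        )
        coords = coordinates.set_index("area_id").loc[per_farm.index, ["x", "y"]]
        k = min(moran_k, len(per_farm) - 1)
        if k >= 1 and per_farm.std() > 0:
            i_stat, p = glmm.morans_i(
                per_farm.to_numpy(), coords.to_numpy(), k_neighbors=k, seed=seed
            )
            diagnostics["morans_i"] = i_stat
            diagnostics["morans_i_p"] = p
    return AnalysisResult(
        analysis=analysis,
        ranking=ranking,
        averaged=averaged,
        best_fit=best,
        diagnostics=diagnostics,
        scaler=scaler,
    )


def descriptive_comparisons(
    bird_semester_stats: pd.DataFrame,
) -> pd.DataFrame:
    """Sex and season comparisons of farms-in-home-range and farms
    visited, plus the visited-farms vs home-range-size rank correlation
    for non-territorial bird-semesters.

    Input columns: bird_id, semester, territorial, sex, breeding,
    n_farms_hr, n_farms_visited, area_k95.  Returns a long-format table
    of test statistics; empty groups yield missing cells.
    """
    out = []
    df = bird_semester_stats
    for metric in ("n_farms_hr", "n_farms_visited"):
        for terr in (True, False):
            for breeding in (1, 0):
                sub = df[(df["territorial"] == terr) & (df["breeding"] == breeding)]
                a = sub.loc[sub["sex"] == "M", metric]
                b = sub.loc[sub["sex"] == "F", metric]
                rec = {
                    "metric": metric,
                    "comparison": "sex",
                    "territorial": terr,
                    "group": "breeding" if breeding else "non-breeding",
                }
                if len(a) >= 2 and len(b) >= 2:
                    w, p = glmm.mann_whitney_u(a, b)
                    rec.update(W=w, p=p)
                else:
                    rec.update(W=np.nan, p=np.nan)
                out.append(rec)
        for terr in (True, False):
            for sex in ("M", "F"):
                sub = df[(df["territorial"] == terr) & (df["sex"] == sex)]
                a = sub.loc[sub["breeding"] == 1, metric]
                b = sub.loc[sub["breeding"] == 0, metric]
                rec = {
                    "metric": metric,
                    "comparison": "season",
                    "territorial": terr,
                    "group": sex,
                }
                if len(a) >= 2 and len(b) >= 2:
                    w, p = glmm.mann_whitney_u(a, b)
                    rec.update(W=w, p=p)
                else:
                    rec.update(W=np.nan, p=np.nan)
                out.append(rec)
    nt = df[~df["territorial"]]
    rec = {
        "metric": "n_farms_visited~area_k95",
        "comparison": "spearman",
        "territorial": False,
        "group": "all",
        "W": np.nan,
    }
    try:
        rec["rho"] = glmm.spearman_rho(nt["n_farms_visited"], nt["area_k95"])
    except ValueError:
        rec["rho"] = np.nan
    out.append(rec)
    return pd.DataFrame(out)
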