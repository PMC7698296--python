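"""Binomial mixed models with crossed random intercepts and multimodel
inference.

The estimation contract is maximum likelihood with a Laplace approximation
to the marginal likelihood, the same approximation used by the standard
mixed-model packages.  For variance parameters ``theta`` (one SD per
random factor, on the logit scale) the random effects are written
``u = sigma * z`` with ``z ~ N(0, I)``.  At fixed ``theta`` the fixed
effects ``beta`` and spherical effects ``z`` are jointly maximized by
penalized Newton iterations (PIRLS), and the profiled Laplace
log-likelihood is

    ll(theta) = loglik(y | eta_hat) - z_hat'z_hat / 2
                - log det(Lambda' Z' W Z Lambda + I) / 2,

which an outer bounded quasi-Newton search maximizes over ``theta >= 0``.
Fits hitting the boundary (a variance estimated at zero) are retained and
flagged singular; the model then degenerates exactly to an ordinary
logistic GLM.

Multimodel inference follows the information-theoretic workflow: AICc
ranking of all admissible fixed-effect subsets, removal of models carrying
uninformative parameters (a model is dropped when a strictly
better-ranked nested submodel sits within 2 AICc units), Akaike weights,
and full (zero-substitution) model averaging with unconditional standard
errors, relative importance, and 85% confidence limits.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial import cKDTree
from scipy.special import expit, gammaln

__all__ = [
    "ModelSpec",
    "FitResult",
    "AveragedModel",
    "fit_binomial_glmm",
    "aicc",
    "enumerate_candidates",
    "collinear_pairs",
    "akaike_weights",
    "prune_uninformative",
    "model_average",
    "vif",
    "overdispersion_ratio",
    "pseudo_r2",
    "morans_i",
    "mann_whitney_u",
    "spearman_rho",
]

log = logging.getLogger(__name__)

#: normal quantile for 85% confidence limits (7.5% and 92.5%)
Z_85 = float(stats.norm.ppf(0.925))


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of one candidate model.

    ``interaction`` holds at most one two-way pair whose main effects must
    both be present; random intercepts are named by grouping columns.
    """

    fixed_terms: tuple[str, ...] = ()
    interaction: tuple[str, str] | None = None
    random_intercepts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.interaction is not None:
            a, b = self.interaction
            if a not in self.fixed_terms or b not in self.fixed_terms:
                raise ValueError("interaction main effects must be present")

    @property
    def term_names(self) -> tuple[str, ...]:
        names = list(self.fixed_terms)
        if self.interaction is not None:
            names.append(":".join(self.interaction))
        return tuple(names)

    def describe(self) -> str:
        return " + ".join(self.term_names) if self.term_names else "1"


@dataclass
class FitResult:
    spec: ModelSpec
    coefficients: pd.Series  # intercept + fixed terms (+ interaction)
    std_errors: pd.Series
    random_sd: dict[str, float]
    loglik: float
    k: int  # fixed coefficients + variance components
    n: int
    aicc: float
    converged: bool = True
    singular: bool = False
    akaike_weight: float | None = None
    _state: dict = field(default_factory=dict, repr=False)

    @property
    def term_names(self) -> tuple[str, ...]:
        return self.spec.term_names


def _design(rows: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(rows))]
    names = ["(Intercept)"]
    for t in spec.fixed_terms:
        cols.append(rows[t].to_numpy(float))
        names.append(t)
    if spec.interaction is not None:
        a, b = spec.interaction
        cols.append(rows[a].to_numpy(float) * rows[b].to_numpy(float))
        names.append(f"{a}:{b}")
    return np.column_stack(cols), names


def _indicators(rows: pd.DataFrame, factors: tuple[str, ...]) -> tuple[sp.csr_matrix, list[int]]:
    """Sparse indicator matrix stacking all random factors column-wise."""
    blocks = []
    sizes = []
    n = len(rows)
    for f in factors:
        codes, levels = pd.factorize(rows[f], sort=True)
        if len(levels) < 2:
            raise ValueError(f"random factor {f!r} has fewer than 2 levels")
        blocks.append(
            sp.csr_matrix((np.ones(n), (np.arange(n), codes)), shape=(n, len(levels)))
        )
        sizes.append(len(levels))
    Z = sp.hstack(blocks, format="csr") if blocks else sp.csr_matrix((n, 0))
    return Z, sizes


def _binom_loglik(y, m, eta):
    # log C(m, y) + y*eta - m*log(1 + exp(eta)), stable for large |eta|
    const = gammaln(m + 1) - gammaln(y + 1) - gammaln(m - y + 1)
    return float(np.sum(const + y * eta - m * np.logaddexp(0.0, eta)))


def fit_binomial_glmm(
    rows: pd.DataFrame,
    spec: ModelSpec,
    *,
    numerator: str = "numerator",
    denominator: str = "denominator",
    max_sigma: float = 15.0,
    theta0: np.ndarray | None = None,
    gtol: float = 1e-6,
) -> FitResult:
    """Fit a binomial-logit mixed model by Laplace maximum likelihood.

    ``rows`` must contain the numerator/denominator columns, one numeric
    column per fixed term, and one grouping column per random intercept.
    With no random factors (or variances shrunk to the boundary) the fit
    coincides with an ordinary logistic GLM.
    """
    y = rows[numerator].to_numpy(float)
    m = rows[denominator].to_numpy(float)
    if np.any(m < 1) or np.any(y < 0) or np.any(y > m):
        raise ValueError("need 0 <= numerator <= denominator and denominator >= 1")
    X, names = _design(rows, spec)
    if not np.isfinite(X).all():
        bad = [n for n, col in zip(names, X.T) if not np.isfinite(col).all()]
        raise ValueError(f"non-finite covariate values in term(s) {bad}; impute first")
    Z, sizes = _indicators(rows, spec.random_intercepts)
    n, p = X.shape
    q = Z.shape[1]
    F = len(sizes)
    # per-column factor index, to expand sigma to Lambda's diagonal
    fac_of_col = np.repeat(np.arange(F), sizes) if F else np.zeros(0, dtype=int)

    state = {"beta": np.zeros(p), "z": np.zeros(q)}

    def inner(theta: np.ndarray) -> dict:
        """Joint penalized Newton for (beta, z) at fixed theta."""
        sig = theta[fac_of_col] if F else np.zeros(0)
        U = Z.multiply(sig[None, :]).tocsr() if q else Z
        beta = state["beta"].copy()
        z = state["z"].copy()

        def objective(beta, z):
            eta = X @ beta + (U @ z if q else 0.0)
            return _binom_loglik(y, m, eta) - 0.5 * float(z @ z), eta

        h, eta = objective(beta, z)
        for _ in range(60):
            mu = m * expit(eta)
            w = np.clip(m * expit(eta) * expit(-eta), 1e-12, None)
            r = y - mu
            g_beta = X.T @ r
            g_z = (U.T @ r - z) if q else np.zeros(0)
            gnorm = max(
                np.abs(g_beta).max() if p else 0.0,
                np.abs(g_z).max() if q else 0.0,
            )
            if gnorm < gtol * max(1.0, m.sum() / n):
                break
            Xw = X * w[:, None]
            A11 = X.T @ Xw
            if q:
                A12 = Xw.T @ U  # dense p x q
                A12 = np.asarray(A12)
                A22 = (U.T.multiply(w) @ U).toarray()
                A22[np.diag_indices(q)] += 1.0
                H = np.block([[A11, A12], [A12.T, A22]])
                g = np.concatenate([g_beta, g_z])
            else:
                H = A11
                g = g_beta
            H[np.diag_indices_from(H)] += 1e-10
            try:
                delta = cho_solve(cho_factor(H, lower=True), g)
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(H, g, rcond=None)[0]
            step = 1.0
            for _ls in range(30):
                nb = beta + step * delta[:p]
                nz = z + step * delta[p:]
                nh, neta = objective(nb, nz)
                if nh >= h - 1e-12:
                    break
                step *= 0.5
            if nh < h - 1e-8:
                break  # no ascent possible
            improved = nh - h
            beta, z, h, eta = nb, nz, nh, neta
            if improved < 1e-10 * max(1.0, abs(h)):
                break
        mu = m * expit(eta)
        w = np.clip(m * expit(eta) * expit(-eta), 1e-12, None)
        if q:
            A22 = (U.T.multiply(w) @ U).toarray()
            A22[np.diag_indices(q)] += 1.0
            sign, logdet = np.linalg.slogdet(A22)
        else:
            logdet = 0.0
        ll = _binom_loglik(y, m, eta) - 0.5 * float(z @ z) - 0.5 * logdet
        state["beta"], state["z"] = beta, z
        return {"beta": beta, "z": z, "eta": eta, "w": w, "loglik": ll, "U": U}

    if F:
        # stage 1: profiled search over theta alone (beta solved jointly
        # with z inside PIRLS) -- cheap and lands very close to the optimum
        x0 = np.ones(F) if theta0 is None else np.asarray(theta0, float)
        res = optimize.minimize(
            lambda th: -inner(np.abs(th))["loglik"],
            x0=np.clip(x0, 0.0, max_sigma),
            method="L-BFGS-B",
            bounds=[(0.0, max_sigma)] * F,
            options={"maxiter": 100, "ftol": 1e-9, "eps": 1e-4},
        )
        theta = np.abs(res.x)
        converged = bool(res.success) or res.status == 1
        fit = inner(theta)

        # stage 2: joint outer optimization over (theta, beta) with the
        # random-effect mode solved inside -- the exact Laplace objective
        # used by the reference mixed-model implementations
        def joint_objective(params: np.ndarray) -> float:
            th = np.abs(params[:F])
            sig = th[fac_of_col]
            U = Z.multiply(sig[None, :]).tocsr()
            beta = params[F:]
            Xb = X @ beta
            z = state["z"].copy()
            for _ in range(100):
                eta = Xb + U @ z
                mu = m * expit(eta)
                w = np.clip(m * expit(eta) * expit(-eta), 1e-12, None)
                g = U.T @ (y - mu) - z
                if np.abs(g).max() < 1e-9 * max(1.0, m.sum() / n):
                    break
                A22 = (U.T.multiply(w) @ U).toarray()
                A22[np.diag_indices(q)] += 1.0
                dz = cho_solve(cho_factor(A22, lower=True), g)
                h0 = _binom_loglik(y, m, eta) - 0.5 * float(z @ z)
                step = 1.0
                for _ls in range(30):
                    nz = z + step * dz
                    nh = _binom_loglik(y, m, Xb + U @ nz) - 0.5 * float(nz @ nz)
                    if nh >= h0 - 1e-12:
                        break
                    step *= 0.5
                z = nz
            eta = Xb + U @ z
            w = np.clip(m * expit(eta) * expit(-eta), 1e-12, None)
            A22 = (U.T.multiply(w) @ U).toarray()
            A22[np.diag_indices(q)] += 1.0
            _, logdet = np.linalg.slogdet(A22)
            state["z"] = z
            return -(_binom_loglik(y, m, eta) - 0.5 * float(z @ z) - 0.5 * logdet)

        res2 = optimize.minimize(
            joint_objective,
            x0=np.concatenate([theta, fit["beta"]]),
            method="L-BFGS-B",
            bounds=[(0.0, max_sigma)] * F + [(None, None)] * p,
            options={"maxiter": 200, "ftol": 1e-10, "eps": 1e-5},
        )
        if np.isfinite(res2.fun) and -res2.fun >= fit["loglik"] - 1e-6:
            ll2 = -joint_objective(res2.x)  # refresh state["z"] at the optimum
            theta = np.abs(res2.x[:F])
            beta = res2.x[F:]
            sig = theta[fac_of_col]
            U = Z.multiply(sig[None, :]).tocsr()
            eta = X @ beta + U @ state["z"]
            converged = converged or bool(res2.success)
            state["beta"] = beta
            fit = {
                "beta": beta,
                "z": state["z"],
                "eta": eta,
                "w": np.clip(m * expit(eta) * expit(-eta), 1e-12, None),
                "loglik": ll2,
                "U": U,
            }
    else:
        theta = np.zeros(0)
        converged = True
        fit = inner(theta)

    # conditional SEs of beta from the joint (beta, z) Hessian at the mode
    w = fit["w"]
    Xw = X * w[:, None]
    A11 = X.T @ Xw
    if q:
        U = fit["U"]
        A12 = np.asarray(Xw.T @ U)
        A22 = (U.T.multiply(w) @ U).toarray()
        A22[np.diag_indices(q)] += 1.0
        H = np.block([[A11, A12], [A12.T, A22]])
    else:
        H = A11
    try:
        cov = np.linalg.inv(H)[:p, :p]
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        converged = False
        se = np.full(p, np.nan)

    k = p + F
    ll = fit["loglik"]
    singular = bool(F and np.any(theta < 1e-4))
    eta = fit["eta"]
    result = FitResult(
        spec=spec,
        coefficients=pd.Series(fit["beta"], index=names),
        std_errors=pd.Series(se, index=names),
        random_sd={f: float(s) for f, s in zip(spec.random_intercepts, theta)},
        loglik=ll,
        k=k,
        n=n,
        aicc=aicc(ll, k, n),
        converged=converged,
        singular=singular,
        _state={
            "eta": eta,
            "fitted_p": expit(eta),
            "y": y,
            "m": m,
            "X": X,
            "theta": theta,
        },
    )
    return result


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Akaike information criterion corrected for small samples."""
    if n <= k + 1:
        raise ValueError("AICc undefined: need n > k + 1")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def collinear_pairs(
    rows: pd.DataFrame, terms: tuple[str, ...], max_abs_rho: float = 0.5
) -> set[frozenset[str]]:
    """Term pairs whose |Spearman correlation| exceeds the threshold."""
    out: set[frozenset[str]] = set()
    for a, b in itertools.combinations(terms, 2):
        rho = stats.spearmanr(rows[a], rows[b]).statistic
        if np.isfinite(rho) and abs(rho) > max_abs_rho:
            out.add(frozenset((a, b)))
    return out


def enumerate_candidates(
    terms: tuple[str, ...],
    rows: pd.DataFrame,
    interactions: tuple[tuple[str, str], ...] = (),
    random_intercepts: tuple[str, ...] = (),
    max_abs_rho: float = 0.5,
) -> list[ModelSpec]:
    """All admissible fixed-effect subsets, from the intercept-only model
    to the full set, excluding subsets containing a collinear pair; plus,
    for each subset, each single two-way interaction whose main effects it
    contains (one interaction per model)."""
    if not terms:
        raise ValueError("empty term pool")
    forbidden = collinear_pairs(rows, terms, max_abs_rho)
    specs: list[ModelSpec] = []
    for r in range(len(terms) + 1):
        for subset in itertools.combinations(terms, r):
            sset = set(subset)
            if any(pair <= sset for pair in forbidden):
                continue
            specs.append(ModelSpec(subset, None, random_intercepts))
            for a, b in interactions:
                if a in sset and b in sset:
                    specs.append(ModelSpec(subset, (a, b), random_intercepts))
    # deterministic order: by size then lexicographic term names
    specs.sort(key=lambda s: (len(s.term_names), s.term_names))
    seen = set()
    unique = []
    for s in specs:
        key = (s.fixed_terms, s.interaction)
        if key not in seen:
            seen.add(key)
            unique.append(s)
    return unique


def akaike_weights(aicc_values) -> np.ndarray:
    a = np.asarray(aicc_values, dtype=float)
    if not np.isfinite(a).any():
        raise ValueError("no finite AICc values")
    delta = a - np.nanmin(a)
    w = np.exp(-delta / 2.0)
    w[~np.isfinite(w)] = 0.0
    return w / w.sum()


def prune_uninformative(fits: list, delta_threshold: float = 2.0) -> list:
    """Drop models carrying uninformative parameters.

    Working down the AICc ranking, a model is discarded when some retained
    model with strictly lower AICc is nested within it (its terms form a
    strict subset) and the AICc gap is at most ``delta_threshold``: the
    extra terms failed to buy a net AICc reduction.
    """
    ranked = sorted(fits, key=lambda f: f.aicc)
    retained: list = []
    for fit in ranked:
        terms = set(fit.term_names)
        drop = any(
            set(r.term_names) < terms
            and r.aicc < fit.aicc
            and fit.aicc - r.aicc <= delta_threshold
            for r in retained
        )
        if not drop:
            retained.append(fit)
    return retained


@dataclass
class AveragedModel:
    """Full model average across the retained candidate set."""

    table: pd.DataFrame  # index: term; estimate, se, ci_lo, ci_hi, ri
    weights: pd.Series  # per retained model description
    single_best: bool = False

    def __repr__(self) -> str:  # pragma: no cover
        kind = "single best model" if self.single_best else "model average"
        return f"<AveragedModel ({kind}, {len(self.table)} terms)>"


def model_average(
    fits: list[FitResult],
    weight_floor: float = 0.001,
    single_model_weight: float = 0.9,
) -> AveragedModel:
    """Akaike-weighted full averaging of the retained candidate set.

    When one model carries at least ``single_model_weight`` of the
    evidence it is reported alone.  Otherwise every model with weight
    above ``weight_floor`` contributes (weights renormalized); a term
    absent from a model contributes an estimate of 0, so averages shrink
    toward zero for weakly supported terms.  Unconditional SEs combine
    within-model variance and between-model spread; relative importance
    (RI) is the summed weight of models containing the term; confidence
    limits are the 7.5% and 92.5% normal quantiles.
    """
    if not fits:
        raise ValueError("no retained models to average")
    w = akaike_weights([f.aicc for f in fits])
    for f, wi in zip(fits, w):
        f.akaike_weight = float(wi)
    order = np.argsort([f.aicc for f in fits])
    fits = [fits[i] for i in order]
    w = w[order]
    labels = [f.spec.describe() for f in fits]

    if w[0] >= single_model_weight:
        best = fits[0]
        tab = pd.DataFrame(
            {
                "estimate": best.coefficients,
                "se": best.std_errors,
                "ci_lo": best.coefficients - Z_85 * best.std_errors,
                "ci_hi": best.coefficients + Z_85 * best.std_errors,
                "ri": 1.0,
            }
        )
        return AveragedModel(
            table=tab, weights=pd.Series(w, index=labels), single_best=True
        )

    keep = w > weight_floor
    sub = [f for f, k in zip(fits, keep) if k]
    wk = w[keep] / w[keep].sum()
    all_terms: list[str] = ["(Intercept)"]
    for f in sub:
        for t in f.term_names:
            if t not in all_terms:
                all_terms.append(t)
    rows = []
    for term in all_terms:
        est = np.array([f.coefficients.get(term, 0.0) for f in sub])
        se = np.array([f.std_errors.get(term, 0.0) for f in sub])
        avg = float(wk @ est)
        se_unc = float(wk @ np.sqrt(se ** 2 + (est - avg) ** 2))
        ri = float(wk[[term in f.term_names or term == "(Intercept)" for f in sub]].sum())
        rows.append(
            {
                "estimate": avg,
                "se": se_unc,
                "ci_lo": avg - Z_85 * se_unc,
                "ci_hi": avg + Z_85 * se_unc,
                "ri": ri,
            }
        )
    tab = pd.DataFrame(rows, index=all_terms)
    return AveragedModel(table=tab, weights=pd.Series(wk, index=[f.spec.describe() for f in sub]))


def vif(design: pd.DataFrame | np.ndarray) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R2_j) from regressing
    each column on the others (columns are centred first, so an intercept
    is implicit)."""
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        Xm = design.to_numpy(float)
    else:
        Xm = np.asarray(design, float)
        names = [f"x{j}" for j in range(Xm.shape[1])]
    if Xm.shape[1] < 2:
        raise ValueError("VIF needs at least two columns")
    Xc = Xm - Xm.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        _, R = np.linalg.qr(Xc)
        aliased = [names[j] for j in range(Xc.shape[1]) if abs(R[j, j]) < 1e-8 * max(1.0, abs(R[0, 0]))]
        raise ValueError(f"design is rank deficient; aliased terms: {aliased}")
    out = []
    for j in range(Xc.shape[1]):
        yj = Xc[:, j]
        Xo = np.delete(Xc, j, axis=1)
        coef, *_ = np.linalg.lstsq(Xo, yj, rcond=None)
        resid = yj - Xo @ coef
        r2 = 1.0 - resid @ resid / (yj @ yj)
        out.append(1.0 / max(1.0 - r2, 1e-12))
    return pd.Series(out, index=names)


def overdispersion_ratio(fit: FitResult) -> float:
    """Sum of squared Pearson residuals over residual degrees of freedom
    (n - k), using conditional fitted values."""
    st = fit._state
    y, m, p = st["y"], st["m"], st["fitted_p"]
    v = np.clip(m * p * (1 - p), 1e-12, None)
    pearson = (y - m * p) / np.sqrt(v)
    return float(pearson @ pearson / (fit.n - fit.k))


def pseudo_r2(fit: FitResult) -> tuple[float, float]:
    """Variance-decomposition (marginal, conditional) pseudo-R2 for the
    logit link: the fixed-effect, random-effect, and distribution-specific
    (pi^2/3) variance components on the latent scale."""
    st = fit._state
    X = st["X"]
    lin_fixed = X @ fit.coefficients.to_numpy()
    var_f = float(np.var(lin_fixed))
    var_r = float(sum(s ** 2 for s in fit.random_sd.values()))
    var_d = np.pi ** 2 / 3.0
    denom = var_f + var_r + var_d
    return var_f / denom, (var_f + var_r) / denom


def morans_i(
    residuals,
    coordinates,
    k_neighbors: int = 15,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Moran's I with row-standardized k-nearest-neighbour weights and a
    permutation p-value (one-sided, positive autocorrelation)."""
    z = np.asarray(residuals, float)
    xy = np.asarray(coordinates, float)
    n = len(z)
    if n < k_neighbors + 1:
        raise ValueError("need more locations than k_neighbors")
    if np.std(z) == 0:
        raise ValueError("constant residuals: Moran's I undefined")
    z = z - z.mean()
    _, nbrs = cKDTree(xy).query(xy, k=k_neighbors + 1)
    nbrs = nbrs[:, 1:]  # drop self

    def stat(zv: np.ndarray) -> float:
        # row-standardized weights: each row's neighbour mean
        lag = zv[nbrs].mean(axis=1)
        return float(zv @ lag / (zv @ zv))

    i_obs = stat(z)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if stat(rng.permutation(z)) >= i_obs:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return i_obs, p


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie correction; exact enumeration for
    combined n <= 12, normal approximation otherwise."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if len(a) + len(b) <= 12 and not _has_ties(a, b) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _has_ties(a, b) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    return float(stats.spearmanr(x, y).statistic)
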