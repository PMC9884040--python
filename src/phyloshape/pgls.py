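"""Phylogenetic generalized least squares with ML Pagel's lambda.

The residual covariance is ``sigma^2 * V(lambda)`` where ``V(lambda)``
rescales the off-diagonal entries of the Brownian-motion covariance.
``lambda`` is profiled out by maximum likelihood (coarse grid followed by
bounded scalar refinement); at the optimum the coefficients are exact GLS
computed through a whitening factorization of ``V(lambda)``.

Also provides the allometry toolkit built on those fits: ANCOVA-design
Type II tests, parametric bootstrap confidence intervals with per-replicate
lambda re-estimation, slope classification against a dimensionless isometric
baseline, per-group slope extraction and comparison, phylogenetic size
correction, and bootstrap group-mean comparisons.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phylo import CovarianceFamily, PhyloCovariance

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "PGLSFit",
    "BootstrapResult",
    "AllometryCall",
    "CollinearityError",
    "identity_family",
    "build_design",
    "fit_pgls",
    "type2_anova",
    "bootstrap_cis",
    "classify_allometry",
    "per_group_slopes",
    "compare_group_slopes",
    "size_correct",
    "group_mean_comparison",
]

LAMBDA_GRID_COARSE = 21
LAMBDA_GRID_BOOT = 101


class CollinearityError(ValueError):
    pass


def identity_family(taxa: Sequence[str]) -> CovarianceFamily:
    """Star-phylogeny covariance (independent species, unit variance)."""
    return CovarianceFamily(PhyloCovariance(list(taxa), np.eye(len(taxa)), 1.0))


# --------------------------------------------------------------------------
# model specification and design matrices
# --------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Response plus an ordered list of terms.

    Terms are column names of the species table; ``"a:b"`` denotes an
    interaction. :meth:`from_formula` accepts ``"y ~ a * b"`` shorthand
    (``a*b`` expands to ``a + b + a:b``). Factors are detected from the
    table dtype; ``reference`` picks the baseline level (default: first
    level in sorted order).
    """

    response: str
    terms: list[str]
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.response in self.terms:
            raise ValueError("response cannot appear among the predictors")

    @classmethod
    def from_formula(cls, formula: str, reference: str | None = None) -> "ModelSpec":
        lhs, _, rhs = formula.partition("~")
        if not rhs:
            raise ValueError(f"formula {formula!r} needs a '~'")
        terms: list[str] = []
        for chunk in rhs.split("+"):
            chunk = chunk.strip()
            if not chunk:
                continue
            if "*" in chunk:
                a, b = (p.strip() for p in chunk.split("*", 1))
                for t in (a, b, f"{a}:{b}"):
                    if t not in terms:
                        terms.append(t)
            elif chunk not in terms:
                terms.append(chunk)
        return cls(response=lhs.strip(), terms=terms, reference=reference)


@dataclass
class DesignInfo:
    colnames: list[str]
    term_cols: dict[str, list[int]]  # term -> column indices (intercept excluded)
    factor: str | None
    levels: list[str]
    reference: str | None


def _is_factor(series: pd.Series) -> bool:
    return series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype) or series.dtype == bool


def build_design(spec: ModelSpec, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, DesignInfo]:
    """Build (y, X, info); X always includes a leading intercept column."""
    if spec.response not in df.columns:
        raise KeyError(f"response {spec.response!r} not in table")
    y = df[spec.response].to_numpy(dtype=float)
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    colnames = ["(Intercept)"]
    term_cols: dict[str, list[int]] = {}
    factor_name: str | None = None
    levels: list[str] = []
    reference: str | None = None

    def factor_dummies(name: str) -> tuple[list[str], np.ndarray]:
        nonlocal factor_name, levels, reference
        vals = df[name].astype(str)
        levs = sorted(vals.unique())
        if len(levs) < 2:
            raise ValueError(f"factor {name!r} needs >= 2 levels")
        ref = spec.reference if spec.reference in levs else levs[0]
        factor_name, levels, reference = name, levs, ref
        others = [l for l in levs if l != ref]
        return others, np.column_stack([(vals == l).to_numpy(float) for l in others])

    for term in spec.terms:
        start = len(colnames)
        if ":" in term:
            a, b = term.split(":", 1)
            for part in (a, b):
                if part not in df.columns:
                    raise KeyError(f"term component {part!r} not in table")
            a_fac, b_fac = _is_factor(df[a]), _is_factor(df[b])
            if a_fac and b_fac:
                raise NotImplementedError("factor:factor interactions are not supported")
            if a_fac or b_fac:
                fac, cont = (a, b) if a_fac else (b, a)
                others, D = factor_dummies(fac)
                x = df[cont].to_numpy(float)
                for j, lev in enumerate(others):
                    cols.append(x * D[:, j])
                    colnames.append(f"{cont}:{fac}[{lev}]")
            else:
                cols.append(df[a].to_numpy(float) * df[b].to_numpy(float))
                colnames.append(term)
        elif _is_factor(df[term]):
            others, D = factor_dummies(term)
            for j, lev in enumerate(others):
                cols.append(D[:, j])
                colnames.append(f"{term}[{lev}]")
        else:
            cols.append(df[term].to_numpy(float))
            colnames.append(term)
        term_cols[term] = list(range(start, len(colnames)))

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        aliased = _find_aliased(X, colnames)
        raise CollinearityError(f"design matrix is rank deficient; aliased columns: {aliased}")
    return y, X, DesignInfo(colnames, term_cols, factor_name, levels, reference)


def _find_aliased(X: np.ndarray, names: list[str]) -> list[str]:
    aliased = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            aliased.append(names[j])
        else:
            kept.append(j)
    return aliased


# --------------------------------------------------------------------------
# GLS engine
# --------------------------------------------------------------------------

class _GLSData:
    """Whitened least-squares solver over the lambda family.

    On ultrametric trees the family shares eigenvectors, so the data are
    rotated once and every lambda evaluation is a diagonal rescale. ``Y``
    may be a matrix (one column per bootstrap replicate).
    """

    def __init__(self, family: CovarianceFamily, X: np.ndarray, Y: np.ndarray):
        self.family = family
        self.X = X
        self.Y = Y if Y.ndim == 2 else Y[:, None]
        self.n, self.p = X.shape
        if family.const_diag:
            self.Xr = family.rotate(X)
            self.Yr = family.rotate(self.Y)

    def solve(self, lam: float) -> tuple[np.ndarray, np.ndarray, float]:
        """Return (beta [p,R], rss [R], logdet V(lam))."""
        if self.family.const_diag:
            e = self.family.scale(lam)
            w = 1.0 / np.sqrt(e)
            Xw = self.Xr * w[:, None]
            Yw = self.Yr * w[:, None]
            logdet = float(np.sum(np.log(e)))
        else:
            W, logdet = self.family.whitener(lam)
            Xw = W @ self.X
            Yw = W @ self.Y
        beta, _, _, _ = np.linalg.lstsq(Xw, Yw, rcond=None)
        resid = Yw - Xw @ beta
        rss = np.einsum("ij,ij->j", resid, resid)
        return beta, rss, logdet

    def loglik(self, lam: float) -> np.ndarray:
        _, rss, logdet = self.solve(lam)
        n = self.n
        with np.errstate(divide="ignore"):
            return -0.5 * (n * np.log(2.0 * np.pi) + n * np.log(rss / n) + n + logdet)


def _profile_lambda(data: _GLSData, grid_size: int = LAMBDA_GRID_COARSE) -> float:
    """ML lambda by coarse grid then bounded scalar refinement."""
    grid = np.linspace(0.0, 1.0, grid_size)
    lls = np.array([float(data.loglik(l)[0]) for l in grid])
    k = int(np.argmax(lls))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid_size - 1)]
    if hi <= lo:
        return float(grid[k])
    res = optimize.minimize_scalar(
        lambda l: -float(data.loglik(float(np.clip(l, 0.0, 1.0)))[0]),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.clip(res.x, 0.0, 1.0))
    # never return worse than the best grid point
    if float(data.loglik(lam)[0]) < lls[k]:
        lam = float(grid[k])
    return lam


@dataclass
class PGLSFit:
    spec: ModelSpec
    info: DesignInfo
    taxa: list[str]
    family: CovarianceFamily
    X: np.ndarray
    y: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    lambda_hat: float
    lambda_fixed: bool
    sigma2_hat: float  # ML estimate rss/n
    log_likelihood: float
    r2: float
    adjusted_r2: float
    rss: float
    null_rss: float

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.info.colnames, self.beta))

    @property
    def standard_errors(self) -> dict[str, float]:
        return dict(zip(self.info.colnames, self.se))

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def df_resid(self) -> int:
        return self.n - self.p

    @property
    def fitted(self) -> np.ndarray:
        return self.X @ self.beta

    @property
    def residuals(self) -> pd.Series:
        return pd.Series(self.y - self.fitted, index=self.taxa, name="residual")


def _align(traits: pd.DataFrame, family: CovarianceFamily) -> pd.DataFrame:
    missing = [t for t in family.taxa if t not in traits.index]
    if missing:
        raise KeyError(f"species missing from trait table: {missing}")
    return traits.loc[list(family.taxa)]


def fit_pgls(
    spec: ModelSpec,
    traits: pd.DataFrame,
    family: CovarianceFamily,
    lam: float | None = None,
    grid_size: int = LAMBDA_GRID_COARSE,
) -> PGLSFit:
    """Fit the GLS model with Pagel's lambda residual structure.

    ``lam=None`` (default) profiles lambda by ML over [0, 1]; a float fixes
    it. The trait table is aligned to ``family.taxa`` (raising on missing
    species), so rows and the covariance are always consistent.
    """
    df = _align(traits, family)
    y, X, info = build_design(spec, df)
    if np.isnan(y).any() or np.isnan(X).any():
        bad = df.index[np.isnan(y) | np.isnan(X).any(axis=1)].tolist()
        raise ValueError(f"NaNs in model variables for species: {bad}")
    data = _GLSData(family, X, y)
    lam_hat = float(lam) if lam is not None else _profile_lambda(data, grid_size)
    if not (0.0 <= lam_hat <= 1.0):
        raise ValueError(f"lambda must lie in [0,1], got {lam_hat}")
    beta, rss, logdet = data.solve(lam_hat)
    beta = beta[:, 0]
    rss = float(rss[0])
    n, p = X.shape
    sigma2_ml = rss / n
    ll = float(-0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2_ml) + n + logdet))

    # SEs from the whitened cross-product with the unbiased variance estimate
    if family.const_diag:
        w = 1.0 / np.sqrt(family.scale(lam_hat))
        Xw = data.Xr * w[:, None]
    else:
        W, _ = family.whitener(lam_hat)
        Xw = W @ X
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    s2_unbiased = rss / (n - p) if n > p else np.nan
    se = np.sqrt(np.clip(np.diag(XtX_inv) * s2_unbiased, 0.0, None))

    # R^2 on the whitened scale against the GLS intercept-only model
    null_data = _GLSData(family, np.ones((n, 1)), y)
    _, null_rss, _ = null_data.solve(lam_hat)
    null_rss = float(null_rss[0])
    r2 = 1.0 - rss / null_rss if null_rss > 0 else np.nan
    k = p - 1  # predictors excluding the intercept
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1) if n - k - 1 > 0 else np.nan

    return PGLSFit(
        spec=spec, info=info, taxa=list(df.index), family=family, X=X, y=y,
        beta=beta, se=se, lambda_hat=lam_hat, lambda_fixed=lam is not None,
        sigma2_hat=sigma2_ml, log_likelihood=ll, r2=r2, adjusted_r2=adj,
        rss=rss, null_rss=null_rss,
    )


# --------------------------------------------------------------------------
# Type II ANOVA
# --------------------------------------------------------------------------

def _contains(term: str, other: str) -> bool:
    """True if interaction ``other`` contains ``term`` as a component."""
    if other == term or ":" not in other:
        return False
    return term in other.split(":")


def type2_anova(fit: PGLSFit) -> pd.DataFrame:
    """Type II sums of squares on the whitened scale at the fitted lambda.

    Each term is tested against the model containing every other term that
    does not include it (marginality respected); F uses the full-model
    residual mean square.
    """
    terms = list(fit.spec.terms)
    for t in terms:
        if ":" in t:
            a, b = t.split(":", 1)
            if a not in terms or b not in terms:
                raise ValueError(
                    f"marginality violation: interaction {t!r} requires both main effects"
                )
    lam = fit.lambda_hat

    def rss_of(cols: list[int]) -> float:
        data = _GLSData(fit.family, fit.X[:, cols], fit.y)
        _, rss, _ = data.solve(lam)
        return float(rss[0])

    rss_full = fit.rss
    df_resid = fit.df_resid
    ms_resid = rss_full / df_resid
    rows = []
    for t in terms:
        excluded = [t] + [o for o in terms if _contains(t, o)]
        base_terms = [o for o in terms if o not in excluded]
        base_cols = [0] + [c for o in base_terms for c in fit.info.term_cols[o]]
        with_cols = sorted(base_cols + fit.info.term_cols[t])
        ss = rss_of(base_cols) - rss_of(with_cols)
        df_t = len(fit.info.term_cols[t])
        F = (ss / df_t) / ms_resid
        p = float(stats.f.sf(F, df_t, df_resid))
        rows.append({"term": t, "df": df_t, "ss": ss, "F": F, "p": p})
    rows.append({"term": "Residuals", "df": df_resid, "ss": rss_full, "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows).set_index("term")


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    n_reps: int
    n_failed: int
    seed: int | None
    coef_names: list[str]
    replicates: np.ndarray  # (p, n_ok)
    ci: dict[str, tuple[float, float]]
    group_slopes: dict[str, float] = field(default_factory=dict)
    group_slope_replicates: dict[str, np.ndarray] = field(default_factory=dict)
    group_slope_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    group_slope_replicate_mean: dict[str, float] = field(default_factory=dict)
    warning: str | None = None


def _slope_weights(fit: PGLSFit) -> dict[str, np.ndarray] | None:
    """Per-group weight vectors turning a coefficient vector into group slopes."""
    info = fit.info
    inter = next((t for t in fit.spec.terms if ":" in t), None)
    if inter is None or info.factor is None:
        return None
    a, b = inter.split(":", 1)
    cont = a if a != info.factor else b
    if cont not in fit.spec.terms:
        return None
    p = fit.p
    base = np.zeros(p)
    base[info.term_cols[cont][0]] = 1.0
    weights = {}
    ref = info.reference
    weights[ref] = base.copy()
    inter_cols = info.term_cols[inter]
    others = [l for l in info.levels if l != ref]
    for lev, col in zip(others, inter_cols):
        w = base.copy()
        w[col] = 1.0
        weights[lev] = w
    return weights


def bootstrap_cis(
    fit: PGLSFit,
    n_reps: int = 1000,
    seed: int | None = None,
    method: Literal["parametric", "residual"] = "parametric",
    lambda_grid: int = LAMBDA_GRID_BOOT,
    alpha: float = 0.05,
) -> BootstrapResult:
    """Bootstrap 95% percentile CIs for all coefficients (and group slopes).

    Parametric by default: responses are simulated from the fitted Gaussian
    process ``N(X beta, sigma2 * V(lambda_hat))`` and the model is refit per
    replicate with lambda re-estimated on a ``lambda_grid``-point grid. A
    nonparametric whitened-residual bootstrap is available as
    ``method="residual"``. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = fit.n
    L = fit.family.sqrt(fit.lambda_hat)
    mu = fit.fitted
    if method == "parametric":
        # simulate with the unbiased residual variance: the ML estimate is
        # biased low by (n-p)/n, which visibly narrows CIs at small n
        s2 = fit.rss / fit.df_resid if fit.df_resid > 0 else fit.sigma2_hat
        eps = rng.standard_normal((n, n_reps)) * np.sqrt(s2)
        Y = mu[:, None] + L @ eps
    elif method == "residual":
        if fit.family.const_diag:
            w = 1.0 / np.sqrt(fit.family.scale(fit.lambda_hat))
            ew = fit.family.rotate(fit.y - mu) * w
        else:
            W, _ = fit.family.whitener(fit.lambda_hat)
            ew = W @ (fit.y - mu)
        idx = rng.integers(0, n, size=(n, n_reps))
        Y = mu[:, None] + L @ ew[idx]
    else:
        raise ValueError(f"unknown bootstrap method {method!r}")

    betas, ok = _refit_many(fit, Y, lambda_grid)
    n_failed = n_reps - int(ok.sum())
    warning = None
    if n_failed > 0.05 * n_reps:
        warning = f"{n_failed}/{n_reps} bootstrap replicates failed to converge"
        logger.warning(warning)
    reps = betas[:, ok]
    qlo, qhi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    ci = {
        name: (float(np.percentile(reps[j], qlo)), float(np.percentile(reps[j], qhi)))
        for j, name in enumerate(fit.info.colnames)
    }
    result = BootstrapResult(
        n_reps=n_reps, n_failed=n_failed, seed=seed,
        coef_names=list(fit.info.colnames), replicates=reps, ci=ci, warning=warning,
    )
    weights = _slope_weights(fit)
    if weights:
        for g, w in weights.items():
            vals = w @ reps
            result.group_slopes[g] = float(w @ fit.beta)
            result.group_slope_replicates[g] = vals
            result.group_slope_ci[g] = (
                float(np.percentile(vals, qlo)),
                float(np.percentile(vals, qhi)),
            )
            result.group_slope_replicate_mean[g] = float(np.mean(vals))
    return result


def _refit_many(
    fit: PGLSFit, Y: np.ndarray, lambda_grid: int
) -> tuple[np.ndarray, np.ndarray]:
    """Refit the model for every response column; lambda re-estimated per
    column over a uniform grid. Returns (betas [p,R], ok mask)."""
    data = _GLSData(fit.family, fit.X, Y)
    grid = np.linspace(0.0, 1.0, lambda_grid) if not fit.lambda_fixed else np.array([fit.lambda_hat])
    n, R = Y.shape
    best_ll = np.full(R, -np.inf)
    best_beta = np.zeros((fit.p, R))
    for lamv in grid:
        beta, rss, logdet = data.solve(float(lamv))
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(rss / n) + n + logdet)
        ll = np.where(rss > 0, ll, np.inf)  # perfect fit: any lambda is optimal
        better = ll > best_ll
        best_ll = np.where(better, ll, best_ll)
        best_beta[:, better] = beta[:, better]
    ok = np.isfinite(best_beta).all(axis=0)
    return best_beta, ok


# --------------------------------------------------------------------------
# allometry classification and comparisons
# --------------------------------------------------------------------------

@dataclass
class AllometryCall:
    slope: float
    ci: tuple[float, float]
    call: Literal["positive", "negative", "not_significant"]
    isometric_slope: float = 0.0
    group: str = "all"
    trait_pair: tuple[str, str] | None = None


def classify_allometry(
    slope: float,
    ci: tuple[float, float],
    isometric_slope: float = 0.0,
    group: str = "all",
    trait_pair: tuple[str, str] | None = None,
) -> AllometryCall:
    """Positive iff the CI lies above the isometric slope, negative iff below."""
    lo, hi = ci
    if lo > hi:
        raise ValueError(f"CI lower bound exceeds upper: {ci}")
    if lo > isometric_slope:
        call = "positive"
    elif hi < isometric_slope:
        call = "negative"
    else:
        call = "not_significant"
    return AllometryCall(float(slope), (float(lo), float(hi)), call, isometric_slope, group, trait_pair)


def per_group_slopes(fit: PGLSFit) -> dict[str, float]:
    """Group-specific slopes from a continuous-by-factor interaction fit."""
    weights = _slope_weights(fit)
    if not weights:
        raise ValueError("model has no continuous-by-factor interaction term")
    return {g: float(w @ fit.beta) for g, w in weights.items()}


def compare_group_slopes(
    slopes: Mapping[str, float], cis: Mapping[str, tuple[float, float]]
) -> pd.DataFrame:
    """Pairwise slope-difference flags from CI exclusion.

    ``different_two_way`` requires each slope to fall outside the other's CI
    (symmetric rule); ``different_one_way`` requires at least one exclusion.
    """
    groups = list(slopes)
    rows = []

    def outside(x: float, ci: tuple[float, float]) -> bool:
        return x < ci[0] or x > ci[1]

    for i, g in enumerate(groups):
        for h in groups[i + 1:]:
            g_out = outside(slopes[g], cis[h])
            h_out = outside(slopes[h], cis[g])
            rows.append({
                "group_a": g, "group_b": h,
                "a_outside_b_ci": g_out, "b_outside_a_ci": h_out,
                "different_two_way": g_out and h_out,
                "different_one_way": g_out or h_out,
            })
    return pd.DataFrame(rows)


def size_correct(
    traits: pd.DataFrame,
    trait: str,
    size: str,
    family: CovarianceFamily,
    lam: float | None = None,
) -> tuple[pd.Series, PGLSFit]:
    """Residuals of ``trait ~ size`` under PGLS (phylogenetic size correction)."""
    fit = fit_pgls(ModelSpec(response=trait, terms=[size]), traits, family, lam=lam)
    resid = fit.residuals
    resid.name = f"sc_{trait}"
    return resid, fit


@dataclass
class GroupMeanComparison:
    means: dict[str, float]
    ci: dict[str, tuple[float, float]]
    flags: pd.DataFrame
    fit: PGLSFit
    bootstrap: BootstrapResult
    warning: str | None = None


def group_mean_comparison(
    values: pd.Series,
    groups: pd.Series,
    family: CovarianceFamily,
    n_reps: int = 1000,
    seed: int | None = None,
) -> GroupMeanComparison:
    """Per-group PGLS means with bootstrap CIs and CI-exclusion flags.

    A group differs from another when its mean lies outside the other's 95%
    bootstrap CI (the one-way rule); the symmetric two-way flag is reported
    alongside.
    """
    df = pd.DataFrame({"value": values, "group": groups.astype(str)}).loc[list(family.taxa)]
    counts = df["group"].value_counts()
    warning = None
    singles = counts[counts < 2].index.tolist()
    if singles:
        warning = f"singleton groups (CI undefined): {singles}"
        logger.warning(warning)
    fit = fit_pgls(ModelSpec(response="value", terms=["group"]), df, family)
    boot = bootstrap_cis(fit, n_reps=n_reps, seed=seed)
    ref = fit.info.reference
    p = fit.p
    weights = {ref: np.eye(p)[0]}
    for lev, col in zip([l for l in fit.info.levels if l != ref], fit.info.term_cols["group"]):
        w = np.eye(p)[0].copy()
        w[col] = 1.0
        weights[lev] = w
    means, cis = {}, {}
    for g, w in weights.items():
        means[g] = float(w @ fit.beta)
        vals = w @ boot.replicates
        cis[g] = (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
    rows = []
    for g in means:
        for h in means:
            if g == h:
                continue
            g_out = means[g] < cis[h][0] or means[g] > cis[h][1]
            h_out = means[h] < cis[g][0] or means[h] > cis[g][1]
            rows.append({
                "group": g, "other": h,
                "outside_other_ci": g_out,
                "different_two_way": g_out and h_out,
            })
    return GroupMeanComparison(
        means=means, ci=cis, flags=pd.DataFrame(rows), fit=fit, bootstrap=boot, warning=warning
    )
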