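"""Randomized residual permutation procedure (RRPP) multiple regression.

The response and design are whitened by a factor of the phylogenetic
covariance (lambda = 1 by default; the covariance can also be omitted for an
ordinary analysis), the sums of squares are decomposed sequentially in
predictor entry order, and each term's null distribution is built by
permuting the residuals of its reduced model, reconstructing pseudo-responses
and recomputing the term's F statistic.

Conventions:

* the observed statistic is included in its own null, so the smallest
  attainable p is 1/(n_iter + 1);
* the effect size Z is the standardized position of the observed statistic
  within the log-transformed null distribution;
* per-table p-values are adjusted by the Benjamini-Hochberg step-up rule.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pgls import CollinearityError
from .phylo import CovarianceFamily

logger = logging.getLogger(__name__)

__all__ = ["RRPPResult", "rrpp_multiple_regression", "rank_components", "bh_adjust"]


@dataclass
class RRPPResult:
    terms: list[str]
    df: dict[str, int]
    ss: dict[str, float]
    r2: dict[str, float]
    F: dict[str, float]
    Z: dict[str, float]
    p_perm: dict[str, float]
    p_adjusted: dict[str, float]
    ss_residual: float
    ss_total: float
    df_residual: int
    df_total: int
    n_iterations: int
    seed: int | None
    exhaustive: bool = False

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "term": t,
                "df": self.df[t],
                "ss": self.ss[t],
                "r2": self.r2[t],
                "F": self.F[t],
                "Z": self.Z[t],
                "p": self.p_perm[t],
                "p_adjusted": self.p_adjusted[t],
            }
            for t in self.terms
        ]
        rows.append({"term": "Residuals", "df": self.df_residual, "ss": self.ss_residual,
                     "r2": self.ss_residual / self.ss_total, "F": np.nan, "Z": np.nan,
                     "p": np.nan, "p_adjusted": np.nan})
        rows.append({"term": "Total", "df": self.df_total, "ss": self.ss_total,
                     "r2": np.nan, "F": np.nan, "Z": np.nan, "p": np.nan, "p_adjusted": np.nan})
        return pd.DataFrame(rows).set_index("term")


def _hat(Xw: np.ndarray) -> np.ndarray:
    # projection onto the column space of the whitened design
    Q, _ = np.linalg.qr(Xw)
    return Q @ Q.T


def rrpp_multiple_regression(
    response: str,
    predictors: Sequence[str],
    traits: pd.DataFrame,
    family: CovarianceFamily | None = None,
    n_iter: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
    lam: float = 1.0,
) -> RRPPResult:
    """Sequential (entry-order) SS decomposition with RRPP significance.

    ``predictors`` sets the decomposition order. ``family=None`` performs a
    non-phylogenetic analysis (identity covariance). ``exhaustive=True``
    enumerates all n! permutations (only sensible for tiny n) instead of
    ``n_iter`` random ones; the identity permutation then plays the role of
    the observed statistic.
    """
    if family is not None:
        df = traits.loc[list(family.taxa)]
    else:
        df = traits
    y = df[response].to_numpy(float)
    n = len(y)
    X = np.column_stack([np.ones(n)] + [df[p].to_numpy(float) for p in predictors])
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("NaNs in response or predictors")
    if n_iter < 99 and not exhaustive:
        logger.warning("n_iter=%d gives coarse p-value granularity", n_iter)

    if family is not None:
        W, _ = family.whitener(lam)
        yw = W @ y
        Xw = W @ X
    else:
        yw, Xw = y.copy(), X.copy()
    if np.linalg.matrix_rank(Xw) < Xw.shape[1]:
        raise CollinearityError("whitened design matrix is rank deficient")

    K = len(predictors)
    # residual-maker matrices for every nested model: intercept-only .. full
    resid_makers = []
    for k in range(K + 1):
        resid_makers.append(np.eye(n) - _hat(Xw[:, : k + 1]))
    rss = [float(yw @ M @ yw) for M in resid_makers]

    ss_total = rss[0]
    ss_resid = rss[K]
    ss = {p: rss[k] - rss[k + 1] for k, p in enumerate(predictors)}
    df_term = {p: 1 for p in predictors}
    df_resid = n - 1 - K
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_resid = ss_resid / df_resid
    F_obs = {p: (ss[p] / df_term[p]) / ms_resid for p in predictors}
    r2 = {p: ss[p] / ss_total for p in predictors}

    # --- permutation null per term ---------------------------------------
    rng = np.random.default_rng(seed)
    if exhaustive:
        perms = np.array(list(itertools.permutations(range(n))))
    else:
        perms = np.array([rng.permutation(n) for _ in range(n_iter)])
    R = len(perms)

    p_perm: dict[str, float] = {}
    Z: dict[str, float] = {}
    M_full = resid_makers[K]
    for k, pred in enumerate(predictors):
        M_red = resid_makers[k]
        M_with = resid_makers[k + 1]
        fitted_red = yw - M_red @ yw
        resid_red = M_red @ yw
        Ystar = fitted_red[None, :] + resid_red[perms]  # (R, n)
        rss_red = np.einsum("rn,nm,rm->r", Ystar, M_red, Ystar)
        rss_with = np.einsum("rn,nm,rm->r", Ystar, M_with, Ystar)
        rss_full = np.einsum("rn,nm,rm->r", Ystar, M_full, Ystar)
        with np.errstate(divide="ignore", invalid="ignore"):
            F_star = ((rss_red - rss_with) / df_term[pred]) / (rss_full / df_resid)
        F_star = np.nan_to_num(F_star, nan=0.0, posinf=np.inf)
        if exhaustive:
            null = F_star  # includes the identity permutation == observed
            count = int(np.sum(null >= F_obs[pred] - 1e-12))
            p_perm[pred] = count / R
        else:
            null = np.concatenate([[F_obs[pred]], F_star])
            count = int(np.sum(null >= F_obs[pred] - 1e-12))
            p_perm[pred] = count / (n_iter + 1)
        logs = np.log(np.clip(null, 1e-300, None))
        sd = float(np.std(logs))
        Z[pred] = (
            float((math.log(max(F_obs[pred], 1e-300)) - np.mean(logs)) / sd)
            if sd > 0
            else 0.0
        )

    p_adj = bh_adjust([p_perm[p] for p in predictors])
    result = RRPPResult(
        terms=list(predictors),
        df=df_term,
        ss=ss,
        r2=r2,
        F=F_obs,
        Z=Z,
        p_perm=p_perm,
        p_adjusted=dict(zip(predictors, p_adj)),
        ss_residual=ss_resid,
        ss_total=ss_total,
        df_residual=df_resid,
        df_total=n - 1,
        n_iterations=R,
        seed=seed,
        exhaustive=exhaustive,
    )
    _check_conservation(result)
    return result


def _check_conservation(res: RRPPResult, tol: float = 1e-8) -> None:
    total = sum(res.ss.values()) + res.ss_residual
    if not math.isclose(total, res.ss_total, rel_tol=tol, abs_tol=tol):
        raise AssertionError(
            f"sequential SS do not sum to the total: {total} vs {res.ss_total}"
        )


def rank_components(result: RRPPResult) -> list[tuple[str, float]]:
    """Terms sorted by descending R^2; ties keep entry order (logged)."""
    ranked = sorted(result.terms, key=lambda t: (-result.r2[t], result.terms.index(t)))
    r2s = [result.r2[t] for t in ranked]
    if len(set(np.round(r2s, 12))) < len(r2s):
        logger.info("tied R^2 values; ties broken by predictor entry order")
    return [(t, result.r2[t]) for t in ranked]


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank downwards, cap at 1
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out.tolist()
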