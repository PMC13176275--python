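"""Canonical discriminant analysis and Mahalanobis distances between treatments.

CDA finds linear combinations of the traits that maximize between-group
relative to pooled within-group variance: the generalized eigenproblem
B v = λ W v with B the between-group and W the pooled within-group scatter
matrix.  Canonical variates are scaled to unit pooled within-group variance
and ordered by eigenvalue; the percent of between-group variability each
explains is λ_k / Σλ.  Structure loadings are the correlations between the
original traits and the canonical scores.  Signs are fixed so that the
trait with the largest |loading| on each variable loads positively.

Mahalanobis squared distances between group centroids use the pooled
covariance S = W/(N−g); significance per pair comes from the Hotelling
T²-to-F transformation with the pooled degrees of freedom ν = N−g:

    T² = (n_g n_h / (n_g + n_h)) D²,   F = T² (ν−p+1)/(ν p) ~ F(p, ν−p+1)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import InputError
from .traits import ANALYSIS_TRAITS

logger = logging.getLogger(__name__)

_MAX_CONDITION = 1e12


@dataclass
class CdaResult:
    eigenvalues: np.ndarray          # descending, length min(p, g-1)
    pct_variance: np.ndarray
    coefficients: pd.DataFrame       # raw canonical coefficients, traits x variables
    loadings: pd.DataFrame           # trait-score correlations, traits x variables
    centroids: pd.DataFrame          # groups x variables
    scores: pd.DataFrame             # per-observation canonical scores + group
    n_per_group: pd.Series
    traits: list[str]


@dataclass
class MahalanobisMatrix:
    d2: pd.DataFrame                 # groups x groups, symmetric, zero diagonal
    p_values: pd.DataFrame
    pooled_df: int


def _scatter(X: np.ndarray, labels: np.ndarray):
    groups = list(dict.fromkeys(labels))
    g = len(groups)
    n, p = X.shape
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    means = {}
    ns = {}
    for lab in groups:
        Xg = X[labels == lab]
        ns[lab] = len(Xg)
        if len(Xg) < 2:
            raise InputError(f"group {lab!r} has n < 2")
        mg = Xg.mean(axis=0)
        means[lab] = mg
        C = Xg - mg
        W += C.T @ C
        d = (mg - grand)[:, None]
        B += len(Xg) * (d @ d.T)
    return groups, ns, means, W, B


def _prep(trait_table: pd.DataFrame, group_column: str, traits):
    traits = list(traits) if traits is not None else ANALYSIS_TRAITS
    for col in traits + [group_column]:
        if col not in trait_table.columns:
            raise InputError(f"trait table has no column {col!r}")
    sub = trait_table[traits + [group_column]]
    complete = sub.dropna()
    dropped = len(sub) - len(complete)
    if dropped:
        logger.warning("listwise deletion removed %d observation(s) with missing traits", dropped)
    labels = complete[group_column].to_numpy()
    if len(set(labels)) < 2:
        raise InputError("need at least two groups")
    return complete[traits].to_numpy(float), labels, traits


def fit_cda(
    trait_table: pd.DataFrame,
    group_column: str = "treatment",
    traits: list[str] | None = None,
) -> CdaResult:
    """Fit the canonical discriminant analysis across the treatment groups."""
    X, labels, traits = _prep(trait_table, group_column, traits)
    groups, ns, means, W, B = _scatter(X, labels)
    n, p = X.shape
    g = len(groups)

    cond = np.linalg.cond(W)
    if not np.isfinite(cond) or cond > _MAX_CONDITION:
        raise InputError(
            f"pooled within-group scatter is near-singular (condition number "
            f"{cond:.3g}); remove collinear or constant traits"
        )

    # generalized symmetric eigenproblem B v = lambda W v
    eigvals, eigvecs = linalg.eigh(B, W)
    order = np.argsort(eigvals)[::-1]
    q = min(p, g - 1)
    eigvals = np.clip(eigvals[order][:q], 0.0, None)
    # eigh normalizes v' W v = 1; rescale to unit pooled within-group variance
    coef = eigvecs[:, order][:, :q] * np.sqrt(n - g)

    total = eigvals.sum()
    pct = 100.0 * eigvals / total if total > 0 else np.zeros_like(eigvals)

    scores = (X - X.mean(axis=0)) @ coef
    # structure loadings: total-sample correlations trait <-> score
    loadings = np.zeros((p, q))
    for k in range(q):
        s = scores[:, k]
        s_sd = s.std()
        for j in range(p):
            x_sd = X[:, j].std()
            if s_sd == 0.0 or x_sd == 0.0:
                loadings[j, k] = 0.0
            else:
                loadings[j, k] = np.corrcoef(X[:, j], s)[0, 1]

    # deterministic sign: largest-|loading| trait positive per variable
    for k in range(q):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
            coef[:, k] *= -1.0
            scores[:, k] *= -1.0

    var_names = [f"CAN{k + 1}" for k in range(q)]
    grand = X.mean(axis=0)
    centroids = pd.DataFrame(
        {v: [(means[lab] - grand) @ coef[:, k] for lab in groups] for k, v in enumerate(var_names)},
        index=pd.Index(groups, name=group_column),
    )
    score_df = pd.DataFrame(scores, columns=var_names)
    score_df[group_column] = labels
    return CdaResult(
        eigenvalues=eigvals,
        pct_variance=pct,
        coefficients=pd.DataFrame(coef, index=traits, columns=var_names),
        loadings=pd.DataFrame(loadings, index=traits, columns=var_names),
        centroids=centroids,
        scores=score_df,
        n_per_group=pd.Series(ns),
        traits=traits,
    )


def mahalanobis_tests(
    trait_table: pd.DataFrame,
    group_column: str = "treatment",
    traits: list[str] | None = None,
) -> MahalanobisMatrix:
    """Pairwise Mahalanobis D² between group centroids with Hotelling-F p-values."""
    X, labels, traits = _prep(trait_table, group_column, traits)
    groups, ns, means, W, _ = _scatter(X, labels)
    n, p = X.shape
    g = len(groups)
    nu = n - g
    if nu <= p - 1:
        raise InputError(f"pooled df {nu} too small for {p} traits")
    S = W / nu
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > _MAX_CONDITION:
        raise InputError(
            f"pooled covariance is near-singular (condition number {cond:.3g})"
        )
    Sinv = np.linalg.inv(S)

    d2 = pd.DataFrame(0.0, index=groups, columns=groups)
    pv = pd.DataFrame(1.0, index=groups, columns=groups)
    for a in range(g):
        for b in range(a + 1, g):
            ga, gb = groups[a], groups[b]
            diff = means[ga] - means[gb]
            dd = float(diff @ Sinv @ diff)
            t2 = ns[ga] * ns[gb] / (ns[ga] + ns[gb]) * dd
            f = t2 * (nu - p + 1) / (nu * p)
            pval = float(stats.f.sf(f, p, nu - p + 1))
            d2.loc[ga, gb] = d2.loc[gb, ga] = dd
            pv.loc[ga, gb] = pv.loc[gb, ga] = pval
    return MahalanobisMatrix(d2=d2, p_values=pv, pooled_df=nu)
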