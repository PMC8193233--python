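"""Shared statistical machinery.

Nonparametric group tests (Kruskal–Wallis with Dunn's post hoc),
Benjamini–Hochberg FDR, Spearman rank correlation with t-approximate
p-values, and redundancy analysis (RDA) with a Monte-Carlo permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    statistic: float
    p: float
    df: int
    method: str


def kruskal_wallis(groups: list[np.ndarray | list]) -> TestResult:
    """Kruskal–Wallis H test (tie-corrected), p from chi-square with g-1 df."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if len(pooled) < 3:
        raise ValueError("need total n >= 3")
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical: H = 0, p = 1")
        return TestResult(0.0, 1.0, len(groups) - 1, "kruskal-wallis")
    h, p = sps.kruskal(*groups)
    return TestResult(float(h), float(p), len(groups) - 1, "kruskal-wallis")


def dunn_posthoc(
    groups: list, labels: list[str] | None = None, correction: str = "bh"
) -> pd.DataFrame:
    """Dunn's post-hoc z-tests on pooled ranks, two-sided, with tie correction.

    Returns a table with one row per group pair: z, p and (if requested)
    BH-adjusted q across all pairs of the family.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array(
        [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))]
    )
    # tie correction term: sum over tie groups of (t^3 - t)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1)))
            * (1.0 / sizes[i] + 1.0 / sizes[j])
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2 * sps.norm.sf(abs(z))
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "z": float(z), "p": float(p)})
    out = pd.DataFrame(rows)
    if correction == "bh":
        out["q"] = bh_fdr(out["p"].to_numpy())
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    return out


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order, clipped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho (mid-ranks, tie-aware) with a t-approximate p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate pair: constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class RdaResult:
    constrained_fractions: np.ndarray
    total_constrained_fraction: float
    site_scores: pd.DataFrame
    variable_scores: pd.DataFrame
    predictor_scores: pd.DataFrame
    p_overall: float
    p_per_predictor: dict[str, float] = field(default_factory=dict)


def rda(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    *,
    per_predictor: bool = True,
) -> RdaResult:
    """Redundancy analysis: PCA of the least-squares fit of Y on X.

    Y is column-centred; X standardised to zero mean / unit variance so
    mixed-unit environmental predictors are comparable.  Constrained axis
    fractions are of Y's total variance.  The overall Monte-Carlo p permutes
    whole rows of X against the trace (total constrained variance) statistic;
    per-predictor p-values permute one column at a time.
    """
    Yc = np.asarray(Y, dtype=float)
    Xm = np.asarray(X, dtype=float)
    n, q = Xm.shape
    if n != Yc.shape[0]:
        raise ValueError("Y and X must have the same samples")
    if n <= q + 1:
        raise ValueError("need n_samples > n_predictors + 1")
    if np.isnan(Yc).any() or np.isnan(Xm).any():
        raise ValueError("missing values not allowed")
    Yc = Yc - Yc.mean(axis=0)
    sd = Xm.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [X.columns[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant predictors: {bad}")
    Xs = (Xm - Xm.mean(axis=0)) / sd
    rank = np.linalg.matrix_rank(Xs)
    if rank < q:
        raise ValueError("collinear predictors: X is rank deficient")

    def constrained_trace(Xmat: np.ndarray) -> tuple[float, np.ndarray]:
        beta, *_ = np.linalg.lstsq(Xmat, Yc, rcond=None)
        fitted = Xmat @ beta
        return float((fitted**2).sum()), fitted

    total = float((Yc**2).sum())
    trace_obs, fitted = constrained_trace(Xs)
    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    n_axes = min(rank, Yc.shape[1])
    eig = s[:n_axes] ** 2
    fractions = eig / total
    axes = [f"RDA{i + 1}" for i in range(n_axes)]
    site = pd.DataFrame(U[:, :n_axes] * s[:n_axes], index=Y.index, columns=axes)
    var_sc = pd.DataFrame(Vt[:n_axes].T, index=Y.columns, columns=axes)
    # predictor scores: correlations of standardised predictors with site scores
    with np.errstate(invalid="ignore"):
        pred = np.array(
            [
                [np.corrcoef(Xs[:, j], site.iloc[:, a])[0, 1] for a in range(n_axes)]
                for j in range(q)
            ]
        )
    pred_sc = pd.DataFrame(np.nan_to_num(pred), index=X.columns, columns=axes)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if constrained_trace(Xs[perm])[0] >= trace_obs:
            count += 1
    p_overall = (count + 1) / (n_perm + 1)

    p_per: dict[str, float] = {}
    if per_predictor:
        for j, name in enumerate(X.columns):
            cnt = 0
            for _ in range(n_perm):
                Xp = Xs.copy()
                Xp[:, j] = Xs[rng.permutation(n), j]
                if constrained_trace(Xp)[0] >= trace_obs:
                    cnt += 1
            p_per[str(name)] = (cnt + 1) / (n_perm + 1)

    return RdaResult(
        constrained_fractions=fractions,
        total_constrained_fraction=trace_obs / total,
        site_scores=site,
        variable_scores=var_sc,
        predictor_scores=pred_sc,
        p_overall=float(p_overall),
        p_per_predictor=p_per,
    )
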