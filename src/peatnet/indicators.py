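"""Indicator-species analysis (IndVal) with permutation significance.

For OTU i and group g the indicator value combines specificity
A = (mean abundance in g) / (sum of group-mean abundances) — the group-mean
form, robust to unequal group sizes — with fidelity B = fraction of group-g
samples where the OTU occurs:

    IndVal_{ig} = sqrt(A_{ig} * B_{ig})

Each OTU is associated with its best group (argmax IndVal); significance
comes from permuting group labels over samples, comparing the permuted
best-group IndVal with the observed one.  Benjamini–Hochberg correction is
applied across OTUs, and indicators are selected at IndVal > 0.85 and
q < 0.05 by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from peatnet.diversity import OtuTable
from peatnet.stats import bh_fdr


@dataclass
class IndicatorResult:
    otu_id: str
    best_group: str
    A: float
    B: float
    indval: float
    p: float
    q: float
    selected: bool


def _group_matrix(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, inv = np.unique(groups, return_inverse=True)
    G = np.zeros((len(uniq), len(groups)))
    G[inv, np.arange(len(groups))] = 1.0
    G /= G.sum(axis=1, keepdims=True)  # rows average within a group
    return uniq, G


def _indval_components(
    X: np.ndarray, G: np.ndarray, *, variant: str = "group_mean"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A, B and IndVal matrices of shape (n_groups, n_otus)."""
    means = G @ X
    if variant == "group_mean":
        denom = means.sum(axis=0, keepdims=True)
    elif variant == "total_abundance":
        # classic IndVal: A from summed (not mean) abundance per group
        sizes = 1.0 / G.max(axis=1, keepdims=True)
        sums = means * sizes
        means = sums
        denom = sums.sum(axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown IndVal variant {variant!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, means / denom, 0.0)
    B = G @ (X > 0)
    return A, B, np.sqrt(A * B)


def indval_statistic(
    abundances, groups, *, variant: str = "group_mean"
) -> pd.DataFrame:
    """Per-group specificity A, fidelity B and IndVal for one OTU."""
    x = np.asarray(abundances, dtype=float)
    g = np.asarray(list(groups))
    if len(x) != len(g):
        raise ValueError("abundances and groups must be paired")
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    uniq, counts = np.unique(g, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    if x.sum() == 0:
        raise ValueError("OTU absent everywhere: IndVal undefined")
    labels, G = _group_matrix(g)
    A, B, iv = _indval_components(x[:, None], G, variant=variant)
    return pd.DataFrame(
        {"A": A[:, 0], "B": B[:, 0], "indval": iv[:, 0]}, index=labels
    )


def indval_test(
    table: OtuTable,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    *,
    indval_threshold: float = 0.85,
    q_threshold: float = 0.05,
    variant: str = "group_mean",
    otu_subset: list[str] | None = None,
    exact: bool = False,
) -> pd.DataFrame:
    """IndVal permutation test for every OTU; one best group tested per OTU.

    The permutation statistic is the IndVal of the OTU's observed best group
    recomputed under relabelling, so the test measures association to that
    specific group.  p = (count of permuted values >= observed + 1) /
    (n_perm + 1); with ``exact=True`` all distinct labelings are enumerated
    instead (feasible only for tiny designs) and p = count / n_labelings,
    the identity labelling included in the count.  q by BH across OTUs;
    ``selected`` flags IndVal > indval_threshold and q < q_threshold.
    """
    if not exact and n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    counts = table.counts[otu_subset] if otu_subset is not None else table.counts
    g = np.asarray(pd.Series(groups, index=table.counts.index).loc[counts.index]) \
        if isinstance(groups, (pd.Series, dict)) else np.asarray(list(groups))
    uniq, csz = np.unique(g, return_counts=True)
    if len(uniq) < 2 or (csz < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    X = counts.to_numpy(dtype=float)
    present = X.sum(axis=0) > 0
    if not present.all():
        skipped = [c for c, ok in zip(counts.columns, present) if not ok]
        warnings.warn(f"skipping {len(skipped)} OTUs absent everywhere")
    otu_ids = [c for c, ok in zip(counts.columns, present) if ok]
    X = X[:, present]
    labels, G = _group_matrix(g)
    A, B, iv = _indval_components(X, G, variant=variant)
    best = iv.argmax(axis=0)
    cols = np.arange(X.shape[1])
    obs = iv[best, cols]
    exceed = np.zeros(X.shape[1], dtype=np.int64)
    if exact:
        from sympy.utilities.iterables import multiset_permutations

        n_labelings = 0
        for lab in multiset_permutations(list(g)):
            n_labelings += 1
            _, Gp = _group_matrix(np.asarray(lab))
            _, _, iv_p = _indval_components(X, Gp, variant=variant)
            exceed += iv_p[best, cols] >= obs - 1e-12
        p = exceed / n_labelings
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(len(g))
            _, _, iv_p = _indval_components(X[perm], G, variant=variant)
            exceed += iv_p[best, cols] >= obs - 1e-12
        p = (exceed + 1) / (n_perm + 1)
    q = bh_fdr(p)
    out = pd.DataFrame(
        {
            "otu_id": otu_ids,
            "best_group": labels[best],
            "A": A[best, cols],
            "B": B[best, cols],
            "indval": obs,
            "p": p,
            "q": q,
        }
    )
    out["selected"] = (out["indval"] > indval_threshold) & (out["q"] < q_threshold)
    return out.set_index("otu_id")
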