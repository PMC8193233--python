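"""OTU-table diversity analysis: rarefaction, alpha/beta diversity, PCoA, PERMANOVA.

Counts enter as a samples x OTUs integer table.  Samples are rarefied to a
common depth by a single subsample without replacement, after which alpha
diversity (observed richness, Chao1, Shannon, Faith's phylogenetic
diversity), beta dissimilarities (Bray–Curtis, binary Jaccard, Euclidean),
principal-coordinate ordination and one-way PERMANOVA are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode


@dataclass
class OtuTable:
    """Samples x OTUs nonnegative integer counts with optional taxonomy."""

    counts: pd.DataFrame  # index = sample ids, columns = OTU ids
    taxonomy: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any() or c.columns.duplicated().any():
            raise ValueError("duplicate sample or OTU ids")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = c.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals, axis=0)

    @classmethod
    def read_tsv(
        cls, path: str | Path, *, samples_as_rows: bool = True,
        taxonomy_path: str | Path | None = None,
    ) -> "OtuTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if not samples_as_rows:
            df = df.T
        tax = None
        if taxonomy_path is not None:
            tdf = pd.read_csv(taxonomy_path, sep="\t", header=None,
                              names=["otu_id", "lineage"])
            tax = dict(zip(tdf["otu_id"].astype(str), tdf["lineage"].astype(str)))
        return cls(df, tax)

    def write_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if (d < 0).any():
            raise ValueError("distances must be nonnegative")
        self.d = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a warning.
    A single draw is taken per sample (not an average over draws).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.counts.sum(axis=1)
    keep = totals[totals >= depth].index
    if len(keep) == 0:
        raise ValueError(f"no sample reaches depth {depth} (max total {totals.max()})")
    dropped = sorted(set(table.sample_ids) - set(keep))
    if dropped:
        warnings.warn(f"dropping {len(dropped)} samples below depth {depth}: {dropped}")
    rng = np.random.default_rng(seed)
    rows = []
    for sid in keep:
        counts = table.counts.loc[sid].to_numpy()
        rows.append(rng.multivariate_hypergeometric(counts, depth))
    out = pd.DataFrame(rows, index=list(keep), columns=table.otu_ids)
    return OtuTable(out, table.taxonomy)


def chao1(counts: np.ndarray) -> float:
    """Chao1 richness: S + F1^2/(2 F2), bias-corrected S + F1(F1-1)/(2(F2+1)) if F2=0."""
    counts = np.asarray(counts)
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def shannon(counts: np.ndarray) -> float:
    """Shannon entropy (natural log) of relative abundances."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty sample")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def faith_pd(present_otus: set[str], tree: TreeNode) -> float:
    """Rooted Faith's PD: branch length of the minimal subtree spanning the
    present taxa and the root (multifurcations allowed)."""
    leaves = {t.name for t in tree.tips()}
    missing = present_otus - leaves
    if missing:
        raise ValueError(f"tree is missing OTUs: {sorted(missing)[:5]}")
    total = 0.0
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            node._pd_hit = node.name in present_otus
        else:
            node._pd_hit = any(c._pd_hit for c in node.children)
        if node._pd_hit and node.length is not None:
            total += node.length
    for node in tree.postorder(include_self=False):
        del node._pd_hit
    return total


def alpha_diversity(table: OtuTable, tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample observed_otus, chao1, shannon and (if a tree is given) faith_pd.

    Faith's PD is the rooted variant: the branch length of the minimal subtree
    spanning the sample's OTUs and the root.
    """
    rows = {}
    otu_ids = table.otu_ids
    for sid in table.sample_ids:
        counts = table.counts.loc[sid].to_numpy()
        if counts.sum() == 0:
            raise ValueError(f"sample {sid} is empty")
        row = {
            "observed_otus": int((counts > 0).sum()),
            "chao1": chao1(counts),
            "shannon": shannon(counts),
        }
        if tree is not None:
            present = {otu_ids[i] for i in np.nonzero(counts)[0]}
            row["faith_pd"] = faith_pd(present, tree)
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


_METRICS = {"bray_curtis": "braycurtis", "jaccard": "jaccard", "euclidean": "euclidean"}


def beta_distance(table: OtuTable | pd.DataFrame, metric: str) -> DistanceMatrix:
    """Pairwise sample dissimilarities (Bray–Curtis, binary Jaccard or Euclidean)."""
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    df = table.counts if isinstance(table, OtuTable) else table
    if df.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    X = df.to_numpy(dtype=float)
    if metric == "jaccard":
        X = (X > 0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # 0/0 for all-zero pairs
        d = squareform(pdist(X, metric=_METRICS[metric]))
    if np.isnan(d).any():
        warnings.warn("all-zero sample pair: distance set to 0")
        d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(list(df.index), d, metric)


def pcoa(dm: DistanceMatrix, k: int | None = None):
    """Principal-coordinate analysis by Gower double-centring.

    Returns (coordinates, eigenvalues, explained_fractions).  All eigenvalues
    are reported, negative ones included; explained fractions are computed
    over the positive eigenvalues only.  Coordinates are returned for the
    ``k`` leading positive axes.
    """
    n = len(dm.ids)
    if k is None:
        k = n - 1
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n - 1:
        raise ValueError("k must be <= n_samples - 1")
    A = -0.5 * dm.d**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    eigvals, eigvecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 0
    frac = np.where(pos, eigvals, 0.0) / eigvals[pos].sum()
    n_axes = min(k, int(pos.sum()))
    coords = eigvecs[:, :n_axes] * np.sqrt(eigvals[:n_axes])
    cols = [f"PCo{i + 1}" for i in range(n_axes)]
    return pd.DataFrame(coords, index=dm.ids, columns=cols), eigvals, frac[:n_axes]


def permanova(
    dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0
) -> tuple[float, float, float]:
    """One-way PERMANOVA (ADONIS) on a distance matrix.

    Pseudo-F from among/within sums of squared distances; p-value by free
    permutation of sample labels with the (count + 1)/(n_perm + 1) estimator.
    Returns (pseudo_F, R2, p).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels = np.asarray(pd.Series(groups, index=dm.ids).loc[dm.ids]) \
        if isinstance(groups, (pd.Series, dict)) else np.asarray(list(groups))
    if len(labels) != len(dm.ids):
        raise ValueError("group labels must match the distance matrix samples")
    uniq, inv = np.unique(labels, return_inverse=True)
    g = len(uniq)
    if g < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(inv)
    if (sizes < 2).any():
        raise ValueError("every group needs at least 2 samples")
    d2 = dm.d**2
    n = len(labels)
    if np.allclose(dm.d[np.triu_indices(n, 1)], dm.d[np.triu_indices(n, 1)][0]):
        raise ValueError("constant distance matrix: PERMANOVA degenerate")
    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def ss_within(inv_labels: np.ndarray) -> float:
        ssw = 0.0
        for gi in range(g):
            idx = np.nonzero(inv_labels == gi)[0]
            ssw += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
        return ssw

    def pseudo_f(inv_labels: np.ndarray) -> float:
        ssw = ss_within(inv_labels)
        ssa = ss_total - ssw
        return (ssa / (g - 1)) / (ssw / (n - g))

    f_obs = pseudo_f(inv)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(inv)) >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    r2 = 1 - ss_within(inv) / ss_total
    return float(f_obs), float(r2), float(p)


def regress_on_covariate(y, x) -> tuple[float, float, float, float]:
    """OLS of y on x with a t-test on the slope: (slope, intercept, r2, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)
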