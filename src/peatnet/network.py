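"""Spearman co-occurrence network over abundant OTUs and environmental variables.

Edges connect node pairs whose Spearman correlation across samples is strong
(|rho| > 0.7 by default) and significant after Benjamini–Hochberg correction
over all tested pairs (q < 0.01).  The observed network is characterised by
node centralities (degree, betweenness, closeness, eigenvector), graph-level
topology (density, clustering, path length, diameter, greedy-modularity
partition) and compared with an ensemble of Erdős–Rényi G(n, m) random
graphs of identical size.  Nodes with the highest betweenness centrality are
reported as keystone taxa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from peatnet.diversity import OtuTable
from peatnet.stats import bh_fdr


def filter_abundant(
    table: OtuTable, threshold_fraction: float = 0.001, rule: str = "mean"
) -> OtuTable:
    """Keep OTUs whose relative abundance exceeds the threshold.

    ``rule`` picks how "across all samples" is aggregated: 'mean' (mean
    relative abundance > threshold, the default), 'all' (every sample) or
    'any' (at least one sample).
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    rel = table.relative_abundance()
    if rule == "mean":
        keep = rel.mean(axis=0) > threshold_fraction
    elif rule == "all":
        keep = (rel > threshold_fraction).all(axis=0)
    elif rule == "any":
        keep = (rel > threshold_fraction).any(axis=0)
    else:
        raise ValueError(f"unknown abundance rule {rule!r}")
    kept = keep[keep].index
    if len(kept) == 0:
        raise ValueError(
            f"no OTU passes relative abundance > {threshold_fraction}; "
            "lower the threshold"
        )
    return OtuTable(table.counts[kept], table.taxonomy)


def correlation_screen(
    rel_abundance: pd.DataFrame, env: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spearman rho/p/q matrices over all node pairs (OTU–OTU, OTU–env, env–env).

    q-values come from a single BH family over every tested unordered pair.
    Constant columns are excluded with a warning before testing.
    """
    mats = [rel_abundance]
    if env is not None:
        if not rel_abundance.index.equals(env.index):
            env = env.loc[rel_abundance.index]
        mats.append(env)
    data = pd.concat(mats, axis=1)
    if data.shape[0] < 5:
        raise ValueError("need >= 5 samples for the correlation screen")
    const = data.columns[data.nunique() == 1]
    if len(const):
        warnings.warn(f"excluding {len(const)} constant columns from the screen")
        data = data.drop(columns=const)
    cols = list(data.columns)
    rho, p = sps.spearmanr(data.to_numpy())
    rho = pd.DataFrame(rho, index=cols, columns=cols)
    p = pd.DataFrame(p, index=cols, columns=cols)
    iu = np.triu_indices(len(cols), 1)
    q_flat = bh_fdr(p.to_numpy()[iu])
    q = np.ones_like(p.to_numpy())
    q[iu] = q_flat
    q[(iu[1], iu[0])] = q_flat
    np.fill_diagonal(q, 0.0)
    return rho, p, pd.DataFrame(q, index=cols, columns=cols)


@dataclass
class CoNetwork:
    """Undirected simple graph over OTU and environmental-variable nodes."""

    graph: nx.Graph
    r_threshold: float
    q_threshold: float
    isolated_nodes: list[str] = field(default_factory=list)

    @property
    def otu_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "otu"]

    @property
    def env_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "env"]


def build_network(
    rho: pd.DataFrame,
    q: pd.DataFrame,
    r_threshold: float = 0.7,
    q_threshold: float = 0.01,
    env_ids: set[str] | frozenset[str] = frozenset(),
) -> CoNetwork:
    """Threshold the correlation screen into a co-occurrence network.

    An edge (u, v) exists iff |rho| > r_threshold AND q < q_threshold (both
    strict).  Nodes left without any edge are dropped from the graph but
    recorded in ``isolated_nodes``.
    """
    if rho.shape != q.shape or not rho.columns.equals(q.columns):
        raise ValueError("rho and q matrices must be conformable")
    cols = sorted(rho.columns)  # canonical order: input-order invariance
    r = rho.loc[cols, cols].to_numpy()
    qq = q.loc[cols, cols].to_numpy()
    iu = np.triu_indices(len(cols), 1)
    hit = (np.abs(r[iu]) > r_threshold) & (qq[iu] < q_threshold)
    if not hit.any():
        near = np.abs(r[iu])[qq[iu] < q_threshold]
        best = float(near.max()) if near.size else float(np.abs(r[iu]).max())
        raise ValueError(
            f"no edge passes |rho| > {r_threshold} and q < {q_threshold} "
            f"(best candidate |rho| = {best:.3f})"
        )
    g = nx.Graph(r_threshold=r_threshold, q_threshold=q_threshold)
    for i, j in zip(iu[0][hit], iu[1][hit]):
        u, v = cols[i], cols[j]
        g.add_edge(u, v, rho=float(r[i, j]), q=float(qq[i, j]),
                   sign="+" if r[i, j] > 0 else "-")
    for n in g.nodes:
        g.nodes[n]["kind"] = "env" if n in env_ids else "otu"
    isolated = [c for c in cols if c not in g]
    return CoNetwork(g, r_threshold, q_threshold, isolated)


def node_topology(net: CoNetwork | nx.Graph) -> pd.DataFrame:
    """Degree, betweenness, closeness and eigenvector centrality per node.

    Betweenness is Brandes' unnormalised pair count; closeness the
    Wasserman–Faust within-component variant; eigenvector centrality is
    computed on the largest connected component and max-normalised (nodes
    outside that component score 0).
    """
    g = net.graph if isinstance(net, CoNetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=False)
    clo = nx.closeness_centrality(g, wf_improved=True)
    comp = max(nx.connected_components(g), key=len)
    # rebuild the component with sorted nodes/edges so float summation order
    # (hence the last bits of the centrality scores) is run-independent
    giant = nx.Graph()
    giant.add_nodes_from(sorted(comp))
    giant.add_edges_from(
        sorted((min(u, v), max(u, v)) for u, v in g.edges(comp) if u in comp and v in comp)
    )
    eig = {n: 0.0 for n in g.nodes}
    if giant.number_of_nodes() > 1:
        ev = nx.eigenvector_centrality(giant, max_iter=1000, tol=1e-10)
        top = max(ev.values())
        eig.update({n: v / top for n, v in ev.items()})
    else:
        eig[next(iter(giant.nodes))] = 1.0
    out = pd.DataFrame(
        {"degree": deg, "betweenness": btw, "closeness": clo, "eigenvector": eig}
    )
    return out.sort_index()


@dataclass
class GraphTopology:
    n_nodes: int
    n_edges: int
    avg_degree: float
    graph_density: float
    clustering_coefficient: float  # mean local clustering; degree<2 nodes count 0
    transitivity: float  # global clustering: 3 * triangles / connected triples
    avg_path_length: float
    diameter: int
    modularity: float
    n_modules: int
    module_of: dict[str, int]
    lcc_fraction: float  # fraction of nodes in the largest component


def graph_topology(
    net: CoNetwork | nx.Graph, *, compute_modularity: bool = True,
    method: str = "greedy", seed: int = 0,
) -> GraphTopology:
    """Graph-level topology; path metrics on the largest connected component.

    The module partition maximises modularity by deterministic greedy
    agglomeration (``method='greedy'``) or seeded Louvain
    (``method='louvain'``).
    """
    g = net.graph if isinstance(net, CoNetwork) else net
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValueError("empty graph")
    avg_degree = 2 * m / n
    density = nx.density(g)
    clustering = nx.average_clustering(g)  # degree<2 nodes contribute 0
    transitivity = nx.transitivity(g)
    comps = list(nx.connected_components(g))
    giant = g.subgraph(max(comps, key=len))
    if giant.number_of_nodes() > 1:
        apl = nx.average_shortest_path_length(giant)
        diam = nx.diameter(giant)
    else:
        apl, diam = float("nan"), 0
    mod, n_modules, module_of = float("nan"), 0, {}
    if compute_modularity and m > 0:
        if method == "greedy":
            comms = nx.community.greedy_modularity_communities(g)
        elif method == "louvain":
            comms = nx.community.louvain_communities(g, seed=seed)
        else:
            raise ValueError(f"unknown modularity method {method!r}")
        mod = nx.community.modularity(g, comms)
        n_modules = len(comms)
        module_of = {node: i + 1 for i, c in enumerate(comms) for node in c}
    return GraphTopology(
        n_nodes=n, n_edges=m, avg_degree=avg_degree, graph_density=density,
        clustering_coefficient=clustering, transitivity=transitivity,
        avg_path_length=apl, diameter=diam,
        modularity=mod, n_modules=n_modules, module_of=module_of,
        lcc_fraction=giant.number_of_nodes() / n,
    )


@dataclass
class NullEnsembleSummary:
    n_reps: int
    seed: int
    metrics: pd.DataFrame  # index = metric, columns = mean, sd, observed, z


_NULL_METRICS = (
    "avg_degree", "graph_density", "clustering_coefficient",
    "avg_path_length", "diameter", "modularity",
)


def er_null_ensemble(
    net: CoNetwork | nx.Graph,
    n_reps: int = 1000,
    seed: int = 0,
    metrics: tuple[str, ...] = _NULL_METRICS,
) -> NullEnsembleSummary:
    """Compare the observed graph with Erdős–Rényi G(n, m) random graphs.

    Every replicate has exactly the observed node and edge counts.  Returns
    per-metric null mean/sd and the empirical z-score of the observed value.
    """
    g = net.graph if isinstance(net, CoNetwork) else net
    n, m = g.number_of_nodes(), g.number_of_edges()
    if m > n * (n - 1) // 2:
        raise ValueError("more edges than a simple graph allows")
    if n_reps < 100:
        raise ValueError("need n_reps >= 100 for stable z-scores")
    obs = graph_topology(g, compute_modularity="modularity" in metrics)
    rng = np.random.default_rng(seed)
    rows = {k: [] for k in metrics}
    for _ in range(n_reps):
        gr = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        topo = graph_topology(gr, compute_modularity="modularity" in metrics)
        for k in metrics:
            rows[k].append(getattr(topo, k))
    table = []
    for k in metrics:
        vals = np.asarray(rows[k], dtype=float)
        mean, sd = float(np.nanmean(vals)), float(np.nanstd(vals, ddof=1))
        observed = float(getattr(obs, k))
        z = (observed - mean) / sd if sd > 0 else float("nan")
        table.append({"metric": k, "mean": mean, "sd": sd,
                      "observed": observed, "z": z})
    return NullEnsembleSummary(
        n_reps=n_reps, seed=seed, metrics=pd.DataFrame(table).set_index("metric")
    )


def degree_powerlaw_check(net: CoNetwork | nx.Graph) -> tuple[float, float]:
    """Log-log least-squares fit of the degree histogram: (slope, r2).

    A power-law degree distribution freq ~ k^(-a) gives slope = -a with high
    r2; requires >= 3 distinct positive degrees.
    """
    g = net.graph if isinstance(net, CoNetwork) else net
    degrees = np.array([d for _, d in g.degree() if d > 0])
    ks, freq = np.unique(degrees, return_counts=True)
    if len(ks) < 3:
        raise ValueError("fewer than 3 distinct positive degrees: fit meaningless")
    slope, _, r, _, _ = sps.linregress(np.log(ks), np.log(freq))
    return float(slope), float(r**2)


def keystones(
    topo: pd.DataFrame, k: int = 10, *, node_kinds: dict[str, str] | None = None
) -> pd.DataFrame:
    """Top-k OTU nodes by betweenness (ties: degree desc, then id).

    Environmental-variable nodes (per ``node_kinds``) are excluded from the
    ranking.  If fewer than k OTU nodes exist, all are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = topo.copy()
    if node_kinds:
        df = df[[node_kinds.get(n, "otu") == "otu" for n in df.index]]
    if len(df) < k:
        warnings.warn(f"only {len(df)} OTU nodes available for {k} keystones")
        k = len(df)
    order = np.lexsort(
        (df.index.to_numpy(), -df["degree"].to_numpy(), -df["betweenness"].to_numpy())
    )
    df = df.iloc[order]
    return df.head(k)
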