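"""End-to-end orchestration of the pore-water community analysis.

Stages, in order: rarefaction → alpha diversity + group tests → beta
distances + PCoA + PERMANOVA → plate CLPP metrics + PCA → RDA of community
and CLPP profiles on the environment → abundance filter → correlation
screen → co-occurrence network, topology, Erdős–Rényi null ensemble and
keystones → IndVal indicator OTUs on the network's OTU node set →
consolidated JSON report, stage TSV/GraphML outputs and a hashed MANIFEST.

The run is deterministic given the config (which carries every seed): two
runs with identical config produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

from peatnet import diversity, ecoplate, indicators, network, stats
from peatnet.diversity import OtuTable
from peatnet.synthetic import ENV_VARS

log = logging.getLogger("peatnet")

BETA_METRICS = ("bray_curtis", "jaccard", "euclidean")


@dataclass
class PipelineConfig:
    otu_table: str = "otu_table.tsv"
    metadata: str = "metadata.tsv"
    plates_dir: str | None = "plates"
    tree: str | None = "tree.nwk"
    group_column: str = "group"
    group_merge: dict[str, str] = field(default_factory=dict)
    env_columns: tuple[str, ...] = ENV_VARS
    rarefaction_depth: int = 40205
    snapshot_h: float = 72.0
    abundance_threshold: float = 0.001
    abundance_rule: str = "mean"
    r_threshold: float = 0.7
    q_threshold: float = 0.01
    permanova_perms: int = 999
    rda_perms: int = 999
    indval_perms: int = 999
    indval_threshold: float = 0.85
    indval_q: float = 0.05
    indval_on_all_abundant: bool = False
    er_reps: int = 1000
    keystone_k: int = 10
    seed: int = 0
    outdir: str = "peatnet_out"

    def __post_init__(self) -> None:
        if not 0 < self.abundance_threshold < 1:
            raise ValueError("abundance_threshold must be in (0,1)")
        if not 0 < self.r_threshold < 1 or not 0 < self.q_threshold <= 1:
            raise ValueError("network thresholds out of range")
        if min(self.permanova_perms, self.indval_perms) < 99 or self.er_reps < 100:
            raise ValueError("permutation/replicate counts too small")


_BOOL_KEYS = {"indval_on_all_abundant"}
_NONE_WORDS = {"", "none", "null"}


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a plain-text key=value config file into a PipelineConfig."""
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        kv[key.strip()] = val.strip()
    kwargs: dict = {}
    ftypes = {f.name: f.type for f in fields(PipelineConfig)}
    for key, val in kv.items():
        if key not in ftypes:
            raise ValueError(f"unknown config key {key!r}")
        if key == "group_merge":
            kwargs[key] = dict(
                pair.split(":", 1) for pair in val.split(",") if pair
            )
        elif key == "env_columns":
            kwargs[key] = tuple(v.strip() for v in val.split(",") if v.strip())
        elif key in _BOOL_KEYS:
            kwargs[key] = val.lower() in {"1", "true", "yes"}
        elif key in {"plates_dir", "tree"} and val.lower() in _NONE_WORDS:
            kwargs[key] = None
        elif key in {"rarefaction_depth", "permanova_perms", "rda_perms",
                     "indval_perms", "er_reps", "keystone_k", "seed"}:
            kwargs[key] = int(val)
        elif key in {"snapshot_h", "abundance_threshold", "r_threshold",
                     "q_threshold", "indval_threshold", "indval_q"}:
            kwargs[key] = float(val)
        else:
            kwargs[key] = val
    return PipelineConfig(**kwargs)


def validate_inputs(cfg: PipelineConfig) -> dict:
    """Pre-flight checks; returns {'errors': [...], 'warnings': [...]}."""
    errors: list[str] = []
    warnings_: list[str] = []
    if not Path(cfg.otu_table).exists():
        errors.append(f"missing OTU table: {cfg.otu_table}")
    if not Path(cfg.metadata).exists():
        errors.append(f"missing metadata: {cfg.metadata}")
    if errors:
        return {"errors": errors, "warnings": warnings_}
    table = OtuTable.read_tsv(cfg.otu_table)
    meta = pd.read_csv(cfg.metadata, sep="\t", index_col=0)
    if cfg.group_column not in meta.columns:
        errors.append(f"metadata lacks group column {cfg.group_column!r}")
    missing_meta = sorted(set(table.sample_ids) - set(meta.index))
    for sid in missing_meta:
        errors.append(f"sample {sid} in OTU table but not in metadata")
    extra_meta = sorted(set(meta.index) - set(table.sample_ids))
    for sid in extra_meta:
        warnings_.append(f"sample {sid} in metadata but not in OTU table")
    missing_env = [c for c in cfg.env_columns if c not in meta.columns]
    if missing_env:
        errors.append(f"metadata lacks environmental columns {missing_env}")
    if cfg.plates_dir is not None:
        pdir = Path(cfg.plates_dir)
        if not pdir.is_dir():
            errors.append(f"missing plates directory: {cfg.plates_dir}")
        else:
            for sid in table.sample_ids:
                if not (pdir / f"{sid}.csv").exists():
                    errors.append(f"missing plate file for sample {sid}")
    if cfg.tree is not None:
        if not Path(cfg.tree).exists():
            errors.append(f"missing tree: {cfg.tree}")
        else:
            tree = TreeNode.read(cfg.tree, convert_underscores=False)
            leaves = {t.name for t in tree.tips()}
            missing = sorted(set(table.otu_ids) - leaves)
            if missing:
                errors.append(f"tree missing {len(missing)} OTUs, e.g. {missing[:3]}")
            elif leaves - set(table.otu_ids):
                warnings_.append("tree covers a superset of the table's OTUs")
    return {"errors": errors, "warnings": warnings_}


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **k):
            t0 = time.perf_counter()
            out = fn(*a, **k)
            log.info("stage=%s wall_s=%.2f", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def _write_tsv(df: pd.DataFrame, path: Path, label: str = "") -> None:
    df.to_csv(path, sep="\t", index_label=label or None, float_format="%.10g")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns the consolidated report (also written to disk)."""
    report_validation = validate_inputs(cfg)
    if report_validation["errors"]:
        raise ValueError(
            "input validation failed: " + "; ".join(report_validation["errors"])
        )
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str, label: str = "") -> None:
        path = outdir / name
        _write_tsv(df, path, label)
        written.append(path)

    report: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in vars(cfg).items()},
                    "validation": report_validation, "stages": {}}

    table = OtuTable.read_tsv(cfg.otu_table)
    meta = pd.read_csv(cfg.metadata, sep="\t", index_col=0).loc[table.sample_ids]
    groups = meta[cfg.group_column].astype(str)
    if cfg.group_merge:
        groups = groups.map(lambda g: cfg.group_merge.get(g, g))
    env = meta[list(cfg.env_columns)].astype(float)
    tree = TreeNode.read(cfg.tree, convert_underscores=False) if cfg.tree else None

    # --- rarefaction -----------------------------------------------------
    depth = cfg.rarefaction_depth
    min_total = int(table.counts.sum(axis=1).min())
    if depth > min_total:
        log.warning("rarefaction depth lowered from %d to %d", depth, min_total)
        depth = min_total
    rare = _stage("rarefy")(diversity.rarefy)(table, depth, seed=cfg.seed)
    meta = meta.loc[rare.sample_ids]
    groups = groups.loc[rare.sample_ids]
    env = env.loc[rare.sample_ids]
    report["stages"]["rarefaction"] = {
        "depth": depth, "seed": cfg.seed, "n_samples": len(rare.sample_ids)
    }

    # --- alpha diversity + group tests ----------------------------------
    alpha = _stage("alpha")(diversity.alpha_diversity)(rare, tree)
    emit(alpha, "alpha_diversity.tsv", "sample_id")
    tests = []
    for metric in alpha.columns:
        by_group = [alpha.loc[groups == g, metric].to_numpy()
                    for g in sorted(groups.unique())]
        kw = stats.kruskal_wallis(by_group)
        dunn = stats.dunn_posthoc(by_group, sorted(groups.unique()))
        tests.append({"metric": metric, "H": kw.statistic, "p": kw.p})
        emit(dunn, f"dunn_{metric}.tsv")
    alpha_tests = pd.DataFrame(tests).set_index("metric")
    emit(alpha_tests, "alpha_group_tests.tsv")
    report["stages"]["alpha"] = {
        "means_by_group": {
            g: alpha.loc[groups == g].mean().round(6).to_dict()
            for g in sorted(groups.unique())
        },
        "kruskal_wallis": alpha_tests.round(6).to_dict("index"),
    }

    # --- alpha ~ covariate regressions ----------------------------------
    regressions = {}
    for metric in alpha.columns:
        for covar in ("WT", "PWT"):
            if covar not in env.columns:
                continue
            slope, intercept, r2, p = diversity.regress_on_covariate(
                alpha[metric], env[covar]
            )
            regressions[f"{metric}~{covar}"] = {
                "slope": slope, "intercept": intercept, "r2": r2, "p": p
            }
    report["stages"]["alpha_regressions"] = {
        k: {kk: round(vv, 8) for kk, vv in v.items()} for k, v in regressions.items()
    }

    # --- beta diversity + PCoA + PERMANOVA ------------------------------
    beta_section = {}
    for metric in BETA_METRICS:
        dm = diversity.beta_distance(rare, metric)
        emit(dm.to_frame(), f"distance_{metric}.tsv", "sample_id")
        f_stat, r2, p = _stage(f"permanova_{metric}")(diversity.permanova)(
            dm, groups, n_perm=cfg.permanova_perms, seed=cfg.seed + 1
        )
        beta_section[metric] = {
            "pseudo_F": round(f_stat, 6), "R2": round(r2, 6), "p": p,
            "n_perm": cfg.permanova_perms, "seed": cfg.seed + 1,
        }
        if metric == "bray_curtis":
            coords, eigvals, frac = diversity.pcoa(dm, k=min(5, len(dm.ids) - 1))
            emit(coords, "pcoa_coordinates.tsv", "sample_id")
            beta_section["pcoa_explained"] = [round(f, 6) for f in frac[:5]]
    report["stages"]["beta"] = beta_section

    # --- CLPP (plates) ---------------------------------------------------
    rsi_df = None
    if cfg.plates_dir is not None:
        clpp_rows, rsi_rows, guild_rows, curves = [], {}, {}, []
        for sid in rare.sample_ids:
            series = ecoplate.read_plate_series(Path(cfg.plates_dir) / f"{sid}.csv")
            resp = ecoplate.blank_corrected_response(series, cfg.snapshot_h)
            m = ecoplate.clpp_metrics(resp)
            clpp_rows.append({
                "sample_id": sid, "time_h": m.time_h, "awcd": m.awcd,
                "mcintosh_u": m.mcintosh_u, "shannon_h": m.shannon_h,
            })
            rsi_rows[sid] = m.rsi
            guild_rows[sid] = {
                g.value: v for g, v in ecoplate.guild_profile(resp, series.layout).items()
            }
            for t, a in ecoplate.awcd_curve(series):
                curves.append({"sample_id": sid, "time_h": t, "awcd": a})
        clpp = pd.DataFrame(clpp_rows).set_index("sample_id")
        rsi_df = pd.DataFrame.from_dict(rsi_rows, orient="index").loc[rare.sample_ids]
        guild_df = pd.DataFrame.from_dict(guild_rows, orient="index").loc[rare.sample_ids]
        emit(clpp, "clpp_metrics.tsv")
        emit(rsi_df, "rsi_matrix.tsv", "sample_id")
        emit(guild_df, "guild_profile.tsv", "sample_id")
        emit(pd.DataFrame(curves), "awcd_curves.tsv")
        scores, loadings, frac = ecoplate.clpp_pca(rsi_df)
        emit(scores, "clpp_pca_scores.tsv", "sample_id")
        emit(loadings, "clpp_pca_loadings.tsv", "substrate_id")
        kw_by_metric = {}
        for metric in ("awcd", "mcintosh_u", "shannon_h"):
            by_group = [clpp.loc[groups == g, metric].to_numpy()
                        for g in sorted(groups.unique())]
            kw = stats.kruskal_wallis(by_group)
            kw_by_metric[metric] = {"H": round(kw.statistic, 6), "p": kw.p}
        u_reg = diversity.regress_on_covariate(clpp["mcintosh_u"], env["PWT"]) \
            if "PWT" in env.columns else None
        report["stages"]["clpp"] = {
            "snapshot_h": cfg.snapshot_h,
            "means_by_group": {
                g: clpp.loc[groups == g].mean().round(6).to_dict()
                for g in sorted(groups.unique())
            },
            "guild_means": guild_df.mean().round(6).to_dict(),
            "pca_explained": [round(f, 6) for f in frac[:5]],
            "kruskal_wallis": kw_by_metric,
            "u_vs_pwt": None if u_reg is None else {
                "slope": round(u_reg[0], 8), "r2": round(u_reg[2], 8), "p": u_reg[3]
            },
        }

    # --- abundance filter + RDA -----------------------------------------
    abundant = _stage("filter")(network.filter_abundant)(
        rare, cfg.abundance_threshold, cfg.abundance_rule
    )
    rel = abundant.relative_abundance()
    rda_section = {}
    for name, Y in (("otu", rel), ("clpp", rsi_df)):
        if Y is None:
            continue
        res = _stage(f"rda_{name}")(stats.rda)(
            Y, env, n_perm=cfg.rda_perms, seed=cfg.seed + 2
        )
        emit(res.site_scores, f"rda_{name}_site_scores.tsv", "sample_id")
        emit(res.variable_scores, f"rda_{name}_variable_scores.tsv", "variable")
        emit(res.predictor_scores, f"rda_{name}_predictor_scores.tsv", "predictor")
        rda_section[name] = {
            "axis_fractions": [round(f, 6) for f in res.constrained_fractions[:4]],
            "total_constrained_fraction": round(res.total_constrained_fraction, 6),
            "p_overall": res.p_overall,
            "p_per_predictor": res.p_per_predictor,
            "n_perm": cfg.rda_perms, "seed": cfg.seed + 2,
        }
    report["stages"]["rda"] = rda_section

    # --- correlation screen + network ------------------------------------
    rho, pmat, q = _stage("screen")(network.correlation_screen)(rel, env)
    net = network.build_network(
        rho, q, cfg.r_threshold, cfg.q_threshold, env_ids=set(env.columns)
    )
    topo_nodes = network.node_topology(net)
    topo_graph = _stage("graph_topology")(network.graph_topology)(net)
    null = _stage("er_null")(network.er_null_ensemble)(
        net, n_reps=cfg.er_reps, seed=cfg.seed + 3
    )
    try:
        pl_slope, pl_r2 = network.degree_powerlaw_check(net)
        powerlaw = {"slope": round(pl_slope, 6), "r2": round(pl_r2, 6)}
    except ValueError as exc:
        powerlaw = {"error": str(exc)}
    keys = network.keystones(
        topo_nodes, cfg.keystone_k,
        node_kinds=dict(net.graph.nodes(data="kind")),
    )
    edges = nx.to_pandas_edgelist(net.graph).rename(
        columns={"source": "source", "target": "target"}
    ).sort_values(["source", "target"]).reset_index(drop=True)
    emit(edges[["source", "target", "rho", "q", "sign"]], "network_edges.tsv")
    node_attrs = topo_nodes.copy()
    node_attrs["kind"] = [net.graph.nodes[n]["kind"] for n in node_attrs.index]
    node_attrs["module"] = [topo_graph.module_of.get(n, 0) for n in node_attrs.index]
    emit(node_attrs, "network_nodes.tsv", "node_id")
    emit(keys, "keystones.tsv", "node_id")
    emit(null.metrics, "er_null.tsv")
    report["stages"]["network"] = {
        "n_nodes": topo_graph.n_nodes, "n_edges": topo_graph.n_edges,
        "n_isolated_dropped": len(net.isolated_nodes),
        "avg_degree": round(topo_graph.avg_degree, 6),
        "graph_density": round(topo_graph.graph_density, 6),
        "clustering_coefficient": round(topo_graph.clustering_coefficient, 6),
        "avg_path_length": round(topo_graph.avg_path_length, 6),
        "diameter": topo_graph.diameter,
        "modularity": round(topo_graph.modularity, 6),
        "n_modules": topo_graph.n_modules,
        "positive_edge_fraction": round(float((edges["rho"] > 0).mean()), 6),
        "powerlaw": powerlaw,
        "er_null": {
            "n_reps": null.n_reps, "seed": null.seed,
            "z": {k: (None if not np.isfinite(v) else round(float(v), 4))
                  for k, v in null.metrics["z"].items()},
        },
        "keystones": list(keys.index),
    }

    # --- indicator species ------------------------------------------------
    otu_nodes = None if cfg.indval_on_all_abundant else [
        n for n in net.otu_nodes if n in abundant.counts.columns
    ]
    ind = _stage("indval")(indicators.indval_test)(
        abundant, groups, n_perm=cfg.indval_perms, seed=cfg.seed + 4,
        indval_threshold=cfg.indval_threshold, q_threshold=cfg.indval_q,
        otu_subset=otu_nodes,
    )
    emit(ind, "indicators.tsv", "otu_id")
    selected = ind[ind.selected]
    report["stages"]["indicators"] = {
        "n_tested": int(len(ind)),
        "n_selected": int(selected.shape[0]),
        "by_group": selected.groupby("best_group").size().to_dict(),
        "n_perm": cfg.indval_perms, "seed": cfg.seed + 4,
    }

    # --- GraphML with indicator + module annotations ---------------------
    g_annot = net.graph.copy()
    for n in g_annot.nodes:
        g_annot.nodes[n]["module"] = int(topo_graph.module_of.get(n, 0))
        g_annot.nodes[n]["indicator_group"] = (
            str(ind.loc[n, "best_group"]) if n in ind.index and ind.loc[n, "selected"]
            else ""
        )
        for col in ("degree", "betweenness", "closeness", "eigenvector"):
            g_annot.nodes[n][col] = float(f"{topo_nodes.loc[n, col]:.10g}")
    gml_path = outdir / "network.graphml"
    sorted_g = nx.Graph()
    sorted_g.add_nodes_from(sorted(g_annot.nodes(data=True)))
    sorted_g.add_edges_from(
        sorted((min(u, v), max(u, v), d) for u, v, d in g_annot.edges(data=True))
    )
    nx.write_graphml(sorted_g, gml_path)
    written.append(gml_path)

    # --- report + manifest ------------------------------------------------
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True,
                                      default=_json_default) + "\n")
    written.append(report_path)
    manifest = pd.DataFrame(
        [{"file": p.name, "sha256": hashlib.sha256(p.read_bytes()).hexdigest()}
         for p in sorted(written)]
    )
    manifest.to_csv(outdir / "MANIFEST.tsv", sep="\t", index=False)
    return report
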