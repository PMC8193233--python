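# peatnet

Analysis toolkit for seasonal surveys of peat pore-water bacterial
communities that pair 16S rRNA OTU tables with Biolog EcoMicroplate
carbon-utilization assays. It is aimed at microbial ecologists who want a
single, scriptable pipeline for the standard question in such surveys: how
do community *structure* (who is there) and community *function* (what
carbon sources they use) respond to seasonal drivers such as water-table
level (WT) and pore-water temperature (PWT)?

## What it computes

**Community-level physiological profiling (CLPP).** For each EcoPlate the
blank-corrected colour response of substrate *i* at a snapshot time
(default 72 h) is `c_i = max(C_i − R, 0)`, where `C_i` is the
replicate-mean (A590 − A750) of the substrate wells and `R` the same for
the water control. From the clamped vector over the n = 31 substrates:

- AWCD = Σ c_i / n (average well-colour development, the overall
  carbon-utilization rate),
- McIntosh U = √(Σ c_i²),
- Shannon H′ = −Σ p_i ln p_i with p_i = c_i / Σ c_j,
- Rsi = c_i / AWCD (inoculum-density-normalised responses; Σ Rsi = n),

plus per-guild profiles (carbohydrates, amino acids, amines, esters,
carboxylic acids, alcohols) and a column-centred PCA of the Rsi matrix.

**Diversity.** Rarefaction to a common depth (single draw without
replacement), observed richness, Chao1 (`S + F1²/2F2`, bias-corrected when
F2 = 0), Shannon, rooted Faith's PD; Bray–Curtis / binary Jaccard /
Euclidean distances; PCoA by Gower double-centring; one-way PERMANOVA with
the (count+1)/(n_perm+1) permutation p; OLS regressions of diversity on
environmental covariates.

**Shared statistics.** Kruskal–Wallis with Dunn's post hoc,
Benjamini–Hochberg FDR, tie-aware Spearman correlation, and redundancy
analysis (RDA: PCA of the least-squares fit Ŷ = X(XᵀX)⁻¹XᵀY, with
Monte-Carlo permutation tests).

**Co-occurrence network.** OTUs filtered at mean relative abundance
> 0.1%, Spearman correlations over all OTU and environmental-variable
pairs, one BH family across all pairs, and an edge wherever |ρ| > 0.7 and
q < 0.01. Node centralities (degree, unnormalised Brandes betweenness,
closeness, eigenvector), graph topology (density, clustering, path length,
diameter, greedy-modularity partition), a 1,000-replicate Erdős–Rényi
G(n, m) null ensemble with empirical z-scores, a log-log power-law check of
the degree distribution, and the top-10 betweenness OTUs as keystone taxa.

**Indicator species.** IndVal = √(A·B) per OTU × month group, with the
group-mean (group-size-corrected) specificity A and occurrence fidelity B,
999 label permutations, BH correction across OTUs, and selection at
IndVal > 0.85, q < 0.05.

**Synthetic scenarios.** Because such field datasets are rarely deposited
in processed form, `peatnet.synthetic` generates complete study bundles —
seasonal metadata with realistic covariate profiles, OTU tables with
planted correlation modules and indicator OTUs, a random phylogeny, and
logistic plate kinetics — together with the ground truth needed to score
recovery.

## Worked example

```
$ peatnet generate --seed 1 --outdir scen1
scenario written to scen1 (36 samples, 600 OTUs)

$ cat > run.cfg <<EOF
otu_table=scen1/otu_table.tsv
metadata=scen1/metadata.tsv
plates_dir=scen1/plates
tree=scen1/tree.nwk
seed=1
outdir=out1
EOF

$ peatnet run --config run.cfg
done: 59 nodes / 162 edges, 15 indicator OTUs; outputs in out1

$ peatnet report out1/report.json
network: 59 nodes, 162 edges, modularity 0.840649, path length 2.969697, diameter 7
indicators: 15 selected of 55 tested
permanova[bray_curtis]: R2=0.187735 p=0.001
permanova[euclidean]: R2=0.155747 p=0.001
permanova[jaccard]: R2=0.04704 p=0.843
```

Reading the output: the thresholded Spearman network keeps 59 of the 220
screened nodes (the rest have no correlation passing |ρ| > 0.7 at
q < 0.01); its modularity of 0.84 against an Erdős–Rényi null z-score of
~31 (see `out1/er_null.tsv`) says the planted correlation modules dominate
the graph. All 15 planted indicator OTUs — 5 per month — are recovered at
IndVal > 0.85, q < 0.05, and none of the unplanted OTUs are selected.
Bray–Curtis PERMANOVA rejects homogeneity across months at the minimum
achievable p (0.001 at 999 permutations), while the binary Jaccard test
does not: the seasonal signal in this scenario lives in abundances, not in
presence/absence. Per-sample CLPP metrics, distance matrices, ordinations,
RDA triplot tables, network exports (GraphML + TSV) and a hashed MANIFEST
are written alongside `report.json`; reruns with the same config are
byte-identical.

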