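# Methods notes

This note records the models implemented in `peatnet`, the defaults and
why they were chosen, what the synthetic scenario generator does and does
not emulate, and the numerical conventions that matter when comparing
results across tools.

## Plate profiling (CLPP)

A Biolog EcoPlate carries 31 carbon substrates plus a water control, each
in triplicate (three 4-column blocks of 32 wells). Readings are taken at
two wavelengths; the metabolic signal of a well is A590 − A750, which
removes turbidity. Per substrate we average the three replicate wells
*before* control subtraction and clamping — treating the 31 substrates as
the statistical units, with an option (`average_replicates=False`) to keep
all 93 wells separate. Responses below the water control carry no
information about dye reduction and are clamped to zero before every
downstream metric (AWCD, U, H′, Rsi, guild means, PCA), so a plate read
early in incubation cannot produce negative utilization.

The snapshot defaults to 72 h, the usual point where EcoPlate colour
development discriminates communities without saturating. If 72 h was not
read, the nearest timepoint within ±6 h is used; linear interpolation is
available behind an explicit flag rather than silently, because
interpolated optical densities are not measurements.

Shannon H′ excludes zero wells (0·ln 0 := 0), so H′ ∈ [0, ln 31] with the
maximum at a perfectly even response. McIntosh U is the Euclidean norm of
the clamped response vector — the square-root form; with 31 wells and AWCD
near 1 OD this puts U near 6, the magnitude such assays report. Guild
profiles are per-guild *means* (not sums) so guilds with 2 substrates
(amines) are comparable with guilds of 8 (carbohydrates, carboxylic
acids). The Rsi PCA is column-centred but not variance-scaled: dividing by
AWCD already removes the inoculum-density scale, and scaling would inflate
substrates with near-zero response.

## Diversity

Rarefaction is a single multivariate-hypergeometric draw per sample
(subsampling without replacement to exactly the requested depth), not an
average over draws; the seed is recorded in the run report. Samples below
the depth are dropped with a warning, and the pipeline auto-lowers the
configured depth (default 40,205) to the minimum sample total when needed.

Chao1 uses S + F1²/(2F2) and switches to the bias-corrected
S + F1(F1−1)/(2(F2+1)) only when F2 = 0, avoiding the division by zero.
Faith's PD is the rooted variant — the branch length of the minimal
subtree spanning the sample's taxa *and the root* — implemented as a
single post-order traversal so multifurcating roots are accepted; on
bifurcating trees it agrees with scikit-bio's implementation (tested).
Jaccard is computed on presence/absence, the usual meaning when cited
alongside Bray–Curtis in microbiome work; Shannon uses natural logs.

PCoA reports *all* eigenvalues, negative ones included (they arise
whenever a dissimilarity is not Euclidean-embeddable, e.g. Bray–Curtis);
explained fractions are taken over the positive spectrum only and no
Lingoes/Cailliez correction is applied by default. PERMANOVA is one-way
with free permutation of sample labels and the unbiased
(count + 1)/(n_perm + 1) estimator, so the smallest attainable p at 999
permutations is 0.001.

## Shared statistics

Spearman p-values use the t approximation with n − 2 df; the network
screen evaluates ~10⁴ pairs, where exact permutation would be pointless
overhead and the t approximation is standard. Dunn's post hoc z-tests are
two-sided with the pooled tie correction, BH-adjusted within the family of
all pairwise comparisons; BH was chosen for consistency with the network
FDR since no specific correction is canonical for Dunn.

RDA standardises predictors to zero mean and unit variance (environmental
variables arrive in mg/L, mV, °C, cm — unscaled least squares would be
dominated by ORP's numeric range); the constrained fraction is invariant
to any invertible linear reparameterisation of X, so this is a
presentation choice, not a model choice. The overall Monte-Carlo test
permutes whole rows of X against the constrained trace; per-predictor
p-values permute one (standardised) column at a time. This marginal scheme
is simple and seedable but conservative for correlated predictors — a
known limitation, not a bug.

## Co-occurrence network

The abundance filter keeps OTUs with *mean* relative abundance above the
threshold (default 0.1%); "every sample" and "any sample" rules are
available (`rule="all"` / `"any"`). Correlations among OTU and
environmental nodes form a single BH family — splitting families would
make env–OTU edges incomparable with OTU–OTU edges. Edge thresholds are
strict inequalities (|ρ| > 0.7, q < 0.01); a pair at exactly ρ = 0.7 is
excluded. Isolated nodes are dropped from the graph but counted in the
report.

Betweenness is Brandes' algorithm with raw (unnormalised) pair counts;
closeness is the Wasserman–Faust within-component variant; eigenvector
centrality is computed on the largest connected component (power
iteration, tol 1e−10) and max-normalised, with nodes outside that
component scored 0. The component is rebuilt with sorted nodes before the
power iteration so floating-point summation order — and therefore the
output bytes — do not depend on the process hash seed.

The module partition uses deterministic greedy modularity agglomeration by
default (seeded Louvain available): determinism was preferred over the
marginally higher modularity Louvain sometimes finds, because the pipeline
promises byte-identical reruns. Path length and diameter are computed on
the largest connected component and reported with the component's coverage
fraction. Two clustering summaries are kept: `clustering_coefficient` is
the mean local coefficient with degree-<2 nodes contributing 0, and
`transitivity` is the global 3·triangles/triples ratio. They differ
systematically on sparse graphs — under G(n, m) the expected transitivity
is the edge density m/C(n,2), while the local mean is deflated by the
fraction of degree-<2 nodes — which is why the null-calibration test
checks transitivity against the closed-form density.

The Erdős–Rényi ensemble uses G(n, m) with exactly the observed node and
edge counts in every replicate (1,000 by default), giving empirical
mean/sd/z per topology metric. Keystones are the top-10 OTU nodes by
betweenness, ties broken by degree then lexicographic id; environmental
nodes are excluded from the ranking since a covariate cannot be a keystone
taxon.

## Indicator species

IndVal uses the group-mean form of specificity, A_g = mean_g / Σ_h mean_h
(the group-size-corrected variant that ecologists' standard software
defaults to), with the classic total-abundance form behind
`variant="total_abundance"`. Each OTU is tested for its best group only,
and the permutation statistic is that *same group's* IndVal recomputed
under relabelling — association to the identified group, not the maximum
over groups. The distinction matters: for a perfect two-group indicator
over 3 + 3 samples, exhaustive enumeration of the 20 distinct labelings
gives p = 1/20 under the fixed-group statistic, whereas a max-over-groups
statistic would also count the complementary labelling and give 2/20.
`exact=True` performs that enumeration (identity labelling counted in the
numerator and denominator); Monte-Carlo mode uses (count + 1)/(n_perm + 1).
FDR is applied across OTUs only, since one test is performed per OTU. The
pipeline runs the test on the network's OTU node set by default, mirroring
the practice of characterising the taxa that made it into the network;
`indval_on_all_abundant=true` widens it to every abundance-filtered OTU.

## Synthetic scenario generator

Defaults describe a three-month survey: 3 groups × 12 samples, 600 OTUs,
multinomial counts at a Poisson read depth around 40,205 (a typical
rarefaction level for such data). The seven covariates (DOC, DO, ORP, EC,
pH, PWT, WT) are Gaussian per group with means/SDs chosen to mimic a
temperate peatland's seasonal contrast — warm, high-water May/August
versus cold, oxidised November.

OTU abundances are log-normal: a per-OTU baseline (log-SD 1.5) plus
structured effects. Each planted module's members share a latent factor
scaled so the pairwise latent correlation equals `module_correlation`
(default 0.9); the first module's factor is blended with the
sample's standardised WT (weight 0.7), mimicking an environmentally driven
module without asserting any particular effect size. Indicator OTUs
(5 per group) are multiplied by `indicator_fold` (default 8) in their own
group and divided by it elsewhere; `indicator_fold=inf` plants
presence/absence indicators. Planted OTUs get elevated baselines so they
survive the 0.1% abundance filter — the recovery questions the generator
serves are about correlation and permutation inference, not about
detection limits.

Plate kinetics are logistic per substrate: colour is ~5% of its plateau at
the end of the 24 h lag, rises steeply to the midpoint at 72 h, and is
>95% complete well before 168 h. Plateau amplitudes are guild-specific
(esters > amino acids > amines > carbohydrates > carboxylic acids >
alcohols, matching the qualitative preference ordering such assays show)
and scaled by an increasing logistic function of the sample's PWT, so warm
months develop more colour at 72 h (AWCD ≈ 1.0 vs ≈ 0.6; U ≈ 6 vs ≈ 3.6
under defaults). Additive Gaussian read noise (sd 0.01 OD) is clipped at
zero.

What the generator does *not* emulate: compositional spurious correlation
at realistic strength (modules are planted on top of weak independent
noise, so network recovery here is easier than in real data), taxonomic
structure, sequencing error, zero-inflation beyond the multinomial,
phylogenetic signal in abundances (the tree is independent of the
counts), and plate-reader drift. Passing recovery tests therefore shows
the inference machinery is correct and calibrated, not that the thresholds
would perform identically on field data.

## Problem sizes and determinism

The test suite's simulations are sized for a desk run: type-I calibration
uses 500 null datasets with 199 permutations each; module/indicator
recovery uses the full default scenario over 20 seeds; the
Erdős–Rényi calibration uses G(100, 200) with 1,000 replicates. The
end-to-end pipeline on the default scenario takes about a minute on one
CPU. Every stochastic component takes an explicit seed; generators are
pure functions of (config, seed), pipeline reruns with identical config
are byte-identical, and permutation p-values never report zero.

## Known limitations

- The Spearman screen is not compositionality-aware (no SparCC/SPIEC-EASI
  style correction); with strongly compositional data, negative bias in
  correlations is expected.
- The ER null fixes only n and m; degree-preserving (configuration-model)
  nulls are out of scope.
- The power-law check is a least-squares fit on the log-log degree
  histogram — a descriptive statistic, not a maximum-likelihood power-law
  test.
- PERMANOVA is one-way with free permutations; no strata/repeated-measures
  designs.
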