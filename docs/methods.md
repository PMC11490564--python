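# Methods

`granuleco` re-implements, as a tested and reusable pipeline, the
ecological-inference machinery used to study microbial succession during
the granulation of activated sludge: Hill-number diversity, phylogenetic
and taxonomic null models of community assembly, dual-method consensus
co-occurrence networks with temporal module dynamics, inter-kingdom
bipartite networks, and constrained-ordination variance partitioning. This
note documents the models, the conventions chosen where the field offers
several, and what the synthetic validation data do and do not show.

## Inputs and preprocessing

The universal inputs are two samples × ASVs integer count tables (one
16S-like prokaryote table, one 18S-like eukaryote table), one rooted
newick phylogeny per kingdom whose tips cover the ASV ids, and a
per-sample metadata table (day, granulation stage, reactor measurements).
Samples are ordered by day. Granulation stages default to floccular
(days 0–15), intermediate (16–115) and granular (≥116), half-open at the
boundaries; they are configurable.

Each table is rarefied to even depth by multivariate-hypergeometric
subsampling (without replacement, seeded). The prevalence/abundance filter
— keep ASVs present in ≥10 % of samples *and* holding ≥0.1 % of the grand
total read count — belongs to the **network analysis only**; diversity,
null models and ordination run on the full rarefied tables. Applying the
filter before the null models would shrink the taxon pool to roughly the
per-sample communities and destroy the contrast the null models measure.
The 0.1 % filter uses the pooled (grand-total) share; a flag switches to
the mean per-sample share.

## Diversity

Alpha diversity is the Hill number ^qTD = (Σ p_i^q)^{1/(1−q)} with the
q→1 limit exp(−Σ p_i ln p_i); q = 0 is richness, q = 2 the inverse Simpson
concentration. Evaluation is done in log space, so the profile is smooth
through q = 1 to ~1e−9.

Beta diversity between two samples uses the multiplicative decomposition
with equal sample weights (N = 2): gamma is the Hill number of the mean
relative-abundance vector; alpha is the two-assemblage
abundance-weighted alpha, ^qDα = ½ (Σ_ij (p_ij/2)^q)^{1/(1−q)}; β = γ/α ∈
[1, 2]. The bounded dissimilarity is the **local** (Sørensen-type) overlap
complement 1 − C_q2 by default, with the regional (Jaccard-type) 1 − U_q2
behind a flag; both equal ln β / ln 2 at q = 1. Identical samples give 0,
disjoint supports give 1 at every order.

Bray–Curtis dissimilarity is 1 − 2Σmin(n_iA, n_iB)/(N_A + N_B) on counts.

## Community-assembly null models

The premise — closely related ASVs have similar environmental preferences
— is tested first. Each ASV's environmental optimum is its
abundance-weighted mean of a measured variable across samples; a Mantel
correlogram relates |optimum_i − optimum_j| to the cophenetic distance in
equal-frequency distance classes. The per-class statistic is sign-flipped
so positive = similarity at that distance; p-values are two-sided
permutation tests (shuffling ASV identities) with progressive Holm
correction (class k corrected within the first k classes). With a single
class the procedure reduces to the plain Mantel test on raw distances.
In the pipeline the correlogram runs on the network-filtered ASVs, whose
optima are well estimated; rare-ASV optima are dominated by sampling
noise.

Within-sample dispersion: abundance-weighted MPD (Σ_{i≠j} f_i f_j d_ij /
Σ f_i f_j) and MNTD (Σ_i f_i min_{j≠i} d_ij) over present taxa, against
the "taxa labels" null that relocates the community (abundances attached)
to uniformly random tip positions of the pool — the pool being the
kingdom's full rarefied table. NRI and NTI are the negated standardized
effect sizes; positive = clustering. Nulls with relative sd ≤ 1e−6 are
flagged degenerate and reported as SES 0 so time series stay aligned.

Between successive samples: abundance-weighted βMNTD
(½[Σ_{i∈A} f_iA min_{j∈B} d_ij + symmetric], minimum including shared
ASVs), standardized against shuffling taxa across all tree tips (both
samples re-mapped with one permutation). βNTI keeps the turnover sign
convention (negative = less turnover than expected); |βNTI| > 2 is the
deterministic-turnover call. Raup–Crick on Bray–Curtis rebuilds both
samples under random assembly — identities drawn without replacement with
probability ∝ occupancy, one read planted per identity, the remaining
reads multinomial with probability ∝ dataset-wide relative abundance —
and reports RC = 2·[#(null < obs) + ½#(null = obs)]/n_null − 1 ∈ [−1, 1];
ties use the midpoint rule; |RC| > 0.95 flags deviation from drift.
A uniform-weights flag is available. All null counts default to 999.

Performance: the series drivers run the nulls through a batched engine —
MPD as a quadratic form q′Dq evaluated for all draws with one float32
matrix product, MNTD/βMNTD via a nearest-neighbour scan over the
distance-sorted taxon order. Both were verified against the plain
per-draw implementations (≤4e−7 for MPD, machine precision otherwise),
and against exhaustive enumeration on small trees in the test suite.
Per-pair and per-sample RNG streams are spawned deterministically from
the master seed.

## Networks

Pairwise associations use two methods on the filtered tables: Spearman's
rank correlation on relative abundances (two-sided p from the
t-approximation) and SparCC. SparCC is implemented from the log-ratio
variance formulation: t_ij = Var(log x_i/x_j); basis variances solve
(p−2)ω_i + Σω_j = Σ_j t_ij under the sparsity approximation; the most
correlated pair above 0.1 is iteratively excluded (10 rounds) and the
system re-solved; fractions come from a Dirichlet posterior (counts + 1)
and the estimate is the median over 20 draws. Pseudo p-values bootstrap
the null by shuffling each ASV's counts independently (100 replicates,
5 inner draws each). Two robustness choices beyond the textbook
algorithm: a component may lose at most max(2, 10 % of p−1) pairs to
exclusion (unbounded exclusion drives a runaway variance shrinkage in
small systems), and components whose basis variance turns non-positive in
a draw have that draw's correlations masked, the median absorbing the
loss. With ~100 bootstraps the smallest attainable pseudo-p is ~1/101;
for small networks (few hundred candidate pairs) BH-corrected
significance then requires more bootstraps — the validation experiments
use 499–1999 where pair counts are small.

A consensus edge requires |ρ| > 0.6, |SparCC r| > 0.6 and both BH-FDR
q-values < 0.05 (FDR computed over the upper triangle of each matrix);
edges whose two correlations disagree in sign are dropped with a warning.
Modules come from the walktrap random-walk algorithm (4 steps, cut
maximizing weighted modularity) on absolute edge weights, the weight
being mean(|ρ|, |r|); isolated nodes are singleton modules; labels are
ordered by summed mean node abundance. Module completeness is the
fraction of a module's nodes detected in a sample; module abundance their
summed relative abundance. Per-time-point networks are the subgraphs
induced on the nodes present in each sample; modularity is re-detected on
each subgraph (restriction of global labels is available behind a flag).
The inter-kingdom bipartite network restricts each kingdom to its core
(present in >75 % of samples), computes cross-kingdom Spearman on
per-kingdom closed compositions and cross-kingdom SparCC on the
concatenated counts with a kingdom-blocked Dirichlet closure, corrects
FDR over the cross-kingdom pair pool only, and keeps positive consensus
edges.

## Ordination

dbRDA embeds the Bray–Curtis matrix by principal coordinates (Gower
double-centering; negative eigenvalues reported, excluded from scores; no
Lingoes/Cailliez correction by default) and regresses the
positive-axis coordinates on standardized predictors (stage enters as
dummy indicators). R² is constrained inertia over total positive inertia,
adjusted by Ezekiel's formula; the p-value permutes predictor rows with
the (B+1) convention, so the smallest attainable p is 1/(n_perm+1).
Forward selection adds, per step, the candidate with the smallest
permutation p for its partial-F contribution if p ≤ α and the adjusted R²
increases; with α = 1 the adjusted-R² guard is waived so all candidates
enter by contribution order (the two stopping rules are contradictory in
that limit, and the ordering interpretation was chosen). Variance
partitioning fits the seven models formed by the non-empty subsets of the
abiotic, biotic (the other kingdom's ^qTD at q = 0, 1, 2) and stage sets
and decomposes adjusted R² by inclusion–exclusion; the fractions plus the
residual sum to 1 identically. Each single set must be full-rank;
combined models tolerate across-set collinearity because the fit is a
projection and the df penalty uses the design rank (identical sets then
show up as fully shared variation, as they should).

## Synthetic reactor communities

The generator is the validation instrument: every downstream claim is
tested against data with known ground truth.

Dynamics are a discrete-time replicator with immigration. ASV i has a
Gaussian fitness kernel w_i(t) = exp(−(E_t − o_i)²/2σ_sel²) around its
environmental optimum; the expected composition is
(1−m)·normalize(x_{t−1} w(t)) + m·pool, and the observed counts are one
multinomial draw at the kingdom's read depth — drift is finite-depth
sampling, with no extra overdispersion. The latent reactor state E_t
takes a distinct mean per stage (0, 1, 2 on a dimensionless granulation
axis) plus noise, and is expressed as four measured covariates (nitrate,
VSS, phosphate, TOC) by affine transforms with noise, giving the
ordination several candidate predictors.

The kingdom trees are built to carry the features of real amplicon
phylogenies that the null models respond to, each added because a
qualitative signature required it:

- guilds are monophyletic: n_guilds balanced Yule clades joined at the
  root (deep lineages with conserved preferences);
- abundant species form tight terminal "tufts" of near-identical sequence
  variants (cluster sizes ∝ species abundance², within-tuft depth 0.01–
  0.04), while most species are isolated singletons;
- terminal branches carry a near-constant extension (ML substitution-rate
  trees are not ultrametric), separating the within-tuft scale from the
  between-species scale;
- optima are centred on the guild's stage mean with a Brownian-motion
  fine-scale spread, and abundant species sit closest to the centre
  (dominance and niche fit co-occur, as for the granule formers).

Species-level lognormal "lottery" noise multiplies fitness each step, so
members of the selected niche exchange dominance while the niche itself
is stable — the mechanism behind homogeneous-selection βNTI. The public
`simulate_tree` operation remains a plain ultrametric Yule tree.

Eukaryote fitness is optionally multiplied by (1 + κ·share of the
same-numbered prokaryote guild), planting true positive inter-kingdom
associations (unidirectional prokaryote → eukaryote). Ground truth —
guild and optimum per ASV, coupled guild pairs, per-stage regime label
(selection when σ_sel ≤ 1) — is recorded in the dataset.

### Presets

Presets are calibrated only to reproduce qualitative signatures, since
the study reports no quantitative effect sizes for its regimes; the sizes
below are package choices.

- **paper_like** — the study design: 52 samples over three stages, read
  depths 43 329/31 420. The ASV universe is (2000, 550) with skewed pool
  abundances so that the 10 %/0.1 % network filter retains a few hundred
  ASVs per kingdom (the study's 411/125 are post-filter counts) and
  per-sample richness stays well below the universe. Selection relaxes
  across stages (σ_sel = 0.25, 0.55, 3.0), reproducing
  deterministic-early / stochastic-late turnover; κ = 1.5.
- **selection** — strong stable filtering: constant environment at the
  first guild's optimum, σ_sel = 0.35, m = 0.06, species-lottery noise
  0.75, 30 samples at depth 1500/1050 over a (411, 125) universe. Yields
  mean NTI > 2 and βNTI < −2 for ≥80 % of successive pairs (pooled over
  seeds).
- **neutral** — selection off (σ_sel = 1e6), immigration 0.95, shallow
  depths, unclustered trees and even pools (phylogenetically random, as
  a neutral null must be). Per-dataset NRI/NTI means scatter around 0
  (the fixed pool induces a per-dataset offset that averages out over
  replicates); RCbray and βNTI sit within their null bands.
- **coupled** — compact two-kingdom scenario (40 samples, 30+16 ASVs)
  with κ = 6 for bipartite-detection experiments.

### What the synthetic data do not emulate

No sequence-level error or chimeras, no taxonomy, no multi-dimensional
environmental space (one latent axis), no granule physics, no
overdispersion beyond multinomial sampling, no time-varying immigration
pool. Passing the validation therefore shows the *inference machinery* is
correct and well calibrated under the stated generative model — not that
real reactor data satisfy that model.

## Problem sizes and numerical choices

The full `paper_like` pipeline (52 samples, 2000/550-ASV universes, full
read depths, 999 nulls and permutations everywhere, 100 SparCC
bootstraps) runs in a few minutes on one CPU and is byte-identical across
reruns with the same master seed; stage RNG streams are spawned from
`SeedSequence(master_seed)` under fixed stage indices (rarefy 0, signal
1, nulls 2, networks 3, bipartite 4, ordination 5; second index =
kingdom), so stages can be re-run in isolation. Validation experiments
use smaller replicates (documented in the test suite) so the whole suite
completes in well under half an hour. Degenerate nulls (sd ≈ 0) are
flagged, not raised; the pipeline skips stages whose statistical
minimums a dataset cannot meet (e.g. SparCC below 10 samples) and says so
in the report.

## Known limitations

- SparCC is unreliable below ~12 components or under extreme dominance;
  the consensus rule inherits the bootstrap's p-value resolution.
- The RC null uses occupancy/abundance weights from the analyzed table
  itself; with very few samples the weights are noisy.
- βNTI's discriminating power vanishes when nearly the whole pool is
  present in every sample (the filter-scope decision above exists for
  this reason).
- The generator's neutral preset approximates drift by strong immigration
  plus shallow sampling; it is not a Hubbell zero-sum drift model.
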