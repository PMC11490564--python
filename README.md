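# granuleco

Community-ecology toolkit for two-kingdom microbial succession in
granular-sludge bioreactors.

When floccular activated sludge is driven to granulate, the prokaryotic
(16S) and micro-eukaryotic (18S) communities pass through a floccular, an
intermediate and a granular stage, and the central ecological questions
are *how much* diversity turns over, *whether* the turnover is driven by
deterministic selection or stochastic drift, and *which* sub-communities
rise and fall together — within and across kingdoms. `granuleco`
implements the full inference chain used to answer those questions from
paired ASV count tables, rooted phylogenies and reactor metadata:

- **Hill-number diversity** — α-diversity ^qTD = (Σ pᵢ^q)^{1/(1−q)}
  (q = 0 richness, q = 1 exp-Shannon, q = 2 inverse Simpson) and the
  bounded β-dissimilarity ^qβdis ∈ [0, 1] between successive samples from
  the multiplicative decomposition β = γ/α.
- **Community-assembly null models** — the phylogenetic-signal Mantel
  correlogram on abundance-weighted environmental optima; NRI/NTI
  (standardized, abundance-weighted MPD/MNTD against taxa-label shuffling);
  βNTI (βMNTD against tip shuffling; |βNTI| > 2 = deterministic turnover)
  and Raup–Crick on Bray–Curtis (RC_bray ∈ [−1, 1]; |RC| ≤ 0.95 =
  consistent with drift) for every successive sample pair.
- **Consensus co-occurrence networks** — edges require Spearman ρ *and*
  SparCC r with |corr| > 0.6 and BH-FDR q < 0.05 for both (SparCC is
  implemented from the log-ratio variance formulation with Dirichlet
  resampling and bootstrap pseudo p-values); walktrap modules, module
  completeness/abundance time series, per-time-point network properties,
  and the inter-kingdom bipartite network of core ASVs (>75 % prevalence).
- **Constrained ordination** — dbRDA on Bray–Curtis with permutation
  forward selection and three-way variance partitioning (abiotic ×
  biotic × stage) on adjusted R².
- **A synthetic reactor-community generator** — replicator-with-immigration
  dynamics under Gaussian environmental filtering on phylogenetically
  conserved optima, with guild turnover across stages, tunable
  inter-kingdom coupling and fully recorded ground truth, so every stage
  of the pipeline is validated against data where the answer is known.

## Worked example

Run the full pipeline on the bundled `paper_like` scenario (52 samples over
days 0–343, two kingdoms rarefied to 43 329 / 31 420 reads):

```python
from granuleco.pipeline import PipelineConfig, run_pipeline

summary = run_pipeline(
    PipelineConfig(scenario_preset="paper_like", seed=7, outdir="out")
)
pk = summary["kingdoms"]["prokaryote"]
print(pk["nti_mean"])                              # 15.01
print(pk["bnti_stage_fraction_deterministic"])     # {'floccular': 1.0,
                                                   #  'intermediate': 0.89,
                                                   #  'granular': 0.5}
print(pk["network"])                               # {'n_nodes': 182,
                                                   #  'n_edges': 5500,
                                                   #  'n_modules': 3, ...}
print(pk["ordination"]["dbrda_adj_r2"])            # 0.834
```

Reading the numbers: the mean nearest-taxon index across samples is
strongly positive (phylogenetic clustering — deterministic assembly at the
tips of the tree); the fraction of successive pairs with |βNTI| > 2 falls
from 1.0 in the floccular stage to 0.5 in the granular stage, the
deterministic-early / stochastic-late succession signature; the filtered
prokaryote table (182 ASVs) yields a consensus network of 5 500 edges in
3 modules whose completeness tracks the guild turnover; and the selected
abiotic predictor plus the eukaryote α-diversity and the stage explain
~83 % (adjusted) of the Bray–Curtis structure. `out/` also holds tidy
TSVs for every intermediate series, `summary.json`, and `run.log` with
all effective parameters and seeds; reruns with the same seed are
byte-identical.

The command line mirrors the library:

```bash
granuleco simulate --preset paper_like --seed 7 --outdir data/
granuleco run --config config.yaml --seed 7 --outdir out/
granuleco nulls --datadir data/ --kingdom prokaryote --seed 1 --outdir out/
```

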