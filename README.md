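# ampelo

**Cross-platform gene-expression compendium construction and exploration.**

`ampelo` builds a single genes × conditions expression matrix out of
heterogeneous transcriptomics data — multiple microarray platforms plus
precomputed per-gene values from sequencing — the way curated crop-species
compendia (e.g., for grapevine, *Vitis vinifera*) are built, and provides
the query operations used to explore such a matrix interactively.

The scientific problem: public repositories hold expression samples from
many incompatible platforms. Probes designed years ago against outdated
annotations cross-hybridize, measure several near-identical paralogs at
once, or miss genes entirely. Directly comparing absolute intensities
across platforms is meaningless. `ampelo` addresses this with three ideas:

1. **Two-tier probe remapping.** Every probe is aligned to the current
   transcript set and filtered twice: a *restrictive* tier (few
   substitutions; the probe can measure the gene) and a *relaxed* tier
   (more substitutions; the probe may still pick up the gene's signal
   through cross-hybridization). A probe is **unique** only when exactly
   one gene survives both tiers; probes touching two or more genes are
   **ambiguous**.

2. **Gene clusters as measurable units.** Ambiguous probes are not
   discarded. Genes connected through shared ambiguous probes (connected
   components of the bipartite probe–gene graph) form a *gene cluster*
   whose expression is only assessable as a whole. The rows of the final
   matrix — the *measurable transcripts* — are the singleton genes plus
   one row per cluster; together they partition the gene universe.

3. **Log-ratio contrasts.** Columns are *sample contrasts*:
   `M = log2(test) − log2(reference)` for a test/reference pair from the
   same experiment, so positive values mean up-regulation in the test
   sample. Ratios are comparable across platforms where absolute signals
   are not; cells a platform cannot measure stay missing (`NA`).

On top of the matrix, the exploration engine offers **quicksearch**
(retrieve the contrasts where a query gene set is most strongly
modulated), co-expression ranking by **uncentered Pearson correlation**
(r = Σxy/√(Σx²·Σy²) over pairwise-complete positions — the zero point
"no change" is meaningful for log-ratios and must not be centered away),
correlation networks, one-sided **hypergeometric term enrichment** with
Benjamini–Hochberg FDR control, hierarchical controlled-vocabulary sample
annotation with contrast-level condition diffs, and deterministic
by-expression row/column ordering for heatmaps.

A synthetic fixture generator produces platforms with planted gene
families (the source of ambiguity clusters) and planted co-expression
modules, so the entire pipeline can be exercised and validated with known
ground truth and no external downloads.

## Worked example

```python
from ampelo.synthetic import FixtureConfig, PlantedModule, generate_platform, simulate_expression
from ampelo.probe_alignment import kmismatch_align, tier_hits, decide_mapping
from ampelo.gene_clusters import build_ambiguity_graph, find_gene_clusters, define_measurables
from ampelo.compendium import summarize_sample, make_contrast, assemble_compendium
from ampelo.module_query import quicksearch, make_module, rank_coexpressed_genes

# 12 genes, four of them a near-identical family; 3 genes up-regulated
# 4-fold (log2 effect 2.0) in conditions c0002/c0003; probe noise sd 0.25
config = FixtureConfig(
    n_genes=12, gene_length=400, families=[(4, 0.01)],
    n_conditions=8, noise_sd=0.25, seed=7,
    planted_modules=[PlantedModule(("g0004", "g0005", "g0006"),
                                   ("c0002", "c0003"), 2.0)],
)
platform = generate_platform(config)

hits = [h for p in platform.probes
        for h in kmismatch_align(p, platform.transcripts, 3)]
tiered = tier_hits(hits, config.thresholds)
decisions = decide_mapping(tiered, [p.probe_id for p in platform.probes])
clusters = find_gene_clusters(build_ambiguity_graph(decisions, tiered))
measurables = define_measurables(sorted(platform.transcripts), clusters)

expr = simulate_expression(config, platform)
profiles = {s: summarize_sample(v, decisions, measurables, sample_id=s)
            for s, v in expr.sample_values.items()}
contrasts = [make_contrast(profiles[t], profiles[r], cid)
             for cid, t, r, _ in expr.pairings]
compendium = assemble_compendium(contrasts, measurables)

module = quicksearch(compendium, ["g0004", "g0005", "g0006"],
                     top_k=3, measurables=measurables)
print(module.values.round(2))
```

This prints (the family collapses into `cluster_0001`, leaving 9
measurable rows; quicksearch correctly surfaces the two perturbed
conditions, with log-ratios near the planted effect of +2):

```
       c0002  c0003  c0005
g0004   1.95   1.87  -0.06
g0005   2.27   2.11  -0.19
g0006   2.23   1.73  -0.24
```

Ranking candidate genes against a module seeded with `g0004`/`g0005`
(over all 8 contrasts) recovers the third planted gene first:

```python
module = make_module(compendium, ["g0004", "g0005"], compendium.contrast_ids)
for g, r in rank_coexpressed_genes(compendium, module, min_overlap=8)[:3]:
    print(f"{g}\t{r:+.3f}")
```

```
g0006   +0.981
g0010   +0.449
cluster_0001    +0.343
```

The same workflow is available from the shell:

```sh
ampelo simulate --out sim --seed 7 --genes 12 --family 4:0.01
ampelo build --transcripts sim/transcripts.fasta --probes sim/probes.tsv \
             --samples-dir sim/samples --pairings sim/pairings.tsv --out build
ampelo query quicksearch --compendium build --genes g0004,g0005 --out result
```

`build` writes the mapping decisions, gene clusters, the compendium matrix
(TSV with `NA` for missing cells) plus a JSON sidecar, and a build report
with probe-status counts and the missing fraction.

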