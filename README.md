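# reactocap

Downstream analysis of 16S amplicon ASV tables with a predicted
metabolic-capacity layer: ASV filtering and composition summaries,
core-microbiota and compartment-overlap analysis, alpha/beta diversity with
permutation tests, and mapping of ASVs to genome-scale metabolic models
(GSMMs) to derive normalized reaction abundances, differential reactions and
direction-aware subsystem enrichment. A fully seeded synthetic-data module
generates communities with planted effects so every stage is testable
without any external downloads.

## Layout

| Module | Purpose |
| --- | --- |
| `reactocap.io_formats` | validated domain objects; TSV/newick/JSON readers and writers |
| `reactocap.synthetic_data` | seeded community, taxonomy, tree, mock and GSMM simulators |
| `reactocap.community` | ASV filtering, relative abundance, lowest-rank aggregation, core and overlap analysis |
| `reactocap.diversity` | rarefaction, alpha indices (observed, Shannon, Pielou, Faith's PD), Jaccard / unweighted UniFrac / Aitchison / PhILR distances, PCoA |
| `reactocap.stats_core` | Kruskal–Wallis + pairwise Wilcoxon, PERMANOVA, PERMDISP, BH adjustment, Pearson mock evaluation, standardized PCA |
| `reactocap.metabolic_capacity` | ASV→GSMM mapping, reaction abundances `a_r`, per-pair t-tests, Fisher subsystem enrichment, report tables |
| `reactocap.pipeline` | end-to-end planted-signal recovery runner |

Protocol defaults: rarefaction depth 1,604; core prevalence 0.80; overlap
presence threshold 0.0005; 999 permutations; significance at adjusted
p < 0.05 (group tests) and adjusted p ≤ 0.05 (reactions/subsystems).

## CLI

```bash
# simulate a planted-effect dataset (counts, taxonomy, tree, metadata, GSMMs)
reactocap simulate --seed 1 --out-dir data/ \
    --config config.json     # optional parameter overrides

# community analysis
reactocap filter   --counts data/counts.tsv --taxonomy data/taxonomy.tsv \
                   --metadata data/metadata.tsv --out-dir out/
reactocap compose  --counts out/counts.filtered.tsv --taxonomy data/taxonomy.tsv \
                   --metadata data/metadata.tsv --out-dir out/
reactocap core     --counts out/counts.filtered.tsv --metadata data/metadata.tsv \
                   --out-dir out/
reactocap overlap  --counts-a digesta.tsv --counts-b feed.tsv --out-dir out/

# diversity
reactocap alpha --counts data/counts.tsv --tree data/tree.nwk --out-dir out/
reactocap beta  --counts data/counts.tsv --tree data/tree.nwk \
                --metric unifrac --out-dir out/          # jaccard|unifrac|aitchison|philr
reactocap permanova --distance-matrix out/unifrac.dm.tsv \
                    --metadata data/metadata.tsv --out-dir out/
reactocap permdisp  --distance-matrix out/unifrac.dm.tsv \
                    --metadata data/metadata.tsv --out-dir out/

# predicted metabolic capacity
reactocap capacity --counts out/counts.filtered.tsv --taxonomy data/taxonomy.tsv \
                   --gsmms data/gsmms.json --out-dir out/
reactocap enrich   --reaction-abundance out/reaction_abundance.tsv \
                   --metadata data/metadata.tsv --gsmms data/gsmms.json --out-dir out/
reactocap report   --enrichment out/subsystem_enrichment.tsv --out-dir out/
```

The GSMM collection is a project-defined JSON with a `models` object (model
id → `{rank, taxon, reactions}`) and a `subsystems` object (reaction id →
subsystem name); see `reactocap.io_formats.read_gsmms`.

## Acceptance

The acceptance contract is property- and simulation-based; each criterion is
a test in `tests/test_acceptance.py` (formula brute-force oracles, exact-test
enumeration oracles, distance oracles, PERMANOVA type-I calibration,
end-to-end planted-signal recovery, protocol-constant checks, and the
filtering contract). The report script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the headline simulation checks from scratch and writes the (empty —
no named numeric targets are defined) target JSON.
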