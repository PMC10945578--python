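# gdcat — gene-derived correlation across tissues

`gdcat` is a gene-centric analysis engine for surveying inter-individual
transcript correlation structure across multiple tissues. Given panels of
genes × subjects expression matrices (GTEx-style human tissues, or
strain-level means from a mouse reference panel such as the HMDP), it asks:
*when one gene's expression varies from person to person, which other
gene-tissue combinations vary with it?* Strong cross-tissue co-variation of
this kind has repeatedly pointed at endocrine signaling and organ cross-talk,
which makes the correlation structure itself a discovery tool.

The package is aimed at systems-biology and computational-genetics users who
want the analysis pipeline behind such pan-tissue queries as a scriptable
library and CLI, testable end to end on synthetic panels.

## What it computes

**Robust correlation core.** All statistics use the biweight
midcorrelation (bicor). Each vector is median-centred and weighted by

    u_i = (x_i − med(x)) / (9·mad(x)),   w_i = (1 − u_i²)² · 𝟙(|u_i| < 1)

    a_i = (x_i − med(x))·w_i / √Σ_j ((x_j − med(x))·w_j)²,   bicor(x, y) = Σ_i a_i b_i

so a handful of outlying subjects cannot inflate a correlation. A vector
with zero MAD but positive variance falls back to the Pearson
standardisation (logged). Two-sided p-values use the Student-t
approximation `t = r·√((n−2)/(1−r²))` on n−2 df, and multiple testing is
handled by Benjamini–Hochberg step-up q-values over the whole emitted
test family. Missing data are removed pairwise per gene pair.

On top of that core:

- **Pan-tissue gene query** (`gene_query`): one source gene-tissue against
  every other gene-tissue combination, tissue-binned significance summaries
  at q < 0.1 / 0.01 / 0.001, deterministic top-correlate lists.
- **Enrichment** (`enrichment`): preranked GSEA with the bicor coefficients
  as rank weights and a gene-label permutation null (activated vs suppressed
  pathways), plus exact hypergeometric overrepresentation tests on top-N
  lists.
- **Networks** (`network`): undirected, signed correlation graphs around a
  query gene; edges kept for 0.6 ≤ |r| ≤ 0.99, exported as edge lists or
  GraphML.
- **Deconvolution** (`deconvolution`): per-subject cell-type proportions by
  non-negative least squares against a signature matrix, projected to the
  probability simplex, and correlation of the inferred fractions with any
  gene.
- **Connectivity survey** (`connectivity`): for a pathway's genes, counts of
  significant cross-tissue correlations at p < 1e-3 / 1e-6 and q < 0.1 /
  0.01 (within-tissue omitted), normalised by pathway size; tissue
  rank-ordering; size-matched random-gene nulls; and a missingness-tertile
  diagnostic relating sparse data to low connectivity rank.
- **Phenotype correlation** (`phenotype`): gene ~ clinical-trait bicor at
  the strain/subject level with top-10 binning and p = 0.05 / 0.001
  reference flags.
- **Simulation** (`simulate`): a seeded latent-factor generator that plants
  hubs, correlated gene-set blocks, cell-type mixtures and trait couplings
  with known ground truth — the basis of the whole test suite.

## Worked example

```python
from gdcat import (simulate_panel, pan_tissue_query, bin_by_tissue,
                   top_correlates, build_network)
from gdcat.simulate import SimConfig, HubSpec

# a hub gene in adipose with planted partners, mostly in liver
targets = [(f"G{i:04d}", "liver", 0.8) for i in range(2, 10)] + [
    ("G0002", "muscle", 0.8)]
cfg = SimConfig(n_subjects=200,
                tissues={"adipose": 100, "liver": 100, "muscle": 100},
                hubs=[HubSpec(("G0001", "adipose"), targets)], seed=7)
panel, manifest = simulate_panel(cfg)

result = pan_tissue_query("G0001", "adipose", panel)
print("records:", len(result.records))
for q in (0.1, 0.01, 0.001):
    s = bin_by_tissue(result, q)
    print(f"q<{q}:", dict(sorted(s.counts.items())), "total", s.total)

top = top_correlates(result, 3, scope="peripheral")
print(top[["gene", "tissue", "bicor", "n", "p", "q"]].round(3).to_string(index=False))

G = build_network(result, panel, n_within=10, n_peripheral=10)
print("network:", G.number_of_nodes(), "nodes,", G.number_of_edges(), "edges")
```

prints

```
records: 299
q<0.1: {'liver': 8, 'muscle': 1} total 9
q<0.01: {'liver': 8, 'muscle': 1} total 9
q<0.001: {'liver': 8, 'muscle': 1} total 9
 gene tissue  bicor   n   p   q
G0007  liver  0.776 200 0.0 0.0
G0002 muscle  0.773 200 0.0 0.0
G0006  liver  0.751 200 0.0 0.0
network: 10 nodes, 14 edges
```

All 299 gene-tissue combinations are tested against the query gene; only
the nine planted partners reach significance at any q cutoff, the tissue
bins attribute eight of them to liver and one to muscle, and the
correlation network around the query recovers the planted neighbourhood.
(p-values below double precision are reported as exact 0.)

The same pipeline is available from the shell:

```bash
gdcat simulate --config sim.yaml --out panel/
gdcat query --gene G0001 --tissue adipose --panel panel.yaml --out query/
gdcat enrich --query query/records.tsv --tissue liver --gmt go_bp.gmt --seed 7 --out enrich.tsv
gdcat network --gene G0001 --tissue adipose --panel panel.yaml --out net.tsv
gdcat connectivity --panel panel.yaml --gmt kegg.gmt --set hsa04062 --null-draws 20 --seed 11 --out conn/
gdcat traits --gene G0001 --tissue adipose --panel panel.yaml --traits traits.tsv --out top_traits.tsv
```

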