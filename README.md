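# splicedegree

Alternative-splicing profiling for long-read RNA sequencing, built around a
deliberately simple metric: the **degree of splicing (DS)** of a gene in a
sample is the number of its transcript isoforms quantified above a TPM
threshold,

    DS_g,s(θ) = #{ isoforms t of gene g : TPM_t,s > θ },

with DS = 0 when no isoform qualifies. Long-read (e.g. nanopore direct RNA)
sequencing quantifies transcript isoforms directly, so this per-gene isoform
count is available without the exon-level surrogates (PSI, exon usage) that
short-read analyses rely on. Because low-abundance isoforms are only seen at
high sequencing depth — a parameter that is hard to control — the threshold
θ is varied systematically (0.1, 1, 10 TPM by default) to separate
biological from technical variation in splicing profiles.

The package is for transcriptomics researchers who have per-sample
transcript quantifications (Salmon-dialect tables) from several biospecimen
types and want to know whether splicing profiles distinguish the types and
which genes drive the difference. It provides:

- **DS matrices** (genes × samples) at each threshold, plus the constrained
  variant restricted to genes with DS > 0 in every sample;
- per-type **overall splicing** (mean qualifying-isoform count / mean
  expressing-gene count) and binned isoform-abundance distributions with
  95% confidence intervals;
- **PCA of DS profiles** (samples as observations, genes as variables,
  mean-centred, no variance scaling): scores, explained-variance ratios and
  unit-eigenvector loadings;
- **gene selection**: box-plot (Tukey-fence) outliers of the PC loadings,
  filtered by per-gene one-way ANOVA across types at p < 0.01;
- **characteristic isoforms**: transcripts detected in exactly one
  biospecimen type, with protein-status tallies;
- a **synthetic-scene generator** that emulates the downstream form of a
  hepatic study design (3 liver + 5 HepG2 + 3 Huh7 samples, ~10⁴
  protein-coding genes, depth-dependent dropout, type-specific isoform
  usage), so the full pipeline is testable without sequencing data.

## Worked example

Tally the packaged reference set of characteristic isoforms called in human
liver tissue, HepG2 and Huh7 cells (long-read direct RNA sequencing,
TPM > 10):

```python
from splicedegree import find_characteristic
from splicedegree.characteristic import build_table, load_reference_table, tally_status

presence, annotation = load_reference_table()
table = build_table(find_characteristic(presence), annotation)
print(len(table), tally_status(table))
```

```
18 {'Canonical form': 6, 'Protein isoform': 6, 'Predicted': 6, 'unannotated': 0}
```

Of the 18 isoforms seen in exactly one specimen type, 6 code for canonical
protein forms, 6 for non-canonical but experimentally detected protein
isoforms, and 6 for computationally predicted proteins — i.e. two thirds
could yield type-specific protein products.

Run the analysis end-to-end on a simulated scene:

```python
import splicedegree as sd
from splicedegree import simulate as sim
from sklearn.metrics import silhouette_score

scene = sim.simulate_scene(sim.SimulationConfig(n_genes=2000, seed=1))
matrix = sd.IsoformAbundanceMatrix(scene.tpm, scene.catalog.tx2gene)

print(sd.overall_splicing(matrix, scene.metadata, 0.1).round(2))
ds = sd.degree_of_splicing(matrix, 10.0)
result = sd.run_pca(ds, n_components=2)
print((100 * result.explained_variance_ratio).round(1))
print(silhouette_score(result.scores, scene.metadata["type"]).round(3))
sel = sd.select_genes(result, ds, scene.metadata, component=1)
print(len(sel.outlier_genes), len(sel.significant_genes))
```

```
liver    1.70
HepG2    1.78
Huh7     1.76
[18.9 15.6]
0.8
381 51
```

Overall splicing sits in the realistic 1.2–2.1 isoforms-per-expressing-gene
range; PC1/PC2 explain 18.9%/15.6% of the DS variance and separate the
three types cleanly (silhouette 0.80); of 381 loading outliers on PC1, 51
genes differ significantly in mean DS between types at p < 0.01.

The same stages are exposed as a CLI (`splicedegree simulate | ds | bins |
overall | pca | select | characteristic | run`); `splicedegree run
--config pipeline.yaml` writes DS matrices, PCA tables, selections,
characteristic isoforms and a JSON manifest for every threshold × variant
combination.

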