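# litnet

Gene–gene co-occurrence networks from biomedical abstracts, rare-event pair
classification, and centrality-based disease-gene prioritization.

## Who this is for

Researchers who want to infer a human gene–gene interaction network directly
from literature (abstract text plus Gene Ontology annotations) and use it to
rank candidate disease genes around a small set of curated seed genes — all
from local files, with no web services.

## What it computes

**Features.** Every unordered gene pair (g1, g2) is described by nine
unitless ratios W1..W9, one per combination of an entity pair and a text
level:

| entities                    | abstract | sentence | semantic |
|-----------------------------|----------|----------|----------|
| g1 and g2                   | W1       | W2       | W3       |
| g1 and the GO terms of g2   | W4       | W5       | W6       |
| g2 and the GO terms of g1   | W7       | W8       | W9       |

The *semantic* level requires an interaction cue phrase ("binds with",
"interacts with", "and", ...) directly between the two mentions in one
sentence.  Each ratio is the Jaccard form c / (n_a + n_b − c): shared units
over either entity's units.

**Classifiers.** True interactions are rare among candidate pairs, so pairs
are classified with case-weighted logistic regression (WLR),

    ln(p/(1−p)) = xβ,
    lnL(β) = Σ_i w_i [ y_i x_i β − ln(1 + e^{x_i β}) ] − (λ/2)‖β‖²,

and its kernelized form (WKLR) with the Gaussian RBF kernel
k(x_i, x_j) = exp(−‖x_i−x_j‖²/2σ²) and logit ln(p/(1−p)) = k_i α.  Weights
follow prior correction (τ/ȳ for events, (1−τ)/(1−ȳ) for non-events) or
class balancing by default; λ and σ are tuned by stratified bootstrap scored
on out-of-bag balanced accuracy.  Classification is strict (y = 1 iff
p > threshold), and sweeping thresholds 0.5–0.8 gives each pair its
*persistence* — the highest threshold at which it stays positive.

**Ranking.** Predicted-positive pairs form a simple undirected network.  A
disease subnetwork keeps every edge touching at least one seed gene; its
nodes are ranked by degree, closeness, betweenness, or eigenvector
centrality and scored by precision@n against benchmark gene sets and by seed
recall.

## Worked example

Simulate a corpus with a hidden interaction graph, run the whole pipeline,
and check recovery:

```python
from litnet.synthetic_data import CorpusSimConfig, simulate_corpus
from litnet.pipeline import run_synthetic_pipeline, edge_f1
from litnet.network import SeedList, extract_disease_subnetwork, degree_centrality, rank_top_n

sim = simulate_corpus(CorpusSimConfig(seed=0))       # 200 genes, 2000 abstracts
res = run_synthetic_pipeline(sim, model="wlr", lam=1e-2)
print("pairs with features:", res.table.n)
print("edge F1:", round(edge_f1(res.predicted_edges, sim.true_edges), 3))

seeds = SeedList("synthetic", sim.seed_genes)
sub = extract_disease_subnetwork(res.network, seeds)
top15 = rank_top_n(degree_centrality(sub), 15)
print("module genes in top 15:", len(set(top15) & set(sim.module_genes)))
```

prints

```
pairs with features: 1173
edge F1: 0.915
module genes in top 15: 10
```

i.e. the classifier recovers the planted edge set with F1 ≈ 0.9, and all ten
genes of the planted disease module surface in the top-15 degree ranking of
the seed-anchored subnetwork.

The same stages are scriptable from the shell:

```
litnet simulate corpus --seed 0 --out sim/
litnet ingest --corpus sim/corpus.tsv --genes sim/genes.txt --go sim/go_annotations.tsv --out index/
litnet extract-features --index index/ --out features.tsv
litnet train --features features.tsv --labels labels.tsv --model wlr --out model.yaml
litnet predict --model model.yaml --features features.tsv --threshold 0.5 --out edges.tsv
litnet subnetwork --net edges.tsv --seeds sim/seed_genes.txt --out sub.tsv
litnet rank --net sub.tsv --measure degree --top 15
```

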