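# Methods

## Problem and pipeline

litnet infers candidate gene–gene interactions from the co-occurrence
statistics of gene names and Gene Ontology (GO) term names in abstract text,
then prioritizes disease genes by graph centrality.  The pipeline has four
stages — mention finding, feature extraction, rare-event classification,
and network ranking — each usable independently.

## Entity recognition

Recognition is dictionary-based.  Gene symbols are matched case-sensitively
as whole alphanumeric token sequences (only official symbols by default;
`GeneLexicon.match_forms` is the extension point for synonyms).  GO terms
are matched by their term *name*, case-insensitively, because names are what
appear in prose; a literal `GO:nnnnnnn` id also matches.  At every token
position the longest candidate wins, consumed tokens cannot join a second
mention, and scanning is left-to-right, so results are deterministic and
independent of lexicon order.

Sentences are segmented at `. ! ?` followed by whitespace and an uppercase
letter or digit, with a configurable abbreviation guard list ("e.", "al.",
"fig.", ...).  The title and body are treated as one abstract-level unit;
the title is always sentence 0.  All character coordinates are 0-based
half-open offsets into `title + " " + body`.

## Co-occurrence features

Three text levels are tracked per entity: the set of abstracts mentioning
it, the set of (abstract, sentence) units mentioning it, and — per entity
pair — the *semantic* units, where a cue phrase ("binds with", "interacts
with", "interact with", "binds to", "associated with", "and", "or") occurs
strictly between the two mentions.  The cue must join the mentions
directly: if a third entity mention lies between the pair, the outer pair is
not linked.  Without this restriction, in "A was studied; B and C rose" the
cue "and" would spuriously link A with C.

A pair (g1, g2) yields nine features: the entity pairs (g1, g2),
(g1, GO terms of g2) and (g2, GO terms of g1), each at the three levels.  A
gene's GO terms act as one composite entity (a unit counts if at least one
term occurs in it), which keeps features in [0, 1]; self-co-occurrence of a
gene with its own GO terms is not a feature.  Counts use set semantics over
units, and each feature is normalized to

    W = c / (n_a + n_b − c)

— the Jaccard ratio (bounded, symmetric).  `min` and `product`
normalizations are available for sensitivity analysis.  Because a semantic
link is a relation, not an entity, its individual counts are taken from the
sentence level, of which semantic links are a subset.  Division by an empty
denominator is defined as 0.

## Rare-event classification

Among all candidate pairs, true interactions are a small minority, so both
classifiers weight cases.  With an assumed population event fraction τ,
events get weight τ/ȳ and non-events (1−τ)/(1−ȳ) (prior correction); without
τ the default is class balancing, n/(2n₁) and n/(2n₀).  Weights are rescaled
to sum to n so that λ retains the same meaning across weighting schemes.

**WLR** maximizes Σ wᵢ[yᵢxᵢβ − ln(1+e^{xᵢβ})] − (λ/2)‖β‖² by Newton–Raphson
with step-halving, a zero start vector, gradient tolerance 1e−8 and a
100-iteration cap.  An intercept is added and excluded from the penalty, so
the event prevalence is absorbable under any weighting.  The log-likelihood
uses `logaddexp`, which stays finite for |xβ| in the hundreds.

**WKLR** uses the Gaussian RBF kernel k(xᵢ,xⱼ) = exp(−‖xᵢ−xⱼ‖²/2σ²) and
maximizes the dual objective Σ wᵢ[yᵢkᵢα − ln(1+e^{kᵢα})] − (λ/2)αᵀKα, again
by damped Newton (tolerance 1e−6, 500 iterations).  A 1e−10 diagonal jitter
conditions the Gram matrix.  The fitted model stores its training features;
prediction evaluates the cross-kernel against them.

λ (and σ) are tuned by stratified bootstrap: per grid point, B resamples
drawn with replacement within each class, the model fitted on the resample
and scored by **balanced accuracy** on the out-of-bag rows at threshold 0.5.
A class-balanced score is used because raw accuracy is dominated by the
majority class exactly in the rare-event regime the method targets.  The
resample plan is shared across grid points so all points see the same data,
ties break toward larger λ (more shrinkage), and the whole search is
reproducible from one seed.  Default grids: λ log-spaced 1e−4…1e4 (13
points), σ ∈ {0.25, 0.5, 1, 2, 4}, B = 100.  The module also ships the
historically reported full-corpus presets (λ = 4328 for WLR; λ = 5.7e−3,
σ = 0.5 for WKLR) as documented constants, not defaults.

Classification is strict: y = 1 iff p > threshold, ties to class 0.  A
pair's *threshold persistence* is the highest of an ascending threshold list
(default 0.5, 0.6, 0.7, 0.8) at which it is still positive; gene-level
persistence is the maximum over incident pairs.  Persistence is monotone in
p by construction.

## Network analysis

Predicted-positive pairs form a simple undirected graph (self-pairs dropped,
duplicates collapsed); predicted probabilities are carried as edge
annotations only and never enter centrality.  A disease subnetwork retains
exactly the edges touching at least one seed gene — an edge between two
non-seed neighbors of seeds is excluded — and records which seeds are absent
from the parent network (the complement of seed recall).

Centrality conventions (all verified against brute-force oracles):

* **degree** — raw neighbor count, unnormalized;
* **closeness** — (|comp|−1)/Σd(v,u) within each connected component
  (isolated nodes 0); the harmonic variant is available for disconnected
  graphs;
* **betweenness** — Brandes accumulation of Σ σ_st(v)/σ_st, endpoints
  excluded, each unordered pair counted once, unnormalized by default;
* **eigenvector** — power iteration from the all-ones vector with L2
  normalization, tolerance 1e−10, up to 1000 iterations.  The iteration
  matrix is A + I rather than A: both have identical eigenvectors, but the
  shift makes the top eigenvalue strictly dominant, whereas raw adjacency
  iteration oscillates forever on bipartite graphs (already on the star
  K₁,₄).  On disconnected graphs the scores reflect the dominant
  component(s); an edgeless graph scores all zeros.

Network statistics report node and edge counts, the diameter of the largest
component, and the mean local clustering coefficient with degree-<2 nodes
contributing 0.  Rankings are by descending score with lexicographic
tie-breaks; the default report depth is the top 15.

## Evaluation

ROC and precision–recall curves sweep all distinct score thresholds under
the same strict p > t convention as classification, so any classification
point lies exactly on the curve.  AUC is the trapezoidal area and equals the
tie-aware pairwise concordance probability.  The PR curve defines precision
at zero predictions as 1 and ends with an explicit all-positive point
(recall 1, precision = prevalence), which a bare threshold sweep would miss
when minimum scores are tied.  precision@n uses exactly the first n genes
(no padding) with exact, case-sensitive symbol matching after whitespace
trimming; multiple benchmarks combine by set union.  Seed recall is the
fraction of a disease's seed genes present as network nodes.

In the bundled 30-gene breast-cancer worked example, "validated" counts rows
flagged YES or YES+Seed; bare Seed and candidate rows do not count.  That
convention reproduces the reference figures of 83.3% validated and 70%
seeds.

## Synthetic data

`simulate_corpus` emulates a literature corpus shaped by a hidden
interaction graph.  The graph is Erdős–Rényi background (mean degree 2 by
default) plus a planted 10-gene clique module whose first 3 genes are the
designated disease seeds.  Each abstract is "about" one focal pair — a true
edge with probability `p_focus_edge` (default 0.5, the literature-attention
bias toward real interactions), otherwise a uniform pair.  Each body
sentence jointly mentions the focal pair with probability `p_cooccur_pos`
(0.3) for edges and `p_cooccur_neg` (0.005) for non-edges; joint mentions
carry a cue phrase with probability `p_cue` (0.6) and sometimes a GO term
name of one partner, which is what gives the six gene–GO features signal.
Non-joint sentences mention one focal gene, optionally with one of its own
GO names.  The defaults (200 genes, 2000 abstracts, 6 sentences each) are
the strong-signal recovery conditions exercised by the test suite; under
them the weighted-logistic pipeline recovers the planted edge set with
F1 ≈ 0.9.

What the generator does *not* emulate: real PubMed prose (sentences are
filled templates), gene-name ambiguity and synonyms, negation, cross-
sentence relations, and corpus-scale imbalance (a real corpus is thousands
of times larger and far sparser per pair).  Passing the recovery tests
therefore demonstrates that the machinery is correct and coherent
end-to-end, not that the method attains any particular accuracy on real
literature.

Two deliberate signal channels exist: the co-occurrence rates
(p_pos vs p_neg) and the attention bias (p_focus_edge).  With equal rates
and the attention bias disabled, edge labels are provably independent of
the text, which the suite checks with a rank test on the extracted
features.

`simulate_feature_table` draws features i.i.d. uniform (or Beta-skewed) in
[0, 1] and labels from a logistic model with known slopes; the intercept is
solved by root-finding so the mean event probability hits the target
prevalence (default 5%).  `fixture_graphs` bundles named small graphs
(P₃, K₁,₄, K₃, K₄, a barbell, and 50 seeded random graphs of ≤8 nodes)
together with centrality tables recomputed on every call by independent
brute-force oracles: exhaustive shortest-path enumeration for betweenness,
BFS sums for closeness, and a dense eigendecomposition for eigenvector
centrality (projection of the all-ones vector onto the dominant eigenspace,
which is the limit of the power iteration and remains well-defined when the
top eigenvalue is degenerate).

All generator randomness flows from a single seed through spawned child
streams (graph vs text), so outputs are byte-identical under a fixed seed.

## Numerical and degenerate-input choices

* Weighted fits require both classes present; separable data at λ = 0
  raises with advice to use λ > 0.
* Unknown entities count 0 at every level; unannotated genes are excluded
  from feature extraction and reported.
* Feature rows are emitted in deterministic (g1, g2) lexicographic order;
  all-zero rows are dropped by default.
* Bootstrap resamples that lose a class are redrawn (at most 100 attempts).
* Model files are self-describing YAML; kernel models embed a SHA-256
  checksum of their stored training features, verified on load.

## Known limitations

The NER is dictionary-only: no disambiguation, no statistical models, and
official symbols only by default, so recall on real text is bounded by
surface-form coverage.  Set semantics ignore repeated mentions within a
unit.  The semantic level sees only within-sentence cue patterns — no
dependency parsing, negation handling, or cross-sentence relations.
Centrality is computed on the unweighted graph; predicted probabilities do
not weight shortest paths.
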