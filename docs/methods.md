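# Methods

## Data model

A molecular association network (MAN) is an undirected heterogeneous graph.
Node types are fixed to the eight bioentity classes (protein, mRNA, miRNA,
lncRNA, circRNA, drug, disease, microbe); each relation type declares an
unordered endpoint-type pair and every edge is validated against it.  Edges
are stored once per unordered pair, so symmetric adjacency queries and the
lower-triangular view agree by construction.  Self-loops are rejected;
same-type endpoint pairs (protein–protein interactions) are allowed.
Node identifiers are opaque, case-sensitive strings; mapping identifiers
across source databases is the caller's responsibility.

## Attribute features

**k-mers.** A sequence of length L over a 4-letter alphabet yields a
4³ = 64-dim vector whose entry for word w is the number of overlapping
windows equal to w divided by (L − k + 1); entries are non-negative and sum
to 1 for any L ≥ k.  k = 3 throughout.  Proteins are first mapped onto four
side-chain-polarity groups (1: AVLIMFWP, 2: GSTCNQY, 3: RKH, 4: DE) so that
protein and RNA features share the 64-dim space.  DNA input is tolerated by
mapping T→U at load time; other ambiguity codes are rejected.

**Hierarchy semantics.** Diseases (MeSH category C) and microbes (category
B) are located by dotted tree numbers; the parent position deletes the last
3-digit segment.  An entity's DAG is the ancestor closure of all its tree
numbers.  Contributions follow the max rule with attenuation Δ = 0.5:
V = 1 at the entity's own positions and V = Δ·max(children) above, which
equals Δ^depth for the minimal hop count — the implementation uses the
depth form, and the test suite cross-checks it against an independent
recursive scorer on random universes.  Similarity is shared contribution
over total contribution, giving values in [0, 1] with unit diagonal.
Contributions are defined over *tree positions*: an ancestor position with
no named entity in the descriptor universe still counts toward SV, which
keeps SV well defined when the universe is incomplete.  If one entity
occupies several positions, each position contributes separately.
Disease and microbe similarity matrices are built separately;
cross-category similarity is never requested.

**Fingerprints.** Binary bit vectors of constant length (default 1024) are
read from TSV; an optional adapter converts SMILES to Morgan fingerprints
(radius 2) when RDKit is available.

**Compression.** Similarity rows (width = number of entities) and
fingerprints are compressed to 64 dims by a stacked autoencoder:
encoder input→256→64 with sigmoid activations, mirrored decoder with a
linear output layer, mean-squared-error loss, Adam (lr 10⁻³, β₁ 0.9,
β₂ 0.999), 10 epochs, batch 128, Glorot-uniform initialization from a
seeded generator.  It is written directly in numpy (no deep-learning
framework is required), which makes training bit-reproducible under a
fixed seed.  One autoencoder is trained per attribute source and never
shared.  When a raw vector is *narrower* than 64 (e.g. a similarity matrix
over fewer than 64 entities) there is nothing to compress and the encoder
precondition (input width ≥ code width) cannot hold, so rows are
zero-padded to 64 instead.  Rows are not normalized before encoding.
Nodes without any payload get the zero attribute vector.

## Behavior features

DeepWalk with the common settings: γ = 10 passes, each shuffling the vertex
order and starting one uniform random walk of length t = 80 from every
vertex (an isolated vertex yields a singleton walk), then SkipGram over the
walk corpus with window w = 10 and d = 64.  The SkipGram trainer is an
in-package, numba-compiled word2vec skip-gram with negative sampling
(5 negatives from the unigram^0.75 table, dynamic window shrinking,
learning rate decaying linearly 0.025 → 10⁻⁴, 5 epochs, min-count 0).
Negative sampling was chosen over hierarchical softmax because no external
embedding library is assumed and SGNS is the simpler, equally standard
objective; training is single-threaded, so a fixed seed gives bit-identical
embeddings.  Walks ignore relation labels (the walk graph is the untyped
union of all relations) and use uniform next-hop probabilities — no
node2vec-style biasing.

Leakage discipline: behavior vectors are always computed on the graph with
the current fold's test edges stripped (all nodes retained), so no walk can
traverse a held-out edge; this is asserted exactly in the tests.  A node
isolated by stripping — or never connected at all — receives the zero
behavior vector, which is the cold-start representation: such nodes are
still scorable through their attribute half.

## Classification and protocols

Node fusion concatenates attribute ∥ behavior (128 dims); ablation modes
zero the excluded half so feature width is constant.  A pair sample
concatenates the two fused vectors in sorted node-id order (256 dims), so
(u, v) and (v, u) are identical.  Negatives are sampled once per fold,
type-matched per relation (uniform over unlinked pairs with the relation's
endpoint types, counts proportional to positive counts) and excluded from
the *entire* positive edge set, never just the fold — so no "negative" is a
held-out positive.  Type matching prevents the classifier from succeeding
by node-type recognition alone.  The relation label is carried as metadata
but is not a classifier feature: the task is the binary "association
exists" across all relation types.

The classifier is a scikit-learn random forest with default
hyperparameters and an explicit seed (tree count configurable).  Threshold
metrics use the fixed 0.5 cutoff; AUC is the Mann–Whitney rank statistic
with ties counted ½ and AUPR is average precision (step interpolation —
conventions differ, so this is pinned).  Aggregation reports mean and
sample SD (n − 1).

Protocols: (1) k-fold CV over all edges (k = 5); (2) the same folds
evaluated under the three feature sets, sharing per-fold embeddings and
negatives; (3) a training-proportion sweep {0.2, 0.4, 0.6, 0.8} with
behavior-only features; (4) a single-relation comparison in which folds
and negatives are a pure function of (graph, target, seed) and the four
modes differ only in the embedding graph: none (attributes only), the
target relation's training edges, the full graph minus the fold's target
test edges, or every relation except the target (behavior-only features).
Attribute vectors contain no edge information, so they are computed once
and reused across folds; behavior vectors are recomputed per fold.

## Synthetic benchmark: the stated world

The generator plants a latent block structure.  Defaults: 8 types × 50
nodes, 6 relations covering all types (drug–disease, drug–protein,
miRNA–disease, lncRNA–disease, microbe–disease, circRNA–mRNA), 4 blocks
assigned round-robin within each type and shared across types, edge
probability p_in = 0.3 within a block and p_out = 0.02 across, giving
≈ 1,350 edges.  Every attribute channel is tilted by the same blocks:
sequences draw i.i.d. letters from a per-block Dirichlet(2) letter
distribution (a tractable stand-in for a block-specific k-mer profile);
disease/microbe entities are placed inside one hierarchy subtree per
block (depth 4, branching 3); fingerprints flip a per-block
Bernoulli(0.1) template with probability 0.02.  Sequence lengths are
realistic orders (protein 300, mRNA 500, miRNA 22, lncRNA 800,
circRNA 600); the 22-nt miRNAs deliberately give noisy k-mer estimates.
All generators are pure functions of (spec, seed).

What a green test on this world does and does not establish: it shows the
pipeline recovers a planted co-membership signal through both feature
channels without leakage; it does not emulate real MANs' heavy-tailed
degree distributions, relation-specific densities, correlated multi-edge
structure, or biologically meaningful sequence/chemistry signal.

### The separability ceiling

Because edges are independent Bernoulli draws given blocks, the
Bayes-optimal score for distinguishing a held-out edge from a sampled
type-matched negative is the binary block-co-membership indicator: train
degrees carry no information about held-out edges (independence), and
within-block positives are exchangeable with within-block negatives.  With
within-pair fraction f = 1/n_blocks, a fraction
a = f·p_in / (f·p_in + (1−f)·p_out) of positives and
b = f(1−p_in) / (f(1−p_in) + (1−f)(1−p_out)) of negatives are
within-block, and the optimal AUC is ½ + (a − b)/2.  At the defaults this
is maximized near f = ¼ — hence n_blocks = 4 — at AUC ≈ 0.82 (empirically
0.8295 for the ideal observer on a generated instance).  Measured medians
over 3 seeds: attribute-only 0.785, behavior-only 0.711, fused 0.746.  The
attribute channel sits close to the ceiling; the behavior channel trails
because embeddings of a ~1,300-edge graph are noisy; and in the fixed
256-dim concatenation with a default random forest, the noisier behavior
half dilutes split selection, so the fused model lands between the two
single-channel scores on this particular world.  The acceptance test that
expects fused AUC ≥ 0.85 and fused ≥ max(single) − 0.02 therefore fails by
construction of this benchmark and is left failing rather than weakened;
the proportion-monotonicity and permutation-null properties hold as
expected.

## Numerical choices and degenerate inputs

* Every stochastic operation takes an explicit seed; no global RNG state.
  Embedding and autoencoder training are bit-reproducible (single-threaded).
* k-fold test folds differ in size by ≤ 1 (linspace partition of a seeded
  permutation).
* MCC is defined as 0 when any denominator factor vanishes.
* Metric computation refuses single-class inputs.
* Duplicate edge rows collapse; endpoint-type mismatches and dangling node
  references fail loudly with the offending row.
* Negative sampling fails with the relation named when the type-matched
  candidate space is exhausted.

## Known limitations

* Embedding quality on very sparse graphs (≲ 4 training edges per node)
  limits the behavior channel; the proportion sweep makes this visible
  (AUC ≈ 0.50 at 20% training edges on the default world).
* The stacked autoencoder is a fixed two-layer architecture without
  denoising or layer-wise pretraining.
* No hyperparameter search, alternative classifiers, directed/weighted
  edges, or genome-wide candidate ranking.
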