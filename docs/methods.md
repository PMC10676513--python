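# Methods

## Data model

A terminology base is a directed acyclic graph of concepts. Hierarchy
triples (child, h, parent) allow multiple parents; attribute triples link
concepts under arbitrary labels; synonym triples are folded into each
concept's synonym set rather than kept as graph nodes, because the text
encoder consumes names while the graph views consume hierarchy/attribute
structure. Concepts without hierarchy edges are retained and flagged
isolated. Readers exist for a TSV triple dialect, a JSON mirror, and an OBO
subset (`id`, `name`, `is_a`, `synonym`), the last parsed through `obonet`.
Validation enforces referential integrity and acyclicity (networkx; the
test suite cross-checks with an independent Kahn's-algorithm oracle).

## Views and fusion

**Encoder and projection.** The encoder contract maps a string to a fixed
d_enc vector (default 768). The default backend is a seeded character-
trigram hashing encoder: each trigram of the lowercased, space-padded
string hashes (keyed BLAKE2b, stable across processes) to a signed
coordinate, and the sum is L2-normalized, so near-identical strings have
high cosine. A pretrained transformer can be swapped in via the config
string `pretrained:<model-name>` without touching any downstream interface.
One shared encoder serves names and serialized paths. A trainable affine
projection (d_enc → 300 by default) produces the working embeddings; path
embeddings pass through the same projection so all views share one
interaction geometry.

**Semantic view.** h₁ = |V(e) − V(e′)| ⊕ [cosine]. The published form of
this view is the scalar cosine score; the gates, however, operate at the
feature level, so the view exposes the elementwise absolute difference with
the cosine kept as the last coordinate. The same pattern gives the
neighborhood view h₂ = |z − z′| ⊕ [ℓ₂], preserving the stated ℓ₂
aggregation as a coordinate while giving the gate something to weight.

**Neighborhood view.** Two GAT layers, two heads, LeakyReLU slope 0.2
(conventional), ELU output nonlinearity, arithmetic mean over heads.
Neighbor sets contain hierarchy parents, hierarchy children, then attribute
neighbors, lexicographically ordered within category and capped at 25 — the
cap and the ordering make truncation deterministic. Empty neighborhoods
fall back to a self-loop so every node has a well-defined output. The
GCN-style ablation replaces attention with a degree-normalized mean under
the same interface.

**Path view.** Paths are windows over root-to-leaf chains centered on the
seed: up to n−k ancestors and k−1 descendants (defaults n=5, k=2 → three
ancestors, one child), truncated — never padded — near roots and leaves.
Enumeration is depth-first with lexicographic tie-breaks, capped at
max_paths=4 per concept to bound the path-pair similarity matrix; paths
that would be bare singletons (no hierarchy context) are dropped, so
isolated concepts are pathless and contribute an all-zero h₃, keeping the
fusion input dimension fixed. Serialization is
⟨CLS⟩ ancestor-names ⟨SEP⟩ name ⟨SEP⟩ child-names ⟨SEP⟩ with empty blocks
omitted but separators preserved. The kernel bank defaults to one
exact-match kernel (μ=1, σ=0.001) plus ten kernels with μ ∈ {−0.9, …, 0.9}
(step 0.2) and σ=0.1, the usual kernel-pooling configuration; log arguments
are clamped at 1e−10 to keep the pooled features finite when a soft-count
underflows. Max pooling (the single largest matrix entry) is available as
an ablation, alone or concatenated with the kernel features.

**Fusion.** Per-view sigmoid gates gᵢ = σ(Wᵢhᵢ), elementwise product, then
a 2-layer MLP (hidden 64, tanh, linear output) over the concatenation. The
gate-removal ablation is the identity gate; removed views simply drop out
of the concatenation and the scorer input shrinks accordingly.

## Training

Two stages, both minimizing the pairwise hinge
L = Σ max{0, γ + d(e,e′⁺) − d(e,e′⁻)} with γ=1 and a small deterministic
Adam (lr 0.01 default, full-batch).

1. *Representation stage* — d is the ℓ₁ distance between projected name
   embeddings; only the projection is updated (the hinge is invariant to
   the projection bias, which therefore stays put).
2. *Interaction stage* — d = −score(e, e′); gates and scorer are updated
   over view features precomputed once per (positive ∪ pool) pair under the
   stage-1 projection. GAT parameters stay at their seeded initialization:
   they act as a fixed random aggregation whose output the gates and scorer
   learn to use, which keeps the interaction stage convex-ish, fast, and
   exactly reproducible.

Negative pools are the 50 nearest target entities per query in the rough
(name-only) embedding space, gold excluded, distance ties broken
lexicographically; five negatives per positive are resampled uniformly each
epoch. Stage 1 ranks pools under the initial projection; stage 2 rebuilds
them once under the trained projection — pools always come from rough
embeddings, never from the evolving interaction model. Unsplit seed sets
are subsampled to at most 15 000 pairs and split 30 % train / 70 %
validation.

Validation Hits@1/Hits@10 are computed after the final epoch (per-epoch
evaluation is available via `eval_every` but off by default, since full
re-ranking dominates the cost of an epoch).

## Evaluation

Ranking is source → target over a caller-chosen candidate set (all target
concepts by default; a `--set`-style category pre-filter never hurts Hits@k
while the gold stays in the set). Score ties break lexicographically by
candidate id for reproducibility. The ablation driver shares the
representation stage and entity caches across variants and retrains only
the interaction stage per variant, with identical negative draws, so
variant differences reflect the feature sets rather than sampling noise.
The training-fraction sweep draws one shuffle of the train split and uses
prefix membership (original order preserved), so subsets are nested and the
100 % fraction reproduces a plain training run exactly; the validation
split is held fixed across fractions.

## Synthetic benchmark

The generator emulates the heterogeneity that makes cross-system alignment
hard, at desk scale. A rooted DAG (default 200 concepts, depth ≤ 4,
branching 2–4, ~8 % of non-roots given a second parent, one attribute
triple per ten concepts) carries compositional names: roots pair an organ-
system token with a clinical head noun ("cardiac ulcer"), children prepend
qualifiers ("partial cardiac ulcer"), so names are unique, hierarchically
correlated, and informative for a character-level encoder. The copy is
perturbed by (i) parent reassignment to a sibling of the original parent —
old and new parent share an ancestor by construction, mirroring how a
revision moves a term to a neighboring category; (ii) intermediate-category
insertion into hierarchy edges; (iii) synonym replacement, rewriting every
replaceable token of a concept's name from a built-in clinical synonym
table so the trigram encoder sees a genuinely different string. The stress
condition used throughout replaces names on 50 % of concepts while leaving
the hierarchy untouched — the regime in which the hierarchy-aware views
must carry the signal.

What the generator does **not** model: the size and branching statistics of
real ICD/SNOMED releases (10⁴–10⁵ concepts), natural-language name variance
beyond token substitution, attribute semantics, and partial (non-bijective)
gold mappings. Passing results therefore demonstrate that the method's
machinery is correct and that the hierarchy views add signal under
controlled heterogeneity — not that the absolute Hits levels transfer to
licensed terminology data with a fine-tuned transformer encoder.

## Problem sizes and numerical choices

The shipped benchmarks use 200-concept pairs, 20 epochs per stage, five
seeds for the directional comparisons, and the 768→300 default dimensions;
the identity benchmark needs no training at all. Determinism holds to the
bit on a single thread: all randomness flows from explicit integer seeds
through `numpy.random.default_rng`, string hashing is keyed BLAKE2b, and
every tie-break (neighbor order, path enumeration, ranking, pool distance)
is lexicographic. Degenerate inputs have defined behavior: empty
neighborhoods self-loop, pathless concepts yield zero path features, empty
names are rejected at parse time, and zero-norm vectors raise rather than
propagate NaNs.

## Known limitations

- GAT parameters are not fine-tuned by the margin objective (see above);
  with a trainable-attention variant the neighborhood view might contribute
  more on real data.
- The OBO reader covers the `id`/`name`/`is_a`/`synonym` subset only — no
  xref semantics, no OWL reasoning.
- Hits@k is the only metric family; MRR would be a straightforward
  extension but is not reported.
- The pretrained-encoder backend is interface-tested only; fine-tuning a
  transformer end-to-end is out of scope for this package.
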