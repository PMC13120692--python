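# Methods

## Overview

`hiergo` predicts protein function as multi-label classification over Gene
Ontology (GO) terms, treating the terms not as independent labels but as a
*sequence* ordered by the ontology DAG. It has two learned components:

1. **An ontology-informed GO term embedder.** Each term's textual definition
   is embedded by a frozen sentence encoder into x_t ∈ R^{d_t}; a trainable
   linear projection z_t = W_emb x_t maps it into a latent space, and three
   decoding heads are trained to recover, from z_t alone, the term's ancestor
   set, its subontology (MF/BP/CC) and its identity. The combined objective

       L = − α_anc Σ_i y_anc,i log ŷ_anc,i − α_sub Σ_i y_sub,i log ŷ_sub,i
           − α_id Σ_i y_id,i log ŷ_id,i

   is the weighted positive-class cross-entropy with softmax heads (a
   sigmoid multi-label mode for the ancestor head is provided, since a
   softmax over a multi-positive target splits probability mass across
   ancestors and therefore has a strictly positive loss floor; the sigmoid
   mode's optimum is exactly zero and is what the overfit sanity check
   uses). Because the encoder consumes only definition text, a term never
   seen in training — e.g. from a newer ontology release — gets a latent
   from the same frozen projection, with no retraining. This is the basis of
   zero-shot prediction.

2. **A hierarchical encoder–decoder transformer.** Residue embeddings
   X ∈ R^{L×d_seq} from a pluggable protein language model are projected
   (H_enc(0) = X W_seq + 1 b_seq^T) and contextualized by N_enc
   self-attention layers. GO latents E ∈ R^{T×d_go}, arranged by a
   topological order π of the aspect's DAG, are projected
   (H_dec(0) = E W_go + 1 b_go^T) and decoded by N_dec layers of causal
   self-attention (lower-triangular mask over π, diagonal included),
   cross-attention to the encoded residues, and a feed-forward sub-layer,
   post-norm with residual connections. A two-layer GELU head with a sigmoid
   yields per-term probabilities; training minimizes binary cross-entropy
   with the residue embeddings and GO latents frozen. The causal mask lets
   information flow from general ancestors to specific descendants — the
   hierarchical inductive bias — while cross-attention lets each term attend
   to the residues relevant to it.

Interpretability comes from the decoder's cross-attention: head-averaged
matrices A̅(l) are aggregated by the recursive rollout R(1) = A̅(1),
R(l) = ½(A̅(l) + R(l−1)); row t of R(N_dec) is the per-residue relevance
profile of term t. Unrolling gives the closed form
R = Σ_l w_l A̅(l) with w_l = 2^{−(N−l+1)} for l > 1 and w_1 = 2^{−(N−1)};
the weights are convex, so row-stochasticity is conserved exactly. This
rollout intentionally aggregates cross-attention only, additively — unlike
the original attention-rollout construction, which composes layer maps
multiplicatively through self-attention.

## Ontology machinery

OBO documents are parsed stanza-wise (via obonet); only `is_a` and `part_of`
edges are retained by default (configurable), obsolete terms are kept as
records but stripped of edges and excluded from all indices, and acyclicity
is verified at parse time. Aspects are assigned by reachability to exactly
one namespace root; a term reaching two roots is rejected. Annotations are
propagated by the true path rule (upward closure over the ancestor index),
which is idempotent and monotone by construction.

The hierarchical decoding order assigns each term the level equal to its
*longest* root→term path, then sorts by (level, term id). Longest-path
levels — rather than shortest-path BFS levels — are what guarantee that every
parent occupies a strictly shallower level than each of its children in a
DAG with multiple paths; lexicographic tie-breaking makes the order (and
hence the causal mask) reproducible. The flat `go_id` ordering (plain
lexicographic sort) is kept as the ablation baseline.

Zero-shot splits remove every record naming a held-out term *before*
propagation, so a protein annotated only with a held-out leaf contributes an
empty term set; a held-out term may still appear as a propagated ancestor of
a different retained annotation. During transformer training the held-out
term columns are additionally masked out of the BCE objective: with their
associations removed they carry no supervision, and treating them as
all-negative targets would actively train the model to suppress exactly the
terms it is later asked to predict (measured: held-out AUC ≈ 0.5 when
trained as negatives, well above with masking).

## Text encoder

The shipped encoder is a deterministic *hash encoder*: each token maps to a
pseudo-random unit-variance vector seeded from a stable digest of the token
text, and the sentence embedding is the mean over token vectors. It is
bit-stable across platforms, needs no downloads, and has the one property
the models rely on: cosine similarity grows with token overlap. Real
biomedical sentence encoders plug in through `TextEncoderSpec.encode_fn`
without entering the dependency set.

## Numerics

The environment this package targets has no deep-learning framework, so the
neural components run on a small reverse-mode autodiff engine over numpy
(`hiergo.nn`): broadcasting arithmetic, batched matmul, reductions, and
primitive softmax / layer-norm / GELU ops with analytic backward passes.
Everything is float32; training is plain Adam (lr 1e-3, β = 0.9/0.999).
Runs are bit-reproducible for a fixed seed. Desk-scale dimensions
(d = 128, 4 heads, N_enc = N_dec = 2, L ≤ 120, T ≈ 66) train in about a
minute per model on one CPU core. Attention masks are additive constants
(−1e9 on forbidden positions), so masked positions receive exactly zero
weight after the softmax; causality and padding invariance hold to machine
precision rather than approximately.

Degenerate inputs: log arguments are clamped at 1e-12; an all-masked
protein, an empty dataset, a single-class AUROC mask, and a truthless Fmax
all raise immediately rather than returning NaN.

## Evaluation conventions

Fmax follows the CAFA protein-centric convention: thresholds sweep
0.01…1.00 in steps of 0.01; precision at τ averages over proteins with at
least one call at τ, recall over proteins with at least one true term;
Fmax is the maximal harmonic mean, smallest τ on ties; if no threshold
yields a call, Fmax is 0 by convention. AUPR uses step-wise interpolation
(average precision); macro averages per-term over terms with ≥ 1 positive,
micro pools all (protein, term) pairs. "Term-centric AUC" is the unweighted
mean of per-term ROC AUCs (Mann–Whitney with half credit for ties) over
terms with at least one positive and one negative; this macro-averaged
reading is the headline number, with the micro variant available. Aspect
roots — trivially true after propagation — are excluded from scoring by
default. Every metric is tested against a first-principles oracle
(exhaustive sweep or O(n²) pair counts) rather than against another
library.

## The synthetic benchmark

The generator produces the statistical structure the method assumes, at desk
scale, with no downloads:

- **Ontology.** Three aspects, each a rooted random DAG: 15 internal terms in
  levels 1–3, 50 leaves at level 4 by default; internal terms draw 1–3
  parents from strictly shallower levels, leaves a single parent (each leaf
  belongs to one *family*, the way a specific function sits under one
  protein family). Definitions are templated sentences carrying a unique
  signature token per term plus the parents' tokens — repeated twice for
  leaves, so the family component is prominent in the mean-pooled sentence
  vector — and internal terms additionally aggregate a capped sample of
  descendant-leaf tokens. Definition similarity under the hash encoder
  thereby correlates with ontology proximity — the property the term
  embedder exploits.
- **Motif signatures.** Every leaf's planted motif is a unit vector mixing a
  leaf-specific component with the mean of its parents' *family* components
  (weight `theme_mix`); both component sets are QR-orthonormalized images of
  signature-token hash vectors under one fixed random projection, keeping
  the text→motif map linear and therefore recoverable for unseen terms.
  Sibling leaves share family content the way members of a protein family
  share a domain.
- **Proteins.** 300 proteins of 40–120 residues; background residues are
  isotropic noise with unit expected norm; each annotated leaf plants an
  8-residue window with signature content at signal-to-noise ratio 3.
  Annotation *families* emulate co-occurrence in curated corpora: each
  protein activates every family independently (Bernoulli, 1.5 expected
  families per protein, never forced), each active family contributes 1–2
  of its leaves (20% escape to a uniform leaf, total capped at 3), and
  themeless proteins carry a single uniform annotation. The independence
  discipline matters for the negative control: activating a *fixed number*
  of families per protein, or forcing at least one, couples families
  negatively, and a wrong-family predictor then scores well *below* chance
  instead of at it (measured during design: control AUC 0.2–0.4 under
  forced or fixed-count schemes, ≈ 0.45 under independent activation).
  Annotations are true-path propagated; binding masks record the planted
  windows per (protein, term).

What the generator does **not** emulate: amino-acid statistics, the
geometry of real protein-language-model embeddings, realistic annotation
depth or evidence codes, and the scale of real corpora (hundreds of
thousands of proteins, thousands of terms). Passing the benchmarks shows
the architecture can recover a planted, linearly-structured text→function
mapping and that its exact algorithms match their specifications — not that
it reaches any particular accuracy on real data.

## Zero-shot protocol and negative control

Three annotated leaves are held out; their associations are removed before
propagation and their columns masked from the training loss. Candidates
must be well annotated (≥ 10 records) and come from pairwise-disjoint
branches, and are ranked by *sibling co-annotation support* — the fraction
of the term's proteins that also carry an annotated sibling — because
definition-driven transfer needs the term's family represented in training
(the analogue of holding out only well-supported classes in real corpora).

At evaluation the model scores held-out terms from their definition latents
alone, over *all* proteins: none of their protein–term pairs ever reached
the objective, and per-term AUC on a small test split alone is dominated by
frozen sampling noise of family overlaps. The negative control keeps the
trained model and the trained projection fixed and only deranges the
*definitions* among the held-out terms (a rotation), recomputing their
latents through the frozen projection — so exactly one thing changes: the
text. If held-out predictions were driven by anything but the definitions,
control and intact would coincide; if text drives them, the control reads
chance (diagnostically, the control score for a term tracks the truth of
the term whose definition it received). Intact, control and rollout
numbers are averaged over five training seeds.

## Parameters that matter

| parameter | default | role |
|---|---|---|
| retained relations | is_a, part_of | ontology edge filter |
| ancestor sets | self-inclusive | autoencoder targets (anc2vec convention) |
| d_t | 256 | hash-encoder sentence dimension |
| d_z (= d_go) | 64 | GO latent dimension |
| α_anc, α_sub, α_id | 1, 1, 1 | multi-task loss weights |
| autoencoder epochs / lr | 1000 / 1e-3 | full-batch Adam to convergence |
| d / heads / N_enc / N_dec | 128 / 4 / 2 / 2 | transformer size (desk scale) |
| positional encodings | off | contextual residue embeddings already carry position; GO order enters via the mask |
| max sequence length | 1000 | truncation bound for real data |
| transformer epochs / lr / batch | 40 / 1e-3 / 16 | Adam, early stopping patience 10 on validation BCE |
| SNR / motif length / theme_mix | 3 / 8 / 0.7 | planted-signal strength and family share |
| thresholds (Fmax) | 0.01 step | CAFA sweep grid |

## Known limitations

- The autoencoder's printed objective (softmax + positive-only CE on a
  multi-positive ancestor target) cannot reach zero loss; structure
  recovery is therefore measured by ranking (ancestor-retrieval AUC), not
  by loss.
- Zero-shot transfer at desk scale is optimization-sensitive: it emerges
  only when training data reward the shared text→motif channel (family
  structure, co-occurrence), and its run-to-run variance across training
  seeds is large compared to what corpus-scale training would give;
  benchmark numbers are therefore averaged over several seeds.
- One model per subontology; joint-aspect training is not provided.
- The encoder ablation (bidirectional term attention) and the MLP ablation
  share the evaluation path but not the rollout path (no causal
  cross-attention stack to aggregate for the MLP).
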