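# hiergo

Hierarchy-aware transformer decoding of Gene Ontology terms for protein
function prediction.

## The problem

Protein function prediction is multi-label classification over Gene
Ontology (GO) terms. Most models treat the terms as independent outputs,
ignoring two things the ontology provides for free: the DAG of
parent–child relations and the curated textual definition of every term.
Both matter most in the *zero-shot* regime — scoring terms that had no
protein associations during training, e.g. terms introduced by a newer GO
release.

`hiergo` implements an architecture that uses both signals:

- **Term embedding.** A frozen sentence encoder embeds each definition;
  a linear projection z_t = W_emb x_t is trained with three recovery heads
  (ancestor set, subontology, term identity — a weighted positive-class
  cross-entropy) so the latent space reflects both semantics and hierarchy.
  Unseen terms get latents from the same frozen projection, with no
  retraining.
- **Hierarchical decoding.** An encoder–decoder transformer: N_enc
  self-attention layers contextualize residue embeddings X W_seq; the GO
  latents, ordered root→leaves by a deterministic topological order, pass
  through N_dec layers of causal self-attention (lower-triangular mask) and
  cross-attention to the residues; a two-layer GELU head with a sigmoid
  emits P(protein carries term t). Information flows from general ancestors
  to specific descendants, and each term attends to the residues relevant
  to it.
- **Evaluation** in CAFA conventions (protein-centric Fmax, macro/micro
  AUPR, term-centric ROC AUC), and **attribution** by attention rollout
  R(l) = ½(A̅(l) + R(l−1)) over head-averaged cross-attention, scored
  against binding-site masks by AUROC.

Everything runs on a small numpy autodiff engine (`hiergo.nn`) — no deep
learning framework required — at desk scale (widths ≈ 128, hundreds of
proteins) on one CPU core. A synthetic benchmark generator
(`hiergo.synthetic`) produces download-free fixtures with the structure the
method assumes: a random three-aspect ontology whose definitions carry
signature tokens, proteins with planted family-structured motif windows,
co-occurring upward-closed annotations, and zero-shot scenarios with a
shuffled-definition negative control. See `docs/methods.md` for the model,
the generator's design and its limits.

## Worked example

```python
from hiergo.pipeline import PipelineConfig, run_pipeline
from hiergo.synthetic import SyntheticConfig

result = run_pipeline(PipelineConfig(synthetic=SyntheticConfig(seed=1)))
r = result.report
print(f"Fmax            {r.fmax:.3f} at threshold {r.fmax_threshold:.2f}")
print(f"macro AUPR      {r.macro_aupr:.3f}")
print(f"term-centric AUC {r.term_centric_auc:.3f}")
print(f"rollout AUROC   {result.rollout_auroc_seen:.3f}")
```

prints, for this seed:

```
Fmax            0.899 at threshold 0.45
macro AUPR      0.884
term-centric AUC 0.992
rollout AUROC   0.953
```

meaning: on 60 held-out proteins the model recovers the planted
term–motif mapping almost perfectly at the protein level (Fmax ≈ 0.90),
ranks positives above negatives for a typical term with AUC ≈ 0.99, and
its cross-attention rollout ranks the planted motif residues above
background with AUROC ≈ 0.95.

The same pipeline drives the ablations (GO embeddings none / structural /
textual / combined; decoder / encoder / MLP integration; hierarchical vs
flat term ordering) and the zero-shot protocol (terms stripped from all
associations before true-path propagation, scored from their definitions
alone, with a deranged-definition negative control).

A CLI mirrors the library for shell use — `hiergo simulate`, `hiergo
ontology prepare`, `hiergo embed terms|go-latent`, `hiergo split
zero-shot`, `hiergo train`, `hiergo predict`, `hiergo evaluate`, `hiergo
rollout`, `hiergo run`, `hiergo ablate`; every command is a thin wrapper
over the modules above.

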