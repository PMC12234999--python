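# csglearn

Reaction-aware molecule representation learning over a **chemical synthesis
graph** (CSG).

Most molecule embedding methods look only at a molecule's own atom graph.
`csglearn` additionally uses the chemistry the molecule participates in: every
reaction `R₁.R₂…>>P₁.P₂…` links a *reactant molecule set* to a *product
molecule set*, and across a corpus these sets form a directed graph — the CSG
— whose edges carry the structural change of the reaction. Embeddings trained
on this graph transfer to product prediction, reaction classification and
molecular property prediction, which makes the package useful to
cheminformatics and drug-discovery groups who want reaction-informed molecule
features without task-specific supervision.

## Model

Three levels, trained end to end:

1. **Molecule encoder.** Atoms carry one-hot attributes (element, formal
   charge, attached H count, ring membership). `L` message-passing layers
   (GCN, GAT, GraphSAGE or TAG) followed by a pooling readout (sum by
   default; avg/max/attention/SortPooling/Set2Set available) give each
   molecule an embedding **m** ∈ ℝᵈ.
2. **CSG embedding.** A node (molecule set) starts from the READ sum
   **R** = Σ **m**ⱼ. One or more CSGNN layers refine it over the graph,
   `Rʰ⁺¹ = Rʰ + Σ_{O∈N(R)} π_{R→O} Oʰ`, with softmax attention weights
   `π ∝ exp(w_aᵀ (R ⊙ O ⊙ T(R,O)))`; the final node embedding averages all
   layers. The edge (transformation-relation) embedding is linear in integer
   count deltas between the two sides:
   `T = ΔNB·e_bond + ΔNR·e_ring + Σⱼ ΔNB_bⱼ·e_bⱼ`,
   over total bonds, SSSR rings and 15 common bond types.
3. **Translational objective.** Embeddings are optimized so each reaction
   satisfies the chemical-balance constraint **R** + **T** ≈ **P**, with a
   margin loss per minibatch B:

   `L = 1/|B| Σᵢ ‖Rᵢ+Tᵢ−Pᵢ‖₂ + 1/(|B|²−|B|) Σ_{i≠j} max(γ − ‖Rᵢ+Tᵢ−Pⱼ‖₂, 0)`

   plus an L2 penalty λ‖Θ‖²_F, minimized with Adam. The recommended margin is
   γ = 4.

Candidate products are ranked by the match score −‖R+T−P‖₂ (MRR, Hit@K);
reaction classification uses frozen concatenated (reactant ‖ product)
embeddings from a CSGNN-free model with an MLP head; property prediction uses
frozen molecule embeddings with logistic regression (ROC AUC).

The numerical core is a small reverse-mode autodiff engine over NumPy
float64 (`csglearn.autodiff`), so runs are deterministic per seed and every
gradient is verifiable against finite differences.

## Worked example

No external data is needed: the package generates a template-based synthetic
corpus (120 molecules; 300 reactions from esterification, amidation,
Diels–Alder, alcohol oxidation and aldehyde oxidation templates).

```python
from csglearn import (
    EncoderConfig, TrainConfig, SplitSpec,
    make_default_corpus, split_dataset, train_model,
)

_, reactions = make_default_corpus(seed=0)
train, valid, test = split_dataset(reactions, SplitSpec(seed=0))

results = train_model(
    train,
    encoder_config=EncoderConfig(gnn_type="gcn", hidden_dim=64, num_layers=2),
    train_config=TrainConfig(margin=4.0, learning_rate=1e-3, epochs=60,
                             batch_size=32, seed=0),
)
print(results.summary())
print("product prediction:", results.evaluate_product_prediction(test).as_dict())
```

prints

```
CSGL model results
==============================================
molecule encoder            GCN (2 layers)
pooling                     sum
embedding dim d             64
CSGNN layers H              1
bond-type vocabulary        15
CSG nodes                   270
trainable parameters        6400
reactions (train)           240
distinct molecules          198
margin γ                    4.0
L2 λ                        1e-05
learning rate               0.001
epochs × batch              60 × 32
final training loss         0.1110
fit time (s)                5.7
==============================================
product prediction: {'mrr': 1.0, 'hit@1': 1.0, 'hit@3': 1.0, 'hit@5': 1.0}
```

The fitted model drove the per-epoch margin loss from ≈2.4 to 0.11, and on
the 30 held-out reactions every true product set is ranked first among the
candidate pool (MRR = Hit@1 = 1.0 — the synthetic corpus is an easy,
fully-learnable benchmark by construction).

A `csgl` console script wraps the same pipeline
(`csgl make-synth`, `csgl train`, `csgl eval-product`, `csgl eval-classify`,
`csgl eval-property`); every command takes `--seed` and writes JSON metric
reports.

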