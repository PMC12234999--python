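# Methods

## The model

`csglearn` learns molecule embeddings from two sources of signal: the atom
graph of each molecule, and a *chemical synthesis graph* (CSG) built from a
reaction corpus. A CSG node is a molecule multiset — the reactant side or the
product side of some reaction — deduplicated corpus-wide by the sorted tuple
of member canonical SMILES, so a set that is the product of one reaction and
the reactant of another is a single node and 2-hop relationships ("two
reactants that make the same product") become graph paths. Each reaction
contributes one directed edge annotated with integer *transformation
features*: reactant-minus-product differences of the total bond count, the
SSSR ring count, and per-type counts over a 15-entry bond-type vocabulary
(the default covers common C/N/O/S/P single, double, triple and aromatic
bonds and is replaceable via YAML/JSON; bonds outside it fall into an OTHER
bucket that is counted but excluded from relation modeling, and the
per-bond-type deltas serve as a cheap proxy for the reaction's energy
change, since that change is dominated by which bonds break and form).

Pipeline:

1. **Atom features.** One-hot blocks for formal charge (clipped to [−2, 2]),
   element (training-corpus vocabulary + UNK), attached hydrogens (clipped to
   [0, 4]) and ring membership; exactly four ones per atom. Hydrogens are
   implicit — only heavy-atom bonds are enumerated — and no bond features are
   used (bond type is inferable from the incident atoms). Aromatic bonds
   count as one bond each without kekulization, which keeps counts
   independent of the kekulé assignment.
2. **Molecule encoder.** `L` message-passing layers (default 2) in one of
   four architectures, each following its published convention: GCN
   (symmetric-normalized adjacency with self-loops), GraphSAGE (self + mean
   neighbor, separate weights), TAG (powers 0..K of the normalized adjacency,
   K = 2), GAT (single-head attention over neighbors ∪ self, LeakyReLU 0.2).
   ReLU between layers, none after the last; no dropout or normalization
   (the simplest defaults — the architecture grid matters far more at this
   scale). Pooling: sum (default), avg, max, MLP-attention (one hidden tanh
   layer scoring each atom, softmax within the molecule, weighted sum),
   SortPooling (sort atoms by the last embedding channel, keep k = 10 rows
   with zero padding, linear projection back to d) and Set2Set (3 LSTM
   processing steps, output projected from 2d to d). All methods except
   SortPooling are permutation-invariant by construction.
3. **CSG embedding.** Node layer 0 is READ — the elementwise sum of member
   molecule embeddings. Each of H CSGNN layers (default 1; H = 0 is the
   CSGNN-free ablation) adds an attention-weighted sum of neighbor
   embeddings to a residual copy of the node. Attention logits are
   `w_aᵀ(center ⊙ neighbor ⊙ T)` with one weight vector per layer, and the
   softmax runs over the neighborhood only — the center is not in its own
   softmax because the update already carries an explicit residual term.
   Neighborhoods include both edge directions; when an edge is traversed
   against its direction the transformation features are negated, preserving
   their linear reactant-minus-product semantics. The final node embedding
   averages layers 0..H. Relation embeddings are linear in the deltas with
   one learned d-vector per channel (bond, ring, and each bond type).
4. **Objective.** Margin-based contrastive loss over minibatches: mean
   positive residual ‖R+T−P‖₂ plus the mean hinge `max(γ − ‖Rᵢ+Tᵢ−Pⱼ‖₂, 0)`
   over all ordered unmatched in-batch pairs (normalizer |B|²−|B|; no
   external negative sampling; Tᵢ always belongs to reaction i, also in the
   negative term). Total loss adds λ‖Θ‖²_F over all parameters. Adam, no
   schedule.

### Defaults

| parameter | default | notes |
|---|---|---|
| embedding dim d | 64 | supported grid 32…1024 |
| encoder layers L | 2 | |
| CSGNN layers H | 1 | 0 = CSGNN-free variant |
| pooling | sum | best-performing simple readout |
| margin γ | 4 | recommended setting; must be > 0 |
| L2 λ | 1e-5 | mild; training is short |
| learning rate | 1e-4 | grid midpoint of {1e-5…1e-2} |
| batch size | 32 | |
| charge / H clip | [−2,2] / [0,4] | bounded one-hot blocks |
| SortPooling k / Set2Set steps | 10 / 3 | conventions of the cited readouts |

All parameters are Glorot-uniform initialized (biases zero) from a seeded
generator; computation is float64 throughout, so identical seeds give
bit-identical splits, training curves and metrics.

## Inference-time conventions

* **Ranking.** Candidates are scored by −‖R+T−P‖₂ with T computed from the
  query reaction. Ties break *pessimistically*: equal-scoring distractors are
  placed ahead of the true product, so reported MRR/Hit@K never benefit from
  ties. The candidate pool is the set of product sides in the test split,
  deduplicated by the same multiset key as CSG nodes.
* **Unseen nodes.** A side absent from the training CSG receives its READ
  embedding (effectively H = 0 for that side); a side whose multiset key
  matches a training node reuses the refined node embedding. The CSG is
  built from the training split only.
* **Transfer tasks.** Classification and property prediction use the
  CSGNN-free model, because the synthesis-graph structure differs between
  pre-training and the downstream corpora. Reaction features are the frozen
  concatenation (READ reactants ‖ READ products); the decoder is a
  standardized one-hidden-layer MLP (width 2d, ReLU, cross-entropy, early
  stopping on a held-out fraction) with macro-averaged precision/recall.
  Property prediction standardizes frozen molecule embeddings and fits a
  logistic regression; the metric is ROC AUC on the test split of an 80/10/10
  partition (rounding favors train).

## Numerical choices

The model runs on an in-repo reverse-mode autodiff engine over NumPy float64
arrays with sparse-matrix message passing; gradients of every op are covered
by central-finite-difference tests. Euclidean norms use a safe square root
whose subgradient at 0 is defined as 0 — distances at exact translations are
exactly zero (no epsilon shift) and the hinge kink at γ uses the standard
subgradient, both measure-zero events during training. Softmaxes subtract
the per-neighborhood maximum before exponentiation. Training forward passes
are vectorized over the whole graph; inference re-derives node tables through
an independent nested-loop-style reference implementation, and the two paths
are cross-checked to 1e-8 in the tests.

## The synthetic corpus

Real benchmark corpora (USPTO-scale) are supported as input formats but not
bundled; development and testing run on a generated corpus with known
structure. A fragment grammar assembles molecules (alkyl chains of 1–6
carbons, optional methyl branch, optional phenyl/cyclopentyl ring, head
group: alcohol, carboxylic acid, primary amine, conjugated diene, terminal
alkene, or none), and five RDKit reaction-SMARTS templates produce labeled
reactions: esterification (Δbonds/Δrings 0/0), amidation (0/0), Diels–Alder
(−2/−1), primary-alcohol oxidation (0/0 with ±1 C–O/C=O type deltas) and
aldehyde oxidation (−1/0). The default fixture is 120 molecules and 300
reactions (60 per template), seed 0, chosen so that training plus all three
evaluations completes in well under a minute on one CPU.

Two generator mechanisms create realistic graph structure: reactants are
drawn from small per-template subpools so sides repeat (node degree ≥ 2 for
over 10% of nodes), and aldehyde-oxidation records consume aldehydes made by
earlier alcohol oxidations, so those nodes carry both in- and out-edges.
Notably, the template set deliberately contains no mutually-reverse template
pair: a pair like esterification/ester-hydrolysis has all-zero deltas in
both directions, the translational constraint then forces READ(R) ≈ READ(P),
and the two classes become indistinguishable from concatenated embeddings —
a degenerate design, not a hard benchmark. Atom conservation is only
approximate (water or HX by-products may be dropped), as in real reaction
records; the method never requires balanced equations.

What passing on this corpus does and does not show: the fixture verifies
that the implementation can recover known structure (near-perfect ranking,
≥ 0.95 classification accuracy, ≥ 0.9 property AUC with a ring-membership
label at 5% flip noise) under the stated conditions. It does not demonstrate
performance on real reaction corpora, which are larger, noisier, contain
stereochemistry and atom-mapping artifacts this package ignores, and have
far sparser synthesis graphs.

## Limitations

* No stereochemistry, atom mapping, charge balancing or reaction-validity
  checking beyond parseability; agents in `reactants>agents>products`
  records are discarded.
* The exact membership of the 15-entry bond-type vocabulary is a
  configuration default; swap in a domain-specific list via
  `BondTypeVocabulary.load` when one is available.
* CSGNN aggregation runs over the full graph with no neighbor sampling —
  appropriate for desk-scale corpora, quadratic-memory-free but not tuned
  for million-edge graphs.
* The CPU/NumPy backend favors exactness and reproducibility over
  throughput; full USPTO-scale training is out of scope.
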