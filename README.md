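# ddisub

Substructure-aware dual graph neural network for typed drug–drug
interaction (DDI) prediction, implemented in pure NumPy (with its own
reverse-mode autodiff engine) on top of RDKit molecular graphs.

## The problem

Co-administered drugs can interact — one drug changes the metabolism,
efficacy or toxicity of another — and the interaction usually traces back
to a *few functional substructures* of each molecule, not to the molecules
as wholes.  `ddisub` predicts, from the two SMILES strings alone, the
probability that a typed interaction `(d_x, d_y, r)` occurs, and reports
*which* substructure pair drives the prediction.

## The model

Each drug is parsed into a directed-bond molecular graph (42-dim atom
features, 6-dim bond features).  A **directed message passing encoder with
substructure attention** maintains hidden states on directed bonds:

    h_ij(0) = W_i x_i + W_j x_j + W_ij x_ij
    h_ij(t) = ReLU( h_ij(0) + W_m Σ_{k∈N(i)\{j}} h_ki(t-1) )

Per-step bond importances β (a line-graph convolution, softmaxed over each
atom's incoming bonds) pool the states into per-step graph summaries
g(t) = Σ_i Σ_j β_ji h_ji(t), and a softmax over steps,
α(t) ∝ exp⟨w_t, tanh(W g(t) + b)⟩, weighs receptive-field radii against
each other.  L such blocks are stacked; layer *l*'s pooled vector
g(l) = Σ_i β_i h_i(l) represents substructures of radius up to *l·T* bonds.

The two drugs' substructure stacks are coupled with **co-attention**

    γ_ij = bᵀ tanh(W_x g_x(i) + W_y g_y(j)),   i,j = 1..L

which reweights each stack (ĝ_x(i) = Σ_j γ_ij · g_x(i)), sums it to a
graph-level vector, and scores the tuple with a per-relation bilinear form

    P(d_x, d_y, r) = σ( g_xᵀ M_r g_y ).

The argmax (h, t) of the pairwise substructure scores ĝ_x(i)ᵀ M_r ĝ_y(j)
names the layer pair — and hence the receptive-field radii — responsible
for the prediction; the top-3 atoms by β of those layers are the
substructure centers that explanations highlight.

Everything is trainable end to end (Adam, exponentially decaying learning
rate, 1:1 corruption-sampled negatives).  No external DDI database is
required: a bundled generator builds small molecules from a fragment
library and plants interaction rules as SMARTS motif pairs, with the motif
atoms recorded as ground truth for explanation experiments.

## Worked example

```sh
ddisub generate --n-drugs 20 --n-tuples 30 --seed 7 --out-dir data
ddisub train data/drugs.csv data/ddis.csv --T 2 --L 2 --hidden 16 \
       --epochs 20 --lr 3e-3 --seed 7 --out-dir run
ddisub explain data/drugs.csv run/checkpoint.npz \
       --drug-x D0002 --drug-y D0005 --out run/explanation.json
```

The `generate` step prints `wrote 20 drugs, 30 tuples to data`; training
ends with a line like

```
test metrics: {'ACC': 0.5833..., 'AUC': 0.46875, 'F1': 0.6153..., 'Prec': 0.4444..., 'Rec': 1.0, 'AUPR': 0.3515..., 'n': 12}
```

(a 20-drug, 30-tuple toy run — scores near chance are expected at this
scale; the bundled experiments below use 60 drugs and 400 tuples).  The
`explain` command prints the predicted probability and the key layer pair,
e.g.

```
probability 0.5546, key layer pairs [[1, 2]]; details in run/explanation.json
```

meaning a radius-1 substructure of drug x interacting with a radius-2
substructure of drug y dominated the score; `run/explanation.json` holds
the γ map, per-layer atom importances, center/member atom sets and the
atom-similarity (Pearson) matrices.

As a library:

```python
from ddisub.experiments import motif_learnability_experiment
res = motif_learnability_experiment(seed=1)
print(res.auc)   # held-out AUC on the planted-motif benchmark, ~0.95
```

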