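# Methods

## Featurization

SMILES are parsed with RDKit; the largest covalent fragment is kept and
atoms are renumbered into RDKit's canonical order so the same structure
always yields identical arrays.  Atom vectors (length 42) concatenate a
16-slot element one-hot (B, C, N, O, F, Si, P, S, Cl, As, Se, Br, Te, I,
At, plus a *meta* slot for anything else), an 11-slot heavy-atom-degree
one-hot (0–10), a 5-slot hybridization one-hot (sp, sp², sp³, sp³d,
sp³d²), a 7-slot implicit-valence one-hot (0–6), and integer fields for
radical electrons, formal charge and aromaticity.  Degree counts heavy
atoms only (hydrogens are implicit and never become nodes).  Out-of-range
degree/valence clamps to the last slot and hybridizations outside the five
listed states leave an all-zero block; both are logged.  Bond vectors
(length 6) are a bond-type one-hot (single, double, triple, aromatic) plus
conjugation and ring flags.  Stereochemistry and isotopes are ignored.

Every chemical bond becomes two directed bonds stored consecutively, so
the reverse of bond *k* is *k XOR 1*.

## Encoder

Bond-state initialization and the per-atom message aggregation are fixed
by the model definition; the *bond-state update itself* admits more than
one reading, and this package adopts the standard directed-MPNN update

    h_ij(t) = ReLU( h_ij(0) + W_m · Σ_{k∈N(i)\{j}} h_ki(t−1) )

with the reverse bond excluded, and with the bond importances β entering
only the node aggregation (not the update).  β is recomputed from the
current (post-update) bond states at every step — the freshest structure
signal — with a `recompute_beta=False` switch that scores the initial
states once instead.  The β scorer is a single graph convolution on the
bond line graph (two directed bonds are adjacent when they share an atom;
a self-loop is included), and its raw scores are softmax-normalized over
each atom's *incoming* bonds so that the per-atom message is a convex
combination.  The step-attention weight vector w(t) is per step; the
shared projection W, b and the update matrix W_m are shared across steps.

The node readout adds a learned input projection W_0·x_i to the summed
incoming bond features before the MLP: the raw atom vector (42-dim) and
the bond states (h-dim) live in different spaces, and a projection is the
minimal change that makes the sum well defined.  Nonlinearities are ReLU,
weights are Glorot-uniform, biases zero, all drawn from one integer seed.

Per-step graph summaries (and hence α) are pooled over the whole graph,
not per connected component; for the single-fragment molecules this
package parses the distinction never arises, and it is documented rather
than special-cased.

## Substructure stacks and co-attention

L encoder blocks are stacked with independent parameters; block l ≥ 2
consumes block l−1's node features (bond features are re-used unchanged).
Per-layer node importances come from a one-layer atom-graph convolution
softmaxed over all atoms — scores are used as weights only; no nodes are
dropped.  The co-attention map γ is left unnormalized by default, exactly
as the bilinear/tanh definition produces it; a `softmax_gamma` switch
row-normalizes it.  The reweighting algebra collapses to scaling each
layer's vector by its γ row (column) sum, and the implementation preserves
this identity exactly even though it is vectorized.

W_x and W_y are deliberately distinct parameters (symmetric weights would
score similar substructures highly by construction), and they are shared
across relation types.  γ feeds the reweighting directly, with no
intervening nonlinearity.

## Scoring and training

Per-relation bilinear matrices M_r are Glorot-initialized and
unconstrained — the score is direction-aware unless the optional
`symmetrize_relations` switch averages M_r with its transpose.  The
key-substructure layer pair (h, t) is the argmax of the pairwise scores of
the *reweighted* stacks, ties broken toward the smallest (h, t); indices
are 1-based because they double as receptive-field radii.

The loss is mean binary cross-entropy.  The probability-space form clamps
p to [1e-7, 1−1e-7] before the logs (the loss is undefined at 0 and 1);
the training loop evaluates the same quantity from logits via the softplus
identity, because clamping also zeroes the gradient of saturated
predictions and would stall optimization.  The optimizer is Adam with L2
weight decay folded into the gradient, under the exponentially decaying
schedule lr·0.96^e.  Negatives are sampled 1:1 by corrupting one side of
each positive (fair coin) with a uniform drug, rejecting candidates that
collide with a known positive.  Dataset splits are made on tuples
(60/20/20 by default, floor allocation with the remainder to train);
model selection keeps the checkpoint with the lowest validation loss.

Default hyperparameters (T = L = 3, hidden 64, lr 1e-4, batch 256,
50 epochs, weight decay 5e-4) follow the reference setting for full-scale
corpora; the bundled experiments override them as described below.

## Synthetic benchmark

The generator assembles 1–3 fragments from a ~30-entry library into unique
small molecules, joining fragments by single bonds at atoms with spare
valence.  Fragment sampling is weighted toward functional-group carriers
so that each default motif appears in roughly 15–35 % of drugs — enough
eligible pairs to support the benchmark's 400 tuples over 60 drugs.
Interactions are planted by two rules: *carboxylic acid + free amine* →
type 0 and *halogen + six-membered aromatic carbocycle* → type 1, each
expressed as SMARTS and matched with RDKit.  Labels of sampled positives
are flipped with a small noise rate (default experiments use 0.05); noise
touches labels only, never structures.  Matched motif atom indices are
recorded per tuple as ground truth.

What the generator does *not* emulate: realistic medicinal-chemistry
property distributions, molecule sizes beyond ~25 atoms, more than a
handful of interaction types, or pharmacological mechanisms beyond
"functional groups imply interaction".  Passing benchmarks here shows the
architecture can discover and localize planted substructure logic — it
does not certify performance on curated DDI corpora.

## Experiment conditions

*Memorization* (capacity check): 10 drugs, 50 random positives + 50
corruptions, T = L = 2, hidden 32, constant lr 3e-3, 300 epochs, no weight
decay.  *Learnability*: 60 drugs, 400 tuples, noise 0.05, split 60/20/20
before negatives are drawn; T = L = 2, hidden 32, lr 1e-2 decaying by
0.99/epoch, batch 256, 80 epochs, weight decay 5e-4, row-softmaxed γ
(stabilizes the scale of the reweighted stacks during optimization), and
negatives redrawn every epoch so the model cannot memorize them.  These
sizes keep each study to minutes on one CPU.

Corruption sampling in the synthetic experiments is *filtered*: rejected
not only against sampled positives but against the full rule closure (all
pairs the generative rules declare interacting), which is knowable exactly
in the synthetic world.  Without filtering, corruptions frequently land on
unsampled true interactions, and no classifier — including the planted
rule itself — can separate the classes well; the rule-indicator ceiling
sits near 0.85 AUC unfiltered versus ≈0.96 filtered (the remainder being
the 5 % label noise).

*Explanation recovery*: every positive test tuple is explained (top-1
layer pair, top-3 β centers per drug); a hit is an explanation whose
centers intersect the recorded motif atoms.  The baseline is the exact
hypergeometric probability that 3 uniformly random distinct atoms hit the
motif set, averaged over explanations; observed hits are tested with a
one-sided binomial test at the mean baseline rate.  The mean-baseline
approximation is slightly conservative in the regime observed (hit
probabilities well above one half).

## Numerical notes

- All tensors are float64; the autodiff engine is a tape of closures over
  NumPy arrays, with scatter-add/gather as the two graph primitives.
- Softmaxes subtract a detached maximum; the segment softmax handles empty
  and singleton buckets explicitly.
- Pearson similarity guards zero-variance feature vectors: their
  off-diagonal similarity is defined as 0, the diagonal stays 1.
- Checkpoints (`.npz`) store the flat parameter list plus the architecture
  config and reject shape mismatches on load.

## Known limitations

- The per-relation matrices grow as |I|·h², which is fine for tens of
  types but would need factorization for hundreds.
- Per-graph (not per-component) pooling, see above.
- Batched training re-encodes each distinct drug once per batch; there is
  no cross-batch caching of encodings, a deliberate simplicity/correctness
  trade-off since gradients must flow through the encoder anyway.
- Probabilities are uncalibrated; threshold-based metrics use 0.5.
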