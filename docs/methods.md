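# Methods

## Problem and model

Single-step retrosynthesis is cast as conditional sequence generation:
given a product molecule, write the `.`-joined SMILES of its reactant set.
The model reads the product twice — as a token sequence and as a molecular
graph — and fuses the two views before decoding.

**Sequence view.** The product SMILES is tokenized with the
community-standard regex (bracket atoms, `Cl`/`Br`, `%nn` ring closures as
single tokens). When the reaction class is known, a literal class token
(`[RX_1]`…`[RX_10]`) is prepended. A transformer encoder stack (pre-norm
residual blocks with a final layer norm; fixed sinusoidal positions)
produces the uni-view embedding `H_s`.

**Graph view.** Atoms carry element / degree / hydrogen-count one-hots
plus charge, aromaticity and ring flags; bonds carry order one-hot,
conjugation and ring flags; each undirected bond is represented as two
directed edges with tied initial features. Bond geometry enters through a
20-center Gaussian radial-basis expansion of interatomic distance on
[0 Å, 6 Å] with width equal to the center spacing. Distances come from a
single ETKDG conformer refined with MMFF (fixed embedding seed); when
embedding fails — or under the default `topological_fallback` policy used
for desk-scale training, where conformer generation would dominate
runtime — graph shortest-path lengths stand in, deterministically, and the
choice is recorded on the `MolGraph`. Positional structure is encoded by
k-step random-walk return probabilities `diag((D^-1 A)^t)`, `t = 1…k`;
isolated nodes get zero rows (the degree-0 walk is undefined, and a zero
row preserves shape without inventing probability mass).

The message-passing encoder keeps three streams (nodes `h`, directed
edges `e`, positions `p`). Per layer, each stream is updated from
learnable message functions over the neighborhood — sum-aggregated
two-layer MLPs — with residual connections and layer normalization on all
three streams (the positional stream is normalized like the node stream;
nothing in the construction requires it to stay a probability vector after
layer 0). Atom- and bond-level reaction-center probabilities are sigmoid
heads on the final node and edge embeddings; the undirected bond score is
the mean over its two directions, since edge updates are
orientation-dependent while center labels are per-bond.

**Captioner.** Projected node embeddings `Ĥ_g = FFN(H_g)` are compared
with every sequence-token embedding by cosine similarity (the similarity
function is configurable; cosine is the convention in the image-text
matching literature this component descends from), mean-pooled over
tokens (PAD positions excluded) and softmax-normalized over nodes into
weights `w`; `H_w = w ⊗ H_g` feeds the fusion. The contrastive loss

```
L_captioner = ‖c_nrc − c_rc + γ‖² + (1/u) Σ ‖ĥ_i^rc − c_rc‖²
             + (1/v) Σ ‖ĥ_j^nrc − c_nrc‖²
```

uses learnable centers and a fixed margin `γ` (scalar broadcast to a
vector, default 1.0). Two reading notes. First, minimizing the first term
drives the center separation *to* `‖γ‖` rather than beyond it; a hinge
would push it past a margin instead. We implement the quadratic form as
written. Its joint stationary point is characterized by
`c_rc − mean(Ĥ^rc) = δ` and `c_nrc − mean(Ĥ^nrc) = −δ` with
`δ = (mean(Ĥ^nrc) − mean(Ĥ^rc) + γ)/3`, so the centers sit exactly on the
group means only when the group means are already separated by `−γ`.
Second, the scatter terms use the projected embeddings `Ĥ_g` (not raw
`H_g`); the projected space is where the weighting similarity lives.
When one group is empty (identity reactions), its scatter term is
dropped. At inference no labels exist; the weighting needs none and the
contrastive loss is training-only.

**Fusion and decoding.** Each dual-view layer runs self-attention, then
cross-attention with the sequence state as queries and `H_w` as keys and
values, then an MLP. The decoder input representation concatenates the
uni-view output and the dual-view output and projects back to model
width. The decoder is a standard causal transformer; its cross-attention
maps (averaged over heads and layers) also carry the SMILES-alignment
supervision: for every atom present on both sides of the reaction, the
cross-entropy between the attention row of the reactant token and the
one-hot position of the product token spelling the mapped atom. This
alignment construction is this package's documented choice — the general
idea (supervising cross-attention with atom-map-derived token alignments)
admits several concrete forms.

**Training objective.** `L = L_LM + L_AG + L_CL + L_captioner`, all
unweighted (weights are exposed in the config, default 1.0 each);
teacher-forced NLL for `L_LM`, no label smoothing by default.

## Ablation toggles

The four configuration toggles reproduce the standard ablation ladder:
sequence-only transformer (`use_graph=False`; the dual layers degenerate
to plain encoder layers, so the architecture is exactly a deeper vanilla
encoder); graph concatenation without cross-attention
(`use_cross_attention=False`: a mean-pooled graph vector is concatenated
per position and projected); cross-attention without the captioner
(`use_captioner=False`: `H_w = H_g` unweighted, no contrastive term); and
the full model.

## Optimization (desk scale)

The network runs on the package's own reverse-mode autodiff core over
NumPy (`retrocap.nn`): float64 tensors, fused kernels for the two-layer
MLP, layer norm, softmax and log-softmax, and a topological-sort backward
pass. Parameters use Glorot-uniform init; token embeddings are drawn at
scale `1/√d` so that, multiplied by `√d`, they match the unit scale of
the sinusoidal positions.

Training is Adam with gradient accumulation (default batch 2), linear
warmup over the first 100 optimizer steps and cosine annealing to 1% of
the peak rate — at desk scale with small batches, fixed-rate Adam leaves
the loss bouncing at a noise floor well above the memorization regime,
and the annealed schedule removes that floor. The full-scale reference
configuration (4/4/8 layers, d = 256, 8 heads, dropout 0.3, lr 1e-3) is
the package default; the `small` preset (2/2/2 layers, d = 64, 4 heads,
lr 3e-3, dropout 0.1) is what the test suite trains. Polyak/EMA weight
averaging is implemented but off by default (with cosine annealing the
final weights already dominate the average). All randomness — parameter
init, shuffling, dropout, augmentation roots — derives from one seed via
spawned NumPy generators; runs are bit-reproducible single-threaded.

Root-enumeration augmentation rewrites the product SMILES rooted at
sampled atoms while keeping the canonical reactant string as the target,
so every augmented copy reinforces the same output; reaction-center
labels and token alignments are re-indexed through the writer's atom
output order. (Rooting the targets as well was evaluated and learns
slower at this scale: it multiplies the set of output strings the decoder
must master.)

## Synthetic data

The generator assembles reactions forward from random fragments with four
single-bond-forming templates — amide coupling, ester formation,
Williamson ether synthesis, aryl–aryl coupling — so the retro-step
reaction center (the formed bond and its endpoints) is known by
construction. Fragments are random carbon trees (skeleton of 2–6 heavy
atoms by default) decorated with fluorine leaves and occasional inserted
ether oxygens, each carrying exactly one role group (carboxylic acid,
primary amine, hydroxyl, alkyl chloride, aryl chloride); benzene rings
anchor the aryl template. Leaving groups (the acid hydroxyl, the
chlorides) appear on the reactant side without product maps, exercising
the unmapped-atom path of the label extractor. Products are deduplicated
(by canonical SMILES) so no molecule crosses the 80/10/10
train/valid/test split. Class tokens follow template identity. Two-step
chains for route planning compose an amide coupling (acid + amino-alcohol,
leaving a free hydroxyl on the intermediate) with an ester formation on
that hydroxyl; the three leaf fragments form the buyable stock.

What this emulates: atom-mapped single-step reactions with well-defined
single-bond centers and a modest token vocabulary. What it does not:
multi-bond and ring-forming transformations, stereochemistry,
protecting-group chemistry, reagent/condition dependence, realistic
drug-like complexity, or the class imbalance of patent-derived data.
Passing tests therefore demonstrate the machinery — label derivation,
multi-task optimization, copy-and-edit decoding, metric accounting, route
recursion — not chemical coverage.

## Evaluation

Top-k exact match compares canonical, order-insensitive reactant
multisets (atom maps stripped; stereo descriptors retained by the
canonical writer — the synthetic data carries none, and the switch is a
one-line change in `canonical_reactant_key`). Top-k validity counts
parseable candidate slots out of N×k; short beams count their missing
slots as invalid. Beam search is length-normalized (total log-probability
divided by token count — without this, short sequences are favored);
candidates deduplicate by canonical reactant multiset, keeping the best
score, and invalid strings are retained in the ranking (they hurt
validity and can never be exact matches — filtering them would silently
inflate the match metric). Route planning is greedy iterative top-1
expansion with memoization of repeated molecules, a no-progress guard
(a prediction equal to its input marks the node terminal), and a depth cap.

## Problem sizes in the test suite

The suite trains the `small` preset on 200 generated reactions with
8 extra rooted writings per reaction for 30 epochs (batch 2), evaluates
training-set top-1 exact match with a width-5 beam, and measures
reaction-center AUROC on a held-out 50-reaction set; the ablation ladder
uses 60 reactions for 12 epochs per variant; route planning overfits the
two chain steps plus distractors. These sizes are the package's chosen
desk-scale study conditions; they are far below the scale at which the
architecture's published ancestors are trained, and training-set
memorization rather than test-set generalization is the appropriate
success criterion at this scale.

## Known limitations

* No KV-cache in the decoder: beam search re-runs the decoder per step
  (acceptable at desk scale, quadratic in output length).
* Single-threaded CPU only; no minibatch vectorization across samples.
* Atom mappings must be given (or generated); the package never infers
  them.
* The contrastive margin enters with the printed sign convention (see
  above); readers expecting a hinge margin should note the difference.
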