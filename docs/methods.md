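# Methods

## Problem formulation

A reaction record is a reaction SMILES `reactants>>products` with five
condition labels — catalyst, solvent1, solvent2, reagent1, reagent2 —
and an optional temperature in °C. Each slot carries a `Null` sentinel
for "this reaction uses no condition of this type". Condition
prediction is cast as a causal sequence task of fixed length 6: the
five slots are decoded in order, each conditioned on the labels already
decoded, and the sixth position is an end token. Temperature is a
scalar regression on top of the same representation.

## Architecture

* **Encoder.** Token embedding + learned absolute positional embedding,
  followed by pre-normalization transformer blocks (bidirectional
  self-attention, then a ReLU feed-forward block, residual connections,
  final layer norm). Defaults: 2 layers, 4 heads, width 64,
  feed-forward 128. Pre-normalization was chosen because it trains
  stably at these small widths without a carefully tuned warmup.
* **Decoder.** A 6-position causal transformer decoder (defaults: 3
  layers, 4 heads) whose inputs are a BOS embedding followed by the
  embeddings of the five previous slot labels. All slots share one
  union label vocabulary and one output head; per-position logits are
  masked to the slot's admissible label set with a −10⁹ additive bias,
  which makes the softmax mass outside the slot exactly zero in float
  arithmetic. A shared embedding table is what makes feeding decoded
  labels back into the decoder well-defined across slots.
* **Temperature head.** The mean-pooled non-PAD encoder memory passes
  through feed-forward net A, the mean of the six decoder states
  through net B; their concatenation passes through net C to one
  scalar. At inference the decoder states come from the top-1 decoded
  condition sequence. The paper-level loss weight α = 0.001 multiplies
  the squared error.

**Loss.** Sum over the six positions of the cross-entropy (natural
log) within the admissible set, averaged over the batch, plus
α·(t − t̂)². The per-position sum (rather than mean) is used so the
classification and regression magnitudes match the stated α. When any
record lacks a temperature the regression term is dropped.

**Temperature standardization.** The regression head operates on
standardized temperatures (train mean/sd), de-standardized for
reporting MAE in °C. This keeps α = 0.001 meaningful across datasets
with different temperature ranges; `TrainConfig.standardize_temperature
= False` recovers raw-°C behaviour. `compute_loss` itself is
scale-agnostic and is fed whichever scale the trainer uses.

## Tokenization

The community-standard SMILES regex: bracket atoms `[...]`, the
digraphs `Br`/`Cl`, the `>>` separator, `%nn` ring closures, the
organic-subset element letters, and single punctuation. Tokenization is
lossless (concatenation of non-special tokens reproduces the input) and
every atom token is aligned to its (side, atom index) pair, with atoms
numbered 0-based in SMILES order across dot-separated molecules,
reactants and products independently. Center flags are set on atom
tokens only; whether the original line of work also flagged bond tokens
inside the center is not documented anywhere we know of, so the
narrower, better-defined choice was taken. The vocabulary is built from
the training corpus with minimum frequency 1; no sub-token merging.

## Pretraining

Two corruption procedures over condition-free reactions:

* **Masked LM** — every maskable token (everything but BOS/EOS/PAD and
  `>>`) is selected independently with probability 0.15.
* **Masked RCM** — reaction-center atom tokens are selected with
  probability 0.5; all other maskable tokens keep 0.15. Center tokens
  are labeled from the reaction template (the generator's changed-atom
  annotation, or any atom-mapped record via `extract_reaction_center`).

Selected positions follow the standard masked-LM replacement recipe —
80% mask token, 10% random token, 10% kept — with random replacements
drawn from the atom-token inventory so corrupted strings stay
atom-like. The recipe fractions are a design choice; only the selection
probabilities are externally specified.

## Training

AdamW (β = 0.9/0.999, weight decay 0.01) with linear warmup, batches
trimmed to the longest real sequence. The best-validation-accuracy
parameters are retained; optional patience-based early stopping, plus a
stop when validation strict top-1 reaches 1. The "enhanced" fine-tune
expands the training set k-fold (default ×5) with random-rooted SMILES
and shuffled molecule order and trains exactly 2 further epochs at
learning rate 1e-6. All randomness (batch order, dropout, corruption,
initialization) is driven by explicit seeds; on one device two runs
with the same seed are bit-identical.

## Inference and evaluation

Decoding is greedy slot by slot conditioned on the running top-1
prefix; the top-k_p labels per slot are kept and the Cartesian product
of the candidate sets is ranked by the product of per-slot softmax
probabilities (ties break by slot-wise candidate rank, catalyst first).
A full beam over prefixes was deliberately not used: the fixed per-slot
portfolio semantics ("top-1 catalyst, top-3 solvent1, ...") guarantees
exactly ∏k combinations, 15 for the default 1/3/1/5/1 portfolio.

Strict accuracy requires exact equality of all compared labels, `Null`
included. Relaxed accuracy maps solvent/reagent labels to
substitutability categories (user-supplied two-column table; a default
ships for the synthetic vocabulary) and compares categories; catalysts
remain strict and `Null` matches only `Null`. Test sets are stratified
by catalyst presence: Alpha (catalyst = Null) is scored on
solvent1+reagent1 with widths (–,3,–,5,–), Beta (catalyst present) on
catalyst+solvent1+reagent1 with widths (2,3,–,5,–); per-slot accuracies
are reported for all five slots, and empty strata are reported as
absent rather than zero. Temperature quality is the MAE in °C over
records with ground truth.

## Interpretability

* **Cross-attention route.** For a chosen (layer, head, condition slot),
  the cross-attention row is restricted to atom tokens and renormalized
  separately over the reactant and product sides; an atom is active
  when its weight ≥ mean + k·std. The std is the population standard
  deviation and the comparison is inclusive; per-side renormalization
  follows from the sides having different lengths. (Layer, head, k,
  slot) are chosen on a validation set by maximizing mean OS − mean
  FPR, ties to the lexicographically smallest tuple.
* **Overlap metrics.** OS = |active ∩ center| / |center|. The FPR is
  implemented literally as |active Δ center| / |active| (symmetric
  difference), which can exceed 1 when the center dwarfs the active
  set; `fp_mode="strict"` provides the conventional
  |active \ center| / |active| for users who want a true rate.
  Fidelity to the published arithmetic first, sanity second; 0/0 is 0.
* **Self-attention / template route.** A pluggable atom mapper produces
  a reactant→product map: the ground-truth passthrough (synthetic
  data), or a greedy mapper that pairs product to reactant atoms by
  descending encoder self-attention subject to element agreement and a
  one-to-one constraint. The greedy mapper is a deliberate
  simplification of neighborhood-propagation attention mappers and is
  not equivalent to them. The changed-atom core extracted from the map
  is the active set.
* **Combined route.** (threshold rule ∪ top-n atoms by weight) ∪
  template-matched atoms; n is a searched parameter. Center-accuracy
  criteria: "half" (overlap ≥ |center|/2) and "at least 2" (overlap ≥
  min(2, |center|)); the min handles singleton centers, a case the
  criterion's usual statement leaves open.
* **ASM.** All reactant/product molecules are BRICS-fragmented; the
  `target_size` (default 103) most frequent fragments form the library
  (attachment dummies stripped before substructure matching). For each
  fragment hit, S_e = (Σ matched-atom weights)/n_atoms where the atom
  weight is the cross-attention toward the slot's label averaged over
  all heads of all decoder layers, per-side renormalized; a cell is the
  mean of S_e over the fragment's hits under that condition label, and
  unmatched cells are absent (NaN), not zero. Columns index ground-truth
  labels by default (configurable to predicted).

## Synthetic data generator

Eight templates (Suzuki-type biaryl coupling, ketone reduction, ester
reduction, benzylic ether deprotection, Grignard addition to aldehydes,
carbodiimide amide coupling, Williamson ether synthesis, nitro
reduction) instantiate reactants from small substituent libraries,
derive the product by explicit RWMol bond edits, and record the changed
atoms — so `extract_reaction_center` recovers the generator's annotation
exactly, which the suite asserts at 100%. Condition labels are a
deterministic function of (template, EWG-substituent flag): Bayes top-1
accuracy on noise-free data is 1 by construction, which is what makes
the learnability check meaningful. Label noise resamples each label
independently within its slot with the configured probability.
Temperatures are Gaussian per rule, rejection-truncated to [−100, 300]
°C — bounds wide enough to cover common organic chemistry. The per-rule
means (80 °C coupling, 60 °C etherification, 50 °C hydrogenation, 25 °C
ambient reactions, 0 °C hydride/organometallic chemistry) and sd 2–5 °C
are what a practitioner would call typical for these transformations.

What the generator does **not** emulate: stereochemistry, yields,
reagent stoichiometry or concentrations, label sparsity/long-tail
distributions of patent data, atom-mapping errors, and drawing-style
variance beyond SMILES surface forms. Passing tests therefore
demonstrate that the machinery is correct and that the model can learn
structure-conditioned rules — not that real-data accuracies of any
published system are reproduced, which would require GPU-scale training
on hundreds of thousands of patent reactions.

## Numerical choices and problem sizes

* Admissibility masking uses −10⁹ additive bias: softmax mass outside
  the slot underflows to exactly zero.
* Attention softmax rows normalize over non-PAD keys to 1 (±1e-5 in
  float32); PAD keys receive zero mass.
* The loss oracle checks hold to 1e-9 because `compute_loss` computes in
  the dtype of its inputs (float64 for hand-built arrays).
* Default test-time problem sizes were chosen to exercise every code
  path at desk scale: 200–500 generated reactions, width-64 models,
  ≤40 epochs; the learnability check reaches validation strict top-1 of
  1.0 in ~26 epochs (~90 s on one CPU).
* Gaussian truncation uses rejection sampling (means are far from the
  bounds, so the loop is effectively a single draw).
* Records with more than five role-assignable conditions simply do not
  arise from the generator; the CSV schema enforces the 5-slot layout
  and anything outside it is a schema error.

## Known limitations

* The NumPy network core is single-threaded and desk-scale by design;
  it is not a route to training on full patent corpora.
* The greedy attention mapper degrades on reactions with many
  same-element atoms and no trained attention structure; the
  ground-truth passthrough exists precisely so interpretability logic
  can be validated independently of mapper quality.
* Relaxed evaluation is only as good as the supplied category table;
  the bundled table covers the synthetic vocabulary only.
* BRICS fragments with their dummies stripped match slightly more
  contexts than the fragment's original environment; counts and ASM
  cells inherit that looseness.
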