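# Methods

## The problem and the model

Given a molecule's SMILES string, the package predicts a scalar
physicochemical property (aqueous solubility logS, partition coefficient
logP, distribution coefficient logD, or any other real-valued target). The
model — BCSA, a **B**idirectional LSTM with **C**hannel and **S**patial
**A**ttention — treats the SMILES as a token sequence and is trained fully
end to end:

1. **Tokenization.** The SMILES is split by a regular expression into
   chemically meaningful tokens: bracket atom expressions (`[nH]`, `[O-]`),
   two-letter halogens (`Cl`, `Br`), single-atom symbols (aromatic
   lowercase included), bond/branch/dot/charge punctuation, ring-bond
   digits and `%NN` two-digit ring labels. Tokens map through a
   frequency-ordered vocabulary (pad = 0, unk = 1) to integer vectors that
   are truncated at `smiles_max_len` and right-padded.

2. **Embedding.** A trainable lookup table maps each token index to an
   `embed_dim`-vector (default: equal to `hidden_size`). There is no
   separate pre-training stage; the embedding is learned jointly with the
   rest of the network.

3. **Bidirectional recurrent encoding.** `num_layers` stacked BiLSTM
   layers process the embedded sequence. Intermediate layers pass the
   concatenated forward/backward states to the next layer (with dropout
   between layers); at the top layer the two directional state sequences
   are fused position-wise by learned linear maps,
   `h_t = We h_t<- + Wv h_t->`, a weighted *sum* rather than a
   concatenation, giving the state sequence `C` of shape
   (positions x hidden_size). The full per-position sequence is kept — the
   spatial attention below is undefined on a single final state.

4. **Parallel attention fused by one sigmoid.** Channel attention pools
   `C` over positions by average and by maximum and passes both
   descriptors through one shared bottleneck MLP
   (`hidden -> hidden/channel_reduction -> hidden`, ReLU between, no
   biases), summing the two outputs into `Mc` (one value per channel).
   Spatial attention applies two 1-D convolutions along the position axis
   (`hidden -> 16` channels, kernel 7, ReLU, then `16 -> 1`, kernel 7;
   symmetric zero padding 3 preserves length), giving `Ms` (one value per
   position). The two maps are broadcast, summed, and squashed by a
   *single* sigmoid: `C' = sigma(Mc + Ms) (x) C`. Note this differs from
   the original sequential CBAM formulation, where each sub-module has its
   own sigmoid and the gates are applied one after another; here the
   modules run in parallel and share one gate, as the fusion equation
   states.

5. **Pooling and head.** `C'` is average-pooled over positions into `O`
   (length `hidden_size`), then passed through two dense layers
   (`hidden -> mlp_hidden_size -> 1`, ReLU between, dropout before each)
   to the scalar prediction.

No padding mask is applied anywhere: pad positions carry the pad-token
embedding and participate in the recurrence, the attention maps and the
average pooling. This is deliberate — the architecture is defined without
masking — and it means the effective pooling denominator is always
`smiles_max_len`. A masked variant would be a different model and is out
of scope.

## Data augmentation and averaged prediction

A molecule admits many valid SMILES (CCO, OCC, C(O)C are all ethanol).
`enumerate_smiles` renumbers the atoms with a seeded random permutation and
writes a non-canonical SMILES from the new order; every variant
canonicalizes back to the parent (this is checked with the RDKit canonical
form as the identity oracle). Up to `10*k` orderings are attempted to
collect `k` distinct strings; simple molecules yield fewer. The source
string itself is always the first variant, so `k = 1` reproduces the
un-augmented dataset exactly — the whole pipeline degenerates to the plain
one, record for record and loss for loss.

Augmentation is applied *after* the train/validation/test split,
independently per split, so no molecule leaks across splits. At prediction
time the model's outputs over a molecule's enumerants are averaged
(test-time augmentation); the across-seed variance of the resulting metric
is measurably smaller than that of a single randomly drawn SMILES per
molecule, which is the practical payoff of enumeration at evaluation time.

## Training and hyperparameter search

Training minimizes mean squared error over shuffled mini-batches with Adam
(beta1 0.9, beta2 0.999, eps 1e-8 — the optimizer is not prescribed by the
architecture; Adam is the field default and the learning rate comes from
the configuration). After every epoch the molecule-averaged validation R2
is computed; the best-R2 parameters are the checkpoint, and training stops
early when the monitor fails to improve for `patience` epochs. A
non-finite loss aborts with a diagnostic rather than silently continuing.
No learning-rate schedule is used. An `init_model` argument allows
resuming from a checkpoint for a few additional fine-tuning epochs.

Hyperparameter search minimizes the negated coefficient of determination,
`-(1 - SS_res/SS_tot)`, on the validation split. The search space is:
batch size {512, 1024}; vocabulary size {120, 150}; maximum SMILES length
{150, 200}; hidden size {16, 32, 64}; 3–5 stacked layers; dropout
[0, 0.6]; head width {32, 64}; learning rate [0.001, 0.01], sampled
log-uniformly (the standard parameterization for learning rates). The
Tree-structured Parzen Estimator here is a compact factorized
implementation: 5 random startup trials, then completed trials are split
at the 25% objective quantile into good/bad sets, each dimension is
modelled by a Parzen density over each set (Laplace-smoothed categorical
for discrete domains, Gaussian mixtures with a width-scaled bandwidth and
a uniform floor for continuous ones), and 24 candidates drawn from the
good density are scored by the good/bad log-density ratio. Diverged trials
are recorded with an infinite objective and skipped.

The reference full-scale protocol is 100 trials of 60 epochs
(patience 20) followed by 400-epoch final training; everything in this
repository runs the same machinery at reduced trial and epoch counts.

## The synthetic data generator

The generator emulates a small-molecule property-regression dataset at
desk scale. Molecules are assembled from 2–8 grammar fragments — alkyl
units (C, CC, CCC), an ether/hydroxyl oxygen, a benzene ring, and up to
two terminal halogens (Cl, F) — concatenated into a valid SMILES, validated
with RDKit and de-duplicated by canonical form. The noise-free target is
the exact dot product of fragment counts with fixed coefficients
(aliphatic C +0.5, O −1.0, benzene ring +2.0, Cl +0.7, F +0.25 — loose
echoes of group-contribution hydrophobicity increments), plus optional
Gaussian noise. Because every coefficient is additive in atoms/rings, any
two generation paths to the same molecule give the same target, so the
structure→property map is a well-defined deterministic function.

What this emulates: a learnable, additive structure-property relation with
controllable noise, short drug-like token vocabularies, and molecules with
many SMILES rewritings. What it does not emulate: stereochemistry,
charged/bracket-atom chemistry, tautomers and ionization states,
heavy-tailed property distributions, and activity cliffs. Passing the
learning tests therefore demonstrates that the pipeline can extract an
additive signal from token sequences under augmentation — not that it
reproduces benchmark accuracy on experimental solubility data, which
requires the original datasets and full-scale training.

## Numerical choices

- All arithmetic is float64 NumPy; gradients of every layer are analytic
  and verified against central finite differences (relative error ~1e-5).
- Parameter initialization is uniform `U(-1/sqrt(fan), 1/sqrt(fan))`
  per tensor (the common recurrent-network convention); initial hidden and
  cell states are zero.
- The sigmoid is evaluated piecewise for numerical stability; gate values
  are therefore strictly inside (0, 1).
- Max-pool backward routes gradient to the argmax position (first index on
  ties, the NumPy convention).
- Dropout is inverted dropout, active only in training mode.
- The channel-attention bottleneck is `max(1, hidden/channel_reduction)`
  with the reduction defaulting to 16, so small hidden sizes degrade to a
  width-1 bottleneck instead of failing.
- Vocabulary construction breaks frequency ties lexicographically, making
  the token->index map bit-reproducible across runs.
- The 8:1:1 split takes floor(0.8 N) / floor(0.1 N) / remainder after a
  seeded shuffle.

## Desk-scale study conditions

The shipped tests and the acceptance script run three studies, sized to
minutes on one CPU:

- **Memorization**: 32 noise-free synthetic molecules, hidden size 64, one
  BiLSTM layer, no dropout, learning rate 5e-3, up to 300 epochs; training
  MSE drops below 0.01.
- **Scaled learning**: 2,000 synthetic molecules with noise 0.1, split
  8:1:1, 10x enumeration augmentation of train and validation, hidden
  size 32, one layer, dropout 0.1, batch 512, learning rate 3e-3,
  12 epochs, max token length 64 (the grammar's upper bound). Test-set R2
  with 10-enumerant averaged prediction exceeds 0.99, and across five
  enumeration seeds the variance of the averaged-prediction R2 is below
  that of single-SMILES prediction.
- **Reduced search**: 10 TPE trials of 5 epochs (patience 3) on 300
  molecules over the full published space; the returned configuration lies
  inside every domain and the trial sequence is seed-reproducible.

## Known limitations

- Pure-NumPy training is CPU-bound and orders of magnitude slower than a
  GPU framework; full-scale runs (10^5+ augmented records, 400 epochs) are
  out of desk reach, which is why the studies above are scaled down.
- No padding mask (see above): predictions depend mildly on
  `smiles_max_len` because pooling averages over pad positions.
- Spearman correlation is reported as NaN when predictions are constant
  (rank correlation is undefined there).
- The enumeration attempt budget (10k orderings per k requested) can
  undercount the distinct variants of highly symmetric molecules.
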