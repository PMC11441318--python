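# Methods

## Objective and reductions

Pre-training jointly minimizes a masked-language-model (MLM) term and a
distillation term, mixed by `alpha` (default 0.2, i.e. distillation
carries more weight):

    L = alpha * L_MLM + (1 - alpha) * L_Distill

Both component losses are printed in the literature as sums over
positions; we use **means over scored positions** instead.  An
unreduced sum would make `L` grow with sequence and batch length and
silently re-weight the `alpha` trade-off; per-position means keep
`alpha` meaningful across corpora.

* `L_MLM` scores **masked positions only** by default (`scored="all"`
  is selectable).  Masked positions are the standard MLM reading: the
  objective is to predict the hidden residue from context, and scoring
  unmasked positions would mostly reward copying.
* `L_Distill` scores **all non-pad positions** by default
  (`masked_only` selectable), is the KL divergence taken
  **from teacher to student** — `KL(p_T || p_S)` — and uses the
  `0·log 0 := 0` convention.  A student zero under teacher support
  returns `+inf` and is flagged in the loss report; softmax outputs
  make this unreachable in practice.
* Distillation compares output **distributions**; an embedding-space
  variant (MSE through a learned linear projection onto the teacher's
  hidden width) is available as `distill_space="embedding"` for users
  who prefer matching hidden vectors.  No temperature parameter is
  used (fixed at 1).

## Student encoder

An encoder-only pre-norm transformer in the T5 family: RMS
normalization without biases, bias-free linear maps, ReLU feed-forward
blocks, learned bucketed relative-position attention biases shared
across layers, and input/output embeddings tied, so per-position
distributions are a softmax over similarities to the 23 residue
embeddings.  Defaults: 6 layers, hidden 256, 4 heads, feed-forward 512,
maximum input length 1000 (longer sequences are truncated to their
first 1000 residues, with the pre-truncation length retained).  Test
and experiment configurations use a 2-layer, hidden-32 "tiny" student;
nothing in the code assumes a particular size.  The student's hidden
width is independent of any teacher's.

The encoder, reverse-mode automatic differentiation, and the AdamW
optimizer (decoupled weight decay 0.01, betas 0.9/0.999) are
implemented directly over NumPy in `protdistill.autodiff` in float64.
This keeps the whole training path dependency-light, bitwise
reproducible on a single thread, and cheap to verify: finite-difference
gradient checks against the autodiff gradients are part of the test
suite (relative tolerance 1e-4 at epsilon 1e-6).

## Masking

Default masking selects each position independently with probability
0.15 and replaces it with the mask token; per-sequence masked counts
are Binomial(N, 0.15) by construction and the suite verifies this with
a chi-square goodness-of-fit test.  A span scheme (contiguous runs,
geometric lengths of mean 3, fraction matched to the rate through a
per-sequence budget) and the BERT-style 80/10/10
replace/randomize/keep convention are available behind flags, both off
by default — the objective only requires predicting originals at
masked positions, so plain replacement is the minimal faithful choice.

## Offline teacher store

Teachers are consumed exclusively through precomputed outputs: an HDF5
container keyed `teacher_id/sequence_id` holding per-position
distributions (float32; optional per-position embeddings), with the
vocabulary recorded in the file manifest and row-stochasticity checked
at write time (tolerance 1e-6).  Synthetic teachers — `oracle` /
`noisy_oracle` (probability `q` on the true residue, remainder
uniform), `uniform`, and `motif` (oracle-like only inside occurrences
of declared motif strings, uniform elsewhere) — are pure functions of
their inputs and stand in for large pre-trained models in every test.

## Teacher-selection policy

Each teacher k is scored by `sigma(w_k·f_k + b_k)` where `f_k` is the
pooled student hidden state concatenated with that teacher's mean
prediction entropy, mean maximum probability, and current distillation
loss on the instance; the three summary columns are centred across
teachers, since what identifies the right teacher is how it compares
to the alternatives, not the shared level.  Scores are normalized to a
categorical, clipped to an exploration floor during training
(`exploration_floor`, default 0.10 — pilots showed the conservative
0.02 floor lets an early lead starve the other teacher before the
per-instance signal is learned), and one teacher is sampled per
instance.

The policy is updated by REINFORCE: the gradient of the log normalized
weight of the chosen teacher, scaled by the learning rate and the
baseline-centred reward; the baseline is an exponential moving average
(decay 0.9), and rewards are standardized by a running scale estimate
so `policy_lr` (default 0.1) is dimensionless.

**Reward definition.**  The default reward is the decrease, across the
optimizer step, of the *instance's own masked-LM loss*
(`reward="instance_mlm"`).  Two alternatives were evaluated and kept
as options:

* `instance_combined` (decrease of the instance's combined loss) is
  self-referential: stepping on any teacher's own distillation loss
  reduces it, so once the student resembles one teacher, the *other*
  teacher's loss offers the larger improvement and the policy flips to
  it — pilots showed exactly this catastrophic oscillation.
* `holdout_mlm` (decrease of the masked-LM loss on a small fixed
  held-out batch) is stable but weak: a freshly initialized student is
  worse than the uniform predictor, so early on even a know-nothing
  teacher "helps", and the per-step signal is a fraction of its noise.

The instance-MLM reward is per-instance attributable and task-aligned:
a teacher earns negative reward as soon as its supervision moves the
student away from predicting this instance's residues.

## Pre-training loop

Defaults mirror the standard recipe: 10 epochs, batch size 16, AdamW
at 3e-4 with linear warm-up over the first 10% of steps and linear
decay to zero afterwards (the decay segment is this package's choice;
only the warm-up ratio is standard), masking probability 0.15.
Batches group similar lengths and pad; pad positions are excluded from
every mean.  A preflight check fails before the first step if any
(teacher, sequence) record is missing.  Full float64 precision is the
only tested path; there is no mixed-precision mode.  Checkpoints hold
parameters, optimizer moments, policy state, and a vocabulary
fingerprint (loading refuses a mismatched vocabulary); training resumed
from an epoch checkpoint reproduces the uninterrupted run bitwise,
because all per-epoch randomness is derived from (seed, epoch, batch)
rather than a mutable global stream.

## Downstream pipeline

Per-protein embeddings are the mean of final hidden states over
non-pad positions.  Heads are two-layer perceptrons (one hidden layer,
default width 256, Adam-family training with early stopping on a
training-loss plateau; scikit-learn's `MLPClassifier`/`MLPRegressor`
stand behind this surface).  Metrics: accuracy for binary/multi-class,
micro-averaged F1 for multi-label, Spearman correlation for
regression — field-standard choices for these task families, and
configurable.  Multi-label training uses independent per-label binary
cross-entropy.  Cross-validation is a seeded shuffled k-fold (default
k = 10) with fold sizes differing by at most one; the split invariant
(no test id in its fold's training set) is asserted on every run.

## Synthetic corpora: what they emulate, and what they do not

`generate_corpus` draws background residues i.i.d. uniformly over the
20 canonical amino acids (a frequency table can be supplied) and plants
one class-defining motif per sequence at a random position (balanced
class counts; multi-label variants insert several motifs at
non-overlapping positions; regression targets are motif copy counts
plus Gaussian noise, default sd 0.1).  The default corpus is 200
sequences of 40–80 residues.  Motif sets used in the experiments are
chosen letter-disjoint so the classification signal is unambiguous; a
bag-of-3-mers logistic baseline verifies each generated task is
solvable before any embedding is tested.

This generator emulates the *structure* of protein benchmark tasks —
variable lengths, localized class-defining signal, four label types —
but not their statistics: real proteins have non-uniform residue
composition, long-range structure, homology between train and test
sequences, and label noise.  Passing the suite demonstrates that the
machinery (losses, selection, training, embedding, evaluation) works
and that distillation transfers a teacher's sequence-functional signal
into pooled embeddings; it does not certify accuracy on any real
benchmark.

## Desk-scale experiment design (`protdistill.experiments`)

* **Distillation recovery** — one noisy-oracle teacher (q = 0.9),
  alpha = 0, 200 training / 20 held-out sequences (30–60 aa), up to
  2000 steps at 3e-4.  Held-out mean per-position KL falls below 0.05:
  the student reproduces the teacher's distribution family almost
  exactly on unseen sequences.
* **Policy convergence** — noisy-oracle (q = 0.9) vs uniform teacher,
  120 sequences, batch size 1 (so each reward is attributable to a
  single selection), 1000 policy steps.  The informative teacher's
  mean selection weight exceeds 0.8 (typically ~0.95).
* **Multi-teacher ablation** — two classes with letter-disjoint 8-mer
  motifs; teacher A is confident only inside class-A motif windows,
  teacher B only inside class-B windows; a combined oracle covers
  both.  Multi-teacher training attains a validation distillation loss
  against the combined oracle no worse than either single-teacher run:
  each single-teacher student only ever learns half the signal.
* **End-to-end recovery** — four letter-disjoint 5-mer motif classes,
  teacher confident only inside motif windows (q = 0.95), 3000 steps
  at 1e-3.  Matching a context-dependent teacher forces the student to
  *recognize* motifs rather than copy residues, so its mean-pooled
  embeddings support ≥0.9 (typically 1.0) 10-fold CV accuracy, while
  an untrained student of identical size stays near the diluted
  composition ceiling (~0.5).  The higher learning rate is used here
  because the motif-recognition function emerges slowly at 3e-4 on so
  small a model; 1e-3 reaches the same solution in a third of the
  steps.

## Numerical choices and degenerate inputs

* All training math is float64; stores hold float32 (teacher outputs
  do not need more, and it halves file size).
* Row-stochasticity tolerances: 1e-6 at store boundaries and on
  student outputs.
* Zero masked positions in a batch make the MLM loss undefined and
  raise; the training loop skips such batches (vanishingly rare at
  15%).
* A non-finite total loss aborts training, restoring and saving the
  last good parameters.
* Sampling uses inverse-CDF draws (one uniform per call) so streams
  are reproducible and cheap to reason about.
* LR schedule edge cases: warm-up of zero steps starts at the base
  rate; `step = total_steps` returns exactly zero.

## Known limitations

* No real-teacher adapters are bundled; wrapping an external model
  into a store is left to the user (the store format is the contract).
* The policy is linear-logistic on fixed features; it can prefer
  teachers per instance but cannot represent deeply non-linear
  selection rules.
* Training is single-threaded CPU; the design favors verifiability
  over throughput, and corpus sizes beyond a few thousand short
  sequences become slow.
* The six-layer default encoder is far smaller than production protein
  language models; the architecture is faithful, the scale is not.
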