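# protdistill

Multi-teacher knowledge distillation for compact protein sequence
embedding models, at a scale that runs on one CPU core.

## The problem

Protein language models turn amino-acid sequences into numerical vectors
that feed downstream predictors (subcellular localization, gene-ontology
terms, stability, solubility, ...).  The best such models have hundreds
of millions of parameters and are expensive to run over large sequence
collections.  Knowledge distillation trains a small *student* encoder to
reproduce the per-position outputs of one or more large, fixed *teacher*
models, keeping most of the representational quality at a fraction of
the cost.  When several teachers are available they rarely agree on
which proteins they represent well, so this package also learns a
per-instance *selection policy* that decides, for every training
example, which teacher should supervise it.

## The model

The student is a small T5-style encoder-only transformer (RMS norm,
relative-position attention biases, tied input/output embeddings; six
layers by default).  Pre-training minimizes

    L = α · L_MLM + (1 − α) · L_Distill,        α = 0.2 by default

where, over a sequence of length N with vocabulary size V = 23
(20 canonical residues + unknown/mask/pad),

* `L_MLM  = − mean over masked positions i of log p_S(x_i = y_i)` —
  masked-language modeling: 15% of positions are replaced by a mask
  token and the student predicts the original residue `y_i`;
* `L_Distill = mean over positions i of D_KL( p_T(x_i) ‖ p_S(x_i) )` —
  the Kullback–Leibler divergence from the teacher's per-position
  output distribution to the student's.

Teachers never run during training: their outputs are precomputed into
an HDF5 *teacher store* keyed `teacher_id/sequence_id` (offline
distillation).  With K > 1 teachers, a logistic policy scores each
teacher from instance features (pooled student hidden state, teacher
prediction entropy and confidence, current distillation loss), one
teacher is sampled per instance, and the policy is updated by REINFORCE
with the improvement of the instance's masked-LM loss as the reward.

After pre-training, a per-protein embedding is the global average pool
of the encoder's hidden states; downstream tasks (binary, multi-class,
multi-label, regression) fine-tune a two-layer MLP head on frozen
embeddings, evaluated by 10-fold cross-validation.

Because real pre-trained teachers are deliberately out of scope,
synthetic teachers with controllable quality (oracle, noisy oracle,
uniform, motif-restricted) and a planted-motif corpus generator make
every code path testable without downloads.

## Worked example

```python
from protdistill import (SyntheticSpec, generate_corpus, build_test_store,
                         tokenize, StudentConfig, PretrainConfig,
                         pretrain, embed, cross_validate)

# 1. simulate a small planted-motif corpus (four classes, one 5-mer motif each)
spec = SyntheticSpec(n_sequences=200, min_length=40, max_length=80,
                     motifs=("ACDEF", "GHIKL", "MNPQR", "STVWY"), seed=51)
records, task = generate_corpus(spec)

# 2. materialize a synthetic teacher: confident only inside motif windows
store = build_test_store(records, [("motif", {"q": 0.95, "teacher_id": "T",
                                              "motifs": list(spec.motifs)})])

# 3. distillation pre-training of a tiny student encoder
corpus = [tokenize(r, store.vocab, 200) for r in records]
student = StudentConfig(num_layers=2, hidden_dim=32, num_heads=4,
                        feedforward_dim=64, vocab_size=23, max_length=200)
cfg = PretrainConfig(epochs=400, batch_size=16, base_lr=1e-3,
                     max_steps=3000, seed=51)
model, _, log = pretrain(corpus, store, cfg, student_config=student)
print(f"final objective: L={log.steps[-1].l_total:.4f} "
      f"(L_MLM={log.steps[-1].l_mlm:.4f}, L_Distill={log.steps[-1].l_distill:.4f})")

# 4. per-protein embeddings (global average pooling) and 10-fold CV
matrix = embed(corpus, model)
result = cross_validate(task, matrix, k=10, seed=51)
print(f"10-fold CV {result.metric_name}: mean={result.mean:.3f}")
```

Output (about three minutes on one core):

```
final objective: L=0.5988 (L_MLM=2.7867, L_Distill=0.0518)
10-fold CV accuracy: mean=1.000
```

The distillation term has collapsed (0.05 nats per position: the student
reproduces the teacher almost exactly), and because this teacher is only
confident *inside* motif windows, matching it forces the student to
recognize motifs in context — so its mean-pooled embeddings separate the
four motif classes perfectly.  The same model before training scores
about 0.52.  The masked-LM term stays higher: with a uniform random
background, masked background residues are inherently unpredictable.

The same pipeline is available from the shell:

```sh
protdistill simulate --spec spec.yaml --out sim/
protdistill teacher-export --fasta sim/corpus.fasta --out teachers.h5 --kind noisy_oracle --q 0.9
protdistill pretrain --fasta sim/corpus.fasta --store teachers.h5 --config train.yaml --out run/
protdistill embed --fasta sim/corpus.fasta --checkpoint run/final.npz --out emb.tsv
protdistill finetune --embeddings emb.tsv --labels sim/labels.tsv --task multiclass --out head.pkl
protdistill evaluate --embeddings emb.tsv --labels sim/labels.tsv --task multiclass --k 10
```

Every run writes its resolved configuration next to its outputs, and
identical seeds give bitwise-identical checkpoints.

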