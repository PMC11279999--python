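# Methods

## Problem and model

Spontaneous adverse-event reports (FAERS/JADER-style) list one patient, one
or more co-administered drugs, and one or more adverse drug reaction (ADR)
terms at MedDRA preferred-term (PT) level; regulators flag a subset of the
drugs as *suspect* causes. `adesig` reproduces a multi-modal classifier of
that suspect label. One training instance is a (report, drug) pair; its
input is six concatenated feature vectors:

| channel | content | width | trainable |
|---|---|---|---|
| Xpd | z-scored age and weight, sex code (0 = male, 1 = female) | 3 | no |
| Xdf | MACCS substructure keys of the drug (RDKit, 166 keys + padding bit) | 167 | no |
| Xdg | graph isomorphism network (GIN) over the heavy-atom graph | `gin_hidden_dim` | yes |
| Xds | Transformer encoder over the SMILES token sequence, masked mean pool | `seq_embed_dim` | yes |
| Xas | system-organ-class (SOC) one-hot: slot *i* set iff some ADR maps to SOC *i* | 27 | no |
| Xap | per-PT trainable embeddings, multi-head self-attention over the term set, average pool | `adr_embed_dim` | yes |

The fused vector passes through a three-layer MLP — two blocks of
affine → batch-norm → ReLU → dropout, one affine → batch-norm → ReLU
block, then a final affine map to one logit; the sigmoid of the logit is
the suspect probability.

GIN layers update `h_v ← MLP((1 + ε) h_v + Σ_{u∈N(v)} (h_u + e_uv))` with a
learnable ε per layer and bond type/direction embeddings `e_uv` added to
neighbour messages; readout is a sum (mean available) over node states.
Node initialisation sums embeddings of element and chirality tag, plus (by
default) formal charge, aromaticity and degree — a bare element+chirality
node set under-determines common GIN practice, so the extras are on by
default with a `minimal_atom_features` switch for the leaner variant.

The ADR attention treats the term list as an unordered set: no positional
encoding, and the "adaptive average pooling" is the mean over the term
axis, so output width equals the embedding width and duplicated terms add
no information. The sequence channel, by contrast, keeps sinusoidal
positional encodings and encodes the SMILES *as written* (fingerprint and
graph channels canonicalise first, so different spellings of one molecule
agree there).

## Training

Loss is binary cross-entropy on the logit; the optimiser is Adam with
decoupled L2 weight decay and an optional linear learning-rate decay
(`final_lr_fraction`, default constant). Demographic standardisation
statistics, the SMILES vocabulary and the PT embedding table are fit on the
training split only and persist inside the checkpoint, so held-out data
never leaks into preprocessing. Batch normalisation in a narrow head is
unstable below ~8 instances, so `batch_size ≥ 8` is enforced, remainder
mini-batches smaller than 8 are skipped, and layer normalisation is a
config alternative (`norm="layer"`). Drugs are de-duplicated by canonical
SMILES inside each mini-batch so the structure encoders run once per unique
molecule.

Defaults (`SDAJMConfig`): lr 1e-3, weight decay 1e-5, batch 64, 10 epochs,
GIN 2×64, sequence encoder 1 layer × 32 dims, ADR embeddings 32, head 64,
dropout 0.1 (GIN) / 0.2 (head), 4 attention heads shared by both attention
blocks. The published main text gives no sizes, loss, or optimiser; these
are conventional choices, exposed in the config, not quoted values.

Hyperparameter search (`optimize_hyperparameters`) is sequential
model-based: random sampling for budgets below 10, otherwise half the
budget random followed by expected-improvement proposals under a
Gaussian-process surrogate (Matérn 5/2, scikit-learn). Failed trials score
NaN and the search continues.

## Evaluation protocols

`compute_metrics` derives accuracy, precision, recall and F1 from the
thresholded confusion counts (threshold 0.5 by default; the source work
states none). ROC-AUC uses the Mann-Whitney rank statistic with average
ranks for ties; PRC-AUC is step-wise average precision with tied scores
grouped at one threshold. A zero denominator yields an explicit `None`
("undefined") plus a warning — never a silent 0 that would deflate or
inflate fold averages. Fold means are unweighted.

Cross-validation offers random 10-fold over reports and 10-fold *by drug*:
the drug set is partitioned, every (report, drug) instance follows its
drug, and reports containing both train- and test-fold drugs are split at
the instance level. The by-drug protocol evaluates generalisation to
structurally unseen drugs and is expected to score lower than the random
protocol, which is the ordering reported for the original FAERS experiment
and the ordering our planted-data experiment checks (direction only).

Signal detection scores one held-out drug against candidate ADR terms, one
single-ADR pseudo-record per candidate (candidate pairs are scored
individually), with the demographic profile defaulting to the training
mean, i.e. Xpd = [0, 0, sex]. The flagging threshold is exposed — the
source work never states the one behind its reported detection rate — and
a training-manifest check refuses drugs seen at training time unless
overridden.

Benchmark mode (`run_benchmark`) feeds only the three drug channels to the
head, splits 8:1:1 randomly or by Bemis–Murcko scaffold (largest scaffold
groups filled into train first, then val, then test, so no scaffold spans
subsets), trains over several seeds, and reports macro ROC-AUC (or
PRC-AUC) over tasks with per-task missing-label masking, or RMSE for
regression with per-task target standardisation.

## Synthetic data

MedDRA is licensed and FAERS is not redistributable, so every experiment
runs on generated data with planted ground truth. Molecules are assembled
from a fragment grammar (alkyl chains, benzene, pyridine, amide, halogen
and carboxylic-acid caps) guaranteeing chemical validity; the marker
substructure defaults to a carboxylic-acid group — common enough to split
any pool, specific enough for the fingerprint and graph channels. The PT
vocabulary (`pt_0000`…) maps onto up to 27 synthetic SOC indices with every
used SOC covered.

The planted rule: a (report, drug) instance is suspect with probability
p1 = 0.9 when the drug carries the marker AND the report lists at least one
target-SOC ADR, else p0 = 0.1. Defaults — 2000 reports, 40 drugs, marker
fraction 0.5, target SOC present in 80% of reports, 1–3 drugs and 1–5 ADRs
per report, age 55 ± 18 y, weight 72 ± 16 kg, balanced sex — put roughly
40% of instances in the high-risk stratum. Under those rates the
Bayes-optimal ROC-AUC of the generating rule is ≈ 0.894 (the label itself
is Bernoulli noise around the planted probabilities), so the ≥ 0.85
recovery check asks the classifier to come within ~0.05 of the ceiling,
and a label-shuffled control must fall back to chance. Label noise is a
symmetric Bernoulli flip, emulating reports where a co-medicated drug with
a known association is nevertheless not the suspect.

What the generator does *not* emulate: reporting delays and underreporting
biases, realistic pharmacology of the molecules, correlated ADR
co-occurrence structure, multi-ingredient products (one SMILES per drug
entry is assumed). Passing these tests therefore demonstrates that the
pipeline can recover a structure-conditional association of this kind at
these sample sizes — not FAERS-scale performance.

## Numerical choices and problem sizes

The trainable encoders run on a small reverse-mode autodiff engine over
float64 NumPy arrays (`adesig/_nn.py`); no GPU framework is used. Masked
softmax adds 1e-12 to the normaliser; layer/batch norm use a 1e-5 variance
floor; BCE clamps probabilities by 1e-12. Checkpoints are a single JSON
file — Python's float repr round-trips exactly, so save→load preserves
predictions bit-for-bit.

Desk-scale experiments (tests and `scripts/acceptance.py`) use a reduced
model — GIN 2×16, sequence 1×16, ADR 16, head 32, batch 256, 8 epochs,
lr 3e-3 — which reaches ≈ 0.887 mean random-split CV ROC-AUC on the
default generator (ceiling ≈ 0.894). The acceptance script runs the CV
battery at 2 generator seeds and the signal-ranking experiment at 3; the
test suite uses 5 of each. Sizes were chosen so a full run completes on
one CPU core in minutes.

## Known limitations

* The published appendix (layer counts, pooling target, optimiser,
  training schedule) was unavailable; all such values are conventions
  exposed in the config.
* Whether ADR attention should operate within SOC groups before pooling is
  ambiguous in the source description; the joint-set reading is
  implemented.
* `optimize_hyperparameters` is a generic SMBO loop, not a re-implementation
  of any specific Bayesian-optimisation package.
* The fragment grammar produces small, synthetically convenient molecules;
  MACCS keys and scaffold diversity are correspondingly limited.
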