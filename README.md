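# adesig

Suspect-drug classification for adverse-drug-event (ADE) reports.

A spontaneous adverse-event report (as collected by FAERS, JADER and
similar pharmacovigilance systems) lists one patient, several
co-administered drugs, and a set of adverse drug reaction (ADR) terms;
regulators mark some of the drugs as *suspect* causes of the event.
`adesig` implements a multi-modal classifier of that per-drug suspect
label, together with its evaluation protocols and a synthetic data
generator, for researchers in pharmacovigilance and cheminformatics who
want to study or extend this class of model without access to FAERS or the
licensed MedDRA dictionary.

## The model

One instance is a (report, drug) pair. Six feature vectors are
concatenated and fed to a three-layer MLP (batch-norm + ReLU, dropout
after the first two activations, final affine map to a single logit):

* **Xpd** — demographics: z-scored age and weight, sex coded 0/1 (width 3);
* **Xdf** — the drug's 167-bit MACCS substructure fingerprint;
* **Xdg** — a graph isomorphism network (GIN) embedding of the drug's
  heavy-atom graph, `h_v ← MLP((1+ε)h_v + Σ_{u∈N(v)}(h_u + e_uv))` with
  bond-type/direction edge embeddings and sum readout;
* **Xds** — a Transformer encoding of the SMILES token sequence
  (masked mean over positions);
* **Xas** — a 27-slot system-organ-class (SOC) one-hot: slot *i* is set
  iff some ADR in the report maps to SOC *i*;
* **Xap** — trainable per-PT embeddings attended over as an unordered set
  and average-pooled.

Training minimises binary cross-entropy with Adam. Around the classifier
the package provides random and by-drug 10-fold cross-validation, ADR
signal detection for drugs held out of training, a molecular-property
benchmark mode (8:1:1 random or Bemis–Murcko scaffold splits, ROC-AUC /
PRC-AUC / RMSE), sequential model-based hyperparameter search, and a
synthetic ADE generator whose planted causal rule — suspect with
probability 0.9 when the drug carries a marker substructure *and* the
report contains a target-SOC ADR, 0.1 otherwise — makes every stage
testable with known ground truth. See `docs/methods.md` for the full
model description and design rationale.

## Worked example

```python
import numpy as np
from adesig import (SyntheticConfig, generate_ade_records, build_vocabulary,
                    compute_metrics)
from adesig.model import SDAJMConfig, build_model, train

cfg = SyntheticConfig(n_records=400, seed=0)
records, soc_map, truth = generate_ade_records(cfg)
print(f"{len(records)} reports, {sum(len(r.drugs) for r in records)} (report, drug) instances")

mcfg = SDAJMConfig(epochs=8, learning_rate=3e-3, batch_size=256,
                   gin_hidden_dim=16, seq_embed_dim=16, seq_ff_dim=32,
                   adr_embed_dim=16, head_hidden_dim=32, n_heads=2, max_len=64)
fit, hold = records[:320], records[320:]
vocab = build_vocabulary(sorted({d.smiles for r in fit for d in r.drugs}), max_len=64)
pts = sorted({a.pt_label for r in fit for a in r.adrs})
model = build_model(mcfg, vocab, soc_map, pts)
train(model, fit, mcfg)
print(f"final training loss: {model.training_log[-1]['loss']:.3f}")

scores = model.predict_scores(hold)
labels = np.array([d.suspect for r in hold for d in r.drugs])
rep = compute_metrics(labels, scores)
print(f"held-out ROC-AUC {rep.roc_auc:.3f}, accuracy {rep.accuracy:.3f}, F1 {rep.f1:.3f}")
```

prints

```
400 reports, 798 (report, drug) instances
final training loss: 0.578
held-out ROC-AUC 0.820, accuracy 0.836, F1 0.819
```

The held-out ROC-AUC of 0.82 on this small run sits below the generator's
Bayes ceiling (≈ 0.89 under the default noise rates — the suspect label is
itself a Bernoulli draw); at the full 2000-report size the cross-validated
mean reaches ≈ 0.89.

The same pipeline is available from a shell:

```sh
adesig simulate --out data --seed 7
adesig cv --records data/records.jsonl --soc-map data/soc_map.tsv --out cv_out
adesig train --records data/records.jsonl --soc-map data/soc_map.tsv --out run
adesig signals --checkpoint run/checkpoint.json --smiles "CCCC(=O)O" \
               --soc-map data/soc_map.tsv --out sig
```

Every command writes a `config_snapshot.json` beside its outputs; re-running
from the snapshot reproduces the outputs byte-for-byte.

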