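"""The suspect-drug classifier: feature fusion, training, checkpoints, search.

One training instance is one (record, drug) pair: the drug's three
structure channels plus the record's demographic and ADR channels, labelled
by that drug's suspect flag. Other drugs in the same report are not part of
the instance.

The fusion head follows the published architecture: the six channels are
concatenated and passed through a three-layer MLP — two blocks of
affine -> batch-norm -> ReLU -> dropout, a third affine -> batch-norm ->
ReLU block without dropout, and a final affine map to a single logit
(sigmoid for the suspect probability). Batch normalisation in a small head
can destabilise with tiny batches, so a minimum batch size of 8 is enforced
and layer normalisation is available as a config switch.

Loss is binary cross-entropy on the logit and the optimiser is Adam with
decoupled L2 weight decay; neither is dictated by the published main text,
so both are conventional defaults exposed in :class:`SDAJMConfig`.

A molecular-property benchmark mode reuses the three drug channels only
(demographic and ADR channels disabled), with a multi-task sigmoid head for
classification or an identity head with masked MSE for regression.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._nn import Adam, Parameter, Tensor, concat
from .ade_io import ADERecord, SOCMap, MolPropTable, N_SOC
from .chem_features import (
    MACCS_LENGTH, Vocabulary, build_vocabulary, canonical_smiles,
    compute_maccs, smiles_to_graph, tokenize,
)
from .encoders import (
    ADRSetEncoder, DemographicStats, GINEncoder, SeqEncoder, GraphBatch,
    encode_demographics, make_graph_batch, soc_encode,
)

logger = logging.getLogger(__name__)

CHECKPOINT_FORMAT_VERSION = "adesig-checkpoint-1"


class CheckpointError(RuntimeError):
    """A checkpoint file is missing, corrupt, or from another format version."""


@dataclass
class SDAJMConfig:
    """Hyperparameters of the classifier.

    ``n_heads`` is shared by the sequence and ADR attention blocks.
    ``norm`` switches the head between batch and layer normalisation.
    """

    batch_size: int = 64
    n_heads: int = 4
    gin_dropout: float = 0.1
    predictor_dropout: float = 0.2
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    epochs: int = 10
    seed: int = 0
    # architecture knobs forwarded to the encoders
    gin_hidden_dim: int = 64
    gin_layers: int = 2
    gin_readout: str = "sum"
    seq_embed_dim: int = 32
    seq_layers: int = 1
    seq_ff_dim: int = 64
    adr_embed_dim: int = 32
    head_hidden_dim: int = 64
    max_len: int = 96
    norm: str = "batch"
    pos_weight: float = 1.0  # optional positive-class weighting, 1 = off
    final_lr_fraction: float = 1.0  # linear lr decay target; 1.0 = constant
    minimal_atom_features: bool = False

    def __post_init__(self):
        if not 0 <= self.gin_dropout < 1 or not 0 <= self.predictor_dropout < 1:
            raise ValueError("dropout rates must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        if self.batch_size < 8:
            raise ValueError("batch_size must be >= 8 (batch-norm stability)")
        if self.norm not in ("batch", "layer"):
            raise ValueError("norm must be 'batch' or 'layer'")
        if not 0 < self.final_lr_fraction <= 1:
            raise ValueError("final_lr_fraction must be in (0, 1]")
        for dim in (self.seq_embed_dim, self.adr_embed_dim):
            if dim % self.n_heads:
                raise ValueError("attention dims must be divisible by n_heads")


class _BatchNorm1d:
    """Batch normalisation with running inference statistics."""

    def __init__(self, dim: int, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            xhat = (x - mu) / ((var + 1e-5) ** 0.5)
        else:
            xhat = ((x - Tensor(self.running_mean[None, :]))
                    / Tensor(np.sqrt(self.running_var[None, :] + 1e-5)))
        return xhat * self.gamma + self.beta


class _LayerNorm1d:
    """Per-instance normalisation alternative for the head."""

    def __init__(self, dim: int):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.running_mean = np.zeros(dim)  # unused; kept for checkpoint shape
        self.running_var = np.ones(dim)

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x: Tensor, training: bool) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + 1e-5) ** 0.5) * self.gamma + self.beta


class FusionHead:
    """Three-layer MLP head with dropout after the first two ReLUs."""

    def __init__(self, in_dim: int, hidden_dim: int, out_dim: int,
                 dropout: float, norm: str, seed: int):
        rng = np.random.default_rng(seed)
        Norm = _BatchNorm1d if norm == "batch" else _LayerNorm1d
        dims = [in_dim, hidden_dim, hidden_dim, hidden_dim]
        self.w = [Parameter(_he(rng, dims[i], dims[i + 1])) for i in range(3)]
        self.b = [Parameter(np.zeros(dims[i + 1])) for i in range(3)]
        self.norms = [Norm(dims[i + 1]) for i in range(3)]
        self.w_out = Parameter(_he(rng, hidden_dim, out_dim))
        self.b_out = Parameter(np.zeros(out_dim))
        self.dropout = dropout

    def parameters(self):
        ps = []
        for i in range(3):
            ps += [self.w[i], self.b[i]] + self.norms[i].parameters()
        ps += [self.w_out, self.b_out]
        return ps

    def forward(self, x: Tensor, training: bool,
                rng: np.random.Generator | None = None) -> Tensor:
        for i in range(3):
            x = self.norms[i].forward(x @ self.w[i] + self.b[i], training)
            x = x.relu()
            if i < 2 and training and self.dropout > 0:  # dropout after first two ReLUs only
                keep = (rng.random(x.shape) >= self.dropout) / (1 - self.dropout)
                x = x * Tensor(keep)
        return x @ self.w_out + self.b_out


def _he(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))


# ----------------------------------------------------------------------
# dataset preparation
# ----------------------------------------------------------------------

@dataclass
class _PreparedData:
    """Precomputed per-drug and per-record arrays for a record list.

    Drugs are de-duplicated by canonical SMILES so the structure encoders
    run once per unique molecule per batch rather than once per instance.
    """

    inst_record: np.ndarray   # (n_inst,) record index
    inst_drug: np.ndarray     # (n_inst,) unique-drug index
    labels: np.ndarray        # (n_inst,)
    graphs: list
    maccs: np.ndarray         # (n_drugs_u, 167)
    tok_ids: np.ndarray       # (n_drugs_u, L)
    tok_mask: np.ndarray
    adr_ids: np.ndarray       # (n_rec, T)
    adr_mask: np.ndarray
    xas: np.ndarray           # (n_rec, 27)
    xpd: np.ndarray           # (n_rec, 3)
    drug_keys: list[str]      # canonical SMILES per unique drug


def _prepare(model: "SDAJMModel", records: list[ADERecord]) -> _PreparedData:
    drug_index: dict[str, int] = {}
    graphs, maccs_rows, tok_rows, mask_rows, keys = [], [], [], [], []
    inst_record, inst_drug, labels = [], [], []

    for r_i, rec in enumerate(records):
        for d in rec.drugs:
            key = canonical_smiles(d.smiles)
            if key not in drug_index:
                drug_index[key] = len(graphs)
                graphs.append(smiles_to_graph(d.smiles))
                maccs_rows.append(compute_maccs(d.smiles))
                seq = tokenize(d.smiles, model.vocab)
                tok_rows.append(seq.ids)
                mask_rows.append(seq.mask)
                keys.append(key)
            inst_record.append(r_i)
            inst_drug.append(drug_index[key])
            labels.append(d.suspect)

    # trim token padding to the longest real sequence present: outputs are
    # padding-invariant, so this only saves attention cost
    tok_ids_arr = np.asarray(tok_rows, dtype=np.intp)
    tok_mask_arr = np.asarray(mask_rows, dtype=np.float64)
    max_l = max(int(tok_mask_arr.sum(axis=1).max()), 1)
    tok_ids_arr = tok_ids_arr[:, :max_l]
    tok_mask_arr = tok_mask_arr[:, :max_l]

    n_rec = len(records)
    max_t = max(len(rec.adrs) for rec in records)
    adr_ids = np.zeros((n_rec, max_t), dtype=np.intp)
    adr_mask = np.zeros((n_rec, max_t), dtype=np.float64)
    xas = np.zeros((n_rec, N_SOC), dtype=np.float64)
    xpd = np.zeros((n_rec, 3), dtype=np.float64)
    for r_i, rec in enumerate(records):
        for t_i, term in enumerate(rec.adrs):
            adr_ids[r_i, t_i] = model.adr_encoder.id_of(term.pt_label)
            adr_mask[r_i, t_i] = 1.0
        xas[r_i] = soc_encode(list(rec.adrs))
        xpd[r_i] = encode_demographics(rec.age, rec.weight, rec.sex, model.stats)

    return _PreparedData(
        inst_record=np.asarray(inst_record, dtype=np.intp),
        inst_drug=np.asarray(inst_drug, dtype=np.intp),
        labels=np.asarray(labels, dtype=np.float64),
        graphs=graphs,
        maccs=np.asarray(maccs_rows, dtype=np.float64),
        tok_ids=tok_ids_arr,
        tok_mask=tok_mask_arr,
        adr_ids=adr_ids, adr_mask=adr_mask, xas=xas, xpd=xpd,
        drug_keys=keys,
    )


# ----------------------------------------------------------------------
# the model
# ----------------------------------------------------------------------

class SDAJMModel:
    """All learned parameters plus preprocessing state.

    Self-contained: prediction needs nothing beyond this object. Built via
    :func:`build_model`, trained with :func:`train`, persisted with
    :meth:`save` / :meth:`load`.
    """

    def __init__(self, config: SDAJMConfig, vocab: Vocabulary,
                 pt_labels: list[str], mode: str = "ade", n_tasks: int = 1,
                 task_kind: str = "classification"):
        if mode not in ("ade", "molprop"):
            raise ValueError("mode must be 'ade' or 'molprop'")
        self.config = config
        self.vocab = vocab
        self.mode = mode
        self.n_tasks = n_tasks
        self.task_kind = task_kind
        self.stats = DemographicStats()
        self.training_log: list[dict] = []
        self.training_manifest: list[str] = []  # canonical SMILES seen in training
        # per-task target standardisation (regression benchmark mode)
        self.target_mean = np.zeros(n_tasks)
        self.target_sd = np.ones(n_tasks)

        c = config
        self.gin = GINEncoder(hidden_dim=c.gin_hidden_dim, n_layers=c.gin_layers,
                              readout=c.gin_readout,
                              minimal_atom_features=c.minimal_atom_features,
                              seed=c.seed)
        self.seq = SeqEncoder(vocab_size=len(vocab), embed_dim=c.seq_embed_dim,
                              n_heads=c.n_heads, n_layers=c.seq_layers,
                              ff_dim=c.seq_ff_dim, max_len=vocab.max_len,
                              seed=c.seed + 1)
        self.adr_encoder = ADRSetEncoder(pt_labels, embed_dim=c.adr_embed_dim,
                                         n_heads=c.n_heads, seed=c.seed + 2)
        if mode == "ade":
            in_dim = (3 + MACCS_LENGTH + c.gin_hidden_dim + c.seq_embed_dim
                      + N_SOC + self.adr_encoder.pooled_dim)
            out_dim = 1
        else:
            in_dim = MACCS_LENGTH + c.gin_hidden_dim + c.seq_embed_dim
            out_dim = n_tasks
        self.head = FusionHead(in_dim, c.head_hidden_dim, out_dim,
                               dropout=c.predictor_dropout, norm=c.norm,
                               seed=c.seed + 3)

    # -- parameters ----------------------------------------------------
    def parameters(self) -> list[Parameter]:
        ps = self.gin.parameters() + self.seq.parameters() + self.head.parameters()
        if self.mode == "ade":
            ps += self.adr_encoder.parameters()
        return ps

    # -- forward -------------------------------------------------------
    def _forward(self, prep: _PreparedData, inst_idx: np.ndarray,
                 training: bool, rng: np.random.Generator | None = None) -> Tensor:
        rec_idx = prep.inst_record[inst_idx]
        drg_idx = prep.inst_drug[inst_idx]

        u_drugs, drg_local = np.unique(drg_idx, return_inverse=True)
        gbatch = make_graph_batch([prep.graphs[i] for i in u_drugs])
        xdg_u = self.gin.forward(gbatch)
        if training and self.config.gin_dropout > 0:
            keep = ((rng.random(xdg_u.shape) >= self.config.gin_dropout)
                    / (1 - self.config.gin_dropout))
            xdg_u = xdg_u * Tensor(keep)
        xds_u = self.seq.forward(prep.tok_ids[u_drugs], prep.tok_mask[u_drugs])
        xdg = xdg_u.gather_rows(drg_local)
        xds = xds_u.gather_rows(drg_local)
        xdf = Tensor(prep.maccs[drg_idx])

        if self.mode == "ade":
            u_recs, rec_local = np.unique(rec_idx, return_inverse=True)
            xap_u = self.adr_encoder.forward(prep.adr_ids[u_recs],
                                             prep.adr_mask[u_recs])
            xap = xap_u.gather_rows(rec_local)
            xpd = Tensor(prep.xpd[rec_idx])
            xas = Tensor(prep.xas[rec_idx])
            fused = concat([xpd, xdf, xdg, xds, xas, xap], axis=1)
        else:
            fused = concat([xdf, xdg, xds], axis=1)
        return self.head.forward(fused, training=training, rng=rng)

    # -- prediction ----------------------------------------------------
    def predict_scores(self, records: list[ADERecord]) -> np.ndarray:
        """Suspect probabilities for every (record, drug) instance, in
        record order then drug order within each record."""
        if not self.stats.fitted:
            raise RuntimeError("model is untrained: demographic stats not fitted")
        prep = _prepare(self, records)
        logits = self._forward(prep, np.arange(len(prep.labels)), training=False)
        return 1.0 / (1.0 + np.exp(-logits.data.ravel()))

    def predict_molprop(self, smiles_list: list[str]) -> np.ndarray:
        """(n, n_tasks) predictions in benchmark mode."""
        if self.mode != "molprop":
            raise RuntimeError("predict_molprop requires molprop mode")
        prep = _prepare_molprop(self, smiles_list)
        out = self._forward(prep, np.arange(len(smiles_list)), training=False)
        if self.task_kind == "classification":
            return 1.0 / (1.0 + np.exp(-out.data))
        return out.data * self.target_sd + self.target_mean

    # -- persistence ---------------------------------------------------
    def _named_arrays(self) -> list[tuple[str, np.ndarray]]:
        out = [(f"p{i:04d}", p.data) for i, p in enumerate(self.parameters())]
        for j, norm in enumerate(self.head.norms):
            out.append((f"bn{j}_mean", norm.running_mean))
            out.append((f"bn{j}_var", norm.running_var))
        return out

    def save(self, path: str | Path) -> None:
        obj = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "mode": self.mode,
            "n_tasks": self.n_tasks,
            "task_kind": self.task_kind,
            "config": asdict(self.config),
            "vocab": {"token_to_id": self.vocab.token_to_id,
                      "max_len": self.vocab.max_len},
            "pt_to_id": self.adr_encoder.pt_to_id,
            "stats": self.stats.to_dict(),
            "training_log": self.training_log,
            "training_manifest": self.training_manifest,
            "target_mean": self.target_mean.tolist(),
            "target_sd": self.target_sd.tolist(),
            "arrays": {name: arr.tolist() for name, arr in self._named_arrays()},
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def load(cls, path: str | Path) -> "SDAJMModel":
        path = Path(path)
        if not path.exists():
            raise CheckpointError(f"checkpoint not found: {path}")
        try:
            obj = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise CheckpointError(f"corrupt checkpoint {path}: {exc}") from None
        version = obj.get("format_version")
        if version != CHECKPOINT_FORMAT_VERSION:
            raise CheckpointError(
                f"checkpoint {path} has format {version!r}; this build reads "
                f"{CHECKPOINT_FORMAT_VERSION!r} — re-train or convert it"
            )
        config = SDAJMConfig(**obj["config"])
        vocab = Vocabulary(token_to_id=dict(obj["vocab"]["token_to_id"]),
                           max_len=obj["vocab"]["max_len"])
        model = cls(config, vocab, pt_labels=[], mode=obj["mode"],
                    n_tasks=obj["n_tasks"], task_kind=obj["task_kind"])
        model.adr_encoder.pt_to_id = {k: int(v) for k, v in obj["pt_to_id"].items()}
        # rebuild embedding with the right row count before loading arrays
        n_rows = len(model.adr_encoder.pt_to_id) + 1
        model.adr_encoder.emb = Parameter(np.zeros((n_rows, config.adr_embed_dim)))
        model.stats = DemographicStats.from_dict(obj["stats"])
        model.training_log = obj["training_log"]
        model.training_manifest = obj["training_manifest"]
        model.target_mean = np.asarray(obj["target_mean"], dtype=np.float64)
        model.target_sd = np.asarray(obj["target_sd"], dtype=np.float64)
        arrays = obj["arrays"]
        for name, target in model._named_arrays():
            loaded = np.asarray(arrays[name], dtype=np.float64)
            if name.startswith("p"):
                idx = int(name[1:])
                model.parameters()[idx].data = loaded.reshape(target.shape)
            elif name.endswith("_mean"):
                model.head.norms[int(name[2])].running_mean = loaded
            else:
                model.head.norms[int(name[2])].running_var = loaded
        return model


def build_model(config: SDAJMConfig, vocab: Vocabulary,
                soc_map: SOCMap | None, pt_labels: list[str]) -> SDAJMModel:
    """Construct an untrained classifier (parameters seeded by the config).

    ``soc_map`` fixes nothing at build time (the SOC channel is a fixed-width
    one-hot), but passing it documents which mapping the model belongs to.
    """
    return SDAJMModel(config, vocab, pt_labels, mode="ade")


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------

def _bce_loss(logits: Tensor, labels: np.ndarray, pos_weight: float) -> Tensor:
    p = logits.sigmoid()
    y = Tensor(labels.reshape(logits.shape))
    w = Tensor(np.where(labels.reshape(logits.shape) > 0.5, pos_weight, 1.0))
    eps = 1e-12
    nll = -(y * (p + eps).log() + (1.0 - y) * (1.0 - p + eps).log()) * w
    return nll.mean()


def train(model: SDAJMModel, records: list[ADERecord],
          config: SDAJMConfig | None = None) -> SDAJMModel:
    """Train in place on (record, drug) instances; returns the model.

    Fits the demographic statistics on ``records`` (training split only),
    then minimises binary cross-entropy with Adam. The trajectory is a pure
    function of the config seed. Per-epoch mean loss is appended to
    ``model.training_log``.
    """
    cfg = config or model.config
    model.stats = DemographicStats.fit(records)
    prep = _prepare(model, records)
    model.training_manifest = sorted(set(prep.drug_keys))

    if len(np.unique(prep.labels)) < 2:
        warnings.warn("training labels are single-class; proceeding anyway",
                      RuntimeWarning)

    params = model.parameters()
    opt = Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    n = len(prep.labels)
    for epoch in range(cfg.epochs):
        if cfg.epochs > 1:
            frac = epoch / (cfg.epochs - 1)
            opt.lr = cfg.learning_rate * (1 - (1 - cfg.final_lr_fraction) * frac)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if len(idx) < 8:      # drop tiny remainder batches (BN stability)
                continue
            opt.zero_grad()
            logits = model._forward(prep, idx, training=True, rng=rng)
            loss = _bce_loss(logits, prep.labels[idx], cfg.pos_weight)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.training_log.append(
            {"epoch": epoch + 1, "loss": float(np.mean(losses)) if losses else float("nan")}
        )
        logger.debug("epoch %d loss %.4f", epoch + 1, model.training_log[-1]["loss"])
    return model


def predict_proba(model: SDAJMModel, record: ADERecord, drug_index: int) -> float:
    """Suspect probability for one drug of one record (evaluation mode)."""
    if not 0 <= drug_index < len(record.drugs):
        raise IndexError(f"drug_index {drug_index} out of range for record "
                         f"{record.record_id!r}")
    scores = model.predict_scores([record])
    return float(scores[drug_index])


# ----------------------------------------------------------------------
# molecular-property benchmark mode
# ----------------------------------------------------------------------

def _prepare_molprop(model: SDAJMModel, smiles_list: list[str]) -> _PreparedData:
    graphs, maccs_rows, tok_rows, mask_rows, keys = [], [], [], [], []
    for smi in smiles_list:
        graphs.append(smiles_to_graph(smi))
        maccs_rows.append(compute_maccs(smi))
        seq = tokenize(smi, model.vocab)
        tok_rows.append(seq.ids)
        mask_rows.append(seq.mask)
        keys.append(canonical_smiles(smi))
    n = len(smiles_list)
    tok_ids_arr = np.asarray(tok_rows, dtype=np.intp)
    tok_mask_arr = np.asarray(mask_rows, dtype=np.float64)
    max_l = max(int(tok_mask_arr.sum(axis=1).max()), 1)
    return _PreparedData(
        inst_record=np.zeros(n, dtype=np.intp),
        inst_drug=np.arange(n, dtype=np.intp),
        labels=np.zeros(n),
        graphs=graphs,
        maccs=np.asarray(maccs_rows, dtype=np.float64),
        tok_ids=tok_ids_arr[:, :max_l],
        tok_mask=tok_mask_arr[:, :max_l],
        adr_ids=np.zeros((1, 1), dtype=np.intp),
        adr_mask=np.ones((1, 1)),
        xas=np.zeros((1, N_SOC)),
        xpd=np.zeros((1, 3)),
        drug_keys=keys,
    )


def build_molprop_model(config: SDAJMConfig, vocab: Vocabulary,
                        n_tasks: int, task_kind: str) -> SDAJMModel:
    """Benchmark-mode model: drug channels only, multi-task head."""
    return SDAJMModel(config, vocab, pt_labels=[], mode="molprop",
                      n_tasks=n_tasks, task_kind=task_kind)


def train_molprop(model: SDAJMModel, smiles_list: list[str],
                  targets: np.ndarray, config: SDAJMConfig | None = None) -> SDAJMModel:
    """Train the benchmark-mode model with per-task missing-label masking."""
    cfg = config or model.config
    prep = _prepare_molprop(model, smiles_list)
    model.stats = DemographicStats(0.0, 1.0, 0.0, 1.0)  # unused in this mode
    model.training_manifest = sorted(set(prep.drug_keys))
    targets = np.asarray(targets, dtype=np.float64)
    if targets.ndim == 1:
        targets = targets[:, None]
    obs = ~np.isnan(targets)
    if model.task_kind == "regression":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model.target_mean = np.nanmean(targets, axis=0)
            model.target_sd = np.maximum(np.nanstd(targets, axis=0), 1e-8)
        model.target_mean = np.nan_to_num(model.target_mean)
        targets = (targets - model.target_mean) / model.target_sd

    params = model.parameters()
    opt = Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    n = len(smiles_list)
    for epoch in range(cfg.epochs):
        if cfg.epochs > 1:
            frac = epoch / (cfg.epochs - 1)
            opt.lr = cfg.learning_rate * (1 - (1 - cfg.final_lr_fraction) * frac)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if len(idx) < 8:
                continue
            opt.zero_grad()
            out = model._forward(prep, idx, training=True, rng=rng)
            y = targets[idx]
            m = obs[idx].astype(np.float64)
            denom = max(m.sum(), 1.0)
            if model.task_kind == "classification":
                p = out.sigmoid()
                yt = Tensor(np.nan_to_num(y))
                eps = 1e-12
                nll = -(yt * (p + eps).log() + (1 - yt) * (1 - p + eps).log())
                loss = (nll * Tensor(m)).sum() / denom
            else:
                diff = out - Tensor(np.nan_to_num(y))
                loss = ((diff ** 2) * Tensor(m)).sum() / denom
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.training_log.append(
            {"epoch": epoch + 1, "loss": float(np.mean(losses)) if losses else float("nan")}
        )
    return model


# ----------------------------------------------------------------------
# hyperparameter search
# ----------------------------------------------------------------------

@dataclass
class SearchSpace:
    """Ranges/choices per hyperparameter plus a trial budget.

    ``ranges`` maps a config field name to either a list of choices or a
    ``(low, high, scale)`` tuple with scale 'linear' or 'log'.
    """

    ranges: dict
    budget: int = 16
    objective: str = "roc_auc"

    def __post_init__(self):
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if not self.ranges:
            raise ValueError("search space must be non-empty")


def _sample_config(space: SearchSpace, base: SDAJMConfig,
                   rng: np.random.Generator) -> tuple[SDAJMConfig, dict]:
    values = {}
    for name, spec in space.ranges.items():
        if isinstance(spec, (list, tuple)) and len(spec) == 3 and spec[2] in ("linear", "log"):
            lo, hi, scale = spec
            if scale == "log":
                values[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                values[name] = float(rng.uniform(lo, hi))
        else:
            values[name] = spec[int(rng.integers(len(spec)))]
    cfg_dict = asdict(base)
    cfg_dict.update(values)
    return SDAJMConfig(**cfg_dict), values


def _encode_trial(values: dict, space: SearchSpace) -> list[float]:
    enc = []
    for name, spec in space.ranges.items():
        v = values[name]
        if isinstance(spec, (list, tuple)) and len(spec) == 3 and spec[2] in ("linear", "log"):
            lo, hi, scale = spec
            if scale == "log":
                enc.append((np.log(v) - np.log(lo)) / (np.log(hi) - np.log(lo)))
            else:
                enc.append((v - lo) / (hi - lo))
        else:
            enc.append(list(spec).index(v) / max(len(spec) - 1, 1))
    return enc


def optimize_hyperparameters(
    eval_fn,
    space: SearchSpace,
    base_config: SDAJMConfig | None = None,
    seed: int = 0,
) -> tuple[SDAJMConfig, list[dict]]:
    """Sequential model-based hyperparameter search.

    ``eval_fn(config) -> float`` scores one configuration (higher is
    better; return NaN to mark a failed trial). For budgets below 10 this
    is plain random search; otherwise the first half of the budget is
    random and the rest proposes the best expected-improvement point among
    random candidates under a Gaussian-process surrogate.

    Returns the best config and the full trial log.
    """
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern
    from scipy.stats import norm as norm_dist

    base = base_config or SDAJMConfig()
    rng = np.random.default_rng(seed)
    trials: list[dict] = []
    X: list[list[float]] = []
    y: list[float] = []

    n_random = space.budget if space.budget < 10 else max(space.budget // 2, 5)
    for t in range(space.budget):
        if t < n_random or len(y) < 3:
            cfg, values = _sample_config(space, base, rng)
        else:
            gp = GaussianProcessRegressor(kernel=Matern(nu=2.5),
                                          normalize_y=True, alpha=1e-4)
            gp.fit(np.array(X), np.array(y))
            best_y = max(y)
            cands = [_sample_config(space, base, rng) for _ in range(50)]
            enc = np.array([_encode_trial(v, space) for _, v in cands])
            mu, sd = gp.predict(enc, return_std=True)
            sd = np.maximum(sd, 1e-9)
            z = (mu - best_y) / sd
            ei = (mu - best_y) * norm_dist.cdf(z) + sd * norm_dist.pdf(z)
            cfg, values = cands[int(np.argmax(ei))]
        try:
            score = float(eval_fn(cfg))
        except Exception as exc:  # noqa: BLE001 - a failed trial must not kill the search
            logger.warning("trial %d failed: %s", t, exc)
            score = float("nan")
        trials.append({"trial": t, "values": values, "score": score})
        if np.isfinite(score):
            X.append(_encode_trial(values, space))
            y.append(score)
    if not y:
        raise RuntimeError("every hyperparameter trial failed")
    finite = [tr for tr in trials if np.isfinite(tr["score"])]
    best = max(finite, key=lambda tr: tr["score"])
    cfg_dict = asdict(base)
    cfg_dict.update(best["values"])
    return SDAJMConfig(**cfg_dict), trials
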