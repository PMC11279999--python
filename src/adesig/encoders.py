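"""The six feature channels fused by the suspect-drug classifier.

For one (record, drug) instance the model sees:

====  =====================================================================
Xpd   demographics: z-scored age and weight plus the sex code (length 3)
Xdf   MACCS substructure fingerprint (length 167, fixed)
Xdg   graph isomorphism network (GIN) embedding of the molecular graph
Xds   Transformer encoding of the SMILES token sequence (masked mean pool)
Xas   27-slot SOC one-hot: slot i is 1 iff some ADR maps to SOC i (fixed)
Xap   ADR semantic embedding: trainable per-PT embeddings, multi-head
      self-attention over the term *set* (no positional encoding — MedDRA
      term lists carry no order), then average pooling over terms
====  =====================================================================

Xpd, Xdf and Xas are deterministic transforms; Xdg, Xds and Xap are
produced by trainable encoders defined here on the package's autodiff
engine and trained end-to-end by the model module.

Demographic standardisation statistics are fit on the training split only
and persist with the model, so held-out records never leak into the
normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from ._nn import Parameter, Tensor, concat, softmax
from .ade_io import ADERecord, ADRTerm, N_SOC
from .chem_features import (
    MolecularGraph, TokenSequence, N_BOND_DIRS, N_BOND_TYPES,
    N_CHIRALITY_TAGS, N_ELEMENT_TYPES, PAD_ID,
)

__all__ = [
    "DemographicStats", "GINEncoder", "SeqEncoder", "ADRSetEncoder",
    "FeatureBundle", "encode_demographics", "gin_encode", "seq_encode",
    "soc_encode", "adr_semantic_encode", "GraphBatch", "make_graph_batch",
]

_MAX_DEGREE = 6          # degrees above this share one embedding row
_CHARGE_OFFSET = 3       # formal charges -3..+3 indexed 0..6
_N_CHARGE = 7


class StateError(RuntimeError):
    """An operation was called before its state was fitted."""


# ----------------------------------------------------------------------
# Xpd: demographics
# ----------------------------------------------------------------------

@dataclass
class DemographicStats:
    """Age/weight standardisation statistics, fit on the training split."""

    age_mean: float | None = None
    age_sd: float | None = None
    weight_mean: float | None = None
    weight_sd: float | None = None

    @property
    def fitted(self) -> bool:
        return self.age_mean is not None

    @classmethod
    def fit(cls, records: list[ADERecord]) -> "DemographicStats":
        ages = np.array([r.age for r in records], dtype=np.float64)
        weights = np.array([r.weight for r in records], dtype=np.float64)
        return cls(
            age_mean=float(ages.mean()),
            age_sd=float(max(ages.std(), 1e-8)),
            weight_mean=float(weights.mean()),
            weight_sd=float(max(weights.std(), 1e-8)),
        )

    def to_dict(self) -> dict:
        return {"age_mean": self.age_mean, "age_sd": self.age_sd,
                "weight_mean": self.weight_mean, "weight_sd": self.weight_sd}

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicStats":
        return cls(**d)


def encode_demographics(age: float, weight: float, sex: int,
                        stats: DemographicStats) -> np.ndarray:
    """Xpd = [(age - mu_a)/sigma_a, (weight - mu_w)/sigma_w, sex]."""
    if not stats.fitted:
        raise StateError("DemographicStats not fitted")
    return np.array([
        (age - stats.age_mean) / stats.age_sd,
        (weight - stats.weight_mean) / stats.weight_sd,
        float(sex),
    ])


# ----------------------------------------------------------------------
# Xas: SOC one-hot
# ----------------------------------------------------------------------

def soc_encode(adrs: list[ADRTerm]) -> np.ndarray:
    """27-slot binary vector; slot i = 1 iff some term has SOC index i.

    The width is fixed at 27 (the full MedDRA SOC count) regardless of how
    many SOCs the active mapping uses; unused slots stay zero.
    """
    out = np.zeros(N_SOC, dtype=np.int8)
    for term in adrs:
        if not 0 <= term.soc_index < N_SOC:
            from .ade_io import MappingError
            raise MappingError(f"soc_index {term.soc_index} outside [0, {N_SOC - 1}]")
        out[term.soc_index] = 1
    return out


# ----------------------------------------------------------------------
# shared initialisation helpers
# ----------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _embed_table(rng: np.random.Generator, n_rows: int, dim: int) -> np.ndarray:
    return rng.normal(0.0, 0.1, size=(n_rows, dim))


def _layer_norm(x: Tensor, gamma: Parameter, beta: Parameter) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return (x - mu) / ((var + 1e-5) ** 0.5) * gamma + beta


def _multi_head_attention(x: Tensor, mask: np.ndarray, n_heads: int,
                          wq: Parameter, wk: Parameter, wv: Parameter,
                          wo: Parameter) -> Tensor:
    """Self-attention over axis 1 of ``x`` (n, L, d); ``mask`` is (n, L)."""
    n, L, d = x.shape
    dh = d // n_heads

    def heads(t: Tensor) -> Tensor:
        return t.reshape(n, L, n_heads, dh).transpose(0, 2, 1, 3)

    q, k, v = heads(x @ wq), heads(x @ wk), heads(x @ wv)
    scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
    key_mask = mask[:, None, None, :]  # broadcast over heads and queries
    attn = softmax(scores, axis=-1, mask=np.broadcast_to(key_mask, scores.shape))
    out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, L, d)
    return out @ wo


# ----------------------------------------------------------------------
# Xdg: graph isomorphism network
# ----------------------------------------------------------------------

@dataclass
class GraphBatch:
    """A block-diagonal batch of molecular graphs.

    ``node_feats`` stacks per-atom categorical indices; ``edge_src/dst``
    list both directions of every undirected bond; ``node_graph`` maps each
    node to its graph index.
    """

    node_feats: np.ndarray     # (total_nodes, 5) int
    edge_src: np.ndarray       # (total_directed_edges,)
    edge_dst: np.ndarray
    edge_type: np.ndarray
    edge_dir: np.ndarray
    node_graph: np.ndarray     # (total_nodes,)
    n_graphs: int
    graph_sizes: np.ndarray


def make_graph_batch(graphs: list[MolecularGraph]) -> GraphBatch:
    feats, src, dst, etype, edir, ngraph, sizes = [], [], [], [], [], [], []
    offset = 0
    for g_idx, g in enumerate(graphs):
        if g.n_atoms == 0:
            raise ValueError("empty molecular graph in batch")
        for a in g.atoms:
            feats.append(a)
            ngraph.append(g_idx)
        for (i, j, bt, bd) in g.bonds:
            src += [offset + i, offset + j]
            dst += [offset + j, offset + i]
            etype += [bt, bt]
            edir += [bd, bd]
        sizes.append(g.n_atoms)
        offset += g.n_atoms
    return GraphBatch(
        node_feats=np.asarray(feats, dtype=np.intp).reshape(-1, 5),
        edge_src=np.asarray(src, dtype=np.intp),
        edge_dst=np.asarray(dst, dtype=np.intp),
        edge_type=np.asarray(etype, dtype=np.intp),
        edge_dir=np.asarray(edir, dtype=np.intp),
        node_graph=np.asarray(ngraph, dtype=np.intp),
        n_graphs=len(graphs),
        graph_sizes=np.asarray(sizes, dtype=np.intp),
    )


class GINEncoder:
    """GIN over annotated molecular graphs.

    Each layer updates ``h_v <- MLP((1 + eps) h_v + sum_u (h_u + e_uv))``
    where ``e_uv`` embeds the bond's type and direction and the MLP is two
    affine maps with a ReLU between. The readout (sum by default, mean
    optional) aggregates node states into the graph vector Xdg. Node
    initialisation sums embeddings of element, chirality and — unless
    ``minimal_atom_features`` — formal charge, aromaticity and degree.
    """

    def __init__(self, hidden_dim: int = 128, n_layers: int = 3,
                 readout: str = "sum", minimal_atom_features: bool = False,
                 seed: int = 0):
        if readout not in ("sum", "mean"):
            raise ValueError("readout must be 'sum' or 'mean'")
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.readout = readout
        self.minimal_atom_features = minimal_atom_features
        rng = np.random.default_rng(seed)
        d = hidden_dim
        self.elem_emb = Parameter(_embed_table(rng, N_ELEMENT_TYPES, d))
        self.chir_emb = Parameter(_embed_table(rng, N_CHIRALITY_TAGS, d))
        self.charge_emb = Parameter(_embed_table(rng, _N_CHARGE, d))
        self.arom_emb = Parameter(_embed_table(rng, 2, d))
        self.degree_emb = Parameter(_embed_table(rng, _MAX_DEGREE + 1, d))
        self.bond_type_emb = Parameter(_embed_table(rng, N_BOND_TYPES, d))
        self.bond_dir_emb = Parameter(_embed_table(rng, N_BOND_DIRS, d))
        self.eps = [Parameter(np.zeros(1)) for _ in range(n_layers)]
        self.w1 = [Parameter(_glorot(rng, d, d)) for _ in range(n_layers)]
        self.b1 = [Parameter(np.zeros(d)) for _ in range(n_layers)]
        self.w2 = [Parameter(_glorot(rng, d, d)) for _ in range(n_layers)]
        self.b2 = [Parameter(np.zeros(d)) for _ in range(n_layers)]

    def parameters(self) -> list[Parameter]:
        ps = [self.elem_emb, self.chir_emb, self.bond_type_emb, self.bond_dir_emb]
        if not self.minimal_atom_features:
            ps += [self.charge_emb, self.arom_emb, self.degree_emb]
        for layer in range(self.n_layers):
            ps += [self.eps[layer], self.w1[layer], self.b1[layer],
                   self.w2[layer], self.b2[layer]]
        return ps

    def forward(self, batch: GraphBatch) -> Tensor:
        nf = batch.node_feats
        h = self.elem_emb.gather_rows(nf[:, 0])
        h = h + self.chir_emb.gather_rows(nf[:, 1])
        if not self.minimal_atom_features:
            charge_idx = np.clip(nf[:, 2] + _CHARGE_OFFSET, 0, _N_CHARGE - 1)
            h = h + self.charge_emb.gather_rows(charge_idx)
            h = h + self.arom_emb.gather_rows(nf[:, 3])
            h = h + self.degree_emb.gather_rows(np.clip(nf[:, 4], 0, _MAX_DEGREE))
        n_nodes = nf.shape[0]
        edge_emb_t = self.bond_type_emb.gather_rows(batch.edge_type)
        edge_emb_d = self.bond_dir_emb.gather_rows(batch.edge_dir)
        for layer in range(self.n_layers):
            if batch.edge_src.size:
                msgs = h.gather_rows(batch.edge_src) + edge_emb_t + edge_emb_d
                agg = msgs.segment_sum(batch.edge_dst, n_nodes)
            else:
                agg = Tensor(np.zeros((n_nodes, self.hidden_dim)))
            z = h * (self.eps[layer] + 1.0) + agg
            z = (z @ self.w1[layer] + self.b1[layer]).relu()
            h = z @ self.w2[layer] + self.b2[layer]
        pooled = h.segment_sum(batch.node_graph, batch.n_graphs)
        if self.readout == "mean":
            pooled = pooled * Tensor(1.0 / batch.graph_sizes[:, None])
        return pooled


def gin_encode(graph: MolecularGraph, encoder: GINEncoder) -> np.ndarray:
    """Xdg for a single molecule (inference path, no gradients kept)."""
    if graph.n_atoms == 0:
        raise ValueError("cannot encode an empty graph")
    return encoder.forward(make_graph_batch([graph])).data[0].copy()


# ----------------------------------------------------------------------
# Xds: SMILES Transformer encoder
# ----------------------------------------------------------------------

def _sinusoidal_table(max_len: int, dim: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    table = np.zeros((max_len, dim))
    table[:, 0::2] = np.sin(angle[:, 0::2])
    table[:, 1::2] = np.cos(angle[:, 1::2])
    return table


class SeqEncoder:
    """Transformer encoder over SMILES token sequences.

    Token embeddings plus fixed sinusoidal positional encodings pass
    through ``n_layers`` pre-norm blocks (multi-head self-attention with
    PAD keys masked, then a ReLU feed-forward, each with a residual); the
    masked mean over real positions yields Xds.
    """

    def __init__(self, vocab_size: int, embed_dim: int = 64, n_heads: int = 4,
                 n_layers: int = 2, ff_dim: int = 128, max_len: int = 128,
                 seed: int = 0):
        if embed_dim % n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        self.vocab_size = vocab_size
        self.embed_dim = embed_dim
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.ff_dim = ff_dim
        self.max_len = max_len
        rng = np.random.default_rng(seed)
        d = embed_dim
        self.tok_emb = Parameter(_embed_table(rng, vocab_size, d))
        self.pos_table = _sinusoidal_table(max_len, d)  # constant
        self.blocks = []
        for _ in range(n_layers):
            blk = {
                "wq": Parameter(_glorot(rng, d, d)),
                "wk": Parameter(_glorot(rng, d, d)),
                "wv": Parameter(_glorot(rng, d, d)),
                "wo": Parameter(_glorot(rng, d, d)),
                "ln1_g": Parameter(np.ones(d)), "ln1_b": Parameter(np.zeros(d)),
                "w_ff1": Parameter(_glorot(rng, d, ff_dim)),
                "b_ff1": Parameter(np.zeros(ff_dim)),
                "w_ff2": Parameter(_glorot(rng, ff_dim, d)),
                "b_ff2": Parameter(np.zeros(d)),
                "ln2_g": Parameter(np.ones(d)), "ln2_b": Parameter(np.zeros(d)),
            }
            self.blocks.append(blk)

    def parameters(self) -> list[Parameter]:
        ps = [self.tok_emb]
        for blk in self.blocks:
            ps += list(blk.values())
        return ps

    def forward(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        """(n, L) int ids and 0/1 mask -> (n, embed_dim)."""
        ids = np.asarray(ids, dtype=np.intp)
        mask = np.asarray(mask, dtype=np.float64)
        if (mask.sum(axis=1) == 0).any():
            raise ValueError("all-PAD token sequence in batch")
        n, L = ids.shape
        if L > self.pos_table.shape[0]:
            self.pos_table = _sinusoidal_table(L, self.embed_dim)
        # PAD embeddings are zeroed so masked positions cannot leak through
        # residual paths into the mean pool.
        x = self.tok_emb.gather_rows(ids.ravel()).reshape(n, L, self.embed_dim)
        x = (x + Tensor(self.pos_table[:L])) * Tensor(mask[:, :, None])
        for blk in self.blocks:
            h = _layer_norm(x, blk["ln1_g"], blk["ln1_b"])
            x = x + _multi_head_attention(h, mask, self.n_heads,
                                          blk["wq"], blk["wk"], blk["wv"], blk["wo"])
            h = _layer_norm(x, blk["ln2_g"], blk["ln2_b"])
            ff = ((h @ blk["w_ff1"] + blk["b_ff1"]).relu() @ blk["w_ff2"]
                  + blk["b_ff2"])
            x = x + ff
        x = x * Tensor(mask[:, :, None])
        denom = Tensor(mask.sum(axis=1, keepdims=True))
        return x.sum(axis=1) / denom


def seq_encode(tokens: TokenSequence, encoder: SeqEncoder) -> np.ndarray:
    """Xds for a single token sequence (inference path)."""
    if tokens.n_real == 0:
        raise ValueError("cannot encode an all-PAD sequence")
    ids = np.asarray(tokens.ids)[None, :]
    mask = np.asarray(tokens.mask)[None, :]
    return encoder.forward(ids, mask).data[0].copy()


# ----------------------------------------------------------------------
# Xap: ADR semantic set encoder
# ----------------------------------------------------------------------

class ADRSetEncoder:
    """Trainable PT embeddings + set self-attention + average pooling.

    Terms form an unordered set, so no positional encoding is used; the
    adaptive average pool is realised as the mean over the term axis,
    giving a fixed ``pooled_dim = embed_dim`` output for any term count.
    Row 0 of the embedding table is the UNK row for PTs unseen at fit time.
    """

    UNK_PT_ID = 0

    def __init__(self, pt_labels: list[str], embed_dim: int = 64,
                 n_heads: int = 4, seed: int = 0):
        if embed_dim % n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        self.embed_dim = embed_dim
        self.pooled_dim = embed_dim
        self.n_heads = n_heads
        self.pt_to_id = {pt: i + 1 for i, pt in enumerate(sorted(set(pt_labels)))}
        rng = np.random.default_rng(seed)
        d = embed_dim
        self.emb = Parameter(_embed_table(rng, len(self.pt_to_id) + 1, d))
        self.wq = Parameter(_glorot(rng, d, d))
        self.wk = Parameter(_glorot(rng, d, d))
        self.wv = Parameter(_glorot(rng, d, d))
        self.wo = Parameter(_glorot(rng, d, d))

    def parameters(self) -> list[Parameter]:
        return [self.emb, self.wq, self.wk, self.wv, self.wo]

    def id_of(self, pt_label: str) -> int:
        return self.pt_to_id.get(pt_label, self.UNK_PT_ID)

    def forward(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        """(n, T) padded PT ids and 0/1 mask -> (n, pooled_dim)."""
        ids = np.asarray(ids, dtype=np.intp)
        mask = np.asarray(mask, dtype=np.float64)
        if (mask.sum(axis=1) == 0).any():
            raise ValueError("record with no ADR terms in batch")
        n, T = ids.shape
        x = self.emb.gather_rows(ids.ravel()).reshape(n, T, self.embed_dim)
        x = x * Tensor(mask[:, :, None])
        attended = _multi_head_attention(x, mask, self.n_heads,
                                         self.wq, self.wk, self.wv, self.wo)
        attended = (x + attended) * Tensor(mask[:, :, None])
        denom = Tensor(mask.sum(axis=1, keepdims=True))
        return attended.sum(axis=1) / denom


def adr_semantic_encode(adrs: list[ADRTerm], encoder: ADRSetEncoder) -> np.ndarray:
    """Xap for one record's term set (inference path)."""
    if not adrs:
        raise ValueError("cannot encode an empty ADR term list")
    ids = np.array([[encoder.id_of(a.pt_label) for a in adrs]])
    mask = np.ones_like(ids)
    return encoder.forward(ids, mask).data[0].copy()


# ----------------------------------------------------------------------
# the assembled bundle
# ----------------------------------------------------------------------

@dataclass
class FeatureBundle:
    """The six concatenable vectors for one (record, drug) instance."""

    Xpd: np.ndarray
    Xdf: np.ndarray
    Xdg: np.ndarray
    Xds: np.ndarray
    Xas: np.ndarray
    Xap: np.ndarray

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.Xpd, self.Xdf, self.Xdg,
                               self.Xds, self.Xas, self.Xap]).astype(np.float64)

    def all_finite(self) -> bool:
        return bool(np.isfinite(self.concatenated()).all())
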