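"""The three learnable encoders.

* :class:`GVPEncoder` — geometric vector perceptron GNN over the residue
  graph.  Scalar channels are rotation/translation invariant, vector channels
  equivariant; messages are aggregated with a 1/sqrt(in-degree) scale,
  followed by residual + LayerNorm updates.
* :class:`SurfaceEncoder` — masked-patch Transformer over surface tokens in
  the point-MAE style: visible tokens (plus positional embeddings from an MLP
  on patch centers) pass through a deep encoder; a light decoder fills masked
  positions with a shared learnable mask token and predicts the K
  center-relative point coordinates of every masked patch.
* :class:`LigandMPNN` — edge-conditioned message passing over the molecular
  graph with sum aggregation and an MLP update, mean-pooled to f_ligand.

Parameters of any model are persisted as a named-array archive plus a config
manifest; loading refuses a checkpoint whose manifest disagrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, dropout, scatter_add
from ._nn import MLP, LayerNorm, Linear, Module, TransformerEncoderLayer, glorot
from .io_formats import AtomCloud, LigandGraph
from .patch_tokenizer import PatchSet, TokenEmbedder
from .protein_graph import ResidueGraph
from .surface_gen import SurfaceCloud


@dataclass
class GvpConfig:
    layers: int = 3
    node_scalar: int = 128
    node_vector: int = 32
    edge_scalar: int = 32
    edge_vector: int = 1
    dropout: float = 0.3

    def __post_init__(self):
        if min(self.layers, self.node_scalar, self.node_vector,
               self.edge_scalar, self.edge_vector) <= 0:
            raise ValueError("all GVP dimensions must be positive")


@dataclass
class SurfaceEncoderConfig:
    token_dim: int = 128
    enc_depth: int = 10
    enc_heads: int = 2
    dec_depth: int = 4
    dec_heads: int = 6
    mask_ratio: float = 0.6
    points_per_patch: int = 32
    dropout: float = 0.0

    def __post_init__(self):
        if self.token_dim % self.enc_heads or self.token_dim % self.dec_heads:
            raise ValueError("token_dim must be divisible by both head counts")


@dataclass
class Embedding:
    """Pooled protein/ligand vector plus the per-token matrix kept for fusion."""

    pooled: Tensor
    tokens: Tensor


# --------------------------------------------------------------------------
# GVP structural encoder


class GVP(Module):
    """One geometric vector perceptron with vector gating."""

    def __init__(self, rng, in_dims, out_dims, activate: bool = True):
        super().__init__()
        self.si, self.vi = in_dims
        self.so, self.vo = out_dims
        self.activate = activate
        self.h = max(self.vi, self.vo)
        if self.vi:
            self.wh = glorot(rng, self.vi, self.h)
            self.ws = Linear(rng, self.si + self.h, self.so)
            if self.vo:
                self.wv = glorot(rng, self.h, self.vo)
                self.wg = Linear(rng, self.so, self.vo)
        else:
            self.ws = Linear(rng, self.si, self.so)

    def __call__(self, s: Tensor, v: Tensor):
        if self.vi:
            vh = v.swapaxes(1, 2) @ self.wh                       # (n, 3, h)
            vn = ((vh * vh).sum(axis=1) + 1e-8).sqrt()            # (n, h) invariant
            s_out = self.ws(concat([s, vn], axis=1))
        else:
            s_out = self.ws(s)
        if self.activate:
            s_out = s_out.relu()
        if self.vo:
            vmu = (vh @ self.wv).swapaxes(1, 2)                   # (n, vo, 3)
            gate = self.wg(s_out).sigmoid()
            v_out = vmu * gate.reshape(gate.shape[0], self.vo, 1)
        else:
            v_out = Tensor(np.zeros((s_out.shape[0], 0, 3)))
        return s_out, v_out


def _vector_layernorm(v: Tensor) -> Tensor:
    n2 = (v * v).sum(axis=2).mean(axis=1, keepdims=True)          # (n, 1)
    inv = (n2 + 1e-8) ** -0.5
    return v * inv.reshape(inv.shape[0], 1, 1)


class GVPConvLayer(Module):
    def __init__(self, rng, node_dims, edge_dims, p_drop: float):
        super().__init__()
        ns, nv = node_dims
        es, ev = edge_dims
        self.msg1 = GVP(rng, (ns + es, nv + ev), node_dims)
        self.msg2 = GVP(rng, node_dims, node_dims, activate=False)
        self.ln1 = LayerNorm(ns)
        self.ff1 = GVP(rng, node_dims, (2 * ns, nv))
        self.ff2 = GVP(rng, (2 * ns, nv), node_dims, activate=False)
        self.ln2 = LayerNorm(ns)
        self.p_drop = p_drop

    def __call__(self, s, v, edge_index, es, ev, inv_sqrt_deg, train=False, rng=None):
        src, dst = edge_index
        ms, mv = self.msg2(*self.msg1(concat([s[src], es], axis=1),
                                      concat([v[src], ev], axis=1)))
        n = s.shape[0]
        agg_s = scatter_add(ms, dst, n) * inv_sqrt_deg.reshape(n, 1)
        agg_v = scatter_add(mv, dst, n) * Tensor(inv_sqrt_deg.data.reshape(n, 1, 1))
        if train and self.p_drop > 0:
            agg_s = dropout(agg_s, self.p_drop, rng, True)
            mask = (rng.random((n, agg_v.shape[1], 1)) >= self.p_drop) / (1 - self.p_drop)
            agg_v = agg_v * Tensor(mask)
        s = self.ln1(s + agg_s)
        v = _vector_layernorm(v + agg_v)
        fs, fv = self.ff2(*self.ff1(s, v))
        if train and self.p_drop > 0:
            fs = dropout(fs, self.p_drop, rng, True)
        s = self.ln2(s + fs)
        v = _vector_layernorm(v + fv)
        return s, v


class GVPEncoder(Module):
    """Stack of GVP message-passing layers; outputs invariant scalar tokens."""

    def __init__(self, rng, cfg: GvpConfig):
        super().__init__()
        self.cfg = cfg
        nd = (cfg.node_scalar, cfg.node_vector)
        ed = (cfg.edge_scalar, cfg.edge_vector)
        self.node_in = GVP(rng, (26, 1), nd)
        self.edge_in = GVP(rng, (16, 1), ed)
        self.layers = [GVPConvLayer(rng, nd, ed, cfg.dropout) for _ in range(cfg.layers)]

    def __call__(self, graph: ResidueGraph, train: bool = False, rng=None) -> Embedding:
        s = Tensor(graph.node_scalar)
        v = Tensor(graph.node_vector)
        es_in = Tensor(graph.edge_scalar)
        ev_in = Tensor(graph.edge_vector)
        s, v = self.node_in(s, v)
        es, ev = self.edge_in(es_in, ev_in)
        deg = np.bincount(graph.edge_index[1], minlength=graph.n_nodes).astype(float)
        inv_sqrt_deg = Tensor(1.0 / np.sqrt(np.maximum(deg, 1.0)))
        for layer in self.layers:
            s, v = layer(s, v, graph.edge_index, es, ev, inv_sqrt_deg, train, rng)
        if not np.all(np.isfinite(s.data)):
            raise FloatingPointError("non-finite values in GVP features")
        return Embedding(pooled=s.mean(axis=0), tokens=s)


# --------------------------------------------------------------------------
# masked-patch surface Transformer


class SurfaceEncoder(Module):
    def __init__(self, rng, cfg: SurfaceEncoderConfig):
        super().__init__()
        self.cfg = cfg
        d = cfg.token_dim
        self.embedder = TokenEmbedder(rng, token_dim=d)
        self.pos_mlp = MLP(rng, [3, 64, d])
        self.enc = [TransformerEncoderLayer(rng, d, cfg.enc_heads, cfg.dropout)
                    for _ in range(cfg.enc_depth)]
        self.enc_ln = LayerNorm(d)
        self.dec = [TransformerEncoderLayer(rng, d, cfg.dec_heads, cfg.dropout)
                    for _ in range(cfg.dec_depth)]
        self.dec_ln = LayerNorm(d)
        self.mask_token = Tensor(np.zeros((1, d)), requires_grad=True)
        self.recon_head = Linear(rng, d, cfg.points_per_patch * 3)

    def __call__(self, surface: SurfaceCloud, patchset: PatchSet, atoms: AtomCloud,
                 mode: str = "inference", train: bool = False, rng=None):
        """Returns (Embedding, recon) — recon is (n_masked, K, 3) in pretrain mode."""
        tokens = self.embedder(surface, patchset, atoms)
        pos = self.pos_mlp(Tensor(patchset.centers))
        g = patchset.n_patches
        if mode == "inference":
            x = tokens + pos
            for layer in self.enc:
                x = layer(x, rng, train)
            x = self.enc_ln(x)
            return Embedding(pooled=x.mean(axis=0), tokens=x), None

        mask = patchset.mask
        if mask.all():
            raise ValueError("all patches masked: nothing for the encoder")
        vis = np.flatnonzero(~mask)
        msk = np.flatnonzero(mask)
        x = tokens[vis] + pos[vis]
        for layer in self.enc:
            x = layer(x, rng, train)
        x = self.enc_ln(x)
        emb = Embedding(pooled=x.mean(axis=0), tokens=x)
        if len(msk) == 0:
            return emb, None
        # decoder sequence in original patch order: encoded visible + mask tokens
        mask_tok = concat([self.mask_token] * len(msk), axis=0) + pos[msk]
        seq = concat([x + pos[vis], mask_tok], axis=0)
        order = np.argsort(np.concatenate([vis, msk]), kind="stable")
        y = seq[order]
        for layer in self.dec:
            y = layer(y, rng, train)
        y = self.dec_ln(y)
        pred = self.recon_head(y[msk])
        K = self.cfg.points_per_patch
        return emb, pred.reshape(len(msk), K, 3)


# --------------------------------------------------------------------------
# ligand MPNN


class LigandMPNN(Module):
    def __init__(self, rng, node_dim: int, edge_dim: int, hidden: int = 64,
                 layers: int = 3, p_drop: float = 0.3):
        super().__init__()
        self.node_in = Linear(rng, node_dim, hidden)
        self.phi = [MLP(rng, [3 * hidden, hidden, hidden]) for _ in range(layers)]
        self.edge_in = Linear(rng, edge_dim, hidden)
        self.psi = [MLP(rng, [2 * hidden, hidden]) for _ in range(layers)]
        self.p_drop = p_drop

    def __call__(self, lig: LigandGraph, train: bool = False, rng=None) -> Embedding:
        h = self.node_in(Tensor(lig.node_feat)).relu()
        n = lig.n_atoms
        has_edges = lig.edge_index.shape[1] > 0
        if has_edges:
            e = self.edge_in(Tensor(lig.edge_feat)).relu()
            src, dst = lig.edge_index
        for phi, psi in zip(self.phi, self.psi):
            if has_edges:
                m = phi(concat([h[dst], h[src], e], axis=1))
                agg = scatter_add(m, dst, n)
            else:
                agg = Tensor(np.zeros(h.shape))
            h = psi(concat([h, agg], axis=1)).relu()
            if train and self.p_drop > 0:
                h = dropout(h, self.p_drop, rng, True)
        return Embedding(pooled=h.mean(axis=0), tokens=h)


# --------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path: str, module: Module, config: dict) -> None:
    """Named-array archive with a JSON manifest of the config."""
    state = {f"param/{k}": v for k, v in module.state_dict().items()}
    np.savez(path, manifest=np.array(json.dumps(config)), **state)


def load_checkpoint(path: str, module: Module, expected_config: dict) -> dict:
    with np.load(path, allow_pickle=False) as f:
        manifest = json.loads(str(f["manifest"]))
        if manifest != expected_config:
            raise ValueError(
                f"checkpoint config mismatch: saved {manifest}, expected {expected_config}"
            )
        state = {k[len("param/"):]: f[k] for k in f.files if k.startswith("param/")}
    module.load_state_dict(state)
    return manifest
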