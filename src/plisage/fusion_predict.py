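"""Structure-surface fusion, prediction heads, metrics and attention export.

Fusion modes:

* ``concat`` — mean-pool each projected token stream, concatenate, one FC;
* ``cross_attn`` — a Transformer decoder lets surface tokens cross-attend to
  the projected structure tokens, then pool/concat/FC;
* ``enc_dec`` — a self-attention encoder first contextualizes the structure
  tokens, the decoder then aligns the surface tokens to them (the adaptive
  fusion used by default).

The fused protein vector is concatenated with the MPNN ligand embedding and
fed to an MLP head: an unbounded scalar for affinity regression, a logit for
interaction classification.  Regression is scored with RMSE, MAE, Pearson,
Spearman, Roy's rm^2 and the concordance index; classification with
AUROC/AUPRC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from ._autodiff import Tensor, concat
from ._nn import (MLP, Adam, Linear, Module, TransformerDecoderLayer,
                  TransformerEncoderLayer)
from .encoders import (GVPEncoder, GvpConfig, LigandMPNN, SurfaceEncoder,
                       SurfaceEncoderConfig)
from .io_formats import AtomCloud, LigandGraph
from .patch_tokenizer import PatchSet
from .protein_graph import ResidueGraph
from .surface_gen import SurfaceCloud

FUSION_MODES = ("concat", "cross_attn", "enc_dec")


@dataclass
class FusionConfig:
    d_model: int = 128
    heads: int = 8
    enc_layers: int = 1
    dec_layers: int = 1
    dropout: float = 0.3
    mode: str = "enc_dec"

    def __post_init__(self):
        if self.d_model % self.heads:
            raise ValueError("d_model must be divisible by heads")
        if self.mode not in FUSION_MODES:
            raise ValueError(f"fusion mode must be one of {FUSION_MODES}")


@dataclass
class ComplexRecord:
    """One (protein, ligand, label) training example."""

    ligand: LigandGraph
    label: float
    task: str                      # "affinity" | "interaction"
    surface: SurfaceCloud | None = None
    patchset: PatchSet | None = None
    graph: ResidueGraph | None = None
    atoms: AtomCloud | None = None
    protein_id: str = ""

    def __post_init__(self):
        if self.task not in ("affinity", "interaction"):
            raise ValueError("task must be 'affinity' or 'interaction'")
        if self.task == "interaction" and self.label not in (0.0, 1.0, 0, 1):
            raise ValueError("interaction labels must be binary")


@dataclass
class AttentionMap:
    """Cross-attention of surface patches onto structure tokens."""

    weights: np.ndarray        # (g, V) averaged over heads; rows sum to 1
    per_head: np.ndarray       # (heads, g, V)
    centers: np.ndarray        # (g, 3)

    def to_table(self) -> pd.DataFrame:
        """One row per patch: center coordinates and a peakedness score.

        The score is the maximum attention the patch places on any structure
        token; sharply focused patches score high, diffuse ones near 1/V.
        """
        return pd.DataFrame({
            "x": self.centers[:, 0], "y": self.centers[:, 1], "z": self.centers[:, 2],
            "score": self.weights.max(axis=1),
        })


class FusionModule(Module):
    def __init__(self, rng, cfg: FusionConfig, struct_dim: int, surf_dim: int):
        super().__init__()
        self.cfg = cfg
        d = cfg.d_model
        self.proj_struct = Linear(rng, struct_dim, d)
        self.proj_surf = Linear(rng, surf_dim, d)
        self.enc = [TransformerEncoderLayer(rng, d, cfg.heads, cfg.dropout)
                    for _ in range(cfg.enc_layers)]
        self.dec = [TransformerDecoderLayer(rng, d, cfg.heads, cfg.dropout)
                    for _ in range(cfg.dec_layers)]
        self.fc = Linear(rng, 2 * d, d)
        self.last_attention: np.ndarray | None = None      # (heads, g, V)

    def __call__(self, struct_tokens: Tensor, surf_tokens: Tensor,
                 train: bool = False, rng=None) -> Tensor:
        if struct_tokens.shape[0] == 0 or surf_tokens.shape[0] == 0:
            raise ValueError("fusion requires non-empty token matrices")
        st = self.proj_struct(struct_tokens)
        su = self.proj_surf(surf_tokens)
        mode = self.cfg.mode
        self.last_attention = None
        if mode in ("cross_attn", "enc_dec"):
            if mode == "enc_dec":
                for layer in self.enc:
                    st = layer(st, rng, train)
            x = su
            for layer in self.dec:
                x = layer(x, st, rng, train)
            self.last_attention = self.dec[-1].cross_attn.last_weights
            su = x
        pooled = concat([su.mean(axis=0).reshape(1, -1),
                         st.mean(axis=0).reshape(1, -1)], axis=1)
        return self.fc(pooled).reshape(-1)


class PredictionModel(Module):
    """Encoders + fusion + ligand MPNN + task head."""

    def __init__(self, rng, gvp_cfg: GvpConfig, surf_cfg: SurfaceEncoderConfig,
                 fusion_cfg: FusionConfig, ligand_node_dim: int = 18,
                 ligand_edge_dim: int = 4, ligand_hidden: int = 64,
                 use_surface: bool = True, use_structure: bool = True,
                 head_dims=(128, 64), head_dropout: float = 0.3):
        super().__init__()
        if not (use_surface or use_structure):
            raise ValueError("at least one protein modality must be enabled")
        self.use_surface, self.use_structure = use_surface, use_structure
        self.gvp_encoder = GVPEncoder(rng, gvp_cfg)
        self.surface_encoder = SurfaceEncoder(rng, surf_cfg)
        self.fusion = FusionModule(rng, fusion_cfg, gvp_cfg.node_scalar,
                                   surf_cfg.token_dim)
        self.mpnn = LigandMPNN(rng, ligand_node_dim, ligand_edge_dim, ligand_hidden)
        self.head = MLP(rng, [fusion_cfg.d_model + ligand_hidden, *head_dims, 1],
                        p_drop=head_dropout)

    # ---- protein side ----------------------------------------------------
    def protein_tokens(self, record: ComplexRecord, train=False, rng=None):
        struct = self.gvp_encoder(record.graph, train, rng).tokens \
            if self.use_structure else None
        surf = self.surface_encoder(record.surface, record.patchset, record.atoms,
                                    mode="inference", train=train, rng=rng)[0].tokens \
            if self.use_surface else None
        return struct, surf

    def fuse_tokens(self, struct_tokens, surf_tokens, train=False, rng=None) -> Tensor:
        if struct_tokens is None:
            struct_tokens = surf_tokens    # single-modality ablation: mirror stream
        if surf_tokens is None:
            surf_tokens = struct_tokens
        return self.fusion(struct_tokens, surf_tokens, train, rng)

    def predict(self, record: ComplexRecord, train: bool = False, rng=None,
                cached_tokens=None) -> Tensor:
        """Scalar prediction: affinity value or classification logit."""
        if cached_tokens is not None:
            struct_tokens, surf_tokens = cached_tokens
            struct_tokens = Tensor(struct_tokens) if struct_tokens is not None else None
            surf_tokens = Tensor(surf_tokens) if surf_tokens is not None else None
        else:
            struct_tokens, surf_tokens = self.protein_tokens(record, train, rng)
        f_protein = self.fuse_tokens(struct_tokens, surf_tokens, train, rng)
        f_ligand = self.mpnn(record.ligand, train, rng).pooled
        f_complex = concat([f_protein.reshape(1, -1), f_ligand.reshape(1, -1)], axis=1)
        return self.head(f_complex, rng, train).reshape(-1)[0]

    def protein_encoder_parameters(self):
        for name, p in self.named_parameters():
            if name.startswith(("gvp_encoder.", "surface_encoder.")):
                yield p


# --------------------------------------------------------------------------
# losses


def loss_affinity(y: np.ndarray, y_hat: Tensor) -> Tensor:
    """Mean squared error."""
    y = np.asarray(y, dtype=np.float64)
    if y.shape[0] != y_hat.shape[0]:
        raise ValueError("length mismatch")
    diff = y_hat - Tensor(y)
    return (diff * diff).mean()


def loss_classification(y: np.ndarray, logits: Tensor) -> Tensor:
    """Numerically stable binary cross-entropy on logits."""
    y = np.asarray(y, dtype=np.float64)
    if y.shape[0] != logits.shape[0]:
        raise ValueError("length mismatch")
    z = logits
    abs_z = z.relu() + (-z).relu()
    return (z.relu() - z * Tensor(y) + (1.0 + (-abs_z).exp()).log()).mean()


# --------------------------------------------------------------------------
# metrics


def concordance_index(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Fraction of comparable label pairs ordered correctly (ties = 0.5)."""
    y, y_hat = np.asarray(y, float), np.asarray(y_hat, float)
    num = den = 0.0
    for i in range(len(y)):
        for j in range(i + 1, len(y)):
            if y[i] == y[j]:
                continue
            den += 1
            diff = (y_hat[i] - y_hat[j]) * (y[i] - y[j])
            num += 1.0 if diff > 0 else (0.5 if diff == 0 else 0.0)
    return num / den if den else float("nan")


def rm_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Roy's modified r^2: r^2 * (1 - sqrt(|r^2 - r0^2|)).

    r0^2 comes from the zero-intercept regression of predictions on labels.
    """
    y, y_hat = np.asarray(y, float), np.asarray(y_hat, float)
    r = np.corrcoef(y, y_hat)[0, 1]
    r2 = r * r
    k = (y * y_hat).sum() / (y * y).sum()
    ss_res = ((y_hat - k * y) ** 2).sum()
    ss_tot = ((y_hat - y_hat.mean()) ** 2).sum()
    r0sq = 1.0 - ss_res / ss_tot
    return r2 * (1.0 - np.sqrt(abs(r2 - r0sq)))


def evaluate(preds: np.ndarray, labels: np.ndarray, task: str) -> dict:
    """Metric table for a prediction set; needs at least 2 samples."""
    preds, labels = np.asarray(preds, float), np.asarray(labels, float)
    if len(preds) < 2:
        raise ValueError("need at least 2 samples to evaluate")
    if task == "affinity":
        if np.ptp(preds) == 0:
            warnings.warn("constant predictions: correlation metrics undefined")
            pear = spear = rm2 = float("nan")
        else:
            pear = stats.pearsonr(labels, preds).statistic
            spear = stats.spearmanr(labels, preds).statistic
            rm2 = rm_squared(labels, preds)
        return {
            "rmse": float(np.sqrt(np.mean((preds - labels) ** 2))),
            "mae": float(np.mean(np.abs(preds - labels))),
            "pearson": float(pear), "spearman": float(spear),
            "rm2": float(rm2), "ci": concordance_index(labels, preds),
        }
    return {
        "auroc": float(roc_auc_score(labels, preds)),
        "auprc": float(average_precision_score(labels, preds)),
    }


def export_attention(model: PredictionModel, record: ComplexRecord) -> AttentionMap:
    """Run one forward pass and capture the fusion cross-attention."""
    if model.fusion.cfg.mode == "concat":
        raise ValueError("attention export needs a cross-attention fusion mode")
    model.predict(record)
    per_head = model.fusion.last_attention
    return AttentionMap(weights=per_head.mean(axis=0), per_head=per_head,
                        centers=record.patchset.centers)


# --------------------------------------------------------------------------
# downstream training


@dataclass
class DownstreamResult:
    model: PredictionModel
    history: list = field(default_factory=list)


def _batch_loss(model, records, task, train, rng, cache):
    preds = [model.predict(r, train=train, rng=rng,
                           cached_tokens=cache.get(r.protein_id) if cache else None)
             for r in records]
    logits = concat([p.reshape(1) for p in preds], axis=0)
    y = np.array([r.label for r in records], dtype=float)
    loss = loss_affinity(y, logits) if task == "affinity" else loss_classification(y, logits)
    return loss, logits.data


def predict_dataset(model, records, cache=None) -> np.ndarray:
    return np.array([model.predict(
        r, cached_tokens=cache.get(r.protein_id) if cache else None).item()
        for r in records])


def build_token_cache(model: PredictionModel, records) -> dict:
    """Precompute protein tokens once when the encoders are frozen."""
    cache = {}
    for r in records:
        if r.protein_id not in cache:
            st, su = model.protein_tokens(r)
            cache[r.protein_id] = (None if st is None else st.data,
                                   None if su is None else su.data)
    return cache


def train_downstream(
    train_records: list[ComplexRecord],
    task: str,
    seed: int = 0,
    val_records: list[ComplexRecord] | None = None,
    checkpoint: str | None = None,
    checkpoint_config: dict | None = None,
    freeze: bool = True,
    epochs: int = 100,
    batch_size: int = 16,
    lr: float = 1e-4,
    weight_decay: float = 5e-4,
    eval_every: int = 10,
    dropout_active: bool = False,
    model: PredictionModel | None = None,
    model_kwargs: dict | None = None,
) -> DownstreamResult:
    """Fine-tune fusion + ligand encoder + head on labeled complexes.

    The protein encoders are loaded from a pretraining checkpoint when given
    and frozen by default; `freeze=False` lets gradients flow into them.
    """
    if not train_records:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    if model is None:
        kw = dict(model_kwargs or {})
        model = PredictionModel(np.random.default_rng(seed + 1), **kw)
    if checkpoint:
        from ._nn import Module as _M

        pre = _M()
        pre.surface_encoder = model.surface_encoder
        pre.gvp_encoder = model.gvp_encoder
        state_names = dict(pre.named_parameters())
        import json as _json

        with np.load(checkpoint, allow_pickle=False) as f:
            manifest = _json.loads(str(f["manifest"]))
            if checkpoint_config is not None and manifest != checkpoint_config:
                raise ValueError("checkpoint config mismatch")
            for k in f.files:
                if k.startswith("param/"):
                    name = k[len("param/"):]
                    if name in state_names:
                        if state_names[name].data.shape != f[k].shape:
                            raise ValueError(f"checkpoint shape mismatch for {name}")
                        state_names[name].data = f[k].astype(np.float64)

    frozen = set(map(id, model.protein_encoder_parameters())) if freeze else set()
    params = [p for p in model.parameters() if id(p) not in frozen]
    optimizer = Adam(params, lr=lr, weight_decay=weight_decay)
    cache = build_token_cache(model, train_records + (val_records or [])) if freeze else None
    drop_rng = np.random.default_rng(seed + 2) if dropout_active else None

    history = []
    n = len(train_records)
    for epoch in range(epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, batch_size):
            batch = [train_records[i] for i in order[start:start + batch_size]]
            loss, _ = _batch_loss(model, batch, task, drop_rng is not None,
                                  drop_rng, cache)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            ep_loss += loss.item() * len(batch)
        rec = {"epoch": epoch, "train_loss": ep_loss / n}
        if val_records and (epoch % eval_every == 0 or epoch == epochs - 1):
            preds = predict_dataset(model, val_records, cache)
            rec.update({f"val_{k}": v for k, v in evaluate(
                preds, [r.label for r in val_records], task).items()})
        history.append(rec)
    return DownstreamResult(model=model, history=history)
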