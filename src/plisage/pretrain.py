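"""Joint self-supervised pretraining of the surface and structure encoders.

Two objectives are optimized together on unlabeled proteins:

* an InfoNCE contrastive loss that aligns each protein's pooled surface
  embedding with its own structure embedding against in-batch negatives
  (cosine similarity at temperature tau, denominator over the structure side);
* a Chamfer reconstruction loss on the masked surface patches, comparing the
  decoder's predicted center-relative point coordinates with the true patch
  points (squared-distance convention).

The total loss is lambda_cont * L_contrastive + lambda_recon * L_recon.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, concat
from ._nn import Adam, Linear, Module
from .encoders import GVPEncoder, SurfaceEncoder
from .io_formats import AtomCloud
from .patch_tokenizer import PatchSet, mask_patches
from .protein_graph import ResidueGraph
from .surface_gen import SurfaceCloud


@dataclass
class ProteinSample:
    """One pretraining example: surface + patches + residue graph."""

    surface: SurfaceCloud
    patchset: PatchSet
    graph: ResidueGraph
    atoms: AtomCloud
    protein_id: str = ""


@dataclass
class PretrainBatch:
    proteins: list
    tau: float = 0.05
    lambda_contrastive: float = 1.0
    lambda_reconstruction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0 or len(self.proteins) < 1:
            raise ValueError("need tau > 0 and at least one protein")
        if self.lambda_contrastive < 0 or self.lambda_reconstruction < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class ReconTarget:
    predicted: Tensor      # (K, 3) center-relative
    true: np.ndarray       # (K, 3) center-relative


def contrastive_loss(f_surf: Tensor, f_struct: Tensor, tau: float = 0.05) -> Tensor:
    """Cosine-similarity InfoNCE averaged over the batch.

    Positives are the matched (surface_i, structure_i) pairs; the denominator
    runs over all structure embeddings in the batch.
    """
    if f_surf.shape != f_struct.shape:
        raise ValueError("batch shapes must match")
    for f in (f_surf, f_struct):
        if np.any(np.linalg.norm(f.data, axis=1) < 1e-12):
            raise FloatingPointError("zero-norm embedding in contrastive loss")
    a = f_surf / f_surf.norm(axis=1, keepdims=True)
    b = f_struct / f_struct.norm(axis=1, keepdims=True)
    sim = (a @ b.swapaxes(0, 1)) * (1.0 / tau)          # (B, B)
    logp = sim.log_softmax(axis=1)
    diag = np.arange(f_surf.shape[0])
    return -logp[diag, diag].mean()


def chamfer_loss(targets: list[ReconTarget]) -> Tensor:
    """Symmetric squared-distance Chamfer loss over all masked patches.

    Normalized by the total number of reconstructed points |M|.
    """
    if not targets:
        raise ValueError("chamfer_loss needs at least one masked patch")
    total = None
    n_points = 0
    for t in targets:
        pred, true = t.predicted, np.asarray(t.true, dtype=np.float64)
        if pred.shape[0] == 0 or len(true) == 0:
            raise ValueError("empty point set in reconstruction target")
        n_points += pred.shape[0]
        diff = pred.reshape(pred.shape[0], 1, 3) - Tensor(true[None, :, :])
        d2 = (diff * diff).sum(axis=2)                  # (K_pred, K_true)
        term = d2.min(axis=1).sum() + d2.min(axis=0).sum()
        total = term if total is None else total + term
    return total * (1.0 / n_points)


class Pretrainer(Module):
    """Owns both protein encoders and the contrastive projection heads."""

    def __init__(self, rng, surface_encoder: SurfaceEncoder, gvp_encoder: GVPEncoder,
                 proj_dim: int = 64):
        super().__init__()
        self.surface_encoder = surface_encoder
        self.gvp_encoder = gvp_encoder
        self.proj_surf = Linear(rng, surface_encoder.cfg.token_dim, proj_dim)
        self.proj_struct = Linear(rng, gvp_encoder.cfg.node_scalar, proj_dim)

    def forward_batch(self, batch: PretrainBatch, mask_seed: int, train: bool = False,
                      rng=None):
        """Per-protein encoder passes; returns (f_surf, f_struct, recon targets)."""
        surf_rows, struct_rows, targets = [], [], []
        ratio = self.surface_encoder.cfg.mask_ratio
        for i, p in enumerate(batch.proteins):
            mask_patches(p.patchset, ratio, seed=mask_seed + 7919 * i)
            emb, recon = self.surface_encoder(
                p.surface, p.patchset, p.atoms, mode="pretrain", train=train, rng=rng)
            s_emb = self.gvp_encoder(p.graph, train=train, rng=rng)
            surf_rows.append(emb.pooled.reshape(1, -1))
            struct_rows.append(s_emb.pooled.reshape(1, -1))
            if recon is not None:
                msk = np.flatnonzero(p.patchset.mask)
                for row, patch in enumerate(msk):
                    true = (p.surface.points[p.patchset.patch_idx[patch]]
                            - p.patchset.centers[patch])
                    targets.append(ReconTarget(recon[row], true))
        f_surf = self.proj_surf(concat(surf_rows, axis=0))
        f_struct = self.proj_struct(concat(struct_rows, axis=0))
        return f_surf, f_struct, targets


def pretrain_step(trainer: Pretrainer, batch: PretrainBatch, optimizer: Adam,
                  step: int, train_rng=None) -> dict:
    """One joint optimization step; returns the loss components."""
    f_surf, f_struct, targets = trainer.forward_batch(
        batch, mask_seed=batch.seed + 104729 * step, train=train_rng is not None,
        rng=train_rng)
    l_cont = contrastive_loss(f_surf, f_struct, batch.tau)
    l_rec = chamfer_loss(targets) if targets else Tensor(0.0)
    lam1, lam2 = batch.lambda_contrastive, batch.lambda_reconstruction
    optimizer.zero_grad()
    if lam1 > 0 or lam2 > 0:
        total = l_cont * lam1 + l_rec * lam2
        if not np.isfinite(total.data):
            raise FloatingPointError(
                f"non-finite pretraining loss at step {step}: "
                f"contrastive={l_cont.item():.4g} reconstruction={l_rec.item():.4g}")
        total.backward()
        total_val = total.item()
    else:
        total_val = 0.0
    optimizer.step()
    return {"step": step, "loss_contrastive": l_cont.item(),
            "loss_reconstruction": l_rec.item(), "loss_total": total_val}


class PlateauScheduler:
    """Halve the learning rate when the loss stops improving."""

    def __init__(self, optimizer: Adam, patience: int = 5, factor: float = 0.5):
        self.opt, self.patience, self.factor = optimizer, patience, factor
        self.best = np.inf
        self.bad = 0

    def update(self, loss: float):
        if loss < self.best - 1e-12:
            self.best, self.bad = loss, 0
        else:
            self.bad += 1
            if self.bad > self.patience:
                self.opt.lr *= self.factor
                self.bad = 0


def pretrain(trainer: Pretrainer, proteins: list, n_steps: int = 50, seed: int = 0,
             lr: float = 1e-4, weight_decay: float = 1e-4, tau: float = 0.05,
             lambda_contrastive: float = 1.0, lambda_reconstruction: float = 1.0,
             dropout_active: bool = False, log_path: str | None = None) -> list[dict]:
    """Full-batch pretraining loop; returns the per-step loss history."""
    optimizer = Adam(trainer.parameters(), lr=lr, weight_decay=weight_decay)
    scheduler = PlateauScheduler(optimizer)
    batch = PretrainBatch(proteins, tau, lambda_contrastive, lambda_reconstruction, seed)
    drop_rng = np.random.default_rng(seed + 1) if dropout_active else None
    history = []
    for step in range(n_steps):
        rec = pretrain_step(trainer, batch, optimizer, step, train_rng=drop_rng)
        scheduler.update(rec["loss_total"])
        history.append(rec)
    if log_path:
        with open(log_path, "w", newline="") as f:
            writer = csv.DictWriter(f, fieldnames=list(history[0].keys()))
            writer.writeheader()
            writer.writerows(history)
    return history
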