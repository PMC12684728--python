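"""Patch tokenization of the surface point cloud.

The surface is partitioned into g overlapping patches: farthest point
sampling (FPS) picks well-spread centers, K-nearest-neighbor grouping collects
each patch's points.  A learnable token embedder turns every patch into one
D-dim vector by message passing over each point's 16 (distance, atom type)
chemical neighbor pairs, concatenating the 10-dim curvature feature and the
patch-center-relative coordinates, applying a shared per-point MLP and
max-pooling over the K points.  Patches can be masked for the reconstruction
pretraining objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from ._autodiff import Tensor, concat
from ._nn import MLP, Module
from .io_formats import AtomCloud
from .protein_graph import rbf_expand
from .surface_gen import SurfaceCloud

CHEM_RBF_CENTERS = np.linspace(0.0, 8.0, 8)
CHEM_RBF_WIDTH = CHEM_RBF_CENTERS[1] - CHEM_RBF_CENTERS[0]


@dataclass
class PatchSet:
    centers: np.ndarray              # (g, 3) patch center coordinates
    center_idx: np.ndarray           # (g,) surface-point index of each center
    patch_idx: np.ndarray            # (g, K) surface-point indices per patch
    center_order: np.ndarray         # FPS visit order (same indices)
    tokens: Tensor | None = None     # (g, D) after embedding
    mask: np.ndarray = field(default=None)  # (g,) bool

    @property
    def n_patches(self) -> int:
        return len(self.center_idx)


def farthest_point_sample(points: np.ndarray, g: int, seed: int = 0):
    """Greedy FPS: returns (indices, visit order), ties to the lower index."""
    n = len(points)
    if g > n:
        raise ValueError(f"cannot sample {g} centers from {n} points")
    rng = np.random.default_rng(seed)
    start = int(rng.integers(n))
    chosen = [start]
    mind = np.linalg.norm(points - points[start], axis=1)
    for _ in range(g - 1):
        nxt = int(np.argmax(mind))          # argmax takes the first max: lower index wins
        chosen.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(points - points[nxt], axis=1))
    order = np.array(chosen, dtype=int)
    return order, order.copy()


def knn_patches(points: np.ndarray, centers: np.ndarray, K: int) -> np.ndarray:
    """(g, K) indices of the K nearest surface points per center index."""
    if K > len(points):
        raise ValueError("K exceeds number of surface points")
    d = cdist(points[centers], points)
    return np.argsort(d, axis=1, kind="stable")[:, :K]


def build_patches(surface: SurfaceCloud, g: int, K: int, seed: int = 0) -> PatchSet:
    """FPS + KNN partitioning; g is clamped to the available point count."""
    n = surface.n_points
    if g > n:
        import warnings

        warnings.warn(f"requested {g} patches from {n} points; clamping g to {n}")
        g = n
    K = min(K, n)
    idx, order = farthest_point_sample(surface.points, g, seed)
    patch_idx = knn_patches(surface.points, idx, K)
    return PatchSet(
        centers=surface.points[idx],
        center_idx=idx,
        patch_idx=patch_idx,
        center_order=order,
        mask=np.zeros(g, dtype=bool),
    )


def mask_patches(patchset: PatchSet, ratio: float = 0.6, seed: int = 0) -> PatchSet:
    """Mask floor(g * ratio) patches uniformly at random (seeded, in place)."""
    if not 0.0 <= ratio < 1.0:
        raise ValueError("ratio must be in [0, 1)")
    g = patchset.n_patches
    n_mask = int(np.floor(g * ratio))
    rng = np.random.default_rng(seed)
    mask = np.zeros(g, dtype=bool)
    mask[rng.choice(g, size=n_mask, replace=False)] = True
    patchset.mask = mask
    return patchset


class TokenEmbedder(Module):
    """Per-patch token: chemical message passing + geometry, max-pooled.

    Translation invariant by construction: only center-relative coordinates,
    atom distances and curvatures enter the embedding.
    """

    def __init__(self, rng, token_dim: int = 128, hidden: int = 64):
        super().__init__()
        n_chem_in = len(CHEM_RBF_CENTERS) + 6      # distance RBF + element one-hot
        self.chem1 = MLP(rng, [n_chem_in, hidden, hidden])
        self.chem2 = MLP(rng, [2 * hidden, hidden])
        self.point_mlp = MLP(rng, [hidden + 10 + 3, hidden, token_dim])
        self.token_dim = token_dim

    def _point_features(self, surface: SurfaceCloud, atoms: AtomCloud,
                        point_idx: np.ndarray, rel_coords: np.ndarray) -> Tensor:
        """(n_pts, D_pre) per-point features for arbitrary point selections."""
        n_pts = len(point_idx)
        dist = surface.chem_dist[point_idx]                 # (n, 16)
        types = atoms.elements[surface.chem_idx[point_idx]]  # (n, 16, 6)
        drbf = rbf_expand(dist, CHEM_RBF_CENTERS, CHEM_RBF_WIDTH)  # (n, 16, 8)
        nbr = Tensor(np.concatenate([drbf, types], axis=2).reshape(n_pts * 16, -1))
        m1 = self.chem1(nbr).relu().reshape(n_pts, 16, -1)   # neighbor messages
        h0 = m1.mean(axis=1)                                  # first aggregation
        h0b = concat([h0.reshape(n_pts, 1, -1)] * 16, axis=1)
        m2 = self.chem2(concat([h0b, m1], axis=2).reshape(n_pts * 16, -1)).relu()
        h_chem = m2.reshape(n_pts, 16, -1).mean(axis=1)       # second aggregation
        geo = Tensor(np.concatenate([surface.geom[point_idx], rel_coords], axis=1))
        return concat([h_chem, geo], axis=1)

    def __call__(self, surface: SurfaceCloud, patchset: PatchSet, atoms: AtomCloud) -> Tensor:
        """(g, D) tokens for all patches."""
        g, K = patchset.patch_idx.shape
        flat = patchset.patch_idx.reshape(-1)
        rel = (surface.points[flat].reshape(g, K, 3) - patchset.centers[:, None, :]).reshape(-1, 3)
        feats = self._point_features(surface, atoms, flat, rel)
        per_point = self.point_mlp(feats).reshape(g, K, self.token_dim)
        return per_point.max(axis=1)

    def embed_patch(self, surface: SurfaceCloud, atoms: AtomCloud,
                    point_idx: np.ndarray, center: np.ndarray) -> Tensor:
        """Token for a single patch given its point indices and center."""
        rel = surface.points[point_idx] - center
        feats = self._point_features(surface, atoms, np.asarray(point_idx), rel)
        return self.point_mlp(feats).max(axis=0)
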