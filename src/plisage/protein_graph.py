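"""Residue-level directed KNN graph with scalar/vector geometric features.

Each residue is a node carrying a 26-dim scalar feature (20-dim amino-acid
one-hot plus sin/cos of the backbone dihedrals phi, psi, omega) and one
3-vector (the unit C-alpha -> C-beta direction; zero for glycine).  A directed
edge j -> i exists when C-alpha of residue j is among the k nearest neighbors
of C-alpha of residue i; edges carry a 16-dim Gaussian RBF expansion of the
C-alpha distance and the unit inter-C-alpha direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io_formats import ResidueBackbone

RBF_CENTERS = np.linspace(0.0, 20.0, 16)
RBF_WIDTH = RBF_CENTERS[1] - RBF_CENTERS[0]
DEFAULT_KNN = 30


@dataclass
class ResidueGraph:
    node_scalar: np.ndarray   # (V, 26)
    node_vector: np.ndarray   # (V, 1, 3)
    edge_index: np.ndarray    # (2, E): row 0 = source j, row 1 = target i
    edge_scalar: np.ndarray   # (E, 16)
    edge_vector: np.ndarray   # (E, 1, 3)

    @property
    def n_nodes(self) -> int:
        return len(self.node_scalar)

    def to_json(self) -> str:
        """Debug dump (arrays as lists)."""
        return json.dumps({
            "n_nodes": self.n_nodes,
            "n_edges": self.edge_index.shape[1],
            "node_scalar": self.node_scalar.tolist(),
            "edge_index": self.edge_index.tolist(),
        })


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral about the p1-p2 axis, radians; 0 if degenerate."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    m = np.linalg.norm(b1)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9 or m < 1e-9:
        return 0.0
    return float(np.arctan2((np.cross(n1, n2) @ b1) / m, n1 @ n2))


def backbone_dihedrals(bb: ResidueBackbone) -> np.ndarray:
    """(V, 3) array of (phi, psi, omega) per residue, radians.

    phi_i uses (C_{i-1}, N_i, CA_i, C_i); psi_i uses (N_i, CA_i, C_i, N_{i+1});
    omega_i uses (CA_i, C_i, N_{i+1}, CA_{i+1}) (peptide bond i -> i+1).
    Angles undefined at a terminus are 0.
    """
    v = bb.n_residues
    ang = np.zeros((v, 3))
    for i in range(v):
        if i > 0:
            ang[i, 0] = dihedral_angle(bb.c[i - 1], bb.n[i], bb.ca[i], bb.c[i])
        if i < v - 1:
            ang[i, 1] = dihedral_angle(bb.n[i], bb.ca[i], bb.c[i], bb.n[i + 1])
            ang[i, 2] = dihedral_angle(bb.ca[i], bb.c[i], bb.n[i + 1], bb.ca[i + 1])
    return ang


def rbf_expand(d, centers: np.ndarray = RBF_CENTERS, width: float = RBF_WIDTH) -> np.ndarray:
    """Gaussian RBF expansion exp(-(d - mu)^2 / (2 w^2)) over the centers."""
    d = np.atleast_1d(np.asarray(d, dtype=np.float64))
    return np.exp(-((d[..., None] - centers) ** 2) / (2.0 * width ** 2))


def build_graph(bb: ResidueBackbone, k: int = DEFAULT_KNN) -> ResidueGraph:
    """Directed KNN residue graph with GVP-style node/edge features."""
    v = bb.n_residues
    if v < 2:
        raise ValueError("need at least 2 residues to build a graph")
    # node scalars: 20-dim AA one-hot (non-canonical -> zeros) + dihedral sin/cos
    onehot = np.zeros((v, 20))
    for i, a in enumerate(bb.aa_index):
        if 0 <= a < 20:
            onehot[i, a] = 1.0
    ang = backbone_dihedrals(bb)
    trig = np.stack(
        [np.sin(ang[:, 0]), np.cos(ang[:, 0]),
         np.sin(ang[:, 1]), np.cos(ang[:, 1]),
         np.sin(ang[:, 2]), np.cos(ang[:, 2])], axis=1)
    node_scalar = np.concatenate([onehot, trig], axis=1)

    # node vectors: unit CA -> CB, zero for glycine / missing CB
    cb_dir = bb.cb - bb.ca
    node_vector = np.zeros((v, 1, 3))
    for i in range(v):
        if np.all(np.isfinite(cb_dir[i])):
            nrm = np.linalg.norm(cb_dir[i])
            if nrm > 1e-9:
                node_vector[i, 0] = cb_dir[i] / nrm

    # directed KNN edges j -> i on CA distances; distances equal within 1e-6 Å
    # count as tied and resolve to the lower residue index, so symmetric
    # chains give the same graph regardless of orientation
    d = squareform(pdist(bb.ca))
    dq = np.round(d, 6)
    kk = min(k, v - 1)
    src, dst = [], []
    for i in range(v):
        cand = np.delete(np.arange(v), i)
        order = np.lexsort((cand, dq[i, cand]))
        for j in cand[order[:kk]]:
            src.append(j)
            dst.append(i)
    edge_index = np.array([src, dst], dtype=int)
    dvec = bb.ca[edge_index[1]] - bb.ca[edge_index[0]]
    dist = np.linalg.norm(dvec, axis=1)
    edge_scalar = rbf_expand(dist)
    edge_vector = (dvec / dist[:, None])[:, None, :]
    return ResidueGraph(node_scalar, node_vector, edge_index, edge_scalar, edge_vector)
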