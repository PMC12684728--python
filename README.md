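# plisage

Predicting protein–ligand binding affinity and interaction from a **joint
surface + structure representation** of the protein, pretrained without
labels.

Structure-based affinity predictors usually encode only the residue graph of
a protein and ignore the molecular surface — the geometric and chemical
interface a ligand actually touches. `plisage` builds both views and aligns
them by self-supervision:

1. **Surface generation.** The molecular surface is the r-level set of a
   smoothed distance function over the atom cloud (atoms restricted to
   {C, H, O, N, S, Se}, van der Waals radii σ):

   `SDF(x) = −σ̄(x) · log Σₖ exp(−‖x − cₖ‖ / σₖ)`,

   with σ̄(x) the softmin-weighted mean radius.  Points are sampled by
   minimizing `½ Σᵢ (SDF(xᵢ) − r)²` at r = 1 Å, then given unit normals
   (∇SDF), mean/Gaussian curvatures (H, K) at scales 1/2/3/5/10 Å from local
   quadric fits, and their 16 nearest atoms with distances as chemical
   context.
2. **Patch tokens.** Farthest point sampling picks g centers, KNN groups K
   points per patch, and a learnable embedder (message passing over each
   point's chemical neighbors, max-pooled with the curvature features) turns
   every patch into one token for a Transformer encoder (a point-MAE style
   masked autoencoder).
3. **Structure encoder.** A geometric vector perceptron (GVP) GNN over the
   residue graph — 26-dim scalar node features (amino-acid one-hot +
   sin/cos φ, ψ, ω), unit Cα→Cβ vectors, directed k=30 nearest-neighbor
   edges with 16 Gaussian RBF distance features — invariant scalars,
   equivariant vectors, messages scaled by 1/√(in-degree).
4. **Joint pretraining.** InfoNCE contrastive loss (cosine similarity,
   τ = 0.05) aligns pooled surface and structure embeddings across the
   batch, while a Chamfer loss reconstructs the 60 % of patches that were
   masked: `L = λ₁·L_contrastive + λ₂·L_reconstruction` (λ₁ = λ₂ = 1).
5. **Prediction.** A ligand MPNN embeds the molecular graph; an adaptive
   fusion module (self-attention over structure tokens, cross-attention of
   surface tokens onto them, pool/concat/FC) yields f_protein;
   `f_complex = [f_protein; f_ligand]` feeds an MLP head trained with MSE
   (affinity) or BCE-with-logits (interaction).  Cross-attention weights can
   be exported per surface patch to localize predicted binding regions.

All tensor math, including backpropagation through the GVP, Transformer and
MPNN, runs on an in-repo reverse-mode autodiff engine over numpy — the
package has no deep-learning-framework dependency.

## Worked example

```python
import numpy as np
from plisage import (SyntheticSpec, make_protein, generate_surface,
                     build_patches, build_graph)

# a 20-residue ideal α-helix written as a PDB-compatible chain
pdb_text, backbone, atoms = make_protein(
    SyntheticSpec(n_residues=20, geometry="helix", seed=1))
surface = generate_surface(atoms, r=1.0, n_init=8, seed=0)
print(surface.n_points)                       # 785 surface points
resid = np.abs(np.linalg.norm(surface.points, axis=1))
patches = build_patches(surface, g=32, K=16, seed=0)
graph = build_graph(backbone, k=10)
print(graph.n_nodes, graph.edge_index.shape[1])   # 20 nodes, 200 edges
print(surface.geom[:, 2].mean().round(3))     # mean curvature at 2 Å scale
```

Running this prints `785`, `20 200` and a positive mean curvature
(`0.058` with these seeds) — the helix surface is convex on average at the
2 Å probe scale, as expected for a thin tube with grooves.  Every retained
surface point satisfies |SDF − 1 Å| ≤ 10⁻³.

A full training round-trip on synthetic data (planted interaction signal:
carboxylate ligands bind helix proteins):

```bash
plisage synth --spec '{"n_complexes": 16, "n_proteins": 4, "label_rule": "motif"}' --out data/
plisage pretrain --data data/ --steps 30 --out ckpt.npz \
    --set token_dim=32 --set enc_depth=2 --set dec_depth=1 --set dec_heads=2 \
    --set node_scalar=32 --set node_vector=8 --set edge_scalar=16 \
    --set gvp_layers=2 --set num_group=32 --set group_size=16
plisage train --task interaction --data data/manifest.tsv --ckpt ckpt.npz --out model.npz [...]
plisage attention --model model.npz --pdb data/prot0.pdb --ligand "CCC(=O)O" --out attn.csv
```

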