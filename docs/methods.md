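# Methods

This note records the model, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Surface model

The protein surface is an implicit surface: the r-level set of a smoothed
distance function (SDF) over the atom cloud,
`SDF(x) = −σ̄(x)·log Σₖ exp(−‖x−cₖ‖/σₖ)`, where σₖ is the van der Waals
radius of atom k (C 1.70, H 1.10, O 1.52, N 1.55, S 1.80, Se 1.90 Å — a
fixed internal table) and `σ̄(x) = Σ wₖσₖ / Σ wₖ` with softmin weights
`wₖ = exp(−‖x−cₖ‖/σₖ)`.  For a single atom the SDF reduces exactly to the
Euclidean distance, which anchors the unit tests.  The level radius defaults
to r = 1 Å.

**Sampling.** Candidates start on spheres of radius σⱼ + r around every atom
(`n_init` Fibonacci directions per atom, default 8, plus seeded jitter) and
descend the residual: each step moves `clip(SDF−r, ±0.5 Å)` along the
normalized analytic gradient, for at most 200 iterations or until the
maximum residual change falls below 1e-5.  Points with |SDF − r| > 1e-3 Å
are discarded.  Survivors are thinned to one per 0.25 Å voxel, keeping the
point closest to the level set; residuals are compared after quantization to
1e-6 so that converged near-ties resolve by candidate index.  The voxel size
was chosen so that small high-curvature features (down to the single-atom
unit sphere, which must carry ≥ 100 points to be a usable patch source)
retain adequate density; there is no canonical target density for point
sampled molecular surfaces and this is an engineering choice.

**Equivariance by construction.** Candidate directions and the thinning grid
are expressed in a canonical frame computed from the atom cloud: covariance
eigenvectors ordered by eigenvalue, signs fixed by third moments, third axis
by right-handedness.  Any rigid motion of the atoms moves the frame with
them, so the sampled point set co-rotates exactly (verified to ~1e-13 Å;
tested at 1e-3).  Degenerate clouds (a single atom, perfectly symmetric
arrangements) fall back to the identity frame; such inputs appear only in
closed-form tests where equivariance is not at issue.  Because several
jittered candidates can converge to the same surface point with equal
residual, comparisons across rigid motions align point sets by nearest
neighbor rather than by row order.

**Features.** Normals are the normalized analytic SDF gradient (outward).
Curvatures at scales {1, 2, 3, 5, 10} Å come from a Gaussian-weighted
(bandwidth = scale/2) least-squares quadric fit `z = au² + buv + cv²` in the
tangent frame, with height measured along the inward direction so that a
convex protrusion has H = a + c > 0 and K = 4ac − b²; neighborhoods with
fewer than 5 points yield (0, 0) rather than an error.  H and K are
invariant to the in-plane tangent basis (trace and determinant of the shape
operator), so no canonical tangent choice is needed.  Chemical context is
the exact 16 nearest atoms with ascending distances; clouds with fewer than
16 atoms repeat the farthest atom.

## Residue graph

Nodes carry a 26-dim scalar (20-dim amino-acid one-hot — non-canonical
residues get an all-zero block — plus sin/cos of φ, ψ, ω) and one vector
(unit Cα→Cβ; zero for glycine or missing Cβ).  ω is assigned to the peptide
bond i→i+1; dihedrals undefined at termini are encoded as 0 (sin 0, cos 1).
Edges j→i connect each residue to its k = 30 nearest Cα neighbors with a
16-center Gaussian RBF expansion of the Cα distance (centers linspace(0,
20 Å), width = spacing) and the unit inter-Cα direction.  Distances equal
within 1e-6 Å count as tied and resolve to the lower residue index, which
keeps graphs of symmetric chains (ideal helices have many exact distance
ties) identical across orientations.

## Encoders

*GVP-GNN*: geometric vector perceptrons with vector gating; messages are
two stacked GVPs on the concatenated neighbor node + edge features,
aggregated with a 1/√(in-degree) scale, followed by residual + LayerNorm
(standard LayerNorm on scalars, RMS normalization over vector channels) and
a feed-forward GVP block.  Scalar channels are rigid-motion invariant,
vectors equivariant; the pooled embedding uses scalars only.  Defaults:
3 layers, 128/32 node dims, 32/1 edge dims, dropout 0.3.

*Surface Transformer*: point-MAE style.  Patch tokens (below) plus a 2-layer
MLP positional embedding of the absolute patch center pass through a
pre-LN Transformer encoder (depth 10, 2 heads by default).  In pretraining,
only unmasked tokens are encoded; a lighter decoder (depth 4, 6 heads)
sees the encoded tokens plus a shared learnable mask token carrying each
masked position's positional embedding, and a linear head predicts the K×3
center-relative coordinates of every masked patch.  Patch K-point
coordinates enter the embedder center-relative, making tokens translation
invariant.

*Patch tokens*: each surface point's 16 (distance, element) neighbor pairs
go through two message-passing layers (distance expanded in 8 RBFs on
[0, 8] Å); the aggregate is concatenated with the 10 curvature features and
the center-relative coordinates, mapped by a shared MLP and max-pooled over
the K patch points — hence permutation invariant within a patch.

*Ligand MPNN*: RDKit-parsed molecular graphs (element/degree one-hots,
formal charge, aromaticity; bond-type edge features, both directions).
Three rounds of edge-conditioned messages with sum aggregation and an MLP
update over the concatenated (state, aggregate), mean-pooled (hidden 64,
dropout 0.3).

## Objectives

Contrastive: linear projection heads map both pooled embeddings to a shared
dimension; the loss is cosine-similarity InfoNCE at τ = 0.05 with in-batch
negatives taken over the structure side only (the printed one-directional
form; a symmetric variant was deliberately not added).  A batch of one gives
exactly zero loss.  Reconstruction: symmetric Chamfer distance with squared
Euclidean distances (the point-cloud-MAE convention), normalized by the
total number of masked points.  Total: `λ₁·L_cont + λ₂·L_recon`, λ₁ = λ₂ = 1.
Optimizer: Adam (lr 1e-4, weight decay 1e-4, plateau halving with patience
5); downstream fine-tuning uses lr 1e-4, weight decay 5e-4, batch 16, with
the protein encoders frozen by default (a flag unfreezes them; whether
fine-tuning should ever update the encoders is a genuinely open choice).

## Numerical engine

All differentiable computation runs on a small reverse-mode autodiff engine
over float64 numpy arrays (`_autodiff.py`) with a conventional layer library
(`_nn.py`).  This keeps the package dependency-light and bitwise
reproducible on CPU: identical seeds give identical loss trajectories.
Attention softmaxes subtract the row maximum; BCE is computed on logits in
the stable |z| form; norms carry a 1e-8 floor so zero vectors (glycine) have
finite gradients.

## Synthetic data and what it shows

The generator builds ideal-geometry single chains by natural-extension
placement (N–Cα 1.46, Cα–C 1.52, C–N 1.33 Å; helix φ=−57°, ψ=−47°; extended
zigzag φ=ψ=180°; random-walk dihedrals; trans ω throughout), with carbonyl O
and ideal Cβ, written as valid PDB files that round-trip through the
reader.  Ligands are short random C/N chains; "binders" end in a planted
carboxylate `C(=O)O`.

Interaction labels are positive when a motif ligand meets a helix protein;
negatives are random protein–ligand re-pairings excluding positives at an
exact 1:1 ratio — so the signal requires both the ligand motif and the
protein's geometry class, and both encoder paths carry usable information.
Affinity labels are a logistic function of the surface-point count within
8 Å of the first residue's Cα (range ≈ 4–8, Gaussian noise sd 0.1 by
default).  The no-leakage control permutes all labels before the split and
averages five permutation seeds, centering the control AUROC at 0.5 up to
evaluation noise.

These fixtures exercise every pipeline stage at desk scale (12–20 residue
chains, ≤ 64 complexes, token dims ≈ 32; training uses lr 1e-3–3e-3
appropriate to these model sizes).  They demonstrate correctness of the
machinery and learnability of a planted geometric/chemical signal.  They do
not emulate real protein surfaces (no side chains beyond Cβ, no packing,
no electrostatics), real chemistry beyond a single motif, or benchmark-scale
generalization; evaluation on public affinity/interaction benchmarks needs
external datasets and large-scale pretraining and is out of scope here.

## Known limitations

- The level-set sampler has no density guarantee in deep crevices; the
  voxel filter bounds density from above only.
- Curvature estimates bias toward zero at scales comparable to the local
  point spacing (the 1 Å scale is noisy at default sampling density).
- The masked decoder predicts a fixed K points per patch; patches are
  defined with constant K, so variable-density surfaces share points
  between overlapping patches rather than adapting K.
- Single-modality ablations mirror the available token stream into both
  fusion inputs rather than redesigning the fusion block; this keeps
  parameter counts comparable across variants.
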