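import numpy as np
import pytest

from plisage.encoders import GvpConfig, SurfaceEncoderConfig
from plisage.fusion_predict import FusionConfig
from plisage.patch_tokenizer import build_patches
from plisage.protein_graph import build_graph
from plisage.surface_gen import generate_surface
from plisage.synthetic import SyntheticSpec, make_dataset, make_protein


@pytest.fixture(scope="session")
def helix_protein():
    """20-residue ideal helix: (pdb_text, backbone, atom cloud)."""
    return make_protein(SyntheticSpec(n_residues=20, geometry="helix", seed=1))


@pytest.fixture(scope="session")
def helix_surface(helix_protein):
    _, _, cloud = helix_protein
    return generate_surface(cloud, r=1.0, n_init=8, seed=0)


@pytest.fixture(scope="session")
def helix_patches(helix_surface):
    return build_patches(helix_surface, g=32, K=16, seed=0)


@pytest.fixture(scope="session")
def helix_graph(helix_protein):
    return build_graph(helix_protein[1], k=10)


@pytest.fixture(scope="session")
def small_gvp_cfg():
    return GvpConfig(layers=2, node_scalar=32, node_vector=8,
                     edge_scalar=16, edge_vector=1, dropout=0.0)


@pytest.fixture(scope="session")
def small_surf_cfg():
    return SurfaceEncoderConfig(token_dim=32, enc_depth=2, enc_heads=2,
                                dec_depth=1, dec_heads=2, mask_ratio=0.6,
                                points_per_patch=16, dropout=0.0)


@pytest.fixture(scope="session")
def small_model_kwargs(small_gvp_cfg, small_surf_cfg):
    return dict(gvp_cfg=small_gvp_cfg, surf_cfg=small_surf_cfg,
                fusion_cfg=FusionConfig(d_model=32, heads=4, dropout=0.0),
                ligand_hidden=32, head_dims=(64, 32), head_dropout=0.0)


@pytest.fixture(scope="session")
def interaction_dataset():
    """64 complexes over 8 proteins with the planted pocket/motif rule."""
    spec = SyntheticSpec(n_complexes=64, label_rule="motif", seed=0,
                         n_patches=32, points_per_patch=16)
    records, manifest = make_dataset(spec)
    train = [r for r, s in zip(records, manifest.split) if s == "train"]
    heldout = [r for r, s in zip(records, manifest.split) if s != "train"]
    return records, manifest, train, heldout
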