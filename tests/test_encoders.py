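import copy

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from plisage._autodiff import Tensor
from plisage._nn import Module
from plisage.encoders import (GVP, GVPEncoder, GvpConfig, LigandMPNN,
                              SurfaceEncoder, SurfaceEncoderConfig,
                              load_checkpoint, save_checkpoint)
from plisage.io_formats import LigandGraph, read_ligand
from plisage.patch_tokenizer import build_patches, mask_patches
from plisage.protein_graph import build_graph
from plisage.synthetic import build_backbone
from helpers import rotate_backbone


class TestGVP:
    def test_scalar_invariant_vector_equivariant(self):
        rng = np.random.default_rng(0)
        gvp = GVP(rng, (8, 2), (6, 3))
        s = Tensor(rng.normal(size=(5, 8)))
        v = Tensor(rng.normal(size=(5, 2, 3)))
        s_out, v_out = gvp(s, v)
        for i in range(10):
            R = Rotation.random(random_state=i).as_matrix()
            s2, v2 = gvp(s, Tensor(v.data @ R.T))
            assert np.abs(s2.data - s_out.data).max() < 1e-10
            assert np.abs(v2.data - v_out.data @ R.T).max() < 1e-10

    def test_encoder_embedding_invariant_under_rigid_motion(self, small_gvp_cfg):
        bb = build_backbone(12, "helix", seed=2)
        graph = build_graph(bb, k=6)
        enc = GVPEncoder(np.random.default_rng(1), small_gvp_cfg)
        base = enc(graph).pooled.data
        scale = np.abs(base).max()
        for i in range(10):
            R = Rotation.random(random_state=100 + i).as_matrix()
            g2 = build_graph(rotate_backbone(bb, R, np.array([2.0, 0.5, -1.0])), k=6)
            out = enc(g2).pooled.data
            assert np.abs(out - base).max() / scale <= 1e-4

    def test_deterministic_without_dropout(self, helix_graph, small_gvp_cfg):
        enc = GVPEncoder(np.random.default_rng(2), small_gvp_cfg)
        a = enc(helix_graph).pooled.data
        b = enc(helix_graph).pooled.data
        assert np.array_equal(a, b)

    def test_two_node_message_pass_matches_hand_computation(self):
        """One conv layer, hand-set weights, recomputed with plain numpy."""
        from plisage.encoders import GVPConvLayer

        rng = np.random.default_rng(3)
        ns, nv = 4, 2
        layer = GVPConvLayer(rng, (ns, nv), (3, 1), p_drop=0.0)
        s = Tensor(np.arange(8, dtype=float).reshape(2, 4) / 10)
        v = Tensor(np.random.default_rng(4).normal(size=(2, nv, 3)))
        es = Tensor(np.random.default_rng(5).normal(size=(2, 3)))
        ev = Tensor(np.random.default_rng(6).normal(size=(2, 1, 3)))
        edge_index = np.array([[1, 0], [0, 1]])       # j -> i both ways
        inv = Tensor(np.ones(2))
        out_s, out_v = layer(s, v, edge_index, es, ev, inv)

        # independent recomputation of one GVP and the aggregation in numpy
        def gvp_np(gvp, s_np, v_np):
            vh = np.einsum("nvc,vh->nhc", v_np, gvp.wh.data)
            vn = np.sqrt((vh ** 2).sum(axis=2) + 1e-8)
            s_o = np.concatenate([s_np, vn], axis=1) @ gvp.ws.w.data + gvp.ws.b.data
            if gvp.activate:
                s_o = np.maximum(s_o, 0)
            vmu = np.einsum("nhc,hk->nkc", vh, gvp.wv.data)
            gate = 1 / (1 + np.exp(-(s_o @ gvp.wg.w.data + gvp.wg.b.data)))
            return s_o, vmu * gate[:, :, None]

        s_cat = np.concatenate([s.data[[1, 0]], es.data], axis=1)
        v_cat = np.concatenate([v.data[[1, 0]], ev.data], axis=1)
        m_s, m_v = gvp_np(layer.msg2, *gvp_np(layer.msg1, s_cat, v_cat))
        # each node receives exactly one message (already target-ordered here)
        res_s = s.data + m_s[[0, 1]]
        mu = res_s.mean(axis=1, keepdims=True)
        var = ((res_s - mu) ** 2).mean(axis=1, keepdims=True)
        ln_s = (res_s - mu) / np.sqrt(var + 1e-5)
        res_v = v.data + m_v[[0, 1]]
        n2 = (res_v ** 2).sum(axis=2).mean(axis=1, keepdims=True)
        ln_v = res_v * (n2 + 1e-8)[:, :, None] ** -0.5
        f_s, f_v = gvp_np(layer.ff2, *gvp_np(layer.ff1, ln_s, ln_v))
        res2 = ln_s + f_s
        mu2 = res2.mean(axis=1, keepdims=True)
        var2 = ((res2 - mu2) ** 2).mean(axis=1, keepdims=True)
        exp_s = (res2 - mu2) / np.sqrt(var2 + 1e-5)
        assert np.abs(out_s.data - exp_s).max() < 1e-10
        res2v = ln_v + f_v
        n2b = (res2v ** 2).sum(axis=2).mean(axis=1, keepdims=True)
        exp_v = res2v * (n2b + 1e-8)[:, :, None] ** -0.5
        assert np.abs(out_v.data - exp_v).max() < 1e-10


@pytest.fixture(scope="module")
def enc(small_surf_cfg):
    return SurfaceEncoder(np.random.default_rng(7), small_surf_cfg)


class TestSurfaceEncoder:

    def test_mask_ratio_zero_matches_inference(self, enc, helix_protein,
                                               helix_surface):
        ps = build_patches(helix_surface, 24, 16, seed=2)
        mask_patches(ps, 0.0, seed=0)
        emb_pre, recon = enc(helix_surface, ps, helix_protein[2], mode="pretrain")
        emb_inf, _ = enc(helix_surface, ps, helix_protein[2], mode="inference")
        assert recon is None
        assert np.abs(emb_pre.pooled.data - emb_inf.pooled.data).max() < 1e-12

    def test_pooled_embedding_invariant_to_patch_order(self, enc, helix_protein,
                                                       helix_surface):
        ps = build_patches(helix_surface, 24, 16, seed=2)
        mask_patches(ps, 0.0, seed=0)
        base = enc(helix_surface, ps, helix_protein[2], mode="inference")[0]
        perm = np.random.default_rng(8).permutation(24)
        ps2 = copy.deepcopy(ps)
        ps2.centers = ps.centers[perm]
        ps2.center_idx = ps.center_idx[perm]
        ps2.patch_idx = ps.patch_idx[perm]
        ps2.mask = ps.mask[perm]
        out = enc(helix_surface, ps2, helix_protein[2], mode="inference")[0]
        assert np.abs(out.pooled.data - base.pooled.data).max() < 1e-5

    def test_reconstruction_shape_contract(self, enc, helix_protein, helix_surface,
                                           small_surf_cfg):
        ps = build_patches(helix_surface, 24, 16, seed=2)
        mask_patches(ps, 0.5, seed=1)
        _, recon = enc(helix_surface, ps, helix_protein[2], mode="pretrain")
        assert recon.shape == (12, small_surf_cfg.points_per_patch, 3)

    def test_all_masked_rejected(self, enc, helix_protein, helix_surface):
        ps = build_patches(helix_surface, 8, 8, seed=2)
        ps.mask = np.ones(8, dtype=bool)
        with pytest.raises(ValueError):
            enc(helix_surface, ps, helix_protein[2], mode="pretrain")


class TestLigandMPNN:
    def test_single_atom_no_bonds(self):
        lig = read_ligand("C")
        mpnn = LigandMPNN(np.random.default_rng(9), lig.node_dim, 4, hidden=16,
                          p_drop=0.0)
        emb = mpnn(lig)
        assert emb.tokens.shape == (1, 16)
        assert np.array_equal(emb.pooled.data, emb.tokens.data[0])

    def test_permutation_invariance(self):
        lig = read_ligand("CCO")
        perm = np.array([2, 0, 1])
        inv = np.argsort(perm)
        lig2 = LigandGraph(lig.node_feat[perm], inv[lig.edge_index],
                           lig.edge_feat, lig.smiles)
        mpnn = LigandMPNN(np.random.default_rng(10), lig.node_dim, 4, hidden=16,
                          p_drop=0.0)
        a = mpnn(lig).pooled.data
        b = mpnn(lig2).pooled.data
        assert np.abs(a - b).max() < 1e-6

    def test_two_atom_hand_computation(self):
        """One round with hand-set linear maps matches a numpy recomputation."""
        lig = LigandGraph(np.array([[1.0, 0.0], [0.0, 1.0]]),
                          np.array([[0, 1], [1, 0]]),
                          np.array([[1.0], [1.0]]))
        mpnn = LigandMPNN(np.random.default_rng(11), 2, 1, hidden=3, layers=1,
                          p_drop=0.0)
        out = mpnn(lig).tokens.data
        relu = lambda x: np.maximum(x, 0)
        h = relu(lig.node_feat @ mpnn.node_in.w.data + mpnn.node_in.b.data)
        e = relu(lig.edge_feat @ mpnn.edge_in.w.data + mpnn.edge_in.b.data)
        phi_in = np.concatenate([h[[1, 0]], h[[0, 1]], e], axis=1)
        l1, l2 = mpnn.phi[0].layers
        m = relu(phi_in @ l1.w.data + l1.b.data) @ l2.w.data + l2.b.data
        agg = np.zeros_like(h)
        np.add.at(agg, [1, 0], m)
        p1 = mpnn.psi[0].layers[0]
        expected = relu(np.concatenate([h, agg], axis=1) @ p1.w.data + p1.b.data)
        assert np.abs(out - expected).max() < 1e-12

    def test_gradients_reach_all_parameter_groups(self):
        lig = read_ligand("CC(=O)O")
        mpnn = LigandMPNN(np.random.default_rng(12), lig.node_dim, 4, hidden=8,
                          p_drop=0.0)
        loss = (mpnn(lig).pooled ** 2.0).sum()
        loss.backward()
        for name, p in mpnn.named_parameters():
            assert p.grad is not None and np.all(np.isfinite(p.grad)), name


class TestCheckpoints:
    def test_round_trip_and_mismatch(self, tmp_path, small_gvp_cfg):
        enc = GVPEncoder(np.random.default_rng(13), small_gvp_cfg)
        path = str(tmp_path / "ck.npz")
        save_checkpoint(path, enc, {"layers": 2})
        enc2 = GVPEncoder(np.random.default_rng(99), small_gvp_cfg)
        load_checkpoint(path, enc2, {"layers": 2})
        for (n1, p1), (n2, p2) in zip(enc.named_parameters(),
                                      enc2.named_parameters()):
            assert n1 == n2 and np.array_equal(p1.data, p2.data)
        with pytest.raises(ValueError):
            load_checkpoint(path, enc2, {"layers": 3})
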