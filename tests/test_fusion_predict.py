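import numpy as np
import pytest

from plisage._autodiff import Tensor
from plisage.encoders import GvpConfig, SurfaceEncoderConfig
from plisage.fusion_predict import (ComplexRecord, FusionConfig, FusionModule,
                                    PredictionModel, build_token_cache,
                                    concordance_index, evaluate,
                                    export_attention, loss_affinity,
                                    loss_classification, predict_dataset,
                                    rm_squared, train_downstream)
from plisage.io_formats import read_ligand


@pytest.fixture(scope="module")
def record(helix_protein, helix_surface, helix_patches, helix_graph):
    return ComplexRecord(ligand=read_ligand("CCC(=O)O"), label=5.0,
                         task="affinity", surface=helix_surface,
                         patchset=helix_patches, graph=helix_graph,
                         atoms=helix_protein[2], protein_id="helix")


@pytest.fixture(scope="module")
def model(small_model_kwargs):
    return PredictionModel(np.random.default_rng(0), **small_model_kwargs)


class TestFusion:
    def test_concat_mode_matches_manual_recomputation(self):
        rng = np.random.default_rng(1)
        fusion = FusionModule(rng, FusionConfig(d_model=8, heads=2, dropout=0.0,
                                                mode="concat"), 6, 6)
        st = rng.normal(size=(5, 6))
        su = rng.normal(size=(7, 6))
        out = fusion(Tensor(st), Tensor(su)).data
        su_p = (su @ fusion.proj_surf.w.data + fusion.proj_surf.b.data).mean(0)
        st_p = (st @ fusion.proj_struct.w.data + fusion.proj_struct.b.data).mean(0)
        expected = np.concatenate([su_p, st_p]) @ fusion.fc.w.data + fusion.fc.b.data
        assert np.abs(out - expected).max() < 1e-12

    @pytest.mark.parametrize("mode", ["cross_attn", "enc_dec"])
    def test_attention_rows_sum_to_one(self, mode):
        rng = np.random.default_rng(2)
        fusion = FusionModule(rng, FusionConfig(d_model=8, heads=2, dropout=0.0,
                                                mode=mode), 6, 6)
        fusion(Tensor(rng.normal(size=(5, 6))), Tensor(rng.normal(size=(7, 6))))
        assert fusion.last_attention.shape == (2, 7, 5)
        assert np.allclose(fusion.last_attention.sum(axis=-1), 1.0, atol=1e-5)

    def test_structure_token_permutation_invariance(self):
        rng = np.random.default_rng(3)
        fusion = FusionModule(rng, FusionConfig(d_model=8, heads=2, dropout=0.0,
                                                mode="enc_dec"), 6, 6)
        st = rng.normal(size=(5, 6))
        su = rng.normal(size=(7, 6))
        base = fusion(Tensor(st), Tensor(su)).data
        perm = rng.permutation(5)
        out = fusion(Tensor(st[perm]), Tensor(su)).data
        assert np.abs(out - base).max() < 1e-5

    def test_empty_tokens_rejected(self):
        rng = np.random.default_rng(4)
        fusion = FusionModule(rng, FusionConfig(d_model=8, heads=2), 6, 6)
        with pytest.raises(ValueError):
            fusion(Tensor(np.zeros((0, 6))), Tensor(np.zeros((3, 6))))


class TestPredict:
    def test_zero_weight_head_returns_bias(self, model, record):
        for layer in model.head.layers:
            layer.w.data[:] = 0.0
            layer.b.data[:] = 0.0
        model.head.layers[-1].b.data[:] = 3.25
        assert model.predict(record).item() == pytest.approx(3.25)
        # restore
        rng = np.random.default_rng(5)
        for layer in model.head.layers:
            layer.w.data[:] = rng.normal(scale=0.1, size=layer.w.shape)

    def test_prediction_deterministic(self, model, record):
        assert model.predict(record).item() == model.predict(record).item()

    def test_task_label_validation(self):
        with pytest.raises(ValueError):
            ComplexRecord(ligand=read_ligand("C"), label=0.3, task="interaction")
        with pytest.raises(ValueError):
            ComplexRecord(ligand=read_ligand("C"), label=1.0, task="bogus")


class TestLosses:
    def test_mse_values(self):
        assert loss_affinity(np.array([1.0, 2.0]),
                             Tensor(np.array([1.0, 2.0]))).item() == 0.0
        assert loss_affinity(np.array([0.0, 2.0]),
                             Tensor(np.array([1.0, 0.0]))).item() == pytest.approx(2.5)

    def test_bce_closed_form(self):
        val = loss_classification(np.array([1.0]), Tensor(np.array([0.0]))).item()
        assert val == pytest.approx(np.log(2.0), abs=1e-12)
        # stable at extreme logits
        big = loss_classification(np.array([1.0]), Tensor(np.array([500.0]))).item()
        assert 0.0 <= big < 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            loss_affinity(np.array([1.0]), Tensor(np.array([1.0, 2.0])))
        with pytest.raises(ValueError):
            loss_classification(np.array([1.0]), Tensor(np.array([1.0, 2.0])))


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = evaluate(y, y, "affinity")
        assert m["rmse"] == 0.0 and m["mae"] == 0.0
        assert m["pearson"] == pytest.approx(1.0)
        assert m["ci"] == 1.0
        assert m["rm2"] == pytest.approx(1.0)
        c = evaluate(np.array([0.9, 0.8, 0.2, 0.1]),
                     np.array([1, 1, 0, 0]), "interaction")
        assert c["auroc"] == 1.0 and c["auprc"] == 1.0

    def test_reversed_predictions_spearman(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = evaluate(y[::-1], y, "affinity")
        assert m["spearman"] == pytest.approx(-1.0)

    def test_ci_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(6)
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        p = rng.normal(size=6)
        num = den = 0.0
        for i in range(6):
            for j in range(6):
                if i < j and y[i] != y[j]:
                    den += 1
                    s = (p[i] - p[j]) * (y[i] - y[j])
                    num += 1.0 if s > 0 else (0.5 if s == 0 else 0.0)
        assert concordance_index(y, p) == pytest.approx(num / den)

    def test_metric_bounds_and_order(self):
        rng = np.random.default_rng(7)
        y, p = rng.normal(size=20), rng.normal(size=20)
        m = evaluate(p, y, "affinity")
        assert 0.0 <= m["ci"] <= 1.0
        assert m["rmse"] >= m["mae"] >= 0.0

    def test_constant_predictions_warn_nan(self):
        with pytest.warns(UserWarning):
            m = evaluate(np.ones(4), np.array([1.0, 2, 3, 4]), "affinity")
        assert np.isnan(m["pearson"])

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            evaluate(np.array([1.0]), np.array([1.0]), "affinity")


class TestAttention:
    def test_export_shape_and_rows(self, small_model_kwargs, record):
        model = PredictionModel(np.random.default_rng(8), **small_model_kwargs)
        amap = export_attention(model, record)
        g = record.patchset.n_patches
        assert amap.weights.shape[0] == g
        assert np.allclose(amap.weights.sum(axis=1), 1.0, atol=1e-5)
        table = amap.to_table()
        assert len(table) == g
        assert list(table.columns) == ["x", "y", "z", "score"]

    def test_uniform_attention_in_degenerate_limit(self, small_model_kwargs,
                                                   record):
        model = PredictionModel(np.random.default_rng(9), **small_model_kwargs)
        attn = model.fusion.dec[-1].cross_attn
        attn.wq.w.data[:] = 0.0
        attn.wq.b.data[:] = 0.0
        amap = export_attention(model, record)
        v = amap.weights.shape[1]
        assert np.abs(amap.weights - 1.0 / v).max() < 1e-12

    def test_concat_mode_unsupported(self, small_model_kwargs, record):
        kw = dict(small_model_kwargs)
        kw["fusion_cfg"] = FusionConfig(d_model=32, heads=4, dropout=0.0,
                                        mode="concat")
        model = PredictionModel(np.random.default_rng(10), **kw)
        with pytest.raises(ValueError):
            export_attention(model, record)


class TestTrainDownstream:
    def test_freeze_keeps_protein_encoders_fixed(self, record,
                                                 small_model_kwargs):
        res = train_downstream([record], "affinity", seed=0, freeze=True,
                               epochs=2, lr=1e-3, model_kwargs=small_model_kwargs)
        model = res.model
        before = {n: p.data.copy() for n, p in model.named_parameters()
                  if n.startswith(("gvp_encoder.", "surface_encoder."))}
        res2 = train_downstream([record], "affinity", seed=0, freeze=True,
                                epochs=3, model=model)
        after = {n: p.data for n, p in res2.model.named_parameters()
                 if n.startswith(("gvp_encoder.", "surface_encoder."))}
        assert all(np.array_equal(before[n], after[n]) for n in before)

    def test_same_seed_identical_history(self, record, small_model_kwargs):
        h1 = train_downstream([record], "affinity", seed=3, freeze=True,
                              epochs=3, model_kwargs=small_model_kwargs).history
        h2 = train_downstream([record], "affinity", seed=3, freeze=True,
                              epochs=3, model_kwargs=small_model_kwargs).history
        assert h1 == h2

    def test_empty_dataset_rejected(self, small_model_kwargs):
        with pytest.raises(ValueError):
            train_downstream([], "affinity", model_kwargs=small_model_kwargs)
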