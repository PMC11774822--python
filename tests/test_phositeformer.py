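import numpy as np
import pytest

from phositec import nn, phositeformer as pf, synth
from phositec.msio import NormalizedPhosMatrix, PhosSiteID


def small_model(n_samples, seed=0, **kw):
    cfg = pf.ModelConfig(
        d_model=16, n_heads=2, encoder_layers=1, decoder_layers=1,
        autodis_anchors=8, autodis_hidden=4, **kw,
    )
    return pf.PhoSiteformer(n_samples, cfg, seed=seed)


class TestMakeMask:
    def test_equal_counts(self):
        row = np.r_[np.full(6, 0.5), np.zeros(10)]
        plan = pf.make_mask(row, 0.5, np.random.default_rng(0))
        assert len(plan.nonzero_masked) == len(plan.zero_masked) == 3

    def test_zero_cap(self):
        row = np.r_[np.full(4, 0.5), np.zeros(1)]
        plan = pf.make_mask(row, 0.5, np.random.default_rng(0))
        assert len(plan.nonzero_masked) == len(plan.zero_masked) == 1

    def test_zero_fraction_empty_plan(self):
        plan = pf.make_mask(np.array([0.5, 0.0]), 0.0, np.random.default_rng(0))
        assert plan.all_masked == ()

    def test_all_zero_row_errors(self):
        with pytest.raises(ValueError):
            pf.make_mask(np.zeros(5), 0.5, np.random.default_rng(0))

    def test_masked_sets_masked_indices_valid(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            row = np.where(rng.random(30) < 0.5, rng.uniform(0.1, 1, 30), 0.0)
            if (row > 0).sum() == 0:
                continue
            plan = pf.make_mask(row, 0.3, rng)
            assert all(row[i] > 0 for i in plan.nonzero_masked)
            assert all(row[i] == 0 for i in plan.zero_masked)


class TestAutoDis:
    def test_convexity_and_determinism(self):
        rng = np.random.default_rng(0)
        emb = pf.AutoDisEmbedder(5, 4, 8, rng)
        v1 = pf.autodis_embed(0.3, emb)
        v2 = pf.autodis_embed(0.3, emb)
        assert np.array_equal(v1, v2)
        max_norm = np.linalg.norm(emb.anchors.data, axis=1).max()
        assert np.linalg.norm(v1) <= max_norm + 1e-12
        w = emb.gate_weights(0.7)
        assert w.min() >= 0 and np.sum(w) == pytest.approx(1.0)

    def test_single_anchor_degenerate(self):
        emb = pf.AutoDisEmbedder(1, 4, 8, np.random.default_rng(0))
        for v in (0.0, 0.5, 1.0):
            assert pf.autodis_embed(v, emb) == pytest.approx(emb.anchors.data[0])

    def test_nonfinite_value_errors(self):
        emb = pf.AutoDisEmbedder(3, 4, 8, np.random.default_rng(0))
        with pytest.raises(ValueError):
            pf.autodis_embed(float("nan"), emb)


class TestMaskedMse:
    def test_values(self):
        mask = np.array([[True, False]])
        assert pf.masked_mse([[1.0, 2.0]], [[1.0, 9.0]], mask) == 0.0
        assert pf.masked_mse([[1.5, 2.0]], [[1.0, 9.0]], mask) == pytest.approx(0.25)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            pf.masked_mse([[1.0]], [[1.0]], np.array([[False]]))


class TestForwardContracts:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.values = np.where(rng.random((4, 10)) < 0.6, rng.uniform(0.1, 1, (4, 10)), 0.0)
        self.values[self.values.sum(axis=1) == 0, 0] = 0.5
        self.zero = self.values == 0
        self.model = small_model(10, seed=3)

    def test_output_shape(self):
        masked = np.zeros_like(self.zero)
        masked[0, np.flatnonzero(self.values[0] > 0)[0]] = True
        with nn.set_grad_enabled(False):
            out = self.model(self.values, masked, self.zero)
        assert out.shape == (4, 10)

    def test_no_leakage_at_masked_cells(self):
        rng = np.random.default_rng(0)
        plan = pf.make_mask(self.values[0], 0.5, rng)
        masked = np.zeros_like(self.zero)
        masked[0] = plan.indicator(10)
        perturbed = self.values.copy()
        j = plan.nonzero_masked[0]
        perturbed[0, j] = 0.987654
        with nn.set_grad_enabled(False):
            a = self.model(self.values, masked, self.zero).data
            b = self.model(perturbed, masked, self.zero).data
        assert np.array_equal(a, b)  # exact: masked truth never enters the graph

    def test_permutation_equivariance_over_samples(self):
        perm = np.random.default_rng(1).permutation(10)
        masked = np.zeros_like(self.zero)
        with nn.set_grad_enabled(False):
            base = self.model(self.values, masked, self.zero).data
        # permute sample columns together with their identity embeddings
        self.model.sample_table.data = self.model.sample_table.data[perm]
        with nn.set_grad_enabled(False):
            permuted = self.model(
                self.values[:, perm], masked[:, perm], self.zero[:, perm]
            ).data
        assert np.allclose(permuted, base[:, perm], atol=1e-5)

    def test_all_masked_or_zero_row_handled(self):
        values = self.values.copy()
        masked = np.zeros_like(self.zero)
        masked[2] = values[2] > 0  # every nonzero token masked
        with nn.set_grad_enabled(False):
            out = self.model(values, masked, self.zero).data
        assert np.all(np.isfinite(out))


class TestPretrain:
    def make_matrix(self, seed=0, n_sites=40, n_samples=12):
        rng = np.random.default_rng(seed)
        vals = np.where(
            rng.random((n_sites, n_samples)) < 0.7,
            rng.uniform(0.05, 1, (n_sites, n_samples)),
            0.0,
        )
        vals[vals.sum(axis=1) == 0, 0] = 0.5
        sites = [PhosSiteID(f"P{i:04d}", "S", 10) for i in range(n_sites)]
        return NormalizedPhosMatrix(sites, [f"s{j}" for j in range(n_samples)], vals)

    def test_deterministic_given_seed(self):
        matrix = self.make_matrix()
        mcfg = pf.ModelConfig(d_model=16, n_heads=2, encoder_layers=1, decoder_layers=1,
                              autodis_anchors=8, autodis_hidden=4)
        pcfg = pf.PretrainConfig(max_epochs=2, batch_size=16, seed=11)
        _, r1 = pf.pretrain(matrix, mcfg, pcfg)
        _, r2 = pf.pretrain(matrix, mcfg, pcfg)
        assert r1.val_mse == r2.val_mse and r1.train_mse[1:] == r2.train_mse[1:]

    def test_zero_mask_fraction_errors(self):
        matrix = self.make_matrix()
        with pytest.raises(ValueError):
            pf.pretrain(matrix, pf.ModelConfig(d_model=16, n_heads=2),
                        pf.PretrainConfig(mask_fraction=0.0))

    def test_loss_decreases(self):
        matrix = self.make_matrix(seed=3)
        mcfg = pf.ModelConfig(d_model=16, n_heads=2, encoder_layers=1, decoder_layers=1,
                              autodis_anchors=8, autodis_hidden=4)
        pcfg = pf.PretrainConfig(max_epochs=6, batch_size=16, lr=2e-3, seed=4)
        _, report = pf.pretrain(matrix, mcfg, pcfg)
        assert min(report.val_mse[1:]) < report.val_mse[0]


class TestExtractEmbeddings:
    def test_max_pool_and_identical_rows(self):
        rng = np.random.default_rng(9)
        vals = np.where(rng.random((6, 8)) < 0.6, rng.uniform(0.1, 1, (6, 8)), 0.0)
        vals[0] = vals[1]  # identical rows -> identical embeddings
        vals[5] = 0.0  # no nonzero values -> no embedding
        for i in range(1, 5):
            if vals[i].sum() == 0:
                vals[i, 0] = 0.5
        sites = [PhosSiteID(f"P{i}", "S", 10) for i in range(6)]
        matrix = NormalizedPhosMatrix(sites, [f"s{j}" for j in range(8)], vals)
        model = small_model(8, seed=1)
        emb = pf.extract_site_embeddings(model, matrix)
        assert np.array_equal(emb[sites[0]], emb[sites[1]])
        assert sites[5] not in emb
        assert emb[sites[0]].shape == (16,)

    def test_single_sample_site_equals_token_vector(self):
        vals = np.zeros((2, 4))
        vals[0, 2] = 0.7
        vals[1, :] = 0.5
        sites = [PhosSiteID("P0", "S", 10), PhosSiteID("P1", "S", 10)]
        matrix = NormalizedPhosMatrix(sites, list("abcd"), vals)
        model = small_model(4, seed=2)
        emb = pf.extract_site_embeddings(model, matrix)
        with nn.set_grad_enabled(False):
            ctx = model.encode(vals[0][None, :], (vals[0] > 0)[None, :]).data[0]
        assert emb[sites[0]] == pytest.approx(ctx[2])


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(2)
        vals = np.where(rng.random((5, 6)) < 0.7, rng.uniform(0.1, 1, (5, 6)), 0.0)
        vals[vals.sum(axis=1) == 0, 0] = 0.5
        sites = [PhosSiteID(f"P{i}", "S", 10) for i in range(5)]
        matrix = NormalizedPhosMatrix(sites, list("abcdef"), vals)
        model = small_model(6, seed=4)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        back = pf.PhoSiteformer.load(path)
        a = pf.extract_site_embeddings(model, matrix)
        b = pf.extract_site_embeddings(back, matrix)
        for s in a:
            assert np.array_equal(a[s], b[s])
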