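"""Cosine similarity, NT-Xent closed forms, and pre-training behaviour."""

import numpy as np
import pytest

import voxbind as vb
from voxbind.contrastive import (
    ContrastiveConfig, cosine_similarity, nt_xent_loss,
    nt_xent_loss_and_grad, pretrain_encoder,
)
from voxbind.networks import encoder_forward, save_checkpoint, load_checkpoint


class TestCosine:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, -3.0])
        assert cosine_similarity(v, 5 * v) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert cosine_similarity(np.array([1.0, 0.0]),
                                 np.array([0.0, 2.0])) == pytest.approx(0.0)

    def test_antiparallel_vectors(self):
        v = np.array([0.3, -1.2, 4.0])
        assert cosine_similarity(v, -v) == pytest.approx(-1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(3), np.ones(3))


class TestNTXent:
    @pytest.mark.parametrize("tau", [0.1, 0.5, 2.0])
    def test_single_pair_loss_is_zero(self, tau):
        """With B=1 the only candidate is the positive, so the softmax is
        degenerate and the loss vanishes for any embeddings and tau."""
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((2, 16))
        assert nt_xent_loss(Z, tau) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("tau", [0.1, 0.5, 2.0])
    def test_identical_quadruplet_gives_ln3(self, tau):
        """B=2 with four identical embeddings: each softmax is uniform over
        3 candidates, so the loss is ln 3 at any temperature."""
        Z = np.tile(np.array([0.5, -1.0, 2.0]), (4, 1))
        assert nt_xent_loss(Z, tau) == pytest.approx(np.log(3.0), abs=1e-12)

    def test_invariant_to_complex_permutation(self):
        rng = np.random.default_rng(1)
        b = 5
        Z = rng.standard_normal((2 * b, 8))
        base = nt_xent_loss(Z, 0.5)
        perm = rng.permutation(b)
        Zp = np.concatenate([Z[:b][perm], Z[b:][perm]])
        assert nt_xent_loss(Zp, 0.5) == pytest.approx(base, rel=1e-12)

    def test_invariant_to_common_orthogonal_transform(self):
        rng = np.random.default_rng(2)
        Z = rng.standard_normal((8, 12))
        Q, _ = np.linalg.qr(rng.standard_normal((12, 12)))
        assert nt_xent_loss(Z @ Q, 0.5) == pytest.approx(
            nt_xent_loss(Z, 0.5), rel=1e-10
        )

    def test_loss_nonnegative(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            Z = rng.standard_normal((6, 5))
            assert nt_xent_loss(Z, 0.5) >= 0.0

    def test_bad_temperature_rejected(self):
        Z = np.ones((2, 3))
        with pytest.raises(ValueError):
            nt_xent_loss(Z, 0.0)
        with pytest.raises(ValueError):
            nt_xent_loss(Z, -1.0)

    def test_gradient_matches_finite_differences(self):
        """Embedding-space gradient of the loss on a 2-complex toy batch."""
        rng = np.random.default_rng(4)
        Z = rng.standard_normal((4, 6))
        loss, dZ = nt_xent_loss_and_grad(Z, 0.5)
        eps = 1e-6
        worst = 0.0
        for i in range(Z.shape[0]):
            for j in range(Z.shape[1]):
                Zp, Zm = Z.copy(), Z.copy()
                Zp[i, j] += eps
                Zm[i, j] -= eps
                fd = (nt_xent_loss(Zp, 0.5) - nt_xent_loss(Zm, 0.5)) / (2 * eps)
                worst = max(worst, abs(fd - dZ[i, j]) / max(1e-8, abs(fd)))
        assert worst < 1e-4


@pytest.fixture(scope="module")
def tiny_pretrain_setup(request):
    """Four small-box pockets plus a fast contrastive config."""
    recs = vb.generate_dataset(4, seed=5)
    from voxbind.pocket import center_on_ligand, extract_pocket

    pockets = [center_on_ligand(extract_pocket(r.pair, 6.0)) for r in recs]
    spec = vb.GridSpec(box_size=21.0)
    cfg = ContrastiveConfig(batch_complexes=2, epochs=2, learning_rate=1e-3,
                            seed=11, projection_dim=16)
    return pockets, spec, cfg


class TestPretrain:
    def test_loss_trace_reproducible(self, tiny_pretrain_setup):
        pockets, spec, cfg = tiny_pretrain_setup
        r1 = pretrain_encoder(pockets, spec, cfg)
        r2 = pretrain_encoder(pockets, spec, cfg)
        assert r1.loss_trace == r2.loss_trace
        assert len(r1.loss_trace) == cfg.epochs
        assert all(np.isfinite(v) for v in r1.loss_trace)

    def test_training_reduces_loss(self, tiny_pretrain_setup):
        pockets, spec, cfg = tiny_pretrain_setup
        cfg2 = ContrastiveConfig(batch_complexes=2, epochs=6,
                                 learning_rate=1e-3, seed=11,
                                 projection_dim=16)
        r = pretrain_encoder(pockets, spec, cfg2)
        assert r.loss_trace[-1] <= r.loss_trace[0]

    def test_checkpoint_reload_reproduces_embeddings(self, tiny_pretrain_setup,
                                                     tmp_path):
        pockets, spec, cfg = tiny_pretrain_setup
        r = pretrain_encoder(pockets, spec, cfg)
        from voxbind.voxelize import gaussian_blur, voxelize_atoms

        g = gaussian_blur(voxelize_atoms(pockets[0], spec)).values.astype(
            np.float32
        )
        h_before = encoder_forward(g, r.encoder)
        save_checkpoint(tmp_path / "enc.npz", r.encoder)
        from voxbind.networks import build_encoder

        fresh = build_encoder(seed=12345)
        load_checkpoint(tmp_path / "enc.npz", fresh)
        np.testing.assert_array_equal(encoder_forward(g, fresh), h_before)

    def test_fewer_than_two_complexes_rejected(self, tiny_pretrain_setup):
        pockets, spec, cfg = tiny_pretrain_setup
        with pytest.raises(ValueError):
            pretrain_encoder(pockets[:1], spec, cfg)

    def test_odd_trailing_batch_skipped_with_warning(self, tiny_pretrain_setup,
                                                     caplog):
        pockets, spec, _ = tiny_pretrain_setup
        cfg = ContrastiveConfig(batch_complexes=2, epochs=1,
                                learning_rate=1e-3, seed=0, projection_dim=16)
        import logging

        with caplog.at_level(logging.WARNING, logger="voxbind"):
            pretrain_encoder(pockets[:3], spec, cfg)
        assert any("skipping batch" in r.message for r in caplog.records)
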