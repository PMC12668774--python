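"""Generator/discriminator building blocks and their symmetry contracts."""

import numpy as np
import pytest

from schicenh import nn
from schicenh.model import (
    Discriminator,
    DiscriminatorConfig,
    Generator,
    GeneratorConfig,
    RankOneBundle,
    RankOneHead,
    SEBlock,
    discriminator_forward,
    generator_forward,
    load_checkpoint,
    rank_one_extract,
    rank_one_reconstruct,
    save_checkpoint,
    se_recalibrate,
)


def small_gcfg(window=12, central=8):
    return GeneratorConfig(window=window, central=central, stem_channels=(4, 8),
                           se_reduction=2, n_rank_one_channels=8,
                           branch_channels=4, fusion_channels=4)


class TestRankOneExtract:
    def test_zero_input_gives_zero_vectors(self, rng):
        head = RankOneHead(rng, 6, 3)
        bundle = rank_one_extract(np.zeros((6, 6, 3)), head)
        assert not bundle.vectors.any()

    @pytest.mark.parametrize("n", [8, 16, 40])
    def test_vector_length_matches_spatial_size(self, rng, n):
        head = RankOneHead(rng, n, 2)
        bundle = rank_one_extract(np.abs(rng.normal(size=(n, n, 2))), head)
        assert bundle.vectors.shape == (2, n)

    def test_ones_kernel_identity_refinement_gives_column_sums(self, rng):
        n = 5
        head = RankOneHead(rng, n, 1)
        head.collapse_w.data = np.ones((1, 1, n))
        head.collapse_b.data = np.zeros(1)
        delta = np.zeros((1, 1, 3))
        delta[0, 0, 1] = 1.0  # identity kernel
        for refine in (head.refine1, head.refine2):
            refine.w.data = delta.copy()
            refine.b.data = np.zeros(1)
        x = np.abs(rng.normal(size=(n, n, 1)))  # nonneg so leaky relus are identity
        bundle = rank_one_extract(x, head)
        np.testing.assert_allclose(bundle.vectors[0], x[:, :, 0].sum(axis=0), rtol=1e-12)

    def test_spatial_mismatch_rejected(self, rng):
        head = RankOneHead(rng, 6, 2)
        with pytest.raises(ValueError, match="spatial"):
            rank_one_extract(np.zeros((5, 5, 2)), head)


class TestRankOneReconstruct:
    def test_hand_outer_product(self):
        b = RankOneBundle(vectors=np.array([[1.0, 2.0]]), channel_weights=np.array([1.0]))
        np.testing.assert_array_equal(rank_one_reconstruct(b)[:, :, 0],
                                      [[1.0, 2.0], [2.0, 4.0]])

    def test_bitwise_symmetry(self, rng):
        b = RankOneBundle(vectors=rng.normal(size=(5, 9)),
                          channel_weights=np.abs(rng.normal(size=5)))
        maps = rank_one_reconstruct(b)
        for c in range(5):
            np.testing.assert_array_equal(maps[:, :, c], maps[:, :, c].T)

    def test_numerical_rank_one(self, rng):
        b = RankOneBundle(vectors=rng.normal(size=(4, 12)),
                          channel_weights=np.abs(rng.normal(size=4)) + 0.1)
        maps = rank_one_reconstruct(b)
        for c in range(4):
            s = np.linalg.svd(maps[:, :, c], compute_uv=False)
            assert s[1] < 1e-8 * s[0]

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            RankOneBundle(vectors=np.ones((1, 3)), channel_weights=np.array([-1.0]))


class TestSE:
    def test_bypass_is_identity(self, rng):
        se = SEBlock(rng, 4, 2)
        x = rng.normal(size=(7, 7, 4))
        np.testing.assert_array_equal(se_recalibrate(x, se, bypass=True), x)

    def test_gates_shrink_magnitudes(self, rng):
        se = SEBlock(rng, 4, 2)
        x = rng.normal(size=(6, 6, 4))
        out = se_recalibrate(x, se)
        assert (np.abs(out) <= np.abs(x) + 1e-12).all()
        gates = se.gates(nn.Tensor(np.transpose(x, (2, 0, 1))[None])).data
        assert ((gates > 0) & (gates < 1)).all()

    def test_symmetric_input_stays_symmetric(self, rng):
        se = SEBlock(rng, 4, 2)
        x = rng.normal(size=(6, 6, 4))
        x = x + np.swapaxes(x, 0, 1)
        out = se_recalibrate(x, se)
        np.testing.assert_array_equal(out, np.swapaxes(out, 0, 1))

    def test_indivisible_reduction_rejected(self, rng):
        with pytest.raises(ValueError, match="divide"):
            SEBlock(rng, 6, 4)


class TestGenerator:
    def test_zero_input_finite_symmetric(self, rng):
        gen = Generator(small_gcfg(), rng)
        out = generator_forward(np.zeros((12, 12)), np.zeros((8, 8)), gen)
        assert np.isfinite(out).all()
        np.testing.assert_array_equal(out, out.T)

    @pytest.mark.parametrize("w,k", [(12, 8), (40, 28)])
    def test_output_shape(self, rng, w, k):
        gen = Generator(small_gcfg(w, k), rng)
        out = generator_forward(rng.uniform(size=(w, w)), rng.uniform(size=(k, k)), gen)
        assert out.shape == (k, k)

    def test_output_range(self, rng):
        gen = Generator(small_gcfg(), rng)
        out = generator_forward(rng.uniform(size=(12, 12)), rng.uniform(size=(8, 8)), gen)
        assert (out >= 0).all() and (out <= 1.2).all()

    def test_no_dead_branch(self, rng):
        gen = Generator(small_gcfg(), rng)
        outer_a = rng.uniform(size=(12, 12))
        central_a = rng.uniform(size=(8, 8))
        central_b = rng.uniform(size=(8, 8))
        out_a = generator_forward(outer_a, central_a, gen)
        out_b = generator_forward(outer_a, central_b, gen)
        assert np.max(np.abs(out_a - out_b)) > 0
        outer_b = rng.uniform(size=(12, 12))
        out_c = generator_forward(outer_b, central_a, gen)
        assert np.max(np.abs(out_a - out_c)) > 0

    def test_transpose_invariance_on_asymmetric_probe(self, rng):
        gen = Generator(small_gcfg(), rng)
        outer = rng.uniform(size=(12, 12))
        central = rng.uniform(size=(8, 8))
        a = generator_forward(outer, central, gen)
        b = generator_forward(outer.T, central.T, gen)
        np.testing.assert_array_equal(a, b)

    def test_nonfinite_input_rejected(self, rng):
        gen = Generator(small_gcfg(), rng)
        bad = np.zeros((12, 12))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            generator_forward(bad, np.zeros((8, 8)), gen)

    def test_default_config_parameter_budget(self, rng):
        gen = Generator(GeneratorConfig(), rng)
        disc = Discriminator(DiscriminatorConfig(), rng)
        assert gen.n_parameters() + disc.n_parameters() < 5 * 10**5


class TestDiscriminator:
    def test_deterministic_scoring(self, rng):
        disc = Discriminator(DiscriminatorConfig(), rng)
        tile = rng.uniform(size=(28, 28))
        assert discriminator_forward(tile, disc) == discriminator_forward(tile, disc)

    def test_finite_on_unit_inputs(self, rng):
        disc = Discriminator(DiscriminatorConfig(), rng)
        for _ in range(5):
            assert np.isfinite(discriminator_forward(rng.uniform(size=(28, 28)), disc))

    def test_patch_output_grid(self, rng):
        disc = Discriminator(DiscriminatorConfig(patch_output=True), rng)
        out = discriminator_forward(rng.uniform(size=(28, 28)), disc)
        assert out.shape == (7, 7)

    def test_trained_discriminator_separates_real_from_sparse(self, short_gan):
        pairs, ckpt, _ = short_gan
        real = ckpt.discriminator(nn.Tensor(pairs.target[:, None])).data.mean()
        sparse = ckpt.discriminator(nn.Tensor(pairs.central[:, None])).data.mean()
        assert real > sparse


class TestCheckpoint:
    def test_round_trip_preserves_forward(self, rng, tmp_path):
        gen = Generator(small_gcfg(), rng)
        disc = Discriminator(DiscriminatorConfig(), rng)
        from schicenh.model import Checkpoint

        ckpt = Checkpoint(gen, disc, gen.cfg, disc.cfg, cap=3.3, seed=11)
        path = tmp_path / "ck.npz"
        save_checkpoint(path, ckpt)
        back = load_checkpoint(path)
        assert back.cap == 3.3 and back.seed == 11
        outer = rng.uniform(size=(12, 12))
        central = rng.uniform(size=(8, 8))
        np.testing.assert_array_equal(
            generator_forward(outer, central, gen),
            generator_forward(outer, central, back.generator),
        )
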