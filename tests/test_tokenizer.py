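"""Tokenizer: patch tiling, background filtering, axis permutation,
quantizer-oracle equivalence, and VQ training behavior."""

import numpy as np
import pytest

from mriclip.tokenizer import (PAPER_TOKENIZER, Codebook, TokenizerConfig,
                               VolumePatch, intensity_filter, patch_volume,
                               quantize, random_axis_permutation,
                               tokenize_volume, train_vqvae, unpatch_volume,
                               mask_to_token_coords)
from mriclip.phantoms import MRIVolume, generate_study


@pytest.fixture(scope="module")
def paper_config():
    return TokenizerConfig(**PAPER_TOKENIZER)


def test_exact_division_patch_count(paper_config):
    vol = np.zeros((64, 64, 8), dtype=np.float32)
    patches = patch_volume(vol, paper_config)
    assert len(patches) == 2 * 2 * 2
    assert all(p.voxels.shape == (32, 32, 4) for p in patches)


def test_ceiling_and_zero_padding(paper_config):
    vol = np.ones((33, 32, 4), dtype=np.float32)
    patches = patch_volume(vol, paper_config)
    assert len(patches) == 2 * 1 * 1
    second = [p for p in patches if p.grid_coord == (1, 0, 0)][0]
    assert second.voxels[0, :, :].sum() == 32 * 4      # one real row
    assert second.voxels[1:, :, :].sum() == 0          # 31 padded rows


def test_patch_unpatch_roundtrip_random_volumes():
    cfg = TokenizerConfig()
    rng = np.random.default_rng(0)
    for _ in range(20):
        shape = tuple(rng.integers(5, 40, size=3))
        vol = rng.normal(size=shape).astype(np.float32)
        patches = patch_volume(vol, cfg)
        assert np.array_equal(unpatch_volume(patches, shape, cfg), vol)
        # partition: each voxel in exactly one patch, coords bijective
        coords = {p.grid_coord for p in patches}
        assert len(coords) == len(patches)


def test_intensity_filter_contracts():
    cfg = TokenizerConfig()
    zero = VolumePatch(np.zeros(cfg.patch_shape, np.float32), (0, 0, 0))
    bright = VolumePatch(np.ones(cfg.patch_shape, np.float32), (1, 0, 0))
    kept = intensity_filter([zero, bright], 0.05, background_level=0.1)
    assert kept == [bright]
    assert intensity_filter([zero, bright], 0.0) == [zero, bright]
    with pytest.raises(ValueError):
        intensity_filter([zero], 1.5)


def test_intensity_filter_matches_voxel_counting_oracle():
    study, _ = generate_study(5, ["tumor"])
    cfg = TokenizerConfig()
    vol = study.sequences[0]
    level = 0.05 * float(vol.voxels.max())
    patches = patch_volume(vol, cfg)
    kept = intensity_filter(patches, 0.05, background_level=level)
    expected = sum(
        1 for p in patches
        if np.sum(p.voxels > level) / p.voxels.size > 0.05)
    assert len(kept) == expected
    # order preserved
    ids = [id(p) for p in patches]
    idx = [ids.index(id(p)) for p in kept]
    assert idx == sorted(idx)


def test_axis_permutation_preserves_voxel_multiset():
    cfg = TokenizerConfig()
    rng = np.random.default_rng(1)
    batch = [VolumePatch(rng.normal(size=cfg.patch_shape).astype(np.float32),
                         (i, 0, 0)) for i in range(4)]
    out = random_axis_permutation(batch, seed=3)
    for a, b in zip(batch, out):
        assert np.array_equal(np.sort(a.voxels.ravel()),
                              np.sort(b.voxels.ravel()))


def test_axis_permutation_uniform_over_six_orders():
    batch = [VolumePatch(np.arange(24, dtype=np.float32).reshape(2, 3, 4),
                         (0, 0, 0))]
    counts = {}
    for seed in range(600):
        out = random_axis_permutation(batch, seed=seed)
        counts[out[0].voxels.shape] = counts.get(out[0].voxels.shape, 0) + 1
    assert len(counts) == 6
    # 100 +/- 3 * sqrt(600 * (1/6)(5/6)) ~ [72, 128]
    assert all(72 <= c <= 128 for c in counts.values())


def test_axis_permutation_rejects_mixed_shapes():
    a = VolumePatch(np.zeros((2, 3, 4), np.float32), (0, 0, 0))
    b = VolumePatch(np.zeros((3, 2, 4), np.float32), (0, 0, 0))
    with pytest.raises(RuntimeError):
        random_axis_permutation([a, b], seed=0)


def test_quantize_single_entry_codebook_forces_index_zero():
    cb = Codebook(vectors=np.array([[0.5, -0.5]], dtype=np.float32))
    rng = np.random.default_rng(0)
    _, idx = quantize(rng.normal(size=(10, 2)), cb)
    assert (idx == 0).all()


def test_quantize_matches_exhaustive_argmin_oracle():
    rng = np.random.default_rng(2)
    cb = Codebook(vectors=rng.normal(size=(16, 2)).astype(np.float32))
    for _ in range(100):
        z = rng.normal(size=(7, 2))
        z_q, idx = quantize(z, cb)
        for row, i in zip(z, idx):
            d = ((cb.vectors.astype(np.float64) - row) ** 2).sum(axis=1)
            assert i == int(np.argmin(d))  # np.argmin ties -> lowest index
        assert np.allclose(z_q, cb.vectors[idx])


def test_quantize_tie_breaks_to_lowest_index():
    cb = Codebook(vectors=np.array([[1.0, 0.0], [1.0, 0.0], [-1.0, 0.0]],
                                   dtype=np.float32))
    _, idx = quantize(np.array([[1.0, 0.0]]), cb)
    assert idx[0] == 0


def test_quantize_rejects_non_finite():
    cb = Codebook(vectors=np.zeros((2, 2), dtype=np.float32))
    with pytest.raises(FloatingPointError):
        quantize(np.array([[np.nan, 0.0]]), cb)


def test_paper_scale_compression_ratio_and_latent_length(paper_config):
    assert paper_config.compression_ratio == 16
    assert paper_config.latent_length == 256


def test_config_invariants():
    with pytest.raises(ValueError):
        TokenizerConfig(patch_shape=(8, 8, 4), latent_grid=(3, 4, 2))
    with pytest.raises(ValueError):
        TokenizerConfig(codebook_size=1)


def test_vqvae_training_reduces_l1_and_uses_multiple_codes(desk_codec,
                                                           small_cohort,
                                                           desk_tok_config):
    study = small_cohort[0][0]
    tok = tokenize_volume(study.sequences[0], desk_codec)
    _, codes = desk_codec.encode_batch(
        np.stack([p.voxels for p in patch_volume(study.sequences[0],
                                                 desk_tok_config)]))
    assert len(np.unique(codes)) > 1          # no codebook collapse
    assert tok.tokens.shape[1] == desk_tok_config.latent_length


def test_vqvae_loss_decreases_and_constant_data_reconstructs():
    cfg = TokenizerConfig(codebook_size=8)
    rng = np.random.default_rng(4)
    patches = [VolumePatch(rng.normal(0.5, 0.2, cfg.patch_shape)
                           .astype(np.float32), (0, 0, 0)) for _ in range(64)]
    _, trace = train_vqvae(patches, cfg, epochs=8, seed=0)
    assert trace["train_l1"][-1] < trace["train_l1"][0]

    const = [VolumePatch(np.full(cfg.patch_shape, 0.7, np.float32), (0, 0, 0))
             for _ in range(32)]
    _, trace_c = train_vqvae(const, cfg, epochs=120, seed=0, lr=2e-2,
                             permute_augment=False)
    assert trace_c["train_l1"][-1] < 0.02


def test_vqvae_permutation_invariant_validation():
    """With permutation augmentation, held-out L1 on axis-permuted patches
    stays within 20% of the unpermuted L1."""
    from mriclip.tokenizer import AXIS_ORDERS
    from mriclip import nn
    from mriclip.tokenizer import quantize as q
    cfg = TokenizerConfig()
    study, _ = generate_study(13, ["tumor"])
    patches = [p for v in study.sequences for p in patch_volume(v, cfg)]
    codec, _ = train_vqvae(patches, cfg, epochs=12, seed=1)
    held = np.stack([p.voxels for p in patches[:40]]).astype(np.float32)

    def l1_of(x):
        with nn.no_grad():
            z, grid, factors = codec.encode_t(nn.Tensor(x))
            z_q, _ = q(z.data, codec.codebook)
            recon = codec.decode_t(nn.Tensor(z_q), grid, factors)
        return float(np.mean(np.abs(recon.data - x)))

    base = l1_of(held)
    perm = np.ascontiguousarray(held.transpose(0, 2, 3, 1))
    assert l1_of(perm) < 1.2 * base


def test_empty_dataset_rejected():
    with pytest.raises(ValueError):
        train_vqvae([], TokenizerConfig())


def test_mask_to_token_coords_matches_manual_tiling():
    cfg = TokenizerConfig()
    mask = np.zeros((32, 32, 16), dtype=bool)
    mask[0:2, 9:11, 14] = True     # spans grid y-cells 1 only, z-cell 3
    cells = mask_to_token_coords(mask, cfg)
    assert cells == {(0, 1, 3)}
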