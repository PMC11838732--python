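"""Hierarchical encoder: shape contracts at both scales, permutation
invariance, weight sharing, and positional feature structure."""

import numpy as np
import pytest

from mriclip import nn
from mriclip.encoder import (PAPER_ENCODER, EncoderConfig,
                             HierarchicalEncoder, sinusoid_features)
from mriclip.tokenizer import TokenizedSequence


def _toy_sequence(rng, n_tokens, dim=64, name="AX_T2"):
    return TokenizedSequence(
        tokens=rng.normal(size=(n_tokens, dim)).astype(np.float32),
        grid_coords=rng.integers(0, 4, size=(n_tokens, 3)),
        plane="axial", orientation="LPS", sequence_name=name)


@pytest.fixture(scope="module")
def desk_setup():
    rng = np.random.default_rng(0)
    enc = HierarchicalEncoder(EncoderConfig(), seed=0)
    from mriclip.textenc import CharNameEncoder
    names = CharNameEncoder(out_dim=enc.config.name_dim, seed=1)
    return enc, names, rng


def test_sinusoid_features_bounded_and_axis_localized():
    f = sinusoid_features(np.array([[0, 0, 0], [1, 0, 0]]))
    assert f.shape == (2, 30)
    assert np.all(f <= 1.0) and np.all(f >= -1.0)
    # coords differing only in axis 0 differ only in the first 10 dims
    diff = np.abs(f[0] - f[1])
    assert diff[:10].max() > 0
    assert np.allclose(diff[10:], 0)


def test_input_length_is_registers_plus_name_plus_tokens(desk_setup):
    enc, names, rng = desk_setup
    ts = _toy_sequence(rng, 12)
    with nn.no_grad():
        x, _ = enc.build_sequence_batch([ts], names.encode_batch([ts.sequence_name]))
    assert x.shape[1] == enc.config.seq_registers + 1 + 12


def test_empty_sequence_rejected(desk_setup):
    enc, names, rng = desk_setup
    ts = _toy_sequence(rng, 1)
    ts.tokens = ts.tokens[:0]
    ts.grid_coords = ts.grid_coords[:0]
    with pytest.raises(ValueError, match="background-filtered"):
        with nn.no_grad():
            enc.build_sequence_batch([ts], names.encode_batch(["x"]))


def test_token_order_permutation_invariance(desk_setup):
    enc, names, rng = desk_setup
    ts = _toy_sequence(rng, 15)
    perm = rng.permutation(15)
    ts_perm = TokenizedSequence(ts.tokens[perm], ts.grid_coords[perm],
                                ts.plane, ts.orientation, ts.sequence_name)
    with nn.no_grad():
        nv = names.encode_batch([ts.sequence_name])
        r1 = enc.vit_seq_forward([ts], nv).data
        r2 = enc.vit_seq_forward([ts_perm], nv).data
    assert np.allclose(r1, r2, atol=1e-4)


def test_sequence_order_permutation_invariance(desk_setup):
    enc, names, rng = desk_setup
    seqs = [_toy_sequence(rng, n) for n in (5, 9, 7)]
    with nn.no_grad():
        nv = names.encode_batch([s.sequence_name for s in seqs])
        reps = enc.vit_seq_forward(seqs, nv)
        stn = names.encode_batch(["MRI BRAIN"])
        v1 = enc.vit_st_forward(reps, [3], stn).data
        perm = nn.Tensor(reps.data[[2, 0, 1]])
        v2 = enc.vit_st_forward(perm, [3], stn).data
    assert np.allclose(v1, v2, atol=1e-4)


def test_single_sequence_study_supported(desk_setup):
    enc, names, rng = desk_setup
    seqs = [_toy_sequence(rng, 6)]
    with nn.no_grad():
        nv = names.encode_batch([seqs[0].sequence_name])
        reps = enc.vit_seq_forward(seqs, nv)
        v = enc.vit_st_forward(reps, [1], names.encode_batch(["MRI"]))
    assert v.shape == (1, enc.config.study_dim)
    with pytest.raises(ValueError):
        enc.vit_st_forward(reps, [], names.encode_batch([]))


def test_batching_matches_single_forward(desk_setup):
    """One shared sequence-transformer parameter set serves every sequence:
    padded batch output equals per-sequence forwards."""
    enc, names, rng = desk_setup
    seqs = [_toy_sequence(rng, n) for n in (4, 11)]
    with nn.no_grad():
        nv = names.encode_batch([s.sequence_name for s in seqs])
        both = enc.vit_seq_forward(seqs, nv).data
        singles = [enc.vit_seq_forward([s], names.encode_batch(
            [s.sequence_name])).data[0] for s in seqs]
    assert np.allclose(both[0], singles[0], atol=1e-4)
    assert np.allclose(both[1], singles[1], atol=1e-4)


def test_different_sequences_get_different_representations(desk_setup):
    enc, names, rng = desk_setup
    seqs = [_toy_sequence(rng, 8), _toy_sequence(rng, 8)]
    with nn.no_grad():
        nv = names.encode_batch([s.sequence_name for s in seqs])
        reps = enc.vit_seq_forward(seqs, nv).data
    assert not np.allclose(reps[0], reps[1], atol=1e-3)


def test_clip_projection_shapes_and_affine_at_zero(desk_setup):
    enc, names, rng = desk_setup
    c = enc.config
    v = nn.Tensor(rng.normal(size=(3, c.study_dim)).astype(np.float32))
    r = nn.Tensor(rng.normal(size=(3, 48)).astype(np.float32))
    with nn.no_grad():
        vm, vr = enc.project_for_clip(v, r)
        zm, _ = enc.project_for_clip(
            nn.Tensor(np.zeros((1, c.study_dim), np.float32)),
            nn.Tensor(np.zeros((1, 48), np.float32)))
    assert vm.shape == (3, c.clip_dim) and vr.shape == (3, c.clip_dim)
    assert np.allclose(zm.data[0], enc.clip_proj_m.b.data)  # bias at zero
    cos = (vm.data[0] @ vr.data[0]) / (np.linalg.norm(vm.data[0])
                                       * np.linalg.norm(vr.data[0]))
    assert -1.0 <= cos <= 1.0


def test_paper_scale_shape_contracts():
    """Full-scale forward: 1024-d sequence vectors, 10240-d study vector,
    128-d contrastive projections (random weights)."""
    cfg = EncoderConfig(**PAPER_ENCODER)
    assert cfg.study_dim == 10240
    enc = HierarchicalEncoder(cfg, seed=0)
    rng = np.random.default_rng(1)
    seqs = [TokenizedSequence(
        tokens=rng.normal(size=(6, 256)).astype(np.float32),
        grid_coords=rng.integers(0, 8, size=(6, 3)),
        plane="axial", orientation="LPS", sequence_name="AX_T2")
        for _ in range(2)]
    name_vecs = nn.Tensor(rng.normal(size=(2, 128)).astype(np.float32))
    with nn.no_grad():
        reps = enc.vit_seq_forward(seqs, name_vecs)
        v = enc.vit_st_forward(reps, [2], nn.Tensor(
            rng.normal(size=(1, 128)).astype(np.float32)))
        vm, vr = enc.project_for_clip(v, nn.Tensor(
            rng.normal(size=(1, 64)).astype(np.float32)))
    assert reps.shape == (2, 1024)
    assert v.shape == (1, 10240)
    assert vm.shape == (1, 128) and vr.shape == (1, 128)
    assert np.all(np.isfinite(v.data))
    # parameter count sanity: tens-to-hundreds of millions at full scale
    assert 10e6 < enc.n_parameters() < 500e6


def test_register_count_validation():
    with pytest.raises(ValueError):
        EncoderConfig(seq_registers=0)
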