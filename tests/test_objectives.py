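"""Training objectives: contrastive loss closed forms, patient-
discrimination loss vs a brute-force oracle, augmentation contracts, and
the abnormal upsampler."""

import numpy as np
import pytest

from mriclip import nn
from mriclip.objectives import (AugmentPolicy, LossState, SELF_LOGIT,
                                abnormal_upsampler, augment_pair, clip_loss,
                                combined_loss, identity_policy,
                                patient_discrimination_loss)
from mriclip.phantoms import ReportRecord
from mriclip.tokenizer import TokenizedSequence


def test_clip_loss_single_pair_is_zero():
    v = np.array([[1.0, 0.0]])
    assert float(clip_loss(v, v, 0.07).data) == pytest.approx(0.0, abs=1e-6)


def test_clip_loss_matches_hand_computed_two_by_two():
    """Orthogonal perfectly-aligned pairs at tau=0.07: each direction's
    cross-entropy is -log(e^s / (e^s + 1)) with s = exp(0.07)."""
    v = np.array([[1.0, 0.0], [0.0, 1.0]])
    s = np.exp(0.07)
    expected = 2 * (-np.log(np.exp(s) / (np.exp(s) + 1.0)))
    assert float(clip_loss(v, v, 0.07).data) == pytest.approx(expected,
                                                              rel=1e-5)


def test_clip_loss_invariant_under_joint_row_permutation():
    rng = np.random.default_rng(0)
    vm, vr = rng.normal(size=(5, 8)), rng.normal(size=(5, 8))
    perm = rng.permutation(5)
    a = float(clip_loss(vm, vr, 0.07).data)
    b = float(clip_loss(vm[perm], vr[perm], 0.07).data)
    assert a == pytest.approx(b, rel=1e-5)


def test_clip_loss_rejects_zero_norm_rows():
    v = np.array([[0.0, 0.0], [1.0, 0.0]])
    with pytest.raises(ValueError):
        clip_loss(v, v, 0.07)


def _patdis_oracle(embeddings, study_ids, tau_p):
    """Independent brute-force evaluation: explicit loops over the cosine
    logit matrix with the -10 self-logit and 1/(study size) row weights."""
    e = embeddings / np.linalg.norm(embeddings, axis=1, keepdims=True)
    N = len(e)
    logits = np.empty((N, N))
    for i in range(N):
        for j in range(N):
            logits[i, j] = (e[i] @ e[j]) / tau_p if i != j else SELF_LOGIT
    loss = 0.0
    for i in range(N):
        q = np.exp(logits[i] - logits[i].max())
        q /= q.sum()
        same = [j for j in range(N) if study_ids[j] == study_ids[i]]
        loss += -np.log(q[same].sum()) / len(same)
    return loss


class _IdentityProjection:
    def __call__(self, x):
        return x


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_patdis_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    k = rng.integers(2, 5)
    sizes = rng.integers(1, 4, size=k)
    ids = np.repeat(np.arange(k), sizes)
    emb = rng.normal(size=(len(ids), 6))
    got = float(patient_discrimination_loss(emb, ids, _IdentityProjection(),
                                            0.1).data)
    assert got == pytest.approx(_patdis_oracle(emb, ids, 0.1), rel=1e-4)


def test_patdis_identical_embeddings_closed_form_strict():
    """Strict-equation variant: with all embeddings identical the same-study
    mass is n_i/N, so the loss is mean_i -log(n_i / N)."""
    ids = np.array([0, 0, 1, 1, 1])
    emb = np.tile(np.array([1.0, 2.0, 3.0]), (5, 1))
    got = float(patient_discrimination_loss(
        emb, ids, _IdentityProjection(), 0.1, strict_equation=True).data)
    expected = np.mean([-np.log(2 / 5), -np.log(3 / 5)])
    assert got == pytest.approx(expected, rel=1e-5)


def test_patdis_decreases_with_within_study_similarity():
    ids = np.array([0, 0, 1, 1])
    loose = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])
    tight = np.array([[1.0, 0.1], [1.0, -0.1], [-1.0, 0.1], [-1.0, -0.1]])
    l_loose = float(patient_discrimination_loss(loose, ids,
                                                _IdentityProjection(), 0.1).data)
    l_tight = float(patient_discrimination_loss(tight, ids,
                                                _IdentityProjection(), 0.1).data)
    assert l_tight < l_loose


def test_patdis_requires_two_studies():
    with pytest.raises(ValueError):
        patient_discrimination_loss(np.ones((3, 4)), [0, 0, 0],
                                    _IdentityProjection(), 0.1)


def test_combined_loss_arithmetic():
    assert combined_loss(1.0, 2.0, 0.03) == pytest.approx(1.06)
    assert combined_loss(5.0, 99.0, 0.0) == pytest.approx(5.0)


def test_temperatures_receive_gradients():
    rng = np.random.default_rng(1)
    state = LossState()
    vm = nn.Tensor(rng.normal(size=(3, 4)).astype(np.float32),
                   requires_grad=True)
    vr = nn.Tensor(rng.normal(size=(3, 4)).astype(np.float32))
    loss = clip_loss(vm, vr, state.tau)
    emb = rng.normal(size=(4, 5))
    loss2 = patient_discrimination_loss(emb, [0, 0, 1, 1],
                                        _IdentityProjection(), state.tau_p)
    (loss + loss2).backward()
    assert state.tau.grad is not None and abs(state.tau.grad) > 0
    assert state.tau_p.grad is not None and abs(state.tau_p.grad) > 0


# ---------------------------------------------------------------------------
# augmentation / sampling

def _tok_study(rng, n_seq=3, n_tok=10):
    return [TokenizedSequence(
        tokens=rng.normal(size=(n_tok, 8)).astype(np.float32),
        grid_coords=rng.integers(0, 4, size=(n_tok, 3)),
        plane="axial", orientation="LPS", sequence_name=f"AX_T{i}",
        content_frac=rng.uniform(0.2, 1.0, size=n_tok))
        for i in range(n_seq)]


def _record():
    return ReportRecord(findings=["a", "b", "c"],
                        labels=np.array([1, 1, 0, 0]), acuity="high",
                        age=50.0, referrals=np.array([1, 0, 0]))


def test_identity_policy_is_identity():
    rng = np.random.default_rng(0)
    study = _tok_study(rng)
    out, rec = augment_pair(study, _record(), identity_policy(), seed=1)
    assert len(out) == len(study)
    for a, b in zip(out, study):
        assert np.array_equal(a.tokens, b.tokens)
        assert a.sequence_name == b.sequence_name
    assert rec.findings == ["a", "b", "c"]


def test_shuffle_preserves_finding_multiset_and_labels():
    rng = np.random.default_rng(0)
    study = _tok_study(rng)
    policy = AugmentPolicy(shuffle_findings=1.0, token_drop=0, unk_name=0,
                           sequence_drop=0, threshold_jitter=0)
    out, rec = augment_pair(study, _record(), policy, seed=5)
    assert sorted(rec.findings) == ["a", "b", "c"]
    assert np.array_equal(rec.labels, _record().labels)


def test_sequence_drop_never_drops_all():
    rng = np.random.default_rng(0)
    study = _tok_study(rng, n_seq=3)
    policy = AugmentPolicy(shuffle_findings=0, token_drop=0, unk_name=0,
                           sequence_drop=1.0, threshold_jitter=0)
    out, _ = augment_pair(study, _record(), policy, seed=2)
    assert len(out) == 1


def test_token_drop_keeps_at_least_one_token():
    rng = np.random.default_rng(0)
    study = _tok_study(rng, n_seq=1, n_tok=5)
    policy = AugmentPolicy(shuffle_findings=0, token_drop=0.99, unk_name=0,
                           sequence_drop=0, threshold_jitter=0)
    out, _ = augment_pair(study, _record(), policy, seed=3)
    assert out[0].tokens.shape[0] >= 1


def test_unk_name_replacement():
    rng = np.random.default_rng(0)
    study = _tok_study(rng)
    policy = AugmentPolicy(shuffle_findings=0, token_drop=0, unk_name=1.0,
                           sequence_drop=0, threshold_jitter=0)
    out, _ = augment_pair(study, _record(), policy, seed=4)
    assert all(ts.sequence_name == "unk" for ts in out)


def test_invalid_probability_rejected():
    with pytest.raises(ValueError):
        AugmentPolicy(token_drop=1.5)


def test_upsampler_multiplicity_and_census_conservation():
    flags = [False] * 10 + [True] * 10
    stream = abnormal_upsampler(flags, factor=4, seed=0)
    assert len(stream) == 10 + 4 * 10
    counts = np.bincount(stream, minlength=20)
    assert (counts[:10] == 1).all()     # each normal exactly once
    assert (counts[10:] == 4).all()     # each abnormal exactly 4 times
    assert len(abnormal_upsampler(flags, factor=1, seed=0)) == 20


def test_upsampler_all_normal_warns_identity():
    with pytest.warns(UserWarning):
        stream = abnormal_upsampler([False] * 5, factor=4, seed=0)
    assert sorted(stream) == list(range(5))


def test_upsampled_abnormal_fraction():
    flags = [False] * 30 + [True] * 10
    stream = abnormal_upsampler(flags, factor=4, seed=1)
    frac = np.mean([flags[i] for i in stream])
    assert frac == pytest.approx(40 / 70, abs=1e-9)
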