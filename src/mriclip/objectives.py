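"""Joint training objective: symmetric contrastive study-report alignment
plus an auxiliary patient sequence-discrimination loss, with the training-
time augmentation policy and abnormal-study upsampling.

Contrastive loss: logits are cosine similarities scaled by exp(tau)
(tau learnable, init 0.07); cross-entropy toward the diagonal is computed in
both directions and summed.  Patient discrimination: sequence embeddings are
projected by a 2-layer MLP, cosine logits are divided by a learnable
temperature tau_p (init 0.1), self-logits are set to -10, rows are
softmaxed, and each row contributes -log(total probability mass on its own
study) weighted by 1/(study size).  The combined objective is
clip + lambda * patdis with lambda = 0.03.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .phantoms import ReportRecord, render_report

SELF_LOGIT = -10.0


@dataclass
class LossState:
    tau: nn.Tensor = field(default_factory=lambda: nn.Tensor(
        np.float32(0.07), requires_grad=True))
    tau_p: nn.Tensor = field(default_factory=lambda: nn.Tensor(
        np.float32(0.1), requires_grad=True))
    lambda_patdis: float = 0.03

    def parameters(self):
        return [self.tau, self.tau_p]


def _lift(x):
    return x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x, dtype=np.float32))


def _normalize_rows(v: nn.Tensor) -> nn.Tensor:
    norms = (v * v).sum(axis=1, keepdims=True).sqrt()
    if float(norms.data.min()) <= 0.0:
        raise ValueError("zero-norm row: cosine similarity undefined")
    return v / norms


def clip_loss(v_m, v_r, tau):
    """Symmetric contrastive loss over a batch of matched pairs.

    v_m, v_r: (k, d) arrays or Tensors; tau: scalar (logit scale exp(tau)).
    Returns a scalar Tensor (use .data for the value).
    """
    v_m, v_r, tau = _lift(v_m), _lift(v_r), _lift(tau)
    k = v_m.shape[0]
    logits = (_normalize_rows(v_m) @ _normalize_rows(v_r).transpose(1, 0)) * tau.exp()
    eye = np.eye(k, dtype=np.float32)
    ce_m = -(logits.log_softmax(axis=-1) * nn.Tensor(eye)).sum() / k
    ce_r = -(logits.transpose(1, 0).log_softmax(axis=-1) * nn.Tensor(eye)).sum() / k
    return ce_m + ce_r


def patient_discrimination_loss(seq_embeddings, study_ids, projection, tau_p,
                                strict_equation=False):
    """Patient sequence-discrimination loss.

    seq_embeddings: (N, d) stacked sequence representations; study_ids: N
    ints grouping sequences into studies; projection: callable 2-layer MLP;
    tau_p: scalar temperature.  Default follows the executable convention
    (self-logit -10, self included in the positive mask, rows weighted by
    1/study size and summed); `strict_equation=True` instead averages
    -log(same-study mass / total mass) with self included everywhere and a
    leading 1/k over studies.
    """
    study_ids = np.asarray(study_ids)
    if len(np.unique(study_ids)) < 2:
        raise ValueError("patient discrimination needs >= 2 studies per batch")
    u = _normalize_rows(projection(_lift(seq_embeddings)))
    tau_p = _lift(tau_p)
    N = u.shape[0]
    sim = u @ u.transpose(1, 0)
    logits = sim / tau_p
    mask = (study_ids[:, None] == study_ids[None, :]).astype(np.float32)
    masksum = mask.sum(axis=1)
    if strict_equation:
        e = (logits).exp()
        num = (e * nn.Tensor(mask)).sum(axis=1)
        den = e.sum(axis=1)
        per_row = -(num / den).log() / nn.Tensor(masksum.astype(np.float32))
        k = len(np.unique(study_ids))
        return per_row.sum() / k
    eye = np.eye(N, dtype=np.float32)
    logits = logits * nn.Tensor(1.0 - eye) + nn.Tensor(SELF_LOGIT * eye)
    q = logits.softmax(axis=-1)
    agg = (q * nn.Tensor(mask)).sum(axis=1)
    return -(agg.log() * nn.Tensor((1.0 / masksum).astype(np.float32))).sum()


def combined_loss(clip, patdis, lam=0.03):
    return clip + lam * patdis


# ---------------------------------------------------------------------------
# augmentation and sampling

@dataclass
class AugmentPolicy:
    shuffle_findings: float = 0.5
    token_drop: float = 0.1       # per-token drop probability
    unk_name: float = 0.1
    sequence_drop: float = 0.1
    threshold_jitter: float = 0.5  # filter threshold scaled by U(1-j, 1+j)
    base_threshold: float = 0.05

    def __post_init__(self):
        for p in (self.shuffle_findings, self.token_drop, self.unk_name,
                  self.sequence_drop):
            if not 0.0 <= p <= 1.0:
                raise ValueError("augmentation probabilities must lie in [0, 1]")


def identity_policy():
    return AugmentPolicy(shuffle_findings=0, token_drop=0, unk_name=0,
                         sequence_drop=0, threshold_jitter=0)


def augment_pair(tok_study, record: ReportRecord, policy: AugmentPolicy,
                 seed=None, rng=None):
    """Augment a (tokenized study, report) pair.

    tok_study: list of TokenizedSequence (tokenized with threshold 0 so the
    filter threshold can be jittered both ways).  Never drops all sequences
    or all tokens of a sequence; the label vector is unchanged.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    seqs = list(tok_study)
    # full-sequence drop, keeping at least one
    if policy.sequence_drop > 0 and len(seqs) > 1:
        kept = [s for s in seqs if rng.random() >= policy.sequence_drop]
        seqs = kept or [seqs[rng.integers(len(seqs))]]
    out = []
    for ts in seqs:
        thr = policy.base_threshold
        if policy.threshold_jitter > 0:
            thr *= float(rng.uniform(1 - policy.threshold_jitter,
                                     1 + policy.threshold_jitter))
        ts = ts.refiltered(thr)
        n = ts.tokens.shape[0]
        if policy.token_drop > 0 and n > 1:
            keep = rng.random(n) >= policy.token_drop
            if not keep.any():
                keep[rng.integers(n)] = True
            ts = replace(ts, tokens=ts.tokens[keep],
                         grid_coords=ts.grid_coords[keep],
                         content_frac=None if ts.content_frac is None
                         else ts.content_frac[keep])
        if policy.unk_name > 0 and rng.random() < policy.unk_name:
            ts = replace(ts, sequence_name="unk")
        out.append(ts)
    findings = list(record.findings)
    if policy.shuffle_findings > 0 and rng.random() < policy.shuffle_findings:
        rng.shuffle(findings)
    new_record = ReportRecord(findings=findings, labels=record.labels,
                              acuity=record.acuity, age=record.age,
                              referrals=record.referrals)
    return out, new_record


def abnormal_upsampler(abnormal_flags, factor=4, seed=None, rng=None):
    """Epoch index stream with abnormal studies repeated `factor` times.

    Normal studies keep their census multiplicity (none duplicated or lost).
    """
    flags = np.asarray(abnormal_flags, dtype=bool)
    rng = rng if rng is not None else np.random.default_rng(seed)
    if not flags.any():
        warnings.warn("all-normal cohort: upsampler is identity")
        factor = 1
    idx = []
    for i, ab in enumerate(flags):
        idx.extend([i] * (factor if ab else 1))
    idx = np.array(idx, dtype=np.int64)
    rng.shuffle(idx)
    return idx


# ---------------------------------------------------------------------------
# joint training loop

def _encode_reports(report_lm, records):
    return report_lm.encode_texts([render_report(r) for r in records])


def retrieval_topk(sim, k):
    order = np.argsort(-sim, axis=1, kind="stable")
    hits = (order[:, :k] == np.arange(sim.shape[0])[:, None]).any(axis=1)
    return float(hits.mean())


def train_clip(tok_studies, records, study_names, encoder, report_lm,
               seq_name_enc, study_name_enc, loss_state=None, epochs=20,
               seed=0, batch_size=8, lr=1e-3, tau_lr=5e-2, val_frac=0.2,
               policy: AugmentPolicy | None = None, upsample_factor=4,
               use_patdis=True, verbose=False):
    """Jointly train the hierarchical encoder and text encoders.

    The tokenizer is frozen (tokens are precomputed); vision and text
    weights, projections, temperatures and the patient-discrimination MLP
    all update.  The scalar temperatures get their own faster learning rate
    (`tau_lr`) since the logit scale exp(tau) must travel far from its 0.07
    initialization.  Returns (loss_state, trace) where trace records
    per-epoch train loss and held-out Top-1/Top-5 retrieval.
    """
    n = len(tok_studies)
    if n < 2:
        raise ValueError("contrastive training needs >= 2 studies")
    rng = np.random.default_rng(seed)
    loss_state = loss_state or LossState()
    policy = policy if policy is not None else AugmentPolicy()

    mlp_rng = np.random.default_rng(seed + 17)
    d = encoder.config.seq_rep_dim
    p_patdis = nn.MLP(mlp_rng, [d, d, d // 2])

    # warm the lazy text projection before collecting parameters
    with nn.no_grad():
        dim_probe = _encode_reports(report_lm, records[:1])
    encoder.ensure_text_proj(dim_probe.shape[-1])

    params = (encoder.parameters() + report_lm.parameters()
              + seq_name_enc.parameters() + study_name_enc.parameters()
              + p_patdis.parameters())
    opt = nn.AdamW(params, lr=lr, weight_decay=1e-4, clip_norm=1.0)
    opt_tau = nn.AdamW(loss_state.parameters(), lr=tau_lr, clip_norm=None)

    order = rng.permutation(n)
    n_val = max(2, int(n * val_frac))
    val_idx, train_idx = order[:n_val], order[n_val:]
    abnormal = np.array([bool(records[i].labels.any()) for i in train_idx])

    trace = {"train_loss": [], "top1": [], "top5": []}
    step = 0
    frac_ab = abnormal.mean() if len(abnormal) else 0.0
    stream_len = len(train_idx) * (1 + (upsample_factor - 1) * frac_ab)
    total_steps = max(1, int(epochs * stream_len / batch_size))
    for epoch in range(epochs):
        stream = train_idx[abnormal_upsampler(abnormal, upsample_factor, rng=rng)]
        losses = []
        for s in range(0, len(stream) - 1, batch_size):
            batch = stream[s:s + batch_size]
            if len(batch) < 2:
                continue
            studies_b, records_b = [], []
            for i in batch:
                ts, rec = augment_pair(tok_studies[i], records[i], policy, rng=rng)
                studies_b.append(ts)
                records_b.append(rec)
            names_b = [study_names[i] for i in batch]
            v, seq_reps, sizes = encoder.encode_study_batch(
                studies_b, seq_name_enc, names_b, study_name_enc)
            r = _encode_reports(report_lm, records_b)
            v_m, v_r = encoder.project_for_clip(v, r)
            loss = clip_loss(v_m, v_r, loss_state.tau)
            if use_patdis and len(sizes) >= 2:
                ids = np.repeat(np.arange(len(sizes)), sizes)
                loss = combined_loss(
                    loss,
                    patient_discrimination_loss(seq_reps, ids, p_patdis,
                                                loss_state.tau_p),
                    loss_state.lambda_patdis)
            opt.zero_grad()
            opt_tau.zero_grad()
            loss.backward()
            opt.step(lr=nn.cosine_lr(lr, step, total_steps, warmup=10,
                                     min_frac=0.15))
            opt_tau.step()
            step += 1
            losses.append(float(loss.data))
        top1, top5 = evaluate_retrieval(
            [tok_studies[i] for i in val_idx], [records[i] for i in val_idx],
            [study_names[i] for i in val_idx], encoder, report_lm,
            seq_name_enc, study_name_enc,
            threshold=policy.base_threshold)
        trace["train_loss"].append(float(np.mean(losses)) if losses else np.nan)
        trace["top1"].append(top1)
        trace["top5"].append(top5)
        if verbose:
            print(f"epoch {epoch}: loss={trace['train_loss'][-1]:.4f} "
                  f"top1={top1:.3f} top5={top5:.3f}")
    return {"p_patdis": p_patdis, "val_idx": val_idx, "train_idx": train_idx,
            "loss_state": loss_state}, trace


def encode_cohort(tok_studies, study_names, encoder, seq_name_enc,
                  study_name_enc, batch_size=16, threshold=0.05):
    """Frozen-forward study embeddings for a tokenized cohort (n, study_dim)."""
    out = []
    with nn.no_grad():
        for s in range(0, len(tok_studies), batch_size):
            chunk = [[ts.refiltered(threshold) for ts in st]
                     for st in tok_studies[s:s + batch_size]]
            v, _, _ = encoder.encode_study_batch(
                chunk, seq_name_enc, study_names[s:s + batch_size],
                study_name_enc)
            out.append(v.data)
    return np.concatenate(out, axis=0)


def evaluate_retrieval(tok_studies, records, study_names, encoder, report_lm,
                       seq_name_enc, study_name_enc, threshold=0.05):
    """Held-out Top-1/Top-5 study-report retrieval accuracy."""
    with nn.no_grad():
        v = encode_cohort(tok_studies, study_names, encoder, seq_name_enc,
                          study_name_enc, threshold=threshold)
        r = _encode_reports(report_lm, records).data
        v_m, v_r = encoder.project_for_clip(nn.Tensor(v), nn.Tensor(r))
        a = v_m.data / np.linalg.norm(v_m.data, axis=1, keepdims=True)
        b = v_r.data / np.linalg.norm(v_r.data, axis=1, keepdims=True)
    sim = a @ b.T
    return retrieval_topk(sim, 1), retrieval_topk(sim, min(5, sim.shape[0]))
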