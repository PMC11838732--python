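"""End-to-end orchestration: phantom cohort -> tokenizer -> text encoders ->
contrastive training -> frozen-embedding transfer heads, plus the classifier
wrapper used for LIME attribution.

The desk preset keeps every stage CPU-sized (small volumes, narrow
transformers, a few hundred studies) while exercising the full method; the
paper-scale encoder/tokenizer configurations remain available as presets for
shape-contract work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .encoder import EncoderConfig, HierarchicalEncoder
from .heads import HeadConfig, predict_head, train_head
from .metrics import multilabel_auroc
from .objectives import AugmentPolicy, encode_cohort, train_clip
from .phantoms import GeneratorConfig, generate_cohort, render_report
from .textenc import CharNameEncoder, pretrain_report_lm, pretrain_sequence_name_encoder
from .tokenizer import (TokenizerConfig, mask_to_token_coords, patch_volume,
                        tokenize_study, train_vqvae)

ACUITY_INDEX = {"normal": 0, "medium": 1, "high": 2}


@dataclass
class DeskSettings:
    n_studies: int = 200
    prevalences: tuple = (0.3, 0.3, 0.3, 0.3)
    vq_patches: int = 800
    vq_epochs: int = 10
    lm_epochs: int = 8
    name_epochs: int = 10
    clip_epochs: int = 40
    clip_batch: int = 24
    clip_lr: float = 1.5e-3
    clip_val_frac: float = 0.2
    head_epochs: int = 60
    policy: AugmentPolicy = field(default_factory=AugmentPolicy)


@dataclass
class PipelineResult:
    cohort: list                  # (MRIStudy, ReportRecord, SubgroupMetadata)
    codec: object
    tok_studies: list             # tokenized with threshold 0
    report_lm: object
    seq_name_enc: object
    study_name_enc: object
    encoder: HierarchicalEncoder
    clip_state: dict
    clip_trace: dict
    embeddings: np.ndarray        # (n, study_dim) frozen study vectors
    heads: dict                   # task -> trained head
    metrics: dict
    generator_config: GeneratorConfig
    tokenizer_config: TokenizerConfig


def run_desk_pipeline(seed=0, settings: DeskSettings | None = None,
                      verbose=False) -> PipelineResult:
    """Run the full desk-scale study: simulate, tokenize, align, transfer."""
    st = settings or DeskSettings()
    rng = np.random.default_rng(seed)
    seeds = {k: int(rng.integers(2 ** 31)) for k in
             ("cohort", "vq", "lm", "name", "clip", "heads")}

    gen_cfg = GeneratorConfig()
    cohort = generate_cohort(st.n_studies, st.prevalences, seed=seeds["cohort"],
                             config=gen_cfg)
    studies = [c[0] for c in cohort]
    records = [c[1] for c in cohort]
    study_names = [s.study_name for s in studies]

    # 1. tokenizer
    tok_cfg = TokenizerConfig()
    patch_rng = np.random.default_rng(seeds["vq"])
    pool = [p for s in studies[:40] for v in s.sequences
            for p in patch_volume(v, tok_cfg)]
    take = patch_rng.choice(len(pool), min(st.vq_patches, len(pool)),
                            replace=False)
    codec, vq_trace = train_vqvae([pool[i] for i in take], tok_cfg,
                                  epochs=st.vq_epochs, seed=seeds["vq"])
    # cache tokens unfiltered so the filter threshold can be augmented
    tok_studies = [tokenize_study(s, codec, threshold=0.0) for s in studies]

    # 2. text encoders
    corpus = [render_report(r) for r in records]
    report_lm, ppl_trace = pretrain_report_lm(corpus, epochs=st.lm_epochs,
                                              seed=seeds["lm"])
    name_pairs = [(ts.sequence_name, ts.tokens)
                  for st_tok in tok_studies[:60] for ts in st_tok]
    seq_name_enc = pretrain_sequence_name_encoder(
        name_pairs, epochs=st.name_epochs, seed=seeds["name"],
        out_dim=EncoderConfig().name_dim)
    study_name_enc = CharNameEncoder(out_dim=EncoderConfig().name_dim,
                                     seed=seeds["name"] % 10007 + 1)

    # 3. joint contrastive training
    encoder = HierarchicalEncoder(EncoderConfig(), seed=seeds["clip"])
    clip_state, clip_trace = train_clip(
        tok_studies, records, study_names, encoder, report_lm, seq_name_enc,
        study_name_enc, epochs=st.clip_epochs, seed=seeds["clip"],
        batch_size=st.clip_batch, lr=st.clip_lr, val_frac=st.clip_val_frac,
        policy=st.policy, verbose=verbose)
    val_idx = clip_state["val_idx"]
    train_idx = clip_state["train_idx"]

    # 4. frozen embeddings + transfer heads
    embeddings = encode_cohort(tok_studies, study_names, encoder,
                               seq_name_enc, study_name_enc,
                               threshold=st.policy.base_threshold)
    labels = np.stack([r.labels for r in records])
    referrals = np.stack([r.referrals for r in records])
    acuity = np.array([ACUITY_INDEX[r.acuity] for r in records])
    ages = np.array([r.age for r in records])

    heads, metrics = {}, {}
    head_seed = seeds["heads"]
    heads["diagnosis"], dx_trace, _ = train_head(
        embeddings, labels,
        HeadConfig(task="diagnosis", out_dim=labels.shape[1],
                   epochs=st.head_epochs),
        seed=head_seed, train_idx=train_idx, val_idx=val_idx)
    heads["referral"], _, _ = train_head(
        embeddings, referrals,
        HeadConfig(task="referral", out_dim=referrals.shape[1],
                   epochs=st.head_epochs),
        seed=head_seed + 1, train_idx=train_idx, val_idx=val_idx)
    heads["acuity"], _, _ = train_head(
        embeddings, acuity, HeadConfig(task="acuity", out_dim=3,
                                       epochs=st.head_epochs),
        seed=head_seed + 2, train_idx=train_idx, val_idx=val_idx)
    heads["age"], _, _ = train_head(
        embeddings, ages, HeadConfig(task="age", out_dim=1,
                                     epochs=st.head_epochs),
        seed=head_seed + 3, train_idx=train_idx, val_idx=val_idx)

    dx_scores = 1.0 / (1.0 + np.exp(-predict_head(heads["diagnosis"],
                                                  embeddings[val_idx])))
    _, mean_auroc = multilabel_auroc(dx_scores, labels[val_idx])
    metrics["val_top1"] = clip_trace["top1"][-1]
    metrics["val_top5"] = clip_trace["top5"][-1]
    metrics["val_mean_auroc"] = mean_auroc
    metrics["val_size"] = int(len(val_idx))
    metrics["vq_final_l1"] = vq_trace["train_l1"][-1]
    metrics["lm_final_perplexity"] = ppl_trace[-1]
    metrics["diagnosis_head_trace"] = dx_trace

    return PipelineResult(
        cohort=cohort, codec=codec, tok_studies=tok_studies,
        report_lm=report_lm, seq_name_enc=seq_name_enc,
        study_name_enc=study_name_enc, encoder=encoder,
        clip_state=clip_state, clip_trace=clip_trace, embeddings=embeddings,
        heads=heads, metrics=metrics, generator_config=gen_cfg,
        tokenizer_config=tok_cfg)


class StudyClassifier:
    """Frozen encoder + diagnosis head exposing per-label logits, including
    the token-subset interface LIME perturbs (single-sequence input)."""

    def __init__(self, result: PipelineResult, threshold=0.05):
        self.encoder = result.encoder
        self.head = result.heads["diagnosis"]
        self.seq_name_enc = result.seq_name_enc
        self.study_name_enc = result.study_name_enc
        self.threshold = threshold

    def logits(self, tok_study, study_name):
        with nn.no_grad():
            v, _, _ = self.encoder.encode_study_batch(
                [[ts.refiltered(self.threshold) for ts in tok_study]],
                self.seq_name_enc, [study_name], self.study_name_enc)
            return predict_head(self.head, v.data)[0]

    def masked_logits(self, tok_seq, masks, target_label, study_name="MRI",
                      chunk=256):
        """Target-label logit for each token-subset mask of one sequence."""
        from dataclasses import replace
        out = np.empty(len(masks))
        for s in range(0, len(masks), chunk):
            batch = []
            for m in np.asarray(masks, dtype=bool)[s:s + chunk]:
                batch.append([replace(tok_seq, tokens=tok_seq.tokens[m],
                                      grid_coords=tok_seq.grid_coords[m],
                                      content_frac=None)])
            with nn.no_grad():
                v, _, _ = self.encoder.encode_study_batch(
                    batch, self.seq_name_enc, [study_name] * len(batch),
                    self.study_name_enc)
                logits = predict_head(self.head, v.data)
            out[s:s + len(batch)] = logits[:, target_label]
        return out


def lesion_token_sets(result: PipelineResult, study_index, class_name):
    """Ground-truth lesion token coordinates per sequence of one study."""
    study = result.cohort[study_index][0]
    masks = study.lesion_masks.get(class_name, {})
    return {si: mask_to_token_coords(m, result.tokenizer_config)
            for si, m in masks.items()}
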