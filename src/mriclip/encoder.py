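"""Two-level hierarchical vision transformer over volume tokens.

The sequence transformer encodes one MRI sequence from its volume tokens
(latent embedding + 30-d sinusoidal position feature from the 3D grid
coordinate + 3-d plane one-hot), a sequence-name embedding, and a set of
learnable register tokens; its representation is a linear projection of the
concatenated final-layer register outputs, and one parameter set is shared
across all sequences.  The study transformer aggregates projected sequence
representations with a study-name embedding and its own registers; the study
representation concatenates its register outputs.  Positional information
enters only through explicit features, so both levels are invariant to the
order of their input tokens/sequences.

Full-scale configuration: 15-layer/16-head sequence ViT (width 1024),
1024-d sequence vectors, 4-layer/8-head study ViT (width 512 with 1024<->512
projections), 20/10 registers, 10240-d study vectors, 128-d contrastive
projections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

SINUSOID_DIMS = 30          # 10 per axis: 5 frequency pairs
PLANE_ONEHOT = {"axial": 0, "coronal": 1, "sagittal": 2}


@dataclass
class EncoderConfig:
    token_dim: int = 64           # flattened latent length
    name_dim: int = 64            # output dim of the name encoders
    seq_width: int = 64
    seq_layers: int = 3
    seq_heads: int = 4
    seq_head_dim: int = 16
    seq_registers: int = 8
    seq_rep_dim: int = 64
    st_width: int = 64
    st_layers: int = 2
    st_heads: int = 4
    st_head_dim: int = 16
    study_registers: int = 4
    clip_dim: int = 48
    mlp_ratio: int = 4

    def __post_init__(self):
        if self.seq_registers < 1 or self.study_registers < 1:
            raise ValueError("register counts must be >= 1")

    @property
    def study_dim(self):
        return self.study_registers * self.seq_rep_dim


PAPER_ENCODER = dict(
    token_dim=256, name_dim=128,
    seq_width=1024, seq_layers=15, seq_heads=16, seq_head_dim=64,
    seq_registers=20, seq_rep_dim=1024,
    st_width=512, st_layers=4, st_heads=8, st_head_dim=64,
    study_registers=10, clip_dim=128,
)


def sinusoid_features(coords: np.ndarray) -> np.ndarray:
    """(n, 3) integer grid coords -> (n, 30) sinusoidal features in [-1, 1].

    10 dims per axis as 5 sin/cos pairs on a geometric frequency schedule.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n_freq = SINUSOID_DIMS // 6
    freqs = 1.0 / (100.0 ** (np.arange(n_freq) / n_freq))
    ang = coords[:, :, None] * freqs[None, None, :]      # (n, 3, 5)
    feat = np.concatenate([np.sin(ang), np.cos(ang)], axis=2)  # (n, 3, 10)
    return feat.reshape(coords.shape[0], -1).astype(np.float32)


def plane_onehot(plane: str) -> np.ndarray:
    v = np.zeros(3, dtype=np.float32)
    v[PLANE_ONEHOT[plane]] = 1.0
    return v


def token_features(tok_seq) -> np.ndarray:
    """Latent embedding + sinusoid position + plane one-hot, per token."""
    n = tok_seq.tokens.shape[0]
    pos = sinusoid_features(tok_seq.grid_coords)
    pl = np.tile(plane_onehot(tok_seq.plane), (n, 1))
    return np.concatenate([tok_seq.tokens, pos, pl], axis=1)


class HierarchicalEncoder(nn.Module):
    def __init__(self, config: EncoderConfig | None = None, seed=0):
        self.config = config or EncoderConfig()
        c = self.config
        rng = np.random.default_rng(seed)
        feat_dim = c.token_dim + SINUSOID_DIMS + 3
        self.token_proj = nn.Linear(rng, feat_dim, c.seq_width)
        self.seq_name_proj = nn.Linear(rng, c.name_dim, c.seq_width)
        self.seq_registers = nn.Tensor(
            rng.normal(0, 0.02, (c.seq_registers, c.seq_width)).astype(np.float32),
            requires_grad=True)
        self.vit_seq = nn.Transformer(rng, c.seq_width, c.seq_layers, c.seq_heads,
                                      c.seq_head_dim, c.mlp_ratio)
        self.seq_readout = nn.Linear(rng, c.seq_registers * c.seq_width,
                                     c.seq_rep_dim)
        self.st_in_proj = nn.Linear(rng, c.seq_rep_dim, c.st_width)
        self.study_name_proj = nn.Linear(rng, c.name_dim, c.st_width)
        self.st_registers = nn.Tensor(
            rng.normal(0, 0.02, (c.study_registers, c.st_width)).astype(np.float32),
            requires_grad=True)
        self.vit_st = nn.Transformer(rng, c.st_width, c.st_layers, c.st_heads,
                                     c.st_head_dim, c.mlp_ratio)
        self.st_out_proj = nn.Linear(rng, c.st_width, c.seq_rep_dim)
        self.clip_proj_m = nn.Linear(rng, c.study_dim, c.clip_dim)
        self.clip_proj_r = None   # created lazily against the text dim
        self._rng = rng

    def ensure_text_proj(self, text_dim):
        if self.clip_proj_r is None:
            self.clip_proj_r = nn.Linear(self._rng, text_dim, self.config.clip_dim)
        return self.clip_proj_r

    # ---- sequence level -------------------------------------------------
    def build_sequence_batch(self, tok_seqs, name_vecs: nn.Tensor):
        """Pad a batch of tokenized sequences into [registers | name | tokens].

        Returns (input Tensor (B, T, W), attention bias) — raises if any
        sequence arrives with zero tokens (fully background-filtered).
        """
        c = self.config
        B = len(tok_seqs)
        counts = [ts.tokens.shape[0] for ts in tok_seqs]
        if min(counts) == 0:
            raise ValueError("sequence fully background-filtered")
        T = c.seq_registers + 1 + max(counts)
        feat_dim = c.token_dim + SINUSOID_DIMS + 3
        feats = np.zeros((B, max(counts), feat_dim), dtype=np.float32)
        valid = np.zeros((B, T), dtype=bool)
        valid[:, : c.seq_registers + 1] = True
        for i, ts in enumerate(tok_seqs):
            feats[i, : counts[i]] = token_features(ts)
            valid[i, c.seq_registers + 1: c.seq_registers + 1 + counts[i]] = True
        tok_part = self.token_proj(nn.Tensor(feats))
        name_part = self.seq_name_proj(name_vecs).reshape(B, 1, c.seq_width)
        reg_part = (self.seq_registers.reshape(1, c.seq_registers, c.seq_width)
                    * nn.Tensor(np.ones((B, 1, 1), dtype=np.float32)))
        x = nn.Tensor.cat([reg_part, name_part, tok_part], axis=1)
        return x, nn.padding_attn_bias(valid)

    def vit_seq_forward(self, tok_seqs, name_vecs: nn.Tensor) -> nn.Tensor:
        """(B tokenized sequences, (B, name_dim) names) -> (B, seq_rep_dim)."""
        c = self.config
        x, bias = self.build_sequence_batch(tok_seqs, name_vecs)
        h = self.vit_seq(x, bias)
        regs = h[:, : c.seq_registers, :].reshape(len(tok_seqs),
                                                  c.seq_registers * c.seq_width)
        return self.seq_readout(regs)

    # ---- study level ----------------------------------------------------
    def vit_st_forward(self, seq_reps: nn.Tensor, study_sizes,
                       study_name_vecs: nn.Tensor) -> nn.Tensor:
        """Grouped sequence representations -> (k, study_dim) study vectors.

        seq_reps stacks all sequences of the batch (N, seq_rep_dim);
        study_sizes lists the number of sequences per study (each >= 1).
        """
        c = self.config
        k = len(study_sizes)
        if k == 0 or min(study_sizes) < 1:
            raise ValueError("every study needs at least one sequence")
        m_max = max(study_sizes)
        T = c.study_registers + 1 + m_max
        # scatter the flat sequence reps into padded per-study slots
        N = seq_reps.shape[0]
        scatter = np.zeros((k, m_max, N), dtype=np.float32)
        valid = np.zeros((k, T), dtype=bool)
        valid[:, : c.study_registers + 1] = True
        pos = 0
        for i, m in enumerate(study_sizes):
            for j in range(m):
                scatter[i, j, pos] = 1.0
                pos += 1
            valid[i, c.study_registers + 1: c.study_registers + 1 + m] = True
        proj = self.st_in_proj(seq_reps)                      # (N, st_width)
        grouped = nn.Tensor(scatter) @ proj                   # (k, m_max, W)
        name_part = self.study_name_proj(study_name_vecs).reshape(k, 1, c.st_width)
        reg_part = (self.st_registers.reshape(1, c.study_registers, c.st_width)
                    * nn.Tensor(np.ones((k, 1, 1), dtype=np.float32)))
        x = nn.Tensor.cat([reg_part, name_part, grouped], axis=1)
        h = self.vit_st(x, nn.padding_attn_bias(valid))
        regs = h[:, : c.study_registers, :]                   # (k, R, W)
        out = self.st_out_proj(regs)                          # (k, R, rep)
        return out.reshape(k, c.study_dim)

    def project_for_clip(self, v_study: nn.Tensor, r_report: nn.Tensor):
        """Linear projections of study and report vectors to the shared
        contrastive space (both outputs have clip_dim columns)."""
        self.ensure_text_proj(r_report.shape[-1])
        return self.clip_proj_m(v_study), self.clip_proj_r(r_report)

    # ---- convenience ----------------------------------------------------
    def encode_study_batch(self, studies_tokens, seq_name_encoder,
                           study_names, study_name_encoder):
        """Full forward for a batch of tokenized studies.

        studies_tokens: list (len k) of lists of TokenizedSequence.
        Returns (study_vectors (k, study_dim), seq_reps (N, seq_rep_dim),
        study_sizes).
        """
        flat = [ts for study in studies_tokens for ts in study]
        sizes = [len(study) for study in studies_tokens]
        names = [ts.sequence_name for ts in flat]
        name_vecs = seq_name_encoder.encode_batch(names)
        seq_reps = self.vit_seq_forward(flat, name_vecs)
        stn_vecs = study_name_encoder.encode_batch(study_names)
        v = self.vit_st_forward(seq_reps, sizes, stn_vecs)
        return v, seq_reps, sizes
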