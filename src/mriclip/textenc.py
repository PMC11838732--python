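"""Text encoders: an autoregressive report language model and character-level
name encoders for sequence/study names.

The report encoder is a small decoder-only transformer pretrained with
next-word prediction on the itemized report corpus; a report is embedded as
the final-position hidden state after an end-of-text token.  Names are
case-folded and encoded character-wise by a 3-layer transformer whose output
is mean-pooled; the sequence-name encoder can be pretrained with a symmetric
contrastive objective against mean-pooled visual token embeddings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from . import nn

PAD, BOS, EOS, UNK = "<pad>", "<bos>", "<eos>", "<unk>"


def word_tokenize(text: str):
    return re.findall(r"[a-z0-9]+|[^\sa-z0-9]", text.lower())


def build_vocabulary(corpus):
    words = sorted({w for t in corpus for w in word_tokenize(t)})
    return [PAD, BOS, EOS, UNK] + words


@dataclass
class TextConfig:
    embed_dim: int = 64
    layers: int = 2
    heads: int = 2
    max_len: int = 64
    mlp_ratio: int = 4


class ReportLM(nn.Module):
    """Decoder-only autoregressive word-level transformer."""

    def __init__(self, vocabulary, config: TextConfig | None = None, seed=0):
        self.config = config or TextConfig()
        self.vocabulary = list(vocabulary)
        self.stoi = {w: i for i, w in enumerate(self.vocabulary)}
        rng = np.random.default_rng(seed)
        d = self.config.embed_dim
        self.tok_emb = nn.Embedding(rng, len(self.vocabulary), d)
        self.pos_emb = nn.Embedding(rng, self.config.max_len, d)
        self.core = nn.Transformer(rng, d, self.config.layers, self.config.heads,
                                   mlp_ratio=self.config.mlp_ratio, causal=True)
        self.head = nn.Linear(rng, d, len(self.vocabulary))

    @property
    def embedding_dim(self):
        return self.config.embed_dim

    def encode_ids(self, text: str):
        unk = self.stoi[UNK]
        ids = [self.stoi[BOS]] + [self.stoi.get(w, unk) for w in word_tokenize(text)]
        ids.append(self.stoi[EOS])
        return ids[: self.config.max_len]

    def _forward_batch(self, id_lists):
        B = len(id_lists)
        T = max(len(ids) for ids in id_lists)
        pad = self.stoi[PAD]
        mat = np.full((B, T), pad, dtype=np.int64)
        valid = np.zeros((B, T), dtype=bool)
        for i, ids in enumerate(id_lists):
            mat[i, :len(ids)] = ids
            valid[i, :len(ids)] = True
        x = self.tok_emb(mat) + self.pos_emb(np.arange(T))
        h = self.core(x, nn.padding_attn_bias(valid))
        return h, mat, valid

    def next_token_nll(self, id_lists):
        """Mean next-token negative log-likelihood over all predicted words."""
        h, mat, valid = self._forward_batch(id_lists)
        logits = self.head(h)
        logp = logits.log_softmax(axis=-1)
        tgt_valid = valid[:, 1:]
        targets = mat[:, 1:]
        onehot = np.zeros(logp.shape[:1] + targets.shape[1:] + (logp.shape[-1],),
                          dtype=np.float32)
        B, Tm1 = targets.shape
        onehot[np.arange(B)[:, None], np.arange(Tm1)[None, :], targets] = 1.0
        onehot *= tgt_valid[..., None]
        picked = (logp[:, :-1, :] * nn.Tensor(onehot)).sum()
        n = float(tgt_valid.sum())
        return -picked / n, n

    def encode_texts(self, texts):
        """Batch of report texts -> (B, embed_dim) final-position states."""
        id_lists = [self.encode_ids(t if t.strip() else EOS) for t in texts]
        h, _, valid = self._forward_batch(id_lists)
        B, T, D = h.shape
        last = valid.sum(axis=1) - 1
        picker = np.zeros((B, T), dtype=np.float32)
        picker[np.arange(B), last] = 1.0
        return (h * nn.Tensor(picker[..., None])).sum(axis=1)

    def encode_report(self, text: str) -> np.ndarray:
        with nn.no_grad():
            return self.encode_texts([text]).data[0]


def perplexity(model: ReportLM, corpus):
    """exp(mean next-token NLL) over a corpus; always >= 1."""
    with nn.no_grad():
        nll, _ = model.next_token_nll([model.encode_ids(t) for t in corpus])
    return float(np.exp(nll.data))


def pretrain_report_lm(corpus, epochs=10, seed=0, config: TextConfig | None = None,
                       batch_size=16, lr=3e-3, val_frac=0.2):
    """Pretrain the report LM with next-word prediction.

    Returns (model, validation perplexity per epoch).
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("empty corpus")
    rng = np.random.default_rng(seed)
    model = ReportLM(build_vocabulary(corpus), config, seed=seed)
    order = rng.permutation(len(corpus))
    n_val = max(1, int(len(corpus) * val_frac)) if len(corpus) > 1 else 0
    val = [corpus[i] for i in order[:n_val]]
    train = [corpus[i] for i in order[n_val:]] or val
    opt = nn.AdamW(model.parameters(), lr=lr, clip_norm=1.0)
    trace = []
    for _ in range(epochs):
        perm = rng.permutation(len(train))
        for s in range(0, len(train), batch_size):
            ids = [model.encode_ids(train[i]) for i in perm[s:s + batch_size]]
            nll, _ = model.next_token_nll(ids)
            opt.zero_grad()
            nll.backward()
            opt.step()
        trace.append(perplexity(model, val if n_val else train))
    return model, trace


# ---------------------------------------------------------------------------
# character-level name encoders

CHAR_VOCAB = "abcdefghijklmnopqrstuvwxyz0123456789_- ."
RESERVED = 0  # unknown characters map here


class CharNameEncoder(nn.Module):
    """3-layer character transformer; names are case-folded, outputs
    mean-pooled over characters and projected to `out_dim`."""

    def __init__(self, out_dim=64, width=32, layers=3, heads=2, seed=0,
                 max_len=32):
        rng = np.random.default_rng(seed)
        self.stoi = {c: i + 1 for i, c in enumerate(CHAR_VOCAB)}
        self.max_len = max_len
        self.char_emb = nn.Embedding(rng, len(CHAR_VOCAB) + 1, width)
        self.pos_emb = nn.Embedding(rng, max_len, width)
        self.core = nn.Transformer(rng, width, layers, heads)
        self.proj = nn.Linear(rng, width, out_dim)
        self.out_dim = out_dim

    def _ids(self, name: str):
        folded = name.lower()[: self.max_len]
        return [self.stoi.get(c, RESERVED) for c in folded] or [RESERVED]

    def encode_batch(self, names):
        id_lists = [self._ids(n) for n in names]
        B = len(id_lists)
        T = max(len(ids) for ids in id_lists)
        mat = np.zeros((B, T), dtype=np.int64)
        valid = np.zeros((B, T), dtype=bool)
        for i, ids in enumerate(id_lists):
            mat[i, :len(ids)] = ids
            valid[i, :len(ids)] = True
        x = self.char_emb(mat) + self.pos_emb(np.arange(T))
        h = self.core(x, nn.padding_attn_bias(valid))
        w = (valid / valid.sum(axis=1, keepdims=True)).astype(np.float32)
        pooled = (h * nn.Tensor(w[..., None])).sum(axis=1)
        return self.proj(pooled)

    def encode_name(self, name: str) -> np.ndarray:
        with nn.no_grad():
            return self.encode_batch([name]).data[0]


def _contrastive(a: nn.Tensor, b: nn.Tensor, scale=10.0):
    an = a / ((a * a).sum(axis=1, keepdims=True).sqrt() + 1e-8)
    bn = b / ((b * b).sum(axis=1, keepdims=True).sqrt() + 1e-8)
    logits = (an @ bn.transpose(1, 0)) * scale
    k = a.shape[0]
    eye = np.eye(k, dtype=np.float32)
    ce_a = -(logits.log_softmax(axis=-1) * nn.Tensor(eye)).sum() / k
    ce_b = -(logits.transpose(1, 0).log_softmax(axis=-1) * nn.Tensor(eye)).sum() / k
    return ce_a + ce_b


def pretrain_sequence_name_encoder(pairs, epochs=20, seed=0, out_dim=64,
                                   batch_size=16, lr=3e-3):
    """Contrastively align name embeddings with mean-pooled visual token
    embeddings.  `pairs` is a list of (name, (n, token_dim) array)."""
    pairs = list(pairs)
    names = [p[0] for p in pairs]
    if len({n.lower() for n in names}) < 2:
        raise ValueError("contrastive pretraining needs >= 2 distinct names")
    rng = np.random.default_rng(seed)
    enc = CharNameEncoder(out_dim=out_dim, seed=seed)
    token_dim = np.asarray(pairs[0][1]).shape[-1]
    vis_proj = nn.Linear(np.random.default_rng(seed + 1), token_dim, out_dim)
    opt = nn.AdamW(enc.parameters() + vis_proj.parameters(), lr=lr, clip_norm=1.0)
    visual = np.stack([np.asarray(v).mean(axis=0) for _, v in pairs]).astype(np.float32)
    for _ in range(epochs):
        perm = rng.permutation(len(pairs))
        for s in range(0, len(pairs), batch_size):
            idx = perm[s:s + batch_size]
            if len(idx) < 2:
                continue
            loss = _contrastive(enc.encode_batch([names[i] for i in idx]),
                                vis_proj(nn.Tensor(visual[idx])))
            opt.zero_grad()
            loss.backward()
            opt.step()
    return enc
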