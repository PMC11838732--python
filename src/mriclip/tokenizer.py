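"""Volume tokenization: patch 3D sequences into subvolumes, filter
background, and compress each subvolume with a vector-quantized autoencoder.

The codec uses non-overlapping strided 3D convolutions (kernel == stride),
so encoding is patchify + shared linear maps; quantization snaps each latent
position's channel vector to its nearest codebook entry (L2, ties to the
lowest index) with a straight-through gradient.  At the full-scale
configuration (32x32x4 patches -> 8x8x2 latents with 2 channels) the
compression ratio is 16 and the flattened latent has length 256.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from . import nn
from .phantoms import MRIVolume

AXIS_ORDERS = tuple(permutations((0, 1, 2)))


@dataclass
class TokenizerConfig:
    patch_shape: tuple = (8, 8, 4)
    latent_grid: tuple = (4, 4, 2)
    latent_channels: int = 2
    codebook_size: int = 256
    background_threshold: float = 0.05
    background_level_frac: float = 0.05   # of the volume max
    hidden_channels: int = 16
    commitment_weight: float = 0.25

    def __post_init__(self):
        for p, g in zip(self.patch_shape, self.latent_grid):
            if p % g:
                raise ValueError("patch dims must divide by the latent grid")
        if self.codebook_size < 2:
            raise ValueError("codebook_size must be >= 2")
        if not 0.0 <= self.background_threshold <= 1.0:
            raise ValueError("background_threshold must lie in [0, 1]")

    @property
    def downsample_factors(self):
        return tuple(p // g for p, g in zip(self.patch_shape, self.latent_grid))

    @property
    def latent_length(self):
        return int(np.prod(self.latent_grid)) * self.latent_channels

    @property
    def compression_ratio(self):
        return int(np.prod(self.patch_shape)) / self.latent_length


PAPER_TOKENIZER = dict(patch_shape=(32, 32, 4), latent_grid=(8, 8, 2),
                       latent_channels=2, codebook_size=8192)


@dataclass
class VolumePatch:
    voxels: np.ndarray
    grid_coord: tuple
    plane: str = "axial"
    orientation: str = "LPS"


@dataclass
class LatentToken:
    embedding: np.ndarray         # flattened, length latent_length
    code_indices: np.ndarray      # ints in [0, codebook_size)
    grid_coord: tuple = (0, 0, 0)


@dataclass
class TokenizedSequence:
    """All retained tokens of one MRI sequence, ready for the sequence ViT."""
    tokens: np.ndarray            # (n, latent_length)
    grid_coords: np.ndarray       # (n, 3) int
    plane: str
    orientation: str
    sequence_name: str
    content_frac: np.ndarray | None = None   # above-background voxel fraction

    def refiltered(self, threshold: float) -> "TokenizedSequence":
        """Re-apply the background filter at a different threshold (only
        meaningful when tokenized with threshold 0, i.e. nothing dropped)."""
        if threshold <= 0 or self.content_frac is None:
            return self
        keep = self.content_frac > threshold
        if not keep.any():
            keep[int(np.argmax(self.content_frac))] = True
        return TokenizedSequence(self.tokens[keep], self.grid_coords[keep],
                                 self.plane, self.orientation,
                                 self.sequence_name, self.content_frac[keep])


# ---------------------------------------------------------------------------
# patching

def patch_volume(volume, config: TokenizerConfig):
    """Tile a volume into zero-padded patches; ceil(dim/patch) per axis."""
    if isinstance(volume, MRIVolume):
        vox, plane, orient = volume.voxels, volume.plane, volume.orientation
    else:
        vox, plane, orient = np.asarray(volume), "axial", "LPS"
    ps = config.patch_shape
    counts = [int(np.ceil(s / p)) for s, p in zip(vox.shape, ps)]
    padded = np.zeros([c * p for c, p in zip(counts, ps)], dtype=vox.dtype)
    padded[:vox.shape[0], :vox.shape[1], :vox.shape[2]] = vox
    patches = []
    for i in range(counts[0]):
        for j in range(counts[1]):
            for k in range(counts[2]):
                sub = padded[i * ps[0]:(i + 1) * ps[0],
                             j * ps[1]:(j + 1) * ps[1],
                             k * ps[2]:(k + 1) * ps[2]]
                patches.append(VolumePatch(voxels=sub.copy(),
                                           grid_coord=(i, j, k),
                                           plane=plane, orientation=orient))
    return patches


def unpatch_volume(patches, original_shape, config: TokenizerConfig):
    """Reassemble patches (dropping padding) — inverse of patch_volume."""
    ps = config.patch_shape
    counts = [int(np.ceil(s / p)) for s, p in zip(original_shape, ps)]
    padded = np.zeros([c * p for c, p in zip(counts, ps)], dtype=np.float32)
    for patch in patches:
        i, j, k = patch.grid_coord
        padded[i * ps[0]:(i + 1) * ps[0],
               j * ps[1]:(j + 1) * ps[1],
               k * ps[2]:(k + 1) * ps[2]] = patch.voxels
    return padded[:original_shape[0], :original_shape[1], :original_shape[2]]


def intensity_filter(patches, threshold, background_level=None):
    """Keep patches whose fraction of above-background voxels exceeds
    `threshold` (threshold 0 keeps everything).  Background level defaults
    to 5% of the max intensity over the given patches.  Order preserved."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if threshold == 0.0:
        return list(patches)
    if background_level is None:
        peak = max((float(p.voxels.max()) for p in patches), default=0.0)
        background_level = 0.05 * peak
    kept = []
    for p in patches:
        frac = float(np.mean(p.voxels > background_level))
        if frac > threshold:
            kept.append(p)
    return kept


def random_axis_permutation(batch, seed=None, rng=None):
    """Apply one uniformly drawn axis order to every patch in the batch.

    All patches in the batch must share a shape (they are bucketed by shape
    upstream); the same permutation is applied to voxels and grid coords so
    the voxel multiset per patch is conserved.
    """
    if not batch:
        return []
    shape0 = batch[0].voxels.shape
    for p in batch:
        if p.voxels.shape != shape0:
            raise RuntimeError("axis permutation requires a same-shape bucket")
    rng = rng if rng is not None else np.random.default_rng(seed)
    order = AXIS_ORDERS[rng.integers(len(AXIS_ORDERS))]
    return [VolumePatch(voxels=np.ascontiguousarray(p.voxels.transpose(order)),
                        grid_coord=tuple(p.grid_coord[a] for a in order),
                        plane=p.plane, orientation=p.orientation)
            for p in batch]


# ---------------------------------------------------------------------------
# vector quantization

@dataclass
class Codebook:
    vectors: np.ndarray           # (codebook_size, latent_channels)


def quantize(z_e, codebook: Codebook):
    """Nearest codebook entry per latent position (L2, ties -> lowest index).

    z_e: (..., latent_channels) array.  Returns (z_q, code_indices).
    """
    z = np.asarray(z_e, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite latents passed to quantize")
    flat = z.reshape(-1, z.shape[-1])
    d2 = ((flat[:, None, :] - codebook.vectors[None].astype(np.float64)) ** 2).sum(-1)
    idx = d2.argmin(axis=1)
    z_q = codebook.vectors[idx].reshape(z.shape)
    return z_q.astype(np.float32), idx.reshape(z.shape[:-1])


class VQCodec(nn.Module):
    """Patch codec: strided-conv (kernel==stride) encoder, codebook, decoder."""

    def __init__(self, config: TokenizerConfig, seed=0):
        self.config = config
        rng = np.random.default_rng(seed)
        f = int(np.prod(config.downsample_factors))
        h, c = config.hidden_channels, config.latent_channels
        self.enc1 = nn.Linear(rng, f, h)
        self.enc2 = nn.Linear(rng, h, c)
        self.dec1 = nn.Linear(rng, c, h)
        self.dec2 = nn.Linear(rng, h, f)
        self.codebook_param = nn.Tensor(
            rng.uniform(-1.0, 1.0, size=(config.codebook_size, c)).astype(np.float32),
            requires_grad=True)

    @property
    def codebook(self):
        return Codebook(vectors=self.codebook_param.data.copy())

    def _factors_for(self, shape):
        """Per-axis downsampling factors for a (possibly axis-permuted) patch."""
        canon = tuple(self.config.patch_shape)
        for order in AXIS_ORDERS:
            if tuple(canon[a] for a in order) == tuple(shape):
                return tuple(self.config.downsample_factors[a] for a in order)
        raise ValueError(f"shape {shape} is not a permutation of {canon}")

    def _cells(self, x: nn.Tensor, factors):
        """(B, X, Y, Z) -> (B, n_positions, prod(factors)) cell layout."""
        B, X, Y, Z = x.shape
        fx, fy, fz = factors
        g = (X // fx, Y // fy, Z // fz)
        x = x.reshape(B, g[0], fx, g[1], fy, g[2], fz)
        x = x.transpose(0, 1, 3, 5, 2, 4, 6)
        return x.reshape(B, g[0] * g[1] * g[2], fx * fy * fz), g

    def encode_t(self, x: nn.Tensor, factors=None):
        factors = factors or self._factors_for(x.shape[1:])
        cells, grid = self._cells(x, factors)
        z = self.enc2(self.enc1(cells).relu())
        return z, grid, factors

    def decode_t(self, z_q: nn.Tensor, grid, factors):
        B = z_q.shape[0]
        fx, fy, fz = factors
        cells = self.dec2(self.dec1(z_q).relu())
        x = cells.reshape(B, grid[0], grid[1], grid[2], fx, fy, fz)
        x = x.transpose(0, 1, 4, 2, 5, 3, 6)
        return x.reshape(B, grid[0] * fx, grid[1] * fy, grid[2] * fz)

    # ---- inference API --------------------------------------------------
    def encode(self, patch) -> LatentToken:
        vox = patch.voxels if isinstance(patch, VolumePatch) else np.asarray(patch)
        with nn.no_grad():
            z, _, _ = self.encode_t(nn.Tensor(vox[None]))
        z_q, idx = quantize(z.data[0], self.codebook)
        return LatentToken(embedding=z_q.reshape(-1).astype(np.float32),
                           code_indices=idx.reshape(-1),
                           grid_coord=getattr(patch, "grid_coord", (0, 0, 0)))

    def encode_batch(self, voxel_stack: np.ndarray):
        """(B, X, Y, Z) -> (B, latent_length) quantized embeddings + codes."""
        with nn.no_grad():
            z, _, _ = self.encode_t(nn.Tensor(voxel_stack))
        z_q, idx = quantize(z.data, self.codebook)
        B = voxel_stack.shape[0]
        return z_q.reshape(B, -1), idx.reshape(B, -1)

    def decode(self, z_q: np.ndarray):
        """Flat (latent_length,) or (B, latent_length) -> patch voxels."""
        z = np.asarray(z_q, dtype=np.float32)
        single = z.ndim == 1
        if single:
            z = z[None]
        grid = self.config.latent_grid
        z = z.reshape(z.shape[0], int(np.prod(grid)), self.config.latent_channels)
        with nn.no_grad():
            x = self.decode_t(nn.Tensor(z), grid, self.config.downsample_factors)
        out = x.data
        return out[0] if single else out

    # ---- training forward ----------------------------------------------
    def loss(self, voxel_stack: np.ndarray):
        """L1 reconstruction + VQ codebook/commitment losses (straight-through)."""
        x = nn.Tensor(voxel_stack)
        z_e, grid, factors = self.encode_t(x)
        z_q_np, idx = quantize(z_e.data, self.codebook)
        e = self.codebook_param.take_rows(idx)           # gradient to codebook
        # straight-through: decoder sees z_e + stopgrad(z_q - z_e)
        z_st = z_e + nn.Tensor(z_q_np - z_e.data)
        recon = self.decode_t(z_st, grid, factors)
        l1 = (recon - x).abs().mean()
        codebook_loss = ((e - z_e.detach()) ** 2).mean()
        commit = ((z_e - nn.Tensor(z_q_np)) ** 2).mean()
        total = l1 + codebook_loss + self.config.commitment_weight * commit
        return total, float(l1.data)


def train_vqvae(patches, config: TokenizerConfig, epochs=20, seed=0,
                batch_size=64, lr=3e-3, val_frac=0.2, permute_augment=True):
    """Train the VQ codec on a list of VolumePatch; returns (codec, trace).

    trace holds per-epoch train/validation L1 reconstruction losses; the
    random axis-permutation augmentation is applied per batch when enabled.
    """
    if not patches:
        raise ValueError("empty patch dataset")
    rng = np.random.default_rng(seed)
    codec = VQCodec(config, seed=seed)
    opt = nn.AdamW(codec.parameters(), lr=lr, clip_norm=1.0)
    stack = np.stack([p.voxels for p in patches]).astype(np.float32)
    n_val = max(1, int(len(stack) * val_frac)) if len(stack) > 1 else 0
    order = rng.permutation(len(stack))
    val, train = stack[order[:n_val]], stack[order[n_val:]]
    if len(train) == 0:
        train = val
    trace = {"train_l1": [], "val_l1": []}
    for _ in range(epochs):
        perm = rng.permutation(len(train))
        epoch_l1 = []
        for s in range(0, len(train), batch_size):
            xb = train[perm[s:s + batch_size]]
            if permute_augment:
                axes = AXIS_ORDERS[rng.integers(len(AXIS_ORDERS))]
                xb = np.ascontiguousarray(xb.transpose((0,) + tuple(a + 1 for a in axes)))
            total, l1 = codec.loss(xb)
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_l1.append(l1)
        trace["train_l1"].append(float(np.mean(epoch_l1)))
        if n_val:
            with nn.no_grad():
                z, grid, factors = codec.encode_t(nn.Tensor(val))
                z_q, _ = quantize(z.data, codec.codebook)
                recon = codec.decode_t(nn.Tensor(z_q), grid, factors)
                trace["val_l1"].append(float(np.mean(np.abs(recon.data - val))))
    return codec, trace


# ---------------------------------------------------------------------------
# sequence-level tokenization

def tokenize_volume(volume: MRIVolume, codec: VQCodec,
                    threshold=None) -> TokenizedSequence:
    """Patch, background-filter, and encode one MRI sequence."""
    config = codec.config
    thr = config.background_threshold if threshold is None else threshold
    patches = patch_volume(volume, config)
    level = config.background_level_frac * float(volume.voxels.max())
    kept = intensity_filter(patches, thr, background_level=level)
    if not kept:
        kept = patches  # callers decide how to treat fully-background input
    stack = np.stack([p.voxels for p in kept]).astype(np.float32)
    emb, _ = codec.encode_batch(stack)
    coords = np.array([p.grid_coord for p in kept], dtype=np.int64)
    frac = np.array([float(np.mean(p.voxels > level)) for p in kept])
    return TokenizedSequence(tokens=emb, grid_coords=coords,
                             plane=volume.plane, orientation=volume.orientation,
                             sequence_name=volume.sequence_name,
                             content_frac=frac)


def tokenize_study(study, codec: VQCodec, threshold=None):
    return [tokenize_volume(v, codec, threshold) for v in study.sequences]


def mask_to_token_coords(mask: np.ndarray, config: TokenizerConfig):
    """Token-grid cells intersecting a voxel mask (for lesion overlap)."""
    ps = config.patch_shape
    coords = np.argwhere(mask)
    cells = {tuple(c // p for c, p in zip(row, ps)) for row in coords}
    return cells
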