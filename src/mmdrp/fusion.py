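"""Fusion of per-modality latents into a single vector.

Low-rank Multimodal Fusion (LMF) forces latents to interact multiplicatively:
conceptually, the outer product of all (1-augmented) modality latents is
contracted with a full fusion weight tensor; factoring that tensor at rank r
makes the computation linear in the number of modalities. Each modality m
holds r factor matrices W_m^(i) of shape (d_m + 1, d_out); the fused vector is

    fused = sum_i  prod_m  ([h_m, 1] @ W_m^(i))        (elementwise product)

The constant-1 augmentation means additive (concat-then-linear) fusion is a
special case, so LMF strictly generalises the concatenation baseline.
Concatenation and elementwise-summation fusers are provided as ablation
baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat

__all__ = ["LMFConfig", "LMFFusion", "lmf_fuse", "concat_fuse", "sum_fuse"]


@dataclass
class LMFConfig:
    rank: int = 4
    output_dim: int = 32
    modality_dims: list[int] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")


def _as_batch(latent) -> Tensor:
    t = latent if isinstance(latent, Tensor) else Tensor(latent)
    if t.ndim == 1:
        t = t.reshape(1, -1)
    return t


def _augment(latent: Tensor) -> Tensor:
    ones = Tensor(np.ones((latent.shape[0], 1)))
    return concat([latent, ones], axis=1)


def lmf_fuse(latents, factors, config: LMFConfig | None = None) -> Tensor:
    """Fuse one latent per modality through rank-decomposed factors.

    ``latents``: list of (n, d_m) arrays/tensors (or 1-D vectors);
    ``factors``: per modality, a list of ``rank`` tensors (d_m + 1, d_out).
    """
    if len(latents) == 0:
        raise ValueError("empty modality list")
    if len(latents) != len(factors):
        raise ValueError(
            f"{len(latents)} latents but factors for {len(factors)} modalities")
    batches = [_as_batch(z) for z in latents]
    rank = len(factors[0])
    if any(len(f) != rank for f in factors):
        raise ValueError("all modalities must carry the same number of rank factors")
    for m, (z, fs) in enumerate(zip(batches, factors)):
        for w in fs:
            if w.shape[0] != z.shape[1] + 1:
                raise ValueError(
                    f"modality {m}: factor expects dim {w.shape[0] - 1}, "
                    f"latent has dim {z.shape[1]}")
    augmented = [_augment(z) for z in batches]
    fused = None
    for i in range(rank):
        term = None
        for z, fs in zip(augmented, factors):
            proj = z @ fs[i]
            term = proj if term is None else term * proj
        fused = term if fused is None else fused + term
    return fused


class LMFFusion:
    """Trainable LMF module: owns the factor tensors."""

    def __init__(self, modality_dims: list[int], rank: int = 4,
                 output_dim: int = 32, seed: int = 0):
        if not modality_dims:
            raise ValueError("need at least one modality")
        self.config = LMFConfig(rank, output_dim, list(modality_dims), seed)
        rng = np.random.default_rng(seed)
        # additive warm start: the bias row (constant-1 augmentation) starts at
        # one and the weight rows small, so each rank term begins as
        # prod_m(1 + eps_m) ~ 1 + sum_m eps_m — a well-conditioned additive
        # fuser — and multiplicative interactions grow during training
        self.factors = []
        for d in modality_dims:
            per_rank = []
            for _ in range(rank):
                w = rng.normal(0.0, 0.3 / np.sqrt(d + 1), (d + 1, output_dim))
                w[d, :] = 1.0 + rng.normal(0.0, 0.01, output_dim)
                per_rank.append(Tensor.param(w))
            self.factors.append(per_rank)

    def params(self) -> list[Tensor]:
        return [w for fs in self.factors for w in fs]

    def __call__(self, latents) -> Tensor:
        return lmf_fuse(latents, self.factors, self.config)


def concat_fuse(latents) -> Tensor:
    """Order-preserving concatenation of modality latents."""
    if len(latents) == 0:
        raise ValueError("empty modality list")
    return concat([_as_batch(z) for z in latents], axis=1)


def sum_fuse(latents) -> Tensor:
    """Elementwise sum; all modalities must share one dimension."""
    if len(latents) == 0:
        raise ValueError("empty modality list")
    batches = [_as_batch(z) for z in latents]
    dims = {b.shape[1] for b in batches}
    if len(dims) > 1:
        raise ValueError(f"sum fusion needs equal dims, got {sorted(dims)}")
    out = batches[0]
    for b in batches[1:]:
        out = out + b
    return out
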