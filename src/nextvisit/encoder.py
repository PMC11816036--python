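"""BERT-style contextual encoder over coded visits.

The input representation is the sum of a token embedding and a visit
embedding (indexed by the 1-based source-visit ordinal; no separate
positional embedding by default).  A stack of post-layer-norm transformer
blocks with padding-masked self-attention produces the contextualized
sequence; the pooled patient representation is the *masked sum* of the
contextual vectors over sequence positions — a sum, not a mean, so PAD rows
must be excluded rather than merely down-weighted.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .codec import Vocabulary
from .config import EncoderConfig

__all__ = [
    "TransformerEncoder",
    "ContextualizedSequence",
    "pool_sum",
    "save_checkpoint",
    "load_checkpoint",
]

NEG_INF = -1e9
CHECKPOINT_VERSION = 1


def _checkpoint_path(path: str | Path) -> Path:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.parent / (path.name + ".npz")
    return path


@dataclass
class ContextualizedSequence:
    """Per-position contextual vectors [batch, max_len, dim] plus the mask."""

    hidden: nn.Tensor
    attention_mask: np.ndarray


class MultiHeadSelfAttention(nn.Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.q = nn.Linear(dim, dim, rng)
        self.k = nn.Linear(dim, dim, rng)
        self.v = nn.Linear(dim, dim, rng)
        self.out = nn.Linear(dim, dim, rng)

    def __call__(self, x: nn.Tensor, attention_mask: np.ndarray) -> nn.Tensor:
        B, L, D = x.shape
        H, hd = self.n_heads, self.head_dim

        def split(t: nn.Tensor) -> nn.Tensor:
            return t.reshape(B, L, H, hd).transpose(0, 2, 1, 3)  # [B,H,L,hd]

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        # PAD keys receive -inf logits so they get zero attention weight
        bias = np.where(attention_mask[:, None, None, :] == 1, 0.0, NEG_INF)
        attn = (scores + nn.Tensor(bias)).softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.out(ctx)


class TransformerBlock(nn.Module):
    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        d = config.embedding_dim
        self.attn = MultiHeadSelfAttention(d, config.n_heads, rng)
        self.ln1 = nn.LayerNorm(d)
        self.ff1 = nn.Linear(d, config.feedforward_dim, rng)
        self.ff2 = nn.Linear(config.feedforward_dim, d, rng)
        self.ln2 = nn.LayerNorm(d)
        self.drop = nn.Dropout(config.dropout, rng)

    def __call__(self, x: nn.Tensor, attention_mask: np.ndarray) -> nn.Tensor:
        x = self.ln1(x + self.drop(self.attn(x, attention_mask)))
        x = self.ln2(x + self.drop(self.ff2(self.ff1(x).gelu())))
        return x


class TransformerEncoder(nn.Module):
    """Token+visit embedding followed by masked transformer blocks."""

    def __init__(self, config: EncoderConfig, vocab_size: int):
        self.config = config
        self.vocab_size = vocab_size
        rng = np.random.default_rng(config.seed)
        self.token_embedding = nn.Embedding(vocab_size, config.embedding_dim, rng)
        self.visit_embedding = nn.Embedding(config.max_visits, config.embedding_dim, rng)
        self.blocks = [TransformerBlock(config, rng) for _ in range(config.n_layers)]
        self.drop = nn.Dropout(config.dropout, rng)

    def set_training(self, training: bool) -> None:
        self.drop.training = training
        for block in self.blocks:
            block.drop.training = training

    def __call__(
        self,
        token_ids: np.ndarray,
        visit_ids: np.ndarray,
        attention_mask: np.ndarray,
    ) -> nn.Tensor:
        token_ids = np.atleast_2d(token_ids)
        visit_ids = np.atleast_2d(visit_ids)
        attention_mask = np.atleast_2d(attention_mask)
        if token_ids.shape != visit_ids.shape or token_ids.shape != attention_mask.shape:
            raise ValueError("token_ids, visit_ids and attention_mask must share a shape")
        if visit_ids.max() >= self.config.max_visits:
            raise ValueError(
                f"visit ordinal {visit_ids.max()} exceeds max_visits={self.config.max_visits}"
            )
        x = self.token_embedding(token_ids) + self.visit_embedding(visit_ids)
        x = self.drop(x)
        for block in self.blocks:
            x = block(x, attention_mask)
        return x

    def encode(self, batch: dict[str, np.ndarray]) -> ContextualizedSequence:
        hidden = self(batch["token_ids"], batch["visit_ids"], batch["attention_mask"])
        return ContextualizedSequence(hidden=hidden, attention_mask=batch["attention_mask"])


def pool_sum(contextual: ContextualizedSequence) -> nn.Tensor:
    """Masked sum over sequence positions -> patient context vector [B, dim]."""
    mask = np.atleast_2d(contextual.attention_mask)
    if (mask.sum(axis=1) == 0).any():
        raise ValueError("cannot pool an all-PAD sequence")
    return (contextual.hidden * nn.Tensor(mask[:, :, None].astype(float))).sum(axis=1)


# -- checkpointing -----------------------------------------------------------


def save_checkpoint(
    path: str | Path,
    encoder: TransformerEncoder,
    vocab: Vocabulary,
    extra: dict | None = None,
) -> None:
    """Single-archive checkpoint: weights + encoder config + vocabulary."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "encoder_config": asdict(encoder.config),
        "vocab": {
            "code_to_id": vocab.code_to_id,
            "target_codes": list(vocab.target_codes),
        },
        "extra": extra or {},
    }
    state = encoder.state_dict()
    np.savez(
        _checkpoint_path(path),
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **state,
    )


def load_checkpoint(path: str | Path) -> tuple[TransformerEncoder, Vocabulary, dict]:
    with np.load(_checkpoint_path(path)) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    vocab = Vocabulary(
        code_to_id={k: int(v) for k, v in meta["vocab"]["code_to_id"].items()},
        target_codes=tuple(meta["vocab"]["target_codes"]),
    )
    encoder = TransformerEncoder(EncoderConfig(**meta["encoder_config"]), vocab.size)
    encoder.load_state_dict(state)
    return encoder, vocab, meta["extra"]
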