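"""Masked-code pretraining with a weight-tied output projection.

The corruption scheme selects a fraction of real code positions for
prediction; of those, 80% are replaced by [MASK], 10% by a random ordinary
code and 10% are left unchanged.  The output projection is the token
embedding table itself (weight tying, no bias by default), so after
pretraining the embedding row of a code doubles as its scorer — the
property the token-prediction and next-visit-mask heads rely on: restricting
the full-vocabulary MLM scores to the eight target ids *is* the mask head.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .cohort import PatientRecord
from .codec import (
    TokenizedPatient,
    Vocabulary,
    batch_tokenized,
    build_vocabulary,
    encode_cohort,
)
from .config import CorruptionConfig, EncoderConfig
from .encoder import TransformerEncoder, save_checkpoint
from .errors import ConfigurationError

__all__ = [
    "IGNORE_INDEX",
    "corrupt_sequence",
    "mlm_logits",
    "masked_cross_entropy",
    "masked_cross_entropy_from_hidden",
    "MaskedLMModel",
    "MaskedLMResults",
    "pretrain",
]

#: Sentinel in prediction targets at positions that do not contribute to loss.
IGNORE_INDEX = -100


def corrupt_sequence(
    token_ids: np.ndarray,
    attention_mask: np.ndarray,
    vocab: Vocabulary,
    config: CorruptionConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the 80/10/10 corruption to a batch of sequences.

    Returns ``(corrupted_ids, prediction_targets)`` where targets hold the
    original id at selected positions and :data:`IGNORE_INDEX` elsewhere.
    PAD and special positions are never selected; random replacements draw
    from ordinary code ids only.
    """
    if vocab.code_ids.size == 0:
        raise ConfigurationError("vocabulary has no non-special code ids")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    token_ids = np.atleast_2d(token_ids)
    attention_mask = np.atleast_2d(attention_mask)

    eligible = (attention_mask == 1) & (token_ids >= 2)
    selected = eligible & (rng.random(token_ids.shape) < config.select_rate)

    targets = np.full_like(token_ids, IGNORE_INDEX)
    targets[selected] = token_ids[selected]

    corrupted = token_ids.copy()
    u = rng.random(token_ids.shape)
    to_mask = selected & (u < config.p_mask)
    to_random = selected & (u >= config.p_mask) & (u < config.p_mask + config.p_random)
    corrupted[to_mask] = 1  # MASK id
    n_random = int(to_random.sum())
    if n_random:
        corrupted[to_random] = rng.choice(vocab.code_ids, size=n_random)
    return corrupted, targets


def mlm_logits(
    contextual: nn.Tensor,
    token_embedding_table: nn.Tensor,
    bias: nn.Tensor | None = None,
) -> nn.Tensor:
    """Full-vocabulary scores: dot product of each contextual vector with
    every token-embedding row (plus optional per-token bias)."""
    if contextual.shape[-1] != token_embedding_table.shape[-1]:
        raise ValueError(
            f"embedding_dim mismatch: {contextual.shape[-1]} vs "
            f"{token_embedding_table.shape[-1]}"
        )
    logits = contextual @ token_embedding_table.transpose(1, 0)
    if bias is not None:
        logits = logits + bias
    return logits


def masked_cross_entropy(logits: nn.Tensor, targets: np.ndarray) -> nn.Tensor:
    """Mean cross-entropy over positions whose target is not IGNORE_INDEX."""
    sel = np.argwhere(targets != IGNORE_INDEX)
    if sel.size == 0:
        raise ValueError("no selected positions contribute to the loss")
    bi, li = sel[:, 0], sel[:, 1]
    ti = targets[bi, li]
    z = logits
    m = nn.Tensor(z.data.max(axis=-1, keepdims=True))
    lse = ((z - m).exp().sum(axis=-1, keepdims=True)).log() + m
    picked = z[(bi, li, ti)]
    norm = lse[(bi, li, np.zeros_like(bi))]
    return (norm - picked).mean()


def masked_cross_entropy_from_hidden(
    hidden: nn.Tensor, token_embedding_table: nn.Tensor, targets: np.ndarray
) -> nn.Tensor:
    """Same loss as :func:`masked_cross_entropy` on :func:`mlm_logits`, but
    scoring only the selected positions (the others never enter the loss, so
    their full-vocabulary logits need not be materialized)."""
    sel = np.argwhere(targets != IGNORE_INDEX)
    if sel.size == 0:
        raise ValueError("no selected positions contribute to the loss")
    bi, li = sel[:, 0], sel[:, 1]
    rows = hidden[(bi, li)]  # [n_selected, dim]
    logits = mlm_logits(rows, token_embedding_table)
    z = logits
    m = nn.Tensor(z.data.max(axis=-1, keepdims=True))
    lse = ((z - m).exp().sum(axis=-1, keepdims=True)).log() + m
    n = len(bi)
    picked = z[(np.arange(n), targets[bi, li])]
    return (lse.reshape(n) - picked).mean()


@dataclass
class MaskedLMResults:
    """Fitted pretraining state: encoder weights, vocabulary and loss history."""

    encoder: TransformerEncoder
    vocab: Vocabulary
    train_losses: list[float]
    val_losses: list[float]
    initial_val_loss: float
    corruption: CorruptionConfig
    seed: int

    @property
    def final_val_loss(self) -> float:
        return self.val_losses[-1]

    def save(self, path: str | Path) -> None:
        save_checkpoint(
            path,
            self.encoder,
            self.vocab,
            extra={
                "kind": "mlm_pretrain",
                "seed": self.seed,
                "initial_val_loss": self.initial_val_loss,
                "val_losses": self.val_losses,
            },
        )

    def summary(self) -> str:
        lines = [
            "Masked-code pretraining",
            f"  vocabulary size      : {self.vocab.size}",
            f"  encoder parameters   : {self.encoder.n_parameters()}",
            f"  epochs run           : {len(self.train_losses)}",
            f"  held-out loss (init) : {self.initial_val_loss:.4f}",
            f"  held-out loss (final): {self.final_val_loss:.4f}",
        ]
        return "\n".join(lines)


class MaskedLMModel:
    """Masked-code pretraining model over a synthetic cohort.

    The pretraining corpus encodes *full* trajectories (onset visits
    included, no next-visit mask): the corpus plays the role of the large
    uncurated EHR pool a foundation model is pretrained on, so disease codes
    appear in context and their embedding rows get trained.
    """

    def __init__(
        self,
        cohort: list[PatientRecord],
        encoder_config: EncoderConfig | None = None,
        corruption: CorruptionConfig | None = None,
        vocab: Vocabulary | None = None,
        max_len: int = 64,
    ):
        self.encoder_config = encoder_config or EncoderConfig()
        self.corruption = corruption or CorruptionConfig()
        self.vocab = vocab or build_vocabulary(cohort)
        self.max_len = max_len
        self.tokenized: list[TokenizedPatient] = encode_cohort(
            cohort, self.vocab, max_len=max_len, add_next_visit_mask=False, censor=False
        )

    def fit(
        self,
        epochs: int = 5,
        batch_size: int = 100,
        learning_rate: float = 1e-3,
        val_fraction: float = 0.1,
        seed: int = 0,
        verbose: bool = False,
    ) -> MaskedLMResults:
        """Run the pretraining loop; deterministic given ``seed``."""
        rng = np.random.default_rng(seed)
        encoder = TransformerEncoder(self.encoder_config, self.vocab.size)
        order = rng.permutation(len(self.tokenized))
        n_val = max(1, int(len(order) * val_fraction))
        val_items = [self.tokenized[i] for i in order[:n_val]]
        train_items = [self.tokenized[i] for i in order[n_val:]]
        if not train_items:
            raise ConfigurationError("cohort too small for the requested val_fraction")
        val_batch = batch_tokenized(val_items)
        # fixed corruption of the held-out split so its loss is comparable across epochs
        val_rng = np.random.default_rng(seed + 1)
        val_corrupt, val_targets = corrupt_sequence(
            val_batch["token_ids"], val_batch["attention_mask"], self.vocab,
            self.corruption, val_rng,
        )

        optimizer = nn.Adam(encoder.parameters(), lr=learning_rate)
        initial_val = self._evaluate(encoder, val_batch, val_corrupt, val_targets)
        train_losses: list[float] = []
        val_losses: list[float] = []
        corrupt_rng = np.random.default_rng(seed + 2)

        for epoch in range(epochs):
            encoder.set_training(True)
            perm = rng.permutation(len(train_items))
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(perm), batch_size):
                items = [train_items[i] for i in perm[start : start + batch_size]]
                batch = batch_tokenized(items)
                corrupted, targets = corrupt_sequence(
                    batch["token_ids"], batch["attention_mask"], self.vocab,
                    self.corruption, corrupt_rng,
                )
                if (targets == IGNORE_INDEX).all():
                    continue
                hidden = encoder(corrupted, batch["visit_ids"], batch["attention_mask"])
                loss = masked_cross_entropy_from_hidden(
                    hidden, encoder.token_embedding.weight, targets
                )
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"MLM loss diverged at epoch {epoch}: {loss.data}"
                    )
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                epoch_loss += float(loss.data)
                n_batches += 1
            encoder.set_training(False)
            train_losses.append(epoch_loss / max(n_batches, 1))
            val_losses.append(self._evaluate(encoder, val_batch, val_corrupt, val_targets))
            if verbose:  # pragma: no cover - logging only
                print(
                    f"epoch {epoch + 1}/{epochs}: train {train_losses[-1]:.4f} "
                    f"val {val_losses[-1]:.4f}"
                )

        return MaskedLMResults(
            encoder=encoder,
            vocab=self.vocab,
            train_losses=train_losses,
            val_losses=val_losses,
            initial_val_loss=initial_val,
            corruption=self.corruption,
            seed=seed,
        )

    @staticmethod
    def _evaluate(encoder, batch, corrupted, targets) -> float:
        encoder.set_training(False)
        with nn.no_grad():
            hidden = encoder(corrupted, batch["visit_ids"], batch["attention_mask"])
            loss = masked_cross_entropy_from_hidden(
                hidden, encoder.token_embedding.weight, targets
            )
            return float(loss.data)


def pretrain(
    cohort: list[PatientRecord],
    encoder_config: EncoderConfig | None = None,
    corruption: CorruptionConfig | None = None,
    out: str | Path | None = None,
    **fit_kwargs,
) -> MaskedLMResults:
    """Convenience wrapper: build the model, fit, optionally save a checkpoint."""
    results = MaskedLMModel(cohort, encoder_config, corruption).fit(**fit_kwargs)
    if out is not None:
        results.save(out)
    return results
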