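"""Interchangeable prediction heads over the encoder.

Three heads turn the encoder output into an onset score:

* **bc** — binary classification: a linear layer on the pooled patient
  context vector, logistic output.
* **sum** — token prediction: dot products of the pooled context vector with
  the label tensor (the 8 target-code embedding rows), elementwise logistic,
  patient score = max of the 8 probabilities.
* **mask** — next-visit masked-token prediction: same dot products but
  against the contextual vector at the appended [MASK] position, i.e. the
  pretraining MLM scores restricted to the 8 target ids.

Per-token probabilities are independent sigmoids (multi-label: "does any
target code have high probability", not "which one"), and no bias is added
to sum/mask logits so the mask head is exactly the restriction of the
full-vocabulary MLM scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .cohort import PatientRecord
from .codec import Vocabulary, batch_tokenized, encode_cohort
from .config import EncoderConfig, FinetuneConfig
from .encoder import ContextualizedSequence, TransformerEncoder, load_checkpoint, pool_sum
from .errors import ConfigurationError
from .mlm import MaskedLMResults

__all__ = [
    "HEAD_KINDS",
    "HeadOutput",
    "label_tensor",
    "bc_head",
    "sum_head",
    "mask_head",
    "finetune_loss",
    "OnsetModel",
    "OnsetResults",
]

HEAD_KINDS = ("bc", "sum", "mask")
_EPS = 1e-12


@dataclass
class HeadOutput:
    """Per-target probabilities (absent for bc) and the final patient score."""

    patient_score: np.ndarray
    per_token_probs: np.ndarray | None = None


def label_tensor(encoder: TransformerEncoder, vocab: Vocabulary, frozen: bool = False) -> nn.Tensor:
    """The [n_targets, dim] matrix of target-code embedding rows.

    Differentiable view into the token embedding table unless ``frozen``, so
    fine-tuning updates flow back into the tied table.
    """
    rows = nn.embedding(encoder.token_embedding.weight, vocab.target_ids)
    return rows.detach() if frozen else rows


def _sigmoid_np(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bc_head(context: nn.Tensor, weight: nn.Tensor, bias: nn.Tensor) -> nn.Tensor:
    """Binary-classification logits: w . context + b, shape [B]."""
    if context.shape[-1] != weight.shape[0]:
        raise ValueError("context / weight dimension mismatch")
    return (context @ weight).reshape(context.shape[0]) + bias


def sum_head(context: nn.Tensor, labels: nn.Tensor) -> nn.Tensor:
    """Token-prediction logits: labels . context per target, shape [B, 8]."""
    if labels.ndim != 2 or context.shape[-1] != labels.shape[1]:
        raise ValueError(
            f"label tensor must be [n_targets, dim={context.shape[-1]}], got {labels.shape}"
        )
    return context @ labels.transpose(1, 0)


def mask_head(
    contextual: ContextualizedSequence,
    mask_positions: np.ndarray,
    labels: nn.Tensor,
    token_ids: np.ndarray | None = None,
) -> nn.Tensor:
    """Masked-token logits at the appended next-visit position, shape [B, 8].

    Equals the restriction of the full-vocabulary MLM logits at that
    position to the target ids (zero-bias configuration).
    """
    mask_positions = np.atleast_1d(np.asarray(mask_positions))
    if (mask_positions < 0).any():
        raise ValueError("mask_position unset for at least one patient")
    if token_ids is not None:
        at_mask = np.atleast_2d(token_ids)[np.arange(len(mask_positions)), mask_positions]
        if (at_mask != 1).any():
            raise ValueError("token at mask_position is not [MASK]")
    B = contextual.hidden.shape[0]
    rows = contextual.hidden[(np.arange(B), mask_positions)]  # [B, dim]
    return sum_head(rows, labels)


def head_output(logits: nn.Tensor, head_kind: str) -> HeadOutput:
    """Turn head logits into probabilities and the max-probability reduction."""
    if head_kind == "bc":
        return HeadOutput(patient_score=_sigmoid_np(logits.data))
    probs = _sigmoid_np(logits.data)
    return HeadOutput(patient_score=probs.max(axis=-1), per_token_probs=probs)


def finetune_loss(
    output: HeadOutput,
    label: np.ndarray | int,
    target_multi_hot: np.ndarray | None,
    head_kind: str,
    policy: str = "per_token",
) -> float:
    """Reference fine-tuning objective on probabilities (clipped BCE).

    bc: binary cross-entropy of the patient score against the label.
    sum/mask, policy "per_token": mean BCE of the 8 per-token probabilities
    against the multi-hot onset target (all-zero for controls);
    policy "max": BCE of the max-probability patient score against the label.
    """
    label = np.atleast_1d(np.asarray(label, dtype=float))
    if head_kind not in HEAD_KINDS:
        raise ConfigurationError(f"unknown head kind {head_kind!r}")
    if head_kind == "bc" or policy == "max":
        p = np.clip(np.atleast_1d(output.patient_score), _EPS, 1 - _EPS)
        return float(-(label * np.log(p) + (1 - label) * np.log(1 - p)).mean())
    if target_multi_hot is None:
        raise ValueError("per-token loss requires target_multi_hot")
    y = np.atleast_2d(np.asarray(target_multi_hot, dtype=float))
    if (y.max(axis=-1) != label).any():
        raise ValueError("target_multi_hot inconsistent with label")
    p = np.clip(np.atleast_2d(output.per_token_probs), _EPS, 1 - _EPS)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def _softplus(t: nn.Tensor) -> nn.Tensor:
    a = t.relu()
    return a + ((t - a - a).exp() + 1.0).log()


def _bce_with_logits(logits: nn.Tensor, targets: np.ndarray) -> nn.Tensor:
    """Numerically stable mean BCE on logits (training-path objective)."""
    y = nn.Tensor(np.asarray(targets, dtype=float))
    return (_softplus(logits) - y * logits).mean()


@dataclass
class OnsetResults:
    """Fitted onset-prediction model: frozen weights plus fit diagnostics."""

    model: "OnsetModel"
    head_kind: str
    epochs_run: int
    best_epoch: int
    train_losses: list[float]
    val_aurocs: list[float]
    seed: int

    def predict_proba(self, records: list[PatientRecord]) -> np.ndarray:
        return self.model._predict(records)

    def predict_output(self, records: list[PatientRecord]) -> HeadOutput:
        return self.model._predict_output(records)

    def auroc(self, records: list[PatientRecord]) -> float:
        from .experiment import auroc as _auroc

        labels = np.array([r.label for r in records])
        return _auroc(self.predict_proba(records), labels)

    def summary(self) -> str:
        lines = [
            f"Onset prediction head: {self.head_kind}",
            f"  encoder parameters : {self.model.encoder.n_parameters()}",
            f"  epochs run         : {self.epochs_run} (best epoch {self.best_epoch + 1})",
            f"  final train loss   : {self.train_losses[-1]:.4f}",
        ]
        if self.val_aurocs:
            lines.append(f"  best val AUROC     : {max(self.val_aurocs):.4f}")
        return "\n".join(lines)


class OnsetModel:
    """Disease-onset prediction model: encoder + one of the three heads.

    Initialized either from a pretrained checkpoint (:class:`MaskedLMResults`
    or a checkpoint path) or from random weights.  ``fit`` fine-tunes the
    whole stack end to end with Adam and early stopping on validation AUROC.
    """

    def __init__(
        self,
        train_records: list[PatientRecord],
        head: str = "bc",
        pretrained: "MaskedLMResults | str | Path | None" = None,
        vocab: Vocabulary | None = None,
        encoder_config: EncoderConfig | None = None,
        finetune: FinetuneConfig | None = None,
        max_len: int = 64,
    ):
        if head not in HEAD_KINDS:
            raise ConfigurationError(f"head must be one of {HEAD_KINDS}, got {head!r}")
        self.head_kind = head
        self.finetune_config = finetune or FinetuneConfig()
        self.max_len = max_len

        if pretrained is not None:
            if isinstance(pretrained, (str, Path)):
                self.encoder, self.vocab, _ = load_checkpoint(pretrained)
            else:
                # fresh encoder seeded from a copy of the pretrained weights, so
                # fine-tuning never mutates the shared pretraining results
                self.vocab = pretrained.vocab
                self.encoder = TransformerEncoder(
                    pretrained.encoder.config, self.vocab.size
                )
                self.encoder.load_state_dict(pretrained.encoder.state_dict())
        else:
            if vocab is None:
                raise ConfigurationError("vocab is required without a pretrained encoder")
            self.vocab = vocab
            self.encoder = TransformerEncoder(
                encoder_config or EncoderConfig(), vocab.size
            )
        self.train_records = train_records
        self._needs_mask = head == "mask"
        self.train_tokens = encode_cohort(
            train_records, self.vocab, max_len=max_len,
            add_next_visit_mask=self._needs_mask, censor=True,
        )
        d = self.encoder.config.embedding_dim
        rng = np.random.default_rng(self.encoder.config.seed + 17)
        self.bc_weight = nn.Parameter(rng.normal(0.0, 0.02, size=(d, 1)))
        self.bc_bias = nn.Parameter(np.zeros(1))

    # -- forward -----------------------------------------------------------
    def _logits(self, batch: dict[str, np.ndarray]) -> nn.Tensor:
        contextual = self.encoder.encode(batch)
        if self.head_kind == "mask":
            labels = label_tensor(
                self.encoder, self.vocab, frozen=self.finetune_config.freeze_label_tensor
            )
            return mask_head(
                contextual, batch["mask_positions"], labels, token_ids=batch["token_ids"]
            )
        # bc and sum pool the mask-free encoding
        context = pool_sum(contextual)
        if self.head_kind == "bc":
            return bc_head(context, self.bc_weight, self.bc_bias)
        labels = label_tensor(
            self.encoder, self.vocab, frozen=self.finetune_config.freeze_label_tensor
        )
        return sum_head(context, labels)

    def _loss(self, batch: dict[str, np.ndarray]) -> nn.Tensor:
        logits = self._logits(batch)
        if self.head_kind == "bc" or self.finetune_config.loss_policy == "max":
            if self.head_kind != "bc":
                # max over targets on the logit scale = logit of the max probability
                B = logits.shape[0]
                arg = logits.data.argmax(axis=-1)
                logits = logits[(np.arange(B), arg)]
            return _bce_with_logits(logits, batch["labels"])
        return _bce_with_logits(logits, batch["target_multi_hot"])

    def _trainable(self) -> list[nn.Parameter]:
        params = list(self.encoder.parameters())
        if self.head_kind == "bc":
            params += [self.bc_weight, self.bc_bias]
        return params

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        valid_records: list[PatientRecord] | None = None,
        seed: int = 0,
        verbose: bool = False,
    ) -> OnsetResults:
        cfg = self.finetune_config
        rng = np.random.default_rng(seed)
        optimizer = nn.Adam(self._trainable(), lr=cfg.learning_rate)
        n = len(self.train_tokens)

        val_scores: list[float] = []
        best_state = None
        best_auroc, best_epoch = -np.inf, -1
        train_losses: list[float] = []

        if valid_records is not None:
            # model selection considers the un-fine-tuned state too: with a
            # pretrained encoder the heads can start better than any epoch
            # of aggressive fine-tuning, and the validation split decides
            from .experiment import auroc as _auroc

            init_labels = np.array([r.label for r in valid_records])
            best_auroc = _auroc(self._predict(valid_records), init_labels)
            best_state = self._snapshot()

        for epoch in range(cfg.max_epochs):
            self.encoder.set_training(True)
            perm = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                items = [self.train_tokens[i] for i in perm[start : start + cfg.batch_size]]
                batch = batch_tokenized(items)
                loss = self._loss(batch)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(f"fine-tuning loss diverged: {loss.data}")
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                epoch_loss += float(loss.data)
                n_batches += 1
            self.encoder.set_training(False)
            train_losses.append(epoch_loss / max(n_batches, 1))

            if valid_records is not None:
                from .experiment import auroc as _auroc

                labels = np.array([r.label for r in valid_records])
                score = _auroc(self._predict(valid_records), labels)
                val_scores.append(score)
                if verbose:  # pragma: no cover
                    print(f"epoch {epoch + 1}: loss {train_losses[-1]:.4f} val AUROC {score:.4f}")
                if score > best_auroc:
                    best_auroc, best_epoch = score, epoch
                    best_state = self._snapshot()
                elif epoch - best_epoch >= cfg.patience:
                    break
            else:
                best_epoch = epoch

        if best_state is not None:
            self._restore(best_state)
        return OnsetResults(
            model=self,
            head_kind=self.head_kind,
            epochs_run=len(train_losses),
            best_epoch=best_epoch,
            train_losses=train_losses,
            val_aurocs=val_scores,
            seed=seed,
        )

    def _snapshot(self) -> dict[str, np.ndarray]:
        state = self.encoder.state_dict()
        state["__bc_w__"] = self.bc_weight.data.copy()
        state["__bc_b__"] = self.bc_bias.data.copy()
        return state

    def _restore(self, state: dict[str, np.ndarray]) -> None:
        state = dict(state)
        self.bc_weight.data = state.pop("__bc_w__")
        self.bc_bias.data = state.pop("__bc_b__")
        self.encoder.load_state_dict(state)

    # -- inference ----------------------------------------------------------
    def _predict_output(self, records: list[PatientRecord]) -> HeadOutput:
        self.encoder.set_training(False)
        tokens = encode_cohort(
            records, self.vocab, max_len=self.max_len,
            add_next_visit_mask=self._needs_mask, censor=True,
        )
        scores, probs = [], []
        with nn.no_grad():
            for start in range(0, len(tokens), 256):
                batch = batch_tokenized(tokens[start : start + 256])
                out = head_output(self._logits(batch), self.head_kind)
                scores.append(np.atleast_1d(out.patient_score))
                if out.per_token_probs is not None:
                    probs.append(np.atleast_2d(out.per_token_probs))
        return HeadOutput(
            patient_score=np.concatenate(scores),
            per_token_probs=np.concatenate(probs) if probs else None,
        )

    def _predict(self, records: list[PatientRecord]) -> np.ndarray:
        return self._predict_output(records).patient_score
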