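"""From-scratch comparison models: LR, LSTM, BiLSTM, GRU, BiGRU.

Logistic regression works on bag-of-codes counts.  The recurrent models
learn their own token embeddings (no pretraining), consume the chronological
token sequence, and classify from the final hidden state at each patient's
last real position (forward and reversed passes concatenated for the
bidirectional variants).
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import LogisticRegression

from . import nn
from .cohort import PatientRecord
from .codec import TokenizedPatient, Vocabulary, batch_tokenized, encode_cohort
from .config import BaselineConfig
from .errors import ConfigurationError

__all__ = ["featurize_bag_of_codes", "BaselineModel", "BaselineResults", "train_baseline"]


def featurize_bag_of_codes(tokenized: TokenizedPatient, vocab: Vocabulary) -> np.ndarray:
    """Counts of non-special tokens, length = vocabulary size."""
    real = tokenized.token_ids[(tokenized.attention_mask == 1) & (tokenized.token_ids >= 2)]
    return np.bincount(real, minlength=vocab.size).astype(np.float64)


class _GRUCell(nn.Module):
    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.w_zr = nn.Linear(in_dim, 2 * hidden, rng)
        self.u_zr = nn.Linear(hidden, 2 * hidden, rng, bias=False)
        self.w_n = nn.Linear(in_dim, hidden, rng)
        self.u_n = nn.Linear(hidden, hidden, rng, bias=False)

    def __call__(self, x: nn.Tensor, h: nn.Tensor) -> nn.Tensor:
        H = self.hidden
        zr = (self.w_zr(x) + self.u_zr(h)).sigmoid()
        z, r = zr[:, :H], zr[:, H:]
        n = (self.w_n(x) + self.u_n(r * h)).tanh()
        return (1.0 - z) * n + z * h


class _LSTMCell(nn.Module):
    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.w = nn.Linear(in_dim, 4 * hidden, rng)
        self.u = nn.Linear(hidden, 4 * hidden, rng, bias=False)

    def __call__(self, x, h, c):
        H = self.hidden
        g = self.w(x) + self.u(h)
        i = g[:, :H].sigmoid()
        f = g[:, H : 2 * H].sigmoid()
        o = g[:, 2 * H : 3 * H].sigmoid()
        cand = g[:, 3 * H :].tanh()
        c = f * c + i * cand
        return o * c.tanh(), c


class _RecurrentClassifier(nn.Module):
    def __init__(self, config: BaselineConfig, vocab_size: int):
        rng = np.random.default_rng(config.seed)
        self.kind = config.model_kind
        self.bidirectional = self.kind.startswith("bi")
        cell_kind = self.kind.removeprefix("bi")
        self.embedding = nn.Embedding(vocab_size, config.embedding_dim, rng)
        make = _GRUCell if cell_kind == "gru" else _LSTMCell
        self.cell_fw = make(config.embedding_dim, config.hidden_dim, rng)
        self.cell_bw = (
            make(config.embedding_dim, config.hidden_dim, rng) if self.bidirectional else None
        )
        out_dim = config.hidden_dim * (2 if self.bidirectional else 1)
        self.out = nn.Linear(out_dim, 1, rng)
        self.hidden_dim = config.hidden_dim

    def _run(self, cell, emb: nn.Tensor, lengths: np.ndarray) -> nn.Tensor:
        B, L = emb.shape[0], emb.shape[1]
        h = nn.Tensor(np.zeros((B, self.hidden_dim)))
        c = nn.Tensor(np.zeros((B, self.hidden_dim)))
        states = []
        for t in range(L):
            x_t = emb[:, t]
            if isinstance(cell, _LSTMCell):
                h, c = cell(x_t, h, c)
            else:
                h = cell(x_t, h)
            states.append(h)
        stacked = nn.stack(states, axis=1)  # [B, L, H]
        return stacked[(np.arange(B), lengths - 1)]

    def logits(self, batch: dict[str, np.ndarray]) -> nn.Tensor:
        ids = batch["token_ids"]
        lengths = batch["attention_mask"].sum(axis=1).astype(int)
        final = self._run(self.cell_fw, self.embedding(ids), lengths)
        if self.bidirectional:
            rev = ids.copy()
            for i, n in enumerate(lengths):  # reverse real tokens, keep PAD at the end
                rev[i, :n] = rev[i, :n][::-1]
            final_bw = self._run(self.cell_bw, self.embedding(rev), lengths)
            final = nn.cat([final, final_bw], axis=1)
        return self.out(final).reshape(final.shape[0])


def _softplus(t: nn.Tensor) -> nn.Tensor:
    a = t.relu()
    return a + ((t - a - a).exp() + 1.0).log()


class BaselineResults:
    """Fitted baseline with a ``predict_proba`` contract over patient records."""

    def __init__(self, model: "BaselineModel", history: list[float]):
        self.model = model
        self.config = model.config
        self.val_history = history

    def predict_proba(self, records: list[PatientRecord]) -> np.ndarray:
        return self.model._predict(records)

    def auroc(self, records: list[PatientRecord]) -> float:
        from .experiment import auroc as _auroc

        return _auroc(self.predict_proba(records), np.array([r.label for r in records]))

    def summary(self) -> str:
        lines = [f"Baseline model: {self.config.model_kind}"]
        if self.val_history:
            lines.append(f"  best val AUROC: {max(self.val_history):.4f}")
        return "\n".join(lines)


class BaselineModel:
    def __init__(
        self,
        train_records: list[PatientRecord],
        vocab: Vocabulary,
        config: BaselineConfig | None = None,
        max_len: int = 64,
    ):
        self.config = config or BaselineConfig()
        self.vocab = vocab
        self.max_len = max_len
        self.train_records = train_records
        labels = {r.label for r in train_records}
        if labels != {0, 1}:
            raise ConfigurationError("training set must contain both classes")
        self._lr: LogisticRegression | None = None
        self._rnn: _RecurrentClassifier | None = None

    def _encode(self, records: list[PatientRecord]) -> list[TokenizedPatient]:
        return encode_cohort(records, self.vocab, max_len=self.max_len, censor=True)

    def fit(self, valid_records: list[PatientRecord] | None = None) -> BaselineResults:
        if self.config.model_kind == "lr":
            X = np.stack(
                [featurize_bag_of_codes(t, self.vocab) for t in self._encode(self.train_records)]
            )
            y = np.array([r.label for r in self.train_records])
            self._lr = LogisticRegression(max_iter=2000, random_state=self.config.seed)
            self._lr.fit(X, y)
            return BaselineResults(self, [])
        return self._fit_rnn(valid_records)

    def _fit_rnn(self, valid_records) -> BaselineResults:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        rnn = _RecurrentClassifier(cfg, self.vocab.size)
        self._rnn = rnn
        optimizer = nn.Adam(rnn.parameters(), lr=cfg.learning_rate)
        tokens = self._encode(self.train_records)
        history: list[float] = []
        best_auroc, best_epoch, best_state = -np.inf, -1, None

        for epoch in range(cfg.max_epochs):
            perm = rng.permutation(len(tokens))
            for start in range(0, len(perm), cfg.batch_size):
                batch = batch_tokenized([tokens[i] for i in perm[start : start + cfg.batch_size]])
                logits = rnn.logits(batch)
                y = nn.Tensor(batch["labels"].astype(float))
                loss = (_softplus(logits) - y * logits).mean()
                if not np.isfinite(loss.data):
                    raise FloatingPointError(f"baseline loss diverged: {loss.data}")
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
            if valid_records is not None:
                from .experiment import auroc as _auroc

                score = _auroc(
                    self._predict(valid_records),
                    np.array([r.label for r in valid_records]),
                )
                history.append(score)
                if score > best_auroc:
                    best_auroc, best_epoch = score, epoch
                    best_state = rnn.state_dict()
                elif epoch - best_epoch >= cfg.patience:
                    break
        if best_state is not None:
            rnn.load_state_dict(best_state)
        return BaselineResults(self, history)

    def _predict(self, records: list[PatientRecord]) -> np.ndarray:
        tokens = self._encode(records)
        if self._lr is not None:
            X = np.stack([featurize_bag_of_codes(t, self.vocab) for t in tokens])
            return self._lr.predict_proba(X)[:, 1]
        if self._rnn is None:
            raise RuntimeError("model is not fitted")
        out = []
        with nn.no_grad():
            for start in range(0, len(tokens), 256):
                batch = batch_tokenized(tokens[start : start + 256])
                z = self._rnn.logits(batch).data
                out.append(1.0 / (1.0 + np.exp(-z)))
        return np.concatenate(out)


def train_baseline(
    config: BaselineConfig,
    train_records: list[PatientRecord],
    valid_records: list[PatientRecord] | None,
    vocab: Vocabulary,
    max_len: int = 64,
) -> BaselineResults:
    """Functional wrapper around :class:`BaselineModel`."""
    return BaselineModel(train_records, vocab, config, max_len=max_len).fit(valid_records)
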