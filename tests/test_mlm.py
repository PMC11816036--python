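"""Masked-code pretraining: corruption scheme, tied logits, training effect."""

from __future__ import annotations

import numpy as np
import pytest

import nextvisit as nv
from nextvisit import nn
from nextvisit.codec import MASK_ID, batch_tokenized, encode_cohort
from nextvisit.config import CorruptionConfig
from nextvisit.errors import ConfigurationError
from nextvisit.mlm import (
    IGNORE_INDEX,
    MaskedLMModel,
    corrupt_sequence,
    masked_cross_entropy,
    masked_cross_entropy_from_hidden,
    mlm_logits,
)


@pytest.fixture(scope="module")
def sequences(tiny_cohort, tiny_vocab):
    batch = batch_tokenized(encode_cohort(tiny_cohort, tiny_vocab, censor=False))
    return batch["token_ids"], batch["attention_mask"]


def test_full_mask_limit_case(sequences, tiny_vocab):
    ids, mask = sequences
    cfg = CorruptionConfig(select_rate=1.0, p_mask=1.0, p_random=0.0, p_keep=0.0)
    corrupted, targets = corrupt_sequence(ids, mask, tiny_vocab, cfg)
    real = (mask == 1) & (ids >= 2)
    assert (corrupted[real] == MASK_ID).all()
    assert (targets[real] == ids[real]).all()
    assert (targets[~real] == IGNORE_INDEX).all()
    assert (corrupted[~real] == ids[~real]).all()


def test_keep_only_limit_case(sequences, tiny_vocab):
    ids, mask = sequences
    cfg = CorruptionConfig(select_rate=1.0, p_mask=0.0, p_random=0.0, p_keep=1.0)
    corrupted, targets = corrupt_sequence(ids, mask, tiny_vocab, cfg)
    np.testing.assert_array_equal(corrupted, ids)
    assert (targets[(mask == 1) & (ids >= 2)] >= 2).all()


def test_corruption_proportions_converge_to_80_10_10(tiny_vocab):
    rng = np.random.default_rng(0)
    ids = rng.integers(2, tiny_vocab.size, size=(300, 64))
    mask = np.ones_like(ids)
    cfg = CorruptionConfig(select_rate=1.0, seed=4)
    corrupted, targets = corrupt_sequence(ids, mask, tiny_vocab, cfg)
    sel = targets != IGNORE_INDEX
    n = int(sel.sum())
    assert n >= 15000
    frac_mask = (corrupted[sel] == MASK_ID).mean()
    changed = (corrupted[sel] != ids[sel]) & (corrupted[sel] != MASK_ID)
    # random replacement can coincide with the original, so measure via the
    # complement: kept = not masked and unchanged
    frac_changed = changed.mean()
    assert abs(frac_mask - 0.8) < 3 * np.sqrt(0.8 * 0.2 / n)
    # changed fraction ~ 0.10 * (1 - 1/n_codes)
    p_eff = 0.10 * (1 - 1 / len(tiny_vocab.code_ids))
    assert abs(frac_changed - p_eff) < 4 * np.sqrt(p_eff * (1 - p_eff) / n)


def test_pad_positions_never_selected_and_random_draws_are_codes(sequences, tiny_vocab):
    ids, mask = sequences
    cfg = CorruptionConfig(seed=8)
    corrupted, targets = corrupt_sequence(ids, mask, tiny_vocab, cfg)
    assert (targets[mask == 0] == IGNORE_INDEX).all()
    assert (corrupted[mask == 0] == ids[mask == 0]).all()
    assert corrupted[mask == 1].min() >= 1  # MASK or real codes, never PAD


def test_corruption_deterministic_given_seed(sequences, tiny_vocab):
    ids, mask = sequences
    cfg = CorruptionConfig(seed=123)
    a = corrupt_sequence(ids, mask, tiny_vocab, cfg)
    b = corrupt_sequence(ids, mask, tiny_vocab, cfg)
    np.testing.assert_array_equal(a[0], b[0])
    np.testing.assert_array_equal(a[1], b[1])


def test_invalid_corruption_configs_rejected():
    with pytest.raises(ConfigurationError):
        CorruptionConfig(p_mask=0.9, p_random=0.2, p_keep=0.1)
    with pytest.raises(ConfigurationError):
        CorruptionConfig(select_rate=0.0)


def test_mlm_logits_are_dot_products_with_embedding_rows(rng):
    table = nn.Parameter(rng.normal(size=(7, 4)))
    contextual = nn.Tensor(rng.normal(size=(2, 3, 4)))
    scores = mlm_logits(contextual, table).data
    for b in range(2):  # brute-force oracle over the tiny vocabulary
        for p in range(3):
            for v in range(7):
                assert scores[b, p, v] == pytest.approx(
                    float(contextual.data[b, p] @ table.data[v]), abs=1e-12
                )
    # contextual row equal to an embedding row -> argmax at that token
    probe = nn.Tensor(table.data[5][None, None, :])
    assert mlm_logits(probe, table).data[0, 0].argmax() == 5


def test_mlm_logits_dimension_mismatch(rng):
    with pytest.raises(ValueError):
        mlm_logits(nn.Tensor(rng.normal(size=(1, 2, 3))), nn.Tensor(rng.normal(size=(5, 4))))


def test_zero_contextual_row_gives_uniform_scores(rng):
    table = nn.Parameter(rng.normal(size=(6, 4)))
    scores = mlm_logits(nn.Tensor(np.zeros((1, 1, 4))), table).data
    np.testing.assert_allclose(scores, 0.0)


def test_loss_only_at_selected_positions(rng):
    logits = nn.Tensor(rng.normal(size=(2, 5, 9)))
    targets = np.full((2, 5), IGNORE_INDEX)
    targets[0, 1] = 3
    targets[1, 4] = 7
    base = float(masked_cross_entropy(logits, targets).data)
    # perturbing logits at unselected positions does not change the loss
    perturbed = logits.data.copy()
    perturbed[0, 0] += 100.0
    perturbed[1, 2] -= 50.0
    assert float(masked_cross_entropy(nn.Tensor(perturbed), targets).data) == pytest.approx(base)
    # selected-position fast path equals the full computation
    table = nn.Parameter(rng.normal(size=(9, 6)))
    hidden = nn.Tensor(rng.normal(size=(2, 5, 6)))
    full = masked_cross_entropy(mlm_logits(hidden, table), targets)
    fast = masked_cross_entropy_from_hidden(hidden, table, targets)
    assert float(fast.data) == pytest.approx(float(full.data), abs=1e-12)


def test_weight_tying_couples_input_and_output(tiny_cohort, tiny_vocab):
    enc = nv.TransformerEncoder(
        nv.EncoderConfig(embedding_dim=8, n_layers=1, n_heads=1, feedforward_dim=8),
        tiny_vocab.size,
    )
    batch = batch_tokenized(encode_cohort(tiny_cohort[:4], tiny_vocab, censor=False))
    tok = int(batch["token_ids"][batch["attention_mask"] == 1][0])
    hidden = enc(batch["token_ids"], batch["visit_ids"], batch["attention_mask"])
    before_scores = mlm_logits(hidden, enc.token_embedding.weight).data.copy()
    enc.token_embedding.weight.data[tok] += 1.0
    hidden2 = enc(batch["token_ids"], batch["visit_ids"], batch["attention_mask"])
    after_scores = mlm_logits(hidden2, enc.token_embedding.weight).data
    # both the input representation and the output column for that token move
    assert not np.allclose(hidden.data, hidden2.data)
    assert not np.allclose(before_scores[..., tok], after_scores[..., tok])


def test_smoke_pretrain_writes_loadable_checkpoint(tmp_path, tiny_cohort):
    results = nv.pretrain(
        tiny_cohort[:50],
        nv.EncoderConfig(embedding_dim=8, n_layers=1, n_heads=1, feedforward_dim=8),
        nv.CorruptionConfig(),
        out=tmp_path / "ck",
        epochs=1,
        seed=0,
    )
    enc, vocab, extra = nv.load_checkpoint(tmp_path / "ck")
    assert extra["kind"] == "mlm_pretrain"
    np.testing.assert_array_equal(
        enc.token_embedding.weight.data, results.encoder.token_embedding.weight.data
    )


def test_pretraining_reduces_heldout_loss(pretrained):
    assert pretrained.final_val_loss < pretrained.initial_val_loss


def test_pretraining_aligns_mask_scores_with_onset_risk(pretrained, study_splits):
    """Functional embedding-geometry oracle: with no fine-tuning at all, the
    dot products between the next-visit [MASK] contextual vector and the
    target-code embedding rows already rank cases above controls.

    (Raw embedding-row cosines are not a valid oracle here: under softmax
    weight tying, rarely occurring codes — the targets — are pushed opposite
    the average context direction, a frequency effect that swamps the
    precursor association.  The usable geometry is context-vs-label-row, which
    is exactly what this measures.)
    """
    _, _, test = study_splits
    model = nv.OnsetModel(test[:5], head="mask", pretrained=pretrained)
    scores = model._predict(test)
    labels = np.array([r.label for r in test])
    assert nv.auroc(scores, labels) > 0.6
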