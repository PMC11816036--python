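"""Prediction heads: scalar oracles, the restriction equality, loss policies."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import expit

import nextvisit as nv
from nextvisit import nn
from nextvisit.codec import batch_tokenized, encode_cohort
from nextvisit.encoder import ContextualizedSequence
from nextvisit.heads import (
    HeadOutput,
    bc_head,
    finetune_loss,
    head_output,
    label_tensor,
    mask_head,
    sum_head,
)
from nextvisit.mlm import mlm_logits


def test_bc_head_matches_scalar_logistic_oracle(rng):
    d = 6
    w = nn.Tensor(rng.normal(size=(d, 1)))
    b = nn.Tensor(rng.normal(size=(1,)))
    ctx = nn.Tensor(rng.normal(size=(3, d)))
    out = head_output(bc_head(ctx, w, b), "bc")
    for i in range(3):
        expected = expit(float(ctx.data[i] @ w.data[:, 0]) + float(b.data[0]))
        assert out.patient_score[i] == pytest.approx(expected, abs=1e-12)
    assert out.per_token_probs is None


def test_bc_head_zero_weights_and_saturation():
    ctx = nn.Tensor(np.ones((1, 4)))
    zero = head_output(bc_head(ctx, nn.Tensor(np.zeros((4, 1))), nn.Tensor(np.zeros(1))), "bc")
    assert zero.patient_score[0] == pytest.approx(0.5)
    sat = head_output(bc_head(ctx, nn.Tensor(np.zeros((4, 1))), nn.Tensor(np.array([50.0]))), "bc")
    assert sat.patient_score[0] == pytest.approx(1.0, abs=1e-12)


def test_sum_head_eight_probabilities_and_geometry(rng):
    labels = nn.Tensor(rng.normal(size=(8, 5)))
    zero_ctx = nn.Tensor(np.zeros((1, 5)))
    out = head_output(sum_head(zero_ctx, labels), "sum")
    assert out.per_token_probs.shape == (1, 8)
    np.testing.assert_allclose(out.per_token_probs, 0.5)
    assert out.patient_score[0] == pytest.approx(0.5)
    # context orthogonal to every label row -> all logits 0 -> score 0.5
    basis = np.zeros((8, 5))
    basis[:, :4] = rng.normal(size=(8, 4))
    ortho = np.zeros((1, 5))
    ortho[0, 4] = 3.0
    out2 = head_output(sum_head(nn.Tensor(ortho), nn.Tensor(basis)), "sum")
    assert out2.patient_score[0] == pytest.approx(0.5)


def test_sum_head_rejects_bad_label_tensor(rng):
    with pytest.raises(ValueError):
        sum_head(nn.Tensor(rng.normal(size=(1, 5))), nn.Tensor(rng.normal(size=(8, 4))))


def test_mask_head_equals_restricted_mlm_logits(tiny_cohort, tiny_vocab):
    """The central alignment oracle: the mask head is exactly the restriction
    of the full-vocabulary tied MLM scores to the 8 target ids."""
    enc = nv.TransformerEncoder(
        nv.EncoderConfig(embedding_dim=16, n_layers=2, n_heads=2, feedforward_dim=16, seed=2),
        tiny_vocab.size,
    )
    batch = batch_tokenized(
        encode_cohort(tiny_cohort[:12], tiny_vocab, add_next_visit_mask=True)
    )
    contextual = enc.encode(batch)
    labels = label_tensor(enc, tiny_vocab)
    got = mask_head(contextual, batch["mask_positions"], labels, token_ids=batch["token_ids"]).data
    full = mlm_logits(contextual.hidden, enc.token_embedding.weight).data
    rows = full[np.arange(len(got)), batch["mask_positions"]]
    np.testing.assert_allclose(got, rows[:, tiny_vocab.target_ids], rtol=1e-10, atol=1e-13)


def test_mask_head_validates_mask_position(tiny_cohort, tiny_vocab, rng):
    enc = nv.TransformerEncoder(nv.EncoderConfig(embedding_dim=8, n_heads=1, feedforward_dim=8), tiny_vocab.size)
    batch = batch_tokenized(encode_cohort(tiny_cohort[:3], tiny_vocab, add_next_visit_mask=False))
    contextual = enc.encode(batch)
    labels = label_tensor(enc, tiny_vocab)
    with pytest.raises(ValueError, match="unset"):
        mask_head(contextual, batch["mask_positions"], labels)
    with pytest.raises(ValueError, match="MASK"):
        mask_head(contextual, np.zeros(3, dtype=int), labels, token_ids=batch["token_ids"])


def test_permuting_label_rows_permutes_probs_not_score(rng):
    labels = rng.normal(size=(8, 5))
    ctx = nn.Tensor(rng.normal(size=(2, 5)))
    out = head_output(sum_head(ctx, nn.Tensor(labels)), "sum")
    perm = rng.permutation(8)
    out_p = head_output(sum_head(ctx, nn.Tensor(labels[perm])), "sum")
    np.testing.assert_allclose(out_p.per_token_probs, out.per_token_probs[:, perm])
    np.testing.assert_allclose(out_p.patient_score, out.patient_score)


def test_max_monotonicity_of_patient_score():
    probs = np.array([[0.1, 0.4, 0.2, 0.05, 0.3, 0.1, 0.2, 0.15]])
    score = probs.max()
    bumped = probs.copy()
    bumped[0, 3] = 0.35  # raising any one probability cannot lower the max
    assert bumped.max() >= score


def test_finetune_loss_closed_forms():
    control_half = HeadOutput(
        patient_score=np.array([0.5]), per_token_probs=np.full((1, 8), 0.5)
    )
    loss = finetune_loss(control_half, 0, np.zeros((1, 8)), "sum", policy="per_token")
    assert loss == pytest.approx(np.log(2.0), abs=1e-12)
    perfect = HeadOutput(
        patient_score=np.array([1.0 - 1e-15]),
        per_token_probs=np.concatenate([np.ones((1, 1)), np.zeros((1, 7))], axis=1),
    )
    mh = np.zeros((1, 8)); mh[0, 0] = 1
    assert finetune_loss(perfect, 1, mh, "mask", policy="per_token") < 1e-9
    bc = HeadOutput(patient_score=np.array([0.25]))
    assert finetune_loss(bc, 0, None, "bc") == pytest.approx(-np.log(0.75))


def test_finetune_loss_rejects_inconsistent_targets():
    out = HeadOutput(patient_score=np.array([0.5]), per_token_probs=np.full((1, 8), 0.5))
    with pytest.raises(ValueError, match="inconsistent"):
        finetune_loss(out, 1, np.zeros((1, 8)), "sum")


def test_per_token_training_loss_gradient_matches_finite_differences(rng):
    from nextvisit.heads import _bce_with_logits

    W = nn.Parameter(rng.normal(size=(5, 8)))
    x = nn.Tensor(rng.normal(size=(3, 5)))
    y = (rng.random((3, 8)) < 0.3).astype(float)

    def f():
        return _bce_with_logits(x @ W, y)

    W.grad = None
    f().backward()
    g = W.grad.copy()
    eps = 1e-6
    num = np.zeros_like(g)
    for i in range(W.data.shape[0]):
        for j in range(W.data.shape[1]):
            W.data[i, j] += eps
            hi = float(f().data)
            W.data[i, j] -= 2 * eps
            lo = float(f().data)
            W.data[i, j] += eps
            num[i, j] = (hi - lo) / (2 * eps)
    np.testing.assert_allclose(g, num, atol=1e-7)
    # and the logit-space objective agrees with the probability-space one
    logits = rng.normal(size=(3, 8))
    ref = finetune_loss(
        HeadOutput(patient_score=expit(logits).max(-1), per_token_probs=expit(logits)),
        y.max(-1), y, "sum",
    )
    assert float(_bce_with_logits(nn.Tensor(logits), y).data) == pytest.approx(ref, abs=1e-9)


def test_bc_with_frozen_identity_encoder_reduces_to_logistic_regression(rng):
    """A 0-layer encoder makes the bc head plain logistic regression on the
    summed (token+visit) embeddings."""
    cfg = nv.EncoderConfig(embedding_dim=6, n_layers=1, n_heads=1, feedforward_dim=6)
    rec = nv.PatientRecord("pt", [["D001"], ["C25.0"]], label=1, onset_target_code="C25.0")
    # emulate 0 layers by emptying the block list
    vocab = nv.build_vocabulary([rec])
    enc = nv.TransformerEncoder(cfg, vocab.size)
    enc.blocks = []
    ids = np.array([[2, 3, 0]])
    vis = np.array([[1, 1, 0]])
    mask = np.array([[1, 1, 0]])
    hidden = enc(ids, vis, mask)
    pooled = nv.pool_sum(ContextualizedSequence(hidden, mask)).data
    E, V = enc.token_embedding.weight.data, enc.visit_embedding.weight.data
    expected = (E[2] + V[1]) + (E[3] + V[1])
    np.testing.assert_allclose(pooled[0], expected, atol=1e-12)
    w = rng.normal(size=(6, 1))
    out = head_output(bc_head(nn.Tensor(pooled), nn.Tensor(w), nn.Tensor(np.zeros(1))), "bc")
    assert out.patient_score[0] == pytest.approx(expit(pooled[0] @ w[:, 0]))
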