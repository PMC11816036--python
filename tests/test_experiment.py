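"""Protocol: splits, few-shot sampling policies, AUROC, learning-curve harness."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nextvisit as nv
from nextvisit.config import SamplingPolicy, SplitSpec
from nextvisit.errors import ConfigurationError, SamplingError


def _mini_cohort(n, n_cases, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        label = 1 if i < n_cases else 0
        visits = [[f"D{rng.integers(0, 30):03d}" for _ in range(3)]]
        if label:
            visits.append(["C25.0"])
        out.append(nv.PatientRecord(f"pt-{i}", visits, label, "C25.0" if label else None))
    rng.shuffle(out)
    return out


@pytest.mark.parametrize(
    "n,expected",
    [
        (31243, (21871, 3124, 6248)),
        (3810, (2667, 381, 762)),
        (10, (7, 1, 2)),
    ],
)
def test_split_sizes_reproduce_published_triples(n, expected):
    cohort = _mini_cohort(n, n // 3)
    train, val, test = nv.split_cohort(cohort, SplitSpec(seed=0))
    assert (len(train), len(val), len(test)) == expected


@settings(derandomize=True, max_examples=30)
@given(n=st.integers(min_value=10, max_value=4000), seed=st.integers(0, 10))
def test_split_is_a_disjoint_exhaustive_partition(n, seed):
    cohort = _mini_cohort(n, n // 4, seed=1)
    train, val, test = nv.split_cohort(cohort, SplitSpec(seed=seed))
    assert len(val) == int(np.floor(0.1 * n))
    assert len(test) == int(np.floor(0.2 * n))
    assert len(train) + len(val) + len(test) == n
    ids = [r.patient_id for part in (train, val, test) for r in part]
    assert len(set(ids)) == n


def test_split_too_small_and_determinism():
    with pytest.raises(ConfigurationError):
        nv.split_cohort(_mini_cohort(9, 3), SplitSpec(seed=0))
    cohort = _mini_cohort(100, 40)
    a = nv.split_cohort(cohort, SplitSpec(seed=5))
    b = nv.split_cohort(cohort, SplitSpec(seed=5))
    assert [r.patient_id for r in a[0]] == [r.patient_id for r in b[0]]


def test_balanced_both_gives_five_and_five_at_size_ten():
    cohort = _mini_cohort(200, 80)
    train, val, _ = nv.split_cohort(cohort, SplitSpec(seed=0))
    ft, va = nv.sample_fewshot(train, val, 10, SamplingPolicy("balanced_both"), seed=3)
    assert len(ft) == 10 and sum(r.label for r in ft) == 5
    assert len(va) == 10 and sum(r.label for r in va) == 5
    # without replacement: no duplicate patients
    assert len({r.patient_id for r in ft}) == 10


def test_balanced_train_full_val_uses_whole_validation_split():
    cohort = _mini_cohort(400, 150)
    train, val, _ = nv.split_cohort(cohort, SplitSpec(seed=0))
    ft, va = nv.sample_fewshot(train, val, 20, SamplingPolicy("balanced_train_full_val"), seed=3)
    assert sum(r.label for r in ft) == 10 and len(ft) == 20
    assert va == list(val)


def test_infeasible_sampling_raises_with_shortfall():
    cohort = _mini_cohort(40, 1)
    train, val, _ = nv.split_cohort(cohort, SplitSpec(seed=0))
    with pytest.raises(SamplingError):
        nv.sample_fewshot(train, val, 4, SamplingPolicy("balanced_both"), seed=0)


@pytest.mark.parametrize("size,regime", [
    (20, "balanced"), (100, "train_balanced_val_allpos"),
    (300, "allpos_both"), (500, "allpos_train_full_val"),
])
def test_external_cohort_ladder_regimes(size, regime):
    # imbalanced source mimicking the external cohort: ~5% cases
    cohort = _mini_cohort(3810, 199)
    train, val, _ = nv.split_cohort(cohort, SplitSpec(seed=0))
    ft, va = nv.sample_fewshot(train, val, size, SamplingPolicy("ehrshot_ladder"), seed=1)
    n_pos_ft = sum(r.label for r in ft)
    n_pos_va = sum(r.label for r in va)
    if regime == "balanced":
        assert len(ft) == size and n_pos_ft == size // 2
        assert len(va) == size and n_pos_va == size // 2
    elif regime == "train_balanced_val_allpos":
        assert len(ft) == size and n_pos_ft == size // 2
        assert len(va) == size and n_pos_va == sum(r.label for r in val)
    elif regime == "allpos_both":
        assert len(ft) == size and n_pos_ft == sum(r.label for r in train)
        assert len(va) == size and n_pos_va == sum(r.label for r in val)
    else:
        assert len(ft) == size and n_pos_ft == sum(r.label for r in train)
        assert va == list(val)


def test_external_ladder_rejects_sizes_beyond_range():
    cohort = _mini_cohort(3810, 199)
    train, val, _ = nv.split_cohort(cohort, SplitSpec(seed=0))
    with pytest.raises(SamplingError):
        nv.sample_fewshot(train, val, 2000, SamplingPolicy("ehrshot_ladder"), seed=0)


def _auroc_pairwise(scores, labels):
    """O(n^2) concordant/discordant/tied-pair oracle."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_auroc_limit_cases():
    assert nv.auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    assert nv.auroc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5
    with pytest.raises(ValueError):
        nv.auroc([0.1, 0.2], [1, 1])


@settings(derandomize=True, max_examples=25)
@given(st.integers(0, 10_000))
def test_auroc_matches_pairwise_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 60))
    labels = rng.integers(0, 2, size=n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    scores = np.round(rng.random(n), 1)  # coarse grid forces ties
    assert nv.auroc(scores, labels) == pytest.approx(_auroc_pairwise(scores, labels))


def test_learning_curve_row_count_determinism_and_aggregation(tiny_cohort):
    cohort = _mini_cohort(500, 200, seed=2)
    kwargs = dict(models=["lr"], sizes=[10, 20], n_runs=3, seed=9)
    res1 = nv.run_learning_curve(cohort, **kwargs)
    res2 = nv.run_learning_curve(cohort, **kwargs)
    assert len(res1.table) == 1 * 2 * 3
    assert res1.table.equals(res2.table)
    summary = res1.summary()
    for _, row in summary.iterrows():
        cell = res1.table[(res1.table["model"] == row["model"]) & (res1.table["size"] == row["size"])]
        assert row["mean"] == pytest.approx(cell["auroc"].mean())
        assert row["std"] == pytest.approx(cell["auroc"].std())
        assert row["n_runs"] == 3


def test_learning_curve_requires_checkpoint_for_heads():
    cohort = _mini_cohort(300, 120)
    with pytest.raises(ConfigurationError, match="checkpoint"):
        nv.run_learning_curve(cohort, models=["mask"], sizes=[10], n_runs=1, seed=0)
    with pytest.raises(ConfigurationError, match="unknown model"):
        nv.run_learning_curve(cohort, models=["svm"], sizes=[10], n_runs=1, seed=0)


def test_learning_curve_plot_writes_figure(tmp_path):
    cohort = _mini_cohort(300, 120, seed=4)
    res = nv.run_learning_curve(cohort, models=["lr"], sizes=[10, 20], n_runs=2, seed=1)
    out = tmp_path / "curve.png"
    nv.plot_learning_curve(res, out)
    assert out.stat().st_size > 0
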