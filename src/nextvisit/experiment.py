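"""Benchmark protocol: splitting, few-shot sampling, AUROC, learning curves.

The 7:1:2 split floors the validation and test counts and gives the
remainder to train, which reproduces the published split triples exactly
(31,243 -> 21,871/3,124/6,248 and 3,810 -> 2,667/381/762).  Few-shot
fine-tuning sets are sampled without replacement under one of three
policies; every cell of the learning curve is evaluated on the full test
split, with 3 runs per cell by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .baselines import BaselineModel
from .cohort import PatientRecord
from .config import (
    BASELINE_KINDS,
    BaselineConfig,
    FinetuneConfig,
    SamplingPolicy,
    SplitSpec,
)
from .errors import ConfigurationError, SamplingError
from .heads import HEAD_KINDS, OnsetModel
from .mlm import MaskedLMResults

__all__ = [
    "split_cohort",
    "sample_fewshot",
    "auroc",
    "LearningCurveResult",
    "run_learning_curve",
    "plot_learning_curve",
]


def split_cohort(
    cohort: list[PatientRecord], spec: SplitSpec | None = None
) -> tuple[list[PatientRecord], list[PatientRecord], list[PatientRecord]]:
    """Patient-level 7:1:2 split; deterministic given ``spec.seed``."""
    spec = spec or SplitSpec()
    n = len(cohort)
    if n < 10:
        raise ConfigurationError(f"cohort of {n} patients is too small to split")
    n_val = int(np.floor(spec.ratios[1] * n))
    n_test = int(np.floor(spec.ratios[2] * n))
    n_train = n - n_val - n_test
    order = np.random.default_rng(spec.seed).permutation(n)
    train = [cohort[i] for i in order[:n_train]]
    val = [cohort[i] for i in order[n_train : n_train + n_val]]
    test = [cohort[i] for i in order[n_train + n_val :]]
    return train, val, test


def _take_balanced(records, size, rng, what: str):
    if size % 2:
        raise SamplingError(f"balanced sampling needs an even size, got {size}")
    half = size // 2
    return _take_mixed(records, half, half, rng, what)


def _take_mixed(records, n_pos: int, n_neg: int, rng, what: str):
    pos = [r for r in records if r.label == 1]
    neg = [r for r in records if r.label == 0]
    if len(pos) < n_pos or len(neg) < n_neg:
        raise SamplingError(
            f"{what}: need {n_pos} cases and {n_neg} controls, "
            f"have {len(pos)} and {len(neg)}"
        )
    chosen = [pos[i] for i in rng.choice(len(pos), n_pos, replace=False)]
    chosen += [neg[i] for i in rng.choice(len(neg), n_neg, replace=False)]
    rng.shuffle(chosen)
    return chosen


def _all_pos_sampled_neg(records, size, rng, what: str):
    n_pos = sum(r.label for r in records)
    if n_pos > size:
        raise SamplingError(f"{what}: {n_pos} cases exceed the target size {size}")
    return _take_mixed(records, n_pos, size - n_pos, rng, what)


def sample_fewshot(
    train: list[PatientRecord],
    validation: list[PatientRecord],
    size: int,
    policy: SamplingPolicy,
    seed: int = 0,
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Draw the fine-tuning and validation sets for one learning-curve cell.

    * ``balanced_both`` — size/2 cases + size/2 controls in both sets.
    * ``balanced_train_full_val`` — balanced fine-tuning set, whole
      validation split (the regime used for sizes >= 2000).
    * ``ehrshot_ladder`` — the external-cohort regimes keyed on size:
      10-30 balanced both; 40-200 balanced train, validation = all cases +
      controls up to size; 300 all cases + controls on both sides; 400-1000
      all cases + controls for train, full validation split.
    """
    rng = np.random.default_rng(seed)
    kind = policy.policy_kind
    if kind == "balanced_both":
        return (
            _take_balanced(train, size, rng, "fine-tuning set"),
            _take_balanced(validation, size, rng, "validation set"),
        )
    if kind == "balanced_train_full_val":
        return _take_balanced(train, size, rng, "fine-tuning set"), list(validation)
    # ehrshot_ladder
    if size <= 30:
        return (
            _take_balanced(train, size, rng, "fine-tuning set"),
            _take_balanced(validation, size, rng, "validation set"),
        )
    if size <= 200:
        return (
            _take_balanced(train, size, rng, "fine-tuning set"),
            _all_pos_sampled_neg(validation, size, rng, "validation set"),
        )
    if size == 300:
        return (
            _all_pos_sampled_neg(train, size, rng, "fine-tuning set"),
            _all_pos_sampled_neg(validation, size, rng, "validation set"),
        )
    if size <= 1000:
        return _all_pos_sampled_neg(train, size, rng, "fine-tuning set"), list(validation)
    raise SamplingError(f"size {size} is outside the external-cohort ladder (10-1000)")


def auroc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney tie convention."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"labels must contain both classes, got {classes}")
    return float(roc_auc_score(labels, scores))


@dataclass
class LearningCurveResult:
    """Per-(model, size, run) test AUROCs plus mean/std aggregation."""

    table: pd.DataFrame  # columns: model, size, run, seed, auroc

    def summary(self) -> pd.DataFrame:
        agg = (
            self.table.groupby(["model", "size"])["auroc"]
            .agg(["mean", "std", "count"])
            .reset_index()
            .rename(columns={"count": "n_runs"})
        )
        return agg

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def to_json_summary(self, path: str | Path) -> None:
        self.summary().to_json(path, orient="records", indent=1)


_ALL_MODELS = tuple(HEAD_KINDS) + BASELINE_KINDS


def _fit_and_score(
    model_name: str,
    finetune_set: list[PatientRecord],
    val_set: list[PatientRecord],
    test_records: list[PatientRecord],
    test_labels: np.ndarray,
    pretrained,
    vocab,
    finetune: FinetuneConfig,
    baseline_defaults: BaselineConfig | None,
    max_len: int,
    seed: int,
) -> float:
    if model_name in HEAD_KINDS:
        if pretrained is None:
            raise ConfigurationError(
                f"head model {model_name!r} requires a pretrained checkpoint"
            )
        model = OnsetModel(
            finetune_set, head=model_name, pretrained=pretrained,
            finetune=finetune, max_len=max_len,
        )
        results = model.fit(valid_records=val_set, seed=seed)
        scores = results.predict_proba(test_records)
    else:
        base = baseline_defaults or BaselineConfig(model_kind=model_name)
        cfg = BaselineConfig(
            model_kind=model_name,
            embedding_dim=base.embedding_dim,
            hidden_dim=base.hidden_dim,
            batch_size=base.batch_size,
            max_epochs=base.max_epochs,
            patience=base.patience,
            seed=seed,
        )
        results = BaselineModel(finetune_set, vocab, cfg, max_len=max_len).fit(val_set)
        scores = results.predict_proba(test_records)
    return auroc(scores, test_labels)


def run_learning_curve(
    cohort: list[PatientRecord],
    models: list[str],
    sizes: list[int],
    pretrained: "MaskedLMResults | str | Path | None" = None,
    n_runs: int = 3,
    seed: int = 0,
    policy: SamplingPolicy | None = None,
    split: SplitSpec | None = None,
    finetune: FinetuneConfig | None = None,
    baseline_config: BaselineConfig | None = None,
    max_len: int = 64,
    verbose: bool = False,
) -> LearningCurveResult:
    """Evaluate every (model, size, run) cell on the full test split.

    Head models start every cell from the same pretrained weights; baselines
    are trained from scratch per cell.  All randomness derives from ``seed``
    through per-cell seed sequences, so reruns reproduce the table exactly.
    """
    for m in models:
        if m not in _ALL_MODELS:
            raise ConfigurationError(f"unknown model {m!r}; choose from {_ALL_MODELS}")
    if any(m in HEAD_KINDS for m in models) and pretrained is None:
        raise ConfigurationError("head models require a pretrained checkpoint")

    policy = policy or SamplingPolicy(policy_kind="balanced_both")
    finetune = finetune or FinetuneConfig()
    split = split or SplitSpec(seed=seed)
    train, val, test = split_cohort(cohort, split)
    test_labels = np.array([r.label for r in test])

    if isinstance(pretrained, (str, Path)):
        from .encoder import load_checkpoint

        enc, vocab, _ = load_checkpoint(pretrained)
        pretrained = MaskedLMResults(
            encoder=enc, vocab=vocab, train_losses=[], val_losses=[0.0],
            initial_val_loss=0.0, corruption=None, seed=seed,
        )
    vocab = pretrained.vocab if pretrained is not None else None
    if vocab is None:
        from .codec import build_vocabulary

        vocab = build_vocabulary(cohort)

    rows = []
    for mi, model_name in enumerate(models):
        for size in sizes:
            for run in range(n_runs):
                cell_seed = int(
                    np.random.SeedSequence([seed, mi, size, run]).generate_state(1)[0]
                    % (2**31)
                )
                finetune_set, val_set = sample_fewshot(
                    train, val, size, policy, seed=cell_seed
                )
                score = _fit_and_score(
                    model_name, finetune_set, val_set, test, test_labels,
                    pretrained, vocab, finetune, baseline_config, max_len, cell_seed,
                )
                rows.append(
                    {"model": model_name, "size": size, "run": run,
                     "seed": cell_seed, "auroc": score}
                )
                if verbose:  # pragma: no cover
                    print(f"{model_name} size={size} run={run}: AUROC {score:.4f}")
    return LearningCurveResult(table=pd.DataFrame(rows))


def plot_learning_curve(result: LearningCurveResult, path: str | Path | None = None):
    """AUC-vs-size curves (mean +/- std per model), mirroring the benchmark figures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for model, grp in result.summary().groupby("model"):
        grp = grp.sort_values("size")
        ax.errorbar(grp["size"], grp["mean"], yerr=grp["std"].fillna(0), label=model,
                    marker="o", capsize=3)
    ax.set_xscale("log")
    ax.set_xlabel("fine-tuning sample size")
    ax.set_ylabel("test AUROC (mean over runs)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
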