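"""Configuration dataclasses shared across the package.

All configs are plain dataclasses validated eagerly in ``__post_init__`` so a
bad value fails before any compute, and all carry an explicit ``seed`` so that
every run is reproducible end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .errors import ConfigurationError

#: The eight ICD-10 pancreatic-cancer codes whose future occurrence defines
#: case status (malignant neoplasm of head, body, tail, duct, endocrine,
#: other parts, overlapping sites, and unspecified part of the pancreas).
TARGET_CODES: tuple[str, ...] = (
    "C25.0",
    "C25.1",
    "C25.2",
    "C25.3",
    "C25.4",
    "C25.7",
    "C25.8",
    "C25.9",
)


def _check_range_pair(name: str, pair) -> tuple[int, int]:
    try:
        lo, hi = int(pair[0]), int(pair[1])
    except (TypeError, ValueError, IndexError) as exc:
        raise ConfigurationError(f"{name} must be an integer pair") from exc
    if lo < 1 or lo > hi:
        raise ConfigurationError(f"{name} must satisfy 1 <= min <= max, got {pair}")
    return lo, hi


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic coded-visit cohort generator.

    Ordinary codes mimic a diagnosis/medication/procedure mix ("D###",
    "M###", "P###"); a fixed subset of them act as precursors whose
    occurrence count raises the log-odds of future disease onset.  Target
    codes are the eight reserved C25.x codes and never appear in a
    patient's input window.
    """

    vocab_size: int = 200
    n_target_codes: int = 8
    n_precursor_codes: int = 10
    n_patients: int = 2000
    visits_per_patient_range: tuple[int, int] = (2, 10)
    codes_per_visit_range: tuple[int, int] = (2, 8)
    base_risk: float = 0.4
    precursor_effect: float = 0.5
    case_fraction_target: float | None = 0.4
    zipf_exponent: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vocab_size < 1:
            raise ConfigurationError("vocab_size must be positive")
        if self.n_target_codes < 1 or self.n_target_codes > len(TARGET_CODES):
            raise ConfigurationError(
                f"n_target_codes must be in [1, {len(TARGET_CODES)}]"
            )
        if not 0 < self.n_precursor_codes <= self.vocab_size:
            raise ConfigurationError("n_precursor_codes must be in [1, vocab_size]")
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be positive")
        self.visits_per_patient_range = _check_range_pair(
            "visits_per_patient_range", self.visits_per_patient_range
        )
        self.codes_per_visit_range = _check_range_pair(
            "codes_per_visit_range", self.codes_per_visit_range
        )
        if not 0.0 <= self.base_risk <= 1.0:
            raise ConfigurationError("base_risk must be a probability")
        if self.precursor_effect < 0:
            raise ConfigurationError("precursor_effect must be non-negative")
        if self.case_fraction_target is not None and not (
            0.0 < self.case_fraction_target < 1.0
        ):
            raise ConfigurationError("case_fraction_target must be in (0, 1)")


@dataclass
class EncoderConfig:
    """Architecture of the BERT-style visit encoder (desk-scale defaults)."""

    embedding_dim: int = 32
    n_layers: int = 2
    n_heads: int = 2
    feedforward_dim: int = 64
    max_visits: int = 32
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("embedding_dim", "n_layers", "n_heads", "feedforward_dim", "max_visits"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.embedding_dim % self.n_heads != 0:
            raise ConfigurationError("embedding_dim must be divisible by n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")


@dataclass
class CorruptionConfig:
    """Masked-code corruption scheme: of the selected positions, 80% become
    [MASK], 10% a random code, 10% stay unchanged."""

    select_rate: float = 0.15
    p_mask: float = 0.80
    p_random: float = 0.10
    p_keep: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.select_rate <= 1.0:
            raise ConfigurationError("select_rate must be in (0, 1]")
        for name in ("p_mask", "p_random", "p_keep"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be a probability")
        if abs(self.p_mask + self.p_random + self.p_keep - 1.0) > 1e-9:
            raise ConfigurationError("p_mask + p_random + p_keep must equal 1")


BASELINE_KINDS = ("lr", "gru", "bigru", "lstm", "bilstm")


@dataclass
class BaselineConfig:
    """From-scratch comparison models.

    Bidirectional recurrent models use a much smaller learning rate (1e-5)
    than the unidirectional ones (1e-3), matching the benchmark protocol.
    """

    model_kind: str = "lr"
    embedding_dim: int = 32
    hidden_dim: int = 32
    learning_rate: float | None = None
    batch_size: int = 100
    max_epochs: int = 50
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.model_kind = self.model_kind.lower()
        if self.model_kind not in BASELINE_KINDS:
            raise ConfigurationError(
                f"model_kind must be one of {BASELINE_KINDS}, got {self.model_kind!r}"
            )
        if self.learning_rate is None:
            self.learning_rate = 1e-5 if self.model_kind in ("bigru", "bilstm") else 1e-3
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")


@dataclass
class FinetuneConfig:
    """Supervised fine-tuning schedule for the encoder heads."""

    learning_rate: float = 1e-3
    batch_size: int = 100
    max_epochs: int = 50
    patience: int = 5
    loss_policy: str = "per_token"  # or "max"
    freeze_label_tensor: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.loss_policy not in ("per_token", "max"):
            raise ConfigurationError("loss_policy must be 'per_token' or 'max'")


@dataclass
class SplitSpec:
    """7:1:2 train/validation/test split.

    Validation and test sizes are floored; the remainder goes to train,
    which reproduces the published split sizes exactly.
    """

    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.ratios) != 3 or abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ConfigurationError("ratios must be three numbers summing to 1")


SAMPLING_POLICIES = ("balanced_both", "balanced_train_full_val", "ehrshot_ladder")


@dataclass
class SamplingPolicy:
    """Few-shot sampling regime applied to the train/validation splits."""

    policy_kind: str = "balanced_both"
    size_ladder: tuple[int, ...] = (10, 20, 50, 100, 200, 500, 1000)

    def __post_init__(self) -> None:
        if self.policy_kind not in SAMPLING_POLICIES:
            raise ConfigurationError(
                f"policy_kind must be one of {SAMPLING_POLICIES}, got {self.policy_kind!r}"
            )
        if any(s < 2 for s in self.size_ladder):
            raise ConfigurationError("sample sizes must be >= 2")


#: Full benchmark ladder of fine-tuning sample sizes.
FULL_SIZE_LADDER: tuple[int, ...] = (
    10, 20, 30, 40, 50, 100, 200, 300, 400, 500,
    1000, 2000, 3000, 4000, 5000, 10000,
)

#: Trimmed desk-scale ladder used by default.
DESK_SIZE_LADDER: tuple[int, ...] = (10, 20, 50, 100, 200, 500, 1000)


def config_to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)


def config_hash(*configs) -> str:
    """Stable hash of one or more configs (canonical JSON, sha256)."""
    payload = json.dumps(
        [dataclasses.asdict(c) if dataclasses.is_dataclass(c) else c for c in configs],
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
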