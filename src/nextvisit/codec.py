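"""Mapping patient records to fixed-length token sequences.

The codec owns the closed vocabulary (PAD=0, MASK=1, codes from 2 in
lexicographic order), the 64-token retention rule (keep the most recent
codes, feed them chronologically), and the next-visit [MASK] insertion used
by the masked-token-prediction head: one MASK token appended with a visit
ordinal one past the last observed visit, standing for the first future
visit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cohort import PatientRecord
from .config import TARGET_CODES
from .errors import CensoringError, VocabularyError

__all__ = [
    "PAD_ID",
    "MASK_ID",
    "Vocabulary",
    "TokenizedPatient",
    "build_vocabulary",
    "encode_patient",
    "encode_cohort",
    "extract_target_multi_hot",
    "batch_tokenized",
]

PAD_ID = 0
MASK_ID = 1
PAD_TOKEN = "[PAD]"
MASK_TOKEN = "[MASK]"


@dataclass
class Vocabulary:
    """Closed code vocabulary with reserved PAD/MASK ids and the target ids."""

    code_to_id: dict[str, int]
    target_codes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.id_to_code = {i: c for c, i in self.code_to_id.items()}
        missing = [c for c in self.target_codes if c not in self.code_to_id]
        if missing:
            raise VocabularyError(f"target codes missing from vocabulary: {missing}")
        self.target_ids = np.array([self.code_to_id[c] for c in self.target_codes])

    @property
    def size(self) -> int:
        return len(self.code_to_id) + 2  # + PAD, MASK

    @property
    def code_ids(self) -> np.ndarray:
        """Ids of ordinary (non-special) codes, ascending."""
        return np.arange(2, self.size)

    def __getitem__(self, code: str) -> int:
        try:
            return self.code_to_id[code]
        except KeyError:
            raise VocabularyError(f"unknown code {code!r}") from None

    def decode(self, token_id: int) -> str:
        if token_id == PAD_ID:
            return PAD_TOKEN
        if token_id == MASK_ID:
            return MASK_TOKEN
        try:
            return self.id_to_code[token_id]
        except KeyError:
            raise VocabularyError(f"unknown token id {token_id}") from None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"code_to_id": self.code_to_id, "target_codes": list(self.target_codes)},
                indent=1,
                sort_keys=True,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        obj = json.loads(Path(path).read_text())
        return cls(
            code_to_id={k: int(v) for k, v in obj["code_to_id"].items()},
            target_codes=tuple(obj["target_codes"]),
        )


def build_vocabulary(
    cohort: list[PatientRecord],
    target_codes: tuple[str, ...] = TARGET_CODES,
) -> Vocabulary:
    """Assign contiguous ids (lexicographic) to every code seen in the cohort,
    registering the target codes even if absent."""
    if not target_codes:
        raise VocabularyError("target_codes must be non-empty")
    if len(set(target_codes)) != len(target_codes):
        raise VocabularyError("duplicate target codes")
    seen: set[str] = set(target_codes)
    for record in cohort:
        for visit in record.visits:
            seen.update(visit)
    code_to_id = {code: i + 2 for i, code in enumerate(sorted(seen))}
    return Vocabulary(code_to_id=code_to_id, target_codes=tuple(target_codes))


@dataclass
class TokenizedPatient:
    """Fixed-length token view of one patient.

    All arrays have length ``max_len``; ``attention_mask`` marks real tokens,
    ``visit_ids`` carry 1-based source-visit ordinals (0 at PAD positions),
    and ``mask_position`` is set only when a next-visit MASK was appended.
    """

    patient_id: str
    token_ids: np.ndarray
    visit_ids: np.ndarray
    attention_mask: np.ndarray
    label: int
    target_multi_hot: np.ndarray
    mask_position: int | None = None

    @property
    def n_tokens(self) -> int:
        return int(self.attention_mask.sum())


def extract_target_multi_hot(record: PatientRecord, vocab: Vocabulary) -> np.ndarray:
    """Multi-hot over the target codes: 1 at the onset code's slot for cases,
    all-zero for controls."""
    out = np.zeros(len(vocab.target_codes), dtype=np.int64)
    if record.label:
        if record.onset_target_code not in vocab.target_codes:
            raise VocabularyError(
                f"onset code {record.onset_target_code!r} is not a target code"
            )
        out[vocab.target_codes.index(record.onset_target_code)] = 1
    return out


def encode_patient(
    record: PatientRecord,
    vocab: Vocabulary,
    max_len: int = 64,
    add_next_visit_mask: bool = False,
    censor: bool = True,
) -> TokenizedPatient:
    """Tokenize one patient.

    Retains the most recent ``max_len`` codes (one slot reserved for the
    appended MASK when requested) and presents them chronologically.  With
    ``censor=True`` (every supervised use) only the input window before the
    index date is encoded and any target code in it is a contract violation;
    ``censor=False`` encodes the full trajectory, the mode used to build the
    unsupervised pretraining corpus.
    """
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    visits = record.input_visits if censor else record.visits
    targets = set(vocab.target_codes)

    flat_ids: list[int] = []
    flat_visits: list[int] = []
    for ordinal, visit in enumerate(visits, start=1):
        for code in visit:
            if censor and code in targets:
                raise CensoringError(
                    f"{record.patient_id}: target code {code!r} in input window"
                )
            flat_ids.append(vocab[code])
            flat_visits.append(ordinal)

    budget = max_len - 1 if add_next_visit_mask else max_len
    flat_ids = flat_ids[-budget:]
    flat_visits = flat_visits[-budget:]
    if not flat_ids:
        raise ValueError(f"{record.patient_id}: no codes retained after truncation")

    mask_position = None
    if add_next_visit_mask:
        mask_position = len(flat_ids)
        flat_ids.append(MASK_ID)
        flat_visits.append(flat_visits[-1] + 1)

    n = len(flat_ids)
    token_ids = np.full(max_len, PAD_ID, dtype=np.int64)
    visit_ids = np.zeros(max_len, dtype=np.int64)
    attention = np.zeros(max_len, dtype=np.int64)
    token_ids[:n] = flat_ids
    visit_ids[:n] = flat_visits
    attention[:n] = 1

    return TokenizedPatient(
        patient_id=record.patient_id,
        token_ids=token_ids,
        visit_ids=visit_ids,
        attention_mask=attention,
        label=record.label,
        target_multi_hot=extract_target_multi_hot(record, vocab),
        mask_position=mask_position,
    )


def encode_cohort(
    cohort: list[PatientRecord],
    vocab: Vocabulary,
    max_len: int = 64,
    add_next_visit_mask: bool = False,
    censor: bool = True,
) -> list[TokenizedPatient]:
    return [
        encode_patient(r, vocab, max_len=max_len, add_next_visit_mask=add_next_visit_mask, censor=censor)
        for r in cohort
    ]


def batch_tokenized(items: list[TokenizedPatient]) -> dict[str, np.ndarray]:
    """Stack tokenized patients into dense batch arrays.

    ``mask_positions`` is -1 where no next-visit MASK was appended.
    """
    return {
        "token_ids": np.stack([t.token_ids for t in items]),
        "visit_ids": np.stack([t.visit_ids for t in items]),
        "attention_mask": np.stack([t.attention_mask for t in items]),
        "labels": np.array([t.label for t in items], dtype=np.int64),
        "target_multi_hot": np.stack([t.target_multi_hot for t in items]),
        "mask_positions": np.array(
            [-1 if t.mask_position is None else t.mask_position for t in items],
            dtype=np.int64,
        ),
    }
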