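"""Synthetic coded-visit cohorts.

Patients are ordered sequences of visits; each visit is a small set of
clinical codes drawn from a fixed vocabulary with a Zipf-like frequency
profile.  A designated subset of ordinary codes act as *precursors*: a
patient's latent onset risk is logistic in the number of precursor-code
occurrences across their visits, giving downstream classifiers a tunable
signal.  Cases receive exactly one target (C25.x) code in a dedicated final
onset visit which is excluded from the model input window, so inputs are
always censored at the index date.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .config import TARGET_CODES, GeneratorConfig
from .errors import ConfigurationError, SchemaError

__all__ = [
    "PatientRecord",
    "CohortSummary",
    "generate_cohort",
    "cohort_summary",
    "read_cohort",
    "write_cohort",
    "ordinary_code_names",
    "precursor_codes",
]


@dataclass
class PatientRecord:
    """One patient's ordered visits of codes plus the onset label.

    ``visits`` includes the onset visit for cases; ``index_visit`` is the
    index of the last visit that may be used as model input, so the input
    window ``visits[: index_visit + 1]`` never contains a target code.
    """

    patient_id: str
    visits: list[list[str]]
    label: int
    onset_target_code: str | None = None
    index_visit: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.index_visit == -1:
            self.index_visit = len(self.visits) - (2 if self.label else 1)
        self.validate()

    @property
    def input_visits(self) -> list[list[str]]:
        return self.visits[: self.index_visit + 1]

    def validate(self) -> None:
        if not self.visits or any(len(v) == 0 for v in self.visits):
            raise SchemaError(f"{self.patient_id}: every patient needs non-empty visits")
        if self.label not in (0, 1):
            raise SchemaError(f"{self.patient_id}: label must be 0 or 1")
        if self.label == 1:
            if self.onset_target_code not in TARGET_CODES:
                raise SchemaError(
                    f"{self.patient_id}: case without a valid onset target code"
                )
        elif self.onset_target_code is not None:
            raise SchemaError(f"{self.patient_id}: control with an onset target code")
        if not 0 <= self.index_visit < len(self.visits):
            raise SchemaError(f"{self.patient_id}: index_visit out of range")
        targets = set(TARGET_CODES)
        for visit in self.input_visits:
            bad = targets.intersection(visit)
            if bad:
                raise SchemaError(
                    f"{self.patient_id}: target code {sorted(bad)} inside the "
                    "censored input window"
                )


@dataclass
class CohortSummary:
    n_patients: int
    n_cases: int
    n_controls: int
    code_frequency: dict[str, int]

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_patients


def ordinary_code_names(vocab_size: int) -> list[str]:
    """Readable ordinary codes cycling a diagnosis/medication/procedure mix."""
    return [f"{'DMP'[i % 3]}{i:03d}" for i in range(vocab_size)]


def _frequency_weights(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    ranks = rng.permutation(config.vocab_size)
    w = 1.0 / np.power(np.argsort(ranks) + 1.0, config.zipf_exponent)
    return w / w.sum()


def precursor_codes(config: GeneratorConfig) -> list[str]:
    """The precursor subset for a config (deterministic given the seed).

    Precursors are taken from moderately common frequency ranks so that they
    occur often enough to carry signal without dominating every visit.
    """
    rng = np.random.default_rng(config.seed)
    codes = ordinary_code_names(config.vocab_size)
    weights = _frequency_weights(config, rng)
    order = np.argsort(-weights)
    start = min(5, max(0, config.vocab_size - config.n_precursor_codes))
    chosen = order[start : start + config.n_precursor_codes]
    if len(chosen) < config.n_precursor_codes:
        chosen = order[: config.n_precursor_codes]
    return [codes[i] for i in chosen]


def generate_cohort(config: GeneratorConfig) -> list[PatientRecord]:
    """Draw a synthetic cohort; deterministic given ``config.seed``.

    The intercept of the logistic risk model is calibrated by root finding so
    the expected case fraction matches ``case_fraction_target`` for the drawn
    exposure counts; with ``precursor_effect=0`` this makes the realized
    prevalence a plain binomial around the target.
    """
    rng = np.random.default_rng(config.seed)
    codes = np.array(ordinary_code_names(config.vocab_size))
    weights = _frequency_weights(config, rng)
    precursors = set(precursor_codes(config))
    targets = list(TARGET_CODES[: config.n_target_codes])

    lo_v, hi_v = config.visits_per_patient_range
    lo_c, hi_c = config.codes_per_visit_range

    all_visits: list[list[list[str]]] = []
    exposure = np.zeros(config.n_patients)
    for i in range(config.n_patients):
        n_visits = int(rng.integers(lo_v, hi_v + 1))
        visits = []
        count = 0
        for _ in range(n_visits):
            n_codes = int(rng.integers(lo_c, hi_c + 1))
            drawn = rng.choice(codes, size=n_codes, p=weights)
            visit = [str(c) for c in drawn]
            count += sum(1 for c in visit if c in precursors)
            visits.append(visit)
        all_visits.append(visits)
        exposure[i] = count

    intercept = _calibrate_intercept(config, exposure)
    risk = expit(intercept + config.precursor_effect * exposure)
    labels = (rng.random(config.n_patients) < risk).astype(int)
    onset_choice = rng.integers(0, len(targets), size=config.n_patients)

    cohort: list[PatientRecord] = []
    for i in range(config.n_patients):
        visits = all_visits[i]
        onset = None
        if labels[i]:
            onset = targets[onset_choice[i]]
            visits = visits + [[onset]]
        cohort.append(
            PatientRecord(
                patient_id=f"pt-{i:06d}",
                visits=visits,
                label=int(labels[i]),
                onset_target_code=onset,
            )
        )
    return cohort


def _calibrate_intercept(config: GeneratorConfig, exposure: np.ndarray) -> float:
    base = logit(np.clip(config.base_risk, 1e-9, 1 - 1e-9))
    if config.case_fraction_target is None:
        return float(base)
    target = config.case_fraction_target

    def gap(b: float) -> float:
        return expit(b + config.precursor_effect * exposure).mean() - target

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:  # pragma: no cover - unreachable for valid targets
        raise ConfigurationError("cannot calibrate base risk to case_fraction_target")
    return float(brentq(gap, lo, hi, xtol=1e-10))


def cohort_summary(cohort: list[PatientRecord]) -> CohortSummary:
    """Counts and a code-frequency table over all visits (onset included)."""
    if not cohort:
        raise ValueError("cannot summarize an empty cohort")
    n_cases = sum(r.label for r in cohort)
    freq: Counter[str] = Counter()
    for record in cohort:
        for visit in record.visits:
            freq.update(visit)
    return CohortSummary(
        n_patients=len(cohort),
        n_cases=n_cases,
        n_controls=len(cohort) - n_cases,
        code_frequency=dict(sorted(freq.items())),
    )


# -- JSONL serialization -----------------------------------------------------

_REQUIRED_KEYS = ("patient_id", "visits", "label", "onset_target_code")


def write_cohort(cohort: list[PatientRecord], path: str | Path) -> None:
    """Serialize one patient per line as UTF-8 JSON with canonical key order."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for record in cohort:
            obj = {
                "patient_id": record.patient_id,
                "visits": record.visits,
                "label": record.label,
                "onset_target_code": record.onset_target_code,
            }
            fh.write(json.dumps(obj, separators=(",", ":")) + "\n")


def read_cohort(path: str | Path) -> list[PatientRecord]:
    path = Path(path)
    cohort: list[PatientRecord] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            missing = [k for k in _REQUIRED_KEYS if k not in obj]
            if missing:
                raise SchemaError(f"{path}:{lineno}: missing keys {missing}")
            try:
                cohort.append(
                    PatientRecord(
                        patient_id=str(obj["patient_id"]),
                        visits=[[str(c) for c in v] for v in obj["visits"]],
                        label=int(obj["label"]),
                        onset_target_code=obj["onset_target_code"],
                    )
                )
            except (SchemaError, TypeError, ValueError) as exc:
                raise SchemaError(f"{path}:{lineno}: {exc}") from exc
    return cohort
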