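"""Chronological token sequences with paired covariate channels.

Raw coded event streams become model-ready sequences in four steps: raw codes
are mapped to a controlled vocabulary (ICD-10 three-character categories for
diagnoses and symptoms, medication groups for prescriptions, abnormality
tokens for lab results); continuous monthly prescriptions are de-duplicated so
refill streams do not dominate the sequence; a vocabulary is built with rare
tokens pruned by distinct-patient count; and each patient's events are encoded
as parallel channels of token id, age in completed years, calendar year and
visit number (a counter over pooled one-month intervals).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ehrclust.synthetic import (
    DEFAULT_CONDITION_CODES,
    DEFAULT_LAB_LINKS,
    DEFAULT_MEDICATION_LINKS,
    PatientRecord,
)

PAD, UNK, CLS, SEP, MASK = "[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]"
SPECIAL_TOKENS = (PAD, UNK, CLS, SEP, MASK)


class ContractError(ValueError):
    """A precondition on the event stream was violated."""


@dataclass(frozen=True)
class MappedEvent:
    """An event whose raw code has been mapped to a vocabulary token."""

    date: _dt.date
    token: str
    source: str
    monthly: bool = False  # monthly-refill medication group?


@dataclass
class CodeMap:
    """Raw-code to token mappings for the three event modalities.

    ``medication_map`` maps a product code to ``(group, monthly)``; the
    monthly flag marks groups prescribed on a continuous monthly cadence,
    which are subject to refill de-duplication.  Raw codes absent from every
    map are unmappable and dropped.
    """

    diagnosis_map: Mapping[str, str] = field(default_factory=dict)
    medication_map: Mapping[str, tuple[str, bool]] = field(default_factory=dict)
    lab_map: Mapping[str, str] = field(default_factory=dict)


def default_codemap() -> CodeMap:
    """Code map matching the synthetic generator's default code universe."""
    diag = {code: code for code in DEFAULT_CONDITION_CODES.values()}
    diag["Z00"] = "Z00"  # general examination / review
    med = {
        group: (group, cadence == "monthly")
        for group, cadence in DEFAULT_MEDICATION_LINKS.values()
    }
    lab = {tok: tok for tok in DEFAULT_LAB_LINKS.values()}
    return CodeMap(diagnosis_map=diag, medication_map=med, lab_map=lab)


def map_events(record: PatientRecord, codemap: CodeMap) -> list[MappedEvent]:
    """Map a record's raw events to vocabulary tokens, dropping unmappables."""
    out: list[MappedEvent] = []
    for ev in record.events:
        if ev.source in ("diagnosis", "symptom"):
            tok = codemap.diagnosis_map.get(ev.code)
            if tok is not None:
                out.append(MappedEvent(ev.date, tok, ev.source))
        elif ev.source == "medication":
            hit = codemap.medication_map.get(ev.code)
            if hit is not None:
                group, monthly = hit
                out.append(MappedEvent(ev.date, group, "medication", monthly=bool(monthly)))
        elif ev.source == "lab":
            tok = codemap.lab_map.get(ev.code)
            if tok is not None:
                out.append(MappedEvent(ev.date, tok, "lab"))
    return out


def dedup_medications(events: Sequence[MappedEvent], gap_months: int = 6) -> list[MappedEvent]:
    """Suppress continuous monthly refills, keeping only stream starts.

    For each monthly-cadence medication group the first prescription is kept;
    later prescriptions of the same group are suppressed until a gap of at
    least ``gap_months`` (6 months = 183 days) separates consecutive raw
    prescriptions, after which the next prescription is kept and the rule
    restarts.  Non-monthly medications and non-medication events pass through
    untouched.  Requires chronological input.
    """
    dates = [e.date for e in events]
    if any(b < a for a, b in zip(dates, dates[1:])):
        raise ContractError("dedup_medications requires chronologically sorted events")
    gap_days = int(gap_months * 30.5)  # 6 months -> 183 days
    last_seen: dict[str, _dt.date] = {}
    out: list[MappedEvent] = []
    for ev in events:
        if ev.source == "medication" and ev.monthly:
            prev = last_seen.get(ev.token)
            keep = prev is None or (ev.date - prev).days >= gap_days
            last_seen[ev.token] = ev.date
            if keep:
                out.append(ev)
        else:
            out.append(ev)
    return out


@dataclass
class Vocabulary:
    """Token/index bijection with distinct-patient counts.

    Non-special tokens seen in fewer than ``min_patient_count`` distinct
    patients are pruned (default 100); special tokens are never pruned.
    Indices are deterministic: special tokens first, then surviving tokens in
    lexicographic order.
    """

    token_to_id: dict[str, int]
    patient_counts: dict[str, int]
    min_patient_count: int = 100

    def __post_init__(self) -> None:
        self.id_to_token = {i: t for t, i in self.token_to_id.items()}
        if len(self.id_to_token) != len(self.token_to_id):
            raise ValueError("token_to_id must be a bijection")

    def __len__(self) -> int:
        return len(self.token_to_id)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    @property
    def cls_id(self) -> int:
        return self.token_to_id[CLS]

    @property
    def mask_id(self) -> int:
        return self.token_to_id[MASK]

    @property
    def special_ids(self) -> frozenset[int]:
        return frozenset(self.token_to_id[t] for t in SPECIAL_TOKENS)

    def encode(self, token: str) -> int:
        return self.token_to_id.get(token, self.unk_id)

    def nonspecial_tokens(self) -> list[str]:
        return [t for t in self.token_to_id if t not in SPECIAL_TOKENS]


def build_vocabulary(
    events_by_patient: Mapping[str, Sequence[MappedEvent]],
    min_patient_count: int = 100,
) -> Vocabulary:
    """Build the vocabulary from a full cohort's mapped events.

    Counts are per distinct patient, not per event: a token occurring 500
    times in one patient contributes one to its count.
    """
    counts: dict[str, int] = {}
    for _, events in events_by_patient.items():
        for tok in {e.token for e in events}:
            counts[tok] = counts.get(tok, 0) + 1
    kept = sorted(t for t, c in counts.items() if c >= min_patient_count)
    token_to_id = {t: i for i, t in enumerate(SPECIAL_TOKENS)}
    for t in kept:
        token_to_id[t] = len(token_to_id)
    return Vocabulary(
        token_to_id=token_to_id,
        patient_counts={t: counts.get(t, 0) for t in token_to_id},
        min_patient_count=min_patient_count,
    )


def assign_visits(events: Sequence[MappedEvent]) -> list[int]:
    """Visit numbers from pooled one-month intervals.

    Events in the same calendar month share a visit number; the counter
    starts at 1 and increments at each new occupied month.
    """
    visits: list[int] = []
    counter = 0
    prev_key: tuple[int, int] | None = None
    for ev in events:
        key = (ev.date.year, ev.date.month)
        if key != prev_key:
            counter += 1
            prev_key = key
        visits.append(counter)
    return visits


@dataclass
class TokenSequence:
    """One patient's encoder input: token ids plus parallel covariate channels."""

    patient_id: str
    gender: str
    token_ids: list[int]
    age_years: list[int]
    calendar_year: list[int]
    visit_number: list[int]

    def __post_init__(self) -> None:
        n = len(self.token_ids)
        if not (len(self.age_years) == len(self.calendar_year) == len(self.visit_number) == n):
            raise ValueError("all channels must have equal length")
        if any(b < a for a, b in zip(self.age_years, self.age_years[1:])):
            raise ValueError("age channel must be nondecreasing")
        if self.visit_number:
            if self.visit_number[0] != 1:
                raise ValueError("visit numbers must start at 1")
            if any(b < a for a, b in zip(self.visit_number, self.visit_number[1:])):
                raise ValueError("visit numbers must be nondecreasing")

    def __len__(self) -> int:
        return len(self.token_ids)

    @property
    def is_empty(self) -> bool:
        return len(self.token_ids) == 0


def build_sequence(
    record: PatientRecord,
    events: Sequence[MappedEvent],
    vocab: Vocabulary,
    max_len: int = 64,
) -> TokenSequence:
    """Encode mapped, de-duplicated events as a TokenSequence.

    Out-of-vocabulary tokens become UNK.  Sequences longer than ``max_len``
    keep the most recent ``max_len`` events (the clustering targets the
    current phenotype); visit numbers are re-based to start at 1 after
    truncation.  An empty result is flagged ineligible downstream via
    :attr:`TokenSequence.is_empty`.
    """
    visits = assign_visits(events)
    if len(events) > max_len:
        events = events[-max_len:]
        visits = visits[-max_len:]
    token_ids = [vocab.encode(e.token) for e in events]
    ages = [min(max(record.age_at(e.date), 0), 110) for e in events]
    years = [e.date.year for e in events]
    if visits:
        base = visits[0] - 1
        visits = [v - base for v in visits]
    return TokenSequence(
        patient_id=record.patient_id,
        gender=record.gender,
        token_ids=token_ids,
        age_years=ages,
        calendar_year=years,
        visit_number=visits,
    )


def prepare_sequences(
    records: Iterable[PatientRecord],
    codemap: CodeMap | None = None,
    min_patient_count: int = 100,
    max_len: int = 64,
    gap_months: int = 6,
    vocab: Vocabulary | None = None,
) -> tuple[list[TokenSequence], Vocabulary]:
    """Full pipeline: map, de-duplicate, build vocabulary, encode.

    Pass an existing ``vocab`` to re-encode new records (e.g. age-spliced
    histories) against a previously built vocabulary.
    """
    codemap = codemap if codemap is not None else default_codemap()
    records = list(records)
    mapped = {
        r.patient_id: dedup_medications(map_events(r, codemap), gap_months=gap_months)
        for r in records
    }
    if vocab is None:
        vocab = build_vocabulary(mapped, min_patient_count=min_patient_count)
    seqs = [build_sequence(r, mapped[r.patient_id], vocab, max_len=max_len) for r in records]
    return seqs, vocab


# ---------------------------------------------------------------------------
# Plain-text I/O


def write_sequences(seqs: Sequence[TokenSequence], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "patient_id": s.patient_id,
            "gender": s.gender,
            "token_ids": " ".join(map(str, s.token_ids)),
            "age_years": " ".join(map(str, s.age_years)),
            "calendar_year": " ".join(map(str, s.calendar_year)),
            "visit_number": " ".join(map(str, s.visit_number)),
        }
        for s in seqs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_sequences(path: str | Path) -> list[TokenSequence]:
    df = pd.read_csv(Path(path), keep_default_na=False)

    def ints(cell: str) -> list[int]:
        return [int(x) for x in str(cell).split()] if str(cell).strip() else []

    return [
        TokenSequence(
            patient_id=str(row.patient_id),
            gender=row.gender,
            token_ids=ints(row.token_ids),
            age_years=ints(row.age_years),
            calendar_year=ints(row.calendar_year),
            visit_number=ints(row.visit_number),
        )
        for row in df.itertuples(index=False)
    ]


def write_vocabulary(vocab: Vocabulary, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"token": t, "index": i, "patient_count": vocab.patient_counts.get(t, 0)}
        for t, i in vocab.token_to_id.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_vocabulary(path: str | Path, min_patient_count: int = 100) -> Vocabulary:
    df = pd.read_csv(Path(path), keep_default_na=False)
    token_to_id = {str(r.token): int(r.index) for r in df.itertuples(index=False)}
    counts = {str(r.token): int(r.patient_count) for r in df.itertuples(index=False)}
    return Vocabulary(token_to_id, counts, min_patient_count=min_patient_count)
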