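"""Sequence construction: mapping, refill de-duplication, vocabulary, visits."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehrclust.sequences import (
    CodeMap,
    ContractError,
    MappedEvent,
    Vocabulary,
    assign_visits,
    build_sequence,
    build_vocabulary,
    dedup_medications,
    default_codemap,
    map_events,
    prepare_sequences,
    read_sequences,
    write_sequences,
    SPECIAL_TOKENS,
)
from ehrclust.synthetic import ClinicalEvent, PatientRecord


def record_with(events, yob=1950, gender="female"):
    return PatientRecord(
        patient_id="p1",
        gender=gender,
        year_of_birth=yob,
        registration_start=dt.date(1990, 1, 1),
        registration_end=dt.date(2022, 12, 31),
        events=events,
    )


def med(day, token="statins", monthly=True):
    return MappedEvent(day, token, "medication", monthly=monthly)


class TestMapEvents:
    CODEMAP = CodeMap(
        diagnosis_map={"raw_htn": "I10", "raw_dm": "E11", "raw_mi": "I21"},
        medication_map={"raw_statin": ("statins", True)},
        lab_map={"raw_hba1c": "LAB_HBA1C_ABN"},
    )

    def test_unmapped_codes_are_dropped(self):
        rec = record_with([ClinicalEvent(dt.date(2020, 1, 1), "NOPE", "diagnosis")])
        assert map_events(rec, self.CODEMAP) == []

    def test_empty_events_give_empty_output(self):
        assert map_events(record_with([]), self.CODEMAP) == []

    def test_mappable_events_keep_original_order(self):
        days = [dt.date(2020, 1, d) for d in range(1, 6)]
        rec = record_with(
            [
                ClinicalEvent(days[0], "raw_htn", "diagnosis"),
                ClinicalEvent(days[1], "junk1", "diagnosis"),
                ClinicalEvent(days[2], "raw_dm", "diagnosis"),
                ClinicalEvent(days[3], "junk2", "lab"),
                ClinicalEvent(days[4], "raw_mi", "diagnosis"),
            ]
        )
        out = map_events(rec, self.CODEMAP)
        assert [e.token for e in out] == ["I10", "E11", "I21"]
        assert [e.date for e in out] == [days[0], days[2], days[4]]

    def test_medication_carries_cadence_flag(self):
        rec = record_with([ClinicalEvent(dt.date(2020, 1, 1), "raw_statin", "medication")])
        out = map_events(rec, self.CODEMAP)
        assert out[0].monthly is True


class TestDedupMedications:
    def test_continuous_monthly_stream_keeps_only_first(self):
        events = [
            med(dt.date(2015, 1, 5)),
            med(dt.date(2015, 2, 3)),
            med(dt.date(2015, 3, 2)),
        ]
        out = dedup_medications(events)
        assert [e.date for e in out] == [dt.date(2015, 1, 5)]

    def test_six_month_gap_restarts_the_stream(self):
        events = [
            med(dt.date(2015, 1, 5)),
            med(dt.date(2015, 2, 3)),
            med(dt.date(2015, 11, 10)),
        ]
        out = dedup_medications(events)
        assert [e.date for e in out] == [dt.date(2015, 1, 5), dt.date(2015, 11, 10)]

    def test_non_monthly_medications_kept_in_full(self):
        events = [
            med(dt.date(2015, m, 1), token="antibiotics", monthly=False) for m in range(1, 5)
        ]
        assert len(dedup_medications(events)) == 4

    def test_non_medication_events_untouched(self):
        events = [
            MappedEvent(dt.date(2015, m, 1), "I10", "diagnosis") for m in range(1, 4)
        ]
        assert dedup_medications(events) == events

    def test_unsorted_input_rejected(self):
        events = [med(dt.date(2015, 2, 1)), med(dt.date(2015, 1, 1))]
        with pytest.raises(ContractError):
            dedup_medications(events)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.integers(min_value=0, max_value=2000), min_size=0, max_size=30
        )
    )
    def test_idempotence_on_random_refill_streams(self, day_offsets):
        base = dt.date(2010, 1, 1)
        events = sorted(
            (med(base + dt.timedelta(days=d)) for d in day_offsets), key=lambda e: e.date
        )
        once = dedup_medications(events)
        assert dedup_medications(once) == once


class TestBuildVocabulary:
    @staticmethod
    def cohort_with_counts(counts):
        """counts: token -> number of distinct patients carrying it."""
        events = {}
        pid = 0
        n = max(counts.values(), default=0)
        for i in range(n):
            evs = [
                MappedEvent(dt.date(2020, 1, 1), tok, "diagnosis")
                for tok, c in counts.items()
                if i < c
            ]
            events[f"p{pid}"] = evs
            pid += 1
        return events

    def test_patient_count_threshold_boundary(self):
        events = self.cohort_with_counts({"A": 99, "B": 100})
        vocab = build_vocabulary(events, min_patient_count=100)
        assert "A" not in vocab and "B" in vocab

    def test_count_is_per_patient_not_per_event(self):
        events = {"p0": [MappedEvent(dt.date(2020, 1, 1), "A", "diagnosis")] * 500}
        vocab = build_vocabulary(events, min_patient_count=1)
        assert vocab.patient_counts["A"] == 1
        assert "A" not in build_vocabulary(events, min_patient_count=2)

    def test_counting_fixture(self):
        events = self.cohort_with_counts({"A": 150, "B": 100, "C": 99, "D": 3, "E": 1})
        vocab = build_vocabulary(events, min_patient_count=100)
        assert sorted(vocab.nonspecial_tokens()) == ["A", "B"]

    def test_empty_cohort_gives_specials_only(self):
        vocab = build_vocabulary({}, min_patient_count=100)
        assert len(vocab) == len(SPECIAL_TOKENS)

    def test_pruning_is_monotone_in_threshold(self):
        events = self.cohort_with_counts({"A": 10, "B": 5, "C": 2, "D": 1})
        sizes = [
            len(build_vocabulary(events, min_patient_count=t)) for t in (1, 2, 5, 10, 11)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestAssignVisits:
    def test_calendar_month_pooling(self):
        events = [
            MappedEvent(dt.date(2010, 1, 3), "A", "diagnosis"),
            MappedEvent(dt.date(2010, 1, 20), "B", "diagnosis"),
            MappedEvent(dt.date(2010, 3, 5), "C", "diagnosis"),
        ]
        assert assign_visits(events) == [1, 1, 2]

    def test_single_event_is_visit_one(self):
        assert assign_visits([MappedEvent(dt.date(2010, 1, 3), "A", "diagnosis")]) == [1]

    def test_twelve_distinct_months_count_to_twelve(self):
        events = [
            MappedEvent(dt.date(2010, m, 1), "A", "diagnosis") for m in range(1, 13)
        ]
        assert assign_visits(events) == list(range(1, 13))


class TestBuildSequence:
    @staticmethod
    def vocab_of(tokens):
        events = {f"p{i}": [MappedEvent(dt.date(2020, 1, 1), t, "diagnosis")] for t in tokens for i in [t]}
        return build_vocabulary(events, min_patient_count=1)

    def test_median_length_corpus_is_untruncated(self):
        vocab = self.vocab_of(["A"])
        events = [
            MappedEvent(dt.date(2000 + i // 2, 1 + i % 12, 1), "A", "diagnosis")
            for i in range(24)
        ]
        events.sort(key=lambda e: e.date)
        seq = build_sequence(record_with([]), events, vocab, max_len=64)
        assert len(seq) == 24

    def test_empty_sequence_flagged(self):
        vocab = self.vocab_of(["A"])
        seq = build_sequence(record_with([]), [], vocab)
        assert seq.is_empty

    def test_truncation_keeps_most_recent_and_ages_nondecreasing(self):
        vocab = self.vocab_of(["A"])
        events = [
            MappedEvent(dt.date(1990, 1, 1) + dt.timedelta(days=30 * i), "A", "diagnosis")
            for i in range(100)
        ]
        seq = build_sequence(record_with([]), events, vocab, max_len=64)
        assert len(seq) == 64
        assert seq.age_years == sorted(seq.age_years)
        # most recent events kept: last date's age present
        rec = record_with([])
        assert seq.age_years[-1] == rec.age_at(events[-1].date)
        assert seq.visit_number[0] == 1

    def test_out_of_vocabulary_becomes_unk(self):
        vocab = self.vocab_of(["A"])
        events = [MappedEvent(dt.date(2020, 1, 1), "ZZZ", "diagnosis")]
        seq = build_sequence(record_with([]), events, vocab)
        assert seq.token_ids == [vocab.unk_id]


class TestPipelineProperties:
    def test_no_sequence_exceeds_max_len_and_channels_aligned(self, small_cohort):
        records, _ = small_cohort
        seqs, _ = prepare_sequences(records, min_patient_count=2, max_len=32)
        for s in seqs:
            assert len(s) <= 32
            assert len(s.age_years) == len(s.calendar_year) == len(s.visit_number) == len(s)

    def test_sequences_roundtrip_through_csv(self, tmp_path, small_sequences):
        seqs, _ = small_sequences
        path = write_sequences(seqs[:20], tmp_path / "seqs.csv")
        back = read_sequences(path)
        assert len(back) == 20
        assert back[3].token_ids == seqs[3].token_ids
        assert back[3].gender == seqs[3].gender

    def test_default_codemap_covers_generator_codes(self, small_cohort):
        records, _ = small_cohort
        cm = default_codemap()
        mapped = [map_events(r, cm) for r in records]
        raw = sum(len(r.events) for r in records)
        kept = sum(len(m) for m in mapped)
        assert kept == raw  # every generated code is mappable
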