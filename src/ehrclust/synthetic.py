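"""Synthetic primary-care cohort generator with planted ground truth.

Real UK primary-care databases (e.g. CPRD GOLD) are access-restricted, so the
package ships a generator that emulates their shape: multi-decade coded event
streams per patient (diagnoses, monthly medication refills, lab-abnormality
codes), archetype-structured disease co-occurrence, enriched comorbidity
pairs, and realistic demographic marginals.  Every patient is drawn from one
archetype (hard assignment), which gives downstream clustering a recoverable
ground truth.

The default configuration (:func:`table1_config`) mirrors the marginals of a
large English primary-care cohort of adults aged 50+: 54.8% female, ethnicity
recorded for 37.7% of patients (93.4% White among recorded), IMD deprivation
linkage for 51.3% (22.6% in the least-deprived quintile), and five disease
archetypes per gender (low-burden, mental-health, cardiometabolic,
respiratory, mixed) with mixing weights matching the published cluster shares.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

EventSource = str  # one of {"diagnosis", "medication", "lab", "symptom"}

_SOURCES = ("diagnosis", "medication", "lab", "symptom")

#: Condition name -> ICD-10 three-character category used for its diagnosis code.
DEFAULT_CONDITION_CODES: dict[str, str] = {
    "addison_disease": "E27",
    "alcohol_misuse": "F10",
    "anxiety": "F41",
    "asthma": "J45",
    "atrial_fibrillation": "I48",
    "bipolar_disorder": "F31",
    "bronchiectasis": "J47",
    "cancer": "C80",
    "chronic_kidney_disease": "N18",
    "chronic_liver_disease": "K74",
    "congenital_disease": "Q89",
    "connective_tissue_disease": "M35",
    "copd": "J44",
    "dementia": "F03",
    "depression": "F32",
    "diabetes": "E11",
    "drug_misuse": "F19",
    "eating_disorder": "F50",
    "epilepsy": "G40",
    "gout": "M10",
    "hearing_impairment": "H91",
    "heart_failure": "I50",
    "hypertension": "I10",
    "ibd": "K51",
    "infectious_disease": "B99",
    "ischaemic_heart_disease": "I25",
    "melanoma": "C43",
    "menieres_disease": "H81",
    "multiple_sclerosis": "G35",
    "obesity": "E66",
    "osteoarthritis": "M19",
    "osteoporosis": "M81",
    "parkinsons_disease": "G20",
    "schizophrenia": "F20",
    "smoking": "F17",
    "stroke": "I63",
}

#: Condition -> (medication group, cadence) used by the default archetypes.
DEFAULT_MEDICATION_LINKS: dict[str, tuple[str, str]] = {
    "hypertension": ("ace_inhibitors", "monthly"),
    "diabetes": ("metformin", "monthly"),
    "ischaemic_heart_disease": ("statins", "monthly"),
    "depression": ("antidepressants", "monthly"),
    "anxiety": ("anxiolytics", "monthly"),
    "asthma": ("bronchodilators", "monthly"),
    "copd": ("inhaled_steroids", "monthly"),
    "schizophrenia": ("antipsychotics", "monthly"),
    "epilepsy": ("anticonvulsants", "monthly"),
    "gout": ("allopurinol", "monthly"),
    "osteoarthritis": ("nsaids", "adhoc"),
    "infectious_disease": ("antibiotics", "adhoc"),
}

#: Condition -> lab-abnormality token emitted alongside the diagnosis.
DEFAULT_LAB_LINKS: dict[str, str] = {
    "diabetes": "LAB_HBA1C_ABN",
    "chronic_kidney_disease": "LAB_EGFR_ABN",
    "chronic_liver_disease": "LAB_LFT_ABN",
    "gout": "LAB_URATE_ABN",
}


@dataclass(frozen=True)
class ClinicalEvent:
    """One dated coded event in a patient's record."""

    date: _dt.date
    code: str
    source: EventSource

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("event code must be non-empty")
        if self.source not in _SOURCES:
            raise ValueError(f"unknown event source {self.source!r}")


@dataclass
class PatientRecord:
    """Demographics plus an ordered stream of coded clinical events."""

    patient_id: str
    gender: str  # "female" | "male"
    year_of_birth: int
    registration_start: _dt.date
    registration_end: _dt.date
    events: list[ClinicalEvent] = field(default_factory=list)
    ethnicity: str | None = None  # None emulates an absent ethnicity record
    imd_quintile: int | None = None  # None emulates no deprivation linkage

    def __post_init__(self) -> None:
        if self.gender not in ("female", "male"):
            raise ValueError(f"gender must be 'female' or 'male', got {self.gender!r}")
        if self.imd_quintile is not None and not 1 <= self.imd_quintile <= 5:
            raise ValueError("imd_quintile must be in 1..5")
        dates = [e.date for e in self.events]
        if any(b < a for a, b in zip(dates, dates[1:])):
            raise ValueError("events must be sorted by date (nondecreasing)")

    @property
    def birth_date(self) -> _dt.date:
        # Mid-year convention: only the birth year is recorded.
        return _dt.date(self.year_of_birth, 7, 1)

    def age_at(self, when: _dt.date) -> int:
        """Completed years of age at ``when``."""
        born = self.birth_date
        return when.year - born.year - ((when.month, when.day) < (born.month, born.day))

    def age_at_last_event(self) -> int | None:
        if not self.events:
            return None
        return self.age_at(self.events[-1].date)


@dataclass
class ArchetypeSpec:
    """A disease archetype: per-condition prevalences and their consequences.

    ``condition_prevalence`` gives the marginal probability that a patient of
    this archetype develops each condition; ``medication_links`` maps a
    condition to its prescribed medication group and refill cadence
    ("monthly" refill streams or "adhoc" one-offs); ``age_at_onset`` holds
    (mean, sd) of a truncated-normal onset age per condition; ``weight`` is
    the archetype's mixing proportion within its gender stratum.
    """

    name: str
    condition_prevalence: Mapping[str, float]
    medication_links: Mapping[str, tuple[str, str]] = field(default_factory=dict)
    lab_links: Mapping[str, str] = field(default_factory=dict)
    age_at_onset: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    weight: float = 1.0

    def __post_init__(self) -> None:
        for cond, p in self.condition_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {cond!r} must be in [0, 1], got {p}")
        for cond, (_, cadence) in self.medication_links.items():
            if cadence not in ("monthly", "adhoc"):
                raise ValueError(f"cadence for {cond!r} must be 'monthly' or 'adhoc'")
        if self.weight < 0:
            raise ValueError("archetype weight must be >= 0")


@dataclass
class CohortConfig:
    """Full description of a synthetic cohort draw."""

    n_patients: int
    archetypes: Mapping[str, Sequence[ArchetypeSpec]]  # gender -> archetypes
    gender_split: float = 0.548  # proportion female
    ethnicity_recorded_prob: float = 0.377
    ethnicity_dist: Mapping[str, float] = field(
        default_factory=lambda: {
            "White": 0.934,
            "South Asian": 0.029,
            "Black": 0.020,
            "Mixed": 0.005,
            "Other": 0.012,
        }
    )
    imd_linked_prob: float = 0.513
    imd_dist: Sequence[float] = (0.226, 0.222, 0.211, 0.183, 0.158)
    comorbidity_pairs: Sequence[tuple[str, str, float]] = ()
    condition_codes: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_CODES)
    )
    start_year: int = 1980
    end_year: int = 2022
    min_age_at_end: int = 53  # ensures 50+ with >= 3 years registration
    max_age_at_end: int = 95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0.0 <= self.gender_split <= 1.0:
            raise ValueError("gender_split must be in [0, 1]")
        for _, _, mult in self.comorbidity_pairs:
            if mult <= 0:
                raise ValueError("comorbidity odds multipliers must be > 0")
        for gender, specs in self.archetypes.items():
            total = sum(a.weight for a in specs)
            if specs and not np.isclose(total, 1.0):
                raise ValueError(
                    f"archetype weights for {gender!r} must sum to 1 (got {total})"
                )


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    """Truncated-normal draw by rejection, falling back to uniform on [lo, hi]."""
    if hi <= lo:
        return lo
    for _ in range(64):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(rng.uniform(lo, hi))


def _condition_probability(
    base: float,
    condition: str,
    present: set[str],
    pairs: Sequence[tuple[str, str, float]],
) -> float:
    """Apply comorbidity-pair odds uplift given already-sampled conditions."""
    if base <= 0.0:
        return 0.0
    if base >= 1.0:
        return 1.0
    odds = base / (1.0 - base)
    for a, b, mult in pairs:
        if b == condition and a in present:
            odds *= mult
        elif a == condition and b in present:
            odds *= mult
    return odds / (1.0 + odds)


def _sample_patient_events(
    rng: np.random.Generator,
    archetype: ArchetypeSpec,
    config: CohortConfig,
    birth_year: int,
    reg_start: _dt.date,
    reg_end: _dt.date,
) -> list[ClinicalEvent]:
    events: list[tuple[_dt.date, str, str]] = []
    birth = _dt.date(birth_year, 7, 1)
    age_start = (reg_start - birth).days / 365.25
    age_end = (reg_end - birth).days / 365.25

    present: set[str] = set()
    # Deterministic iteration order: conditions sorted by name.
    for cond in sorted(archetype.condition_prevalence):
        base = archetype.condition_prevalence[cond]
        p = _condition_probability(base, cond, present, config.comorbidity_pairs)
        if rng.random() < p:
            present.add(cond)

    for cond in sorted(present):
        code = config.condition_codes.get(cond, cond)
        mean, sd = archetype.age_at_onset.get(cond, (62.0, 12.0))
        onset_age = _truncnorm(rng, mean, sd, age_start + 0.1, age_end)
        onset = birth + _dt.timedelta(days=int(onset_age * 365.25))
        onset = min(max(onset, reg_start), reg_end)
        events.append((onset, code, "diagnosis"))

        lab = archetype.lab_links.get(cond)
        if lab is not None:
            # Abnormal-result codes appear around diagnosis and at reviews.
            n_lab = 1 + rng.poisson(1.0)
            for _ in range(n_lab):
                d = onset + _dt.timedelta(days=int(rng.integers(0, 366)))
                if d <= reg_end:
                    events.append((d, lab, "lab"))

        link = archetype.medication_links.get(cond)
        if link is not None:
            group, cadence = link
            if cadence == "monthly":
                day = onset
                while day <= reg_end:
                    events.append((day, group, "medication"))
                    day = day + _dt.timedelta(days=int(30 + rng.integers(-3, 4)))
            else:
                n_rx = 1 + int(rng.poisson(1.5))
                span = max((reg_end - onset).days, 1)
                for _ in range(n_rx):
                    d = onset + _dt.timedelta(days=int(rng.integers(0, span)))
                    events.append((d, group, "medication"))

    # A final review visit near registration end keeps the record current,
    # so the age-50+ eligibility filter sees recent activity.
    review = reg_end - _dt.timedelta(days=int(rng.integers(0, 180)))
    if review >= reg_start:
        events.append((review, "Z00", "symptom"))

    events.sort(key=lambda t: (t[0], t[2], t[1]))
    return [ClinicalEvent(date=d, code=c, source=s) for d, c, s in events]


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Draw a synthetic cohort.

    Returns the patient records and a ground-truth table with one row per
    patient (``patient_id``, ``gender``, ``archetype``).  Reproducible:
    identical config and seed give a byte-identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    records: list[PatientRecord] = []
    truth_rows: list[dict] = []
    eth_names = sorted(config.ethnicity_dist)
    eth_probs = np.array([config.ethnicity_dist[k] for k in eth_names], dtype=float)
    eth_probs = eth_probs / eth_probs.sum()
    imd_probs = np.asarray(config.imd_dist, dtype=float)
    imd_probs = imd_probs / imd_probs.sum()
    end_date = _dt.date(config.end_year, 12, 31)

    for i in range(config.n_patients):
        pid = f"P{i:07d}"
        gender = "female" if rng.random() < config.gender_split else "male"
        specs = list(config.archetypes.get(gender, ()))
        if not specs:
            raise ValueError(f"no archetypes configured for gender {gender!r}")
        weights = np.array([a.weight for a in specs], dtype=float)
        archetype = specs[rng.choice(len(specs), p=weights / weights.sum())]

        age_end = int(rng.integers(config.min_age_at_end, config.max_age_at_end + 1))
        birth_year = config.end_year - age_end
        reg_age = float(rng.uniform(min(40, age_end - 5), age_end - 3))
        reg_start = _dt.date(birth_year, 7, 1) + _dt.timedelta(days=int(reg_age * 365.25))
        reg_start = max(reg_start, _dt.date(config.start_year, 1, 1))

        ethnicity = None
        if rng.random() < config.ethnicity_recorded_prob:
            ethnicity = eth_names[rng.choice(len(eth_names), p=eth_probs)]
        imd = None
        if rng.random() < config.imd_linked_prob:
            imd = int(rng.choice(5, p=imd_probs)) + 1

        events = _sample_patient_events(
            rng, archetype, config, birth_year, reg_start, end_date
        )
        records.append(
            PatientRecord(
                patient_id=pid,
                gender=gender,
                year_of_birth=birth_year,
                registration_start=reg_start,
                registration_end=end_date,
                events=events,
                ethnicity=ethnicity,
                imd_quintile=imd,
            )
        )
        truth_rows.append({"patient_id": pid, "gender": gender, "archetype": archetype.name})

    truth = pd.DataFrame(truth_rows, columns=["patient_id", "gender", "archetype"])
    return records, truth


def apply_eligibility(
    records: Iterable[PatientRecord],
    min_age: int = 50,
    min_registration_years: float = 3.0,
) -> list[PatientRecord]:
    """Keep patients aged ``min_age``+ at their last event with long-enough registration."""
    kept = []
    for r in records:
        age = r.age_at_last_event()
        if age is None or age < min_age:
            continue
        span = (r.registration_end - r.registration_start).days / 365.25
        if span < min_registration_years:
            continue
        kept.append(r)
    return kept


def summarize_demographics(
    records: Iterable[PatientRecord] | None = None,
    counts: Mapping[str, Mapping[str, int]] | None = None,
    totals: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Tabulate counts and percentages by gender, ethnicity and IMD quintile.

    Percentages use the recording denominators: ethnicity percentages are
    among ethnicity-recorded patients and IMD percentages among IMD-linked
    patients.  Externally supplied count tables are accepted through
    ``counts`` (variable -> category -> count), with an optional explicit
    denominator per variable in ``totals``; this lets the summariser be run
    directly on published cohort tables.
    """
    if (records is None) == (counts is None):
        raise ValueError("provide exactly one of records or counts")

    if records is not None:
        records = list(records)
        counts_: dict[str, dict[str, int]] = {"gender": {}, "ethnicity": {}, "imd_quintile": {}}
        for r in records:
            counts_["gender"][r.gender] = counts_["gender"].get(r.gender, 0) + 1
            if r.ethnicity is not None:
                counts_["ethnicity"][r.ethnicity] = counts_["ethnicity"].get(r.ethnicity, 0) + 1
            if r.imd_quintile is not None:
                key = str(r.imd_quintile)
                counts_["imd_quintile"][key] = counts_["imd_quintile"].get(key, 0) + 1
        counts = counts_
        totals = None

    rows = []
    for variable in counts:
        var_counts = counts[variable]
        denom = None
        if totals is not None and variable in totals:
            denom = totals[variable]
        else:
            denom = sum(var_counts.values())
        for category in sorted(var_counts, key=str):
            n = var_counts[category]
            pct = 100.0 * n / denom if denom else 0.0
            rows.append(
                {"variable": variable, "category": category, "count": n, "percent": pct}
            )
    return pd.DataFrame(rows, columns=["variable", "category", "count", "percent"])


def _default_archetypes(gender: str) -> list[ArchetypeSpec]:
    """Five archetypes per gender mirroring published cluster-group shares."""
    links = DEFAULT_MEDICATION_LINKS
    labs = DEFAULT_LAB_LINKS

    def spec(name, weight, prevalence, onset):
        conds = set(prevalence)
        return ArchetypeSpec(
            name=name,
            condition_prevalence=prevalence,
            medication_links={c: links[c] for c in conds if c in links},
            lab_links={c: labs[c] for c in conds if c in labs},
            age_at_onset=onset,
            weight=weight,
        )

    low_burden = spec(
        "low_burden",
        0.203 if gender == "female" else 0.146,
        {"smoking": 0.30, "asthma": 0.20, "alcohol_misuse": 0.10, "hypertension": 0.10},
        {"smoking": (35, 10), "asthma": (30, 15), "alcohol_misuse": (40, 12), "hypertension": (60, 10)},
    )
    mental_health = spec(
        "mental_health",
        0.356 if gender == "female" else 0.199,
        {
            "depression": 0.80,
            "anxiety": 0.70,
            "smoking": 0.45,
            "drug_misuse": 0.20,
            "alcohol_misuse": 0.25,
            "eating_disorder": 0.10 if gender == "female" else 0.03,
            "schizophrenia": 0.08,
            "bipolar_disorder": 0.10,
            "epilepsy": 0.08,
            "ibd": 0.10,
        },
        {
            "depression": (38, 12),
            "anxiety": (36, 12),
            "smoking": (30, 10),
            "drug_misuse": (32, 10),
            "alcohol_misuse": (38, 12),
            "eating_disorder": (25, 8),
            "schizophrenia": (30, 10),
            "bipolar_disorder": (32, 10),
            "epilepsy": (30, 15),
            "ibd": (40, 15),
        },
    )
    cardiometabolic = spec(
        "cardiometabolic",
        0.188 if gender == "female" else 0.346,
        {
            "hypertension": 0.90,
            "diabetes": 0.60,
            "ischaemic_heart_disease": 0.55,
            "heart_failure": 0.30,
            "atrial_fibrillation": 0.30,
            "stroke": 0.20,
            "chronic_kidney_disease": 0.40,
            "obesity": 0.40,
            "gout": 0.25,
            "dementia": 0.15,
            "parkinsons_disease": 0.06,
        },
        {
            "hypertension": (58, 10),
            "diabetes": (58, 10),
            "ischaemic_heart_disease": (65, 9),
            "heart_failure": (74, 8),
            "atrial_fibrillation": (72, 9),
            "stroke": (72, 9),
            "chronic_kidney_disease": (70, 9),
            "obesity": (50, 12),
            "gout": (60, 12),
            "dementia": (80, 6),
            "parkinsons_disease": (74, 8),
        },
    )
    respiratory = spec(
        "respiratory",
        0.040 if gender == "female" else 0.095,
        {
            "asthma": 0.85,
            "copd": 0.60,
            "bronchiectasis": 0.25,
            "smoking": 0.50,
            "ibd": 0.15,
            "connective_tissue_disease": 0.15,
            "infectious_disease": 0.30,
        },
        {
            "asthma": (30, 15),
            "copd": (62, 9),
            "bronchiectasis": (55, 12),
            "smoking": (28, 10),
            "ibd": (42, 14),
            "connective_tissue_disease": (50, 12),
            "infectious_disease": (55, 15),
        },
    )
    mixed = spec(
        "mixed",
        0.213 if gender == "female" else 0.214,
        {
            "cancer": 0.45,
            "osteoarthritis": 0.60,
            "osteoporosis": 0.35 if gender == "female" else 0.12,
            "dementia": 0.20,
            "hearing_impairment": 0.30,
            "menieres_disease": 0.10,
            "multiple_sclerosis": 0.06,
            "gout": 0.15,
            "connective_tissue_disease": 0.12,
            "hypertension": 0.40,
        },
        {
            "cancer": (68, 10),
            "osteoarthritis": (60, 10),
            "osteoporosis": (70, 8),
            "dementia": (80, 6),
            "hearing_impairment": (65, 12),
            "menieres_disease": (55, 12),
            "multiple_sclerosis": (40, 10),
            "gout": (60, 12),
            "connective_tissue_disease": (55, 12),
            "hypertension": (62, 10),
        },
    )
    specs = [low_burden, mental_health, cardiometabolic, respiratory, mixed]
    total = sum(s.weight for s in specs)
    for s in specs:
        s.weight = s.weight / total
    return specs


#: Comorbidity pairs planted by the default configuration (odds multiplier > 1).
DEFAULT_COMORBIDITY_PAIRS: tuple[tuple[str, str, float], ...] = (
    ("diabetes", "hypertension", 3.0),
    ("depression", "anxiety", 4.0),
    ("heart_failure", "chronic_kidney_disease", 3.0),
    ("copd", "smoking", 3.0),
    ("osteoporosis", "dementia", 2.0),
    ("gout", "chronic_kidney_disease", 2.0),
)


def table1_config(n_patients: int, seed: int = 0) -> CohortConfig:
    """Default cohort configuration with published demographic marginals."""
    return CohortConfig(
        n_patients=n_patients,
        archetypes={
            "female": _default_archetypes("female"),
            "male": _default_archetypes("male"),
        },
        comorbidity_pairs=DEFAULT_COMORBIDITY_PAIRS,
        seed=seed,
    )


def gaussian_mixture_embeddings(
    n: int,
    dim: int = 32,
    n_components: int = 15,
    separation: float = 5.0,
    within_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Embeddings drawn from well-separated spherical Gaussian components.

    Component centres are random directions scaled so every pairwise
    centre distance is at least ``separation`` times the within-component
    standard deviation.  Returns ``(embeddings, component_labels)``; used to
    validate cluster-number selection and recovery with a known component
    count.
    """
    rng = np.random.default_rng(seed)
    radius = max(2.0 * separation * within_sd, 1.0)
    for _ in range(100):
        dirs = rng.normal(size=(n_components, dim))
        centres = radius * dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        d = np.linalg.norm(centres[:, None] - centres[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() >= separation * within_sd:
            break
    else:
        raise RuntimeError("could not place well-separated component centres")
    labels = rng.integers(0, n_components, size=n)
    X = centres[labels] + rng.normal(scale=within_sd, size=(n, dim))
    return X, labels


def separable_archetype_config(
    n_patients: int,
    n_archetypes: int = 5,
    conditions_per_archetype: int = 5,
    prevalence: float = 0.9,
    seed: int = 0,
) -> CohortConfig:
    """Cohort with disjoint condition blocks per archetype and distinct onset ages.

    This configuration plants a cleanly recoverable ground truth: each
    archetype draws its conditions from its own block of the condition list
    at high prevalence, with an archetype-specific age-at-onset profile
    (mirroring the age-phenotype correlation seen in real cohorts).  Used to
    validate that the embedding/clustering pipeline can recover known
    structure; the realistic overlapping archetypes of :func:`table1_config`
    are deliberately harder.
    """
    conds = sorted(DEFAULT_CONDITION_CODES)
    need = n_archetypes * conditions_per_archetype
    if need > len(conds):
        raise ValueError("not enough conditions for the requested archetype blocks")
    onset_means = np.linspace(45, 80, n_archetypes)
    archetypes = []
    for i in range(n_archetypes):
        block = conds[i * conditions_per_archetype : (i + 1) * conditions_per_archetype]
        archetypes.append(
            ArchetypeSpec(
                name=f"archetype_{i}",
                condition_prevalence={c: prevalence for c in block},
                age_at_onset={c: (float(onset_means[i]), 8.0) for c in block},
                weight=1.0 / n_archetypes,
            )
        )
    return CohortConfig(
        n_patients=n_patients,
        archetypes={"female": archetypes, "male": archetypes},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Plain-text I/O


def write_cohort(
    records: Sequence[PatientRecord], truth: pd.DataFrame, outdir: str | Path
) -> dict[str, Path]:
    """Write events, demographics and ground-truth tables as CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ev_rows = [
        {
            "patient_id": r.patient_id,
            "date": e.date.isoformat(),
            "source": e.source,
            "code": e.code,
        }
        for r in records
        for e in r.events
    ]
    events = pd.DataFrame(ev_rows, columns=["patient_id", "date", "source", "code"])
    demo = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "gender": r.gender,
                "year_of_birth": r.year_of_birth,
                "ethnicity": r.ethnicity if r.ethnicity is not None else "",
                "imd_quintile": r.imd_quintile if r.imd_quintile is not None else "",
                "registration_start": r.registration_start.isoformat(),
                "registration_end": r.registration_end.isoformat(),
            }
            for r in records
        ]
    )
    paths = {
        "events": outdir / "events.csv",
        "demographics": outdir / "demographics.csv",
        "truth": outdir / "truth.csv",
    }
    events.to_csv(paths["events"], index=False)
    demo.to_csv(paths["demographics"], index=False)
    truth.to_csv(paths["truth"], index=False)
    return paths


def read_cohort(indir: str | Path) -> list[PatientRecord]:
    """Read a cohort previously written by :func:`write_cohort`."""
    indir = Path(indir)
    demo = pd.read_csv(indir / "demographics.csv", dtype={"imd_quintile": "Int64"})
    events = pd.read_csv(indir / "events.csv")
    by_patient: dict[str, list[ClinicalEvent]] = {}
    for row in events.itertuples(index=False):
        by_patient.setdefault(row.patient_id, []).append(
            ClinicalEvent(
                date=_dt.date.fromisoformat(row.date), code=str(row.code), source=row.source
            )
        )
    records = []
    for row in demo.itertuples(index=False):
        evs = sorted(by_patient.get(row.patient_id, []), key=lambda e: e.date)
        records.append(
            PatientRecord(
                patient_id=row.patient_id,
                gender=row.gender,
                year_of_birth=int(row.year_of_birth),
                registration_start=_dt.date.fromisoformat(row.registration_start),
                registration_end=_dt.date.fromisoformat(row.registration_end),
                events=evs,
                ethnicity=None if pd.isna(row.ethnicity) or row.ethnicity == "" else row.ethnicity,
                imd_quintile=None if pd.isna(row.imd_quintile) else int(row.imd_quintile),
            )
        )
    return records
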