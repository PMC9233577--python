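"""Seeded synthetic claims generator with planted archetypes.

The real study database is proprietary, so the pipeline is exercised on
simulated persons and claims. Six archetypes plant one population per
classifier branch:

=====================  ==============  =========================================
archetype              intended tier   defining events
=====================  ==============  =========================================
A_CONDITION            high            one any-age qualifying diagnosis
PANHYPOPIT             high            deficiency diagnoses on three axes
GH_TREATED_ADULT       high            one adult GH prescription
GH_TREATED_EXCLUDED    low             adult GH prescription + exclusion-list
                                       diagnosis + a GHD test (exercises the
                                       moderate bypass of vetoed GH users)
TEST_ONLY_MODERATE     moderate        three axis tests (a configurable share)
                                       or a single GHD test
HEALTHY_LOW            low             no qualifying events
=====================  ==============  =========================================

Tier membership is planted constructively — archetype counts come from
largest-remainder apportionment of the weights, never from Bernoulli draws —
so classifier-recovery checks are exact. Comorbidity diagnoses, by contrast,
are sampled per person at configured prevalences into the final observation
year, since they feed statistical rather than logical checks. Every person
gets their own pseudo-random stream derived from (seed, person index), so a
cohort is reproducible and byte-identical for a fixed seed and config.

Demographics default to the shape real stratified claims cohorts show
(female excess and older ages in the high/moderate tiers); nothing
downstream depends on those defaults.
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .claims_model import (
    CodedEvent,
    CodeSystem,
    EventKind,
    Person,
    Sex,
    write_events,
    write_persons,
)
from .errors import ConfigurationError

_ENROLL_EPOCH = datetime.date(2001, 1, 1)
_ENROLL_LATEST_START = datetime.date(2015, 12, 31)


class Archetype(str, enum.Enum):
    A_CONDITION = "A_CONDITION"
    PANHYPOPIT = "PANHYPOPIT"
    GH_TREATED_ADULT = "GH_TREATED_ADULT"
    GH_TREATED_EXCLUDED = "GH_TREATED_EXCLUDED"
    TEST_ONLY_MODERATE = "TEST_ONLY_MODERATE"
    HEALTHY_LOW = "HEALTHY_LOW"


ARCHETYPE_TIER: Mapping[Archetype, str] = {
    Archetype.A_CONDITION: "high",
    Archetype.PANHYPOPIT: "high",
    Archetype.GH_TREATED_ADULT: "high",
    Archetype.GH_TREATED_EXCLUDED: "low",
    Archetype.TEST_ONLY_MODERATE: "moderate",
    Archetype.HEALTHY_LOW: "low",
}

#: One representative planted code per comorbidity list; each matches its
#: own list under the shipped defaults and nothing the classifier reads.
COMORBIDITY_CODES: Mapping[str, str] = {
    "hypertensive_disorder": "I10",
    "hyperlipidemia": "E785",
    "heart_disease": "I509",
    "diabetes_mellitus_or_igt": "E119",
    "osteoarthritis": "M179",
    "malignant_neoplastic_disease": "C189",
    "hematologic_neoplasm": "C9100",
    "depressive_disorder": "F329",
    "visual_system_disorder": "H409",
    "acute_respiratory_disease": "J069",
}

# Age-band mixes (age_lo, age_hi_exclusive, probability) per intended tier
_AGE_MIX = {
    "high": ((18, 30, 0.12), (30, 40, 0.10), (40, 50, 0.17), (50, 60, 0.25),
             (60, 70, 0.27), (70, 80, 0.07), (80, 90, 0.02)),
    "moderate": ((18, 30, 0.11), (30, 40, 0.16), (40, 50, 0.24), (50, 60, 0.30),
                 (60, 70, 0.17), (70, 80, 0.02)),
    "low": ((18, 30, 0.25), (30, 40, 0.20), (40, 50, 0.18), (50, 60, 0.18),
            (60, 70, 0.15), (70, 80, 0.04)),
}
_FEMALE_FRACTION = {"high": 0.593, "moderate": 0.716, "low": 0.504}

# Tier-graded default prevalences (last observation year)
_DEFAULT_PREVALENCE = {
    "high": {
        "hypertensive_disorder": 0.314,
        "hyperlipidemia": 0.326,
        "heart_disease": 0.156,
        "osteoarthritis": 0.171,
        "malignant_neoplastic_disease": 0.239,
        "hematologic_neoplasm": 0.045,
        "depressive_disorder": 0.139,
        "acute_respiratory_disease": 0.302,
    },
    "moderate": {
        "hypertensive_disorder": 0.259,
        "hyperlipidemia": 0.288,
        "heart_disease": 0.107,
        "osteoarthritis": 0.149,
        "malignant_neoplastic_disease": 0.057,
        "hematologic_neoplasm": 0.008,
        "depressive_disorder": 0.133,
        "acute_respiratory_disease": 0.296,
    },
    "low": {
        "hypertensive_disorder": 0.146,
        "hyperlipidemia": 0.146,
        "heart_disease": 0.054,
        "osteoarthritis": 0.062,
        "malignant_neoplastic_disease": 0.025,
        "hematologic_neoplasm": 0.003,
        "depressive_disorder": 0.056,
        "acute_respiratory_disease": 0.201,
    },
}


@dataclass(frozen=True)
class ArchetypeSpec:
    """One planted subpopulation: its weight, demographics, and the
    comorbidity prevalences sampled into its last observation year."""

    name: Archetype
    weight: float
    target_tier: str = ""
    age_bands: tuple[tuple[int, int, float], ...] = ()
    female_fraction: float = 0.5
    prevalences: Mapping[str, float] = field(default_factory=dict)
    axis_test_share: float = 0.978  # TEST_ONLY_MODERATE: share via >=3 axis tests

    def __post_init__(self) -> None:
        if not self.target_tier:
            object.__setattr__(self, "target_tier", ARCHETYPE_TIER[self.name])
        if not self.age_bands:
            object.__setattr__(self, "age_bands", _AGE_MIX[self.target_tier])
        for _, _, p in self.age_bands:
            if p < 0:
                raise ConfigurationError("negative age-band probability")
        for name, p in self.prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"prevalence {name}={p} outside [0, 1]")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigurationError("female_fraction outside [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    n: int
    archetypes: tuple[ArchetypeSpec, ...]
    index_date: datetime.date = datetime.date(2017, 12, 31)
    min_enrollment_days: int = 183

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigurationError("n must be non-negative")
        total = sum(a.weight for a in self.archetypes)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"archetype weights sum to {total}, not 1")


def default_generator_config(
    n: int = 600,
    weights: Optional[Mapping[Archetype | str, float]] = None,
) -> GeneratorConfig:
    """Config with equal archetype weights (or the given ones) and the
    default tier-graded demographics and prevalences."""
    if weights is None:
        weights = {a: 1.0 / len(Archetype) for a in Archetype}
    else:
        weights = {Archetype(k): float(v) for k, v in weights.items()}
    specs = []
    for arch in Archetype:  # fixed order ⇒ deterministic apportionment
        w = weights.get(arch, 0.0)
        tier = ARCHETYPE_TIER[arch]
        specs.append(
            ArchetypeSpec(
                name=arch,
                weight=w,
                female_fraction=_FEMALE_FRACTION[tier],
                prevalences=_DEFAULT_PREVALENCE[tier],
            )
        )
    return GeneratorConfig(n=n, archetypes=tuple(specs))


def _apportion(n: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment; ties broken by position."""
    raw = [n * w for w in weights]
    counts = [int(x) for x in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _draw_age(rng: np.random.Generator, bands: Sequence[tuple[int, int, float]]) -> int:
    probs = np.array([p for _, _, p in bands], dtype=float)
    probs = probs / probs.sum()
    i = int(rng.choice(len(bands), p=probs))
    lo, hi, _ = bands[i]
    return int(rng.integers(lo, hi))


def _defining_events(
    pid: str,
    spec: ArchetypeSpec,
    idx_in_archetype: int,
    count_in_archetype: int,
    year: int,
) -> list[CodedEvent]:
    d = lambda m, day: datetime.date(year, m, day)
    diag = lambda code, date: CodedEvent(pid, date, CodeSystem.ICD10CM, code, EventKind.DIAGNOSIS)
    rx = lambda code, date: CodedEvent(pid, date, CodeSystem.ATC, code, EventKind.PHARMACY)
    proc = lambda code, date: CodedEvent(pid, date, CodeSystem.CPT, code, EventKind.PROCEDURE)

    arch = spec.name
    if arch is Archetype.A_CONDITION:
        return [diag("D352", d(3, 15))]
    if arch is Archetype.PANHYPOPIT:
        return [diag("E038", d(2, 1)), diag("E2740", d(2, 15)), diag("E2910", d(3, 1))]
    if arch is Archetype.GH_TREATED_ADULT:
        return [rx("H01AC01", d(4, 1))]
    if arch is Archetype.GH_TREATED_EXCLUDED:
        return [rx("H01AC01", d(4, 1)), diag("N183", d(5, 1)), proc("84305", d(6, 1))]
    if arch is Archetype.TEST_ONLY_MODERATE:
        n_axis = round(spec.axis_test_share * count_in_archetype)
        if idx_in_archetype < n_axis:
            return [proc("84443", d(2, 10)), proc("82533", d(3, 10)), proc("84403", d(4, 10))]
        return [proc("84305", d(5, 10))]
    return []  # HEALTHY_LOW


@dataclass
class GeneratedCohort:
    persons: list[Person]
    events: list[CodedEvent]
    truth: pd.DataFrame  # person_id, archetype, intended_tier
    config: GeneratorConfig
    seed: int

    def write(self, out_dir: Path | str) -> dict[str, Path]:
        """Write persons/events/truth as canonical delimited files."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "persons": out / "persons.csv",
            "events": out / "events.csv",
            "truth": out / "truth.csv",
        }
        write_persons(self.persons, paths["persons"])
        write_events(self.events, paths["events"])
        self.truth.to_csv(paths["truth"], index=False, lineterminator="\n")
        return paths


def generate_cohort(config: GeneratorConfig, seed: int) -> GeneratedCohort:
    """Draw a cohort of ``config.n`` persons with planted archetypes.

    Identical (config, seed) pairs produce identical cohorts; every person's
    draws come from an independent stream keyed by (seed, person index).
    """
    counts = _apportion(config.n, [a.weight for a in config.archetypes])
    index_year = config.index_date.year

    persons: list[Person] = []
    events: list[CodedEvent] = []
    truth_rows: list[tuple[str, str, str]] = []
    idx = 0
    for spec, count in zip(config.archetypes, counts):
        for j in range(count):
            rng = np.random.default_rng((seed, idx))
            pid = f"P{idx:07d}"
            age = _draw_age(rng, spec.age_bands)
            sex = Sex.FEMALE if rng.random() < spec.female_fraction else Sex.MALE
            start_offset = int(rng.integers(0, (_ENROLL_LATEST_START - _ENROLL_EPOCH).days + 1))
            person = Person(
                person_id=pid,
                sex=sex,
                birth_year=index_year - age,
                enroll_start=_ENROLL_EPOCH + datetime.timedelta(days=start_offset),
                enroll_end=config.index_date,
            )
            person.validate()
            persons.append(person)
            events.extend(_defining_events(pid, spec, j, count, index_year))
            # last observation year = calendar index year (enrollment ends at
            # the index date by construction)
            for name, prevalence in spec.prevalences.items():
                if rng.random() < prevalence:
                    day = int(rng.integers(0, 364))
                    events.append(
                        CodedEvent(
                            pid,
                            config.index_date - datetime.timedelta(days=day),
                            CodeSystem.ICD10CM,
                            COMORBIDITY_CODES[name],
                            EventKind.DIAGNOSIS,
                        )
                    )
            if spec.name is Archetype.HEALTHY_LOW and rng.random() < 0.3:
                # inert wellness-visit noise; matches no configured list
                events.append(
                    CodedEvent(
                        pid,
                        datetime.date(index_year, 7, 1),
                        CodeSystem.ICD10CM,
                        "Z0000",
                        EventKind.DIAGNOSIS,
                    )
                )
            truth_rows.append((pid, spec.name.value, spec.target_tier))
            idx += 1
    truth = pd.DataFrame(truth_rows, columns=["person_id", "archetype", "intended_tier"])
    return GeneratedCohort(persons=persons, events=events, truth=truth, config=config, seed=seed)


# ---------------------------------------------------------------------------
# Minimal-person factory for exhaustive truth-table checks
# ---------------------------------------------------------------------------

PREDICATES = (
    "groupA",
    "groupB",
    "pitdef3",
    "ghrx",
    "hrt3",
    "exclusion",
    "testGHD",
    "testAxis3",
)

_PREDICATE_EVENTS: Mapping[str, tuple[tuple[CodeSystem, str, EventKind, tuple[int, int]], ...]] = {
    "groupA": ((CodeSystem.ICD10CM, "D352", EventKind.DIAGNOSIS, (1, 10)),),
    "groupB": ((CodeSystem.ICD10CM, "S065X9A", EventKind.DIAGNOSIS, (1, 20)),),
    "pitdef3": (
        (CodeSystem.ICD10CM, "E038", EventKind.DIAGNOSIS, (2, 1)),
        (CodeSystem.ICD10CM, "E2740", EventKind.DIAGNOSIS, (2, 11)),
        (CodeSystem.ICD10CM, "E2910", EventKind.DIAGNOSIS, (2, 21)),
    ),
    "ghrx": ((CodeSystem.ATC, "H01AC01", EventKind.PHARMACY, (3, 1)),),
    "hrt3": (
        (CodeSystem.ATC, "G03CA03", EventKind.PHARMACY, (4, 1)),
        (CodeSystem.ATC, "H02AB06", EventKind.PHARMACY, (4, 11)),
        (CodeSystem.ATC, "H03AA01", EventKind.PHARMACY, (4, 21)),
    ),
    "exclusion": ((CodeSystem.ICD10CM, "N183", EventKind.DIAGNOSIS, (5, 1)),),
    "testGHD": ((CodeSystem.CPT, "84305", EventKind.PROCEDURE, (6, 1)),),
    "testAxis3": (
        (CodeSystem.CPT, "84443", EventKind.PROCEDURE, (7, 1)),
        (CodeSystem.CPT, "82533", EventKind.PROCEDURE, (7, 11)),
        (CodeSystem.CPT, "84403", EventKind.PROCEDURE, (7, 21)),
    ),
}


def make_minimal_person(
    predicates: set[str] | frozenset[str],
    year: int = 2016,
) -> tuple[Person, list[CodedEvent]]:
    """Smallest event set realizing exactly the given classifier predicates
    under the shipped default code lists.

    Predicates are drawn from :data:`PREDICATES`. The person is an enrolled
    adult, so every combination (including the empty set) is realizable.
    """
    unknown = set(predicates) - set(PREDICATES)
    if unknown:
        raise ConfigurationError(f"unknown predicate(s): {sorted(unknown)}")
    person = Person(
        person_id="MIN",
        sex=Sex.FEMALE,
        birth_year=1970,
        enroll_start=datetime.date(2010, 1, 1),
        enroll_end=datetime.date(2017, 12, 31),
    )
    events: list[CodedEvent] = []
    for name in PREDICATES:  # fixed order ⇒ deterministic event list
        if name in predicates:
            for system, code, kind, (month, day) in _PREDICATE_EVENTS[name]:
                events.append(
                    CodedEvent(person.person_id, datetime.date(year, month, day), system, code, kind)
                )
    return person, events


__all__ = [
    "Archetype",
    "ARCHETYPE_TIER",
    "COMORBIDITY_CODES",
    "ArchetypeSpec",
    "GeneratorConfig",
    "default_generator_config",
    "GeneratedCohort",
    "generate_cohort",
    "PREDICATES",
    "make_minimal_person",
]
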