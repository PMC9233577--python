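"""The likelihood rule engine.

Every eligible adult is placed into exactly one of three tiers describing
the likelihood of adult growth hormone deficiency (AGHD):

high
    at least one of, in fixed precedence order:
    (1) GROUP_A  — a qualifying condition diagnosed at any age;
    (2) GROUP_B  — a qualifying condition diagnosed at adult age;
    (3) PIT_DEF_3 — deficiency diagnoses on >= 3 distinct pituitary axes
        besides GH (threshold raised from two to three in the final rule
        revision, held in ``min_deficiency_axes``);
    (4) GH_RX    — an adult GH-replacement prescription, provided no
        diagnosis on either exclusion list is present anywhere on record;
    (5) HRT_3    — adult prescriptions for >= 3 distinct hormone-replacement
        classes besides GH within one calendar year, same exclusion proviso.
moderate
    no high path, but >= 1 GHD diagnostic test (TEST_GHD) or tests of >= 3
    pituitary axes besides GH (TEST_AXIS_3); test results are unknown in
    claims, hence only "moderate".
low
    nothing above. A person whose adult GH prescription was vetoed by an
    exclusion-list diagnosis falls straight to low — the flowchart never
    routes GH-treated adults into the moderate tier
    (``gh_veto_bypasses_moderate``).

Precedence affects only the reported reason, never the tier. Exclusion
lists touch only the two prescription paths; diagnosis-based paths ignore
them. All matching is set-semantic, so duplicated claims change nothing.
"""

from __future__ import annotations

import datetime
import enum
import hashlib
import json
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .claims_model import (
    CodedEvent,
    CohortWindow,
    EventKind,
    Person,
    eligible,
)
from .codelists import CodeListRegistry, default_registry, distinct_axes, matches
from .errors import ConfigurationError, InputDataError


class Tier(str, enum.Enum):
    HIGH = "high"
    MODERATE = "moderate"
    LOW = "low"


class Reason(str, enum.Enum):
    GROUP_A = "GROUP_A"
    GROUP_B = "GROUP_B"
    PIT_DEF_3 = "PIT_DEF_3"
    GH_RX = "GH_RX"
    HRT_3 = "HRT_3"
    TEST_GHD = "TEST_GHD"
    TEST_AXIS_3 = "TEST_AXIS_3"
    NONE = "NONE"


HIGH_REASONS = (Reason.GROUP_A, Reason.GROUP_B, Reason.PIT_DEF_3, Reason.GH_RX, Reason.HRT_3)
MODERATE_REASONS = (Reason.TEST_GHD, Reason.TEST_AXIS_3)


class ReplacementWindow(str, enum.Enum):
    CALENDAR_YEAR = "calendar_year"


@dataclass(frozen=True)
class AlgorithmConfig:
    """Tunable parameters of the rule engine, with their final published
    defaults (three deficiency axes, three replacement classes, adulthood at
    18, calendar-year replacement window, index date 2017-12-31)."""

    registry: CodeListRegistry = field(default_factory=default_registry)
    min_deficiency_axes: int = 3
    min_replacement_classes: int = 3
    adult_age: int = 18
    replacement_window: ReplacementWindow = ReplacementWindow.CALENDAR_YEAR
    index_date: datetime.date = datetime.date(2017, 12, 31)
    gh_veto_bypasses_moderate: bool = True

    def __post_init__(self) -> None:
        if self.min_deficiency_axes < 1:
            raise ConfigurationError("min_deficiency_axes must be >= 1")
        if self.min_replacement_classes < 1:
            raise ConfigurationError("min_replacement_classes must be >= 1")

    def config_hash(self) -> str:
        """Stable digest of the parameters and code-list version."""
        payload = {
            "min_deficiency_axes": self.min_deficiency_axes,
            "min_replacement_classes": self.min_replacement_classes,
            "adult_age": self.adult_age,
            "replacement_window": self.replacement_window.value,
            "index_date": self.index_date.isoformat(),
            "gh_veto_bypasses_moderate": self.gh_veto_bypasses_moderate,
            "codelist_version": self.registry.version,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


@dataclass(frozen=True)
class LikelihoodResult:
    """Tier assignment plus the reason path that produced it."""

    person_id: str
    tier: Tier
    reason: Reason
    excluded_paths: frozenset[Reason] = frozenset()

    def __post_init__(self) -> None:
        consistent = (
            (self.tier is Tier.HIGH and self.reason in HIGH_REASONS)
            or (self.tier is Tier.MODERATE and self.reason in MODERATE_REASONS)
            or (self.tier is Tier.LOW and self.reason is Reason.NONE)
        )
        if not consistent:
            raise ValueError(f"inconsistent tier/reason: {self.tier}/{self.reason}")


def _adult_at(event: CodedEvent, person: Person, adult_age: int) -> bool:
    # year-granular age, consistent with the cohort age rule
    return event.service_date.year - person.birth_year >= adult_age


def high_criteria(
    person: Person,
    events: Sequence[CodedEvent],
    cfg: AlgorithmConfig,
) -> tuple[list[Reason], set[Reason]]:
    """Evaluate the five high-likelihood paths in precedence order.

    Returns the ordered list of satisfied reasons and the set of
    prescription paths that would have fired but were vetoed by an
    exclusion-list diagnosis.
    """
    reg = cfg.registry
    diagnoses = [e for e in events if e.kind is EventKind.DIAGNOSIS]
    pharmacy = [e for e in events if e.kind is EventKind.PHARMACY]

    satisfied: list[Reason] = []
    excluded: set[Reason] = set()

    group_a = reg.get("GROUP_A_CONDITIONS")
    if any(matches(group_a, e) for e in diagnoses):
        satisfied.append(Reason.GROUP_A)

    group_b = reg.get("GROUP_B_CONDITIONS")
    if any(
        matches(group_b, e) and _adult_at(e, person, cfg.adult_age) for e in diagnoses
    ):
        satisfied.append(Reason.GROUP_B)

    deficiency = reg.get("PITUITARY_DEFICIENCY_DX")
    if len(distinct_axes(diagnoses, deficiency)) >= cfg.min_deficiency_axes:
        satisfied.append(Reason.PIT_DEF_3)

    # exclusion lists apply as a union, to prescription paths only, with no
    # temporal relation to the prescription
    excl_1 = reg.get("EXCLUSION_1")
    excl_2 = reg.get("EXCLUSION_2")
    exclusion_hit = any(
        matches(excl_1, e) or matches(excl_2, e) for e in diagnoses
    )

    gh_rx = reg.get("GH_THERAPY_RX")
    adult_gh = any(
        matches(gh_rx, e) and _adult_at(e, person, cfg.adult_age) for e in pharmacy
    )
    if adult_gh:
        if exclusion_hit:
            excluded.add(Reason.GH_RX)
        else:
            satisfied.append(Reason.GH_RX)

    replacement = reg.get("HORMONE_REPLACEMENT_RX")
    by_year: dict[int, list[CodedEvent]] = defaultdict(list)
    for e in pharmacy:
        if _adult_at(e, person, cfg.adult_age):
            by_year[e.service_date.year].append(e)
    hrt = any(
        len(distinct_axes(year_events, replacement)) >= cfg.min_replacement_classes
        for year_events in by_year.values()
    )
    if hrt:
        if exclusion_hit:
            excluded.add(Reason.HRT_3)
        else:
            satisfied.append(Reason.HRT_3)

    return satisfied, excluded


def moderate_criteria(
    person: Person,
    events: Sequence[CodedEvent],
    cfg: AlgorithmConfig,
) -> list[Reason]:
    """Diagnostic-test paths (test results are unknown in claims data)."""
    reg = cfg.registry
    procedures = [e for e in events if e.kind is EventKind.PROCEDURE]
    satisfied: list[Reason] = []
    if any(matches(reg.get("GHD_TEST_CPT"), e) for e in procedures):
        satisfied.append(Reason.TEST_GHD)
    if len(distinct_axes(procedures, reg.get("AXIS_TEST_CPT"))) >= cfg.min_deficiency_axes:
        satisfied.append(Reason.TEST_AXIS_3)
    return satisfied


def classify_person(
    person: Person,
    events: Sequence[CodedEvent],
    cfg: AlgorithmConfig,
) -> LikelihoodResult:
    """Assign one tier and the first satisfied reason on its path."""
    high, excluded = high_criteria(person, events, cfg)
    if high:
        return LikelihoodResult(person.person_id, Tier.HIGH, high[0], frozenset(excluded))
    if cfg.gh_veto_bypasses_moderate and Reason.GH_RX in excluded:
        # GH-treated adults are never routed into the moderate tier
        return LikelihoodResult(person.person_id, Tier.LOW, Reason.NONE, frozenset(excluded))
    moderate = moderate_criteria(person, events, cfg)
    if moderate:
        return LikelihoodResult(
            person.person_id, Tier.MODERATE, moderate[0], frozenset(excluded)
        )
    return LikelihoodResult(person.person_id, Tier.LOW, Reason.NONE, frozenset(excluded))


@dataclass
class CohortClassification:
    """Per-person results for the eligible cohort, the ineligible remainder
    with reasons, and ids of events that referenced no known person."""

    results: pd.DataFrame      # person_id, tier, reason, excluded_paths
    ineligible: pd.DataFrame   # person_id, reason
    unknown_person_ids: list[str]

    def tier_counts(self) -> dict[str, int]:
        counts = self.results["tier"].value_counts().to_dict()
        return {t.value: int(counts.get(t.value, 0)) for t in Tier}


def classify_cohort(
    persons: Sequence[Person],
    events: Sequence[CodedEvent],
    cfg: AlgorithmConfig,
    window: Optional[CohortWindow] = None,
) -> CohortClassification:
    """Classify every eligible person; deterministic given identical inputs.

    Ineligible persons (under-age, under-enrolled, or dead at the index
    date) are reported separately and never classified. Events whose
    person_id matches nobody are ignored with a warning record.
    """
    if window is None:
        window = CohortWindow(index_date=cfg.index_date, adult_age=cfg.adult_age)
    ids = {p.person_id for p in persons}
    if len(ids) != len(persons):
        raise InputDataError("duplicate person_id in cohort")

    by_person: dict[str, list[CodedEvent]] = defaultdict(list)
    unknown: list[str] = []
    unknown_seen: set[str] = set()
    for e in events:
        if e.person_id in ids:
            by_person[e.person_id].append(e)
        elif e.person_id not in unknown_seen:
            unknown_seen.add(e.person_id)
            unknown.append(e.person_id)

    rows: list[tuple[str, str, str, str]] = []
    inel: list[tuple[str, str]] = []
    for person in persons:
        verdict = eligible(person, window)
        if not verdict.eligible:
            inel.append((person.person_id, verdict.reason or ""))
            continue
        res = classify_person(person, by_person.get(person.person_id, ()), cfg)
        rows.append(
            (
                res.person_id,
                res.tier.value,
                res.reason.value,
                "|".join(sorted(r.value for r in res.excluded_paths)),
            )
        )
    results = pd.DataFrame(rows, columns=["person_id", "tier", "reason", "excluded_paths"])
    ineligible = pd.DataFrame(inel, columns=["person_id", "reason"])
    return CohortClassification(results=results, ineligible=ineligible, unknown_person_ids=unknown)


__all__ = [
    "Tier",
    "Reason",
    "HIGH_REASONS",
    "MODERATE_REASONS",
    "ReplacementWindow",
    "AlgorithmConfig",
    "LikelihoodResult",
    "high_criteria",
    "moderate_criteria",
    "classify_person",
    "classify_cohort",
    "CohortClassification",
]
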