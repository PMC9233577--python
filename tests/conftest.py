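"""Shared fixtures: default registry/config, an independent truth-table
oracle for the rule engine, and a fuzz-cohort factory drawing random events
from every configured code list."""

from __future__ import annotations

import datetime
import functools

import numpy as np
import pytest

from aghdstrat.claims_model import CodedEvent, CodeSystem, EventKind, Person, Sex
from aghdstrat.classifier import AlgorithmConfig
from aghdstrat.codelists import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def algo_cfg(registry):
    return AlgorithmConfig(registry=registry)


def oracle_classify(p: dict[str, bool]) -> tuple[str, str]:
    """Independent restatement of the flowchart as a flat truth table.

    high = any qualifying diagnosis path, or a prescription path not vetoed
    by an exclusion diagnosis; a vetoed GH user skips moderate entirely;
    otherwise a test path gives moderate; else low.
    """
    if p["groupA"]:
        return "high", "GROUP_A"
    if p["groupB"]:
        return "high", "GROUP_B"
    if p["pitdef3"]:
        return "high", "PIT_DEF_3"
    if p["ghrx"] and not p["exclusion"]:
        return "high", "GH_RX"
    if p["hrt3"] and not p["exclusion"]:
        return "high", "HRT_3"
    if p["ghrx"] and p["exclusion"]:
        return "low", "NONE"
    if p["testGHD"]:
        return "moderate", "TEST_GHD"
    if p["testAxis3"]:
        return "moderate", "TEST_AXIS_3"
    return "low", "NONE"


def _event_pool(registry) -> list[tuple[CodeSystem, str, EventKind]]:
    """One drawable event per code-list entry (prefix entries get a child
    code), spanning every list the pipeline reads."""
    kind_of_list = {
        "GROUP_A_CONDITIONS": EventKind.DIAGNOSIS,
        "GROUP_B_CONDITIONS": EventKind.DIAGNOSIS,
        "PITUITARY_DEFICIENCY_DX": EventKind.DIAGNOSIS,
        "EXCLUSION_1": EventKind.DIAGNOSIS,
        "EXCLUSION_2": EventKind.DIAGNOSIS,
        "GH_THERAPY_RX": EventKind.PHARMACY,
        "HORMONE_REPLACEMENT_RX": EventKind.PHARMACY,
        "GHD_TEST_CPT": EventKind.PROCEDURE,
        "AXIS_TEST_CPT": EventKind.PROCEDURE,
    }
    pool = []
    for name, kind in kind_of_list.items():
        for entry in registry.get(name).entries:
            code = entry.pattern if entry.match_mode.value == "exact" else entry.pattern + "1"
            pool.append((entry.system, code, kind))
    for name in registry.comorbidity_names:
        for entry in registry.comorbidities[name].entries:
            pool.append((entry.system, entry.pattern + "1", EventKind.DIAGNOSIS))
    pool.append((CodeSystem.ICD10CM, "Z0000", EventKind.DIAGNOSIS))  # inert noise
    return pool


@functools.lru_cache(maxsize=1)
def _cached_pool():
    return _event_pool(default_registry())


def fuzz_cohort(seed: int, n_persons: int = 12):
    """Random persons (some ineligible) with random events drawn from all
    code lists. Deterministic in the seed."""
    rng = np.random.default_rng(100_000 + seed)
    pool = _cached_pool()
    persons: list[Person] = []
    events: list[CodedEvent] = []
    for i in range(n_persons):
        pid = f"F{seed}_{i}"
        birth_year = int(rng.integers(1940, 2006))
        start = datetime.date(2001, 1, 1) + datetime.timedelta(days=int(rng.integers(0, 6000)))
        end = start + datetime.timedelta(days=int(rng.integers(0, 4000)))
        persons.append(
            Person(
                person_id=pid,
                sex=Sex.FEMALE if rng.random() < 0.5 else Sex.MALE,
                birth_year=birth_year,
                enroll_start=start,
                enroll_end=end,
                death_date=None,
            )
        )
        for _ in range(int(rng.integers(0, 12))):
            system, code, kind = pool[int(rng.integers(0, len(pool)))]
            day = datetime.date(2010, 1, 1) + datetime.timedelta(days=int(rng.integers(0, 2921)))
            events.append(CodedEvent(pid, day, system, code, kind))
    return persons, events
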