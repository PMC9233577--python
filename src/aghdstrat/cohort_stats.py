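"""Descriptive surfaces for a classified cohort.

Reproduces the reporting shapes a claims stratification study prints: tier
proportions with per-reason shares, an age-by-sex cross-tabulation (cells as
percentages of the whole cohort, so the three tier columns sum row-wise to
the cohort column), per-tier comorbidity incidence over each person's last
365 observed days, per-tier diagnostic-test usage, and pairwise standardized
differences of comorbidity proportions with the conventional |d| <= 0.1
negligibility flag.

The standardized difference implemented is the standard pooled form for a
binary covariate, d = (p2 - p1) / sqrt((p1(1-p1) + p2(1-p2)) / 2): negative
when the first-listed group has the larger proportion. The formula choice is
explicit because published balance tables do not always state theirs.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .claims_model import (
    CodedEvent,
    CohortWindow,
    EventKind,
    Person,
    observation_bounds,
)
from .classifier import CohortClassification, Reason, Tier
from .codelists import CodeListRegistry, matches
from .errors import EmptyCohortError, InputDataError

NEGLIGIBLE_SD = 0.1

TIER_ORDER = [Tier.HIGH.value, Tier.MODERATE.value, Tier.LOW.value]


# ---------------------------------------------------------------------------
# Tier and reason proportions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TierProportions:
    """Cohort-level shares: ``tiers`` sums to 1 over {high, moderate, low};
    ``reason_shares[tier]`` sums to 1 within each non-empty tier."""

    tiers: Mapping[str, float]
    reason_shares: Mapping[str, Mapping[str, float]]
    n: int


def tier_proportions(results: pd.DataFrame) -> TierProportions:
    if results.empty:
        raise EmptyCohortError("tier proportions undefined for an empty cohort")
    n = len(results)
    tier_counts = results["tier"].value_counts()
    tiers = {t: float(tier_counts.get(t, 0)) / n for t in TIER_ORDER}
    shares: dict[str, dict[str, float]] = {}
    for tier in TIER_ORDER:
        sub = results.loc[results["tier"] == tier, "reason"]
        if len(sub) == 0:
            shares[tier] = {}
            continue
        counts = sub.value_counts()
        shares[tier] = {r: float(c) / len(sub) for r, c in counts.items()}
    return TierProportions(tiers=tiers, reason_shares=shares, n=n)


# ---------------------------------------------------------------------------
# Age / sex cross-tabulation
# ---------------------------------------------------------------------------

AGE_BAND_EDGES = (30, 40, 50, 60, 70, 80)


def _age_band_labels(adult_age: int) -> list[str]:
    lo = adult_age
    labels = []
    for hi in AGE_BAND_EDGES:
        labels.append(f"{lo}-{hi}")
        lo = hi
    labels.append(f">{AGE_BAND_EDGES[-1]}")
    return labels


def age_sex_table(
    persons: Sequence[Person],
    results: pd.DataFrame,
    window: CohortWindow,
) -> pd.DataFrame:
    """Cross-tabulate the classified cohort by sex and index-date age band.

    Rows: All, female, male, then the age bands; columns: the three tiers
    plus the whole study cohort. Every cell is a percentage of the whole
    cohort, hence the "All" row and the cohort column each total 100.
    """
    if results.empty:
        raise EmptyCohortError("age/sex table undefined for an empty cohort")
    by_id = {p.person_id: p for p in persons}
    missing = [pid for pid in results["person_id"] if pid not in by_id]
    if missing:
        raise InputDataError(f"result person_id {missing[0]!r} joins to no person")

    n = len(results)
    labels = _age_band_labels(window.adult_age)
    bins = [window.adult_age - 1, *AGE_BAND_EDGES, math.inf]

    frame = results[["person_id", "tier"]].copy()
    frame["sex"] = [by_id[pid].sex.value for pid in frame["person_id"]]
    ages = [window.index_date.year - by_id[pid].birth_year for pid in frame["person_id"]]
    frame["band"] = pd.cut(ages, bins=bins, labels=labels)

    rows = ["All", "female", "male", *labels]
    table = pd.DataFrame(0.0, index=rows, columns=[*TIER_ORDER, "cohort"])
    for tier in [*TIER_ORDER, None]:
        col = tier if tier is not None else "cohort"
        sub = frame if tier is None else frame[frame["tier"] == tier]
        table.loc["All", col] = 100.0 * len(sub) / n
        for sex in ("female", "male"):
            table.loc[sex, col] = 100.0 * (sub["sex"] == sex).sum() / n
        band_counts = sub["band"].value_counts()
        for band in labels:
            table.loc[band, col] = 100.0 * band_counts.get(band, 0) / n
    return table


# ---------------------------------------------------------------------------
# Comorbidity incidence over the last year of observation
# ---------------------------------------------------------------------------

LOOKBACK_DAYS = 364  # closed window [last_date - 364, last_date]: 365 days


def comorbidity_incidence(
    persons: Sequence[Person],
    events: Sequence[CodedEvent],
    results: pd.DataFrame,
    registry: CodeListRegistry,
    window: CohortWindow,
) -> pd.DataFrame:
    """Per-tier fraction of persons with >= 1 matching diagnosis in their
    final 365 observed days. Each person counts at most once per
    comorbidity; event order and duplication are irrelevant.
    """
    by_id = {p.person_id: p for p in persons}
    tier_of = dict(zip(results["person_id"], results["tier"]))
    tier_sizes = {t: int((results["tier"] == t).sum()) for t in TIER_ORDER}

    events_by_person: dict[str, list[CodedEvent]] = {}
    for e in events:
        if e.kind is EventKind.DIAGNOSIS and e.person_id in tier_of:
            events_by_person.setdefault(e.person_id, []).append(e)

    names = registry.comorbidity_names
    hits = {name: {t: 0 for t in TIER_ORDER} for name in names}
    for pid, tier in tier_of.items():
        person = by_id.get(pid)
        if person is None:
            raise InputDataError(f"result person_id {pid!r} joins to no person")
        _, last = observation_bounds(person, (), window)
        start = last - datetime.timedelta(days=LOOKBACK_DAYS)
        window_events = [
            e for e in events_by_person.get(pid, ()) if start <= e.service_date <= last
        ]
        for name in names:
            clist = registry.comorbidities[name]
            if any(matches(clist, e) for e in window_events):
                hits[name][tier] += 1

    data = {
        t: [hits[name][t] / tier_sizes[t] if tier_sizes[t] else 0.0 for name in names]
        for t in TIER_ORDER
    }
    return pd.DataFrame(data, index=pd.Index(names, name="comorbidity"))


# ---------------------------------------------------------------------------
# Standardized differences
# ---------------------------------------------------------------------------

def standardized_difference(p1: float, p2: float) -> float:
    """Pooled standardized difference of two proportions.

    d = (p2 - p1) / sqrt((p1(1-p1) + p2(1-p2)) / 2). Zero when both
    variances vanish with equal proportions (all-0 or all-1 groups).
    """
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion {p} outside [0, 1]")
    denom_sq = (p1 * (1.0 - p1) + p2 * (1.0 - p2)) / 2.0
    if denom_sq == 0.0:
        return 0.0
    return (p2 - p1) / math.sqrt(denom_sq)


@dataclass(frozen=True)
class EffectSizeRow:
    """One comorbidity's per-tier incidence with pairwise effect sizes."""

    comorbidity: str
    p_high: float
    p_moderate: float
    p_low: float
    sd_high_low: float
    sd_high_mod: float
    sd_mod_low: float
    negligible_high_low: bool
    negligible_high_mod: bool
    negligible_mod_low: bool


def effect_size_table(incidence: pd.DataFrame) -> list[EffectSizeRow]:
    """Pairwise standardized differences for every comorbidity row of a
    :func:`comorbidity_incidence` table, first-listed group first (so the
    sign is negative when the higher-likelihood group has more disease)."""
    rows: list[EffectSizeRow] = []
    for name, rec in incidence.iterrows():
        ph, pm, pl = float(rec["high"]), float(rec["moderate"]), float(rec["low"])
        sd_hl = standardized_difference(ph, pl)
        sd_hm = standardized_difference(ph, pm)
        sd_ml = standardized_difference(pm, pl)
        rows.append(
            EffectSizeRow(
                comorbidity=str(name),
                p_high=ph,
                p_moderate=pm,
                p_low=pl,
                sd_high_low=sd_hl,
                sd_high_mod=sd_hm,
                sd_mod_low=sd_ml,
                negligible_high_low=abs(sd_hl) <= NEGLIGIBLE_SD,
                negligible_high_mod=abs(sd_hm) <= NEGLIGIBLE_SD,
                negligible_mod_low=abs(sd_ml) <= NEGLIGIBLE_SD,
            )
        )
    return rows


def effect_size_frame(incidence: pd.DataFrame) -> pd.DataFrame:
    rows = effect_size_table(incidence)
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("comorbidity")


# ---------------------------------------------------------------------------
# Diagnostic-test usage
# ---------------------------------------------------------------------------

def diagnostic_test_usage(
    persons: Sequence[Person],
    events: Sequence[CodedEvent],
    results: pd.DataFrame,
    registry: CodeListRegistry,
) -> pd.DataFrame:
    """Fraction of the high and moderate tiers with >= 1 procedure matching
    each GHD-test sublabel, over the full observation (low tier omitted by
    reporting convention). Empty tiers produce zero rows, not errors."""
    test_list = registry.get("GHD_TEST_CPT")
    labels = test_list.labels
    if not labels:
        raise InputDataError("GHD_TEST_CPT entries carry no sublabels")
    tiers = [Tier.HIGH.value, Tier.MODERATE.value]
    tier_of = dict(zip(results["person_id"], results["tier"]))
    tier_sizes = {t: int((results["tier"] == t).sum()) for t in tiers}

    entry_by_label = {
        label: [e for e in test_list.entries if e.label == label] for label in labels
    }
    hit_counts = {label: {t: 0 for t in tiers} for label in labels}
    procs_by_person: dict[str, list[CodedEvent]] = {}
    for e in events:
        if e.kind is EventKind.PROCEDURE and tier_of.get(e.person_id) in tiers:
            procs_by_person.setdefault(e.person_id, []).append(e)
    for pid, procs in procs_by_person.items():
        tier = tier_of[pid]
        for label in labels:
            if any(
                entry.matches_code(e.system, e.code)
                for e in procs
                for entry in entry_by_label[label]
            ):
                hit_counts[label][tier] += 1

    data = {
        t: [hit_counts[label][t] / tier_sizes[t] if tier_sizes[t] else 0.0 for label in labels]
        for t in tiers
    }
    return pd.DataFrame(data, index=pd.Index(labels, name="test"))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_summary(
    proportions: TierProportions,
    codelist_version: str,
    config_hash: str,
    classification: Optional[CohortClassification] = None,
) -> str:
    """Human-readable summary block: counts and proportions per tier and per
    reason, stamped with the code-list version and configuration hash."""
    lines = [
        "AGHD likelihood stratification summary",
        f"code-list version: {codelist_version}",
        f"config hash: {config_hash}",
        f"eligible cohort size: {proportions.n}",
        "",
        "tier proportions:",
    ]
    for tier in TIER_ORDER:
        share = proportions.tiers[tier]
        lines.append(f"  {tier:<9} {share * proportions.n:>10.0f}  ({100.0 * share:6.2f}%)")
    lines.append("")
    lines.append("reason shares within tier:")
    for tier in TIER_ORDER:
        shares = proportions.reason_shares.get(tier, {})
        for reason in [r.value for r in Reason]:
            if reason in shares:
                lines.append(f"  {tier:<9} {reason:<12} {100.0 * shares[reason]:6.2f}%")
    if classification is not None:
        lines.append("")
        lines.append(f"ineligible persons: {len(classification.ineligible)}")
        if classification.unknown_person_ids:
            lines.append(
                f"events ignored for {len(classification.unknown_person_ids)} "
                "unknown person id(s)"
            )
    return "\n".join(lines) + "\n"


__all__ = [
    "NEGLIGIBLE_SD",
    "TIER_ORDER",
    "LOOKBACK_DAYS",
    "TierProportions",
    "tier_proportions",
    "age_sex_table",
    "comorbidity_incidence",
    "standardized_difference",
    "EffectSizeRow",
    "effect_size_table",
    "effect_size_frame",
    "diagnostic_test_usage",
    "render_summary",
]
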