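"""Configurable registry of clinical code lists with deterministic matching.

The stratification algorithm is driven entirely by named lists of ICD-9-CM /
ICD-10-CM diagnosis codes, CPT procedure codes and ATC drug codes. Each list
entry matches either exactly or by prefix (the natural semantics for the
hierarchical ICD and ATC terminologies; CPT codes are flat, so exact is their
default), and entries on deficiency/replacement/test lists carry a pituitary
*axis* label (thyroid, adrenal, gonadal, prolactin, gh, posterior) so that
"at least three deficiencies" counts distinct hormonal axes, never repeat
claims on one axis.

The shipped default lists are approximate, clearly-versioned placeholders
assembled from clinical anchors (somatropin-type agents H01AC, sex hormones
G03, systemic corticosteroids H02AB, thyroid preparations H03AA, the five
named GHD work-up tests); real deployments supply their own validated lists
as configuration. Every downstream report carries the list version string so
outputs are never mistaken for results under another code set.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .claims_model import CodedEvent, CodeSystem
from .errors import ConfigurationError, InvalidCodeError

_WILDCARDS = set("*?%[]")

#: Lists the classifier requires; a config missing any of these is rejected.
MANDATORY_LISTS = (
    "GROUP_A_CONDITIONS",
    "GROUP_B_CONDITIONS",
    "PITUITARY_DEFICIENCY_DX",
    "EXCLUSION_1",
    "EXCLUSION_2",
    "GH_THERAPY_RX",
    "HORMONE_REPLACEMENT_RX",
    "GHD_TEST_CPT",
    "AXIS_TEST_CPT",
)


class Axis(str, enum.Enum):
    """One pituitary hormonal pathway (anterior axes plus posterior)."""

    THYROID = "thyroid"
    ADRENAL = "adrenal"
    GONADAL = "gonadal"
    PROLACTIN = "prolactin"
    GH = "gh"
    POSTERIOR = "posterior"


class MatchMode(str, enum.Enum):
    EXACT = "exact"
    PREFIX = "prefix"


def normalize_code(system: CodeSystem, raw: str) -> str:
    """Canonical form of a clinical code.

    ICD codes are uppercased with dots and whitespace removed ("e23.0" →
    "E230"); CPT codes are kept as their 5-character string; ATC codes are
    uppercased unchanged. Idempotent by construction.
    """
    if raw is None:
        raise InvalidCodeError("code is None")
    out = raw.strip().upper()
    if system in (CodeSystem.ICD9CM, CodeSystem.ICD10CM):
        out = out.replace(".", "").replace(" ", "")
    if not out:
        raise InvalidCodeError(f"code {raw!r} is empty after normalization")
    return out


def default_match_mode(system: CodeSystem) -> MatchMode:
    """Prefix for hierarchical terminologies (ICD, ATC); exact for CPT."""
    return MatchMode.EXACT if system is CodeSystem.CPT else MatchMode.PREFIX


@dataclass(frozen=True)
class CodeEntry:
    """One pattern in a code list.

    ``axis`` labels the pituitary axis the code speaks to (where relevant);
    ``label`` is a display sublabel used by per-test usage reports.
    """

    system: CodeSystem
    pattern: str
    match_mode: MatchMode
    axis: Optional[Axis] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", normalize_code(self.system, self.pattern))
        if self.match_mode is MatchMode.PREFIX and (_WILDCARDS & set(self.pattern)):
            raise ConfigurationError(
                f"prefix pattern {self.pattern!r} must not contain wildcard characters"
            )

    def matches_code(self, system: CodeSystem, code: str) -> bool:
        if system is not self.system:
            return False
        if self.match_mode is MatchMode.EXACT:
            return code == self.pattern
        return code.startswith(self.pattern)


@dataclass(frozen=True)
class CodeList:
    """A named, versioned set of code entries."""

    name: str
    entries: tuple[CodeEntry, ...]
    version: str = ""

    def __post_init__(self) -> None:
        if not self.entries:
            raise ConfigurationError(f"code list {self.name!r} has no entries")
        seen: set[tuple] = set()
        for e in self.entries:
            key = (e.system, e.pattern, e.match_mode)
            if key in seen:
                raise ConfigurationError(
                    f"code list {self.name!r} has duplicate entry "
                    f"({e.system.value}, {e.pattern}, {e.match_mode.value})"
                )
            seen.add(key)

    def matching_entries(self, event: CodedEvent) -> list[CodeEntry]:
        return [e for e in self.entries if e.matches_code(event.system, event.code)]

    @property
    def has_axes(self) -> bool:
        return any(e.axis is not None for e in self.entries)

    @property
    def labels(self) -> list[str]:
        """Distinct sublabels in entry order."""
        out: list[str] = []
        for e in self.entries:
            if e.label is not None and e.label not in out:
                out.append(e.label)
        return out


def matches(code_list: CodeList, event: CodedEvent) -> bool:
    """True iff some entry shares the event's system and matches its code."""
    return any(e.matches_code(event.system, event.code) for e in code_list.entries)


def distinct_axes(events: Iterable[CodedEvent], code_list: CodeList) -> set[Axis]:
    """Axes touched by at least one matching event, the GH axis excluded.

    Deficiency/replacement/test counting is per axis, not per claim: repeat
    hits on one axis count once, and the GH axis never counts (the rules are
    all "besides GH").
    """
    if not code_list.has_axes:
        raise ConfigurationError(
            f"code list {code_list.name!r} carries no axis labels; "
            "axis counting is undefined"
        )
    axes: set[Axis] = set()
    for event in events:
        for entry in code_list.matching_entries(event):
            if entry.axis is not None and entry.axis is not Axis.GH:
                axes.add(entry.axis)
    return axes


@dataclass(frozen=True)
class CodeListRegistry:
    """All code lists for one run: the algorithm's lists plus the
    comorbidity lists used by descriptive reporting."""

    version: str
    lists: Mapping[str, CodeList]
    comorbidities: Mapping[str, CodeList] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [n for n in MANDATORY_LISTS if n not in self.lists]
        if missing:
            raise ConfigurationError(f"missing code list {missing[0]}")

    def get(self, name: str) -> CodeList:
        if name in self.lists:
            return self.lists[name]
        if name in self.comorbidities:
            return self.comorbidities[name]
        raise ConfigurationError(f"unknown code list {name!r}")

    @property
    def comorbidity_names(self) -> list[str]:
        return list(self.comorbidities)


def _parse_entry(raw: Mapping, list_name: str) -> CodeEntry:
    try:
        system = CodeSystem(str(raw["system"]))
    except (KeyError, ValueError):
        raise ConfigurationError(
            f"entry {raw!r} in list {list_name!r} has a missing/unknown system"
        ) from None
    pattern = raw.get("pattern")
    if pattern is None:
        raise ConfigurationError(f"entry {raw!r} in list {list_name!r} lacks a pattern")
    mode = (
        MatchMode(str(raw["match_mode"]))
        if "match_mode" in raw
        else default_match_mode(system)
    )
    axis = Axis(str(raw["axis"])) if raw.get("axis") else None
    label = str(raw["label"]) if raw.get("label") else None
    return CodeEntry(system=system, pattern=str(pattern), match_mode=mode, axis=axis, label=label)


def _parse_list(name: str, raw_entries: Sequence[Mapping], version: str) -> CodeList:
    if not isinstance(raw_entries, Sequence) or isinstance(raw_entries, (str, bytes)):
        raise ConfigurationError(f"list {name!r} must be a sequence of entries")
    return CodeList(
        name=name,
        entries=tuple(_parse_entry(e, name) for e in raw_entries),
        version=version,
    )


def load_codelists(path: Path | str) -> CodeListRegistry:
    """Load a registry from a YAML config file.

    Layout: a top-level ``version`` string, a ``lists`` mapping holding the
    mandatory algorithm lists, and an optional ``comorbidities`` mapping of
    reporting lists. Each entry is ``{system, pattern, match_mode?, axis?,
    label?}``; match_mode defaults by terminology.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"code-list config not found: {path}")
    with path.open() as handle:
        doc = yaml.safe_load(handle)
    return _registry_from_doc(doc, source=str(path))


def _registry_from_doc(doc, source: str) -> CodeListRegistry:
    if not isinstance(doc, Mapping):
        raise ConfigurationError(f"code-list config {source} is not a mapping")
    version = str(doc.get("version", "unversioned"))
    raw_lists = doc.get("lists") or {}
    raw_com = doc.get("comorbidities") or {}
    lists = {n: _parse_list(n, v, version) for n, v in raw_lists.items()}
    comorbidities = {n: _parse_list(n, v, version) for n, v in raw_com.items()}
    return CodeListRegistry(version=version, lists=lists, comorbidities=comorbidities)


@functools.lru_cache(maxsize=1)
def default_registry() -> CodeListRegistry:
    """The shipped approximate default lists (see module docstring)."""
    text = resources.files("aghdstrat").joinpath("data/default_codelists.yaml").read_text()
    return _registry_from_doc(yaml.safe_load(text), source="default_codelists.yaml")


__all__ = [
    "Axis",
    "MatchMode",
    "MANDATORY_LISTS",
    "normalize_code",
    "default_match_mode",
    "CodeEntry",
    "CodeList",
    "CodeListRegistry",
    "matches",
    "distinct_axes",
    "load_codelists",
    "default_registry",
]
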