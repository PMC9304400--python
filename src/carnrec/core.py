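"""Shared domain types for the large-carnivore recovery pipeline.

The central object is :class:`SpeciesRecord`: one taxon with its traits,
current Red List status and population trend, a dated assessment history,
threat observations, conservation-action flags and realm-range proportions.
Red List categories form an ordinal scale (LC < NT < VU < EN < CR < EW < EX);
Data Deficient (DD) and Not Evaluated (NE) carry no rank.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "StatusCategory",
    "TaxonGroup",
    "Trend",
    "Timing",
    "Scope",
    "Severity",
    "AssessmentEvent",
    "ThreatObservation",
    "ActionFlag",
    "SpeciesRecord",
    "status_from_text",
    "THREATENED",
]


class StatusCategory(enum.Enum):
    """IUCN Red List extinction-risk category.

    Ordinal ranks are LC=0, NT=1, VU=2, EN=3, CR=4, EW=5, EX=6.  DD and NE
    are unranked: arithmetic on status changes is undefined for them.
    """

    LC = "LC"
    NT = "NT"
    VU = "VU"
    EN = "EN"
    CR = "CR"
    EW = "EW"
    EX = "EX"
    DD = "DD"
    NE = "NE"

    @property
    def rank(self) -> Optional[int]:
        return _RANKS.get(self)

    @property
    def threatened(self) -> bool:
        """True iff the category is Vulnerable, Endangered or Critically Endangered."""
        return self in THREATENED

    @property
    def known(self) -> bool:
        """An evaluated, data-sufficient category (anything but DD/NE)."""
        return self not in (StatusCategory.DD, StatusCategory.NE)


_RANKS = {
    StatusCategory.LC: 0,
    StatusCategory.NT: 1,
    StatusCategory.VU: 2,
    StatusCategory.EN: 3,
    StatusCategory.CR: 4,
    StatusCategory.EW: 5,
    StatusCategory.EX: 6,
}

THREATENED = frozenset({StatusCategory.VU, StatusCategory.EN, StatusCategory.CR})

_STATUS_NAMES = {
    "least concern": StatusCategory.LC,
    "near threatened": StatusCategory.NT,
    "vulnerable": StatusCategory.VU,
    "endangered": StatusCategory.EN,
    "critically endangered": StatusCategory.CR,
    "extinct in the wild": StatusCategory.EW,
    "extinct": StatusCategory.EX,
    "data deficient": StatusCategory.DD,
    "not evaluated": StatusCategory.NE,
}


def status_from_text(label: str) -> StatusCategory:
    """Parse a Red List category from its full name or two-letter code.

    Parsing is case-insensitive and tolerant of surrounding whitespace;
    IUCN exports vary in capitalization.

    Raises
    ------
    ValueError
        If the label is not one of the nine category names or codes.
    """
    key = str(label).strip()
    try:
        return StatusCategory(key.upper())
    except ValueError:
        pass
    norm = " ".join(key.lower().split())
    if norm in _STATUS_NAMES:
        return _STATUS_NAMES[norm]
    raise ValueError(f"unrecognized Red List category: {label!r}")


class TaxonGroup(enum.Enum):
    SHARKS_RAYS = "sharks_rays"
    BONY_FISHES = "bony_fishes"
    REPTILES_AMPHIBIANS = "reptiles_amphibians"
    BIRDS = "birds"
    TERRESTRIAL_MAMMALS = "terrestrial_mammals"
    MARINE_MAMMALS = "marine_mammals"


class Trend(enum.Enum):
    INCREASING = "increasing"
    DECREASING = "decreasing"
    STABLE = "stable"
    UNKNOWN = "unknown"


class Timing(enum.Enum):
    PAST = "past"
    ONGOING = "ongoing"
    FUTURE = "future"
    UNKNOWN = "unknown"


class Scope(enum.Enum):
    WHOLE = "whole"
    MAJORITY = "majority"
    MINORITY = "minority"
    UNKNOWN = "unknown"


class Severity(enum.Enum):
    VERY_RAPID = "very_rapid"
    RAPID = "rapid"
    SLOW_SIGNIFICANT = "slow_significant"
    NEGLIGIBLE = "negligible"
    NO_DECLINE = "no_decline"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class AssessmentEvent:
    """A dated Red List assessment.

    ``genuine`` marks whether the change from the previously listed category
    reflects a real change in extinction risk (as opposed to new data or
    revised criteria).  The first event of a history carries genuine=False
    by convention.
    """

    year: int
    category: StatusCategory
    genuine: bool = False


@dataclass(frozen=True)
class ThreatObservation:
    """One threat listed against one species, with IUCN timing/scope/severity."""

    raw_code: str
    timing: Timing = Timing.UNKNOWN
    scope: Scope = Scope.UNKNOWN
    severity: Severity = Severity.UNKNOWN
    author_category: Optional[str] = None


@dataclass(frozen=True)
class ActionFlag:
    """A conservation action recorded for a species under one coding scheme."""

    scheme: str  # "iucn" or "author"
    category: str
    in_place: bool = True


@dataclass
class SpeciesRecord:
    species_id: str
    name: str
    taxon_group: TaxonGroup
    system_flags: frozenset = frozenset()  # subset of {terrestrial, freshwater, marine}
    body_mass_kg: float = float("nan")
    trophic_position: Optional[float] = None
    percent_carnivory: Optional[float] = None
    herbivorous_family: bool = False
    scavenger: bool = False
    current_status: StatusCategory = StatusCategory.NE
    population_trend: Trend = Trend.UNKNOWN
    assessments: list = field(default_factory=list)
    threats: list = field(default_factory=list)
    actions: list = field(default_factory=list)
    realm_proportions: dict = field(default_factory=dict)  # realm -> proportion
    altitude_limits: Optional[tuple] = None  # (min_m, max_m)

    def __post_init__(self) -> None:
        self.assessments = sorted(self.assessments, key=lambda a: a.year)
        if self.body_mass_kg is not None and self.body_mass_kg == self.body_mass_kg:
            if self.body_mass_kg <= 0:
                raise ValueError(
                    f"{self.species_id}: body mass must be positive, got {self.body_mass_kg}"
                )

    @property
    def threatened(self) -> bool:
        return self.current_status.threatened

    def actions_in_place(self, scheme: str) -> set:
        return {a.category for a in self.actions if a.scheme == scheme and a.in_place}
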