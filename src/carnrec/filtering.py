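"""Roster assembly: the trait-based large-carnivore filter.

A candidate vertebrate is retained when it (a) is not in an excluded
herbivorous family, (b) meets its taxon/system-specific body-mass threshold,
(c) if a shark, ray or bony fish, has mean trophic position at or above the
minimum, and (d) if a mammal, has percent carnivory at or above the minimum.
Default mass thresholds (kg): sharks/rays, marine teleosts and marine
mammals 50; freshwater teleosts 20; reptiles and amphibians 10; birds 1;
terrestrial mammals 12.  All thresholds are inclusive (>=) and configurable.

Every decision is audited: a species' audit lists each rule it failed, so
``retained`` is equivalent to an empty reason list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core import SpeciesRecord, TaxonGroup

log = logging.getLogger(__name__)

__all__ = ["FilterCriteria", "FilterAudit", "apply_filter", "known_status_subset"]

DEFAULT_MASS_THRESHOLDS_KG = {
    "sharks_rays": 50.0,
    "marine_teleost": 50.0,
    "marine_mammal": 50.0,
    "freshwater_teleost": 20.0,
    "reptiles_amphibians": 10.0,
    "birds": 1.0,
    "terrestrial_mammals": 12.0,
}


@dataclass(frozen=True)
class FilterCriteria:
    mass_threshold_kg: dict = field(
        default_factory=lambda: dict(DEFAULT_MASS_THRESHOLDS_KG)
    )
    trophic_min: float = 4.0
    carnivory_min_pct: float = 50.0
    exclude_herbivorous_families: bool = True
    inclusive: bool = True  # thresholds met at equality

    def __post_init__(self):
        if any(v <= 0 for v in self.mass_threshold_kg.values()):
            raise ValueError("mass thresholds must be strictly positive")
        if self.trophic_min <= 0 or self.carnivory_min_pct <= 0:
            raise ValueError("trait thresholds must be strictly positive")

    def meets(self, value: float, threshold: float) -> bool:
        return value >= threshold if self.inclusive else value > threshold


@dataclass
class FilterAudit:
    species_id: str
    retained: bool
    reasons: list = field(default_factory=list)


def mass_class(record: SpeciesRecord) -> str:
    """Threshold class for a record: fishes split by system, others by taxon.

    A bony fish flagged both marine and freshwater takes the lower
    (freshwater, 20 kg) threshold so borderline species are not falsely
    excluded.
    """
    g = record.taxon_group
    if g is TaxonGroup.BONY_FISHES:
        if "freshwater" in record.system_flags:
            return "freshwater_teleost"
        return "marine_teleost"
    if g is TaxonGroup.MARINE_MAMMALS:
        return "marine_mammal"
    return g.value


_FISH_GROUPS = (TaxonGroup.SHARKS_RAYS, TaxonGroup.BONY_FISHES)
_MAMMAL_GROUPS = (TaxonGroup.TERRESTRIAL_MAMMALS, TaxonGroup.MARINE_MAMMALS)


def audit_species(record: SpeciesRecord, criteria: FilterCriteria) -> FilterAudit:
    reasons = []
    if criteria.exclude_herbivorous_families and record.herbivorous_family:
        reasons.append("herbivorous_family")
    threshold = criteria.mass_threshold_kg[mass_class(record)]
    if not (record.body_mass_kg == record.body_mass_kg):  # NaN mass
        reasons.append("missing_mass")
    elif not criteria.meets(record.body_mass_kg, threshold):
        reasons.append("mass")
    if record.taxon_group in _FISH_GROUPS:
        if record.trophic_position is None:
            reasons.append("missing_trophic")
        elif not criteria.meets(record.trophic_position, criteria.trophic_min):
            reasons.append("trophic")
    if record.taxon_group in _MAMMAL_GROUPS:
        if record.percent_carnivory is None:
            reasons.append("missing_diet")
        elif not criteria.meets(record.percent_carnivory, criteria.carnivory_min_pct):
            reasons.append("carnivory")
    return FilterAudit(record.species_id, retained=not reasons, reasons=reasons)


def apply_filter(roster, criteria: FilterCriteria | None = None):
    """Apply the large-carnivore criteria; returns (retained, audits).

    Idempotent: filtering the retained set again changes nothing, and raising
    any threshold can only shrink the retained set.
    """
    criteria = criteria or FilterCriteria()
    audits = [audit_species(r, criteria) for r in roster]
    retained = [r for r, a in zip(roster, audits) if a.retained]
    return retained, audits


def known_status_subset(cohort):
    """Drop Data Deficient and Not Evaluated species; report how many.

    Returns (retained, n_removed).
    """
    retained = [r for r in cohort if r.current_status.known]
    n_removed = len(cohort) - len(retained)
    if n_removed:
        log.info("known_status_subset: removed %d DD/NE species", n_removed)
    if not retained:
        log.warning("known_status_subset: no species with known status remain")
    return retained, n_removed
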