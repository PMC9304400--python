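"""Threat recoding, impact scoring and binary design matrices.

Raw IUCN threat classification codes are recoded into 23 analyst-defined
categories naming the human sector or activity behind the threat (fishing,
bycatch, conflict, ecosystem modification, hydrological changes, ...).  The
code-to-category mapping ships as an editable table and is never hard-coded
into the analyses.

Each threat-by-species observation gets an *impact score*: the sum of
integer scores for its timing, scope and severity, classed low (<= 5),
medium, or high (>= 8).  Association models exclude low-impact threats and
threats whose timing is still in the future; both exclusions can be toggled
independently for sensitivity comparison.

Conservation actions are coded under two schemes: the 11 IUCN
"Conservation Actions In-Place" categories and a 15-category analyst scheme
nested in 5 broader groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .core import Scope, Severity, ThreatObservation, Timing

log = logging.getLogger(__name__)

__all__ = [
    "THREAT_CATEGORIES",
    "IUCN_ACTION_CATEGORIES",
    "AUTHOR_ACTION_CATEGORIES",
    "AUTHOR_ACTION_GROUPS",
    "ImpactRule",
    "impact_score",
    "filter_threats",
    "recode",
    "recode_cohort",
    "build_design",
    "load_threat_mapping",
    "default_threat_mapping",
]

#: The 23 anthropogenic threat categories.
THREAT_CATEGORIES = (
    "agriculture",
    "aquaculture",
    "bycatch",
    "climate_change",
    "conflict",
    "dietary_toxins",
    "disease",
    "disturbance",
    "ecosystem_modification",
    "energy",
    "fire",
    "fishing",
    "hunting",
    "hydrological_changes",
    "logging",
    "mining",
    "persecution",
    "poisoning",
    "pollution",
    "prey_depletion",
    "species_introductions",
    "trade",
    "urbanization",
)

#: The 11 IUCN "Conservation Actions In-Place" categories.
IUCN_ACTION_CATEGORIES = (
    "action_recovery_plan",
    "area_protection",
    "conservation_sites_identified",
    "education_programs",
    "ex_situ_conservation",
    "harvest_management_plan",
    "international_legislation",
    "invasive_species_control",
    "reintroduction",
    "systematic_monitoring",
    "trade_controls",
)

#: 15 analyst-defined conservation actions nested in 5 broader groups.
AUTHOR_ACTION_GROUPS = {
    "legislation": ("national_legislation", "international_legislation", "local_regulation"),
    "exploitation_management": ("harvest_plan", "fishing_quota", "trade_restriction"),
    "habitat": ("area_protection", "habitat_restoration", "site_management"),
    "species_interventions": ("reintroduction", "captive_breeding", "threat_abatement"),
    "social": ("education", "community_engagement", "compensation_schemes"),
}
AUTHOR_ACTION_CATEGORIES = tuple(
    c for group in AUTHOR_ACTION_GROUPS.values() for c in group
)

ACTION_SCHEMES = {"iucn": IUCN_ACTION_CATEGORIES, "author": AUTHOR_ACTION_CATEGORIES}


@dataclass(frozen=True)
class ImpactRule:
    """Integer scoring of a threat's timing, scope and severity.

    Defaults follow published Red List impact-scoring guidance: the three
    components sum to a score classed low (<= ``low_max``), medium, or high
    (>= ``high_min``).  Fully configurable because assessment practice varies.
    """

    timing_score: dict = field(
        default_factory=lambda: {
            Timing.ONGOING: 3,
            Timing.PAST: 1,
            Timing.FUTURE: 1,
            Timing.UNKNOWN: 2,
        }
    )
    scope_score: dict = field(
        default_factory=lambda: {
            Scope.WHOLE: 3,
            Scope.MAJORITY: 2,
            Scope.MINORITY: 1,
            Scope.UNKNOWN: 2,
        }
    )
    severity_score: dict = field(
        default_factory=lambda: {
            Severity.VERY_RAPID: 3,
            Severity.RAPID: 2,
            Severity.SLOW_SIGNIFICANT: 1,
            Severity.NEGLIGIBLE: 0,
            Severity.NO_DECLINE: 0,
            Severity.UNKNOWN: 1,
        }
    )
    low_max: int = 5
    high_min: int = 8

    def __post_init__(self):
        for m in (self.timing_score, self.scope_score, self.severity_score):
            if any(v < 0 for v in m.values()):
                raise ValueError("impact scores must be non-negative")


def impact_score(threat: ThreatObservation, rule: ImpactRule | None = None):
    """Score one threat observation; returns (score, class) with class in
    {low, medium, high}."""
    rule = rule or ImpactRule()
    score = (
        rule.timing_score[threat.timing]
        + rule.scope_score[threat.scope]
        + rule.severity_score[threat.severity]
    )
    if score <= rule.low_max:
        klass = "low"
    elif score >= rule.high_min:
        klass = "high"
    else:
        klass = "medium"
    return score, klass


def filter_threats(
    threats,
    rule: ImpactRule | None = None,
    drop_future: bool = True,
    drop_low: bool = True,
) -> list[ThreatObservation]:
    """Drop future-timed and/or low-impact threats (idempotent).

    Both switches are independent so the sensitivity comparison — with and
    without low-impact and future threats — reruns on the same inputs.
    """
    rule = rule or ImpactRule()
    out = []
    for t in threats:
        if drop_future and t.timing is Timing.FUTURE:
            continue
        if drop_low and impact_score(t, rule)[1] == "low":
            continue
        out.append(t)
    return out


def default_threat_mapping() -> dict[str, str]:
    """Identity-style default: raw codes of the form ``<category>.<n>`` map to
    the category; bare category names map to themselves."""
    return {c: c for c in THREAT_CATEGORIES}


def load_threat_mapping(path) -> dict[str, str]:
    """Load a raw_code -> author_category table (CSV with those two columns)."""
    df = pd.read_csv(path, dtype=str)
    for col in ("raw_code", "author_category"):
        if col not in df.columns:
            raise ValueError(f"threat mapping: missing column {col}")
    bad = sorted(set(df["author_category"]) - set(THREAT_CATEGORIES))
    if bad:
        raise ValueError(f"threat mapping: unknown categories {bad}")
    return dict(zip(df["raw_code"], df["author_category"]))


def recode(threat: ThreatObservation, mapping: dict[str, str]) -> ThreatObservation:
    """Assign the analyst category for a raw code; unmapped codes stay
    unassigned with a warning (never silently)."""
    base = threat.raw_code.split(".")[0]
    category = mapping.get(threat.raw_code, mapping.get(base))
    if category is None:
        log.warning("unmapped threat code: %r", threat.raw_code)
    return ThreatObservation(
        raw_code=threat.raw_code,
        timing=threat.timing,
        scope=threat.scope,
        severity=threat.severity,
        author_category=category,
    )


def recode_cohort(cohort, mapping: dict[str, str] | None = None) -> list[str]:
    """Recode every species' threats in place; returns the unmapped codes."""
    mapping = mapping if mapping is not None else default_threat_mapping()
    unmapped = set()
    for rec in cohort:
        coded = []
        for t in rec.threats:
            c = recode(t, mapping)
            if c.author_category is None:
                unmapped.add(t.raw_code)
            coded.append(c)
        rec.threats = coded
    return sorted(unmapped)


def build_design(
    cohort,
    scheme: str | None = None,
    threat_rule: ImpactRule | None = None,
    drop_future: bool = True,
    drop_low: bool = True,
) -> pd.DataFrame:
    """Binary species x category design matrix.

    With ``scheme`` ("iucn" or "author"), columns are that scheme's action
    categories and a cell is 1 iff the action is in place for the species.
    Without a scheme, columns are the 23 threat categories and a cell is 1
    iff the species retains a threat of that category after impact/future
    filtering.  Duplicate flags collapse to 1 with a warning.
    """
    ids = [r.species_id for r in cohort]
    if scheme is not None:
        if scheme not in ACTION_SCHEMES:
            raise ValueError(f"unknown action scheme: {scheme}")
        columns = list(ACTION_SCHEMES[scheme])
        data = []
        for r in cohort:
            flags = [a.category for a in r.actions if a.scheme == scheme and a.in_place]
            if len(flags) != len(set(flags)):
                log.warning("%s: duplicate action flags collapsed", r.species_id)
            present = set(flags)
            data.append([1 if c in present else 0 for c in columns])
    else:
        columns = list(THREAT_CATEGORIES)
        data = []
        for r in cohort:
            kept = filter_threats(r.threats, threat_rule, drop_future, drop_low)
            present = {t.author_category for t in kept if t.author_category}
            data.append([1 if c in present else 0 for c in columns])
    return pd.DataFrame(data, index=pd.Index(ids, name="species_id"), columns=columns)
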