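"""Status summaries, genuine status-change trajectories, and recovery indicators.

A *genuine* category change is one IUCN attributes to a real change in
extinction risk rather than to new data or revised criteria.  Change metrics
count only genuine steps occurring on or after the taxon's comprehensive
baseline assessment year (mammals 1996, birds 1988, reptiles and amphibians
1980, all other taxa 1996; configurable).  A step is the signed rank
difference, positive when risk decreases — e.g. Vulnerable to Least Concern
is +2.

Two indicators define recovery: a genuine cumulative improvement in status,
or an IUCN-listed increasing population trend.  Percent-threatened summaries
carry bounds reflecting the Data Deficient species: the lower bound assumes
every DD species is non-threatened, the upper bound that all are threatened.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field

from .core import SpeciesRecord, StatusCategory, TaxonGroup, Trend

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_BASELINES",
    "ChangeSummary",
    "OutcomeVector",
    "RiskSummary",
    "genuine_steps",
    "classify_change",
    "outcomes",
    "cohort_outcomes",
    "dd_bounds",
    "risk_summary",
    "assessment_ages",
]

#: Comprehensive-assessment baseline year per taxon group.
DEFAULT_BASELINES = {
    TaxonGroup.TERRESTRIAL_MAMMALS: 1996,
    TaxonGroup.MARINE_MAMMALS: 1996,
    TaxonGroup.BIRDS: 1988,
    TaxonGroup.REPTILES_AMPHIBIANS: 1980,
    TaxonGroup.SHARKS_RAYS: 1996,
    TaxonGroup.BONY_FISHES: 1996,
}


@dataclass(frozen=True)
class ChangeSummary:
    species_id: str
    genuine_steps: tuple
    last_change: int
    cumulative_change: int
    classification: str  # improved | declined | unchanged


@dataclass(frozen=True)
class OutcomeVector:
    species_id: str
    threatened: bool
    improved: bool
    declined: bool
    increasing: bool
    decreasing: bool

    @property
    def recovery(self) -> bool:
        return self.improved or self.increasing


@dataclass
class RiskSummary:
    group: str
    n_known: int
    n_dd: int
    n_threatened: int
    pct_threatened: float
    lower_bound: float
    upper_bound: float
    category_shares: dict = field(default_factory=dict)


def genuine_steps(
    history,
    baselines: dict | None = None,
    taxon: TaxonGroup | None = None,
) -> list[int]:
    """Signed genuine status steps since the taxon's baseline year.

    One step per consecutive assessment pair where the later event is
    flagged genuine and its year is on or after the baseline; the step is
    rank(previous) - rank(later), so improvement (risk down) is positive.
    Pairs involving an unrankable category (DD/NE) are skipped with a warning.
    """
    baselines = baselines if baselines is not None else DEFAULT_BASELINES
    baseline_year = baselines.get(taxon, 1996) if taxon is not None else 1996
    events = sorted(history, key=lambda a: a.year)
    steps = []
    for prev, curr in zip(events, events[1:]):
        if not curr.genuine or curr.year < baseline_year:
            continue
        if prev.category.rank is None or curr.category.rank is None:
            log.warning(
                "skipping genuine change %s->%s (%d): unrankable category",
                prev.category.value,
                curr.category.value,
                curr.year,
            )
            continue
        steps.append(prev.category.rank - curr.category.rank)
    return steps


def classify_change(species_id: str, steps) -> ChangeSummary:
    """Summarize genuine steps into last/cumulative change and a class."""
    steps = list(steps)
    cumulative = sum(steps)
    if cumulative > 0:
        cls = "improved"
    elif cumulative < 0:
        cls = "declined"
    else:
        cls = "unchanged"
    return ChangeSummary(
        species_id=species_id,
        genuine_steps=tuple(steps),
        last_change=steps[-1] if steps else 0,
        cumulative_change=cumulative,
        classification=cls,
    )


def change_summary(record: SpeciesRecord, baselines: dict | None = None) -> ChangeSummary:
    steps = genuine_steps(record.assessments, baselines, record.taxon_group)
    return classify_change(record.species_id, steps)


def outcomes(record: SpeciesRecord, change: ChangeSummary) -> OutcomeVector:
    """Derive the boolean outcome vector used by the association models.

    Unknown population trend yields increasing=False and decreasing=False
    (merged into the negative class by default).
    """
    return OutcomeVector(
        species_id=record.species_id,
        threatened=record.threatened,
        improved=change.classification == "improved",
        declined=change.classification == "declined",
        increasing=record.population_trend is Trend.INCREASING,
        decreasing=record.population_trend is Trend.DECREASING,
    )


def cohort_outcomes(cohort, baselines: dict | None = None) -> dict[str, OutcomeVector]:
    return {
        r.species_id: outcomes(r, change_summary(r, baselines)) for r in cohort
    }


def dd_bounds(n_threatened: int, n_known: int, n_dd: int) -> tuple[float, float, float]:
    """Percent threatened with Data-Deficient uncertainty bounds.

    pct = 100*T/K over known-status species; the bounds re-express the
    fraction over all assessed species with every DD species assumed
    non-threatened (lower) or threatened (upper).
    """
    if n_known <= 0:
        raise ValueError("n_known must be positive")
    if min(n_threatened, n_dd) < 0 or n_threatened > n_known:
        raise ValueError("inconsistent counts")
    pct = 100.0 * n_threatened / n_known
    lower = 100.0 * n_threatened / (n_known + n_dd)
    upper = 100.0 * (n_threatened + n_dd) / (n_known + n_dd)
    return pct, lower, upper


def _risk_for_group(label: str, members) -> RiskSummary:
    known = [r for r in members if r.current_status.known]
    n_dd = sum(1 for r in members if r.current_status is StatusCategory.DD)
    n_thr = sum(1 for r in known if r.threatened)
    pct, lo, hi = dd_bounds(n_thr, len(known), n_dd)
    shares = {}
    for r in known:
        shares[r.current_status.value] = shares.get(r.current_status.value, 0) + 1
    shares = {k: 100.0 * v / len(known) for k, v in sorted(shares.items())}
    return RiskSummary(
        group=label,
        n_known=len(known),
        n_dd=n_dd,
        n_threatened=n_thr,
        pct_threatened=pct,
        lower_bound=lo,
        upper_bound=hi,
        category_shares=shares,
    )


def risk_summary(cohort, group_by: str = "all") -> list[RiskSummary]:
    """Percent threatened (with DD bounds) and category shares per group.

    ``group_by`` is one of ``all``, ``taxon_group`` or ``realm``; category
    shares are over known-status species only.  Groups with no known-status
    species are omitted with a warning.
    """
    if group_by == "all":
        groups = {"all": list(cohort)}
    elif group_by == "taxon_group":
        groups: dict = {}
        for r in cohort:
            groups.setdefault(r.taxon_group.value, []).append(r)
    elif group_by == "realm":
        groups = {}
        for r in cohort:
            for realm, prop in r.realm_proportions.items():
                if prop > 0:
                    groups.setdefault(realm, []).append(r)
    else:
        raise ValueError(f"unknown group_by: {group_by}")
    out = []
    for label in sorted(groups):
        members = groups[label]
        if not any(r.current_status.known for r in members):
            log.warning("risk_summary: group %r has no known-status species; omitted", label)
            continue
        out.append(_risk_for_group(label, members))
    return out


def assessment_ages(cohort, reference_date: float):
    """Age in years of each species' latest assessment, plus per-taxon medians.

    Returns (ages: dict species_id -> age, medians: dict taxon -> median age).
    """
    ages: dict[str, float] = {}
    by_taxon: dict[str, list] = {}
    for r in cohort:
        if not r.assessments:
            raise ValueError(f"{r.species_id}: no assessments")
        age = reference_date - max(a.year for a in r.assessments)
        ages[r.species_id] = age
        by_taxon.setdefault(r.taxon_group.value, []).append(age)
    medians = {t: statistics.median(v) for t, v in sorted(by_taxon.items())}
    return ages, medians
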