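import pytest

from carnrec.core import (
    AssessmentEvent,
    SpeciesRecord,
    StatusCategory,
    TaxonGroup,
    Trend,
    status_from_text,
)


def make_record(
    species_id="sp0",
    taxon=TaxonGroup.TERRESTRIAL_MAMMALS,
    mass=40.0,
    trophic=None,
    carnivory=80.0,
    status="LC",
    trend=Trend.UNKNOWN,
    assessments=(),
    systems=("terrestrial",),
    **kw,
):
    """Minimal valid SpeciesRecord for unit tests."""
    return SpeciesRecord(
        species_id=species_id,
        name=f"Testus {species_id}",
        taxon_group=taxon,
        system_flags=frozenset(systems),
        body_mass_kg=mass,
        trophic_position=trophic,
        percent_carnivory=carnivory,
        current_status=status_from_text(status),
        population_trend=trend,
        assessments=[AssessmentEvent(*a) for a in assessments],
        **kw,
    )


def hist(*events):
    """Shorthand: hist((2000, "VU"), (2008, "LC", True)) -> AssessmentEvent list."""
    out = []
    for ev in events:
        year, cat = ev[0], status_from_text(ev[1])
        genuine = bool(ev[2]) if len(ev) > 2 else False
        out.append(AssessmentEvent(year=year, category=cat, genuine=genuine))
    return out


@pytest.fixture
def boundary_roster():
    """20 species straddling every filter threshold, with hand-derived audits.

    Returns (roster, expected) where expected maps species_id to the exact
    list of exclusion reasons (empty list = retained).
    """
    TG = TaxonGroup
    rows = [
        # id, taxon, mass, trophic, carnivory, systems, herb, expected reasons
        ("shark_49kg", TG.SHARKS_RAYS, 49.0, 4.5, None, ("marine",), False, ["mass"]),
        ("shark_50kg", TG.SHARKS_RAYS, 50.0, 4.5, None, ("marine",), False, []),
        ("shark_lowtroph", TG.SHARKS_RAYS, 120.0, 3.9, None, ("marine",), False, ["trophic"]),
        ("teleost_t40", TG.BONY_FISHES, 60.0, 4.0, None, ("marine",), False, []),
        ("teleost_t39", TG.BONY_FISHES, 60.0, 3.9, None, ("marine",), False, ["trophic"]),
        ("fw_fish_20kg", TG.BONY_FISHES, 20.0, 4.2, None, ("freshwater",), False, []),
        ("fw_fish_19kg", TG.BONY_FISHES, 19.0, 4.2, None, ("freshwater",), False, ["mass"]),
        ("diadromous_25kg", TG.BONY_FISHES, 25.0, 4.2, None, ("marine", "freshwater"), False, []),
        ("fish_no_troph", TG.BONY_FISHES, 60.0, None, None, ("marine",), False, ["missing_trophic"]),
        ("bird_1kg", TG.BIRDS, 1.0, None, None, ("terrestrial",), False, []),
        ("bird_09kg", TG.BIRDS, 0.9, None, None, ("terrestrial",), False, ["mass"]),
        ("reptile_10kg", TG.REPTILES_AMPHIBIANS, 10.0, None, None, ("terrestrial",), False, []),
        ("reptile_99kg", TG.REPTILES_AMPHIBIANS, 9.9, None, None, ("terrestrial",), False, ["mass"]),
        ("tmammal_12kg_c50", TG.TERRESTRIAL_MAMMALS, 12.0, None, 50.0, ("terrestrial",), False, []),
        ("tmammal_119kg", TG.TERRESTRIAL_MAMMALS, 11.9, None, 80.0, ("terrestrial",), False, ["mass"]),
        ("tmammal_c49", TG.TERRESTRIAL_MAMMALS, 15.0, None, 49.0, ("terrestrial",), False, ["carnivory"]),
        ("tmammal_nodiet", TG.TERRESTRIAL_MAMMALS, 15.0, None, None, ("terrestrial",), False, ["missing_diet"]),
        ("mmammal_50kg", TG.MARINE_MAMMALS, 50.0, None, 90.0, ("marine",), False, []),
        ("mmammal_49kg_c49", TG.MARINE_MAMMALS, 49.0, None, 49.0, ("marine",), False, ["mass", "carnivory"]),
        ("herbivore_bird", TG.BIRDS, 2.0, None, None, ("terrestrial",), True, ["herbivorous_family"]),
    ]
    roster, expected = [], {}
    for sid, taxon, mass, troph, carn, systems, herb, reasons in rows:
        roster.append(
            make_record(
                sid, taxon, mass=mass, trophic=troph, carnivory=carn,
                systems=systems, herbivorous_family=herb,
            )
        )
        expected[sid] = reasons
    return roster, expected


@pytest.fixture
def tiny_cohort():
    """Three species spanning taxa, statuses and trends."""
    return [
        make_record(
            "a", TaxonGroup.MARINE_MAMMALS, mass=800, status="VU",
            trend=Trend.INCREASING, systems=("marine",),
            assessments=((1998, StatusCategory.EN), (2008, StatusCategory.VU, True)),
        ),
        make_record(
            "b", TaxonGroup.BIRDS, mass=4.0, carnivory=None, status="LC",
            trend=Trend.STABLE,
            assessments=((2004, StatusCategory.LC),),
        ),
        make_record(
            "c", TaxonGroup.SHARKS_RAYS, mass=120, trophic=4.5, carnivory=None,
            status="EN", trend=Trend.DECREASING, systems=("marine",),
            assessments=((2000, StatusCategory.VU), (2010, StatusCategory.EN, True)),
        ),
    ]
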