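"""Readers and writers for the five delimited input tables and for reports.

The canonical schema (one row per species / assessment event / threat /
action / realm share):

* ``species.csv`` — species_id, name, taxon_group, systems (semicolon list),
  body_mass_kg, trophic_position, percent_carnivory, herbivorous_family,
  scavenger, current_status, population_trend, altitude_min_m, altitude_max_m
* ``assessments.csv`` — species_id, year, category, genuine
* ``threats.csv`` — species_id, raw_code, timing, scope, severity
* ``actions.csv`` — species_id, scheme, category, in_place
* ``realms.csv`` — species_id, realm, proportion, realm_type

Raw IUCN export dialects are mapped onto this schema with a rename table
(``COLUMN_RENAMES``) before loading.  Rows referencing unknown species ids
are reported and skipped, never silently dropped.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .core import (
    ActionFlag,
    AssessmentEvent,
    Scope,
    Severity,
    SpeciesRecord,
    TaxonGroup,
    ThreatObservation,
    Timing,
    Trend,
    status_from_text,
)

log = logging.getLogger(__name__)

SPECIES_COLUMNS = [
    "species_id",
    "name",
    "taxon_group",
    "systems",
    "body_mass_kg",
    "trophic_position",
    "percent_carnivory",
    "herbivorous_family",
    "scavenger",
    "current_status",
    "population_trend",
    "altitude_min_m",
    "altitude_max_m",
]
ASSESSMENT_COLUMNS = ["species_id", "year", "category", "genuine"]
THREAT_COLUMNS = ["species_id", "raw_code", "timing", "scope", "severity"]
ACTION_COLUMNS = ["species_id", "scheme", "category", "in_place"]
REALM_COLUMNS = ["species_id", "realm", "proportion", "realm_type"]

#: Documented mapping from common IUCN Red List export column names onto the
#: canonical schema; applied (case-insensitively) before validation.
COLUMN_RENAMES = {
    "internalTaxonId": "species_id",
    "scientificName": "name",
    "redlistCategory": "current_status",
    "populationTrend": "population_trend",
    "yearPublished": "year",
    "code": "raw_code",
    "ElevationLower.limit": "altitude_min_m",
    "ElevationUpper.limit": "altitude_max_m",
}


class DatasetError(ValueError):
    """Raised for malformed input tables (missing columns, duplicate keys)."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DatasetError(f"{table}: missing mandatory column(s) {missing}")


def _read_table(path, required, table) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"species_id": str})
    df = df.rename(columns=COLUMN_RENAMES)
    _require_columns(df, required, table)
    return df


def _as_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    if isinstance(x, (int, float)):
        return bool(x)
    return str(x).strip().lower() in ("true", "1", "yes", "t")


def _opt_float(x) -> Optional[float]:
    if x is None or (isinstance(x, float) and x != x) or x == "":
        return None
    return float(x)


def read_dataset(
    species_path,
    assessments_path=None,
    threats_path=None,
    actions_path=None,
    realms_path=None,
) -> list[SpeciesRecord]:
    """Load and link the tabular inputs into :class:`SpeciesRecord` objects.

    Auxiliary tables are optional; rows whose ``species_id`` does not appear
    in the species table are counted, logged, and skipped.  Duplicate
    (species, year) assessment rows raise :class:`DatasetError`.
    """
    sp = _read_table(species_path, ["species_id", "name", "taxon_group"], "species")
    if sp["species_id"].duplicated().any():
        dups = sp.loc[sp["species_id"].duplicated(), "species_id"].tolist()
        raise DatasetError(f"species: duplicate species_id {dups}")

    records: dict[str, SpeciesRecord] = {}
    for row in sp.itertuples(index=False):
        d = row._asdict()
        systems = d.get("systems", "")
        flags = frozenset(
            s.strip() for s in str(systems).split(";") if s.strip() and str(systems) != "nan"
        )
        alt_min = _opt_float(d.get("altitude_min_m"))
        alt_max = _opt_float(d.get("altitude_max_m"))
        rec = SpeciesRecord(
            species_id=str(d["species_id"]),
            name=str(d["name"]),
            taxon_group=TaxonGroup(d["taxon_group"]),
            system_flags=flags,
            body_mass_kg=float(d.get("body_mass_kg", float("nan"))),
            trophic_position=_opt_float(d.get("trophic_position")),
            percent_carnivory=_opt_float(d.get("percent_carnivory")),
            herbivorous_family=_as_bool(d.get("herbivorous_family", False)),
            scavenger=_as_bool(d.get("scavenger", False)),
            current_status=status_from_text(d.get("current_status", "NE")),
            population_trend=Trend(str(d.get("population_trend", "unknown")).lower()),
            altitude_limits=(alt_min, alt_max) if alt_min is not None or alt_max is not None else None,
        )
        records[rec.species_id] = rec

    def _link(path, columns, table, apply):
        if path is None:
            return
        df = _read_table(path, columns, table)
        skipped = 0
        for row in df.itertuples(index=False):
            d = row._asdict()
            sid = str(d["species_id"])
            if sid not in records:
                skipped += 1
                continue
            apply(records[sid], d)
        if skipped:
            log.warning("%s: skipped %d row(s) with unknown species id", table, skipped)

    def _add_assessment(rec, d):
        ev = AssessmentEvent(
            year=int(d["year"]),
            category=status_from_text(d["category"]),
            genuine=_as_bool(d["genuine"]),
        )
        if any(a.year == ev.year for a in rec.assessments):
            raise DatasetError(
                f"assessments: duplicate (species={rec.species_id}, year={ev.year})"
            )
        rec.assessments.append(ev)

    def _add_threat(rec, d):
        rec.threats.append(
            ThreatObservation(
                raw_code=str(d["raw_code"]),
                timing=Timing(str(d["timing"]).lower()),
                scope=Scope(str(d["scope"]).lower()),
                severity=Severity(str(d["severity"]).lower()),
            )
        )

    def _add_action(rec, d):
        rec.actions.append(
            ActionFlag(
                scheme=str(d["scheme"]).lower(),
                category=str(d["category"]),
                in_place=_as_bool(d["in_place"]),
            )
        )

    def _add_realm(rec, d):
        rec.realm_proportions[str(d["realm"])] = float(d["proportion"])

    _link(assessments_path, ASSESSMENT_COLUMNS, "assessments", _add_assessment)
    _link(threats_path, THREAT_COLUMNS, "threats", _add_threat)
    _link(actions_path, ACTION_COLUMNS, "actions", _add_action)
    _link(realms_path, REALM_COLUMNS, "realms", _add_realm)

    for rec in records.values():
        rec.assessments.sort(key=lambda a: a.year)
    return list(records.values())


def cohort_to_tables(cohort: Iterable[SpeciesRecord]) -> dict[str, pd.DataFrame]:
    """Render a cohort back into the five canonical tables (round-trippable)."""
    sp_rows, as_rows, th_rows, ac_rows, re_rows = [], [], [], [], []
    for r in cohort:
        alt = r.altitude_limits or (None, None)
        sp_rows.append(
            {
                "species_id": r.species_id,
                "name": r.name,
                "taxon_group": r.taxon_group.value,
                "systems": ";".join(sorted(r.system_flags)),
                "body_mass_kg": r.body_mass_kg,
                "trophic_position": r.trophic_position,
                "percent_carnivory": r.percent_carnivory,
                "herbivorous_family": r.herbivorous_family,
                "scavenger": r.scavenger,
                "current_status": r.current_status.value,
                "population_trend": r.population_trend.value,
                "altitude_min_m": alt[0],
                "altitude_max_m": alt[1],
            }
        )
        for a in r.assessments:
            as_rows.append(
                {
                    "species_id": r.species_id,
                    "year": a.year,
                    "category": a.category.value,
                    "genuine": a.genuine,
                }
            )
        for t in r.threats:
            th_rows.append(
                {
                    "species_id": r.species_id,
                    "raw_code": t.raw_code,
                    "timing": t.timing.value,
                    "scope": t.scope.value,
                    "severity": t.severity.value,
                }
            )
        for ac in r.actions:
            ac_rows.append(
                {
                    "species_id": r.species_id,
                    "scheme": ac.scheme,
                    "category": ac.category,
                    "in_place": ac.in_place,
                }
            )
        for realm, prop in sorted(r.realm_proportions.items()):
            re_rows.append(
                {
                    "species_id": r.species_id,
                    "realm": realm,
                    "proportion": prop,
                    "realm_type": "marine" if realm.startswith("marine") else "terrestrial",
                }
            )
    return {
        "species": pd.DataFrame(sp_rows, columns=SPECIES_COLUMNS),
        "assessments": pd.DataFrame(as_rows, columns=ASSESSMENT_COLUMNS),
        "threats": pd.DataFrame(th_rows, columns=THREAT_COLUMNS),
        "actions": pd.DataFrame(ac_rows, columns=ACTION_COLUMNS),
        "realms": pd.DataFrame(re_rows, columns=REALM_COLUMNS),
    }


def write_cohort(cohort: Iterable[SpeciesRecord], out_dir) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in cohort_to_tables(cohort).items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        paths[name] = p
    return paths


def write_report(report, path, format: str = "auto") -> None:
    """Write an analysis product as delimited text or structured JSON.

    Outputs are byte-stable given identical inputs: column order is fixed,
    floats are rendered with a fixed format, and dict keys are sorted.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "auto":
        format = "json" if path.suffix == ".json" else "csv"
    if format == "csv":
        df = report if isinstance(report, pd.DataFrame) else pd.DataFrame(report)
        df.to_csv(path, index=False, float_format="%.10g")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format: {format}")


def _json_default(obj):
    import enum as _enum

    import numpy as np

    if isinstance(obj, _enum.Enum):
        return obj.value
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
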