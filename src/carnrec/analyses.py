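"""Orchestration of the prevalence analyses and association models.

Four prevalence analyses compare observed outcome distributions against
null expectations compiled from 2007-2018 Red List data (supplied as a
:class:`BaselineSet` artifact, never computed from live data): population
trend by taxon, trend by realm, change-in-status by taxon, and change by
realm.  Each uses a chi-square goodness-of-fit test (Monte Carlo p-values
when expected counts are small), post-hoc exact binomial tests with Holm
correction when significant, and an accompanying test of independence
(chi-square, or Fisher's exact when expected counts are small).

Association models relate conservation actions to recovery outcomes
(backwards-AIC binomial logistic regression) and threats to negative
outcomes (forward/backward LRT selection), with sensitivity reruns
excluding marine mammals or obligate scavengers.  Exclusion reruns operate
on copies; the primary cohort is never mutated.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import coding, io, stats
from .core import SpeciesRecord, TaxonGroup, Trend
from .filtering import FilterCriteria, apply_filter, known_status_subset
from .recovery import assessment_ages, cohort_outcomes, risk_summary
from .simulate import SimulationConfig, block_cells, generate_cohort

log = logging.getLogger(__name__)

__all__ = [
    "BaselineSet",
    "AnalysisReport",
    "prevalence_analysis",
    "action_association",
    "threat_association",
    "run_all",
]

TREND_LEVELS = ("increasing", "decreasing", "stable")
CHANGE_LEVELS = ("improved", "declined", "unchanged")


@dataclass
class BaselineSet:
    """Null expected outcome distributions (2007-2018 compilation artifact).

    ``trend_props``/``change_props`` map a taxon-group name (or ``"global"``)
    to a proportion map over the trend / change-in-status levels.  Missing
    taxa fall back to the global vector.
    """

    trend_props: dict = field(
        default_factory=lambda: {
            "global": {"increasing": 0.07, "decreasing": 0.38, "stable": 0.55}
        }
    )
    change_props: dict = field(
        default_factory=lambda: {
            "global": {"improved": 0.02, "declined": 0.07, "unchanged": 0.91}
        }
    )

    def __post_init__(self):
        for name, table in (("trend_props", self.trend_props), ("change_props", self.change_props)):
            if "global" not in table:
                raise ValueError(f"{name} must include a 'global' entry")
            for group, vec in table.items():
                total = sum(vec.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"{name}[{group}] sums to {total}, expected 1")

    def trend(self, group: str) -> dict:
        return self.trend_props.get(group, self.trend_props["global"])

    def change(self, group: str) -> dict:
        return self.change_props.get(group, self.change_props["global"])

    @classmethod
    def from_file(cls, path) -> "BaselineSet":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class AnalysisReport:
    """End-to-end analysis product with provenance."""

    seed: int
    config_digest: str
    n_input: int
    n_retained: int
    n_known_status: int
    n_dd: int
    risk_summaries: dict = field(default_factory=dict)
    outcome_table: pd.DataFrame | None = None
    gof_results: dict = field(default_factory=dict)
    glm_fits: dict = field(default_factory=dict)
    assessment_age_medians: dict = field(default_factory=dict)
    age_kruskal: dict = field(default_factory=dict)
    independence: dict = field(default_factory=dict)
    richness_total: np.ndarray | None = None
    richness_recovering: np.ndarray | None = None
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "provenance": {"seed": self.seed, "config_digest": self.config_digest},
            "counts": {
                "n_input": self.n_input,
                "n_retained": self.n_retained,
                "n_known_status": self.n_known_status,
                "n_dd": self.n_dd,
            },
            "risk_summaries": {
                grp: [vars(r) for r in summaries] for grp, summaries in self.risk_summaries.items()
            },
            "gof_results": {
                analysis: {g: res.to_dict() for g, res in groups.items()}
                for analysis, groups in self.gof_results.items()
            },
            "glm_fits": {name: fit.to_dict() for name, fit in self.glm_fits.items()},
            "independence": self.independence,
            "assessment_age_medians": self.assessment_age_medians,
            "age_kruskal": self.age_kruskal,
            "warnings": self.warnings,
        }


def _counts(members, levels, level_of) -> np.ndarray:
    counts = dict.fromkeys(levels, 0)
    for m in members:
        lv = level_of(m)
        if lv in counts:
            counts[lv] += 1
    return np.array([counts[lv] for lv in levels], dtype=float)


def _gof_with_posthoc(obs, props, levels, seed, n_sim=10000) -> stats.GOFResult:
    # drop levels with zero expected proportion up front
    keep = [i for i, p in enumerate(props) if p > 0]
    obs_k = np.asarray(obs, dtype=float)[keep]
    props_k = np.asarray(props, dtype=float)[keep]
    props_k = props_k / props_k.sum()
    levels_k = [levels[i] for i in keep]
    res = stats.gof_chisq(obs_k, props_k, seed=seed, n_sim=n_sim)
    if res.significant:
        res.posthoc = stats.posthoc_binomial(
            obs_k.astype(int), int(obs_k.sum()), props_k, categories=levels_k
        )
    return res


def _independence_test(table: np.ndarray, seed: int, n_sim=10000) -> dict:
    """Chi-square test of independence; Fisher's exact when any expected < 5."""
    table = np.asarray(table, dtype=int)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return {"method": "degenerate", "p_value": float("nan")}
    chi2, p, dof, expected = sps.chi2_contingency(table)
    if (expected < 5).any():
        p = stats.fisher_exact(table, seed=seed)
        return {"method": "fisher_exact", "statistic": float(chi2), "p_value": float(p)}
    return {"method": "chi2_independence", "statistic": float(chi2), "df": int(dof), "p_value": float(p)}


def _realm_groups(cohort) -> dict:
    groups: dict[str, list] = {}
    for r in cohort:
        for realm, prop in r.realm_proportions.items():
            if prop > 0:
                groups.setdefault(realm, []).append(r)
    return groups


def prevalence_analysis(
    cohort,
    baselines: BaselineSet | None = None,
    outcomes: dict | None = None,
    seed: int = 0,
    n_sim: int = 10000,
) -> dict:
    """Run the four prevalence analyses; returns GOF results per group plus
    an independence test per analysis.

    Trend analyses use species with a known (non-unknown) population trend;
    change analyses use all species with computed change classifications.
    Groups with no species are skipped with a warning.
    """
    baselines = baselines or BaselineSet()
    outcomes = outcomes if outcomes is not None else cohort_outcomes(cohort)

    def trend_level(rec):
        return rec.population_trend.value

    def change_level(rec):
        ov = outcomes[rec.species_id]
        if ov.improved:
            return "improved"
        if ov.declined:
            return "declined"
        return "unchanged"

    taxon_groups = {}
    for r in cohort:
        taxon_groups.setdefault(r.taxon_group.value, []).append(r)
    realm_groups = _realm_groups(cohort)

    results: dict = {}
    analyses = [
        ("trend_by_taxon", taxon_groups, TREND_LEVELS, trend_level, baselines.trend, True),
        ("trend_by_realm", realm_groups, TREND_LEVELS, trend_level, lambda g: baselines.trend("global"), True),
        ("change_by_taxon", taxon_groups, CHANGE_LEVELS, change_level, baselines.change, False),
        ("change_by_realm", realm_groups, CHANGE_LEVELS, change_level, lambda g: baselines.change("global"), False),
    ]
    rng = np.random.default_rng(seed)
    for name, groups, levels, level_of, expected_of, known_trend_only in analyses:
        per_group = {}
        tables = []
        for gname in sorted(groups):
            members = groups[gname]
            if known_trend_only:
                members = [m for m in members if m.population_trend is not Trend.UNKNOWN]
            if not members:
                log.warning("%s: group %r empty; skipped", name, gname)
                continue
            obs = _counts(members, levels, level_of)
            if obs.sum() == 0:
                log.warning("%s: group %r has no classifiable species; skipped", name, gname)
                continue
            props = np.array([expected_of(gname)[lv] for lv in levels], dtype=float)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            per_group[gname] = _gof_with_posthoc(obs, props, list(levels), sub_seed, n_sim)
            tables.append(obs)
        results[name] = per_group
        if len(tables) >= 2:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            results[f"{name}_independence"] = _independence_test(
                np.array(tables), sub_seed, n_sim
            )
    return results


def _exclude(cohort, exclusion: str):
    """Copy of the cohort with the named sensitivity group removed."""
    if exclusion == "none":
        return list(cohort)
    if exclusion == "marine_mammals":
        return [r for r in cohort if r.taxon_group is not TaxonGroup.MARINE_MAMMALS]
    if exclusion == "scavengers":
        return [r for r in cohort if not r.scavenger]
    raise ValueError(f"unknown exclusion set: {exclusion}")


def _prune_degenerate(design: pd.DataFrame) -> pd.DataFrame:
    """Drop constant (all-0/all-1) predictor columns, which carry no
    information and destabilize the fit; the drop is logged."""
    keep = [c for c in design.columns if design[c].nunique() > 1]
    dropped = sorted(set(design.columns) - set(keep))
    if dropped:
        log.info("dropping constant design column(s): %s", dropped)
    return design[keep]


def _response_vector(cohort, outcomes: dict, response: str) -> np.ndarray:
    vals = []
    for r in cohort:
        ov = outcomes[r.species_id]
        vals.append(
            {
                "improved": ov.improved,
                "declined": ov.declined,
                "increasing": ov.increasing,
                "decreasing": ov.decreasing,
                "threatened": ov.threatened,
                "recovery": ov.recovery,
            }[response]
        )
    return np.asarray(vals, dtype=float)


def action_association(
    cohort,
    scheme: str,
    response: str,
    outcomes: dict | None = None,
    exclusion: str = "none",
) -> stats.GLMFit:
    """Backwards-AIC logistic model of a recovery outcome on action flags."""
    if response not in ("improved", "increasing", "recovery"):
        raise ValueError(f"invalid recovery response: {response}")
    outcomes = outcomes if outcomes is not None else cohort_outcomes(cohort)
    sub = _exclude(cohort, exclusion)
    design = _prune_degenerate(coding.build_design(sub, scheme=scheme))
    y = _response_vector(sub, outcomes, response)
    fit = stats.stepwise_aic(design, y)
    fit.exclusion = exclusion
    return fit


def threat_association(
    cohort,
    response: str,
    outcomes: dict | None = None,
    exclusion: str = "none",
    drop_future: bool = True,
    drop_low: bool = True,
) -> stats.GLMFit:
    """Forward/backward-LRT logistic model of a negative outcome on coded,
    impact-filtered threat indicators."""
    if response not in ("threatened", "declined", "decreasing"):
        raise ValueError(f"invalid decline response: {response}")
    outcomes = outcomes if outcomes is not None else cohort_outcomes(cohort)
    sub = _exclude(cohort, exclusion)
    design = _prune_degenerate(
        coding.build_design(sub, drop_future=drop_future, drop_low=drop_low)
    )
    y = _response_vector(sub, outcomes, response)
    fit = stats.stepwise_lrt(design, y)
    fit.exclusion = exclusion
    return fit


def _config_digest(cfg: SimulationConfig) -> str:
    def sanitize(obj):
        if isinstance(obj, dict):
            return {str(getattr(k, "value", k)): sanitize(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
        if isinstance(obj, (list, tuple)):
            return [sanitize(x) for x in obj]
        return getattr(obj, "value", obj)

    payload = json.dumps(sanitize(vars(cfg)), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    out_dir=None,
    baselines: BaselineSet | None = None,
    n_sim: int = 10000,
) -> AnalysisReport:
    """Simulate (or accept) a cohort and run the full analysis pipeline.

    Stages: trait filter -> known-status subset -> threat recoding ->
    outcome vectors -> risk summaries -> four prevalence analyses ->
    action/threat association models with sensitivity reruns -> assessment
    ages -> richness maps.  A fixed seed yields byte-identical outputs.
    """
    cfg = config or SimulationConfig()
    if seed is not None:
        cfg.seed = seed
    baselines = baselines or BaselineSet()
    log.info("run_all: simulating cohort (n=%d, seed=%d)", cfg.n_species, cfg.seed)
    cohort, gt = generate_cohort(cfg)

    retained, audits = apply_filter(cohort, FilterCriteria())
    log.info("filter: retained %d/%d species", len(retained), len(cohort))
    known, n_dd_ne = known_status_subset(retained)
    n_dd = sum(1 for r in retained if r.current_status.value == "DD")
    coding.recode_cohort(known)
    outcomes = cohort_outcomes(known)

    report = AnalysisReport(
        seed=cfg.seed,
        config_digest=_config_digest(cfg),
        n_input=len(cohort),
        n_retained=len(retained),
        n_known_status=len(known),
        n_dd=n_dd,
    )

    report.risk_summaries = {
        "all": risk_summary(retained, "all"),
        "taxon_group": risk_summary(retained, "taxon_group"),
        "realm": risk_summary(retained, "realm"),
    }
    report.outcome_table = pd.DataFrame(
        [
            {
                "species_id": ov.species_id,
                "threatened": ov.threatened,
                "improved": ov.improved,
                "declined": ov.declined,
                "increasing": ov.increasing,
                "decreasing": ov.decreasing,
                "recovery": ov.recovery,
            }
            for ov in (outcomes[r.species_id] for r in known)
        ]
    )

    prev_seed = int(np.random.SeedSequence(cfg.seed).spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
    prevalence = prevalence_analysis(known, baselines, outcomes, seed=prev_seed, n_sim=n_sim)
    report.gof_results = {k: v for k, v in prevalence.items() if not k.endswith("_independence")}
    report.independence = {k: v for k, v in prevalence.items() if k.endswith("_independence")}

    fits: dict[str, stats.GLMFit] = {}
    for response in ("improved", "increasing"):
        fits[f"iucn_actions~{response}"] = action_association(known, "iucn", response, outcomes)
    fits["author_actions~recovery"] = action_association(known, "author", "recovery", outcomes)
    fits["iucn_actions~improved|no_marine_mammals"] = action_association(
        known, "iucn", "improved", outcomes, exclusion="marine_mammals"
    )
    for response in ("threatened", "declined", "decreasing"):
        fits[f"threats~{response}"] = threat_association(known, response, outcomes)
    fits["threats~declined|no_scavengers"] = threat_association(
        known, "declined", outcomes, exclusion="scavengers"
    )
    report.glm_fits = fits

    ages, medians = assessment_ages(known, reference_date=2020.0)
    report.assessment_age_medians = medians
    taxa = sorted({r.taxon_group.value for r in known})
    groups = [
        [ages[r.species_id] for r in known if r.taxon_group.value == t] for t in taxa
    ]
    groups = [g for g in groups if g]
    if len(groups) >= 2:
        H, df, p = stats.kruskal_wallis(groups)
        report.age_kruskal = {"H": H, "df": df, "p_value": p}

    from .ranges import GridSpec, richness as richness_op

    grid = GridSpec(*cfg.grid)
    layers = {
        r.species_id: block_cells(gt.range_blocks[r.species_id]) for r in known
    }
    report.richness_total = richness_op(layers, grid)
    recovering = [sid for sid, ov in outcomes.items() if ov.recovery]
    report.richness_recovering = richness_op(layers, grid, subset=recovering)

    if out_dir is not None:
        _write_outputs(report, Path(out_dir))
    return report


def _write_outputs(report: AnalysisReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    io.write_report(report.outcome_table, out_dir / "outcomes.csv")
    risk_rows = []
    for grouping, summaries in report.risk_summaries.items():
        for s in summaries:
            row = {k: v for k, v in vars(s).items() if k != "category_shares"}
            row["grouping"] = grouping
            risk_rows.append(row)
    io.write_report(pd.DataFrame(risk_rows), out_dir / "risk_summary.csv")
    fit_rows = []
    for name, fit in report.glm_fits.items():
        df = fit.to_frame()
        df.insert(0, "model", name)
        df["exclusion"] = fit.exclusion
        fit_rows.append(df)
    io.write_report(pd.concat(fit_rows, ignore_index=True), out_dir / "glm_fits.csv")
    io.write_report(report.to_dict(), out_dir / "report.json")
    np.savetxt(out_dir / "richness_total.csv", report.richness_total, fmt="%d", delimiter=",")
    np.savetxt(
        out_dir / "richness_recovering.csv", report.richness_recovering, fmt="%d", delimiter=","
    )
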