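"""Cohort construction: drug-group assignment, event matching, analysis rows.

Group assignment follows an inclusion–exclusion precedence over cleanser
components found among a report's drugs (primary-suspect role by default):
any bisacodyl component wins; otherwise a PEG component without an oral
sulfate/picosulfate (OSS) component is PEG; an OSS component without PEG is
OSS; a PEG+OSS combination without bisacodyl falls outside both group
definitions and is excluded (logged). Sodium-phosphate regimens are
recognized and tagged but never grouped.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptive import season_of, worst_outcomes_by_report, MISSING_OUTCOME
from .dictionaries import (
    DRUG_GROUPS,
    DrugGroupSpec,
    EventSpec,
    GROUP_BISACODYL,
    GROUP_NONE,
    GROUP_OSS,
    GROUP_PEG,
    TAG_SODIUM_PHOSPHATE,
    default_drug_groups,
    sodium_phosphate_terms,
)
from .errors import ConfigError
from .records import (
    QuarterBundle,
    ages_in_years,
    concat_frames,
    reporter_type,
    weights_in_kg,
)

COHORT_COLUMNS = [
    "primaryid", "caseid", "drug_group", "is_target_event", "role_used", "year",
    "season", "season_source", "age_years", "sex", "weight_kg", "reporter_type",
    "country", "worst_outcome", "indication", "concomitants",
]


def _normalize_pt(s: pd.Series) -> pd.Series:
    # normalize on the unique PT strings only; corpora repeat PTs heavily
    codes, uniques = pd.factorize(s.fillna(""))
    norm = np.asarray([" ".join(str(u).lower().split()) for u in uniques], dtype=object)
    return pd.Series(norm[codes], index=s.index)


def match_event(reactions, spec: EventSpec | None = None,
                first_only: bool = False) -> bool:
    """True iff a reaction PT names the target event (case/whitespace
    insensitive). With ``first_only`` only the first-listed reaction counts
    (the stricter reading of "primary adverse event")."""
    spec = spec or EventSpec()
    terms = spec.normalized_terms()
    if isinstance(reactions, pd.DataFrame):
        pts = reactions["pt"].tolist()
    else:
        pts = list(reactions)
    if first_only:
        pts = pts[:1]
    return any(" ".join(str(p).lower().split()) in terms for p in pts)


def _component_table(drugs: pd.DataFrame, specs: list[DrugGroupSpec],
                     role: str | None) -> pd.DataFrame:
    """Per-report boolean component flags from substring matching."""
    sub = drugs
    if role:
        sub = drugs[drugs["role_cod"].str.upper().str.strip() == role]
    if sub.empty:
        return pd.DataFrame(columns=["primaryid"])
    # match on unique names only, then broadcast back through the codes
    codes, uniques = pd.factorize(sub["drugname"].fillna(""))
    low_u = np.asarray([str(u).lower() for u in uniques], dtype=object)
    flags = pd.DataFrame({"primaryid": sub["primaryid"].to_numpy()})
    components: dict[str, np.ndarray] = {}

    def match_terms(terms) -> np.ndarray:
        mask_u = np.zeros(len(low_u), dtype=bool)
        for term in terms:
            t = term.lower()
            mask_u |= np.fromiter((t in name for name in low_u), bool, len(low_u))
        return mask_u[codes]

    for spec in specs:
        mask = match_terms(spec.include_terms)
        for tag in spec.component_tags:
            components[tag] = components.get(tag, np.zeros(len(sub), bool)) | mask
    components[TAG_SODIUM_PHOSPHATE] = match_terms(sodium_phosphate_terms())
    for tag, mask in components.items():
        flags[tag] = mask
    return flags.groupby("primaryid", sort=False).any().reset_index()


def _resolve_groups(flags: pd.DataFrame) -> pd.Series:
    """Apply the precedence rule to a per-report component-flag frame."""
    bis = flags.get(GROUP_BISACODYL, pd.Series(False, index=flags.index))
    peg = flags.get(GROUP_PEG, pd.Series(False, index=flags.index))
    oss = flags.get(GROUP_OSS, pd.Series(False, index=flags.index))
    group = np.select(
        [bis.to_numpy(), (peg & ~oss).to_numpy(), (oss & ~peg).to_numpy()],
        [GROUP_BISACODYL, GROUP_PEG, GROUP_OSS],
        default=GROUP_NONE,
    )
    return pd.Series(group, index=flags.index)


def assign_drug_group(drugs, specs: list[DrugGroupSpec] | None = None,
                      role: str | None = "PS") -> str:
    """Cleanser group of one report's drug rows ('none' if no match).

    ``drugs`` may be a DRUG DataFrame or a list of drug-name strings (all
    treated as the filtered role).
    """
    specs = specs if specs is not None else default_drug_groups()
    _check_specs(specs)
    if not isinstance(drugs, pd.DataFrame):
        drugs = pd.DataFrame({"primaryid": ["_"] * len(list(drugs)),
                              "role_cod": role or "PS",
                              "drugname": list(drugs)})
    if drugs.empty:
        return GROUP_NONE
    flags = _component_table(drugs, specs, role)
    if flags.empty:
        return GROUP_NONE
    return str(_resolve_groups(flags).iloc[0])


def _check_specs(specs: list[DrugGroupSpec]) -> None:
    names = {s.name for s in specs}
    missing = set(DRUG_GROUPS) - names
    if missing:
        raise ConfigError(f"drug group specs must cover {DRUG_GROUPS}; missing {missing}")


@dataclass
class Background:
    """Whole-database totals the contingency cells c and d need, plus the
    per-PT and per-year material for profiles and trend series."""

    n_reports: int
    n_event_reports: int
    group_counts: dict[str, int]
    group_event_counts: dict[str, int]
    group_year: pd.DataFrame  # drug_group, year, n_reports, n_cases
    reac: pd.DataFrame        # primaryid, pt (retained reports)
    group_of: pd.Series       # primaryid -> drug_group (incl. 'none')
    exclusion_log: list[dict] = field(default_factory=list)


def build_cohort(bundles: list[QuarterBundle], retained: set[str] | None = None,
                 specs: list[DrugGroupSpec] | None = None,
                 event_spec: EventSpec | None = None,
                 role: str | None = "PS",
                 event_first_only: bool = False,
                 ) -> tuple[pd.DataFrame, Background]:
    """Assemble the cleanser cohort and the background totals.

    One cohort row per retained report whose drug group is not 'none';
    the :class:`Background` carries the totals over *all* retained reports
    needed for the contingency cells, annual series and PT profiles.
    ``retained`` defaults to all reports (callers normally pass the output
    of :func:`faersig.io.deduplicate`).
    """
    from .io import deduplicate

    specs = specs if specs is not None else default_drug_groups()
    _check_specs(specs)
    event_spec = event_spec or EventSpec()

    demo = concat_frames(bundles, "DEMO")
    if retained is None:
        retained = deduplicate(demo)
    demo = demo[demo["primaryid"].isin(retained)].drop_duplicates("primaryid")
    drugs = concat_frames(bundles, "DRUG")
    reac = concat_frames(bundles, "REAC")
    outc = concat_frames(bundles, "OUTC")
    indi = concat_frames(bundles, "INDI")
    drugs = drugs[drugs["primaryid"].isin(retained)]
    reac = reac[reac["primaryid"].isin(retained)]
    outc = outc[outc["primaryid"].isin(retained)]
    indi = indi[indi["primaryid"].isin(retained)]

    # event flag per report (optionally only the first-listed reaction)
    if reac.empty:
        event_ids: set[str] = set()
    else:
        scope = reac.drop_duplicates("primaryid") if event_first_only else reac
        norm = _normalize_pt(scope["pt"].fillna(""))
        event_ids = set(scope.loc[norm.isin(event_spec.normalized_terms()), "primaryid"])

    # component flags and groups per report
    flags = _component_table(drugs, specs, role)
    exclusion_log: list[dict] = []
    if not flags.empty:
        groups = _resolve_groups(flags)
        peg = flags.get(GROUP_PEG, pd.Series(False, index=flags.index))
        oss = flags.get(GROUP_OSS, pd.Series(False, index=flags.index))
        bis = flags.get(GROUP_BISACODYL, pd.Series(False, index=flags.index))
        for pid in flags.loc[(peg & oss & ~bis), "primaryid"]:
            exclusion_log.append({"primaryid": pid,
                                  "reason": "PEG+OSS combination outside both group definitions"})
        for pid in flags.loc[flags[TAG_SODIUM_PHOSPHATE] & (groups == GROUP_NONE), "primaryid"]:
            exclusion_log.append({"primaryid": pid,
                                  "reason": "sodium-phosphate regimen (tagged, not grouped)"})
        group_of = pd.Series(groups.to_numpy(), index=flags["primaryid"].to_numpy())
    else:
        group_of = pd.Series(dtype=object)
    group_of = group_of.reindex(demo["primaryid"]).fillna(GROUP_NONE)
    group_of.index = demo["primaryid"].to_numpy()

    # per-report derived fields
    demo = demo.set_index("primaryid", drop=False)
    year = pd.to_numeric(demo["fda_dt"].str[:4], errors="coerce").astype("Int64")
    is_event = demo["primaryid"].isin(event_ids)
    groups_all = group_of.reindex(demo.index).fillna(GROUP_NONE)

    # background per-group per-year series (all retained reports)
    gy = pd.DataFrame({"drug_group": groups_all.to_numpy(), "year": year.to_numpy(),
                       "is_target_event": is_event.to_numpy()})
    gy = gy.dropna(subset=["year"])
    if len(gy):
        gy["year"] = gy["year"].astype(int)
        group_year = (gy.groupby(["drug_group", "year"])
                        .agg(n_reports=("is_target_event", "size"),
                             n_cases=("is_target_event", "sum"))
                        .reset_index())
        group_year["n_cases"] = group_year["n_cases"].astype(int)
    else:
        group_year = pd.DataFrame(columns=["drug_group", "year", "n_reports", "n_cases"])

    background = Background(
        n_reports=int(len(demo)),
        n_event_reports=int(is_event.sum()),
        group_counts={g: int((groups_all == g).sum()) for g in DRUG_GROUPS},
        group_event_counts={g: int(((groups_all == g) & is_event).sum()) for g in DRUG_GROUPS},
        group_year=group_year,
        reac=reac[["primaryid", "pt"]].copy(),
        group_of=groups_all,
        exclusion_log=exclusion_log,
    )

    in_cohort = groups_all.isin(DRUG_GROUPS)
    cohort_demo = demo[in_cohort.to_numpy()]
    if cohort_demo.empty:
        return pd.DataFrame(columns=COHORT_COLUMNS), background

    idx = cohort_demo.index
    cohort_ids = set(idx)
    worst = worst_outcomes_by_report(outc[outc["primaryid"].isin(cohort_ids)])
    indi_c = indi[indi["primaryid"].isin(cohort_ids)]
    indi_first = (indi_c[indi_c["indi_pt"].str.strip() != ""]
                  .groupby("primaryid")["indi_pt"].first()) if len(indi_c) else pd.Series(dtype=object)
    conc = drugs[drugs["primaryid"].isin(cohort_ids)
                 & (drugs["role_cod"].str.upper().str.strip() == "C")]
    conc_join = (conc.groupby("primaryid")["drugname"].agg("; ".join)
                 if len(conc) else pd.Series(dtype=object))
    season_date = cohort_demo["event_dt"].where(
        cohort_demo["event_dt"].str.len() >= 6, cohort_demo["fda_dt"])
    seasons = season_date.map(season_of)
    season_source = np.where(cohort_demo["event_dt"].str.len() >= 6, "event_dt", "fda_dt")
    cohort = pd.DataFrame({
        "primaryid": cohort_demo["primaryid"].to_numpy(),
        "caseid": cohort_demo["caseid"].to_numpy(),
        "drug_group": groups_all[in_cohort].to_numpy(),
        "is_target_event": is_event[in_cohort].to_numpy(),
        "role_used": role or "any",
        "year": year[in_cohort.to_numpy()].to_numpy(),
        "season": seasons.to_numpy(),
        "season_source": season_source,
        "age_years": ages_in_years(cohort_demo).to_numpy(),
        "sex": cohort_demo["sex"].str.upper().str.strip().to_numpy(),
        "weight_kg": weights_in_kg(cohort_demo).to_numpy(),
        "reporter_type": cohort_demo["occp_cod"].map(reporter_type).to_numpy(),
        "country": cohort_demo["reporter_country"].to_numpy(),
        "worst_outcome": worst.reindex(idx).fillna(MISSING_OUTCOME).to_numpy(),
        "indication": indi_first.reindex(idx).fillna("").to_numpy(),
        "concomitants": conc_join.reindex(idx).fillna("").to_numpy(),
    })
    return cohort.reset_index(drop=True), background
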