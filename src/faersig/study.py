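"""End-to-end study orchestration: ingest -> dedup -> cohort -> signals ->
descriptives, emitting the report tables as TSV plus a run manifest.

Every number in the report bundle is recomputable from the emitted cohort
TSV and the contingency cells — there is no hidden state, and a fixed seed
yields a byte-identical bundle.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel

from . import __version__
from .cohort import Background, build_cohort
from .descriptive import (
    OUTCOME_CATEGORIES,
    categorize_concomitants,
    chi2_test,
    demographics_summary,
    fisher_rxc,
    seasonal_counts,
)
from .dictionaries import (
    DRUG_GROUPS,
    ConcomitantDictionary,
    EventSpec,
    default_drug_groups,
    load_dictionaries,
)
from .errors import ConfigError, DataError, EnumerationLimitError
from .io import deduplicate, discover_quarters, parse_quarter
from .simulate import SimConfig, generate
from .signals import pt_profile, round_for_report, signal_table


class StudyConfig(BaseModel):
    """One study run: exactly one input mode (FAERS directory or synthetic)."""

    faers_dir: str | None = None
    quarters: list[str] | None = None
    sim: SimConfig | None = None
    dictionaries_path: str | None = None
    role: str = "PS"
    output_dir: str = "study_out"
    seed: int = 0

    def model_post_init(self, __context):
        if (self.faers_dir is None) == (self.sim is None):
            raise ConfigError("exactly one input mode: faers_dir or sim")


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class StudyResult:
    cohort: pd.DataFrame
    background: Background
    tables: dict[str, pd.DataFrame]
    output_dir: Path


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full pipeline and write the report bundle to the output dir."""
    if config.dictionaries_path:
        specs, event_spec, conc_dict = load_dictionaries(config.dictionaries_path)
    else:
        specs, event_spec, conc_dict = (default_drug_groups(), EventSpec(),
                                        ConcomitantDictionary())

    if config.sim is not None:
        bundles, _ledger = generate(config.sim, seed=config.seed)
    else:
        labels = config.quarters or discover_quarters(config.faers_dir)
        if not labels:
            raise DataError(f"no quarterly files found in {config.faers_dir}")
        bundles = [parse_quarter(config.faers_dir, q) for q in labels]

    retained = deduplicate(bundles)
    cohort, background = build_cohort(bundles, retained, specs, event_spec,
                                      role=config.role)
    tables: dict[str, pd.DataFrame] = {}

    # Signal table (disproportionality twin) + per-group PT profiles
    present = [g for g in DRUG_GROUPS if background.group_counts.get(g)]
    tables["signals"] = round_for_report(
        signal_table(background, present + (["all"] if present else [])))
    profiles = []
    for g in present:
        prof = pt_profile(background, g)
        prof.insert(0, "drug_group", g)
        profiles.append(prof)
    tables["pt_profile"] = (round_for_report(pd.concat(profiles, ignore_index=True))
                            if profiles else pd.DataFrame())

    # Demographics of the target-event cases (clinical-features twin)
    cases = cohort[cohort["is_target_event"]]
    demo_tables = demographics_summary(cases) if len(cases) else {}
    for name, df in demo_tables.items():
        tables[f"demographics_{name}"] = round_for_report(df)

    # Indication x group cross-tab and per-outcome group comparisons
    if len(cases):
        ind = (cases.assign(indication=cases["indication"].replace("", "Missing"))
               .pivot_table(index="indication", columns="drug_group",
                            values="primaryid", aggfunc="count", fill_value=0)
               .reset_index())
        tables["indications"] = ind
        comp_rows = []
        for outcome in OUTCOME_CATEGORIES:
            counts = []
            for g in present:
                sub = cases[cases["drug_group"] == g]
                k = int((sub["worst_outcome"] == outcome).sum())
                counts.append([k, len(sub) - k])
            table = np.asarray(counts)
            if table.size == 0 or table[:, 0].sum() == 0:
                continue
            try:
                p_exact = fisher_rxc(table, max_tables=2_000_000)
                test = "fisher_rxc"
            except EnumerationLimitError:
                p_exact = fisher_rxc(table, monte_carlo=20000, seed=config.seed)
                test = "fisher_rxc_mc"
            stat, df_, p_chi2 = chi2_test(table)
            comp_rows.append({"comparison": f"{outcome} by drug group",
                              "test": test, "p_exact": p_exact,
                              "chi2": stat, "df": df_, "p_chi2": p_chi2})
        tables["comparisons"] = round_for_report(pd.DataFrame(comp_rows), 4)

        # Concomitant categories, total and severe-outcome cases
        def conc_names(frame: pd.DataFrame) -> list[str]:
            out: list[str] = []
            for joined in frame["concomitants"]:
                if joined:
                    out.extend(x.strip() for x in joined.split(";") if x.strip())
            return out

        total_cat = categorize_concomitants(conc_names(cases), conc_dict)
        severe = cases[cases["worst_outcome"].isin(["Death", "Life-threatening"])]
        severe_cat = categorize_concomitants(conc_names(severe), conc_dict)
        merged = total_cat.merge(severe_cat, on="category",
                                 suffixes=("_total", "_severe"))
        tables["concomitants"] = round_for_report(merged)

        # Annual series per group and seasonal distribution of cases
        annual_frames = []
        for g in present + ["all"]:
            gy = background.group_year
            sub = (gy[gy["drug_group"].isin(DRUG_GROUPS)] if g == "all"
                   else gy[gy["drug_group"] == g])
            flat = sub.groupby("year")[["n_reports", "n_cases"]].sum().reset_index()
            per = pd.DataFrame({
                "year": flat["year"], "n_cases": flat["n_cases"],
                "n_reports": flat["n_reports"],
                "proportion_pct": 100.0 * flat["n_cases"] / flat["n_reports"],
            })
            per.insert(0, "drug_group", g)
            annual_frames.append(per)
        tables["annual"] = round_for_report(
            pd.concat(annual_frames, ignore_index=True), 4)
        tables["seasonal"] = round_for_report(seasonal_counts(cases["season"]))

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_out = cohort.copy()
    tables_written = {}
    _write_tsv(cohort_out, out / "cohort.tsv")
    for name, df in tables.items():
        _write_tsv(df, out / f"{name}.tsv")
        tables_written[name] = f"{name}.tsv"

    dict_payload = yaml.safe_dump({
        "groups": [{g.name: g.include_terms} for g in specs],
        "event": event_spec.pt_terms,
        "concomitant": list(conc_dict.categories),
    }, sort_keys=True)
    manifest = {
        "faersig_version": __version__,
        "pandas_version": pd.__version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "role": config.role,
        "input_mode": "synthetic" if config.sim is not None else "faers_dir",
        "n_retained_reports": background.n_reports,
        "n_cohort_reports": int(len(cohort)),
        "n_target_event_cases": int(cohort["is_target_event"].sum()) if len(cohort) else 0,
        "dictionary_hash": _sha256(dict_payload),
        "tables": tables_written,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return StudyResult(cohort=cohort, background=background, tables=tables,
                       output_dir=out)
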