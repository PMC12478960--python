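"""Shared fixtures: small synthetic corpora and printed-table fixtures."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import faersig as fs


@pytest.fixture(scope="session")
def paperlike_small():
    """A small paper-like corpus with duplicates: (bundles, ledger)."""
    cfg = fs.scenario_paperlike(n_reports=2000, seed=11)
    return fs.generate(cfg)


@pytest.fixture(scope="session")
def paperlike_pipeline(paperlike_small):
    """Deduplicated cohort + background of the small corpus."""
    bundles, ledger = paperlike_small
    retained = fs.deduplicate(bundles)
    cohort, background = fs.build_cohort(bundles, retained)
    return cohort, background, ledger, retained


def demo_frame(rows):
    """Build a DEMO frame from (caseid, fda_dt, primaryid) triples."""
    return pd.DataFrame({
        "primaryid": [str(p) for _, _, p in rows],
        "caseid": [str(c) for c, _, _ in rows],
        "fda_dt": [str(d) for _, d, _ in rows],
        "event_dt": "", "age": "", "age_cod": "", "sex": "",
        "wt": "", "wt_cod": "", "occp_cod": "",
        "reporter_country": "", "occr_country": "",
    }, dtype=object)


def dedup_oracle(rows) -> set[str]:
    """Brute-force group-by-maximum dedup over (caseid, fda_dt, primaryid)."""
    best: dict[str, tuple] = {}
    for caseid, fda, pid in rows:
        key = (str(fda) or "00000000", int(pid))
        if caseid not in best or key > best[caseid]:
            best[caseid] = key
    return {str(key[1]) for key in best.values()}


# ---- printed-count fixtures (clinical-features and concomitant tables) ----

#: 75-case outcome multiset: category counts of the published cohort
PRINTED_OUTCOME_COUNTS = {
    "Hospitalization": 30, "Other serious": 29, "Death": 6,
    "Life-threatening": 3, "Disability": 1, "Missing": 6,
}
PRINTED_SEX_COUNTS = {"F": 48, "M": 23, "": 4}
OUTCOME_TO_CODE = {"Hospitalization": "HO", "Other serious": "OT", "Death": "DE",
                   "Life-threatening": "LT", "Disability": "DS"}


def printed_cases_frame() -> pd.DataFrame:
    """75 cases realizing the published sex/age-missing/outcome counts."""
    rng = np.random.default_rng(0)
    sexes = [s for s, k in PRINTED_SEX_COUNTS.items() for _ in range(k)]
    outcomes = [o for o, k in PRINTED_OUTCOME_COUNTS.items() for _ in range(k)]
    # 19 missing ages; 26 in 18-64.9; 30 in 65-85 (published bins)
    ages = ([np.nan] * 19 + list(rng.uniform(30, 64.9, 26))
            + list(rng.uniform(65, 85, 30)))
    weights = ([np.nan] * 57 + list(rng.uniform(40, 49, 2))
               + list(rng.uniform(50, 99, 15)) + [120.0])
    return pd.DataFrame({
        "sex": sexes,
        "age_years": ages,
        "weight_kg": weights,
        "worst_outcome": outcomes,
    })


#: printed per-category concomitant counts (total cases / severe cases);
#: the published table's percentages use totals of 138 and 41
PRINTED_CONCOMITANT_COUNTS = {
    "Cardiovascular Drugs": (30, 16),
    "Gastrointestinal Drugs": (8, 6),
    "Antibiotics": (6, 2),
    "Analgesics": (8, 1),
    "Antiallergics": (4, 1),
    "Antidepressants": (6, 1),
    "Hormonal Drugs": (7, 1),
    "Vitamins and Minerals": (9, 0),
    "Urological Drugs": (1, 1),
    "Others": (12, 6),
    "Unknown or Unclassified": (5, 0),
}
CONCOMITANT_TOTALS = (138, 41)

#: one representative drug name per category (matches the default dictionary)
CATEGORY_EXAMPLE = {
    "Cardiovascular Drugs": "ATORVASTATIN",
    "Gastrointestinal Drugs": "OMEPRAZOLE",
    "Antibiotics": "AMOXICILLIN",
    "Analgesics": "TRAMADOL",
    "Antiallergics": "CETIRIZINE",
    "Antidepressants": "SERTRALINE",
    "Hormonal Drugs": "LEVOTHYROXINE",
    "Vitamins and Minerals": "MULTIVITAMIN",
    "Urological Drugs": "TAMSULOSIN",
    "Others": "GABAPENTIN",
    "Unknown or Unclassified": "ZZZ-UNKNOWN-REMEDY",
}


def concomitant_fixture(column: int) -> list[str]:
    """Names realizing the printed counts, padded to the printed total with
    extra 'Others'-category names (the source's rows do not sum to its
    total; the padding keeps every other category's share as printed)."""
    names = []
    for cat, counts in PRINTED_CONCOMITANT_COUNTS.items():
        names += [CATEGORY_EXAMPLE[cat]] * counts[column]
    names += ["GABAPENTIN"] * (CONCOMITANT_TOTALS[column] - len(names))
    return names
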