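"""Synthetic FAERS-shaped corpora with known ground truth.

The generator emulates the features of real spontaneous-report data the
pipeline must survive — duplicate CASEID resubmissions, heavy demographic
missingness, mixed weight units, drug role codes, MedDRA PT strings,
outcome codes — while planting a drug–event association of specified
strength: for a report whose primary-suspect drug belongs to a cleanser
group with planted odds multiplier r, the target-event probability is
derived from baseline odds × r, so the generating odds ratio equals the
planted value exactly by construction.

Severity is drawn from a logistic model in 1[age >= 70] and
1[cardiovascular concomitant]; the intercept is calibrated in-sample so the
marginal outcome shares match the configured multiset while the covariate
shifts stay active.

Every run is reproducible from the seed and returns, besides the quarter
bundles, a ground-truth ledger recording each report's drug group, event
flag and duplicate lineage.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .cohort import assign_drug_group
from .dictionaries import (
    DEFAULT_CONCOMITANT_CATEGORIES,
    GROUP_NONE,
)
from .errors import ConfigError
from .records import QuarterBundle, quarter_bounds

#: default MedDRA-PT name for the target event
IC_PT = "Colitis ischaemic"

_BASE_BACKGROUND_PTS = [
    "Nausea", "Vomiting", "Diarrhoea", "Abdominal pain", "Headache",
    "Dizziness", "Fatigue", "Rash", "Pruritus", "Pyrexia", "Dyspnoea",
    "Drug ineffective", "Product use issue", "Dehydration", "Constipation",
    "Abdominal distension", "Malaise", "Hypotension", "Syncope", "Insomnia",
]

DEFAULT_BACKGROUND_DRUGS = [
    "ASPIRIN", "METFORMIN", "LISINOPRIL", "OMEPRAZOLE", "ATORVASTATIN",
    "IBUPROFEN", "LEVOTHYROXINE", "AMOXICILLIN", "SERTRALINE", "GABAPENTIN",
    "AMLODIPINE", "ALBUTEROL", "INSULIN GLARGINE", "WARFARIN", "PREDNISONE",
]

#: example concomitant names per Table-8-style category, for generation
CONCOMITANT_NAME_POOLS = {
    cat: [frag.upper() for frag in frags[:8]]
    for cat, frags in DEFAULT_CONCOMITANT_CATEGORIES.items()
}
CONCOMITANT_NAME_POOLS["Unknown or Unclassified"] = [
    "HERBAL PREPARATION NOS", "UNSPECIFIED MEDICATION", "TRADITIONAL REMEDY",
]


class SimConfig(BaseModel):
    """Generative parameters for a synthetic FAERS corpus."""

    n_reports: int = Field(ge=0)
    start: str = "2004Q1"
    end: str = "2024Q3"
    #: primary-suspect drug label -> marginal probability; the remaining
    #: mass is spread uniformly over ``background_drugs``
    drug_marginals: dict[str, float] = Field(default_factory=dict)
    background_drugs: list[str] = Field(default_factory=lambda: list(DEFAULT_BACKGROUND_DRUGS))
    baseline_event_prob: float = 0.005
    #: cleanser group -> target odds multiplier for the event PT
    planted_ror: dict[str, float] = Field(default_factory=dict)
    duplicate_rate: float = 0.0
    duplicate_tie_fraction: float = 0.2
    missing_age: float = 0.253
    missing_sex: float = 0.053
    missing_weight: float = 0.76
    missing_event_dt: float = 0.2
    sex_female: float = 0.64  # share of all reports (missing counted separately)
    age_mean: float = 66.0
    age_sd: float = 12.5
    age_min: float = 18.0
    age_max: float = 85.0
    weight_mean: float = 75.0
    weight_sd: float = 15.0
    lbs_fraction: float = 0.2
    outcome_probs: dict[str, float] = Field(default_factory=lambda: {
        "HO": 0.400, "OT": 0.387, "DE": 0.080, "LT": 0.040, "DS": 0.013,
        "missing": 0.080,
    })
    severe_age_logodds: float = 0.0
    severe_cardio_logodds: float = 0.0
    concomitant_rate: float = 0.8
    concomitant_category_probs: dict[str, float] = Field(default_factory=lambda: {
        "Cardiovascular Drugs": 0.22, "Gastrointestinal Drugs": 0.06,
        "Antibiotics": 0.04, "Analgesics": 0.06, "Antiallergics": 0.03,
        "Antidepressants": 0.04, "Hormonal Drugs": 0.05,
        "Vitamins and Minerals": 0.07, "Urological Drugs": 0.01,
        "Others": 0.38, "Unknown or Unclassified": 0.04,
    })
    indication_probs: dict[str, float] = Field(default_factory=lambda: {
        "Colonoscopy": 0.40, "Bowel preparation": 0.30, "Constipation": 0.10,
        "Endoscopy large bowel": 0.07,
        "Product used for unknown indication": 0.05, "": 0.08,
    })
    reporter_hp: float = 0.811
    reporter_nonhp: float = 0.106
    country_probs: dict[str, float] = Field(default_factory=lambda: {
        "US": 0.493, "JP": 0.293, "FR": 0.08, "DE": 0.08, "": 0.027,
        "IN": 0.014, "GB": 0.013,
    })
    n_background_pts: int = 50
    extra_pt_rate: float = 0.8
    seed: int = 0

    @field_validator("baseline_event_prob", "duplicate_rate", "duplicate_tie_fraction",
                     "missing_age", "missing_sex", "missing_weight", "missing_event_dt",
                     "sex_female", "lbs_fraction", "reporter_hp", "reporter_nonhp")
    @classmethod
    def _prob_range(cls, v, info):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{info.field_name} must be in [0, 1], got {v}")
        return v

    @field_validator("planted_ror")
    @classmethod
    def _ror_positive(cls, v):
        for k, r in v.items():
            if r <= 0:
                raise ValueError(f"planted_ror[{k!r}] must be > 0")
        return v

    @model_validator(mode="after")
    def _consistent(self):
        for name, probs in (("drug_marginals", self.drug_marginals),
                            ("outcome_probs", self.outcome_probs),
                            ("concomitant_category_probs", self.concomitant_category_probs),
                            ("indication_probs", self.indication_probs),
                            ("country_probs", self.country_probs)):
            if any(p < 0 or p > 1 for p in probs.values()):
                raise ValueError(f"{name} probabilities must be in [0, 1]")
        if sum(self.drug_marginals.values()) > 1.0 + 1e-9:
            raise ValueError("drug_marginals must sum to <= 1")
        if self.sex_female + self.missing_sex > 1.0 + 1e-9:
            raise ValueError("sex_female + missing_sex must be <= 1")
        if abs(sum(self.outcome_probs.values()) - 1.0) > 1e-6:
            raise ValueError("outcome_probs must sum to 1")
        return self


def scenario_paperlike(n_reports: int = 10_000, seed: int = 0) -> SimConfig:
    """Named default scenario matching the published cohort's marginals:
    64% female (5.3% missing sex), age ~ 66 ± 12.5 truncated to [18, 85],
    76% missing weight, 25.3% missing age, and the published outcome
    multiset (40% hospitalization, 38.7% other-serious, 8% death, 4%
    life-threatening, 1.3% disability, 8% missing). Cleanser exposure and
    planted lifts mirror the published group signal strengths at a
    baseline event probability workable at simulation scale.

    The latent (pre-truncation) age mean is 68.22, chosen so the mean of
    the truncated distribution equals the published 66."""
    return SimConfig(
        n_reports=n_reports,
        seed=seed,
        age_mean=68.22,
        drug_marginals={
            "BISACODYL": 0.010,
            "POLYETHYLENE GLYCOL 3350": 0.030,
            "SODIUM PICOSULFATE": 0.005,
        },
        planted_ror={"bisacodyl": 237.25, "PEG": 2.18, "OSS": 3.64},
        baseline_event_prob=0.005,
        duplicate_rate=0.05,
    )


def _dates_to_str(dates: np.ndarray) -> np.ndarray:
    """datetime64[D] -> 'YYYYMMDD' strings, vectorized."""
    if len(dates) == 0:
        return np.empty(0, dtype=object)
    iso = dates.astype("datetime64[D]").astype(str)
    return np.char.replace(iso, "-", "").astype(object)


def _quarter_labels(dates: np.ndarray) -> np.ndarray:
    """datetime64[D] -> 'YYYYQq' labels, vectorized."""
    years = dates.astype("datetime64[Y]").astype(str)
    months = (dates.astype("datetime64[M]").astype(int) % 12)
    q = (months // 3 + 1).astype(str)
    return np.char.add(np.char.add(years, "Q"), q).astype(object)


def _sample_categorical(rng, keys: list, probs: list[float], n: int) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    total = p.sum()
    if total <= 0:
        raise ConfigError("categorical probabilities sum to zero")
    return np.asarray(keys, dtype=object)[rng.choice(len(keys), size=n, p=p / total)]


def _truncated_normal(rng, mean, sd, lo, hi, n) -> np.ndarray:
    """Rejection-free truncated normal via inverse-CDF."""
    from scipy.stats import norm
    a, b = norm.cdf(lo, mean, sd), norm.cdf(hi, mean, sd)
    u = rng.uniform(a, b, size=n)
    return norm.ppf(u, mean, sd)


def _calibrate_intercept(eta_shift: np.ndarray, target: float) -> float:
    """Intercept b0 such that mean(sigmoid(b0 + eta_shift)) == target."""
    if target <= 0:
        return -math.inf
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        mean_p = float(np.mean(1.0 / (1.0 + np.exp(-(mid + eta_shift)))))
        if mean_p < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def background_pt_pool(n: int) -> list[str]:
    pool = list(_BASE_BACKGROUND_PTS[:n])
    i = 1
    while len(pool) < n:
        pool.append(f"Adverse event {i:02d}")
        i += 1
    return pool


def generate(config: SimConfig, seed: int | None = None
             ) -> tuple[list[QuarterBundle], pd.DataFrame]:
    """Generate quarter bundles plus the ground-truth ledger.

    The ledger has one row per *case* (not per submission) with the true
    drug label/group, event flag, severity covariates, and the primaryid
    the dedup rule should retain.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_reports
    ledger_cols = ["caseid", "primaryid", "retained_primaryid", "ps_drug",
                   "drug_group", "is_target_event", "age_years", "sex",
                   "has_cardio_concomitant", "outcome_code", "duplicated",
                   "fda_dt", "quarter"]
    if n == 0:
        return [], pd.DataFrame(columns=ledger_cols)

    caseid_num = 100_000_000 + np.arange(n, dtype=np.int64)
    pid_num = caseid_num * 10 + 1
    caseid = caseid_num.astype(str)
    primaryid = pid_num.astype(str)

    start_day = np.datetime64(quarter_bounds(config.start)[0].date())
    end_day = np.datetime64(quarter_bounds(config.end)[1].date())
    span = int((end_day - start_day) / np.timedelta64(1, "D"))
    fda_days = start_day + rng.integers(0, span + 1, size=n).astype("timedelta64[D]")
    fda_dt = _dates_to_str(fda_days)
    event_days = fda_days - rng.integers(0, 91, size=n).astype("timedelta64[D]")
    event_dt = _dates_to_str(event_days)
    event_dt[rng.random(n) < config.missing_event_dt] = ""

    # primary-suspect drug and its cleanser group
    labels = list(config.drug_marginals)
    probs = [config.drug_marginals[k] for k in labels]
    rest = 1.0 - sum(probs)
    if rest < -1e-9:
        raise ConfigError("drug_marginals sum exceeds 1")
    bg = config.background_drugs or ["PLACEBO"]
    labels = labels + list(bg)
    probs = probs + [max(rest, 0.0) / len(bg)] * len(bg)
    ps_drug = _sample_categorical(rng, labels, probs, n)
    group_of_label = {lab: assign_drug_group([lab]) for lab in set(labels)}
    group = np.asarray([group_of_label[lab] for lab in ps_drug], dtype=object)

    # planted association: exposed odds = baseline odds x planted multiplier
    base_odds = config.baseline_event_prob / (1.0 - config.baseline_event_prob)
    p_event = np.full(n, config.baseline_event_prob)
    for grp, r in config.planted_ror.items():
        odds = base_odds * r
        p_event[group == grp] = odds / (1.0 + odds)
    is_event = rng.random(n) < p_event

    # demographics
    sex = _sample_categorical(
        rng, ["F", "M", ""],
        [config.sex_female, 1.0 - config.sex_female - config.missing_sex,
         config.missing_sex], n)
    age_true = _truncated_normal(rng, config.age_mean, config.age_sd,
                                 config.age_min, config.age_max, n)
    age_str = np.round(age_true).astype(int).astype(str).astype(object)
    age_cod = np.full(n, "YR", dtype=object)
    age_missing = rng.random(n) < config.missing_age
    age_str[age_missing] = ""
    age_cod[age_missing] = ""

    weight_kg = np.maximum(rng.normal(config.weight_mean, config.weight_sd, n), 30.0)
    use_lbs = rng.random(n) < config.lbs_fraction
    wt_val = np.where(use_lbs, weight_kg / 0.4536, weight_kg)
    wt_str = np.round(wt_val, 1).astype(str).astype(object)
    wt_cod = np.where(use_lbs, "LBS", "KG").astype(object)
    wt_missing = rng.random(n) < config.missing_weight
    wt_str[wt_missing] = ""
    wt_cod[wt_missing] = ""

    occp = _sample_categorical(
        rng, ["MD", "CN", ""],
        [config.reporter_hp, config.reporter_nonhp,
         max(1.0 - config.reporter_hp - config.reporter_nonhp, 0.0)], n)
    country = _sample_categorical(rng, list(config.country_probs),
                                  list(config.country_probs.values()), n)

    # concomitant medications (role C) and the cardiovascular flag
    n_conc = rng.poisson(config.concomitant_rate, n)
    conc_owner = np.repeat(np.arange(n), n_conc)
    total_conc = int(n_conc.sum())
    conc_cat = _sample_categorical(rng, list(config.concomitant_category_probs),
                                   list(config.concomitant_category_probs.values()),
                                   total_conc)
    conc_name = np.empty(total_conc, dtype=object)
    for cat, pool in CONCOMITANT_NAME_POOLS.items():
        mask = conc_cat == cat
        k = int(mask.sum())
        if k:
            conc_name[mask] = np.asarray(pool, dtype=object)[rng.integers(0, len(pool), k)]
    has_cardio = np.zeros(n, dtype=bool)
    np.add.at(has_cardio, conc_owner[conc_cat == "Cardiovascular Drugs"], True)

    # outcomes: severity via calibrated logistic in age>=70 and cardio comed
    op = config.outcome_probs
    p_severe = op.get("DE", 0.0) + op.get("LT", 0.0)
    outcome = np.empty(n, dtype=object)
    if p_severe > 0:
        eta_shift = (config.severe_age_logodds * (age_true >= 70)
                     + config.severe_cardio_logodds * has_cardio)
        b0 = _calibrate_intercept(eta_shift, p_severe)
        p_sev_i = 1.0 / (1.0 + np.exp(-(b0 + eta_shift)))
        severe = rng.random(n) < p_sev_i
        p_de = op.get("DE", 0.0) / p_severe
        outcome[severe] = np.where(rng.random(int(severe.sum())) < p_de, "DE", "LT")
    else:
        severe = np.zeros(n, dtype=bool)
    nonsevere_keys = [k for k in op if k not in ("DE", "LT") and op[k] > 0]
    nonsevere_probs = [op[k] for k in nonsevere_keys]
    n_nonsev = int((~severe).sum())
    if n_nonsev and nonsevere_keys:
        outcome[~severe] = _sample_categorical(rng, nonsevere_keys, nonsevere_probs,
                                               n_nonsev)
    elif n_nonsev:
        outcome[~severe] = "missing"

    # reactions: event PT for true cases, plus background PTs
    pool = background_pt_pool(config.n_background_pts)
    n_extra = rng.poisson(config.extra_pt_rate, n) + (~is_event).astype(int)
    extra_owner = np.repeat(np.arange(n), n_extra)
    extra_pt = np.asarray(pool, dtype=object)[rng.integers(0, len(pool), len(extra_owner))]
    reac_owner = np.concatenate([np.flatnonzero(is_event), extra_owner])
    reac_pt = np.concatenate([np.full(int(is_event.sum()), IC_PT, dtype=object), extra_pt])

    # indications for cleanser reports
    is_cleanser = group != GROUP_NONE
    indi_owner = np.flatnonzero(is_cleanser)
    indi_pt = _sample_categorical(rng, list(config.indication_probs),
                                  list(config.indication_probs.values()),
                                  len(indi_owner))
    keep = indi_pt != ""
    indi_owner, indi_pt = indi_owner[keep], indi_pt[keep]

    # duplicates: resubmissions with strictly later fda_dt and larger
    # primaryid; a configurable fraction get an equal fda_dt to exercise the
    # primaryid tie-break
    m = int(round(config.duplicate_rate * n))
    dup_idx = rng.choice(n, size=m, replace=False) if m else np.array([], dtype=int)
    dup_pid = (caseid_num[dup_idx] * 10 + 2).astype(str)
    tie = rng.random(m) < config.duplicate_tie_fraction
    dup_days = fda_days[dup_idx] + np.where(
        tie, np.timedelta64(0, "D"),
        rng.integers(1, 301, size=m).astype("timedelta64[D]"))
    dup_fda = _dates_to_str(dup_days)

    duplicated = np.zeros(n, dtype=bool)
    duplicated[dup_idx] = True
    retained = primaryid.copy()
    retained[dup_idx] = dup_pid  # later fda_dt, or equal fda_dt + higher pid

    # ---- assemble frames (all strings, "" for missing)
    demo = pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid, "fda_dt": fda_dt,
        "event_dt": event_dt, "age": age_str, "age_cod": age_cod, "sex": sex,
        "wt": wt_str, "wt_cod": wt_cod, "occp_cod": occp,
        "reporter_country": country, "occr_country": country,
    }, dtype=object)

    drug_ps = pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid, "drug_seq": "1",
        "role_cod": "PS", "drugname": ps_drug, "prod_ai": "", "dose_vbm": "",
    }, dtype=object)
    if total_conc:
        seq_within = (pd.Series(conc_owner).groupby(conc_owner).cumcount() + 2).astype(str)
        drug_c = pd.DataFrame({
            "primaryid": primaryid[conc_owner], "caseid": caseid[conc_owner],
            "drug_seq": seq_within.to_numpy(dtype=object), "role_cod": "C",
            "drugname": conc_name, "prod_ai": "", "dose_vbm": "",
        }, dtype=object)
        drug = pd.concat([drug_ps, drug_c], ignore_index=True)
    else:
        drug = drug_ps

    reac = pd.DataFrame({
        "primaryid": primaryid[reac_owner], "caseid": caseid[reac_owner],
        "pt": reac_pt,
    }, dtype=object)

    has_outc = outcome != "missing"
    outc = pd.DataFrame({
        "primaryid": primaryid[has_outc], "caseid": caseid[has_outc],
        "outc_cod": outcome[has_outc],
    }, dtype=object)

    ther = pd.DataFrame({
        "primaryid": primaryid[is_cleanser], "caseid": caseid[is_cleanser],
        "dsg_drug_seq": "1", "start_dt": event_dt[is_cleanser], "end_dt": "",
    }, dtype=object)
    indi = pd.DataFrame({
        "primaryid": primaryid[indi_owner], "caseid": caseid[indi_owner],
        "indi_drug_seq": "1", "indi_pt": indi_pt,
    }, dtype=object)

    # duplicate submissions: copy of the demo row and all children
    if m:
        pid_map = dict(zip(primaryid[dup_idx], dup_pid))
        demo_dup = demo.iloc[dup_idx].copy()
        demo_dup["primaryid"] = dup_pid
        demo_dup["fda_dt"] = dup_fda
        demo = pd.concat([demo, demo_dup], ignore_index=True)

        def dup_children(frame: pd.DataFrame) -> pd.DataFrame:
            sub = frame[frame["primaryid"].isin(pid_map)].copy()
            if sub.empty:
                return frame
            sub["primaryid"] = sub["primaryid"].map(pid_map)
            return pd.concat([frame, sub], ignore_index=True)

        drug, reac, outc, ther, indi = (dup_children(f) for f in
                                        (drug, reac, outc, ther, indi))

    # quarter of each submission follows its own fda_dt
    q_report = _quarter_labels(fda_days)
    if m:
        demo_q = np.concatenate([q_report, _quarter_labels(dup_days)])
    else:
        demo_q = q_report
    demo["_q"] = demo_q
    q_series = pd.Series(demo_q, index=demo["primaryid"].to_numpy())
    bundles = []
    child = {"DRUG": drug, "REAC": reac, "OUTC": outc, "THER": ther, "INDI": indi}
    for kind, frame in child.items():
        frame["_q"] = frame["primaryid"].map(q_series).to_numpy()
    quarters = sorted(demo["_q"].unique())
    named = (("demo", demo), ("drug", drug), ("reac", reac),
             ("outc", outc), ("ther", ther), ("indi", indi))
    if len(quarters) == 1:
        bundles.append(QuarterBundle(
            quarter=quarters[0],
            **{name: frame.drop(columns="_q") for name, frame in named}))
    else:
        for q in quarters:
            parts = {name: frame[frame["_q"] == q].drop(columns="_q").reset_index(drop=True)
                     for name, frame in named}
            bundles.append(QuarterBundle(quarter=q, **parts))
    for _, frame in named:
        frame.drop(columns="_q", inplace=True, errors="ignore")

    ledger = pd.DataFrame({
        "caseid": caseid, "primaryid": primaryid, "retained_primaryid": retained,
        "ps_drug": ps_drug, "drug_group": group, "is_target_event": is_event,
        "age_years": np.where(age_missing, np.nan, np.round(age_true)),
        "sex": sex, "has_cardio_concomitant": has_cardio,
        "outcome_code": outcome, "duplicated": duplicated,
        "fda_dt": fda_dt, "quarter": q_report,
    })
    return bundles, ledger


def write_corpus(config: SimConfig, directory, seed: int | None = None) -> pd.DataFrame:
    """Generate and write a corpus as FAERS ASCII files; returns the ledger."""
    from .io import write_quarters

    bundles, ledger = generate(config, seed=seed)
    write_quarters(bundles, directory)
    return ledger
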