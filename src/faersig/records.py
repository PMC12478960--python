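"""Record schemas, code sets and field-normalization helpers for FAERS-style data.

Quarterly bundles hold one pandas DataFrame per file kind (DEMO/DRUG/REAC/
OUTC/THER/INDI). All cells are stored as plain strings with "" for missing,
which makes write -> parse round-trips exact; numeric/date views are derived
on demand by the helpers below.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# FAERS code sets
ROLE_CODES = ("PS", "SS", "C", "I")
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")
AGE_UNITS = ("YR", "DEC", "MON", "WK", "DY", "HR")

#: multiplicative factor from one unit to years
AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

WEIGHT_UNIT_TO_KG = {"KG": 1.0, "LBS": 0.4536}

#: occupation codes considered health professionals
HP_OCCP_CODES = {"MD", "PH", "OT", "HP", "RN"}
NONHP_OCCP_CODES = {"CN", "LW"}

FILE_KINDS = ("DEMO", "DRUG", "REAC", "OUTC", "THER", "INDI")

#: canonical (normalized) column order per file kind
CANONICAL_COLUMNS = {
    "DEMO": [
        "primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
        "sex", "wt", "wt_cod", "occp_cod", "reporter_country", "occr_country",
    ],
    "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai", "dose_vbm"],
    "REAC": ["primaryid", "caseid", "pt"],
    "OUTC": ["primaryid", "caseid", "outc_cod"],
    "THER": ["primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"],
    "INDI": ["primaryid", "caseid", "indi_drug_seq", "indi_pt"],
}

#: columns that must be present (after alias normalization) for a parse to proceed
MANDATORY_COLUMNS = {
    "DEMO": ["primaryid", "caseid", "fda_dt"],
    "DRUG": ["primaryid", "role_cod", "drugname"],
    "REAC": ["primaryid", "pt"],
    "OUTC": ["primaryid", "outc_cod"],
    "THER": ["primaryid"],
    "INDI": ["primaryid"],
}

#: legacy (pre-2012Q4 LAERS era) header names -> canonical names
LAERS_ALIASES = {
    "isr": "primaryid",
    "case": "caseid",
    "gndr_cod": "sex",
    "drug_rec_act": "drug_rec_act",
}


def era_for_quarter(quarter_label: str) -> str:
    """FAERS schema era implied by a quarter label: 'laers' before 2012Q4."""
    year, q = parse_quarter_label(quarter_label)
    return "laers" if (year, q) < (2012, 4) else "faers"


def parse_quarter_label(label: str) -> tuple[int, int]:
    try:
        year, q = label.upper().split("Q")
        year_i, q_i = int(year), int(q)
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"bad quarter label {label!r}; expected e.g. '2017Q3'") from exc
    if not (1 <= q_i <= 4):
        raise ValueError(f"bad quarter label {label!r}; quarter must be 1-4")
    return year_i, q_i


def quarter_label_for_date(yyyymmdd: str) -> str:
    month = int(yyyymmdd[4:6])
    return f"{yyyymmdd[:4]}Q{(month - 1) // 3 + 1}"


def quarter_bounds(label: str) -> tuple[pd.Timestamp, pd.Timestamp]:
    """First and last calendar day of a quarter."""
    year, q = parse_quarter_label(label)
    start = pd.Timestamp(year=year, month=3 * (q - 1) + 1, day=1)
    end = start + pd.offsets.QuarterEnd(0)
    return start, end


def quarter_filename(kind: str, label: str) -> str:
    year, q = parse_quarter_label(label)
    return f"{kind}{year % 100:02d}Q{q}.txt"


def age_in_years(value: str | float, unit: str) -> float:
    """Normalize an age to years; unparseable input -> NaN."""
    try:
        v = float(value)
    except (TypeError, ValueError):
        return math.nan
    factor = AGE_UNIT_TO_YEARS.get(str(unit).upper().strip() or "YR")
    if factor is None:
        return math.nan
    return v * factor


def weight_in_kg(value: str | float, unit: str) -> float:
    """Normalize a weight to kilograms; unparseable input -> NaN."""
    try:
        v = float(value)
    except (TypeError, ValueError):
        return math.nan
    factor = WEIGHT_UNIT_TO_KG.get(str(unit).upper().strip() or "KG")
    if factor is None:
        return math.nan
    return v * factor


def reporter_type(occp_cod: str) -> str:
    code = str(occp_cod).upper().strip()
    if code in HP_OCCP_CODES:
        return "Health professional"
    if code in NONHP_OCCP_CODES:
        return "Non-health professional"
    return "Missing"


def ages_in_years(demo: pd.DataFrame) -> pd.Series:
    """Vectorized age normalization over a DEMO frame."""
    vals = pd.to_numeric(demo["age"], errors="coerce")
    factors = demo["age_cod"].str.upper().str.strip().replace("", "YR").map(AGE_UNIT_TO_YEARS)
    return vals * factors


def weights_in_kg(demo: pd.DataFrame) -> pd.Series:
    vals = pd.to_numeric(demo["wt"], errors="coerce")
    factors = demo["wt_cod"].str.upper().str.strip().replace("", "KG").map(WEIGHT_UNIT_TO_KG)
    return vals * factors


def empty_frame(kind: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in CANONICAL_COLUMNS[kind]})


@dataclass
class QuarterBundle:
    """All records of one FAERS quarter, one DataFrame per file kind.

    Every cell is a plain string; "" encodes missing. ``parse_log`` holds
    one dict per skipped/rejoined/orphan row diagnostic.
    """

    quarter: str
    demo: pd.DataFrame = field(default_factory=lambda: empty_frame("DEMO"))
    drug: pd.DataFrame = field(default_factory=lambda: empty_frame("DRUG"))
    reac: pd.DataFrame = field(default_factory=lambda: empty_frame("REAC"))
    outc: pd.DataFrame = field(default_factory=lambda: empty_frame("OUTC"))
    ther: pd.DataFrame = field(default_factory=lambda: empty_frame("THER"))
    indi: pd.DataFrame = field(default_factory=lambda: empty_frame("INDI"))
    parse_log: list[dict] = field(default_factory=list)

    def frame(self, kind: str) -> pd.DataFrame:
        return getattr(self, kind.lower())

    def n_reports(self) -> int:
        return len(self.demo)


@dataclass
class CaseReport:
    """One deduplicated report joined across file kinds."""

    primaryid: str
    caseid: str
    demo: dict
    drugs: pd.DataFrame
    reactions: pd.DataFrame
    outcomes: pd.DataFrame
    therapies: pd.DataFrame
    indications: pd.DataFrame

    @property
    def outcome_codes(self) -> set[str]:
        if self.outcomes.empty:
            return set()
        return set(self.outcomes["outc_cod"].str.upper().str.strip()) - {""}


def concat_frames(bundles: list[QuarterBundle], kind: str) -> pd.DataFrame:
    frames = [b.frame(kind) for b in bundles if len(b.frame(kind))]
    if not frames:
        return empty_frame(kind)
    return pd.concat(frames, ignore_index=True)
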