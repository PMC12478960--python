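"""Disproportionality statistics on 2x2 report-count tables.

The table cells count unique deduplicated reports:

    a  target drug & target event        b  target drug & other events
    c  other drugs & target event        d  neither

Four statistics are computed, each with its published signal criterion:

* ROR, reporting odds ratio (a·d)/(b·c), Wald CI on the log scale;
  signal if a >= 3 and the lower 95% bound exceeds 1.
* PRR, proportional reporting ratio [a/(a+b)]/[c/(c+d)], same criterion.
* BCPNN information component IC = log2[aN/((a+b)(a+c))], with a lower
  credibility bound IC025 from the closed-form posterior moments of the
  Bayesian confidence propagation neural network (priors alpha1=beta1=1,
  alpha=beta=2, gamma11=1, gamma tuned to the margins so prior dependence
  is neutral); banded -, +, ++, +++ by IC025.
* EBGM, here the observed/expected reporting ratio aN/((a+b)(a+c)) with a
  one-sided lower bound EBGM05 = exp(ln EBGM - 1.64*sqrt(1/a+1/b+1/c+1/d));
  signal if EBGM05 > 2 and a > 0. (This follows the source method as
  published — a relative reporting ratio, not a full gamma-Poisson
  shrinkage fit.)

Zero-cell policy: a = 0 leaves the frequentist estimates undefined (never a
signal); if a > 0 and any of b, c, d is 0, the Haldane–Anscombe +0.5
correction is applied to ROR/PRR/EBGM and flagged. BCPNN needs no
correction — its priors regularize empty cells.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .cohort import Background
from .dictionaries import DRUG_GROUPS
from .errors import DataError

Z95 = 1.96
Z90_ONESIDED = 1.64

BAND_NONE = "-"
BAND_LOW = "+"
BAND_MEDIUM = "++"
BAND_HIGH = "+++"


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts a, b, c, d of the drug-event 2x2 table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise DataError(f"cell {name} must be a non-negative integer, got {v}")
        if self.n == 0:
            raise DataError("contingency table is empty (N = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def corrected(self, delta: float = 0.5) -> tuple[float, float, float, float]:
        return self.a + delta, self.b + delta, self.c + delta, self.d + delta


@dataclass(frozen=True)
class BcpnnPriors:
    """Hyperparameters of the BCPNN posterior; gamma is derived from the
    margins so that the prior expectation of dependence is neutral."""

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha, self.beta, self.gamma11) <= 0:
            raise DataError("BCPNN priors must be strictly positive")

    def gamma(self, t: ContingencyTable) -> float:
        n = t.n
        return (self.gamma11 * (n + self.alpha) * (n + self.beta)
                / ((t.a + t.b + self.alpha1) * (t.a + t.c + self.beta1)))


@dataclass
class SignalEstimates:
    """Point estimates, intervals and signal flags for one 2x2 table."""

    a: int
    ror: float = math.nan
    ror_ci_low: float = math.nan
    ror_ci_high: float = math.nan
    se_ln_ror: float = math.nan
    prr: float = math.nan
    prr_ci_low: float = math.nan
    prr_ci_high: float = math.nan
    se_ln_prr: float = math.nan
    ic: float = math.nan
    ic_expectation: float = math.nan
    ic_variance: float = math.nan
    ic025: float = math.nan
    ebgm: float = math.nan
    ebgm05: float = math.nan
    bcpnn_band: str = BAND_NONE
    correction_applied: bool = False
    undefined: bool = False
    flags: dict = field(default_factory=dict)


def ror_estimate(t: ContingencyTable, z: float = Z95) -> tuple[float, float, float, float, bool]:
    """(ror, ci_low, ci_high, se_ln_ror, corrected); NaNs when a = 0."""
    if t.a == 0:
        return math.nan, math.nan, math.nan, math.nan, False
    corrected = 0 in (t.b, t.c, t.d)
    a, b, c, d = t.corrected() if corrected else (t.a, t.b, t.c, t.d)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-z * se), ror * math.exp(z * se), se, corrected


def prr_estimate(t: ContingencyTable, z: float = Z95) -> tuple[float, float, float, float, bool]:
    """(prr, ci_low, ci_high, se_ln_prr, corrected); NaNs when a = 0."""
    if t.a == 0:
        return math.nan, math.nan, math.nan, math.nan, False
    corrected = 0 in (t.b, t.c, t.d)
    a, b, c, d = t.corrected() if corrected else (t.a, t.b, t.c, t.d)
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return prr, prr * math.exp(-z * se), prr * math.exp(z * se), se, corrected


def classify_band(ic025: float) -> str:
    """Signal band from the IC lower bound: -, +, ++, +++."""
    if not math.isfinite(ic025) or ic025 <= 0:
        return BAND_NONE
    if ic025 <= 1.5:
        return BAND_LOW
    if ic025 <= 3:
        return BAND_MEDIUM
    return BAND_HIGH


def bcpnn_estimate(t: ContingencyTable, priors: BcpnnPriors | None = None,
                   z: float = Z95) -> tuple[float, float, float, float, str]:
    """(ic, e_ic, v_ic, ic025, band) from the closed-form posterior moments.

    The point IC is the observed/expected log2 ratio; when a = 0 it is -inf
    (reported as NaN-free -inf) and the posterior moments are driven by the
    priors alone.
    """
    priors = priors or BcpnnPriors()
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    al1, be1, al, be, g11 = (priors.alpha1, priors.beta1, priors.alpha,
                             priors.beta, priors.gamma11)
    g = priors.gamma(t)
    expected = (a + b) * (a + c) / n
    ic = math.log2(a * n / ((a + b) * (a + c))) if a > 0 and expected > 0 else -math.inf
    e_ic = math.log2(
        (a + g11) * (n + al) * (n + be)
        / ((n + g) * (a + b + al1) * (a + c + be1))
    )
    v_ic = (1 / math.log(2) ** 2) * (
        (n - a + g - g11) / ((a + g11) * (1 + n + g))
        + (n - (a + b) + al - al1) / ((a + b + al1) * (1 + n + al))
        + (n - (a + c) + be - be1) / ((a + c + be1) * (1 + n + be))
    )
    ic025 = e_ic - z * math.sqrt(v_ic)
    return ic, e_ic, v_ic, ic025, classify_band(ic025)


def ebgm_estimate(t: ContingencyTable) -> tuple[float, float, bool]:
    """(ebgm, ebgm05, corrected); NaNs when a = 0 (undefined, no signal)."""
    if t.a == 0:
        return math.nan, math.nan, False
    corrected = 0 in (t.b, t.c, t.d)
    a, b, c, d = t.corrected() if corrected else (t.a, t.b, t.c, t.d)
    n = a + b + c + d
    ebgm = a * n / ((a + c) * (a + b))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ebgm05 = math.exp(math.log(ebgm) - Z90_ONESIDED * se)
    return ebgm, ebgm05, corrected


def evaluate_signal(est: SignalEstimates, a: int | None = None) -> dict[str, bool]:
    """Per-method signal flags from the published criteria."""
    a = est.a if a is None else a
    flags = {
        "ror_signal": bool(a >= 3 and est.ror_ci_low > 1),
        "prr_signal": bool(a >= 3 and est.prr_ci_low > 1),
        "bcpnn_signal": est.bcpnn_band != BAND_NONE,
        "mgps_signal": bool(a > 0 and est.ebgm05 > 2),
    }
    est.flags.update(flags)
    return flags


def signal_estimates(t: ContingencyTable, priors: BcpnnPriors | None = None,
                     z: float = Z95) -> SignalEstimates:
    """All four statistics plus criteria flags for one table."""
    est = SignalEstimates(a=t.a)
    est.ror, est.ror_ci_low, est.ror_ci_high, est.se_ln_ror, c1 = ror_estimate(t, z)
    est.prr, est.prr_ci_low, est.prr_ci_high, est.se_ln_prr, c2 = prr_estimate(t, z)
    est.ic, est.ic_expectation, est.ic_variance, est.ic025, est.bcpnn_band = \
        bcpnn_estimate(t, priors, z)
    est.ebgm, est.ebgm05, c3 = ebgm_estimate(t)
    est.correction_applied = c1 or c2 or c3
    est.undefined = t.a == 0
    evaluate_signal(est)
    return est


# ---------------------------------------------------------------------------
# Table construction from a cohort + background

def make_table(background: Background, drug_group: str,
               complement_event: bool = False) -> ContingencyTable:
    """2x2 table for one group (or 'all' for the whole cleanser class)
    against the rest of the database.

    ``complement_event=True`` swaps the event with its complement (all
    other adverse events), producing the non-target rows of the report.
    """
    if background.n_reports == 0:
        raise DataError("empty background: no retained reports")
    if drug_group in ("all", "total"):
        n_group = sum(background.group_counts[g] for g in DRUG_GROUPS)
        a = sum(background.group_event_counts[g] for g in DRUG_GROUPS)
    elif drug_group in DRUG_GROUPS:
        n_group = background.group_counts[drug_group]
        a = background.group_event_counts[drug_group]
    else:
        raise DataError(f"unknown drug group {drug_group!r}")
    if n_group == 0:
        raise DataError(f"no reports for drug group {drug_group!r}")
    b = n_group - a
    c = background.n_event_reports - a
    d = background.n_reports - n_group - c
    t = ContingencyTable(a, b, c, d)
    if complement_event:
        t = ContingencyTable(t.b, t.a, t.d, t.c)
    return t


def signal_table(background: Background, groups: list[str] | None = None,
                 priors: BcpnnPriors | None = None) -> pd.DataFrame:
    """Machine twin of the published disproportionality table: target and
    complement-event rows per group plus the whole-class totals."""
    groups = groups or [g for g in DRUG_GROUPS if background.group_counts.get(g)] + ["all"]
    rows = []
    for group in groups:
        for complement, label in ((False, "target"), (True, "non-target")):
            t = make_table(background, group, complement_event=complement)
            est = signal_estimates(t, priors)
            rows.append({
                "drug_group": group, "pt_or_class": label,
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "ror": est.ror, "ror_l": est.ror_ci_low, "ror_u": est.ror_ci_high,
                "prr": est.prr, "prr_l": est.prr_ci_low, "prr_u": est.prr_ci_high,
                "ic": est.ic, "ic025": est.ic025,
                "ebgm": est.ebgm, "ebgm05": est.ebgm05,
                "band": est.bcpnn_band,
                "ror_signal": est.flags["ror_signal"],
                "prr_signal": est.flags["prr_signal"],
                "bcpnn_signal": est.flags["bcpnn_signal"],
                "mgps_signal": est.flags["mgps_signal"],
                "correction_applied": est.correction_applied,
            })
    return pd.DataFrame(rows)


def pt_profile(background: Background, drug_group: str,
               decile: float = 0.10) -> pd.DataFrame:
    """Top-decile preferred terms of one group by case frequency, each with
    its own 2x2 ROR against all other drugs."""
    if drug_group in ("all", "total"):
        group_ids = set(background.group_of.index[background.group_of.isin(DRUG_GROUPS)])
        n_group = len(group_ids)
    else:
        group_ids = set(background.group_of.index[background.group_of == drug_group])
        n_group = background.group_counts.get(drug_group, 0)
    reac = background.reac
    if reac.empty or n_group == 0:
        return pd.DataFrame(columns=["pt", "n", "ror", "ror_l", "ror_u"])
    reac = reac.drop_duplicates(["primaryid", "pt"])
    in_group = reac["primaryid"].isin(group_ids)
    group_counts = reac.loc[in_group, "pt"].value_counts()
    if group_counts.empty:
        return pd.DataFrame(columns=["pt", "n", "ror", "ror_l", "ror_u"])
    other_counts = reac.loc[~in_group, "pt"].value_counts()
    k = math.ceil(decile * len(group_counts))
    # deterministic order: count desc, then name
    top = (group_counts.rename("n").reset_index()
           .sort_values(["n", "pt"], ascending=[False, True], kind="stable")
           .head(k))
    n_total = background.n_reports
    rows = []
    for pt, n_pt in zip(top["pt"], top["n"]):
        a = int(n_pt)
        c = int(other_counts.get(pt, 0))
        b = n_group - a
        d = n_total - n_group - c
        est_t = ContingencyTable(a, b, c, d)
        ror, lo, hi, _, _ = ror_estimate(est_t)
        rows.append({"pt": pt, "n": a, "ror": ror, "ror_l": lo, "ror_u": hi})
    return pd.DataFrame(rows)


def round_for_report(df: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Published-style rounding (2 decimals) of the float columns; internal
    computations keep full precision."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(decimals)
    return out
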