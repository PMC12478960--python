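"""Descriptive, trend, outcome-comparison and regression analyses.

Covers the per-case severity roll-up, demographic summaries, annual
reporting-proportion series, seasonal mapping, exact and asymptotic
contingency tests, concomitant-medication categorization, and a logistic
regression facility with Wald intervals.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .dictionaries import ConcomitantDictionary
from .errors import DataError, EnumerationLimitError, SeparationError

# ---------------------------------------------------------------------------
# Severity roll-up

#: seriousness ranking, worst first; CA (congenital anomaly) folds into
#: Other-serious
SEVERITY_ORDER = [
    ("DE", "Death"),
    ("LT", "Life-threatening"),
    ("DS", "Disability"),
    ("HO", "Hospitalization"),
    ("RI", "Required intervention"),
    ("OT", "Other serious"),
    ("CA", "Other serious"),
]
SEVERITY_RANK = {code: i for i, (code, _) in enumerate(SEVERITY_ORDER)}
SEVERITY_LABEL = {code: label for code, label in SEVERITY_ORDER}
MISSING_OUTCOME = "Missing"

#: display order for outcome tables
OUTCOME_CATEGORIES = ["Death", "Life-threatening", "Disability", "Hospitalization",
                      "Required intervention", "Other serious", MISSING_OUTCOME]


def worst_outcome(codes) -> str:
    """Most severe outcome category among a case's OUTC codes.

    Empty input -> ``"Missing"``; an unknown code raises :class:`DataError`
    naming it.
    """
    cleaned = {str(c).upper().strip() for c in codes} - {""}
    if not cleaned:
        return MISSING_OUTCOME
    unknown = cleaned - set(SEVERITY_RANK)
    if unknown:
        raise DataError(f"unknown outcome code(s): {sorted(unknown)}")
    best = min(cleaned, key=SEVERITY_RANK.__getitem__)
    return SEVERITY_LABEL[best]


def worst_outcomes_by_report(outc: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`worst_outcome` over an OUTC frame, keyed by primaryid.

    Reports absent from the frame are simply absent here; callers fill
    ``"Missing"``.
    """
    if outc.empty:
        return pd.Series(dtype=object)
    codes = outc["outc_cod"].str.upper().str.strip()
    ranks = codes.map(SEVERITY_RANK)
    if ranks.isna().any():
        bad = sorted(set(codes[ranks.isna()]) - {""})
        if bad:
            raise DataError(f"unknown outcome code(s): {bad}")
    frame = pd.DataFrame({"primaryid": outc["primaryid"], "rank": ranks}).dropna()
    if frame.empty:
        return pd.Series(dtype=object)
    best = frame.groupby("primaryid")["rank"].min().astype(int)
    return best.map(lambda r: SEVERITY_LABEL[SEVERITY_ORDER[r][0]])


# ---------------------------------------------------------------------------
# Seasons

_SEASON_BY_MONTH = {3: "spring", 4: "spring", 5: "spring",
                    6: "summer", 7: "summer", 8: "summer",
                    9: "autumn", 10: "autumn", 11: "autumn",
                    12: "winter", 1: "winter", 2: "winter"}
SEASONS = ["spring", "summer", "autumn", "winter", "unknown"]


def season_of(date: str | None, log: list | None = None) -> str:
    """Meteorological season of a YYYYMMDD date; missing/invalid -> unknown."""
    s = str(date or "").strip()
    if not s:
        return "unknown"
    try:
        month = int(s[4:6])
        season = _SEASON_BY_MONTH[month]
    except (ValueError, KeyError, IndexError):
        if log is not None:
            log.append({"reason": "invalid date", "value": s})
        return "unknown"
    return season


# ---------------------------------------------------------------------------
# Demographics

AGE_BINS = [("<18", -math.inf, 18), ("18-64.9", 18, 65), ("65-85", 65, 85.0000001),
            (">85", 85.0000001, math.inf)]
WEIGHT_BINS = [("<50", -math.inf, 50), ("50-100", 50, 100.0000001),
               (">100", 100.0000001, math.inf)]


def _bin_counts(values: pd.Series, bins) -> pd.DataFrame:
    n = len(values)
    rows = []
    for label, lo, hi in bins:
        rows.append((label, int(((values >= lo) & (values < hi)).sum())))
    rows.append(("Missing", int(values.isna().sum())))
    df = pd.DataFrame(rows, columns=["bin", "count"])
    df["pct"] = 100.0 * df["count"] / n if n else 0.0
    return df


def _dist_stats(values: pd.Series) -> dict:
    v = values.dropna().astype(float)
    if v.empty:
        return {"n": 0, "mean": math.nan, "sd": math.nan, "median": math.nan,
                "q1": math.nan, "q3": math.nan}
    # SD undefined (NaN) for a single observation; quantiles type-7 linear
    return {
        "n": int(len(v)),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if len(v) > 1 else math.nan,
        "median": float(np.percentile(v, 50)),
        "q1": float(np.percentile(v, 25)),
        "q3": float(np.percentile(v, 75)),
    }


def demographics_summary(cases: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Table-3-style summary of a cohort.

    Expects columns ``age_years``, ``sex``, ``weight_kg`` and optionally
    ``reporter_type``, ``worst_outcome``, ``country``. Percentages are over
    all cases, missing counted explicitly.
    """
    n = len(cases)
    out: dict[str, pd.DataFrame] = {}

    sex = cases["sex"].fillna("").replace("", "Missing")
    sex_counts = sex.value_counts()
    sex_df = pd.DataFrame({
        "sex": ["F", "M", "Missing"],
        "count": [int(sex_counts.get(k, 0)) for k in ("F", "M", "Missing")],
    })
    sex_df["pct"] = 100.0 * sex_df["count"] / n if n else 0.0
    out["sex"] = sex_df

    age = pd.to_numeric(cases["age_years"], errors="coerce")
    stats_rows = [{"group": "overall", **_dist_stats(age)}]
    for label, code in (("female", "F"), ("male", "M")):
        stats_rows.append({"group": label, **_dist_stats(age[sex == code])})
    out["age_stats"] = pd.DataFrame(stats_rows)
    out["age_bins"] = _bin_counts(age, AGE_BINS)

    weight = pd.to_numeric(cases["weight_kg"], errors="coerce")
    wrows = [{"group": "overall", **_dist_stats(weight)}]
    out["weight_stats"] = pd.DataFrame(wrows)
    out["weight_bins"] = _bin_counts(weight, WEIGHT_BINS)

    if "reporter_type" in cases:
        rep = cases["reporter_type"].fillna("Missing").replace("", "Missing")
        rc = rep.value_counts()
        levels = ["Health professional", "Non-health professional", "Missing"]
        rdf = pd.DataFrame({"reporter": levels,
                            "count": [int(rc.get(k, 0)) for k in levels]})
        rdf["pct"] = 100.0 * rdf["count"] / n if n else 0.0
        out["reporter"] = rdf

    if "worst_outcome" in cases:
        oc = cases["worst_outcome"].fillna(MISSING_OUTCOME).value_counts()
        odf = pd.DataFrame({"outcome": OUTCOME_CATEGORIES,
                            "count": [int(oc.get(k, 0)) for k in OUTCOME_CATEGORIES]})
        odf["pct"] = 100.0 * odf["count"] / n if n else 0.0
        out["outcome"] = odf
    return out


# ---------------------------------------------------------------------------
# Trends

def annual_series(group_reports: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-year case counts and reporting proportions for one drug group.

    ``group_reports`` has one row per report with the group drug as primary
    suspect, columns ``year`` (int or NA) and ``is_target_event`` (bool).
    Returns the per-year series and the median reporting proportion (%) over
    years with at least one group report.
    """
    valid = group_reports.dropna(subset=["year"]).copy()
    if valid.empty:
        return (pd.DataFrame(columns=["year", "n_cases", "n_reports", "proportion_pct"]),
                math.nan)
    valid["year"] = valid["year"].astype(int)
    per = valid.groupby("year").agg(
        n_cases=("is_target_event", "sum"), n_reports=("is_target_event", "size"))
    per = per.reset_index()
    per["n_cases"] = per["n_cases"].astype(int)
    per["proportion_pct"] = 100.0 * per["n_cases"] / per["n_reports"]
    median = float(per.loc[per["n_reports"] >= 1, "proportion_pct"].median())
    return per, median


def seasonal_counts(seasons: pd.Series) -> pd.DataFrame:
    counts = seasons.value_counts()
    df = pd.DataFrame({"season": SEASONS,
                       "count": [int(counts.get(s, 0)) for s in SEASONS]})
    n = int(df["count"].sum())
    df["pct"] = 100.0 * df["count"] / n if n else 0.0
    return df


# ---------------------------------------------------------------------------
# Exact and asymptotic contingency tests

_TIE_SLACK = 1e-12


def fisher2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table, point-probability method.

    Sums hypergeometric probabilities (fixed margins) of all tables whose
    point probability does not exceed the observed one (relative slack
    1e-12). Degenerate margins give p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise DataError("fisher2x2 expects a non-negative 2x2 table")
    a, b = t[0]
    c, d = t[1]
    n_total = int(t.sum())
    row1, col1 = a + b, a + c
    if n_total == 0 or row1 in (0, n_total) or col1 in (0, n_total):
        return 1.0
    lo = max(0, row1 + col1 - n_total)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n_total, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n_total, col1, row1)
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_SLACK)].sum())
    return min(p, 1.0)


def _iter_tables(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def fill(row_idx, cols_left, current):
        if row_idx == r - 1:
            last = cols_left
            if (last >= 0).all():
                yield current + [list(last)]
            return
        target = row_sums[row_idx]

        def fill_row(col_idx, remaining, row_acc):
            if col_idx == c - 1:
                if 0 <= remaining <= cols_left[col_idx]:
                    yield row_acc + [remaining]
                return
            for v in range(min(remaining, cols_left[col_idx]) + 1):
                yield from fill_row(col_idx + 1, remaining - v, row_acc + [v])

        for row in fill_row(0, target, []):
            yield from fill(row_idx + 1, cols_left - np.array(row), current + [row])

    yield from fill(0, np.asarray(col_sums, dtype=np.int64), [])


def _count_tables(row_sums, col_sums, limit):
    count = 0
    for _ in _iter_tables(row_sums, col_sums):
        count += 1
        if count > limit:
            return count
    return count


def _log_table_prob(flat, log_const):
    return log_const - gammaln(np.asarray(flat) + 1.0).sum()


def fisher_rxc(table, *, max_tables: int = 10_000_000,
               monte_carlo: int | None = None, seed: int | None = None) -> float:
    """Freeman–Halton exact test for an r x c table.

    Exact mode enumerates every margin-fixed table (guarded at
    ``max_tables``; beyond that :class:`EnumerationLimitError` advises the
    seeded Monte-Carlo mode, ``monte_carlo=<n samples>``).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or (t < 0).any():
        raise DataError("fisher_rxc expects a non-negative 2-D table")
    # drop all-zero rows/columns: they carry no information
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.size == 0 or t.shape[0] < 2 or t.shape[1] < 2:
        return 1.0
    if t.shape == (2, 2):
        return fisher2x2(t)
    row_sums, col_sums = t.sum(axis=1), t.sum(axis=0)
    n_total = int(t.sum())
    log_const = (gammaln(row_sums + 1.0).sum() + gammaln(col_sums + 1.0).sum()
                 - gammaln(n_total + 1.0))
    logp_obs = _log_table_prob(t.ravel(), log_const)

    if monte_carlo is not None:
        rng = np.random.default_rng(seed)
        # permutation null: contingency of two label vectors with fixed margins
        rows = np.repeat(np.arange(len(row_sums)), row_sums)
        cols = np.repeat(np.arange(len(col_sums)), col_sums)
        hits = 0
        for _ in range(monte_carlo):
            perm = rng.permutation(cols)
            sim = np.zeros_like(t)
            np.add.at(sim, (rows, perm), 1)
            if _log_table_prob(sim.ravel(), log_const) <= logp_obs + math.log1p(_TIE_SLACK):
                hits += 1
        return (hits + 1) / (monte_carlo + 1)

    if _count_tables(row_sums, col_sums, max_tables) > max_tables:
        raise EnumerationLimitError(
            f"more than {max_tables} margin-fixed tables; use monte_carlo=<n> "
            "with a seed instead")
    total = 0.0
    for cand in _iter_tables(row_sums, col_sums):
        logp = _log_table_prob(np.asarray(cand).ravel(), log_const)
        if logp <= logp_obs + math.log1p(_TIE_SLACK):
            total += math.exp(logp)
    return min(total, 1.0)


def chi2_test(table) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction: (statistic, df, p)."""
    t = np.asarray(table, dtype=float)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.size == 0 or t.shape[0] < 2 or t.shape[1] < 2:
        return 0.0, 0, 1.0
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


# ---------------------------------------------------------------------------
# Concomitant medications

def categorize_concomitants(names, dictionary: ConcomitantDictionary | None = None
                            ) -> pd.DataFrame:
    """Assign each medication name to its first matching category.

    Returns all categories (including zero counts) with percentages over
    total medications, not cases.
    """
    dictionary = dictionary or ConcomitantDictionary()
    cats = [dictionary.categorize(n) for n in names]
    counts = pd.Series(cats).value_counts() if cats else pd.Series(dtype=int)
    levels = dictionary.category_names()
    df = pd.DataFrame({"category": levels,
                       "count": [int(counts.get(k, 0)) for k in levels]})
    total = int(df["count"].sum())
    df["pct"] = 100.0 * df["count"] / total if total else 0.0
    return df


# ---------------------------------------------------------------------------
# Logistic regression

@dataclass
class LogisticResult:
    """Tidy logistic-fit output: one row per model term plus references."""

    table: pd.DataFrame  # term, level, odds_ratio, ci_low, ci_high, p_value, reference
    n_used: int
    converged: bool
    log_likelihood: float


def logistic_fit(data: pd.DataFrame, outcome: str, covariates: list[str],
                 reference: dict[str, str] | None = None) -> LogisticResult:
    """Maximum-likelihood logistic regression with Wald 95% intervals.

    Categorical covariates are dummy-coded against the given (else first
    observed) reference level; numeric covariates enter linearly.
    Complete-case analysis on the included columns. Complete separation or
    non-convergence raises :class:`SeparationError` — no silent estimates.
    """
    import statsmodels.api as sm

    reference = reference or {}
    cols = [outcome] + list(covariates)
    frame = data[cols].dropna().copy()
    y = frame[outcome].astype(float)
    if y.nunique() < 2:
        raise SeparationError("outcome has no variation after complete-case filtering")

    design = pd.DataFrame(index=frame.index)
    meta = []  # (column, term, level)
    for cov in covariates:
        col = frame[cov]
        if pd.api.types.is_numeric_dtype(col):
            design[cov] = col.astype(float)
            meta.append((cov, cov, None))
        else:
            levels = list(pd.unique(col.astype(str)))
            ref = reference.get(cov, levels[0])
            if ref not in levels:
                raise SeparationError(f"reference level {ref!r} absent for {cov!r}")
            for lev in levels:
                if lev == ref:
                    continue
                name = f"{cov}[{lev} vs {ref}]"
                design[name] = (col.astype(str) == lev).astype(float)
                meta.append((name, cov, lev))
    design = sm.add_constant(design, has_constant="add")

    model = sm.Logit(y, design)
    try:
        fit = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError et al.
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge")
    slopes = fit.params.drop("const")
    if len(slopes) and float(np.abs(slopes).max()) > 15:
        raise SeparationError("coefficients diverged: quasi-complete separation")

    rows = []
    conf = fit.conf_int(alpha=0.05)
    for name, term, level in meta:
        coef = fit.params[name]
        rows.append({
            "term": term, "level": level if level is not None else "(linear)",
            "odds_ratio": float(np.exp(coef)),
            "ci_low": float(np.exp(conf.loc[name, 0])),
            "ci_high": float(np.exp(conf.loc[name, 1])),
            "p_value": float(fit.pvalues[name]),
            "reference": False,
        })
    for cov in covariates:
        col = frame[cov]
        if not pd.api.types.is_numeric_dtype(col):
            ref = reference.get(cov, str(pd.unique(col.astype(str))[0]))
            rows.append({"term": cov, "level": ref, "odds_ratio": 1.0,
                         "ci_low": math.nan, "ci_high": math.nan,
                         "p_value": math.nan, "reference": True})
    return LogisticResult(table=pd.DataFrame(rows), n_used=int(len(frame)),
                          converged=True, log_likelihood=float(fit.llf))
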