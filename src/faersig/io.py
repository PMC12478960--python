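"""Reading and writing FAERS quarterly ASCII files, and report deduplication.

FAERS quarters ship as ``$``-delimited text files with a header row
(DEMOyyQq.txt, DRUGyyQq.txt, ...). Known dialect quirks are handled
explicitly: a trailing ``$`` on a row, and rows broken by embedded newlines,
which are rejoined when the field count works out and logged otherwise.
Malformed rows are never silently dropped — every skip lands in the bundle's
parse log.

The deduplication rule collapses resubmissions of the same case: within each
CASEID keep the report with the most recent FDA_DT, ties broken by the
numerically highest PRIMARYID. A missing FDA_DT always sorts lowest.
"""
from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CaseNotFoundError, DataError, DialectError, SchemaError
from .records import (
    CANONICAL_COLUMNS,
    FILE_KINDS,
    LAERS_ALIASES,
    MANDATORY_COLUMNS,
    CaseReport,
    QuarterBundle,
    concat_frames,
    empty_frame,
    era_for_quarter,
    quarter_filename,
)

DELIM = "$"


def _normalize_header(fields: list[str]) -> list[str]:
    out = []
    for name in fields:
        n = name.strip().lower()
        out.append(LAERS_ALIASES.get(n, n))
    return out


def _parse_dollar_file(path: Path, kind: str, quarter: str, log: list[dict]) -> pd.DataFrame:
    """Parse one ``$``-delimited file into a canonical-column string frame."""
    text = path.read_text(encoding="utf-8", errors="replace")
    lines = text.splitlines()
    if not lines:
        return empty_frame(kind)

    header = _normalize_header(lines[0].rstrip(DELIM).split(DELIM))
    missing = [c for c in MANDATORY_COLUMNS[kind] if c not in header]
    if missing:
        era = era_for_quarter(quarter)
        raise SchemaError(
            f"{path.name} ({quarter}, expected {era!r}-era schema): header lacks "
            f"mandatory column(s) {missing}; found {header}"
        )
    ncols = len(header)

    rows: list[list[str]] = []
    pending: list[str] | None = None
    pending_line = 0

    def log_skip(fields: list[str], lineno: int, reason: str) -> None:
        log.append({
            "file": path.name, "line": lineno, "reason": reason,
            "n_fields": len(fields), "expected": ncols,
            "raw": DELIM.join(fields)[:200],
        })

    for lineno, raw in enumerate(lines[1:], start=2):
        fields = raw.split(DELIM)
        # trailing-delimiter dialect: one spurious empty field at the end
        if len(fields) == ncols + 1 and fields[-1] == "":
            fields = fields[:-1]
        if pending is not None:
            merged = pending[:-1] + [pending[-1] + " " + fields[0]] + fields[1:]
            if len(merged) < ncols:
                pending = merged
                continue
            if len(merged) == ncols:
                rows.append(merged)
                log.append({"file": path.name, "line": pending_line,
                            "reason": "rejoined embedded newline", "expected": ncols})
                pending = None
                continue
            # rejoin overflows: the fragment alone was malformed
            log_skip(pending, pending_line, "wrong field count")
            pending = None
        if len(fields) == ncols:
            rows.append(fields)
        elif len(fields) < ncols:
            pending, pending_line = fields, lineno
        else:
            log_skip(fields, lineno, "wrong field count")
    if pending is not None:
        log_skip(pending, pending_line, "wrong field count")

    if rows:
        df = pd.DataFrame(rows, columns=header, dtype=object)
    else:
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in header})
    # project onto the canonical column set; absent optional columns become ""
    for col in CANONICAL_COLUMNS[kind]:
        if col not in df.columns:
            df[col] = "" if len(df) else pd.Series(dtype=object)
    df = df[CANONICAL_COLUMNS[kind]].map(lambda s: s.strip() if isinstance(s, str) else s)
    return df


def parse_quarter(path: str | os.PathLike, quarter_label: str) -> QuarterBundle:
    """Parse one quarter's files from a directory into a :class:`QuarterBundle`.

    DEMO is mandatory (hard error if absent); the other kinds yield empty
    frames with a log note when their file is missing. Child rows whose
    primaryid has no DEMO parent are kept but flagged ``orphan`` in the log.
    """
    directory = Path(path)
    log: list[dict] = []
    frames: dict[str, pd.DataFrame] = {}
    for kind in FILE_KINDS:
        fpath = directory / quarter_filename(kind, quarter_label)
        if not fpath.exists():
            if kind == "DEMO":
                raise DataError(f"mandatory file {fpath.name} missing in {directory}")
            log.append({"file": fpath.name, "reason": "file absent", "line": 0})
            frames[kind] = empty_frame(kind)
            continue
        frames[kind] = _parse_dollar_file(fpath, kind, quarter_label, log)

    bundle = QuarterBundle(quarter=quarter_label, parse_log=log,
                           **{k.lower(): v for k, v in frames.items()})
    known = set(bundle.demo["primaryid"])
    for kind in ("DRUG", "REAC", "OUTC", "THER", "INDI"):
        frame = bundle.frame(kind)
        if frame.empty:
            continue
        orphans = sorted(set(frame["primaryid"]) - known)
        for pid in orphans:
            log.append({"file": quarter_filename(kind, quarter_label),
                        "reason": "orphan", "primaryid": pid, "line": -1})
    return bundle


def discover_quarters(path: str | os.PathLike) -> list[str]:
    """Quarter labels present in a directory, from DEMO file names."""
    labels = []
    for p in sorted(Path(path).glob("DEMO*.txt")):
        stem = p.stem[4:]  # yyQq
        if len(stem) == 4 and stem[2] == "Q":
            yy = int(stem[:2])
            year = 2000 + yy if yy < 50 else 1900 + yy
            labels.append(f"{year}Q{stem[3]}")
    return labels


def write_quarters(bundles: list[QuarterBundle], directory: str | os.PathLike) -> list[Path]:
    """Write bundles back out as FAERS-style ``$``-delimited quarter files.

    Values containing the delimiter or a newline cannot be represented in
    the dialect and are rejected with :class:`DialectError` rather than
    silently corrupting the row structure.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for bundle in bundles:
        for kind in FILE_KINDS:
            frame = bundle.frame(kind)
            cols = CANONICAL_COLUMNS[kind]
            fpath = directory / quarter_filename(kind, bundle.quarter)
            lines = [DELIM.join(cols)]
            if len(frame):
                values = frame[cols].to_numpy(dtype=object)
                for row in values:
                    cells = ["" if v is None else str(v) for v in row]
                    for v in cells:
                        if DELIM in v or "\n" in v or "\r" in v:
                            raise DialectError(
                                f"value {v!r} in {fpath.name} contains the '$' delimiter "
                                "or a newline and cannot be written"
                            )
                    lines.append(DELIM.join(cells))
            fpath.write_text("\n".join(lines) + "\n", encoding="utf-8")
            written.append(fpath)
    return written


def deduplicate(demo: pd.DataFrame | list[QuarterBundle]) -> set[str]:
    """Primaryids retained after collapsing duplicate CASEIDs.

    Keeps, within each caseid group, the row maximizing
    ``(fda_dt, numeric primaryid)``; missing fda_dt sorts lowest. Accepts a
    DEMO frame or a list of bundles (concatenated). Empty input -> empty set.
    """
    if isinstance(demo, list):
        demo = concat_frames(demo, "DEMO")
    if demo.empty:
        return set()
    fda = pd.to_datetime(demo["fda_dt"], format="%Y%m%d", errors="coerce")
    pid = pd.to_numeric(demo["primaryid"], errors="coerce")
    order = pd.DataFrame({
        "caseid": demo["caseid"].to_numpy(),
        "fda": fda.fillna(pd.Timestamp.min).to_numpy(),
        "pid": pid.to_numpy(),
        "primaryid": demo["primaryid"].to_numpy(),
    })
    keep = order.sort_values(["fda", "pid"], kind="stable").groupby("caseid", sort=False).tail(1)
    return set(keep["primaryid"])


def join_case(bundles: list[QuarterBundle], primaryid: str) -> CaseReport:
    """Aggregate all rows of one report across bundles into a :class:`CaseReport`.

    Raises :class:`CaseNotFoundError` when no DEMO row carries the id.
    Reports with no OUTC rows yield an empty outcome frame (summarized
    downstream as Missing).
    """
    primaryid = str(primaryid)
    demo_rows = []
    parts: dict[str, list[pd.DataFrame]] = {k: [] for k in ("DRUG", "REAC", "OUTC", "THER", "INDI")}
    for bundle in bundles:
        hit = bundle.demo[bundle.demo["primaryid"] == primaryid]
        if len(hit):
            demo_rows.append(hit)
        for kind in parts:
            frame = bundle.frame(kind)
            if len(frame):
                sub = frame[frame["primaryid"] == primaryid]
                if len(sub):
                    parts[kind].append(sub)
    if not demo_rows:
        raise CaseNotFoundError(f"primaryid {primaryid!r} not found in any bundle")
    demo = pd.concat(demo_rows, ignore_index=True).iloc[0].to_dict()

    def cat(kind: str) -> pd.DataFrame:
        return (pd.concat(parts[kind], ignore_index=True) if parts[kind]
                else empty_frame(kind))

    return CaseReport(
        primaryid=primaryid, caseid=demo.get("caseid", ""), demo=demo,
        drugs=cat("DRUG"), reactions=cat("REAC"), outcomes=cat("OUTC"),
        therapies=cat("THER"), indications=cat("INDI"),
    )
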