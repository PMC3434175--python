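"""Delimited text formats for trial tables, threshold tables and fit records.

No standard on-disk format exists for psychophysics trial data, so the
package uses plain delimited text: a mandatory header, an optional leading
``#``-comment version line, and comma or tab delimiters (writers emit comma).
Fits are serialised as flat ``key=value`` records.
"""

from __future__ import annotations

import csv
import io as _stdio
import math
from pathlib import Path

import pandas as pd

from .errors import TableFormatError
from .pooling import ThresholdTriple
from .psychometric import CONDITIONS, RESPONSES, PsychometricFit

TRIAL_HEADER = ["subject_id", "condition", "level", "response"]
THRESHOLD_HEADER = ["subject_id", "T_a", "T_m", "T_am"]
FORMAT_COMMENT = "# cuefidelity table v1"


def _open_rows(path):
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines()]
    # locate header, skipping comment lines
    start = 0
    while start < len(lines) and (not lines[start].strip() or lines[start].startswith("#")):
        start += 1
    if start >= len(lines):
        raise TableFormatError(f"{path}: no header line found")
    delim = "\t" if "\t" in lines[start] else ","
    reader = csv.reader(_stdio.StringIO("\n".join(lines[start:])), delimiter=delim)
    return reader, start + 1  # 1-based line number of the header


def read_trials(path) -> pd.DataFrame:
    """Read a forced-choice trial table.

    Returns a DataFrame with columns ``subject_id, condition, level, response,
    excluded`` — rows with response "none" are retained but flagged excluded
    (fits discount them).  Malformed rows raise :class:`TableFormatError`
    naming the line number.
    """
    reader, header_line = _open_rows(path)
    header = next(reader)
    if [h.strip() for h in header] != TRIAL_HEADER:
        raise TableFormatError(
            f"{path}:{header_line}: expected header {','.join(TRIAL_HEADER)}, "
            f"got {','.join(header)}"
        )
    rows = []
    for i, row in enumerate(reader, start=header_line + 1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != 4:
            raise TableFormatError(f"{path}:{i}: expected 4 fields, got {len(row)}")
        sid, cond, level_s, resp = (f.strip() for f in row)
        if cond not in CONDITIONS:
            raise TableFormatError(f"{path}:{i}: unknown condition label {cond!r}")
        if resp not in RESPONSES:
            raise TableFormatError(f"{path}:{i}: unknown response label {resp!r}")
        try:
            level = float(level_s)
        except ValueError:
            raise TableFormatError(f"{path}:{i}: level {level_s!r} is not a number")
        if not math.isfinite(level) or level == 0:
            raise TableFormatError(f"{path}:{i}: level must be finite and nonzero")
        rows.append((sid, cond, level, resp))
    df = pd.DataFrame(rows, columns=TRIAL_HEADER)
    df["excluded"] = df["response"] == "none"
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table (comma-delimited, versioned comment line)."""
    with open(path, "w", newline="") as fh:
        fh.write(FORMAT_COMMENT + "\n")
        writer = csv.writer(fh)
        writer.writerow(TRIAL_HEADER)
        for row in trials[TRIAL_HEADER].itertuples(index=False):
            writer.writerow([row.subject_id, row.condition,
                             f"{row.level:.6g}", row.response])


def read_thresholds(path) -> list[ThresholdTriple]:
    """Read a per-subject threshold table (subject_id, T_a, T_m, T_am)."""
    reader, header_line = _open_rows(path)
    header = next(reader)
    if [h.strip() for h in header] != THRESHOLD_HEADER:
        raise TableFormatError(
            f"{path}:{header_line}: expected header {','.join(THRESHOLD_HEADER)}"
        )
    triples = []
    for i, row in enumerate(reader, start=header_line + 1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != 4:
            raise TableFormatError(f"{path}:{i}: expected 4 fields, got {len(row)}")
        try:
            triples.append(ThresholdTriple(
                subject_id=row[0].strip(),
                T_a=float(row[1]), T_m=float(row[2]), T_am=float(row[3]),
            ))
        except ValueError as exc:
            raise TableFormatError(f"{path}:{i}: {exc}")
    return triples


def write_thresholds(triples, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(FORMAT_COMMENT + "\n")
        writer = csv.writer(fh)
        writer.writerow(THRESHOLD_HEADER)
        for tr in triples:
            writer.writerow([tr.subject_id, f"{tr.T_a:.6g}",
                             f"{tr.T_m:.6g}", f"{tr.T_am:.6g}"])


def fit_to_record(fit: PsychometricFit) -> str:
    """Serialise a psychometric fit as a flat key=value text record."""
    pairs = {
        "subject_id": fit.subject_id or "",
        "condition": fit.condition or "",
        "A": f"{fit.A:.6g}", "B": f"{fit.B:.6g}",
        "x0": f"{fit.x0:.10g}", "m": f"{fit.m:.10g}",
        "threshold81": f"{fit.threshold81:.10g}",
        "loglik": f"{fit.loglik:.10g}",
    }
    return "\n".join(f"{k}={v}" for k, v in pairs.items()) + "\n"


def record_to_fit(text: str) -> PsychometricFit:
    kv = {}
    for i, line in enumerate(text.strip().splitlines(), start=1):
        if "=" not in line:
            raise TableFormatError(f"fit record line {i}: missing '='")
        k, v = line.split("=", 1)
        kv[k.strip()] = v.strip()
    try:
        return PsychometricFit(
            x0=float(kv["x0"]), m=float(kv["m"]),
            A=float(kv["A"]), B=float(kv["B"]),
            threshold81=float(kv["threshold81"]),
            loglik=float(kv["loglik"]),
            subject_id=kv.get("subject_id") or None,
            condition=kv.get("condition") or None,
        )
    except KeyError as exc:
        raise TableFormatError(f"fit record missing key {exc}")
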