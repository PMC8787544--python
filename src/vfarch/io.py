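"""CSV I/O for visual-field tables.

Dialect: comma-separated UTF-8 with a mandatory header row; one row per
eye-visit.  TD columns are named ``td_00 .. td_51`` (24-2) or ``td_00 ..
td_73`` (30-2) in the documented grid order; optional raw sensitivities use
``sens_*`` with the same indexing.  A file may mix grid patterns, in which
case the TD columns are sized to the larger grid and 24-2 rows leave the
surplus cells empty.  Round-trips are lossless for every field.
"""

from __future__ import annotations

import csv
from typing import List, Optional, Sequence

import numpy as np

from .grids import VFFormatError, get_grid
from .vf_core import VFRecord

_META_COLS = [
    "subject_id",
    "eye_id",
    "laterality",
    "visit_day",
    "pattern",
    "fixation_loss",
    "false_pos",
    "false_neg",
    "md",
    "psd",
    "va_logmar",
    "cs_letters",
    "expert_label",
    "projected_baseline",
    "treatment_arm",
]

_REQUIRED = ["subject_id", "eye_id", "laterality", "visit_day", "pattern"]

_FLOAT_FIELDS = [
    "fixation_loss",
    "false_pos",
    "false_neg",
    "md",
    "psd",
    "va_logmar",
    "cs_letters",
]


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return repr(x)
    return str(x)


def write_vf_table(records: Sequence[VFRecord], path) -> None:
    """Write records to CSV in the documented dialect."""
    records = list(records)
    max_dim = max((r.grid.n_analysis for r in records), default=52)
    has_sens = any(r.sensitivity is not None for r in records)
    td_cols = [f"td_{i:02d}" for i in range(max_dim)]
    sens_cols = [f"sens_{i:02d}" for i in range(max_dim)] if has_sens else []
    header = _META_COLS + td_cols + sens_cols
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for r in records:
            row = [
                r.subject_id,
                r.eye_id,
                r.laterality,
                str(r.visit_day),
                r.grid.pattern_id,
                _fmt(r.fixation_loss),
                _fmt(r.false_pos),
                _fmt(r.false_neg),
                _fmt(r.md),
                _fmt(r.psd),
                _fmt(r.va_logmar),
                _fmt(r.cs_letters),
                r.expert_label or "",
                "true" if r.projected_baseline else "false",
                r.treatment_arm or "",
            ]
            td = [""] * max_dim
            if r.td is not None:
                td[: r.grid.n_analysis] = [repr(float(v)) for v in r.td]
            row.extend(td)
            if has_sens:
                sv = [""] * max_dim
                if r.sensitivity is not None:
                    sv[: r.grid.n_analysis] = [repr(float(v)) for v in r.sensitivity]
                row.extend(sv)
            w.writerow(row)


def _parse_float(cell: str, line_no: int, col: str) -> Optional[float]:
    if cell == "" or cell is None:
        return None
    try:
        return float(cell)
    except ValueError:
        raise VFFormatError(
            f"line {line_no}: non-numeric value {cell!r} in column {col!r}"
        )


def read_vf_table(path) -> List[VFRecord]:
    """Read a visual-field CSV, validating rows and reporting line numbers."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise VFFormatError(f"{path}: empty file without header")
        for col in _REQUIRED:
            if col not in reader.fieldnames:
                raise VFFormatError(f"{path}: missing required column {col!r}")
        td_cols = sorted(c for c in reader.fieldnames if c.startswith("td_"))
        sens_cols = sorted(c for c in reader.fieldnames if c.startswith("sens_"))
        records: List[VFRecord] = []
        for row in reader:
            line_no = reader.line_num
            pattern = row["pattern"]
            grid = get_grid(pattern)
            dim = grid.n_analysis
            if len(td_cols) < dim:
                raise VFFormatError(
                    f"line {line_no}: grid {pattern} needs {dim} td columns, "
                    f"file has {len(td_cols)}"
                )

            def vec(cols):
                cells = [row[c] for c in cols[:dim]]
                if all(c == "" for c in cells):
                    return None
                vals = [_parse_float(c, line_no, name) for c, name in zip(cells, cols)]
                if any(v is None for v in vals):
                    col = cols[vals.index(None)]
                    raise VFFormatError(
                        f"line {line_no}: missing value in column {col!r}"
                    )
                return np.array(vals, dtype=float)

            floats = {f: _parse_float(row.get(f, ""), line_no, f) for f in _FLOAT_FIELDS}
            try:
                visit_day = int(row["visit_day"])
            except ValueError:
                raise VFFormatError(
                    f"line {line_no}: non-integer visit_day {row['visit_day']!r}"
                )
            records.append(
                VFRecord(
                    subject_id=row["subject_id"],
                    eye_id=row["eye_id"],
                    laterality=row["laterality"],
                    visit_day=visit_day,
                    grid=grid,
                    td=vec(td_cols),
                    sensitivity=vec(sens_cols) if sens_cols else None,
                    expert_label=row.get("expert_label") or None,
                    projected_baseline=row.get("projected_baseline", "false").lower()
                    == "true",
                    treatment_arm=row.get("treatment_arm") or None,
                    **floats,
                )
            )
    return records
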