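"""Core visual-field data model and per-field operations.

A :class:`VFRecord` holds one eye-visit: a total-deviation (TD) vector over
the analysis locations of its grid, optional raw sensitivities, reliability
indices, global indices (MD, PSD), acuity and contrast sensitivity, and an
optional expert defect classification.  Vectors are stored in the record's
*native* layout: the documented right-eye grid order for right eyes, the
mirrored layout for left eyes.  :func:`to_right_eye_format` permutes a
left-eye record into right-eye format; :func:`convert_30_2_to_24_2` restricts
a right-format 30-2 field to the 24-2 analysis set.  Together they normalize
any record to the 52-point right-eye 24-2 analysis vector the archetype
engine consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .grids import (
    GRID_24_2,
    GRID_30_2,
    GridSpec,
    VFDataError,
    VFFormatError,
    mirror_permutation,
    subset_indices,
    subset_indices_mirrored,
)

__all__ = [
    "VFRecord",
    "NormativeMap",
    "ReliabilityPolicy",
    "ON_RELIABILITY_POLICY",
    "CONTROL_RELIABILITY_POLICY",
    "to_right_eye_format",
    "convert_30_2_to_24_2",
    "normalize_record",
    "derive_td",
    "reliability_pass",
    "compute_md",
    "compute_psd",
]


@dataclass(frozen=True)
class VFRecord:
    """One visual-field test of one eye at one visit."""

    subject_id: str
    eye_id: str
    laterality: str  # "left" | "right"
    visit_day: int
    grid: GridSpec
    td: Optional[np.ndarray] = None
    sensitivity: Optional[np.ndarray] = None
    fixation_loss: Optional[float] = None
    false_pos: Optional[float] = None
    false_neg: Optional[float] = None
    md: Optional[float] = None
    psd: Optional[float] = None
    va_logmar: Optional[float] = None
    cs_letters: Optional[float] = None
    expert_label: Optional[str] = None
    projected_baseline: bool = False
    treatment_arm: Optional[str] = None

    def __post_init__(self):
        if self.laterality not in ("left", "right"):
            raise VFFormatError(f"laterality must be left/right, got {self.laterality!r}")
        for name in ("td", "sensitivity"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                object.__setattr__(self, name, v)
                if v.shape != (self.grid.n_analysis,):
                    raise VFFormatError(
                        f"{name} has {v.shape[0]} entries; grid "
                        f"{self.grid.pattern_id} expects {self.grid.n_analysis}"
                    )
        for name in ("fixation_loss", "false_pos", "false_neg"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise VFDataError(f"{name}={v} outside [0, 1]")
        if self.projected_baseline and self.sensitivity is not None:
            if not np.all(self.sensitivity == 0.0):
                raise VFDataError("projected baseline must have all-zero sensitivity")


@dataclass(frozen=True)
class NormativeMap:
    """Expected healthy sensitivity (dB) at each analysis location of a grid."""

    grid: GridSpec
    normal_sensitivity: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.normal_sensitivity, dtype=float)
        object.__setattr__(self, "normal_sensitivity", v)
        if v.shape != (self.grid.n_analysis,):
            raise VFFormatError("normative map length does not match grid")
        if not np.all(np.isfinite(v)):
            raise VFDataError("normative map contains non-finite values")


@dataclass(frozen=True)
class ReliabilityPolicy:
    """Exclusive upper limits on the three reliability indices."""

    max_fixation_loss: float
    max_false_pos: float
    max_false_neg: float

    def __post_init__(self):
        for name in ("max_fixation_loss", "max_false_pos", "max_false_neg"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise VFDataError(f"{name}={v} outside (0, 1]")


#: Trial criteria: fixation losses < 20%, false positives/negatives < 33%.
ON_RELIABILITY_POLICY = ReliabilityPolicy(0.20, 0.33, 0.33)
#: Control criteria: fixation losses < 20%, false positives/negatives < 10%.
CONTROL_RELIABILITY_POLICY = ReliabilityPolicy(0.20, 0.10, 0.10)


def to_right_eye_format(record: VFRecord) -> VFRecord:
    """Convert a left-eye record to right-eye format (mirror across x = 0).

    A value measured at mirrored location (-x, y) of a left eye is reassigned
    to (x, y).  Right-eye records are returned unchanged.  The multiset of
    values is preserved exactly; the operation on coordinates is an involution.
    """
    if record.grid.pattern_id not in ("24-2", "30-2"):
        raise VFFormatError(f"unknown grid pattern {record.grid.pattern_id!r}")
    if record.laterality == "right":
        return record
    perm = np.asarray(mirror_permutation(record.grid), dtype=int)
    kw = {"laterality": "right"}
    if record.td is not None:
        kw["td"] = record.td[perm]
    if record.sensitivity is not None:
        kw["sensitivity"] = record.sensitivity[perm]
    return replace(record, **kw)


def convert_30_2_to_24_2(record: VFRecord) -> VFRecord:
    """Restrict a 30-2 record to the 24-2 analysis locations.

    Every 24-2 location coincides with a 30-2 location and carries that
    location's value.  24-2 records pass through unchanged.  Left-eye
    records are converted within their mirrored layout, so the operation
    commutes with :func:`to_right_eye_format`.
    """
    if record.grid.pattern_id == "24-2":
        return record
    if record.grid.pattern_id != "30-2":
        raise VFFormatError(f"unknown grid pattern {record.grid.pattern_id!r}")
    if record.laterality == "right":
        sel = np.asarray(subset_indices(GRID_24_2, GRID_30_2), dtype=int)
    else:
        sel = np.asarray(subset_indices_mirrored(GRID_24_2, GRID_30_2), dtype=int)
    kw = {"grid": GRID_24_2}
    if record.td is not None:
        kw["td"] = record.td[sel]
    if record.sensitivity is not None:
        kw["sensitivity"] = record.sensitivity[sel]
    return replace(record, **kw)


def normalize_record(record: VFRecord) -> VFRecord:
    """Normalize any record to right-eye 24-2 format (mirror, then restrict)."""
    return convert_30_2_to_24_2(to_right_eye_format(record))


def derive_td(record: VFRecord, norm: NormativeMap) -> VFRecord:
    """Derive total deviation as measured minus age-normal sensitivity."""
    if record.sensitivity is None:
        raise VFDataError("record has no sensitivity values to derive TD from")
    if norm.grid.pattern_id != record.grid.pattern_id:
        raise VFDataError(
            f"normative map grid {norm.grid.pattern_id} does not match "
            f"record grid {record.grid.pattern_id}"
        )
    return replace(record, td=record.sensitivity - norm.normal_sensitivity)


def reliability_pass(
    record: VFRecord,
    policy: ReliabilityPolicy,
    missing: str = "fail",
) -> bool:
    """True iff every reliability index is strictly below its policy limit.

    ``missing`` controls records lacking an index: ``"fail"`` (default)
    excludes them, ``"pass"`` ignores the missing index.
    """
    if missing not in ("fail", "pass"):
        raise ValueError("missing must be 'fail' or 'pass'")
    checks = (
        (record.fixation_loss, policy.max_fixation_loss),
        (record.false_pos, policy.max_false_pos),
        (record.false_neg, policy.max_false_neg),
    )
    for value, limit in checks:
        if value is None:
            if missing == "fail":
                return False
            continue
        if not value < limit:
            return False
    return True


def compute_md(td: np.ndarray) -> float:
    """Mean deviation: unweighted arithmetic mean of the TD vector (dB)."""
    td = np.asarray(td, dtype=float)
    if td.size == 0:
        raise VFDataError("cannot compute MD of an empty TD vector")
    return float(td.mean())


def compute_psd(td: np.ndarray) -> float:
    """Pattern standard deviation: unweighted sample SD of TD about MD (dB)."""
    td = np.asarray(td, dtype=float)
    if td.size < 2:
        raise VFDataError("PSD requires at least 2 locations")
    return float(td.std(ddof=1))
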