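"""Subject-level feature assembly: exclusion logic, the 39-column modeling
table (3 segments x 13 features), and its canonical CSV schema."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .morphometry import FEATURE_SUFFIXES, SegmentFeatures

__all__ = [
    "SEGMENT_LABELS",
    "FEATURE_COLUMNS",
    "TABLE_COLUMNS",
    "SubjectRecord",
    "Exclusion",
    "apply_exclusions",
    "assemble_table",
    "write_table",
    "read_table",
]

#: The three modeled segments, in block order.
SEGMENT_LABELS = ("R-ICA", "L-ICA", "BA")

#: The 39 feature columns: R-ICA block, then L-ICA, then BA; 13 names per block.
FEATURE_COLUMNS = tuple(f"{seg}_{suf}" for seg in SEGMENT_LABELS for suf in FEATURE_SUFFIXES)

#: Full on-disk schema (id column first, then age, then the 39 features).
TABLE_COLUMNS = ("subject_id", "age") + FEATURE_COLUMNS


@dataclass
class SubjectRecord:
    """One subject's per-segment features plus QC outcomes."""

    subject_id: str
    age: float
    features: dict[str, SegmentFeatures | None] = field(default_factory=dict)
    qc_suspect: dict[str, bool] = field(default_factory=dict)  # per-segment path QC
    segmentation_ok: bool = True

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"subject {self.subject_id!r}: age must be > 0, got {self.age}")

    def feature_row(self) -> dict[str, float]:
        row: dict[str, float] = {"subject_id": self.subject_id, "age": float(self.age)}
        for label in SEGMENT_LABELS:
            feats = self.features.get(label)
            if feats is None:
                raise ValueError(f"subject {self.subject_id!r}: segment {label!r} missing")
            row.update(feats.to_dict())
        return row


@dataclass(frozen=True)
class Exclusion:
    subject_id: str
    criterion: int  # 1 = segmentation QC, 2 = missing segment/features, 3 = suspect path
    detail: str


def _missing_segments(record: SubjectRecord) -> list[str]:
    missing = []
    for label in SEGMENT_LABELS:
        feats = record.features.get(label)
        if feats is None or not feats.is_complete():
            missing.append(label)
    return missing


def apply_exclusions(records: Iterable[SubjectRecord]) -> tuple[list[SubjectRecord], list[Exclusion]]:
    """Partition records into (retained, exclusion log).

    Criteria: (1) segmentation QC
    failure, (2) a required segment absent or with incomplete features,
    (3) a suspect path-QC flag on a required segment.
    """
    retained: list[SubjectRecord] = []
    log: list[Exclusion] = []
    for rec in records:
        if not rec.segmentation_ok:
            log.append(Exclusion(rec.subject_id, 1, "segmentation quality check failed"))
            continue
        missing = _missing_segments(rec)
        if missing:
            log.append(Exclusion(rec.subject_id, 2, f"missing/incomplete segments: {', '.join(missing)}"))
            continue
        suspect = [lab for lab in SEGMENT_LABELS if rec.qc_suspect.get(lab, False)]
        if suspect:
            log.append(Exclusion(rec.subject_id, 3, f"suspect centerline path: {', '.join(suspect)}"))
            continue
        retained.append(rec)
    return retained, log


def assemble_table(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Build the subjects x (age + 39 features) modeling table.

    Rows are sorted by subject id; duplicate ids are rejected.
    """
    ids = [r.subject_id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate subject ids: {sorted(dupes)}")
    rows = [r.feature_row() for r in sorted(records, key=lambda r: r.subject_id)]
    table = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    return table.reset_index(drop=True)


def validate_table(table: pd.DataFrame) -> None:
    expected = list(TABLE_COLUMNS)
    got = list(table.columns)
    missing = [c for c in expected if c not in got]
    extra = [c for c in got if c not in expected]
    if missing or extra:
        raise ValueError(
            f"table schema mismatch: missing columns {missing}, unexpected columns {extra}"
        )
    if got != expected:
        raise ValueError("table columns present but out of canonical order")


def write_table(table: pd.DataFrame, path, excel: bool = False) -> None:
    """Write the modeling table; CSV is canonical, .xlsx optional."""
    validate_table(table)
    if excel or str(path).endswith(".xlsx"):
        table.to_excel(path, index=False)
    else:
        table.to_csv(path, index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"subject_id": str})
    validate_table(table)
    numeric = table.drop(columns=["subject_id"])
    if numeric.isna().any().any():
        bad = numeric.columns[numeric.isna().any()].tolist()
        raise ValueError(f"table contains missing values in columns {bad}")
    return table
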