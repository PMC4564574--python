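"""Reading and writing eye-tracker sample tables and trial event tables.

The on-disk dialect emulates a simple eye-tracker export: tab-separated,
header row, UTF-8, ``.`` decimal, one file per subject x task.  Sample
files carry per-eye pupil diameters (mm) with per-eye validity flags at a
nominal sampling rate; event files carry one row per trial.  Empty strings
encode absent values (no response, no RT).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, EmptyInputError, SchemaError
from .preprocess import MonoTrace

__all__ = [
    "SAMPLE_COLUMNS",
    "EVENT_COLUMNS",
    "TASKS",
    "SampleTable",
    "read_samples",
    "write_samples",
    "read_events",
    "write_events",
    "validate_events",
    "combine_eyes",
]

SAMPLE_COLUMNS = ["time_ms", "left_mm", "right_mm", "left_valid", "right_valid"]
EVENT_COLUMNS = [
    "subject_id",
    "task",
    "trial_index",
    "block",
    "onset_ms",
    "condition",
    "stimulus",
    "response",
    "correct",
    "rt_ms",
]
TASKS = ("2back", "stroop", "switch")

#: allowed relative deviation of the inter-sample interval from nominal
_JITTER_TOL = 0.20


@dataclass
class SampleTable:
    """Raw binocular pupil record with per-eye validity flags."""

    time_ms: np.ndarray
    left_mm: np.ndarray
    right_mm: np.ndarray
    left_valid: np.ndarray
    right_valid: np.ndarray
    rate_hz: float = 60.0

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.left_mm = np.asarray(self.left_mm, dtype=float)
        self.right_mm = np.asarray(self.right_mm, dtype=float)
        self.left_valid = np.asarray(self.left_valid, dtype=bool)
        self.right_valid = np.asarray(self.right_valid, dtype=bool)
        n = self.time_ms.size
        for name in ("left_mm", "right_mm", "left_valid", "right_valid"):
            if getattr(self, name).size != n:
                raise ValueError(f"column {name} length != time_ms length")
        self._validate()

    def _validate(self) -> None:
        n = len(self)
        if n >= 2:
            dt = np.diff(self.time_ms)
            bad = np.flatnonzero(dt <= 0)
            if bad.size:
                row = int(bad[0]) + 1  # 0-based row index of the offending sample
                raise DataError(f"time_ms not strictly increasing at row {row}")
            nominal = 1000.0 / self.rate_hz
            off = np.flatnonzero(np.abs(dt - nominal) > _JITTER_TOL * nominal)
            if off.size:
                row = int(off[0]) + 1
                raise DataError(
                    f"inter-sample interval at row {row} ({dt[off[0]]:.3f} ms) deviates "
                    f"more than {_JITTER_TOL:.0%} from nominal {nominal:.3f} ms"
                )
        for mm, valid, eye in (
            (self.left_mm, self.left_valid, "left"),
            (self.right_mm, self.right_valid, "right"),
        ):
            bad = np.flatnonzero(valid & ~(mm > 0))
            if bad.size:
                raise DataError(
                    f"{eye} eye flagged valid with non-positive diameter at row {int(bad[0])}"
                )

    def __len__(self) -> int:
        return self.time_ms.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.time_ms,
                "left_mm": self.left_mm,
                "right_mm": self.right_mm,
                "left_valid": self.left_valid.astype(int),
                "right_valid": self.right_valid.astype(int),
            }
        )


def read_samples(path: str | Path, rate_hz: float = 60.0) -> SampleTable:
    """Read a sample TSV into a validated :class:`SampleTable`.

    Raises :class:`SchemaError` for missing columns or unparseable rows
    (reported with line numbers) and :class:`DataError` for invariant
    violations such as non-monotone timestamps.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing column(s) {missing_cols}")
    if len(raw) == 0:
        raise SchemaError(f"{path}: no data rows")
    numeric = {}
    for col in SAMPLE_COLUMNS:
        probe = pd.to_numeric(raw[col], errors="coerce")
        bad = np.flatnonzero(probe.isna().to_numpy())
        if bad.size:
            lines = [int(i) + 2 for i in bad[:5]]  # +2: header line + 1-based
            raise SchemaError(f"{path}: malformed value(s) in column {col!r} at line(s) {lines}")
        # numpy's parser is correctly rounded, so written values round-trip
        numeric[col] = raw[col].to_numpy(dtype=np.float64)
    try:
        return SampleTable(
            time_ms=numeric["time_ms"],
            left_mm=numeric["left_mm"],
            right_mm=numeric["right_mm"],
            left_valid=numeric["left_valid"] != 0,
            right_valid=numeric["right_valid"] != 0,
            rate_hz=rate_hz,
        )
    except DataError as exc:
        raise DataError(f"{path}: {exc}") from exc


def write_samples(table: SampleTable, path: str | Path) -> None:
    """Write a sample TSV; float formatting round-trips values bit-exact."""
    # 17 significant digits reproduce any IEEE double exactly
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def validate_events(events: pd.DataFrame, path: str | None = None) -> pd.DataFrame:
    """Validate an event table's schema and ordering invariants."""
    where = f"{path}: " if path else ""
    missing_cols = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing_cols:
        raise SchemaError(f"{where}missing column(s) {missing_cols}")
    bad_task = set(events["task"].unique()) - set(TASKS)
    if bad_task:
        raise DataError(f"{where}unknown task label(s) {sorted(bad_task)}")
    for (subj, task), grp in events.groupby(["subject_id", "task"], sort=False):
        onset = grp["onset_ms"].to_numpy(dtype=float)
        if onset.size >= 2 and not (np.diff(onset) > 0).all():
            raise DataError(f"{where}onset_ms not increasing for subject {subj}, task {task}")
    return events


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an event TSV; empty strings become missing values."""
    path = Path(path)
    try:
        events = pd.read_csv(
            path, sep="\t", dtype=str, keep_default_na=False, na_values=[""]
        )
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    validate_events(events, path=str(path))
    events = events.astype(
        {
            "trial_index": int,
            "block": int,
            "onset_ms": float,
            "rt_ms": float,
        }
    )
    events["correct"] = events["correct"].map(
        {"1": True, "0": False, "True": True, "False": False}
    ).astype("boolean")
    return events


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    out = events.copy()
    if out["correct"].dtype != object:
        out["correct"] = out["correct"].map({True: 1, False: 0}).astype("Int64")
    out.to_csv(path, sep="\t", index=False, na_rep="")


def combine_eyes(samples: SampleTable) -> MonoTrace:
    """Combine the two eyes into one diameter per timestamp.

    A sample is missing when the left and/or right eye is invalid;
    otherwise its diameter is the mean of the two eyes.  Using only the
    surviving eye would contradict the binocular missing-data rule, so
    monocular samples are treated as missing and later interpolated.
    """
    if len(samples) == 0:
        raise EmptyInputError("empty sample table")
    both_valid = samples.left_valid & samples.right_valid
    diameter = np.where(both_valid, 0.5 * (samples.left_mm + samples.right_mm), np.nan)
    return MonoTrace(
        time_ms=samples.time_ms.copy(),
        diameter_mm=diameter,
        missing=~both_valid,
        rate_hz=samples.rate_hz,
    )
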