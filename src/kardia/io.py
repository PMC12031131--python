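"""Reading, writing and validation of RR-interval series and subject metadata.

The canonical internal unit is **milliseconds**: every downstream formula
(SDNN, RMSSD, spectral band powers in ms², Poincaré axes) assumes ms, which
is how the short-term HRV normative literature tabulates its values.

Two on-disk dialects are supported:

* plain text, one RR interval per line (the shape most acquisition-software
  exports reduce to);
* a delimited table (CSV/TSV) with a header containing at least an ``rr``
  column, optionally a ``subject_id`` column for multi-subject files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RRSeries",
    "SubjectMeta",
    "RRParseError",
    "RRValidationError",
    "read_rr",
    "write_rr",
    "validate",
    "read_metadata",
    "write_metadata",
]

#: raw-value threshold separating seconds from milliseconds in ``unit="auto"``.
#: Physiological RR is 0.3–2 s or 300–2000 ms, so the gap around 10 is wide.
AUTO_UNIT_THRESHOLD = 10.0


class RRParseError(ValueError):
    """A file could not be parsed as RR intervals (names the offending line)."""


class RRValidationError(ValueError):
    """An RRSeries violates a structural invariant."""


@dataclass(frozen=True)
class RRSeries:
    """One subject's beat-to-beat RR intervals.

    Parameters
    ----------
    intervals : ndarray
        RR intervals in **milliseconds**, one per beat-to-beat gap.
    subject_id : str
        Identifier used in tables and error messages.
    unit_declared : {"ms", "s"}
        Unit the data carried on disk (informational; storage is always ms).
    meta : mapping, optional
        Free-form metadata (group label, age, sex, ...).

    Notes
    -----
    Beat times are derived with the first beat at ``t = 0`` s and interval
    ``k`` spanning ``(beat_times[k-1], beat_times[k]]``; consequently there
    are ``len(intervals) + 1`` beat times.
    """

    intervals: np.ndarray
    subject_id: str = "anonymous"
    unit_declared: str = "ms"
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", arr)
        issues = validate(self)
        if issues:
            raise RRValidationError(
                f"invalid RRSeries {self.subject_id!r}: "
                + "; ".join(i["message"] for i in issues)
            )

    @property
    def beat_times(self) -> np.ndarray:
        """Cumulative beat times in seconds, first beat at t=0."""
        return np.concatenate([[0.0], np.cumsum(self.intervals) / 1000.0])

    @property
    def duration_s(self) -> float:
        """Total spanned time in seconds."""
        return float(np.sum(self.intervals) / 1000.0)

    def __len__(self) -> int:
        return int(self.intervals.size)

    def replace_intervals(self, intervals: np.ndarray) -> "RRSeries":
        """Return a copy of this series with new interval values."""
        return RRSeries(
            intervals=np.asarray(intervals, dtype=float),
            subject_id=self.subject_id,
            unit_declared=self.unit_declared,
            meta=dict(self.meta),
        )

    def slice_beats(self, start: int, stop: int) -> "RRSeries":
        """Contiguous sub-series over interval indices ``[start, stop)``."""
        return self.replace_intervals(self.intervals[start:stop])


@dataclass(frozen=True)
class SubjectMeta:
    """Demographics and clinical covariates for one subject.

    ``clinical`` maps scale name to numeric score; the scales handled by the
    cohort pipeline are FIQ (fibromyalgia impact, 0–100), NRS (pain, 0–10),
    SF-36 PHI (physical health, 0–100), MAF, SAS, SDS, MOS, WPI, SS and
    disease duration in years.
    """

    subject_id: str
    group: str
    age: float
    sex: str = "F"
    clinical: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in {"HC", "FM"}:
            raise RRValidationError(
                f"subject {self.subject_id!r}: group must be 'HC' or 'FM', "
                f"got {self.group!r}"
            )
        fiq = self.clinical.get("fiq")
        if fiq is not None and not math.isnan(fiq) and not 0 <= fiq <= 100:
            raise RRValidationError(
                f"subject {self.subject_id!r}: FIQ {fiq} outside [0, 100]"
            )
        nrs = self.clinical.get("nrs")
        if nrs is not None and not math.isnan(nrs) and not 0 <= nrs <= 10:
            raise RRValidationError(
                f"subject {self.subject_id!r}: NRS {nrs} outside [0, 10]"
            )


def _rows_to_issues(series: RRSeries) -> Iterable[dict]:
    intervals = np.asarray(series.intervals, dtype=float)
    if intervals.ndim != 1:
        yield {"index": None, "rule": "1-d", "message": "intervals must be 1-d"}
        return
    if intervals.size < 2:
        yield {
            "index": None,
            "rule": "length >= 2",
            "message": f"need at least 2 intervals, got {intervals.size}",
        }
    bad = np.flatnonzero(~(intervals > 0) | ~np.isfinite(intervals))
    for idx in bad:
        yield {
            "index": int(idx),
            "rule": "positive interval",
            "message": f"interval at index {idx} is {intervals[idx]!r}, "
            "expected a positive finite value",
        }


def validate(series: RRSeries) -> list[dict]:
    """Check RRSeries invariants; return a list of issue records.

    Each record has keys ``index`` (beat index or None for series-level
    rules), ``rule`` and ``message``.  An empty list means the series is
    valid.  This never raises.
    """
    return list(_rows_to_issues(series))


def _infer_unit(values: np.ndarray) -> str:
    return "s" if float(np.median(values)) < AUTO_UNIT_THRESHOLD else "ms"


def read_rr(
    path: str | Path,
    unit: str = "auto",
    subject_id: str | None = None,
    column: str = "rr",
) -> RRSeries:
    """Read one subject's RR intervals from disk.

    Parameters
    ----------
    path : path
        Plain-text file (one float per line, ``#`` comments allowed) or a
        delimited table with a header naming `column`.
    unit : {"ms", "s", "auto"}
        Unit of the stored values.  ``auto`` infers seconds when the median
        raw value is below 10, else milliseconds.
    subject_id : str, optional
        Defaults to the file stem.
    column : str
        Interval column name when the file is a delimited table.

    Returns
    -------
    RRSeries
        Intervals converted to milliseconds.
    """
    path = Path(path)
    if unit not in {"ms", "s", "auto"}:
        raise ValueError(f"unit must be 'ms', 's' or 'auto', got {unit!r}")
    text = path.read_text()
    first = next((ln for ln in text.splitlines()
                  if ln.strip() and not ln.lstrip().startswith("#")), "")
    delim = "," if "," in first else ("\t" if "\t" in first else None)
    values: list[float] = []
    if delim is not None or any(c.isalpha() for c in first.replace("e", "").replace("E", "")):
        # delimited table with header
        df = pd.read_csv(path, sep=delim or r"\s+", engine="python")
        if column not in df.columns:
            raise RRParseError(
                f"{path}: no {column!r} column among {list(df.columns)}"
            )
        col = pd.to_numeric(df[column], errors="coerce")
        if col.isna().any():
            bad = int(col.index[col.isna()][0]) + 2  # +1 header, +1 one-based
            raise RRParseError(f"{path}: non-numeric value at line {bad}")
        values = col.to_numpy(dtype=float).tolist()
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            try:
                values.append(float(stripped))
            except ValueError:
                raise RRParseError(
                    f"{path}: non-numeric value {stripped!r} at line {lineno}"
                ) from None
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise RRParseError(f"{path}: no RR values found")
    resolved = _infer_unit(arr) if unit == "auto" else unit
    if resolved == "s":
        arr = arr * 1000.0
    if np.any(arr <= 0):
        idx = int(np.flatnonzero(arr <= 0)[0])
        raise RRValidationError(
            f"{path}: non-positive RR interval {arr[idx]!r} at entry {idx + 1}"
        )
    return RRSeries(
        intervals=arr,
        subject_id=subject_id or path.stem,
        unit_declared=resolved,
    )


def write_rr(series: RRSeries, path: str | Path) -> None:
    """Write intervals as plain text, one value per line, in ms.

    Uses ``repr``-style shortest round-trip formatting so that
    ``read_rr(write_rr(x))`` reproduces the values bit-identically.
    """
    path = Path(path)
    lines = "\n".join(repr(float(v)) for v in series.intervals)
    path.write_text(lines + "\n")


_CLINICAL_COLUMNS = (
    "fiq", "nrs", "sf36_phi", "maf", "sas", "sds", "mos", "wpi", "ss",
    "disease_duration",
)


def read_metadata(path: str | Path) -> list[SubjectMeta]:
    """Read a subject metadata table (CSV with header).

    Required columns: ``subject_id``, ``group``, ``age``.  Optional: ``sex``
    plus any of the clinical scales (missing cells become NaN).
    """
    df = pd.read_csv(path)
    required = {"subject_id", "group", "age"}
    missing = required - set(df.columns)
    if missing:
        raise RRParseError(f"{path}: metadata table missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        clinical = {
            c: float(row[c]) for c in _CLINICAL_COLUMNS if c in df.columns
        }
        out.append(
            SubjectMeta(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                sex=str(row.get("sex", "F")),
                clinical=clinical,
            )
        )
    return out


def write_metadata(subjects: Sequence[SubjectMeta], path: str | Path) -> None:
    """Write subject metadata as a CSV table (inverse of :func:`read_metadata`)."""
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id,
            "group": s.group,
            "age": s.age,
            "sex": s.sex,
        }
        row.update({k: s.clinical.get(k, float("nan")) for k in _CLINICAL_COLUMNS})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
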