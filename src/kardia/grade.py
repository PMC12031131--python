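"""Composite HRV grade: abnormality count over SDNN, RMSSD and total power.

The grade is a 0–3 screening score: each of the three linear indices is
compared against a normative limit and the grade counts how many fall
outside it (0 = no abnormality, 3 = all three abnormal).  The default
direction is ``low_only`` — reduced variability is what the score screens
for — with a ``two_sided`` mode for range checks.  Values exactly equal to
a limit count as normal (deterministic tie rule).

The packaged normative table carries per-value source labels and is meant
to be overridden where site-specific norms exist; no cutoff here is treated
as canonical.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .metrics import HRVProfile

__all__ = [
    "NormativeLimit",
    "NormativeTable",
    "GradeResult",
    "GRADE_INDICES",
    "default_normative_table",
    "load_normative_table",
    "grade",
]

GRADE_INDICES = ("sdnn", "rmssd", "total_power")


@dataclass(frozen=True)
class NormativeLimit:
    """Normal range for one index; ``upper=None`` means unbounded above."""

    lower: float
    upper: float | None
    units: str
    source: str

    def __post_init__(self) -> None:
        if self.lower <= 0:
            raise ValueError(f"lower limit must be positive, got {self.lower}")
        if self.upper is not None and self.upper <= self.lower:
            raise ValueError(
                f"upper limit {self.upper} must exceed lower {self.lower}"
            )


@dataclass(frozen=True)
class NormativeTable:
    """Per-index normal limits with provenance."""

    limits: Mapping[str, NormativeLimit]
    source: str = "packaged default"

    def __post_init__(self) -> None:
        missing = set(GRADE_INDICES) - set(self.limits)
        if missing:
            raise ValueError(f"normative table missing indices {sorted(missing)}")

    def merge(self, overrides: Mapping[str, NormativeLimit]) -> "NormativeTable":
        """New table with the named limits replaced, the rest kept."""
        merged = dict(self.limits)
        merged.update(overrides)
        return NormativeTable(limits=merged, source=f"{self.source} + overrides")


@dataclass(frozen=True)
class GradeResult:
    """HRV grade (0–3) with per-index normal/abnormal flags."""

    grade: int
    flags: Mapping[str, str]
    table_source: str


def _parse_limits(raw: Mapping[str, Mapping]) -> dict[str, NormativeLimit]:
    out = {}
    for index, entry in raw.items():
        out[index] = NormativeLimit(
            lower=float(entry["lower"]),
            upper=None if entry.get("upper") is None else float(entry["upper"]),
            units=str(entry.get("units", "")),
            source=str(entry.get("source", "unspecified")),
        )
    return out


def default_normative_table() -> NormativeTable:
    """The packaged short-term normative table (see ``data/normative.yaml``)."""
    raw = yaml.safe_load(
        resources.files("kardia").joinpath("data/normative.yaml").read_text()
    )
    return NormativeTable(limits=_parse_limits(raw), source="packaged default")


def load_normative_table(path: str | Path,
                         base: NormativeTable | None = None) -> NormativeTable:
    """Load a YAML normative table; with ``base``, override only named limits."""
    raw = yaml.safe_load(Path(path).read_text())
    overrides = _parse_limits(raw)
    if base is not None:
        return base.merge(overrides)
    return NormativeTable(limits=overrides, source=str(path))


def grade(profile: HRVProfile | Mapping[str, float],
          table: NormativeTable | None = None,
          mode: str = "low_only") -> GradeResult:
    """Grade one subject's profile against the normative table.

    An index is abnormal iff strictly below its lower limit (``low_only``)
    or strictly outside ``[lower, upper]`` (``two_sided``); boundary-equal
    values are normal.  The grade is the abnormal count over
    SDNN, RMSSD and total power, hence monotone: lowering any of the three
    values can only raise it.
    """
    if mode not in {"low_only", "two_sided"}:
        raise ValueError(f"mode must be 'low_only' or 'two_sided', got {mode!r}")
    table = table or default_normative_table()
    values = profile.as_dict() if isinstance(profile, HRVProfile) else dict(profile)
    flags: dict[str, str] = {}
    for index in GRADE_INDICES:
        value = values.get(index)
        if value is None or not (value == value):  # missing or NaN
            raise ValueError(f"profile has no finite value for index {index!r}")
        limit = table.limits[index]
        abnormal = value < limit.lower
        if mode == "two_sided":
            if limit.upper is None:
                raise ValueError(
                    f"two_sided grading needs an upper limit for {index!r}"
                )
            abnormal = abnormal or value > limit.upper
        flags[index] = "abnormal" if abnormal else "normal"
    n_abnormal = sum(f == "abnormal" for f in flags.values())
    return GradeResult(grade=n_abnormal, flags=flags, table_source=table.source)
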