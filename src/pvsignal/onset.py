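"""Time-to-onset of target-drug adverse events.

Onset is the event date of the report minus the therapy start date of the
matched primary-suspect drug, in days.  Only day-precision dates qualify;
reports with partial or missing dates, or with an event date before the start
date (an input error), are excluded and tallied by reason.  The summary is
the median with interquartile range plus a 30-day-bin histogram (0-30, 31-60,
..., 331-360, >360 days).
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .faers_io import DemoRecord, TherRecord

__all__ = [
    "OnsetRecord",
    "OnsetResult",
    "OnsetSummary",
    "BIN_LABELS",
    "compute_onset",
    "summarize_onset",
]

#: 30-day onset bins; days are integers so (30, 60] reads "31-60".
BIN_LABELS: tuple[str, ...] = tuple(
    f"{lo}-{lo + 29 if lo else 30}" for lo in (0, *range(31, 361, 30))
) + (">360",)


@dataclasses.dataclass(frozen=True)
class OnsetRecord:
    caseid: str
    onset_days: int

    def __post_init__(self) -> None:
        if self.onset_days < 0:
            raise ValueError("onset_days must be >= 0")


@dataclasses.dataclass
class OnsetResult:
    """Onset records plus exclusion accounting (included + excluded = cohort)."""

    records: list[OnsetRecord]
    exclusions: Counter

    @property
    def n_included(self) -> int:
        return len(self.records)

    @property
    def n_excluded(self) -> int:
        return sum(self.exclusions.values())


def compute_onset(
    demo: Sequence[DemoRecord],
    ther: Sequence[TherRecord],
    cohort: Cohort,
) -> OnsetResult:
    """One onset per target report with usable dates.

    THER rows are linked to the matched primary-suspect drug via
    (primaryid, drug_seq); when several start dates exist the earliest
    day-precision one is used ("start of the target drug" = first exposure).
    Each excluded report lands in exactly one reason bucket, checked in the
    order: no therapy row, no day-precision start date, no day-precision
    event date, event before start.
    """
    starts: dict[str, list] = {}
    has_ther: set[str] = set()
    for t in ther:
        if (t.primaryid, t.dsg_drug_seq) in cohort.ps_keys:
            has_ther.add(t.primaryid)
            if t.start_dt.is_full:
                starts.setdefault(t.primaryid, []).append(t.start_dt.to_date())

    records: list[OnsetRecord] = []
    excl: Counter = Counter()
    for r in demo:
        if r.caseid not in cohort.target:
            continue
        if r.primaryid not in has_ther:
            excl["no_therapy_row"] += 1
            continue
        if r.primaryid not in starts:
            excl["start_date_not_day_precision"] += 1
            continue
        if not r.event_dt.is_full:
            excl["event_date_not_day_precision"] += 1
            continue
        start = min(starts[r.primaryid])
        delta = (r.event_dt.to_date() - start).days
        if delta < 0:
            excl["event_before_start"] += 1
            continue
        records.append(OnsetRecord(caseid=r.caseid, onset_days=delta))
    return OnsetResult(records=records, exclusions=excl)


@dataclasses.dataclass(frozen=True)
class OnsetSummary:
    n_with_onset: int
    median_days: float
    q1: float
    q3: float
    bins: pd.DataFrame  # columns: bin, count, percent

    @property
    def iqr(self) -> tuple[float, float]:
        return (self.q1, self.q3)

    @property
    def is_empty(self) -> bool:
        return self.n_with_onset == 0


def _bin_index(days: int) -> int:
    if days <= 30:
        return 0
    return min((days - 1) // 30, 12)


def summarize_onset(records: Sequence[OnsetRecord]) -> OnsetSummary:
    """Median/IQR (linear-interpolation quartiles) and 30-day-bin histogram.

    Empty input yields an explicit empty summary (NaN statistics, zero bins).
    """
    counts = Counter(_bin_index(r.onset_days) for r in records)
    n = len(records)
    bins = pd.DataFrame(
        {
            "bin": BIN_LABELS,
            "count": [counts.get(i, 0) for i in range(len(BIN_LABELS))],
        }
    )
    bins["percent"] = (
        (100.0 * bins["count"] / n).round(2) if n else 0.0
    )
    if n == 0:
        return OnsetSummary(0, float("nan"), float("nan"), float("nan"), bins)
    days = np.array([r.onset_days for r in records], dtype=float)
    q1, med, q3 = np.percentile(days, [25, 50, 75])  # linear interpolation
    return OnsetSummary(n, float(med), float(q1), float(q3), bins)
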