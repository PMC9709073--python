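"""Report-level 2x2 contingency tables and the comparator-reconstruction oracle.

Disproportionality analysis reduces a spontaneous-report corpus to one 2x2
table per adverse-event term::

                      term present   term absent
    target drug            a             b
    all other drugs        c             d

The counting unit is the deduplicated report: a report mentioning the same
Preferred Term twice counts once, and at System Organ Class level a report
counts once per SOC no matter how many of its PTs map there.

:func:`reconstruct_comparator` inverts the reporting-odds-ratio Wald interval:
given the published (a, cohort size, ROR, 95% CI) for a term it back-solves
the comparator cells (c, d), which lets every downstream statistic be
recomputed from a published table row alone.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from collections import Counter
from typing import Iterable, Iterator, Mapping, Sequence

from .cohort import Cohort, normalize_term
from .faers_io import EventMention

__all__ = [
    "ContingencyTable",
    "SocMap",
    "TableSet",
    "UNMAPPED_SOC",
    "build_tables",
    "reconstruct_comparator",
    "reconstruct_table",
    "InfeasibleReconstructionError",
]

UNMAPPED_SOC = "Unmapped"


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """2x2 drug-term report counts (cells may be reals after reconstruction)."""

    term: str
    level: str  # "pt" | "soc"
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in table for {self.term!r}")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def n_target(self) -> float:
        return self.a + self.b

    @property
    def expected(self) -> float:
        """Expected a under independence: (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.n


class SocMap:
    """PT -> System Organ Class mapping (user-supplied; MedDRA is licensed
    and cannot be redistributed, so only a small demo mapping ships)."""

    def __init__(self, mapping: Mapping[str, str]):
        self._map: dict[str, str] = {}
        for pt, soc in mapping.items():
            key = normalize_term(pt)
            prev = self._map.get(key)
            if prev is not None and prev != soc.strip():
                raise ValueError(f"PT {pt!r} mapped to two SOCs")
            self._map[key] = soc.strip()

    @classmethod
    def from_csv(cls, path) -> "SocMap":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"pt", "soc"} <= set(
                h.strip().lower() for h in reader.fieldnames
            ):
                raise ValueError("soc map CSV needs header columns pt,soc")
            mapping = {}
            for row in reader:
                row = {k.strip().lower(): (v or "") for k, v in row.items()}
                if row["pt"].strip():
                    mapping[row["pt"]] = row["soc"]
        return cls(mapping)

    def get(self, pt: str) -> str | None:
        return self._map.get(normalize_term(pt))

    def __len__(self) -> int:
        return len(self._map)


@dataclasses.dataclass
class TableSet:
    """Tables for one level plus the PTs that had no SOC mapping."""

    level: str
    tables: list[ContingencyTable]
    unmapped_pts: set[str] = dataclasses.field(default_factory=set)

    def __iter__(self) -> Iterator[ContingencyTable]:
        return iter(self.tables)

    def __len__(self) -> int:
        return len(self.tables)

    def by_term(self) -> dict[str, ContingencyTable]:
        return {t.term: t for t in self.tables}


def build_tables(
    cohort: Cohort,
    events: Iterable[EventMention],
    level: str = "pt",
    soc_map: SocMap | None = None,
    *,
    case_of: Mapping[str, str],
) -> TableSet:
    """One 2x2 table per term observed anywhere in the deduplicated corpus.

    ``case_of`` maps surviving primaryids to caseids; events of superseded
    report versions are ignored.  At SOC level, PTs missing from ``soc_map``
    are routed to the ``Unmapped`` pseudo-SOC and reported, never dropped.
    Row order of ``events`` does not affect the result.
    """
    level = level.lower()
    if level not in ("pt", "soc"):
        raise ValueError("level must be 'pt' or 'soc'")
    if level == "soc" and soc_map is None:
        raise ValueError("SOC level requires a soc_map")

    unmapped: set[str] = set()
    pairs: set[tuple[str, str]] = set()
    for ev in events:
        cid = case_of.get(ev.primaryid)
        if cid is None or not ev.pt:
            continue
        if level == "pt":
            term = ev.pt
        else:
            term = soc_map.get(ev.pt)  # type: ignore[union-attr]
            if term is None:
                unmapped.add(ev.pt)
                term = UNMAPPED_SOC
        pairs.add((cid, term))

    a_counts: Counter = Counter()
    c_counts: Counter = Counter()
    for cid, term in pairs:
        if cid in cohort.target:
            a_counts[term] += 1
        elif cid in cohort.background:
            c_counts[term] += 1

    n_t = cohort.n_target
    n_b = cohort.n_background
    tables = [
        ContingencyTable(
            term=term,
            level=level,
            a=a_counts.get(term, 0),
            b=n_t - a_counts.get(term, 0),
            c=c_counts.get(term, 0),
            d=n_b - c_counts.get(term, 0),
        )
        for term in sorted(set(a_counts) | set(c_counts))
    ]
    return TableSet(level=level, tables=tables, unmapped_pts=unmapped)


class InfeasibleReconstructionError(ValueError):
    """Raised when printed (a, n, ROR, CI) admit no positive comparator cells.

    The Wald width contributes 1/a + 1/b as a hard floor on the squared
    log-CI half-width; CI bounds printed to 2 decimals can fall below it.
    """


def reconstruct_comparator(
    a: float,
    n_target: float,
    ror: float,
    ci_low: float,
    ci_high: float,
    *,
    z: float = 1.96,
) -> tuple[float, float]:
    """Back-solve comparator cells (c, d) from a published ROR row.

    With b = n_target - a known, the Wald relations

        ror = (a d)/(b c)
        ln(ci_high/ci_low) / (2 z) = sqrt(1/a + 1/b + 1/c + 1/d)

    pin c and d in closed form: writing r = s^2 - 1/a - 1/b with s the
    log-scale half-width, 1/c + 1/d = r and d = ror*b*c/a give

        c = (1 + a/(ror b)) / r,      d = ror b c / a.

    Returns positive reals; forward-computing ROR and its CI from
    (a, b, c, d) reproduces the inputs up to the rounding of the printed CI.
    """
    if a < 1 or n_target <= a:
        raise ValueError("need a >= 1 and n_target > a")
    if not (0 < ci_low < ror < ci_high):
        raise ValueError("need ci_low < ror < ci_high, all positive")
    b = n_target - a
    s = math.log(ci_high / ci_low) / (2.0 * z)
    resid = s * s - 1.0 / a - 1.0 / b
    if resid <= 0:
        raise InfeasibleReconstructionError(
            f"printed CI width implies 1/c + 1/d = {resid:.3g} <= 0 "
            "(below the 1/a + 1/b floor at printed rounding)"
        )
    c = (1.0 + a / (ror * b)) / resid
    d = ror * b * c / a
    return c, d


def reconstruct_table(
    term: str,
    a: float,
    n_target: float,
    ror: float,
    ci_low: float,
    ci_high: float,
    *,
    level: str = "pt",
    z: float = 1.96,
    integer: bool = False,
) -> ContingencyTable:
    """Convenience wrapper returning a :class:`ContingencyTable`.

    ``integer=True`` rounds the comparator cells to the nearest counts
    (the 2-decimal printed inputs cannot pin exact integers).
    """
    c, d = reconstruct_comparator(a, n_target, ror, ci_low, ci_high, z=z)
    if integer:
        c, d = round(c), round(d)
    return ContingencyTable(term=term, level=level, a=a, b=n_target - a, c=c, d=d)
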