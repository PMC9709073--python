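"""Target-drug cohort construction and descriptive characteristics.

The study design is a case/non-case comparison inside a deduplicated
spontaneous-report corpus: the *target cohort* is every case with at least one
drug row naming the drug of interest (generic or trade name) with role code
``PS`` (primary suspect); every other case is the *background*.  The module
also produces the usual descriptive table (sex, age bands, indications,
serious outcomes, countries, reporter occupation, reporting year) and the
consumer-exclusion sensitivity variant.
"""

from __future__ import annotations

import dataclasses
import re
from collections import Counter
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .faers_io import (
    DemoRecord,
    DrugMention,
    IndicationRecord,
    OutcomeRecord,
)

__all__ = [
    "Cohort",
    "build_cohort",
    "match_target",
    "matched_ps_mentions",
    "summarize_characteristics",
    "exclude_consumers",
    "normalize_term",
]

_WS = re.compile(r"\s+")


def normalize_term(s: str) -> str:
    """Trim, collapse internal whitespace and case-fold a free-text term."""
    return _WS.sub(" ", s.strip()).casefold()


def _name_regex(name: str) -> re.Pattern[str]:
    # word-boundary substring: "niraparib" matches "NIRAPARIB TOSYLATE
    # MONOHYDRATE" but not "xniraparibx"
    return re.compile(rf"(?<!\w){re.escape(normalize_term(name))}(?!\w)")


@dataclasses.dataclass(frozen=True)
class Cohort:
    """Partition of deduplicated cases into target and background.

    ``ps_keys`` holds the (primaryid, drug_seq) pairs of the matched
    primary-suspect mentions; they anchor indication and therapy-date joins.
    """

    target: frozenset[str]
    background: frozenset[str]
    name_list: tuple[str, ...]
    ps_keys: frozenset[tuple[str, str]] = frozenset()

    @property
    def n_target(self) -> int:
        return len(self.target)

    @property
    def n_background(self) -> int:
        return len(self.background)

    @property
    def all_cases(self) -> frozenset[str]:
        return self.target | self.background


def matched_ps_mentions(
    drug_mentions: Iterable[DrugMention], names: Sequence[str]
) -> list[DrugMention]:
    """Drug rows whose name matches the target list with role ``PS``."""
    if not names:
        raise ValueError("target name list must be non-empty")
    patterns = [_name_regex(n) for n in names]

    def hit(mention: DrugMention) -> bool:
        if mention.role_cod != "PS":
            return False
        for text in (mention.drugname, mention.prod_ai or ""):
            if not text:
                continue
            norm = normalize_term(text)
            if any(p.search(norm) for p in patterns):
                return True
        return False

    return [m for m in drug_mentions if hit(m)]


def match_target(
    drug_mentions: Iterable[DrugMention],
    names: Sequence[str],
    case_of: Mapping[str, str],
) -> set[str]:
    """Case ids whose kept report version has a PS mention of a target name.

    ``case_of`` maps the surviving ``primaryid`` of each deduplicated case to
    its ``caseid``; mentions belonging to superseded report versions are
    ignored.
    """
    return {
        case_of[m.primaryid]
        for m in matched_ps_mentions(drug_mentions, names)
        if m.primaryid in case_of
    }


def build_cohort(
    demo: Sequence[DemoRecord],
    drug_mentions: Iterable[DrugMention],
    names: Sequence[str],
) -> Cohort:
    """Build the target/background partition on deduplicated DEMO records."""
    case_of = {r.primaryid: r.caseid for r in demo}
    mentions = matched_ps_mentions(drug_mentions, names)
    target = {case_of[m.primaryid] for m in mentions if m.primaryid in case_of}
    background = {r.caseid for r in demo} - target
    ps_keys = {
        (m.primaryid, m.drug_seq) for m in mentions if m.primaryid in case_of
    }
    return Cohort(
        target=frozenset(target),
        background=frozenset(background),
        name_list=tuple(names),
        ps_keys=frozenset(ps_keys),
    )


# --------------------------------------------------------------------------
# Descriptive characteristics
# --------------------------------------------------------------------------

# Age unit codes: decades, years, months, weeks, days.
_AGE_FACTOR = {"DEC": 10.0, "YR": 1.0, "MON": 1 / 12.0, "WK": 1 / 52.14, "DY": 1 / 365.25}

_OCCP_LABEL = {
    "CN": "Consumer",
    "MD": "Physician",
    "PH": "Pharmacist",
    "HP": "Health professional",
    "LW": "Lawyer",
    "OT": "Other health-professional",
}

_OUTCOME_ROWS = (
    ("DE", "Death"),
    ("DS", "Disability"),
    ("HO", "Hospitalization-initial or prolonged"),
    ("LT", "Life-threatening"),
    ("OT", "Other serious medical events"),
)


def age_in_years(age: float | None, age_cod: str | None) -> float | None:
    """Convert a reported age to years using its unit code.

    A missing unit with a plausible value (0-122 y) is taken as years;
    anything unconvertible is unknown.  122 y is the oldest verified human
    lifespan, used here as a plausibility bound.
    """
    if age is None:
        return None
    if age_cod is None:
        return age if 0 <= age <= 122 else None
    factor = _AGE_FACTOR.get(age_cod.upper())
    if factor is None:
        return None
    years = age * factor
    return years if 0 <= years <= 122 else None


def _age_band(years: float | None) -> str:
    # "40-50" is inclusive at both ends; ">50" strictly greater.
    if years is None:
        return "Unknown or missing"
    if years < 40:
        return "<40"
    if years <= 50:
        return "40-50"
    return ">50"


def _pct(count: int, total: int) -> float:
    return round(100.0 * count / total, 2) if total else 0.0


def summarize_characteristics(
    cohort: Cohort,
    demo: Sequence[DemoRecord],
    outc: Sequence[OutcomeRecord] = (),
    indi: Sequence[IndicationRecord] = (),
    *,
    top_k_indications: int = 4,
    top_k_countries: int = 5,
) -> pd.DataFrame:
    """Descriptive table of the target cohort.

    Returns a DataFrame with columns ``category, level, count, percent``.
    Sex, age band and reporting year partition the cohort (percentages sum to
    100); outcome rows may overlap because a report can carry several outcome
    codes, and each code contributes to its own row.  Percentages are always
    relative to the cohort size, to 2 decimals.  An empty cohort yields
    all-zero counts rather than a division error.
    """
    n = cohort.n_target
    target_demo = [r for r in demo if r.caseid in cohort.target]
    target_pids = {r.primaryid for r in target_demo}

    rows: list[tuple[str, str, int, float]] = []

    def emit(category: str, counter: Counter, order: Sequence[str]) -> None:
        for level in order:
            c = counter.get(level, 0)
            rows.append((category, level, c, _pct(c, n)))

    # sex
    sex_counter = Counter(
        {"Female": 0, "Male": 0, "Unknown": 0}
    )
    for r in target_demo:
        sex_counter[{"F": "Female", "M": "Male"}.get(r.sex or "", "Unknown")] += 1
    emit("sex", sex_counter, ["Female", "Male", "Unknown"])

    # age bands
    age_counter: Counter = Counter()
    for r in target_demo:
        age_counter[_age_band(age_in_years(r.age, r.age_cod))] += 1
    emit("age", age_counter, ["<40", "40-50", ">50", "Unknown or missing"])

    # indications of the matched PS drug rows only
    indi_cases: dict[str, set[str]] = {}
    for rec in indi:
        if (rec.primaryid, rec.indi_drug_seq) in cohort.ps_keys and rec.indi_pt:
            indi_cases.setdefault(rec.indi_pt, set()).add(rec.primaryid)
    indi_counter = Counter({pt: len(p) for pt, p in indi_cases.items()})
    top_indi = [pt for pt, _ in indi_counter.most_common(top_k_indications)]
    emit("indication", indi_counter, top_indi)

    # serious outcomes; a report with several codes lands in several rows.
    # CA (congenital anomaly) and RI (required intervention) are rare and
    # reported under one catch-all row.
    outc_cases: dict[str, set[str]] = {}
    for rec in outc:
        if rec.primaryid in target_pids:
            outc_cases.setdefault(rec.outc_cod, set()).add(rec.primaryid)
    for code, label in _OUTCOME_ROWS:
        c = len(outc_cases.get(code, ()))
        rows.append(("serious_outcome", label, c, _pct(c, n)))
    other = len(outc_cases.get("CA", set()) | outc_cases.get("RI", set()))
    rows.append(("serious_outcome", "Other outcomes (CA/RI)", other, _pct(other, n)))

    # reporter countries (top k)
    country_counter = Counter(
        (r.occr_country or "Unknown") for r in target_demo
    )
    top_countries = [c for c, _ in country_counter.most_common(top_k_countries)]
    emit("country", country_counter, top_countries)

    # reporter occupation
    occp_counter: Counter = Counter()
    for r in target_demo:
        occp_counter[_OCCP_LABEL.get((r.occp_cod or "").upper(), "Unknown")] += 1
    emit(
        "occupation",
        occp_counter,
        [*_OCCP_LABEL.values(), "Unknown"],
    )

    # reporting year from the kept version's FDA receipt date
    year_counter: Counter = Counter()
    for r in target_demo:
        year_counter[str(r.fda_dt.year) if r.fda_dt.year else "Unknown"] += 1
    years = sorted(year_counter)
    emit("reporting_year", year_counter, years)

    return pd.DataFrame(rows, columns=["category", "level", "count", "percent"])


def exclude_consumers(cohort: Cohort, demo: Sequence[DemoRecord]) -> Cohort:
    """Sensitivity variant: drop consumer-submitted reports (``occp_cod`` CN)
    from target and background alike.  Idempotent."""
    consumer_cases = {r.caseid for r in demo if (r.occp_cod or "").upper() == "CN"}
    consumer_pids = {
        r.primaryid for r in demo if (r.occp_cod or "").upper() == "CN"
    }
    return Cohort(
        target=cohort.target - consumer_cases,
        background=cohort.background - consumer_cases,
        name_list=cohort.name_list,
        ps_keys=frozenset(
            k for k in cohort.ps_keys if k[0] not in consumer_pids
        ),
    )
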