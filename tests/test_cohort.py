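"""Cohort construction, descriptive characteristics, consumer exclusion."""

import pytest

from pvsignal import faers_io
from pvsignal.cohort import (
    build_cohort,
    exclude_consumers,
    match_target,
    summarize_characteristics,
)
from pvsignal.faers_io import DemoRecord, DrugMention, OutcomeRecord, parse_date
from pvsignal.synthetic import SimulationConfig, simulate_corpus

NAMES = ["niraparib", "zejula"]


def _mention(pid, name, role, seq="1", prod_ai=None):
    return DrugMention(primaryid=pid, drug_seq=seq, drugname=name,
                       role_cod=role, prod_ai=prod_ai)


@pytest.mark.parametrize(
    "name, role, prod_ai, matched",
    [
        ("ZEJULA", "PS", None, True),
        ("Niraparib", "C", None, False),  # role filter
        ("NIRAPARIB TOSYLATE MONOHYDRATE", "PS", None, True),  # word boundary
        ("PANIRAPARIBOL", "PS", None, False),  # substring inside a word
        ("UNRELATED DRUG", "PS", "NIRAPARIB", True),  # match via prod_ai
        ("  zejula  ", "PS", None, True),  # whitespace normalization
    ],
)
def test_match_target_name_rules(name, role, prod_ai, matched):
    case_of = {"11": "1"}
    got = match_target([_mention("11", name, role, prod_ai=prod_ai)], NAMES, case_of)
    assert (got == {"1"}) is matched


def test_match_target_empty_name_list_is_error():
    with pytest.raises(ValueError):
        match_target([_mention("11", "ZEJULA", "PS")], [], {"11": "1"})


def test_cohort_partitions_all_cases(fixture_demo, fixture_cohort):
    cases = {r.caseid for r in fixture_demo}
    assert fixture_cohort.target | fixture_cohort.background == cases
    assert not (fixture_cohort.target & fixture_cohort.background)
    assert fixture_cohort.n_target == len(
        {r.caseid for r in fixture_demo} & fixture_cohort.target
    )


def test_mentions_of_superseded_versions_ignored():
    demo = [DemoRecord(primaryid="12", caseid="1", fda_dt=parse_date("20210101"))]
    # PS mention sits on the stale version "11" only
    cohort = build_cohort(demo, [_mention("11", "NIRAPARIB", "PS")], NAMES)
    assert cohort.n_target == 0 and cohort.background == {"1"}


def _demo(pid, caseid, sex=None, age=None, age_cod=None, occp=None,
          country=None, fda="20210301"):
    return DemoRecord(primaryid=pid, caseid=caseid, fda_dt=parse_date(fda),
                      age=age, age_cod=age_cod, sex=sex, occp_cod=occp,
                      occr_country=country)


def _summary_count(df, category, level):
    sel = df[(df.category == category) & (df.level == level)]
    return int(sel["count"].iloc[0]) if len(sel) else 0


def test_summarize_counts_and_percentages():
    demo = [
        _demo("11", "1", sex="F", age=63, age_cod="YR", occp="CN", fda="20210301"),
        _demo("21", "2", sex="F", age=540, age_cod="MON", occp="MD", fda="20200101"),
        _demo("31", "3", sex="M", age=4.5, age_cod="DEC", occp="CN", fda="20210601"),
        _demo("41", "4", age=200, fda="20190101"),  # implausible age -> unknown
    ]
    mentions = [_mention(f"{c}1", "NIRAPARIB", "PS") for c in "1234"]
    cohort = build_cohort(demo, mentions, NAMES)
    outc = [OutcomeRecord("11", "DE"), OutcomeRecord("11", "HO"),
            OutcomeRecord("21", "HO"), OutcomeRecord("31", "CA")]
    df = summarize_characteristics(cohort, demo, outc)

    assert _summary_count(df, "sex", "Female") == 2
    assert _summary_count(df, "sex", "Male") == 1
    assert _summary_count(df, "sex", "Unknown") == 1
    # 540 months = 45 y; 4.5 decades = 45 y; 200 y implausible
    assert _summary_count(df, "age", "40-50") == 2
    assert _summary_count(df, "age", ">50") == 1
    assert _summary_count(df, "age", "Unknown or missing") == 1
    # one report with two outcome codes contributes to both rows
    assert _summary_count(df, "serious_outcome", "Death") == 1
    assert _summary_count(df, "serious_outcome",
                          "Hospitalization-initial or prolonged") == 2
    assert _summary_count(df, "serious_outcome", "Other outcomes (CA/RI)") == 1
    assert _summary_count(df, "reporting_year", "2021") == 2
    fem = df[(df.category == "sex") & (df.level == "Female")]["percent"].iloc[0]
    assert fem == 50.0


@pytest.mark.parametrize("category", ["sex", "age", "reporting_year"])
def test_partition_category_percentages_sum_to_100(fixture_demo, fixture_cohort,
                                                   fixture_records, category):
    df = summarize_characteristics(fixture_cohort, fixture_demo,
                                   fixture_records["OUTC"],
                                   fixture_records["INDI"])
    total = df[df.category == category]["percent"].sum()
    assert abs(total - 100.0) <= 0.05


def test_summarize_empty_cohort_is_all_zero():
    demo = [_demo("11", "1", sex="F")]
    cohort = build_cohort(demo, [_mention("11", "ASPIRIN", "PS")], NAMES)
    # target empty; summarize over the empty target set
    df = summarize_characteristics(cohort, demo)
    assert (df["count"] == 0).all() and (df["percent"] == 0.0).all()


def test_known_sex_mix_recovered_exactly():
    """Counting is exact: the summary equals the generator's sampled draws."""
    cfg = SimulationConfig(n_reports=10_000, seed=5, duplicate_rate=0.0)
    cfg.sex_mix = {"F": 0.6, "M": 0.4}
    corpus = simulate_corpus(cfg)
    recs = corpus.to_records()
    demo = faers_io.deduplicate(recs["DEMO"])
    cohort = build_cohort(demo, recs["DRUG"], NAMES)
    df = summarize_characteristics(cohort, demo)
    drawn_f = sum(
        1 for r in demo if r.caseid in cohort.target and r.sex == "F"
    )
    assert _summary_count(df, "sex", "Female") == drawn_f
    assert _summary_count(df, "sex", "Unknown") == 0
    # the 60/40 mix is recovered within binomial noise
    frac = drawn_f / cohort.n_target
    assert abs(frac - 0.6) < 0.05


def test_indications_linked_to_matched_ps_drug_only(fixture_cohort,
                                                    fixture_records,
                                                    fixture_demo):
    df = summarize_characteristics(fixture_cohort, fixture_demo,
                                   fixture_records["OUTC"],
                                   fixture_records["INDI"])
    indi = df[df.category == "indication"]
    # background-drug indications must not leak into the target summary
    assert "Product used for unknown indication" not in set(indi.level) or (
        _summary_count(df, "indication", "Product used for unknown indication")
        <= fixture_cohort.n_target
    )
    assert _summary_count(df, "indication", "Ovarian cancer") > 0


def test_exclude_consumers_noop_and_total():
    demo_no_cn = [_demo("11", "1", occp="MD"), _demo("21", "2", occp="PH")]
    cohort = build_cohort(demo_no_cn, [_mention("11", "ZEJULA", "PS")], NAMES)
    assert exclude_consumers(cohort, demo_no_cn) == cohort

    demo_all_cn = [_demo("11", "1", occp="CN")]
    cohort = build_cohort(demo_all_cn, [_mention("11", "ZEJULA", "PS")], NAMES)
    reduced = exclude_consumers(cohort, demo_all_cn)
    assert reduced.n_target == 0 and reduced.n_background == 0


def test_exclude_consumers_idempotent(fixture_cohort, fixture_demo):
    once = exclude_consumers(fixture_cohort, fixture_demo)
    assert exclude_consumers(once, fixture_demo) == once


def test_exclude_consumers_default_mix_leaves_about_23_percent():
    cfg = SimulationConfig(n_reports=8_000, seed=3, duplicate_rate=0.0)
    corpus = simulate_corpus(cfg)
    recs = corpus.to_records()
    demo = faers_io.deduplicate(recs["DEMO"])
    cohort = build_cohort(demo, recs["DRUG"], NAMES)
    reduced = exclude_consumers(cohort, demo)
    frac = reduced.n_target / cohort.n_target
    # default reporter mix is 77.43% consumers
    assert abs(frac - 0.2257) < 0.05
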