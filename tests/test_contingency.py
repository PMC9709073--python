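"""Report-level 2x2 tables and the comparator-reconstruction oracle."""

import random

import pytest

from pvsignal.cohort import Cohort
from pvsignal.contingency import (
    ContingencyTable,
    InfeasibleReconstructionError,
    SocMap,
    UNMAPPED_SOC,
    build_tables,
    reconstruct_comparator,
    reconstruct_table,
)
from pvsignal.faers_io import EventMention
from pvsignal.signal_stats import compute_prr, compute_ror

SOC_MAP = SocMap({"Nausea": "Gastrointestinal disorders",
                  "Vomiting": "Gastrointestinal disorders",
                  "Anaemia": "Blood and lymphatic system disorders"})


def _cohort(target, background):
    return Cohort(target=frozenset(target), background=frozenset(background),
                  name_list=("niraparib",))


def _events(*pairs):
    return [EventMention(primaryid=p, pt=t) for p, t in pairs]


CASE_OF = {"11": "1", "21": "2", "31": "3"}


def test_same_pt_twice_counts_once():
    cohort = _cohort({"1"}, {"2"})
    events = _events(("11", "Nausea"), ("11", "Nausea"), ("21", "Nausea"))
    tables = build_tables(cohort, events, "pt", case_of=CASE_OF).by_term()
    t = tables["Nausea"]
    assert (t.a, t.b, t.c, t.d) == (1, 0, 1, 0)


def test_soc_counts_once_per_report():
    cohort = _cohort({"1"}, {"2"})
    events = _events(("11", "Nausea"), ("11", "Vomiting"), ("21", "Anaemia"))
    tables = build_tables(cohort, events, "soc", SOC_MAP, case_of=CASE_OF).by_term()
    assert tables["Gastrointestinal disorders"].a == 1
    assert tables["Blood and lymphatic system disorders"].c == 1


def test_unmapped_pt_routed_not_dropped():
    cohort = _cohort({"1"}, set())
    result = build_tables(cohort, _events(("11", "Mystery term")), "soc",
                          SOC_MAP, case_of=CASE_OF)
    assert result.unmapped_pts == {"Mystery term"}
    assert result.by_term()[UNMAPPED_SOC].a == 1


def test_margins_constant_across_terms(fixture_cohort, fixture_records,
                                       fixture_case_of):
    tables = build_tables(fixture_cohort, fixture_records["REAC"], "pt",
                          case_of=fixture_case_of)
    n_t = fixture_cohort.n_target
    n_all = n_t + fixture_cohort.n_background
    for t in tables:
        assert t.a + t.b == n_t
        assert t.n == n_all


def test_cells_match_generator_bookkeeping(fixture_corpus, fixture_cohort,
                                           fixture_records, fixture_case_of):
    tables = build_tables(fixture_cohort, fixture_records["REAC"], "pt",
                          case_of=fixture_case_of).by_term()
    gt = fixture_corpus.ground_truth.pt_report_counts.set_index("pt")
    for pt, row in gt.iterrows():
        if row.target_reports == 0 and row.background_reports == 0:
            continue
        t = tables[pt]
        assert t.a == row.target_reports
        assert t.c == row.background_reports


def test_conservation_of_report_term_pairs(fixture_cohort, fixture_records,
                                           fixture_case_of):
    tables = build_tables(fixture_cohort, fixture_records["REAC"], "pt",
                          case_of=fixture_case_of)
    pairs = {
        (fixture_case_of[e.primaryid], e.pt)
        for e in fixture_records["REAC"]
        if e.primaryid in fixture_case_of
    }
    target_pairs = sum(1 for cid, _ in pairs if cid in fixture_cohort.target)
    background_pairs = len(pairs) - target_pairs
    assert sum(t.a for t in tables) == target_pairs
    assert sum(t.c for t in tables) == background_pairs


def test_build_tables_invariant_to_row_order(fixture_cohort, fixture_records,
                                             fixture_case_of):
    events = list(fixture_records["REAC"])
    shuffled = events[:]
    random.Random(4).shuffle(shuffled)
    t1 = build_tables(fixture_cohort, events, "pt", case_of=fixture_case_of)
    t2 = build_tables(fixture_cohort, shuffled, "pt", case_of=fixture_case_of)
    assert t1.tables == t2.tables


# ---------------------------------------------------------------------------
# Reconstruction oracle
# ---------------------------------------------------------------------------

N_COHORT = 11701


def test_reconstruct_anaemia_row():
    """Published anaemia row: cells land near 2.9e4 / 3.5e6 and the forward
    PRR reproduces the published 8.02."""
    c, d = reconstruct_comparator(772, N_COHORT, 8.52, 7.91, 9.17)
    assert c == pytest.approx(2.88e4, rel=0.01)
    assert d == pytest.approx(3.47e6, rel=0.01)
    t = reconstruct_table("Anaemia", 772, N_COHORT, 8.52, 7.91, 9.17)
    assert round(compute_prr(t).prr, 2) == 8.02


def test_reconstruct_round_trip_identity():
    t0 = ContingencyTable("x", "pt", 50, 950, 500, 99500)
    r = compute_ror(t0)
    c, d = reconstruct_comparator(50, 1000, r.ror, r.ci_low, r.ci_high)
    assert c == pytest.approx(500, rel=1e-9)
    assert d == pytest.approx(99500, rel=1e-9)


def test_reconstruct_infeasible_nausea_row():
    # the printed CI width falls below the 1/a + 1/b floor
    with pytest.raises(InfeasibleReconstructionError):
        reconstruct_comparator(3459, N_COHORT, 11.59, 11.14, 12.06)


def test_reconstruct_rejects_invalid_inputs():
    with pytest.raises(ValueError):
        reconstruct_comparator(0, 100, 2.0, 1.5, 2.5)
    with pytest.raises(ValueError):
        reconstruct_comparator(10, 100, 2.0, 2.5, 1.5)


@pytest.mark.parametrize(
    "a, ror, lo, hi",
    [
        (772, 8.52, 7.91, 9.17),
        (606, 11.02, 10.15, 11.97),
        (2499, 27.71, 26.50, 28.99),
        (2330, 54.14, 51.67, 56.72),
        (116, 21.91, 18.19, 26.39),
    ],
)
def test_forward_ror_matches_input(a, ror, lo, hi):
    t = reconstruct_table("t", a, N_COHORT, ror, lo, hi)
    fwd = compute_ror(t)
    assert abs(fwd.ror - ror) / ror <= 0.005
    assert fwd.ci_low == pytest.approx(lo, rel=0.005)
    assert fwd.ci_high == pytest.approx(hi, rel=0.005)


def test_integer_variant_rounds_cells():
    t = reconstruct_table("Anaemia", 772, N_COHORT, 8.52, 7.91, 9.17,
                          integer=True)
    assert t.c == int(t.c) and t.d == int(t.d)


def test_soc_map_duplicate_pt_rejected():
    with pytest.raises(ValueError):
        SocMap({"Nausea": "A", "nausea ": "B"})
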