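"""The four disproportionality estimators and the signal criteria."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from pvsignal.contingency import ContingencyTable
from pvsignal.signal_stats import (
    GammaPoissonModel,
    SignalEstimates,
    Thresholds,
    apply_criteria,
    compute_ebgm,
    compute_estimates,
    compute_ic,
    compute_prr,
    compute_ror,
)


def _t(a, b, c, d):
    return ContingencyTable("t", "pt", a, b, c, d)


cells = st.integers(min_value=1, max_value=5000)


def test_symmetric_table_gives_unit_ror_with_log_symmetric_ci():
    r = compute_ror(_t(10, 10, 10, 10))
    assert r.ror == pytest.approx(1.0)
    assert r.ci_low * r.ci_high == pytest.approx(1.0)


def test_ror_hand_value():
    assert compute_ror(_t(20, 80, 100, 800)).ror == pytest.approx(2.0)


def test_prr_hand_values():
    p = compute_prr(_t(20, 80, 100, 800))
    assert p.prr == pytest.approx(1.8)
    # proportional table: prr 1, chi2 0
    p0 = compute_prr(_t(10, 90, 100, 900))
    assert p0.prr == pytest.approx(1.0)
    assert p0.chi2 == pytest.approx(0.0)


def test_ic_hand_values():
    # N=10000, a=10, margins 100/100: observed/expected = 10
    i = compute_ic(_t(10, 90, 90, 9810))
    assert i.ic == pytest.approx(math.log2(10))
    assert i.ic025 < i.ic
    # independence: a*N == (a+b)(a+c)
    assert compute_ic(_t(10, 90, 90, 810)).ic == pytest.approx(0.0)


def test_simplified_ebgm_null_value_and_hand_value():
    assert compute_ebgm(_t(10, 90, 90, 810)).ebgm == pytest.approx(1.0)
    e = compute_ebgm(_t(10, 90, 90, 9810))
    assert e.ebgm == pytest.approx(10.0)
    assert e.ebgm05 < e.ebgm


@given(cells, cells, cells, cells)
@settings(max_examples=200, deadline=None)
def test_simplified_ebgm_is_two_to_the_ic(a, b, c, d):
    t = _t(a, b, c, d)
    e = compute_ebgm(t)
    i = compute_ic(t)
    assert e.ebgm == pytest.approx(2.0 ** i.ic, rel=1e-12)


@given(cells, cells, cells, cells)
@settings(max_examples=200, deadline=None)
def test_interval_bounds_bracket_the_estimates(a, b, c, d):
    t = _t(a, b, c, d)
    e = compute_estimates(t)
    assert e.ror_low <= e.ror <= e.ror_high
    assert e.ic025 <= e.ic
    assert e.ebgm05 <= e.ebgm
    assert all(map(math.isfinite, (e.ror, e.prr, e.chi2, e.ic, e.ebgm)))


def test_monotone_in_a_with_margins_fixed():
    # increase a by moving one report from b and c into a (margins a+b, a+c,
    # N all fixed)
    prev = None
    for a in (5, 10, 20, 40):
        t = _t(a, 100 - a, 200 - a, 9700 + a)
        e = compute_estimates(t)
        if prev is not None:
            assert e.ror > prev.ror
            assert e.prr > prev.prr
            assert e.ic > prev.ic
            assert e.ebgm > prev.ebgm
        prev = e


def test_prr_approaches_ror_in_rare_event_limit():
    gaps = []
    for scale in (10, 100, 1000, 10000):
        # event rate shrinks as 1/scale in both arms; odds ratio fixed at 2
        t = _t(20, 20 * scale, 100, 10 * scale * 20)
        e = compute_estimates(t)
        gaps.append(abs(e.prr - e.ror))
    assert all(x > y for x, y in zip(gaps, gaps[1:]))
    assert gaps[-1] < 0.01


def test_zero_cell_nan_without_haldane_finite_with():
    t = _t(0, 100, 50, 9850)
    assert math.isnan(compute_ror(t).ror)
    assert math.isnan(compute_ebgm(t).ebgm)
    r = compute_ror(t, haldane=True)
    assert math.isfinite(r.ror) and r.ror > 0


def test_ic_gamma_variant_close_to_delta_for_large_counts():
    t = _t(772, 10929, 28854, 3480279)
    delta = compute_ic(t, variant="delta")
    gamma = compute_ic(t, variant="gamma")
    assert gamma.ic == pytest.approx(delta.ic, abs=0.01)
    assert gamma.ic025 == pytest.approx(delta.ic025, abs=0.02)


def _estimates(**kw):
    base = dict(ror=1.0, ror_low=0.5, ror_high=2.0, prr=1.0, chi2=0.0,
                ic=0.0, ic025=-1.0, ebgm=1.0, ebgm05=0.5)
    base.update(kw)
    return SignalEstimates(**base)


def test_criteria_published_soc_row_flags_exactly_ror_and_ic():
    # Eye-disorders-style SOC row: ROR and IC criteria met, PRR and EBGM not
    e = _estimates(ror=1.11, ror_low=1.02, ror_high=1.21, prr=1.10,
                   chi2=5.53, ic=0.14, ic025=0.01, ebgm=1.10, ebgm05=1.01)
    f = apply_criteria(e, a=551, th=Thresholds())
    assert (f.ror_sig, f.prr_sig, f.ic_sig, f.ebgm_sig) == (True, False, True, False)
    assert not f.all_four


def test_criteria_boundary_ci_low_exactly_one_not_significant():
    e = _estimates(ror_low=1.0)
    assert not apply_criteria(e, a=100, th=Thresholds()).ror_sig


def test_criteria_min_a_gates_ror_and_prr():
    e = _estimates(ror=10, ror_low=5, ror_high=20, prr=10, chi2=100,
                   ic025=1.0, ebgm05=5.0)
    f = apply_criteria(e, a=2, th=Thresholds())
    assert not f.ror_sig and not f.prr_sig
    assert f.ic_sig and f.ebgm_sig


def test_criteria_dominant_estimates_flag_all_four_and_label_match():
    e = _estimates(ror=10, ror_low=5, ror_high=20, prr=10, chi2=100,
                   ic=3, ic025=1.0, ebgm=10, ebgm05=5.0)
    f = apply_criteria(e, a=50, th=Thresholds(), label_terms=["Nausea"],
                       term="NAUSEA")
    assert f.all_four and f.expected
    g = apply_criteria(e, a=50, th=Thresholds(), label_terms=["Nausea"],
                       term="Photosensitivity reaction")
    assert g.all_four and not g.expected


def test_nan_estimates_never_flag():
    e = _estimates(ror=math.nan, ror_low=math.nan, prr=math.nan,
                   chi2=math.nan, ic025=math.nan, ebgm05=math.nan)
    f = apply_criteria(e, a=100, th=Thresholds())
    assert not f.any_sig


def test_thresholds_reject_unknown_keys():
    with pytest.raises(ValueError):
        Thresholds.from_dict({"min_a": 3, "bogus": 1})


def test_shrinkage_refuses_small_collections():
    tables = [_t(5, 95, 50, 950) for _ in range(10)]
    with pytest.raises(ValueError, match="50 tables"):
        GammaPoissonModel.fit(tables)


def test_shrinkage_pulls_small_counts_toward_prior():
    # 99 null tables plus one high-ratio table with a tiny count: the
    # posterior mean ratio must sit well below the raw ratio
    tables = [_t(10, 990, 100, 9900) for _ in range(99)] + [_t(3, 997, 3, 9997)]
    model = GammaPoissonModel.fit(tables)
    raw = tables[-1].a / tables[-1].expected
    shrunk = compute_ebgm(tables[-1], mode="shrinkage", model=model).ebgm
    assert shrunk < raw
    assert compute_ebgm(tables[-1], mode="shrinkage", model=model).ebgm05 < shrunk
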