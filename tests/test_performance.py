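"""Fourfold tables, exact CIs, likelihood ratio, Fisher's exact test."""

import math

import numpy as np
import pytest
import scipy.stats

from conftest import fisher_two_sided_oracle, make_record

from kidsms.performance import (
    FourfoldTable,
    build_fourfold,
    clopper_pearson_ci,
    fisher_exact,
    format_report,
    performance,
    report_keyvalues,
    unpaired_t_test,
)

FOLLOWUP_TABLE = FourfoldTable(tp=24, fp=19, fn=0, tn=63)


# --- fourfold construction ----------------------------------------------


def test_build_fourfold_cross_tabulates():
    cohort = (
        [make_record(patient_id=f"A{i}", ectopia_lentis=True, family_history_mfs=True) for i in range(3)]
        + [make_record(patient_id=f"B{i}", ectopia_lentis=True) for i in range(2)]
        + [make_record(patient_id=f"C{i}") for i in range(4)]
    )
    table = build_fourfold(
        cohort, lambda r: r.ectopia_lentis, lambda r: r.family_history_mfs
    )
    assert table.as_counts() == (3, 2, 0, 4)


def test_identical_predicates_give_no_discordance():
    cohort = [make_record(patient_id=str(i), ectopia_lentis=i % 2 == 0) for i in range(10)]
    table = build_fourfold(cohort, lambda r: r.ectopia_lentis, lambda r: r.ectopia_lentis)
    assert table.fp == table.fn == 0


def test_empty_cohort_is_error():
    with pytest.raises(ValueError):
        build_fourfold([], lambda r: True, lambda r: True)


def test_table_rejects_negative_counts():
    with pytest.raises(ValueError):
        FourfoldTable(tp=-1, fp=0, fn=0, tn=1)
    with pytest.raises(ValueError):
        FourfoldTable(tp=0, fp=0, fn=0, tn=0)


# --- Clopper-Pearson ----------------------------------------------------


def test_perfect_sensitivity_lower_bound_24_of_24():
    """For k = n the lower bound has the closed form (alpha/2)^(1/n)."""
    ci = clopper_pearson_ci(24, 24)
    assert ci.ci_low == pytest.approx(0.025 ** (1 / 24), abs=1e-12)
    assert round(ci.ci_low, 2) == 0.86
    assert ci.ci_high == 1.0


def test_perfect_npv_lower_bound_63_of_63():
    ci = clopper_pearson_ci(63, 63)
    assert ci.ci_low == pytest.approx(0.025 ** (1 / 63), abs=1e-12)
    assert round(ci.ci_low, 2) == 0.94
    assert ci.ci_high == 1.0


def test_zero_numerator_lower_bound_is_exactly_zero():
    ci = clopper_pearson_ci(0, 10)
    assert ci.ci_low == 0.0
    assert 0 < ci.ci_high < 1


def test_ci_bounds_bracket_estimate_and_shrink_with_n():
    narrow = clopper_pearson_ci(50, 100)
    wide = clopper_pearson_ci(5, 10)
    for ci in (narrow, wide):
        assert 0 <= ci.ci_low <= ci.estimate <= ci.ci_high <= 1
    assert narrow.ci_high - narrow.ci_low < wide.ci_high - wide.ci_low


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        clopper_pearson_ci(1, 0)
    with pytest.raises(ValueError):
        clopper_pearson_ci(5, 4)
    with pytest.raises(ValueError):
        clopper_pearson_ci(1, 2, level=1.5)


def test_clopper_pearson_achieves_nominal_coverage():
    """Empirical coverage at n = 50 is at least nominal (the exact
    interval is conservative) for small, middling and large p."""
    rng = np.random.default_rng(20150312)
    n, reps, level = 50, 10_000, 0.95
    mc_error = 3 * math.sqrt(level * (1 - level) / reps)
    for p in (0.05, 0.5, 0.95):
        ks = rng.binomial(n, p, size=reps)
        # vectorized CP bounds, same beta quantiles as the implementation
        low = np.where(ks == 0, 0.0, scipy.stats.beta.ppf(0.025, ks, n - ks + 1))
        high = np.where(ks == n, 1.0, scipy.stats.beta.ppf(0.975, ks + 1, n - ks))
        coverage = np.mean((low <= p) & (p <= high))
        assert coverage >= level - mc_error
        # spot-check the vectorized bounds against the scalar implementation
        ci = clopper_pearson_ci(int(ks[0]), n)
        assert ci.ci_low == pytest.approx(float(low[0]), abs=1e-12)
        assert ci.ci_high == pytest.approx(float(high[0]), abs=1e-12)


# --- performance summary ------------------------------------------------


def test_followup_table_reproduces_headline_statistics():
    perf = performance(FOLLOWUP_TABLE)
    assert perf.sensitivity.estimate == 1.0
    assert perf.specificity.estimate == pytest.approx(63 / 82)
    assert perf.ppv.estimate == pytest.approx(24 / 43)
    assert perf.npv.estimate == 1.0
    assert perf.positive_lr == pytest.approx(82 / 19)
    assert perf.undefined == ()
    report = format_report(FOLLOWUP_TABLE, perf)
    assert "Sensitivity: 100%" in report
    assert "Specificity: 77%" in report
    assert "PPV:         56%" in report
    assert "NPV:         100%" in report
    assert "likelihood ratio: 4.3" in report


def test_perfect_test_has_infinite_likelihood_ratio():
    perf = performance(FourfoldTable(tp=1, fp=0, fn=0, tn=1))
    assert perf.sensitivity.estimate == perf.specificity.estimate == 1.0
    assert perf.positive_lr == math.inf
    kv = report_keyvalues(FourfoldTable(tp=1, fp=0, fn=0, tn=1), perf)
    assert kv["positive_lr"] == "inf"


def test_empty_positive_margin_flags_ppv_undefined():
    perf = performance(FourfoldTable(tp=0, fp=0, fn=1, tn=1))
    assert perf.ppv is None
    assert "ppv" in perf.undefined
    assert perf.npv is not None  # the other margins still computable


# --- Fisher's exact test ------------------------------------------------


def test_followup_table_is_significant():
    assert fisher_exact(FOLLOWUP_TABLE) < 0.05


def test_degenerate_margin_gives_p_one():
    assert fisher_exact(FourfoldTable(tp=0, fp=0, fn=3, tn=5)) == pytest.approx(1.0)
    assert fisher_exact(FourfoldTable(tp=2, fp=0, fn=7, tn=0)) == pytest.approx(1.0)


def test_fisher_matches_exhaustive_oracle_on_small_tables():
    """Probability-ordering agreement with exact integer enumeration for
    a dense sample of tables with total <= 12 (the full sweep up to 30
    runs in the acceptance suite)."""
    total_checked = 0
    for tp in range(0, 13):
        for fp in range(0, 13 - tp):
            for fn in range(0, 13 - tp - fp):
                for tn in range(0, 13 - tp - fp - fn):
                    if tp + fp + fn + tn == 0:
                        continue
                    table = FourfoldTable(tp=tp, fp=fp, fn=fn, tn=tn)
                    assert fisher_exact(table) == pytest.approx(
                        fisher_two_sided_oracle(tp, fp, fn, tn), rel=1e-7, abs=1e-12
                    )
                    total_checked += 1
    assert total_checked > 1000


def test_unpaired_t_test_matches_scipy_convention():
    a, b = [1.0, 2.0, 3.0, 4.0], [2.5, 3.5, 4.5, 5.5]
    assert unpaired_t_test(a, b) == pytest.approx(
        float(scipy.stats.ttest_ind(a, b).pvalue)
    )
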