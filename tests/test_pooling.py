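"""Rubin's rules, D2 combination, mediation decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sleepsem.pooling import (
    d2_pool_chisq,
    mediation_decompose,
    pooled_mediation_report,
    rubin_pool,
)


def test_rubin_zero_between_variance():
    p = rubin_pool([0.5, 0.5, 0.5], [0.04, 0.04, 0.04])
    assert p.qbar == 0.5
    assert p.between_var == 0.0
    assert p.total_var == pytest.approx(0.04)
    assert p.df_rubin == np.inf
    # reproduces the single-imputation interval exactly
    assert p.ci95[0] == pytest.approx(0.5 - 1.959964 * 0.2)


def test_rubin_hand_example():
    # estimates (0.4, 0.5, 0.6), Ubar = 0.01, m = 3 -> B = 0.01,
    # T = 0.01 + (4/3) * 0.01 = 0.02333
    p = rubin_pool([0.4, 0.5, 0.6], [0.01, 0.01, 0.01])
    assert p.qbar == pytest.approx(0.5)
    assert p.between_var == pytest.approx(0.01)
    assert p.total_var == pytest.approx(0.0233333, abs=1e-6)
    # identity T = Ubar + (1 + 1/m) B holds exactly
    assert p.total_var == p.within_var + (1 + 1 / 3) * p.between_var
    assert p.ci95[0] < p.qbar < p.ci95[1]
    # Barnard-Rubin style df
    expected_df = 2 * (1 + 0.01 / ((4 / 3) * 0.01)) ** 2
    assert p.df_rubin == pytest.approx(expected_df)


@given(
    vals=st.lists(st.floats(-5, 5), min_size=3, max_size=8),
    u=st.floats(0.001, 1.0),
)
@settings(derandomize=True, max_examples=60)
def test_rubin_permutation_invariant(vals, u):
    us = [u] * len(vals)
    a = rubin_pool(vals, us)
    b = rubin_pool(list(reversed(vals)), us)
    assert a.total_var == pytest.approx(b.total_var, rel=1e-12)
    assert a.qbar == pytest.approx(b.qbar, rel=1e-12)


def test_rubin_m1_warns():
    p = rubin_pool([0.3], [0.01])
    assert p.qbar == 0.3
    assert np.isnan(p.between_var)
    assert p.warning is not None


def test_rubin_rejects_bad_input():
    with pytest.raises(ValueError):
        rubin_pool([0.1, 0.2], [0.01, -0.01])


def test_d2_identical_chisqs_limit():
    # identical chi2 = 100 on 50 df: r = 0, F = 2.0, chi-square reference
    F, df1, df2, p = d2_pool_chisq([100.0, 100.0, 100.0], 50)
    assert F == 2.0
    assert df1 == 50 and df2 == np.inf
    assert p == pytest.approx(stats.chi2.sf(100, 50))


def test_d2_hand_formula():
    chi2s = np.array([90.0, 100.0, 110.0])
    k, m = 50, 3
    F, df1, df2, p = d2_pool_chisq(chi2s, k)
    dbar = chi2s.mean()
    r = (1 + 1 / m) * np.sqrt(chi2s).var(ddof=1)
    F_exp = (dbar / k - (m + 1) / (m - 1) * r) / (1 + r)
    df2_exp = k ** (-3 / m) * (m - 1) * (1 + 1 / r) ** 2
    assert F == pytest.approx(F_exp)
    assert df2 == pytest.approx(df2_exp)
    assert p == pytest.approx(stats.f.sf(F_exp, k, df2_exp))


def test_d2_decreases_in_replication_variance():
    k = 20
    dbar = 60.0
    prev = np.inf
    for spread in (0.5, 2.0, 5.0, 10.0):
        chi2s = [dbar - spread, dbar, dbar + spread]
        F, *_ = d2_pool_chisq(chi2s, k)
        assert F < prev
        prev = F


def test_d2_domain_errors():
    with pytest.raises(ValueError):
        d2_pool_chisq([-1.0, 2.0], 5)
    with pytest.raises(ValueError):
        d2_pool_chisq([1.0, 2.0], 0)


def test_mediation_printed_worked_examples():
    # girls' SQI path pair from the fitted model
    row = mediation_decompose(0.141, 0.142, 0.015)
    assert round(row["indirect"], 3) == 0.020
    assert round(row["pm"]) == 57
    # WASD: two negative paths give a positive indirect effect
    row = mediation_decompose(-0.234, -0.042, 0.015)
    assert round(row["indirect"], 3) == 0.010
    # chronotype
    row = mediation_decompose(0.304, 0.037, 0.015)
    assert round(row["indirect"], 3) == 0.011


def test_mediation_edge_cases():
    row = mediation_decompose(0.0, 0.5, 0.1)
    assert row["indirect"] == 0.0 and row["pm"] == 0.0
    row = mediation_decompose(0.3, 0.4, -0.5)  # indirect and total oppose
    assert row["flag"] == "inconsistent_mediation" and np.isnan(row["pm"])
    row = mediation_decompose(0.5, 0.2, -0.05)  # suppression: PM above 100
    assert row["pm"] == pytest.approx(200.0)
    row = mediation_decompose(0.0, 0.0, 0.0)
    assert row["flag"] == "total_effect_zero"
    with pytest.raises(ValueError):
        mediation_decompose(np.nan, 0.1, 0.1)


def test_pm_scale_invariant_to_outcome_rescaling():
    # rescaling the outcome rescales b and c' jointly; PM is unchanged
    base = mediation_decompose(0.141, 0.142, 0.015)
    scaled = mediation_decompose(0.141, 0.142 * 3.7, 0.015 * 3.7)
    assert base["pm"] == pytest.approx(scaled["pm"])


def test_pm_ci_methods():
    row = mediation_decompose(
        0.2, 0.3, 0.1, indirect_ci=(0.04, 0.08), total_ci=(0.12, 0.2)
    )
    lo, hi = row["pm_ci"]
    assert lo == pytest.approx(100 * 0.04 / 0.12)
    assert hi == pytest.approx(100 * 0.08 / 0.2)
    assert row["flag"] == "pm_ci_approximate"
    row_d = mediation_decompose(
        0.2, 0.3, 0.1, pm_ci_method="delta", indirect_var=0.001, total_var=0.002
    )
    assert row_d["pm_ci"][0] < row_d["pm"] < row_d["pm_ci"][1]


def test_pooled_mediation_report_small_pipeline(small_panel):
    """Shape contract and recovery direction on a small complete panel."""
    from sleepsem import models, sem
    from sleepsem.sleepmetrics import derive_sleep_facets

    d = derive_sleep_facets(small_panel)
    spec = models.primary_mediation_spec()
    fits = [sem.fit(spec, data=d, se=True)] * 3  # same data, contract check
    table = pooled_mediation_report(fits, mediators=models.PRIMARY_MEDIATORS)
    assert len(table) == 2 * 3  # groups x mediators
    assert list(table.mediator.unique()) == ["sqi", "wasd", "msf"]  # order
    assert (table.n_fits_pooled == 3).all()
    # indirect = a*b and total = indirect + c' to machine precision on the
    # pooled coefficients is not an identity (pooling of products), but the
    # per-row decomposition from pooled a, b, c' must be sign-consistent
    girls_sqi = table[(table.group == "girl") & (table.mediator == "sqi")].iloc[0]
    assert girls_sqi.a > 0 and girls_sqi.b > 0


def test_pooled_mediation_report_rejects_nonconverged(small_panel):
    from sleepsem import models, sem
    from sleepsem.sleepmetrics import derive_sleep_facets

    d = derive_sleep_facets(small_panel)
    spec = models.primary_mediation_spec()
    good = sem.fit(spec, data=d, se=True)
    bad = sem.FitResult(
        spec=good.spec, estimates=good.estimates, theta=good.theta,
        chi2=good.chi2, df=good.df, baseline_chi2=good.baseline_chi2,
        baseline_df=good.baseline_df, n_per_group=good.n_per_group,
        fmin=good.fmin, converged=False, n_iter=0, grad_norm=1.0,
    )
    with pytest.raises(RuntimeError, match="non-converged"):
        pooled_mediation_report([good, bad], mediators=("sqi",))
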