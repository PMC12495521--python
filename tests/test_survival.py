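import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank

from conftest import simulate_ph_cohort
from hexki67.io import PipelineConfig
from hexki67.survival import (
    cox_fit,
    find_cutoff,
    fit_model_suite,
    harrell_c,
    km_estimate,
    logrank_test,
    two_group_logrank_chi2,
)


def test_km_all_censored_is_flat():
    kmf = km_estimate([5.0, 8.0, 12.0], [False, False, False])
    assert kmf.predict(12.0) == pytest.approx(1.0)


def test_km_two_events_closed_form():
    kmf = km_estimate([1.0, 2.0], [True, True])
    assert kmf.predict(0.5) == pytest.approx(1.0)
    assert kmf.predict(1.5) == pytest.approx(0.5)
    assert kmf.predict(2.5) == pytest.approx(0.0)


def test_km_matches_hand_product_limit():
    # 6 subjects: events at 2, 4, 4; censored at 3, 5; event at 6
    t = np.array([2.0, 3.0, 4.0, 4.0, 5.0, 6.0])
    e = np.array([True, False, True, True, False, True])
    kmf = km_estimate(t, e)
    # hand product-limit: S(2)=5/6; S(4)=5/6 * 2/4; S(6)=... * 0/1
    assert kmf.predict(2.0) == pytest.approx(5 / 6)
    assert kmf.predict(4.5) == pytest.approx(5 / 6 * 2 / 4)
    assert kmf.predict(6.0) == pytest.approx(0.0)


def test_km_equals_one_minus_ecdf_without_censoring(rng):
    t = rng.exponential(10, 50).round(1) + 0.1
    kmf = km_estimate(t, np.ones(50, bool))
    for probe in np.percentile(t, [10, 50, 90]):
        assert kmf.predict(probe) == pytest.approx((t > probe).mean())


def test_logrank_identical_groups_null():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    e = np.array([True, True, False, True])
    chi2, p = logrank_test([(t, e), (t, e)])
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_detects_complete_separation(rng):
    ta = rng.uniform(1, 10, 20)
    tb = rng.uniform(20, 30, 20)
    ones = np.ones(20, bool)
    chi2, p = logrank_test([(ta, ones), (tb, ones)])
    assert p < 0.01


def test_fast_logrank_matches_lifelines(rng):
    for _ in range(10):
        n = 80
        t = rng.exponential(50, n).round(0) + 1
        e = rng.random(n) < 0.6
        g = rng.random(n) < 0.4
        if e.sum() == 0 or g.all() or not g.any():
            continue
        mine = two_group_logrank_chi2(t, e, g)
        ref = ll_logrank(t[g], t[~g], e[g], e[~g]).test_statistic
        assert mine == pytest.approx(ref, abs=1e-9)


def test_fast_logrank_matches_small_table_hand_computation():
    # textbook O-E/V on 10 subjects, no ties across groups at event times
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
    e = np.array([1, 1, 0, 1, 1, 0, 1, 0, 1, 0], dtype=bool)
    g = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0], dtype=bool)
    o_minus_e, v = 0.0, 0.0
    for tt in t[e]:
        at_risk = t >= tt
        n1, n_tot = g[at_risk].sum(), at_risk.sum()
        d = 1
        o_minus_e += (g & (t == tt) & e).sum() - d * n1 / n_tot
        if n_tot > 1:
            v += d * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d) / (n_tot - 1)
    assert two_group_logrank_chi2(t, e, g) == pytest.approx(o_minus_e**2 / v)


def test_find_cutoff_equals_brute_force_scan(rng):
    x, t, e = simulate_ph_cohort(rng, n=60, hr=3.0)
    v = rng.normal(5, 2, 60) + 2 * x
    res = find_cutoff(v, t, e, min_group_frac=0.1)
    best = None
    for thr in np.unique(v):
        hi = v > thr
        if hi.sum() < 6 or (~hi).sum() < 6:
            continue
        r = ll_logrank(t[hi], t[~hi], e[hi], e[~hi])
        if best is None or r.test_statistic > best[1] + 1e-12:
            best = (thr, r.test_statistic, r.p_value)
    assert res.cutoff == pytest.approx(best[0])
    assert res.p == pytest.approx(best[2], rel=1e-9)
    assert res.n_low + res.n_high == 60


def test_find_cutoff_rejects_constant_values(rng):
    _, t, e = simulate_ph_cohort(rng, n=30)
    with pytest.raises(ValueError):
        find_cutoff(np.ones(30), t, e)


def test_cox_single_covariate_matches_efron_grid_oracle():
    t = np.array([3.0, 5.0, 5.0, 8.0, 10.0, 10.0, 12.0, 15.0])
    e = np.array([1, 1, 1, 0, 1, 1, 0, 1], dtype=bool)
    x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0, 0.0])

    def efron_ll(beta):
        ll = 0.0
        for tt in np.unique(t[e]):
            dead = (t == tt) & e
            risk = t >= tt
            d = dead.sum()
            s_dead = np.exp(beta * x[dead]).sum()
            s_risk = np.exp(beta * x[risk]).sum()
            ll += beta * x[dead].sum()
            for ell in range(d):
                ll -= np.log(s_risk - ell / d * s_dead)
        return ll

    coarse = np.arange(-3, 3, 1e-2)
    b0 = coarse[np.argmax([efron_ll(b) for b in coarse])]
    fine = np.arange(b0 - 2e-2, b0 + 2e-2, 1e-6)
    b_oracle = fine[np.argmax([efron_ll(b) for b in fine])]
    fit = cox_fit(pd.DataFrame({"x": x}), t, e)
    assert fit.coef[0] == pytest.approx(b_oracle, abs=1e-4)
    assert fit.hr[0] == pytest.approx(np.exp(fit.coef[0]))
    assert fit.ci_lower[0] < fit.hr[0] < fit.ci_upper[0]


def test_cox_score_test_at_zero_equals_logrank(rng):
    # classical identity, binary covariate, no tied event times
    n = 40
    t = rng.permutation(np.arange(1.0, n + 1))
    e = rng.random(n) < 0.7
    x = rng.random(n) < 0.5
    u, info = 0.0, 0.0
    for tt in t[e]:
        risk = t >= tt
        xbar = x[risk].mean()
        u += x[(t == tt) & e].sum() - xbar
        info += x[risk].var()
    assert u**2 / info == pytest.approx(two_group_logrank_chi2(t, e, x), rel=1e-9)


def test_cox_rejects_degenerate_designs(rng):
    _, t, e = simulate_ph_cohort(rng, n=30)
    with pytest.raises(ValueError):
        cox_fit(pd.DataFrame({"x": np.ones(30)}), t, e)


def test_cox_null_covariate_lr_p_roughly_uniform(rng):
    ps = []
    for _ in range(60):
        x, t, e = simulate_ph_cohort(rng, n=80, hr=1.0)
        ps.append(cox_fit(pd.DataFrame({"x": x}), t, e).lr_p)
    ps = np.asarray(ps)
    # under the null, p-values are uniform: mean ~0.5, ~5% below 0.05
    assert ps.mean() == pytest.approx(0.5, abs=0.12)
    assert (ps < 0.05).mean() <= 0.15


def test_harrell_c_extremes_and_null(rng):
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    ones = np.ones(5, bool)
    assert harrell_c(-t, t, ones) == 1.0  # risk decreasing in survival time
    assert harrell_c(t, t, ones) == 0.0
    cs = [
        harrell_c(rng.normal(size=200), rng.exponential(10, 200), rng.random(200) < 0.5)
        for _ in range(20)
    ]
    assert np.mean(cs) == pytest.approx(0.5, abs=0.05)


def test_harrell_c_degrades_with_noise(rng):
    x, t, e = simulate_ph_cohort(rng, n=300, hr=3.0)
    c_true = harrell_c(x, t, e)
    c_noisy = np.mean(
        [harrell_c(x + rng.normal(0, 2, 300), t, e) for _ in range(10)]
    )
    assert c_true > c_noisy


def test_model_suite_schema_and_marker_rows(rng):
    x, t, e = simulate_ph_cohort(rng, n=120, hr=2.5)
    data = pd.DataFrame(
        {
            "node_positive": x.astype(bool),
            "grade_g3": rng.random(120) < 0.2,
            "time_months": t,
            "event": e,
            "marker": rng.normal(10, 3, 120) + 3 * x,
        }
    )
    models, covars = fit_model_suite(
        data, [("base", None), ("marker", "marker")], PipelineConfig(), seed=4
    )
    assert set(models.columns) >= {"model", "lr_stat", "lr_p", "c_index_test", "cutoff"}
    assert len(models) == 2
    marker_covs = covars[covars["model"] == "marker"]["covariate"].tolist()
    assert "marker_high" in marker_covs and "node_positive" in marker_covs
    base_covs = covars[covars["model"] == "base"]["covariate"].tolist()
    assert base_covs == ["node_positive", "grade_g3"]
    assert np.isfinite(models["c_index_test"]).all()
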