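import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import codshift as cs
from codshift.causemix import adjusted_rr_poisson, stratify_records


def test_published_count_proportions():
    """Published era count tables reproduce their printed percentages."""
    immuno = cs.cause_proportions({"lung cancer": 33_950, "other": 40_172 - 33_950})
    assert round(100 * immuno.loc["lung cancer", "proportion"], 1) == 84.5
    pre = cs.cause_proportions({"lung cancer": 144_029, "other": 166_321 - 144_029})
    assert round(100 * pre.loc["lung cancer", "proportion"], 1) == 86.6
    nl_pre = cs.cause_proportions({"non-lung cancer": 11_986, "other": 166_321 - 11_986})
    assert round(100 * nl_pre.loc["non-lung cancer", "proportion"], 1) == 7.2


def test_proportions_from_records_sum_to_one(retained_100k):
    out = cs.cause_proportions(retained_100k)
    assert out["proportion"].sum() == pytest.approx(1.0, abs=1e-12)
    assert out["count"].sum() == len(retained_100k)
    single = cs.cause_proportions(cs.records_frame([cs.DeathRecord(2005, 1, "COPD")]))
    assert single.loc["COPD", "proportion"] == 1.0
    with pytest.raises(ValueError, match="empty"):
        cs.cause_proportions({})


def test_crude_rr_closed_form():
    assert cs.crude_rr(20, 1000, 10, 1000).rr == pytest.approx(2.0)
    null = cs.crude_rr(10, 1000, 10, 1000)
    assert null.rr == pytest.approx(1.0) and null.ci_low < 1.0 < null.ci_high
    res = cs.crude_rr(2100, 40_172, 7249, 166_321)
    assert res.rr == pytest.approx(1.1994, abs=5e-5)
    assert res.p_value < 0.001


def test_crude_rr_zero_count_handling():
    res = cs.crude_rr(0, 100, 5, 100)
    assert "continuity-corrected" in res.flags and res.rr > 0
    undef = cs.crude_rr(0, 100, 0, 100)
    assert "undefined" in undef.flags and math.isnan(undef.rr)


def test_excess_deaths_arithmetic():
    assert cs.excess_deaths_per_100k(10, 100, 10, 100) == 0.0
    assert cs.excess_deaths_per_100k(1, 100, 2, 100) == pytest.approx(-1000.0)
    assert cs.excess_deaths_per_100k(2100, 40_172, 7249, 166_321) == pytest.approx(869.1, abs=0.05)


def test_excess_and_rr_sign_consistency():
    rng = np.random.default_rng(2)
    for _ in range(50):
        c1, c0 = rng.integers(1, 50, 2)
        t1, t0 = rng.integers(100, 500, 2)
        rr = cs.crude_rr(int(c1), int(t1), int(c0), int(t0)).rr
        excess = cs.excess_deaths_per_100k(int(c1), int(t1), int(c0), int(t0))
        assert (rr > 1) == (excess > 0) or excess == 0


def _strata_frame(rows):
    return pd.DataFrame(rows, columns=["era", "z", "cause_count", "total"])


def test_adjusted_collapses_to_crude_without_axes():
    strata = pd.DataFrame({"era": [0, 1], "cause_count": [7249, 2100], "total": [166_321, 40_172]})
    adj = adjusted_rr_poisson(strata, adjust_axes=())
    crude = cs.crude_rr(2100, 40_172, 7249, 166_321)
    assert adj.rr == pytest.approx(crude.rr, rel=1e-8)


def test_adjusted_null_when_rates_equal():
    strata = _strata_frame([(0, "a", 50, 1000), (0, "b", 25, 500), (1, "a", 100, 2000), (1, "b", 10, 200)])
    adj = adjusted_rr_poisson(strata, adjust_axes=("z",))
    assert abs(math.log(adj.rr)) < 1e-8


def test_irls_agrees_with_direct_likelihood_maximization():
    """GLM estimates match an independent BFGS maximization of the Poisson
    log-likelihood on random stratified tables."""
    rng = np.random.default_rng(7)
    for _ in range(10):
        rows = []
        for era in (0, 1):
            for z in ("a", "b"):
                total = int(rng.integers(200, 2000))
                rate = 0.02 * (1.5 ** era) * (2.0 if z == "b" else 1.0)
                rows.append((era, z, int(rng.poisson(total * rate)), total))
        strata = _strata_frame(rows)
        adj = adjusted_rr_poisson(strata, adjust_axes=("z",))

        y = strata["cause_count"].to_numpy(float)
        X = np.column_stack(
            [np.ones(4), strata["era"].to_numpy(float), (strata["z"] == "b").to_numpy(float)]
        )
        off = np.log(strata["total"].to_numpy(float))

        def negll(beta):
            eta = X @ beta + off
            return np.sum(np.exp(eta) - y * eta)

        opt = optimize.minimize(negll, np.zeros(3), method="BFGS", options={"gtol": 1e-10})
        assert math.log(adj.rr) == pytest.approx(opt.x[1], abs=1e-6)


def test_separation_triggers_continuity_correction():
    strata = _strata_frame([(0, "a", 0, 500), (1, "a", 12, 400)])
    adj = adjusted_rr_poisson(strata, adjust_axes=())
    assert "continuity-corrected" in adj.flags and adj.rr > 1


def test_subgroup_detects_sex_specific_planted_effect():
    """A female-only planted effect shows up in the female subgroup RR and
    not in the male one."""
    cfg = cs.default_config(
        n_records=120_000,
        seed=17,
        covariate_rr={},
        covariate_rr_post={"female": {"septicemia": 4.0}},
        cause_mix_post=dict(cs.default_config().cause_mix_pre),
    )
    rec = cs.generate_cohort(cfg)
    model = cs.CauseShiftModel(rec)
    rr_f = model.subgroup("sex", "female", "septicemia")
    rr_m = model.subgroup("sex", "male", "septicemia")
    assert rr_f.rr > 2.0 and rr_f.p_value < 0.01
    assert rr_m.ci_low < 1.0 < rr_m.ci_high


def test_subgroup_full_population_matches_adjusted(retained_100k):
    model = cs.CauseShiftModel(retained_100k)
    res = model.fit()
    labels = model.taxonomy.labels_in_group(cs.CauseGroup.NON_CANCER)
    strata = stratify_records(model.pre, model.immuno, labels)
    direct = adjusted_rr_poisson(strata)
    assert res.table.loc["NON_CANCER", "rr"] == pytest.approx(direct.rr, rel=1e-12)
    # restricting to a level of an axis not adjusted away keeps a valid result
    sub = model.subgroup("race", "white", cs.CauseGroup.NON_CANCER)
    assert sub.subgroup == ("race", "white") and sub.rr > 0


def test_results_table_well_formed(retained_100k):
    res = cs.CauseShiftModel(retained_100k).fit()
    t = res.table
    assert (t["ci_low"] <= t["rr"]).all() and (t["rr"] <= t["ci_high"]).all()
    assert t["p_bh"].between(0, 1).all()
    assert "NON_CANCER" in t.index and "heart diseases" in t.index
    assert "immunotherapy era" in res.summary()
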