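import itertools
import math

import numpy as np
import pytest
from scipy import stats

import codshift as cs

def test_monthly_hazard_division():
    rec = cs.records_frame(
        [cs.DeathRecord(2005, 0, "lung cancer")] * 5 + [cs.DeathRecord(2005, 1, "lung cancer")] * 3
        + [cs.DeathRecord(2005, 1, "COPD")] * 92
    )
    curve = cs.monthly_hazard(rec, cs.CauseGroup.LUNG_CANCER, M=2)
    assert curve.at_risk.tolist() == [100, 95]
    assert curve.risk.tolist() == pytest.approx([0.05, 3 / 95])


def test_all_deaths_at_month_zero():
    rec = cs.records_frame([cs.DeathRecord(2005, 0, "lung cancer")] * 4)
    curve = cs.monthly_hazard(rec, cs.CauseGroup.LUNG_CANCER, M=12)
    assert curve.months.tolist() == [0] and curve.risk.tolist() == [1.0]


def test_life_table_identity_and_decomposition(retained_100k):
    """The cumulative product of (1 - all-cause risk) equals the empirical
    survivor fraction, and group-specific risks sum to the all-cause risk."""
    split = cs.assign_era(retained_100k)
    grp = split.pre
    tax = cs.default_taxonomy()
    parts = [
        cs.monthly_hazard(grp, g, M=36, taxonomy=tax)
        for g in (cs.CauseGroup.LUNG_CANCER, cs.CauseGroup.NON_LUNG_CANCER, cs.CauseGroup.NON_CANCER)
    ]
    total_risk = sum(p.risk for p in parts)
    months = grp["survival_months"].to_numpy()
    surv = np.cumprod(1.0 - total_risk)
    for j_idx, j in enumerate(parts[0].months):
        frac_alive_after = (months > j).mean()
        assert surv[j_idx] == pytest.approx(frac_alive_after, abs=1e-12)
    # decomposition: per-month group deaths partition all deaths (no unknown here)
    assert (sum(p.deaths for p in parts) == np.bincount(months, minlength=36)[:36][parts[0].months]).all()


@pytest.mark.parametrize("frac", [0.3, 0.6, 1.0])
def test_lowess_exact_on_linear_data(frac):
    x = np.arange(20.0)
    y = 2.0 * x + 1.0
    fit = cs.lowess_smooth(x, y, frac=frac, robust_iters=1)
    assert np.max(np.abs(fit - y)) < 1e-10
    const = cs.lowess_smooth(x, np.full(20, 3.3), frac=frac)
    assert np.max(np.abs(const - 3.3)) < 1e-12


def test_lowess_matches_direct_weighted_normal_equations():
    """Each fitted value (robust_iters=0) equals the independent solution of
    the tricube-weighted 2x2 normal equations at that point."""
    rng = np.random.default_rng(3)
    x = np.sort(rng.random(25)) * 10
    y = np.sin(x) + rng.normal(0, 0.1, 25)
    frac = 0.4
    fit = cs.lowess_smooth(x, y, frac=frac, robust_iters=0)
    r = math.ceil(frac * len(x))
    for i in range(len(x)):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:r]
        w = (1 - (d[idx] / d[idx].max()) ** 3) ** 3
        A = np.array([[w.sum(), (w * x[idx]).sum()], [(w * x[idx]).sum(), (w * x[idx] ** 2).sum()]])
        b = np.array([(w * y[idx]).sum(), (w * x[idx] * y[idx]).sum()])
        a0, a1 = np.linalg.solve(A, b)
        assert fit[i] == pytest.approx(a0 + a1 * x[i], abs=1e-9)


def test_lowess_translation_invariance():
    rng = np.random.default_rng(8)
    x = np.arange(30.0)
    y = rng.random(30)
    base = cs.lowess_smooth(x, y)
    shifted = cs.lowess_smooth(x, y + 5.0)
    assert np.allclose(shifted, base + 5.0, atol=1e-9)


def test_lowess_input_validation():
    with pytest.raises(ValueError, match="distinct"):
        cs.lowess_smooth([1.0, 1.0, 1.0], [1, 2, 3])
    with pytest.raises(ValueError, match="3 points"):
        cs.lowess_smooth([1.0, 2.0], [1, 2])


def test_auc_trapezoid():
    months = np.arange(36)
    assert cs.auc_trapezoid(months, np.full(36, 0.05)) == pytest.approx(0.05 * 35)
    assert cs.auc_trapezoid(months, np.zeros(36)) == 0.0
    rng = np.random.default_rng(0)
    vals = rng.random(36)
    fine_x = np.linspace(0, 35, 35 * 2000 + 1)
    fine_y = np.interp(fine_x, months, vals)
    riemann = np.trapezoid(fine_y, fine_x)
    assert cs.auc_trapezoid(months, vals) == pytest.approx(riemann, abs=1e-12)


def _curve(months, risk, smoothed=None):
    n = len(months)
    return cs.HazardCurve(
        "g", np.asarray(months), np.full(n, 1000), (np.asarray(risk) * 1000).astype(int),
        np.asarray(risk, float), None if smoothed is None else np.asarray(smoothed, float),
    )


def test_percent_risk_reduction_examples():
    months = np.arange(10)
    risk = np.full(10, 0.05)
    assert cs.percent_risk_reduction(_curve(months, risk), _curve(months, risk)) == 0.0
    assert cs.percent_risk_reduction(_curve(months, risk), _curve(months, 0.7 * risk)) == pytest.approx(30.0)
    # antisymmetry up to the change of denominator
    a, b = _curve(months, risk), _curve(months, 0.7 * risk)
    fwd = cs.percent_risk_reduction(a, b)
    rev = cs.percent_risk_reduction(b, a)
    assert rev == pytest.approx(-fwd * a.auc / b.auc)
    assert math.isnan(cs.percent_risk_reduction(_curve(months, np.zeros(10)), a))


def test_wilcoxon_degenerate_and_sign_extreme():
    same = cs.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
    assert same.p_value == 1.0 and "all-differences-zero" in same.flags
    res = cs.wilcoxon_signed_rank([2, 3, 4, 5, 6, 7], [1, 1, 1, 1, 1, 1])
    assert res.p_value == pytest.approx(2 / 64)


def test_wilcoxon_exact_matches_brute_force_enumeration():
    rng = np.random.default_rng(10)
    for _ in range(5):
        d = rng.normal(0.2, 1.0, 10)
        d[d == 0] = 0.1
        res = cs.wilcoxon_signed_rank(d, np.zeros(10))
        ranks = stats.rankdata(np.abs(d))
        wobs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        total = ranks.sum()
        count = 0
        for signs in itertools.product([0, 1], repeat=10):
            wp = sum(r for r, s in zip(ranks, signs) if s)
            if wp <= wobs + 1e-12 or wp >= total - wobs - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(min(1.0, count / 2 ** 10))


def test_wilcoxon_agrees_with_scipy_on_tie_free_data():
    rng = np.random.default_rng(6)
    d = rng.normal(0.3, 1.0, 12)
    ours = cs.wilcoxon_signed_rank(d, np.zeros(12))
    ref = stats.wilcoxon(d, np.zeros(12), alternative="two-sided", method="exact")
    assert ours.p_value == pytest.approx(ref.pvalue)
    # large-n path: normal approximation close to scipy's
    d = rng.normal(0.1, 1.0, 36)
    ours = cs.wilcoxon_signed_rank(d, np.zeros(36))
    ref = stats.wilcoxon(d, np.zeros(36), alternative="two-sided", method="approx", correction=True)
    assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)
    assert ours.method == "normal"


def test_hazard_contrast_end_to_end(retained_100k):
    split = cs.assign_era(retained_100k)
    res = cs.HazardContrast(split.pre, split.immuno).fit()
    t = res.table
    assert set(t.index) == {"LUNG_CANCER", "NON_CANCER", "NON_LUNG_CANCER"}
    # planted conditions: lower hazard + higher non-cancer share post era
    assert t.loc["LUNG_CANCER", "percent_reduction"] > 0
    assert t.loc["NON_CANCER", "percent_reduction"] < 0
    assert (t["auc_pre"] > 0).all()
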