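import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import codshift as cs
from conftest import random_cube


def tiny_cube(data: dict[tuple[int, int], dict[str, int]], causes) -> cs.CountCube:
    idx = pd.MultiIndex.from_tuples(sorted(data), names=["year", "month"])
    rows = [[data[key].get(c, 0) for c in causes] for key in sorted(data)]
    return cs.CountCube(pd.DataFrame(rows, index=idx, columns=list(causes)))


def test_prior_weights_are_per_month_means():
    cube = tiny_cube({(2000, 0): {"a": 10}, (2001, 0): {"a": 20}, (2000, 1): {"a": 6}, (2001, 1): {"a": 0}}, "a")
    N = cs.compute_prior_weights(cube)
    assert N.loc[0] == 15.0 and N.loc[1] == 3.0
    single = tiny_cube({(2000, 0): {"a": 7}}, "a")
    assert cs.compute_prior_weights(single).loc[0] == 7.0


def test_year_proportions_normalize():
    cube = tiny_cube({(2000, 0): {"a": 10, "b": 30}, (2000, 1): {"a": 20, "b": 40}}, "ab")
    theta = cs.compute_year_proportions(cube)
    assert theta.loc[2000, "a"] == pytest.approx(0.3)
    assert theta.loc[2000, "b"] == pytest.approx(0.7)
    one = tiny_cube({(2000, 0): {"a": 5}}, "a")
    assert cs.compute_year_proportions(one).loc[2000, "a"] == 1.0
    empty_year = tiny_cube({(2000, 0): {"a": 0}}, "a")
    with pytest.raises(ValueError, match="2000"):
        cs.compute_year_proportions(empty_year)


def test_posterior_mean_limits():
    assert cs.posterior_mean(100, 0.5, 30, 100) == pytest.approx(0.4)
    assert cs.posterior_mean(50, 0.42, 0, 0) == pytest.approx(0.42)  # no data -> prior
    assert cs.posterior_mean(0, 0.9, 3, 10) == pytest.approx(0.3)  # no prior weight -> empirical
    assert cs.posterior_mean(0, 0.9, 0, 0) == pytest.approx(0.9)  # degenerate -> prior
    with pytest.raises(ValueError, match="exceeds"):
        cs.posterior_mean(10, 0.5, 11, 10)


@settings(max_examples=200, deadline=None)
@given(
    N=st.floats(0, 1e4),
    theta=st.floats(0, 1),
    n=st.integers(0, 10_000),
    frac=st.floats(0, 1),
)
def test_posterior_mean_interpolates(N, theta, n, frac):
    """theta_hat always lies weakly between the prior mean and the raw
    proportion, and shrinks monotonically with N."""
    m = int(round(frac * n))
    est = cs.posterior_mean(N, theta, m, n)
    if n > 0:
        lo, hi = sorted([theta, m / n])
        assert lo - 1e-12 <= est <= hi + 1e-12
        # more prior weight pulls the estimate no farther from the prior
        est2 = cs.posterior_mean(2 * N, theta, m, n)
        assert abs(est2 - theta) <= abs(est - theta) + 1e-12
    else:
        assert est == pytest.approx(theta)


def test_feature_matrix_substitution_and_fixed_point():
    cube = tiny_cube({(2000, 0): {"a": 3, "b": 7}}, "ab")
    params = cs.SmoothingParams(
        prior_weights=pd.Series({0: 10.0}),
        year_proportions=pd.DataFrame({"a": [0.5], "b": [0.5]}, index=pd.Index([2000], name="year")),
    )
    fm = cs.build_feature_matrix(cube, params)
    assert fm.theta.loc[(2000, 0)].tolist() == pytest.approx([0.4, 0.6])
    # fixed point: m = n * Theta  =>  theta_hat = Theta
    cube_fp = tiny_cube({(2000, 0): {"a": 5, "b": 5}}, "ab")
    fm_fp = cs.build_feature_matrix(cube_fp, params)
    assert fm_fp.theta.loc[(2000, 0)].tolist() == pytest.approx([0.5, 0.5])


def test_large_n_approaches_empirical_with_shrinkage_bound():
    cube = tiny_cube({(2000, 0): {"a": 900, "b": 100}}, "ab")
    params = cs.SmoothingParams(
        prior_weights=pd.Series({0: 10.0}),
        year_proportions=pd.DataFrame({"a": [0.5], "b": [0.5]}, index=pd.Index([2000], name="year")),
    )
    fm = cs.build_feature_matrix(cube, params)
    gap = np.abs(fm.theta.loc[(2000, 0)].to_numpy() - np.array([0.9, 0.1]))
    assert gap.max() <= 10.0 / (10.0 + 1000.0) + 1e-12


def test_rows_match_elementwise_formula_on_random_cubes():
    """Every smoothed value equals a brute-force scalar evaluation of
    (N_j Theta_ic + m_ijc) / (N_j + n_ij), and rows sum to 1."""
    rng = np.random.default_rng(4)
    for _ in range(20):
        cube = random_cube(rng)
        params = cs.SmoothingParams.from_cube(cube)
        fm = cs.build_feature_matrix(cube, params)
        years = sorted(set(cube.counts.index.get_level_values("year")))
        for (i, j), row in cube.counts.iterrows():
            n_ij = row.sum()
            # independent N_j / Theta_i from raw loops
            N_j = sum(cube.counts.loc[(y, j)].sum() for y in years) / len(years)
            year_tot = cube.counts.loc[i].to_numpy().sum()
            for c in cube.causes:
                theta_ic = cube.counts.loc[i, c].sum() / year_tot
                expect = (N_j * theta_ic + row[c]) / (N_j + n_ij)
                assert fm.theta.loc[(i, j), c] == pytest.approx(expect, abs=1e-12)
        assert np.allclose(fm.theta.sum(axis=1), 1.0, atol=1e-9)


def test_missing_cause_or_year_raises():
    cube = tiny_cube({(2000, 0): {"a": 3, "b": 7}}, "ab")
    params = cs.SmoothingParams(
        prior_weights=pd.Series({0: 10.0}),
        year_proportions=pd.DataFrame({"a": [1.0]}, index=pd.Index([2000], name="year")),
    )
    with pytest.raises(KeyError, match="causes absent"):
        cs.build_feature_matrix(cube, params)
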