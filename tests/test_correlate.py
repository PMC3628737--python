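"""Biweight midcorrelation, significance, q-values and clustering."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gutlipid import correlate as co


def bicor_oracle(x, y, c=9.0):
    """Independent brute-force transcription of the biweight formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def weights(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return v - v.mean(), np.ones_like(v)  # Pearson fallback
        u = (v - med) / (9.0 * mad)
        return v - med, (1 - u**2) ** 2 * (np.abs(u) < 1)

    xc, wx = weights(x)
    yc, wy = weights(y)
    num = np.sum(xc * wx * yc * wy)
    den = np.sqrt(np.sum((xc * wx) ** 2) * np.sum((yc * wy) ** 2))
    return num / den


finite_vec = st.lists(
    st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=8, max_size=30
)


@settings(max_examples=300, deadline=None)
@given(data=st.data())
def test_bicor_matches_bruteforce_oracle(data):
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    n = data.draw(st.integers(8, 40))
    x = rng.normal(size=n)
    y = 0.5 * x + rng.normal(size=n)
    assert co.bicor(x, y) == pytest.approx(bicor_oracle(x, y), abs=1e-12)


def test_bicor_self_and_antisymmetry():
    rng = np.random.default_rng(0)
    x = rng.normal(size=25)
    assert co.bicor(x, x) == pytest.approx(1.0, abs=1e-12)
    assert co.bicor(x, -x) == pytest.approx(-1.0, abs=1e-12)


def test_bicor_symmetric_in_arguments():
    rng = np.random.default_rng(3)
    x, y = rng.normal(size=20), rng.normal(size=20)
    assert co.bicor(x, y) == pytest.approx(co.bicor(y, x), abs=1e-14)


def test_bicor_agrees_with_pearson_without_outliers():
    rng = np.random.default_rng(1)
    cov = [[1, 0.5], [0.5, 1]]
    x, y = rng.multivariate_normal([0, 0], cov, size=1000).T
    assert abs(co.bicor(x, y) - stats.pearsonr(x, y).statistic) < 0.05


def test_bicor_more_robust_than_pearson_to_single_outlier():
    """One 10-SD outlier in a rho=0.8, n=50 pair moves bicor less than Pearson."""
    wins = 0
    n_seeds = 200
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        cov = [[1, 0.8], [0.8, 1]]
        x, y = rng.multivariate_normal([0, 0], cov, size=50).T
        r_b0, r_p0 = co.bicor(x, y), stats.pearsonr(x, y).statistic
        xo = x.copy()
        xo[0] = 10.0
        y_o = y.copy()
        y_o[0] = -10.0
        moved_b = abs(co.bicor(xo, y_o) - r_b0)
        moved_p = abs(stats.pearsonr(xo, y_o).statistic - r_p0)
        wins += moved_b < moved_p
    assert wins / n_seeds >= 0.95


def test_bicor_mad_zero_falls_back_to_pearson():
    x = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 5.0])  # mad = 0
    y = np.arange(7.0)
    with pytest.warns(RuntimeWarning, match="median absolute deviation"):
        r = co.bicor(x, y)
    assert np.isfinite(r)


def test_bicor_matrix_matches_pairwise(default_cohort):
    shared = default_cohort["abundance"].index.intersection(default_cohort["lipid"].index)
    X = default_cohort["abundance"].loc[shared].iloc[:, :5]
    Y = default_cohort["lipid"].loc[shared].iloc[:, :4]
    R = co.bicor_matrix(X, Y)
    for i in range(5):
        for j in range(4):
            assert R.iat[i, j] == pytest.approx(
                co.bicor(X.iloc[:, i], Y.iloc[:, j]), abs=1e-12
            )


def test_bicor_input_validation():
    with pytest.raises(ValueError):
        co.bicor([1, 2, 3], [1, 2, 3])  # too short
    with pytest.raises(ValueError):
        co.bicor(np.ones(10), np.arange(10.0))  # constant after weighting


def test_pvalue_limits_and_monotonicity():
    assert co.bicor_pvalue(0.0, 44) == pytest.approx(1.0)
    assert co.bicor_pvalue(1.0, 44) == 0.0
    rs = np.linspace(0, 0.99, 50)
    ps = co.bicor_pvalue(rs, 44)
    assert np.all(np.diff(ps) <= 0)


def test_pvalue_matches_permutation_oracle():
    """Analytic t-approximation vs permutation at r ~ 0.6, n = 44."""
    rng = np.random.default_rng(8)
    cov = [[1, 0.6], [0.6, 1]]
    x, y = rng.multivariate_normal([0, 0], cov, size=44).T
    r = co.bicor(x, y)
    p_t = co.bicor_pvalue(r, 44)
    B = 20000
    p_perm = co.bicor_permutation_pvalue(x, y, n_permutations=B, rng=np.random.default_rng(1))
    mc_sd = np.sqrt(max(p_perm, 1 / B) * (1 - p_perm) / B)
    assert abs(p_t - p_perm) <= 3 * mc_sd + 2 / B


def test_qvalues_reduce_to_bh_when_pi0_is_one():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(2)
    p = rng.uniform(size=500)
    q = co.qvalues(p, pi0=1.0)
    bh = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(q, bh)


def test_qvalues_monotone_in_p():
    rng = np.random.default_rng(4)
    p = np.concatenate([rng.uniform(size=400), rng.uniform(0, 1e-3, size=20)])
    q = co.qvalues(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert np.all((q >= 0) & (q <= 1))


def test_qvalues_all_ones_degenerate():
    q = co.qvalues(np.ones(10))
    assert np.allclose(q, 1.0)


def test_pi0_estimate_near_one_under_null():
    estimates = [
        co.estimate_pi0(np.random.default_rng(seed).uniform(size=10000))
        for seed in range(5)
    ]
    assert all(0.9 <= e <= 1.0 for e in estimates)


def test_pi0_detects_signal_fraction():
    rng = np.random.default_rng(6)
    p = np.concatenate([rng.uniform(size=8000), rng.beta(0.1, 10, size=2000)])
    assert co.estimate_pi0(p) < 0.95


def test_qvalues_reject_invalid_input():
    with pytest.raises(ValueError):
        co.qvalues([0.5, 1.5])
    with pytest.raises(ValueError):
        co.qvalues([0.5, np.nan])


def test_screen_counts_invariant_to_ordering(default_cohort):
    ab = default_cohort["abundance"]
    lip = default_cohort["lipid"]
    scr = co.screen(ab, lip)
    rng = np.random.default_rng(0)
    ab_shuf = ab.iloc[rng.permutation(len(ab)), rng.permutation(ab.shape[1])]
    lip_shuf = lip.iloc[:, rng.permutation(lip.shape[1])]
    scr2 = co.screen(ab_shuf, lip_shuf)
    assert scr2.n_significant == scr.n_significant
    assert set(scr2.significant_taxa) == set(scr.significant_taxa)
    assert set(scr2.significant_lipids) == set(scr.significant_lipids)


def test_screen_requires_shared_samples(default_cohort):
    ab = default_cohort["abundance"]
    lip = default_cohort["lipid"].copy()
    lip.index = [f"x{i}" for i in range(len(lip))]
    with pytest.raises(ValueError):
        co.screen(ab, lip)


def test_two_way_cluster_blocks_contiguous():
    """Rows of a planted block end up adjacent in leaf order."""
    rng = np.random.default_rng(9)
    r = rng.normal(0, 0.05, size=(12, 16))
    r[:4, :6] += 0.8
    r[8:, 10:] -= 0.8
    df = pd.DataFrame(r, index=[f"t{i}" for i in range(12)], columns=[f"l{j}" for j in range(16)])
    ordered, _, _ = co.two_way_cluster(df)
    pos = {lab: k for k, lab in enumerate(ordered.index)}
    block = sorted(pos[f"t{i}"] for i in range(4))
    assert block == list(range(block[0], block[0] + 4))


def test_two_way_cluster_identical_rows_merge_first():
    rng = np.random.default_rng(10)
    r = rng.normal(size=(5, 8))
    r[3] = r[1]
    _, row_link, _ = co.two_way_cluster(pd.DataFrame(r))
    assert row_link[0, 2] == pytest.approx(0.0, abs=1e-12)
    assert {int(row_link[0, 0]), int(row_link[0, 1])} == {1, 3}


def test_two_way_cluster_permutation_invariant_topology():
    """Row permutation changes labels, not the dendrogram's cophenetic structure."""
    from scipy.cluster.hierarchy import cophenet
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(12)
    r = rng.normal(size=(8, 10))
    df = pd.DataFrame(r, index=[f"t{i}" for i in range(8)])
    _, link1, _ = co.two_way_cluster(df)
    perm = rng.permutation(8)
    _, link2, _ = co.two_way_cluster(df.iloc[perm])
    coph1 = squareform(cophenet(link1))
    coph2 = squareform(cophenet(link2))
    # row i of the original sits at position perm^-1[i] in the permuted fit
    inv = np.argsort(perm)
    assert np.allclose(coph1, coph2[np.ix_(inv, inv)])
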