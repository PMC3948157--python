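"""Mean-rank permutation test and FDR control.

The independent oracle for exact-mode p-values is an integer
dynamic-programming enumeration of the Wilcoxon rank-sum null (complete,
tie-free data), computed here without touching the implementation's
permutation machinery.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from phosphosig import AnalysisConfig, bh_fdr, mean_rank_statistic, mean_rank_test
from phosphosig.stats import (
    SKIP_TOO_FEW_NONRESPONDER,
    SKIP_TOO_FEW_RESPONDER,
    StatsError,
    differential_sites,
)

from conftest import make_manifest, make_matrix, wilcoxon_exact_two_sided


def test_mean_rank_statistic_examples():
    # responders hold the two smallest of four values
    assert mean_rank_statistic(
        [0.1, 0.2, 0.3, 0.4], [True, True, False, False]
    ) == 1.5
    # mid-rank tie: both values equal, one per group
    assert mean_rank_statistic([0.5, 0.5], [True, False]) == 1.5
    # missing entries are excluded from ranking
    assert mean_rank_statistic(
        [0.1, np.nan, 0.3, 0.4], [True, True, False, False]
    ) == 1.0


def test_mean_rank_test_small_exact_cases():
    # [1,2] vs [3,4]: 2 of the C(4,2)=6 assignments are as extreme
    assert mean_rank_test([1, 2, 3, 4], [True, True, False, False]) == pytest.approx(
        2 / 6
    )
    # degenerate: all observed values identical
    assert mean_rank_test([2.0, 2.0, 2.0, 2.0], [True, True, False, False]) == 1.0
    with pytest.raises(StatsError):
        mean_rank_test([1.0, 2.0, np.nan], [True, True, False])


@settings(deadline=None, max_examples=60)
@given(data=st.data())
def test_exact_p_matches_wilcoxon_oracle(data):
    """Exact-mode p equals the integer-enumeration Wilcoxon two-sided p
    bit for bit on complete tie-free data, and scipy's exact p to 1e-12."""
    m = data.draw(st.integers(4, 8))
    n1 = data.draw(st.integers(2, m - 2))
    vals = data.draw(
        st.lists(
            st.floats(-100, 100, allow_nan=False),
            min_size=m, max_size=m, unique=True,
        )
    )
    vals = np.asarray(vals)
    labels = np.zeros(m, bool)
    labels[data.draw(st.permutations(range(m)))[:n1]] = True
    p = mean_rank_test(vals, labels)
    from scipy.stats import rankdata

    s_obs = rankdata(vals)[labels].sum()
    assert p == wilcoxon_exact_two_sided(m, n1, s_obs)
    p_scipy = mannwhitneyu(
        vals[labels], vals[~labels], alternative="two-sided", method="exact"
    ).pvalue
    assert p == pytest.approx(p_scipy, abs=1e-12)


def test_label_flip_leaves_p_unchanged():
    rng = np.random.default_rng(3)
    for _ in range(20):
        vals = rng.normal(size=10)
        labels = np.zeros(10, bool)
        labels[rng.choice(10, 4, replace=False)] = True
        assert mean_rank_test(vals, labels) == mean_rank_test(vals, ~labels)


def test_monte_carlo_mode_seed_stability():
    rng = np.random.default_rng(9)
    vals = rng.normal(size=20)
    labels = np.array([True] * 10 + [False] * 10)
    # force Monte-Carlo by shrinking the exact limit
    p1 = mean_rank_test(vals, labels, n_permutations=4000, seed=1, exact_limit=10)
    p2 = mean_rank_test(vals, labels, n_permutations=4000, seed=1, exact_limit=10)
    assert p1 == p2
    p_exact = mean_rank_test(vals, labels)
    p3 = mean_rank_test(vals, labels, n_permutations=4000, seed=2, exact_limit=10)
    se = np.sqrt(p_exact * (1 - p_exact) / 4000)
    assert abs(p3 - p_exact) < 3 * se + 1e-3


def test_bh_fdr_examples():
    np.testing.assert_allclose(
        bh_fdr([0.001, 0.02, 0.9]), [0.003, 0.03, 0.9], atol=1e-12
    )
    assert bh_fdr([1.0]) == [1.0]
    q = bh_fdr([0.04, 0.04, 0.04])
    assert len(set(q)) == 1
    # monotone non-decreasing in p-order
    rng = np.random.default_rng(0)
    p = np.sort(rng.random(50))
    assert (np.diff(bh_fdr(p)) >= -1e-15).all()
    with pytest.raises(StatsError):
        bh_fdr([0.5, 1.5])


def test_differential_sites_structure_and_sorting():
    rng = np.random.default_rng(11)
    vals = rng.normal(size=(50, 12))
    vals[0, :6] += 5.0  # strong planted effect in responders
    m = make_matrix(vals)
    manifest = make_manifest(m.sample_ids, 6)
    res = differential_sites(m, manifest, AnalysisConfig())
    assert list(res.columns[:2]) == ["site_id", "n_obs_responder"]
    # sorted by p ascending (tested sites first)
    tested = res[res["skip_reason"] == ""]
    assert tested["p_value"].is_monotonic_increasing
    assert res.iloc[0]["p_value"] == tested["p_value"].min()
    # planted site attains the exact-mode floor 2/C(12,6)
    planted = res[res["site_id"] == m.site_ids[0]].iloc[0]
    assert planted["p_value"] == pytest.approx(2 / 924)


def test_differential_sites_skip_rules():
    vals = np.full((3, 8), np.nan)
    vals[0] = [1, 2, 3, 4, 5, 6, 7, 8]
    vals[1, :4] = [1, 2, 3, 4]          # observed only in responders
    vals[2, [0, 1, 4, 5, 6]] = [1, 2, 3, 4, 5]
    m = make_matrix(vals)
    manifest = make_manifest(m.sample_ids, 4)
    res = differential_sites(m, manifest, AnalysisConfig()).set_index("site_id")
    assert res.loc[m.site_ids[0], "skip_reason"] == ""
    assert res.loc[m.site_ids[1], "skip_reason"] == SKIP_TOO_FEW_NONRESPONDER
    assert not res.loc[m.site_ids[1], "significant"]
    assert np.isnan(res.loc[m.site_ids[1], "p_value"])
    assert res.loc[m.site_ids[2], "skip_reason"] == ""
    # a site observed in no responder at all is skipped with the other code
    vals2 = vals.copy()
    vals2[1] = np.nan
    vals2[1, 4:] = [1, 2, 3, 4]
    res2 = differential_sites(
        make_matrix(vals2), manifest, AnalysisConfig()
    ).set_index("site_id")
    assert res2.loc[m.site_ids[1], "skip_reason"] == SKIP_TOO_FEW_RESPONDER


def test_differential_sites_needs_two_per_group():
    m = make_matrix(np.random.default_rng(0).normal(size=(5, 4)))
    with pytest.raises(StatsError, match="two samples per response group"):
        differential_sites(m, make_manifest(m.sample_ids, 1), AnalysisConfig())


def test_differential_label_flip_symmetry():
    rng = np.random.default_rng(21)
    vals = rng.normal(size=(30, 10))
    vals[rng.random((30, 10)) < 0.15] = np.nan
    m = make_matrix(vals)
    a = differential_sites(m, make_manifest(m.sample_ids, 4), AnalysisConfig())
    flipped = make_manifest(m.sample_ids, 4).frame.copy()
    flipped["response"] = np.where(
        flipped["response"] == "responder", "nonresponder", "responder"
    )
    from phosphosig import SampleManifest

    b = differential_sites(m, SampleManifest(flipped), AnalysisConfig())
    a_p = a.set_index("site_id")["p_value"]
    b_p = b.set_index("site_id")["p_value"]
    np.testing.assert_array_equal(a_p.sort_index().to_numpy(),
                                  b_p.sort_index().to_numpy())
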