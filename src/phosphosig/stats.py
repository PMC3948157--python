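"""Rank-based differential phosphorylation testing with missing values.

The mean-rank test compares responder and non-responder samples site by
site. For one site, the observed log2 ratios (missing entries dropped) are
ranked ascending with mid-ranks for ties; the statistic is the mean rank of
the responder group's observations,

    T = (1 / n_r) * sum of responder ranks,    E[T] = (m + 1) / 2

for m observed values of which n_r are responders. The two-sided p-value is
the fraction of group-label reassignments (preserving the observed group
sizes) with |T - E[T]| >= |T_obs - E[T]|. All C(m, n_r) reassignments are
enumerated when that count is small; otherwise Monte-Carlo sampling is used
with the (b + 1) / (B + 1) convention, which includes the observed
assignment and guarantees p > 0.

Ranking only the observed entries makes the test robust to the ~10%
missingness typical of spike-in-standard phosphoproteomics, at the cost of
per-site null distributions that depend on the missingness pattern — which
is why the null is recomputed (or re-enumerated) per pattern.

On complete, tie-free data T is a monotone transform of the Wilcoxon
rank-sum statistic, so the exact-mode p-value coincides with the exact
two-sided Wilcoxon rank-sum p-value; tests exploit this as an independent
oracle.
"""

from __future__ import annotations

import warnings
from functools import lru_cache
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .io import SampleManifest
from .preprocess import RatioMatrix

# reason codes for sites that cannot be tested
SKIP_TOO_FEW_RESPONDER = "too_few_observed_responder"
SKIP_TOO_FEW_NONRESPONDER = "too_few_observed_nonresponder"

_MIN_OBS_PER_GROUP = 2  # below this the two-sided permutation null degenerates

_EPS = 1e-9  # slack for |T - E| comparisons; rank sums are exact half-integers


class StatsError(ValueError):
    pass


@lru_cache(maxsize=128)
def _combo_matrix(m: int, n1: int) -> np.ndarray:
    """All C(m, n1) responder-index assignments as a boolean (combos, m) array."""
    out = np.zeros((comb(m, n1), m), dtype=bool)
    for row, idx in enumerate(combinations(range(m), n1)):
        out[row, list(idx)] = True
    return out


def mean_rank_statistic(
    values: Sequence[float] | np.ndarray, is_responder: Sequence[bool] | np.ndarray
) -> float:
    """Mean rank of the responder observations among the observed values.

    ``values`` may contain NaN (missing); ranks are computed over the
    observed entries only, ascending, with mid-ranks for ties.
    """
    values = np.asarray(values, dtype=float)
    is_responder = np.asarray(is_responder, dtype=bool)
    if values.shape != is_responder.shape:
        raise StatsError("values and labels have different lengths")
    obs = ~np.isnan(values)
    resp_obs = obs & is_responder
    if not resp_obs.any() or not (obs & ~is_responder).any():
        raise StatsError("each group needs at least one observed value")
    ranks = rankdata(values[obs])
    return float(ranks[is_responder[obs]].mean())


def mean_rank_test(
    values: Sequence[float] | np.ndarray,
    is_responder: Sequence[bool] | np.ndarray,
    n_permutations: int = 10_000,
    seed: int = 0,
    exact_limit: int = 20_000,
) -> float:
    """Two-sided permutation p-value for one site.

    Exact enumeration of all responder/non-responder reassignments over the
    observed entries when their number is at most ``exact_limit``; otherwise
    Monte-Carlo with ``n_permutations`` draws from ``seed``. Degenerate
    sites (all observed values identical) return p = 1.0 by convention.
    """
    values = np.asarray(values, dtype=float)
    is_responder = np.asarray(is_responder, dtype=bool)
    obs = ~np.isnan(values)
    v = values[obs]
    r = is_responder[obs]
    m = len(v)
    n1 = int(r.sum())
    if n1 < 1 or m - n1 < 1:
        raise StatsError("each group needs at least one observed value")
    if np.all(v == v[0]):
        return 1.0
    ranks = rankdata(v)
    # work on the rank-sum scale: sums of mid-ranks are exact in floats
    s_obs = float(ranks[r].sum())
    center = n1 * (m + 1) / 2.0
    d_obs = abs(s_obs - center)
    n_combos = comb(m, n1)
    if n_combos <= exact_limit:
        combos = _combo_matrix(m, n1)
        sums = combos @ ranks
        count = int(np.count_nonzero(np.abs(sums - center) >= d_obs - _EPS))
        return count / n_combos
    rng = np.random.default_rng(seed)
    hits = 0
    block = 2000
    remaining = n_permutations
    while remaining > 0:
        b = min(block, remaining)
        # sample b random n1-subsets via argpartition of uniform keys
        keys = rng.random((b, m))
        take = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
        sums = ranks[take].sum(axis=1)
        hits += int(np.count_nonzero(np.abs(sums - center) >= d_obs - _EPS))
        remaining -= b
    return (hits + 1) / (n_permutations + 1)


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_sites(
    matrix: RatioMatrix,
    manifest: SampleManifest,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Mean-rank test over every site of the matrix, with BH-FDR control.

    Returns a DataFrame with one row per site and columns

    ``site_id, n_obs_responder, n_obs_nonresponder, mean_rank_statistic,
    p_value, q_value, mean_log_ratio_responder, mean_log_ratio_nonresponder,
    significant, skip_reason``

    sorted by p ascending, ties broken by |difference of group means|
    descending, then site_id. Sites with fewer than two observations in
    either group are skipped with a reason code (NaN p, not significant) and
    listed after the tested sites. Sites sharing a missingness pattern share
    one enumerated null, which keeps exact mode fast on complete matrices.
    """
    labels = manifest.labels_for(matrix.sample_ids)
    is_resp = (labels == "responder").to_numpy()
    if is_resp.sum() < 2 or (~is_resp).sum() < 2:
        raise StatsError(
            "need at least two samples per response group "
            f"(got {int(is_resp.sum())} responders, "
            f"{int((~is_resp).sum())} non-responders)"
        )

    vals = matrix.values.to_numpy(dtype=float)
    site_ids = matrix.site_ids
    n_sites, n_samples = vals.shape
    obs = ~np.isnan(vals)

    n_obs_resp = obs[:, is_resp].sum(axis=1)
    n_obs_non = obs[:, ~is_resp].sum(axis=1)

    # nanmean of an all-missing group row is NaN by design; silence its warning
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_resp = np.nanmean(np.where(is_resp, vals, np.nan), axis=1)
        mean_non = np.nanmean(np.where(~is_resp, vals, np.nan), axis=1)

    p = np.full(n_sites, np.nan)
    t_stat = np.full(n_sites, np.nan)
    skip = np.array([""] * n_sites, dtype=object)

    skip[n_obs_resp < _MIN_OBS_PER_GROUP] = SKIP_TOO_FEW_RESPONDER
    mask_non = (n_obs_non < _MIN_OBS_PER_GROUP) & (skip == "")
    skip[mask_non] = SKIP_TOO_FEW_NONRESPONDER
    testable = np.flatnonzero(skip == "")

    # group testable sites by observation pattern so the enumerated null is
    # shared; on complete data this is a single vectorized block
    patterns: dict[bytes, list[int]] = {}
    for i in testable:
        patterns.setdefault(obs[i].tobytes(), []).append(i)

    for key, idx_list in patterns.items():
        pattern = np.frombuffer(key, dtype=bool)
        m = int(pattern.sum())
        resp_cols = is_resp[pattern]
        n1 = int(resp_cols.sum())
        block_vals = vals[np.ix_(idx_list, np.flatnonzero(pattern))]
        ranks = rankdata(block_vals, axis=1)
        s_obs = ranks[:, resp_cols].sum(axis=1)
        center = n1 * (m + 1) / 2.0
        d_obs = np.abs(s_obs - center)
        t_stat[idx_list] = s_obs / n1
        degenerate = np.all(block_vals == block_vals[:, :1], axis=1)
        n_combos = comb(m, n1)
        if n_combos <= config.exact_limit:
            combos = _combo_matrix(m, n1)
            sums = ranks @ combos.T.astype(float)  # (block, combos)
            counts = (np.abs(sums - center) >= d_obs[:, None] - _EPS).sum(axis=1)
            p_block = counts / n_combos
        else:
            p_block = np.empty(len(idx_list))
            for j, i in enumerate(idx_list):
                p_block[j] = mean_rank_test(
                    vals[i],
                    is_resp,
                    n_permutations=config.n_permutations,
                    seed=_site_seed(config.seed, i),
                    exact_limit=config.exact_limit,
                )
        p_block = np.where(degenerate, 1.0, p_block)
        p[idx_list] = p_block

    q = np.full(n_sites, np.nan)
    if len(testable):
        q[testable] = bh_fdr(p[testable])

    out = pd.DataFrame(
        {
            "site_id": site_ids,
            "n_obs_responder": n_obs_resp,
            "n_obs_nonresponder": n_obs_non,
            "mean_rank_statistic": t_stat,
            "p_value": p,
            "q_value": q,
            "mean_log_ratio_responder": mean_resp,
            "mean_log_ratio_nonresponder": mean_non,
            "significant": (q <= config.fdr_q) & ~np.isnan(q),
            "skip_reason": skip,
        }
    )
    out["_absdiff"] = (out["mean_log_ratio_responder"]
                       - out["mean_log_ratio_nonresponder"]).abs()
    out = out.sort_values(
        by=["p_value", "_absdiff", "site_id"],
        ascending=[True, False, True],
        na_position="last",
        kind="mergesort",
    ).drop(columns="_absdiff").reset_index(drop=True)
    return out


def _site_seed(master_seed: int, site_index: int) -> int:
    """Stable per-site Monte-Carlo seed below 2**31."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(site_index,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))
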