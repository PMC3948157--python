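"""Shared fixtures: small in-memory tables and matrix/manifest builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phosphosig import PhosphoSiteTable, SampleManifest
from phosphosig.preprocess import RatioMatrix


def make_matrix(values, site_ids=None, sample_ids=None) -> RatioMatrix:
    values = np.asarray(values, dtype=float)
    n_sites, n_samples = values.shape
    site_ids = site_ids or [f"S{i:04d}" for i in range(n_sites)]
    sample_ids = sample_ids or [f"A{j:02d}" for j in range(n_samples)]
    return RatioMatrix(pd.DataFrame(values, index=site_ids, columns=sample_ids))


def make_manifest(
    sample_ids, n_responders, cohort="training"
) -> SampleManifest:
    n = len(sample_ids)
    return SampleManifest(
        pd.DataFrame(
            {
                "sample_id": list(sample_ids),
                "cohort": cohort,
                "response": ["responder"] * n_responders
                + ["nonresponder"] * (n - n_responders),
            }
        )
    )


def make_site_table(ratios, loc_probs=None) -> PhosphoSiteTable:
    """Ratio-scale (positive) table with autogenerated annotations."""
    ratios = np.asarray(ratios, dtype=float)
    n_sites, n_samples = ratios.shape
    if loc_probs is None:
        loc_probs = np.full(n_sites, 0.99)
    site_ids = [f"GENE{i:03d}_S{i + 1}" for i in range(n_sites)]
    sites = pd.DataFrame(
        {
            "site_id": site_ids,
            "protein_accession": [f"P{i:03d}" for i in range(n_sites)],
            "gene": [f"GENE{i:03d}" for i in range(n_sites)],
            "residue": "S",
            "position": np.arange(1, n_sites + 1),
            "localization_prob": loc_probs,
        }
    )
    frame = pd.DataFrame(
        ratios,
        index=site_ids,
        columns=[f"A{j:02d}" for j in range(n_samples)],
    )
    return PhosphoSiteTable(sites, frame)


def wilcoxon_exact_two_sided(m: int, n1: int, s_obs: float) -> float:
    """Independent oracle: P(|S - E| >= |s_obs - E|) for the rank-sum S of an
    n1-subset of ranks {1..m}, via integer dynamic programming over
    subset-sum counts (no permutation enumeration)."""
    from math import comb

    max_sum = m * (m + 1) // 2
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=object)
    dp[0][0] = 1
    for r in range(1, m + 1):
        for k in range(min(n1, r), 0, -1):
            for s in range(max_sum, r - 1, -1):
                if dp[k - 1][s - r]:
                    dp[k][s] += dp[k - 1][s - r]
    center = n1 * (m + 1) / 2.0
    d = abs(s_obs - center)
    count = sum(
        int(dp[n1][s]) for s in range(max_sum + 1)
        if abs(s - center) >= d - 1e-9
    )
    return count / comb(m, n1)


@pytest.fixture
def noise_matrix_12():
    """500 pure-noise sites x 12 samples, deterministic."""
    rng = np.random.default_rng(42)
    return make_matrix(rng.normal(size=(500, 12)))


@pytest.fixture
def manifest_6v6(noise_matrix_12):
    return make_manifest(noise_matrix_12.sample_ids, 6)
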