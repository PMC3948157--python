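"""Phosphorylation vs protein-expression correlation.

Distinguishes whether a predictive phosphosite's signal reflects changed
site stoichiometry or simply changed abundance of the carrier protein:
a high Pearson correlation between the site's log2 phospho-ratios and the
protein's log2 expression ratios across samples argues for the latter.

Correlations use pairwise-complete observations only (samples quantified in
both vectors); the p-value is the standard two-sided t-test on
``t = r * sqrt((n - 2) / (1 - r^2))`` with n - 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import RatioMatrix

DEFAULT_MIN_PAIRS = 3


@dataclass(frozen=True)
class CorrelationResult:
    site_id: str
    protein_id: str
    n: int
    pearson_r: float | None
    p_value: float | None
    insufficient_data: bool = False


def phospho_protein_correlation(
    phospho_row: np.ndarray | pd.Series,
    protein_row: np.ndarray | pd.Series,
    site_id: str = "",
    protein_id: str = "",
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> CorrelationResult:
    """Pearson r between one site's phospho-ratios and its protein's expression.

    Only samples observed in *both* vectors enter; with fewer than
    ``min_pairs`` complete pairs the result is flagged insufficient and
    carries no r.
    """
    x = np.asarray(phospho_row, dtype=float)
    y = np.asarray(protein_row, dtype=float)
    if x.shape != y.shape:
        raise ValueError("phospho and protein rows have different lengths")
    both = ~np.isnan(x) & ~np.isnan(y)
    n = int(both.sum())
    if n < min_pairs:
        return CorrelationResult(site_id, protein_id, n, None, None, True)
    r, p = sps.pearsonr(x[both], y[both])
    return CorrelationResult(site_id, protein_id, n, float(r), float(p))


def correlate_sites(
    phospho: RatioMatrix,
    protein: RatioMatrix,
    pairs: pd.DataFrame,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> pd.DataFrame:
    """Correlate each (site_id, protein_id) pair over shared samples.

    ``pairs`` has columns ``site_id`` and ``protein_id``; protein rows are
    looked up by ``protein_id`` in the protein matrix index. Returns one row
    per pair with n, pearson_r, p_value and the insufficiency flag.
    """
    shared = [s for s in phospho.sample_ids if s in set(protein.sample_ids)]
    if not shared:
        raise ValueError("phospho and protein matrices share no samples")
    rows = []
    for rec in pairs.itertuples(index=False):
        site, prot = str(rec.site_id), str(rec.protein_id)
        if site not in phospho.values.index:
            raise KeyError(f"site {site!r} not in phospho matrix")
        if prot not in protein.values.index:
            raise KeyError(f"protein {prot!r} not in protein matrix")
        res = phospho_protein_correlation(
            phospho.values.loc[site, shared],
            protein.values.loc[prot, shared],
            site_id=site,
            protein_id=prot,
            min_pairs=min_pairs,
        )
        rows.append(res.__dict__)
    return pd.DataFrame(rows)
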