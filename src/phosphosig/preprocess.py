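"""Raw ratio tables -> analysis-ready log2 matrix.

Pipeline order: class-I localization filter, log2 transform, minimum
quantification filter (the two-thirds rule), per-sample median centering.
Missing values stay missing throughout; downstream stages are built to
tolerate them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import PhosphoSiteTable


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class RatioMatrix:
    """Log2 ratio matrix (sites x samples) with an explicit missing mask.

    ``values`` is a float DataFrame indexed by site_id with sample columns;
    missing cells are NaN. ``provenance`` records the filters applied, in
    order, so written outputs can carry their history.
    """

    values: pd.DataFrame
    provenance: tuple[str, ...] = ()

    @property
    def site_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def mask_observed(self) -> pd.DataFrame:
        return self.values.notna()

    def observed_fraction_per_site(self) -> pd.Series:
        return self.values.notna().mean(axis=1)

    def with_provenance(self, entry: str) -> "RatioMatrix":
        return replace(self, provenance=self.provenance + (entry,))

    def subset_samples(self, sample_ids: list[str]) -> "RatioMatrix":
        absent = [s for s in sample_ids if s not in self.values.columns]
        if absent:
            raise PreprocessError(f"samples not in matrix: {absent}")
        return RatioMatrix(self.values[sample_ids], self.provenance)


def log_transform(table: PhosphoSiteTable) -> RatioMatrix:
    """log2 of each positive ratio; missing stays missing."""
    values = np.log2(table.ratios)
    return RatioMatrix(values, provenance=("log2",))


def filter_class_I(table: PhosphoSiteTable, threshold: float) -> PhosphoSiteTable:
    """Keep sites whose localization probability is >= ``threshold``.

    The boundary is inclusive: a site at exactly the class-I cutoff counts
    as confidently localized.
    """
    if not 0.0 <= threshold <= 1.0:
        raise PreprocessError(f"classI threshold must be in [0, 1], got {threshold}")
    keep = table.sites["localization_prob"].to_numpy() >= threshold
    return table.subset_sites(keep)


def filter_min_quantification(matrix: RatioMatrix, min_fraction: float) -> RatioMatrix:
    """Keep sites observed in at least ``ceil(min_fraction * n_samples)`` samples.

    Ceiling rounding is the strict reading of "at least two thirds": with 12
    samples the cutoff is 8 observed, with 9 samples it is 6.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise PreprocessError(f"min_fraction must be in (0, 1], got {min_fraction}")
    n = matrix.n_samples
    cutoff = math.ceil(min_fraction * n - 1e-9)  # guard ceil(2/3*12)=8 not 9
    observed = matrix.values.notna().sum(axis=1)
    keep = observed >= cutoff
    if not keep.any():
        raise PreprocessError(
            f"no sites survive the quantification filter "
            f"(cutoff {cutoff} of {n} samples)"
        )
    out = RatioMatrix(matrix.values.loc[keep.to_numpy()], matrix.provenance)
    return out.with_provenance(
        f"filter: min_quantification fraction={min_fraction:.6g} cutoff={cutoff}"
    )


def normalize_samples(matrix: RatioMatrix) -> RatioMatrix:
    """Median-center each sample column over its observed values."""
    all_missing = matrix.values.isna().all(axis=0)
    if all_missing.any():
        bad = matrix.values.columns[all_missing][0]
        raise PreprocessError(f"sample {bad!r} has no observed values")
    medians = matrix.values.median(axis=0, skipna=True)
    centered = matrix.values.sub(medians, axis=1)
    return RatioMatrix(
        centered, matrix.provenance + ("normalize: per-sample median centering",)
    )


def missingness_summary(matrix: RatioMatrix) -> tuple[pd.Series, float]:
    """Per-site and overall missing fractions."""
    missing = matrix.values.isna()
    per_site = missing.mean(axis=1)
    overall = float(missing.to_numpy().mean()) if matrix.n_sites else 0.0
    return per_site, overall


def preprocess(
    table: PhosphoSiteTable,
    classI_threshold: float,
    min_quant_fraction: float,
    normalize: bool = True,
) -> RatioMatrix:
    """Default pipeline: class-I filter -> log2 -> 2/3 rule -> median centering."""
    filtered = filter_class_I(table, classI_threshold)
    matrix = log_transform(filtered).with_provenance(
        f"filter: class_I threshold={classI_threshold:.6g} "
        f"kept={filtered.n_sites}/{table.n_sites}"
    )
    matrix = filter_min_quantification(matrix, min_quant_fraction)
    if normalize:
        matrix = normalize_samples(matrix)
    return matrix
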