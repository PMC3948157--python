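"""Frozen-signature evaluation on an independent cohort.

The validation stage never refits anything: the signature's sites, weights
and calibration are applied as-is to samples that were processed (and
median-centered) independently of training. A disjointness guard rejects
any overlap between training and validation sample ids before scoring.
"""

from __future__ import annotations

from typing import Any

import pandas as pd

from .config import AnalysisConfig
from .io import SampleManifest
from .preprocess import RatioMatrix
from .signature import MetricsReport, SignatureModel, compute_metrics, predict


class LeakageError(ValueError):
    """A validation sample also appears in the signature's training set."""


def validate_cohort(
    model: SignatureModel,
    matrix: RatioMatrix,
    manifest: SampleManifest,
    config: AnalysisConfig,
) -> tuple[pd.DataFrame, MetricsReport, dict[str, Any]]:
    """Score the validation cohort with a frozen signature.

    ``manifest`` should be restricted to the validation cohort (use
    ``manifest.cohort("validation")``). Returns (predictions, metrics,
    attestation), where the attestation records the verified disjointness
    of training and validation sample ids.
    """
    val_ids = [s for s in matrix.sample_ids if s in set(manifest.sample_ids)]
    if not val_ids:
        raise LeakageError("matrix contains no samples from the given manifest")
    overlap = sorted(set(val_ids) & model.training_sample_ids)
    if overlap:
        raise LeakageError(
            f"validation samples also present in training: {overlap}"
        )
    predictions = predict(
        model,
        matrix.subset_samples(val_ids),
        decision_threshold=config.decision_threshold,
        manifest=manifest,
    )
    report = compute_metrics(predictions)
    attestation = {
        "training_samples": sorted(model.training_sample_ids),
        "validation_samples": val_ids,
        "disjoint": True,
    }
    return predictions, report, attestation
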