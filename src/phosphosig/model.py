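"""High-level Model/Results interface over the discovery workflow.

:class:`PhosphoSignature` is constructed from a site table and a manifest,
mirroring how regression models are built from data elsewhere in the
scientific Python stack; :meth:`PhosphoSignature.fit` runs preprocessing,
differential testing, nested leave-one-out cross-validation, final-model
training and (when a validation cohort exists) frozen-signature validation,
and returns a :class:`PhosphoSignatureResults` carrying every artifact plus
a printable summary.

Example
-------
>>> from phosphosig import SyntheticConfig, generate_dataset, PhosphoSignature
>>> data = generate_dataset(SyntheticConfig(n_sites=300, seed=7))
>>> res = PhosphoSignature(data.phospho, data.manifest).fit()
>>> res.model.sites          # doctest: +SKIP
('GENE00042_S1287', ...)
>>> print(res.summary())     # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd

from .config import AnalysisConfig
from .io import (
    PhosphoSiteTable,
    SampleManifest,
    read_manifest,
    read_site_table,
)
from .preprocess import (
    RatioMatrix,
    log_transform,
    missingness_summary,
    normalize_samples,
    preprocess,
)
from .signature import (
    MetricsReport,
    SignatureModel,
    loocv,
    percent,
    rank_features,
    select_top_k,
    train_classifier,
)
from .validate import validate_cohort


class PhosphoSignature:
    """Responder-signature discovery model for a phosphosite ratio table.

    Parameters
    ----------
    table
        Sites x samples ratio table (ratios to the spike-in standard).
    manifest
        Cohort and response labels for the table's sample columns. Training
        samples drive discovery; a validation cohort, if present, is scored
        with the frozen signature.
    config
        Analysis knobs; defaults follow the package's standard workflow
        (class-I 0.75, two-thirds quantification, FDR 10%, k = 5).
    """

    def __init__(
        self,
        table: PhosphoSiteTable,
        manifest: SampleManifest,
        config: AnalysisConfig | None = None,
    ):
        self.table = table
        self.manifest = manifest
        self.config = config or AnalysisConfig()

    @classmethod
    def from_files(
        cls,
        site_table: str | Path,
        manifest: str | Path,
        config: AnalysisConfig | None = None,
    ) -> "PhosphoSignature":
        return cls(read_site_table(site_table), read_manifest(manifest), config)

    def _cohort_matrix(self, cohort: str, full_preprocess: bool) -> RatioMatrix:
        sub_manifest = self.manifest.cohort(cohort)
        ids = [s for s in self.table.sample_ids if s in set(sub_manifest.sample_ids)]
        table = PhosphoSiteTable(self.table.sites, self.table.ratios[ids])
        if full_preprocess:
            return preprocess(
                table,
                classI_threshold=self.config.classI_threshold,
                min_quant_fraction=self.config.min_quant_fraction,
            )
        # frozen-signature application: keep every row (the signature's
        # sites must not be filtered away), normalize per sample as usual
        return normalize_samples(log_transform(table))

    def fit(self) -> "PhosphoSignatureResults":
        """Run the full discovery workflow on the training cohort."""
        cfg = self.config
        train_matrix = self._cohort_matrix("training", full_preprocess=True)
        train_manifest = self.manifest.cohort("training")
        per_site_missing, overall_missing = missingness_summary(train_matrix)

        from .stats import differential_sites

        differential = differential_sites(train_matrix, train_manifest, cfg)
        cv_predictions, cv_metrics, fold_log = loocv(
            train_matrix, train_manifest, cfg
        )
        sites = select_top_k(
            rank_features(train_matrix, train_manifest, cfg), cfg.signature_size_k
        )
        model = train_classifier(train_matrix, train_manifest, cfg, sites)

        val_predictions = val_metrics = attestation = None
        if self.manifest.has_cohort("validation"):
            val_matrix = self._cohort_matrix("validation", full_preprocess=False)
            val_predictions, val_metrics, attestation = validate_cohort(
                model, val_matrix, self.manifest.cohort("validation"), cfg
            )

        return PhosphoSignatureResults(
            config=cfg,
            train_matrix=train_matrix,
            differential=differential,
            model=model,
            loocv_predictions=cv_predictions,
            loocv_metrics=cv_metrics,
            fold_log=fold_log,
            overall_missing_fraction=overall_missing,
            validation_predictions=val_predictions,
            validation_metrics=val_metrics,
            attestation=attestation,
        )


@dataclass
class PhosphoSignatureResults:
    """Artifacts of one fitted discovery run."""

    config: AnalysisConfig
    train_matrix: RatioMatrix
    differential: pd.DataFrame
    model: SignatureModel
    loocv_predictions: pd.DataFrame
    loocv_metrics: MetricsReport
    fold_log: list[dict[str, Any]]
    overall_missing_fraction: float
    validation_predictions: pd.DataFrame | None = None
    validation_metrics: MetricsReport | None = None
    attestation: dict[str, Any] | None = None

    @property
    def significant_sites(self) -> list[str]:
        sig = self.differential[self.differential["significant"]]
        return list(sig["site_id"])

    def summary(self) -> str:
        """Human-readable run summary in the spirit of a model-results table."""
        cfg = self.config
        n_sig = len(self.significant_sites)
        lines = [
            "Phospho-signature discovery summary",
            "=" * 51,
            f"Tested sites:               {len(self.differential[self.differential['skip_reason'] == ''])}",
            f"Missing values (training):  {self.overall_missing_fraction:.1%}",
            f"Significant at q<={cfg.fdr_q:.2f}:     {n_sig}",
            f"Signature size k:           {cfg.signature_size_k}",
            f"Signature sites (best first):",
        ]
        for rank, s in enumerate(self.model.sites, start=1):
            lines.append(f"  {rank}. {s}")
        m = self.loocv_metrics
        lines += [
            "-" * 51,
            "Leave-one-out cross-validation (training cohort)",
            f"  accuracy    {m.accuracy:.3f} ({percent(m.accuracy)}%)",
            f"  sensitivity {m.sensitivity:.3f} ({percent(m.sensitivity)}%)",
            f"  specificity {m.specificity:.3f} ({percent(m.specificity)}%)",
            f"  AUROC       {'n/a' if m.auroc is None else f'{m.auroc:.3f} ({percent(m.auroc)}%)'}",
        ]
        if self.validation_metrics is not None:
            v = self.validation_metrics
            lines += [
                "-" * 51,
                "Independent validation cohort (frozen signature)",
                f"  accuracy    {v.accuracy:.3f} ({percent(v.accuracy)}%)",
                f"  sensitivity {v.sensitivity:.3f} ({percent(v.sensitivity)}%)",
                f"  specificity {v.specificity:.3f} ({percent(v.specificity)}%)",
                f"  AUROC       {'n/a' if v.auroc is None else f'{v.auroc:.3f} ({percent(v.auroc)}%)'}",
            ]
        return "\n".join(lines)
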