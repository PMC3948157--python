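"""End-to-end pipeline driver with provenance.

Runs preprocess -> differential test -> nested LOOCV -> final training ->
(optional) validation -> (optional) correlation in order, persists each
stage's output under one directory, and records a RunRecord (config echo,
seed, input digests, per-stage counts, versions, timestamps). With exact
permutation mode a rerun from the same inputs reproduces the differential
TSV and the signature JSON byte for byte; only the RunRecord timestamp
differs.
"""

from __future__ import annotations

import hashlib
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .config import AnalysisConfig
from .correlation import correlate_sites
from .io import read_manifest, read_site_table, write_signature
from .model import PhosphoSignature
from .preprocess import log_transform, normalize_samples

logger = logging.getLogger("phosphosig")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_yaml(obj: Any, path: Path) -> None:
    path.write_text(yaml.safe_dump(obj, sort_keys=True), encoding="utf-8")


def run_pipeline(
    site_table_path: str | Path,
    manifest_path: str | Path,
    outdir: str | Path,
    config: AnalysisConfig | None = None,
    protein_table_path: str | Path | None = None,
    pairs_path: str | Path | None = None,
) -> dict[str, Any]:
    """Execute every stage and return the RunRecord.

    The correlation stage runs only when a protein table and a
    site-to-protein pairs TSV are both supplied; the validation stage runs
    only when the manifest contains a validation cohort (its absence is a
    logged notice, not an error).
    """
    site_table_path = Path(site_table_path)
    manifest_path = Path(manifest_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or AnalysisConfig()

    record: dict[str, Any] = {
        "tool": "phosphosig",
        "version": __version__,
        "started": datetime.now(timezone.utc).isoformat(),
        "config": config.to_dict(),
        "seed": config.seed,
        "inputs": {
            "site_table": {"path": str(site_table_path),
                           "sha256": _sha256(site_table_path)},
            "manifest": {"path": str(manifest_path),
                         "sha256": _sha256(manifest_path)},
        },
        "stages": {},
        "complete": False,
    }

    stage = "read"
    try:
        table = read_site_table(site_table_path)
        manifest = read_manifest(manifest_path)
        record["stages"]["read"] = {
            "n_sites": table.n_sites, "n_samples": table.n_samples,
            "n_manifest": len(manifest),
        }

        stage = "fit"
        logger.info("fitting discovery workflow on %d sites", table.n_sites)
        results = PhosphoSignature(table, manifest, config).fit()
        record["stages"]["preprocess"] = {
            "n_sites_tested": int(
                (results.differential["skip_reason"] == "").sum()
            ),
            "missing_fraction": results.overall_missing_fraction,
            "provenance": list(results.train_matrix.provenance),
        }

        stage = "difftest"
        diff_path = outdir / "differential.tsv"
        results.differential.to_csv(diff_path, sep="\t", index=False)
        record["stages"]["difftest"] = {
            "n_significant": int(results.differential["significant"].sum()),
            "out": str(diff_path),
        }

        stage = "crossval"
        results.loocv_predictions.to_csv(
            outdir / "loocv_predictions.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            [
                {"held_out": f["held_out"],
                 "sites": ";".join(f["sites"])}
                for f in results.fold_log
            ]
        ).to_csv(outdir / "loocv_fold_sites.tsv", sep="\t", index=False)
        record["stages"]["crossval"] = results.loocv_metrics.to_dict()

        stage = "train"
        sig_path = outdir / "signature.json"
        write_signature(results.model, sig_path)
        record["stages"]["train"] = {
            "sites": list(results.model.sites), "out": str(sig_path)
        }

        stage = "validate"
        if results.validation_metrics is not None:
            results.validation_predictions.to_csv(
                outdir / "validation_predictions.tsv", sep="\t", index=False
            )
            _write_yaml(
                {
                    "metrics": results.validation_metrics.to_dict(),
                    "attestation": results.attestation,
                },
                outdir / "validation_report.yaml",
            )
            record["stages"]["validate"] = results.validation_metrics.to_dict()
        else:
            logger.info("no validation cohort in manifest; stage skipped")
            record["stages"]["validate"] = "skipped: no validation cohort"

        stage = "correlate"
        if protein_table_path is not None and pairs_path is not None:
            protein_table_path = Path(protein_table_path)
            pairs = pd.read_csv(pairs_path, sep="\t", dtype=str)
            protein = read_site_table(protein_table_path)
            phospho_m = normalize_samples(log_transform(table))
            protein_m = normalize_samples(log_transform(protein))
            corr = correlate_sites(phospho_m, protein_m, pairs)
            corr.to_csv(outdir / "correlation.tsv", sep="\t", index=False)
            record["inputs"]["protein_table"] = {
                "path": str(protein_table_path),
                "sha256": _sha256(protein_table_path),
            }
            record["stages"]["correlate"] = {"n_pairs": len(corr)}
        else:
            record["stages"]["correlate"] = "skipped: no protein table"
    except Exception as exc:
        record["failed_stage"] = stage
        record["error"] = str(exc)
        _write_yaml(record, outdir / "run_record.yaml")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    record["complete"] = True
    record["finished"] = datetime.now(timezone.utc).isoformat()
    _write_yaml(record, outdir / "run_record.yaml")
    return record
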