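"""Synthetic super-SILAC phosphosite data with planted group effects.

The generator emulates what the analysis assumes about spike-in-standard
phosphoproteomics of patient blasts:

* per-site baseline ``b_i ~ Normal(0, base_ratio_sd^2)`` shared across
  samples (biological spread of log2 ratios to the common standard);
* observation ``x_ij = b_i + effect_size * [site planted & sample responder]
  + Normal(0, noise_sd^2)`` on the log2 scale;
* missingness from a mixture of MCAR and an abundance-dependent (MNAR)
  mechanism: cell dropout log-odds are
  ``logit(mcar_rate) + mnar_strength * (-b_i)``, using the site baseline as
  abundance proxy, so low-abundance sites drop out more often;
* a paired protein-expression table coupled to the phospho table at
  correlation ``protein_coupling`` per cell;
* localization probabilities from a mixture: class-I sites Uniform(0.75, 1),
  the rest Uniform(0, 0.75).

All randomness comes from one seeded stream in a documented order (site
baselines, planted-site choice, localization, then per cohort: noise,
missingness, protein noise), so identical config + seed gives bit-identical
tables. :func:`generate_study` draws a training and a validation cohort
over one shared site universe, mirroring a two-stage biomarker study.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import SyntheticConfig
from .io import (
    PhosphoSiteTable,
    SampleManifest,
    write_manifest,
    write_site_table,
)

_RESIDUES = np.array(["S", "T", "Y"])
_RESIDUE_WEIGHTS = np.array([0.84, 0.14, 0.02])  # typical phospho-STY shares
_CLASS_I_CUT = 0.75


class GroundTruthError(ValueError):
    """Config and dataset fingerprints disagree."""


@dataclass(frozen=True)
class SyntheticDataset:
    """Everything one simulated cohort produces.

    ``phospho`` and ``protein`` are ratio tables sharing site and sample
    ids; ``manifest`` labels the columns; ``planted`` is the ground-truth
    sidecar (site_id, planted_flag, true_effect); ``fingerprint`` ties the
    dataset to the config that produced it.
    """

    phospho: PhosphoSiteTable
    manifest: SampleManifest
    protein: PhosphoSiteTable
    planted: pd.DataFrame
    fingerprint: str
    config: SyntheticConfig


def _config_fingerprint(config: SyntheticConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _site_universe(config: SyntheticConfig, rng: np.random.Generator):
    """Site-level draws shared by every cohort of one study."""
    n_sites = config.n_sites
    baselines = rng.normal(0.0, config.base_ratio_sd, size=n_sites)
    planted_mask = np.zeros(n_sites, dtype=bool)
    planted_mask[rng.choice(n_sites, size=config.n_differential,
                            replace=False)] = True
    n_classI = int(round(config.classI_fraction * n_sites))
    classI = np.zeros(n_sites, dtype=bool)
    classI[rng.choice(n_sites, size=n_classI, replace=False)] = True
    loc_prob = np.where(
        classI,
        rng.uniform(_CLASS_I_CUT, 1.0, size=n_sites),
        rng.uniform(0.0, _CLASS_I_CUT, size=n_sites),
    )
    residues = rng.choice(_RESIDUES, size=n_sites, p=_RESIDUE_WEIGHTS)
    positions = rng.integers(1, 2000, size=n_sites)
    genes = [f"GENE{i:05d}" for i in range(n_sites)]
    site_ids = [f"{g}_{r}{p}" for g, r, p in zip(genes, residues, positions)]
    sites = pd.DataFrame(
        {
            "site_id": site_ids,
            "protein_accession": [f"P{i:05d}" for i in range(n_sites)],
            "gene": genes,
            "residue": residues,
            "position": positions,
            "localization_prob": loc_prob,
        }
    )
    return sites, baselines, planted_mask


def _draw_cohort(
    config: SyntheticConfig,
    rng: np.random.Generator,
    sites: pd.DataFrame,
    baselines: np.ndarray,
    planted_mask: np.ndarray,
    n_responders: int,
    n_nonresponders: int,
    cohort: str,
) -> SyntheticDataset:
    n_sites = config.n_sites
    n_samples = n_responders + n_nonresponders
    is_resp = np.zeros(n_samples, dtype=bool)
    is_resp[:n_responders] = True

    effect = np.outer(planted_mask * config.effect_size, is_resp)
    noise = rng.normal(0.0, config.noise_sd, size=(n_sites, n_samples))
    log_ratios = baselines[:, None] + effect + noise

    if config.mcar_rate == 0.0:
        p_miss = np.zeros((n_sites, 1))
    else:
        logit = np.log(config.mcar_rate / (1.0 - config.mcar_rate))
        cell_logit = logit + config.mnar_strength * (-baselines)[:, None]
        p_miss = 1.0 / (1.0 + np.exp(-cell_logit))
    missing = rng.random((n_sites, n_samples)) < p_miss

    rho = config.protein_coupling
    protein_log = rho * log_ratios + np.sqrt(1.0 - rho**2) * rng.normal(
        0.0, config.noise_sd + config.base_ratio_sd, size=(n_sites, n_samples)
    )
    protein_missing = rng.random((n_sites, n_samples)) < p_miss

    site_ids = list(sites["site_id"])
    prefix = "T" if cohort == "training" else "V"
    sample_ids = [f"AML{prefix}{j + 1:03d}" for j in range(n_samples)]

    ratios = np.exp2(log_ratios)
    ratios[missing] = np.nan
    phospho = PhosphoSiteTable(
        sites, pd.DataFrame(ratios, index=site_ids, columns=sample_ids)
    )
    prot = np.exp2(protein_log)
    prot[protein_missing] = np.nan
    protein = PhosphoSiteTable(
        sites, pd.DataFrame(prot, index=site_ids, columns=sample_ids)
    )
    manifest = SampleManifest(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "cohort": cohort,
                "response": np.where(is_resp, "responder", "nonresponder"),
            }
        )
    )
    planted = pd.DataFrame(
        {
            "site_id": site_ids,
            "planted_flag": planted_mask,
            "true_effect": np.where(planted_mask, config.effect_size, 0.0),
        }
    )
    return SyntheticDataset(
        phospho=phospho,
        manifest=manifest,
        protein=protein,
        planted=planted,
        fingerprint=_config_fingerprint(config),
        config=config,
    )


def generate_dataset(
    config: SyntheticConfig, cohort: str = "training"
) -> SyntheticDataset:
    """Simulate one cohort's phospho table, manifest and protein table."""
    rng = np.random.default_rng(config.seed)
    sites, baselines, planted_mask = _site_universe(config, rng)
    return _draw_cohort(
        config, rng, sites, baselines, planted_mask,
        config.n_responders, config.n_nonresponders, cohort,
    )


def generate_study(
    config: SyntheticConfig,
    n_val_responders: int = 6,
    n_val_nonresponders: int = 3,
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Simulate a training and a validation cohort over one site universe.

    The training cohort uses ``config.n_responders`` / ``n_nonresponders``;
    the validation cohort sizes default to the 6-responder, 3-non-responder
    shape of a small confirmatory group. Site annotations, baselines and
    the planted differential sites are shared; sample-level noise and
    missingness are drawn independently per cohort from the same stream.
    """
    rng = np.random.default_rng(config.seed)
    sites, baselines, planted_mask = _site_universe(config, rng)
    train = _draw_cohort(
        config, rng, sites, baselines, planted_mask,
        config.n_responders, config.n_nonresponders, "training",
    )
    val = _draw_cohort(
        config, rng, sites, baselines, planted_mask,
        n_val_responders, n_val_nonresponders, "validation",
    )
    return train, val


def combine_cohorts(
    train: SyntheticDataset, val: SyntheticDataset
) -> tuple[PhosphoSiteTable, SampleManifest]:
    """One table and one manifest covering both cohorts of a study."""
    if list(train.phospho.site_ids) != list(val.phospho.site_ids):
        raise GroundTruthError("cohorts do not share a site universe")
    ratios = pd.concat([train.phospho.ratios, val.phospho.ratios], axis=1)
    table = PhosphoSiteTable(train.phospho.sites, ratios)
    manifest = SampleManifest(
        pd.concat([train.manifest.frame, val.manifest.frame],
                  ignore_index=True)
    )
    return table, manifest


def ground_truth(config: SyntheticConfig, dataset: SyntheticDataset) -> set[str]:
    """Planted truly-differential site ids for a dataset of this config."""
    if dataset.fingerprint != _config_fingerprint(config):
        raise GroundTruthError(
            "dataset was not generated from this config (fingerprint mismatch)"
        )
    flagged = dataset.planted.loc[dataset.planted["planted_flag"], "site_id"]
    return set(flagged)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Persist all tables plus the ground-truth sidecar and the config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "phospho": outdir / "phospho_sites.tsv",
        "protein": outdir / "protein_expression.tsv",
        "manifest": outdir / "manifest.csv",
        "ground_truth": outdir / "ground_truth.tsv",
        "config": outdir / "synthetic_config.yaml",
    }
    write_site_table(dataset.phospho, paths["phospho"])
    write_site_table(dataset.protein, paths["protein"])
    write_manifest(dataset.manifest, paths["manifest"])
    dataset.planted.to_csv(paths["ground_truth"], sep="\t", index=False)
    paths["config"].write_text(
        yaml.safe_dump(dataset.config.to_dict(), sort_keys=True), encoding="utf-8"
    )
    return paths
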