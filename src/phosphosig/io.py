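"""Readers and writers for the pipeline's tabular formats.

The site table is a simplified, documented dialect of a MaxQuant-style
phosphosite table: plain TSV with the annotation columns

    site_id  protein_accession  gene  residue  position  localization_prob

followed by one ``ratio_<sample_id>`` column per sample. Cells hold the
positive ratio of the sample's intensity to the spike-in standard; empty,
``NA`` and ``NaN`` cells are missing. The manifest is a CSV with columns
``sample_id,cohort,response``. Trained signatures round-trip through JSON.

All readers validate strictly and report the offending row/column; nothing
is silently coerced.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_RESIDUES = frozenset({"S", "T", "Y"})
VALID_COHORTS = frozenset({"training", "validation"})
VALID_RESPONSES = frozenset({"responder", "nonresponder"})
MISSING_TOKENS = frozenset({"", "NA", "NaN", "nan"})

ANNOTATION_COLUMNS = [
    "site_id",
    "protein_accession",
    "gene",
    "residue",
    "position",
    "localization_prob",
]

SIGNATURE_SCHEMA_VERSION = 1


class FormatError(ValueError):
    """A file violates the documented dialect; the message carries coordinates."""


@dataclass(frozen=True)
class SiteRecord:
    """Annotation of one phosphorylation site."""

    site_id: str
    protein_accession: str
    gene: str
    residue: str
    position: int
    localization_prob: float

    def __post_init__(self) -> None:
        if self.residue not in VALID_RESIDUES:
            raise FormatError(
                f"site {self.site_id!r}: residue must be one of S/T/Y, "
                f"got {self.residue!r}"
            )
        if not 0.0 <= self.localization_prob <= 1.0:
            raise FormatError(
                f"site {self.site_id!r}: localization_prob must be in [0, 1], "
                f"got {self.localization_prob}"
            )
        if self.position < 1:
            raise FormatError(
                f"site {self.site_id!r}: position must be >= 1, got {self.position}"
            )


class PhosphoSiteTable:
    """Sites x samples ratio matrix with per-site annotations.

    Parameters
    ----------
    sites
        DataFrame with :data:`ANNOTATION_COLUMNS`, one row per site.
    ratios
        DataFrame indexed by ``site_id`` with one column per sample; values
        are positive ratios to the spike-in standard, ``NaN`` where the site
        was not quantified in that run.
    """

    def __init__(self, sites: pd.DataFrame, ratios: pd.DataFrame):
        sites = sites.reset_index(drop=True)
        missing_cols = [c for c in ANNOTATION_COLUMNS if c not in sites.columns]
        if missing_cols:
            raise FormatError(f"missing annotation columns: {missing_cols}")
        ids = sites["site_id"]
        dup = ids[ids.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate site_id: {dup.iloc[0]!r}")
        if ratios.columns.duplicated().any():
            dup_s = ratios.columns[ratios.columns.duplicated()][0]
            raise FormatError(f"duplicate sample identifier: {dup_s!r}")
        if not (list(ratios.index) == list(ids)):
            ratios = ratios.reindex(ids)
        vals = ratios.to_numpy(dtype=float)
        bad = np.argwhere(~np.isnan(vals) & (vals <= 0))
        if len(bad):
            i, j = bad[0]
            raise FormatError(
                f"non-positive ratio {vals[i, j]} at site {ids.iloc[i]!r}, "
                f"sample {ratios.columns[j]!r}: ratios of intensities must be > 0"
            )
        for rec in sites.itertuples(index=False):
            SiteRecord(
                site_id=str(rec.site_id),
                protein_accession=str(rec.protein_accession),
                gene=str(rec.gene),
                residue=str(rec.residue),
                position=int(rec.position),
                localization_prob=float(rec.localization_prob),
            )
        self.sites = sites
        self.ratios = ratios.astype(float)

    @property
    def site_ids(self) -> list[str]:
        return list(self.sites["site_id"])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ratios.columns)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return self.ratios.shape[1]

    def subset_sites(self, keep: Sequence[bool] | pd.Series) -> "PhosphoSiteTable":
        mask = np.asarray(keep, dtype=bool)
        return PhosphoSiteTable(self.sites.loc[mask], self.ratios.loc[mask])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhosphoSiteTable):
            return NotImplemented
        return self.sites.equals(other.sites) and self.ratios.equals(other.ratios)


@dataclass(frozen=True)
class SampleManifest:
    """Sample-level supervision: cohort membership and response label."""

    frame: pd.DataFrame  # columns sample_id, cohort, response

    def __post_init__(self) -> None:
        f = self.frame
        for col in ("sample_id", "cohort", "response"):
            if col not in f.columns:
                raise FormatError(f"manifest missing column {col!r}")
        if len(f) == 0:
            raise FormatError("manifest is empty")
        dup = f["sample_id"][f["sample_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate sample_id in manifest: {dup.iloc[0]!r}")
        bad_cohort = set(f["cohort"]) - VALID_COHORTS
        if bad_cohort:
            raise FormatError(
                f"unknown cohort label {sorted(bad_cohort)[0]!r}; "
                f"expected one of {sorted(VALID_COHORTS)}"
            )
        bad_resp = set(f["response"]) - VALID_RESPONSES
        if bad_resp:
            raise FormatError(
                f"unknown response label {sorted(bad_resp)[0]!r}; labels must be "
                f"pre-mapped to one of {sorted(VALID_RESPONSES)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def cohort(self, name: str) -> "SampleManifest":
        sub = self.frame[self.frame["cohort"] == name].reset_index(drop=True)
        if len(sub) == 0:
            raise FormatError(f"no samples in cohort {name!r}")
        return SampleManifest(sub)

    def has_cohort(self, name: str) -> bool:
        return bool((self.frame["cohort"] == name).any())

    def labels_for(self, sample_ids: Iterable[str]) -> pd.Series:
        """Response labels aligned to ``sample_ids``; missing sample -> error."""
        lookup = self.frame.set_index("sample_id")["response"]
        ids = list(sample_ids)
        absent = [s for s in ids if s not in lookup.index]
        if absent:
            raise FormatError(f"samples absent from manifest: {absent}")
        return lookup.loc[ids]

    def __len__(self) -> int:
        return len(self.frame)


def read_site_table(path: str | Path) -> PhosphoSiteTable:
    """Read and validate a phosphosite TSV in the documented dialect."""
    path = Path(path)
    raw = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, comment="#"
    )
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise FormatError(f"{path.name}: missing columns {missing_cols}")
    ratio_cols = [c for c in raw.columns if c.startswith("ratio_")]
    if not ratio_cols:
        raise FormatError(f"{path.name}: no ratio_<sample_id> columns found")
    sample_ids = [c[len("ratio_"):] for c in ratio_cols]

    sites = raw[ANNOTATION_COLUMNS].copy()
    try:
        sites["position"] = sites["position"].astype(int)
        sites["localization_prob"] = sites["localization_prob"].astype(float)
    except ValueError as exc:
        raise FormatError(f"{path.name}: bad annotation value: {exc}") from exc

    vals = np.full((len(raw), len(ratio_cols)), np.nan)
    for j, col in enumerate(ratio_cols):
        for i, cell in enumerate(raw[col]):
            cell = cell.strip()
            if cell in MISSING_TOKENS:
                continue
            try:
                v = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path.name}: unparseable ratio {cell!r} at site "
                    f"{raw['site_id'].iloc[i]!r}, column {col!r}"
                ) from None
            if not math.isfinite(v) or v <= 0:
                raise FormatError(
                    f"{path.name}: non-positive ratio {cell!r} at site "
                    f"{raw['site_id'].iloc[i]!r}, column {col!r}"
                )
            vals[i, j] = v
    ratios = pd.DataFrame(vals, index=raw["site_id"].tolist(), columns=sample_ids)
    return PhosphoSiteTable(sites, ratios)


def write_site_table(
    table: PhosphoSiteTable, path: str | Path, provenance: Sequence[str] = ()
) -> None:
    """Write the TSV dialect; missing cells become empty strings."""
    path = Path(path)
    out = table.sites.copy()
    for s in table.sample_ids:
        col = table.ratios[s].map(
            lambda v: "" if pd.isna(v) else repr(float(v))
        )
        out[f"ratio_{s}"] = col.to_numpy()
    with open(path, "w", encoding="utf-8") as fh:
        for line in provenance:
            fh.write(f"#{line}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_manifest(path: str | Path) -> SampleManifest:
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path.name}: manifest file is empty") from None
    if len(frame) == 0:
        raise FormatError(f"{path.name}: manifest has a header but no samples")
    return SampleManifest(frame)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    manifest.frame.to_csv(path, index=False)


def write_signature(model, path: str | Path) -> None:
    """Serialize a trained :class:`~phosphosig.signature.SignatureModel` to JSON.

    Floats are written via ``repr`` (17 significant digits) so the
    read/write round trip is bit-exact.
    """
    payload = {
        "schema_version": SIGNATURE_SCHEMA_VERSION,
        "sites": list(model.sites),
        "weights": [float(w) for w in model.weights],
        "bias": float(model.bias),
        "calibration": {"A": float(model.calibration[0]),
                        "B": float(model.calibration[1])},
        "imputation_constant": float(model.imputation_constant),
        "training_meta": model.training_meta,
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def read_signature(path: str | Path):
    from .signature import SignatureModel

    path = Path(path)
    payload = json.loads(path.read_text(encoding="utf-8"))
    version = payload.get("schema_version")
    if version != SIGNATURE_SCHEMA_VERSION:
        raise FormatError(
            f"{path.name}: signature schema_version {version!r} is not "
            f"supported (expected {SIGNATURE_SCHEMA_VERSION})"
        )
    for key in ("sites", "weights", "bias", "calibration", "imputation_constant"):
        if key not in payload:
            raise FormatError(f"{path.name}: signature file missing {key!r} key")
    cal = payload["calibration"]
    return SignatureModel(
        sites=tuple(payload["sites"]),
        weights=np.asarray(payload["weights"], dtype=float),
        bias=float(payload["bias"]),
        calibration=(float(cal["A"]), float(cal["B"])),
        imputation_constant=float(payload["imputation_constant"]),
        training_meta=payload.get("training_meta", {}),
    )
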