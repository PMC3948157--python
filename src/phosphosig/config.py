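"""Configuration objects for the analysis pipeline and the data simulator.

Both configs are frozen dataclasses validated on construction; a bad field
raises :class:`ConfigError` naming the offending field so CLI users get an
actionable message rather than a downstream numpy error.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping


class ConfigError(ValueError):
    """A configuration field is out of its documented range."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the discovery workflow.

    Parameters
    ----------
    fdr_q
        Benjamini–Hochberg false-discovery-rate level for calling a site
        differentially phosphorylated. Default 0.10.
    min_quant_fraction
        Minimum fraction of samples in which a site must be quantified to
        enter the analysis (the "two-thirds rule"). Counted with ceiling
        rounding: a row passes iff observed >= ceil(fraction * n_samples).
    classI_threshold
        Localization-probability cutoff for class-I sites (0.75 is the
        conventional MaxQuant definition).
    signature_size_k
        Number of phosphosites in the learned signature.
    n_permutations
        Monte-Carlo permutation budget for the mean-rank test when exact
        enumeration is infeasible (> ``exact_limit`` reassignments).
    decision_threshold
        Responder-class probability above which a sample is called a
        responder.
    seed
        Master seed; every stochastic stage derives its stream from it.
    svm_C
        Regularization constant of the linear maximum-margin classifier.
        Fixed rather than tuned: a dozen samples and five features leave no
        room for a model search.
    exact_limit
        Largest number of label reassignments for which the permutation
        null is enumerated exhaustively.
    """

    fdr_q: float = 0.10
    min_quant_fraction: float = 2.0 / 3.0
    classI_threshold: float = 0.75
    signature_size_k: int = 5
    n_permutations: int = 10_000
    decision_threshold: float = 0.5
    seed: int = 0
    svm_C: float = 1.0
    exact_limit: int = 20_000

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_q < 1.0:
            raise ConfigError("fdr_q", f"must be in (0, 1), got {self.fdr_q}")
        if not 0.0 < self.min_quant_fraction <= 1.0:
            raise ConfigError(
                "min_quant_fraction",
                f"must be in (0, 1], got {self.min_quant_fraction}",
            )
        if not 0.0 <= self.classI_threshold <= 1.0:
            raise ConfigError(
                "classI_threshold",
                f"must be in [0, 1], got {self.classI_threshold}",
            )
        if self.signature_size_k < 1:
            raise ConfigError(
                "signature_size_k", f"must be >= 1, got {self.signature_size_k}"
            )
        if self.n_permutations < 1:
            raise ConfigError(
                "n_permutations", f"must be >= 1, got {self.n_permutations}"
            )
        if not 0.0 < self.decision_threshold < 1.0:
            raise ConfigError(
                "decision_threshold",
                f"must be in (0, 1), got {self.decision_threshold}",
            )
        if self.svm_C <= 0:
            raise ConfigError("svm_C", f"must be > 0, got {self.svm_C}")
        if self.exact_limit < 1:
            raise ConfigError("exact_limit", f"must be >= 1, got {self.exact_limit}")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown configuration field")
        return cls(**d)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic phosphosite-ratio generator.

    The generator emulates a super-SILAC experiment: each cell is the
    log2 ratio of a sample's phosphopeptide intensity to a common spike-in
    standard. Defaults mirror the study conditions this package targets:
    a ~2000-site tested matrix with ~10.6% missing values, 6 responders vs
    6 non-responders in training and 6 vs 3 in validation.

    ``effect_size`` is the log2-ratio shift added to the responder group at
    the ``n_differential`` planted sites. ``mnar_strength`` adds
    abundance-dependent dropout: a site's missingness log-odds increase by
    ``mnar_strength`` per unit decrease of its baseline log2 ratio (the
    abundance proxy), emulating low-abundance peptides dropping out of MS
    runs more often.
    """

    n_sites: int = 2000
    n_responders: int = 6
    n_nonresponders: int = 6
    n_differential: int = 5
    effect_size: float = 2.0
    noise_sd: float = 0.5
    base_ratio_sd: float = 1.0
    mcar_rate: float = 0.106
    mnar_strength: float = 0.0
    classI_fraction: float = 1.0
    protein_coupling: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sites", "n_responders", "n_nonresponders"):
            if getattr(self, name) < 1:
                raise ConfigError(name, f"must be >= 1, got {getattr(self, name)}")
        if self.n_differential < 0:
            raise ConfigError(
                "n_differential", f"must be >= 0, got {self.n_differential}"
            )
        if self.n_differential > self.n_sites:
            raise ConfigError(
                "n_differential",
                f"{self.n_differential} exceeds n_sites={self.n_sites}",
            )
        for name in ("noise_sd", "base_ratio_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(name, f"must be > 0, got {getattr(self, name)}")
        for name in ("mcar_rate", "classI_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(name, f"must be in [0, 1], got {v}")
        if self.mnar_strength < 0:
            raise ConfigError(
                "mnar_strength", f"must be >= 0, got {self.mnar_strength}"
            )
        if not -1.0 <= self.protein_coupling <= 1.0:
            raise ConfigError(
                "protein_coupling",
                f"must be in [-1, 1], got {self.protein_coupling}",
            )

    @property
    def n_samples(self) -> int:
        return self.n_responders + self.n_nonresponders

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown configuration field")
        return cls(**d)
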