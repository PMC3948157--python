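"""Phospho-signature learning and leak-free performance estimation.

A signature is an ordered set of k phosphosites plus a frozen linear
maximum-margin classifier over their log2 ratios. Feature importance is the
mean-rank-test p-value (ties: larger |group-mean difference| first, then
site_id), so selection and differential testing share one statistic.
Missing signature values are imputed with a constant (default 0, i.e. "no
regulation" on the median-centered log2 scale).

Performance on the training cohort is estimated by leave-one-out
cross-validation with feature selection *inside* each fold: ranking,
selection and classifier training are redone on the n-1 retained samples,
so the held-out sample never influences which sites are chosen. The
deliberately leaky variant (selection once, on all samples, before CV) is
provided only to demonstrate the optimistic bias that nesting removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .config import AnalysisConfig
from .io import SampleManifest
from .preprocess import RatioMatrix
from .stats import differential_sites


class SignatureError(ValueError):
    pass


@dataclass(frozen=True)
class SignatureModel:
    """Frozen k-site predictor.

    ``sites`` are in importance order (best first). The decision value of a
    sample with imputed feature vector x is ``w @ x + bias``; the responder
    probability is ``1 / (1 + exp(A * f + B))`` with calibration ``(A, B)``
    fitted on the training decision values.
    """

    sites: tuple[str, ...]
    weights: np.ndarray
    bias: float
    calibration: tuple[float, float]
    imputation_constant: float
    training_meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sites) != len(self.weights):
            raise SignatureError(
                f"{len(self.sites)} sites but {len(self.weights)} weights"
            )

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.bias

    def probabilities(self, X: np.ndarray) -> np.ndarray:
        A, B = self.calibration
        return _sigmoid(self.decision_values(X), A, B)

    @property
    def training_sample_ids(self) -> frozenset[str]:
        return frozenset(self.training_meta.get("sample_ids", ()))


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and summary metrics with responder as positive class."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    auroc: float | None

    def to_dict(self) -> dict[str, Any]:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auroc": self.auroc,
        }


def percent(x: float) -> int:
    """Round-half-up to integer percent (11/12 -> 92, 5/6 -> 83, 2/3 -> 67)."""
    return int(np.floor(x * 100.0 + 0.5))


def _sigmoid(f: np.ndarray, A: float, B: float) -> np.ndarray:
    z = A * np.asarray(f, dtype=float) + B
    # numerically stable logistic
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    out[~pos] = np.exp(z[~pos]) / (1.0 + np.exp(z[~pos]))
    return 1.0 - out  # p = 1 / (1 + exp(A f + B))


def _fit_platt(decision_values: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-parameter sigmoid calibration of margins to probabilities.

    Smoothed targets keep the fit finite on separable training sets and make
    the map equivariant under label negation (p -> 1 - p).
    """
    f = np.asarray(decision_values, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def loss(params: np.ndarray) -> float:
        A, B = params
        p = _sigmoid(f, A, B)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(-(t * np.log(p) + (1 - t) * np.log(1 - p)).sum())

    x0 = np.array([0.0, np.log((n_neg + 1.0) / (n_pos + 1.0))])
    res = minimize(loss, x0, method="BFGS", options={"gtol": 1e-10, "maxiter": 500})
    return float(res.x[0]), float(res.x[1])


def rank_features(
    matrix: RatioMatrix, manifest: SampleManifest, config: AnalysisConfig
) -> list[str]:
    """Site ids ordered by importance (rank 1 = best).

    Importance orders the testable sites by the absolute difference of
    responder and non-responder mean log2 ratios (descending), breaking
    ties by the mean-rank-test p-value (ascending) and then site_id. The
    continuous effect size must lead: with a dozen samples the exact
    permutation p has a hard floor of 2 / C(n, n_r) (~0.002 at 6 vs 6), so
    among thousands of candidates many strong sites saturate the p scale
    and p alone cannot order the top of the list. Ranking is symmetric
    under label flips and deterministic.
    """
    results = differential_sites(matrix, manifest, config)
    tested = results[results["skip_reason"] == ""].copy()
    tested["_absdiff"] = (
        tested["mean_log_ratio_responder"] - tested["mean_log_ratio_nonresponder"]
    ).abs()
    tested = tested.sort_values(
        by=["_absdiff", "p_value", "site_id"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return list(tested["site_id"])


def select_top_k(ranked_sites: Sequence[str], k: int) -> list[str]:
    if k > len(ranked_sites):
        raise SignatureError(
            f"k={k} exceeds the {len(ranked_sites)} available ranked sites"
        )
    return list(ranked_sites[:k])


def _design_matrix(
    matrix: RatioMatrix, sites: Sequence[str], imputation_constant: float
) -> np.ndarray:
    """Samples x sites matrix with missing entries imputed."""
    absent = [s for s in sites if s not in matrix.values.index]
    if absent:
        raise SignatureError(f"signature sites absent from matrix: {absent}")
    X = matrix.values.loc[list(sites)].to_numpy(dtype=float).T
    return np.where(np.isnan(X), imputation_constant, X)


def train_classifier(
    matrix: RatioMatrix,
    manifest: SampleManifest,
    config: AnalysisConfig,
    sites: Sequence[str],
    imputation_constant: float = 0.0,
) -> SignatureModel:
    """Fit the linear maximum-margin classifier on the selected sites.

    Missing entries are imputed with ``imputation_constant`` before fitting;
    a sigmoid calibration from margin to responder probability is fitted on
    the training decision values.
    """
    labels = manifest.labels_for(matrix.sample_ids)
    y = (labels == "responder").to_numpy().astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise SignatureError("training data must contain both response classes")
    X = _design_matrix(matrix, sites, imputation_constant)
    # tight tolerance: the margin must negate exactly under a label flip so
    # calibrated probabilities map p -> 1 - p
    svc = SVC(kernel="linear", C=config.svm_C, tol=1e-9)
    svc.fit(X, y)
    weights = svc.coef_[0].copy()
    bias = float(svc.intercept_[0])
    f = X @ weights + bias
    A, B = _fit_platt(f, y)
    return SignatureModel(
        sites=tuple(sites),
        weights=weights,
        bias=bias,
        calibration=(A, B),
        imputation_constant=imputation_constant,
        training_meta={
            "sample_ids": list(matrix.sample_ids),
            "config": config.to_dict(),
            "seed": config.seed,
        },
    )


def predict(
    model: SignatureModel,
    matrix: RatioMatrix,
    decision_threshold: float = 0.5,
    manifest: SampleManifest | None = None,
) -> pd.DataFrame:
    """Responder probabilities and calls for every sample column of ``matrix``.

    Returns a DataFrame with columns ``sample_id, probability_responder,
    predicted_class, true_label`` (true_label NaN without a manifest). A
    signature site absent from the matrix is an error; a sample merely
    missing a value uses the imputation constant.
    """
    X = _design_matrix(matrix, model.sites, model.imputation_constant)
    prob = model.probabilities(X)
    pred = np.where(prob > decision_threshold, "responder", "nonresponder")
    out = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "probability_responder": prob,
            "predicted_class": pred,
        }
    )
    if manifest is not None:
        out["true_label"] = manifest.labels_for(matrix.sample_ids).to_numpy()
    else:
        out["true_label"] = np.nan
    return out


def compute_metrics(predictions: pd.DataFrame) -> MetricsReport:
    """Confusion counts, accuracy, sensitivity, specificity and AUROC.

    Responder is the positive class. AUROC uses the rank method with
    mid-rank tie handling (all-equal probabilities give 0.5); it is reported
    as None when only one true class is present.
    """
    labeled = predictions.dropna(subset=["true_label"])
    if len(labeled) == 0:
        raise SignatureError("no labeled predictions to score")
    truth = labeled["true_label"] == "responder"
    called = labeled["predicted_class"] == "responder"
    tp = int((truth & called).sum())
    fp = int((~truth & called).sum())
    tn = int((~truth & ~called).sum())
    fn = int((truth & ~called).sum())
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    if truth.any() and (~truth).any():
        auroc = float(
            roc_auc_score(truth.to_numpy(), labeled["probability_responder"])
        )
    else:
        auroc = None
    return MetricsReport(tp, fp, tn, fn, accuracy, sensitivity, specificity, auroc)


def loocv(
    matrix: RatioMatrix,
    manifest: SampleManifest,
    config: AnalysisConfig,
    leaky: bool = False,
) -> tuple[pd.DataFrame, MetricsReport, list[dict[str, Any]]]:
    """Leave-one-out cross-validation with in-fold feature selection.

    For each sample, ranking, top-k selection and classifier training are
    re-run on the remaining n-1 samples; the held-out sample is then scored
    by that fold's model. Returns (held-out predictions, metrics over them,
    per-fold log of the selected sites).

    ``leaky=True`` switches to the anti-pattern in which the signature is
    selected once on the full cohort before cross-validation; it exists only
    to quantify selection bias and must never be used for reporting.
    """
    sample_ids = matrix.sample_ids
    labels = manifest.labels_for(sample_ids)
    n = len(sample_ids)
    if n < 4:
        raise SignatureError(f"cross-validation needs >= 4 samples, got {n}")
    y = (labels == "responder").to_numpy()
    if y.sum() < 2 or (~y).sum() < 2:
        raise SignatureError(
            "cross-validation needs >= 2 samples per class "
            f"(got {int(y.sum())} responders, {int((~y).sum())} non-responders)"
        )

    preselected: list[str] | None = None
    if leaky:
        preselected = select_top_k(
            rank_features(matrix, manifest, config), config.signature_size_k
        )

    rows = []
    fold_log: list[dict[str, Any]] = []
    for i, held_out in enumerate(sample_ids):
        train_ids = [s for s in sample_ids if s != held_out]
        train_matrix = matrix.subset_samples(train_ids)
        if preselected is not None:
            sites = preselected
        else:
            sites = select_top_k(
                rank_features(train_matrix, manifest, config),
                config.signature_size_k,
            )
        model = train_classifier(train_matrix, manifest, config, sites)
        pred = predict(
            model,
            matrix.subset_samples([held_out]),
            decision_threshold=config.decision_threshold,
            manifest=manifest,
        )
        rows.append(pred)
        fold_log.append({"held_out": held_out, "sites": list(sites)})
    predictions = pd.concat(rows, ignore_index=True)
    report = compute_metrics(predictions)
    return predictions, report, fold_log
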