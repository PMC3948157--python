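"""Feature ranking, classifier training, prediction, LOOCV and metrics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosphosig import AnalysisConfig, SampleManifest
from phosphosig.signature import (
    SignatureError,
    compute_metrics,
    loocv,
    percent,
    predict,
    rank_features,
    select_top_k,
    train_classifier,
)

from conftest import make_manifest, make_matrix


@pytest.fixture
def planted_matrix():
    rng = np.random.default_rng(17)
    vals = rng.normal(size=(40, 12))
    vals[7, :6] += 4.0  # one site with a large responder shift
    return make_matrix(vals)


def test_rank_features_puts_planted_site_first(planted_matrix):
    manifest = make_manifest(planted_matrix.sample_ids, 6)
    ranked = rank_features(planted_matrix, manifest, AnalysisConfig())
    assert ranked[0] == planted_matrix.site_ids[7]


def test_rank_features_duplicate_rows_tiebreak_by_site_id():
    rng = np.random.default_rng(3)
    row = rng.normal(size=12)
    vals = np.vstack([row, rng.normal(size=(5, 12)), row])
    m = make_matrix(vals, site_ids=["B_dup", "C1", "C2", "C3", "C4", "C5", "A_dup"])
    ranked = rank_features(m, make_manifest(m.sample_ids, 6), AnalysisConfig())
    i, j = ranked.index("A_dup"), ranked.index("B_dup")
    assert j == i + 1  # adjacent, alphabetical


def test_rank_features_label_flip_invariant(planted_matrix):
    manifest = make_manifest(planted_matrix.sample_ids, 6)
    flipped = manifest.frame.copy()
    flipped["response"] = np.where(
        flipped["response"] == "responder", "nonresponder", "responder"
    )
    a = rank_features(planted_matrix, manifest, AnalysisConfig())
    b = rank_features(planted_matrix, SampleManifest(flipped), AnalysisConfig())
    assert a == b


def test_select_top_k():
    ranked = [f"S{i}" for i in range(10)]
    assert select_top_k(ranked, 5) == ranked[:5]
    assert select_top_k(ranked, 10) == ranked
    with pytest.raises(SignatureError):
        select_top_k(ranked, 11)


def test_separable_training_is_perfect():
    vals = np.zeros((5, 12))
    vals[:, :6] = 2.0
    vals[:, 6:] = -2.0
    m = make_matrix(vals)
    manifest = make_manifest(m.sample_ids, 6)
    model = train_classifier(m, manifest, AnalysisConfig(), m.site_ids)
    preds = predict(model, m, manifest=manifest)
    assert (preds["predicted_class"] == preds["true_label"]).all()
    assert (preds["probability_responder"][:6] > 0.5).all()


def test_label_flip_maps_probabilities_to_complement():
    rng = np.random.default_rng(5)
    m = make_matrix(rng.normal(size=(5, 12)))
    manifest = make_manifest(m.sample_ids, 6)
    flipped = manifest.frame.copy()
    flipped["response"] = np.where(
        flipped["response"] == "responder", "nonresponder", "responder"
    )
    m1 = train_classifier(m, manifest, AnalysisConfig(), m.site_ids)
    m2 = train_classifier(m, SampleManifest(flipped), AnalysisConfig(), m.site_ids)
    probe = make_matrix(rng.normal(size=(5, 9)), site_ids=m.site_ids)
    p1 = predict(m1, probe)["probability_responder"].to_numpy()
    p2 = predict(m2, probe)["probability_responder"].to_numpy()
    np.testing.assert_allclose(p1, 1.0 - p2, atol=1e-6)


def test_single_class_training_rejected():
    m = make_matrix(np.random.default_rng(0).normal(size=(3, 6)))
    with pytest.raises(SignatureError, match="both response classes"):
        train_classifier(m, make_manifest(m.sample_ids, 6), AnalysisConfig(),
                         m.site_ids)


def test_all_missing_sample_uses_imputation_constant():
    rng = np.random.default_rng(6)
    m = make_matrix(rng.normal(size=(4, 12)))
    manifest = make_manifest(m.sample_ids, 6)
    model = train_classifier(m, manifest, AnalysisConfig(), m.site_ids)
    probe_vals = np.full((4, 2), np.nan)
    probe_vals[:, 1] = model.imputation_constant
    probe = make_matrix(probe_vals, site_ids=m.site_ids)
    p = predict(model, probe)["probability_responder"]
    assert p.iloc[0] == p.iloc[1]


def test_predict_missing_signature_site_is_error():
    rng = np.random.default_rng(7)
    m = make_matrix(rng.normal(size=(4, 12)))
    manifest = make_manifest(m.sample_ids, 6)
    model = train_classifier(m, manifest, AnalysisConfig(), m.site_ids)
    probe = make_matrix(rng.normal(size=(3, 5)), site_ids=m.site_ids[:3])
    with pytest.raises(SignatureError, match=m.site_ids[3]):
        predict(model, probe)


def test_predict_deterministic(planted_matrix):
    manifest = make_manifest(planted_matrix.sample_ids, 6)
    model = train_classifier(
        planted_matrix, manifest, AnalysisConfig(), planted_matrix.site_ids[:5]
    )
    a = predict(model, planted_matrix)
    b = predict(model, planted_matrix)
    pd.testing.assert_frame_equal(a, b)


def test_loocv_selection_is_leak_free(planted_matrix):
    """Perturbing only the held-out sample's values never changes that
    fold's selected sites."""
    manifest = make_manifest(planted_matrix.sample_ids, 6)
    cfg = AnalysisConfig(signature_size_k=3)
    _, _, log_a = loocv(planted_matrix, manifest, cfg)
    perturbed = planted_matrix.values.copy()
    held = planted_matrix.sample_ids[0]
    perturbed[held] = perturbed[held] + 100.0
    _, _, log_b = loocv(make_matrix(perturbed.to_numpy(),
                                    site_ids=planted_matrix.site_ids,
                                    sample_ids=planted_matrix.sample_ids),
                        manifest, cfg)
    fold_a = next(f for f in log_a if f["held_out"] == held)
    fold_b = next(f for f in log_b if f["held_out"] == held)
    assert fold_a["sites"] == fold_b["sites"]


def test_loocv_accuracy_counts_held_out_errors():
    """11 of 12 held-out predictions correct reports accuracy 11/12."""
    rng = np.random.default_rng(30)
    vals = rng.normal(scale=0.3, size=(10, 12))
    vals[:3, :6] += 3.0  # strong signal: LOOCV should be near-perfect
    m = make_matrix(vals)
    manifest = make_manifest(m.sample_ids, 6)
    preds, report, _ = loocv(m, manifest, AnalysisConfig(signature_size_k=3))
    n_correct = int((preds["predicted_class"] == preds["true_label"]).sum())
    assert report.accuracy == n_correct / 12


def test_loocv_preconditions():
    m = make_matrix(np.random.default_rng(0).normal(size=(6, 3)))
    with pytest.raises(SignatureError, match=">= 4 samples"):
        loocv(m, make_manifest(m.sample_ids, 2), AnalysisConfig())
    m2 = make_matrix(np.random.default_rng(0).normal(size=(6, 6)))
    with pytest.raises(SignatureError, match="per class"):
        loocv(m2, make_manifest(m2.sample_ids, 1), AnalysisConfig())


def _preds(probs, truth, threshold=0.5):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(probs))],
            "probability_responder": probs,
            "predicted_class": np.where(
                np.asarray(probs) > threshold, "responder", "nonresponder"
            ),
            "true_label": truth,
        }
    )


def test_compute_metrics_printed_confusions():
    # 6 responders with 1 missed, 3 non-responders with 1 false call
    probs = [0.9, 0.8, 0.7, 0.9, 0.6, 0.2, 0.1, 0.7, 0.3]
    truth = ["responder"] * 6 + ["nonresponder"] * 3
    rep = compute_metrics(_preds(probs, truth))
    assert rep.sensitivity == pytest.approx(5 / 6)
    assert rep.specificity == pytest.approx(2 / 3)
    assert rep.accuracy == pytest.approx(7 / 9)
    assert (percent(rep.sensitivity), percent(rep.specificity),
            percent(rep.accuracy)) == (83, 67, 78)


def test_compute_metrics_edge_cases():
    rep = compute_metrics(_preds([0.9, 0.9, 0.1], ["responder"] * 2 + ["nonresponder"]))
    assert rep.accuracy == rep.sensitivity == rep.specificity == 1.0
    assert rep.auroc == 1.0
    tied = compute_metrics(
        _preds([0.4] * 6, ["responder"] * 3 + ["nonresponder"] * 3)
    )
    assert tied.auroc == 0.5  # mid-rank convention for constant scores
    one_class = compute_metrics(_preds([0.9, 0.8], ["responder"] * 2))
    assert one_class.auroc is None


@settings(deadline=None, max_examples=100)
@given(
    tp=st.integers(0, 20), fp=st.integers(0, 20),
    tn=st.integers(0, 20), fn=st.integers(0, 20),
)
def test_metric_identities_hold_for_any_confusion(tp, fp, tn, fn):
    if tp + fp + tn + fn == 0:
        return
    probs = [0.9] * tp + [0.9] * fp + [0.1] * tn + [0.1] * fn
    truth = (["responder"] * tp + ["nonresponder"] * fp
             + ["nonresponder"] * tn + ["responder"] * fn)
    rep = compute_metrics(_preds(probs, truth))
    assert (rep.tp, rep.fp, rep.tn, rep.fn) == (tp, fp, tn, fn)
    assert rep.accuracy == (tp + tn) / (tp + tn + fp + fn)
    if tp + fn:
        assert rep.sensitivity == tp / (tp + fn)
    if tn + fp:
        assert rep.specificity == tn / (tn + fp)


def test_threshold_consistency():
    probs = [0.49, 0.5, 0.51]
    truth = ["responder"] * 3
    df = _preds(probs, truth)
    # class flips only strictly above the threshold
    assert list(df["predicted_class"]) == [
        "nonresponder", "nonresponder", "responder"
    ]
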