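"""Metrics, model selection protocol, and bundle behaviour."""

import math

import numpy as np
import pandas as pd
import pytest

from hydrosom.models import (
    FAMILY_ORDER,
    ModelBundle,
    ModelError,
    compute_metrics,
    finalize,
    predict_sites,
    prepare_dataset,
    pretrain,
    select_top,
    tune,
)


def test_compute_metrics_reference_cases():
    perfect = compute_metrics(5, 5, 0, 0)
    assert (perfect.acc, perfect.recall, perfect.precision, perfect.mcc) == (1, 1, 1, 1)

    chance = compute_metrics(0, 5, 5, 0)
    assert chance.acc == 0.5 and chance.mcc == 0.0

    m = compute_metrics(2, 3, 1, 1)
    assert math.isclose(m.mcc, 5 / 12, rel_tol=1e-12)

    inverted = compute_metrics(0, 0, 5, 5)
    assert inverted.acc == 0.0 and inverted.mcc == -1.0

    degenerate = compute_metrics(0, 5, 0, 5)  # nothing ever called positive
    assert "mcc_undefined" in degenerate.flags and degenerate.mcc == 0.0
    assert "precision_undefined" in degenerate.flags


def test_compute_metrics_rejects_bad_counts():
    with pytest.raises(ModelError):
        compute_metrics(-1, 0, 0, 1)
    with pytest.raises(ModelError):
        compute_metrics(0, 0, 0, 0)


def test_select_top_separation_and_ties():
    clear = pd.DataFrame(
        {"family": list(FAMILY_ORDER), "cv_accuracy": [0.9] * 5 + [0.5] * 3}
    )
    assert set(select_top(clear, 5)) == set(FAMILY_ORDER[:5])

    tied = pd.DataFrame({"family": list(FAMILY_ORDER), "cv_accuracy": [0.8] * 8})
    assert select_top(tied, 5) == list(FAMILY_ORDER[:5])

    with pytest.raises(ModelError):
        select_top(tied.head(3), 5)


def test_pretrain_beats_majority_baseline(global_split):
    prep = prepare_dataset(global_split)
    baseline = max(prep.y_train.mean(), 1 - prep.y_train.mean())
    table = pretrain(prep, families=("dt", "lda"), folds=3, seed=7)
    assert (table["cv_accuracy"] > baseline).all()


def test_tune_is_seeded_and_contains_default(global_split):
    prep = prepare_dataset(global_split)
    t1 = tune("dt", prep, n_configs=4, folds=3, seed=11)
    t2 = tune("dt", prep, n_configs=4, folds=3, seed=11)
    assert t1.params == t2.params and t1.cv_accuracy == t2.cv_accuracy
    default_only = tune("dt", prep, n_configs=1, folds=3, seed=11)
    assert default_only.params == {}
    assert t1.cv_accuracy >= default_only.cv_accuracy


def test_finalize_winner_is_argmax(mini_train):
    metrics = mini_train.candidate_metrics
    winner_mcc = metrics.loc[metrics["family"] == mini_train.bundle.family, "MCC"].iloc[0]
    assert winner_mcc >= metrics["MCC"].max() - 1e-12


def test_finalize_single_candidate(global_split):
    prep = prepare_dataset(global_split)
    cand = tune("dt", prep, n_configs=1, folds=3, seed=7)
    bundle, table = finalize(prep, [cand], seed=7)
    assert bundle.family == "dt" and len(table) == 1


def test_predict_sites_probability_contract(mini_train, small_corpus):
    bundle = mini_train.bundle
    for rec in small_corpus.records[:20]:
        preds = predict_sites(bundle, rec.parent)
        assert preds
        for sp in preds:
            assert 0.0 <= sp.probability <= 1.0
            assert sp.is_site == (sp.probability >= sp.threshold)


def test_predict_sites_no_class_atoms(global_split):
    """An N-only bundle scores nothing on a nitrogen-free molecule."""
    prep = prepare_dataset(global_split)
    cand = tune("dt", prep, n_configs=1, folds=3, seed=7)
    bundle, _ = finalize(prep, [cand], seed=7)
    bundle.dataset_name = "N-Hydrolysis"  # restrict the served class
    assert predict_sites(bundle, "CCOC(C)=O") == []


def test_bundle_roundtrip_and_version_guard(tmp_path, mini_train, small_corpus):
    bundle = mini_train.bundle
    d = tmp_path / "bundle"
    bundle.save(d)
    back = ModelBundle.load(d)
    smi = small_corpus.records[0].parent
    p1 = [sp.probability for sp in predict_sites(bundle, smi)]
    p2 = [sp.probability for sp in predict_sites(back, smi)]
    np.testing.assert_allclose(p1, p2, atol=0)

    meta = (d / "metadata.json").read_text()
    (d / "metadata.json").write_text(meta.replace("rdkit-morgan", "other-dialect"))
    with pytest.raises(ModelError, match="feature version"):
        ModelBundle.load(d)


def test_test_rows_never_influence_fits(global_split):
    """Permuting held-out labels changes neither selector nor classifier."""
    import copy

    shuffled = copy.deepcopy(global_split)
    rng = np.random.default_rng(0)
    shuffled.test_rows["label"] = rng.permutation(shuffled.test_rows["label"].to_numpy())

    prep_a, prep_b = prepare_dataset(global_split), prepare_dataset(shuffled)
    assert np.array_equal(prep_a.selector.t_mask, prep_b.selector.t_mask)
    cand = tune("dt", prep_a, n_configs=1, folds=3, seed=3)
    ba, _ = finalize(prep_a, [cand], seed=3)
    bb, _ = finalize(prep_b, [cand], seed=3)
    assert np.array_equal(
        ba.classifier.predict(prep_a.X_test), bb.classifier.predict(prep_b.X_test)
    )
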