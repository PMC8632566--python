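"""Cross-validation protocol: cleaning, folds, standardisation, models."""

import numpy as np
import pandas as pd
import pytest

from voicestate import build_group_dataset, build_state_dataset
from voicestate.labeling import LabeledDataset
from voicestate.modeling import (
    CVConfig,
    apply_standardizer,
    clean_features,
    fit_rf,
    fit_standardizer,
    majority_vote_baseline,
    make_participant_folds,
    random_baseline,
    run_user_dependent,
    run_user_independent,
)
from voicestate.resampling import ResampleConfig
from conftest import brute_force_auc


def test_clean_features_drops_missing_rows_and_constant_columns():
    frame = pd.DataFrame(
        {
            "participant_id": list("AAAAB"),
            "timestamp": ["2019-01-01T10:00:00"] * 5,
            "f0001": [1.0, 2.0, np.nan, 4.0, 5.0],
            "f0002": [3.7] * 5,
            "f0003": [0.1, 0.2, 0.3, 0.4, 0.5],
        }
    )
    cleaned = clean_features(frame)
    assert len(cleaned) == 4
    assert "f0002" not in cleaned.columns
    assert list(cleaned.columns) == ["participant_id", "timestamp", "f0001", "f0003"]

    intact = frame.drop(columns="f0002").dropna()
    pd.testing.assert_frame_equal(clean_features(intact), intact.reset_index(drop=True))

    with pytest.raises(ValueError, match="every call entry"):
        clean_features(frame.assign(f0003=np.nan))


def test_participant_folds_partition_evenly_and_deterministically():
    ids = [f"P{i}" for i in range(10)]
    folds = make_participant_folds(ids, 5, fold_seed=3)
    test_sets = [set(te) for _, te in folds]
    assert all(len(s) == 2 for s in test_sets)
    assert set().union(*test_sets) == set(ids)
    for train, test in folds:
        assert not set(train) & set(test)
    again = make_participant_folds(ids, 5, fold_seed=3)
    for (tr1, te1), (tr2, te2) in zip(folds, again):
        np.testing.assert_array_equal(te1, te2)
    with pytest.raises(ValueError, match="folds"):
        make_participant_folds(ids[:3], 5, fold_seed=0)


def test_standardizer_uses_population_variance_and_train_only_params():
    std = fit_standardizer(np.array([[2.0], [4.0]]))
    np.testing.assert_allclose(std.transform(np.array([[2.0], [4.0]])), [[-1], [1]])
    np.testing.assert_allclose(std.transform(np.array([[5.0]])), [[2.0]])
    # already standardized -> identity
    rng = np.random.default_rng(0)
    X = rng.normal(size=(200, 3))
    X = (X - X.mean(0)) / X.std(0)
    np.testing.assert_allclose(fit_standardizer(X).transform(X), X, atol=1e-9)
    # constant column maps to zero
    const = fit_standardizer(np.full((5, 1), 7.0))
    np.testing.assert_allclose(const.transform(np.full((3, 1), 7.0)), 0.0)


def test_rf_separable_and_deterministic():
    rng = np.random.default_rng(1)
    X = np.vstack([rng.normal(-3, 0.3, (10, 2)), rng.normal(3, 0.3, (10, 2))])
    y = np.array([0] * 10 + [1] * 10)
    cfg = CVConfig(n_trees=25)
    clf = fit_rf(X, y, cfg, seed=0)
    assert (clf.predict_proba(X)[:, 1] >= 0.5).astype(int).tolist() == y.tolist()
    p1 = fit_rf(X, y, cfg, seed=5).predict_proba(X)
    p2 = fit_rf(X, y, cfg, seed=5).predict_proba(X)
    np.testing.assert_array_equal(p1, p2)


def test_rf_shuffled_labels_give_chance_auc():
    """Held-out AUC under label shuffling hovers at 0.5 (20 repetitions)."""
    rng = np.random.default_rng(7)
    aucs = []
    for _ in range(20):
        X = rng.normal(size=(120, 4))
        y = rng.integers(0, 2, 120)
        clf = fit_rf(X[:80], y[:80], CVConfig(n_trees=25), seed=0)
        scores = clf.predict_proba(X[80:])[:, 1]
        if len(np.unique(y[80:])) == 2:
            aucs.append(brute_force_auc(scores, y[80:]))
    assert abs(np.mean(aucs) - 0.5) < 0.06


def test_majority_vote_baseline_rules():
    labels, scores = majority_vote_baseline(np.array([1, 1, 0]), 4, seed=0)
    assert labels.tolist() == [1, 1, 1, 1]
    assert scores.tolist() == [1.0] * 4
    labels, _ = majority_vote_baseline(np.array([0, 0, 1]), 3, seed=0)
    assert labels.tolist() == [0, 0, 0]
    # exact tie: per-row random, reproducible given seed
    t1, _ = majority_vote_baseline(np.array([1, 0]), 50, seed=9)
    t2, _ = majority_vote_baseline(np.array([1, 0]), 50, seed=9)
    np.testing.assert_array_equal(t1, t2)
    assert 0 < t1.sum() < 50


def test_random_baseline_uniform_and_reproducible():
    labels, scores = random_baseline(4000, seed=3)
    np.testing.assert_array_equal(labels.astype(float), scores)
    assert abs(labels.mean() - 0.5) < 0.03
    again, _ = random_baseline(4000, seed=3)
    np.testing.assert_array_equal(labels, again)


@pytest.fixture(scope="module")
def strong_group_dataset():
    from voicestate import SyntheticConfig, generate_cohort

    cfg = SyntheticConfig(
        n_bd=20, n_ur=0, n_hc=20, days_per_participant=(8, 15),
        calls_per_day=1.5, n_features=16, group_effect=1.5,
        affected_fraction=0.5, fingerprint_sd=0.5, seed=1,
    )
    cohort = generate_cohort(cfg)
    return build_group_dataset(cohort.roster, clean_features(cohort.entries), "BD_vs_HC")


def test_user_independent_strong_effect_auc(strong_group_dataset):
    result = run_user_independent(
        strong_group_dataset, "rf", CVConfig(n_trees=50, with_b10=False)
    )
    assert result.mean_auc() > 0.9
    assert result.mode == "user_independent"
    assert len(result.fold_metrics) == 5


def test_user_independent_null_cohort_auc_near_half():
    from voicestate import SyntheticConfig, generate_cohort

    cfg = SyntheticConfig(
        n_bd=10, n_ur=0, n_hc=10, days_per_participant=(10, 14),
        calls_per_day=1.5, n_features=8, group_effect=0.0,
        state_effect=0.0, fingerprint_sd=0.0, seed=6,
    )
    cohort = generate_cohort(cfg)
    ds = build_group_dataset(cohort.roster, clean_features(cohort.entries), "BD_vs_HC")
    result = run_user_independent(ds, "rf", CVConfig(n_trees=30, with_b10=False))
    auc = result.summary["auc"]
    assert abs(auc.mean - 0.5) <= 2 * max(auc.sd, 0.05)


def test_no_participant_leakage_and_standardizer_purity(strong_group_dataset):
    """Train/test participant sets are disjoint in every fold, and the
    fitted standardisation parameters do not move when test-fold rows are
    perturbed (test statistics never enter the fit)."""
    cv = CVConfig(n_trees=5, with_b10=False, fold_seed=2)
    result = run_user_independent(strong_group_dataset, "rf", cv)
    pids = strong_group_dataset.participants
    for fold in result.folds:
        test_pids = set(pids[fold.test_index])
        train_pids = set(np.delete(pids, fold.test_index))
        assert test_pids.isdisjoint(train_pids)

    # perturb only the rows of fold 0's test participants, rerun
    perturbed = strong_group_dataset.frame.copy()
    mask = perturbed.index.isin(result.folds[0].test_index)
    fcols = strong_group_dataset.feature_names
    perturbed.loc[mask, fcols] = perturbed.loc[mask, fcols] * 10 + 100
    ds2 = LabeledDataset(perturbed, "BD_vs_HC", "BD")
    result2 = run_user_independent(ds2, "rf", cv)
    np.testing.assert_allclose(
        result.folds[0].standardizer.mean, result2.folds[0].standardizer.mean
    )
    np.testing.assert_allclose(
        result.folds[0].standardizer.scale, result2.folds[0].standardizer.scale
    )


def test_resampling_never_touches_test_rows(strong_group_dataset):
    """Every dataset row appears exactly once as a test row, with its
    original label (the test multiset is unchanged by rebalancing)."""
    result = run_user_independent(
        strong_group_dataset, "rf", CVConfig(n_trees=5, with_b10=False)
    )
    seen = np.concatenate([f.test_index for f in result.folds])
    assert sorted(seen) == list(range(len(strong_group_dataset)))
    for fold in result.folds:
        np.testing.assert_array_equal(
            fold.y_true, strong_group_dataset.y[fold.test_index]
        )


def test_row_level_folds_inflate_auc_on_fingerprint_cohort():
    """With zero group effect but strong vocal fingerprints, row-level
    (leaky) folds let the model learn identities and inflate the AUC,
    while participant-based folds stay near chance."""
    from voicestate import SyntheticConfig, generate_cohort

    cfg = SyntheticConfig(
        n_bd=6, n_ur=0, n_hc=6, days_per_participant=(15, 25),
        calls_per_day=1.5, n_features=12, group_effect=0.0,
        state_effect=0.0, fingerprint_sd=2.0, seed=13,
    )
    cohort = generate_cohort(cfg)
    ds = build_group_dataset(cohort.roster, clean_features(cohort.entries), "BD_vs_HC")
    cv = CVConfig(n_trees=30, with_b10=False)
    leaky = run_user_independent(ds, "rf", cv, fold_unit="row").mean_auc()
    honest = run_user_independent(ds, "rf", cv, fold_unit="participant").mean_auc()
    assert leaky > 0.8
    assert leaky > honest + 0.15


def test_user_dependent_eligibility_and_single_patient_identity(bd_state_cohort):
    ds = build_state_dataset(
        bd_state_cohort.reports,
        clean_features(bd_state_cohort.entries),
        "depression_vs_euthymia",
    )
    # keep one patient, drop everyone else -> summary equals that patient
    pid = ds.frame["participant_id"].iloc[0]
    solo = LabeledDataset(
        ds.frame[ds.frame["participant_id"] == pid].reset_index(drop=True),
        ds.contrast_name,
        ds.positive_class,
    )
    result = run_user_dependent(solo, "rf", CVConfig(n_trees=10, with_b10=False))
    assert len(result.per_patient) == 1
    assert result.summary["auc"].mean == pytest.approx(
        result.per_patient["auc"].iloc[0]
    )

    # a patient with only euthymia days is excluded
    all_euth = ds.frame[ds.frame["label"] == 0].copy()
    all_euth["participant_id"] = "ONLY_EUTH"
    mixed = LabeledDataset(
        pd.concat([solo.frame, all_euth], ignore_index=True),
        ds.contrast_name,
        ds.positive_class,
    )
    result2 = run_user_dependent(mixed, "rf", CVConfig(n_trees=10, with_b10=False))
    assert list(result2.per_patient["participant_id"]) == [pid]

    only_ineligible = LabeledDataset(
        all_euth.reset_index(drop=True), ds.contrast_name, ds.positive_class
    )
    with pytest.raises(ValueError, match="no patient eligible"):
        run_user_dependent(only_ineligible, "rf", CVConfig(with_b10=False))


def test_user_dependent_beats_user_independent_with_fingerprints(bd_state_cohort):
    """Personalised models recover within-person state shifts that the
    pooled model cannot see past strong between-person fingerprints."""
    ds = build_state_dataset(
        bd_state_cohort.reports,
        clean_features(bd_state_cohort.entries),
        "depression_vs_euthymia",
    )
    cv = CVConfig(n_trees=30, with_b10=False)
    dep = run_user_dependent(ds, "rf", cv).mean_auc()
    ind = run_user_independent(ds, "rf", cv).mean_auc()
    assert dep > ind
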