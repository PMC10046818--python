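"""Tests for Wilcoxon screening, splitting, SVM training, and ROC reporting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, rankdata

from hdmi.stats import (
    delong_ci,
    evaluate,
    run_models,
    select_features,
    split_cohort,
    train_svm,
    wilcoxon_rank_sum,
)
from hdmi.synthetic import BIOMARKER_COLUMNS, sample_cohort


def brute_force_rank_sum_p(x, y):
    """Independent exact two-sided p: enumerate every split of the pooled
    midranks and count rank sums at least as extreme as observed."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    nx, n = len(x), len(pooled)
    mu = nx * (n + 1) / 2
    obs = abs(ranks[:nx].sum() - mu)
    hits = total = 0
    for comb in itertools.combinations(range(n), nx):
        total += 1
        if abs(sum(ranks[i] for i in comb) - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


# ----------------------------------------------------------------- wilcoxon

def test_identical_samples_give_p_one():
    assert wilcoxon_rank_sum([1.0, 1.0], [1.0, 1.0]) == 1.0
    assert wilcoxon_rank_sum([1, 2, 3], [4.5, 5.5]) < 1.0


def test_two_by_two_exact_enumeration():
    assert wilcoxon_rank_sum([1, 2], [3, 4]) == pytest.approx(1 / 3, abs=1e-15)


@pytest.mark.parametrize("seed", range(4))
def test_auto_mode_matches_brute_force_on_small_samples(seed):
    rng = np.random.default_rng(seed)
    nx, ny = rng.integers(2, 5), rng.integers(2, 5)
    x = np.round(rng.normal(size=nx), 1)  # rounding induces ties
    y = np.round(rng.normal(0.5, size=ny), 1)
    assert wilcoxon_rank_sum(x, y, "auto") == pytest.approx(
        brute_force_rank_sum_p(x, y), abs=1e-12)


def test_normal_approximation_matches_scipy():
    rng = np.random.default_rng(1)
    for _ in range(5):
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.4, 1.3, 18)
        ours = wilcoxon_rank_sum(x, y, "normal_approx")
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert ours == pytest.approx(ref, rel=1e-10)


def test_wilcoxon_rejects_empty_and_bad_mode():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([1.0], [2.0], mode="bogus")


# ----------------------------------------------------------------- screening

def _noise_cohort(n_benign=57, n_malignant=35, seed=0, shifted=None, shift=5.0):
    rng = np.random.default_rng(seed)
    n = n_benign + n_malignant
    df = pd.DataFrame({c: rng.normal(0, 1, n) for c in BIOMARKER_COLUMNS})
    df.insert(0, "label", ["benign"] * n_benign + ["malignant"] * n_malignant)
    df.insert(0, "id", [f"n{i}" for i in range(n)])
    if shifted:
        df.loc[df.label == "malignant", shifted] += shift
    return df


def test_screen_selects_only_the_shifted_feature():
    hits = 0
    for seed in range(10):
        cohort = _noise_cohort(seed=seed, shifted="mvFD")
        selected, table = select_features(cohort)
        if selected == ["mvFD"]:
            hits += 1
        assert "mvFD" in selected
    assert hits >= 6  # other features false-positive at rate ~ 11*alpha


def test_alpha_one_selects_every_biomarker():
    cohort = _noise_cohort(seed=3)
    selected, _ = select_features(cohort, alpha=1.0)
    assert selected == BIOMARKER_COLUMNS


def test_screen_validates_class_structure():
    cohort = _noise_cohort()
    with pytest.raises(ValueError):
        select_features(cohort.assign(label="benign"))


# -------------------------------------------------------------------- split

def test_split_fractions_and_stratification():
    cohort = _noise_cohort(57, 35, seed=5)
    train, test = split_cohort(cohort, 0.7, seed=1)
    assert abs(len(train) - 64) <= 1
    assert abs((train.label == "benign").sum() - 40) <= 1
    assert abs((train.label == "malignant").sum() - 24) <= 1


def test_split_is_a_deterministic_partition():
    cohort = _noise_cohort(30, 20, seed=6)
    t1, e1 = split_cohort(cohort, seed=9)
    t2, e2 = split_cohort(cohort, seed=9)
    assert t1.equals(t2) and e1.equals(e2)
    assert set(t1.id) | set(e1.id) == set(cohort.id)
    assert not set(t1.id) & set(e1.id)


def test_split_rejects_degenerate_classes():
    cohort = _noise_cohort(30, 20, seed=0)
    with pytest.raises(ValueError):
        split_cohort(cohort[cohort.label == "benign"])


# --------------------------------------------------------------- train / eval

def _separable_cohort(n=80, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    df = pd.DataFrame({
        "id": [f"n{i}" for i in range(n)],
        "label": ["benign"] * half + ["malignant"] * (n - half),
        "f1": np.concatenate([rng.normal(-3, 0.3, half), rng.normal(3, 0.3, n - half)]),
        "f2": rng.normal(0, 1, n),
    })
    return df.sample(frac=1.0, random_state=0).reset_index(drop=True)


def test_separable_features_reach_perfect_performance():
    cohort = _separable_cohort()
    train, test = split_cohort(cohort, seed=0)
    model = train_svm(train, ["f1", "f2"], seed=0)
    assert model.cv_auc == pytest.approx(1.0)
    report = evaluate(model, test)
    assert report.auc == pytest.approx(1.0)
    assert report.accuracy == pytest.approx(1.0)
    assert report.sensitivity == 1.0 and report.specificity == 1.0


def test_shuffled_labels_give_null_cv_auc():
    rng = np.random.default_rng(4)
    cohort = _separable_cohort(seed=4)
    cohort["label"] = rng.permutation(cohort["label"].to_numpy())
    train, _ = split_cohort(cohort, seed=0)
    model = train_svm(train, ["f1", "f2"], seed=0)
    assert 0.35 <= model.cv_auc <= 0.65


def test_duplicated_rows_keep_same_hyperparameters():
    cohort = _separable_cohort(n=40, seed=2)
    train, _ = split_cohort(cohort, seed=0)
    doubled = pd.concat([train, train], ignore_index=True)
    m1 = train_svm(train, ["f1", "f2"], seed=0)
    m2 = train_svm(doubled, ["f1", "f2"], seed=0)
    assert m1.best_params["svm__C"] == m2.best_params["svm__C"]
    assert m1.best_params["svm__gamma"] == pytest.approx(
        m2.best_params["svm__gamma"], rel=1e-9)


def test_constant_feature_is_dropped_with_warning():
    cohort = _separable_cohort(n=40, seed=3)
    cohort["flat"] = 1.0
    train, _ = split_cohort(cohort, seed=0)
    with pytest.warns(UserWarning, match="constant"):
        model = train_svm(train, ["f1", "f2", "flat"], seed=0)
    assert model.features == ["f1", "f2"]
    assert model.dropped_features == ["flat"]


def test_evaluate_rejects_single_class_test_set():
    cohort = _separable_cohort(n=40, seed=5)
    train, test = split_cohort(cohort, seed=0)
    model = train_svm(train, ["f1"], seed=0)
    with pytest.raises(ValueError, match="single class"):
        evaluate(model, test[test.label == "benign"])


def test_optimal_cutoff_matches_exhaustive_scan():
    rng = np.random.default_rng(7)
    cohort = _separable_cohort(n=120, seed=7)
    cohort["f1"] += rng.normal(0, 3, len(cohort))  # overlap the classes
    train, test = split_cohort(cohort, seed=1)
    model = train_svm(train, ["f1", "f2"], seed=1)
    report = evaluate(model, test)
    y = (test.label == "malignant").astype(int).to_numpy()
    s = model.scores(test)
    best = min(
        (np.sqrt(((s >= t) & (y == 0)).sum() ** 2 / max((y == 0).sum(), 1) ** 2
                 + (1 - ((s >= t) & (y == 1)).sum() / max((y == 1).sum(), 1)) ** 2), t)
        for t in np.concatenate([[np.inf], np.sort(s)])
    )
    fpr_c = ((s >= report.cutoff) & (y == 0)).sum() / (y == 0).sum()
    tpr_c = ((s >= report.cutoff) & (y == 1)).sum() / (y == 1).sum()
    assert np.sqrt(fpr_c ** 2 + (1 - tpr_c) ** 2) == pytest.approx(best[0], abs=1e-12)


def test_auc_equals_sklearn_and_is_monotone_invariant():
    from sklearn.metrics import roc_auc_score
    rng = np.random.default_rng(8)
    y = rng.random(200) > 0.6
    s = rng.normal(size=200) + y * 0.8
    auc, (lo, hi) = delong_ci(y, s)
    assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)
    assert lo <= auc <= hi
    auc2, _ = delong_ci(y, np.exp(2.0 * s))  # strictly monotone transform
    assert auc2 == pytest.approx(auc, abs=1e-12)


def test_standardization_uses_train_statistics_only():
    cohort = _separable_cohort(n=60, seed=9)
    train, test = split_cohort(cohort, seed=2)
    model = train_svm(train, ["f1", "f2"], seed=2)
    scaler = model.pipeline.named_steps["scale"]
    x_train = train[model.features].to_numpy(float)
    np.testing.assert_allclose(scaler.mean_, x_train.mean(axis=0), rtol=1e-12)
    np.testing.assert_allclose(scaler.scale_, x_train.std(axis=0), rtol=1e-12)


# --------------------------------------------------------------- run_models

def test_clinical_column_equal_to_label_gives_perfect_auc():
    cohort = sample_cohort(40, 30, seed=0)
    cohort["age"] = (cohort.label == "malignant").astype(float)
    cohort["nodule_size"] = 1.0 + np.arange(len(cohort)) % 3
    cohort["tirads"] = 4
    _, rep = run_models(cohort, clinical=["age", "nodule_size", "tirads"], seed=0)
    assert rep.auc == pytest.approx(1.0)


def test_run_models_is_deterministic():
    cohort = sample_cohort(40, 30, seed=1, include_clinical=True)
    a1, b1 = run_models(cohort, clinical=["age", "nodule_size", "tirads"], seed=3)
    a2, b2 = run_models(cohort, clinical=["age", "nodule_size", "tirads"], seed=3)
    assert a1.to_json() == a2.to_json()
    assert b1.to_json() == b2.to_json()
    assert set(a1.train_ids) & set(a1.test_ids) == set()


def test_run_models_requires_clinical_columns():
    cohort = sample_cohort(20, 15, seed=2)
    with pytest.raises(ValueError, match="clinical"):
        run_models(cohort, clinical=["age"], seed=0)


def test_uninformative_clinical_columns_leave_auc_unchanged():
    """Adding pure-noise covariates moves the test AUC by < 0.05 (median)."""
    deltas = []
    for seed in range(5):
        cohort = sample_cohort(60, 40, seed=seed)
        rng = np.random.default_rng(seed)
        cohort["age"] = rng.normal(50, 10, len(cohort))
        cohort["nodule_size"] = rng.normal(20, 5, len(cohort))
        cohort["tirads"] = rng.integers(2, 6, len(cohort))
        base, withc = run_models(cohort, clinical=["age", "nodule_size", "tirads"],
                                 seed=seed)
        deltas.append(abs(base.auc - withc.auc))
    assert np.median(deltas) < 0.05


def test_train_split_screening_mode_runs():
    cohort = sample_cohort(40, 30, seed=4)
    rep, _ = run_models(cohort, seed=1, screen_on="train")
    assert 0.5 <= rep.auc <= 1.0
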