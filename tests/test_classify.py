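"""Feature construction, SMOTE, half-split SVM evaluation, trial averaging."""

import numpy as np
import pytest
from scipy.stats import binom

import conscidet as cd
from conscidet.classify import (FeatureSet, build_features, evaluate_contrast,
                                smote_oversample, trial_averaged_curve)

from conftest import make_epochs


def _clouds(n_per=40, dim=30, sep=10.0, seed=0, weights=None):
    """Two Gaussian clouds `sep` standard deviations apart."""
    rng = np.random.default_rng(seed)
    n_pos, n_neg = (n_per, n_per) if weights is None else weights
    Xp = rng.normal(size=(n_pos, dim))
    Xn = rng.normal(size=(n_neg, dim))
    Xp[:, 0] += sep
    X = np.vstack([Xp, Xn])
    y = np.concatenate([np.ones(n_pos), -np.ones(n_neg)]).astype(int)
    return FeatureSet(X, y, trial_ids=np.arange(len(y)), description="clouds")


def test_feature_vector_length_and_labels(conscious_epochs):
    fs = build_features(conscious_epochs, "stimulus", positive="deviant",
                        negative="standard", mode="active")
    n_scalp = len(conscious_epochs.scalp_names)
    assert n_scalp == 28
    assert fs.X.shape[1] == n_scalp * 100
    dev = conscious_epochs.mask(stimulus_type="deviant", mode="active").sum()
    assert (fs.y == 1).sum() == dev


def test_zero_epochs_give_zero_features():
    ep = make_epochs(np.zeros((4, 32, 301)))
    fs = build_features(ep, "stimulus", positive="deviant",
                       negative="deviant")
    assert np.abs(fs.X).max() == 0.0


def test_unknown_contrast_rejected(conscious_epochs):
    with pytest.raises(ValueError):
        build_features(conscious_epochs, "wavelength", "a", "b")


def test_smote_balances_exactly():
    fs = _clouds(weights=(50, 200), sep=3.0)
    out = smote_oversample(fs, k=5, seed=1)
    assert (out.y == 1).sum() == (out.y == -1).sum() == 200
    assert (out.trial_ids == -1).sum() == 150


def test_smote_noop_when_balanced():
    fs = _clouds()
    assert smote_oversample(fs, seed=1) is fs


def test_smote_two_point_minority_interpolates_on_segment():
    a, b = np.array([0.0, 0.0]), np.array([1.0, 2.0])
    X = np.vstack([a, b] + [np.random.default_rng(0).normal(size=2) + 10
                            for _ in range(8)])
    y = np.array([1, 1] + [-1] * 8)
    fs = FeatureSet(X, y, np.arange(10))
    out = smote_oversample(fs, k=1, seed=2)
    synth = out.X[out.trial_ids == -1]
    # every synthetic point is a + u(b - a) for u in [0, 1]
    u = synth[:, 1] / 2.0
    assert np.allclose(synth[:, 0] * 2.0, synth[:, 1])
    assert np.all((u >= 0) & (u <= 1))


def test_smote_stays_in_minority_bounding_box():
    fs = _clouds(weights=(20, 60), sep=4.0, seed=3)
    out = smote_oversample(fs, k=5, seed=3)
    minority = fs.X[fs.y == 1]
    synth = out.X[out.trial_ids == -1]
    lo, hi = minority.min(axis=0), minority.max(axis=0)
    assert np.all(synth >= lo - 1e-12) and np.all(synth <= hi + 1e-12)


def test_smote_small_minority_errors_and_warns():
    fs = _clouds(weights=(1, 10))
    with pytest.raises(ValueError):
        smote_oversample(fs, seed=0)
    fs = _clouds(weights=(3, 10))
    with pytest.warns(UserWarning, match="reducing"):
        smote_oversample(fs, k=5, seed=0)


def test_separable_clouds_classified_near_perfectly():
    res = evaluate_contrast(_clouds(sep=10.0, dim=10), n_repeats=10, seed=0)
    assert res.accuracy >= 0.95


def test_permuted_labels_within_binomial_band():
    """Pure-noise labels: mean accuracy stays inside the exact binomial
    95% interval around 0.5 for the test-set size."""
    rng = np.random.default_rng(4)
    fs = _clouds(sep=0.0, n_per=40, seed=4)
    fs = FeatureSet(fs.X, rng.permutation(fs.y), fs.trial_ids)
    res = evaluate_contrast(fs, n_repeats=10, seed=5)
    n = int(res.n_test)
    lo = binom.ppf(0.025, n, 0.5) / n
    hi = binom.ppf(0.975, n, 0.5) / n
    assert lo <= res.accuracy <= hi


def test_indistinguishable_classes_score_chance():
    """Two classes drawn from the same distribution are inseparable.

    (Literal duplication of one sample set into both classes is *not*
    used: a margin classifier then sees each test point's twin in
    training with the opposite label and scores systematically below
    0.5 by memorization, not separability.)"""
    rng = np.random.default_rng(5)
    X = rng.normal(size=(80, 20))
    y = np.concatenate([np.ones(40), -np.ones(40)]).astype(int)
    res = evaluate_contrast(FeatureSet(X, y, np.arange(80)), n_repeats=10,
                            seed=6)
    assert abs(res.accuracy - 0.5) < 0.12


def test_label_symmetry_swaps_sensitivity_and_specificity():
    """Swapping the class labels swaps sensitivity and specificity and
    leaves accuracy unchanged.  The half-split is exactly symmetric by
    construction; a small tolerance absorbs the SMO solver's numerical
    tie-breaking for samples sitting on the margin."""
    fs = _clouds(sep=1.5, seed=7)
    res = evaluate_contrast(fs, n_repeats=5, seed=8)
    flipped = FeatureSet(fs.X, -fs.y, fs.trial_ids)
    res_f = evaluate_contrast(flipped, n_repeats=5, seed=8)
    assert res.accuracy == pytest.approx(res_f.accuracy, abs=0.02)
    assert res.sensitivity == pytest.approx(res_f.specificity, abs=0.02)
    assert res.specificity == pytest.approx(res_f.sensitivity, abs=0.02)


def test_curve_level_one_equals_plain_evaluation():
    fs = _clouds(sep=2.0, seed=9)
    plain = evaluate_contrast(fs, n_repeats=5, seed=10)
    curve = trial_averaged_curve(fs, n_avg_levels=(1, 2), n_repeats=5, seed=10)
    level1 = next(r for r in curve if r.n_avg == 1)
    assert level1.accuracy == pytest.approx(plain.accuracy, abs=1e-12)
    assert level1.sensitivity == pytest.approx(plain.sensitivity, abs=1e-12)


def test_averaging_improves_noisy_signal_and_not_pure_noise():
    """Trial averaging shrinks test noise ∝ 1/n: accuracy rises (within
    2 SE) for a weak signal and stays flat for label noise."""
    signal = _clouds(sep=1.0, n_per=60, seed=11)
    curve = trial_averaged_curve(signal, n_repeats=10, seed=12)
    accs = {r.n_avg: r for r in curve}
    slack = 2 * max(r.accuracy_se for r in curve)
    assert accs[5].accuracy >= accs[1].accuracy - slack
    for a, b in zip(sorted(accs), sorted(accs)[1:]):
        assert accs[b].accuracy >= accs[a].accuracy - 2 * slack

    rng = np.random.default_rng(13)
    noise = _clouds(sep=0.0, n_per=60, seed=13)
    noise = FeatureSet(noise.X, rng.permutation(noise.y), noise.trial_ids)
    curve0 = trial_averaged_curve(noise, n_repeats=10, seed=14)
    accs0 = {r.n_avg: r.accuracy for r in curve0}
    se5 = next(r for r in curve0 if r.n_avg == 5).accuracy_se
    assert abs(accs0[5] - accs0[1]) <= max(4 * se5, 0.15)


def test_insufficient_test_trials_skips_level():
    fs = _clouds(n_per=6, sep=3.0, seed=15)
    with pytest.warns(UserWarning, match="skipped"):
        curve = trial_averaged_curve(fs, n_avg_levels=(1, 4), n_repeats=3,
                                     seed=16)
    assert [r.n_avg for r in curve] == [1]


def test_synthetic_samples_never_reach_test_sets():
    """SMOTE rows carry id −1 and the purity assertion inside evaluation
    guarantees they never cross into a test half."""
    fs = _clouds(weights=(12, 40), sep=2.0, seed=17)
    res = evaluate_contrast(fs, n_repeats=10, seed=18)   # asserts internally
    assert res.n_repeats == 10
    out = smote_oversample(fs, seed=19)
    assert set(out.trial_ids[len(fs.y):]) == {-1}


def test_mode_ordering_on_conscious_subject(conscious_epochs):
    """Active-mode stimulus discrimination beats breathing-mode
    discrimination on a conscious synthetic subject."""
    res = {}
    for mode in ("active", "breathing"):
        fs = build_features(conscious_epochs, "stimulus", positive="deviant",
                            negative="standard", mode=mode)
        res[mode] = evaluate_contrast(fs, n_repeats=10, seed=20)
    assert res["active"].accuracy > res["breathing"].accuracy
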