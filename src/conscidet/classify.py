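"""Single-trial EEG classification.

Feature vectors are the post-stimulus 0–1000 ms of every scalp channel,
downsampled to 100 Hz and concatenated.  A linear max-margin classifier
(SVM) is trained on a stratified random half of the samples — with the
minority class oversampled by SMOTE on the training half only — and
evaluated on the untouched other half; the half-split is repeated
(default 10×) and accuracy, sensitivity (+1 class) and specificity (−1
class) are averaged across repeats.  Trial-averaged test sets (means of
n disjoint same-class test trials, n = 1..5) quantify how averaging
raises the signal-to-noise ratio and with it the accuracy.

Label convention: deviant, correct-novel, and active-mode trials are +1;
standard, incorrect-novel, and other-mode trials are −1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import resample_poly
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import EpochSet

TARGET_RATE_HZ = 100.0
FEATURE_WINDOW_MS = (0.0, 1000.0)
C_GRID = (0.001, 0.1, 10.0)
POSITIVE = {"stimulus": ("deviant", "correct_novel"), "mode": ("active",)}


@dataclass
class FeatureSet:
    """Trials × (channels · timepoints) design matrix with ±1 labels."""

    X: np.ndarray
    y: np.ndarray                       # ±1
    trial_ids: np.ndarray               # row index into the source EpochSet;
                                        # −1 marks synthetic (SMOTE) samples
    description: str = ""
    n_channels: int = 0
    n_times: int = 0

    def __post_init__(self) -> None:
        if set(np.unique(self.y)) - {-1, 1}:
            raise ValueError("labels must be ±1")
        if len(self.X) != len(self.y) or len(self.y) != len(self.trial_ids):
            raise ValueError("X, y, trial_ids must align")


@dataclass
class ClassificationResult:
    accuracy: float
    sensitivity: float
    specificity: float
    accuracy_se: float
    sensitivity_se: float
    specificity_se: float
    n_repeats: int
    n_test: float                        # mean test-set size across repeats
    per_repeat: dict = field(default_factory=dict)
    description: str = ""
    n_avg: int = 1

    def __post_init__(self) -> None:
        for v in (self.accuracy, self.sensitivity, self.specificity):
            if not (0.0 <= v <= 1.0 + 1e-12):
                raise ValueError("metrics must lie in [0, 1]")


def _downsample(segment: np.ndarray, fs: float) -> np.ndarray:
    """Anti-aliased resampling of the trailing axis from fs to 100 Hz."""
    if fs == TARGET_RATE_HZ:
        return segment
    up, down = int(TARGET_RATE_HZ), int(round(fs))
    g = np.gcd(up, down)
    return resample_poly(segment, up // g, down // g, axis=-1)


def build_features(ep: EpochSet, contrast: str, positive: str, negative: str,
                   mode: str | None = None, stimulus_type: str | None = None,
                   channels=None) -> FeatureSet:
    """Assemble the design matrix for one contrast.

    ``contrast`` is ``"stimulus"`` (positive/negative are stimulus types,
    within the given ``mode``) or ``"mode"`` (positive/negative are task
    modes, within the given ``stimulus_type``).
    """
    if contrast not in ("stimulus", "mode"):
        raise ValueError(f"unknown contrast kind {contrast!r}")
    channels = tuple(channels) if channels is not None else ep.scalp_names
    ch_idx = ep.indices(channels)
    fs = ep.sampling_rate_hz
    t0, t1 = FEATURE_WINDOW_MS
    smask = (ep.times_ms >= t0 - 1e-9) & (ep.times_ms < t1 - 1e-9)

    if contrast == "stimulus":
        sel_pos = ep.mask(stimulus_type=positive, mode=mode)
        sel_neg = ep.mask(stimulus_type=negative, mode=mode)
        desc = f"{positive} vs {negative} ({mode or 'all modes'})"
    else:
        sel_pos = ep.mask(mode=positive, stimulus_type=stimulus_type)
        sel_neg = ep.mask(mode=negative, stimulus_type=stimulus_type)
        desc = f"{positive} vs {negative} ({stimulus_type or 'all stimuli'})"
    if not sel_pos.any() or not sel_neg.any():
        raise ValueError(f"contrast {desc}: a class has no trials")

    rows = np.nonzero(sel_pos | sel_neg)[0]
    seg = ep.data[np.ix_(rows, ch_idx, np.nonzero(smask)[0])]
    seg = _downsample(seg, fs)
    n_t = seg.shape[-1]
    X = seg.reshape(len(rows), -1)
    y = np.where(sel_pos[rows], 1, -1)
    return FeatureSet(X, y, trial_ids=rows, description=desc,
                      n_channels=len(channels), n_times=n_t)


def smote_oversample(fs: FeatureSet, k: int = 5,
                     seed: int | np.random.Generator = 0) -> FeatureSet:
    """Balance classes by synthetic-minority oversampling.

    Each synthetic sample is x_i + u · (x_nn − x_i) with x_i a random
    minority sample, x_nn one of its k nearest minority neighbours
    (Euclidean) and u ~ Uniform(0, 1); synthetic rows carry trial id −1.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_pos, n_neg = int((fs.y == 1).sum()), int((fs.y == -1).sum())
    if n_pos == n_neg:
        return fs
    minority = 1 if n_pos < n_neg else -1
    need = abs(n_pos - n_neg)
    Xm = fs.X[fs.y == minority]
    if len(Xm) < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")
    if len(Xm) <= k:
        warnings.warn(f"minority class has {len(Xm)} samples; reducing "
                      f"k from {k} to {len(Xm) - 1}")
        k = len(Xm) - 1
    d2 = ((Xm[:, None, :] - Xm[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1)[:, :k]

    base = rng.integers(0, len(Xm), size=need)
    pick = rng.integers(0, k, size=need)
    u = rng.uniform(0.0, 1.0, size=need)
    Xs = Xm[base] + u[:, None] * (Xm[nn[base, pick]] - Xm[base])
    X = np.vstack([fs.X, Xs])
    y = np.concatenate([fs.y, np.full(need, minority)])
    ids = np.concatenate([fs.trial_ids, np.full(need, -1)])
    return FeatureSet(X, y, ids, fs.description, fs.n_channels, fs.n_times)


def _make_svm(c: float):
    """Feature standardization + linear max-margin classifier.

    The dual (kernel) formulation is used because the problems here have
    far more features than samples; standardization is fit on training
    data only, inside the model object."""
    return make_pipeline(StandardScaler(), SVC(kernel="linear", C=c))


def _fit_linear_svm(X: np.ndarray, y: np.ndarray, seed: int):
    """Linear SVM with the regularization strength chosen by stratified
    cross-validation on the training data only (log grid)."""
    min_class = min(int((y == 1).sum()), int((y == -1).sum()))
    n_splits = min(5, min_class)
    best_c, best_score = 1.0, -np.inf
    if n_splits >= 2:
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        folds = list(cv.split(X, y))
        for c in C_GRID:
            scores = []
            for tr, va in folds:
                m = _make_svm(c)
                m.fit(X[tr], y[tr])
                scores.append(float((m.predict(X[va]) == y[va]).mean()))
            score = float(np.mean(scores))
            if score > best_score:
                best_c, best_score = c, score
    model = _make_svm(best_c)
    model.fit(X, y)
    return model


def _half_split(y: np.ndarray, rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random half split from one shared permutation.

    Using a single label-independent permutation makes the partition
    invariant under swapping the class labels, so sensitivity and
    specificity swap exactly while accuracy is unchanged."""
    order = rng.permutation(len(y))
    is_train = np.zeros(len(y), dtype=bool)
    for cls in (1, -1):
        members = order[y[order] == cls]
        is_train[members[:len(members) // 2]] = True
    tr = order[is_train[order]]
    te = order[~is_train[order]]
    if not all((y[part] == c).any() for part in (tr, te) for c in (1, -1)):
        raise ValueError("need at least 2 samples per class to half-split")
    return tr, te


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    acc = float((y_pred == y_true).mean())
    pos, neg = y_true == 1, y_true == -1
    sens = float((y_pred[pos] == 1).mean()) if pos.any() else np.nan
    spec = float((y_pred[neg] == -1).mean()) if neg.any() else np.nan
    return acc, sens, spec


def _repeat_seeds(seed: int, n_repeats: int) -> list[int]:
    """Per-repeat seeds derived from the master seed via SeedSequence."""
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(seed).spawn(n_repeats)]


def evaluate_contrast(fs: FeatureSet, n_repeats: int = 10, seed: int = 0,
                      smote_k: int = 5) -> ClassificationResult:
    """Repeated stratified half-split evaluation of one contrast.

    SMOTE is applied to the training half only whenever the classes are
    imbalanced; the test half is never altered.
    """
    res = _evaluate(fs, n_repeats=n_repeats, seed=seed, smote_k=smote_k,
                    n_avg_levels=(1,))
    return res[0]


def trial_averaged_curve(fs: FeatureSet, n_avg_levels=(1, 2, 3, 4, 5),
                         n_repeats: int = 10, seed: int = 0,
                         smote_k: int = 5) -> list[ClassificationResult]:
    """Accuracy as a function of the number of test trials averaged.

    Training is identical to ``evaluate_contrast``; at level n the test
    samples are means of n same-class test trials drawn without
    replacement into disjoint groups (leftover trials discarded).  Level 1
    is the plain repeated half-split result.
    """
    return _evaluate(fs, n_repeats=n_repeats, seed=seed, smote_k=smote_k,
                     n_avg_levels=tuple(n_avg_levels))


def _evaluate(fs: FeatureSet, n_repeats: int, seed: int, smote_k: int,
              n_avg_levels: tuple[int, ...]) -> list[ClassificationResult]:
    for cls in (1, -1):
        if (fs.y == cls).sum() < 2:
            raise ValueError("need at least 2 samples per class")
    seeds = _repeat_seeds(seed, n_repeats)
    per_level: dict[int, list[tuple[float, float, float, int]]] = \
        {n: [] for n in n_avg_levels}
    for rseed in seeds:
        rng = np.random.default_rng(rseed)
        tr, te = _half_split(fs.y, rng)
        train = FeatureSet(fs.X[tr], fs.y[tr], fs.trial_ids[tr],
                           fs.description, fs.n_channels, fs.n_times)
        if (train.y == 1).sum() != (train.y == -1).sum():
            train = smote_oversample(train, k=smote_k, seed=rng)
        assert not np.isin(fs.trial_ids[te], train.trial_ids[train.trial_ids >= 0]).any()
        model = _fit_linear_svm(train.X, train.y, seed=rseed)

        for n_avg in n_avg_levels:
            Xte, yte = _averaged_test_set(fs.X[te], fs.y[te], n_avg, rng)
            if Xte is None:
                warnings.warn(f"n_avg={n_avg}: too few test trials; level "
                              "skipped")
                continue
            acc, sens, spec = _metrics(yte, model.predict(Xte))
            per_level[n_avg].append((acc, sens, spec, len(yte)))

    out = []
    for n_avg in n_avg_levels:
        vals = per_level[n_avg]
        if not vals:
            continue
        arr = np.array([v[:3] for v in vals])
        se = arr.std(axis=0, ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 \
            else np.zeros(3)
        out.append(ClassificationResult(
            accuracy=float(arr[:, 0].mean()),
            sensitivity=float(arr[:, 1].mean()),
            specificity=float(arr[:, 2].mean()),
            accuracy_se=float(se[0]), sensitivity_se=float(se[1]),
            specificity_se=float(se[2]),
            n_repeats=len(vals),
            n_test=float(np.mean([v[3] for v in vals])),
            per_repeat={"accuracy": arr[:, 0].tolist(),
                        "sensitivity": arr[:, 1].tolist(),
                        "specificity": arr[:, 2].tolist()},
            description=fs.description, n_avg=n_avg))
    return out


def _averaged_test_set(X: np.ndarray, y: np.ndarray, n_avg: int,
                       rng: np.random.Generator):
    """Disjoint groups of n_avg same-class test trials, averaged."""
    if n_avg == 1:
        return X, y
    Xg, yg = [], []
    for cls in (1, -1):
        idx = rng.permutation(np.nonzero(y == cls)[0])
        n_groups = len(idx) // n_avg
        if n_groups == 0:
            return None, None
        for g in range(n_groups):
            Xg.append(X[idx[g * n_avg:(g + 1) * n_avg]].mean(axis=0))
            yg.append(cls)
    return np.array(Xg), np.array(yg)
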