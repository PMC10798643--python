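"""Time-resolved multivariate decoding with regularised LDA.

The classifier is a shrinkage linear discriminant: the pooled within-class
covariance S is regularised as S + reg * mean(diag(S)) * I before
inversion.  All time-resolved analyses use leave-one-sequence-out
cross-validation: folds are the presentation sequences, so train and test
events never share a sequence.  Accuracy is the pooled proportion of
correct test predictions across folds, per timepoint.

``RegularizedLDA`` is a scikit-learn compatible estimator; the
time-resolved drivers use an equivalent batched implementation that
factorises the per-timepoint linear algebra into one stacked solve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .simulate import EpochedDataset
from .stimuli import (
    N_LEVELS,
    ConjunctionContrast,
    build_stimulus_set,
    enumerate_conjunction_contrasts,
    select_interaction_subset,
    _check_feature,
)

DEFAULT_REG = 0.01


class RegularizedLDA(ClassifierMixin, BaseEstimator):
    """Multiclass linear discriminant with diagonal shrinkage.

    Parameters
    ----------
    reg : float, default 0.01
        Shrinkage strength: the pooled within-class covariance S is
        replaced by S + reg * mean(diag(S)) * I.

    Prediction is the argmax of the linear discriminant score
    x' S^-1 mu_k - mu_k' S^-1 mu_k / 2 + log pi_k; ties resolve to the
    lowest class index.
    """

    def __init__(self, reg: float = DEFAULT_REG):
        self.reg = reg

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        counts = np.bincount(y_idx)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        if counts.min() < 2:
            raise ValueError("every class needs at least 2 samples")
        n, p = X.shape
        k = len(self.classes_)
        self.priors_ = counts / n
        self.means_ = np.stack([X[y_idx == i].mean(axis=0) for i in range(k)])
        xc = X - self.means_[y_idx]
        cov = xc.T @ xc / (n - k)
        cov = cov + self.reg * np.mean(np.diag(cov)) * np.eye(p)
        self.covariance_ = cov
        self.coef_ = np.linalg.solve(cov, self.means_.T).T
        self.intercept_ = -0.5 * np.sum(self.means_ * self.coef_, axis=1) + np.log(
            self.priors_
        )
        return self

    def decision_function(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return X @ self.coef_.T + self.intercept_

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


@dataclass
class AccuracyTimecourse:
    """Cross-validated decoding accuracy per timepoint for one subject."""

    subject_id: str
    times: np.ndarray
    accuracy: np.ndarray
    chance: float
    label: str

    def __post_init__(self):
        if len(self.accuracy) != len(self.times):
            raise ValueError("accuracy and times must have equal length")

    def peak_time(self) -> float:
        """Time of maximum accuracy, post-stimulus; ties -> earliest."""
        post = self.times >= 0
        return float(self.times[post][np.argmax(self.accuracy[post])])


@dataclass
class GeneralisationMatrix:
    subject_id: str
    train_times: np.ndarray
    test_times: np.ndarray
    accuracy: np.ndarray  # (train, test)
    chance: float
    label: str


@dataclass
class SearchlightMap:
    subject_id: str
    times: np.ndarray
    accuracy: np.ndarray  # (channels, times)
    neighbourhood_size: int
    chance: float
    label: str


@dataclass
class InteractionResult:
    """Per-conditioning-level decoding of one feature."""

    decoded_feature: str
    conditioning_feature: str
    timecourses: list  # one AccuracyTimecourse per conditioning level
    peak_ms: float
    peak_window_means: np.ndarray  # (4,)


# ---------------------------------------------------------------------------
# batched CV kernel


def _fold_predictions(Xtr, ytr, Xte, reg):
    """Batched-over-time LDA predictions.

    Xtr: (n_train, channels, T); ytr: int labels; Xte: (n_test, channels, T).
    Returns predicted labels (n_test, T).  Identical maths to
    RegularizedLDA applied per timepoint.
    """
    classes, y_idx = np.unique(ytr, return_inverse=True)
    k = len(classes)
    n, c, T = Xtr.shape
    counts = np.bincount(y_idx, minlength=k).astype(Xtr.dtype)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 training samples per fold")
    onehot = np.zeros((k, n), dtype=Xtr.dtype)
    onehot[y_idx, np.arange(n)] = 1
    mu = (onehot @ Xtr.reshape(n, -1)).reshape(k, c, T) / counts[:, None, None]

    xc = (Xtr - mu[y_idx]).transpose(2, 0, 1)  # (T, n, c)
    S = xc.transpose(0, 2, 1) @ xc / (n - k)  # (T, c, c)
    mean_diag = np.einsum("tii->t", S) / c
    S = S + (reg * mean_diag)[:, None, None] * np.eye(c, dtype=S.dtype)

    W = np.linalg.solve(S, mu.transpose(2, 1, 0))  # (T, c, k)
    b = -0.5 * np.einsum("kct,tck->tk", mu, W) + np.log(counts / n)
    scores = Xte.transpose(2, 0, 1) @ W + b[:, None, :]  # (T, n_te, k)
    return classes[np.argmax(scores, axis=2)].T


def _cv_accuracy(data, labels, fold_ids, reg, sample_mask=None):
    """Leave-one-fold-out accuracy per timepoint (pooled over folds)."""
    if sample_mask is not None:
        data, labels, fold_ids = data[sample_mask], labels[sample_mask], fold_ids[sample_mask]
    T = data.shape[2]
    correct = np.zeros(T)
    total = 0
    for f in np.unique(fold_ids):
        te = fold_ids == f
        tr = ~te
        assert not np.any(te & tr)  # train/test never share events
        pred = _fold_predictions(data[tr], labels[tr], data[te], reg)
        correct += (pred == labels[te][:, None]).sum(axis=0)
        total += int(te.sum())
    return correct / total


def _select_times(dataset, times):
    if times is None:
        return np.arange(len(dataset.times)), dataset.times
    idx = np.flatnonzero(np.isin(dataset.times, np.asarray(times)))
    if len(idx) != len(np.asarray(times)):
        raise ValueError("requested times not all on the dataset's time grid")
    return idx, dataset.times[idx]


def _labels(dataset: EpochedDataset, feature: str) -> np.ndarray:
    _check_feature(feature)
    col = feature + "_level"
    if col not in dataset.events:
        raise ValueError(f"feature {feature!r} absent from event metadata")
    return dataset.events[col].to_numpy()


def _sequences(dataset: EpochedDataset) -> np.ndarray:
    seq = dataset.events["sequence"].to_numpy()
    if len(np.unique(seq)) < 2:
        raise ValueError("leave-one-sequence-out needs at least 2 sequences")
    return seq


# ---------------------------------------------------------------------------
# analyses


def decode_feature_timecourse(
    dataset: EpochedDataset, feature: str, reg: float = DEFAULT_REG, times=None
) -> AccuracyTimecourse:
    """4-class decoding of one feature, leave-one-sequence-out (chance 0.25)."""
    idx, sel_times = _select_times(dataset, times)
    acc = _cv_accuracy(dataset.data[:, :, idx], _labels(dataset, feature), _sequences(dataset), reg)
    return AccuracyTimecourse(
        subject_id=dataset.subject_id,
        times=sel_times,
        accuracy=acc,
        chance=1 / N_LEVELS,
        label=feature,
    )


def time_generalisation(
    dataset: EpochedDataset, feature: str, reg: float = DEFAULT_REG, times=None
) -> GeneralisationMatrix:
    """Train at each timepoint, test at all timepoints (same folds).

    The diagonal equals ``decode_feature_timecourse`` exactly: identical
    folds and classifier, only the test times differ.
    """
    idx, sel_times = _select_times(dataset, times)
    data = dataset.data[:, :, idx]
    labels = _labels(dataset, feature)
    seqs = _sequences(dataset)
    T = data.shape[2]
    correct = np.zeros((T, T))
    total = 0
    for f in np.unique(seqs):
        te = seqs == f
        Xtr, ytr, Xte = data[~te], labels[~te], data[te]
        classes, y_idx = np.unique(ytr, return_inverse=True)
        k = len(classes)
        n, c, _ = Xtr.shape
        counts = np.bincount(y_idx, minlength=k).astype(Xtr.dtype)
        onehot = np.zeros((k, n), dtype=Xtr.dtype)
        onehot[y_idx, np.arange(n)] = 1
        mu = (onehot @ Xtr.reshape(n, -1)).reshape(k, c, T) / counts[:, None, None]
        xc = (Xtr - mu[y_idx]).transpose(2, 0, 1)
        S = xc.transpose(0, 2, 1) @ xc / (n - k)
        mean_diag = np.einsum("tii->t", S) / c
        S = S + (reg * mean_diag)[:, None, None] * np.eye(c, dtype=S.dtype)
        W = np.linalg.solve(S, mu.transpose(2, 1, 0))  # (T_train, c, k)
        b = -0.5 * np.einsum("kct,tck->tk", mu, W) + np.log(counts / n)
        # scores: test event i at test time u under the model trained at t
        scores = np.einsum("icu,tck->iutk", Xte, W) + b[None, None]
        pred = classes[np.argmax(scores, axis=3)]  # (n_te, T_test, T_train)
        correct += (pred == labels[te][:, None, None]).sum(axis=0).T
        total += int(te.sum())
    return GeneralisationMatrix(
        subject_id=dataset.subject_id,
        train_times=sel_times,
        test_times=sel_times,
        accuracy=correct / total,
        chance=1 / N_LEVELS,
        label=feature,
    )


def searchlight_timecourse(
    dataset: EpochedDataset,
    feature: str,
    reg: float = DEFAULT_REG,
    n_neighbours: int = 4,
    times=None,
) -> SearchlightMap:
    """Channel-searchlight decoding: each centre + its nearest neighbours.

    Neighbourhoods use straight-line Euclidean distance between 3-D sensor
    positions; distance ties break on channel index (stable sort).
    """
    n_ch = dataset.n_channels
    if n_ch < n_neighbours + 1:
        raise ValueError(f"need at least {n_neighbours + 1} channels")
    idx, sel_times = _select_times(dataset, times)
    labels = _labels(dataset, feature)
    seqs = _sequences(dataset)
    pos = dataset.channel_positions
    dist = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
    acc = np.empty((n_ch, len(idx)))
    for ch in range(n_ch):
        hood = np.argsort(dist[ch], kind="stable")[: n_neighbours + 1]
        acc[ch] = _cv_accuracy(dataset.data[:, hood][:, :, idx], labels, seqs, reg)
    return SearchlightMap(
        subject_id=dataset.subject_id,
        times=sel_times,
        accuracy=acc,
        neighbourhood_size=n_neighbours + 1,
        chance=1 / N_LEVELS,
        label=feature,
    )


def interaction_decoding(
    dataset: EpochedDataset,
    decoded_feature: str,
    conditioning_feature: str,
    reg: float = DEFAULT_REG,
    peak_ms: float | None = None,
    peak_window_ms: float = 10.0,
    times=None,
) -> InteractionResult:
    """Decode one feature within each level of another (chance 0.25).

    The per-level timecourses are summarised by the mean accuracy in a
    20 ms window centred on the peak of the full-data decoding of the
    decoded feature (peak +/- 10 ms inclusive).  ``peak_ms`` can be given
    (e.g. a group-level peak); otherwise it is estimated from this dataset.
    """
    if decoded_feature == conditioning_feature:
        raise ValueError("decoded and conditioning features must differ")
    if peak_ms is None:
        peak_ms = decode_feature_timecourse(dataset, decoded_feature, reg, times).peak_time()
    idx, sel_times = _select_times(dataset, times)
    labels = _labels(dataset, decoded_feature)
    seqs = _sequences(dataset)
    cond = _labels(dataset, conditioning_feature)
    window = np.abs(sel_times - peak_ms) <= peak_window_ms
    tcs, means = [], []
    for level in range(N_LEVELS):
        mask = cond == level
        if not mask.any():
            raise ValueError(f"no events at {conditioning_feature} level {level}")
        acc = _cv_accuracy(dataset.data[:, :, idx], labels, seqs, reg, sample_mask=mask)
        tcs.append(
            AccuracyTimecourse(
                subject_id=dataset.subject_id,
                times=sel_times,
                accuracy=acc,
                chance=1 / N_LEVELS,
                label=f"{decoded_feature}|{conditioning_feature}={level}",
            )
        )
        means.append(acc[window].mean())
    return InteractionResult(
        decoded_feature=decoded_feature,
        conditioning_feature=conditioning_feature,
        timecourses=tcs,
        peak_ms=peak_ms,
        peak_window_means=np.array(means),
    )


def conjunction_decoding(
    dataset: EpochedDataset,
    feature_a: str,
    feature_b: str,
    reg: float = DEFAULT_REG,
    times=None,
    stimuli=None,
):
    """Two-class conjunction decoding, averaged over the 36 contrasts.

    Each contrast pits two diagonally-paired feature-level cells against
    the other two (32 stimuli per class, chance 0.5); no single feature
    separates the classes, so above-chance accuracy indicates a response
    to the feature *combination*.

    Returns (mean AccuracyTimecourse, per-contrast accuracy array (36, T),
    contrast list).
    """
    stimuli = stimuli if stimuli is not None else build_stimulus_set()
    contrasts = enumerate_conjunction_contrasts(feature_a, feature_b)
    idx, sel_times = _select_times(dataset, times)
    seqs = _sequences(dataset)
    sids = dataset.events["stimulus_id"].to_numpy()
    per_contrast = np.empty((len(contrasts), len(idx)))
    for i, contrast in enumerate(contrasts):
        ids1, ids2 = contrast.class_stimuli(stimuli)
        in1 = np.isin(sids, ids1)
        in2 = np.isin(sids, ids2)
        mask = in1 | in2
        labels = in2.astype(int)  # 0 = class1, 1 = class2
        per_contrast[i] = _cv_accuracy(
            dataset.data[:, :, idx], labels, seqs, reg, sample_mask=mask
        )
    mean_tc = AccuracyTimecourse(
        subject_id=dataset.subject_id,
        times=sel_times,
        accuracy=per_contrast.mean(axis=0),
        chance=0.5,
        label=f"conjunction:{feature_a}x{feature_b}",
    )
    return mean_tc, per_contrast, contrasts


def pairwise_rdm_decoding(
    dataset: EpochedDataset,
    stimulus_ids=None,
    reg: float = DEFAULT_REG,
    times=None,
):
    """Pairwise stimulus decoding for neural RDMs.

    For every stimulus pair, 2-class leave-one-sequence-out accuracy
    (chance 0.5) is stored symmetrically; the diagonal is 0.  Returns
    (rdm_stack (T, n, n), stimulus_ids, times).  ``stimulus_ids`` may
    subset the stimuli for reduced-scale runs.
    """
    sids = dataset.events["stimulus_id"].to_numpy()
    if stimulus_ids is None:
        stimulus_ids = np.unique(sids)
    else:
        stimulus_ids = np.asarray(stimulus_ids)
        missing = np.setdiff1d(stimulus_ids, sids)
        if len(missing):
            raise ValueError(f"stimuli with no events: {missing.tolist()}")
    idx, sel_times = _select_times(dataset, times)
    seqs = _sequences(dataset)
    n = len(stimulus_ids)
    rdm = np.zeros((len(idx), n, n))
    for i in range(n):
        for j in range(i):
            mask = np.isin(sids, (stimulus_ids[i], stimulus_ids[j]))
            labels = (sids == stimulus_ids[i]).astype(int)
            acc = _cv_accuracy(dataset.data[:, :, idx], labels, seqs, reg, sample_mask=mask)
            rdm[:, i, j] = rdm[:, j, i] = acc
    return rdm, stimulus_ids, sel_times
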