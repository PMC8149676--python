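"""Category decoding: localizer cross-validation, wake→sleep temporal
generalization, surrogate nulls, and a channel-space searchlight.

The pipeline mirrors a standard MVPA recipe for event-locked EEG:

1. baseline-correct each trial over the whole epoch,
2. z-score across trials per channel × time point,
3. PCA on the pooled wake+sleep data, keep the first 30 components,
4. smooth with a 150-ms running average,
5. shrinkage-regularized LDA, scored with AUC.

Estimators follow the scikit-learn protocol (``fit`` plus trailing-underscore
attributes) and operate on 3-D arrays shaped (events, features, times), like
:mod:`mne.decoding`. Thin functions accepting :class:`~sleepreplay.core.EpochSet`
wrap them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.stats
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .core import EpochSet

logger = logging.getLogger(__name__)


@dataclass
class PreprocSpec:
    """Preprocessing configuration for the decoding pipeline."""

    zscore_mode: str = "per-timepoint-across-trials"
    baseline_window: tuple[float, float] | None = None  # None = whole trial
    n_components: int = 30
    smooth_window: float = 0.150  # seconds


@dataclass
class DecodingMap:
    """Train-time × test-time AUC matrix with its surrogate baseline."""

    auc: np.ndarray  # (n_train_times, n_test_times)
    surrogate_auc: np.ndarray | None
    train_times: np.ndarray
    test_times: np.ndarray
    n_shuffles: int = 0

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez_compressed(
            path,
            auc=self.auc,
            surrogate_auc=np.empty(0) if self.surrogate_auc is None else self.surrogate_auc,
            train_times=self.train_times,
            test_times=self.test_times,
        )
        path.with_suffix(".json").write_text(
            json.dumps({"n_shuffles": self.n_shuffles, "has_surrogate": self.surrogate_auc is not None})
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "DecodingMap":
        path = Path(path)
        if not path.suffix:
            path = path.with_suffix(".npz")
        meta = json.loads(path.with_suffix(".json").read_text())
        with np.load(path) as z:
            return cls(
                auc=z["auc"],
                surrogate_auc=z["surrogate_auc"] if meta["has_surrogate"] else None,
                train_times=z["train_times"],
                test_times=z["test_times"],
                n_shuffles=meta["n_shuffles"],
            )


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def rank_auc(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """AUC from decision scores via the rank-sum identity, vectorized.

    ``scores`` has events on the last axis; ``y`` is binary (the positive
    class is ``max(y)``). Ties receive average ranks, so tied scores count
    one half, matching the trapezoidal ROC area.
    """
    y = np.asarray(y)
    pos = y == y.max()
    n1 = int(pos.sum())
    n0 = y.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = scipy.stats.rankdata(scores, axis=-1, method="average")
    return (ranks[..., pos].sum(axis=-1) - n1 * (n1 + 1) / 2) / (n0 * n1)


def make_lda(shrinkage: float = 0.01) -> LinearDiscriminantAnalysis:
    """The default classifier: LDA with a small identity shrinkage."""
    return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)


def lda_weights_multi(
    X: np.ndarray, y: np.ndarray, shrinkage: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Shrinkage-LDA weights fitted independently at every time point.

    Vectorized equivalent of fitting ``make_lda()`` per time point on
    ``X[:, :, t]``: the pooled within-class covariance (class-prior weighted,
    biased) is shrunk toward ``trace/p`` times the identity and inverted
    against the class-mean difference. Returns ``W`` (n_times, n_features)
    and intercepts ``b`` (n_times,) such that the decision score for a trial
    ``x_t`` is ``W[t] @ x_t + b[t]`` (positive = second class in sort order).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two classes are required")
    sel1 = y == classes[1]
    X0, X1 = X[~sel1], X[sel1]
    m0, m1 = X0.mean(axis=0), X1.mean(axis=0)  # (f, T)
    n = X.shape[0]
    C0 = X0 - m0
    C1 = X1 - m1
    # pooled biased covariance per time point: (T, f, f)
    S = (np.einsum("nft,ngt->tfg", C0, C0) + np.einsum("nft,ngt->tfg", C1, C1)) / n
    p = S.shape[1]
    tr = np.trace(S, axis1=1, axis2=2) / p
    S = (1.0 - shrinkage) * S
    idx = np.arange(p)
    S[:, idx, idx] += shrinkage * tr[:, None]
    W = np.linalg.solve(S, (m1 - m0).T[:, :, None])[:, :, 0]  # (T, f)
    b = -np.einsum("tf,tf->t", W, ((m0 + m1) / 2).T)
    return W, b


# ---------------------------------------------------------------------------
# Transformers
# ---------------------------------------------------------------------------

class EpochZScorer(TransformerMixin, BaseEstimator):
    """Z-score each feature × time point across trials (sample SD).

    Features with zero variance are mapped to 0 (and counted in
    ``n_zero_variance_``).
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X: np.ndarray, y=None) -> "EpochZScorer":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("z-scoring requires at least 2 trials")
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0, ddof=self.ddof)
        self.n_zero_variance_ = int((self.std_ == 0).sum())
        if self.n_zero_variance_:
            logger.warning(
                "%d zero-variance features set to 0 during z-scoring",
                self.n_zero_variance_,
            )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        std = np.where(self.std_ == 0, np.inf, self.std_)
        return (X - self.mean_) / std


class BaselineCorrector(TransformerMixin, BaseEstimator):
    """Subtract, per trial × feature, the mean over a time window.

    ``window=None`` uses the whole trial. ``times`` must match the input's
    last axis.
    """

    def __init__(self, times: np.ndarray | None = None, window: tuple[float, float] | None = None):
        self.times = times
        self.window = window

    def fit(self, X: np.ndarray, y=None) -> "BaselineCorrector":
        n_times = np.asarray(X).shape[-1]
        if self.window is None:
            self.mask_ = np.ones(n_times, dtype=bool)
        else:
            if self.times is None:
                raise ValueError("a times vector is required with an explicit window")
            times = np.asarray(self.times)
            self.mask_ = (times >= self.window[0]) & (times <= self.window[1])
            if not self.mask_.any():
                raise ValueError("baseline window outside the epoch")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X - X[..., self.mask_].mean(axis=-1, keepdims=True)


class PooledPCA(TransformerMixin, BaseEstimator):
    """PCA fitted on channel-space samples pooled over several epoch sets.

    Every (trial, time) sample of every set contributes one observation of
    the channel vector. ``transform`` maps (events, channels, times) arrays
    to component space; ``inverse_transform`` back-projects to sensors.
    """

    def __init__(self, n_components: int = 30):
        self.n_components = n_components

    @staticmethod
    def _pool(Xs) -> np.ndarray:
        mats = []
        for X in Xs:
            X = np.asarray(X, dtype=float)
            mats.append(np.moveaxis(X, 1, 2).reshape(-1, X.shape[1]))
        return np.vstack(mats)

    def fit(self, Xs, y=None) -> "PooledPCA":
        if isinstance(Xs, np.ndarray) and Xs.ndim == 3:
            Xs = [Xs]
        pooled = self._pool(Xs)
        if self.n_components > min(pooled.shape):
            raise ValueError(
                f"n_components={self.n_components} exceeds pooled data rank bound "
                f"{min(pooled.shape)}"
            )
        self.pca_ = PCA(n_components=self.n_components, svd_solver="covariance_eigh")
        self.pca_.fit(pooled)
        self.components_ = self.pca_.components_
        self.explained_variance_ratio_ = self.pca_.explained_variance_ratio_
        logger.info(
            "pooled PCA: %d components explain %.1f%% variance",
            self.n_components,
            100 * self.explained_variance_ratio_.sum(),
        )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n_ev, n_ch, n_t = X.shape
        flat = np.moveaxis(X, 1, 2).reshape(-1, n_ch)
        comp = self.pca_.transform(flat).reshape(n_ev, n_t, self.n_components)
        return np.moveaxis(comp, 1, 2)

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n_ev, k, n_t = X.shape
        flat = np.moveaxis(X, 1, 2).reshape(-1, k)
        sens = self.pca_.inverse_transform(flat).reshape(n_ev, n_t, -1)
        return np.moveaxis(sens, 1, 2)


class RunningAverageSmoother(TransformerMixin, BaseEstimator):
    """Centred running average along time; edge windows shrink symmetrically.

    The window covers ``round(width * sfreq)`` samples, forced odd so the
    window is centred (150 ms at 200 Hz → 31 samples).
    """

    def __init__(self, width: float = 0.150, sfreq: float | None = None):
        self.width = width
        self.sfreq = sfreq

    def fit(self, X: np.ndarray, y=None) -> "RunningAverageSmoother":
        if self.sfreq is None:
            raise ValueError("sfreq is required")
        n = int(round(self.width * self.sfreq))
        if n % 2 == 0:
            n += 1
        self.n_samples_ = max(n, 1)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n = self.n_samples_
        if n == 1:
            return X.copy()
        # running sums via cumulative sums: fast along the last axis
        c = np.cumsum(
            np.concatenate([np.zeros(X.shape[:-1] + (1,)), X], axis=-1), axis=-1
        )
        h = n // 2
        idx_hi = np.minimum(np.arange(X.shape[-1]) + h + 1, X.shape[-1])
        idx_lo = np.maximum(np.arange(X.shape[-1]) - h, 0)
        return (c[..., idx_hi] - c[..., idx_lo]) / (idx_hi - idx_lo)


# ---------------------------------------------------------------------------
# EpochSet-level wrappers (the pipeline surface)
# ---------------------------------------------------------------------------

def zscore_epochs(epochs: EpochSet) -> EpochSet:
    """Z-score across trials per channel × time point (sample SD)."""
    out = epochs.copy()
    out.data = EpochZScorer().fit(epochs.data).transform(epochs.data)
    return out


def baseline_correct(epochs: EpochSet, window: tuple[float, float] | None = None) -> EpochSet:
    """Subtract the per-trial mean over ``window`` (whole trial by default)."""
    out = epochs.copy()
    bc = BaselineCorrector(times=epochs.times, window=window).fit(epochs.data)
    out.data = bc.transform(epochs.data)
    return out


def smooth_running_average(epochs: EpochSet, width: float = 0.150) -> EpochSet:
    out = epochs.copy()
    sm = RunningAverageSmoother(width=width, sfreq=epochs.sfreq).fit(epochs.data)
    out.data = sm.transform(epochs.data)
    return out


def fit_pca_pooled(
    wake: EpochSet, sleep: EpochSet, n_components: int = 30
) -> tuple[PooledPCA, EpochSet, EpochSet]:
    """Fit PCA on pooled wake+sleep samples; project both sets to components."""
    if wake.n_channels != sleep.n_channels:
        raise ValueError("wake and sleep sets must share the channel space")
    pca = PooledPCA(n_components=n_components).fit([wake.data, sleep.data])
    names = [f"PC{i + 1}" for i in range(n_components)]
    wake_t, sleep_t = wake.copy(), sleep.copy()
    wake_t.data, wake_t.channel_names = pca.transform(wake.data), names
    sleep_t.data, sleep_t.channel_names = pca.transform(sleep.data), list(names)
    wake_t.channel_positions = sleep_t.channel_positions = None
    return pca, wake_t, sleep_t


def preprocess_for_decoding(
    wake: EpochSet, sleep: EpochSet, spec: PreprocSpec | None = None
) -> tuple[EpochSet, EpochSet, PooledPCA, list[str]]:
    """Full preprocessing chain; returns both sets, the projector and a log.

    Order: baseline → z-score (each set across its own trials) → pooled PCA →
    150-ms smoothing (in component space).
    """
    spec = spec or PreprocSpec()
    log: list[str] = []
    wake = baseline_correct(wake, spec.baseline_window)
    sleep = baseline_correct(sleep, spec.baseline_window)
    log.append("baseline: whole-trial" if spec.baseline_window is None else f"baseline: {spec.baseline_window}")
    wake, sleep = zscore_epochs(wake), zscore_epochs(sleep)
    log.append("z-score: per time point across trials")
    pca, wake, sleep = fit_pca_pooled(wake, sleep, spec.n_components)
    log.append(f"PCA: pooled wake+sleep, {spec.n_components} components")
    wake = smooth_running_average(wake, spec.smooth_window)
    sleep = smooth_running_average(sleep, spec.smooth_window)
    log.append(f"smooth: running average {spec.smooth_window * 1000:.0f} ms")
    return wake, sleep, pca, log


# ---------------------------------------------------------------------------
# Decoders
# ---------------------------------------------------------------------------

class TimeResolvedDecoder(BaseEstimator):
    """Cross-validated per-time-point classification of one epoch set.

    ``fit(X, y)`` runs stratified fivefold cross-validation, repeated
    ``n_repeats`` times with re-randomized folds, training one classifier per
    time point; ``auc_`` holds the fold/repeat-averaged AUC per time point.
    ``surrogate_auc_`` averages ``n_shuffles`` runs in which the *training*
    labels are permuted and the test labels left intact.
    """

    def __init__(
        self,
        clf: BaseEstimator | None = None,
        n_folds: int = 5,
        n_repeats: int = 5,
        n_shuffles: int = 250,
        time_step: int = 1,
        random_state: int | None = None,
    ):
        self.clf = clf
        self.n_folds = n_folds
        self.n_repeats = n_repeats
        self.n_shuffles = n_shuffles
        self.time_step = time_step
        self.random_state = random_state

    def _splits(self, y: np.ndarray, seed: int):
        skf = StratifiedKFold(self.n_folds, shuffle=True, random_state=seed)
        return list(skf.split(np.zeros(y.size), y))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TimeResolvedDecoder":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.unique(y).size != 2:
            raise ValueError("exactly two classes are required")
        rng = np.random.default_rng(self.random_state)
        t_idx = np.arange(0, X.shape[-1], self.time_step)
        self.time_indices_ = t_idx
        Xs = X[:, :, t_idx]

        def run(labels_train_fn, splits) -> np.ndarray:
            auc = np.zeros(t_idx.size)
            for tr, te in splits:
                y_tr = labels_train_fn(y[tr])
                if np.unique(y_tr).size < 2 or np.unique(y[te]).size < 2:
                    raise ValueError("a class is absent from a fold")
                if self.clf is None:
                    W, b = lda_weights_multi(Xs[tr], y_tr)
                    scores = np.einsum("tf,eft->te", W, Xs[te]) + b[:, None]
                    auc += rank_auc(scores, y[te])
                else:
                    for k, ti in enumerate(t_idx):
                        clf = clone(self.clf).fit(X[tr, :, ti], y_tr)
                        auc[k] += rank_auc(clf.decision_function(X[te, :, ti]), y[te])
            return auc / len(splits)

        aucs = [
            run(lambda lab: lab, self._splits(y, int(rng.integers(2**31))))
            for _ in range(self.n_repeats)
        ]
        self.auc_ = np.mean(aucs, axis=0)

        if self.n_shuffles:
            surr = np.zeros(t_idx.size)
            for _ in range(self.n_shuffles):
                splits = self._splits(y, int(rng.integers(2**31)))
                surr += run(lambda lab: rng.permutation(lab), splits)
            self.surrogate_auc_ = surr / self.n_shuffles
        else:
            self.surrogate_auc_ = None
        return self


class TemporalGeneralizationDecoder(BaseEstimator):
    """Train per localizer time point, test on every sleep time point.

    ``fit(X, y)`` fits one classifier per (subsampled) training time point;
    ``score_map(X_test, y_test)`` returns the train×test AUC matrix. No
    cross-validation is involved: training and test sets are independent
    recordings. ``surrogate_map`` refits with permuted training labels
    ``n_shuffles`` times and averages the resulting maps.
    """

    def __init__(
        self,
        clf: BaseEstimator | None = None,
        n_shuffles: int = 250,
        train_step: int = 1,
        test_step: int = 1,
        random_state: int | None = None,
    ):
        self.clf = clf
        self.n_shuffles = n_shuffles
        self.train_step = train_step
        self.test_step = test_step
        self.random_state = random_state

    def _fit_weights(self, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t_idx = np.arange(0, X.shape[-1], self.train_step)
        if self.clf is None:
            return lda_weights_multi(X[:, :, t_idx], y)
        W = np.empty((t_idx.size, X.shape[1]))
        b = np.empty(t_idx.size)
        for k, ti in enumerate(t_idx):
            clf = clone(self.clf).fit(X[:, :, ti], y)
            W[k] = clf.coef_.ravel()
            b[k] = float(np.ravel(clf.intercept_)[0])
        return W, b

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TemporalGeneralizationDecoder":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.unique(y).size != 2:
            raise ValueError("exactly two classes are required")
        self.train_X_, self.train_y_ = X, y
        self.train_time_indices_ = np.arange(0, X.shape[-1], self.train_step)
        self.W_, self.b_ = self._fit_weights(X, y)
        return self

    def _map_from_weights(
        self, W: np.ndarray, b: np.ndarray, X_test: np.ndarray, y_test: np.ndarray
    ) -> np.ndarray:
        te_idx = np.arange(0, X_test.shape[-1], self.test_step)
        # scores: (n_train, n_events, n_test)
        scores = np.einsum("tf,efs->tes", W, X_test[:, :, te_idx]) + b[:, None, None]
        return rank_auc(np.moveaxis(scores, 1, 2), y_test)

    def score_map(self, X_test: np.ndarray, y_test: np.ndarray) -> np.ndarray:
        X_test = np.asarray(X_test, dtype=float)
        if X_test.shape[1] != self.train_X_.shape[1]:
            raise ValueError(
                "feature-space mismatch between training and test epochs "
                f"({self.train_X_.shape[1]} vs {X_test.shape[1]})"
            )
        self.test_time_indices_ = np.arange(0, X_test.shape[-1], self.test_step)
        return self._map_from_weights(self.W_, self.b_, X_test, np.asarray(y_test))

    def surrogate_map(self, X_test: np.ndarray, y_test: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng(self.random_state)
        acc = np.zeros(
            (self.train_time_indices_.size, np.arange(0, X_test.shape[-1], self.test_step).size)
        )
        for _ in range(self.n_shuffles):
            W, b = self._fit_weights(self.train_X_, rng.permutation(self.train_y_))
            acc += self._map_from_weights(W, b, np.asarray(X_test), np.asarray(y_test))
        return acc / self.n_shuffles


def cv_decode_timecourse(
    localizer: EpochSet,
    labels: np.ndarray | None = None,
    n_folds: int = 5,
    n_repeats: int = 5,
    n_shuffles: int = 250,
    time_step: int = 1,
    random_state: int | None = None,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Cross-validated AUC time course on localizer epochs.

    Returns ``(auc, surrogate_auc, times)`` on the (possibly subsampled)
    time grid.
    """
    y = localizer.labels if labels is None else np.asarray(labels)
    if y is None:
        raise ValueError("labels are required")
    dec = TimeResolvedDecoder(
        n_folds=n_folds,
        n_repeats=n_repeats,
        n_shuffles=n_shuffles,
        time_step=time_step,
        random_state=random_state,
    ).fit(localizer.data, y)
    return dec.auc_, dec.surrogate_auc_, localizer.times[dec.time_indices_]


def temporal_generalization(
    localizer: EpochSet,
    sleep: EpochSet,
    localizer_labels: np.ndarray | None = None,
    sleep_labels: np.ndarray | None = None,
    n_shuffles: int = 250,
    train_step: int = 1,
    test_step: int = 1,
    random_state: int | None = None,
) -> DecodingMap:
    """Wake→sleep temporal-generalization AUC map with its surrogate baseline.

    Sleep test labels are the category learned in the epoch's session, so
    AUC > 0.5 indicates reactivation of the just-learned category.
    """
    y_loc = localizer.labels if localizer_labels is None else np.asarray(localizer_labels)
    y_sleep = sleep.labels if sleep_labels is None else np.asarray(sleep_labels)
    if y_loc is None or y_sleep is None:
        raise ValueError("labels are required for both epoch sets")
    dec = TemporalGeneralizationDecoder(
        n_shuffles=n_shuffles,
        train_step=train_step,
        test_step=test_step,
        random_state=random_state,
    ).fit(localizer.data, y_loc)
    auc = dec.score_map(sleep.data, y_sleep)
    surrogate = dec.surrogate_map(sleep.data, y_sleep) if n_shuffles else None
    return DecodingMap(
        auc=auc,
        surrogate_auc=surrogate,
        train_times=localizer.times[dec.train_time_indices_],
        test_times=sleep.times[dec.test_time_indices_],
        n_shuffles=n_shuffles,
    )


# ---------------------------------------------------------------------------
# Searchlight
# ---------------------------------------------------------------------------

def channel_neighborhoods(
    positions: np.ndarray,
    names: list[str],
    min_size: int = 5,
    max_size: int = 9,
) -> dict[str, list[int]]:
    """Spatial neighborhoods (centre + neighbours) of size ``min_size..max_size``.

    A global radius (the median 7th-nearest-neighbour distance) defines the
    neighbourhood; channels are then clamped to the size bounds by taking the
    nearest channels, breaking distance ties by channel-name order.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    dists = np.linalg.norm(positions[:, None] - positions[None, :], axis=-1)
    name_rank = np.argsort(np.argsort(names))
    radius = float(np.median(np.sort(dists, axis=1)[:, min(6, n - 1)]))
    out: dict[str, list[int]] = {}
    for i in range(n):
        order = np.lexsort((name_rank, dists[i]))
        size = int((dists[i] <= radius).sum())
        size = int(np.clip(size, min(min_size, n), min(max_size, n)))
        out[names[i]] = sorted(order[:size].tolist())
    return out


def searchlight_decode(
    localizer_sensor: EpochSet,
    sleep_sensor: EpochSet,
    train_window: tuple[float, float],
    test_window: tuple[float, float],
    neighborhoods: dict[str, list[int]] | None = None,
    train_step: int = 1,
    test_step: int = 1,
    min_size: int = 5,
    max_size: int = 9,
) -> dict[str, float]:
    """Per-channel decoding map collapsed over the windows of interest.

    Both epoch sets must be in *sensor* space (back-project PCA components
    with :meth:`PooledPCA.inverse_transform` first). For each centre channel
    the temporal-generalization analysis is repeated on its neighbourhood's
    channels and the AUC is averaged over ``train_window × test_window``.
    Neighbourhoods with fewer than 2 channels are skipped.
    """
    if neighborhoods is None:
        if localizer_sensor.channel_positions is None:
            raise ValueError("channel positions are required to build neighborhoods")
        neighborhoods = channel_neighborhoods(
            localizer_sensor.channel_positions,
            localizer_sensor.channel_names,
            min_size,
            max_size,
        )
    tr_mask = localizer_sensor.time_mask(*train_window)
    te_mask = sleep_sensor.time_mask(*test_window)
    result: dict[str, float] = {}
    for name, idx in neighborhoods.items():
        if len(idx) < 2:
            logger.info("searchlight: skipping %s (neighborhood < 2 channels)", name)
            continue
        dec = TemporalGeneralizationDecoder(
            n_shuffles=0, train_step=train_step, test_step=test_step
        ).fit(
            localizer_sensor.data[:, idx, :][:, :, tr_mask], localizer_sensor.labels
        )
        auc = dec.score_map(
            sleep_sensor.data[:, idx, :][:, :, te_mask], sleep_sensor.labels
        )
        result[name] = float(auc.mean())
    return result
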