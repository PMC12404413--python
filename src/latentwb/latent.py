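"""Dimensionality reduction of parcellated BOLD and latent-dimension selection.

Every time point of every subject is one training vector of length d_init.
Two reduction families are provided: a dense symmetric auto-encoder
(encoder widths 0.75, 0.5 and 0.25 x d_init before the bottleneck) and a
linear principal-subspace projection.  The latent dimension is chosen by
two criteria: the elbow of the cross-validated reconstruction-MSE curve,
and the smallest dimension whose latent-FC classification accuracy is no
worse than in the natural space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVC

from .types import (
    BoldTimeSeries,
    InputError,
    LatentTimeSeries,
    ParameterError,
)


class NoElbowError(ValueError):
    """The MSE curve has no elbow (e.g. it is monotone increasing)."""


# ---------------------------------------------------------------------------
# Resampling (datasets with different TR are interpolated to a common grid)
# ---------------------------------------------------------------------------

def resample_to_tr(series: BoldTimeSeries, target_tr: float) -> BoldTimeSeries:
    """Linear time-interpolation of each region onto a ``target_tr`` grid.

    The duration T x TR is preserved, so a 200-point series at TR = 2.4 s
    becomes a 240-point series at TR = 2 s.
    """
    if target_tr <= 0:
        raise ParameterError("target_tr must be positive")
    if target_tr == series.tr:
        return series
    T = series.n_timepoints
    t_old = np.arange(T) * series.tr
    n_new = int(round(T * series.tr / target_tr))
    t_new = np.arange(n_new) * target_tr
    data = np.empty((series.n_regions, n_new))
    for i in range(series.n_regions):
        data[i] = np.interp(t_new, t_old, series.data[i])
    return BoldTimeSeries(data, tr=target_tr, subject_id=series.subject_id,
                          condition=series.condition)


# ---------------------------------------------------------------------------
# Reduction models
# ---------------------------------------------------------------------------

@dataclass
class ReductionModel:
    """A fitted encoder/decoder pair between natural and latent space."""

    kind: str  # "autoencoder" | "linear"
    d_latent: int
    encode: Callable[[np.ndarray], np.ndarray]
    decode: Callable[[np.ndarray], np.ndarray]
    training_mse: float
    mean_: np.ndarray = None
    scale_: np.ndarray = None

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.scale_

    def unstandardize(self, X: np.ndarray) -> np.ndarray:
        return X * self.scale_ + self.mean_

    def transform_series(self, series: BoldTimeSeries) -> LatentTimeSeries:
        """Encode a (regions x T) series into (d_latent x T)."""
        Z = self.encode(self.standardize(series.data.T))
        return LatentTimeSeries(Z.T, tr=series.tr, subject_id=series.subject_id,
                                condition=series.condition)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Standardized-space reconstruction of standardized row vectors."""
        return self.decode(self.encode(X))


def _pool_timepoints(dataset) -> np.ndarray:
    """Stack every subject's time points as rows (N_total x d_init)."""
    if not dataset:
        raise ParameterError("dataset must be non-empty")
    d = dataset[0].data.shape[0]
    if any(s.data.shape[0] != d for s in dataset):
        raise InputError("all subjects must share the same region count")
    return np.concatenate([s.data.T for s in dataset], axis=0)


def _standardizer(X: np.ndarray):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return mean, scale


DEFAULT_AE_HYPER = {"lr": 1e-4, "batch": 20, "epochs": 15}


def train_autoencoder(
    dataset,
    d_latent: int,
    hyper: dict | None = None,
    seed: int = 0,
) -> ReductionModel:
    """Train the dense symmetric auto-encoder on pooled time-point vectors.

    Encoder widths are ceil(0.75 d), ceil(0.5 d), ceil(0.25 d) then the
    bottleneck; the decoder mirrors them.  Inputs are z-scored per region
    over the training set.  tanh activations, Adam.
    """
    X = _pool_timepoints(dataset)
    d_init = X.shape[1]
    if d_latent >= d_init:
        raise ParameterError("d_latent must be smaller than d_init")
    h = dict(DEFAULT_AE_HYPER)
    h.update(hyper or {})
    mean, scale = _standardizer(X)
    Xz = (X - mean) / scale
    widths = [int(np.ceil(f * d_init)) for f in (0.75, 0.5, 0.25)]
    layers = tuple(widths + [d_latent] + widths[::-1])
    net = MLPRegressor(
        hidden_layer_sizes=layers,
        activation="tanh",
        solver="adam",
        learning_rate_init=h["lr"],
        batch_size=h["batch"],
        max_iter=h["epochs"],
        shuffle=True,
        random_state=seed,
        tol=0.0,
        n_iter_no_change=h["epochs"] + 1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # few-epoch training never "converges"
        net.fit(Xz, Xz)
    coefs, biases = net.coefs_, net.intercepts_
    n_enc = len(widths) + 1  # layers up to and including the bottleneck

    def encode(V: np.ndarray) -> np.ndarray:
        A = np.atleast_2d(V)
        for W, b in zip(coefs[:n_enc], biases[:n_enc]):
            A = np.tanh(A @ W + b)
        return A

    def decode(Z: np.ndarray) -> np.ndarray:
        A = np.atleast_2d(Z)
        for k, (W, b) in enumerate(zip(coefs[n_enc:], biases[n_enc:])):
            A = A @ W + b
            if k < len(coefs) - n_enc - 1:  # output layer is linear
                A = np.tanh(A)
        return A

    mse = float(np.mean((decode(encode(Xz)) - Xz) ** 2))
    return ReductionModel("autoencoder", d_latent, encode, decode, mse,
                          mean_=mean, scale_=scale)


def fit_linear_reduction(dataset, d_latent: int) -> ReductionModel:
    """Principal-subspace projection of the pooled time-point vectors."""
    X = _pool_timepoints(dataset)
    mean, scale = _standardizer(X)
    Xz = (X - mean) / scale
    rank = np.linalg.matrix_rank(Xz)
    if d_latent > rank:
        raise ParameterError(f"d_latent={d_latent} exceeds data rank {rank}")
    pca = PCA(n_components=d_latent, svd_solver="full")
    pca.fit(Xz)

    def encode(V: np.ndarray) -> np.ndarray:
        return pca.transform(np.atleast_2d(V))

    def decode(Z: np.ndarray) -> np.ndarray:
        return pca.inverse_transform(np.atleast_2d(Z))

    mse = float(np.mean((decode(encode(Xz)) - Xz) ** 2))
    return ReductionModel("linear", d_latent, encode, decode, mse,
                          mean_=mean, scale_=scale)


def reconstruction_curve(
    dataset,
    dims,
    k_folds: int = 10,
    seed: int = 0,
    method: str = "linear",
    hyper: dict | None = None,
) -> dict:
    """Mean held-out reconstruction MSE per candidate latent dimension.

    Folds split by subject (a subject's time points never straddle the
    train/test boundary), k = 10 by default.
    """
    if k_folds < 2:
        raise ParameterError("k_folds must be at least 2")
    if len(dataset) < k_folds:
        raise ParameterError("need at least as many subjects as folds")
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    curve = {int(d): [] for d in dims}
    idx = np.arange(len(dataset))
    for fold, (tr_idx, te_idx) in enumerate(kf.split(idx)):
        train = [dataset[i] for i in tr_idx]
        test = [dataset[i] for i in te_idx]
        X_test = _pool_timepoints(test)
        for d in dims:
            if method == "linear":
                model = fit_linear_reduction(train, int(d))
            else:
                model = train_autoencoder(train, int(d), hyper=hyper,
                                          seed=seed * 1000 + fold)
            Xz = model.standardize(X_test)
            mse = float(np.mean((model.reconstruct(Xz) - Xz) ** 2))
            curve[int(d)].append(mse)
    return {d: float(np.mean(v)) for d, v in curve.items()}


def detect_elbow(curve: dict) -> int:
    """Dimension of maximum discrete curvature of the normalized MSE curve.

    Both axes are scaled to [0, 1]; the elbow is the interior point
    maximizing the second difference.  A curve that never decreases has no
    elbow and raises :class:`NoElbowError`.
    """
    dims = np.array(sorted(curve))
    if dims.size < 4:
        raise ParameterError("need at least 4 points to detect an elbow")
    mse = np.array([curve[d] for d in dims], dtype=float)
    if np.all(np.diff(mse) >= 0):
        raise NoElbowError("MSE curve is monotone increasing: no elbow")
    x = (dims - dims.min()) / (dims.max() - dims.min())
    span = mse.max() - mse.min()
    y = (mse - mse.min()) / span if span > 0 else np.zeros_like(mse)
    curvature = y[:-2] - 2 * y[1:-1] + y[2:]
    return int(dims[1 + int(np.argmax(curvature))])


# ---------------------------------------------------------------------------
# Functional connectivity in latent space
# ---------------------------------------------------------------------------

def latent_fc(series: LatentTimeSeries) -> np.ndarray:
    """Pearson correlation matrix of the latent dimensions."""
    if np.any(series.data.std(axis=1) == 0):
        raise InputError("zero-variance latent dimension")
    return np.corrcoef(series.data)


def split_fc_augment(series: LatentTimeSeries, n_splits: int = 4) -> list:
    """FC matrices of ``n_splits`` contiguous equal windows (remainder to
    the last), the data-augmentation step before classification."""
    T = series.n_timepoints
    if T < 2 * n_splits:
        raise InputError("series too short for the requested splits")
    width = T // n_splits
    fcs = []
    for k in range(n_splits):
        stop = T if k == n_splits - 1 else (k + 1) * width
        window = series.data[:, k * width:stop]
        if np.any(window.std(axis=1) == 0):
            raise InputError("zero-variance window")
        fcs.append(np.corrcoef(window))
    return fcs


# ---------------------------------------------------------------------------
# SVM condition classification
# ---------------------------------------------------------------------------

DEFAULT_SVM_KERNEL = {"type": "polynomial", "degree": 3, "C": 0.1, "gamma": 7.5}


def _upper_triangle(fc: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(fc.shape[0], k=1)
    return fc[iu]


def classify_conditions(fcs, labels, subject_ids, kernel: dict | None = None) -> float:
    """Leave-one-subject-out accuracy of an SVM on vectorized FC matrices.

    All FC matrices of the held-out subject form the test items of its
    fold, so no subject contributes to both training and testing.
    """
    kernel = {**DEFAULT_SVM_KERNEL, **(kernel or {})}
    X = np.array([_upper_triangle(fc) for fc in fcs])
    y = np.asarray(labels)
    groups = np.asarray(subject_ids)
    if len({*y}) < 2:
        raise ParameterError("need at least two classes")
    correct = 0
    for subject in np.unique(groups):
        test = groups == subject
        if test.all():
            raise ParameterError("cannot hold out the only subject")
        if (groups[~test] == subject).any():  # pragma: no cover - guard
            raise RuntimeError("subject leaked across the fold boundary")
        clf = SVC(kernel="poly", degree=kernel["degree"], C=kernel["C"],
                  gamma=kernel["gamma"])
        clf.fit(X[~test], y[~test])
        correct += int((clf.predict(X[test]) == y[test]).sum())
    return correct / len(y)


def select_latent_dim(acc_by_dim: dict, natural_acc: float, tolerance: float = 0.0):
    """Smallest dimension classifying at least as well as the natural space
    (within ``tolerance``); None when no dimension qualifies."""
    if not acc_by_dim:
        raise ParameterError("acc_by_dim must be non-empty")
    for dim in sorted(acc_by_dim):
        if acc_by_dim[dim] >= natural_acc - tolerance:
            return int(dim)
    return None
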