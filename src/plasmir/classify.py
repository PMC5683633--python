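"""Nearest-centroid classification with filtered features and validation.

The protocol: rank features by a filter statistic (Welch |t| by
default), keep the top n, standardize on the training samples only,
store per-class mean vectors as centroids, and assign new samples to
the nearest centroid.  Validation is by a single stratified split,
leave-one-out cross-validation, or a multiple-random-validation scheme
(repeated stratified 50% splits with full refitting), which also yields
per-feature panel inclusion rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from plasmir.normalize import TransformedMatrix


@dataclass
class CentroidModel:
    """Fitted nearest-centroid predictor."""

    feature_ids: list[str]  # ordered by filter rank
    classes: list[str]
    centroids: np.ndarray  # classes x features, standardized space
    means: np.ndarray  # training standardization, per feature
    sds: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if len(self.feature_ids) < 1:
            raise ValueError("model needs >= 1 feature")
        if self.centroids.shape != (len(self.classes), len(self.feature_ids)):
            raise ValueError("centroid shape mismatch")


@dataclass
class ValidationReport:
    """Misclassification distribution and feature inclusion rates."""

    protocol: str  # split | loocv | mrv
    rates: np.ndarray  # per-iteration misclassification fraction
    inclusion_counts: pd.Series  # feature -> number of panels entered
    n_iterations: int
    train_fraction: float | None
    panel_size: int
    seed: int | None

    @property
    def median_rate(self) -> float:
        return float(np.median(self.rates))

    @property
    def iqr(self) -> tuple[float, float]:
        return (
            float(np.percentile(self.rates, 25)),
            float(np.percentile(self.rates, 75)),
        )

    @property
    def inclusion_rates(self) -> pd.Series:
        return self.inclusion_counts / self.n_iterations

    def summary(self) -> dict:
        lo, hi = self.iqr
        return {
            "protocol": self.protocol,
            "n_iterations": self.n_iterations,
            "panel_size": self.panel_size,
            "median_misclassification": self.median_rate,
            "iqr": [lo, hi],
        }


def _welch_t(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Welch t statistics (x, y: features x samples)."""
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1, v2 = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    denom = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    return t


def rank_features(
    tm: TransformedMatrix, labels: Sequence, statistic: str = "t"
) -> list[str]:
    """Order features by decreasing filter statistic; lexicographic ties.

    ``t``: Welch |t|;  ``fc``: absolute mean difference.  Zero-variance,
    zero-difference features sort last.
    """
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError("feature ranking requires exactly two classes")
    a = tm.values[:, labels == classes[0]]
    b = tm.values[:, labels == classes[1]]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each class needs >= 2 training samples")
    if statistic == "t":
        stat = np.abs(_welch_t(a, b))
    elif statistic == "fc":
        stat = np.abs(a.mean(axis=1) - b.mean(axis=1))
    else:
        raise ValueError(f"unknown filter statistic {statistic!r}")
    stat = np.nan_to_num(stat, nan=-np.inf)  # degenerate features rank last
    order = sorted(
        range(tm.n_features), key=lambda i: (-stat[i], tm.feature_ids[i])
    )
    return [tm.feature_ids[i] for i in order]


def fit_nearest_centroid(
    tm: TransformedMatrix,
    labels: Sequence,
    n_features: int,
    statistic: str = "t",
    metric: str = "euclidean",
) -> CentroidModel:
    """Select top-ranked features, standardize on training, store centroids."""
    if n_features < 1 or n_features > tm.n_features:
        raise ValueError("n_features out of range")
    labels = np.asarray(labels)
    ranked = rank_features(tm, labels, statistic=statistic)
    feats = ranked[:n_features]
    idx = [tm.feature_ids.index(f) for f in feats]
    x = tm.values[idx, :]
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    z = (x - mean[:, None]) / sd[:, None]
    classes = sorted(set(labels.tolist()))
    centroids = np.vstack([z[:, labels == c].mean(axis=1) for c in classes])
    return CentroidModel(feats, [str(c) for c in classes], centroids, mean, sd, metric)


def predict(
    model: CentroidModel, tm_new: TransformedMatrix
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Assign each sample to the nearest centroid.

    Returns (labels, distances samples x classes, ambiguous flags).
    Exact distance ties go to the first listed class and are flagged.
    """
    idx = []
    for f in model.feature_ids:
        if f not in tm_new.feature_ids:
            raise KeyError(f"feature {f!r} missing from new data")
        idx.append(tm_new.feature_ids.index(f))
    z = (tm_new.values[idx, :] - model.means[:, None]) / model.sds[:, None]

    nsamp = z.shape[1]
    dists = np.zeros((nsamp, len(model.classes)))
    for k in range(len(model.classes)):
        c = model.centroids[k][:, None]
        if model.metric == "euclidean":
            dists[:, k] = np.sqrt(((z - c) ** 2).sum(axis=0))
        elif model.metric == "correlation":
            zc = z - z.mean(axis=0, keepdims=True)
            cc = c - c.mean()
            denom = np.linalg.norm(zc, axis=0) * np.linalg.norm(cc)
            denom = np.where(denom > 0, denom, 1.0)
            dists[:, k] = 1.0 - (zc * cc).sum(axis=0) / denom
        else:
            raise ValueError(f"unknown metric {model.metric!r}")
    best = dists.argmin(axis=1)
    ambiguous = np.array(
        [(dists[j] == dists[j, best[j]]).sum() > 1 for j in range(nsamp)]
    )
    labels = [model.classes[b] for b in best]
    return labels, dists, ambiguous


def _misclassification(
    tm: TransformedMatrix,
    labels: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    n_features: int,
    statistic: str,
    metric: str,
) -> tuple[float, list[str]]:
    tr = tm.subset_samples([tm.sample_ids[i] for i in train_idx])
    te = tm.subset_samples([tm.sample_ids[i] for i in test_idx])
    model = fit_nearest_centroid(
        tr, labels[train_idx], n_features, statistic=statistic, metric=metric
    )
    pred, _, _ = predict(model, te)
    truth = [str(l) for l in labels[test_idx]]
    rate = float(np.mean([p != t for p, t in zip(pred, truth)]))
    return rate, model.feature_ids


def _stratified_split(
    labels: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train, test = [], []
    for c in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n_train = max(2, int(round(train_fraction * len(idx))))
        if len(idx) - n_train < 1:
            raise ValueError(f"class {c!r} too small for the requested split")
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return np.asarray(sorted(train)), np.asarray(sorted(test))


def validate_mrv(
    tm: TransformedMatrix,
    labels: Sequence,
    n_iter: int = 1000,
    train_fraction: float = 0.5,
    n_features: int = 80,
    seed: int = 0,
    statistic: str = "t",
    metric: str = "euclidean",
) -> ValidationReport:
    """Multiple random validation: stratified splits with full refitting."""
    labels = np.asarray(labels)
    for c in sorted(set(labels.tolist())):
        if (labels == c).sum() < 4:
            raise ValueError(f"class {c!r} needs >= 4 samples for splitting")
    n_features = min(n_features, tm.n_features)
    rng = np.random.default_rng(seed)
    rates = np.zeros(n_iter)
    counts = pd.Series(0, index=tm.feature_ids, dtype=int)
    for it in range(n_iter):
        tr, te = _stratified_split(labels, train_fraction, rng)
        rate, feats = _misclassification(
            tm, labels, tr, te, n_features, statistic, metric
        )
        rates[it] = rate
        counts[feats] += 1
    return ValidationReport(
        "mrv", rates, counts, n_iter, train_fraction, n_features, seed
    )


def validate_split(
    tm: TransformedMatrix,
    labels: Sequence,
    train_fraction: float = 0.5,
    n_features: int = 80,
    seed: int = 0,
    **kw,
) -> ValidationReport:
    """Single stratified training/test split."""
    rep = validate_mrv(
        tm, labels, n_iter=1, train_fraction=train_fraction,
        n_features=n_features, seed=seed, **kw,
    )
    rep.protocol = "split"
    return rep


def validate_loocv(
    tm: TransformedMatrix,
    labels: Sequence,
    n_features: int = 80,
    statistic: str = "t",
    metric: str = "euclidean",
) -> ValidationReport:
    """Leave-one-out cross-validation with full refit per fold (deterministic)."""
    labels = np.asarray(labels)
    for c in sorted(set(labels.tolist())):
        if (labels == c).sum() < 3:
            raise ValueError(f"class {c!r} too small for LOOCV refits")
    n_features = min(n_features, tm.n_features)
    n = len(tm.sample_ids)
    errors = 0
    counts = pd.Series(0, index=tm.feature_ids, dtype=int)
    for j in range(n):
        tr = np.asarray([i for i in range(n) if i != j])
        rate, feats = _misclassification(
            tm, labels, tr, np.asarray([j]), n_features, statistic, metric
        )
        errors += rate > 0
        counts[feats] += 1
    rates = np.asarray([errors / n])
    return ValidationReport("loocv", rates, counts, n, None, n_features, None)


def misclassification_curve(
    tm: TransformedMatrix,
    labels: Sequence,
    panel_sizes: Sequence[int],
    protocol: str = "mrv",
    n_iter: int = 100,
    seed: int = 0,
    **kw,
) -> pd.DataFrame:
    """Median misclassification rate as a function of panel size."""
    if any(s < 1 for s in panel_sizes):
        raise ValueError("panel sizes must be >= 1")
    rows = []
    for size in sorted(set(int(s) for s in panel_sizes)):
        if protocol == "mrv":
            rep = validate_mrv(tm, labels, n_iter=n_iter, n_features=size,
                               seed=seed, **kw)
        elif protocol == "loocv":
            rep = validate_loocv(tm, labels, n_features=size, **kw)
        else:
            raise ValueError(f"unknown protocol {protocol!r}")
        rows.append((size, rep.median_rate))
    return pd.DataFrame(rows, columns=["panel_size", "median_misclassification"])
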