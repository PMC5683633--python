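"""Detection filtering, library-size normalization, count transforms, PCA.

Three transforms feed the downstream analyses: plain log-CPM, log-CPM
with mean-variance-trend precision weights (voom-style), and a
closed-form negative-binomial variance-stabilizing transform.  These
are faithful-in-spirit simplifications of the cited ecosystem tools,
validated by distributional properties rather than bit-compatibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from plasmir.counts_io import CountMatrix


@dataclass
class TransformedMatrix:
    """Real-valued features x samples matrix on a named transform scale."""

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    transform_id: str  # logcpm | weighted_logcpm | vst
    weights: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("transformed values must be finite")
        if self.transform_id == "weighted_logcpm":
            if self.weights is None:
                raise ValueError("weighted_logcpm requires weights")
            if self.weights.shape != self.values.shape or (self.weights <= 0).any():
                raise ValueError("weights must be positive and match values in shape")
        elif self.weights is not None:
            raise ValueError(f"{self.transform_id} does not carry weights")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    def feature_row(self, feature_id: str) -> np.ndarray:
        return self.values[self.feature_ids.index(feature_id), :]

    def subset_samples(self, sample_ids: Sequence[str]) -> "TransformedMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return TransformedMatrix(
            self.values[:, idx],
            list(self.feature_ids),
            [self.sample_ids[i] for i in idx],
            self.transform_id,
            None if self.weights is None else self.weights[:, idx],
            dict(self.params),
        )


def filter_detected(
    cm: CountMatrix, min_reads: int = 1, min_fraction: float = 0.25
) -> CountMatrix:
    """Keep features detected (>= min_reads) in at least min_fraction of samples.

    Both comparisons are inclusive, so at 4 samples a single detection
    meets the default 25% rule.  Idempotent; preserves feature order.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    frac = (cm.counts >= min_reads).mean(axis=1)
    keep = frac >= min_fraction
    if not keep.any():
        warnings.warn("detection filter removed every feature", stacklevel=2)
    return cm.subset_features(keep)


def size_factors_median_ratio(cm: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1."""
    counts = cm.counts.astype(float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no feature has nonzero counts in every sample")
    geomean = np.exp(np.log(counts[all_pos, :]).mean(axis=1))
    factors = np.median(counts[all_pos, :] / geomean[:, None], axis=0)
    return factors / np.exp(np.mean(np.log(factors)))


def _upper_quartile_cpm(counts: np.ndarray) -> np.ndarray:
    lib = counts.sum(axis=0).astype(float)
    return np.quantile(counts / lib[None, :] * 1e6, 0.75, axis=0)


def norm_factors_tmm(
    cm: CountMatrix,
    reference_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference column is the sample whose CPM upper quartile is
    closest to the mean upper quartile.  Per sample, log-ratios M vs the
    reference are doubly trimmed (``trim_m`` on each M tail, ``trim_a``
    on each average-abundance tail) and averaged with binomial precision
    weights.
    """
    counts = cm.counts.astype(float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        j = int(np.argmin(lib))
        raise ValueError(f"sample {cm.sample_ids[j]!r} has zero total count")
    if reference_sample is None:
        uq = _upper_quartile_cpm(counts)
        ref = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref = cm.sample_ids.index(reference_sample)

    log_factors = np.zeros(cm.n_samples)
    pr = counts[:, ref] / lib[ref]
    for j in range(cm.n_samples):
        if j == ref:
            continue
        pj = counts[:, j] / lib[j]
        ok = (pj > 0) & (pr > 0)
        if not ok.any():
            raise ValueError(f"sample {cm.sample_ids[j]!r} shares no detected feature "
                             "with the reference")
        m = np.log2(pj[ok] / pr[ok])
        a = 0.5 * np.log2(pj[ok] * pr[ok])
        # precision weights: delta-method variance of M for binomial counts
        w = 1.0 / (
            (1 - counts[ok, j] / lib[j]) / counts[ok, j]
            + (1 - counts[ok, ref] / lib[ref]) / counts[ok, ref]
        )
        keep = np.ones(ok.sum(), dtype=bool)
        if keep.sum() > 4:
            m_lo, m_hi = np.quantile(m, [trim_m, 1 - trim_m])
            a_lo, a_hi = np.quantile(a, [trim_a, 1 - trim_a])
            keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
            if not keep.any():
                keep = np.ones(ok.sum(), dtype=bool)
        log_factors[j] = np.average(m[keep], weights=w[keep])
    log_factors -= log_factors.mean()
    return np.exp2(log_factors)


def no_norm_factors(cm: CountMatrix) -> np.ndarray:
    """All-ones factors for the equal-input-volume reading of the design."""
    return np.ones(cm.n_samples)


FACTOR_METHODS = {
    "median-ratio": size_factors_median_ratio,
    "tmm": norm_factors_tmm,
    "none": no_norm_factors,
}


def _effective_libs(cm: CountMatrix, factors: np.ndarray) -> np.ndarray:
    lib = cm.counts.sum(axis=0).astype(float) * np.asarray(factors, dtype=float)
    if (lib <= 0).any():
        raise ValueError("zero effective library size")
    return lib


def log_cpm(
    cm: CountMatrix, factors: np.ndarray | None = None, prior: float = 0.5
) -> TransformedMatrix:
    """log2 counts per million with a prior count: log2((c+p)/(L+2p) * 1e6)."""
    if prior <= 0:
        raise ValueError("prior count must be > 0")
    if factors is None:
        factors = np.ones(cm.n_samples)
    lib = _effective_libs(cm, factors)
    vals = np.log2((cm.counts + prior) / (lib[None, :] + 2 * prior) * 1e6)
    return TransformedMatrix(
        vals, list(cm.feature_ids), list(cm.sample_ids), "logcpm",
        params={"prior": prior},
    )


def precision_weights(
    cm: CountMatrix,
    factors: np.ndarray | None = None,
    prior: float = 0.5,
    span: float = 0.5,
) -> TransformedMatrix:
    """log-CPM with voom-style inverse-variance observation weights.

    A LOWESS curve of sqrt(per-feature residual sd of log-CPM) against
    average log2 count is evaluated at each observation's predicted
    log-count; weight = fitted_sd^-4.
    """
    if cm.n_features < 10:
        raise ValueError("need >= 10 features to fit the mean-variance trend")
    tm = log_cpm(cm, factors, prior)
    lib = _effective_libs(cm, factors if factors is not None else np.ones(cm.n_samples))

    resid = tm.values - tm.values.mean(axis=1, keepdims=True)
    sd = resid.std(axis=1, ddof=1)
    mean_logcount = tm.values.mean(axis=1) + np.log2(lib.mean() + 1) - np.log2(1e6)

    fit = lowess(np.sqrt(sd), mean_logcount, frac=span, return_sorted=True)
    fx, fy = fit[:, 0], np.maximum(fit[:, 1], 1e-4)

    # predicted log2 count of each observation under its own library size
    pred = tm.values + np.log2(lib[None, :] + 1) - np.log2(1e6)
    sqrt_sd_hat = np.interp(pred, fx, fy)
    weights = sqrt_sd_hat ** -4.0
    return TransformedMatrix(
        tm.values, list(cm.feature_ids), list(cm.sample_ids), "weighted_logcpm",
        weights=weights, params={"prior": prior, "span": span},
    )


def vst(
    cm: CountMatrix, factors: np.ndarray | None = None, dispersion: float = 0.1
) -> TransformedMatrix:
    """Closed-form NB variance stabilizer on CPM at a trend-level dispersion.

    value = 2/ln(2) * asinh(sqrt(phi * cpm)): the anti-derivative of
    1/sqrt(var) under var = mu + phi*mu^2, rescaled to the log2 scale so
    that value - log2(cpm) converges to a constant for large cpm.
    Monotone in the count.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if factors is None:
        factors = np.ones(cm.n_samples)
    lib = _effective_libs(cm, factors)
    cpm = cm.counts / lib[None, :] * 1e6
    vals = 2.0 / np.log(2) * np.arcsinh(np.sqrt(dispersion * cpm))
    return TransformedMatrix(
        vals, list(cm.feature_ids), list(cm.sample_ids), "vst",
        params={"dispersion": dispersion},
    )


def transform_counts(
    cm: CountMatrix,
    method: str = "weighted_logcpm",
    factor_method: str | None = None,
    **kwargs,
) -> TransformedMatrix:
    """Dispatch: logcpm (TMM), weighted_logcpm (TMM), or vst (median-ratio)."""
    defaults = {"logcpm": "tmm", "weighted_logcpm": "tmm", "vst": "median-ratio"}
    if method not in defaults:
        raise ValueError(f"unknown transform {method!r}")
    fm = factor_method or defaults[method]
    factors = FACTOR_METHODS[fm](cm)
    fn = {"logcpm": log_cpm, "weighted_logcpm": precision_weights, "vst": vst}[method]
    tm = fn(cm, factors, **kwargs)
    tm.params["factor_method"] = fm
    return tm


def pca_scores(
    tm: TransformedMatrix, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Feature-centered SVD sample scores and explained-variance fractions."""
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    x = tm.values - tm.values.mean(axis=1, keepdims=True)
    if n_components > min(x.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = (vt[:n_components, :] * s[:n_components, None]).T  # samples x comps
    var = s**2
    evf = var[:n_components] / var.sum() if var.sum() > 0 else np.zeros(n_components)
    return scores, evf
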