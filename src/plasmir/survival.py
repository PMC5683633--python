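"""Rank-based survival screen with a permutation null, Cox PH, Kaplan-Meier.

Counts are equalized across sequencing depths by repeated binomial
down-sampling to the minimum depth, rank-transformed per feature
(midranks), and averaged over resamples.  Each feature's association
with mortality is the Cox partial-likelihood score statistic at zero
effect on those averaged ranks; significance is calibrated by permuting
the (time, event) pairs, which also yields the expected order
statistics for a Q-Q display and SAM-style q-values.  Leading features
are confirmed with a univariable Cox model on median-dichotomized
levels; survival is summarized by the product-limit estimator with
Greenwood variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from plasmir.counts_io import CountMatrix


@dataclass
class CoxResult:
    """Univariable Cox PH fit for a binary predictor."""

    feature_id: str
    log_hr: float
    hr: float
    se: float
    pvalue: float
    n_events: int
    predictor: str
    monotone: bool = False  # likelihood maximized at the boundary

    def as_row(self) -> dict:
        return {
            "feature_id": self.feature_id,
            "hr": self.hr,
            "log_hr": self.log_hr,
            "se": self.se,
            "pvalue": self.pvalue,
            "n_events": self.n_events,
            "predictor": self.predictor,
            "monotone": self.monotone,
        }


@dataclass
class KMCurve:
    """Product-limit survival estimate with Greenwood 95% CI."""

    times: np.ndarray  # ordered distinct event times
    survival: np.ndarray
    variance: np.ndarray  # Greenwood variance of S
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_at_risk: np.ndarray

    def at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


def depth_standardized_ranks(
    cm: CountMatrix, n_resamples: int = 20, seed: int = 0
) -> pd.DataFrame:
    """Down-sample every column to the minimum depth, rank, and average.

    Per resample, counts[i, j] are binomially thinned with probability
    min_depth / depth_j, then each feature row is midrank-transformed
    across samples; ranks are averaged over resamples.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    depths = cm.library_sizes.astype(float)
    if (depths <= 0).any():
        j = int(np.argmin(depths))
        raise ValueError(f"sample {cm.sample_ids[j]!r} has zero depth")
    p = depths.min() / depths
    rng = np.random.default_rng(seed)
    acc = np.zeros(cm.counts.shape)
    for _ in range(n_resamples):
        if np.all(p == 1.0):
            thinned = cm.counts
        else:
            thinned = rng.binomial(cm.counts, p[None, :])
        acc += np.apply_along_axis(stats.rankdata, 1, thinned)
    return pd.DataFrame(acc / n_resamples, index=cm.feature_ids,
                        columns=cm.sample_ids)


def _cox_score_stat(x: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Cox score statistic at beta=0 (log-rank type) for one covariate.

    U = sum over event times of (x of failing subjects - d * risk-set
    mean); V = sum of d (n-d)/(n-1) * risk-set variance of x.  Positive
    sign means higher x, higher hazard.
    """
    order = np.argsort(time, kind="stable")
    x, time, event = x[order], time[order], event[order]
    n = len(x)
    u = 0.0
    v = 0.0
    etimes = np.unique(time[event == 1])
    for t in etimes:
        at_risk = time >= t
        nr = int(at_risk.sum())
        fail = (time == t) & (event == 1)
        d = int(fail.sum())
        xbar = x[at_risk].mean()
        u += x[fail].sum() - d * xbar
        if nr > 1:
            var = ((x[at_risk] - xbar) ** 2).sum() / nr
            v += d * (nr - d) / (nr - 1) * var
    if v <= 0:
        return 0.0
    return float(u / np.sqrt(v))


def _cox_score_stats_matrix(
    x: np.ndarray, time: np.ndarray, event: np.ndarray
) -> np.ndarray:
    """Row-wise Cox score statistics (x: features x samples), vectorized."""
    n_feat = x.shape[0]
    u = np.zeros(n_feat)
    v = np.zeros(n_feat)
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        fail = (time == t) & (event == 1)
        nr = int(at_risk.sum())
        d = int(fail.sum())
        xr = x[:, at_risk]
        xbar = xr.mean(axis=1)
        u += x[:, fail].sum(axis=1) - d * xbar
        if nr > 1:
            var = ((xr - xbar[:, None]) ** 2).sum(axis=1) / nr
            v += d * (nr - d) / (nr - 1) * var
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(v > 0, u / np.sqrt(np.maximum(v, 1e-300)), 0.0)
    return z


def cox_score_screen(
    ranks: pd.DataFrame, time: np.ndarray, event: np.ndarray
) -> pd.Series:
    """Per-feature standardized Cox score statistics on averaged ranks."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise ValueError("survival screen needs >= 1 event")
    scores = _cox_score_stats_matrix(ranks.to_numpy(dtype=float), time, event)
    return pd.Series(scores, index=ranks.index, name="score")


def permutation_null(
    ranks: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
    return_perm: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, np.ndarray]:
    """Permutation-calibrated screen: expected scores, q-values, Q-Q pairs.

    (time, event) pairs are permuted jointly across samples; expected
    score at rank position k is the mean k-th order statistic over
    permutations; the q-value at threshold |t| is the median permuted
    exceedance count over the observed exceedance count, capped at 1 and
    monotonized in |score|.  With ``return_perm`` the per-permutation
    sorted score matrix (n_perm x n_features) is also returned, e.g. for
    Q-Q envelope construction.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    observed = cox_score_screen(ranks, time, event)
    nf = len(observed)
    rng = np.random.default_rng(seed)
    n = len(time)

    perm_sorted = np.zeros((n_perm, nf))
    perm_abs = np.zeros((n_perm, nf))
    rmat = ranks.to_numpy(dtype=float)
    for b in range(n_perm):
        perm = rng.permutation(n)
        sc = _cox_score_stats_matrix(rmat, time[perm], event[perm])
        perm_sorted[b] = np.sort(sc)
        perm_abs[b] = np.abs(sc)

    expected = perm_sorted.mean(axis=0)  # k-th order statistic means

    order = np.argsort(observed.to_numpy())
    obs_sorted = observed.to_numpy()[order]

    abs_obs = np.abs(observed.to_numpy())
    desc = np.argsort(-abs_obs, kind="stable")  # most significant first
    raw = np.empty(nf)
    for pos, i in enumerate(desc):
        t_thr = abs_obs[i]
        n_obs = int((abs_obs >= t_thr - 1e-12).sum())
        n_perm_exceed = np.median((perm_abs >= t_thr - 1e-12).sum(axis=1))
        raw[pos] = min(1.0, n_perm_exceed / n_obs)
    # monotonize: each feature's q is the best rate achievable at its own
    # or any weaker threshold (step-up, as in BH)
    q_desc = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty(nf)
    q[desc] = q_desc

    out = pd.DataFrame(
        {
            "feature_id": [observed.index[i] for i in order],
            "observed": obs_sorted,
            "expected": expected,
            "qvalue": q[order],
        }
    )
    if return_perm:
        return out, perm_sorted
    return out


def dichotomize_median(values: np.ndarray) -> np.ndarray:
    """1 iff strictly above the median; ties at the median go to 0."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need >= 2 samples to dichotomize")
    return (values > np.median(values)).astype(int)


def _cox_partial_loglik(
    beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, float, float]:
    """(loglik, score, information) for scalar beta, Breslow ties."""
    eta = beta * x
    exp_eta = np.exp(eta)
    ll = 0.0
    u = 0.0
    info = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        fail = (time == t) & (event == 1)
        d = int(fail.sum())
        s0 = exp_eta[at_risk].sum()
        s1 = (x[at_risk] * exp_eta[at_risk]).sum()
        s2 = (x[at_risk] ** 2 * exp_eta[at_risk]).sum()
        ll += eta[fail].sum() - d * np.log(s0)
        u += x[fail].sum() - d * s1 / s0
        info += d * (s2 / s0 - (s1 / s0) ** 2)
    return ll, u, info


def cox_fit_binary(
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    feature_id: str = "",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxResult:
    """Newton-Raphson Cox PH fit for a binary covariate (Breslow ties).

    Monotone likelihood (all events in one level) is flagged; the HR is
    reported as infinite (or zero) and the p-value comes from the score
    test at beta = 0.
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(np.unique(x)) < 2:
        raise ValueError("both predictor levels must be present")
    n_events = int(event.sum())
    if n_events < 1:
        raise ValueError("need >= 1 event")

    ev_hi = int(event[x == x.max()].sum())
    _, u0, i0 = _cox_partial_loglik(0.0, x, time, event)
    if ev_hi == 0 or ev_hi == n_events:
        z = u0 / np.sqrt(i0) if i0 > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        hr = np.inf if ev_hi == n_events else 0.0
        log_hr = np.inf if hr == np.inf else -np.inf
        return CoxResult(feature_id, log_hr, hr, np.nan, float(p), n_events,
                         f"{feature_id} above median", monotone=True)

    beta = 0.0
    for _ in range(max_iter):
        _, u, info = _cox_partial_loglik(beta, x, time, event)
        if info <= 0:
            break
        step = u / info
        beta += step
        if abs(step) < tol:
            break
    _, _, info = _cox_partial_loglik(beta, x, time, event)
    se = float(1.0 / np.sqrt(info)) if info > 0 else np.nan
    z = beta / se if se and np.isfinite(se) else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return CoxResult(feature_id, float(beta), float(np.exp(beta)), se, float(p),
                     n_events, f"{feature_id} above median")


def km_curve(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Kaplan-Meier estimate with Greenwood variance and log-scale 95% CI."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) < 1:
        raise ValueError("need >= 1 subject")
    if (time < 0).any():
        raise ValueError("negative times")

    etimes = np.unique(time[event == 1])
    s = 1.0
    green = 0.0
    surv, var, nrisk, lo, hi = [], [], [], [], []
    for t in etimes:
        nr = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / nr
        if nr > d:
            green += d / (nr * (nr - d))
        g_var = s**2 * green
        surv.append(s)
        var.append(g_var)
        nrisk.append(nr)
        if s > 0:
            se_log = np.sqrt(green)
            lo.append(s * np.exp(-1.959963984540054 * se_log))
            hi.append(min(1.0, s * np.exp(1.959963984540054 * se_log)))
        else:
            lo.append(0.0)
            hi.append(0.0)
    return KMCurve(
        etimes, np.asarray(surv), np.asarray(var),
        np.asarray(lo), np.asarray(hi), np.asarray(nrisk),
    )
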