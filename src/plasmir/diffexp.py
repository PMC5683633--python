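"""Three two-group differential-abundance tests on counts and their consensus.

The three routes are deliberately independent in mechanism:

* ``nbwald``  — per-feature negative-binomial log-link model fitted by
  maximum likelihood at a fixed (trend-shrunken) dispersion, Wald test.
* ``nbexact`` — exact conditional NB test of the two group sums given
  their total, after scaling samples to a common effective library.
* ``modt``    — moderated t on precision-weighted log-CPM, with an
  empirical-Bayes variance prior estimated by method of moments.

A feature earns a consensus call when at least two of the three methods
reach BH significance with the same sign of log2 fold-change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from plasmir.counts_io import CountMatrix
from plasmir.normalize import TransformedMatrix

LN2 = np.log(2.0)
METHODS = ("nbwald", "nbexact", "modt")


@dataclass
class DispersionFit:
    """Per-feature NB dispersions: raw method-of-moments, trend, shrunken."""

    phi_raw: np.ndarray
    trend_coefs: tuple[float, float]  # phi_tr(mu) = a0 + a1/mu
    phi_shrunk: np.ndarray
    prior_weight: float
    mean_norm_counts: np.ndarray

    def trend_at(self, mu: np.ndarray | float) -> np.ndarray:
        a0, a1 = self.trend_coefs
        return a0 + a1 / np.maximum(np.asarray(mu, dtype=float), 1e-8)


def _group_indices(groups: Sequence[str]) -> tuple[np.ndarray, np.ndarray, str, str]:
    """Split sample indices into (control-like, patient-like) halves.

    With exactly two labels, 'control' (if present) is the reference;
    otherwise the lexicographically smaller label is.
    """
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"need exactly two group labels, got {labels}")
    ref = "control" if "control" in labels else labels[0]
    alt = [l for l in labels if l != ref][0]
    g = np.asarray(groups)
    return np.flatnonzero(g == ref), np.flatnonzero(g == alt), ref, alt


def estimate_dispersions(
    cm: CountMatrix,
    factors: np.ndarray,
    groups: Sequence[str],
    prior_weight: float = 0.5,
) -> DispersionFit:
    """Method-of-moments dispersions with an a0 + a1/mu trend and shrinkage.

    Raw phi is pooled within groups on factor-normalized counts; the
    trend is a non-negative least-squares fit of phi on 1/mean after one
    outlier-trimming pass; the shrunken value is a fixed-weight convex
    combination of raw and trend.
    """
    g = np.asarray(groups)
    labels = np.unique(g)
    for lab in labels:
        if (g == lab).sum() < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
    norm = cm.counts / np.asarray(factors, dtype=float)[None, :]

    num = np.zeros(cm.n_features)
    den = 0.0
    mu_all = norm.mean(axis=1)
    for lab in labels:
        cols = g == lab
        n = int(cols.sum())
        mu = norm[:, cols].mean(axis=1)
        s2 = norm[:, cols].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_g = np.where(mu > 0, (s2 - mu) / mu**2, 0.0)
        num += (n - 1) * np.nan_to_num(phi_g)
        den += n - 1
    phi_raw = np.maximum(num / den, 0.0)

    ok = mu_all > 0
    if ok.sum() < 20:
        raise ValueError("need >= 20 expressed features for the dispersion trend")
    x = np.column_stack([np.ones(ok.sum()), 1.0 / mu_all[ok]])
    y = phi_raw[ok]
    coef, _ = optimize.nnls(x, y)
    resid = np.abs(y - x @ coef)
    keep = resid <= np.quantile(resid, 0.9)  # single trimming pass
    if keep.sum() >= 20:
        coef, _ = optimize.nnls(x[keep], y[keep])
    a0, a1 = float(coef[0]), float(coef[1])

    phi_tr = a0 + a1 / np.maximum(mu_all, 1e-8)
    phi_shrunk = prior_weight * phi_tr + (1 - prior_weight) * phi_raw
    return DispersionFit(phi_raw, (a0, a1), np.maximum(phi_shrunk, 0.0),
                         prior_weight, mu_all)


def _de_frame(
    feature_ids: Sequence[str], lfc: np.ndarray, p: np.ndarray,
    method: str, comparison: str,
) -> pd.DataFrame:
    p = np.clip(p, 0.0, 1.0)
    return pd.DataFrame(
        {
            "feature_id": list(feature_ids),
            "log2fc": lfc,
            "pvalue": p,
            "qvalue": bh_adjust(p),
            "method": method,
            "comparison": comparison,
        }
    )


def _fit_nb_group(
    y: np.ndarray, offset_log: np.ndarray, phi: np.ndarray, n_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-feature NB MLE of a single group intercept (log link).

    Returns (beta, fisher_information).  y: features x samples of the
    group; offset_log: log effective library size per sample; phi:
    per-feature dispersion.
    """
    tot = y.sum(axis=1)
    off = np.exp(offset_log)
    beta = np.log(np.maximum(tot, 0.5) / off.sum())
    phi = phi[:, None]
    for _ in range(n_iter):
        mu = np.exp(beta[:, None] + offset_log[None, :])
        score = ((y - mu) / (1.0 + phi * mu)).sum(axis=1)
        info = (mu / (1.0 + phi * mu)).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5, 5)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = np.exp(beta[:, None] + offset_log[None, :])
    info = (mu / (1.0 + phi * mu)).sum(axis=1)
    return beta, info


def de_test_nbwald(
    cm: CountMatrix,
    groups: Sequence[str],
    factors: np.ndarray,
    disp: DispersionFit,
    comparison: str | None = None,
) -> pd.DataFrame:
    """NB Wald test: MLE group means at fixed dispersion, normal z on logFC."""
    i_ref, i_alt, ref, alt = _group_indices(groups)
    if len(i_ref) < 2 or len(i_alt) < 2:
        raise ValueError("each group needs >= 2 samples")
    comparison = comparison or f"{alt}_vs_{ref}"
    lib = cm.counts.sum(axis=0).astype(float) * np.asarray(factors, dtype=float)
    offset = np.log(lib)
    phi = disp.phi_shrunk

    y = cm.counts.astype(float)
    b_ref, i_ref_info = _fit_nb_group(y[:, i_ref], offset[i_ref], phi)
    b_alt, i_alt_info = _fit_nb_group(y[:, i_alt], offset[i_alt], phi)

    dbeta = b_alt - b_ref
    se = np.sqrt(1.0 / np.maximum(i_ref_info, 1e-12)
                 + 1.0 / np.maximum(i_alt_info, 1e-12))
    z = dbeta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    lfc = dbeta / LN2

    allzero = cm.counts.sum(axis=1) == 0
    onesided_zero = (y[:, i_ref].sum(axis=1) == 0) | (y[:, i_alt].sum(axis=1) == 0)
    bad = allzero | ~np.isfinite(p) | ~np.isfinite(lfc)
    p = np.where(bad, 1.0, p)
    lfc = np.where(allzero, 0.0, np.where(np.isfinite(lfc), lfc, 0.0))
    # one group all-zero: logFC is at the working boundary; keep the Wald p
    # from the damped fit rather than claiming infinite fold-change
    lfc = np.where(onesided_zero & ~allzero, np.clip(lfc, -30, 30), lfc)
    return _de_frame(cm.feature_ids, lfc, p, "nbwald", comparison)


def _log_nb_pmf_range(k: np.ndarray, r: float, p1: float) -> np.ndarray:
    """log NB pmf over a contiguous integer range via a stable recurrence.

    Parameterization: pmf(k) = C(k+r-1, k) p1^r (1-p1)^k.
    """
    k0 = int(k[0])
    base = (
        special.gammaln(k0 + r) - special.gammaln(r) - special.gammaln(k0 + 1)
        + r * np.log(p1) + k0 * np.log1p(-p1)
    )
    if len(k) == 1:
        return np.array([base])
    kk = k[:-1].astype(float)
    steps = np.log(kk + r) - np.log(kk + 1.0) + np.log1p(-p1)
    return base + np.concatenate([[0.0], np.cumsum(steps)])


def _exact_nb_split_pvalue(
    s1: int, s2: int, n1: int, n2: int, phi: float, window_sd: float = 12.0
) -> float:
    """Two-sided exact conditional NB test of the split (s1, s2) given s1+s2.

    Group sums are NB with size n_g/phi and a common per-sample mean m;
    conditioning removes m only approximately unless the sizes are
    proportional to n_g — which they are here, so the conditional law
    P(S1=k | S1+S2=s) ∝ f1(k) f2(s-k) is mean-free.  The enumeration is
    windowed for large totals (the conditional mass outside ±window_sd
    conditional standard deviations is negligible).
    """
    s = s1 + s2
    if s == 0:
        return 1.0
    m = s / (n1 + n2)  # per-sample mean under the null
    if phi <= 0:
        phi = 1e-12
    r1, r2 = n1 / phi, n2 / phi
    # NB success prob shared by both groups: p = r/(r+mean) with mean = n_g*m
    p1 = r1 / (r1 + n1 * m)

    mean1 = s * n1 / (n1 + n2)
    var1 = n1 * m * (1.0 + phi * m)
    var2 = n2 * m * (1.0 + phi * m)
    cond_sd = np.sqrt(max(var1 * var2 / (var1 + var2), 0.25))
    lo = max(0, int(np.floor(mean1 - window_sd * cond_sd)))
    hi = min(s, int(np.ceil(mean1 + window_sd * cond_sd)))
    if s <= 10_000:
        lo, hi = 0, s
    k = np.arange(lo, hi + 1)
    logf = _log_nb_pmf_range(k, r1, p1) + _log_nb_pmf_range(s - k[::-1], r2, p1)[::-1]
    logf -= special.logsumexp(logf)
    f = np.exp(logf)
    obs = np.clip(s1, lo, hi) - lo
    lower = f[: obs + 1].sum()
    upper = f[obs:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def de_test_nbexact(
    cm: CountMatrix,
    groups: Sequence[str],
    factors: np.ndarray,
    disp: DispersionFit,
    comparison: str | None = None,
) -> pd.DataFrame:
    """Exact conditional NB test on group sums of library-equalized pseudo-counts."""
    i_ref, i_alt, ref, alt = _group_indices(groups)
    comparison = comparison or f"{alt}_vs_{ref}"
    lib = cm.counts.sum(axis=0).astype(float) * np.asarray(factors, dtype=float)
    common = np.exp(np.mean(np.log(lib)))
    pseudo = np.round(cm.counts * (common / lib)[None, :]).astype(np.int64)

    n1, n2 = len(i_ref), len(i_alt)
    s_ref = pseudo[:, i_ref].sum(axis=1)
    s_alt = pseudo[:, i_alt].sum(axis=1)

    p = np.ones(cm.n_features)
    lfc = np.zeros(cm.n_features)
    for i in range(cm.n_features):
        s1, s2 = int(s_alt[i]), int(s_ref[i])
        if s1 + s2 == 0:
            continue
        phi = float(disp.phi_shrunk[i])
        p[i] = _exact_nb_split_pvalue(s1, s2, n2, n1, phi)
        m1 = (s1 + 0.5) / n2
        m2 = (s2 + 0.5) / n1
        lfc[i] = np.log2(m1 / m2)
    allzero = (s_ref + s_alt) == 0
    lfc[allzero] = 0.0
    return _de_frame(cm.feature_ids, lfc, p, "nbexact", comparison)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/y asymptote start)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif / y) < 1e-10:
            break
    return float(y)


def de_test_modt(
    tm: TransformedMatrix,
    groups: Sequence[str],
    comparison: str | None = None,
) -> pd.DataFrame:
    """Moderated t on precision-weighted log-CPM.

    Per feature, a weighted two-group least-squares fit; residual
    variances are shrunk toward a common prior (d0, s0^2) estimated by
    method of moments on log s^2; t has d0 + d degrees of freedom.
    """
    if tm.transform_id != "weighted_logcpm" or tm.weights is None:
        raise ValueError("de_test_modt requires a weighted_logcpm matrix")
    i_ref, i_alt, ref, alt = _group_indices(groups)
    comparison = comparison or f"{alt}_vs_{ref}"
    n = len(i_ref) + len(i_alt)
    d = n - 2
    if d < 1:
        raise ValueError("need more than 2 samples in total")

    v, w = tm.values, tm.weights
    sw_ref = w[:, i_ref].sum(axis=1)
    sw_alt = w[:, i_alt].sum(axis=1)
    mean_ref = (w[:, i_ref] * v[:, i_ref]).sum(axis=1) / sw_ref
    mean_alt = (w[:, i_alt] * v[:, i_alt]).sum(axis=1) / sw_alt
    delta = mean_alt - mean_ref

    rss = (w[:, i_ref] * (v[:, i_ref] - mean_ref[:, None]) ** 2).sum(axis=1) + (
        w[:, i_alt] * (v[:, i_alt] - mean_alt[:, None]) ** 2
    ).sum(axis=1)
    s2 = rss / d
    c = 1.0 / sw_ref + 1.0 / sw_alt

    s2_safe = np.maximum(s2, 1e-300)
    if len(s2) >= 2:
        e = np.log(s2_safe)
        var_e = e.var(ddof=1)
        target = var_e - special.polygamma(1, d / 2.0)
        if target > 1e-8:
            d0 = 2.0 * _trigamma_inverse(float(target))
            log_s0 = (
                e.mean()
                - special.digamma(d / 2.0) + np.log(d / 2.0)
                + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
            )
            s0 = np.exp(log_s0)
        else:
            # variances indistinguishable: infinite prior df at their
            # geometric mean, so moderation is a no-op at a common value
            d0 = np.inf
            s0 = np.exp(e.mean())
    else:
        d0, s0 = 0.0, 0.0  # single feature: no pooling possible

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0 + d * s2) / (d0 + d)
        df_total = d0 + d

    t = delta / np.sqrt(s2_tilde * c)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return _de_frame(tm.feature_ids, delta, p, "modt", comparison)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def consensus_calls(
    tables: Sequence[pd.DataFrame], alpha: float = 0.05, use_raw_p: bool = False
) -> pd.DataFrame:
    """>=2-of-3 consensus with sign agreement.

    A method votes for a feature when its (BH-adjusted, by default)
    p-value is <= alpha.  Consensus requires at least two votes with an
    identical log2FC sign; mixed-sign vote sets are flagged discordant.
    """
    if len(tables) != 3:
        raise ValueError("consensus requires exactly three method tables")
    feats = list(tables[0]["feature_id"])
    for t in tables[1:]:
        if list(t["feature_id"]) != feats:
            raise ValueError("method tables cover different feature sets")
    col = "pvalue" if use_raw_p else "qvalue"

    votes = np.column_stack([t[col].to_numpy() <= alpha for t in tables])
    signs = np.column_stack([np.sign(t["log2fc"].to_numpy()) for t in tables])

    n_sig = votes.sum(axis=1).astype(int)
    direction = []
    consensus = []
    for i in range(len(feats)):
        s = signs[i, votes[i]]
        s = s[s != 0]
        if n_sig[i] >= 2 and len(s) >= 2 and (s > 0).all():
            direction.append("up"); consensus.append(True)
        elif n_sig[i] >= 2 and len(s) >= 2 and (s < 0).all():
            direction.append("down"); consensus.append(True)
        elif n_sig[i] >= 2 and len(np.unique(s)) > 1:
            direction.append("discordant"); consensus.append(False)
        else:
            direction.append("none"); consensus.append(False)
    return pd.DataFrame(
        {
            "feature_id": feats,
            "n_significant": n_sig,
            "direction": direction,
            "consensus": consensus,
        }
    )
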