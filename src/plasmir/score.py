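"""Composite standardized biomarker scores and Mann-Whitney ROC/AUC.

Features are z-scored against a reference cohort (mean 0, sd 1 on that
cohort; external samples are projected with the same parameters).  The
composite score of a panel adds the z of up-regulated features and
subtracts the z of down-regulated ones.  Discrimination is quantified
by the Mann-Whitney AUC with midrank tie handling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from plasmir.diffexp import bh_adjust
from plasmir.normalize import TransformedMatrix


@dataclass
class ScorePanel:
    """Disjoint up/down feature sets with per-feature standardization params."""

    up_features: list[str]
    down_features: list[str]
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    cohort: list[str] = field(default_factory=list)
    transform_id: str = ""

    def __post_init__(self) -> None:
        overlap = set(self.up_features) & set(self.down_features)
        if overlap:
            raise ValueError(f"features in both directions: {sorted(overlap)}")
        if any(sd <= 0 for sd in self.sds.values()):
            raise ValueError("standardization sd must be > 0")

    @property
    def features(self) -> list[str]:
        return self.up_features + self.down_features


def standardize_features(
    tm: TransformedMatrix, cohort: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, float], dict[str, float]]:
    """z-score every feature against the given cohort; project all samples.

    Returns (z features x samples, means, sds).  Features with zero sd
    on the cohort are dropped with a warning.
    """
    cohort = list(cohort)
    if len(cohort) < 2:
        raise ValueError("standardization cohort needs >= 2 samples")
    idx = [tm.sample_ids.index(s) for s in cohort]
    sub = tm.values[:, idx]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [f for f, k in zip(tm.feature_ids, keep) if not k]
        warnings.warn(f"dropped zero-variance feature(s): {dropped}", stacklevel=2)
    z = (tm.values[keep] - mean[keep, None]) / sd[keep, None]
    feats = [f for f, k in zip(tm.feature_ids, keep) if k]
    zdf = pd.DataFrame(z, index=feats, columns=tm.sample_ids)
    means = dict(zip(feats, mean[keep]))
    sds = dict(zip(feats, sd[keep]))
    return zdf, means, sds


def composite_score(z: pd.DataFrame, panel: ScorePanel) -> pd.Series:
    """Per-sample sum of up-feature z minus sum of down-feature z."""
    missing = [f for f in panel.features if f not in z.index]
    if missing:
        raise KeyError(f"panel feature(s) absent from z-matrix: {missing}")
    score = pd.Series(0.0, index=z.columns)
    if panel.up_features:
        score = score + z.loc[panel.up_features].sum(axis=0)
    if panel.down_features:
        score = score - z.loc[panel.down_features].sum(axis=0)
    score.name = "composite_score"
    return score


def auc_mw(
    values: np.ndarray,
    labels: np.ndarray,
    case_label=1,
    exact_below: int = 12,
) -> tuple[float, float]:
    """Mann-Whitney AUC = P(case > control) + 0.5 P(tie), with a p-value.

    p comes from the normal approximation with tie-corrected variance;
    below ``exact_below`` total samples the exact permutation null of U
    is enumerated instead.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    cases = values[labels == case_label]
    ctrls = values[labels != case_label]
    n1, n2 = len(cases), len(ctrls)
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be non-empty")

    ranks = stats.rankdata(values)
    u = ranks[labels == case_label].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n2)

    n = n1 + n2
    if n <= exact_below:
        idx = np.arange(n)
        us = []
        for combo in combinations(idx, n1):
            r = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
            us.append(r)
        us = np.asarray(us)
        p = np.mean(np.abs(us - n1 * n2 / 2.0) >= abs(u - n1 * n2 / 2.0) - 1e-12)
        return float(auc), float(p)

    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        return float(auc), 1.0
    zstat = (u - n1 * n2 / 2.0) / math.sqrt(var_u)
    p = 2.0 * stats.norm.sf(abs(zstat))
    return float(auc), float(min(p, 1.0))


def per_feature_auc(
    tm: TransformedMatrix,
    labels: Sequence,
    case_label=1,
) -> pd.DataFrame:
    """AUC and BH-adjusted p per feature, oriented case-vs-control.

    AUC < 0.5 indicates a feature lower in cases (down-regulated).
    """
    labels = np.asarray(labels)
    out = []
    for i, f in enumerate(tm.feature_ids):
        auc, p = auc_mw(tm.values[i, :], labels, case_label=case_label)
        out.append((f, auc, p))
    df = pd.DataFrame(out, columns=["feature_id", "auc", "pvalue"])
    df["qvalue"] = bh_adjust(df["pvalue"].to_numpy())
    return df


def score_panels_from_consensus(
    consensus: pd.DataFrame,
    means: dict[str, float] | None = None,
    sds: dict[str, float] | None = None,
    cohort: Sequence[str] = (),
    transform_id: str = "",
) -> dict[str, ScorePanel]:
    """Build up-only / down-only / all panels from a consensus table."""
    up = list(consensus.loc[
        consensus["consensus"] & (consensus["direction"] == "up"), "feature_id"
    ])
    down = list(consensus.loc[
        consensus["consensus"] & (consensus["direction"] == "down"), "feature_id"
    ])
    if not up and not down:
        warnings.warn("no consensus calls; panels are empty", stacklevel=2)

    def mk(u: list[str], d: list[str]) -> ScorePanel:
        feats = u + d
        return ScorePanel(
            up_features=u,
            down_features=d,
            means={f: means[f] for f in feats} if means else {},
            sds={f: sds[f] for f in feats} if sds else {},
            cohort=list(cohort),
            transform_id=transform_id,
        )

    return {"up": mk(up, []), "down": mk([], down), "all": mk(up, down)}


def panel_aucs(
    z: pd.DataFrame,
    panels: dict[str, ScorePanel],
    labels: Sequence,
    case_label=1,
) -> pd.DataFrame:
    """Composite-score AUC for each panel (skipping empty panels)."""
    labels = np.asarray(labels)
    rows = []
    for name, panel in panels.items():
        if not panel.features:
            continue
        s = composite_score(z, panel)
        auc, p = auc_mw(s.to_numpy(), labels, case_label=case_label)
        rows.append((name, len(panel.features), auc, p))
    return pd.DataFrame(rows, columns=["panel", "n_features", "auc", "pvalue"])
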