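"""Synthetic plasma miRNA-seq cohorts with known ground truth.

Generates integer count matrices that mimic small-RNA sequencing of
plasma: a heavily skewed baseline abundance profile (a few species
dominate total reads), log-normal library sizes, negative-binomial
overdispersion following a mean-dispersion trend, group-specific
log2 fold-changes in both directions, and exponential survival times
whose hazard is linked to selected feature abundances.

The negative binomial is parameterized as var = mu + phi * mu^2 and is
drawn as a gamma-Poisson mixture.  Fold-changes are applied to latent
relative abundances *before* renormalization to compositions, so an
injected effect induces small compensatory shifts in the other features,
as real sequencing does.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from plasmir.counts_io import CountMatrix, SampleTable, GROUPS

DEFAULT_GROUP_SIZES = {"control": 20, "DLBCL": 14, "HL": 11}


@dataclass
class SurvSpec:
    """Hazard link from selected features to survival outcome."""

    feature_coefs: dict[int, float] = field(default_factory=dict)
    baseline_hazard: float = 0.08  # events per year
    censoring_rate: float = 0.1
    horizon: float = 5.3  # follow-up horizon, years

    def __post_init__(self) -> None:
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring rate must be in [0, 1)")
        if self.horizon <= 0:
            raise ValueError("follow-up horizon must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be > 0")


@dataclass
class SimConfig:
    """Parameters of a simulated cohort."""

    n_features: int = 159
    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    baseline_logmean_params: tuple[float, float] = (0.0, 2.4)  # (meanlog, sdlog)
    libsize_params: tuple[float, float] = (math.log(1e6), 0.35)
    dispersion_trend: tuple[float, float] = (0.05, 2.0)  # phi(mu) = a0 + a1/mu
    biological_sdlog: float = 0.25  # per-cell latent abundance jitter (natural-log sd)
    de_spec: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    surv_spec: SurvSpec = field(default_factory=SurvSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}; allowed: {list(GROUPS)}")
            if n < 1:
                raise ValueError(f"non-positive size for group {g!r}")
        if (
            self.baseline_logmean_params[1] < 0
            or self.libsize_params[1] < 0
            or self.biological_sdlog < 0
        ):
            raise ValueError("sdlog must be >= 0")
        a0, a1 = self.dispersion_trend
        if a0 < 0 or a1 < 0:
            raise ValueError("dispersion trend coefficients must be >= 0")
        for g, spec in self.de_spec.items():
            if g not in self.group_sizes:
                raise ValueError(f"de_spec group {g!r} not in group_sizes")
            for idx, lfc in spec:
                if not (0 <= idx < self.n_features):
                    raise ValueError(f"de_spec feature index {idx} out of range")
                if abs(lfc) > 10:
                    raise ValueError("|log2FC| must be <= 10")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort, for recovery tests."""

    log2fc: pd.DataFrame  # features x patient groups
    surv_features: dict[str, float]  # feature id -> log-hazard coefficient
    baseline_abundance: pd.Series  # latent relative abundance per feature
    latent_logabund: pd.DataFrame  # features x samples, pre-noise log2 abundance

    def to_json(self, path: str | Path) -> None:
        payload = {
            "log2fc": self.log2fc.to_dict(),
            "surv_features": self.surv_features,
            "baseline_abundance": self.baseline_abundance.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _feature_ids(n: int) -> list[str]:
    return [f"miR-sim-{i + 1:03d}" for i in range(n)]


def nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean=mu, var=mu+phi*mu^2) via gamma-Poisson; phi=0 falls back to Poisson."""
    mu = np.asarray(mu, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    lam = mu.copy()
    pos = (phi > 0) & (mu > 0)
    if pos.any():
        lam[pos] = rng.gamma(shape=1.0 / phi[pos], scale=mu[pos] * phi[pos])
    return rng.poisson(lam).astype(np.int64)


def simulate_cohort(
    config: SimConfig,
) -> tuple[CountMatrix, SampleTable, SimTruth]:
    """Draw a full cohort: counts, sample sheet (with survival), and ground truth.

    Identical config (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    nf = config.n_features
    fids = _feature_ids(nf)

    meanlog, sdlog = config.baseline_logmean_params
    base = rng.lognormal(meanlog, sdlog, size=nf)
    base = np.sort(base)[::-1]  # dominant species first, plasma-style
    base /= base.sum()

    sample_ids: list[str] = []
    groups: list[str] = []
    for g in GROUPS:
        n = config.group_sizes.get(g, 0)
        for k in range(n):
            sample_ids.append(f"{g}-{k + 1:02d}")
            groups.append(g)
    ns = len(sample_ids)

    lfc = np.zeros((nf, ns))
    for g, spec in config.de_spec.items():
        cols = [j for j, gr in enumerate(groups) if gr == g]
        for idx, l2 in spec:
            lfc[idx, cols] = l2

    q = base[:, None] * np.power(2.0, lfc)  # latent abundances, then renormalize
    if config.biological_sdlog > 0:
        q = q * np.exp(rng.normal(0.0, config.biological_sdlog, size=q.shape))
    comp = q / q.sum(axis=0, keepdims=True)

    lib_meanlog, lib_sdlog = config.libsize_params
    libs = rng.lognormal(lib_meanlog, lib_sdlog, size=ns)

    mu = libs[None, :] * comp
    a0, a1 = config.dispersion_trend
    with np.errstate(divide="ignore"):
        phi = np.where(mu > 0, a0 + a1 / np.maximum(mu, 1e-12), 0.0)
    counts = nb_draw(rng, mu, phi)

    cm = CountMatrix(counts, fids, sample_ids)

    truth_lfc = pd.DataFrame(0.0, index=fids, columns=[g for g in GROUPS if g != "control"])
    for g, spec in config.de_spec.items():
        if g == "control":
            continue
        for idx, l2 in spec:
            truth_lfc.loc[fids[idx], g] = l2
    truth = SimTruth(
        log2fc=truth_lfc,
        surv_features={
            fids[i]: c for i, c in config.surv_spec.feature_coefs.items()
        },
        baseline_abundance=pd.Series(base, index=fids),
        latent_logabund=pd.DataFrame(np.log2(comp), index=fids, columns=sample_ids),
    )

    st = SampleTable(pd.DataFrame({"sample_id": sample_ids, "group": groups}))
    st = simulate_survival(config, truth, st, rng=rng)
    return cm, st, truth


def simulate_survival(
    config: SimConfig,
    latent: SimTruth,
    samples: SampleTable,
    rng: np.random.Generator | None = None,
) -> SampleTable:
    """Attach exponential survival times to patient samples.

    log-hazard = log(baseline) + sum over linked features of
    coef * z(latent log abundance), z-scored across patients.  Random
    censoring is exponential, calibrated so that under the baseline
    hazard a fraction ``censoring_rate`` of subjects is censored before
    their event; administrative censoring applies at the horizon.
    """
    spec = config.surv_spec
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    df = samples.frame.copy()
    patients = df["group"] != "control"
    if not patients.any():
        return samples
    pat_ids = list(df.loc[patients, "sample_id"])

    loghaz = np.full(len(pat_ids), math.log(spec.baseline_hazard))
    for fid, coef in latent.surv_features.items():
        vals = latent.latent_logabund.loc[fid, pat_ids].to_numpy(dtype=float)
        sd = vals.std(ddof=0)
        z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
        loghaz = loghaz + coef * z

    t_event = rng.exponential(1.0 / np.exp(loghaz))
    if spec.censoring_rate > 0:
        c_rate = spec.baseline_hazard * spec.censoring_rate / (1 - spec.censoring_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=len(pat_ids))
    else:
        t_cens = np.full(len(pat_ids), np.inf)
    t_cens = np.minimum(t_cens, spec.horizon)

    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-6)  # times strictly positive

    df["time"] = np.nan
    df["event"] = np.nan
    df.loc[patients, "time"] = time
    df.loc[patients, "event"] = event.astype(float)
    return SampleTable(df)


def default_de_spec(
    n_features: int = 159,
    n_up: int = 8,
    n_down: int = 8,
    log2fc: float = 1.5,
    seed: int = 0,
) -> dict[str, list[tuple[int, float]]]:
    """Pick disjoint up/down feature sets for both patient groups.

    Indices are drawn from the mid-abundance range (skipping the top-5
    dominant species) so injected effects are detectable but do not
    overwhelm the composition.
    """
    rng = np.random.default_rng(seed)
    lo, hi = 5, max(6, int(0.8 * n_features))
    spec: dict[str, list[tuple[int, float]]] = {}
    for g in ("DLBCL", "HL"):
        idx = rng.choice(np.arange(lo, hi), size=n_up + n_down, replace=False)
        spec[g] = [(int(i), log2fc) for i in idx[:n_up]] + [
            (int(i), -log2fc) for i in idx[n_up:]
        ]
    return spec
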