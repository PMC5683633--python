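"""End-to-end orchestration of the plasma miRNA analysis under one seed.

Stages run in dependency order: load-or-simulate, detection filter,
normalization/transforms + PCA, per-comparison DE consensus, composite
scores and per-feature AUCs, classifier validation, survival screen and
Cox confirmation.  Each stage writes plain TSV/JSON outputs into the
run directory and contributes to a machine-readable summary.  A single
global seed deterministically spawns per-stage sub-seeds, so stages are
reproducible in isolation.
"""

from __future__ import annotations

import json
import logging
import time as _time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from plasmir import classify, counts_io, diffexp, normalize, score, simdata, survival
from plasmir.counts_io import CountMatrix, SampleTable, write_table

log = logging.getLogger("plasmir")


@dataclass
class PipelineConfig:
    """Flat configuration mirroring the CLI flags."""

    counts_path: str | None = None
    samples_path: str | None = None
    simulate: bool = False
    sim: dict = field(default_factory=dict)  # forwarded to SimConfig
    comparisons: list[str] = field(default_factory=lambda: ["DLBCL", "HL"])
    alpha: float = 0.05
    min_reads: int = 1
    min_fraction: float = 0.25
    de_transform: str = "weighted_logcpm"
    score_transform: str = "weighted_logcpm"
    classifier_transform: str = "weighted_logcpm"
    classifier_protocol: str = "mrv"
    n_iter: int = 1000
    train_fraction: float = 0.5
    panel_size: int = 80
    inclusion_n_iter: int = 200
    survival_n_resamples: int = 20
    survival_n_perm: int = 100
    seed: int = 0
    out_dir: str = "plasmir-run"

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if not self.simulate and (self.counts_path is None or self.samples_path is None):
            raise ValueError("either set simulate or provide counts and samples paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed from the stage name."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class ReportBundle:
    """Manifest of stage outputs plus the run summary."""

    out_dir: Path
    manifest: list[str]
    summary: dict[str, Any]

    def write(self) -> None:
        (self.out_dir / "summary.json").write_text(
            json.dumps(self.summary, indent=2, sort_keys=True, default=_jsonable)
        )
        (self.out_dir / "manifest.json").write_text(
            json.dumps(sorted(self.manifest), indent=2)
        )


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _load_inputs(
    cfg: PipelineConfig,
) -> tuple[CountMatrix, SampleTable, simdata.SimTruth | None]:
    if cfg.simulate:
        sim_kwargs = dict(cfg.sim)
        if "de_spec" not in sim_kwargs:
            sim_kwargs["de_spec"] = simdata.default_de_spec(
                sim_kwargs.get("n_features", 159), seed=cfg.seed
            )
        if "surv_spec" in sim_kwargs and isinstance(sim_kwargs["surv_spec"], dict):
            sim_kwargs["surv_spec"] = simdata.SurvSpec(**sim_kwargs["surv_spec"])
        sim_kwargs.setdefault("seed", stage_seed(cfg.seed, "simulate"))
        sc = simdata.SimConfig(**sim_kwargs)
        cm, st, truth = simdata.simulate_cohort(sc)
        return cm, st, truth
    cm = counts_io.read_counts(cfg.counts_path)
    st = counts_io.read_samples(cfg.samples_path)
    missing = set(st.sample_ids) - set(cm.sample_ids)
    if missing:
        raise ValueError(f"sample sheet ids absent from counts: {sorted(missing)}")
    cm = cm.subset_samples(st.sample_ids)
    return cm, st, None


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute all stages; identical config + seed gives identical outputs."""
    t0 = _time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict[str, Any] = {"seed": cfg.seed, "stages": {}}

    def emit(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        write_table(df, path, index=index)
        manifest.append(name)

    cm, st, truth = _load_inputs(cfg)
    log.info("input: %d features x %d samples", cm.n_features, cm.n_samples)
    counts_io.write_counts(cm, out / "counts.tsv")
    counts_io.write_samples(st, out / "samples.tsv")
    manifest += ["counts.tsv", "samples.tsv"]
    if truth is not None:
        truth.to_json(out / "sim_truth.json")
        manifest.append("sim_truth.json")

    # --- detection filter -------------------------------------------------
    cm_f = normalize.filter_detected(cm, cfg.min_reads, cfg.min_fraction)
    summary["stages"]["filter"] = {
        "n_input": cm.n_features, "n_detected": cm_f.n_features,
    }
    log.info("filter: %d of %d features detected", cm_f.n_features, cm.n_features)

    # --- transforms and PCA ----------------------------------------------
    groups_all = [st.groups[s] for s in cm_f.sample_ids]
    tm = normalize.transform_counts(cm_f, cfg.de_transform)
    scores_pca, evf = normalize.pca_scores(tm, n_components=min(4, cm_f.n_samples - 1))
    pca_df = pd.DataFrame(
        scores_pca, index=cm_f.sample_ids,
        columns=[f"PC{i + 1}" for i in range(scores_pca.shape[1])],
    )
    pca_df["group"] = groups_all
    emit(pca_df.rename_axis("sample_id"), "pca_scores.tsv", index=True)
    summary["stages"]["pca"] = {"explained_variance": list(map(float, evf))}

    # --- per-comparison DE, scores, classifier ---------------------------
    for patient_group in cfg.comparisons:
        comp = f"{patient_group}_vs_control"
        ids = st.ids_in_group("control") + st.ids_in_group(patient_group)
        if len(st.ids_in_group(patient_group)) < 2:
            summary["stages"][comp] = {"skipped": "fewer than 2 patient samples"}
            continue
        sub = cm_f.subset_samples(ids)
        groups = [st.groups[s] for s in ids]
        labels01 = np.asarray([0 if g == "control" else 1 for g in groups])

        mr = normalize.size_factors_median_ratio(sub)
        tmm = normalize.norm_factors_tmm(sub)
        disp = diffexp.estimate_dispersions(sub, mr, groups)
        tm_w = normalize.precision_weights(sub, tmm)

        t_wald = diffexp.de_test_nbwald(sub, groups, mr, disp, comparison=comp)
        t_exact = diffexp.de_test_nbexact(sub, groups, tmm, disp, comparison=comp)
        t_modt = diffexp.de_test_modt(tm_w, groups, comparison=comp)
        for t in (t_wald, t_exact, t_modt):
            emit(t, f"de_{t['method'].iloc[0]}_{comp}.tsv")
        cons = diffexp.consensus_calls([t_wald, t_exact, t_modt], alpha=cfg.alpha)
        emit(cons, f"consensus_{comp}.tsv")

        z, means, sds = score.standardize_features(tm_w, ids)
        panels = score.score_panels_from_consensus(
            cons, means, sds, cohort=ids, transform_id=tm_w.transform_id
        )
        aucs = score.panel_aucs(z, panels, labels01)
        emit(aucs, f"panel_auc_{comp}.tsv")
        feat_auc = score.per_feature_auc(tm_w, labels01)
        emit(feat_auc, f"feature_auc_{comp}.tsv")

        scores_df = pd.DataFrame({"sample_id": ids, "group": groups})
        for name, panel in panels.items():
            if panel.features:
                scores_df[f"score_{name}"] = score.composite_score(z, panel).to_numpy()
        emit(scores_df, f"composite_scores_{comp}.tsv")

        cls_seed = stage_seed(cfg.seed, f"classify-{comp}")
        rep = classify.validate_mrv(
            tm_w, labels01, n_iter=cfg.n_iter, train_fraction=cfg.train_fraction,
            n_features=cfg.panel_size, seed=cls_seed,
        )
        inc = classify.validate_mrv(
            tm_w, labels01, n_iter=cfg.inclusion_n_iter,
            train_fraction=cfg.train_fraction,
            n_features=min(80, tm_w.n_features), seed=cls_seed + 1,
        )
        emit(
            pd.DataFrame({"iteration": np.arange(len(rep.rates)), "rate": rep.rates}),
            f"misclassification_{comp}.tsv",
        )
        emit(
            inc.inclusion_rates.sort_values(ascending=False)
            .rename("inclusion_rate").rename_axis("feature_id").reset_index(),
            f"inclusion_rates_{comp}.tsv",
        )
        summary["stages"][comp] = {
            "n_consensus": int(cons["consensus"].sum()),
            "n_up": int((cons["direction"] == "up").sum()),
            "n_down": int((cons["direction"] == "down").sum()),
            "panel_auc": {r["panel"]: float(r["auc"]) for _, r in aucs.iterrows()},
            "misclassification_median": rep.median_rate,
            "misclassification_iqr": list(rep.iqr),
        }

    # --- survival ---------------------------------------------------------
    if st.has_survival:
        pat_ids = [s for s in st.sample_ids if st.groups[s] != "control"]
        pat = st.subset(pat_ids)
        t = pat.frame["time"].to_numpy(dtype=float)
        e = pat.frame["event"].to_numpy(dtype=int)
        cm_pat = cm_f.subset_samples(pat_ids)
        sseed = stage_seed(cfg.seed, "survival")
        ranks = survival.depth_standardized_ranks(
            cm_pat, n_resamples=cfg.survival_n_resamples, seed=sseed
        )
        screen = survival.permutation_null(
            ranks, t, e, n_perm=cfg.survival_n_perm, seed=sseed + 1
        )
        emit(screen, "survival_screen.tsv")

        top = screen.reindex(screen["observed"].abs().sort_values(ascending=False).index)
        cox_rows = []
        for fid in top["feature_id"].head(8):
            x = survival.dichotomize_median(ranks.loc[fid].to_numpy())
            if len(np.unique(x)) < 2:
                continue
            cox_rows.append(survival.cox_fit_binary(x, t, e, feature_id=fid).as_row())
        if cox_rows:
            emit(pd.DataFrame(cox_rows), "cox_top_features.tsv")

        km = survival.km_curve(t, e)
        emit(
            pd.DataFrame({
                "time": km.times, "survival": km.survival,
                "ci_lower": km.ci_lower, "ci_upper": km.ci_upper,
                "n_at_risk": km.n_at_risk,
            }),
            "km_all_patients.tsv",
        )
        summary["stages"]["survival"] = {
            "n_patients": len(pat_ids),
            "n_events": int(e.sum()),
            "n_hits_q25": int((screen["qvalue"] < 0.25).sum()),
            "km_5y": km.at(5.0),
        }
    else:
        summary["stages"]["survival"] = {"skipped": "no survival columns"}
        log.info("survival stage skipped: no survival columns")

    # run metadata is kept out of summary.json so reruns under the same
    # seed stay byte-identical
    import plasmir

    (out / "run_meta.json").write_text(json.dumps({
        "version": plasmir.__version__,
        "seed": cfg.seed,
        "wall_time_s": round(_time.time() - t0, 3),
    }, indent=2))
    bundle = ReportBundle(
        out, manifest + ["summary.json", "manifest.json", "run_meta.json"], summary
    )
    bundle.write()
    return bundle
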