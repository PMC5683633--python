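# plasmir

Plasma circulating-miRNA biomarker discovery, packaged as a tested,
reusable pipeline:

- **simdata** — synthetic plasma miRNA-seq cohorts (skewed abundance
  profile, log-normal library sizes, NB overdispersion with a
  mean-dispersion trend, injected group log2 fold-changes, exponential
  survival linked to selected features) with full ground truth.
- **counts_io** — validated count-matrix / sample-sheet I/O (TSV/CSV,
  optional gzip) and technical-repeat aggregation.
- **normalize** — detection filter (≥1 read in ≥25% of samples),
  median-of-ratios and TMM factors, log-CPM, voom-style precision
  weights, a closed-form NB variance-stabilizing transform, and PCA.
- **diffexp** — three independent two-group differential-abundance
  tests (NB Wald, exact conditional NB, moderated t on weighted
  log-CPM), BH adjustment, and the ≥2-of-3 sign-consistent consensus
  caller.
- **score** — per-feature z-standardization, composite
  up-minus-down biomarker scores, and Mann-Whitney ROC/AUC for single
  features and panels.
- **classify** — nearest-centroid classification with Welch-|t| feature
  filtering, single-split / LOOCV / multiple-random-validation
  protocols, misclassification distributions and feature inclusion
  rates.
- **survival** — depth-standardized rank screen with a permutation
  null (Q-Q expected scores, SAM-style q-values), univariable Cox PH on
  median-dichotomized levels, Kaplan-Meier with Greenwood CIs.
- **pipeline** — seeded end-to-end orchestration with TSV/JSON outputs.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: brute-force
oracle equivalences, null calibration of the three DE tests (200
simulations), injected-signal recovery, classifier sanity (including an
information-leakage check), and survival-effect recovery.

## Command line

Every stage is a subcommand of `plasmir` (or `python -m plasmir.cli`):

```bash
# simulate a cohort (159 miRNAs; 20 control / 14 DLBCL / 11 HL)
plasmir simulate --seed 7 --out run/

# three DE tests + consensus for one comparison
plasmir de --counts run/counts.tsv --samples run/samples.tsv \
    --comparison DLBCL_vs_control --alpha 0.05 --out run/

# composite scores and AUCs from the consensus panel
plasmir score --counts run/counts.tsv --samples run/samples.tsv \
    --consensus run/consensus_DLBCL_vs_control.tsv --panel all --out run/

# nearest-centroid multiple random validation (1000 x 50% splits)
plasmir classify --counts run/counts.tsv --samples run/samples.tsv \
    --protocol mrv --n-iter 1000 --panel-size 80 --seed 7 --out run/

# survival screen + Cox confirmation
plasmir survival --counts run/counts.tsv --samples run/samples.tsv \
    --n-perm 100 --seed 7 --out run/

# everything, from a YAML config
plasmir all --config examples/pipeline.yaml --seed 7 --out run/
```

A minimal pipeline config:

```yaml
simulate: true            # or counts_path/samples_path for real data
alpha: 0.05
n_iter: 1000              # MRV iterations
panel_size: 80
survival_n_perm: 100
seed: 7
out_dir: run
```

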