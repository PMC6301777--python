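# csme

Cell-subtype Specific Methylation Estimation (CSME): estimate per-CpG
cell-type methylation differences from mixed-cell (whole blood) beta values
and per-sample cell-type proportions, using per-CpG simple linear
regression, and quantify how trustworthy those estimates are.

The package provides the full evaluation pipeline:

1. **`csme.synthetic_data`** — simulate paired cell-sorted / mixed-cell
   beta-value datasets under the linear mixing model
   `y_ij = Σ_k p_ik·x_jk + e_ij`, `e_ij ~ Normal(0, σ_j)`, clipped to
   [0, 1] (clipping counted, never silent). Supports a `fixed_remainder`
   design (exact noiseless recovery oracle) and a `dirichlet` design
   (realistic correlated compositions).
2. **`csme.data_io`** — beta matrices, proportion tables, cell-type schemes
   (7 leukocyte base types plus the Lymphocyte-I/II, Myeloid-I/II and Pan-T
   lineage groupings), TSV readers/writers, proportion agglomeration.
3. **`csme.reference_panels`** — cell-sorted reference estimates
   (difference of sorted means) and candidate CpG panels via two-sample
   pooled t-tests with Benjamini–Hochberg FDR control (default 1e-4).
4. **`csme.lr_estimation`** — per-CpG OLS of mixed betas on the
   (agglomerated) target proportion; the slope is the estimate of the
   target-minus-rest methylation difference (deliberately unconstrained).
5. **`csme.calibration_filter`** — affine calibration of the estimates
   against the reference over the candidate panel, the standardized
   discrepancy `D = (calibrated − cell_sorted) / SE(calibrated)`, and the
   two-sided t(N−2) screen (alpha 0.05) that yields the robust panel.
6. **`csme.evaluation_report`** — MAE / MMCE / R² panel summaries
   (12-row report for the default scheme), panel-overlap validation, and
   hierarchical clustering of sorted samples with a label-purity score.

## CLI

```bash
csme simulate --config config.yaml --out-dir data/        # synthetic bundle
csme panels   --sorted data/betas_sorted.tsv --out-dir out/
csme estimate --mixed data/betas_mixed.tsv --proportions data/proportions.tsv \
              --panel out/panel_CD8T.tsv --out-dir out/
csme robust   --panel out/panel_CD8T.tsv --estimates out/estimates_CD8T.tsv \
              --reference out/reference_CD8T.tsv --n-samples 6 --out-dir out/
csme evaluate --sorted data/betas_sorted.tsv --mixed data/betas_mixed.tsv \
              --proportions data/proportions.tsv --out-dir out/   # report.tsv
csme validate --panel-a out/robust_CD8T.tsv --panel-b other/robust_CD8T.tsv
csme cluster  --sorted data/betas_sorted.tsv --panel out/panel_CD8T.tsv --top-n 1000
```

Common flags: `--fdr` (default 1e-4), `--d-alpha` (default 0.05),
`--ae-threshold` (default 0.05), `--seed`, `--out-dir`, `--log-level`.

A minimal simulation config:

```yaml
n_cpgs: 20000
n_subjects: 6
diff_fraction: 0.05
effect_size: 0.4
noise_sd: 0.01
within_subject_sd: 0.01
proportion_mode: fixed_remainder   # or dirichlet
target: CD8T                       # varied target in fixed_remainder mode
seed: 1
```

## Python API

```python
from csme import SimulationConfig, generate_dataset, DEFAULT_SCHEME, run_all

bundle = generate_dataset(SimulationConfig(n_cpgs=5000, n_subjects=6, seed=1))
report, results = run_all(
    bundle.sorted_data, bundle.mixed_data, bundle.proportions, DEFAULT_SCHEME
)
print(report)   # 12 rows: panel_size, MAE, MMCE, R², %AE<0.05, mean proportion
```

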