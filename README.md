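# ensemblerate

Models and analysis pipeline for rating experiments in which observers
report either the pleasure of **one of four** simultaneously shown images
or the **combined** pleasure of all four, against single-image baseline
ratings on a 1–9 key-press scale.

The package provides:

* **Data model & IO** (`ensemblerate.data`) — a validated trial-level
  schema (`TrialRecord`, `BaselineTable`, `Dataset`) stored as plain CSV
  (`trials.csv`, `baselines.csv`), plus a column-map importer for
  externally deposited raw data.
* **Rating models** (`ensemblerate.models`) — eight single-target
  families (faithful, averaging, average-biased, position-weighted,
  weighted-average-biased, linear, pleasure-rank-weighted, high-pleasure
  attenuation) and three combined families (faithful averaging, linear
  transform, attenuation), all with declared box/simplex parameter
  bounds.
* **Synthetic observers** (`ensemblerate.synth`) — seeded generation of
  the full trial design (alternating precue/postcue blocks, every image
  once as target and once in a combined quadruple per block, final
  baseline block) and response simulation with per-condition late noise,
  half-up rounding, clipping, and a constant uniform-guess rate.
* **Fitting & cross-validation** (`ensemblerate.fitting`) — per
  participant leave-one-out cross-validated RMSE fitting with a fixed
  deterministic multi-start grid (closed-form solutions where the
  objective is quadratic), plus cross-participant comparison tables with
  SEMs and winner counts.
* **Analysis** (`ensemblerate.analysis`) — faithful-prediction errors
  with 1-point prediction binning, per-bin rating SDs, Pearson
  correlations and paired t-tests across conditions, and seeded k-means
  clustering of fitted linear-transform parameters with an elbow rule.
* **Pipeline & CLI** (`ensemblerate.pipeline`, `ensemblerate.cli`) —
  simulate → fit → analyze → report as one reproducible, byte-stable run.

## CLI

```bash
# synthetic dataset (CSV tables) for 25 observers
ensemblerate simulate --n-participants 25 --seed 1 \
    --observer-config observers.yaml --out data/

# LOOCV fits for all model families and conditions
ensemblerate fit --data data/ --models all --conditions all --out fits.csv

# error/variability summaries, tests, clustering
ensemblerate analyze --data data/ --fits fits.csv --out analysis/

# everything at once, from a YAML config
ensemblerate run --config run.yaml
ensemblerate report --bundle out/
```

An observer config describes the generative population, e.g.

```yaml
single_model:
  precue:  {family: faithful}
  postcue: {family: high_pleasure_attenuation, params: {P_beau: 4.6, g: 0.5}}
combined_model: {family: linear_combined, params: {a: -1.4, b: 1.2}}
sigma_late: {postcue_1of4: 1.65}   # unspecified conditions keep defaults (1.5)
guess_rate: 0.05
jitter: {P_beau: 0.5, g: 0.1}      # per-participant parameter spread
```

A `run.yaml` for the full pipeline:

```yaml
seed: 1
out_dir: out
design: {n_participants: 25, n_images: 36, n_blocks: 8}
observer_population:
  single_model:
    postcue: {family: high_pleasure_attenuation, params: {P_beau: 4.6, g: 0.5}}
```

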