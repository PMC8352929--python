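# icer

Re-quantification of label-free DDA proteomics data by hybrid peptide
identity propagation (PIP) and direct ion current extraction (DICE).

Per-sample MS2 identifications in data-dependent acquisition are
stochastic, so peptide tables accumulate missing values as sample counts
grow. This package rescues those values from the MS1 ion maps: detected
peptide features are aligned and aggregated across samples, retention-time
and m/z drift are modelled per sample, and each consensus feature is
re-quantified in every sample inside a narrow feature-specific RT x m/z
window located by kernel-density peak detection. Decoy windows provide a
background-noise model, empirical significance scores, masking-based FDR
estimates for the peak selection, and noise-level imputation for truly
absent peptides. Peptide intensities roll up to proteins via Top3, total
sum, or MaxLFQ.

## Workflow stages

1. Alignment windows from cross-sample deviations of shared peptide
   identities (RT: 1.5 x IQR of absolute deviations; m/z: 1.0 x IQR),
   with user floors and fixed overrides.
2. Consensus feature assembly at per-key median RT/m-z; out-of-window
   contributors excluded; sequence-less features attached; overlapping
   features (delta mass < 0.002 Th, same charge, overlapping RT extents)
   merged.
3. Decoy companions (windows x 5 offset) and +1-isotope companions
   (+1.002/charge Th) per consensus feature.
4. Per-sample correction models: random forest (100 trees, 4 candidate
   splits, 100-row terminal nodes) for the uncalibrated-minus-calibrated
   m/z deviation; smoothing-spline RT-deviation model with an alternating
   drift-corrected consensus RT refinement.
5. Feature-based PIP: per-sample provenance labels
   (sequenced / feature-propagated / to recover by ion PIP).
6. Decoy extraction and RT-dependent noise models.
7. 50 x 50 normal-KDE ion accumulation maps in window-standardized
   coordinates; up to 5 local-maxima candidates per feature and sample.
8. Window selection (known / transferred / expected-fallback) and DICE
   extraction with signal/background decomposition (noise mean + 2 sd).
9. Empirical ion-count significance against decoy counts (p < 0.05).
10. Peak-selection outlier filters (feature-level IQR fence, per-sample
    robust z, isotope agreement).
11. Masking FDR: sequenced features re-selected as if undetected.
12. Noise-model imputation (imputed and non-imputed tables in parallel).
13. Filtering (contaminants, reverse, >= 2 peptides/protein), median
    normalization, and Top3 / sum / MaxLFQ protein rollup.

A fully seeded synthetic-data module generates multi-sample experiments
(mzXML ion maps + feature tables + ground truth) with Gaussian elution
peaks, isotope envelopes, smooth RT drift, ppm-scale mass error,
identification dropout, truly absent species, uniform background ions,
interference peaks, and group-wise spike-in ratios, so every stage is
testable offline.

## CLI

```sh
# generate a synthetic experiment (mzXML + feature tables + truth)
icer simulate --config sim.yaml --out data/

# run the full workflow
icer run --config run.yaml [--rt-window W] [--mz-window W] [--seed N] \
         [--rollup {top3,sum,maxlfq}] [--min-peptides N]

# FDR report only / rollup variants
icer fdr --config run.yaml
icer rollup --config run.yaml --rollup maxlfq
```

`run.yaml` is a flat YAML mapping of `icer.pipeline.PipelineConfig`
fields, e.g.:

```yaml
ion_map_paths: {S01: data/S01.mzXML, S02: data/S02.mzXML}
feature_table_paths: {S01: data/S01.features.tsv, S02: data/S02.features.tsv}
feature_dialect: generic   # or allpeptides / evidence
output_dir: out
rollup_method: top3
seed: 1
```

Outputs are tab-delimited text tables (`peptides.tsv`,
`peptides_nonimputed.tsv`, `proteins.tsv`, `events.tsv`,
`consensus.tsv`, `fdr_report.tsv`, `alignment_diagnostics.tsv`,
`normalization_factors.tsv`) plus `manifest.json`. Identical config and
seed reproduce identical outputs.

## Python API

```python
from icer import PipelineConfig, SyntheticConfig, generate_dataset, run_on_data
from icer.synthetic_data import detected_features

ion_maps, tables, truth = generate_dataset(SyntheticConfig(
    n_samples=6, n_species=500, id_dropout_rate=0.3,
    noise_ion_density=0.5, rt_drift_amplitude=0.3, mz_error_ppm=3.0, seed=42))
result = run_on_data(ion_maps, detected_features(tables), PipelineConfig(seed=1))
result.peptide_table          # imputed, wide: one column per sample
result.protein_table          # rolled up
result.fdr_report             # masking-based peak-selection FDR
```
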