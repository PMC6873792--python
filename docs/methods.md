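# Methods

## LFQ processing

Input is a gene-level LFQ intensity matrix (linear scale, missing values
allowed) and a sample sheet assigning each column an approach (MXL, WCXL,
WCXL_EtBr), a condition (crosslinked / control) and biological/technical
replicate numbers. For the WCXL_EtBr approach the "control" condition holds
the crosslinked, ethidium-bromide-treated samples, so the same
crosslinked-minus-control computation yields the intended contrast
(crosslinking over crosslinking under mitochondrial transcription
inhibition).

Processing steps, in order:

1. **log2 transform and imputation.** Intensities are log2-transformed;
   missing cells are set to the lowest log2 intensity observed anywhere in
   the matrix. The floor is global rather than per-sample: it is the
   simplest reading of "lowest measured", and a per-sample mode would make
   imputed values depend on column composition. A per-sample variant is not
   currently exposed because nothing downstream needed it; the imputation
   mask is kept so imputed cells remain identifiable.
2. **Replicate averaging.** Technical replicates are averaged within each
   biological replicate, then biological-replicate means are averaged
   (`mode="hierarchical"`, the default). This keeps biological replicates
   equally weighted when technical-replicate counts differ; `mode="flat"`
   (plain mean over all samples) is available for comparison.
3. **Fold-change.** `log2_fc = mean_log2(crosslinked) − mean_log2(control)`
   per approach. A protein counts as *detected* in an approach if it carried
   at least one measured (non-imputed) value there.
4. **Enrichment call.** Detected proteins with `log2_fc ≥ log2(3)` are
   enriched. The boundary is inclusive; both the threshold and the
   inclusivity are arguments.
5. **Combined evidence value.** The mtRNA-interaction track is the mean of
   the MXL and WCXL fold-changes where both approaches detected the protein,
   the single available value where only one did (discarding one-sided
   detections would defeat WCXL's purpose of catching proteins MXL misses),
   and missing where neither did — such genes fall into the missing-data bin
   of the integration. WCXL_EtBr is computed and reported but excluded from
   the combined track.

Reported percentages are rounded half-up to integers; sensitivities to three
decimals.

## Training sets

Positives are a curated gene list (one id per line; de-duplicated with a
warning, unknown ids are an error). Negatives are rule-built from GO-style
flags in the annotation table: category 1 is *every* gene with the
mitochondrion flag and a TCA-cycle or OXPHOS flag but not the RNA-binding
flag; category 2 is a uniform, seeded, without-replacement sample from genes
with the RNA-binding flag but not the mitochondrion flag, sized to match
category 1 so both contaminant classes contribute equally. Curated positives
are excluded from both categories before sampling. The sampling seed is
recorded in the training-set JSON; identical seeds give identical sets.

## Binned naive-Bayes integration

Continuous tracks default to quantile bins (5 requested; duplicate
quantiles on tied tracks are merged) computed over the genes that have a
value in the track — an unsupervised summary of the universe, so bin
borders are fixed inputs to any later refitting. Intervals are half-open
`[lo, hi)` with open-ended outer bins; binary tracks collapse to a single
0.5 border; every track has an additional bin for missing genes, scored
like any other bin (absence from a dataset is evidence). All borders are
written to the run log.

Per bin, `frac_pos = n_pos/|positives|` and `frac_neg = n_neg/|negatives|`;
a zero fraction of either class is replaced by `0.5/|negatives|`. Using the
negative-set size for both classes is the method's stated convention and is
implemented literally; a symmetric variant (`0.5/|own class|`) is available
via `pseudo_count_mode="own"`. The per-gene score is the log2
prior odds plus the sum of the gene's per-track bin log-ratios; sums use
correctly-rounded summation (`math.fsum`) so genes with the same multiset
of ratios tie exactly and a prior change can never reorder two genes.

Ranking sorts by descending score, breaking ties by descending combined
fold-change (genes without one come last within a tie), then by gene id.
When per-track contributions are available the sort key is their
prior-free sum, which makes the ranking bit-identical under any prior.
Ranked tables are written at full float precision, and reading one back and
re-ranking reproduces it exactly.

## Evaluation

* **Cutoff metrics.** Sensitivity and specificity are computed on training
  genes only at `score ≥ cutoff`. The corrected FDR re-weights the
  training-set FDR by the genome-wide prior odds
  `n_expected/(n_genes − n_expected)` (the plain odds, not its log — the
  log form would produce negative rates). An empty selection has cFDR 0 by
  convention.
* **ROC/AUC** via score-threshold sweep with tie groups handled jointly
  (scikit-learn's construction); the trapezoidal area equals the
  Mann–Whitney concordance probability, which the tests verify against an
  exhaustive concordant-pair count.
* **Cross-validation.** Folds are assigned by round-robin after a seeded
  shuffle, stratified within positives and within negatives, so every
  training gene is held out exactly once and fold sizes differ by at most
  one per class. Per fold, bin tables are refit from the remaining genes
  (same pseudo-count rule at the fold's negative-set size), the whole
  universe is re-ranked, and held-out ranks are pooled into a single ROC
  (score = negated rank). Bin borders are not refit per fold: they are
  unsupervised and label-free, and holding them fixed is what makes the
  leakage guarantee testable — perturbing a held-out gene's evidence cannot
  change the bin tables of the fold that ranks it.

## Synthetic studies

The generator emulates the statistical structure the analysis assumes, not
any particular real dataset. Ground truth assigns three disjoint signal
roles: true mtRNA interactors (always mitochondrial), additional
mitochondrial non-RNA genes, and cytosolic RNA binders — the two
contaminant classes the negative training set encodes.

Key defaults (all overridable on `SimulationConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_genes`, `n_true` | 20129, 300 | universe and true-interactor count, mirroring the prior |
| `lfq_effect` | 2.5 | log2 shift of interactors in crosslinked samples (≈5.7-fold, above the log2(3) call threshold) |
| `lfq_noise_sd` | 0.8 | replicate noise, log2 scale |
| `n_bioreps`, `n_techreps` | 3, 2 | per condition and approach |
| `missing_rate_detected/background` | 0.1 / 0.6 | per-cell dropout; the low rate applies to cells whose expected abundance carries the enrichment shift (signal genes, crosslinked condition), because LFQ dropout tracks per-sample abundance |
| `wcxl_attenuation`, `contaminant_shift` | 0.7, 1.0 | WCXL sees a weaker interactor effect plus co-purifying cytosolic RNA binders, encoding its lower specificity |
| `mito_flag_tpr/fpr` | 0.90 / 0.02 | localization-inventory membership noise |
| `rna_domain_tpr/fpr` | 0.70 / 0.05 | domain-annotation noise |
| `coexpr_shift` | 1.5 | co-expression score shift of interactors (sd 1) |
| `ppi_lambda_pos/neg` | 3.0 / 0.3 | Poisson interaction counts |
| `training_pos_size`, `training_neg_size_per_category` | 24, 124 | study-design training-set sizes |

TCA/OXPHOS flags are planted on exactly `training_neg_size_per_category`
mitochondrial non-RNA genes so the rule-built negative set has the intended
size; GO flags are exact by default (they define the training sets), with
optional flip noise. Tracks are conditionally independent given the class —
the naive-Bayes assumption — with an optional `track_correlation` knob that
adds a shared latent factor to the localization and co-expression scores.
Everything is deterministic under `(config, seed)`, with sub-stages drawing
from independently derived streams; outputs are byte-identical across runs.

What the generator does **not** emulate: protein-group ambiguity, intensity
normalization artefacts, intensity-dependent dropout (off by default;
`intensity_dependent_missingness=True` approximates it), correlated
annotation errors, and the background fold-change distribution of real
pulldowns — background genes here get symmetric, imputation-driven
fold-change noise, so the enrichment call's false-positive rate on
background genes is higher than on real data while interactor recovery is
realistic. Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted signal, not performance on real
MS data.

`scaled_config(n_genes)` shrinks the universe while keeping class
proportions (floor of 40 true interactors so the 24-gene positive set stays
drawable; the per-category negative size shrinks only when a small
universe's mitochondrial pool cannot supply 124). `null_config()` zeroes
every class-conditional effect while keeping GO flags exact, so training
sets exist but no evidence track carries signal.

## Test problem sizes and bands

Pipeline-level tests run at 600–2000 genes; the parameter-recovery check
runs the default-strength study at 5000 genes (cross-validated pooled AUC
≥ 0.9; integrated ≥ every single track). The chance-level check uses the
null configuration at 5000 genes with enlarged training sets (200
positives, 2 × 150 negatives): with the study-size sets (24 positives) the
chance-level pooled AUC fluctuates by several hundredths across seeds,
more than the ±0.05 band being asserted, so the calibration check uses set
sizes at which the band is meaningful. All stochastic assertions are
seeded.

## Known limitations

* Bin borders are quantile-based by default; scores depend on the borders,
  so analyses using hand-chosen borders are reproducible only if those
  borders are supplied through the bin-spec config.
* The cFDR is a training-set quantity reweighted by a prior guess; it is
  only as calibrated as `n_expected`.
* GO-DAG propagation, identifier mapping and protein-group inference are
  upstream of this package: annotation flags and gene-level LFQ tables are
  consumed as given.
* The volcano-plot style per-protein significance test is out of scope; the
  integration deliberately consumes raw fold-changes instead of a
  thresholded significant list.
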