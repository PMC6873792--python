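# mtri — predicting the mitochondrial poly(A) RNA interacting proteome

Nuclear-encoded proteins that bind mitochondrial RNA (mitoribosome
assembly factors, RNA processing, modification and degradation enzymes) are
hard to identify directly: UV-crosslinking / poly(A)-capture proteomics of
whole cells is dominated by cytosolic RNA binders, and mitochondrial
isolation alone does not prove RNA contact. `mtri` implements the analysis
strategy for this problem: take label-free quantification (LFQ) tables from
two crosslinking approaches — *in organello* crosslinking of isolated
mitochondria (MXL) and whole-cell crosslinking followed by mitochondrial
isolation (WCXL) — call RNA-binding enrichment from fold-changes, and
integrate the enrichment with genome-wide annotation evidence through a
binned naive-Bayes model that ranks **every** gene for the likelihood that
its protein product interacts with mitochondrial poly(A) RNA.

It is written for computational biologists who have gene-level LFQ tables
(MaxQuant `proteinGroups`-style) plus per-gene annotation tracks, and want a
reproducible, seeded ranking with honest uncertainty reporting. A synthetic
study generator makes the entire pipeline testable without any external
download.

## The model

Each evidence track *i* (crosslinking log2 fold-change, mitochondrial
localization score, RNA-binding-domain flag, co-expression with known
interactors, interaction counts) is cut into bins, with an extra bin for
genes absent from the track. Curated training sets — positives with
literature evidence of mtRNA interaction, negatives built by GO logic
(mitochondrial TCA/OXPHOS proteins without the RNA-binding term, and
RNA binders without the mitochondrion term) — give each bin a log-likelihood
ratio, and a gene's score is

```
mtRNAscore(g) = log2( P(mtRNA) / P(non-mtRNA) )
              + Σ_i log2( mtRNA_pos_i(g) / mtRNA_neg_i(g) )
```

where `mtRNA_pos_i(g)` / `mtRNA_neg_i(g)` are the fractions of positive and
negative training genes in the bin gene *g* occupies in track *i*; a zero
fraction is replaced by `0.5 / |negative set|` so every ratio is finite.
The prior term defaults to 300 expected interactors among 20129
protein-coding genes; it shifts all scores equally and never changes the
ranking. Ranking ties are broken by crosslinking fold-change, then gene id,
so the output is a deterministic total order.

Because the training sets are far richer in positives than the genome, the
training-set FDR at a score cutoff is corrected with the prior odds:

```
cFDR = (1 - specificity) / ( (1 - specificity) + sensitivity · Oprior )
```

with `Oprior = n_expected / (n_genes - n_expected)`. Ranking quality is
evaluated by ROC/AUC and by ten-fold cross-validation in which the per-bin
ratios are refit without each fold and the held-out genes' ranks are pooled
into one ROC curve.

The integration is exposed as a scikit-learn estimator
(`mtri.BinnedBayesClassifier` with `fit` / `decision_function` / `predict`),
so it composes with sklearn tooling; the pipeline functions are thin
wrappers around it.

## Worked example

Simulate a small study and run the full pipeline:

```
mtri simulate --n-genes 2000 --seed 1 --out study
mtri run-all --lfq study/lfq.tsv --samples study/samples.tsv \
    --annotations study/annotations.tsv --positives study/positives.txt \
    --seed 1 --out run
```

`run/metrics.json` then contains (numbers printed by the run above):

```json
{
 "cutoff": {
  "cutoff_score": 1.69,
  "n_selected": 23,
  "sensitivity": 0.6666666666666666,
  "specificity": 0.9895833333333334,
  "cfdr": 0.08133971291866002,
  "cfdr_percent": 8
 },
 "training_roc_auc": 0.9895833333333334,
 "crossval_pooled_auc": 0.9835069444444444,
 "identified_set": {
  "n_selected": 23,
  "mito_and_rna_go": 22,
  "mito_only": 1,
  "rna_go_only": 0,
  "neither": 0
 }
}
```

Reading: at the score cutoff 1.69, 23 of 2000 genes are selected; the cutoff
recovers 67% of the positive training genes while excluding 99% of the
negatives, for a prior-corrected FDR of 8%; the cross-validated pooled AUC
of 0.98 says held-out training genes are ranked almost perfectly. The first
lines of `run/ranked.tsv` show the score decomposition per gene — one
`contrib_<track>` column per evidence track — plus the tie-breaking
fold-change and training-set membership. `run/run_log.json` records every
resolved parameter, seed, bin border and input hash needed to re-create the
run; re-running with the same config is byte-identical.

The same stages are available individually (`process-lfq`,
`build-training`, `integrate`, `evaluate`, `crossval`) and as library
functions (`mtri.fold_change_table`, `mtri.integrate`,
`mtri.cross_validate`, ...).

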