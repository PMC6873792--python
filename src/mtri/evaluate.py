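"""Ranking evaluation: cutoff metrics, corrected FDR, ROC/AUC, cross-validation.

The training-set false discovery rate at a score cutoff does not reflect the
genome-wide class balance (24 positives vs 248 negatives is far richer in
positives than ~300 true interactors among 20129 genes), so it is corrected
with the prior odds:

    cFDR = (1 - specificity) / ((1 - specificity) + sensitivity * prior_odds)

where prior_odds = n_expected / (n_genes - n_expected). Ten-fold
cross-validation refits the per-bin likelihood ratios without each fold of
training genes, re-ranks the whole universe, and pools the held-out genes'
ranks into one ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from ._util import rng_from, round_half_up
from .bayes import BinSpec, BinnedBayesClassifier, PriorSpec, integrate, rank_genes
from .training import TrainingSets


@dataclass(frozen=True)
class CutoffMetrics:
    """Training-set performance of a score cutoff."""

    cutoff_score: float
    n_selected: int
    sensitivity: float
    specificity: float
    cfdr: float | None = None

    @property
    def cfdr_percent(self) -> int | None:
        if self.cfdr is None:
            return None
        return int(round_half_up(100.0 * self.cfdr))

    def as_dict(self) -> dict:
        return {
            "cutoff_score": self.cutoff_score,
            "n_selected": self.n_selected,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "cfdr": self.cfdr,
            "cfdr_percent": self.cfdr_percent,
        }


@dataclass(frozen=True)
class RocCurve:
    """ROC points from (0,0) to (1,1) and the trapezoidal area under them."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds})


@dataclass
class CrossValidationResult:
    """Held-out ranks and pooled ROC of a k-fold cross-validation."""

    fold_of: pd.Series
    heldout: pd.DataFrame
    roc: RocCurve
    seed: int
    k: int
    fold_bin_tables: list[dict[str, pd.DataFrame]] = field(repr=False, default_factory=list)

    @property
    def auc(self) -> float:
        return self.roc.auc


def confusion_at_cutoff(
    scores: pd.Series | pd.DataFrame,
    sets: TrainingSets,
    cutoff_score: float,
) -> CutoffMetrics:
    """Sensitivity/specificity of selecting genes with score >= cutoff.

    ``scores`` may be a per-gene Series or an integration result frame with
    an ``mtRNA_score`` column. A cutoff above the maximum score selects
    nothing and yields sensitivity 0.
    """
    if isinstance(scores, pd.DataFrame):
        scores = scores["mtRNA_score"]
    missing = set(sets.all_genes) - set(scores.index)
    if missing:
        raise KeyError(f"training genes without scores: {sorted(missing)}")
    selected = scores.index[scores >= cutoff_score]
    selected_set = set(selected)
    n_pos_hit = sum(g in selected_set for g in sets.positives)
    n_neg_hit = sum(g in selected_set for g in sets.negatives)
    return CutoffMetrics(
        cutoff_score=float(cutoff_score),
        n_selected=int(len(selected)),
        sensitivity=n_pos_hit / len(sets.positives),
        specificity=1.0 - n_neg_hit / len(sets.negatives),
    )


def corrected_fdr(sensitivity: float, specificity: float, prior_odds: float) -> float:
    """Prior-corrected false discovery rate at a cutoff.

    ``prior_odds`` is the plain (non-log) odds n_expected/(n_genes -
    n_expected). An empty selection (sensitivity 0 at specificity 1) has no
    false discoveries, so the cFDR is defined as 0 there.
    """
    if not 0 <= sensitivity <= 1 or not 0 <= specificity <= 1:
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if prior_odds <= 0:
        raise ValueError("prior_odds must be positive")
    fpr = 1.0 - specificity
    denom = fpr + sensitivity * prior_odds
    if denom == 0:
        return 0.0
    return fpr / denom


def cutoff_metrics(
    scores: pd.Series | pd.DataFrame,
    sets: TrainingSets,
    cutoff_score: float,
    prior: PriorSpec,
) -> CutoffMetrics:
    """confusion_at_cutoff plus the corrected FDR in one object."""
    base = confusion_at_cutoff(scores, sets, cutoff_score)
    return CutoffMetrics(
        cutoff_score=base.cutoff_score,
        n_selected=base.n_selected,
        sensitivity=base.sensitivity,
        specificity=base.specificity,
        cfdr=corrected_fdr(base.sensitivity, base.specificity, prior.prior_odds),
    )


def roc_auc(scores: pd.Series, labels: pd.Series) -> RocCurve:
    """ROC over score thresholds with trapezoidal AUC.

    Tied scores are handled jointly (one ROC vertex per distinct score), so
    the area equals the Mann-Whitney concordance probability.
    """
    scores, labels = scores.align(labels, join="inner")
    y = labels.astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs at least one positive and one negative")
    fpr, tpr, thr = _sk_roc_curve(y, scores.to_numpy(dtype=float), drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_sk_auc(fpr, tpr)))


def assign_folds(sets: TrainingSets, k: int, seed: int) -> pd.Series:
    """Seeded fold labels, stratified within positives and within negatives.

    Round-robin after a per-class shuffle: fold sizes within each class
    differ by at most one, and every training gene is held out exactly once.
    """
    if len(sets.positives) < k or len(sets.negatives) < k:
        raise ValueError(
            f"need at least k={k} genes in each class "
            f"(have {len(sets.positives)} positives, {len(sets.negatives)} negatives)"
        )
    rng = rng_from(seed, 0xF0)
    fold_of: dict[str, int] = {}
    for group in (list(sets.positives), list(sets.negatives)):
        order = list(rng.permutation(group))
        for i, gene in enumerate(order):
            fold_of[str(gene)] = i % k
    out = pd.Series(fold_of, name="fold", dtype=int)
    return out.loc[sets.all_genes]


def _drop_fold(sets: TrainingSets, fold_of: pd.Series, fold: int) -> TrainingSets:
    keep = fold_of.index[fold_of != fold]
    keep_set = set(keep)
    return TrainingSets(
        positives=[g for g in sets.positives if g in keep_set],
        negatives_mito_nonrna=[g for g in sets.negatives_mito_nonrna if g in keep_set],
        negatives_rna_nonmito=[g for g in sets.negatives_rna_nonmito if g in keep_set],
        seed=sets.seed,
    )


def cross_validate(
    evidence: pd.DataFrame,
    sets: TrainingSets,
    bin_specs: dict[str, BinSpec],
    prior: PriorSpec | None = None,
    k: int = 10,
    seed: int = 0,
    fc_tie_break: pd.Series | None = None,
    pseudo_count_mode: str = "negative",
) -> CrossValidationResult:
    """k-fold cross-validated ranking evaluation.

    Bin borders (``bin_specs``) are fixed inputs — they are unsupervised
    summaries of the universe — while the per-bin likelihood ratios are
    refit per fold from the remaining 9/10 of training genes, so a held-out
    gene never influences the bin table it is ranked against. The pooled ROC
    is built from held-out ranks (higher rank number = less likely
    interactor, so the ROC score is the negated rank).
    """
    prior = prior or PriorSpec()
    fold_of = assign_folds(sets, k=k, seed=seed)
    rows = []
    fold_bin_tables = []
    for fold in range(k):
        fold_sets = _drop_fold(sets, fold_of, fold)
        result, model = integrate(
            evidence, fold_sets, bin_specs=bin_specs, prior=prior,
            pseudo_count_mode=pseudo_count_mode,
        )
        ranked = rank_genes(result, fc_tie_break=fc_tie_break)
        rank_of = pd.Series(ranked["rank"].to_numpy(), index=ranked.index)
        heldout_genes = fold_of.index[fold_of == fold]
        for gene in heldout_genes:
            rows.append(
                {
                    "gene_id": gene,
                    "fold": fold,
                    "label": 1 if gene in set(sets.positives) else 0,
                    "rank": int(rank_of.loc[gene]),
                    "score": float(result.loc[gene, "mtRNA_score"]),
                }
            )
        fold_bin_tables.append(model.bin_tables_)
    heldout = pd.DataFrame(rows).set_index("gene_id")
    roc = roc_auc(-heldout["rank"].astype(float), heldout["label"])
    return CrossValidationResult(
        fold_of=fold_of, heldout=heldout, roc=roc, seed=seed, k=k,
        fold_bin_tables=fold_bin_tables,
    )


def rank_to_metrics_table(
    ranked: pd.DataFrame,
    sets: TrainingSets,
    prior: PriorSpec,
) -> pd.DataFrame:
    """Sensitivity, specificity and cFDR at every rank cutoff (0..N).

    Row r describes selecting the top r genes of the ranking; row 0 is the
    empty selection (cFDR 0 by convention).
    """
    if "rank" not in ranked.columns:
        raise ValueError("ranked frame must carry a 'rank' column (see rank_genes)")
    order = ranked.sort_values("rank")
    is_pos = order.index.isin(set(sets.positives)).astype(int)
    is_neg = order.index.isin(set(sets.negatives)).astype(int)
    cum_pos = np.concatenate([[0], np.cumsum(is_pos)])
    cum_neg = np.concatenate([[0], np.cumsum(is_neg)])
    sens = cum_pos / len(sets.positives)
    spec = 1.0 - cum_neg / len(sets.negatives)
    fpr = 1.0 - spec
    denom = fpr + sens * prior.prior_odds
    cfdr = np.divide(fpr, denom, out=np.zeros_like(fpr), where=denom > 0)
    return pd.DataFrame(
        {
            "rank_cutoff": np.arange(len(order) + 1),
            "n_selected": np.arange(len(order) + 1),
            "sensitivity": sens,
            "specificity": spec,
            "cFDR": cfdr,
        }
    )
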