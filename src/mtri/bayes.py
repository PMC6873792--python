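"""Binned naive-Bayes evidence integration and gene ranking.

Each evidence track (crosslinking fold-change, mitochondrial-localization
score, RNA-binding-domain flag, co-expression, protein-interaction count) is
cut into bins, with one extra bin for genes missing from the track — absence
from a dataset is itself evidence. Within every bin the fractions of
positive and negative training-set genes give a log2 likelihood ratio; a
gene's mtRNA score is the log2 prior odds plus the sum of the ratios of the
bins it falls in:

    score(g) = log2(P(mtRNA) / P(non-mtRNA))
             + sum_i log2( frac_pos_i(bin_i(g)) / frac_neg_i(bin_i(g)) )

A fraction of zero is replaced by the pseudo-fraction 0.5 / |negative set|
(for either class), which keeps every ratio finite. The prior defaults to
300 expected mitochondrial-RNA interactors among 20129 protein-coding
genes; it shifts all scores by a constant and never changes the ranking.

:class:`BinnedBayesClassifier` exposes this as a scikit-learn estimator;
:func:`integrate` and :func:`rank_genes` apply it over a gene universe and
produce the tie-broken ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .training import TrainingSets

MISSING_BIN = "missing"

#: pseudo-fraction denominators: "negative" uses the negative-set size for
#: both classes (the literal rule); "own" uses each class's own size.
PSEUDO_COUNT_MODES = ("negative", "own")


@dataclass(frozen=True)
class BinSpec:
    """Binning of one evidence track.

    ``borders`` are strictly increasing cut points defining half-open
    intervals ``(-inf, b0), [b0, b1), ..., [b_last, +inf)``; a flag track is
    just ``borders=(0.5,)``. Every spec carries an implicit extra bin for
    genes with no value in the track.
    """

    name: str
    kind: str = "continuous"
    borders: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "discrete", "flag"):
            raise ValueError(f"unknown bin kind {self.kind!r}")
        b = np.asarray(self.borders, dtype=float)
        if b.size and not np.all(np.diff(b) > 0):
            raise ValueError(f"bin borders must be strictly increasing, got {self.borders}")

    @property
    def n_value_bins(self) -> int:
        return len(self.borders) + 1

    @property
    def n_bins(self) -> int:
        """Value bins plus the missing bin."""
        return self.n_value_bins + 1

    @property
    def missing_index(self) -> int:
        return self.n_value_bins

    def labels(self) -> list[str]:
        b = list(self.borders)
        if not b:
            labels = ["(-inf, inf)"]
        else:
            labels = [f"(-inf, {b[0]:g})"]
            labels += [f"[{lo:g}, {hi:g})" for lo, hi in zip(b[:-1], b[1:])]
            labels += [f"[{b[-1]:g}, inf)"]
        return labels + [MISSING_BIN]

    def assign(self, values: pd.Series) -> pd.Series:
        """Map every gene to a bin index; missing values go to the missing bin."""
        v = pd.to_numeric(values, errors="coerce")
        idx = np.digitize(v.to_numpy(dtype=float), self.borders, right=False)
        idx = np.where(v.isna().to_numpy(), self.missing_index, idx)
        return pd.Series(idx, index=values.index, name=self.name)


def make_quantile_bins(values: pd.Series, name: str, n_bins: int = 5) -> BinSpec:
    """Quantile-based borders over the genes that have a value.

    Binary (0/1) tracks collapse to a single 0.5 border; duplicate quantiles
    on heavily tied tracks are merged, so the realised number of bins can be
    smaller than requested.
    """
    present = pd.to_numeric(values, errors="coerce").dropna()
    if present.empty:
        return BinSpec(name=name, kind="continuous", borders=())
    uniq = np.unique(present.to_numpy(dtype=float))
    if set(uniq).issubset({0.0, 1.0}):
        return BinSpec(name=name, kind="flag", borders=(0.5,))
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    borders = np.unique(np.quantile(present.to_numpy(dtype=float), qs))
    return BinSpec(name=name, kind="continuous", borders=tuple(float(b) for b in borders))


def make_default_bin_specs(
    evidence: pd.DataFrame, n_bins: int = 5
) -> dict[str, BinSpec]:
    """One quantile BinSpec per evidence column, computed over the universe."""
    return {col: make_quantile_bins(evidence[col], name=col, n_bins=n_bins) for col in evidence.columns}


def bin_dataset(values: pd.Series, spec: BinSpec) -> pd.Series:
    """Assign every gene in the universe to exactly one bin of the track."""
    return spec.assign(values)


@dataclass(frozen=True)
class PriorSpec:
    """Prior expectation on the number of mtRNA-interacting genes."""

    n_expected: int = 300
    n_genes: int = 20129

    def __post_init__(self) -> None:
        if not 0 < self.n_expected < self.n_genes:
            raise ValueError(
                f"need 0 < n_expected ({self.n_expected}) < n_genes ({self.n_genes})"
            )

    @property
    def prior_odds(self) -> float:
        return self.n_expected / (self.n_genes - self.n_expected)

    @property
    def oprior_log2(self) -> float:
        return float(np.log2(self.prior_odds))


def compute_oprior(n_expected: int, n_genes: int) -> PriorSpec:
    return PriorSpec(n_expected=n_expected, n_genes=n_genes)


def _bin_table(
    n_pos: np.ndarray,
    n_neg: np.ndarray,
    n_pos_total: int,
    n_neg_total: int,
    pseudo_count_mode: str = "negative",
) -> pd.DataFrame:
    if pseudo_count_mode not in PSEUDO_COUNT_MODES:
        raise ValueError(f"pseudo_count_mode must be one of {PSEUDO_COUNT_MODES}")
    if n_pos_total == 0 or n_neg_total == 0:
        raise ValueError("empty training set")
    frac_pos = n_pos / n_pos_total
    frac_neg = n_neg / n_neg_total
    pseudo_neg = 0.5 / n_neg_total
    pseudo_pos = pseudo_neg if pseudo_count_mode == "negative" else 0.5 / n_pos_total
    frac_pos = np.where(frac_pos == 0, pseudo_pos, frac_pos)
    frac_neg = np.where(frac_neg == 0, pseudo_neg, frac_neg)
    return pd.DataFrame(
        {
            "n_pos": n_pos.astype(int),
            "n_neg": n_neg.astype(int),
            "frac_pos": frac_pos,
            "frac_neg": frac_neg,
            "log2_ratio": np.log2(frac_pos / frac_neg),
        }
    )


def score_bins(
    assignments: pd.Series,
    sets: TrainingSets,
    spec: BinSpec,
    pseudo_count_mode: str = "negative",
) -> pd.DataFrame:
    """Per-bin training-set counts, fractions and log2 likelihood ratios.

    ``assignments`` must cover the training genes (typically the whole
    universe). The returned frame is indexed by bin label in bin order.
    """
    missing_train = set(sets.all_genes) - set(assignments.index)
    if missing_train:
        raise KeyError(f"training genes missing from assignments: {sorted(missing_train)}")
    n_bins = spec.n_bins
    pos_idx = assignments.loc[sets.positives].to_numpy(dtype=int)
    neg_idx = assignments.loc[sets.negatives].to_numpy(dtype=int)
    n_pos = np.bincount(pos_idx, minlength=n_bins)
    n_neg = np.bincount(neg_idx, minlength=n_bins)
    table = _bin_table(n_pos, n_neg, len(sets.positives), len(sets.negatives), pseudo_count_mode)
    table.index = pd.Index(spec.labels(), name="bin")
    return table


class BinnedBayesClassifier(ClassifierMixin, BaseEstimator):
    """Naive-Bayes gene classifier over binned evidence tracks.

    Parameters
    ----------
    bin_specs:
        mapping column name -> :class:`BinSpec`. When None, quantile bins are
        computed from the data seen at :meth:`fit`; for genome-wide work pass
        specs precomputed over the full universe with
        :func:`make_default_bin_specs` so borders do not depend on which
        genes are labelled.
    n_bins:
        requested bins per continuous track when specs are computed in fit.
    n_expected, n_genes:
        prior: expected true interactors among protein-coding genes.
    pseudo_count_mode:
        "negative" (default): zero fractions of either class are replaced by
        0.5/|negatives|; "own": 0.5/|own class|.
    score_cutoff:
        decision threshold on the mtRNA score used by :meth:`predict`.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        [0, 1].
    bin_specs_ : dict[str, BinSpec]
        binning actually used per track.
    bin_tables_ : dict[str, DataFrame]
        per-track bin score table (n_pos, n_neg, fractions, log2_ratio).
    prior_ : PriorSpec
        resolved prior; ``prior_.oprior_log2`` is the additive offset.

    Examples
    --------
    >>> X = pd.DataFrame({"fc": [3.1, 2.8, 0.1, np.nan]}, index=list("abcd"))
    >>> y = [1, 1, 0, 0]
    >>> clf = BinnedBayesClassifier(n_bins=2).fit(X, y)
    >>> clf.decision_function(X).shape
    (4,)
    """

    def __init__(
        self,
        bin_specs: dict[str, BinSpec] | None = None,
        n_bins: int = 5,
        n_expected: int = 300,
        n_genes: int = 20129,
        pseudo_count_mode: str = "negative",
        score_cutoff: float = 0.0,
    ):
        self.bin_specs = bin_specs
        self.n_bins = n_bins
        self.n_expected = n_expected
        self.n_genes = n_genes
        self.pseudo_count_mode = pseudo_count_mode
        self.score_cutoff = score_cutoff

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (genes x evidence tracks)")
        return pd.DataFrame(X, columns=[f"track_{i}" for i in range(X.shape[1])])

    def fit(self, X, y):
        """Learn per-bin log2 likelihood ratios from labelled genes.

        ``y`` is 1 for positive training genes, 0 for negatives; NaN in ``X``
        means the gene is absent from that track.
        """
        frame = self._as_frame(X)
        y = np.asarray(y)
        labels = np.unique(y)
        if not set(labels).issubset({0, 1}) or len(labels) < 2:
            raise ValueError("y must contain both classes, coded 0 (negative) and 1 (positive)")
        self.prior_ = PriorSpec(n_expected=self.n_expected, n_genes=self.n_genes)
        if self.bin_specs is not None:
            missing = [c for c in frame.columns if c not in self.bin_specs]
            if missing:
                raise ValueError(f"no BinSpec for evidence track(s): {missing}")
            self.bin_specs_ = {c: self.bin_specs[c] for c in frame.columns}
        else:
            self.bin_specs_ = make_default_bin_specs(frame, n_bins=self.n_bins)
        pos_mask = y == 1
        n_pos_total = int(pos_mask.sum())
        n_neg_total = int((~pos_mask).sum())
        self.bin_tables_ = {}
        for col in frame.columns:
            spec = self.bin_specs_[col]
            idx = spec.assign(frame[col]).to_numpy()
            n_pos = np.bincount(idx[pos_mask], minlength=spec.n_bins)
            n_neg = np.bincount(idx[~pos_mask], minlength=spec.n_bins)
            table = _bin_table(n_pos, n_neg, n_pos_total, n_neg_total, self.pseudo_count_mode)
            table.index = pd.Index(spec.labels(), name="bin")
            self.bin_tables_[col] = table
        self.classes_ = np.array([0, 1])
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_features_in_ = frame.shape[1]
        return self

    def contributions(self, X) -> pd.DataFrame:
        """Per-track log2 likelihood-ratio contribution for every gene."""
        check_is_fitted(self, "bin_tables_")
        frame = self._as_frame(X)
        extra = [c for c in frame.columns if c not in self.bin_tables_]
        if extra:
            raise ValueError(f"unseen evidence track(s): {extra}")
        out = pd.DataFrame(index=frame.index)
        for col in frame.columns:
            spec = self.bin_specs_[col]
            ratios = self.bin_tables_[col]["log2_ratio"].to_numpy()
            out[col] = ratios[spec.assign(frame[col]).to_numpy()]
        return out

    def decision_function(self, X) -> np.ndarray:
        """mtRNA score: log2 prior odds + summed per-track contributions.

        The sum is correctly rounded (math.fsum), so genes with the same
        multiset of bin ratios get byte-identical scores regardless of track
        order, and changing the prior can never invert two genes' order.
        """
        contrib = self.contributions(X)
        oprior = self.prior_.oprior_log2
        return np.array([math.fsum([oprior, *row]) for row in contrib.to_numpy()])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= self.score_cutoff).astype(int)


def integrate(
    evidence: pd.DataFrame,
    sets: TrainingSets,
    bin_specs: dict[str, BinSpec] | None = None,
    prior: PriorSpec | None = None,
    n_bins: int = 5,
    pseudo_count_mode: str = "negative",
) -> tuple[pd.DataFrame, BinnedBayesClassifier]:
    """Score every gene of the universe; returns (result frame, fitted model).

    ``evidence`` is the full universe (genes x tracks, NaN = absent). Bin
    borders default to quantiles over the universe. The result frame carries
    ``mtRNA_score`` plus one ``contrib_<track>`` column per track.
    """
    prior = prior or PriorSpec()
    if bin_specs is None:
        bin_specs = make_default_bin_specs(evidence, n_bins=n_bins)
    labels = sets.labels()
    missing_train = set(labels.index) - set(evidence.index)
    if missing_train:
        raise KeyError(f"training genes missing from evidence universe: {sorted(missing_train)}")
    model = BinnedBayesClassifier(
        bin_specs=bin_specs,
        n_expected=prior.n_expected,
        n_genes=prior.n_genes,
        pseudo_count_mode=pseudo_count_mode,
    )
    model.fit(evidence.loc[labels.index], labels.to_numpy())
    contrib = model.contributions(evidence)
    result = contrib.rename(columns={c: f"contrib_{c}" for c in contrib.columns})
    result.insert(0, "mtRNA_score", model.decision_function(evidence))
    result.index.name = "gene_id"
    return result, model


def rank_genes(
    result: pd.DataFrame,
    fc_tie_break: pd.Series | None = None,
    sets: TrainingSets | None = None,
) -> pd.DataFrame:
    """Total ordering of the universe by mtRNA score.

    Ties in score are broken by descending crosslinking fold-change (genes
    without a fold-change come after those with one), then lexicographically
    by gene id so the ranking is byte-identical across runs.

    When per-track contribution columns are present the sort key is their
    correctly-rounded sum rather than the score itself: the prior only adds
    a constant, so this is the same ordering, but it is bit-identical under
    any prior (re-adding a shifted constant could turn an epsilon gap into a
    tie or back).
    """
    ranked = result.copy()
    if fc_tie_break is not None:
        ranked["tie_break_fc"] = fc_tie_break.reindex(ranked.index)
    else:
        ranked["tie_break_fc"] = np.nan
    contrib_cols = [c for c in ranked.columns if c.startswith("contrib_")]
    if contrib_cols:
        score_key = np.array([math.fsum(row) for row in ranked[contrib_cols].to_numpy()])
    else:
        score_key = ranked["mtRNA_score"].to_numpy()
    order_fc = ranked["tie_break_fc"].fillna(-np.inf)
    key = pd.DataFrame(
        {"score": -score_key, "fc": -order_fc, "gene": ranked.index},
        index=ranked.index,
    )
    ranked = ranked.loc[key.sort_values(["score", "fc", "gene"]).index]
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    if sets is not None:
        ranked["in_positive_set"] = ranked.index.isin(set(sets.positives))
        ranked["in_negative_set"] = ranked.index.isin(set(sets.negatives))
    return ranked


def write_ranked_table(ranked: pd.DataFrame, path: str | Path) -> None:
    # full float precision: the written table must re-rank to itself exactly
    ranked.to_csv(path, sep="\t", na_rep="NA")


def read_ranked_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA"], float_precision="round_trip"
    )
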