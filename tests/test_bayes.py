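"""Binned naive-Bayes integration: binning, bin scoring, prior, ranking, and
equivalence with a brute-force posterior-odds oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from mtri.bayes import (
    BinnedBayesClassifier,
    BinSpec,
    PriorSpec,
    bin_dataset,
    compute_oprior,
    integrate,
    make_quantile_bins,
    rank_genes,
    score_bins,
)
from mtri.training import TrainingSets


class TestBinning:
    def test_half_open_intervals_with_missing_bin(self):
        spec = BinSpec("fc", borders=(0.0, 2.0))
        values = pd.Series({"A": 1.0, "B": 3.0, "C": np.nan, "D": -1.0, "E": 2.0})
        idx = bin_dataset(values, spec)
        labels = spec.labels()
        assert labels[idx["A"]] == "[0, 2)"
        assert labels[idx["B"]] == "[2, inf)"
        assert labels[idx["E"]] == "[2, inf)"  # left-closed boundary
        assert labels[idx["C"]] == "missing"
        assert labels[idx["D"]] == "(-inf, 0)"

    def test_flag_track_has_two_value_bins(self):
        spec = make_quantile_bins(pd.Series([0.0, 1.0, 1.0, 0.0]), name="flag")
        assert spec.kind == "flag" and spec.n_bins == 3

    def test_all_missing_goes_to_missing_bin(self):
        spec = BinSpec("x", borders=(1.0,))
        values = pd.Series([np.nan, np.nan], index=["A", "B"])
        assert (bin_dataset(values, spec) == spec.missing_index).all()

    def test_borders_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            BinSpec("x", borders=(2.0, 1.0))

    def test_quantile_bins_cover_every_gene(self):
        rng = np.random.default_rng(0)
        values = pd.Series(rng.normal(size=500))
        spec = make_quantile_bins(values, "x", n_bins=5)
        idx = spec.assign(values)
        assert idx.between(0, spec.n_value_bins - 1).all()
        assert spec.n_value_bins == 5


def _sets(n_pos=10, n_neg=10):
    pos = [f"p{i}" for i in range(n_pos)]
    half = n_neg // 2
    return TrainingSets(pos, [f"n{i}" for i in range(half)], [f"n{i}" for i in range(half, n_neg)], seed=0)


class TestScoreBins:
    def test_log2_ratio_of_fractions(self):
        sets = _sets(10, 10)
        spec = BinSpec("x", borders=(0.5,))
        # bin [0.5, inf): 4 positives, 1 negative
        values = pd.Series(
            {**{f"p{i}": 1.0 if i < 4 else 0.0 for i in range(10)},
             **{f"n{i}": 1.0 if i < 1 else 0.0 for i in range(10)}}
        )
        table = score_bins(spec.assign(values), sets, spec)
        assert table.loc["[0.5, inf)", "log2_ratio"] == pytest.approx(2.0)

    def test_zero_count_uses_negative_set_pseudofraction(self):
        sets = _sets(10, 10)
        spec = BinSpec("x", borders=(0.5,))
        # bin [0.5, inf): 0 positives, 2 negatives -> log2(0.05 / 0.2) = -2
        values = pd.Series(
            {**{f"p{i}": 0.0 for i in range(10)},
             **{f"n{i}": 1.0 if i < 2 else 0.0 for i in range(10)}}
        )
        table = score_bins(spec.assign(values), sets, spec)
        assert table.loc["[0.5, inf)", "log2_ratio"] == pytest.approx(-2.0)

    def test_equal_fractions_are_uninformative(self):
        sets = _sets(8, 8)
        spec = BinSpec("x", borders=(0.5,))
        values = pd.Series(
            {**{f"p{i}": float(i < 4) for i in range(8)},
             **{f"n{i}": float(i < 4) for i in range(8)}}
        )
        table = score_bins(spec.assign(values), sets, spec)
        assert (table["log2_ratio"] == 0).all()

    def test_counts_conserved(self):
        rng = np.random.default_rng(3)
        sets = _sets(12, 20)
        spec = BinSpec("x", borders=(-0.5, 0.5))
        values = pd.Series(rng.normal(size=40), index=sets.all_genes + [f"u{i}" for i in range(8)])
        values[rng.random(40) < 0.3] = np.nan
        table = score_bins(spec.assign(values), sets, spec)
        assert table["n_pos"].sum() == 12
        assert table["n_neg"].sum() == 20

    @given(
        n_pos=st.integers(1, 12),
        n_neg=st.integers(2, 12).map(lambda v: 2 * (v // 2) or 2),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=40, deadline=None)
    def test_ratios_always_finite(self, n_pos, n_neg, seed):
        """The pseudo-fraction rule keeps every bin ratio finite regardless of
        how training genes distribute over bins."""
        rng = np.random.default_rng(seed)
        sets = _sets(n_pos, n_neg)
        spec = BinSpec("x", borders=(0.25, 0.75))
        values = pd.Series(rng.random(len(sets.all_genes)), index=sets.all_genes)
        values[rng.random(len(values)) < 0.4] = np.nan
        table = score_bins(spec.assign(values), sets, spec)
        assert np.isfinite(table["log2_ratio"]).all()


class TestPrior:
    def test_study_scale_prior(self):
        prior = compute_oprior(300, 20129)
        assert prior.prior_odds == pytest.approx(300 / 19829)
        assert prior.oprior_log2 == pytest.approx(math.log2(300 / 19829), abs=1e-9)
        assert prior.oprior_log2 == pytest.approx(-6.047, abs=5e-4)

    def test_alternative_prior(self):
        assert compute_oprior(1000, 20129).prior_odds == pytest.approx(1000 / 19129)

    def test_even_split_is_even_odds(self):
        prior = compute_oprior(500, 1000)
        assert prior.prior_odds == 1.0 and prior.oprior_log2 == 0.0

    @pytest.mark.parametrize("n_expected, n_genes", [(0, 100), (100, 100), (150, 100)])
    def test_invalid_prior_rejected(self, n_expected, n_genes):
        with pytest.raises(ValueError):
            compute_oprior(n_expected, n_genes)


def _random_instance(rng, n_tracks, n_genes, n_pos, n_neg):
    genes = [f"g{i}" for i in range(n_genes)]
    evidence = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    specs = {}
    for t in range(n_tracks):
        col = f"t{t}"
        n_borders = rng.integers(1, 3)  # 2-3 value bins
        specs[col] = BinSpec(col, borders=tuple(sorted(rng.uniform(0, 1, n_borders))))
        vals = rng.random(n_genes)
        vals[rng.random(n_genes) < 0.25] = np.nan
        evidence[col] = vals
    order = rng.permutation(genes)
    sets = TrainingSets(
        list(order[:n_pos]),
        list(order[n_pos : n_pos + n_neg // 2]),
        list(order[n_pos + n_neg // 2 : n_pos + n_neg]),
        seed=0,
    )
    return evidence, specs, sets


def brute_force_log2_posterior_odds(evidence, specs, sets, prior):
    """Direct naive-Bayes posterior odds: count training genes per bin with
    plain loops and multiply likelihood ratios per gene."""
    pos, neg = set(sets.positives), set(sets.negatives)
    scores = {}
    for gene in evidence.index:
        odds = prior.prior_odds
        for col, spec in specs.items():
            def bin_of(g):
                v = evidence.loc[g, col]
                if pd.isna(v):
                    return "missing"
                for j, b in enumerate(spec.borders):
                    if v < b:
                        return j
                return len(spec.borders)
            b = bin_of(gene)
            fp = sum(bin_of(g) == b for g in pos) / len(pos)
            fn = sum(bin_of(g) == b for g in neg) / len(neg)
            fp = fp or 0.5 / len(neg)
            fn = fn or 0.5 / len(neg)
            odds *= fp / fn
        scores[gene] = math.log2(odds)
    return pd.Series(scores)


class TestIntegrate:
    def test_score_is_prior_plus_contributions(self):
        rng = np.random.default_rng(5)
        evidence, specs, sets = _random_instance(rng, 4, 40, 6, 10)
        prior = PriorSpec(300, 20129)
        result, _ = integrate(evidence, sets, bin_specs=specs, prior=prior)
        contrib = result.filter(like="contrib_").sum(axis=1)
        assert np.allclose(result["mtRNA_score"], prior.oprior_log2 + contrib, atol=1e-12)

    def test_matches_brute_force_oracle(self):
        prior = PriorSpec(300, 20129)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            evidence, specs, sets = _random_instance(
                rng, rng.integers(1, 5), rng.integers(20, 51), rng.integers(3, 8), 2 * rng.integers(2, 6)
            )
            result, _ = integrate(evidence, sets, bin_specs=specs, prior=prior)
            oracle = brute_force_log2_posterior_odds(evidence, specs, sets, prior)
            assert np.allclose(result["mtRNA_score"], oracle.loc[result.index], atol=1e-9)

    def test_uninformative_track_changes_nothing(self):
        rng = np.random.default_rng(9)
        evidence, specs, sets = _random_instance(rng, 3, 30, 5, 8)
        base, _ = integrate(evidence, sets, bin_specs=specs)
        wider = evidence.copy()
        wider["flat"] = 0.5  # single-bin track: every gene, ratio log2(1) = 0
        specs2 = {**specs, "flat": BinSpec("flat", borders=())}
        extended, _ = integrate(wider, sets, bin_specs=specs2)
        assert np.allclose(base["mtRNA_score"], extended["mtRNA_score"], atol=1e-12)

    def test_prior_shifts_scores_but_not_ranking(self):
        rng = np.random.default_rng(13)
        evidence, specs, sets = _random_instance(rng, 3, 45, 6, 10)
        r300, _ = integrate(evidence, sets, bin_specs=specs, prior=PriorSpec(300, 20129))
        r1000, _ = integrate(evidence, sets, bin_specs=specs, prior=PriorSpec(1000, 20129))
        delta = r1000["mtRNA_score"] - r300["mtRNA_score"]
        expected = PriorSpec(1000, 20129).oprior_log2 - PriorSpec(300, 20129).oprior_log2
        assert np.allclose(delta, expected, atol=1e-12)
        order300 = rank_genes(r300).index
        order1000 = rank_genes(r1000).index
        assert list(order300) == list(order1000)

    def test_training_genes_missing_from_universe_rejected(self):
        rng = np.random.default_rng(1)
        evidence, specs, sets = _random_instance(rng, 2, 20, 4, 6)
        with pytest.raises(KeyError, match="missing"):
            integrate(evidence.iloc[5:], sets, bin_specs=specs)


class TestRankGenes:
    def _result(self, scores):
        frame = pd.DataFrame({"mtRNA_score": pd.Series(scores, dtype=float)})
        frame.index.name = "gene_id"
        return frame

    def test_score_ties_broken_by_fold_change(self):
        ranked = rank_genes(
            self._result({"A": 5.0, "B": 5.0, "C": 3.0}),
            fc_tie_break=pd.Series({"A": 1.0, "B": 2.0}),
        )
        assert list(ranked.index) == ["B", "A", "C"]
        assert ranked["rank"].tolist() == [1, 2, 3]

    def test_distinct_scores_ignore_fold_change(self):
        ranked = rank_genes(
            self._result({"A": 1.0, "B": 2.0}),
            fc_tie_break=pd.Series({"A": 100.0, "B": -100.0}),
        )
        assert list(ranked.index) == ["B", "A"]

    def test_full_tie_falls_back_to_gene_id(self):
        ranked = rank_genes(self._result({"B": 1.0, "A": 1.0, "C": 1.0}))
        assert list(ranked.index) == ["A", "B", "C"]

    def test_gene_with_fold_change_precedes_missing_on_tie(self):
        ranked = rank_genes(
            self._result({"A": 2.0, "B": 2.0}), fc_tie_break=pd.Series({"B": -5.0})
        )
        assert list(ranked.index) == ["B", "A"]

    def test_ranks_are_a_permutation(self):
        rng = np.random.default_rng(2)
        scores = {f"g{i}": float(rng.integers(0, 4)) for i in range(50)}
        ranked = rank_genes(self._result(scores))
        assert sorted(ranked["rank"]) == list(range(1, 51))
        assert (ranked["mtRNA_score"].diff().dropna() <= 0).all()


class TestEstimatorInterface:
    def test_fit_predict_shapes_and_clone(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)})
        X.loc[::5, "a"] = np.nan
        y = np.r_[np.ones(10, dtype=int), np.zeros(20, dtype=int)]
        clf = BinnedBayesClassifier(n_bins=3, n_expected=300, n_genes=1000)
        cloned = clone(clf)
        clf.fit(X, y)
        assert set(clf.bin_tables_) == {"a", "b"}
        assert clf.decision_function(X).shape == (30,)
        assert set(clf.predict(X)) <= {0, 1}
        assert cloned.get_params() == clf.get_params()

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="both classes"):
            BinnedBayesClassifier().fit(X, [1, 1])

    def test_params_roundtrip(self):
        clf = BinnedBayesClassifier(n_bins=4, pseudo_count_mode="own")
        params = clf.get_params()
        assert params["n_bins"] == 4 and params["pseudo_count_mode"] == "own"
        clf.set_params(n_bins=7)
        assert clf.n_bins == 7
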