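"""Metrics against brute-force oracles, split construction, statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from splitbench.corpus import SequenceWindow, SourceCorpus
from splitbench.evaluate import (
    EvalReport,
    EvaluationError,
    ProtocolInapplicableError,
    SplitConfig,
    auc,
    compare_reports,
    kfold_cv,
    make_experiment_splits,
    sensitivity_at_specificity,
)
from splitbench.synth import SynthConfig, generate_corpus


from oracles import brute_force_auc, brute_force_sn_at_sp


class TestAUC:
    def test_worked_example(self):
        assert auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == 0.75

    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            auc([0.1, 0.2], [1, 1])

    @given(st.data())
    @settings(max_examples=300, deadline=None)
    def test_equals_pairwise_counting(self, data):
        n = data.draw(st.integers(4, 50))
        labels = data.draw(
            st.lists(st.sampled_from([0, 1]), min_size=n, max_size=n).filter(
                lambda l: 0 < sum(l) < len(l)
            )
        )
        # coarse grid forces plenty of ties
        scores = data.draw(
            st.lists(st.sampled_from([i / 10 for i in range(11)]),
                     min_size=n, max_size=n)
        )
        assert auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )


class TestSensitivityAtSpecificity:
    def test_perfect_separation_any_target(self):
        for t in (0.5, 0.9, 0.99):
            assert sensitivity_at_specificity([0.9, 0.8, 0.2, 0.1],
                                              [1, 1, 0, 0], t) == 1.0

    def test_scores_equal_labels(self):
        labels = [1] * 5 + [0] * 10
        assert sensitivity_at_specificity(labels, labels, 0.9) == 1.0

    def test_matches_exhaustive_enumeration_on_random_data(self):
        rng = np.random.default_rng(123)
        scores = np.r_[rng.uniform(0.5, 1.5, 10), rng.uniform(0, 1, 10)]
        labels = np.r_[np.ones(10), np.zeros(10)]
        got = sensitivity_at_specificity(scores, labels, 0.9)
        assert got == pytest.approx(brute_force_sn_at_sp(scores, labels, 0.9))

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_non_increasing_in_target(self, data):
        n = data.draw(st.integers(4, 30))
        labels = data.draw(
            st.lists(st.sampled_from([0, 1]), min_size=n, max_size=n).filter(
                lambda l: 0 < sum(l) < len(l)
            )
        )
        scores = data.draw(
            st.lists(st.floats(0, 1, allow_nan=False), min_size=n, max_size=n)
        )
        values = [
            sensitivity_at_specificity(scores, labels, t)
            for t in (0.1, 0.5, 0.9, 0.99)
        ]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_bad_target_rejected(self):
        with pytest.raises(EvaluationError):
            sensitivity_at_specificity([0.1, 0.9], [0, 1], 1.0)


def _mini_corpus(source_sizes: dict[str, int], shared: dict[tuple[str, ...], int],
                 n_negatives: int = 40) -> SourceCorpus:
    """Corpus whose windows are synthetic 61-mers with known source layout."""
    corpus = SourceCorpus()
    counter = 0

    def fresh_window(sources):
        nonlocal counter
        counter += 1
        tag = np.base_repr(counter, 20)
        seq = ("".join("ACDEFGHILMNPQRSTVWYX"[int(c, 20)] for c in tag)
               .rjust(30, "A"))[:30] + "K" + "A" * 30
        return SequenceWindow(seq, frozenset(["Kme1", "Kme"]), frozenset(sources))

    for srcs, count in shared.items():
        for _ in range(count):
            w = fresh_window(srcs)
            corpus.positives[w.sequence] = w
            for s in srcs:
                corpus.source_index.setdefault(s, set()).add(w.sequence)
    for src, size in source_sizes.items():
        have = len(corpus.source_index.get(src, ()))
        for _ in range(size - have):
            w = fresh_window([src])
            corpus.positives[w.sequence] = w
            corpus.source_index.setdefault(src, set()).add(w.sequence)
    for i in range(n_negatives):
        seq = f"{i:05d}".replace("0", "G").replace("1", "L").replace(
            "2", "M").replace("3", "N").replace("4", "P").replace(
            "5", "R").replace("6", "S").replace("7", "T").replace(
            "8", "V").replace("9", "W").rjust(30, "C")[:30] + "K" + "C" * 30
        corpus.negatives[seq] = SequenceWindow(seq)
    corpus.validate()
    return corpus


class TestMakeExperimentSplits:
    CFG = SplitConfig(n_negatives_total=20, min_test_sets=2,
                      min_positives_per_test=5, seed=0)

    def test_shared_windows_removed_from_test(self):
        corpus = _mini_corpus({"A": 10, "B": 8}, {("A", "B"): 3})
        splits = make_experiment_splits(corpus, "Kme1", self.CFG)
        split_a = next(s for s in splits if s.held_out_source == "A")
        assert len(split_a.test_positives) == 7
        assert len(split_a.train_positives) == 8  # all of B, shared included

    def test_source_below_minimum_dropped(self):
        corpus = _mini_corpus({"A": 10, "B": 10, "C": 4}, {})
        splits = make_experiment_splits(corpus, "Kme1", self.CFG)
        assert {s.held_out_source for s in splits} == {"A", "B"}

    def test_pairwise_disjoint_sources_give_one_split_each(self):
        sizes = {f"S{i}": 6 for i in range(6)}
        corpus = _mini_corpus(sizes, {})
        splits = make_experiment_splits(corpus, "Kme1", self.CFG)
        assert len(splits) == 6
        for s in splits:
            assert len(s.test_positives) == 6
            assert len(s.train_positives) == 30

    def test_protocol_inapplicable_when_too_few_test_sets(self):
        corpus = _mini_corpus({"A": 10, "B": 4}, {})
        with pytest.raises(ProtocolInapplicableError, match="inapplicable"):
            make_experiment_splits(corpus, "Kme1", self.CFG)

    def test_absent_mod_type_rejected(self):
        corpus = _mini_corpus({"A": 6, "B": 6}, {})
        with pytest.raises(EvaluationError, match="Kme3"):
            make_experiment_splits(corpus, "Kme3", self.CFG)

    def test_insufficient_negatives_message(self):
        corpus = _mini_corpus({"A": 6, "B": 6}, {}, n_negatives=10)
        with pytest.raises(EvaluationError, match="n_negatives_total"):
            make_experiment_splits(corpus, "Kme1", self.CFG)

    def test_negative_halves_disjoint_and_sized(self):
        corpus = _mini_corpus({"A": 6, "B": 6}, {})
        splits = make_experiment_splits(corpus, "Kme1", self.CFG)
        for s in splits:
            assert len(s.train_negatives) == len(s.test_negatives) == 10
            tr = {w.sequence for w in s.train_negatives}
            te = {w.sequence for w in s.test_negatives}
            assert not tr & te

    def test_shared_negatives_flag_reuses_one_draw(self):
        corpus = _mini_corpus({"A": 6, "B": 6}, {})
        cfg = SplitConfig(n_negatives_total=20, min_test_sets=2,
                          min_positives_per_test=5, seed=3, shared_negatives=True)
        splits = make_experiment_splits(corpus, "Kme1", cfg)
        pools = [
            {w.sequence for w in s.train_negatives + s.test_negatives}
            for s in splits
        ]
        assert all(p == pools[0] for p in pools)

    def test_odd_negative_total_rejected(self):
        with pytest.raises(EvaluationError, match="even"):
            SplitConfig(n_negatives_total=11)


def test_split_leakage_fuzz_over_random_corpora():
    """No emitted split shares a window sequence between train and test."""
    for seed in range(25):
        cfg = SynthConfig(n_sources=5, positives_per_source=12, n_proteins=40,
                          mean_protein_length=150, overlap_rate=0.3,
                          heterogeneity=0.5, seed=seed)
        corpus = generate_corpus(cfg).build()
        try:
            splits = make_experiment_splits(
                corpus, "Kme",
                SplitConfig(n_negatives_total=200, min_test_sets=2, seed=seed),
            )
        except ProtocolInapplicableError:
            continue
        for s in splits:
            s.validate()
            assert len(s.test_positives) >= 5


@pytest.fixture(scope="module")
def toy_data():
    rng = np.random.default_rng(0)

    def windows(base, n):
        out = []
        for _ in range(n):
            flank = list(base * 60)
            for _ in range(8):
                flank[rng.integers(0, 60)] = "ACDEFGHILMNPQRSTVWY"[
                    rng.integers(0, 19)]
            out.append("".join(flank[:30]) + "K" + "".join(flank[30:60]))
        return sorted(set(out))

    return windows("A", 60), windows("G", 80)


class TestKFoldCV:
    def test_fold_sizes_and_partition(self, toy_data):
        pos, neg = toy_data
        from splitbench.evaluate import stratified_folds
        y = np.r_[np.ones(len(pos), dtype=int), np.zeros(len(pos), dtype=int)]
        test_idx = [te for _, te in stratified_folds(y, 10, seed=0)]
        for cls in (0, 1):
            per_fold = [np.sum(y[t] == cls) for t in test_idx]
            assert max(per_fold) - min(per_fold) <= 1
        assert sorted(np.concatenate(test_idx)) == list(range(len(y)))
        assert [len(t) for t in stratified_folds(y, 10, seed=0)[0]] == [
            len(t) for t in stratified_folds(y, 10, seed=0)[0]
        ]

    def test_separable_data_high_auc_and_determinism(self, toy_data):
        pos, neg = toy_data
        from splitbench.models import ModelSpec
        from splitbench.train import TrainConfig
        spec = ModelSpec(conv1=(8, 9), conv2=(8, 7), fc_width=8)
        tcfg = TrainConfig(batch_size=32, max_epochs=8, learning_rate=2e-3, seed=0)
        rep = kfold_cv(pos, neg, spec, tcfg, k=5, balanced=True, seed=1)
        rep2 = kfold_cv(pos, neg, spec, tcfg, k=5, balanced=True, seed=1)
        assert rep.aucs == rep2.aucs
        assert rep.mean > 0.9
        assert len(rep.aucs) == 5
        # balanced: each fold tests on equal class counts (up to rounding)
        assert rep.sd == pytest.approx(float(np.std(rep.aucs, ddof=1)))

    def test_too_small_k_rejected(self, toy_data):
        pos, neg = toy_data
        from splitbench.models import ModelSpec
        from splitbench.train import TrainConfig
        with pytest.raises(EvaluationError):
            kfold_cv(pos, neg, ModelSpec(), TrainConfig(), k=1)


class TestCompareReports:
    def test_zero_variance_single_sample_rejected(self):
        with pytest.raises(EvaluationError, match="zero variance"):
            compare_reports([0.5, 0.5, 0.5, 0.5], reference=0.5,
                            test="single_sample")

    def test_paired_identical_vectors_rejected(self):
        with pytest.raises(EvaluationError, match="identical"):
            compare_reports([0.1, 0.2, 0.3], [0.1, 0.2, 0.3], test="paired")

    def test_single_sample_against_published_reference(self):
        """49 AUCs ~ N(0.6, 0.1^2) against a reference of 0.951: p << 1e-6."""
        rng = np.random.default_rng(99)
        values = rng.normal(0.6, 0.1, size=49)
        p = compare_reports(values, reference=0.951, test="single_sample")
        # independent verification through the t CDF
        t_stat = (values.mean() - 0.951) / (values.std(ddof=1) / np.sqrt(49))
        p_manual = 2 * stats.t.cdf(-abs(t_stat), df=48)
        assert p == pytest.approx(p_manual, rel=1e-10)
        assert p < 1e-6

    def test_paired_and_two_sample_match_scipy(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.8, 0.02, 10)
        b = a - rng.normal(0.05, 0.02, 10)
        assert compare_reports(a, b, test="paired") == pytest.approx(
            stats.ttest_rel(a, b).pvalue)
        c = rng.normal(0.7, 0.1, 8)
        assert compare_reports(a, c, test="two_sample") == pytest.approx(
            stats.ttest_ind(a, c, equal_var=False).pvalue)

    def test_unknown_test_rejected(self):
        with pytest.raises(EvaluationError):
            compare_reports([1, 2], [3, 4], test="anova")


class TestEvalReport:
    def test_mean_sd_consistent_and_summary_renders(self):
        rep = EvalReport("cv", ["f1", "f2", "f3"], [0.8, 0.7, 0.9], [0.5, 0.4, 0.6])
        assert rep.mean == pytest.approx(0.8)
        assert rep.sd == pytest.approx(np.std([0.8, 0.7, 0.9], ddof=1))
        text = rep.summary()
        assert "0.8000" in text and "f2" in text
        d = rep.to_dict()
        assert d["auc_mean"] == rep.mean and len(d["auc"]) == 3
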