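"""Synthetic corpus generator: determinism, structure, and signal control."""

import numpy as np
import pytest

from splitbench.corpus import build_corpus
from splitbench.evaluate import auc
from splitbench.models import ModelSpec, build_model
from splitbench.synth import (
    SynthConfig,
    SynthError,
    describe_corpus,
    generate_corpus,
)
from splitbench.train import TrainConfig, train

SMALL = dict(n_sources=4, positives_per_source=15, n_proteins=40,
             mean_protein_length=150)


class TestConfigValidation:
    def test_bounds_checked(self):
        with pytest.raises(SynthError):
            SynthConfig(heterogeneity=1.5)
        with pytest.raises(SynthError):
            SynthConfig(overlap_rate=-0.1)
        with pytest.raises(SynthError):
            SynthConfig(motif_strength=-1)
        with pytest.raises(SynthError):
            SynthConfig(mod_type_probs=(0.5, 0.5, 0.5))

    def test_core_motif_shape_checked(self):
        with pytest.raises(SynthError):
            SynthConfig(core_motif=np.ones((10, 20)))
        bad = np.full((60, 20), 0.1)
        with pytest.raises(SynthError, match="sum to 1"):
            SynthConfig(core_motif=bad)


class TestGeneration:
    def test_same_seed_byte_identical(self):
        a = generate_corpus(SynthConfig(**SMALL, heterogeneity=0.0, seed=5))
        b = generate_corpus(SynthConfig(**SMALL, heterogeneity=0.0, seed=5))
        assert a.proteome == b.proteome
        assert a.records == b.records
        c = generate_corpus(SynthConfig(**SMALL, heterogeneity=0.0, seed=6))
        assert c.proteome != a.proteome

    def test_zero_overlap_gives_disjoint_sources(self):
        sc = generate_corpus(SynthConfig(**SMALL, overlap_rate=0.0, seed=1))
        corpus = sc.build()
        srcs = corpus.sources()
        for i, a in enumerate(srcs):
            for b in srcs[i + 1:]:
                assert not corpus.source_index[a] & corpus.source_index[b]

    def test_positive_overlap_rate_yields_shared_windows(self):
        sc = generate_corpus(SynthConfig(**SMALL, overlap_rate=0.5, seed=1))
        corpus = sc.build()
        multi = [w for w in corpus.positives.values() if len(w.sources) > 1]
        assert multi

    def test_capacity_error(self):
        with pytest.raises(SynthError, match="at most"):
            generate_corpus(SynthConfig(n_sources=10, positives_per_source=500,
                                        n_proteins=5, mean_protein_length=100))

    def test_round_trip_through_files(self, tmp_path):
        sc = generate_corpus(SynthConfig(**SMALL, seed=9))
        fasta, table = tmp_path / "p.fasta", tmp_path / "s.tsv"
        sc.write(fasta, table)
        from splitbench.corpus import read_fasta, read_site_table
        corpus_direct = sc.build()
        corpus_files = build_corpus(read_site_table(table), read_fasta(fasta))
        assert corpus_direct.positives == corpus_files.positives
        assert corpus_direct.negatives.keys() == corpus_files.negatives.keys()
        assert corpus_direct.source_index == corpus_files.source_index

    def test_all_mod_types_represented_at_scale(self):
        sc = generate_corpus(SynthConfig(n_sources=8, positives_per_source=50,
                                         n_proteins=100, mean_protein_length=300,
                                         seed=2))
        mods = {m for r in sc.records for m in r.mod_types}
        assert mods == {"Kme1", "Kme2", "Kme3"}


class TestDescribeCorpus:
    def test_counts_and_overlap_consistency(self, small_synth_corpus):
        _, corpus = small_synth_corpus
        counts, overlap = describe_corpus(corpus)
        for src in corpus.sources():
            assert counts.loc[src, "total"] == len(corpus.source_index[src])
            assert overlap.loc[src, src] == len(corpus.source_index[src])
        assert (overlap.values == overlap.values.T).all()
        assert len(corpus.positives) <= counts["total"].sum()

    def test_window_in_three_sources_counts_three_times(self):
        from splitbench.corpus import SequenceWindow, SourceCorpus
        w = SequenceWindow("A" * 30 + "K" + "A" * 30,
                           frozenset(["Kme1", "Kme"]),
                           frozenset(["E1", "E2", "E3"]))
        corpus = SourceCorpus({w.sequence: w}, {},
                              {s: {w.sequence} for s in w.sources})
        counts, overlap = describe_corpus(corpus)
        assert counts["total"].sum() == 3
        assert (overlap.values == 1).all()


class TestSignalControl:
    def test_zero_strength_auc_near_half(self):
        """With no planted signal any classifier's expected AUC is 0.5."""
        aucs = []
        for seed in range(10):
            cfg = SynthConfig(**SMALL, motif_strength=0.0, seed=seed)
            corpus = generate_corpus(cfg).build()
            pos = corpus.positive_windows("Kme")
            neg = corpus.negative_windows()
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(neg), 2 * len(pos), replace=False)
            tr_n = [neg[i] for i in idx[:len(pos)]]
            te_n = [neg[i] for i in idx[len(pos):]]
            half = len(pos) // 2
            spec = ModelSpec(conv1=(8, 9), conv2=(8, 7), fc_width=8)
            model = build_model(spec, seed=seed)
            cfg_t = TrainConfig(batch_size=64, max_epochs=8,
                                learning_rate=2e-3, seed=seed)
            fitted = train(model, pos[:half], tr_n, cfg_t)
            scores = fitted.score(pos[half:] + te_n)
            labels = np.r_[np.ones(len(pos) - half), np.zeros(len(te_n))]
            aucs.append(auc(scores, labels))
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_auc_increases_with_motif_strength(self):
        """Held-out AUC is monotone over three strength levels (fixed seeds)."""
        means = []
        for strength in (0.0, 1.5, 3.0):
            vals = []
            for seed in (0, 1):
                cfg = SynthConfig(n_sources=4, positives_per_source=30,
                                  n_proteins=60, mean_protein_length=200,
                                  motif_strength=strength, heterogeneity=0.0,
                                  seed=seed)
                corpus = generate_corpus(cfg).build()
                pos = corpus.positive_windows("Kme")
                neg = corpus.negative_windows()
                rng = np.random.default_rng(seed)
                idx = rng.choice(len(neg), 2 * len(pos), replace=False)
                tr_n = [neg[i] for i in idx[:len(pos)]]
                te_n = [neg[i] for i in idx[len(pos):]]
                half = len(pos) // 2
                spec = ModelSpec(conv1=(16, 9), conv2=(8, 7), fc_width=16)
                fitted = train(
                    build_model(spec, seed=seed), pos[:half], tr_n,
                    TrainConfig(batch_size=64, max_epochs=15,
                                learning_rate=2e-3, seed=seed),
                )
                scores = fitted.score(pos[half:] + te_n)
                labels = np.r_[np.ones(len(pos) - half), np.zeros(len(te_n))]
                vals.append(auc(scores, labels))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_gap_increases_with_heterogeneity(self, homo_benchmark,
                                              hetero_benchmark):
        """CV-minus-split gap grows from heterogeneity 0 to 0.8."""
        assert hetero_benchmark.gap > homo_benchmark.gap

    def test_homogeneous_sources_close_protocols(self, homo_benchmark):
        """With one shared motif the two protocols estimate the same thing."""
        assert abs(homo_benchmark.gap) < 0.05


def test_human_background_frequencies_used():
    cfg = SynthConfig(**SMALL, background="human", motif_strength=0.0, seed=0)
    sc = generate_corpus(cfg)
    text = "".join(sc.proteome.values())
    # leucine is ~10% in the human table, tryptophan ~1.2%
    assert text.count("L") / len(text) > 2.5 * text.count("W") / len(text)
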