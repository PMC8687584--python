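"""Shared fixtures: tiny hand-built corpora and the replicated benchmark.

The two session-scoped benchmark fixtures run the full CV-vs-experiment-split
comparison (10 corpus replicates each) and dominate the suite's runtime; every
test that needs replicate-level results shares them.
"""

from __future__ import annotations

import numpy as np
import pytest

from splitbench.benchmark import BenchmarkResult, run_replicates
from splitbench.corpus import SiteRecord, build_corpus
from splitbench.synth import SynthConfig, generate_corpus

BENCHMARK_SEED = 101


@pytest.fixture(scope="session")
def hetero_benchmark() -> BenchmarkResult:
    """10 replicates at heterogeneity 0.8: sources carry mostly private motifs."""
    return run_replicates(0.8, n_replicates=10, seed=BENCHMARK_SEED)


@pytest.fixture(scope="session")
def homo_benchmark() -> BenchmarkResult:
    """10 replicates at heterogeneity 0: every source shares one motif."""
    return run_replicates(0.0, n_replicates=10, seed=BENCHMARK_SEED)


@pytest.fixture()
def toy_proteome() -> dict[str, str]:
    rng = np.random.default_rng(42)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return {
        f"P{i}": "".join(rng.choice(aa, size=120)) for i in range(6)
    }


@pytest.fixture()
def toy_corpus(toy_proteome):
    """Small corpus with two sources sharing some annotated lysines."""
    records = []
    for pid, seq in toy_proteome.items():
        ks = [i + 1 for i, c in enumerate(seq) if c == "K"]
        for j, pos in enumerate(ks[:3]):
            sources = {"E1"} if j % 2 == 0 else {"E2"}
            if j == 2:
                sources = {"E1", "E2"}
            records.append(
                SiteRecord(pid, pos, frozenset(["Kme1"]), frozenset(sources))
            )
    return build_corpus(records, toy_proteome)


@pytest.fixture(scope="session")
def small_synth_corpus():
    """Desk corpus from the generator defaults at heterogeneity 0.5."""
    cfg = SynthConfig(n_sources=5, positives_per_source=20, n_proteins=60,
                      mean_protein_length=200, heterogeneity=0.5, seed=7)
    sc = generate_corpus(cfg)
    return sc, sc.build()
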