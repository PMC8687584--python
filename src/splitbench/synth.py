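"""Synthetic multi-source site corpora with controllable source heterogeneity.

The generator emulates the statistical structure the leave-one-source-out
benchmark cares about, without any real proteome:

* a random proteome drawn from background amino-acid frequencies;
* positive lysine sites whose nearby flanking context is sampled from a
  position weight matrix (PWM) — a convex blend of one *core* motif shared by
  all experimental sources and a *source-specific* motif, with blend weight
  ``heterogeneity`` (0 = every source shares one context distribution,
  1 = purely source-private motifs);
* a fraction ``overlap_rate`` of sites attributed to a second source,
  emulating the same site being rediscovered by independent experiments;
* per-source sizes drawn with a log-normal multiplier, since real
  experimental sources are far from uniform in size;
* every remaining lysine in the proteome is an implicit negative.

With heterogeneity high, a classifier trained on mixed sources can exploit
every source's motif while a held-out source's private motif stays unseen —
exactly the condition under which mixed-source cross-validation should
overestimate generalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import (
    AMINO_ACIDS,
    FLANK,
    SiteRecord,
    SourceCorpus,
    build_corpus,
    write_fasta,
    write_site_table,
)

#: Approximate human-proteome amino-acid frequencies (UniProt averages),
#: in the order of :data:`splitbench.corpus.AMINO_ACIDS`.
HUMAN_AA_FREQS = np.array([
    0.070, 0.023, 0.047, 0.071, 0.037, 0.066, 0.026, 0.043, 0.057, 0.100,
    0.021, 0.036, 0.063, 0.048, 0.056, 0.083, 0.054, 0.060, 0.012, 0.027,
])
HUMAN_AA_FREQS = HUMAN_AA_FREQS / HUMAN_AA_FREQS.sum()

_DEFAULT_MOTIF_OFFSETS = (-5, -4, -3, -2, -1, 1, 2, 3, 4, 5)


class SynthError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Generator settings; the defaults are the desk-scale study conditions.

    ``motif_strength`` scales the log-enrichment of each motif position's
    preferred residue over background (0 = no signal, positives are
    indistinguishable from negatives).  ``heterogeneity`` in [0, 1] is the
    fraction of motif information that is source-specific.
    ``size_dispersion`` is the sigma of the log-normal multiplier on
    per-source positive counts.  ``mod_type_probs`` gives the mono/di/tri
    methylation mix, defaulting to the roughly 0.81 / 0.11 / 0.08 split seen
    in curated human lysine-methylation data.
    """

    n_sources: int = 8
    positives_per_source: int = 50
    n_proteins: int = 500
    mean_protein_length: int = 400
    motif_strength: float = 3.0
    heterogeneity: float = 0.0
    overlap_rate: float = 0.1
    size_dispersion: float = 0.25
    mod_type_probs: tuple[float, float, float] = (0.81, 0.11, 0.08)
    motif_offsets: tuple[int, ...] = _DEFAULT_MOTIF_OFFSETS
    background: str = "uniform"  # or "human"
    core_motif: np.ndarray | None = None  # optional (2*FLANK, 20) PWM
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.heterogeneity <= 1.0:
            raise SynthError("heterogeneity must be in [0, 1]")
        if not 0.0 <= self.overlap_rate <= 1.0:
            raise SynthError("overlap_rate must be in [0, 1]")
        if self.motif_strength < 0:
            raise SynthError("motif_strength must be >= 0")
        if abs(sum(self.mod_type_probs) - 1.0) > 1e-9:
            raise SynthError("mod_type_probs must sum to 1")
        if self.background not in ("uniform", "human"):
            raise SynthError(f"unknown background {self.background!r}")
        if self.core_motif is not None:
            pwm = np.asarray(self.core_motif)
            if pwm.shape != (2 * FLANK, 20):
                raise SynthError(f"core_motif must be {2 * FLANK} x 20")
            if not np.allclose(pwm.sum(axis=1), 1.0):
                raise SynthError("core_motif columns must sum to 1")

    @property
    def background_freqs(self) -> np.ndarray:
        if self.background == "human":
            return HUMAN_AA_FREQS
        return np.full(20, 1.0 / 20.0)


@dataclass
class SynthCorpus:
    """Generated proteome + site annotations, ready to write or build."""

    proteome: dict[str, str]
    records: list[SiteRecord]
    config: SynthConfig

    def write(self, fasta_path: str | Path, table_path: str | Path) -> None:
        write_fasta(self.proteome, fasta_path)
        write_site_table(self.records, table_path)

    def build(self) -> SourceCorpus:
        return build_corpus(self.records, self.proteome)


def _motif_pwm(rng: np.random.Generator, offsets, strength: float,
               background: np.ndarray) -> np.ndarray:
    """Full (2*FLANK, 20) PWM: background everywhere except enriched offsets.

    Each motif offset prefers one residue with probability proportional to
    background * exp(strength).
    """
    pwm = np.tile(background, (2 * FLANK, 1))
    for off in offsets:
        row = off + FLANK if off < 0 else off + FLANK - 1  # flank rows skip center
        logits = np.log(background).copy()
        logits[rng.integers(20)] += strength
        col = np.exp(logits)
        pwm[row] = col / col.sum()
    return pwm


def _flank_row(offset: int) -> int:
    """Map a nonzero center offset to its row in the (2*FLANK, 20) PWM."""
    return offset + FLANK if offset < 0 else offset + FLANK - 1


def generate_corpus(config: SynthConfig) -> SynthCorpus:
    """Draw a proteome and plant multi-source positive sites into it.

    Sites are placed at least 11 residues apart so planted motif contexts
    never overwrite each other; the central residue is set to 'K' and each
    motif offset is sampled from the source's blended PWM.  Raises
    :class:`SynthError` when the requested number of positives exceeds the
    placement capacity of the proteome.
    """
    rng = np.random.default_rng(config.seed)
    bg = config.background_freqs
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

    # --- proteome ---------------------------------------------------------
    lengths = np.maximum(80, rng.poisson(config.mean_protein_length,
                                         size=config.n_proteins))
    proteins = [
        bytearray(aa[rng.choice(20, size=n, p=bg)].tobytes()) for n in lengths
    ]
    names = [f"SYN{i + 1:04d}" for i in range(config.n_proteins)]

    # --- motifs -----------------------------------------------------------
    core = (config.core_motif if config.core_motif is not None
            else _motif_pwm(rng, config.motif_offsets, config.motif_strength, bg))
    h = config.heterogeneity
    blends = []
    for _ in range(config.n_sources):
        src_pwm = _motif_pwm(rng, config.motif_offsets, config.motif_strength, bg)
        blends.append((1.0 - h) * core + h * src_pwm)

    # --- per-source site counts ------------------------------------------
    sizes = np.full(config.n_sources, config.positives_per_source, dtype=float)
    if config.size_dispersion > 0:
        sizes *= rng.lognormal(0.0, config.size_dispersion, size=config.n_sources)
    sizes = np.maximum(1, np.round(sizes).astype(int))
    total = int(sizes.sum())

    min_sep = 11  # > 2 * max|offset|, keeps planted contexts disjoint
    capacity = sum(max(0, (n - 10) // min_sep) for n in lengths)
    if total > capacity:
        raise SynthError(
            f"requested {total} positive sites but the proteome can hold at "
            f"most {capacity}; enlarge the proteome or reduce the sources"
        )

    # --- placement --------------------------------------------------------
    occupied: dict[int, list[int]] = {i: [] for i in range(config.n_proteins)}
    protein_probs = lengths / lengths.sum()
    placements: list[tuple[int, int]] = []
    tries = 0
    while len(placements) < total:
        tries += 1
        if tries > 200 * total:
            raise SynthError("could not place all sites; proteome too crowded")
        p = rng.choice(config.n_proteins, p=protein_probs)
        pos = int(rng.integers(6, lengths[p] - 4))  # 1-based, +/-5 in bounds
        if all(abs(pos - q) >= min_sep for q in occupied[p]):
            occupied[p].append(pos)
            placements.append((p, pos))

    # --- plant contexts and emit records ---------------------------------
    mod_names = np.array(["Kme1", "Kme2", "Kme3"])
    records: list[SiteRecord] = []
    site_iter = iter(placements)
    for s in range(config.n_sources):
        pwm = blends[s]
        for _ in range(sizes[s]):
            p, pos = next(site_iter)
            seq = proteins[p]
            seq[pos - 1] = ord("K")
            for off in config.motif_offsets:
                col = pwm[_flank_row(off)]
                seq[pos - 1 + off] = aa[rng.choice(20, p=col)]
            sources = {f"E{s + 1}"}
            if config.n_sources > 1 and rng.random() < config.overlap_rate:
                extra = int(rng.integers(config.n_sources - 1))
                extra = extra if extra < s else extra + 1
                sources.add(f"E{extra + 1}")
            mod = mod_names[rng.choice(3, p=config.mod_type_probs)]
            records.append(
                SiteRecord(names[p], pos, frozenset([mod]), frozenset(sources))
            )

    proteome = {name: bytes(seq).decode() for name, seq in zip(names, proteins)}
    return SynthCorpus(proteome, records, config)


def describe_corpus(corpus: SourceCorpus):
    """Per-source counts and the pairwise window-overlap matrix.

    Returns ``(counts, overlap)`` DataFrames.  ``counts`` has one row per
    source with positive-window counts per label; ``overlap[i, j]`` is the
    number of distinct windows attributed to both sources (diagonal = source
    size).  A window in three sources contributes to all three counts.
    """
    import pandas as pd

    srcs = corpus.sources()
    labels = ["Kme1", "Kme2", "Kme3", "Kme"]
    counts = pd.DataFrame(0, index=srcs, columns=labels + ["total"])
    for src in srcs:
        ws = [corpus.positives[s] for s in corpus.source_index[src]]
        counts.loc[src, "total"] = len(ws)
        for lab in labels:
            counts.loc[src, lab] = sum(lab in w.labels for w in ws)
    overlap = pd.DataFrame(0, index=srcs, columns=srcs)
    for i, a in enumerate(srcs):
        for b in srcs[i:]:
            n = len(corpus.source_index[a] & corpus.source_index[b])
            overlap.loc[a, b] = n
            overlap.loc[b, a] = n
    return counts, overlap
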