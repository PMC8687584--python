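"""Window corpus construction for lysine-methylation site benchmarking.

A predictor in this package scores 61-residue sequence windows centered on a
lysine.  This module turns a proteome (FASTA) plus a site-annotation table
(protein accession, 1-based position, modification type, experimental source)
into a deduplicated :class:`SourceCorpus`:

* positive windows — one per distinct 61-mer; annotations from records that
  collapse onto the same window are merged (union of labels, union of sources);
* negative windows — every other lysine-centered 61-mer in the proteome;
* a source index mapping each experimental source to the positive windows it
  contributed, which is the unit the leave-one-source-out evaluation holds out.

Coordinates are 1-based throughout, matching UniProt-style site annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids (alphabetical one-letter codes).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Padding / unknown-residue symbol used beyond protein termini.
PAD = "X"

#: Individual methylation states: mono-, di- and tri-methyl lysine.
MOD_TYPES = ("Kme1", "Kme2", "Kme3")

#: Union label carried by every methylated window regardless of state.
UNION_LABEL = "Kme"

#: Half-width of the sequence window; the window is 2*FLANK + 1 residues.
FLANK = 30

WINDOW_LENGTH = 2 * FLANK + 1
CENTER = FLANK  # 0-based index of the central lysine

_VALID_SET = frozenset(AMINO_ACIDS)


class CorpusError(ValueError):
    """Malformed annotations or unresolvable accessions."""


def sanitize_sequence(sequence: str) -> str:
    """Uppercase and map non-standard residues (B, Z, U, O, ``*`` ...) to 'X'.

    The encoder alphabet has exactly 21 symbols (20 amino acids plus the
    padding symbol), so everything outside it is collapsed onto 'X' before
    windowing.
    """
    seq = sequence.upper()
    if _VALID_SET.issuperset(seq):
        return seq
    return "".join(c if c in _VALID_SET else PAD for c in seq)


@dataclass(frozen=True)
class SiteRecord:
    """One annotated lysine site.

    Parameters
    ----------
    protein_id : accession of the parent protein.
    position : 1-based residue index of the lysine.
    mod_types : subset of :data:`MOD_TYPES`; non-empty for positive records.
    sources : experimental sources reporting the site (opaque identifiers).
    """

    protein_id: str
    position: int
    mod_types: frozenset[str]
    sources: frozenset[str]
    residue: str = "K"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise CorpusError(f"position must be >= 1, got {self.position}")
        if not self.mod_types:
            raise CorpusError(f"{self.protein_id}:{self.position}: empty mod_types")
        bad = set(self.mod_types) - set(MOD_TYPES)
        if bad:
            raise CorpusError(f"unknown modification types {sorted(bad)}")
        if not self.sources:
            raise CorpusError(f"{self.protein_id}:{self.position}: empty sources")


@dataclass(frozen=True)
class SequenceWindow:
    """A 61-residue window with its labels and experimental sources.

    ``labels`` is empty for negatives; a positive window always carries the
    union label ``Kme`` in addition to the specific methylation states.
    """

    sequence: str
    labels: frozenset[str] = frozenset()
    sources: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.sequence) != WINDOW_LENGTH:
            raise CorpusError(
                f"window length {len(self.sequence)} != {WINDOW_LENGTH}"
            )
        if self.sequence[CENTER] != "K":
            raise CorpusError("window center is not 'K'")

    @property
    def is_positive(self) -> bool:
        return bool(self.labels)


@dataclass
class SourceCorpus:
    """Deduplicated positive/negative windows indexed by experimental source."""

    positives: dict[str, SequenceWindow] = field(default_factory=dict)
    negatives: dict[str, SequenceWindow] = field(default_factory=dict)
    #: source id -> set of positive window sequences attributed to it
    source_index: dict[str, set[str]] = field(default_factory=dict)

    def positive_windows(self, mod_type: str | None = None) -> list[SequenceWindow]:
        """Positive windows, optionally restricted to one label (e.g. 'Kme1')."""
        ws = self.positives.values()
        if mod_type is None:
            return list(ws)
        return [w for w in ws if mod_type in w.labels]

    def negative_windows(self) -> list[SequenceWindow]:
        return list(self.negatives.values())

    def sources(self) -> list[str]:
        return sorted(self.source_index)

    def validate(self) -> None:
        """Assert the structural invariants (disjointness, index consistency)."""
        overlap = self.positives.keys() & self.negatives.keys()
        if overlap:
            raise CorpusError(f"{len(overlap)} sequences in both classes")
        for src, seqs in self.source_index.items():
            for s in seqs:
                w = self.positives.get(s)
                if w is None or src not in w.sources:
                    raise CorpusError(f"source index inconsistent for {src!r}")


def extract_window(protein_sequence: str, position: int, flank: int = FLANK) -> str:
    """Cut the ``2*flank + 1`` window centered on a 1-based lysine position.

    Windows running past either terminus are padded with 'X' on that side so
    every window has the same length.  Raises :class:`CorpusError` if the
    position is out of range or the central residue is not 'K' (a malformed
    annotation should fail loudly, not silently shrink the benchmark).
    """
    n = len(protein_sequence)
    if not 1 <= position <= n:
        raise CorpusError(f"position {position} out of range 1..{n}")
    center = protein_sequence[position - 1]
    if center != "K":
        raise CorpusError(
            f"central residue at position {position} is {center!r}, expected 'K'"
        )
    lo, hi = position - 1 - flank, position + flank
    left = PAD * max(0, -lo) + protein_sequence[max(0, lo):position - 1]
    right = protein_sequence[position:hi] + PAD * max(0, hi - n)
    return left + center + right


def build_positive_set(
    records: Iterable[SiteRecord],
    proteome: Mapping[str, str],
    flank: int = FLANK,
    skip_invalid: bool = False,
) -> dict[str, SequenceWindow]:
    """Window every record and merge records that yield the same 61-mer.

    Identical window sequences (possibly from different proteins) are collapsed
    into one window carrying the union of modification labels (plus the union
    label ``Kme``) and the union of sources.  Returns a mapping keyed by window
    sequence.

    With ``skip_invalid`` a record whose central residue is not 'K' is logged
    and dropped instead of aborting the build.
    """
    records = list(records)
    missing = sorted({r.protein_id for r in records} - set(proteome))
    if missing:
        raise CorpusError(f"accessions not in proteome: {missing}")

    merged: dict[str, tuple[set[str], set[str]]] = {}
    for rec in records:
        seq = sanitize_sequence(proteome[rec.protein_id])
        try:
            window = extract_window(seq, rec.position, flank)
        except CorpusError as err:
            if skip_invalid:
                logger.warning("skipping %s:%d: %s", rec.protein_id, rec.position, err)
                continue
            raise CorpusError(f"{rec.protein_id}:{rec.position}: {err}") from err
        labels, sources = merged.setdefault(window, (set(), set()))
        labels.update(rec.mod_types)
        sources.update(rec.sources)

    return {
        seq: SequenceWindow(seq, frozenset(labels | {UNION_LABEL}), frozenset(sources))
        for seq, (labels, sources) in merged.items()
    }


def harvest_negatives(
    proteome: Mapping[str, str],
    positives: Mapping[str, SequenceWindow],
    flank: int = FLANK,
) -> dict[str, SequenceWindow]:
    """Collect every lysine-centered window not in the positive set.

    Scans all lysines in the supplied proteome; duplicates collapse to one
    window.  The number of negatives is therefore a property of the proteome,
    not a tuning constant.
    """
    negatives: dict[str, SequenceWindow] = {}
    for seq in proteome.values():
        seq = sanitize_sequence(seq)
        pos = seq.find("K")
        while pos != -1:
            window = extract_window(seq, pos + 1, flank)
            if window not in positives and window not in negatives:
                negatives[window] = SequenceWindow(window)
            pos = seq.find("K", pos + 1)
    return negatives


def build_corpus(
    records: Iterable[SiteRecord],
    proteome: Mapping[str, str],
    skip_invalid: bool = False,
) -> SourceCorpus:
    """Full pipeline: positives, negatives and the per-source index."""
    positives = build_positive_set(records, proteome, skip_invalid=skip_invalid)
    negatives = harvest_negatives(proteome, positives)
    source_index: dict[str, set[str]] = {}
    for seq, w in positives.items():
        for src in w.sources:
            source_index.setdefault(src, set()).add(seq)
    corpus = SourceCorpus(positives, negatives, source_index)
    corpus.validate()
    return corpus


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly line-wrapped) multi-record FASTA.

    The accession is the first whitespace-delimited token of the header line.
    """
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(proteome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for acc, seq in proteome.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


SITE_TABLE_COLUMNS = ["protein_id", "position", "mod_type", "source"]


def read_site_table(path: str | Path) -> list[SiteRecord]:
    """Read the tab-separated site table; one row per (site, mod_type, source).

    Rows sharing (protein_id, position) are aggregated into a single
    :class:`SiteRecord` with the union of modification types and sources.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "source": str})
    missing = set(SITE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise CorpusError(f"site table missing columns: {sorted(missing)}")
    records = []
    for (pid, pos), grp in df.groupby(["protein_id", "position"], sort=True):
        records.append(
            SiteRecord(
                protein_id=pid,
                position=int(pos),
                mod_types=frozenset(grp["mod_type"]),
                sources=frozenset(grp["source"]),
            )
        )
    return records


def write_site_table(records: Iterable[SiteRecord], path: str | Path) -> None:
    rows = [
        (r.protein_id, r.position, m, s)
        for r in records
        for m in sorted(r.mod_types)
        for s in sorted(r.sources)
    ]
    pd.DataFrame(rows, columns=SITE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_corpus(corpus: SourceCorpus, path: str | Path) -> None:
    """Serialize as TSV: sequence, comma-joined labels/sources, is_positive."""
    rows = [
        (w.sequence, ",".join(sorted(w.labels)), ",".join(sorted(w.sources)), True)
        for w in corpus.positives.values()
    ] + [(w.sequence, "", "", False) for w in corpus.negatives.values()]
    pd.DataFrame(
        rows, columns=["sequence", "labels", "sources", "is_positive"]
    ).to_csv(path, sep="\t", index=False)


def read_corpus(path: str | Path) -> SourceCorpus:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    corpus = SourceCorpus()
    for row in df.itertuples(index=False):
        labels = frozenset(filter(None, str(row.labels).split(",")))
        sources = frozenset(filter(None, str(row.sources).split(",")))
        w = SequenceWindow(row.sequence, labels, sources)
        if w.is_positive:
            corpus.positives[w.sequence] = w
            for src in sources:
                corpus.source_index.setdefault(src, set()).add(w.sequence)
        else:
            corpus.negatives[w.sequence] = w
    corpus.validate()
    return corpus
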