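"""Numeric encodings of 61-residue sequence windows.

Two encodings are produced here:

* **One-Hot (OH)** — each residue becomes a 21-dimensional indicator vector
  (20 amino acids plus the terminal-padding symbol 'X'), giving a 61 x 21
  binary matrix per window.
* **PSSM** — each residue becomes its 20-dimensional log-odds row from a
  PSI-BLAST position-specific scoring matrix, giving a 61 x 20 matrix; rows
  falling outside the protein are all-zero (the 'X' analogue).  Scores are by
  default squashed through the logistic function to bound the model inputs.

The word-embedding encoding is *not* produced here: it is a learned linear
layer (21 -> 5, no activation) and therefore lives inside the model
architectures (see :mod:`splitbench.models`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import FLANK, WINDOW_LENGTH

#: Fixed symbol order of the One-Hot encoding: 'Q' occupies slot 1, 'H'
#: slot 20 and the padding symbol 'X' the last slot.  Kept as a single named
#: constant so an alternative convention is a one-line change.
ONE_HOT_ORDER = "QARNDCEGILKMFPSTWYVHX"

_INDEX = {c: i for i, c in enumerate(ONE_HOT_ORDER)}


class EncodingError(ValueError):
    """Characters outside the alphabet or malformed PSSM files."""


@dataclass
class EncodedWindow:
    """A window as a 61 x C numeric matrix (C = 21 for OH, 20 for PSSM)."""

    matrix: np.ndarray
    encoding_tag: str  # "OH" or "PSSM"


def one_hot_encode(window: str) -> EncodedWindow:
    """Encode one 61-character window as a 61 x 21 binary indicator matrix.

    Every row has exactly one 1, at the slot of its residue under
    :data:`ONE_HOT_ORDER`.
    """
    if len(window) != WINDOW_LENGTH:
        raise EncodingError(f"window length {len(window)} != {WINDOW_LENGTH}")
    m = np.zeros((WINDOW_LENGTH, len(ONE_HOT_ORDER)), dtype=np.float32)
    for r, c in enumerate(window):
        try:
            m[r, _INDEX[c]] = 1.0
        except KeyError:
            raise EncodingError(
                f"character {c!r} at position {r + 1} is outside the "
                f"21-symbol alphabet"
            ) from None
    return EncodedWindow(m, "OH")


def one_hot_decode(matrix: np.ndarray) -> str:
    """Invert :func:`one_hot_encode` via per-row argmax."""
    return "".join(ONE_HOT_ORDER[i] for i in np.asarray(matrix).argmax(axis=1))


def one_hot_batch(windows: list[str]) -> np.ndarray:
    """Stack many windows into an (N, 61, 21) float32 array."""
    out = np.zeros((len(windows), WINDOW_LENGTH, len(ONE_HOT_ORDER)), dtype=np.float32)
    for i, w in enumerate(windows):
        out[i] = one_hot_encode(w).matrix
    return out


# ---------------------------------------------------------------------------
# PSSM
# ---------------------------------------------------------------------------

@dataclass
class ProteinPSSM:
    """Per-residue log-odds scores for one protein.

    ``scores`` is an L x 20 grid whose row i corresponds to residue i
    (1-based); ``column_order`` is the amino-acid order exactly as read from
    the file header.
    """

    protein_id: str
    scores: np.ndarray
    column_order: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise EncodingError(
                f"PSSM must have 20 score columns, got shape {self.scores.shape}"
            )


def read_pssm(path: str | Path, protein_id: str | None = None) -> ProteinPSSM:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Only the first numeric block (the 20 log-odds columns) is kept.  The
    header line of 40 amino-acid labels repeats the 20-letter order twice
    (log-odds block, then weighted-percentage block); a bare 20-label header
    is accepted too.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    header_idx = None
    for i, line in enumerate(lines):
        tokens = line.split()
        if tokens and all(len(t) == 1 and t.isalpha() for t in tokens):
            if len(tokens) in (20, 40):
                header_idx = i
                order = "".join(tokens[:20])
                break
            raise EncodingError(
                f"{path.name}:{i + 1}: expected 20 or 40 amino-acid column "
                f"labels, found {len(tokens)}"
            )
    if header_idx is None:
        raise EncodingError(f"{path.name}: no PSSM header line found")

    rows: list[list[float]] = []
    positions: list[int] = []
    for lineno, line in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        tokens = line.split()
        if not tokens:
            continue
        if not tokens[0].isdigit():
            break  # trailing K/Lambda statistics block
        # residue index, residue letter, then >= 20 numeric fields
        if len(tokens) < 22:
            raise EncodingError(
                f"{path.name}:{lineno}: expected at least 22 fields, got {len(tokens)}"
            )
        try:
            rows.append([float(t) for t in tokens[2:22]])
        except ValueError as err:
            raise EncodingError(f"{path.name}:{lineno}: {err}") from None
        positions.append(int(tokens[0]))

    if not rows:
        raise EncodingError(f"{path.name}: no score rows found")
    if positions != list(range(1, len(positions) + 1)):
        raise EncodingError(f"{path.name}: residue indices are not 1..L")

    return ProteinPSSM(protein_id or path.stem, np.array(rows), order)


def logistic(x: np.ndarray) -> np.ndarray:
    """Elementwise 1 / (1 + exp(-x)); bounds raw log-odds scores to (0, 1)."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def pssm_encode(
    protein_pssm: ProteinPSSM,
    position: int,
    flank: int = FLANK,
    squash: bool = True,
) -> EncodedWindow:
    """Assemble the (2*flank+1) x 20 PSSM window around a 1-based position.

    Rows outside the protein are all-zero.  With ``squash`` (the default) the
    logistic transform is applied to in-protein rows before padding, so padded
    rows stay exactly zero.
    """
    scores = protein_pssm.scores
    n = scores.shape[0]
    if not 1 <= position <= n:
        raise EncodingError(f"position {position} out of range 1..{n}")
    width = 2 * flank + 1
    out = np.zeros((width, 20), dtype=np.float32)
    lo = position - 1 - flank
    src_lo, src_hi = max(0, lo), min(n, position + flank)
    block = scores[src_lo:src_hi]
    if squash:
        block = logistic(block)
    out[src_lo - lo:src_lo - lo + block.shape[0]] = block
    return EncodedWindow(out, "PSSM")


def pseudo_pssm_from_sequence(sequence: str, protein_id: str = "synthetic") -> ProteinPSSM:
    """Synthetic stand-in PSSM: BLOSUM62 substitution rows broadcast per residue.

    This is *not* equivalent to an alignment-derived PSI-BLAST profile — it
    carries no evolutionary information beyond residue identity.  It exists so
    the PSSM-encoded architectures can be exercised and demonstrated without
    running PSI-BLAST.  'X' (and any non-standard residue) gets an all-zero row.
    """
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    order = ONE_HOT_ORDER[:20]
    rows = np.zeros((len(sequence), 20))
    for i, res in enumerate(sequence):
        if res in order:
            rows[i] = [blosum[res][c] for c in order]
    return ProteinPSSM(protein_id, rows, order)


# ---------------------------------------------------------------------------
# optional HDF5 serialization of encoded windows
# ---------------------------------------------------------------------------

def save_encodings(path: str | Path, encoded: dict[str, EncodedWindow]) -> None:
    """Write encoded windows to HDF5, one dataset per window sequence."""
    import h5py

    with h5py.File(path, "w") as fh:
        for seq, enc in encoded.items():
            ds = fh.create_dataset(seq, data=enc.matrix)
            ds.attrs["encoding_tag"] = enc.encoding_tag


def load_encodings(path: str | Path) -> dict[str, EncodedWindow]:
    import h5py

    out = {}
    with h5py.File(path, "r") as fh:
        for seq in fh:
            out[seq] = EncodedWindow(fh[seq][...], fh[seq].attrs["encoding_tag"])
    return out
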