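"""Alignment containers, indicator (one-hot) encoding and column filtering.

A multiple sequence alignment (MSA) is held as a character matrix over the
20 standard amino acids plus the gap symbol ``-``.  For the regression setup
each column is mapped to an integer factor with 21 levels (amino acids
1..20 in alphabetical one-letter order, gap = 21) and expanded into a
binary indicator matrix ``M`` with 21 columns per alignment column: the
entry for the observed character is 1, the other 20 are 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

logger = logging.getLogger("rmrcm")

#: Fixed amino-acid order defining integer levels 1..20; gap is level 21.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
N_STATES = 21
ALPHABET = AA_ORDER + GAP

#: character -> integer level (1-based, gap = 21)
AA_TO_INT = {aa: i + 1 for i, aa in enumerate(AA_ORDER)}
AA_TO_INT[GAP] = N_STATES
INT_TO_AA = {v: k for k, v in AA_TO_INT.items()}

#: ambiguity / non-standard codes collapsed onto the gap level (21)
AMBIGUOUS = set("BZXUOJ")


@dataclass
class Alignment:
    """A gapped protein multiple sequence alignment.

    Parameters
    ----------
    ids
        One identifier per sequence (row).
    chars
        ``(n_seq, n_col)`` matrix of single characters over the 20 amino
        acids and the gap symbol.
    molecule_labels
        Optional per-column integer tag partitioning the columns into two
        molecules (e.g. receptor = 0, peptide = 1) for inter/intra-molecular
        analyses.
    """

    ids: list[str]
    chars: np.ndarray
    molecule_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.chars = np.asarray(self.chars, dtype="<U1")
        if self.chars.ndim != 2:
            raise ValueError("chars must be a 2-D character matrix")
        if self.chars.shape[0] != len(self.ids):
            raise ValueError("number of ids does not match number of rows")
        if self.chars.shape[0] < 2:
            raise ValueError("an alignment needs at least 2 sequences")
        if self.molecule_labels is not None:
            self.molecule_labels = np.asarray(self.molecule_labels)
            if self.molecule_labels.shape != (self.chars.shape[1],):
                raise ValueError("molecule_labels must have one entry per column")

    @property
    def n_seq(self) -> int:
        return self.chars.shape[0]

    @property
    def n_col(self) -> int:
        return self.chars.shape[1]

    def sequences(self) -> list[str]:
        return ["".join(row) for row in self.chars]


@dataclass
class EncodedAlignment:
    """Integer and indicator form of an alignment.

    ``A`` holds the factor levels (1..21); ``M`` is the ``n_seq x 21*n_col``
    binary indicator expansion.  ``column_map[i]`` lists the 21 indicator
    column indices belonging to original column ``i``, so
    ``M[s, column_map[i][A[s, i] - 1]] == 1``.
    """

    A: np.ndarray
    M: np.ndarray
    column_map: np.ndarray
    aa_order: str = field(default=ALPHABET)

    @property
    def n_seq(self) -> int:
        return self.A.shape[0]

    @property
    def n_col(self) -> int:
        return self.A.shape[1]


def read_alignment(path, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Stockholm file into an :class:`Alignment`.

    Characters are upper-cased; both ``.`` and ``-`` gap conventions are
    normalised to ``-``.  Raises ``ValueError`` for ragged or empty input,
    naming the first offending sequence.
    """
    from Bio import SeqIO

    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format: {format!r}")
    path = Path(path)
    records = list(SeqIO.parse(str(path), format))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper().replace(".", GAP) for r in records]
    length = len(seqs[0])
    for rid, s in zip(ids, seqs):
        if len(s) != length:
            raise ValueError(
                f"ragged alignment: sequence {rid!r} has length {len(s)}, "
                f"expected {length}"
            )
    chars = np.array([list(s) for s in seqs], dtype="<U1")
    return Alignment(ids=ids, chars=chars)


def write_alignment(aln: Alignment, path) -> None:
    """Write an alignment as FASTA."""
    with open(path, "w") as fh:
        for rid, seq in zip(aln.ids, aln.sequences()):
            fh.write(f">{rid}\n{seq}\n")


def sanitize(aln: Alignment) -> Alignment:
    """Map ambiguity codes (B/Z/X/U/O/J) onto the gap level with a warning."""
    chars = aln.chars.copy()
    bad = ~np.isin(chars, list(ALPHABET))
    if bad.any():
        unknown = set(chars[bad].tolist()) - AMBIGUOUS
        if unknown:
            raise ValueError(f"invalid characters in alignment: {sorted(unknown)}")
        logger.warning(
            "mapped %d ambiguous residues (%s) to gap",
            int(bad.sum()),
            ",".join(sorted(set(chars[bad].tolist()))),
        )
        warnings.warn("ambiguous residue codes mapped to gap", stacklevel=2)
        chars[bad] = GAP
    return Alignment(ids=list(aln.ids), chars=chars, molecule_labels=aln.molecule_labels)


def encode(aln: Alignment) -> EncodedAlignment:
    """Build the integer factor matrix ``A`` and indicator matrix ``M``."""
    aln = sanitize(aln)
    n_seq, n_col = aln.chars.shape
    lut = np.zeros(128, dtype=np.int64)
    for ch, lev in AA_TO_INT.items():
        lut[ord(ch)] = lev
    codes = aln.chars.view(np.uint32).reshape(n_seq, n_col)
    A = lut[codes]
    M = np.zeros((n_seq, N_STATES * n_col), dtype=np.float64)
    cols = np.arange(n_col) * N_STATES
    flat = cols[None, :] + (A - 1)
    M[np.arange(n_seq)[:, None], flat] = 1.0
    column_map = cols[:, None] + np.arange(N_STATES)[None, :]
    return EncodedAlignment(A=A, M=M, column_map=column_map)


def decode(A: np.ndarray, ids: Optional[list[str]] = None) -> Alignment:
    """Inverse of :func:`encode`: integer levels back to characters."""
    A = np.asarray(A)
    chars = np.empty(A.shape, dtype="<U1")
    for lev, ch in INT_TO_AA.items():
        chars[A == lev] = ch
    if ids is None:
        ids = [f"seq{i}" for i in range(A.shape[0])]
    return Alignment(ids=ids, chars=chars)


def filter_gap_columns(aln: Alignment, cutoff: float = 0.5):
    """Drop columns whose gap fraction exceeds ``cutoff``.

    Returns the filtered alignment and ``kept_index_map``, the original
    0-based column index of every retained column (user-facing reports add 1).
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    gap_frac = (aln.chars == GAP).mean(axis=0)
    keep = gap_frac <= cutoff
    if not keep.any():
        raise ValueError("gap filtering removed every column")
    kept_index_map = np.flatnonzero(keep)
    labels = aln.molecule_labels[keep] if aln.molecule_labels is not None else None
    return (
        Alignment(ids=list(aln.ids), chars=aln.chars[:, keep], molecule_labels=labels),
        kept_index_map,
    )


def pairwise_identity(aln: Alignment) -> tuple[float, float]:
    """Mean and s.d. of fractional identity over all unordered sequence pairs.

    Identity of a pair = matching positions / positions where both sequences
    are non-gap; a pair with no comparable positions scores 0.
    """
    enc = encode(aln)
    A = enc.A
    n_seq, n_col = A.shape
    # match counts via per-state indicator Gram matrices (gap state excluded)
    match = np.zeros((n_seq, n_seq))
    comparable = np.zeros((n_seq, n_seq))
    nongap = (A != N_STATES).astype(np.float64)
    comparable = nongap @ nongap.T
    for lev in range(1, N_STATES):
        ind = (A == lev).astype(np.float64)
        match += ind @ ind.T
    iu = np.triu_indices(n_seq, k=1)
    m = match[iu]
    c = comparable[iu]
    ident = np.where(c > 0, m / np.maximum(c, 1), 0.0)
    return float(ident.mean()), float(ident.std())


def encoded_to_tsv(enc: EncodedAlignment, path) -> None:
    """Dump A and M as TSV for debugging."""
    import pandas as pd

    pd.DataFrame(enc.A).to_csv(str(path) + ".A.tsv", sep="\t", index=False)
    pd.DataFrame(enc.M.astype(int)).to_csv(str(path) + ".M.tsv", sep="\t", index=False)
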