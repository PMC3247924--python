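"""Mutual information between alignment columns, with joint-entropy
correction.

Raw plug-in MI between two columns overestimates dependence for
high-entropy pairs; dividing by the pair's joint entropy ("corrected MI")
normalizes it to [0, 1].  Gaps count as an ordinary 21st character, on the
same footing the regression treats them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignment import Alignment, N_STATES, encode
from .core import LinkMatrix

__all__ = ["ColumnPairStats", "column_mi", "corrected_mi", "mi_matrix", "mean_corrected_mi"]


@dataclass
class ColumnPairStats:
    """Joint 21 x 21 count table of a column pair plus its marginals."""

    joint_counts: np.ndarray
    n_seq: int

    def __post_init__(self) -> None:
        self.joint_counts = np.asarray(self.joint_counts, dtype=float)
        if self.joint_counts.sum() != self.n_seq:
            raise ValueError("joint table must sum to n_seq")

    @property
    def marginals(self) -> tuple[np.ndarray, np.ndarray]:
        return self.joint_counts.sum(axis=1), self.joint_counts.sum(axis=0)

    @classmethod
    def from_columns(cls, a: np.ndarray, b: np.ndarray) -> "ColumnPairStats":
        """Build from two integer-level columns (values 1..21)."""
        a = np.asarray(a, dtype=np.int64)
        b = np.asarray(b, dtype=np.int64)
        table = np.bincount(
            (a - 1) * N_STATES + (b - 1), minlength=N_STATES * N_STATES
        ).reshape(N_STATES, N_STATES)
        return cls(joint_counts=table.astype(float), n_seq=a.size)


def column_mi(stats: ColumnPairStats, base: float = math.e) -> float:
    """Plug-in mutual information sum p(a,b) log[p(a,b)/(p(a)p(b))]."""
    pj = stats.joint_counts / stats.n_seq
    pa, pb = stats.marginals
    pa = pa / stats.n_seq
    pb = pb / stats.n_seq
    mask = pj > 0
    outer = pa[:, None] * pb[None, :]
    mi = float(np.sum(pj[mask] * np.log(pj[mask] / outer[mask])))
    return max(mi, 0.0) / math.log(base)


def joint_entropy(stats: ColumnPairStats, base: float = math.e) -> float:
    pj = stats.joint_counts / stats.n_seq
    mask = pj > 0
    return float(-np.sum(pj[mask] * np.log(pj[mask]))) / math.log(base)


def corrected_mi(stats: ColumnPairStats, variant: str = "divide") -> float:
    """MI normalized by the joint entropy (0 when the pair is conserved).

    The default (and the correction used everywhere in this package)
    divides MI by H_joint. ``variant='subtract'`` instead returns
    MI - (H_joint - MI), the subtractive form found in parts of the
    literature; it is exposed but never the default.
    """
    h = joint_entropy(stats)
    mi = column_mi(stats)
    if variant == "divide":
        if h <= 0.0:
            return 0.0
        return mi / h
    if variant == "subtract":
        return mi - (h - mi)
    raise ValueError(f"unknown correction variant: {variant!r}")


def _all_pair_tables(A: np.ndarray) -> np.ndarray:
    """Joint count tables for all column pairs via one Gram matrix on the
    indicator expansion: shape (n_col, n_col, 21, 21)."""
    n_seq, n_col = A.shape
    M = np.zeros((n_seq, n_col * N_STATES))
    cols = np.arange(n_col) * N_STATES + (A - 1)
    M[np.arange(n_seq)[:, None], cols] = 1.0
    gram = M.T @ M
    return (
        gram.reshape(n_col, N_STATES, n_col, N_STATES).transpose(0, 2, 1, 3)
    )


def mi_matrix(aln: Alignment, variant: str = "divide") -> LinkMatrix:
    """Corrected MI for every column pair, as a LinkMatrix."""
    enc = encode(aln)
    A = enc.A
    n_seq, n_col = A.shape
    tables = _all_pair_tables(A)
    pj = tables / n_seq
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(pj > 0, np.log(np.where(pj > 0, pj, 1.0)), 0.0)
    h_joint = -(pj * logp).sum(axis=(2, 3))
    pa = pj.sum(axis=3)  # (i, j, a) marginal of column i within pair (i,j)
    pb = pj.sum(axis=2)
    outer = pa[:, :, :, None] * pb[:, :, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((pj > 0) & (outer > 0), pj / np.where(outer > 0, outer, 1.0), 1.0)
        mi = (pj * np.log(ratio)).sum(axis=(2, 3))
    mi = np.maximum(mi, 0.0)
    if variant == "divide":
        scores = np.where(h_joint > 0, mi / np.where(h_joint > 0, h_joint, 1.0), 0.0)
    elif variant == "subtract":
        scores = mi - (h_joint - mi)
    else:
        raise ValueError(f"unknown correction variant: {variant!r}")
    np.fill_diagonal(scores, 0.0)
    scores = 0.5 * (scores + scores.T)  # symmetric up to roundoff already
    return LinkMatrix(scores=scores, scoring_mode=f"corrected_mi_{variant}"
                      if variant != "divide" else "corrected_mi")


def mean_corrected_mi(aln: Alignment) -> tuple[float, float]:
    """Mean and s.d. of corrected MI over all unordered column pairs
    (the simulator's interaction-strength calibration statistic)."""
    lm = mi_matrix(aln)
    iu = np.triu_indices(lm.n_col, k=1)
    vals = lm.scores[iu]
    return float(vals.mean()), float(vals.std())
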