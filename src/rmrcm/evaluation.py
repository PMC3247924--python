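"""Validation of predicted links against ground-truth networks and
protein structures.

Simulated data are scored by the AUC of the link ranking against the true
edge set (rank-sum / Mann-Whitney formulation, exact under ties).
Structure-based validation follows the CASP residue-residue contact
protocol: contacts are residue pairs whose Cbeta atoms (Calpha for
glycine) lie within 8 A, candidate pairs are separated by at least 24
residues along the sequence, and the top L/5 or L/10 ranked pairs are
scored by accuracy TP/(TP+FP) and by Xd, a 15-bin contrast between the
distance distribution of predicted pairs and that of all pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy.stats import chi2_contingency, rankdata

from .core import LinkMatrix
from .simulator import InteractionNetwork

__all__ = [
    "ContactMap",
    "EvalResult",
    "auc",
    "auc_scores",
    "contact_map",
    "residue_coordinates_from_pdb",
    "read_coordinate_table",
    "casp_scores",
    "accuracy_vs_percentile",
    "f_score",
    "distance_enrichment",
]


@dataclass
class ContactMap:
    """Residue-residue distances (A) with a contact cutoff.

    ``residue_to_column`` maps structure residue indices (0-based) to
    alignment column indices; identity by default.
    """

    distances: np.ndarray
    contact_cutoff: float = 8.0
    residue_to_column: Optional[dict] = None

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        d = self.distances
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if (d < 0).any():
            raise ValueError("distances must be nonnegative")
        if self.residue_to_column is None:
            self.residue_to_column = {i: i for i in range(d.shape[0])}

    @property
    def n_res(self) -> int:
        return self.distances.shape[0]

    def contacts(self) -> np.ndarray:
        c = self.distances <= self.contact_cutoff
        np.fill_diagonal(c, False)
        return c


@dataclass
class EvalResult:
    auc: Optional[float] = None
    accuracy_L5: Optional[float] = None
    accuracy_L10: Optional[float] = None
    xd_L5: Optional[float] = None
    xd_L10: Optional[float] = None
    f_score: Optional[float] = None
    enrichment: Optional[dict] = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {}
        for k in ("auc", "accuracy_L5", "accuracy_L10", "xd_L5", "xd_L10", "f_score"):
            v = getattr(self, k)
            if v is not None:
                out[k] = v
        if self.enrichment is not None:
            out["enrichment"] = self.enrichment
        out.update(self.extra)
        return out


# ---------------------------------------------------------------------------
# AUC


def auc_scores(scores, labels) -> float:
    """Rank-sum AUC of scores against binary labels (ties share ranks)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: need both positive and negative pairs")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def auc(links: LinkMatrix, truth: InteractionNetwork) -> float:
    """AUC of the link-score ranking of all unordered column pairs against
    the true edge set (self-pairs excluded)."""
    if links.n_col != truth.n_nodes:
        raise ValueError("link matrix and network have different sizes")
    adj = truth.adjacency()
    iu = np.triu_indices(links.n_col, k=1)
    return auc_scores(links.scores[iu], adj[iu])


# ---------------------------------------------------------------------------
# structures


def residue_coordinates_from_pdb(path, chain: Optional[str] = None):
    """Representative-atom coordinates per residue from a PDB file.

    Uses Cbeta, falling back to Calpha for glycine; residues missing their
    representative atom are skipped with a warning.  Returns
    ``(coords, residue_ids)``.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    coords = []
    res_ids = []
    for ch in model:
        if chain is not None and ch.id != chain:
            continue
        for res in ch:
            if res.id[0] != " ":
                continue
            atom_name = "CA" if res.get_resname() == "GLY" else "CB"
            if atom_name in res:
                coords.append(res[atom_name].coord)
                res_ids.append((ch.id, res.id[1]))
            elif "CA" in res:
                coords.append(res["CA"].coord)
                res_ids.append((ch.id, res.id[1]))
            else:
                warnings.warn(
                    f"residue {ch.id}:{res.id[1]} lacks CB/CA; excluded",
                    stacklevel=2,
                )
    return np.asarray(coords, dtype=float), res_ids


def read_coordinate_table(path):
    """Plain TSV of residue_index, residue_name, x, y, z."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    return coords, list(df[cols[0]])


def contact_map(coords: np.ndarray, cutoff: float = 8.0,
                residue_to_column: Optional[dict] = None) -> ContactMap:
    """Euclidean distance matrix from per-residue representative-atom
    coordinates; contact iff distance <= cutoff."""
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    dist = squareform(pdist(coords))
    return ContactMap(distances=dist, contact_cutoff=cutoff,
                      residue_to_column=residue_to_column)


# ---------------------------------------------------------------------------
# CASP-style scoring


def _ranked_pairs(links: LinkMatrix, cmap: ContactMap, min_separation: int):
    """Candidate residue pairs with |i-j| >= min_separation, ranked by
    descending link score (ties by ascending pair index).  Returns
    (pairs, scores, distances)."""
    col_of = cmap.residue_to_column
    residues = sorted(col_of)
    pairs, scores, dists = [], [], []
    for a in range(len(residues)):
        for b in range(a + 1, len(residues)):
            ri, rj = residues[a], residues[b]
            if abs(rj - ri) < min_separation:
                continue
            ci, cj = col_of[ri], col_of[rj]
            pairs.append((ri, rj))
            scores.append(links.scores[ci, cj])
            dists.append(cmap.distances[ri, rj])
    scores = np.asarray(scores)
    dists = np.asarray(dists)
    order = np.lexsort((np.arange(len(pairs)), -scores))
    return [pairs[k] for k in order], scores[order], dists[order]


def xd_score(pred_dists: np.ndarray, all_dists: np.ndarray) -> float:
    """Xd: 15 bins of 4 A over 0-60 A (distances beyond 60 A clipped into
    the last bin); Xd = sum_i (Pp_i - Pa_i) / (15 * d_i) with d_i the bin's
    upper bound normalized by 60.  Positive Xd means the predicted pairs
    sit at shorter distances than the background."""
    edges = np.arange(0.0, 64.0, 4.0)
    pred = np.clip(pred_dists, 0.0, 59.999)
    allp = np.clip(all_dists, 0.0, 59.999)
    pp, _ = np.histogram(pred, bins=edges)
    pa, _ = np.histogram(allp, bins=edges)
    pp = pp / max(len(pred), 1)
    pa = pa / max(len(allp), 1)
    d = edges[1:] / 60.0
    return float(np.sum((pp - pa) / (15.0 * d)))


def casp_scores(links: LinkMatrix, cmap: ContactMap, L: Optional[int] = None,
                top_fraction: float = 0.2, min_separation: int = 24):
    """Accuracy and Xd of the top floor(L * top_fraction) ranked pairs.

    ``L`` defaults to the number of mapped residues.  Only pairs separated
    by at least ``min_separation`` residues are candidates.
    """
    pairs, _, dists = _ranked_pairs(links, cmap, min_separation)
    if L is None:
        L = cmap.n_res
    n_top = int(np.floor(L * top_fraction))
    if n_top > len(pairs):
        warnings.warn(
            f"only {len(pairs)} candidate pairs for {n_top} requested",
            stacklevel=2,
        )
        n_top = len(pairs)
    if n_top == 0:
        raise ValueError("no candidate pairs to evaluate")
    top_d = dists[:n_top]
    tp = int((top_d <= cmap.contact_cutoff).sum())
    accuracy = tp / n_top
    return accuracy, xd_score(top_d, dists)


def accuracy_vs_percentile(links: LinkMatrix, cmap: ContactMap,
                           percentiles, min_separation: int = 0):
    """Accuracy among the top n% ranked pairs for each n (fractions in
    [0, 1])."""
    pairs, _, dists = _ranked_pairs(links, cmap, min_separation)
    is_contact = dists <= cmap.contact_cutoff
    out = []
    for frac in percentiles:
        k = max(1, int(round(frac * len(pairs))))
        out.append((float(frac), float(is_contact[:k].mean())))
    return out


def f_score(predicted: set, contacts: set) -> float:
    """Harmonic mean of precision and recall of a predicted pair set."""
    predicted = {tuple(sorted(p)) for p in predicted}
    contacts = {tuple(sorted(p)) for p in contacts}
    tp = len(predicted & contacts)
    if tp == 0:
        return 0.0
    precision = tp / len(predicted)
    recall = tp / len(contacts)
    return 2.0 * precision * recall / (precision + recall)


def distance_enrichment(links: LinkMatrix, cmap: ContactMap, top_n: int,
                        cutoffs, min_separation: int = 0) -> dict:
    """Short-distance enrichment of the top_n predictions.

    For each cutoff: the fraction of the top_n pairs within it, the
    background fraction over all candidate pairs, and a 2x2 chi-square test
    (predicted vs background, short vs long; no continuity correction).
    """
    pairs, _, dists = _ranked_pairs(links, cmap, min_separation)
    if top_n > len(pairs):
        raise ValueError("top_n exceeds the number of scored pairs")
    out = {}
    for cutoff in cutoffs:
        top_short = int((dists[:top_n] <= cutoff).sum())
        all_short = int((dists <= cutoff).sum())
        table = np.array(
            [
                [top_short, top_n - top_short],
                [all_short, len(pairs) - all_short],
            ]
        )
        if table.min() >= 0 and table.sum(axis=1).min() > 0 and table.sum(axis=0).min() > 0:
            chi2, p = chi2_contingency(table, correction=False)[:2]
        else:
            chi2, p = float("nan"), float("nan")
        out[float(cutoff)] = {
            "top_fraction": top_short / top_n,
            "background_fraction": all_short / len(pairs),
            "chi2": float(chi2),
            "p_value": float(p),
        }
    return out
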