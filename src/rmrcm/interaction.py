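"""Interaction prediction from a fitted two-molecule model.

A regression model trained on a paired alignment (receptor columns +
ligand/peptide columns, e.g. PDZ domains with their bound peptides) can
score *new* candidate pairs: each aligned candidate sequence is scored by
the summed per-column log-likelihood of its observed characters under the
minimum-BIC fit of every column, with a pseudocount of 1/210 keeping
probabilities away from zero.  High scores mark candidate pairs consistent
with the covariation the training pairs exhibit, which transfers
interaction information across species.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alignment import AA_TO_INT, ALPHABET, Alignment, N_STATES, encode
from .core import FitConfig, bic_select, fit_alignment_paths, molecule_predictor_mask
from .evaluation import auc_scores

__all__ = [
    "InteractionModel",
    "fit_interaction_model",
    "loglik_score",
    "rank_interactions",
]

#: additive pseudocount on class probabilities
PSEUDOCOUNT = 1.0 / 210.0


@dataclass
class ColumnFit:
    classes: np.ndarray  # observed response levels (1..21)
    predictor_cols: np.ndarray  # indicator-column indices into M
    coef: np.ndarray  # (n_pred, n_classes), original scale
    intercept: np.ndarray  # (n_classes,)
    lambda_index: int
    degenerate: bool = False


@dataclass
class InteractionModel:
    """Per-column minimum-BIC fits plus the metadata needed to score
    candidates aligned to the training columns."""

    n_col: int
    fits: dict  # column index -> ColumnFit
    mask_mode: str
    molecule_labels: Optional[np.ndarray] = None
    aa_order: str = ALPHABET
    kept_index_map: Optional[np.ndarray] = None

    def save(self, path) -> None:
        payload = {
            "n_col": self.n_col,
            "mask_mode": self.mask_mode,
            "aa_order": self.aa_order,
            "molecule_labels": None
            if self.molecule_labels is None
            else np.asarray(self.molecule_labels).tolist(),
            "kept_index_map": None
            if self.kept_index_map is None
            else np.asarray(self.kept_index_map).tolist(),
            "fits": {
                str(i): {
                    "classes": f.classes.tolist(),
                    "predictor_cols": f.predictor_cols.tolist(),
                    "coef": f.coef.tolist(),
                    "intercept": f.intercept.tolist(),
                    "lambda_index": f.lambda_index,
                    "degenerate": f.degenerate,
                }
                for i, f in self.fits.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "InteractionModel":
        with open(path) as fh:
            payload = json.load(fh)
        fits = {
            int(i): ColumnFit(
                classes=np.asarray(d["classes"], dtype=np.int64),
                predictor_cols=np.asarray(d["predictor_cols"], dtype=np.int64),
                coef=np.asarray(d["coef"], dtype=float),
                intercept=np.asarray(d["intercept"], dtype=float),
                lambda_index=d["lambda_index"],
                degenerate=d["degenerate"],
            )
            for i, d in payload["fits"].items()
        }
        return cls(
            n_col=payload["n_col"],
            fits=fits,
            mask_mode=payload["mask_mode"],
            molecule_labels=None
            if payload["molecule_labels"] is None
            else np.asarray(payload["molecule_labels"]),
            aa_order=payload["aa_order"],
            kept_index_map=None
            if payload["kept_index_map"] is None
            else np.asarray(payload["kept_index_map"]),
        )


def fit_interaction_model(train_aln: Alignment, config: Optional[FitConfig] = None,
                          mask_mode: str = "intermolecular_only") -> InteractionModel:
    """Fit per-column paths under the molecule mask and keep the
    minimum-BIC entry of each."""
    if train_aln.molecule_labels is None:
        raise ValueError("training alignment needs molecule_labels")
    if config is None:
        config = FitConfig()
    config.predictor_mask = molecule_predictor_mask(train_aln.molecule_labels, mask_mode)
    paths = fit_alignment_paths(train_aln, config)
    fits = {}
    for i, path in enumerate(paths):
        idx, coef, intercept = bic_select(path, train_aln.n_seq)
        fits[i] = ColumnFit(
            classes=path.classes,
            predictor_cols=path.predictor_cols,
            coef=np.asarray(coef),
            intercept=np.asarray(intercept),
            lambda_index=idx,
            degenerate=path.degenerate,
        )
    return InteractionModel(
        n_col=train_aln.n_col,
        fits=fits,
        mask_mode=mask_mode,
        molecule_labels=train_aln.molecule_labels,
    )


def _encode_candidate(seq, n_col: int) -> np.ndarray:
    if isinstance(seq, str):
        chars = list(seq.upper().replace(".", "-"))
    else:
        chars = [str(c).upper() for c in seq]
    if len(chars) != n_col:
        raise ValueError(
            f"candidate length {len(chars)} does not match model columns {n_col}"
        )
    return np.array([AA_TO_INT.get(c, N_STATES) for c in chars], dtype=np.int64)


def _column_probability(fit: ColumnFit, codes: np.ndarray, observed: int,
                        pseudocount: str = "renormalize") -> float:
    """P-tilde(observed char | fitted column model, rest of the candidate).

    Softmax over the fitted classes (characters unseen in training have
    probability 0), then the pseudocount: with ``renormalize`` (default)
    P-tilde = (p + 1/210) / (1 + 21/210); with ``raw``, p + 1/210.
    """
    eta = fit.intercept.copy()
    if fit.coef.size:
        # active indicators of this candidate among the stored predictors
        active = codes[fit.predictor_cols // N_STATES] == (fit.predictor_cols % N_STATES) + 1
        if active.any():
            eta = eta + fit.coef[active].sum(axis=0)
    eta = eta - eta.max()
    probs = np.exp(eta)
    probs /= probs.sum()
    where = np.flatnonzero(fit.classes == observed)
    p = float(probs[where[0]]) if where.size else 0.0
    if pseudocount == "renormalize":
        return (p + PSEUDOCOUNT) / (1.0 + N_STATES * PSEUDOCOUNT)
    if pseudocount == "raw":
        return p + PSEUDOCOUNT
    raise ValueError(f"unknown pseudocount mode: {pseudocount!r}")


def loglik_score(model: InteractionModel, paired_seq,
                 pseudocount: str = "renormalize") -> float:
    """Summed per-column log-likelihood of one aligned candidate pair."""
    codes = _encode_candidate(paired_seq, model.n_col)
    total = 0.0
    for i in range(model.n_col):
        fit = model.fits[i]
        total += np.log(_column_probability(fit, codes, int(codes[i]), pseudocount))
    return float(total)


def rank_interactions(model: InteractionModel, candidates, labels=None,
                      pseudocount: str = "renormalize"):
    """Rank candidate pairs by descending score (stable for ties).

    Returns a list of (candidate_index, score, rank) triples; when binary
    ``labels`` are given, also the AUC of scores against labels.
    """
    if len(candidates) == 0:
        raise ValueError("need at least one candidate")
    scores = np.array([loglik_score(model, c, pseudocount) for c in candidates])
    order = np.argsort(-scores, kind="stable")
    ranked = [(int(k), float(scores[k]), r + 1) for r, k in enumerate(order)]
    if labels is None:
        return ranked
    return ranked, auc_scores(scores, np.asarray(labels))


def randomized_negatives(pairs: list[tuple[str, str]], seed: int,
                         max_tries: int = 1000) -> list[tuple[str, str]]:
    """Shuffle ligands among receptors, avoiding observed combinations,
    to build a non-interacting candidate set."""
    rng = np.random.default_rng(seed)
    receptors = [p[0] for p in pairs]
    ligands = [p[1] for p in pairs]
    observed = set(pairs)
    for _ in range(max_tries):
        perm = rng.permutation(len(ligands))
        neg = [(receptors[i], ligands[perm[i]]) for i in range(len(pairs))]
        if not any(p in observed for p in neg):
            return neg
    # fall back: keep only the non-observed shuffled pairs
    return [p for p in neg if p not in observed]
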