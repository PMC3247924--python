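"""Synthetic alignments from Markov-Random-Field models on random networks.

Ground truth is an Erdos-Renyi style interaction network.  Each node (an
alignment column) carries a 21-state node potential with one preferred
character; each edge carries a 21 x 21 potential table in which every
character has two randomly chosen preferred partner characters.  Sequences
are rows sampled by single-site Gibbs sweeps; thinning controls how
correlated consecutive rows are, which emulates phylogenetic relatedness.

Perturbations mirror common pathologies of real alignments: position noise
(random residue flips, a crude misalignment model), sequence noise
(rows drawn from node potentials only, i.e. sequences that do not share the
interaction set), and duplicate-sequence injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .alignment import Alignment, N_STATES, decode

__all__ = [
    "InteractionNetwork",
    "MRFModel",
    "GibbsConfig",
    "generate_network",
    "build_potentials",
    "gibbs_sample",
    "add_position_noise",
    "add_sequence_noise",
    "add_duplicates",
    "derive_seed",
]


def derive_seed(master: int, *keys) -> int:
    """Deterministic per-task seed from a master seed and integer keys
    (replicate index, condition index, ...); always below 2**31."""
    ss = np.random.SeedSequence([int(master)] + [int(k) for k in keys])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class InteractionNetwork:
    n_nodes: int
    edges: list[tuple[int, int]]  # sorted (i, j), i < j, 0-based
    density: float

    def __post_init__(self) -> None:
        self.edges = sorted({(min(i, j), max(i, j)) for i, j in self.edges})
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-loops are not allowed")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError("edge endpoint out of range")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[int, int]]:
        return set(self.edges)

    def adjacency(self) -> np.ndarray:
        adj = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for i, j in self.edges:
            adj[i, j] = adj[j, i] = True
        return adj

    def to_tsv(self, path) -> None:
        """Write the edge list as TSV with 1-based node numbers."""
        with open(path, "w") as fh:
            fh.write("node_i\tnode_j\n")
            for i, j in self.edges:
                fh.write(f"{i + 1}\t{j + 1}\n")


@dataclass
class MRFModel:
    """Node and edge potential tables of the generating MRF.

    ``node_potentials[v]`` is a 21-vector summing to 1 with a single entry
    ``p_prefnode`` and twenty entries ``(1 - p_prefnode) / 20``.  Each edge
    table ``edge_potentials[e]`` (axis 0 = state of the lower-numbered node)
    has, per row, two preferred-partner entries of value ``p_prefedge`` and
    the rest ``(1 - p_prefedge) / 399``; the tables act as unnormalised
    weights in the Gibbs conditional.
    """

    network: InteractionNetwork
    node_potentials: np.ndarray  # (n_nodes, 21)
    edge_potentials: np.ndarray  # (n_edges, 21, 21)
    p_prefnode: float
    p_prefedge: float

    @property
    def n_nodes(self) -> int:
        return self.network.n_nodes


@dataclass
class GibbsConfig:
    n_iterations: int = 100_000
    thinning: int = 50
    n_samples: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples * self.thinning > self.n_iterations:
            raise ValueError("n_samples * thinning must not exceed n_iterations")


def generate_network(n_nodes: int, density: float, seed: int) -> InteractionNetwork:
    """Include each of the ``n(n-1)/2`` candidate edges independently with
    probability ``density``."""
    if n_nodes < 2:
        raise ValueError("a network needs at least 2 nodes")
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_nodes, k=1)
    mask = rng.random(iu[0].shape[0]) < density
    edges = list(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))
    return InteractionNetwork(n_nodes=n_nodes, edges=edges, density=density)


def build_potentials(
    net: InteractionNetwork, p_prefnode: float, p_prefedge: float, seed: int
) -> MRFModel:
    """Draw preferred characters/partners uniformly and fill the tables.

    All 21 states (20 amino acids + gap) take part both as preferred node
    characters and as preferred edge partners.
    """
    if not (0.0 < p_prefnode < 1.0 and 0.0 < p_prefedge < 1.0):
        raise ValueError("potentials must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = net.n_nodes
    node_pot = np.full((n, N_STATES), (1.0 - p_prefnode) / 20.0)
    preferred = rng.integers(0, N_STATES, size=n)
    node_pot[np.arange(n), preferred] = p_prefnode

    n_e = net.n_edges
    # The 42 preferred cells share the preferred mass p_prefedge and the
    # 399 others share 1 - p_prefedge, so each table sums to 1.  This makes
    # p_prefedge = 0.1 an almost-uniform ("weak") coupling and 0.3 a
    # ~4-fold per-cell preference ("strong").
    off = (1.0 - p_prefedge) / (N_STATES * N_STATES - N_STATES * 2)  # = (1-p)/399
    pref = p_prefedge / (N_STATES * 2)  # p/42
    edge_pot = np.full((n_e, N_STATES, N_STATES), off)
    for e in range(n_e):
        for a in range(N_STATES):
            partners = rng.choice(N_STATES, size=2, replace=False)
            edge_pot[e, a, partners] = pref
    return MRFModel(
        network=net,
        node_potentials=node_pot,
        edge_potentials=edge_pot,
        p_prefnode=p_prefnode,
        p_prefedge=p_prefedge,
    )


@njit(cache=True)
def _gibbs_kernel(
    log_node, indptr, nbr, dir_tab, log_edge_dir, states, n_iter, thinning, n_samples, seed
):
    # log_edge_dir[d, s_neighbor, a_self] is contiguous in a_self
    np.random.seed(seed)
    n = log_node.shape[0]
    out = np.empty((n_samples, n), dtype=np.int64)
    rec = 0
    start_rec = n_iter - n_samples * thinning
    logits = np.empty(N_STATES)
    probs = np.empty(N_STATES)
    for t in range(1, n_iter + 1):
        for v in range(n):
            for a in range(N_STATES):
                logits[a] = log_node[v, a]
            for k in range(indptr[v], indptr[v + 1]):
                su = states[nbr[k]]
                d = dir_tab[k]
                for a in range(N_STATES):
                    logits[a] += log_edge_dir[d, su, a]
            m = logits[0]
            for a in range(1, N_STATES):
                if logits[a] > m:
                    m = logits[a]
            tot = 0.0
            for a in range(N_STATES):
                probs[a] = np.exp(logits[a] - m)
                tot += probs[a]
            u = np.random.random() * tot
            acc = 0.0
            chosen = N_STATES - 1
            for a in range(N_STATES):
                acc += probs[a]
                if u < acc:
                    chosen = a
                    break
            states[v] = chosen
        if t > start_rec and (n_iter - t) % thinning == 0:
            out[rec] = states
            rec += 1
    return out


def _adjacency_csr(model: MRFModel):
    """Directed neighbour structure: for node v and neighbour u, the table
    index whose row is indexed by u's state and column by v's candidate
    state."""
    n = model.n_nodes
    nbrs: list[list[int]] = [[] for _ in range(n)]
    tabs: list[list[int]] = [[] for _ in range(n)]
    log_dir = np.empty((2 * model.network.n_edges, N_STATES, N_STATES))
    for e, (i, j) in enumerate(model.network.edges):
        with np.errstate(divide="ignore"):
            lt = np.log(model.edge_potentials[e])
        # updating j (the column axis): rows indexed by state of i
        log_dir[2 * e] = lt
        # updating i (the row axis): rows indexed by state of j
        log_dir[2 * e + 1] = lt.T
        nbrs[j].append(i)
        tabs[j].append(2 * e)
        nbrs[i].append(j)
        tabs[i].append(2 * e + 1)
    indptr = np.zeros(n + 1, dtype=np.int64)
    for v in range(n):
        indptr[v + 1] = indptr[v] + len(nbrs[v])
    nbr = np.empty(indptr[-1], dtype=np.int64)
    dir_tab = np.empty(indptr[-1], dtype=np.int64)
    for v in range(n):
        nbr[indptr[v] : indptr[v + 1]] = nbrs[v]
        dir_tab[indptr[v] : indptr[v + 1]] = tabs[v]
    return indptr, nbr, dir_tab, log_dir


def gibbs_sample(model: MRFModel, config: GibbsConfig) -> Alignment:
    """Sample an alignment by sequential-scan Gibbs sweeps.

    One iteration is a full sweep over nodes 0..n-1; the state vector is
    recorded after every ``thinning``-th sweep and the last ``n_samples``
    recordings become the alignment rows (most recent last).  Each node is
    initialised from its node-potential distribution.
    """
    rng = np.random.default_rng(config.seed)
    n = model.n_nodes
    init = np.empty(n, dtype=np.int64)
    for v in range(n):
        init[v] = rng.choice(N_STATES, p=model.node_potentials[v])
    indptr, nbr, dir_tab, log_dir = _adjacency_csr(model)
    with np.errstate(divide="ignore"):
        log_node = np.log(model.node_potentials)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    samples = _gibbs_kernel(
        log_node,
        indptr,
        nbr,
        dir_tab,
        log_dir,
        init,
        config.n_iterations,
        config.thinning,
        config.n_samples,
        kernel_seed,
    )
    A = samples + 1  # 0-based states -> 1..21 levels
    ids = [f"sample_{i:05d}" for i in range(A.shape[0])]
    return decode(A, ids=ids)


def add_position_noise(aln: Alignment, rate: float, seed: int) -> Alignment:
    """Flip an exact fraction ``rate`` of all cells to a different amino acid.

    Replacement characters are drawn uniformly from the 20 amino acids
    excluding the cell's current character; gaps are never introduced.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    chars = aln.chars.copy()
    n_cells = chars.size
    n_mut = int(round(rate * n_cells))
    if n_mut == 0:
        return Alignment(list(aln.ids), chars, aln.molecule_labels)
    flat = rng.choice(n_cells, size=n_mut, replace=False)
    rows, cols = np.unravel_index(flat, chars.shape)
    from .alignment import AA_ORDER

    for r, c in zip(rows, cols):
        current = chars[r, c]
        choices = [a for a in AA_ORDER if a != current]
        chars[r, c] = choices[rng.integers(0, len(choices))]
    return Alignment(list(aln.ids), chars, aln.molecule_labels)


def add_sequence_noise(aln: Alignment, model: MRFModel, rate: float, seed: int) -> Alignment:
    """Replace ``round(rate * n_seq)`` rows by sequences drawn from node
    potentials only (columns mutually independent, no edge coupling)."""
    if model.n_nodes != aln.n_col:
        raise ValueError("model and alignment disagree on the number of columns")
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_rep = int(round(rate * aln.n_seq))
    chars = aln.chars.copy()
    if n_rep == 0:
        return Alignment(list(aln.ids), chars, aln.molecule_labels)
    rows = rng.choice(aln.n_seq, size=n_rep, replace=False)
    from .alignment import INT_TO_AA

    for r in rows:
        states = np.empty(aln.n_col, dtype=np.int64)
        for v in range(aln.n_col):
            states[v] = rng.choice(N_STATES, p=model.node_potentials[v]) + 1
        chars[r] = [INT_TO_AA[s] for s in states]
    return Alignment(list(aln.ids), chars, aln.molecule_labels)


def add_duplicates(aln: Alignment, n_copies: int, seed: int) -> Alignment:
    """Append ``n_copies`` copies of one uniformly chosen row (originals
    first, copies appended)."""
    if n_copies < 0:
        raise ValueError("n_copies must be nonnegative")
    if n_copies == 0:
        return Alignment(list(aln.ids), aln.chars.copy(), aln.molecule_labels)
    rng = np.random.default_rng(seed)
    src = int(rng.integers(0, aln.n_seq))
    extra = np.repeat(aln.chars[src : src + 1], n_copies, axis=0)
    chars = np.vstack([aln.chars, extra])
    ids = list(aln.ids) + [f"{aln.ids[src]}_copy{k + 1}" for k in range(n_copies)]
    return Alignment(ids, chars, aln.molecule_labels)
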