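"""Random walk with restart (RWR) on a weighted undirected gene network.

Candidate disease genes for a genetically heterogeneous disorder tend to
be functionally related to the already-known disease genes.  Network
propagation quantifies that relatedness: a walker starts on the seed
genes and at each step either moves along a network edge or restarts at
the seeds with probability ``r``.  Following Köhler et al.'s formulation
the update is

    p(t+1) = (1 - r) * A @ p(t) + r * p0

with A = D^{-1/2} W D^{-1/2} the symmetrically normalised adjacency
matrix and p0 putting mass 1/s on each of the s seed genes.  Under
symmetric normalisation the columns of A do not sum to one, so p(t) is
not a probability distribution — the steady-state entries are relative
affinity scores, which is all ranking requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np
import scipy.sparse as sp
from scipy.stats import rankdata

__all__ = [
    "GeneNetwork",
    "WalkParams",
    "ScoreVector",
    "build_network",
    "read_edge_list",
    "write_edge_list",
    "rwr_scores",
    "rank_candidates",
    "top_fraction",
]


class GeneNetwork:
    """Weighted undirected gene graph with its symmetric normalisation.

    Holds the node list, the sparse symmetric weight matrix ``W``, the
    degree vector (row sums of W) and the normalised matrix
    ``A = D^{-1/2} W D^{-1/2}``, with the rows/columns of isolated
    (degree-0) nodes defined as zero so no division by zero occurs.
    """

    def __init__(self, nodes: Sequence[str], W: sp.spmatrix):
        self.nodes: list[str] = list(nodes)
        self.index: dict[str, int] = {g: i for i, g in enumerate(self.nodes)}
        if len(self.index) != len(self.nodes):
            raise ValueError("duplicate node ids")
        W = sp.csr_matrix(W, dtype=float)
        if W.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("weight matrix shape does not match node list")
        if (abs(W - W.T) > 1e-12 * max(1.0, abs(W).max() if W.nnz else 1.0)).nnz:
            raise ValueError("weight matrix must be symmetric")
        if W.nnz and W.data.min() < 0:
            raise ValueError("edge weights must be non-negative")
        self.W = W
        self.degrees = np.asarray(W.sum(axis=1)).ravel()
        with np.errstate(divide="ignore"):
            inv_sqrt = 1.0 / np.sqrt(self.degrees)
        inv_sqrt[~np.isfinite(inv_sqrt)] = 0.0  # isolated nodes
        Dhalf = sp.diags(inv_sqrt)
        self.A = sp.csr_matrix(Dhalf @ W @ Dhalf)

    @property
    def n(self) -> int:
        return len(self.nodes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.index

    def __repr__(self) -> str:
        return f"GeneNetwork({self.n} nodes, {self.W.nnz // 2} edges)"


def build_network(
    edge_list: Iterable[tuple[str, str, float]],
    extra_nodes: Iterable[str] = (),
) -> GeneNetwork:
    """Build a :class:`GeneNetwork` from (gene, gene, weight) triples.

    Duplicate undirected edges are merged keeping the maximum weight;
    self-loops are dropped; ``extra_nodes`` lets callers retain isolated
    genes that carry no edge.
    """
    weights: dict[tuple[str, str], float] = {}
    nodes: dict[str, None] = {}
    for g1, g2, w in edge_list:
        w = float(w)
        if w < 0:
            raise ValueError(f"negative edge weight {w} on ({g1}, {g2})")
        g1, g2 = str(g1), str(g2)
        nodes.setdefault(g1)
        nodes.setdefault(g2)
        if g1 == g2:
            continue
        key = (g1, g2) if g1 < g2 else (g2, g1)
        if w > weights.get(key, -1.0):
            weights[key] = w
    for g in extra_nodes:
        nodes.setdefault(str(g))
    node_list = list(nodes)
    idx = {g: i for i, g in enumerate(node_list)}
    if weights:
        r = np.fromiter((idx[a] for a, _ in weights), dtype=np.int64, count=len(weights))
        c = np.fromiter((idx[b] for _, b in weights), dtype=np.int64, count=len(weights))
        d = np.fromiter(weights.values(), dtype=float, count=len(weights))
        n = len(node_list)
        W = sp.coo_matrix(
            (np.concatenate([d, d]), (np.concatenate([r, c]), np.concatenate([c, r]))),
            shape=(n, n),
        ).tocsr()
    else:
        W = sp.csr_matrix((len(node_list), len(node_list)))
    return GeneNetwork(node_list, W)


@dataclass
class WalkParams:
    """Restart probability, convergence tolerance and iteration cap."""

    restart: float = 0.5
    tol: float = 1e-6  # L1 change between successive iterates
    max_iter: int = 10_000

    def __post_init__(self):
        if not 0.0 < self.restart <= 1.0:
            raise ValueError(f"restart probability must be in (0, 1], got {self.restart}")
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class ScoreVector:
    """Steady-state RWR scores aligned with ``network.nodes``."""

    nodes: list[str]
    scores: np.ndarray
    iterations: int
    converged: bool

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.nodes, self.scores.tolist()))

    def __getitem__(self, gene: str) -> float:
        return float(self.scores[self.nodes.index(gene)])


def rwr_scores(
    network: GeneNetwork,
    seeds: Iterable[str],
    params: WalkParams | None = None,
) -> ScoreVector:
    """Iterate the restart walk to its fixed point.

    Starts from p0 with mass 1/s on each seed; stops when the L1 change
    between iterates drops below ``params.tol`` (or flags
    non-convergence at ``max_iter``, still returning the last iterate).
    The result satisfies p* = (1-r) A p* + r p0 within tolerance.
    """
    params = params or WalkParams()
    seed_list = sorted(set(seeds))
    if not seed_list:
        raise ValueError("seed set is empty")
    missing = [g for g in seed_list if g not in network]
    if missing:
        raise KeyError(f"seed genes absent from network: {missing}")
    p0 = np.zeros(network.n)
    p0[[network.index[g] for g in seed_list]] = 1.0 / len(seed_list)

    r = params.restart
    p = p0.copy()
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        p_next = (1.0 - r) * (network.A @ p) + r * p0
        delta = float(np.abs(p_next - p).sum())
        p = p_next
        if delta < params.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"random walk did not converge in {params.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return ScoreVector(nodes=network.nodes, scores=p, iterations=it, converged=converged)


def rank_candidates(
    scores: ScoreVector | Mapping[str, float],
    candidate_ids: Sequence[str],
) -> list[tuple[str, float, float, float]]:
    """Rank candidate genes by descending score.

    Returns (gene, score, rank, percentile) tuples sorted best-first.
    Ties receive the mean of the tied rank positions; percentile is
    rank / number of candidates.  Candidates absent from the scored
    universe get score 0 (and hence typically rank last), with a
    warning — treating network non-members as unconnected.
    """
    if isinstance(scores, ScoreVector):
        lookup = scores.as_dict()
    else:
        lookup = dict(scores)
    vals = np.empty(len(candidate_ids))
    for i, g in enumerate(candidate_ids):
        if g in lookup:
            vals[i] = lookup[g]
        else:
            warnings.warn(f"candidate {g!r} absent from network; scored 0", stacklevel=2)
            vals[i] = 0.0
    ranks = rankdata(-vals, method="average")
    n = len(candidate_ids)
    out = [
        (g, float(v), float(r), float(r) / n)
        for g, v, r in zip(candidate_ids, vals, ranks)
    ]
    out.sort(key=lambda t: (t[2], t[0]))
    return out


def top_fraction(
    scores: ScoreVector | Mapping[str, float], fraction: float = 0.20
) -> set[str]:
    """The ceil(fraction * n) best-scoring genes of the scored universe.

    Boundary ties are broken deterministically by lexicographic gene id.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    items = (
        scores.as_dict().items() if isinstance(scores, ScoreVector) else dict(scores).items()
    )
    ordered = sorted(items, key=lambda kv: (-kv[1], kv[0]))
    k = int(np.ceil(fraction * len(ordered)))
    return {g for g, _ in ordered[:k]}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> GeneNetwork:
    """Read a 3-column TSV edge list (gene, gene, weight)."""
    edges = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 columns (gene, gene, weight)")
            try:
                edges.append((parts[0], parts[1], float(parts[2])))
            except ValueError:
                raise ValueError(f"{path}:{ln}: malformed weight {parts[2]!r}") from None
    return build_network(edges)


def write_edge_list(network: GeneNetwork, path: str | Path) -> None:
    """Write edges as 3-column TSV; isolated nodes as zero-weight self-loops.

    ``build_network`` registers the endpoints of a self-loop but drops
    the loop itself, so the round trip preserves isolated nodes.
    """
    coo = sp.triu(network.W, k=1).tocoo()
    with open(path, "w") as fh:
        fh.write("#gene1\tgene2\tweight\n")
        order = np.lexsort((coo.col, coo.row))
        for i in order:
            fh.write(
                f"{network.nodes[coo.row[i]]}\t{network.nodes[coo.col[i]]}\t{coo.data[i]:.10g}\n"
            )
        for i in np.flatnonzero(network.degrees == 0):
            fh.write(f"{network.nodes[i]}\t{network.nodes[i]}\t0\n")
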