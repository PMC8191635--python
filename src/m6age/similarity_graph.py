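"""Sample-similarity graph learned by fast linear neighborhood similarity.

Each sample is reconstructed as a nonnegative weighted combination of its c
nearest neighbors (Euclidean distance in feature space). The weights W are
found by minimizing

    F(W) = 1/2 ||X - (C o W) X||_F^2  +  mu/2 ||(C o W) e - e||^2

subject to W >= 0 and support C (the neighbor indicator), where o is the
Hadamard product and e the all-ones vector. The second term softly enforces
row sums of one; the multiplicative update below is the standard
majorize-minimize update for this objective and keeps W nonnegative
provided X is nonnegative, which is why features are min-max rescaled to
[0, 1] per column first. At convergence rows are renormalized to sum
exactly one, thresholded at t, binarized, and symmetrized into an
undirected, unweighted, connected sample graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .sequence_features import FeatureBlock


@dataclass
class FlnsaParams:
    """Neighborhood-similarity learning parameters.

    c: neighbors per sample (0 < c < m); mu: row-sum penalty coefficient;
    t: edge-weight cutoff, or None for the median of positive weights;
    max_escalations bounds the c-doubling retries used to reach a
    connected graph.
    """

    c: int = 10
    mu: float = 1.0
    max_iter: int = 200
    tol: float = 1e-6
    t: float | None = None
    seed: int = 0
    max_escalations: int = 6

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.t is not None and self.t < 0:
            raise ValueError("threshold t must be >= 0")


@dataclass
class SimilarityGraph:
    """FLNSA weights and the derived unweighted sample graph."""

    W: np.ndarray                    # m x m, nonnegative, support C
    C: np.ndarray                    # m x m binary neighbor indicator
    node_ids: list[str]
    adjacency: np.ndarray | None = None   # m x m binary symmetric
    objective_trace: list[float] = field(default_factory=list)
    effective_c: int = 0

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    @classmethod
    def from_adjacency(cls, adj: np.ndarray,
                       node_ids: list[str] | None = None) -> "SimilarityGraph":
        """Wrap an existing 0/1 symmetric adjacency (for embedding a known
        graph directly, bypassing similarity learning)."""
        adj = np.asarray(adj, dtype=float)
        if not np.array_equal(adj, adj.T) or np.any(np.diag(adj) != 0):
            raise ValueError("adjacency must be symmetric with zero diagonal")
        ids = node_ids or [str(i) for i in range(adj.shape[0])]
        return cls(W=adj.copy(), C=(adj > 0).astype(float), node_ids=ids,
                   adjacency=adj)

    def edges(self) -> list[tuple[int, int]]:
        if self.adjacency is None:
            raise ValueError("graph not built yet")
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        return list(zip(ii.tolist(), jj.tolist()))

    def write_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            for i, j in self.edges():
                fh.write(f"{self.node_ids[i]}\t{self.node_ids[j]}\n")


def minmax_rescale(X: np.ndarray) -> np.ndarray:
    """Per-column min-max rescale to [0, 1]; constant columns map to 0."""
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span = np.where(span > 0, span, 1.0)
    return (X - lo) / span


def _neighbor_indicator(X: np.ndarray, c: int) -> np.ndarray:
    """Binary c-nearest-neighbor indicator, self excluded.

    Equidistant candidates are broken toward the lowest row index
    (stable argsort), so the indicator is deterministic.
    """
    m = X.shape[0]
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2) if m <= 512 else None
    if d2 is None:
        sq = (X ** 2).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
        np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")
    C = np.zeros((m, m))
    rows = np.repeat(np.arange(m), c)
    C[rows, order[:, :c].ravel()] = 1.0
    return C


def flnsa_objective(W: np.ndarray, C: np.ndarray, X: np.ndarray,
                    mu: float) -> float:
    S = C * W
    resid = X - S @ X
    row_sums = S.sum(axis=1)
    return 0.5 * float((resid ** 2).sum()) \
        + 0.5 * mu * float(((row_sums - 1.0) ** 2).sum())


def flnsa_similarity(X_block: FeatureBlock | np.ndarray,
                     params: FlnsaParams | None = None) -> SimilarityGraph:
    """Learn the FLNSA neighbor-weight matrix by multiplicative updates.

    W is initialized uniformly at random on the neighbor support (seeded),
    updated by W <- W * (X X^T + mu e e^T) / ((C o W)(X X^T) + mu (C o W) e e^T)
    elementwise on the support until the objective decrease falls below tol,
    then row-renormalized so each row of C o W sums to one.
    """
    params = params or FlnsaParams()
    if isinstance(X_block, FeatureBlock):
        X = X_block.matrix
        node_ids = X_block.sample_ids or [str(i) for i in range(X_block.n_samples)]
    else:
        X = np.asarray(X_block, dtype=float)
        node_ids = [str(i) for i in range(X.shape[0])]
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in the feature matrix")
    m = X.shape[0]
    if m < 3:
        raise ValueError("need at least 3 samples")
    if params.c >= m:
        raise ValueError(f"c={params.c} must be < number of samples m={m}")

    X = minmax_rescale(X)
    C = _neighbor_indicator(X, params.c)
    rng = np.random.default_rng(params.seed)

    # sparse support bookkeeping: row i has exactly c neighbor columns
    nbrs = np.nonzero(C)[1].reshape(m, params.c)        # (m, c)
    Wv = rng.uniform(0.5, 1.5, size=(m, params.c))       # weights on support

    G = X @ X.T + params.mu                              # XX^T + mu*ee^T >= 0
    trace: list[float] = []

    def objective(Wv_: np.ndarray) -> float:
        SX = np.einsum("ij,ijk->ik", Wv_, X[nbrs])
        rows = Wv_.sum(axis=1)
        return 0.5 * float(((X - SX) ** 2).sum()) \
            + 0.5 * params.mu * float(((rows - 1.0) ** 2).sum())

    num = G[np.arange(m)[:, None], nbrs]                 # (m, c)
    prev = objective(Wv)
    trace.append(prev)
    for _ in range(params.max_iter):
        # denominator: ((C o W) G)_{i,j} over the support, via (m,c,c) gather
        Gsub = G[nbrs[:, :, None], nbrs[:, None, :]]     # (m, c, c) = G[nbr_l, nbr_j]
        den = np.einsum("il,ilj->ij", Wv, Gsub)
        Wv = Wv * num / np.maximum(den, 1e-300)
        cur = objective(Wv)
        trace.append(cur)
        if prev - cur < params.tol:
            break
        prev = cur

    # exact row normalization at exit
    Wv = Wv / Wv.sum(axis=1, keepdims=True)

    W = np.zeros((m, m))
    W[np.arange(m)[:, None], nbrs] = Wv
    return SimilarityGraph(W=W, C=C, node_ids=node_ids,
                           objective_trace=trace, effective_c=params.c)


def _connected(adj: np.ndarray) -> bool:
    n_comp = sp.csgraph.connected_components(
        sp.csr_matrix(adj), directed=False, return_labels=False
    )
    return n_comp == 1


def build_graph(X_block: FeatureBlock | np.ndarray,
                params: FlnsaParams | None = None) -> SimilarityGraph:
    """Learn FLNSA weights and derive a connected, unweighted sample graph.

    W is symmetrized by elementwise max with its transpose (a strong
    one-directional neighbor relation survives), the diagonal zeroed, edges
    below the threshold t removed and survivors set to 1. If the result is
    disconnected, c is escalated (c <- min(2c, m-1)) and the learning rerun;
    at c = m-1 with t = 0 the mutual-kNN union is complete, so the loop
    terminates.
    """
    params = params or FlnsaParams()
    m = X_block.n_samples if isinstance(X_block, FeatureBlock) else X_block.shape[0]
    cur = params
    for _ in range(params.max_escalations + 1):
        sim = flnsa_similarity(X_block, cur)
        Wsym = np.maximum(sim.W, sim.W.T)
        np.fill_diagonal(Wsym, 0.0)
        t = cur.t
        if t is None:
            t = float(np.median(Wsym[Wsym > 0]))
        adj = (Wsym > t).astype(float) if t > 0 else (Wsym > 0).astype(float)
        if _connected(adj):
            sim.adjacency = adj
            sim.effective_c = cur.c
            return sim
        if cur.c >= m - 1 and (cur.t or 0) == 0:
            raise RuntimeError(
                "graph disconnected at c = m-1 and t = 0; this should be "
                "impossible and signals an upstream defect"
            )
        # escalate: more neighbors; drop the threshold once c is exhausted
        if cur.c < m - 1:
            cur = replace(cur, c=min(2 * cur.c, m - 1))
        else:
            cur = replace(cur, t=0.0)
    raise RuntimeError(
        f"could not obtain a connected graph after {params.max_escalations} "
        "neighbor-count escalations; lower the threshold t"
    )
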