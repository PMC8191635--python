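"""Unsupervised node embeddings of the sample graph.

Three neighborhood-based methods, each returning a FeatureBlock whose rows
follow the graph's node order:

* **SocDim** — the top eigenvectors of the modularity matrix
  B = A - d d^T / (2|E|), the spectral relaxation of modularity-maximizing
  community assignment; node coordinates in community space.
* **Node2Vec** — second-order biased random walks (return parameter p,
  in-out parameter q) fed to a skip-gram model with negative sampling.
  The walk sampler and the SGNS trainer are implemented here with
  numba-compiled inner loops and are fully seeded.
* **GraRep** — truncated SVD factors of the positive log k-step transition
  matrices, concatenated over k = 1..k_max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from numba import njit
from scipy.sparse.linalg import LinearOperator, eigsh
from sklearn.utils.extmath import randomized_svd

from .sequence_features import FeatureBlock
from .similarity_graph import SimilarityGraph


@dataclass
class EmbeddingParams:
    """Shared embedding configuration; per-method fields are prefixed."""

    dim: int = 16
    seed: int = 0
    # node2vec
    p: float = 1.0
    q: float = 1.0
    walk_length: int = 30
    walks_per_node: int = 20
    window: int = 5
    epochs: int = 3
    negatives: int = 5
    learning_rate: float = 0.025
    # grarep
    k_max: int = 2

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be > 0")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if self.walk_length < 2:
            raise ValueError("walk_length must be >= 2")


def _require_connected_adjacency(G: SimilarityGraph) -> np.ndarray:
    if G.adjacency is None:
        raise ValueError("graph not built; run build_graph first")
    return G.adjacency


# ---------------------------------------------------------------------------
# SocDim
# ---------------------------------------------------------------------------

def modularity_matrix(adj: np.ndarray, node_normalizer: bool = False) -> np.ndarray:
    """B = A - d d^T / (2|E|); rows sum to zero with the edge normalizer.

    ``node_normalizer=True`` divides by the node count instead — a
    non-standard variant kept for comparison; its rows do not sum to zero.
    """
    d = adj.sum(axis=1)
    two_m = adj.shape[0] if node_normalizer else d.sum()
    return adj - np.outer(d, d) / two_m


def socdim_embed(G: SimilarityGraph, params: EmbeddingParams | None = None,
                 node_normalizer: bool = False) -> FeatureBlock:
    """Top-d modularity eigenvectors as node coordinates, unit-norm columns.

    Eigenvectors of the d algebraically largest eigenvalues; signs fixed by
    making each vector's largest-magnitude entry positive.
    """
    params = params or EmbeddingParams()
    adj = _require_connected_adjacency(G)
    m = adj.shape[0]
    if params.dim >= m:
        raise ValueError(f"dim={params.dim} must be < number of nodes {m}")
    d = adj.sum(axis=1)
    two_m = float(m if node_normalizer else d.sum())
    A = sp.csr_matrix(adj)

    if params.dim < m - 1 and m > 50:
        # B = A - d d^T / 2m applied implicitly: rank-1 corrected matvec
        def mv(v):
            v = np.asarray(v).ravel()
            return A @ v - d * (d @ v) / two_m

        op = LinearOperator((m, m), matvec=mv, dtype=float)
        v0 = np.random.default_rng(params.seed).standard_normal(m)
        vals, vecs = eigsh(op, k=params.dim, which="LA", v0=v0)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
    else:
        B = modularity_matrix(adj, node_normalizer)
        vals, vecs = np.linalg.eigh(B)
        vals, vecs = vals[::-1][: params.dim], vecs[:, ::-1][:, : params.dim]

    vecs = vecs / np.linalg.norm(vecs, axis=0, keepdims=True)
    flip = np.sign(vecs[np.abs(vecs).argmax(axis=0), np.arange(vecs.shape[1])])
    vecs = vecs * flip
    columns = [f"{i + 1}" for i in range(params.dim)]
    return FeatureBlock("SocDim", vecs, columns, list(G.node_ids))


# ---------------------------------------------------------------------------
# Node2Vec
# ---------------------------------------------------------------------------

@njit(cache=True)
def _biased_walks(indptr, indices, starts, walk_length, p, q, seed):  # pragma: no cover
    n_walks = starts.shape[0]
    walks = np.empty((n_walks, walk_length), dtype=np.int64)
    np.random.seed(seed)
    inv_p = 1.0 / p
    inv_q = 1.0 / q
    for w in range(n_walks):
        cur = starts[w]
        walks[w, 0] = cur
        # first hop: uniform over neighbors
        nbr = indices[indptr[cur]: indptr[cur + 1]]
        cur = nbr[np.random.randint(nbr.shape[0])]
        walks[w, 1] = cur
        for step in range(2, walk_length):
            prev = walks[w, step - 2]
            nbr = indices[indptr[cur]: indptr[cur + 1]]
            k = nbr.shape[0]
            weights = np.empty(k)
            prev_nbr = indices[indptr[prev]: indptr[prev + 1]]
            total = 0.0
            for t in range(k):
                x = nbr[t]
                if x == prev:
                    wgt = inv_p
                else:
                    # is x adjacent to prev? (sorted neighbor list, binary search)
                    lo, hi = 0, prev_nbr.shape[0]
                    found = False
                    while lo < hi:
                        mid = (lo + hi) // 2
                        if prev_nbr[mid] == x:
                            found = True
                            break
                        elif prev_nbr[mid] < x:
                            lo = mid + 1
                        else:
                            hi = mid
                    wgt = 1.0 if found else inv_q
                weights[t] = wgt
                total += wgt
            r = np.random.random() * total
            acc = 0.0
            chosen = nbr[k - 1]
            for t in range(k):
                acc += weights[t]
                if r <= acc:
                    chosen = nbr[t]
                    break
            walks[w, step] = chosen
            cur = chosen
    return walks


@njit(cache=True)
def _sgns_train(walks, n_nodes, dim, window, negatives, epochs, lr0,
                neg_table, seed):  # pragma: no cover
    np.random.seed(seed)
    syn0 = (np.random.random((n_nodes, dim)) - 0.5) / dim
    syn1 = np.zeros((n_nodes, dim))
    n_walks, walk_length = walks.shape
    table_size = neg_table.shape[0]
    total_steps = epochs * n_walks
    step = 0
    for ep in range(epochs):
        for w in range(n_walks):
            lr = lr0 * (1.0 - step / max(total_steps, 1))
            if lr < lr0 * 0.0001:
                lr = lr0 * 0.0001
            step += 1
            for pos in range(walk_length):
                center = walks[w, pos]
                span = np.random.randint(1, window + 1)  # dynamic window
                lo = max(0, pos - span)
                hi = min(walk_length, pos + span + 1)
                for cpos in range(lo, hi):
                    if cpos == pos:
                        continue
                    context = walks[w, cpos]
                    # one positive + `negatives` sampled negatives
                    neu = np.zeros(dim)
                    v = syn0[context]
                    for s in range(negatives + 1):
                        if s == 0:
                            target = center
                            label = 1.0
                        else:
                            target = neg_table[np.random.randint(table_size)]
                            if target == center:
                                continue
                            label = 0.0
                        u = syn1[target]
                        x = 0.0
                        for dd in range(dim):
                            x += v[dd] * u[dd]
                        if x > 6.0:
                            g = (label - 1.0) * lr
                        elif x < -6.0:
                            g = label * lr
                        else:
                            g = (label - 1.0 / (1.0 + np.exp(-x))) * lr
                        for dd in range(dim):
                            neu[dd] += g * u[dd]
                            syn1[target, dd] += g * v[dd]
                    for dd in range(dim):
                        syn0[context, dd] += neu[dd]
    return syn0


def generate_walks(G: SimilarityGraph, params: EmbeddingParams) -> np.ndarray:
    """Seeded second-order biased walks, ``walks_per_node`` from every node."""
    adj = _require_connected_adjacency(G)
    A = sp.csr_matrix(adj)
    m = adj.shape[0]
    rng = np.random.default_rng(params.seed)
    starts = np.tile(np.arange(m), params.walks_per_node)
    rng.shuffle(starts)
    return _biased_walks(
        A.indptr.astype(np.int64), A.indices.astype(np.int64), starts,
        params.walk_length, params.p, params.q,
        int(rng.integers(0, 2 ** 31 - 1)),
    )


def node2vec_embed(G: SimilarityGraph,
                   params: EmbeddingParams | None = None) -> FeatureBlock:
    """Biased-walk skip-gram node embeddings (negative sampling).

    Walk transition probabilities follow the return/in-out bias: weight 1/p
    back to the previous node, 1 to common neighbors of the previous node,
    1/q otherwise. The skip-gram trains with a dynamic window, unigram^0.75
    negative table, and linearly decaying learning rate.
    """
    params = params or EmbeddingParams()
    adj = _require_connected_adjacency(G)
    m = adj.shape[0]
    walks = generate_walks(G, params)

    counts = np.bincount(walks.ravel(), minlength=m).astype(float)
    probs = counts ** 0.75
    probs /= probs.sum()
    table_size = max(10 * m, 100_000)
    neg_table = np.random.default_rng(params.seed + 1).choice(
        m, size=table_size, p=probs
    ).astype(np.int64)

    emb = _sgns_train(walks, m, params.dim, params.window, params.negatives,
                      params.epochs, params.learning_rate, neg_table,
                      (params.seed + 2) % (2 ** 31 - 1))
    columns = [f"{i + 1}" for i in range(params.dim)]
    return FeatureBlock("N2V", emb, columns, list(G.node_ids))


# ---------------------------------------------------------------------------
# GraRep
# ---------------------------------------------------------------------------

def transition_matrix(adj: np.ndarray) -> np.ndarray:
    """Row-normalized adjacency (one-step random-walk transition matrix)."""
    deg = adj.sum(axis=1)
    if np.any(deg == 0):
        raise ValueError("isolated node: graph must be connected")
    return adj / deg[:, None]


def grarep_embed(G: SimilarityGraph,
                 params: EmbeddingParams | None = None) -> FeatureBlock:
    """Concatenated truncated-SVD factors of k-step log-transition matrices.

    For each k in 1..k_max: Y_k = max(log(T^k_ij / colmean_j(T^k)), 0),
    factorized by randomized truncated SVD; the k-step representation is
    U_d sqrt(S_d), sign-fixed so each singular vector's largest-magnitude
    entry is positive. Output width k_max * dim.
    """
    params = params or EmbeddingParams()
    adj = _require_connected_adjacency(G)
    m = adj.shape[0]
    if params.k_max * params.dim >= m:
        raise ValueError("k_max * dim must be < number of nodes")
    T = transition_matrix(adj)
    Tk = np.eye(m)
    reps = []
    for k in range(1, params.k_max + 1):
        Tk = Tk @ T
        col_mean = Tk.mean(axis=0, keepdims=True)
        with np.errstate(divide="ignore"):
            Y = np.log(np.where(Tk > 0, Tk, 1e-300) / col_mean)
        Y = np.maximum(Y, 0.0)
        U, S, _ = randomized_svd(Y, n_components=params.dim,
                                 random_state=params.seed + k)
        Wk = U * np.sqrt(S)
        flip = np.sign(Wk[np.abs(Wk).argmax(axis=0), np.arange(Wk.shape[1])])
        flip[flip == 0] = 1.0
        reps.append(Wk * flip)
    matrix = np.hstack(reps)
    columns = [f"k{k}_{i + 1}" for k in range(1, params.k_max + 1)
               for i in range(params.dim)]
    return FeatureBlock("GraRep", matrix, columns, list(G.node_ids))


EMBEDDING_TAGS = ("SocDim", "N2V", "GraRep")


def embed_graph(tag: str, G: SimilarityGraph,
                params: EmbeddingParams | None = None) -> FeatureBlock:
    if tag == "SocDim":
        return socdim_embed(G, params)
    if tag == "N2V":
        return node2vec_embed(G, params)
    if tag == "GraRep":
        return grarep_embed(G, params)
    raise ValueError(f"unknown embedding tag {tag!r}")
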