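"""Raw network-embedding representations.

Two embedding families are provided:

* **Diffusion-state embedding** ("Mashup-style"): random walk with restart
  (RWR) from every node gives a diffusion-state matrix S, where S[i, j] is
  the stationary probability that a restart-walk from i sits at j; truncated
  SVD of S yields the embedding U_d sqrt(sigma_d).
* **Biased-walk embedding** ("node2vec-style"): second-order random walks
  biased by return parameter p and in-out parameter q generate a node
  corpus; a skip-gram model with negative sampling embeds co-visited nodes
  nearby.

Both are deterministic given an explicit seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from sklearn.base import BaseEstimator

from .network import WeightedNetwork

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    pass


@dataclass
class DiffusionMatrix:
    """RWR stationary distributions, one row per source node.

    Row i solves  s_i = r e_i + (1 - r) P^T s_i  with P the row-normalized
    weighted adjacency.  Rows sum to 1; the diagonal entry is at least the
    restart probability (the restart mass always sits at home).
    """

    nodes: list[str]
    states: np.ndarray  # (n, n), row i = diffusion state of node i
    restart_prob: float


@dataclass
class EmbeddingMatrix:
    """Protein x d real-valued representation with provenance."""

    proteins: list[str]
    vectors: np.ndarray
    method: str  # mashup | node2vec | string2go
    network: str = ""
    params: dict = field(default_factory=dict)

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    def validate(self) -> None:
        if self.vectors.shape[0] != len(self.proteins):
            raise ValueError("one row per protein required")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding contains NaN/Inf")
        if self.d <= 0:
            raise ValueError("dimension must be positive")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for pid, row in zip(self.proteins, self.vectors):
                vals = "\t".join(f"{v:.9g}" for v in row)
                fh.write(f"{pid}\t{vals}\n")

    @classmethod
    def from_tsv(cls, path, method: str = "", network: str = "") -> "EmbeddingMatrix":
        proteins, rows = [], []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                proteins.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        return cls(proteins=proteins, vectors=np.asarray(rows, dtype=float),
                   method=method, network=network)


def _transition_matrix(net: WeightedNetwork) -> tuple[list[str], sp.csr_matrix]:
    """Row-normalized weighted adjacency.  Isolated nodes keep a zero row;
    the RWR solver treats them as absorbing (diffusion state = indicator)."""
    nodes = net.nodes
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    for u, v, w in net.edges():
        if w < 0:
            raise ValueError(f"negative weight on edge ({u!r}, {v!r})")
        i, j = index[u], index[v]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    adj = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    degree = np.asarray(adj.sum(axis=1)).ravel()
    inv = np.zeros(n)
    nz = degree > 0
    inv[nz] = 1.0 / degree[nz]
    P = sp.diags(inv) @ adj
    return nodes, P.tocsr()


def rwr_diffusion(
    net: WeightedNetwork,
    restart_prob: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 10000,
    direct_solve_max_nodes: int = 2000,
) -> DiffusionMatrix:
    """Diffusion states of every node by random walk with restart.

    Solves  S = r I + (1 - r) S P  (each row s_i = r e_i + (1-r) P^T s_i).
    Small networks (<= ``direct_solve_max_nodes`` nodes) use a direct dense
    linear solve; larger ones use power iteration to an L1 residual below
    ``tol``.  Isolated nodes get the indicator diffusion state.
    """
    if net.n_nodes == 0:
        raise ValueError("network is empty")
    if not (0.0 < restart_prob < 1.0):
        raise ValueError("restart_prob must lie in (0, 1)")
    nodes, P = _transition_matrix(net)
    n = len(nodes)
    r = restart_prob
    isolated = np.asarray(P.sum(axis=1)).ravel() == 0
    if n <= direct_solve_max_nodes:
        # stacking s_i = r e_i + (1-r) P^T s_i over i gives S = r (I - (1-r) P)^{-1}
        A = np.eye(n) - (1.0 - r) * P.toarray()
        S = r * np.linalg.inv(A)
    else:
        S = np.eye(n)
        for _ in range(max_iter):
            S_next = r * np.eye(n) + (1.0 - r) * (S @ P)
            resid = np.abs(S_next - S).sum(axis=1).max()
            S = S_next
            if resid < tol:
                break
        else:
            raise ConvergenceError(
                f"RWR did not converge in {max_iter} iterations "
                f"(final residual {resid:.3e})"
            )
    # walk mass leaving an isolated node has nowhere to go: indicator state
    if isolated.any():
        S[isolated] = 0.0
        S[isolated, np.flatnonzero(isolated)] = 1.0
    # also fix rows that lost mass through zero-degree columns on the path
    S = S / S.sum(axis=1, keepdims=True)
    return DiffusionMatrix(nodes=nodes, states=S, restart_prob=r)


def mashup_embed(
    diff: DiffusionMatrix, d: int = 800, log_transform: bool = False
) -> EmbeddingMatrix:
    """Truncated SVD of the diffusion-state matrix: embedding = U_d sqrt(s_d).

    ``log_transform`` optionally applies log(S + 1/n) before factorizing.
    ``d`` larger than the node count is clamped with a warning.
    """
    if d <= 0:
        raise ValueError("embedding dimension must be positive")
    S = diff.states
    n = S.shape[0]
    if log_transform:
        S = np.log(S + 1.0 / n)
    if d > n:
        logger.warning("clamping d=%d to the node count %d", d, n)
        d = n
    if d >= min(S.shape):
        U, sigma, Vt = np.linalg.svd(S, full_matrices=False)
        U, sigma, Vt = U[:, :d], sigma[:d], Vt[:d]
    else:
        U, sigma, Vt = spla.svds(S, k=d, random_state=0)
        order = np.argsort(sigma)[::-1]
        U, sigma, Vt = U[:, order], sigma[order], Vt[order]
    # fix sign indeterminacy for reproducibility
    signs = np.sign(U[np.abs(U).argmax(axis=0), np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    U = U * signs
    Vt = Vt * signs[:, None]
    vectors = U * np.sqrt(sigma)
    return EmbeddingMatrix(
        proteins=diff.nodes, vectors=vectors, method="mashup",
        params={"d": d, "restart_prob": diff.restart_prob,
                "log_transform": log_transform, "singular_values": sigma,
                "vt": Vt},
    )


@dataclass
class WalkCorpus:
    """Corpus of biased random walks (sequences of node ids)."""

    walks: list[list[str]]
    walk_length: int
    walks_per_node: int
    p: float
    q: float

    def node_set(self) -> set[str]:
        return {v for walk in self.walks for v in walk}


def node2vec_transition_probs(
    net: WeightedNetwork, prev: str, current: str, p: float, q: float
) -> tuple[list[str], np.ndarray]:
    """Unnormalized second-order weights from ``current`` given ``prev``,
    returned normalized.  Weight to neighbor x is w(current, x) times 1/p if
    x == prev, 1 if x neighbors prev, and 1/q otherwise."""
    g = net.graph
    neighbors = list(g.neighbors(current))
    weights = np.empty(len(neighbors))
    prev_nbrs = set(g.neighbors(prev))
    for i, x in enumerate(neighbors):
        w = g.edges[current, x]["weight"]
        if x == prev:
            w /= p
        elif x in prev_nbrs:
            pass  # distance 1 from prev: bias factor 1
        else:
            w /= q
        weights[i] = w
    return neighbors, weights / weights.sum()


def node2vec_walks(
    net: WeightedNetwork,
    walk_length: int = 10,
    walks_per_node: int = 10,
    p: float = 1.0,
    q: float = 2.0,
    seed: int = 0,
) -> WalkCorpus:
    """Second-order biased random walks from every node.

    The first step samples neighbors proportionally to edge weight; later
    steps apply the p/q bias relative to the previous node.  q > 1 keeps the
    walk close to the source neighborhood.  Walks from isolated nodes are the
    single-node sequence.
    """
    if p <= 0 or q <= 0:
        raise ValueError("p and q must be positive")
    rng = np.random.default_rng(seed)
    g = net.graph
    nodes = net.nodes
    nbrs: dict[str, list[str]] = {}
    first_probs: dict[str, np.ndarray] = {}
    for v in nodes:
        ns = list(g.neighbors(v))
        nbrs[v] = ns
        if ns:
            w = np.array([g.edges[v, x]["weight"] for x in ns])
            first_probs[v] = w / w.sum()
    walks = []
    for _ in range(walks_per_node):
        for start in nodes:
            walk = [start]
            if not nbrs[start]:
                walks.append(walk)
                continue
            current = nbrs[start][rng.choice(len(nbrs[start]),
                                             p=first_probs[start])]
            walk.append(current)
            while len(walk) < walk_length:
                if not nbrs[current]:
                    break
                prev = walk[-2]
                options, probs = node2vec_transition_probs(net, prev, current,
                                                           p, q)
                current = options[rng.choice(len(options), p=probs)]
                walk.append(current)
            walks.append(walk)
    return WalkCorpus(walks=walks, walk_length=walk_length,
                      walks_per_node=walks_per_node, p=p, q=q)


def skipgram_embed(
    corpus: WalkCorpus,
    d: int = 128,
    window: int = 5,
    negatives: int = 5,
    epochs: int = 5,
    learning_rate: float = 2.5,
    seed: int = 0,
    all_nodes: list[str] | None = None,
) -> EmbeddingMatrix:
    """Skip-gram with negative sampling over a walk corpus.

    Center/context pairs are all co-occurrences within ``window`` positions;
    negatives are drawn from the unigram distribution raised to 3/4.  The
    model is trained single-threaded with minibatch SGD, so results are
    reproducible given the seed.  Nodes in ``all_nodes`` absent from the
    corpus receive zero vectors with a warning.
    """
    if d <= 0:
        raise ValueError("embedding dimension must be positive")
    if not corpus.walks:
        raise ValueError("walk corpus is empty")
    rng = np.random.default_rng(seed)
    vocab = sorted(corpus.node_set())
    index = {v: i for i, v in enumerate(vocab)}
    counts = np.zeros(len(vocab))
    encoded = []
    for walk in corpus.walks:
        ids = np.array([index[v] for v in walk], dtype=np.int64)
        encoded.append(ids)
        np.add.at(counts, ids, 1)
    noise = counts ** 0.75
    noise /= noise.sum()
    centers, contexts = [], []
    for ids in encoded:
        L = len(ids)
        for pos in range(L):
            lo, hi = max(0, pos - window), min(L, pos + window + 1)
            for ctx in range(lo, hi):
                if ctx != pos:
                    centers.append(ids[pos])
                    contexts.append(ids[ctx])
    centers = np.asarray(centers, dtype=np.int64)
    contexts = np.asarray(contexts, dtype=np.int64)
    n_pairs = len(centers)
    V = len(vocab)
    W_in = (rng.random((V, d)) - 0.5) / d
    W_out = np.zeros((V, d))
    batch = 1024
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for s in range(0, n_pairs, batch):
            idx = order[s:s + batch]
            c, o = centers[idx], contexts[idx]
            neg = rng.choice(V, size=(len(idx), negatives), p=noise)
            vc = W_in[c]                              # (b, d)
            targets = np.concatenate([o[:, None], neg], axis=1)  # (b, 1+k)
            vt = W_out[targets]                       # (b, 1+k, d)
            score = np.einsum("bd,bkd->bk", vc, vt)
            sig = 1.0 / (1.0 + np.exp(-np.clip(score, -30, 30)))
            label = np.zeros_like(sig)
            label[:, 0] = 1.0
            err = sig - label                          # (b, 1+k)
            grad_c = np.einsum("bk,bkd->bd", err, vt)
            grad_t = err[..., None] * vc[:, None, :]
            # mean-gradient minibatch step: stable even when the same node
            # index recurs many times within a batch
            step = learning_rate / len(idx)
            np.add.at(W_in, c, -step * grad_c)
            np.add.at(W_out, targets.ravel(),
                      -step * grad_t.reshape(-1, d))
    proteins = list(all_nodes) if all_nodes is not None else vocab
    vectors = np.zeros((len(proteins), d))
    missing = 0
    for i, v in enumerate(proteins):
        if v in index:
            vectors[i] = W_in[index[v]]
        else:
            missing += 1
    if missing:
        logger.warning("%d nodes absent from the walk corpus got zero vectors",
                       missing)
    return EmbeddingMatrix(
        proteins=proteins, vectors=vectors, method="node2vec",
        params={"d": d, "window": window, "negatives": negatives,
                "epochs": epochs, "seed": seed},
    )


class MashupEmbedding(BaseEstimator):
    """Diffusion-state embedding estimator (RWR + truncated SVD).

    Parameters mirror :func:`rwr_diffusion` and :func:`mashup_embed`.
    After :meth:`fit`, ``embedding_`` holds the :class:`EmbeddingMatrix`.
    """

    def __init__(self, d: int = 800, restart_prob: float = 0.5,
                 tol: float = 1e-8, max_iter: int = 10000,
                 log_transform: bool = False):
        self.d = d
        self.restart_prob = restart_prob
        self.tol = tol
        self.max_iter = max_iter
        self.log_transform = log_transform

    def fit(self, net: WeightedNetwork, y=None):
        diff = rwr_diffusion(net, restart_prob=self.restart_prob,
                             tol=self.tol, max_iter=self.max_iter)
        emb = mashup_embed(diff, d=self.d, log_transform=self.log_transform)
        emb.network = net.name
        self.diffusion_ = diff
        self.embedding_ = emb
        return self

    def fit_transform(self, net: WeightedNetwork, y=None) -> EmbeddingMatrix:
        return self.fit(net).embedding_


class Node2VecEmbedding(BaseEstimator):
    """Second-order biased walk + skip-gram embedding estimator."""

    def __init__(self, d: int = 128, walk_length: int = 10,
                 walks_per_node: int = 10, p: float = 1.0, q: float = 2.0,
                 window: int = 5, negatives: int = 5, epochs: int = 5,
                 learning_rate: float = 2.5, seed: int = 0):
        self.d = d
        self.walk_length = walk_length
        self.walks_per_node = walks_per_node
        self.p = p
        self.q = q
        self.window = window
        self.negatives = negatives
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed

    def fit(self, net: WeightedNetwork, y=None):
        corpus = node2vec_walks(
            net, walk_length=self.walk_length,
            walks_per_node=self.walks_per_node, p=self.p, q=self.q,
            seed=self.seed,
        )
        emb = skipgram_embed(
            corpus, d=self.d, window=self.window, negatives=self.negatives,
            epochs=self.epochs, learning_rate=self.learning_rate,
            seed=self.seed, all_nodes=net.nodes,
        )
        emb.network = net.name
        self.corpus_ = corpus
        self.embedding_ = emb
        return self

    def fit_transform(self, net: WeightedNetwork, y=None) -> EmbeddingMatrix:
        return self.fit(net).embedding_
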