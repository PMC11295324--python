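"""t-SNE engine with a Bhattacharyya input metric and Bregman objectives.

Two modes share one optimizer:

* baseline — pairwise Euclidean distances, Student-t low-dimensional
  kernel, Kullback-Leibler cost (classic t-SNE);
* modified — pairwise Bhattacharyya distances between probability-vector
  rows, with either the Student-t kernel (default, stable) or a literal
  "distributions in the embedding" kernel that passes each embedded row
  through a softmax and uses the Bhattacharyya coefficient as affinity.

The cost is a Bregman divergence B_phi(P, Q) = phi(P) - phi(Q)
- <grad phi(Q), P - Q>; the generalized-KL generator phi = sum p log p
reduces to ordinary KL on normalized affinities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "EmbedConfig",
    "bhattacharyya_distance",
    "bhattacharyya_coefficient",
    "pairwise_distances",
    "conditional_affinities",
    "joint_affinities",
    "bregman_divergence",
    "tsne_embed",
    "tsne_gradient",
    "trustworthiness",
]

_SIMPLEX_ATOL = 1e-6


@dataclass(frozen=True)
class EmbedConfig:
    """Hyper-parameters for :func:`tsne_embed`.

    The baseline mode is ``input_metric="euclidean"``,
    ``low_dim_kernel="student_t"``, ``divergence="kl"``.
    """

    perplexity: float = 30.0
    out_dim: int = 2
    max_iter: int = 1000
    learning_rate: float = 100.0
    momentum_early: float = 0.5
    momentum_late: float = 0.8
    momentum_switch_iter: int = 250
    early_exaggeration: float = 4.0
    early_exaggeration_iters: int = 100
    seed: int = 0
    input_metric: str = "euclidean"  # euclidean | bhattacharyya
    low_dim_kernel: str = "student_t"  # student_t | simplex_bhattacharyya
    divergence: str = "kl"  # kl | generalized_kl | squared_euclidean
    init: str = "random"  # random | pca

    def __post_init__(self) -> None:
        if self.perplexity <= 1:
            raise ValueError("perplexity must be > 1")
        if self.out_dim < 1 or self.max_iter < 1 or self.learning_rate <= 0:
            raise ValueError("invalid optimizer settings")
        if not (0 <= self.momentum_early < 1 and 0 <= self.momentum_late < 1):
            raise ValueError("momentum values must be in [0, 1)")
        if self.early_exaggeration < 1:
            raise ValueError("early_exaggeration must be >= 1")
        if self.input_metric not in ("euclidean", "bhattacharyya"):
            raise ValueError(f"unknown input_metric {self.input_metric!r}")
        if self.low_dim_kernel not in ("student_t", "simplex_bhattacharyya"):
            raise ValueError(f"unknown low_dim_kernel {self.low_dim_kernel!r}")
        if self.divergence not in ("kl", "generalized_kl", "squared_euclidean"):
            raise ValueError(f"unknown divergence {self.divergence!r}")
        if self.init not in ("random", "pca"):
            raise ValueError(f"unknown init {self.init!r}")


def _check_simplex(arr: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"{name} must be a 1-D probability vector")
    if np.any(a < -_SIMPLEX_ATOL):
        raise ValueError(f"{name} has negative entries")
    if abs(a.sum() - 1.0) > _SIMPLEX_ATOL:
        raise ValueError(f"{name} does not sum to 1")
    return np.clip(a, 0.0, None)


def bhattacharyya_coefficient(p, q) -> float:
    """Overlap BC(P, Q) = sum_x sqrt(P(x) Q(x)), in [0, 1]."""
    pv = _check_simplex(p, "P")
    qv = _check_simplex(q, "Q")
    if pv.shape != qv.shape:
        raise ValueError("dimension mismatch between P and Q")
    return float(min(np.sqrt(pv * qv).sum(), 1.0))


def bhattacharyya_distance(p, q) -> float:
    """D(P, Q) = -ln BC(P, Q); 0 iff P = Q, +inf for disjoint supports.

    Symmetric and nonnegative but not a metric (no triangle inequality).
    """
    bc = bhattacharyya_coefficient(p, q)
    if bc == 0.0:
        return float("inf")
    return max(-float(np.log(bc)), 0.0)


def pairwise_distances(X, metric: str = "euclidean") -> np.ndarray:
    """Symmetric zero-diagonal distance matrix over the rows of X.

    For ``metric="bhattacharyya"`` every row must be a probability vector
    (apply :func:`qdl.image_prep.features_to_distribution` upstream).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if metric == "euclidean":
        D = squareform(pdist(X, metric="euclidean"))
    elif metric == "bhattacharyya":
        for i, row in enumerate(X):
            _check_simplex(row, f"row {i}")
        bc = np.sqrt(np.clip(X, 0.0, None)) @ np.sqrt(np.clip(X, 0.0, None)).T
        bc = np.clip(bc, 0.0, 1.0)
        with np.errstate(divide="ignore"):
            D = -np.log(bc)
        D = np.clip(D, 0.0, None)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def _cap_infinities(D: np.ndarray) -> np.ndarray:
    """Replace +inf distances by 10x the largest finite one (keeps the
    bandwidth bisection well-posed for disjoint-support pairs)."""
    if not np.isinf(D).any():
        return D
    finite = D[np.isfinite(D)]
    cap = (finite.max() if finite.size else 1.0) * 10.0
    return np.where(np.isinf(D), cap, D)


def _row_affinity(d2: np.ndarray, beta: float) -> np.ndarray:
    a = np.exp(-(d2 - d2.min()) * beta)
    s = a.sum()
    return a / s


def _row_perplexity(p: np.ndarray) -> float:
    nz = p[p > 0]
    h = -(nz * np.log2(nz)).sum()
    return float(2.0**h)


def conditional_affinities(D, perplexity: float, *, rtol: float = 1e-4, max_iter: int = 200) -> np.ndarray:
    """Row-stochastic affinities p(j|i) ~ exp(-beta_i d_ij^2).

    beta_i is found by bisection so the achieved perplexity 2^H (entropy in
    bits) of each row matches ``perplexity`` within relative tolerance
    ``rtol``.  Rows where all off-diagonal distances are equal are uniform
    and already achieve perplexity n-1; they are returned as-is.
    """
    D = _cap_infinities(np.asarray(D, dtype=float))
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("D must be square")
    if not 1.0 < perplexity < n:
        raise ValueError("need 1 < perplexity < n")
    P = np.zeros((n, n))
    for i in range(n):
        d2 = np.delete(D[i], i) ** 2
        if np.allclose(d2, d2[0]):
            row = np.full(n - 1, 1.0 / (n - 1))
        else:
            lo, hi = 0.0, None
            beta = 1.0
            row = _row_affinity(d2, beta)
            for _ in range(max_iter):
                perp = _row_perplexity(row)
                if abs(perp - perplexity) <= rtol * perplexity:
                    break
                if perp > perplexity:  # too flat -> increase beta
                    lo = beta
                    beta = beta * 2.0 if hi is None else (beta + hi) / 2.0
                else:
                    hi = beta
                    beta = (lo + beta) / 2.0
                row = _row_affinity(d2, beta)
        P[i, np.arange(n) != i] = row
    if not np.all(np.isfinite(P)):
        raise ValueError("non-finite affinity row; check the distance matrix")
    return P


def joint_affinities(P_cond: np.ndarray) -> np.ndarray:
    """Symmetrized joint p_ij = (p(j|i) + p(i|j)) / (2n); sums to 1."""
    n = P_cond.shape[0]
    P = (P_cond + P_cond.T) / (2.0 * n)
    return np.maximum(P, 0.0)


def bregman_divergence(P, Q, generator: str = "generalized_kl") -> float:
    """Elementwise Bregman divergence between two nonnegative arrays.

    ``generalized_kl`` (generator phi = sum p log p) gives
    sum p log(p/q) - sum p + sum q, which equals textbook KL when both
    inputs are normalized; ``squared_euclidean`` (phi = ||.||^2 / 2) gives
    half the squared Frobenius distance.  ``kl`` is accepted as an alias
    for ``generalized_kl``.  A zero in Q facing positive P yields +inf,
    never an exception.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("shape mismatch")
    if generator in ("generalized_kl", "kl"):
        pos = P > 0
        if np.any(Q[pos] == 0):
            return float("inf")
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(pos, P * (np.log(np.where(pos, P, 1.0)) - np.log(np.where(Q > 0, Q, 1.0))), 0.0)
        return float(terms.sum() - P.sum() + Q.sum())
    if generator == "squared_euclidean":
        return float(0.5 * ((P - Q) ** 2).sum())
    raise ValueError(f"unknown generator {generator!r}")


# ---------------------------------------------------------------------------
# low-dimensional kernels


def _student_t_kernel(Y: np.ndarray) -> tuple[np.ndarray, float]:
    """W_ij = (1 + ||y_i - y_j||^2)^-1 with zero diagonal, and its sum."""
    sq = squareform(pdist(Y, metric="sqeuclidean"))
    W = 1.0 / (1.0 + sq)
    np.fill_diagonal(W, 0.0)
    return W, float(W.sum())


def _softmax_rows(Y: np.ndarray) -> np.ndarray:
    Z = Y - Y.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


def _simplex_bhatt_kernel(Y: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """W_ij = BC(softmax(y_i), softmax(y_j)), zero diagonal."""
    S = _softmax_rows(Y)
    R = np.sqrt(S)
    W = R @ R.T
    np.fill_diagonal(W, 0.0)
    return W, float(W.sum()), S


def _dC_dW(P: np.ndarray, W: np.ndarray, Ssum: float, divergence: str) -> np.ndarray:
    """G_ij = dC/dW_ij for C = divergence(P, W/Ssum); zero diagonal.

    Constant shifts of the per-entry derivative L cancel (sum Q = 1), so the
    KL and generalized-KL cases share one expression.
    """
    Q = W / Ssum
    np.clip(Q, 1e-12, None, out=Q)
    if divergence in ("kl", "generalized_kl"):
        L = -P / Q
    elif divergence == "squared_euclidean":
        L = -(P - Q)
    else:  # pragma: no cover - guarded by EmbedConfig
        raise ValueError(divergence)
    np.fill_diagonal(L, 0.0)
    A = float((L * Q).sum())
    G = (L - A) / Ssum
    np.fill_diagonal(G, 0.0)
    return G


def tsne_gradient(P: np.ndarray, Y: np.ndarray, cfg: EmbedConfig) -> tuple[float, np.ndarray]:
    """Cost and analytic gradient of the configured objective at Y."""
    if cfg.low_dim_kernel == "student_t":
        W, Ssum = _student_t_kernel(Y)
        Q = np.clip(W / Ssum, 1e-12, None)
        np.fill_diagonal(Q, 0.0)
        cost = bregman_divergence(P, Q, cfg.divergence)
        G = _dC_dW(P, W, Ssum, cfg.divergence)
        # dW_ij/dy_i = -2 W_ij^2 (y_i - y_j); G is symmetric
        M = G * W * W
        grad = -4.0 * (M.sum(axis=1)[:, None] * Y - M @ Y)
        return cost, grad
    # simplex_bhattacharyya: w_ij = sum_x sqrt(s_ix s_jx), s = softmax(y)
    W, Ssum, S = _simplex_bhatt_kernel(Y)
    Q = np.clip(W / Ssum, 1e-12, None)
    np.fill_diagonal(Q, 0.0)
    cost = bregman_divergence(P, Q, cfg.divergence)
    G = _dC_dW(P, W, Ssum, cfg.divergence)
    R = np.sqrt(S)
    # dC/dy_ik = sum_j G_ij (sqrt(s_ik s_jk) - s_ik w_ij), G symmetric;
    # the 1/2 from d(sqrt)/ds cancels the factor 2 from the two matrix
    # orientations (i,j) and (j,i)
    grad = R * (G @ R) - S * (G * W).sum(axis=1)[:, None]
    return cost, grad


def _init_embedding(X: np.ndarray | None, n: int, cfg: EmbedConfig) -> np.ndarray:
    rng = np.random.default_rng(cfg.seed)
    if cfg.init == "pca":
        if X is None:
            raise ValueError("pca init requires a feature matrix, not a distance matrix")
        Xc = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        Y = Xc @ Vt[: cfg.out_dim].T
        # small jitter breaks exact ties deterministically
        return Y + rng.normal(0.0, 1e-6, Y.shape)
    return rng.normal(0.0, 1e-4, (n, cfg.out_dim))


def tsne_embed(X, cfg: EmbedConfig, *, precomputed: bool = False) -> tuple[np.ndarray, list[float]]:
    """Embed rows of X (or a precomputed distance matrix) in ``out_dim`` dims.

    Returns the embedding and the per-iteration cost trace.  Optimization is
    full-batch gradient descent with momentum and early exaggeration; it
    stops at ``max_iter`` or when the relative cost change over 50
    iterations drops below 1e-7 (after the exaggeration phase).
    """
    X = np.asarray(X, dtype=float)
    if precomputed:
        D = X
        feats = None
    else:
        D = pairwise_distances(X, metric=cfg.input_metric)
        feats = X
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    if not cfg.perplexity < n:
        raise ValueError("perplexity must be < n")

    P = joint_affinities(conditional_affinities(D, cfg.perplexity))
    np.clip(P, 1e-12, None, out=P)
    np.fill_diagonal(P, 0.0)

    Y = _init_embedding(feats, n, cfg)
    inc = np.zeros_like(Y)
    trace: list[float] = []
    ee = cfg.early_exaggeration
    for it in range(cfg.max_iter):
        Pt = P * ee if it < cfg.early_exaggeration_iters else P
        cost, grad = tsne_gradient(Pt, Y, cfg)
        if not np.all(np.isfinite(grad)):
            raise RuntimeError(f"non-finite gradient at iteration {it}; cost={cost}")
        momentum = cfg.momentum_early if it < cfg.momentum_switch_iter else cfg.momentum_late
        inc = momentum * inc - cfg.learning_rate * grad
        Y = Y + inc
        Y = Y - Y.mean(axis=0)
        trace.append(float(cost))
        if it >= cfg.early_exaggeration_iters + 50:
            prev = trace[-51]
            if prev > 0 and abs(prev - trace[-1]) / prev < 1e-7:
                break
    return Y, trace


def trustworthiness(D_high, Y, k: int) -> float:
    """Neighborhood-preservation score in [0, 1] (1 = perfect).

    Penalizes points that enter the k-neighborhood in the embedding without
    being among the k nearest in the original space, weighted by how far
    down the original ranking they sit.
    """
    D_high = _cap_infinities(np.asarray(D_high, dtype=float))
    Y = np.asarray(Y, dtype=float)
    n = D_high.shape[0]
    if not 0 < k < n / 2:
        raise ValueError("need 0 < k < n/2")
    D_low = squareform(pdist(Y))
    big = np.inf
    Dh = D_high.copy()
    Dl = D_low.copy()
    np.fill_diagonal(Dh, big)
    np.fill_diagonal(Dl, big)
    # rank of j among i's original neighbors (1 = nearest), ties by index
    order_high = np.argsort(Dh, axis=1, kind="stable")
    ranks = np.empty_like(order_high)
    rows = np.arange(n)[:, None]
    ranks[rows, order_high] = np.arange(n)[None, :] + 1
    knn_high = order_high[:, :k]
    knn_low = np.argsort(Dl, axis=1, kind="stable")[:, :k]
    total = 0.0
    for i in range(n):
        high_set = set(knn_high[i].tolist())
        for j in knn_low[i]:
            if j not in high_set:
                total += ranks[i, j] - k
    denom = n * k * (2 * n - 3 * k - 1)
    return float(1.0 - 2.0 * total / denom)
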