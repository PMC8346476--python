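"""Coupled nonnegative matrix factorization of scATAC-seq and scRNA-seq.

Solves the constrained optimization

    min  1/2 ||O - W1 H1||_F^2 + lambda1/2 ||E - W2 H2||_F^2
         - lambda2 tr(W2^T A W1)
    s.t. columns of W1 and W2 have unit squared sum; all factors >= 0

where O (peaks x cells) is the accessibility matrix, E (genes x cells) the
expression matrix, and A (genes x peaks) the coupling matrix rewarding
agreement between peak factors and gene factors at linked loci.  The trace
reward aligns the K factors across modalities so that cluster k of the
scATAC-seq cells matches cluster k of the scRNA-seq cells.

Optimized by multiplicative updates derived from the KKT conditions of the
norm-constrained Lagrangian (the diag(...) terms absorb the Lagrange
multipliers of the unit-norm constraints); H1/H2 take standard Lee-Seung
steps.  The coupling strength is set through two interpretable parameters:
``alpha_couple`` (the coupling-to-factorization ratio, default 0.1%) and
``beta_balance`` (the scATAC/scRNA balance, default 0.5), converted to
(lambda1, lambda2) against a standard-NMF warm start.  An annealing schedule
runs alpha down the series [10000, 1000, ..., target], warm-starting each
stage from the previous solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import NMF
from sklearn.manifold import TSNE

__all__ = [
    "SingleCellMatrix",
    "FactorizationResult",
    "ClusterAssignment",
    "preprocess",
    "quantile_normalize",
    "select_lambdas",
    "coupled_nmf",
    "coupled_objective",
    "assign_clusters",
    "joint_embed",
    "ANNEAL_SERIES",
]

ANNEAL_SERIES = (10000.0, 1000.0, 100.0, 10.0, 1.0, 0.1, 0.01, 0.001)
_EPS = 1e-16


@dataclass
class SingleCellMatrix:
    """Nonnegative feature x cell matrix with identifiers and modality tag."""

    values: np.ndarray
    feature_ids: list[str]
    cell_ids: list[str]
    modality: str                 # "rna" or "atac"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < 0:
            raise ValueError("single-cell matrices must be nonnegative")
        if self.modality not in ("rna", "atac"):
            raise ValueError(f"modality must be 'rna' or 'atac', got {self.modality!r}")
        if self.values.shape != (len(self.feature_ids), len(self.cell_ids)):
            raise ValueError("shape does not match feature/cell id counts")


@dataclass
class FactorizationResult:
    W1: np.ndarray            # p1 x K (atac factors)
    H1: np.ndarray            # K x n1
    W2: np.ndarray            # p2 x K (rna factors)
    H2: np.ndarray            # K x n2
    K: int
    lambda1: float
    lambda2: float
    alpha_couple: float
    beta_balance: float
    objective_trace: list[float] = field(default_factory=list)


@dataclass
class ClusterAssignment:
    """Hard per-cell labels (0..K-1) per modality plus cluster mean profiles."""

    atac_labels: np.ndarray
    rna_labels: np.ndarray
    atac_profiles: np.ndarray      # p1 x K cluster means (NaN for empty clusters)
    rna_profiles: np.ndarray       # p2 x K
    atac_ties: np.ndarray          # cells whose argmax was tied
    rna_ties: np.ndarray
    empty_clusters: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def quantile_normalize(X: np.ndarray) -> np.ndarray:
    """Quantile normalization across columns (cells).

    Every column is mapped onto the mean sorted profile, so after the
    transform all cells share the same sorted value vector.  Ties within a
    column receive the values in their (stable) sort order.
    """
    X = np.asarray(X, dtype=float)
    order = np.argsort(X, axis=0, kind="stable")
    ranks = np.empty_like(order)
    n = X.shape[0]
    ar = np.arange(n)
    for c in range(X.shape[1]):
        ranks[order[:, c], c] = ar
    target = np.sort(X, axis=0).mean(axis=1)
    return target[ranks]


def preprocess(counts: SingleCellMatrix, drop_empty_cells: bool = True) -> SingleCellMatrix:
    """Quantile normalization then log transform (log2 for rna, log10 for atac).

    A pseudocount of 1 is used inside the log.  All-zero cells are dropped.
    """
    X = counts.values
    cell_ids = list(counts.cell_ids)
    keep = X.sum(axis=0) > 0
    if drop_empty_cells and not keep.all():
        X = X[:, keep]
        cell_ids = [c for c, k in zip(cell_ids, keep) if k]
    Xq = quantile_normalize(X)
    log = np.log2 if counts.modality == "rna" else np.log10
    return SingleCellMatrix(
        values=log(1.0 + Xq),
        feature_ids=list(counts.feature_ids),
        cell_ids=cell_ids,
        modality=counts.modality,
        normalized=True,
    )


# ---------------------------------------------------------------------------
# Parameter selection
# ---------------------------------------------------------------------------

def select_lambdas(O, E, A, W10, H10, W20, H20, alpha_couple=0.001, beta_balance=0.5):
    """Convert (alpha, beta) to (lambda1, lambda2) against an NMF warm start.

    alpha*beta     = mean(lambda2/2 * A^T W20) / mean(O H10^T)
    alpha*(1-beta) = mean(lambda2/(2 lambda1) * A W10) / mean(E H20^T)

    Means are elementwise over all matrix entries.
    """
    if alpha_couple < 0:
        raise ValueError("alpha_couple must be nonnegative")
    if not 0.0 < beta_balance < 1.0:
        raise ValueError("beta_balance must lie strictly in (0, 1)")
    A = np.asarray(A) if not hasattr(A, "toarray") else A.toarray()
    m_atw2 = float(np.mean(A.T @ W20))
    m_aw1 = float(np.mean(A @ W10))
    if m_atw2 <= 0:
        raise ValueError(
            "mean(A^T W20) is zero: the coupling matrix does not touch the "
            "factors -- check that A links the supplied genes and peaks"
        )
    m_oh = float(np.mean(O @ H10.T))
    m_eh = float(np.mean(E @ H20.T))
    lambda2 = 2.0 * alpha_couple * beta_balance * m_oh / m_atw2
    lambda1 = lambda2 * m_aw1 / (2.0 * alpha_couple * (1.0 - beta_balance) * m_eh)
    return lambda1, lambda2


# ---------------------------------------------------------------------------
# CoupledNMF
# ---------------------------------------------------------------------------

def coupled_objective(O, E, A, W1, H1, W2, H2, lambda1, lambda2) -> float:
    rec1 = 0.5 * np.linalg.norm(O - W1 @ H1, "fro") ** 2
    rec2 = 0.5 * lambda1 * np.linalg.norm(E - W2 @ H2, "fro") ** 2
    couple = lambda2 * float(np.trace(W2.T @ (A @ W1)))
    return rec1 + rec2 - couple


def _col_diag(W, M):
    # diagonal of W^T M as a (K,) vector
    return np.einsum("ik,ik->k", W, M)


def _sweep(O, E, A, At, W1, H1, W2, H2, lambda1, lambda2):
    """One full multiplicative update of W1, W2, H1, H2 (in place-ish)."""
    OH = O @ H1.T
    coup1 = lambda2 * (At @ W2)
    WHH = W1 @ (H1 @ H1.T)
    num = OH + coup1 + W1 * _col_diag(W1, WHH)[None, :]
    den = WHH + W1 * _col_diag(W1, OH + coup1)[None, :]
    W1 = np.maximum(W1 * num / np.maximum(den, _EPS), _EPS)

    EH = E @ H2.T
    coup2 = (lambda2 / lambda1) * (A @ W1) if lambda1 > 0 else np.zeros_like(EH)
    WHH2 = W2 @ (H2 @ H2.T)
    num = EH + coup2 + W2 * _col_diag(W2, WHH2)[None, :]
    den = WHH2 + W2 * _col_diag(W2, EH + coup2)[None, :]
    W2 = np.maximum(W2 * num / np.maximum(den, _EPS), _EPS)

    H1 = np.maximum(H1 * (W1.T @ O) / np.maximum(W1.T @ W1 @ H1, _EPS), _EPS)
    H2 = np.maximum(H2 * (W2.T @ E) / np.maximum(W2.T @ W2 @ H2, _EPS), _EPS)
    return W1, H1, W2, H2


def _warm_start_nmf(X, K, seed, max_iter=200):
    model = NMF(
        n_components=K, init="random", solver="mu", beta_loss="frobenius",
        max_iter=max_iter, random_state=seed, tol=1e-10,
    )
    W = model.fit_transform(X)
    return np.maximum(W, _EPS), np.maximum(model.components_, _EPS)


def coupled_nmf(
    O: np.ndarray,
    E: np.ndarray,
    A,
    K: int,
    alpha_couple: float = 0.001,
    beta_balance: float = 0.5,
    anneal: tuple[float, ...] = ANNEAL_SERIES,
    seed: int = 0,
    max_sweeps: int = 500,
    tol: float = 1e-6,
    stage_sweeps: int = 100,
    lambdas: tuple[float, float] | None = None,
) -> FactorizationResult:
    """Constrained CoupledNMF with annealing on the coupling strength.

    ``anneal`` values larger than ``alpha_couple`` are run for
    ``stage_sweeps`` sweeps each (largest first, warm-starting the next
    stage); the final stage at ``alpha_couple`` runs to convergence
    (relative objective change < ``tol`` or ``max_sweeps``).  Passing
    ``lambdas`` bypasses the (alpha, beta) selection entirely (useful for
    the decoupled lambda2 = 0 limit).  W columns are renormalized to unit
    squared sum at the end, with compensating row scaling of H.
    """
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    O = np.asarray(O, dtype=float)
    E = np.asarray(E, dtype=float)
    A = A.toarray() if hasattr(A, "toarray") else np.asarray(A, dtype=float)
    At = A.T.copy()

    rng = np.random.default_rng(seed)
    W1 = rng.uniform(0.0, 1.0, size=(O.shape[0], K)) + _EPS
    H1 = rng.uniform(0.0, 1.0, size=(K, O.shape[1])) + _EPS
    W2 = rng.uniform(0.0, 1.0, size=(E.shape[0], K)) + _EPS
    H2 = rng.uniform(0.0, 1.0, size=(K, E.shape[1])) + _EPS

    if lambdas is None:
        W10, H10 = _warm_start_nmf(O, K, seed)
        W20, H20 = _warm_start_nmf(E, K, seed)
        warm = (W10, H10, W20, H20)
        stages = [a for a in sorted(set(anneal), reverse=True) if a > alpha_couple]
        stages.append(alpha_couple)
    else:
        warm = None
        stages = [alpha_couple]

    trace: list[float] = []
    lambda1 = lambda2 = None
    for stage_i, alpha in enumerate(stages):
        final = stage_i == len(stages) - 1
        if lambdas is not None:
            lambda1, lambda2 = lambdas
        else:
            lambda1, lambda2 = select_lambdas(
                O, E, A, *warm, alpha_couple=alpha, beta_balance=beta_balance
            )
        budget = max_sweeps if final else stage_sweeps
        prev = coupled_objective(O, E, A, W1, H1, W2, H2, lambda1, lambda2)
        for _ in range(budget):
            W1, H1, W2, H2 = _sweep(O, E, A, At, W1, H1, W2, H2, lambda1, lambda2)
            obj = coupled_objective(O, E, A, W1, H1, W2, H2, lambda1, lambda2)
            if not np.isfinite(obj):
                raise FloatingPointError("CoupledNMF objective diverged")
            if final:
                trace.append(obj)
            if abs(prev - obj) <= tol * max(abs(prev), 1.0):
                prev = obj
                break
            prev = obj

    # enforce the unit column-norm constraint, compensating in H
    for W, H in ((W1, H1), (W2, H2)):
        norms = np.sqrt((W ** 2).sum(axis=0))
        norms = np.maximum(norms, _EPS)
        W /= norms[None, :]
        H *= norms[:, None]

    return FactorizationResult(
        W1=W1, H1=H1, W2=W2, H2=H2, K=K,
        lambda1=float(lambda1), lambda2=float(lambda2),
        alpha_couple=alpha_couple, beta_balance=beta_balance,
        objective_trace=trace,
    )


# ---------------------------------------------------------------------------
# Cluster assignment and embedding
# ---------------------------------------------------------------------------

def _argmax_labels(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    colsum = np.maximum(H.sum(axis=0), _EPS)
    Hn = H / colsum[None, :]
    labels = Hn.argmax(axis=0)
    ties = (np.isclose(Hn, Hn.max(axis=0)[None, :])).sum(axis=0) > 1
    return labels, np.nonzero(ties)[0]


def assign_clusters(
    result: FactorizationResult,
    O: np.ndarray | None = None,
    E: np.ndarray | None = None,
) -> ClusterAssignment:
    """Hard labels = argmax of the column-normalized H; ties go to the lowest
    index.  Per-cluster profiles are means over member cells of the supplied
    data matrices (or of the reconstructions W H if not supplied)."""
    l1, t1 = _argmax_labels(result.H1)
    l2, t2 = _argmax_labels(result.H2)
    O = result.W1 @ result.H1 if O is None else np.asarray(O, dtype=float)
    E = result.W2 @ result.H2 if E is None else np.asarray(E, dtype=float)
    K = result.K
    prof1 = np.full((O.shape[0], K), np.nan)
    prof2 = np.full((E.shape[0], K), np.nan)
    empty = []
    for k in range(K):
        m1, m2 = l1 == k, l2 == k
        if m1.any():
            prof1[:, k] = O[:, m1].mean(axis=1)
        if m2.any():
            prof2[:, k] = E[:, m2].mean(axis=1)
        if not m1.any() and not m2.any():
            empty.append(k)
    return ClusterAssignment(
        atac_labels=l1, rna_labels=l2,
        atac_profiles=prof1, rna_profiles=prof2,
        atac_ties=t1, rna_ties=t2, empty_clusters=empty,
    )


def joint_embed(
    H1: np.ndarray,
    H2: np.ndarray,
    seed: int = 0,
    perplexity: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint t-SNE of both modalities from their K-dimensional loadings.

    Columns of H1 and H2 are normalized to unit squared sum, concatenated
    over cells, and embedded to 2D.  Returns (coords, modality) where
    ``coords`` is (n1 + n2) x 2 and ``modality`` tags each row "atac"/"rna".
    """
    if H1.shape[0] != H2.shape[0]:
        raise ValueError("H matrices must share the factor dimension K")
    if H1.shape[0] < 2:
        raise ValueError("joint embedding needs K >= 2")

    def colnorm(H):
        s = np.sqrt((H ** 2).sum(axis=0))
        return H / np.maximum(s, _EPS)[None, :]

    X = np.hstack([colnorm(np.asarray(H1, float)), colnorm(np.asarray(H2, float))]).T
    n = X.shape[0]
    perplexity = min(perplexity, max((n - 1) / 3.0, 2.0))
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    coords = tsne.fit_transform(X)
    modality = np.array(["atac"] * H1.shape[1] + ["rna"] * H2.shape[1])
    return coords, modality
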