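"""NNDSVD-initialized NMF with split-half stability rank selection.

The solver is hierarchical alternating least squares (column-wise block
coordinate descent) on the Frobenius objective ||X - WH||_F. Every block
update is a non-negative least-squares step, so the objective is monotone
non-increasing from the deterministic NNDSVD start; the per-iteration
objective trace is recorded so that monotonicity is auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.utils.extmath import randomized_svd

from cortexlv.assembly import METRICS, StackedInput
from cortexlv.errors import ConfigError, FitError


@dataclass
class NMFModel:
    W: np.ndarray  # (n_vertices, k), spatial components
    H: np.ndarray  # (k, n_columns), subject x metric weights
    k: int
    recon_error: float  # Frobenius norm of X - WH at convergence
    objective_history: np.ndarray  # squared Frobenius objective per iteration
    iterations: int
    seed: int


@dataclass
class StabilityCurve:
    ks: np.ndarray
    stability: np.ndarray  # mean matched cosine similarity across splits
    recon_error: np.ndarray  # full-data reconstruction error per k
    error_gradient: np.ndarray  # per-k change in recon_error
    n_splits: int = 0
    seed: int = 0


def _as_matrix(X: StackedInput | np.ndarray) -> np.ndarray:
    M = X.matrix if isinstance(X, StackedInput) else np.asarray(X, dtype=float)
    if not np.isfinite(M).all():
        raise FitError("input matrix contains non-finite entries")
    if M.min() < -1e-12:
        raise FitError("NMF input must be non-negative (min-shift it first)")
    return M


# ---------------------------------------------------------------------------
# initialization


def nndsvd_init(
    X: np.ndarray, k: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative double SVD initialization (plain variant, zeros kept).

    Each leading singular triplet is split into its positive and negative
    parts; the part pair with the larger product of norms seeds the factor.
    Zeros are retained (not noise-filled) to preserve the sparsity the
    construction creates. For large inputs the truncated SVD is computed
    with a seeded randomized algorithm, so the result is deterministic for
    a given seed.
    """
    X = _as_matrix(X)
    m, n = X.shape
    if not 1 <= k <= min(m, n):
        raise ConfigError(f"k={k} out of range for a {m}x{n} matrix")
    if min(m, n) <= max(3 * k, 32):
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        U, S, Vt = U[:, :k], S[:k], Vt[:k]
    else:
        U, S, Vt = randomized_svd(
            X, n_components=k, n_iter=7, random_state=seed
        )
    W = np.zeros((m, k))
    H = np.zeros((k, n))
    # leading pair is non-negative up to sign (Perron-Frobenius)
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, k):
        u, v = U[:, j], Vt[j, :]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        nup, nun = np.linalg.norm(up), np.linalg.norm(un)
        nvp, nvn = np.linalg.norm(vp), np.linalg.norm(vn)
        if nup * nvp >= nun * nvn:
            term, uu, vv, nu, nv = nup * nvp, up, vp, nup, nvp
        else:
            term, uu, vv, nu, nv = nun * nvn, un, vn, nun, nvn
        if term > 0:
            scale = np.sqrt(S[j] * term)
            W[:, j] = scale * uu / nu
            H[j, :] = scale * vv / nv
    return W, H


# ---------------------------------------------------------------------------
# solver


def _hals_sweeps(V: np.ndarray, G: np.ndarray, F: np.ndarray, n_inner: int) -> None:
    """HALS column sweeps updating F in-place for objective ||X - F G'||.

    V = X @ G' (m, k); G = Gram of the fixed factor (k, k). The expensive
    products V and G are computed once by the caller; the cheap column
    sweeps are repeated ``n_inner`` times, each one a monotone non-negative
    least-squares step.
    """
    k = F.shape[1]
    for _ in range(n_inner):
        for j in range(k):
            denom = G[j, j]
            if denom <= 0:
                continue
            delta = (V[:, j] - F @ G[:, j]) / denom
            F[:, j] = np.maximum(F[:, j] + delta, 0.0)


def fit_nmf(
    X: StackedInput | np.ndarray,
    k: int,
    max_iter: int = 500,
    tol: float = 1e-5,
    seed: int = 0,
    n_inner: int = 8,
) -> NMFModel:
    """Fit X ~ W H by HALS from the NNDSVD start.

    Stops when the relative change of the squared-Frobenius objective falls
    below ``tol`` or after ``max_iter`` outer iterations (each outer
    iteration performs ``n_inner`` column sweeps per factor).
    """
    M = _as_matrix(X)
    if k < 1:
        raise ConfigError("k must be >= 1")
    W, H = nndsvd_init(M, k, seed=seed)
    eps = 1e-12
    norm_sq = float(np.einsum("ij,ij->", M, M))
    history: list[float] = []
    prev = None
    it = 0
    for it in range(1, max_iter + 1):
        # update W with H fixed
        _hals_sweeps(M @ H.T, H @ H.T, W, n_inner)
        # update H with W fixed (transpose problem)
        Ht = H.T
        WtX = W.T @ M
        _hals_sweeps(WtX.T, W.T @ W, Ht, n_inner)
        H = Ht.T
        # objective via Gram identity: ||X||^2 - 2<H, W'X> + tr(W'W HH')
        obj = (
            norm_sq
            - 2.0 * float(np.einsum("ij,ij->", H, WtX))
            + float(np.einsum("ij,ij->", W.T @ W, H @ H.T))
        )
        obj = max(obj, 0.0)
        history.append(obj)
        if prev is not None and prev - obj <= tol * max(prev, eps):
            break
        prev = obj
    return NMFModel(
        W=W,
        H=H,
        k=k,
        recon_error=float(np.sqrt(history[-1])),
        objective_history=np.array(history),
        iterations=it,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# component matching and stability


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    return (A.T @ B) / np.outer(na, nb)


def match_components(
    W_a: np.ndarray, W_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one component assignment by total cosine similarity.

    Returns (assignment, similarities): component j of ``W_a`` is paired
    with component ``assignment[j]`` of ``W_b``.
    """
    W_a, W_b = np.asarray(W_a, float), np.asarray(W_b, float)
    if W_a.shape != W_b.shape:
        raise ConfigError(
            f"component matrices differ in shape: {W_a.shape} vs {W_b.shape}"
        )
    sim = _cosine_matrix(W_a, W_b)
    rows, cols = linear_sum_assignment(-sim)
    order = np.argsort(rows)
    assignment = cols[order]
    similarities = sim[rows[order], assignment]
    return assignment, similarities


def split_half_stability(
    X: StackedInput,
    k_range: list[int],
    n_splits: int = 10,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    n_inner: int = 16,
) -> StabilityCurve:
    """Split-half spatial stability and full-data error across ranks.

    Subjects are partitioned at random into halves (all metric columns of a
    subject travel together), NMF is fit per half per k, and stability(k)
    is the mean matched cosine similarity between the half-specific spatial
    component matrices, averaged over splits.
    """
    if n_splits < 1:
        raise ConfigError("n_splits must be >= 1")
    subjects = X.subject_ids
    n = len(subjects)
    if n < 4:
        raise ConfigError("split-half stability needs at least 4 subjects")
    ks = sorted(int(k) for k in k_range)
    # subject -> columns lookup (metric-major layout)
    col_of = {}
    for j, (sid, _) in enumerate(X.column_index):
        col_of.setdefault(sid, []).append(j)
    rng = np.random.default_rng(seed)
    stability = np.zeros(len(ks))
    for s in range(n_splits):
        perm = rng.permutation(n)
        half_a = [subjects[i] for i in perm[: n // 2]]
        half_b = [subjects[i] for i in perm[n // 2 :]]
        cols_a = np.array([j for sid in half_a for j in col_of[sid]])
        cols_b = np.array([j for sid in half_b for j in col_of[sid]])
        Xa, Xb = X.matrix[:, cols_a], X.matrix[:, cols_b]
        for ki, k in enumerate(ks):
            fa = fit_nmf(Xa, k, max_iter=max_iter, tol=tol, seed=seed,
                         n_inner=n_inner)
            fb = fit_nmf(Xb, k, max_iter=max_iter, tol=tol, seed=seed,
                         n_inner=n_inner)
            _, sims = match_components(fa.W, fb.W)
            stability[ki] += sims.mean()
    stability /= n_splits
    recon = np.array(
        [
            fit_nmf(X.matrix, k, max_iter=max_iter, tol=tol, seed=seed,
                    n_inner=n_inner).recon_error
            for k in ks
        ]
    )
    # forward difference: the error still to be gained by growing the rank
    grad = np.zeros(len(ks))
    if len(ks) > 1:
        dk = np.diff(np.asarray(ks, float))
        grad[:-1] = np.diff(recon) / dk
        grad[-1] = grad[-2]
    return StabilityCurve(
        ks=np.asarray(ks),
        stability=stability,
        recon_error=recon,
        error_gradient=grad,
        n_splits=n_splits,
        seed=seed,
    )


def select_rank(
    curve: StabilityCurve,
    stability_margin: float = 0.05,
    gradient_frac: float = 0.25,
) -> int:
    """Pick the most parsimonious rank balancing stability and error.

    A rank qualifies when its stability is within ``stability_margin`` of
    the best stability AND the magnitude of its (forward) error gradient
    has fallen below ``gradient_frac`` of the initial gradient magnitude.
    The smallest qualifying rank — the first point where the error curve
    has flattened while stability still sits on its plateau — is returned.
    Ranks beyond the true dimensionality keep a flat error curve and can
    stay within the stability margin by chance, so parsimony is the
    correct tie-break. If the error curve is flat everywhere the gradient
    rule is uninformative and the largest rank is returned with a warning;
    if no rank qualifies, the stability argmax is returned with a warning.
    """
    ks = np.asarray(curve.ks)
    if ks.size == 0:
        raise ConfigError("empty stability curve")
    if ks.size == 1:
        return int(ks[0])
    g0 = np.abs(curve.error_gradient[0])
    if g0 == 0:
        warnings.warn("flat error curve; returning the largest candidate rank")
        return int(ks[-1])
    stab_ok = curve.stability >= curve.stability.max() - stability_margin
    grad_ok = np.abs(curve.error_gradient) <= gradient_frac * g0
    both = stab_ok & grad_ok
    if not both.any():
        warnings.warn(
            "no rank satisfies both stability and error-gradient rules; "
            "falling back to the stability argmax"
        )
        return int(ks[int(np.argmax(curve.stability))])
    return int(ks[np.nonzero(both)[0][0]])


# ---------------------------------------------------------------------------
# outputs


def assign_vertex_labels(
    W: np.ndarray, threshold_frac: float = 0.25
) -> tuple[list[set[int]], np.ndarray]:
    """Threshold components at a fraction of their max and label winners.

    Vertex v carries component c iff W[v, c] >= threshold_frac * max(W[:, c]);
    the winner label is the argmax component per vertex.
    """
    W = np.asarray(W, float)
    if W.min() < 0:
        raise ConfigError("W must be non-negative")
    col_max = W.max(axis=0)
    memberships: list[set[int]] = [set() for _ in range(W.shape[0])]
    for c in range(W.shape[1]):
        if col_max[c] == 0:
            warnings.warn(f"component {c} is all-zero; it labels no vertices")
            continue
        hit = np.nonzero(W[:, c] >= threshold_frac * col_max[c])[0]
        for v in hit:
            memberships[v].add(c)
    winners = np.argmax(W, axis=1)
    return memberships, winners


def extract_subject_metric_weights(
    model: NMFModel, column_index: list[tuple[str, str]]
) -> pd.DataFrame:
    """Reshape H to a subjects x (component, metric) weight matrix.

    Columns are ordered component-major then metric order
    (C1-CT, C1-SA, ..., C1-RD, C2-CT, ...); the reshape is lossless.
    """
    if len(column_index) != model.H.shape[1]:
        raise ConfigError("column_index does not cover all H columns")
    subjects: list[str] = []
    for sid, _ in column_index:
        if sid not in subjects:
            subjects.append(sid)
    pos = {(sid, metric): j for j, (sid, metric) in enumerate(column_index)}
    metrics = [m for m in METRICS if any(m == met for _, met in column_index)]
    k = model.k
    data = np.zeros((len(subjects), k * len(metrics)))
    cols = []
    for c in range(k):
        for mi, metric in enumerate(metrics):
            cols.append(f"C{c + 1}_{metric}")
            for i, sid in enumerate(subjects):
                data[i, c * len(metrics) + mi] = model.H[c, pos[(sid, metric)]]
    return pd.DataFrame(data, index=subjects, columns=cols)
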