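"""Behavioral PLS linking brain weights to cognitive trajectory coefficients.

Both blocks are column z-scored; the cross-block correlation matrix
C = X_z' Y_z / (n - 1) is decomposed by SVD, C = U S V'. Each latent
variable (LV) pairs a brain salience (column of U) with a cognition
salience (column of V); s_i^2 / sum(s^2) is the fraction of cross-block
covariance it explains. Inference follows the standard behavioral-PLS
recipe: permutation of one block's rows for LV significance (with
Procrustes re-alignment of the permuted saliences onto the originals) and
subject-level bootstrap for salience reliability (bootstrap ratios for
brain variables, percentile CIs on loading correlations for cognitive
variables).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cortexlv.errors import ConfigError, FitError


@dataclass
class PLSResult:
    singular_values: np.ndarray  # (L,), descending
    brain_saliences: np.ndarray  # (p, L)
    cognition_saliences: np.ndarray  # (q, L)
    cov_explained: np.ndarray  # (L,), sums to 1
    brain_scores: np.ndarray  # (n, L)
    cognition_scores: np.ndarray  # (n, L)
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    brain_labels: list[str] = field(default_factory=list)
    cognition_labels: list[str] = field(default_factory=list)
    perm_p: np.ndarray | None = None
    bsr: np.ndarray | None = None  # (p, L)
    loading_corr: np.ndarray | None = None  # (q, L)
    loading_ci: np.ndarray | None = None  # (q, L, 2)
    n_perm: int = 0
    n_boot: int = 0
    seed: int = 0


def _as_array(M) -> tuple[np.ndarray, list[str]]:
    if isinstance(M, pd.DataFrame):
        return M.to_numpy(dtype=float), [str(c) for c in M.columns]
    M = np.asarray(M, dtype=float)
    return M, [f"v{j}" for j in range(M.shape[1])]


def _zscore(M: np.ndarray, name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise FitError(f"{name}: zero-variance column(s) at index {bad.tolist()[:5]}")
    return (M - mean) / sd, mean, sd


def _svd_sign_fix(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic gauge: largest-|.| element of each cognition salience > 0."""
    for l in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, l])))
        if V[j, l] < 0:
            V[:, l] *= -1
            U[:, l] *= -1
    return U, V


def run_pls(X, Y) -> PLSResult:
    """Point-estimate PLS: z-score, cross-correlate, SVD, subject scores."""
    Xa, xlab = _as_array(X)
    Ya, ylab = _as_array(Y)
    if Xa.shape[0] != Ya.shape[0]:
        raise ConfigError("X and Y must have the same number of subjects")
    n = Xa.shape[0]
    if n <= max(Xa.shape[1], Ya.shape[1]):
        warnings.warn(
            "fewer subjects than variables; latent variables may be unstable"
        )
    Xz, xm, xs = _zscore(Xa, "brain block")
    Yz, ym, ys = _zscore(Ya, "cognition block")
    C = Xz.T @ Yz / (n - 1)
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    V = Vt.T
    U, V = _svd_sign_fix(U, V)
    total = float(np.sum(s**2))
    cov_explained = s**2 / total if total > 0 else np.zeros_like(s)
    return PLSResult(
        singular_values=s,
        brain_saliences=U,
        cognition_saliences=V,
        cov_explained=cov_explained,
        brain_scores=Xz @ U,
        cognition_scores=Yz @ V,
        x_mean=xm,
        x_sd=xs,
        y_mean=ym,
        y_sd=ys,
        brain_labels=xlab,
        cognition_labels=ylab,
    )


def compute_subject_scores(X, Y, result: PLSResult) -> tuple[np.ndarray, np.ndarray]:
    """Project (z-scored) data onto the saliences: per-subject LV scores."""
    Xa, _ = _as_array(X)
    Ya, _ = _as_array(Y)
    if Xa.shape[1] != result.brain_saliences.shape[0] or Ya.shape[1] != result.cognition_saliences.shape[0]:
        raise ConfigError("data shapes do not match the PLS result")
    Xz = (Xa - result.x_mean) / result.x_sd
    Yz = (Ya - result.y_mean) / result.y_sd
    return Xz @ result.brain_saliences, Yz @ result.cognition_saliences


def _procrustes_rotation(V_new: np.ndarray, V_ref: np.ndarray) -> np.ndarray:
    """Orthogonal Q minimizing ||V_new Q - V_ref||_F."""
    A, _, Bt = np.linalg.svd(V_new.T @ V_ref)
    return A @ Bt


def permutation_test(
    X, Y, n_perm: int = 10000, seed: int = 0, rotate: bool = False
) -> np.ndarray:
    """Permutation p-values per LV from row-permuted cognition blocks.

    p_i = (1 + #{perm s_i >= s_i}) / (n_perm + 1), comparing the i-th
    largest permuted singular value with the i-th observed one. With
    ``rotate=True`` the permuted singular values are first re-aligned to
    the original LV axes by a Procrustes rotation of the permuted
    cognition saliences; this is offered as a sensitivity option only,
    because the rotation mixes (and therefore shrinks) the leading
    permuted singular values while the observed value stays unrotated,
    which makes the test anticonservative under the null.
    """
    if n_perm < 100:
        raise ConfigError("n_perm must be >= 100 for a usable p-value floor")
    base = run_pls(X, Y)
    Xa, _ = _as_array(X)
    Ya, _ = _as_array(Y)
    n = Xa.shape[0]
    Xz = (Xa - base.x_mean) / base.x_sd
    Yz = (Ya - base.y_mean) / base.y_sd
    s_obs = base.singular_values
    V_ref = base.cognition_saliences
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(s_obs)
    XzT = Xz.T / (n - 1)
    for _ in range(n_perm):
        Cp = XzT @ Yz[rng.permutation(n)]
        Up, sp, Vpt = np.linalg.svd(Cp, full_matrices=False)
        if rotate:
            Q = _procrustes_rotation(Vpt.T, V_ref)
            s_al = np.linalg.norm(sp[:, None] * Q, axis=0)
        else:
            s_al = sp
        exceed += s_al >= s_obs
    return (1.0 + exceed) / (n_perm + 1.0)


def bootstrap_inference(
    X,
    Y,
    n_boot: int = 1000,
    seed: int = 0,
    max_redraw_frac: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bootstrap ratios (brain) and loading-correlation CIs (cognition).

    Subjects are resampled with replacement jointly in both blocks; each
    replicate's saliences are Procrustes-aligned to the originals. The BSR
    of a brain variable is its original salience over the bootstrap SE of
    the aligned salience. The loading correlation of a cognitive variable
    is its Pearson r with the LV's brain scores, with a percentile
    2.5/97.5% CI over replicates.

    Returns (bsr (p, L), loading_corr (q, L), loading_ci (q, L, 2)).
    """
    if n_boot < 100:
        raise ConfigError("n_boot must be >= 100")
    base = run_pls(X, Y)
    Xa, _ = _as_array(X)
    Ya, _ = _as_array(Y)
    n, p = Xa.shape
    q = Ya.shape[1]
    L = base.singular_values.size
    rng = np.random.default_rng(seed)
    U_ref, V_ref = base.brain_saliences, base.cognition_saliences

    u_samples = np.empty((n_boot, p, L))
    r_samples = np.empty((n_boot, q, L))
    redraws = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        Xb, Yb = Xa[idx], Ya[idx]
        sx = Xb.std(axis=0, ddof=1)
        sy = Yb.std(axis=0, ddof=1)
        if np.any(sx == 0) or np.any(sy == 0):
            redraws += 1
            if redraws > max_redraw_frac * n_boot:
                raise FitError(
                    "too many degenerate bootstrap replicates "
                    f"({redraws} redraws for {n_boot} replicates)"
                )
            continue
        Xzb = (Xb - Xb.mean(axis=0)) / sx
        Yzb = (Yb - Yb.mean(axis=0)) / sy
        Cb = Xzb.T @ Yzb / (n - 1)
        Ub, sb, Vbt = np.linalg.svd(Cb, full_matrices=False)
        Vb = Vbt.T
        Q = _procrustes_rotation(Vb, V_ref)
        u_samples[b] = Ub @ Q
        brain_scores_b = Xzb @ (Ub @ Q)
        bs = brain_scores_b - brain_scores_b.mean(axis=0)
        bs_sd = bs.std(axis=0, ddof=1)
        yc = Yzb - Yzb.mean(axis=0)
        num = yc.T @ bs / (n - 1)
        r_samples[b] = num / np.outer(yc.std(axis=0, ddof=1), bs_sd)
        b += 1

    se = u_samples.std(axis=0, ddof=1)
    se[se == 0] = np.inf
    bsr = U_ref / se

    # original loading correlations
    Xz = (Xa - base.x_mean) / base.x_sd
    Yz = (Ya - base.y_mean) / base.y_sd
    bscore = Xz @ U_ref
    bc = bscore - bscore.mean(axis=0)
    yc = Yz - Yz.mean(axis=0)
    loading = (yc.T @ bc / (n - 1)) / np.outer(
        yc.std(axis=0, ddof=1), bc.std(axis=0, ddof=1)
    )
    ci = np.stack(
        [
            np.percentile(r_samples, 2.5, axis=0),
            np.percentile(r_samples, 97.5, axis=0),
        ],
        axis=-1,
    )
    return bsr, loading, ci


def behavioral_pls(
    X,
    Y,
    n_perm: int = 10000,
    n_boot: int = 1000,
    seed: int = 0,
    rotate: bool = False,
) -> PLSResult:
    """Full analysis: point estimates, permutation p-values, bootstrap."""
    ss = np.random.SeedSequence(seed)
    s_perm, s_boot = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]
    result = run_pls(X, Y)
    result.perm_p = permutation_test(X, Y, n_perm=n_perm, seed=s_perm, rotate=rotate)
    result.bsr, result.loading_corr, result.loading_ci = bootstrap_inference(
        X, Y, n_boot=n_boot, seed=s_boot
    )
    result.n_perm = n_perm
    result.n_boot = n_boot
    result.seed = seed
    return result


def reliable_brain_variables(result: PLSResult, lv: int, cutoff: float = 1.96) -> list[str]:
    """Brain variables with |BSR| above the cutoff for one LV (0-based)."""
    if result.bsr is None:
        raise ConfigError("run bootstrap_inference first")
    hit = np.abs(result.bsr[:, lv]) > cutoff
    return [result.brain_labels[j] for j in np.nonzero(hit)[0]]


def contributing_cognitive_variables(result: PLSResult, lv: int) -> list[str]:
    """Cognitive variables whose loading-correlation CI excludes zero."""
    if result.loading_ci is None:
        raise ConfigError("run bootstrap_inference first")
    lo = result.loading_ci[:, lv, 0]
    hi = result.loading_ci[:, lv, 1]
    hit = (lo > 0) | (hi < 0)
    return [result.cognition_labels[j] for j in np.nonzero(hit)[0]]
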