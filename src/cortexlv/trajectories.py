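"""Per-test linear mixed-effects trajectories and subject coefficients.

Model for one cognitive test, subject i at time t (years since the
subject's first wave), with baseline age centered at the sample mean:

    score_it = b0 + b1*age_i + b2*t + b3*age_i*t + u0_i + u1_i*t + e_it

(u0, u1) ~ N(0, Psi) are correlated random intercepts/slopes and e_it has
a continuous AR(1) correlation structure, corr(e_is, e_it) =
phi ** |s - t| with phi per year, estimated by REML. The likelihood is
evaluated per subject with the Woodbury identity, which stays numerically
stable when the residual variance collapses (noiseless data).

Subject-specific coefficients are the fixed-effect line implied by the
subject's baseline age plus the BLUP random deviations — each subject's
model-implied intercept and slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from cortexlv.errors import ConfigError, FitError, SchemaError

FE_NAMES = ("intercept", "baseline_age", "time", "baseline_age:time")

_PHI_MAX = 0.999


@dataclass
class TrajectoryFit:
    test_name: str
    fixed_effects: dict[str, float]
    fixed_se: dict[str, float]
    random_effects: pd.DataFrame  # index subject_id, cols intercept_dev, slope_dev
    re_cov: np.ndarray  # 2x2 covariance of (intercept, slope) deviations
    serial_corr: float  # residual correlation at one typical wave gap
    phi_per_year: float
    residual_sd: float
    convergence_flag: bool
    n_subjects: int
    n_observations: int
    age_center: float
    baseline_age: pd.Series  # per-subject baseline age (uncentered)
    reml_criterion: float = np.nan
    single_obs_subjects: list[str] = field(default_factory=list)


def _design(age_c: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(t), age_c, t, age_c * t])


class _Blocks:
    """Per-test data grouped by identical within-subject time patterns."""

    def __init__(self, df: pd.DataFrame, center_age: bool):
        subjects = list(dict.fromkeys(df["subject_id"]))
        base_age = df.groupby("subject_id", sort=False)["baseline_age"].first()
        self.age_center = float(base_age.mean()) if center_age else 0.0
        self.subjects = subjects
        self.baseline_age = base_age.reindex(subjects)
        groups: dict[tuple, dict] = {}
        order: list[tuple[tuple, int]] = []
        for sid, sub in df.groupby("subject_id", sort=False):
            t = sub["time"].to_numpy(float)
            if np.any(np.diff(t) <= 0) and len(t) > 1:
                srt = np.argsort(t)
                sub = sub.iloc[srt]
                t = t[srt]
            key = tuple(np.round(t, 9))
            g = groups.setdefault(key, {"X": [], "y": [], "sids": [], "t": t})
            a = float(base_age[sid]) - self.age_center
            g["X"].append(_design(np.full_like(t, a), t))
            g["y"].append(sub["score"].to_numpy(float))
            g["sids"].append(sid)
        self.groups = []
        for key, g in groups.items():
            self.groups.append(
                {
                    "t": g["t"],
                    "X": np.stack(g["X"]),
                    "y": np.stack(g["y"]),
                    "sids": g["sids"],
                }
            )
        self.n_obs = int(sum(g["X"].shape[0] * g["X"].shape[1] for g in self.groups))


def _unpack(theta: np.ndarray, serial: bool) -> tuple[np.ndarray, float, float]:
    s0, s1 = np.exp(theta[0]), np.exp(theta[1])
    rho = np.tanh(theta[2])
    sigma = np.exp(theta[3])
    phi = _PHI_MAX / (1.0 + np.exp(-theta[4])) if serial else 0.0
    psi = np.array(
        [[s0 * s0, rho * s0 * s1], [rho * s0 * s1, s1 * s1]]
    )
    return psi, sigma, phi


def _reml_pieces(blocks: _Blocks, psi: np.ndarray, sigma: float, phi: float):
    """Accumulate RE(ML) sufficient statistics across pattern groups."""
    sig2 = sigma * sigma
    psi_inv = np.linalg.inv(psi)
    sign, logdet_psi = np.linalg.slogdet(psi)
    A = np.zeros((4, 4))
    b = np.zeros(4)
    c = 0.0
    logdet = 0.0
    cache = []
    for g in blocks.groups:
        t, X, y = g["t"], g["X"], g["y"]
        ni, gcount = len(t), X.shape[0]
        Z = np.column_stack([np.ones(ni), t])
        if phi > 0 and ni > 1:
            dt = np.abs(t[:, None] - t[None, :])
            R = phi**dt
            R_inv = np.linalg.inv(R)
            _, logdet_R = np.linalg.slogdet(R)
        else:
            R = np.eye(ni)
            R_inv = np.eye(ni)
            logdet_R = 0.0
        RZ = R_inv @ Z
        M = sig2 * psi_inv + Z.T @ RZ
        M_inv = np.linalg.inv(M)
        _, logdet_M = np.linalg.slogdet(M)
        logdet += gcount * ((ni - 2) * np.log(sig2) + logdet_R + logdet_psi + logdet_M)
        RX = np.einsum("ij,gjp->gip", R_inv, X)
        Ry = np.einsum("ij,gj->gi", R_inv, y)
        ZX = np.einsum("ja,gjp->gap", RZ, X)  # Z^T R^-1 X per subject
        Zy = np.einsum("ja,gj->ga", RZ, y)
        A += (
            np.einsum("gip,giq->pq", X, RX)
            - np.einsum("gap,ab,gbq->pq", ZX, M_inv, ZX)
        ) / sig2
        b += (
            np.einsum("gip,gi->p", X, Ry)
            - np.einsum("gap,ab,gb->p", ZX, M_inv, Zy)
        ) / sig2
        c += (
            np.einsum("gi,gi->", y, Ry)
            - np.einsum("ga,ab,gb->", Zy, M_inv, Zy)
        ) / sig2
        cache.append({"RZ": RZ, "M_inv": M_inv, "R_inv": R_inv})
    return A, b, c, logdet, cache


def _reml_criterion(theta, blocks, serial) -> float:
    psi, sigma, phi = _unpack(np.asarray(theta), serial)
    try:
        A, b, c, logdet, _ = _reml_pieces(blocks, psi, sigma, phi)
        beta = np.linalg.solve(A, b)
        quad = c - b @ beta
        _, logdet_A = np.linalg.slogdet(A)
        val = logdet + quad + logdet_A
    except np.linalg.LinAlgError:
        return 1e12
    if not np.isfinite(val):
        return 1e12
    return float(val)


def _fit_reml(blocks: _Blocks, serial: bool) -> tuple[np.ndarray, bool]:
    """Optimize the REML criterion; returns (theta, success)."""
    # moment-based starting values from per-subject OLS lines
    a_list, b_list, resid = [], [], []
    for g in blocks.groups:
        t, y = g["t"], g["y"]
        if len(t) >= 2 and np.ptp(t) > 0:
            T = np.column_stack([np.ones_like(t), t])
            coefs, *_ = np.linalg.lstsq(T, y.T, rcond=None)
            a_list.append(coefs[0])
            b_list.append(coefs[1])
            resid.append((y.T - T @ coefs).ravel())
    scale = max(float(np.std(np.concatenate([g["y"].ravel() for g in blocks.groups]))), 1e-8)
    s0 = float(np.std(np.concatenate(a_list))) if a_list else 0.5 * scale
    s1 = float(np.std(np.concatenate(b_list))) if b_list else 0.1 * scale
    sig = float(np.std(np.concatenate(resid))) if resid else 0.5 * scale
    lo, hi = np.log(1e-6 * scale), np.log(1e3 * scale)
    theta0 = np.array(
        [
            np.clip(np.log(max(s0, 1e-5 * scale)), lo, hi),
            np.clip(np.log(max(s1, 1e-5 * scale)), lo, hi),
            0.0,
            np.clip(np.log(max(sig, 1e-5 * scale)), lo, hi),
            0.0,
        ]
    )
    bounds = [(lo, hi), (lo, hi), (-2.6, 2.6), (lo, hi), (-8.0, 8.0)]
    res = minimize(
        _reml_criterion,
        theta0,
        args=(blocks, serial),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 300},
    )
    if not res.success:
        # L-BFGS-B with finite-difference gradients can stall in the line
        # search near the optimum; polish with a derivative-free pass
        res2 = minimize(
            _reml_criterion,
            res.x,
            args=(blocks, serial),
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxiter": 2000, "fatol": 1e-8, "xatol": 1e-6},
        )
        if res2.fun <= res.fun:
            res = res2
    return res.x, bool(res.success)


def fit_trajectory_model(
    long_table: pd.DataFrame,
    test_name: str,
    center_age: bool = True,
    serial_corr: bool = True,
) -> TrajectoryFit:
    """REML fit of the trajectory mixed model for one test."""
    df = long_table[long_table["test"] == test_name]
    if df.empty:
        raise ConfigError(f"no rows for test {test_name!r}")
    counts = df.groupby("subject_id", sort=False).size()
    if (counts >= 2).sum() == 0:
        raise FitError(f"{test_name}: every subject has fewer than 2 waves")
    frac2 = float((counts >= 2).mean())
    if frac2 < 0.8:
        warnings.warn(
            f"{test_name}: only {frac2:.0%} of subjects have >=2 observations"
        )
    blocks = _Blocks(df, center_age)
    Xall = np.concatenate([g["X"].reshape(-1, 4) for g in blocks.groups])
    if np.linalg.matrix_rank(Xall) < 4:
        raise FitError(f"{test_name}: rank-deficient fixed-effect design")

    # degenerate shortcut: data exactly on the fixed-effect plane
    yall = np.concatenate([g["y"].ravel() for g in blocks.groups])
    beta_ols, *_ = np.linalg.lstsq(Xall, yall, rcond=None)
    ols_resid = yall - Xall @ beta_ols
    if float(np.max(np.abs(ols_resid))) < 1e-8 * (1.0 + float(np.std(yall))):
        re = pd.DataFrame(
            0.0,
            index=pd.Index(blocks.subjects, name="subject_id"),
            columns=["intercept_dev", "slope_dev"],
        )
        return TrajectoryFit(
            test_name=test_name,
            fixed_effects=dict(zip(FE_NAMES, beta_ols)),
            fixed_se=dict(zip(FE_NAMES, np.zeros(4))),
            random_effects=re,
            re_cov=np.zeros((2, 2)),
            serial_corr=0.0,
            phi_per_year=0.0,
            residual_sd=0.0,
            convergence_flag=True,
            n_subjects=len(blocks.subjects),
            n_observations=blocks.n_obs,
            age_center=blocks.age_center,
            baseline_age=blocks.baseline_age,
            single_obs_subjects=list(counts.index[counts < 2]),
        )

    theta, ok = _fit_reml(blocks, serial_corr)
    used_serial = serial_corr
    if not ok and serial_corr:
        theta, ok = _fit_reml(blocks, serial=False)
        used_serial = False
        warnings.warn(
            f"{test_name}: serial-correlation fit did not converge; "
            "refit without serial correlation"
        )
    psi, sigma, phi = _unpack(theta, used_serial)
    A, b, c, logdet, cache = _reml_pieces(blocks, psi, sigma, phi)
    beta = np.linalg.solve(A, b)
    cov_beta = np.linalg.inv(A)
    se = np.sqrt(np.diag(cov_beta))

    # BLUPs: u_i = (sigma^2 Psi^-1 + Z' R^-1 Z)^-1 Z' R^-1 r_i
    dev_rows = {}
    for g, cc in zip(blocks.groups, cache):
        X, y = g["X"], g["y"]
        r = y - np.einsum("gip,p->gi", X, beta)
        Zr = np.einsum("ja,gj->ga", cc["RZ"], r)
        u = np.einsum("ab,gb->ga", cc["M_inv"], Zr)
        for sid, ui in zip(g["sids"], u):
            dev_rows[sid] = ui
    re = pd.DataFrame.from_dict(dev_rows, orient="index", columns=["intercept_dev", "slope_dev"])
    re = re.reindex(blocks.subjects)
    re.index.name = "subject_id"

    gaps = np.concatenate(
        [np.diff(g["t"]) for g in blocks.groups if len(g["t"]) > 1]
    )
    typical_gap = float(np.median(gaps)) if gaps.size else 1.0
    return TrajectoryFit(
        test_name=test_name,
        fixed_effects=dict(zip(FE_NAMES, beta)),
        fixed_se=dict(zip(FE_NAMES, se)),
        random_effects=re,
        re_cov=psi,
        serial_corr=float(phi**typical_gap),
        phi_per_year=float(phi),
        residual_sd=float(sigma),
        convergence_flag=ok,
        n_subjects=len(blocks.subjects),
        n_observations=blocks.n_obs,
        age_center=blocks.age_center,
        baseline_age=blocks.baseline_age,
        reml_criterion=_reml_criterion(theta, blocks, used_serial),
        single_obs_subjects=list(counts.index[counts < 2]),
    )


def extract_subject_coefficients(fit: TrajectoryFit) -> pd.DataFrame:
    """Per-subject model-implied (intercept, slope): fixed + BLUP parts."""
    if not fit.convergence_flag:
        raise FitError(f"{fit.test_name}: fit did not converge")
    age_c = fit.baseline_age.to_numpy(float) - fit.age_center
    fe = fit.fixed_effects
    intercept = (
        fe["intercept"]
        + fe["baseline_age"] * age_c
        + fit.random_effects["intercept_dev"].to_numpy()
    )
    slope = (
        fe["time"]
        + fe["baseline_age:time"] * age_c
        + fit.random_effects["slope_dev"].to_numpy()
    )
    return pd.DataFrame(
        {"intercept": intercept, "slope": slope},
        index=fit.random_effects.index,
    )


def build_cognition_matrix(
    fits: list[TrajectoryFit],
    subject_order: list[str] | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Stack per-test (intercept, slope) columns into the cognition matrix.

    Column order follows the fit list, intercept before slope per test;
    7 tests give 14 columns. Subjects missing from any fit are dropped with
    a warning (or raise under ``strict``).
    """
    if not fits:
        raise ConfigError("no trajectory fits supplied")
    coefs = {f.test_name: extract_subject_coefficients(f) for f in fits}
    common = set(coefs[fits[0].test_name].index)
    for f in fits[1:]:
        common &= set(coefs[f.test_name].index)
    if subject_order is None:
        subject_order = [s for s in coefs[fits[0].test_name].index if s in common]
    else:
        missing = [s for s in subject_order if s not in common]
        if missing:
            if strict:
                raise SchemaError(
                    f"subjects missing from at least one fit: {missing[:5]}"
                )
            warnings.warn(
                f"{len(missing)} subjects missing from at least one fit; excluded: "
                f"{missing[:5]}"
            )
            subject_order = [s for s in subject_order if s in common]
    data = {}
    for f in fits:
        sub = coefs[f.test_name].loc[subject_order]
        data[f"{f.test_name}_intercept"] = sub["intercept"].to_numpy()
        data[f"{f.test_name}_slope"] = sub["slope"].to_numpy()
    out = pd.DataFrame(data, index=pd.Index(subject_order, name="subject_id"))
    return out


def fit_all_trajectories(
    long_table: pd.DataFrame,
    tests: list[str] | None = None,
    center_age: bool = True,
    serial_corr: bool = True,
) -> list[TrajectoryFit]:
    """Fit every test present (or the given list, in order)."""
    if tests is None:
        tests = list(dict.fromkeys(long_table["test"]))
    return [
        fit_trajectory_model(long_table, t, center_age, serial_corr) for t in tests
    ]
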