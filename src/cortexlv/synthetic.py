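"""Simulated multimodal brain-cognition cohorts with known ground truth.

The generator emulates the structure of a longitudinal aging study: five
correlated vertex-wise cortical metrics built from non-negative spatial
components, subject x metric component weights coupled to latent factors,
and per-test cognitive trajectories (fixed baseline-age x time plane,
correlated random intercepts/slopes, serially correlated residuals) whose
subject coefficients covary with the same latent factors. A follow-up wave
evaluates each trajectory at a later time so latent-variable scores have a
future outcome to predict.

Latent coupling convention: ``coupling_strength`` is dimensionless — the
latent-driven part of any coupled variable is expressed in units of that
variable's idiosyncratic SD, so coupling 1 means latent and idiosyncratic
variation contribute equally.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cortexlv.assembly import (
    DIFFUSION_METRICS,
    METRICS,
    VertexMetricMatrix,
    write_mask,
    write_vertex_table,
)
from cortexlv.errors import ConfigError

#: Cognitive tests: two verbal fluencies, free-recall memory, the three
#: reasoning scores (total + subscores), and a vocabulary test. Vocabulary
#: is not administered at the follow-up wave.
TESTS = (
    "semantic_fluency",
    "lexical_fluency",
    "memory",
    "inductive_reasoning",
    "mathematical_reasoning",
    "verbal_reasoning",
    "vocabulary",
)
FOLLOWUP_TESTS = TESTS[:6]

#: Per-test mean baseline score (count-like scales differ across tests).
_TEST_INTERCEPTS = {
    "semantic_fluency": 23.0,
    "lexical_fluency": 17.0,
    "memory": 15.0,
    "inductive_reasoning": 46.0,
    "mathematical_reasoning": 25.0,
    "verbal_reasoning": 25.0,
    "vocabulary": 25.0,
}


@dataclass
class TrajectoryParams:
    """Generative mixed-model parameters for one cognitive test.

    Fixed effects follow score ~ intercept + age*age_c + time*t +
    age_time*age_c*t with baseline age centered at its sample mean;
    random intercept/slope SDs, their correlation, the residual SD and the
    adjacent-wave serial correlation of residuals complete the model.
    """

    intercept: float = 25.0
    age: float = 0.1
    time: float = -0.5
    age_time: float = -0.02
    sd_intercept: float = 2.0
    sd_slope: float = 0.2
    re_corr: float = -0.2
    sd_resid: float = 1.0
    serial_corr: float = 0.3


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort (desk-scale defaults)."""

    n_vertices: int = 2000
    n_subjects: int = 400
    k_true: int = 10
    n_lv: int = 2
    overlap_frac: float = 0.1
    noise_sd: float = 0.05
    weight_cv: float = 0.15
    coupling_strength: float = 2.0
    #: relative strength of successive latent factors: the first LV dominates
    #: the shared covariance, as in real brain-cognition panels
    lv_strengths: tuple[float, ...] = (1.0, 0.6)
    n_waves: int = 5
    wave_spacing: float = 5.0
    followup_gap: float = 5.0
    dropout_prob: float = 0.0
    round_scores: bool = True
    followup_noise_sd: float = 1.0
    scanner_levels: tuple[str, ...] = ("A", "B")
    scanner_probs: tuple[float, ...] = (0.3, 0.7)
    scanner_offset_sd: float = 0.2
    baseline_age_mean: float = 50.0
    baseline_age_sd: float = 3.0
    female_frac: float = 0.23
    trajectory_params: dict[str, TrajectoryParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k_true > self.n_vertices:
            raise ConfigError("k_true cannot exceed n_vertices")
        if not 0 <= self.overlap_frac < 1:
            raise ConfigError("overlap_frac must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.coupling_strength < 0:
            raise ConfigError("coupling_strength must be non-negative")
        if self.n_waves < 2:
            raise ConfigError("n_waves must be at least 2")
        if len(self.lv_strengths) < self.n_lv:
            self.lv_strengths = tuple(self.lv_strengths) + tuple(
                0.4 for _ in range(self.n_lv - len(self.lv_strengths))
            )
        for test in TESTS:
            self.trajectory_params.setdefault(
                test, TrajectoryParams(intercept=_TEST_INTERCEPTS[test])
            )


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream recovery checks."""

    spatial_components: np.ndarray  # (n_vertices, k_true), >= 0
    metric_weights: np.ndarray  # (k_true, n_subjects * n_metrics), >= 0
    latent_factors: np.ndarray  # (n_subjects, n_lv), standardized
    brain_saliences: np.ndarray  # (k_true * n_metrics, n_lv), unit columns
    cognition_saliences: np.ndarray  # (2 * n_tests, n_lv), unit columns
    trajectory_params: dict[str, TrajectoryParams]
    scanner_offsets: dict[str, dict[str, float]]
    subject_ids: list[str]
    scanner_labels: list[str]
    baseline_age: np.ndarray
    config: CohortConfig
    seed: int
    true_intercepts: dict[str, np.ndarray] = field(default_factory=dict)
    true_slopes: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def brain_weights(self) -> pd.DataFrame:
        """Planted subject x (component, metric) weights, column order
        component-major (C1-CT ... C1-RD, C2-CT, ...)."""
        n = len(self.subject_ids)
        k = self.spatial_components.shape[1]
        cols, data = [], []
        for c in range(k):
            for mi, metric in enumerate(METRICS):
                cols.append(f"C{c + 1}_{metric}")
                data.append(self.metric_weights[c, mi * n : (mi + 1) * n])
        return pd.DataFrame(
            np.column_stack(data), index=self.subject_ids, columns=cols
        )


@dataclass
class SimulatedCohort:
    metric_tables: dict[str, VertexMetricMatrix]
    cognitive_long_table: pd.DataFrame
    followup_table: pd.DataFrame
    covariates: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# components and vertex data


def generate_components(
    n_vertices: int, k_true: int, overlap_frac: float, seed: int
) -> np.ndarray:
    """Non-negative spatial components: one dominant parcel per vertex.

    Vertices are split into k contiguous parcels with mildly varying
    positive amplitudes; a fraction ``overlap_frac`` of vertices receives a
    secondary loading on a neighbouring component.
    """
    if not 1 <= k_true <= n_vertices:
        raise ConfigError("need n_vertices >= k_true >= 1")
    if not 0 <= overlap_frac < 1:
        raise ConfigError("overlap_frac must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    W = np.zeros((n_vertices, k_true))
    parcels = np.array_split(np.arange(n_vertices), k_true)
    for c, idx in enumerate(parcels):
        W[idx, c] = rng.uniform(0.8, 1.2, size=len(idx))
    n_overlap = int(np.floor(overlap_frac * n_vertices))
    if n_overlap > 0 and k_true > 1:
        chosen = rng.choice(n_vertices, size=n_overlap, replace=False)
        for v in chosen:
            primary = int(np.argmax(W[v]))
            other = (primary + rng.integers(1, k_true)) % k_true
            W[v, other] = rng.uniform(0.3, 0.6)
    return W


def _standardize_columns(F: np.ndarray) -> np.ndarray:
    return (F - F.mean(axis=0)) / F.std(axis=0)


def _planted_brain_saliences(k: int, n_lv: int) -> np.ndarray:
    """Unit-norm brain salience vectors over (component, metric) variables.

    Each latent factor loads on its own half of the components, with a
    metric-specific sign fingerprint (structure up / diffusivity down and
    vice versa), so factors occupy disjoint, orthogonal supports.
    """
    p = k * len(METRICS)
    A = np.zeros((p, n_lv))
    sign_patterns = [
        np.array([1.0, 1.0, -1.0, 1.0, -1.0]),  # CT,SA,FA up; MD,RD down
        np.array([1.0, -1.0, 1.0, -1.0, 1.0]),
    ]
    comp_groups = np.array_split(np.arange(k), n_lv)
    for l in range(n_lv):
        pattern = sign_patterns[l % len(sign_patterns)]
        for c in comp_groups[l]:
            A[c * len(METRICS) : (c + 1) * len(METRICS), l] = pattern
        A[:, l] /= np.linalg.norm(A[:, l])
    return A


def _planted_cognition_saliences(n_lv: int) -> np.ndarray:
    """Unit-norm cognition saliences over (intercept, slope) x test columns.

    Factor 1 is a global severity axis (lower baselines, faster decline on
    every test); factor 2 trades fluency/memory decline against reasoning
    improvement, orthogonal to factor 1 by construction.
    """
    q = 2 * len(TESTS)
    C = np.zeros((q, n_lv))
    # columns ordered test-major: (test0 intercept, test0 slope, test1 ...)
    c1 = np.zeros(q)
    for t in range(len(TESTS)):
        c1[2 * t] = -0.5
        c1[2 * t + 1] = -1.0
    C[:, 0] = c1 / np.linalg.norm(c1)
    if n_lv >= 2:
        c2 = np.zeros(q)
        for t, s in enumerate((-1.0, -1.0, -1.0, 1.0, 1.0, 1.0, 0.0)):
            c2[2 * t] = 0.5 * s
            c2[2 * t + 1] = 1.0 * s
        C[:, 1] = c2 / np.linalg.norm(c2)
    if n_lv > 2:
        rng = np.random.default_rng(0)
        for l in range(2, n_lv):
            v = rng.standard_normal(q)
            v -= C[:, :l] @ (C[:, :l].T @ v)
            C[:, l] = v / np.linalg.norm(v)
    return C


def make_ground_truth(config: CohortConfig, seed: int) -> GroundTruth:
    """Draw all planted quantities for one cohort."""
    ss = np.random.SeedSequence(seed)
    s_comp, s_lat, s_wt, s_subj = [int(s.generate_state(1)[0] % 2**31)
                                   for s in ss.spawn(4)]
    cfg = config
    W = generate_components(cfg.n_vertices, cfg.k_true, cfg.overlap_frac, s_comp)

    rng_lat = np.random.default_rng(s_lat)
    F = _standardize_columns(
        rng_lat.standard_normal((cfg.n_subjects, cfg.n_lv))
    )
    A = _planted_brain_saliences(cfg.k_true, cfg.n_lv)
    C = _planted_cognition_saliences(cfg.n_lv)

    # subject x (component, metric) weights, multiplicative around a base
    rng_wt = np.random.default_rng(s_wt)
    p = cfg.k_true * len(METRICS)
    base = rng_wt.uniform(0.8, 1.2, size=p)
    idio = rng_wt.standard_normal((cfg.n_subjects, p))
    strengths = np.asarray(cfg.lv_strengths[: cfg.n_lv])
    latent = cfg.coupling_strength * ((F * strengths) @ A.T)
    B = base * (1.0 + cfg.weight_cv * (idio + latent))
    B = np.maximum(B, 1e-3)

    # reorder to H: (k, n_subjects * n_metrics), metric-major columns
    n = cfg.n_subjects
    H = np.zeros((cfg.k_true, n * len(METRICS)))
    for c in range(cfg.k_true):
        for mi in range(len(METRICS)):
            H[c, mi * n : (mi + 1) * n] = B[:, c * len(METRICS) + mi]

    rng_subj = np.random.default_rng(s_subj)
    subject_ids = [f"S{i:04d}" for i in range(n)]
    scanner_labels = list(
        rng_subj.choice(cfg.scanner_levels, size=n, p=cfg.scanner_probs)
    )
    baseline_age = rng_subj.normal(cfg.baseline_age_mean, cfg.baseline_age_sd, n)
    offsets = {
        metric: {
            level: (0.0 if li == 0
                    else float(rng_subj.normal(0.0, cfg.scanner_offset_sd)))
            for li, level in enumerate(cfg.scanner_levels)
        }
        for metric in METRICS
    }
    return GroundTruth(
        spatial_components=W,
        metric_weights=H,
        latent_factors=F,
        brain_saliences=A,
        cognition_saliences=C,
        trajectory_params=dict(cfg.trajectory_params),
        scanner_offsets=offsets,
        subject_ids=subject_ids,
        scanner_labels=scanner_labels,
        baseline_age=baseline_age,
        config=cfg,
        seed=seed,
    )


def generate_vertex_data(
    truth: GroundTruth, noise_sd: float, seed: int
) -> dict[str, VertexMetricMatrix]:
    """Vertex tables per metric: W @ H_block + scanner offset + noise."""
    if noise_sd < 0:
        raise ConfigError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n = len(truth.subject_ids)
    n_vertices = truth.spatial_components.shape[0]
    scanners = np.asarray(truth.scanner_labels)
    mask = np.arange(n_vertices)
    out: dict[str, VertexMetricMatrix] = {}
    for mi, metric in enumerate(METRICS):
        block = truth.metric_weights[:, mi * n : (mi + 1) * n]
        values = truth.spatial_components @ block
        offs = truth.scanner_offsets.get(metric, {})
        offset_row = np.array([offs.get(s, 0.0) for s in scanners])
        values = values + offset_row[None, :]
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=values.shape)
        if metric in DIFFUSION_METRICS:
            values = np.maximum(values, 0.0)
        out[metric] = VertexMetricMatrix(
            metric_name=metric,
            values=values,
            subject_ids=list(truth.subject_ids),
            scanner_labels=list(truth.scanner_labels),
            mask=mask.copy(),
        )
    return out


# ---------------------------------------------------------------------------
# cognition


def _ar1_corr(times: np.ndarray, rho_adjacent: float, spacing: float) -> np.ndarray:
    """Continuous AR(1) correlation with rho_adjacent at one wave spacing."""
    if rho_adjacent <= 0:
        return np.eye(len(times))
    phi_year = rho_adjacent ** (1.0 / spacing)
    dt = np.abs(times[:, None] - times[None, :])
    return phi_year**dt


def subject_trajectory_coefficients(
    truth: GroundTruth, coupling_strength: float, seed: int
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Planted per-subject (intercept, slope) for every test.

    intercept_i = fe.intercept + fe.age * age_c_i + sd_int * (eta0 + coupling*g_int)
    slope_i     = fe.time + fe.age_time * age_c_i + sd_slope * (eta1 + coupling*g_slope)
    with (eta0, eta1) correlated idiosyncratic deviations and g the latent
    contribution from the planted cognition saliences.
    """
    if coupling_strength < 0:
        raise ConfigError("coupling_strength must be non-negative")
    rng = np.random.default_rng(seed)
    cfg = truth.config
    F = truth.latent_factors * np.asarray(cfg.lv_strengths[: cfg.n_lv])
    C = truth.cognition_saliences
    age_c = truth.baseline_age - truth.baseline_age.mean()
    n = len(truth.subject_ids)
    intercepts: dict[str, np.ndarray] = {}
    slopes: dict[str, np.ndarray] = {}
    for t, test in enumerate(TESTS):
        par = truth.trajectory_params[test]
        cov = np.array(
            [
                [1.0, par.re_corr],
                [par.re_corr, 1.0],
            ]
        )
        eta = rng.multivariate_normal(np.zeros(2), cov, size=n)
        g_int = F @ C[2 * t, :]
        g_slope = F @ C[2 * t + 1, :]
        intercepts[test] = (
            par.intercept
            + par.age * age_c
            + par.sd_intercept * (eta[:, 0] + coupling_strength * g_int)
        )
        slopes[test] = (
            par.time
            + par.age_time * age_c
            + par.sd_slope * (eta[:, 1] + coupling_strength * g_slope)
        )
    return intercepts, slopes


def generate_cognitive_panel(
    truth: GroundTruth,
    n_waves: int,
    wave_spacing: float,
    coupling_strength: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format cognitive table plus a follow-up wave per subject.

    Observed score at wave j: intercept_i + slope_i * t_j + AR(1) residual;
    scores are floored at 0 and, when configured, rounded to integers to
    mimic count-like tests. The follow-up score evaluates the trajectory at
    the follow-up time plus independent noise (no serial tie to the panel).
    """
    if n_waves < 2:
        raise ConfigError("n_waves must be at least 2")
    if coupling_strength < 0:
        raise ConfigError("coupling_strength must be non-negative")
    cfg = truth.config
    ss = np.random.SeedSequence(seed)
    s_coef, s_resid, s_drop, s_fup = [
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)
    ]
    intercepts, slopes = subject_trajectory_coefficients(
        truth, coupling_strength, s_coef
    )
    truth.true_intercepts = intercepts
    truth.true_slopes = slopes

    n = len(truth.subject_ids)
    times = np.arange(n_waves) * wave_spacing
    followup_time = (n_waves - 1) * wave_spacing + cfg.followup_gap

    rng_resid = np.random.default_rng(s_resid)
    rng_drop = np.random.default_rng(s_drop)
    rng_fup = np.random.default_rng(s_fup)

    # monotone dropout: once a subject misses a wave they stay missing
    n_obs = np.full(n, n_waves)
    if cfg.dropout_prob > 0:
        for i in range(n):
            for j in range(1, n_waves):
                if rng_drop.random() < cfg.dropout_prob:
                    n_obs[i] = j
                    break

    rows = []
    fup_rows = {"subject_id": list(truth.subject_ids)}
    for test in TESTS:
        par = truth.trajectory_params[test]
        R = _ar1_corr(times, par.serial_corr, wave_spacing)
        L = np.linalg.cholesky(R + 1e-12 * np.eye(n_waves))
        eps = (
            par.sd_resid * (rng_resid.standard_normal((n, n_waves)) @ L.T)
            if par.sd_resid > 0
            else np.zeros((n, n_waves))
        )
        scores = intercepts[test][:, None] + slopes[test][:, None] * times[None, :]
        scores = scores + eps
        scores = np.maximum(scores, 0.0)
        if cfg.round_scores:
            scores = np.rint(scores)
        for i, sid in enumerate(truth.subject_ids):
            for j in range(n_obs[i]):
                rows.append(
                    (
                        sid,
                        j,
                        truth.baseline_age[i],
                        times[j],
                        test,
                        scores[i, j],
                    )
                )
        if test in FOLLOWUP_TESTS:
            fup = intercepts[test] + slopes[test] * followup_time
            if cfg.followup_noise_sd > 0:
                fup = fup + rng_fup.normal(0.0, cfg.followup_noise_sd, n)
            fup = np.maximum(fup, 0.0)
            if cfg.round_scores:
                fup = np.rint(fup)
            fup_rows[test] = fup
    long_table = pd.DataFrame(
        rows,
        columns=["subject_id", "wave", "baseline_age", "time", "test", "score"],
    )
    followup = pd.DataFrame(fup_rows)
    followup["time"] = followup_time
    return long_table, followup


def _generate_covariates(truth: GroundTruth, seed: int) -> pd.DataFrame:
    cfg = truth.config
    rng = np.random.default_rng(seed)
    n = len(truth.subject_ids)
    imaging_offset = (cfg.n_waves - 1) * cfg.wave_spacing + cfg.followup_gap / 2
    age_at_imaging = truth.baseline_age + imaging_offset
    sex = (rng.random(n) < cfg.female_frac).astype(int)
    education = np.clip(np.rint(rng.normal(14.2, 3.0, n)), 8, 25)
    moca = np.clip(np.rint(rng.normal(27.3, 2.2, n)), 15, 30)
    return pd.DataFrame(
        {
            "subject_id": truth.subject_ids,
            "age_at_imaging": age_at_imaging,
            "sex": sex,
            "education": education,
            "moca": moca,
            "scanner": truth.scanner_labels,
        }
    )


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> SimulatedCohort:
    """Generate a complete simulated study from one master seed."""
    cfg = config or CohortConfig()
    ss = np.random.SeedSequence(seed)
    s_truth, s_vertex, s_cog, s_cov = [
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)
    ]
    truth = make_ground_truth(cfg, s_truth)
    metric_tables = generate_vertex_data(truth, cfg.noise_sd, s_vertex)
    long_table, followup = generate_cognitive_panel(
        truth, cfg.n_waves, cfg.wave_spacing, cfg.coupling_strength, s_cog
    )
    covariates = _generate_covariates(truth, s_cov)
    return SimulatedCohort(
        metric_tables=metric_tables,
        cognitive_long_table=long_table,
        followup_table=followup,
        covariates=covariates,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# disk output


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Write a cohort as plain-text tables plus a ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for metric, table in cohort.metric_tables.items():
        write_vertex_table(table, outdir / f"{metric.lower()}.tsv")
    first = next(iter(cohort.metric_tables.values()))
    write_mask(first.mask, outdir / "mask.txt")
    pd.DataFrame(
        {"subject_id": first.subject_ids, "scanner": first.scanner_labels}
    ).to_csv(outdir / "subjects.csv", index=False)
    cohort.cognitive_long_table.to_csv(outdir / "cognition.csv", index=False)
    cohort.followup_table.to_csv(outdir / "followup.csv", index=False)
    cohort.covariates.to_csv(outdir / "covariates.csv", index=False)
    truth = cohort.truth
    sidecar = {
        "seed": truth.seed,
        "config": {
            **{k: v for k, v in asdict(truth.config).items()
               if k != "trajectory_params"},
            "trajectory_params": {
                t: asdict(p) for t, p in truth.config.trajectory_params.items()
            },
        },
        "spatial_components": truth.spatial_components.tolist(),
        "metric_weights": truth.metric_weights.tolist(),
        "latent_factors": truth.latent_factors.tolist(),
        "brain_saliences": truth.brain_saliences.tolist(),
        "cognition_saliences": truth.cognition_saliences.tolist(),
        "scanner_offsets": truth.scanner_offsets,
        "baseline_age": truth.baseline_age.tolist(),
        "true_intercepts": {t: v.tolist() for t, v in truth.true_intercepts.items()},
        "true_slopes": {t: v.tolist() for t, v in truth.true_slopes.items()},
    }
    (outdir / "truth.json").write_text(json.dumps(sidecar))
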