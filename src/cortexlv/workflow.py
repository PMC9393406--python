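"""End-to-end orchestration: cohort tables in, prediction report out."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cortexlv import assembly, nmf, pls, prediction, synthetic, trajectories


@dataclass
class PipelineResult:
    stacked: assembly.StackedInput
    nmf_model: nmf.NMFModel
    brain_weights: pd.DataFrame
    cognition_matrix: pd.DataFrame
    pls_result: pls.PLSResult
    lv_scores: pd.DataFrame  # cognition scores for the retained LVs
    prediction_report: pd.DataFrame | None


def retained_lv_scores(
    result: pls.PLSResult,
    index,
    alpha: float = 0.05,
    max_lvs: int = 2,
) -> pd.DataFrame:
    """Cognition scores of the significant LVs (perm p < alpha), capped."""
    if result.perm_p is None:
        keep = list(range(min(max_lvs, result.cognition_scores.shape[1])))
    else:
        keep = [l for l in range(len(result.perm_p)) if result.perm_p[l] < alpha]
        keep = keep[:max_lvs]
        if not keep:
            keep = [0]
    return pd.DataFrame(
        result.cognition_scores[:, keep],
        index=index,
        columns=[f"LV{l + 1}" for l in keep],
    )


def analyze_cohort(
    cohort: synthetic.SimulatedCohort,
    k: int | None = None,
    k_range: list[int] | None = None,
    n_splits: int = 10,
    n_perm: int = 500,
    n_boot: int = 500,
    seed: int = 0,
    predict: bool = True,
) -> PipelineResult:
    """Run the full analysis on a cohort.

    If ``k`` is None the rank is selected by split-half stability over
    ``k_range``; otherwise the scan is skipped and ``k`` is used directly.
    """
    tables = [cohort.metric_tables[m] for m in assembly.METRICS]
    stacked = assembly.assemble(tables)
    if k is None:
        if k_range is None:
            k_range = list(range(4, 17, 2))
        curve = nmf.split_half_stability(
            stacked, k_range, n_splits=n_splits, seed=seed
        )
        k = nmf.select_rank(curve)
    model = nmf.fit_nmf(stacked, k=k, seed=seed)
    X = nmf.extract_subject_metric_weights(model, stacked.column_index)
    fits = trajectories.fit_all_trajectories(
        cohort.cognitive_long_table, tests=list(synthetic.TESTS)
    )
    Y = trajectories.build_cognition_matrix(fits, subject_order=list(X.index))
    result = pls.behavioral_pls(X, Y, n_perm=n_perm, n_boot=n_boot, seed=seed)
    lv = retained_lv_scores(result, Y.index)
    report = None
    if predict:
        report = prediction.fit_prediction_model(
            cohort.followup_table, lv, cohort.covariates
        )
    return PipelineResult(
        stacked=stacked,
        nmf_model=model,
        brain_weights=X,
        cognition_matrix=Y,
        pls_result=result,
        lv_scores=lv,
        prediction_report=report,
    )


def planted_followup_coupling(
    truth: synthetic.GroundTruth,
) -> pd.DataFrame:
    """Planted latent effect of each factor on each follow-up test.

    The latent part of a follow-up score per unit of factor l is
    sd_int * c_l[intercept] + T_followup * sd_slope * c_l[slope]; its sign
    is what a correctly recovered LV coefficient should reproduce.
    """
    cfg = truth.config
    t_fu = (cfg.n_waves - 1) * cfg.wave_spacing + cfg.followup_gap
    C = truth.cognition_saliences
    rows = {}
    for ti, test in enumerate(synthetic.TESTS):
        if test not in synthetic.FOLLOWUP_TESTS:
            continue
        par = truth.trajectory_params[test]
        rows[test] = [
            C[2 * ti, l] * par.sd_intercept
            + t_fu * C[2 * ti + 1, l] * par.sd_slope
            for l in range(C.shape[1])
        ]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"LV{l+1}" for l in range(C.shape[1])]
    )


def align_lv_scores_to_truth(
    lv_scores: pd.DataFrame, truth: synthetic.GroundTruth
) -> pd.DataFrame:
    """Flip LV score signs so each correlates positively with its factor.

    The SVD sign gauge is arbitrary relative to the generator's latent
    factors; recovery checks compare against the planted couplings after
    this alignment.
    """
    F = truth.latent_factors
    out = lv_scores.copy()
    for j, col in enumerate(out.columns):
        if j < F.shape[1]:
            r = np.corrcoef(out[col].to_numpy(), F[:, j])[0, 1]
            if r < 0:
                out[col] = -out[col]
    return out
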