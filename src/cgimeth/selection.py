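"""The β-value biomarker-selection cascade with dual-cohort AUC gating.

A candidate CpG island passes three gates:

1. its mean β in normal/peritumoural samples is *lower than* 0.25 (strict);
2. β exceeds 0.45 in *at least* 75% of tumours while β exceeds 0.25 in
   *not more than* 25% of normals (fractions over present values);
3. the Mann–Whitney AUC separating tumours from normals is *higher than*
   0.95 in the discovery cohort **and** in the validation cohort.

Comparison strictness follows the published wording literally: "lower
than"/"higher than" are strict, "at least"/"not more than" are inclusive.
AUC direction is fixed with tumour as case (hypermethylation scores
higher); an AUC below 0.5 is reported as-is, never flipped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import RunConfig
from .errors import ComputationError, ValidationError
from .io import BetaMatrix, CGIKey

__all__ = [
    "auc",
    "group_means",
    "stage1_filter",
    "stage2_filter",
    "cohort_auc",
    "select_biomarkers",
    "select_from_summary",
]


def auc(case_scores, control_scores) -> float:
    """Mann–Whitney AUC: P(case > control) with ties counted 1/2.

    Equals the trapezoidal area under the empirical ROC curve. Computed
    from midranks, so it is exact for tied data and invariant under any
    strictly monotone transform of the pooled scores.
    """
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ComputationError("AUC needs at least one case and one control score")
    if np.isnan(cases).any() or np.isnan(controls).any():
        raise ComputationError("AUC scores must not contain NaN")
    pooled = np.concatenate([cases, controls])
    ranks = rankdata(pooled)  # midranks
    r_case = ranks[: cases.size].sum()
    n1, n0 = cases.size, controls.size
    u = r_case - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def group_means(matrix: BetaMatrix, cohort: str | None = None,
                missingness_cap: float = 0.20) -> pd.DataFrame:
    """Per-CGI arithmetic mean β by group, over present values only.

    Returns a frame indexed like the matrix with columns ``mean_tumour``,
    ``mean_normal``, per-group present counts, the missing fraction and a
    ``computable`` flag. A CGI whose missing fraction exceeds
    ``missingness_cap``, or with a group left without any present value,
    is marked not computable (NaN means) rather than dropped.
    """
    rows = []
    n_samples = len(matrix.samples.samples_in(cohort=cohort))
    for cgi in matrix.cgis:
        tum = matrix.group_values(cgi, "tumour", cohort)
        nor = matrix.group_values(cgi, "normal", cohort)
        n_present = tum.size + nor.size
        frac_missing = 1.0 - n_present / n_samples if n_samples else 1.0
        computable = (
            tum.size > 0 and nor.size > 0 and frac_missing <= missingness_cap
        )
        rows.append(
            {
                "mean_tumour": tum.mean() if computable else np.nan,
                "mean_normal": nor.mean() if computable else np.nan,
                "n_tumour": tum.size,
                "n_normal": nor.size,
                "frac_missing": frac_missing,
                "computable": computable,
            }
        )
    return pd.DataFrame(rows, index=matrix.cgis)


def stage1_filter(means: pd.DataFrame, t1: float = 0.25) -> pd.Series:
    """Low-normal-methylation gate: pass iff mean_normal < t1 (strict).

    Incomputable CGIs fail.
    """
    ok = means["computable"] & (means["mean_normal"] < t1)
    return ok.astype(bool)


def stage2_filter(
    matrix: BetaMatrix,
    cohort: str | None = None,
    t_high: float = 0.45,
    f_tum: float = 0.75,
    t_low: float = 0.25,
    f_norm: float = 0.25,
) -> pd.Series:
    """Prevalence gate.

    Pass iff the fraction of tumours with β > t_high is >= f_tum **and**
    the fraction of normals with β > t_low is <= f_norm, both fractions
    computed over present (non-missing) values. A group with zero present
    values fails.
    """
    flags = {}
    for cgi in matrix.cgis:
        tum = matrix.group_values(cgi, "tumour", cohort)
        nor = matrix.group_values(cgi, "normal", cohort)
        if tum.size == 0 or nor.size == 0:
            flags[cgi] = False
            continue
        frac_tum = np.mean(tum > t_high)
        frac_nor = np.mean(nor > t_low)
        flags[cgi] = bool(frac_tum >= f_tum and frac_nor <= f_norm)
    return pd.Series(flags, index=matrix.cgis, dtype=bool)


def cohort_auc(matrix: BetaMatrix, cohort: str | None = None) -> pd.Series:
    """Per-CGI tumour-vs-normal AUC (NaN where a group has no present values)."""
    out = {}
    for cgi in matrix.cgis:
        tum = matrix.group_values(cgi, "tumour", cohort)
        nor = matrix.group_values(cgi, "normal", cohort)
        if tum.size == 0 or nor.size == 0:
            out[cgi] = np.nan
        else:
            out[cgi] = auc(tum, nor)
    return pd.Series(out, index=matrix.cgis, dtype=float)


def _cohort_columns(matrix: BetaMatrix, tag: str, config: RunConfig) -> pd.DataFrame:
    means = group_means(matrix, missingness_cap=config.missingness_cap)
    aucs = cohort_auc(matrix)
    frame = pd.DataFrame(
        {
            f"mean_beta_tumour_{tag}": means["mean_tumour"],
            f"mean_beta_normal_{tag}": means["mean_normal"],
            f"delta_beta_{tag}": means["mean_tumour"] - means["mean_normal"],
            f"auc_{tag}": aucs,
        },
        index=matrix.cgis,
    )
    stage1 = stage1_filter(means, config.stage1_max_normal_mean)
    stage2 = stage2_filter(
        matrix,
        None,
        config.stage2_beta_high,
        config.stage2_min_tumour_frac,
        config.stage2_beta_low,
        config.stage2_max_normal_frac,
    )
    frame[f"pass_stage1_{tag}"] = stage1
    frame[f"pass_stage2_{tag}"] = stage2
    return frame


def select_biomarkers(
    discovery: BetaMatrix,
    validation: BetaMatrix,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Run the full cascade and return one record per CGI, sorted by key.

    Stage 1–2 gating uses the discovery cohort by default
    (``stage_cohort_policy='discovery_only'``) or the intersection of both
    cohorts (``'both_cohorts_intersect'``); the AUC gate always requires
    AUC > ``auc_min`` in *both* cohorts. ``selected`` implies every pass
    flag is true.
    """
    config = config or RunConfig()
    disc_keys = set(discovery.cgis)
    val_keys = set(validation.cgis)
    if disc_keys != val_keys:
        diff = sorted(str(k) for k in disc_keys.symmetric_difference(val_keys))
        raise ValidationError(f"CGI universes disagree; symmetric difference: {diff}")

    disc = _cohort_columns(discovery, "discovery", config)
    val = _cohort_columns(validation, "validation", config)
    records = disc.join(val)

    if config.stage_cohort_policy == "discovery_only":
        pass1 = records["pass_stage1_discovery"]
        pass2 = records["pass_stage2_discovery"]
    else:  # both_cohorts_intersect
        pass1 = records["pass_stage1_discovery"] & records["pass_stage1_validation"]
        pass2 = records["pass_stage2_discovery"] & records["pass_stage2_validation"]

    pass_auc = (records["auc_discovery"] > config.auc_min) & (
        records["auc_validation"] > config.auc_min
    )
    records["pass_stage1"] = pass1
    records["pass_stage2"] = pass2
    # cascade: later gates only apply to survivors of earlier ones
    records["pass_auc"] = pass_auc.fillna(False) & pass1 & pass2
    records["selected"] = records["pass_stage1"] & records["pass_stage2"] & records["pass_auc"]
    records["gene"] = [k.gene for k in records.index]
    return records.sort_index()


def select_from_summary(table: pd.DataFrame, auc_min: float = 0.95) -> pd.DataFrame:
    """Apply the dual-cohort AUC gate to precomputed per-CGI AUC columns.

    Supports worked examples where published AUCs (rather than raw β
    matrices) are the input. Expects columns ``auc_discovery`` and
    ``auc_validation``; returns the table with a ``selected`` flag.
    """
    out = table.copy()
    out["selected"] = (out["auc_discovery"] > auc_min) & (
        out["auc_validation"] > auc_min
    )
    return out
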