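"""Relative expression (ΔΔCt), Welch's t-test and regulation calls.

Transcript abundance is expressed relative to the endogenous reference
gene TFRC: ΔCt = gene mean Ct − TFRC mean Ct, so a *larger* ΔCt means
*lower* expression. For a matched tumour/normal pair
ΔΔCt = ΔCt_tumour − ΔCt_normal and the fold change is 2^(−ΔΔCt).

Group comparisons use Welch's unequal-variance t-test with
Welch–Satterthwaite degrees of freedom, run on ΔCt values (or on
normalized band intensities for protein), never on fold changes, whose
ratio distribution is skewed. A gene is called up-/downregulated only
when the two-sided p-value clears alpha (default 0.05); otherwise the
groups are reported as similar.

Protein bands are normalized lane-wise to the NaK-ATPase loading control
and duplicate lanes are averaged per sample before testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, ValidationError
from .io import BandMeasurement
from .methylight import CtSummary

__all__ = [
    "ExpressionRecord",
    "WelchResult",
    "delta_ct",
    "fold_change",
    "welch_t",
    "classify_regulation",
    "normalize_bands",
]


@dataclass(frozen=True)
class ExpressionRecord:
    """ΔΔCt bookkeeping for one matched pair and gene."""

    pair_id: str
    gene: str
    delta_ct_tumour: float
    delta_ct_normal: float
    delta_delta_ct: float
    fold_change: float


@dataclass(frozen=True)
class WelchResult:
    """Welch's two-sample t-test summary.

    ``df`` is the fractional Welch–Satterthwaite approximation.
    ``degenerate`` marks the zero-variance corner cases where the t
    statistic is not well defined.
    """

    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    var_a: float
    var_b: float
    n_a: int
    n_b: int
    degenerate: bool = False


def delta_ct(gene_summary: CtSummary, reference_summary: CtSummary) -> float | None:
    """ΔCt = gene mean Ct − reference mean Ct; ``None`` if the gene was
    not detected."""
    if not reference_summary.detected or reference_summary.mean_ct is None:
        raise ComputationError("reference gene undetected: ΔCt undefined")
    if not gene_summary.detected or gene_summary.mean_ct is None:
        return None
    return gene_summary.mean_ct - reference_summary.mean_ct


def fold_change(
    delta_ct_tumour: float, delta_ct_normal: float, pair_id: str = "", gene: str = ""
) -> ExpressionRecord:
    """ΔΔCt = ΔCt_tumour − ΔCt_normal; fold change = 2^(−ΔΔCt)."""
    ddct = delta_ct_tumour - delta_ct_normal
    return ExpressionRecord(
        pair_id=pair_id,
        gene=gene,
        delta_ct_tumour=delta_ct_tumour,
        delta_ct_normal=delta_ct_normal,
        delta_delta_ct=ddct,
        fold_change=2.0 ** (-ddct),
    )


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance t-test (two-sided).

    t = (x̄_a − x̄_b) / sqrt(s²_a/n_a + s²_b/n_b) with Welch–Satterthwaite
    degrees of freedom. Degenerate inputs (both sample variances zero)
    return t = 0, p = 1 when the means agree and p = 0 (flagged) when they
    differ.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("welch_t needs at least 2 observations per group")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("welch_t input contains NaN")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    var_a = float(a.var(ddof=1))
    var_b = float(b.var(ddof=1))
    na, nb = a.size, b.size
    va, vb = var_a / na, var_b / nb
    denom = va + vb
    if denom == 0.0:
        same = mean_a == mean_b
        return WelchResult(
            t=0.0 if same else math.inf * math.copysign(1.0, mean_a - mean_b),
            df=float(na + nb - 2),
            p=1.0 if same else 0.0,
            mean_a=mean_a,
            mean_b=mean_b,
            var_a=var_a,
            var_b=var_b,
            n_a=na,
            n_b=nb,
            degenerate=True,
        )
    t = (mean_a - mean_b) / math.sqrt(denom)
    df = denom**2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(
        t=float(t),
        df=float(df),
        p=min(p, 1.0),
        mean_a=mean_a,
        mean_b=mean_b,
        var_a=var_a,
        var_b=var_b,
        n_a=na,
        n_b=nb,
        degenerate=False,
    )


def classify_regulation(
    welch: WelchResult,
    direction: Literal["ct", "intensity"] = "ct",
    alpha: float = 0.05,
) -> str:
    """Regulation class of tumour (group a) vs normal (group b).

    With ``direction='ct'`` the compared values are ΔCt, where a higher
    tumour mean means lower expression; with ``direction='intensity'``
    higher values mean higher expression (normalized band intensities).
    Returns ``downregulated``, ``upregulated`` or ``similar``.
    """
    if direction not in ("ct", "intensity"):
        raise ValidationError(f"unknown direction {direction!r}")
    if welch.p >= alpha:
        return "similar"
    tumour_higher = welch.mean_a > welch.mean_b
    lower_expression = tumour_higher if direction == "ct" else not tumour_higher
    return "downregulated" if lower_expression else "upregulated"


def normalize_bands(measurements: Sequence[BandMeasurement]) -> pd.DataFrame:
    """Lane-wise target/loading ratios, duplicates averaged per sample.

    Returns one row per (sample, target) with the mean normalized
    intensity, the lane count, and the group label. Samples without any
    lane for a target are simply absent (missing lysates are tolerated
    and recorded by omission).
    """
    if not measurements:
        raise ValidationError("normalize_bands: empty input")
    rows = [
        {
            "sample": m.sample_id,
            "group": m.group,
            "target": m.target,
            "normalized": m.normalized,
        }
        for m in measurements
    ]
    frame = pd.DataFrame(rows)
    out = (
        frame.groupby(["target", "sample", "group"], sort=True)["normalized"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "normalized", "count": "n_lanes"})
    )
    return out
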