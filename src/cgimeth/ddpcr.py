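"""Droplet digital PCR Poisson quantification on merged wells.

Replicate wells of one (sample, target) are pooled by summing droplet
counts ("merged well"). With droplet volume V_d and a fraction
p_neg = n_negative / n_total of negative droplets, the mean number of
template copies per droplet is λ̂ = −ln(p_neg) and the target
concentration is λ̂ / V_d copies/µL.

Confidence intervals come from two routes: a delta-method normal interval
on λ̂ with SE(λ̂) = sqrt((1 − p̂_neg) / (n_total · p̂_neg)), and an exact
route that transforms a Clopper–Pearson binomial interval on p_neg
through −ln(·)/V_d. In ``auto`` mode (default) the exact interval is used
whenever fewer than 10 positive or 10 negative droplets were observed,
where the normal approximation fails.

A saturated merged well (no negative droplets) has no finite point
estimate: the estimate is flagged rather than returned as infinity, and
only the one-sided lower confidence bound is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ComputationError, SaturatedWellError, ValidationError
from .io import DropletWell

__all__ = [
    "MergedWell",
    "ConcentrationEstimate",
    "merge_wells",
    "estimate_concentration",
    "poisson_ci",
    "detection_call",
    "quantify",
]


@dataclass(frozen=True)
class MergedWell:
    """Pooled droplet counts across the replicate wells of one assay."""

    sample_id: str
    target: str
    n_total: int
    n_positive: int
    n_wells: int

    @property
    def n_negative(self) -> int:
        return self.n_total - self.n_positive

    @property
    def saturated(self) -> bool:
        return self.n_negative == 0


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Poisson concentration estimate for one merged well.

    ``lambda_hat`` is mean copies per droplet (dimensionless);
    ``concentration`` and the CI bounds are in copies/µL. For a saturated
    well ``lambda_hat``/``concentration`` are NaN, ``saturated`` is set,
    and only ``ci_low`` is finite.
    """

    lambda_hat: float
    concentration: float
    ci_low: float
    ci_high: float
    ci_level: float
    ci_method: str
    saturated: bool


def merge_wells(wells: Sequence[DropletWell]) -> MergedWell:
    """Pool replicate wells by exact integer summation of droplet counts."""
    if not wells:
        raise ValidationError("merge_wells: empty input")
    keys = {(w.sample_id, w.target) for w in wells}
    if len(keys) > 1:
        raise ValidationError(f"merge_wells: mixed samples/targets {sorted(keys)}")
    sample_id, target = next(iter(keys))
    return MergedWell(
        sample_id=sample_id,
        target=target,
        n_total=sum(w.n_total for w in wells),
        n_positive=sum(w.n_positive for w in wells),
        n_wells=len(wells),
    )


def lambda_from_counts(n_total: int, n_positive: int) -> float:
    """λ̂ = −ln(n_negative / n_total); raises on a saturated partition set."""
    if n_total <= 0:
        raise ValidationError("n_total must be > 0")
    n_negative = n_total - n_positive
    if n_negative == 0:
        raise SaturatedWellError(
            f"all {n_total} droplets positive: concentration unbounded"
        )
    return -math.log(n_negative / n_total)


def estimate_concentration(
    merged: MergedWell, droplet_volume_ul: float = 8.5e-4
) -> ConcentrationEstimate:
    """Point estimate (no CI) for a merged well; see :func:`quantify`."""
    return quantify(merged, droplet_volume_ul, ci=False)


def poisson_ci(
    merged: MergedWell,
    droplet_volume_ul: float = 8.5e-4,
    level: float = 0.95,
    method: str = "auto",
    exact_below: int = 10,
) -> tuple[float, float]:
    """Confidence interval for the concentration (copies/µL).

    ``method`` is ``delta``, ``exact`` (Clopper–Pearson transformed) or
    ``auto`` (exact when n_positive or n_negative < ``exact_below``).
    For a saturated well only the lower bound is finite.
    """
    if droplet_volume_ul <= 0:
        raise ValidationError("droplet_volume_ul must be > 0")
    n, k = merged.n_total, merged.n_positive
    n_neg = n - k
    if method == "auto":
        method = "exact" if (k < exact_below or n_neg < exact_below) else "delta"
    alpha = 1.0 - level

    if method == "exact":
        # Clopper-Pearson on p_neg (n_neg "successes" of n), mapped through
        # lambda = -ln(p_neg), which is decreasing in p_neg.
        if n_neg == 0:
            # zero negatives: CP upper bound on p_neg is 1 - (alpha/2)^(1/n)
            p_neg_hi = float(stats.beta.ppf(1 - alpha / 2.0, 1, n))
            lam_lo = -math.log(p_neg_hi)
            return lam_lo / droplet_volume_ul, math.inf
        p_neg_lo = (
            float(stats.beta.ppf(alpha / 2.0, n_neg, k + 1)) if k > 0 else None
        )
        p_neg_hi = (
            float(stats.beta.ppf(1 - alpha / 2.0, n_neg + 1, k)) if k > 0 else 1.0
        )
        if k == 0:
            # all droplets negative: lambda lower bound is exactly 0,
            # one-sided upper bound from the CP lower bound on p_neg
            p_neg_lo = float(stats.beta.ppf(alpha / 2.0, n, 1))
            return 0.0, -math.log(p_neg_lo) / droplet_volume_ul
        lam_lo = max(0.0, -math.log(p_neg_hi))
        lam_hi = -math.log(p_neg_lo)
        return lam_lo / droplet_volume_ul, lam_hi / droplet_volume_ul

    if method != "delta":
        raise ValidationError(f"unknown CI method {method!r}")
    if n_neg == 0:
        raise SaturatedWellError("delta-method CI undefined for a saturated well")
    lam = lambda_from_counts(n, k)
    p_neg = n_neg / n
    se = math.sqrt((1.0 - p_neg) / (n * p_neg))
    z = float(stats.norm.ppf(1 - alpha / 2.0))
    lo = max(0.0, lam - z * se) / droplet_volume_ul
    hi = (lam + z * se) / droplet_volume_ul
    return lo, hi


def quantify(
    merged: MergedWell,
    droplet_volume_ul: float = 8.5e-4,
    level: float = 0.95,
    method: str = "auto",
    exact_below: int = 10,
    ci: bool = True,
) -> ConcentrationEstimate:
    """Full Poisson quantification of a merged well.

    Returns concentration in copies/µL with its CI. A well with zero
    positive droplets yields concentration 0 with a one-sided upper bound;
    a saturated well is flagged with NaN point estimate and a one-sided
    lower bound.
    """
    if droplet_volume_ul <= 0:
        raise ValidationError("droplet_volume_ul must be > 0")
    if merged.saturated:
        if not ci:
            raise SaturatedWellError(
                f"{merged.sample_id}/{merged.target}: all droplets positive"
            )
        lo, hi = poisson_ci(merged, droplet_volume_ul, level, "exact", exact_below)
        return ConcentrationEstimate(
            lambda_hat=math.nan,
            concentration=math.nan,
            ci_low=lo,
            ci_high=hi,
            ci_level=level,
            ci_method="exact",
            saturated=True,
        )
    lam = lambda_from_counts(merged.n_total, merged.n_positive)
    conc = lam / droplet_volume_ul
    if not ci:
        return ConcentrationEstimate(lam, conc, math.nan, math.nan, level, "none", False)
    used = method
    if method == "auto":
        used = (
            "exact"
            if (merged.n_positive < exact_below or merged.n_negative < exact_below)
            else "delta"
        )
    lo, hi = poisson_ci(merged, droplet_volume_ul, level, used, exact_below)
    # clip for numerical safety: the CI must bracket the point estimate
    lo = min(lo, conc)
    hi = max(hi, conc)
    return ConcentrationEstimate(lam, conc, lo, hi, level, used, False)


def detection_call(merged: MergedWell, min_positive: int = 3) -> str:
    """``methylated`` iff the merged well has at least ``min_positive``
    positive droplets, else ``undetectable_methylation``."""
    return "methylated" if merged.n_positive >= min_positive else "undetectable_methylation"
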