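"""MethyLight qPCR calling.

Triplicate Ct values are summarized per (sample, matrix, target); the
repetitive-element Alu reaction, which amplifies independently of
methylation, normalizes DNA input. A tumour/normal tissue pair is called
hypermethylated when ΔCt = (mean Ct normal − mean Ct tumour) > 2 cycles
and hypomethylated when ΔCt < −2 (strict on both sides); stool samples
get a binary methylated/undetectable call. A sample whose Alu reaction
fails is invalid: absence of target signal cannot be distinguished from
absence of DNA.

The ΔCt rule is applied to Alu-normalized mean Ct by default, because raw
Ct comparisons across specimens are confounded by input amount; raw-Ct
mode is available via ``RunConfig.normalize_ct_to_alu = False``.
"Undetermined" replicates are never imputed as Ct 50 — the mean runs over
amplified replicates only, and a 2-of-3 detection quorum decides whether
a target counts as detected at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .io import CtMeasurement

__all__ = [
    "CtSummary",
    "MethylationCall",
    "StoolCall",
    "summarize_replicates",
    "normalize_to_alu",
    "call_paired_tissue",
    "call_tissue_pair",
    "call_stool_detection",
    "group_measurements",
]


class MethylationCall(str, Enum):
    HYPERMETHYLATED = "hypermethylated"
    HYPOMETHYLATED = "hypomethylated"
    NOT_DIFFERENTIALLY_METHYLATED = "not_differentially_methylated"
    UNDETECTABLE_METHYLATION = "undetectable_methylation"
    INVALID = "invalid"


class StoolCall(str, Enum):
    METHYLATED = "methylated"
    UNDETECTABLE_METHYLATION = "undetectable_methylation"
    INVALID = "invalid"


@dataclass(frozen=True)
class CtSummary:
    """Replicate-level summary of one qPCR assay."""

    n_replicates: int
    n_amplified: int
    mean_ct: float | None
    detected: bool


def summarize_replicates(
    measurements: Sequence[CtMeasurement], quorum: int = 2
) -> CtSummary:
    """Summarize replicates sharing one (sample, matrix, target).

    The mean is taken over amplified replicates only; ``detected`` requires
    at least ``quorum`` amplified replicates (default 2 of 3).
    """
    if not measurements:
        raise ValidationError("summarize_replicates: empty input")
    keys = {(m.sample_id, m.matrix, m.target) for m in measurements}
    if len(keys) > 1:
        raise ValidationError(
            f"replicates span multiple assays: {sorted(keys)}"
        )
    cts = [m.ct for m in measurements if m.amplified]
    mean_ct = float(np.mean(cts)) if cts else None
    return CtSummary(
        n_replicates=len(measurements),
        n_amplified=len(cts),
        mean_ct=mean_ct,
        detected=len(cts) >= quorum,
    )


def normalize_to_alu(target: CtSummary, alu: CtSummary) -> float | None:
    """Input-normalized Ct: target mean Ct − Alu mean Ct.

    Returns ``None`` when the target was not detected. Raises if Alu was
    not detected, since without the input control the sample is invalid.
    """
    if not alu.detected:
        raise ValidationError("Alu reaction undetected: sample invalid (no DNA input)")
    if not target.detected or target.mean_ct is None:
        return None
    return target.mean_ct - alu.mean_ct


def call_paired_tissue(
    tumour_norm_ct: float | None,
    normal_norm_ct: float | None,
    delta: float = 2.0,
) -> MethylationCall:
    """Categorical call for a tumour/normal pair from normalized Cts.

    ΔCt = normal − tumour. ΔCt > delta -> hypermethylated; ΔCt < −delta ->
    hypomethylated; otherwise not differentially methylated (the ±delta
    boundaries themselves are not differential, the inequalities being
    strict). A tumour target that did not amplify while its Alu control
    did (``tumour_norm_ct is None``) is undetectable methylation.
    """
    if tumour_norm_ct is None:
        return MethylationCall.UNDETECTABLE_METHYLATION
    if normal_norm_ct is None:
        # no methylation signal in the normal: any tumour signal is a gain
        return MethylationCall.HYPERMETHYLATED
    delta_ct = normal_norm_ct - tumour_norm_ct
    if delta_ct > delta:
        return MethylationCall.HYPERMETHYLATED
    if delta_ct < -delta:
        return MethylationCall.HYPOMETHYLATED
    return MethylationCall.NOT_DIFFERENTIALLY_METHYLATED


def call_tissue_pair(
    tumour_target: CtSummary,
    tumour_alu: CtSummary,
    normal_target: CtSummary,
    normal_alu: CtSummary,
    delta: float = 2.0,
    normalize: bool = True,
) -> tuple[MethylationCall, float | None]:
    """Full tissue-pair call from raw summaries; returns (call, ΔCt).

    Propagates ``invalid`` when either specimen's Alu control failed.
    """
    if not tumour_alu.detected or not normal_alu.detected:
        return MethylationCall.INVALID, None
    if normalize:
        t = normalize_to_alu(tumour_target, tumour_alu)
        n = normalize_to_alu(normal_target, normal_alu)
    else:
        t = tumour_target.mean_ct if tumour_target.detected else None
        n = normal_target.mean_ct if normal_target.detected else None
    call = call_paired_tissue(t, n, delta)
    delta_ct = (n - t) if (t is not None and n is not None) else None
    return call, delta_ct


def call_stool_detection(target: CtSummary, alu: CtSummary) -> StoolCall:
    """Binary stool call: methylated iff both target and Alu are detected."""
    if not alu.detected:
        return StoolCall.INVALID
    if target.detected:
        return StoolCall.METHYLATED
    return StoolCall.UNDETECTABLE_METHYLATION


def group_measurements(
    measurements: Iterable[CtMeasurement],
) -> dict[tuple[str, str, str], list[CtMeasurement]]:
    """Group a flat Ct table by (sample, matrix, target), preserving order."""
    groups: dict[tuple[str, str, str], list[CtMeasurement]] = {}
    for m in measurements:
        groups.setdefault((m.sample_id, m.matrix, m.target), []).append(m)
    return groups
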