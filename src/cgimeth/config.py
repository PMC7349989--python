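"""Run configuration: every threshold and policy the pipeline applies.

The defaults encode the published analysis settings: the β filter cascade
(normal mean < 0.25; β > 0.45 in ≥ 75% of tumours; β > 0.25 in ≤ 25% of
normals; AUC > 0.95 in both cohorts), the MethyLight ΔCt ±2 call rule with
a 50-cycle cap, and QX200-style ddPCR quantification (0.85 nL droplets).
The config serializes losslessly to YAML so a run is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError

STAGE_POLICIES = ("discovery_only", "both_cohorts_intersect")
CI_METHODS = ("auto", "delta", "exact")


@dataclass
class RunConfig:
    # biomarker selection (Fig. 6-style cascade)
    stage1_max_normal_mean: float = 0.25   # strict <
    stage2_beta_high: float = 0.45         # tumour beta must exceed (strict >)
    stage2_min_tumour_frac: float = 0.75   # inclusive >=
    stage2_beta_low: float = 0.25          # normal beta exceeding counts against
    stage2_max_normal_frac: float = 0.25   # inclusive <=
    auc_min: float = 0.95                  # strict >, required in both cohorts
    stage_cohort_policy: str = "discovery_only"
    missingness_cap: float = 0.20          # per-CGI fraction above which it is excluded

    # MethyLight calling
    delta_ct_cutoff: float = 2.0           # strict on both sides
    detection_quorum: int = 2              # amplified replicates required out of n
    ct_cap: float = 50.0                   # protocol cycle count
    normalize_ct_to_alu: bool = True

    # ddPCR quantification
    droplet_volume_ul: float = 8.5e-4      # 0.85 nL per droplet (QX200 convention)
    min_positive_droplets: int = 3         # detection threshold on the merged well
    ci_level: float = 0.95
    ci_method: str = "auto"                # exact at low counts, delta otherwise
    ci_exact_below: int = 10               # switch to exact when pos or neg count < this

    # expression statistics
    alpha: float = 0.05                    # two-sided Welch significance level

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def _in(name: str, lo: float, hi: float) -> None:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValidationError(f"{name}={v} outside [{lo}, {hi}]")

        for name in (
            "stage1_max_normal_mean",
            "stage2_beta_high",
            "stage2_min_tumour_frac",
            "stage2_beta_low",
            "stage2_max_normal_frac",
            "missingness_cap",
        ):
            _in(name, 0.0, 1.0)
        _in("auc_min", 0.0, 1.01)
        if not 0.0 < self.ci_level < 1.0:
            raise ValidationError(f"ci_level={self.ci_level} outside (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha={self.alpha} outside (0, 1)")
        if self.delta_ct_cutoff < 0:
            raise ValidationError("delta_ct_cutoff must be >= 0")
        if self.ct_cap <= 0:
            raise ValidationError("ct_cap must be > 0")
        if self.droplet_volume_ul <= 0:
            raise ValidationError("droplet_volume_ul must be > 0")
        if self.detection_quorum < 1:
            raise ValidationError("detection_quorum must be >= 1")
        if self.min_positive_droplets < 1:
            raise ValidationError("min_positive_droplets must be >= 1")
        if self.stage_cohort_policy not in STAGE_POLICIES:
            raise ValidationError(
                f"stage_cohort_policy must be one of {STAGE_POLICIES}"
            )
        if self.ci_method not in CI_METHODS:
            raise ValidationError(f"ci_method must be one of {CI_METHODS}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s) {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(data)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
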