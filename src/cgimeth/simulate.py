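"""Seeded synthetic data with the statistical structure the analysis assumes.

Four artifact families are generated, each from its own RNG stream derived
from the master seed (so regenerating one table never perturbs another):

* **Methylation cohorts** — CGI-by-sample β matrices for a discovery
  cohort (18 tumours / 4 normals) and a larger validation cohort
  (100 / 40). β values are Beta-distributed, parameterized by mean and
  precision so they respect the [0, 1] support. Out of 74 candidate CGIs,
  24 are planted true biomarkers (normal mean β ≈ 0.10, tumour mean
  β ≈ 0.50, tightly dispersed so that β > 0.45 in well over 75% of
  tumours); the remaining 50 are decoys, each engineered to violate
  exactly one gate of the selection cascade: 20 fail the low-normal gate
  (normal mean 0.35), 18 fail the tumour-prevalence gate (tumour mean
  0.35) and 12 pass both β gates yet fail the AUC gate (a quarter of
  their normals, a fixed contaminated subset, sit at β ≈ 0.6, capping
  the AUC near 0.75). With these counts the cascade reduces
  74 → 36 → 24.

* **qPCR Ct tables** — each replicate draws its template-molecule count
  from a Poisson law with mean (concentration × input volume ×
  amplification efficiency); zero molecules, or a Ct beyond the 50-cycle
  cap, is emitted as ``Undetermined``; otherwise
  Ct = baseline − slope·log2(molecules) + Gaussian noise. The Alu input
  control amplifies independently of methylation. Stool reactions carry a
  reduced MethyLight amplification efficiency (PCR inhibitors in stool
  DNA), which ddPCR partitioning is not subject to — this is what puts
  low-concentration stool samples in the ddPCR-hit / MethyLight-miss
  regime.

* **ddPCR droplet tables** — three wells per (sample, target); per well
  the droplet count is Poisson around 20,000 and the positive count is
  Binomial(n_total, 1 − e^(−c·V_d)) with c the in-reaction concentration.

* **Protein band tables** — lognormal loading-control lanes; target
  intensity = loading × true ratio × lognormal noise; duplicate lanes
  per sample.

Patient truth is organized around a per-patient *tumour* methylated-DNA
concentration: the tissue specimen sees it scaled by a specimen purity
(1 for high-purity specimens, 0.1 for low-purity ones, 0 for specimens
that missed the tumour entirely), while stool sees the patient's true
concentration diluted 1/50 — so a tissue-undetectable sample can still be
stool-positive, and one designated patient sheds no tumour DNA into
stool at all.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (
    BandMeasurement,
    BetaMatrix,
    CGIKey,
    CtMeasurement,
    DropletWell,
    SampleSheet,
)

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_methylation_cohorts",
    "simulate_qpcr",
    "simulate_droplets",
    "simulate_protein",
    "simulate_all",
]

METHYLATION_TARGETS = ("GRIA4", "VIPR2")
EXPRESSION_GENES = ("GRIA4", "VIPR2", "SPOCK1", "SLC6A3")
REFERENCE_GENE = "TFRC"
ALU = "Alu"

LABEL_TRUE = "true_biomarker"
LABEL_STAGE1 = "decoy_stage1_fail"
LABEL_STAGE2 = "decoy_stage2_fail"
LABEL_AUC = "decoy_auc_fail"


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults define the study conditions."""

    seed: int = 0

    # --- methylation cohorts ---------------------------------------------
    n_cgi_total: int = 74
    n_true_biomarkers: int = 24
    n_stage1_decoys: int = 20
    n_stage2_decoys: int = 18
    n_auc_decoys: int = 12
    normal_beta_mean: float = 0.10
    tumour_beta_mean: float = 0.50
    stage1_decoy_normal_mean: float = 0.35
    stage2_decoy_tumour_mean: float = 0.35
    auc_decoy_low_normal_mean: float = 0.08
    auc_decoy_high_normal_mean: float = 0.60
    auc_decoy_high_normal_frac: float = 0.25
    beta_precision: float = 500.0  # Beta a+b; math.inf -> point masses
    n_tumour_discovery: int = 18
    n_normal_discovery: int = 4
    n_tumour_validation: int = 100
    n_normal_validation: int = 40

    # --- patients and methylated-DNA concentrations -----------------------
    n_patients: int = 10
    tissue_conc_median: float = 75.0      # methylated copies/uL, pure tumour
    tissue_conc_log10_sd: float = 0.4
    normal_background_ratio: float = 0.05  # matched normal vs tumour concentration
    stool_dilution: float = 0.02           # stool vs tumour concentration (1/50)
    n_low_purity: int = 2                  # specimens with purity 0.1
    n_no_tumour_cells: int = 2             # specimens that missed the tumour
    low_purity: float = 0.1
    n_stool_dropout: int = 1               # patients shedding no tumour DNA in stool

    # --- qPCR / MethyLight -------------------------------------------------
    ct_baseline: float = 40.0   # Ct of a single template molecule
    ct_slope: float = 1.0       # cycles per log2(copies); 1 = perfect doubling
    ct_noise_sd: float = 0.3
    ct_cap: float = 50.0
    n_ct_replicates: int = 3
    methylight_input_ul: float = 5.0
    methylight_efficiency_tissue: float = 1.0
    methylight_efficiency_stool: float = 0.12
    alu_ct_mean: float = 20.0

    # --- ddPCR --------------------------------------------------------------
    droplets_per_well_mean: float = 20000.0
    n_wells: int = 3
    droplet_volume_ul: float = 8.5e-4
    ddpcr_input_ul: float = 5.0
    ddpcr_reaction_ul: float = 20.0

    # --- expression ---------------------------------------------------------
    expression_delta_delta_ct: dict[str, float] = field(
        default_factory=lambda: {
            "GRIA4": 2.0,
            "VIPR2": 1.5,
            "SPOCK1": 1.5,
            "SLC6A3": 3.0,
        }
    )
    reference_ct_mean: float = 22.0
    baseline_delta_ct: float = 6.0
    expression_biological_sd: float = 0.5

    # --- protein -------------------------------------------------------------
    protein_ratio_tumour: dict[str, float] = field(
        default_factory=lambda: {
            "GRIA4": 0.30,
            "VIPR2": 0.80,
            "SPOCK1": 0.40,
            "SLC6A3": 0.25,
        }
    )
    protein_duplicates: int = 2
    protein_loading_mean: float = 1000.0
    protein_measurement_log_sd: float = 0.15
    protein_biological_log_sd: float = 0.25

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        decoys = self.n_stage1_decoys + self.n_stage2_decoys + self.n_auc_decoys
        if self.n_true_biomarkers + decoys != self.n_cgi_total:
            raise ValidationError(
                "CGI labels must partition the universe: "
                f"{self.n_true_biomarkers} + {decoys} != {self.n_cgi_total}"
            )
        if self.tumour_beta_mean <= self.normal_beta_mean:
            raise ValidationError(
                "true biomarkers need tumour mean beta > normal mean beta"
            )
        for name in (
            "normal_beta_mean",
            "tumour_beta_mean",
            "stage1_decoy_normal_mean",
            "stage2_decoy_tumour_mean",
            "auc_decoy_low_normal_mean",
            "auc_decoy_high_normal_mean",
            "auc_decoy_high_normal_frac",
            "stool_dilution",
            "normal_background_ratio",
            "low_purity",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        for name, lo in (
            ("n_tumour_discovery", 2),
            ("n_normal_discovery", 2),
            ("n_tumour_validation", 2),
            ("n_normal_validation", 2),
            ("n_patients", 1),
            ("n_ct_replicates", 1),
            ("n_wells", 1),
        ):
            if getattr(self, name) < lo:
                raise ValidationError(f"{name} must be >= {lo}")
        if self.n_low_purity + self.n_no_tumour_cells > self.n_patients:
            raise ValidationError("purity classes exceed the patient count")
        if self.beta_precision <= 0:
            raise ValidationError("beta_precision must be > 0")
        if self.droplet_volume_ul <= 0 or self.ddpcr_input_ul <= 0:
            raise ValidationError("ddPCR volumes must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TruthTable:
    """Ground truth for parameter-recovery tests.

    ``cgi_labels`` maps every CGI to its planted class (a partition);
    ``patients`` carries per-patient methylated-DNA concentrations for
    tissue and stool per target; ``expression_delta_delta_ct`` and
    ``protein_ratio_tumour`` are the planted effect sizes.
    """

    cgi_labels: pd.Series
    patients: pd.DataFrame
    expression_delta_delta_ct: dict[str, float]
    protein_ratio_tumour: dict[str, float]

    @property
    def true_biomarkers(self) -> list[CGIKey]:
        return sorted(self.cgi_labels.index[self.cgi_labels == LABEL_TRUE])


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """One independent RNG stream per artifact family."""
    names = ("methylation", "patients", "qpcr", "ddpcr", "protein")
    seqs = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(seq) for name, seq in zip(names, seqs)}


def _draw_beta(rng: np.random.Generator, mean: float, precision: float, size) -> np.ndarray:
    """Beta draw parameterized by mean/precision; infinite precision is a
    point mass at the mean."""
    if math.isinf(precision):
        return np.full(size, mean, dtype=float)
    mean = min(max(mean, 1e-9), 1 - 1e-9)
    a = mean * precision
    b = (1.0 - mean) * precision
    return rng.beta(a, b, size=size)


def _make_cgi_universe(config: SimulationConfig, rng: np.random.Generator):
    """Synthetic CGI keys plus a shuffled truth-label assignment."""
    labels = (
        [LABEL_TRUE] * config.n_true_biomarkers
        + [LABEL_STAGE1] * config.n_stage1_decoys
        + [LABEL_STAGE2] * config.n_stage2_decoys
        + [LABEL_AUC] * config.n_auc_decoys
    )
    labels = list(np.array(labels)[rng.permutation(len(labels))])
    cgis = []
    for i in range(config.n_cgi_total):
        chrom = f"chr{(i % 22) + 1}"
        start = 1_000_000 + 10_000 * i
        cgis.append(CGIKey(chrom, start, start + 999, f"SIM{i + 1:03d}"))
    return cgis, labels


def _cohort_sheet(tag: str, cohort: str, n_tumour: int, n_normal: int) -> SampleSheet:
    rows = []
    for i in range(n_tumour):
        rows.append(
            {
                "sample_id": f"{tag}_T{i + 1:03d}",
                "group": "tumour",
                "cohort": cohort,
                "pair_id": "",
            }
        )
    for i in range(n_normal):
        rows.append(
            {
                "sample_id": f"{tag}_N{i + 1:03d}",
                "group": "normal",
                "cohort": cohort,
                "pair_id": "",
            }
        )
    return SampleSheet(pd.DataFrame(rows))


def _simulate_cohort(
    config: SimulationConfig,
    rng: np.random.Generator,
    cgis: list[CGIKey],
    labels: list[str],
    sheet: SampleSheet,
) -> BetaMatrix:
    tumours = sheet.samples_in("tumour")
    normals = sheet.samples_in("normal")
    kappa = config.beta_precision
    n_high = int(round(config.auc_decoy_high_normal_frac * len(normals)))
    values = np.empty((len(cgis), len(tumours) + len(normals)))
    for i, label in enumerate(labels):
        if label == LABEL_TRUE:
            t_mean, n_means = config.tumour_beta_mean, [config.normal_beta_mean] * len(normals)
        elif label == LABEL_STAGE1:
            t_mean = config.tumour_beta_mean
            n_means = [config.stage1_decoy_normal_mean] * len(normals)
        elif label == LABEL_STAGE2:
            t_mean = config.stage2_decoy_tumour_mean
            n_means = [config.normal_beta_mean] * len(normals)
        else:  # LABEL_AUC: a fixed contaminated subset of normals runs high
            t_mean = config.tumour_beta_mean
            n_means = [config.auc_decoy_high_normal_mean] * n_high + [
                config.auc_decoy_low_normal_mean
            ] * (len(normals) - n_high)
        values[i, : len(tumours)] = _draw_beta(rng, t_mean, kappa, len(tumours))
        values[i, len(tumours) :] = np.array(
            [_draw_beta(rng, m, kappa, 1)[0] for m in n_means]
        )
    frame = pd.DataFrame(values, index=cgis, columns=tumours + normals)
    return BetaMatrix(frame, sheet)


def simulate_methylation_cohorts(
    config: SimulationConfig,
) -> tuple[BetaMatrix, BetaMatrix, TruthTable]:
    """Generate discovery and validation β matrices sharing one truth."""
    config.validate()
    streams = _streams(config.seed)
    rng = streams["methylation"]
    cgis, labels = _make_cgi_universe(config, rng)
    disc_sheet = _cohort_sheet(
        "DISC", "discovery", config.n_tumour_discovery, config.n_normal_discovery
    )
    val_sheet = _cohort_sheet(
        "VAL", "validation", config.n_tumour_validation, config.n_normal_validation
    )
    discovery = _simulate_cohort(config, rng, cgis, labels, disc_sheet)
    validation = _simulate_cohort(config, rng, cgis, labels, val_sheet)
    truth = TruthTable(
        cgi_labels=pd.Series(labels, index=cgis),
        patients=simulate_patient_truth(config),
        expression_delta_delta_ct=dict(config.expression_delta_delta_ct),
        protein_ratio_tumour=dict(config.protein_ratio_tumour),
    )
    return discovery, validation, truth


def simulate_patient_truth(config: SimulationConfig) -> pd.DataFrame:
    """Per-patient, per-target methylated-DNA concentrations (copies/µL).

    Columns: tumour_conc (in the tumour itself), specimen_purity,
    tissue_tumour_conc, tissue_normal_conc, stool_conc, stool_sheds.
    Purity classes and the stool-dropout patient are assigned to the last
    patients in id order, deterministically.
    """
    rng = _streams(config.seed)["patients"]
    samples = [f"CRC_{i + 1:02d}" for i in range(config.n_patients)]
    purity = np.ones(config.n_patients)
    if config.n_low_purity:
        purity[-(config.n_low_purity + config.n_no_tumour_cells) : len(purity)
               - config.n_no_tumour_cells] = config.low_purity
    if config.n_no_tumour_cells:
        purity[len(purity) - config.n_no_tumour_cells :] = 0.0
    sheds = np.ones(config.n_patients, dtype=bool)
    if config.n_stool_dropout:
        sheds[: config.n_stool_dropout] = False
    rows = []
    for target in METHYLATION_TARGETS:
        conc = config.tissue_conc_median * 10.0 ** rng.normal(
            0.0, config.tissue_conc_log10_sd, size=config.n_patients
        )
        for j, sample in enumerate(samples):
            tumour_conc = conc[j]
            rows.append(
                {
                    "sample": sample,
                    "target": target,
                    "tumour_conc": tumour_conc,
                    "specimen_purity": purity[j],
                    "tissue_tumour_conc": purity[j] * tumour_conc,
                    "tissue_normal_conc": config.normal_background_ratio * tumour_conc,
                    "stool_conc": (
                        config.stool_dilution * tumour_conc if sheds[j] else 0.0
                    ),
                    "stool_sheds": bool(sheds[j]),
                }
            )
    return pd.DataFrame(rows)


def _draw_ct(
    rng: np.random.Generator,
    expected_molecules: float,
    config: SimulationConfig,
) -> float | None:
    """One qPCR replicate: Poisson template sampling, then the standard
    log-linear Ct response, capped at the protocol cycle count."""
    if expected_molecules < 0:
        raise ValidationError("expected molecule count must be >= 0")
    molecules = rng.poisson(expected_molecules)
    if molecules == 0:
        return None
    ct = (
        config.ct_baseline
        - config.ct_slope * math.log2(molecules)
        + rng.normal(0.0, config.ct_noise_sd)
    )
    if ct > config.ct_cap:
        return None
    return max(ct, 1e-6)


def simulate_qpcr(
    config: SimulationConfig, truth: TruthTable
) -> tuple[list[CtMeasurement], list[CtMeasurement]]:
    """Ct tables for MethyLight (targets + Alu over tissue pairs and stool)
    and for the expression assay (four genes + TFRC on tissue pairs).

    Returns ``(methylight_measurements, expression_measurements)``.
    """
    config.validate()
    rng = _streams(config.seed)["qpcr"]
    methylight: list[CtMeasurement] = []

    conc_of = {
        (row["sample"], row["target"]): row for _, row in truth.patients.iterrows()
    }
    samples = sorted({s for s, _ in conc_of})

    for sample in samples:
        for matrix, eff in (
            ("tissue_tumour", config.methylight_efficiency_tissue),
            ("tissue_normal", config.methylight_efficiency_tissue),
            ("stool", config.methylight_efficiency_stool),
        ):
            for target in METHYLATION_TARGETS:
                row = conc_of[(sample, target)]
                conc = {
                    "tissue_tumour": row["tissue_tumour_conc"],
                    "tissue_normal": row["tissue_normal_conc"],
                    "stool": row["stool_conc"],
                }[matrix]
                lam = conc * config.methylight_input_ul * eff
                for rep in range(1, config.n_ct_replicates + 1):
                    methylight.append(
                        CtMeasurement(
                            sample, matrix, target, rep, _draw_ct(rng, lam, config)
                        )
                    )
            # Alu: abundant and methylation-independent, never at the cap
            for rep in range(1, config.n_ct_replicates + 1):
                ct = rng.normal(config.alu_ct_mean, config.ct_noise_sd)
                methylight.append(
                    CtMeasurement(sample, matrix, ALU, rep, float(max(ct, 1e-6)))
                )

    expression: list[CtMeasurement] = []
    patient_samples = sorted(truth.patients["sample"].unique())
    for sample in patient_samples:
        # per-specimen input shift cancels in ΔCt
        shift = {m: rng.normal(0.0, 0.5) for m in ("tissue_tumour", "tissue_normal")}
        base_dct = {
            gene: config.baseline_delta_ct
            + rng.normal(0.0, config.expression_biological_sd)
            for gene in EXPRESSION_GENES
        }
        for matrix in ("tissue_tumour", "tissue_normal"):
            ref_ct = config.reference_ct_mean + shift[matrix]
            for rep in range(1, config.n_ct_replicates + 1):
                expression.append(
                    CtMeasurement(
                        sample,
                        matrix,
                        REFERENCE_GENE,
                        rep,
                        float(ref_ct + rng.normal(0.0, config.ct_noise_sd)),
                    )
                )
            for gene in EXPRESSION_GENES:
                ddct = (
                    truth.expression_delta_delta_ct.get(gene, 0.0)
                    if matrix == "tissue_tumour"
                    else 0.0
                )
                gene_ct = ref_ct + base_dct[gene] + ddct
                for rep in range(1, config.n_ct_replicates + 1):
                    expression.append(
                        CtMeasurement(
                            sample,
                            matrix,
                            gene,
                            rep,
                            float(
                                min(
                                    gene_ct + rng.normal(0.0, config.ct_noise_sd),
                                    config.ct_cap,
                                )
                            ),
                        )
                    )
    return methylight, expression


def simulate_droplets(config: SimulationConfig, truth: TruthTable) -> list[DropletWell]:
    """Stool ddPCR wells: Poisson droplet counts, Binomial positives."""
    config.validate()
    rng = _streams(config.seed)["ddpcr"]
    wells: list[DropletWell] = []
    frame = truth.patients.sort_values(["sample", "target"])
    dilution = config.ddpcr_input_ul / config.ddpcr_reaction_ul
    for _, row in frame.iterrows():
        c_reaction = row["stool_conc"] * dilution
        p_pos = 1.0 - math.exp(-c_reaction * config.droplet_volume_ul)
        for w in range(1, config.n_wells + 1):
            n_total = max(1, int(rng.poisson(config.droplets_per_well_mean)))
            n_pos = int(rng.binomial(n_total, p_pos))
            wells.append(
                DropletWell(row["sample"], row["target"], f"W{w:02d}", n_total, n_pos)
            )
    return wells


def simulate_protein(config: SimulationConfig, truth: TruthTable) -> list[BandMeasurement]:
    """Western-blot band intensities in duplicate per sample and gene."""
    config.validate()
    rng = _streams(config.seed)["protein"]
    bands: list[BandMeasurement] = []
    samples = sorted(truth.patients["sample"].unique())
    for gene in EXPRESSION_GENES:
        ratio_t = truth.protein_ratio_tumour.get(gene, 1.0)
        for sample in samples:
            for group, ratio in (("tumour", ratio_t), ("normal", 1.0)):
                sample_ratio = ratio * math.exp(
                    rng.normal(0.0, config.protein_biological_log_sd)
                )
                for rep in range(1, config.protein_duplicates + 1):
                    loading = config.protein_loading_mean * math.exp(
                        rng.normal(0.0, config.protein_measurement_log_sd)
                    )
                    target_int = (
                        loading
                        * sample_ratio
                        * math.exp(rng.normal(0.0, config.protein_measurement_log_sd))
                    )
                    bands.append(
                        BandMeasurement(sample, group, gene, rep, target_int, loading)
                    )
    return bands


def simulate_all(config: SimulationConfig):
    """Generate every artifact family at once.

    Returns ``(discovery, validation, truth, methylight_ct, expression_ct,
    droplet_wells, protein_bands)``.
    """
    discovery, validation, truth = simulate_methylation_cohorts(config)
    methylight_ct, expression_ct = simulate_qpcr(config, truth)
    wells = simulate_droplets(config, truth)
    bands = simulate_protein(config, truth)
    return discovery, validation, truth, methylight_ct, expression_ct, wells, bands
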