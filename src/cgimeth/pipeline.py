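"""End-to-end orchestration: simulate -> select -> call -> quantify -> compare.

``run_all`` drives every stage on synthetic inputs, writes each
intermediate table to disk in the package's text formats, and emits a run
manifest (JSON) recording the config hash, seed, per-stage record counts
and every threshold actually applied, so a run is auditable. The report
contains a selection table (one row per candidate CGI with Δβ, AUC and
pass flags per cohort) and a call matrix (tissue MethyLight call, stool
MethyLight call, stool ddPCR call per patient and target) mirroring the
published table structures.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import ddpcr, expression, methylight
from .config import RunConfig
from .errors import ValidationError
from .io import (
    write_band_table,
    write_beta_matrix,
    write_ct_table,
    write_droplet_table,
    write_sample_sheet,
)
from .selection import select_biomarkers
from .simulate import (
    EXPRESSION_GENES,
    METHYLATION_TARGETS,
    REFERENCE_GENE,
    SimulationConfig,
    simulate_all,
)

__all__ = ["RunManifest", "run_all", "concordance_table", "call_matrix_from_tables"]


@dataclass
class RunManifest:
    seed: int
    config_hash: str
    out_dir: str
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def add_stage(self, name: str, n_records: int, files: list[str]) -> None:
        self.stages[name] = {"n_records": int(n_records), "files": list(files)}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _fmt_frame(frame: pd.DataFrame, path: Path, index_name: str | None = None) -> None:
    out = frame.copy()
    if index_name is not None:
        out.index = [str(i) for i in out.index]
        out.index.name = index_name
        out.to_csv(path, sep="\t", lineterminator="\n")
    else:
        out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def call_matrix_from_tables(
    methylight_ct, droplet_wells, config: RunConfig
) -> pd.DataFrame:
    """Build the per-patient call matrix from raw Ct and droplet tables.

    One row per (sample, target) with the tissue MethyLight call and its
    ΔCt, the stool MethyLight call, and the stool ddPCR call with merged
    counts and concentration.
    """
    groups = methylight.group_measurements(methylight_ct)
    samples = sorted({k[0] for k in groups})
    targets = sorted({k[2] for k in groups if k[2] != "Alu"})

    by_well: dict[tuple[str, str], list] = {}
    for w in droplet_wells:
        by_well.setdefault((w.sample_id, w.target), []).append(w)

    rows = []
    for sample in samples:
        for target in targets:
            def summ(matrix: str, tgt: str):
                key = (sample, matrix, tgt)
                if key not in groups:
                    return None
                return methylight.summarize_replicates(
                    groups[key], config.detection_quorum
                )

            tissue_call, delta_ct = None, None
            tt, ta = summ("tissue_tumour", target), summ("tissue_tumour", "Alu")
            nt, na = summ("tissue_normal", target), summ("tissue_normal", "Alu")
            if all(s is not None for s in (tt, ta, nt, na)):
                call, delta_ct = methylight.call_tissue_pair(
                    tt, ta, nt, na, config.delta_ct_cutoff, config.normalize_ct_to_alu
                )
                tissue_call = call.value

            stool_call = None
            st, sa = summ("stool", target), summ("stool", "Alu")
            if st is not None and sa is not None:
                stool_call = methylight.call_stool_detection(st, sa).value

            dd_call, conc, n_pos, n_tot = None, None, None, None
            wells = by_well.get((sample, target))
            if wells:
                merged = ddpcr.merge_wells(wells)
                dd_call = ddpcr.detection_call(merged, config.min_positive_droplets)
                n_pos, n_tot = merged.n_positive, merged.n_total
                if not merged.saturated:
                    est = ddpcr.quantify(
                        merged,
                        config.droplet_volume_ul,
                        config.ci_level,
                        config.ci_method,
                        config.ci_exact_below,
                    )
                    conc = est.concentration

            rows.append(
                {
                    "sample": sample,
                    "target": target,
                    "tissue_call": tissue_call,
                    "tissue_delta_ct": delta_ct,
                    "stool_methylight": stool_call,
                    "stool_ddpcr": dd_call,
                    "stool_ddpcr_positives": n_pos,
                    "stool_ddpcr_droplets": n_tot,
                    "stool_ddpcr_copies_per_ul": conc,
                }
            )
    return pd.DataFrame(rows)


def concordance_table(calls: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate stool MethyLight vs stool ddPCR calls per target.

    Expects a frame with columns sample, target, stool_methylight,
    stool_ddpcr over one shared sample/target universe. Returns counts of
    every (MethyLight call x ddPCR call) pair plus per-assay detection
    rates.
    """
    needed = {"sample", "target", "stool_methylight", "stool_ddpcr"}
    if not needed <= set(calls.columns):
        raise ValidationError(f"concordance needs columns {sorted(needed)}")
    if calls[["sample", "target"]].duplicated().any():
        raise ValidationError("duplicated (sample, target) in call table")
    rows = []
    for target, sub in calls.groupby("target", sort=True):
        pair_counts = (
            sub.groupby(["stool_methylight", "stool_ddpcr"]).size().reset_index(name="n")
        )
        n = len(sub)
        for _, pc in pair_counts.iterrows():
            rows.append(
                {
                    "target": target,
                    "stool_methylight": pc["stool_methylight"],
                    "stool_ddpcr": pc["stool_ddpcr"],
                    "n": int(pc["n"]),
                    "methylight_detection_rate": float(
                        (sub["stool_methylight"] == "methylated").mean()
                    ),
                    "ddpcr_detection_rate": float(
                        (sub["stool_ddpcr"] == "methylated").mean()
                    ),
                    "n_samples": n,
                }
            )
    return pd.DataFrame(rows)


def expression_report(expression_ct, protein_bands, config: RunConfig) -> pd.DataFrame:
    """Per-gene ΔΔCt/fold-change summary with Welch tests and regulation calls.

    mRNA: per-sample ΔCt (gene − reference) in tumour and normal tissue,
    group Welch test on ΔCt values, per-pair median fold change. Protein:
    Welch test on loading-normalized band intensities.
    """
    groups = methylight.group_measurements(expression_ct)
    samples = sorted({k[0] for k in groups})
    rows = []
    for gene in sorted({k[2] for k in groups if k[2] != REFERENCE_GENE}):
        dct: dict[str, dict[str, float]] = {"tissue_tumour": {}, "tissue_normal": {}}
        for matrix in ("tissue_tumour", "tissue_normal"):
            for sample in samples:
                gkey, rkey = (sample, matrix, gene), (sample, matrix, REFERENCE_GENE)
                if gkey not in groups or rkey not in groups:
                    continue
                gsum = methylight.summarize_replicates(
                    groups[gkey], config.detection_quorum
                )
                rsum = methylight.summarize_replicates(
                    groups[rkey], config.detection_quorum
                )
                value = expression.delta_ct(gsum, rsum)
                if value is not None:
                    dct[matrix][sample] = value
        shared = sorted(set(dct["tissue_tumour"]) & set(dct["tissue_normal"]))
        tumour_vals = [dct["tissue_tumour"][s] for s in shared]
        normal_vals = [dct["tissue_normal"][s] for s in shared]
        welch = expression.welch_t(tumour_vals, normal_vals)
        records = [
            expression.fold_change(t, n, pair_id=s, gene=gene)
            for s, t, n in zip(shared, tumour_vals, normal_vals)
        ]
        fcs = pd.Series([r.fold_change for r in records])
        rows.append(
            {
                "gene": gene,
                "assay": "mrna",
                "n_pairs": len(shared),
                "mean_delta_ct_tumour": welch.mean_a,
                "mean_delta_ct_normal": welch.mean_b,
                "mean_delta_delta_ct": float(
                    pd.Series([r.delta_delta_ct for r in records]).mean()
                ),
                "median_fold_change": float(fcs.median()),
                "t": welch.t,
                "df": welch.df,
                "p": welch.p,
                "regulation": expression.classify_regulation(
                    welch, "ct", config.alpha
                ),
            }
        )

    if protein_bands:
        normalized = expression.normalize_bands(protein_bands)
        for gene, sub in normalized.groupby("target", sort=True):
            tum = sub[sub["group"] == "tumour"]["normalized"].tolist()
            nor = sub[sub["group"] == "normal"]["normalized"].tolist()
            welch = expression.welch_t(tum, nor)
            rows.append(
                {
                    "gene": gene,
                    "assay": "protein",
                    "n_pairs": min(len(tum), len(nor)),
                    "mean_delta_ct_tumour": None,
                    "mean_delta_ct_normal": None,
                    "mean_delta_delta_ct": None,
                    "median_fold_change": float(
                        pd.Series(tum).median() / pd.Series(nor).median()
                    ),
                    "t": welch.t,
                    "df": welch.df,
                    "p": welch.p,
                    "regulation": expression.classify_regulation(
                        welch, "intensity", config.alpha
                    ),
                }
            )
    return pd.DataFrame(rows)


def run_all(
    sim_config: SimulationConfig,
    run_config: RunConfig | None = None,
    out_dir: str | Path = "cgimeth_run",
) -> RunManifest:
    """Run every stage end to end; deterministic under the simulation seed."""
    run_config = run_config or RunConfig()
    out = Path(out_dir)
    inputs = out / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)

    (
        discovery,
        validation,
        truth,
        methylight_ct,
        expression_ct,
        wells,
        bands,
    ) = simulate_all(sim_config)

    manifest = RunManifest(
        seed=sim_config.seed,
        config_hash=run_config.hash(),
        out_dir=str(out),
    )

    # ---- write simulated inputs ------------------------------------------
    write_beta_matrix(discovery, inputs / "discovery_beta.tsv")
    write_sample_sheet(discovery.samples, inputs / "discovery_samples.csv")
    write_beta_matrix(validation, inputs / "validation_beta.tsv")
    write_sample_sheet(validation.samples, inputs / "validation_samples.csv")
    write_ct_table(methylight_ct, inputs / "methylight_ct.csv")
    write_ct_table(expression_ct, inputs / "expression_ct.csv")
    write_droplet_table(wells, inputs / "ddpcr_droplets.csv")
    write_band_table(bands, inputs / "protein_bands.csv")
    truth.cgi_labels.rename("label").to_frame().pipe(
        _fmt_frame, inputs / "truth_cgi_labels.tsv", index_name="cgi"
    )
    manifest.add_stage(
        "simulate",
        len(discovery.cgis),
        sorted(str(p.relative_to(out)) for p in inputs.iterdir()),
    )

    # ---- selection --------------------------------------------------------
    if not discovery.samples.samples_in("tumour") or not discovery.samples.samples_in(
        "normal"
    ):
        raise ValidationError("selection stage: empty cohort group")
    records = select_biomarkers(discovery, validation, run_config)
    _fmt_frame(records, out / "selection.tsv", index_name="cgi")
    manifest.add_stage("select", int(records["selected"].sum()), ["selection.tsv"])

    # ---- MethyLight + ddPCR call matrix -----------------------------------
    calls = call_matrix_from_tables(methylight_ct, wells, run_config)
    _fmt_frame(calls, out / "call_matrix.tsv")
    conc = concordance_table(calls)
    _fmt_frame(conc, out / "concordance.tsv")
    manifest.add_stage("call", len(calls), ["call_matrix.tsv", "concordance.tsv"])

    # ---- expression --------------------------------------------------------
    expr = expression_report(expression_ct, bands, run_config)
    _fmt_frame(expr, out / "expression.tsv")
    manifest.add_stage("expression", len(expr), ["expression.tsv"])

    # ---- summary -----------------------------------------------------------
    summary = {
        "seed": sim_config.seed,
        "n_cgi_total": len(discovery.cgis),
        "n_selected": int(records["selected"].sum()),
        "selected_genes": sorted(
            k.gene for k in records.index[records["selected"]]
        ),
        "thresholds": run_config.to_dict(),
        "detection_rates": {
            target: {
                "methylight": float(
                    (calls[calls["target"] == target]["stool_methylight"] == "methylated").mean()
                ),
                "ddpcr": float(
                    (calls[calls["target"] == target]["stool_ddpcr"] == "methylated").mean()
                ),
            }
            for target in sorted(calls["target"].unique())
        },
        "regulation": {
            f"{r['gene']}_{r['assay']}": r["regulation"] for _, r in expr.iterrows()
        },
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (out / "manifest.json").write_text(manifest.to_json() + "\n", encoding="utf-8")
    return manifest
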