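"""Worked-example data from a published colorectal-cancer stool-methylation
study, shipped as plain-text package data.

Three tables are included:

* ``crc_selected_cgis.tsv`` — the 24 promoter CpG islands that cleared the
  selection cascade, with per-cohort Δβ (mean tumour β − mean normal β)
  and tumour-vs-normal AUC in the discovery and validation cohorts;
* ``crc_methylation_calls.tsv`` — the per-patient call matrix for the two
  assayed islands (GRIA4, VIPR2): tissue-pair MethyLight call, stool
  MethyLight call, and stool ddPCR call for ten patients;
* ``assay_primers.tsv`` — MethyLight/ddPCR primer-probe and qRT-PCR primer
  sequences for the assayed targets.

These serve as ready-made inputs for the summary-level operations
(AUC gating on precomputed AUCs, call counting, assay concordance) and as
reference points for the synthetic generator's defaults.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import CGIKey

__all__ = [
    "load_selected_cgis",
    "load_call_matrix",
    "load_assay_primers",
    "tissue_call_counts",
    "detection_counts",
]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("cgimeth.data") / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", keep_default_na=False)


def load_selected_cgis() -> pd.DataFrame:
    """Selection summary of the 24 published CpG islands.

    Columns: cgi (string key), gene, delta_beta_discovery, auc_discovery,
    delta_beta_validation, auc_validation, plus a parsed ``key`` column of
    :class:`~cgimeth.io.CGIKey`.
    """
    table = _read("crc_selected_cgis.tsv")
    table["key"] = [
        CGIKey.parse(c, g) for c, g in zip(table["cgi"], table["gene"])
    ]
    return table


def load_call_matrix() -> pd.DataFrame:
    """Published per-patient methylation call matrix (10 patients x 2 targets).

    Columns: sample, target, tissue_call, stool_methylight, stool_ddpcr.
    """
    return _read("crc_methylation_calls.tsv")


def load_assay_primers() -> pd.DataFrame:
    """Primer/probe sequences of the MethyLight, ddPCR and qRT-PCR assays."""
    return _read("assay_primers.tsv")


def tissue_call_counts(calls: pd.DataFrame, target: str) -> dict[str, int]:
    """Count tissue-pair call categories for one target."""
    sub = calls[calls["target"] == target]
    return sub["tissue_call"].value_counts().to_dict()


def detection_counts(calls: pd.DataFrame, target: str, assay: str) -> tuple[int, int]:
    """(detected, total) stool detections for ``assay`` in
    {'stool_methylight', 'stool_ddpcr'}."""
    if assay not in ("stool_methylight", "stool_ddpcr"):
        raise ValueError(f"unknown stool assay column {assay!r}")
    sub = calls[calls["target"] == target]
    return int((sub[assay] == "methylated").sum()), int(len(sub))
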