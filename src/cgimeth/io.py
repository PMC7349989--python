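"""Tabular input/output for every table the pipeline touches.

All formats are plain text: TSV for the CGI-by-sample β matrix and result
tables, CSV for sample sheets, qPCR Ct tables, droplet-count tables and
protein band-intensity tables, BED6 for exporting CGI intervals.

Conventions
-----------
* CGI coordinates are 1-based inclusive in their string form
  (``chr11:105481126-105481422``); BED export converts to 0-based
  half-open.
* Decimal point only, UTF-8, Unix newlines on write (any newline accepted
  on read).
* The qPCR token ``Undetermined`` is parsed as a no-amplification flag and
  is never coerced to a number.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "CGIKey",
    "SampleSheet",
    "BetaMatrix",
    "CtMeasurement",
    "DropletWell",
    "BandMeasurement",
    "UNDETERMINED",
    "GROUPS",
    "COHORTS",
    "CT_MATRICES",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_ct_table",
    "write_ct_table",
    "read_droplet_table",
    "write_droplet_table",
    "read_band_table",
    "write_band_table",
    "write_cgi_bed",
]

GROUPS = ("tumour", "normal")
COHORTS = ("discovery", "validation")
CT_MATRICES = ("tissue_tumour", "tissue_normal", "stool")
UNDETERMINED = "Undetermined"

_CGI_RE = re.compile(r"^(?P<chrom>[A-Za-z0-9_.]+):(?P<start>\d+)-(?P<end>\d+)$")


def _fmt(x: float) -> str:
    """Canonical text form of a float (shortest repr, '' for missing)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return repr(float(x))


# ---------------------------------------------------------------------------
# CGI keys
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class CGIKey:
    """A CpG island identified by its genomic interval.

    Coordinates are 1-based inclusive, so the printed form
    ``chrom:start-end`` round-trips exactly and ``width == end - start + 1``.
    """

    chrom: str
    start: int
    end: int
    gene: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"CGI start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"CGI end {self.end} precedes start {self.start} ({self.chrom})"
            )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def parse(cls, text: str, gene: str = "") -> "CGIKey":
        m = _CGI_RE.match(text.strip())
        if m is None:
            raise ValidationError(f"malformed CGI key {text!r}")
        return cls(m["chrom"], int(m["start"]), int(m["end"]), gene)


def write_cgi_bed(cgis: Iterable[CGIKey], path: str | Path) -> None:
    """Export CGIs as BED6 (0-based half-open; name column = gene symbol)."""
    lines = []
    for cgi in cgis:
        lines.append(
            "\t".join(
                [cgi.chrom, str(cgi.start - 1), str(cgi.end), cgi.gene or ".", "0", "."]
            )
        )
    Path(path).write_text("".join(line + "\n" for line in lines), encoding="utf-8")


def read_cgi_bed(path: str | Path) -> list[CGIKey]:
    """Read a BED6 file back into 1-based inclusive CGI keys."""
    cgis = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
        cgis.append(CGIKey(fields[0], int(fields[1]) + 1, int(fields[2]), name))
    return cgis


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------


@dataclass
class SampleSheet:
    """Assignment of samples to group (tumour/normal) and cohort.

    ``pair_id`` optionally links a tumour to its matched normal; when
    present each pair id must map to exactly one tumour and one normal.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "cohort"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns {sorted(missing)}")
        if "pair_id" not in self.table.columns:
            self.table = self.table.assign(pair_id="")
        self.table = self.table.fillna({"pair_id": ""}).reset_index(drop=True)
        ids = self.table["sample_id"]
        dup = ids[ids.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate sample id {dup.iloc[0]!r}")
        bad_group = set(self.table["group"]) - set(GROUPS)
        if bad_group:
            raise ValidationError(f"unknown group(s) {sorted(bad_group)}")
        bad_cohort = set(self.table["cohort"]) - set(COHORTS)
        if bad_cohort:
            raise ValidationError(f"unknown cohort(s) {sorted(bad_cohort)}")
        for pid, sub in self.table[self.table["pair_id"] != ""].groupby("pair_id"):
            counts = sub["group"].value_counts()
            if counts.get("tumour", 0) != 1 or counts.get("normal", 0) != 1:
                raise ValidationError(
                    f"pair {pid!r} must link exactly one tumour and one normal"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_in(self, group: str | None = None, cohort: str | None = None) -> list[str]:
        sub = self.table
        if group is not None:
            sub = sub[sub["group"] == group]
        if cohort is not None:
            sub = sub[sub["cohort"] == cohort]
        return list(sub["sample_id"])

    def subset(self, cohort: str) -> "SampleSheet":
        return SampleSheet(self.table[self.table["cohort"] == cohort].copy())


def read_sample_sheet(path: str | Path) -> SampleSheet:
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    return SampleSheet(table)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Beta matrix
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """CGI-by-sample β values with group/cohort labels attached.

    ``values`` is indexed by :class:`CGIKey` with one column per sample;
    entries are floats in [0, 1] or NaN for missing. Missing values are
    flagged, never dropped, and downstream statistics exclude them
    pairwise.
    """

    values: pd.DataFrame
    samples: SampleSheet

    def __post_init__(self) -> None:
        unknown = [c for c in self.values.columns if c not in self.samples.sample_ids]
        if unknown:
            raise ValidationError(f"unknown sample id in header: {unknown[0]!r}")
        keys = list(self.values.index)
        if len(set(keys)) != len(keys):
            seen: set[CGIKey] = set()
            for k in keys:
                if k in seen:
                    raise ValidationError(f"duplicate CGI key {k}")
                seen.add(k)
        arr = self.values.to_numpy(dtype=float)
        bad = np.argwhere(~np.isnan(arr) & ((arr < 0.0) | (arr > 1.0)))
        if len(bad):
            i, j = bad[0]
            raise ValidationError(
                f"beta value {arr[i, j]} outside [0, 1] at CGI "
                f"{self.values.index[i]}, sample {self.values.columns[j]!r}"
            )

    @property
    def cgis(self) -> list[CGIKey]:
        return list(self.values.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def group_values(
        self, cgi: CGIKey, group: str, cohort: str | None = None
    ) -> np.ndarray:
        """Present (non-missing) β values for one CGI restricted to a group."""
        cols = [
            s for s in self.samples.samples_in(group, cohort) if s in self.values.columns
        ]
        row = self.values.loc[cgi, cols].to_numpy(dtype=float)
        return row[~np.isnan(row)]

    def subset(self, cohort: str) -> "BetaMatrix":
        sheet = self.samples.subset(cohort)
        cols = [c for c in self.values.columns if c in sheet.sample_ids]
        return BetaMatrix(self.values[cols].copy(), sheet)


def read_beta_matrix(path: str | Path, sample_sheet: SampleSheet) -> BetaMatrix:
    """Read a β-value TSV (columns: cgi, gene, then one column per sample).

    Rows and columns are preserved in file order. Values must be numeric in
    [0, 1] or empty/NA for missing; violations raise
    :class:`~cgimeth.errors.ValidationError` naming the offending cell.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if len(raw.columns) < 2 or raw.columns[0] != "cgi":
        raise ValidationError("beta matrix must start with a 'cgi' column")
    has_gene = len(raw.columns) > 1 and raw.columns[1] == "gene"
    sample_cols = list(raw.columns[2 if has_gene else 1 :])
    keys = []
    for _, row in raw.iterrows():
        keys.append(CGIKey.parse(row["cgi"], row["gene"] if has_gene else ""))
    data = {}
    for col in sample_cols:
        parsed = []
        for key, cell in zip(keys, raw[col]):
            cell = cell.strip()
            if cell == "" or cell.upper() in {"NA", "NAN"}:
                parsed.append(np.nan)
                continue
            try:
                value = float(cell)
            except ValueError:
                raise ValidationError(
                    f"non-numeric beta value {cell!r} at CGI {key}, sample {col!r}"
                ) from None
            parsed.append(value)
        data[col] = parsed
    values = pd.DataFrame(data, index=keys, dtype=float)
    return BetaMatrix(values, sample_sheet)


def write_beta_matrix(matrix: BetaMatrix, path: str | Path) -> None:
    """Write the canonical TSV form (see :func:`read_beta_matrix`)."""
    lines = ["\t".join(["cgi", "gene", *matrix.values.columns])]
    for cgi, row in matrix.values.iterrows():
        cells = [str(cgi), cgi.gene]
        cells.extend(_fmt(v) for v in row)
        lines.append("\t".join(cells))
    Path(path).write_text("".join(line + "\n" for line in lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CtMeasurement:
    """One qPCR replicate: a Ct value or a no-amplification flag.

    ``ct`` is ``None`` when the replicate did not amplify within the cycle
    cap (the instrument reports ``Undetermined``).
    """

    sample_id: str
    matrix: str
    target: str
    replicate: int
    ct: float | None

    @property
    def amplified(self) -> bool:
        return self.ct is not None


def read_ct_table(path: str | Path, ct_cap: float = 50.0) -> list[CtMeasurement]:
    """Read a Ct CSV (columns: sample, matrix, target, replicate, ct).

    ``ct`` is a number or the literal token ``Undetermined``. Replicate
    indices must be unique within (sample, matrix, target); Ct values must
    lie in (0, ct_cap].
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"sample", "matrix", "target", "replicate", "ct"}
    missing = required - set(raw.columns)
    if missing:
        raise ValidationError(f"Ct table missing columns {sorted(missing)}")
    out: list[CtMeasurement] = []
    seen: set[tuple[str, str, str, int]] = set()
    for i, row in raw.iterrows():
        mat = row["matrix"]
        if mat not in CT_MATRICES:
            raise ValidationError(f"unknown matrix {mat!r} on line {i + 2}")
        rep = int(row["replicate"])
        key = (row["sample"], mat, row["target"], rep)
        if key in seen:
            raise ValidationError(f"duplicate replicate index {key} on line {i + 2}")
        seen.add(key)
        token = row["ct"].strip()
        if token == UNDETERMINED:
            ct: float | None = None
        else:
            ct = float(token)
            if ct <= 0:
                raise ValidationError(f"non-positive Ct {ct} on line {i + 2}")
            if ct > ct_cap:
                raise ValidationError(
                    f"Ct {ct} exceeds the {ct_cap}-cycle cap on line {i + 2}"
                )
        out.append(CtMeasurement(row["sample"], mat, row["target"], rep, ct))
    return out


def write_ct_table(measurements: Sequence[CtMeasurement], path: str | Path) -> None:
    lines = ["sample,matrix,target,replicate,ct"]
    for m in measurements:
        token = UNDETERMINED if m.ct is None else _fmt(m.ct)
        lines.append(f"{m.sample_id},{m.matrix},{m.target},{m.replicate},{token}")
    Path(path).write_text("".join(line + "\n" for line in lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# ddPCR droplet tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DropletWell:
    """Droplet counts of a single ddPCR well, pre-classified by the reader."""

    sample_id: str
    target: str
    well: str
    n_total: int
    n_positive: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValidationError(
                f"well {self.well!r} ({self.sample_id}/{self.target}): n_total must be > 0"
            )
        if not 0 <= self.n_positive <= self.n_total:
            raise ValidationError(
                f"well {self.well!r} ({self.sample_id}/{self.target}): "
                f"n_positive {self.n_positive} outside [0, {self.n_total}]"
            )


def read_droplet_table(path: str | Path) -> list[DropletWell]:
    """Read a droplet CSV (columns: sample, target, well, n_total, n_positive)."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"sample", "target", "well", "n_total", "n_positive"}
    missing = required - set(raw.columns)
    if missing:
        raise ValidationError(f"droplet table missing columns {sorted(missing)}")
    out = []
    for _, row in raw.iterrows():
        out.append(
            DropletWell(
                row["sample"],
                row["target"],
                row["well"],
                int(row["n_total"]),
                int(row["n_positive"]),
            )
        )
    return out


def write_droplet_table(wells: Sequence[DropletWell], path: str | Path) -> None:
    lines = ["sample,target,well,n_total,n_positive"]
    for w in wells:
        lines.append(f"{w.sample_id},{w.target},{w.well},{w.n_total},{w.n_positive}")
    Path(path).write_text("".join(line + "\n" for line in lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# Protein band-intensity tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandMeasurement:
    """One western-blot lane: target band and loading-control intensities."""

    sample_id: str
    group: str
    target: str
    replicate: int
    target_intensity: float
    loading_intensity: float

    def __post_init__(self) -> None:
        if self.target_intensity <= 0 or self.loading_intensity <= 0:
            raise ValidationError(
                f"non-positive band intensity for {self.sample_id}/{self.target}"
            )

    @property
    def normalized(self) -> float:
        return self.target_intensity / self.loading_intensity


def read_band_table(path: str | Path) -> list[BandMeasurement]:
    """Read a band CSV (sample, group, target, replicate, target_intensity,
    loading_intensity)."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {
        "sample",
        "group",
        "target",
        "replicate",
        "target_intensity",
        "loading_intensity",
    }
    missing = required - set(raw.columns)
    if missing:
        raise ValidationError(f"band table missing columns {sorted(missing)}")
    out = []
    for _, row in raw.iterrows():
        if row["group"] not in GROUPS:
            raise ValidationError(f"unknown group {row['group']!r}")
        out.append(
            BandMeasurement(
                row["sample"],
                row["group"],
                row["target"],
                int(row["replicate"]),
                float(row["target_intensity"]),
                float(row["loading_intensity"]),
            )
        )
    return out


def write_band_table(bands: Sequence[BandMeasurement], path: str | Path) -> None:
    lines = ["sample,group,target,replicate,target_intensity,loading_intensity"]
    for b in bands:
        lines.append(
            f"{b.sample_id},{b.group},{b.target},{b.replicate},"
            f"{_fmt(b.target_intensity)},{_fmt(b.loading_intensity)}"
        )
    Path(path).write_text("".join(line + "\n" for line in lines), encoding="utf-8")
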