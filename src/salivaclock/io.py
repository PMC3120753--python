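"""Tabular input/output for methylation beta matrices and sample metadata.

The on-disk conventions follow the GenomeStudio beta-table layout: probes in
rows, samples in columns, tab-separated, ``NA`` for missing.  Sample sheets
and probe annotations are comma-separated with mandatory headers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "SampleSheet",
    "ProbeAnnotation",
    "FormatError",
    "ValidationError",
    "AlignmentError",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_probe_annotation",
    "write_probe_annotation",
    "align",
]


class FormatError(ValueError):
    """Malformed table: duplicate identifiers, missing columns, bad header."""


class ValidationError(ValueError):
    """Well-formed table with out-of-contract values (e.g. beta outside [0,1])."""


class AlignmentError(ValueError):
    """No overlap between the identifiers of the tables being aligned."""


SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "pair_id",
    "age",
    "sex",
    "batch_id",
    "replicate_of",
    "cohort",
]

ANNOTATION_COLUMNS = [
    "probe_id",
    "chrom",
    "position",
    "gene_symbol",
    "tss_offset",
    "in_cpg_island",
]


@dataclass
class BetaMatrix:
    """Probes × samples matrix of methylation fractions.

    Each value is the beta value of a CpG probe in a sample: the fraction of
    methylated cytosines at that locus, bounded in [0, 1].  Missing values are
    stored as NaN.
    """

    data: pd.DataFrame  # index = probe ids, columns = sample ids

    def __post_init__(self) -> None:
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.data.index.name = "probe_id"
        self.data.columns.name = None
        self.validate()

    # -- container surface -------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def validate(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate probe id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        vals = self.data.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {vals[i, j]!r} outside [0, 1] at probe "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )

    def drop_incomplete_probes(self) -> "BetaMatrix":
        """Drop probes with any missing value (statistics assume complete rows)."""
        return BetaMatrix(self.data.dropna(axis=0))

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(self.data.copy())


@dataclass
class SampleSheet:
    """Per-sample metadata: twin pair, age, sex, batch and replicate links."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns {missing}")
        self.data = self.data[SAMPLE_SHEET_COLUMNS].copy()
        self.data["sample_id"] = self.data["sample_id"].astype(str)
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def validate(self) -> None:
        sid = self.data["sample_id"]
        if sid.duplicated().any():
            raise FormatError(f"duplicate sample id {sid[sid.duplicated()].iloc[0]!r}")
        ages = pd.to_numeric(self.data["age"], errors="coerce")
        if not np.isfinite(ages).all() or (ages <= 0).any():
            raise ValidationError("ages must be finite and > 0")
        self.data["age"] = ages.astype(float)
        known = set(sid)
        reps = self.data["replicate_of"].dropna()
        reps = reps[reps.astype(str).str.len() > 0]
        unknown = set(reps.astype(str)) - known
        if unknown:
            raise ValidationError(f"replicate_of points at unknown samples {sorted(unknown)}")
        primaries = self.data[self.data["replicate_of"].isna() | (self.data["replicate_of"] == "")]
        counts = primaries["pair_id"].dropna()
        counts = counts[counts.astype(str).str.len() > 0].value_counts()
        bad_pairs = counts[counts != 2]
        if len(bad_pairs):
            raise ValidationError(
                f"pair ids must label exactly 2 non-replicate samples; offending: "
                f"{dict(bad_pairs)}"
            )

    def row(self, sample_id: str) -> pd.Series:
        return self.data.set_index("sample_id").loc[sample_id]

    def subset(self, sample_ids: list[str]) -> "SampleSheet":
        sub = self.data[self.data["sample_id"].isin(sample_ids)].copy()
        # replicate links to dropped samples become dangling; sever them
        keep = set(sub["sample_id"])
        sub.loc[~sub["replicate_of"].isin(keep), "replicate_of"] = np.nan
        return SampleSheet(sub)

    def ages_for(self, sample_ids: list[str]) -> np.ndarray:
        return self.data.set_index("sample_id").loc[sample_ids, "age"].to_numpy(float)


@dataclass
class ProbeAnnotation:
    """Probe genomic context: position, gene, TSS offset, CpG-island flag.

    ``tss_offset`` is signed: negative = upstream of the transcription start
    site (promoter side).  Positions are 1-based.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"probe annotation missing columns {missing}")
        self.data = self.data[ANNOTATION_COLUMNS].copy()
        self.data["probe_id"] = self.data["probe_id"].astype(str)
        self.validate()

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data["probe_id"])

    def validate(self) -> None:
        pid = self.data["probe_id"]
        if pid.duplicated().any():
            raise FormatError(f"duplicate probe id {pid[pid.duplicated()].iloc[0]!r}")
        pos = pd.to_numeric(self.data["position"], errors="coerce")
        if (pos < 1).any() or pos.isna().any():
            raise ValidationError("positions must be integers >= 1")
        self.data["in_cpg_island"] = self.data["in_cpg_island"].astype(bool)

    def subset(self, probe_ids: list[str]) -> "ProbeAnnotation":
        return ProbeAnnotation(self.data[self.data["probe_id"].isin(probe_ids)].copy())


# -- readers / writers ------------------------------------------------------

def read_beta_matrix(path: str | Path, dialect: str = "tsv") -> BetaMatrix:
    """Read a probes × samples beta table (first column probe ids, header samples)."""
    if dialect != "tsv":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""], dtype=str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric beta value in {path}: {exc}") from exc
    return BetaMatrix(df)


def write_beta_matrix(bm: BetaMatrix, path: str | Path) -> None:
    df = bm.data.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6f")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, dtype={"sample_id": str, "pair_id": str,
                                  "batch_id": str, "replicate_of": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data.to_csv(path, index=False)


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    df = pd.read_csv(path, dtype={"probe_id": str, "chrom": str})
    return ProbeAnnotation(df)


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    ann.data.to_csv(path, index=False)


# -- alignment ---------------------------------------------------------------

@dataclass
class AlignmentReport:
    dropped_samples: list[str] = field(default_factory=list)
    dropped_sheet_rows: list[str] = field(default_factory=list)
    unannotated_probes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dropped_samples": self.dropped_samples,
            "dropped_sheet_rows": self.dropped_sheet_rows,
            "n_unannotated_probes": len(self.unannotated_probes),
        }


def align(
    bm: BetaMatrix, sheet: SampleSheet, ann: ProbeAnnotation
) -> tuple[BetaMatrix, SampleSheet, ProbeAnnotation, AlignmentReport]:
    """Restrict the three tables to shared identifiers, in sample-sheet order.

    Columns are reordered to the sheet's order restricted to shared samples;
    probes absent from the annotation are kept but reported as unannotated.
    """
    shared_samples = [s for s in sheet.sample_ids if s in set(bm.sample_ids)]
    if not shared_samples:
        raise AlignmentError("no samples shared between beta matrix and sample sheet")
    annotated = set(ann.probe_ids)
    unannotated = [p for p in bm.probe_ids if p not in annotated]
    report = AlignmentReport(
        dropped_samples=[s for s in bm.sample_ids if s not in set(shared_samples)],
        dropped_sheet_rows=[s for s in sheet.sample_ids if s not in set(bm.sample_ids)],
        unannotated_probes=unannotated,
    )
    bm2 = BetaMatrix(bm.data.loc[:, shared_samples])
    sheet2 = sheet.subset(shared_samples)
    ann2 = ann.subset(bm.probe_ids)
    return bm2, sheet2, ann2, report


def write_run_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
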