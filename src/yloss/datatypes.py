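"""Core in-memory containers for the pipeline.

All containers are thin, validated wrappers around pandas objects. The
expression matrix is transcripts x samples on the log2 scale; coverage,
methylation and amplicon tables are long-format DataFrames. Validation is
eager: invariant violations raise at construction, naming the offending
record where possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOMES = tuple(str(i) for i in range(1, 23))
VALID_CHROMS = AUTOSOMES + ("X", "Y", "MT")


class ValidationError(ValueError):
    """A container invariant was violated."""


def normalize_chrom(c) -> str:
    """Strip an optional 'chr' prefix; the only place this conversion happens."""
    s = str(c)
    return s[3:] if s.lower().startswith("chr") else s


ANNOTATION_COLUMNS = ("chromosome", "gene_symbol", "cross_hybridisation",
                      "mrna_assigned", "probe_category")


@dataclass
class ExpressionMatrix:
    """Transcripts x samples log2 intensity matrix with transcript annotations.

    ``values``: DataFrame indexed by transcript id, columns sample ids.
    ``annotation``: DataFrame indexed by transcript id with columns
    chromosome, gene_symbol, cross_hybridisation (int), mrna_assigned (bool),
    probe_category (str).
    """

    values: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValidationError(f"duplicate transcript id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        arr = v.to_numpy()
        if arr.size and not np.isfinite(arr.astype(float)).all():
            raise ValidationError("expression values must be finite")
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.annotation.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        if not v.index.isin(self.annotation.index).all():
            extra = v.index[~v.index.isin(self.annotation.index)][0]
            raise ValidationError(f"transcript {extra!r} lacks annotation")
        self.annotation = self.annotation.loc[v.index].copy()
        self.annotation["chromosome"] = (
            self.annotation["chromosome"].map(normalize_chrom)
        )
        bad = ~self.annotation["chromosome"].isin(VALID_CHROMS)
        if bad.any():
            raise ValidationError(
                f"invalid chromosome {self.annotation['chromosome'][bad].iloc[0]!r}"
            )

    @property
    def transcripts(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_transcripts(self, ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[ids], self.annotation.loc[ids])

    def subset_samples(self, ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(ids)], self.annotation)


METADATA_COLUMNS = ("sample_id", "patient_id", "tissue", "sex", "age",
                    "histology", "smoking", "stage", "fev1", "bmi",
                    "time", "event")


@dataclass
class SampleMetadata:
    """Per-sample clinical records (one row per sample).

    tissue in {tumour, normal}; sex in {M, F}; histology in {LUAD, LUSC};
    smoking in {NS, EX, CS, NR}; stage an ordered label; time/event the
    right-censored survival outcome (per patient, replicated on both
    tissues). Each patient may contribute at most one tumour and one normal
    sample.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in METADATA_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if t["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in metadata")
        counts = t.groupby(["patient_id", "tissue"]).size()
        if (counts > 1).any():
            pid, tis = counts[counts > 1].index[0]
            raise ValidationError(
                f"patient {pid!r} has multiple {tis!r} samples")
        bad_tissue = ~t["tissue"].isin(["tumour", "normal"])
        if bad_tissue.any():
            raise ValidationError(
                f"invalid tissue {t['tissue'][bad_tissue].iloc[0]!r}")
        if not t["sex"].isin(["M", "F"]).all():
            raise ValidationError("sex must be 'M' or 'F'")
        times = pd.to_numeric(t["time"], errors="coerce")
        if (times.dropna() < 0).any():
            raise ValidationError("follow-up time must be >= 0")
        ev = t["event"].astype("boolean")
        if (ev.fillna(False) & times.isna()).any():
            raise ValidationError("event recorded without follow-up time")
        self.table = t.reset_index(drop=True)

    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    def for_samples(self, sample_ids) -> pd.DataFrame:
        """Rows aligned to the given sample order."""
        idx = self.table.set_index("sample_id")
        return idx.loc[list(sample_ids)].reset_index()


COVERAGE_COLUMNS = ("sample_id", "gene", "chromosome", "gene_length", "read_count")


@dataclass
class CoverageTable:
    """Per-gene, per-sample read counts plus per-sample library sizes."""

    table: pd.DataFrame
    library_sizes: pd.Series  # indexed by sample id

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in COVERAGE_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"coverage table missing columns: {missing}")
        if (t["read_count"] < 0).any():
            raise ValidationError("read counts must be >= 0")
        if (t["gene_length"] <= 0).any():
            raise ValidationError("gene lengths must be > 0")
        t = t.copy()
        t["chromosome"] = t["chromosome"].map(normalize_chrom)
        samples = t["sample_id"].unique()
        missing_lib = [s for s in samples if s not in self.library_sizes.index]
        if missing_lib:
            raise ValidationError(f"no library size for sample {missing_lib[0]!r}")
        sums = t.groupby("sample_id")["read_count"].sum()
        libs = self.library_sizes.loc[sums.index]
        short = sums[sums > libs]
        if len(short):
            raise ValidationError(
                f"library size smaller than listed counts for {short.index[0]!r}")
        self.table = t.reset_index(drop=True)


@dataclass
class MethylationTable:
    """Per-CpG methylation counts for one sample.

    ``table`` columns: chromosome, position (1-based), coverage, methylated;
    positions strictly increasing within each chromosome.
    """

    sample_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for c in ("chromosome", "position", "coverage", "methylated"):
            if c not in t.columns:
                raise ValidationError(f"methylation table missing column {c!r}")
        t = t.copy()
        t["chromosome"] = t["chromosome"].map(normalize_chrom)
        if (t["methylated"] > t["coverage"]).any():
            row = t[t["methylated"] > t["coverage"]].iloc[0]
            raise ValidationError(
                f"methylated > coverage at {row['chromosome']}:{row['position']}")
        if (t["methylated"] < 0).any() or (t["coverage"] < 0).any():
            raise ValidationError("negative counts in methylation table")
        for chrom, grp in t.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(
                    f"positions not strictly increasing on chromosome {chrom}")
        self.table = t.reset_index(drop=True)


AMPLICON_COLUMNS = ("sample_id", "site_id", "replicate", "y_intensity",
                    "control_intensity")


@dataclass
class AmpliconTable:
    """PCR amplification intensities: Y-linked site vs non-Y control, 3 reps."""

    table: pd.DataFrame
    incomplete: list = field(default_factory=list)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in AMPLICON_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"amplicon table missing columns: {missing}")
        if (t["y_intensity"] <= 0).any() or (t["control_intensity"] <= 0).any():
            raise ValidationError("amplicon intensities must be > 0")
        counts = t.groupby(["sample_id", "site_id"]).size()
        self.incomplete = [k for k, v in counts.items() if v != 3]
        self.table = t.reset_index(drop=True)
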