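"""Readers and writers for every file format the pipeline touches.

All bespoke tables are plain TSV/CSV with explicit headers. BED follows the
UCSC dialect (0-based, half-open); methylation positions are 1-based.
Chromosome names are normalised by stripping an optional "chr" prefix at
parse time. Readers validate eagerly and raise ParseError naming the
offending content; writer/reader pairs round-trip at text precision.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from intervaltree import Interval, IntervalTree

from .datatypes import (AmpliconTable, ANNOTATION_COLUMNS, CoverageTable,
                        ExpressionMatrix, MethylationTable, SampleMetadata,
                        ValidationError, normalize_chrom)
from .network import NetworkParams
from .simulate import PlantedDMR, SyntheticConfig, TruthLabels

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# expression


def read_expression(path, annotation_path=None) -> ExpressionMatrix:
    """Expression TSV (first column transcript id, header of sample ids)
    plus a sidecar annotation TSV (default: <path>.annotation.tsv)."""
    path = Path(path)
    if annotation_path is None:
        annotation_path = path.with_suffix(path.suffix + ".annotation.tsv")
    try:
        values = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate transcript id {dup!r}")
    non_numeric = values.columns[
        [not pd.api.types.is_numeric_dtype(values[c]) for c in values.columns]]
    if len(non_numeric):
        raise ParseError(f"{path}: non-numeric column {non_numeric[0]!r}")
    try:
        ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"{annotation_path}: {exc}") from exc
    try:
        return ExpressionMatrix(values, ann)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_expression(m: ExpressionMatrix, path, annotation_path=None) -> None:
    path = Path(path)
    if annotation_path is None:
        annotation_path = path.with_suffix(path.suffix + ".annotation.tsv")
    m.values.to_csv(path, sep="\t", index_label="transcript_id",
                    float_format=FLOAT_FORMAT)
    m.annotation.to_csv(annotation_path, sep="\t",
                        index_label="transcript_id")


# ---------------------------------------------------------------------------
# metadata


def read_metadata(path) -> SampleMetadata:
    try:
        t = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    try:
        return SampleMetadata(t)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# coverage


def read_coverage(path, library_path=None) -> CoverageTable:
    """Coverage TSV plus per-sample library sizes
    (default sidecar: <path>.libsizes.tsv)."""
    path = Path(path)
    if library_path is None:
        library_path = path.with_suffix(path.suffix + ".libsizes.tsv")
    try:
        t = pd.read_csv(path, sep="\t")
        libs = pd.read_csv(library_path, sep="\t")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not {"sample_id", "library_size"} <= set(libs.columns):
        raise ParseError(f"{library_path}: need sample_id and library_size")
    series = libs.set_index("sample_id")["library_size"]
    try:
        return CoverageTable(t, series)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_coverage(cov: CoverageTable, path, library_path=None) -> None:
    path = Path(path)
    if library_path is None:
        library_path = path.with_suffix(path.suffix + ".libsizes.tsv")
    cov.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    cov.library_sizes.rename("library_size").to_csv(
        library_path, sep="\t", index_label="sample_id",
        float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# methylation


def read_methylation(path, sample_id: str | None = None) -> MethylationTable:
    """One sample's CpG counts.

    Accepts the Bismark-style 6-column coverage dialect without header
    (chrom, start [0-based], end, methylation %, methylated, unmethylated)
    or a headered CpG-report TSV (chromosome, position [1-based], coverage,
    methylated, optionally sample_id).
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if "position" in first and "coverage" in first:
        t = pd.read_csv(path, sep="\t")
        if sample_id is None:
            sample_id = (str(t["sample_id"].iloc[0]) if "sample_id" in t
                         else path.stem)
        if "sample_id" in t.columns:
            t = t[t["sample_id"].astype(str) == str(sample_id)]
            t = t.drop(columns=["sample_id"])
        tab = t[["chromosome", "position", "coverage", "methylated"]].copy()
    else:
        t = pd.read_csv(path, sep="\t", header=None,
                        names=["chromosome", "start", "end", "pct",
                               "methylated", "unmethylated"])
        if t[["methylated", "unmethylated"]].isna().any().any():
            raise ParseError(
                f"{path}: need the 6-column coverage dialect with counts")
        tab = pd.DataFrame({
            "chromosome": t["chromosome"],
            "position": t["start"].astype(int) + 1,  # 0-based -> 1-based
            "coverage": (t["methylated"] + t["unmethylated"]).astype(int),
            "methylated": t["methylated"].astype(int),
        })
        if sample_id is None:
            sample_id = path.stem
    try:
        return MethylationTable(sample_id=str(sample_id), table=tab)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_methylation_set(path) -> list[MethylationTable]:
    """Combined CpG-report TSV with a sample_id column -> one table per sample."""
    t = pd.read_csv(path, sep="\t")
    if "sample_id" not in t.columns:
        raise ParseError(f"{path}: combined report needs a sample_id column")
    out = []
    for sid, grp in t.groupby("sample_id", sort=True):
        tab = grp[["chromosome", "position", "coverage", "methylated"]]
        try:
            out.append(MethylationTable(sample_id=str(sid),
                                        table=tab.reset_index(drop=True)))
        except ValidationError as exc:
            raise ParseError(f"{path} (sample {sid}): {exc}") from exc
    return out


def write_methylation_set(tables: list[MethylationTable], path) -> None:
    frames = []
    for t in tables:
        f = t.table.copy()
        f.insert(0, "sample_id", t.sample_id)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_methylation_bedgraph(t: MethylationTable, path) -> None:
    """Bismark-style 6-column coverage file (no header)."""
    tab = t.table
    out = pd.DataFrame({
        "chromosome": tab["chromosome"],
        "start": tab["position"] - 1,
        "end": tab["position"],
        "pct": np.where(tab["coverage"] > 0,
                        100.0 * tab["methylated"] / tab["coverage"].clip(lower=1),
                        0.0),
        "methylated": tab["methylated"],
        "unmethylated": tab["coverage"] - tab["methylated"],
    })
    out.to_csv(path, sep="\t", index=False, header=False,
               float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# amplicons


def read_amplicons(path) -> AmpliconTable:
    try:
        t = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    try:
        return AmpliconTable(t)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_amplicons(amp: AmpliconTable, path) -> None:
    amp.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# BED intervals


def read_bed(path) -> dict[str, IntervalTree]:
    """BED3+ -> per-chromosome IntervalTree, 0-based half-open.

    Optional columns 4 (name) and 6 (strand) are kept in the interval data.
    Output trees are sorted by construction; start >= end is an error.
    """
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: need >= 3 BED columns")
            chrom = normalize_chrom(parts[0])
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise ParseError(
                    f"{path}:{lineno}: start {start} >= end {end}")
            data = {"name": parts[3] if len(parts) > 3 else f"iv{lineno}",
                    "strand": parts[5] if len(parts) > 5 else "."}
            trees.setdefault(chrom, IntervalTree()).add(
                Interval(start, end, data))
    return trees


def write_bed(trees: dict[str, IntervalTree], path) -> None:
    rows = []
    for chrom in sorted(trees):
        for iv in sorted(trees[chrom]):
            rows.append((chrom, iv.begin, iv.end, iv.data.get("name", "."),
                         0, iv.data.get("strand", ".")))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def promoters_from_genes(genes: dict[str, IntervalTree],
                         upstream: int = 1000) -> dict[str, IntervalTree]:
    """1-kb (by default) upstream promoter intervals from stranded gene bodies.

    For '+' (or unstranded) genes the promoter is [start-upstream, start);
    for '-' genes it is [end, end+upstream). The only coordinate arithmetic
    on BED intervals happens here.
    """
    out: dict[str, IntervalTree] = {}
    for chrom, tree in genes.items():
        t = IntervalTree()
        for iv in tree:
            if iv.data.get("strand") == "-":
                start, end = iv.end, iv.end + upstream
            else:
                start, end = max(0, iv.begin - upstream), iv.begin
            if start < end:
                t.add(Interval(start, end, dict(iv.data)))
        out[chrom] = t
    return out


# ---------------------------------------------------------------------------
# truth labels, config


def write_truth(truth: TruthLabels, path) -> None:
    rows = [("low_y_sample", sid, str(bool(v)))
            for sid, v in truth.low_y.items()]
    rows += [("module_transcript", tid, str(int(v)))
             for tid, v in truth.modules.items()]
    rows += [("deficient_patient", pid, str(bool(v)))
             for pid, v in truth.deficient.items()]
    rows += [("log_hr", "planted", repr(truth.log_hr)),
             ("methylation_shift", "planted", repr(truth.methylation_shift)),
             ("degraded_module", "planted", str(truth.degraded_module))]
    pd.DataFrame(rows, columns=["kind", "id", "value"]).to_csv(
        path, sep="\t", index=False)


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(SyntheticConfig)}
_NETWORK_FIELDS = {f.name for f in dataclasses.fields(NetworkParams)}


def load_config(path) -> tuple[SyntheticConfig, NetworkParams]:
    """YAML config holding SyntheticConfig and NetworkParams keys, flat."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _CONFIG_FIELDS - _NETWORK_FIELDS
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    sim_kw = {k: v for k, v in raw.items() if k in _CONFIG_FIELDS}
    if "module_sizes" in sim_kw:
        sim_kw["module_sizes"] = tuple(sim_kw["module_sizes"])
    if "planted_dmrs" in sim_kw:
        sim_kw["planted_dmrs"] = tuple(
            PlantedDMR(**d) for d in sim_kw["planted_dmrs"])
    net_kw = {k: v for k, v in raw.items() if k in _NETWORK_FIELDS}
    return SyntheticConfig(**sim_kw), NetworkParams(**net_kw)


def write_table(df: pd.DataFrame, path) -> None:
    """Uniform TSV writer for result tables (fixed float format)."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
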