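"""Transcript filtering applied before network construction.

Two rules: (1) a transcript must exceed the global data-set median (the
median over every cell of the matrix) in at least one sample — strict
inequality; (2) its annotation must show unique hybridisation
(cross_hybridisation == 1), a non-missing mRNA assignment and membership of
the main probe-set design category. The median rule runs first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, ValidationError


@dataclass
class FilterReport:
    n_input: int
    n_after_median_filter: int
    n_after_annotation_filter: int
    removed: dict = field(default_factory=dict)  # rule -> list of transcript ids
    order: tuple = ("median", "annotation")

    def __post_init__(self) -> None:
        if not (self.n_input >= self.n_after_median_filter
                >= self.n_after_annotation_filter):
            raise ValidationError("filter counts must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": ["input", "median", "annotation"],
             "n_transcripts": [self.n_input, self.n_after_median_filter,
                               self.n_after_annotation_filter]})


def median_exceedance_filter(m: ExpressionMatrix):
    """Keep transcripts whose maximum exceeds the global median of all values."""
    if m.values.size == 0:
        raise ValidationError("empty expression matrix")
    global_median = float(np.median(m.values.to_numpy()))
    keep = m.values.max(axis=1) > global_median
    removed = list(m.values.index[~keep])
    out = m.subset_transcripts(m.values.index[keep])
    report = FilterReport(
        n_input=len(m.values),
        n_after_median_filter=int(keep.sum()),
        n_after_annotation_filter=int(keep.sum()),
        removed={"median": removed})
    return out, report


def annotation_filter(m: ExpressionMatrix):
    """Keep transcripts passing all three annotation predicates."""
    ann = m.annotation
    keep = ((ann["cross_hybridisation"] == 1)
            & ann["mrna_assigned"].astype(bool)
            & (ann["probe_category"] == "main"))
    removed = list(m.values.index[~keep])
    out = m.subset_transcripts(m.values.index[keep])
    report = FilterReport(
        n_input=len(m.values),
        n_after_median_filter=len(m.values),
        n_after_annotation_filter=int(keep.sum()),
        removed={"annotation": removed})
    return out, report


def filter_transcripts(m: ExpressionMatrix):
    """Median filter followed by annotation filter, with a combined report."""
    m1, r1 = median_exceedance_filter(m)
    m2, r2 = annotation_filter(m1)
    report = FilterReport(
        n_input=r1.n_input,
        n_after_median_filter=r1.n_after_median_filter,
        n_after_annotation_filter=r2.n_after_annotation_filter,
        removed={"median": r1.removed["median"],
                 "annotation": r2.removed["annotation"]})
    return m2, report
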