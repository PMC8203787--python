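"""Autosomal methylation summaries, group tests, DMR calling, promoters.

Per-sample summaries are medians of per-CpG methylation percentages over
autosomal CpGs (X, Y and MT are excluded throughout, so chromosome-Y read
depth cannot confound the methylation signal). The DMR caller is a
simplified single-replicate-capable smoothed Wald test: per-group
proportions are smoothed with a coverage-weighted 500-bp window, tested on
the arcsine-square-root scale with a binomial variance plus a
method-of-moments dispersion term shrunk toward the chromosome-wide mean,
and candidate CpGs are merged into regions. Everything here is
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from ._stats import (DegenerateTestError, hodges_lehmann_one_sample,
                     rank_sum_test, signed_rank_ci)
from .datatypes import AUTOSOMES, MethylationTable

logger = logging.getLogger(__name__)

DEFAULT_MIN_COVERAGE = 5
SMOOTH_WINDOW_BP = 500
MERGE_DISTANCE_BP = 1000
MIN_DMR_CPGS = 3
MIN_DMR_LENGTH_BP = 50


def median_methylation(t: MethylationTable,
                       min_coverage: int = DEFAULT_MIN_COVERAGE) -> float:
    """Median per-CpG methylation percentage over qualifying autosomal CpGs."""
    tab = t.table
    keep = tab["chromosome"].isin(AUTOSOMES) & (tab["coverage"] >= min_coverage)
    sub = tab[keep]
    if len(sub) == 0:
        raise ValueError(
            f"no autosomal CpGs at coverage >= {min_coverage} "
            f"for sample {t.sample_id!r}")
    pct = 100.0 * sub["methylated"] / sub["coverage"]
    return float(np.median(pct))


def paired_methylation_test(tumour_medians, normal_medians,
                            alpha: float = 0.05,
                            alpha_normality: float = 0.05):
    """Paired tumour-vs-normal comparison with a Shapiro–Wilk gate.

    Differences (tumour - normal) normal at ``alpha_normality`` -> paired
    two-sided t-test with the mean difference and its t CI; otherwise
    Wilcoxon signed-rank with the Hodges–Lehmann difference and exact CI.
    Returns (test name, statistic, estimate, (lo, hi), p).
    """
    x = np.asarray(tumour_medians, dtype=float)
    y = np.asarray(normal_medians, dtype=float)
    if x.size != y.size:
        raise ValueError("paired inputs must have equal length")
    if x.size < 4:
        raise ValueError("need >= 4 pairs")
    d = x - y
    if np.all(d == 0):
        raise DegenerateTestError("all paired differences are zero")
    if stats.shapiro(d).pvalue > alpha_normality:
        res = stats.ttest_rel(x, y)
        n = d.size
        se = d.std(ddof=1) / np.sqrt(n)
        tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
        est = float(d.mean())
        return ("paired-t", float(res.statistic), est,
                (est - tcrit * se, est + tcrit * se), float(res.pvalue))
    res = stats.wilcoxon(d, alternative="two-sided")
    est = hodges_lehmann_one_sample(d)
    lo, hi = signed_rank_ci(d, alpha)
    return ("wilcoxon", float(res.statistic), est, (lo, hi),
            float(res.pvalue))


def unpaired_methylation_test(group_a, group_b, alpha: float = 0.05):
    """Two-sided Mann–Whitney with HL shift estimate (A minus B) and CI."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need >= 3 values per group")
    return rank_sum_test(a, b, alpha)


# ---------------------------------------------------------------------------
# DMR calling


@dataclass
class DMR:
    chromosome: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    n_cpgs: int
    mean_diff: float  # group1 - group2, percentage points, smoothed
    min_p: float


def _pool_group(tables: list[MethylationTable]) -> pd.DataFrame:
    """Outer-join CpGs across samples, summing counts (missing = uncovered)."""
    frames = [t.table[["chromosome", "position", "coverage", "methylated"]]
              for t in tables]
    cat = pd.concat(frames, ignore_index=True)
    return (cat.groupby(["chromosome", "position"], as_index=False)
            [["coverage", "methylated"]].sum())


def _smooth(pos: np.ndarray, cov: np.ndarray, meth: np.ndarray,
            window: int = SMOOTH_WINDOW_BP):
    """Coverage-weighted moving-window proportion and effective coverage."""
    n = pos.size
    p_s = np.empty(n)
    cov_s = np.empty(n)
    lo = 0
    hi = 0
    csum_cov = np.concatenate([[0.0], np.cumsum(cov)])
    csum_meth = np.concatenate([[0.0], np.cumsum(meth)])
    half = window / 2.0
    for i in range(n):
        while pos[lo] < pos[i] - half:
            lo += 1
        while hi < n and pos[hi] <= pos[i] + half:
            hi += 1
        c = csum_cov[hi] - csum_cov[lo]
        m = csum_meth[hi] - csum_meth[lo]
        cov_s[i] = c
        p_s[i] = m / c if c > 0 else np.nan
    return p_s, cov_s


def call_dmrs(group1: list[MethylationTable], group2: list[MethylationTable],
              delta_min: float = 20.0, p_max: float = 0.001) -> list[DMR]:
    """Call regions differentially methylated between two sample groups.

    Per chromosome: counts are pooled within each group and smoothed
    (coverage-weighted, 500-bp window); each CpG covered in both groups is
    tested by a Wald statistic on the arcsine-sqrt scale whose variance is
    the binomial sampling term 1/(4*cov) per group plus a dispersion term
    shrunk toward the chromosome-wide method-of-moments estimate; candidate
    CpGs (p < p_max and |smoothed difference| > delta_min percentage points)
    within 1 kb of each other merge into regions, and regions must span >= 3
    CpGs and >= 50 bp. Sign convention: negative difference = hypomethylated
    in group1.
    """
    g1 = _pool_group(group1)
    g2 = _pool_group(group2)
    merged = g1.merge(g2, on=["chromosome", "position"], how="outer",
                      suffixes=("_1", "_2")).sort_values(
                          ["chromosome", "position"])
    dmrs: list[DMR] = []
    for chrom, grp in merged.groupby("chromosome", sort=False):
        grp = grp.dropna(subset=["coverage_1", "coverage_2"])
        grp = grp[(grp["coverage_1"] > 0) & (grp["coverage_2"] > 0)]
        if len(grp) < 2:
            if len(grp) == 1:
                logger.warning("chromosome %s has a single shared CpG; "
                               "no calls possible", chrom)
            continue
        pos = grp["position"].to_numpy(dtype=float)
        c1 = grp["coverage_1"].to_numpy(dtype=float)
        m1 = grp["methylated_1"].to_numpy(dtype=float)
        c2 = grp["coverage_2"].to_numpy(dtype=float)
        m2 = grp["methylated_2"].to_numpy(dtype=float)
        p1s, c1s = _smooth(pos, c1, m1)
        p2s, c2s = _smooth(pos, c2, m2)
        diff = p1s - p2s
        t1 = np.arcsin(np.sqrt(np.clip(p1s, 0, 1)))
        t2 = np.arcsin(np.sqrt(np.clip(p2s, 0, 1)))
        var_binom = 1.0 / (4.0 * c1s) + 1.0 / (4.0 * c2s)
        # extra-binomial dispersion, method of moments on the per-CpG RAW
        # between-group differences (the CpG's own mean level cancels, so
        # this estimates biological/overdispersion variance, not CpG-to-CpG
        # heterogeneity). The per-CpG 1-df estimates are too noisy to use
        # individually and a CpG's own signal would inflate its variance, so
        # shrinkage is taken to its limit: the chromosome-wide mean over
        # CpGs that do not themselves look signal-like.
        raw_diff = m1 / c1 - m2 / c2
        d_raw = np.arcsin(np.sqrt(m1 / c1)) - np.arcsin(np.sqrt(m2 / c2))
        excess = d_raw**2 - (1.0 / (4.0 * c1) + 1.0 / (4.0 * c2))
        background = np.abs(raw_diff) * 100.0 <= delta_min
        pool = excess[background] if background.any() else excess
        disp = max(float(np.mean(pool)), 0.0)
        # smoothing averages ~W CpGs; the dispersion term shrinks with the
        # effective window size (window coverage / single-CpG coverage)
        w_eff = np.maximum((c1s / c1 + c2s / c2) / 2.0, 1.0)
        var = var_binom + disp / w_eff
        z = (t1 - t2) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(np.abs(z))
        candidate = (p < p_max) & (np.abs(diff) * 100.0 > delta_min)
        # raw (unsmoothed) per-CpG evidence, used only to refine region
        # boundaries: the smoothed statistic is contaminated by out-of-region
        # CpGs within half a window of an edge
        var_raw = 1.0 / (4.0 * c1) + 1.0 / (4.0 * c2) + disp
        p_raw = 2.0 * stats.norm.sf(np.abs(d_raw) / np.sqrt(var_raw))
        raw_ok = (p_raw < p_max) & (np.abs(raw_diff) * 100.0 > delta_min)
        dmrs.extend(_merge_candidates(chrom, pos, candidate, diff * 100.0, p,
                                      raw_ok, raw_diff * 100.0))
    return dmrs


def _merge_candidates(chrom, pos, candidate, diff_pct, p,
                      raw_ok=None, raw_diff_pct=None) -> list[DMR]:
    out = []
    idx = np.flatnonzero(candidate)
    if idx.size == 0:
        return out
    runs = []
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if pos[i] - pos[prev] <= MERGE_DISTANCE_BP and \
                np.sign(diff_pct[i]) == np.sign(diff_pct[prev]):
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    n_pos = len(pos)
    for s, e in runs:
        sign = np.sign(diff_pct[s])
        if raw_ok is not None:
            # extend over flanking CpGs with independent raw evidence
            while (s > 0 and raw_ok[s - 1]
                   and np.sign(raw_diff_pct[s - 1]) == sign
                   and pos[s] - pos[s - 1] <= MERGE_DISTANCE_BP):
                s -= 1
            while (e < n_pos - 1 and raw_ok[e + 1]
                   and np.sign(raw_diff_pct[e + 1]) == sign
                   and pos[e + 1] - pos[e] <= MERGE_DISTANCE_BP):
                e += 1
        members = np.flatnonzero(candidate[s:e + 1]) + s
        if raw_ok is not None:
            raw_members = np.flatnonzero(
                raw_ok[s:e + 1]
                & (np.sign(raw_diff_pct[s:e + 1]) == sign)) + s
            members = np.union1d(members, raw_members).astype(int)
        n = members.size
        length = pos[e] - pos[s] + 1
        if n >= MIN_DMR_CPGS and length >= MIN_DMR_LENGTH_BP:
            out.append(DMR(chromosome=str(chrom), start=int(pos[s]),
                           end=int(pos[e]), n_cpgs=int(n),
                           mean_diff=float(np.mean(diff_pct[members])),
                           min_p=float(np.min(p[members]))))
    return out


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"chromosome": d.chromosome, "start": d.start, "end": d.end,
          "n_cpgs": d.n_cpgs, "mean_diff": d.mean_diff, "min_p": d.min_p}
         for d in dmrs],
        columns=["chromosome", "start", "end", "n_cpgs", "mean_diff",
                 "min_p"])


# ---------------------------------------------------------------------------
# promoter intersection


def promoter_overlap(dmrs: list[DMR], promoters) -> tuple[list, list, dict]:
    """Genes whose 1-kb upstream promoter a DMR overlaps by >= 1 bp.

    ``promoters`` is a per-chromosome interval collection (BED convention,
    0-based half-open) whose interval data carry gene names — the structure
    produced by io.read_bed. DMR coordinates are 1-based inclusive and are
    converted here, the only conversion site. A gene counts once; negative
    DMR differences mark hypomethylation.
    """
    hypo, hyper = set(), set()
    for d in dmrs:
        tree: IntervalTree | None = promoters.get(d.chromosome)
        if tree is None:
            continue
        # 1-based inclusive [start, end] -> 0-based half-open [start-1, end)
        hits = tree.overlap(d.start - 1, d.end)
        for h in hits:
            name = h.data["name"] if isinstance(h.data, dict) else h.data
            (hypo if d.mean_diff < 0 else hyper).add(name)
    counts = {"hypomethylated": len(hypo), "hypermethylated": len(hyper)}
    return sorted(hypo), sorted(hyper), counts
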