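"""Loss-of-Y detection and quantification.

Three independent lines of evidence are implemented: (1) a low-Y expression
cluster among male tumours, called from the sex-associated module's
transcripts; (2) chromosome-Y loss quantified from sequencing read depth
normalised by gene length and library size; (3) PCR amplification indices
(Y-linked amplicon vs non-Y control) summarised as tumour:normal ratios.
Group comparisons follow a Shapiro–Wilk normality gate between t and rank
tests, as is conventional for these small cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist

from ._stats import DegenerateTestError, rank_sum_test, signed_rank_test
from .datatypes import AmpliconTable, CoverageTable, ExpressionMatrix

logger = logging.getLogger(__name__)

# Y-panel genes named by the low-Y expression cluster; used whenever present,
# otherwise every Y-annotated transcript forms the panel.
Y_PANEL_GENES = ("DDX3Y", "EIF1AY", "KDM5D", "RPS4Y1", "TXLNGY", "USP9Y", "UTY")

LOW_Y_Z_THRESHOLD = -1.0


@dataclass
class LowYCalls:
    """Per-sample low-Y expression calls plus the sample dendrogram."""

    table: pd.DataFrame  # sample_id, mean_y_z, cluster, threshold_call,
    #                      branch_call, low_y
    dendrogram: np.ndarray | None  # linkage over all samples (visualisation)
    male_dendrogram: np.ndarray | None  # linkage over male samples (calling)
    panel: tuple


def _panel_transcripts(m: ExpressionMatrix) -> pd.Index:
    ann = m.annotation
    on_y = ann.index[ann["chromosome"] == "Y"]
    if len(on_y) == 0:
        raise ValueError("module contains no Y-chromosome transcripts")
    named = on_y[ann.loc[on_y, "gene_symbol"].isin(Y_PANEL_GENES)]
    return named if len(named) else on_y


def call_low_y(m: ExpressionMatrix, metadata: pd.DataFrame,
               z_threshold: float = LOW_Y_Z_THRESHOLD) -> LowYCalls:
    """Flag male tumour samples with deficient Y-panel expression.

    ``m`` must be restricted to the (sex-associated) module's transcripts;
    ``metadata`` is a per-sample frame with sample_id, sex, tissue.

    Two calls are made and combined:

    * threshold call — per-transcript z-scores are referenced to the male
      samples (mean/SD over males); a sample's mean z over the Y panel must
      be <= ``z_threshold``;
    * branch call — male samples are clustered (average linkage, Euclidean
      distance) on the Y-panel z-scores corrected for the sample's overall
      module activity (its mean z over the module's non-Y transcripts).
      The correction cancels the module's shared latent component, which
      otherwise makes whole samples drift low without any Y-specific loss.
      The branch with the lower corrected Y-panel mean qualifies as the
      low-Y branch only if that branch mean is itself <= ``z_threshold``
      (otherwise the split merely tracks continuous co-expression and no
      discrete low-Y branch exists).

    ``low_y`` requires both calls and is only ever assigned to male tumours.
    """
    meta = metadata.set_index("sample_id").loc[list(m.samples)]
    sexes = meta["sex"]
    if sexes.nunique() < 2:
        logger.warning("only one sex present in the sample set")
    panel = _panel_transcripts(m)
    X = m.values.to_numpy(dtype=float)

    male_ids = m.samples[(sexes == "M").to_numpy()]
    if len(male_ids) < 3:
        raise ValueError("need >= 3 male samples to call low-Y")
    male_mask = m.samples.isin(male_ids)
    mu = X[:, male_mask].mean(axis=1, keepdims=True)
    sd = X[:, male_mask].std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z_male_ref = (X - mu) / sd  # all samples, male-referenced
    panel_rows = m.transcripts.isin(panel)
    mean_y_z = pd.Series(z_male_ref[panel_rows].mean(axis=0), index=m.samples)

    # full-cohort dendrogram (visualisation): cohort-referenced z-scores
    mu_all = X.mean(axis=1, keepdims=True)
    sd_all = X.std(axis=1, ddof=1, keepdims=True)
    sd_all[sd_all == 0] = 1.0
    z_all = (X - mu_all) / sd_all
    dendro = (average(pdist(z_all.T)) if m.values.shape[1] >= 3 else None)

    # branch call among males, on activity-corrected Y-panel z-scores
    non_y_rows = ~m.annotation["chromosome"].eq("Y").to_numpy()
    if non_y_rows.any():
        activity = z_male_ref[non_y_rows][:, male_mask].mean(axis=0)
    else:
        activity = np.zeros(int(male_mask.sum()))
    corrected = z_male_ref[panel_rows][:, male_mask] - activity[None, :]
    corrected_mean = pd.Series(corrected.mean(axis=0), index=male_ids)
    male_link = average(pdist(corrected.T))
    branches = fcluster(male_link, t=2, criterion="maxclust")
    branch_means = {b: corrected_mean[male_ids][branches == b].mean()
                    for b in np.unique(branches)}
    low_branch = min(branch_means, key=lambda b: branch_means[b])
    branch_is_low = branch_means[low_branch] <= z_threshold
    branch_call = pd.Series(False, index=m.samples)
    if branch_is_low:
        branch_call[male_ids[branches == low_branch]] = True

    cluster_id = pd.Series(0, index=m.samples)
    cluster_id[male_ids] = branches

    is_male_tumour = ((sexes == "M") & (meta["tissue"] == "tumour"))
    threshold_call = (mean_y_z <= z_threshold) & is_male_tumour.reindex(
        m.samples).fillna(False)
    low_y = threshold_call & branch_call

    table = pd.DataFrame({
        "sample_id": m.samples,
        "mean_y_z": mean_y_z.values,
        "cluster": cluster_id.values,
        "threshold_call": threshold_call.values,
        "branch_call": branch_call.values,
        "low_y": low_y.values,
    })
    return LowYCalls(table=table, dendrogram=dendro, male_dendrogram=male_link,
                     panel=tuple(panel))


# ---------------------------------------------------------------------------
# read depth


def normalize_depth(cov: CoverageTable) -> pd.DataFrame:
    """Depth per gene per sample: reads per kilobase per 10^9 library reads."""
    t = cov.table
    libs = cov.library_sizes.loc[t["sample_id"]].to_numpy(dtype=float)
    if (libs <= 0).any():
        raise ValueError("library sizes must be > 0")
    length_kb = t["gene_length"].to_numpy(dtype=float) / 1000.0
    d = t["read_count"].to_numpy(dtype=float) / (length_kb * libs) * 1e9
    out = t[["sample_id", "gene", "chromosome"]].copy()
    out["depth"] = d
    return out


def _paired_depths(depths: pd.DataFrame, metadata: pd.DataFrame,
                   genes=None) -> pd.DataFrame:
    """Tumour/normal depth pairs per (patient, gene)."""
    meta = metadata.set_index("sample_id")
    d = depths.copy()
    d["patient_id"] = meta.loc[d["sample_id"], "patient_id"].to_numpy()
    d["tissue"] = meta.loc[d["sample_id"], "tissue"].to_numpy()
    if genes is not None:
        d = d[d["gene"].isin(list(genes))]
    wide = d.pivot_table(index=["patient_id", "gene"], columns="tissue",
                         values="depth", aggfunc="first")
    for col in ("tumour", "normal"):
        if col not in wide.columns:
            wide[col] = np.nan
    wide = wide.dropna(subset=["tumour", "normal"]).reset_index()
    return wide.rename(columns={"tumour": "d_tumour", "normal": "d_normal"})


def paired_depth_test(depths: pd.DataFrame, metadata: pd.DataFrame,
                      patients, genes=None, alpha: float = 0.05):
    """Wilcoxon signed-rank on pooled per-(gene, patient) percent differences.

    The unit is the percent difference 100*(d_T - d_N)/d_N for every gene x
    patient pair in the group; returns (V, Hodges–Lehmann estimate, CI, p).
    """
    pairs = _paired_depths(depths, metadata, genes)
    pairs = pairs[pairs["patient_id"].isin(list(patients))]
    pairs = pairs[pairs["d_normal"] > 0]
    if len(pairs) < 6:
        raise ValueError("need >= 6 paired (gene, patient) units")
    pct = 100.0 * (pairs["d_tumour"] - pairs["d_normal"]) / pairs["d_normal"]
    d = pct.to_numpy()
    if np.all(d == 0):
        raise DegenerateTestError("all paired differences are zero")
    return signed_rank_test(d, alpha)


def percent_loy(depths: pd.DataFrame, metadata: pd.DataFrame, patient,
                genes=None, aggregate: str = "median") -> float:
    """%LOY = 100 * max(0, 1 - median_g d_T(g)/d_N(g)) over captured Y genes.

    ``aggregate`` may be "mean" as an alternative reading of the per-region
    summary.
    """
    pairs = _paired_depths(depths, metadata, genes)
    pairs = pairs[pairs["patient_id"] == patient]
    pairs = pairs[pairs["d_normal"] > 0]
    if len(pairs) < 3:
        raise ValueError(
            f"need matched depths for >= 3 captured genes (patient {patient!r})")
    ratio = (pairs["d_tumour"] / pairs["d_normal"]).to_numpy()
    agg = np.median(ratio) if aggregate == "median" else np.mean(ratio)
    return float(100.0 * max(0.0, 1.0 - agg))


def group_loss_test(values_a, values_b, alpha_normality: float = 0.05):
    """Two-group comparison with a Shapiro–Wilk gate.

    Both groups normal at ``alpha_normality`` -> unpaired two-sided t-test;
    otherwise two-sided Mann–Whitney U. Returns (test name, statistic, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need >= 3 values per group")
    normal = (stats.shapiro(a).pvalue > alpha_normality
              and stats.shapiro(b).pvalue > alpha_normality)
    if normal:
        res = stats.ttest_ind(a, b)
        return "t", float(res.statistic), float(res.pvalue)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return "mann-whitney", float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# PCR amplification (Y-index)


@dataclass
class YIndex:
    per_sample_site: pd.DataFrame  # sample_id, site_id, y_index
    ratios: pd.DataFrame  # patient_id, site_id, tn_ratio
    per_patient: pd.DataFrame  # patient_id, grand_mean, sd


def compute_y_index(amp: AmpliconTable, metadata: pd.DataFrame) -> YIndex:
    """Y-index per sample x site, tumour:normal ratios and patient summaries.

    The Y-index is the mean over replicates of y_intensity/control_intensity;
    samples with fewer than 3 replicates are used as-is but were flagged at
    parse time.
    """
    t = amp.table.copy()
    t["rel"] = t["y_intensity"] / t["control_intensity"]
    per = (t.groupby(["sample_id", "site_id"])["rel"].mean()
           .rename("y_index").reset_index())
    meta = metadata.set_index("sample_id")
    per["patient_id"] = meta.loc[per["sample_id"], "patient_id"].to_numpy()
    per["tissue"] = meta.loc[per["sample_id"], "tissue"].to_numpy()
    wide = per.pivot_table(index=["patient_id", "site_id"], columns="tissue",
                           values="y_index", aggfunc="first")
    wide = wide.dropna(subset=["tumour", "normal"])
    ratios = (wide["tumour"] / wide["normal"]).rename("tn_ratio").reset_index()
    per_patient = (ratios.groupby("patient_id")["tn_ratio"]
                   .agg(grand_mean="mean", sd=lambda v: v.std(ddof=1))
                   .reset_index())
    return YIndex(per_sample_site=per[["sample_id", "site_id", "y_index"]],
                  ratios=ratios, per_patient=per_patient)


def index_expression_correlation(y_index_values, expression_values):
    """Pearson r between site amplification indices and co-located expression.

    Returns (r, df, two-sided p) with df = n - 2.
    """
    x = np.asarray(y_index_values, dtype=float)
    y = np.asarray(expression_values, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError("need >= 4 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), x.size - 2, float(p)


def two_group_location_test(x, y, alpha: float = 0.05):
    """Two-sided Wilcoxon rank-sum with Hodges–Lehmann shift estimate and CI.

    Orientation: the estimate is the location of x minus y. Reusable for the
    gametolog dosage comparison and generic two-group expression checks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need >= 3 values per group")
    return rank_sum_test(x, y, alpha)
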