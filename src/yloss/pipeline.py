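"""Stage orchestration: the analysis chain behind the CLI's subcommands.

Each stage is a plain function taking in-memory objects and returning a
dict of result tables, so the same code path serves the CLI, the tests and
reproduction scripts. Stages log one structured line with input shapes,
parameters and output shapes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import loy as loy_mod
from . import methylation as meth_mod
from . import network as net
from . import survival as surv
from .datatypes import ExpressionMatrix, SampleMetadata
from .preprocess import filter_transcripts

logger = logging.getLogger(__name__)


def stage_filter(m: ExpressionMatrix):
    filtered, report = filter_transcripts(m)
    logger.info("filter: %d -> %d (median) -> %d (annotation)",
                report.n_input, report.n_after_median_filter,
                report.n_after_annotation_filter)
    return {"expression": filtered, "report": report.to_frame()}


def _trait_frame(meta: pd.DataFrame, samples) -> pd.DataFrame:
    """Numeric trait coding: binary {0,1}, ordered by rank."""
    rows = meta.set_index("sample_id").loc[list(samples)]
    traits = pd.DataFrame(index=rows.index)
    traits["sex"] = (rows["sex"] == "M").astype(float)
    traits["age"] = pd.to_numeric(rows["age"], errors="coerce")
    traits["histology"] = (rows["histology"] == "LUSC").astype(float)
    smoke_rank = {"NS": 0.0, "EX": 1.0, "CS": 2.0}
    traits["smoking"] = rows["smoking"].map(smoke_rank)
    if "fev1" in rows:
        traits["fev1"] = pd.to_numeric(rows["fev1"], errors="coerce")
    if "bmi" in rows:
        traits["bmi"] = pd.to_numeric(rows["bmi"], errors="coerce")
    return traits


def stage_network(tumour: ExpressionMatrix, normal: ExpressionMatrix,
                  metadata: SampleMetadata,
                  params: net.NetworkParams | None = None,
                  opts: net.CorrelationOptions | None = None):
    """Consensus plus single-tissue networks, trait association, specificity."""
    params = params or net.NetworkParams()
    opts = opts or net.CorrelationOptions()
    consensus = net.build_consensus([tumour, normal], params, opts)
    tumour_net = net.build_network(tumour, params, opts)
    normal_net = net.build_network(normal, params, opts)
    traits = _trait_frame(metadata.table, normal.samples)
    assoc = (net.module_trait_correlation(normal_net.eigengenes, traits, opts)
             if len(normal_net.eigengenes.columns) else pd.DataFrame())
    spec_flags_n, spec_table_n = net.module_overlap_specificity(
        normal_net.labels, consensus.labels)
    spec_flags_t, spec_table_t = net.module_overlap_specificity(
        tumour_net.labels, consensus.labels)
    logger.info("network stage: consensus %d modules, tumour %d, normal %d",
                len(consensus.module_ids()), len(tumour_net.module_ids()),
                len(normal_net.module_ids()))
    return {"consensus": consensus, "tumour": tumour_net,
            "normal": normal_net, "trait_association": assoc,
            "normal_specific": spec_flags_n,
            "normal_overlap_table": spec_table_n,
            "tumour_specific": spec_flags_t,
            "tumour_overlap_table": spec_table_t}


def sex_module(assoc: pd.DataFrame) -> str | None:
    """Module (ME column name) with the strongest sex association."""
    if assoc.empty:
        return None
    sex_rows = assoc[assoc["trait"] == "sex"].dropna(subset=["bicor"])
    if sex_rows.empty:
        return None
    return sex_rows.loc[sex_rows["bicor"].abs().idxmax(), "module"]


def sex_module_transcripts(assoc: pd.DataFrame, labels: pd.Series,
                           annotation: pd.DataFrame) -> pd.Index | None:
    """Transcripts of the sex-associated module for downstream low-Y calling.

    Prefers the most sex-associated module that contains at least one
    Y-chromosome transcript; if no module does, falls back to every
    Y-annotated transcript in the analysis (with a warning).
    """
    if not assoc.empty:
        sex_rows = assoc[assoc["trait"] == "sex"].dropna(subset=["bicor"])
        for _, row in sex_rows.reindex(
                sex_rows["bicor"].abs().sort_values(ascending=False).index
        ).iterrows():
            lab = int(str(row["module"]).removeprefix("ME"))
            members = labels.index[labels == lab]
            if (annotation.loc[members, "chromosome"] == "Y").any():
                return members
    on_y = annotation.index[annotation["chromosome"] == "Y"]
    on_y = on_y.intersection(labels.index)
    if len(on_y):
        logger.warning("no sex-associated module with Y content; using all "
                       "%d Y-annotated transcripts", len(on_y))
        return on_y
    return None


def stage_loy(tumour: ExpressionMatrix, normal: ExpressionMatrix,
              metadata: SampleMetadata, module_transcripts,
              coverage=None):
    """Low-Y calls on the sex module plus read-depth quantification."""
    combined = ExpressionMatrix(
        pd.concat([tumour.values.loc[module_transcripts],
                   normal.values.loc[module_transcripts]], axis=1),
        tumour.annotation.loc[module_transcripts])
    calls = loy_mod.call_low_y(combined, metadata.table)
    out = {"low_y_calls": calls.table, "panel": calls.panel}
    if coverage is not None:
        depths = loy_mod.normalize_depth(coverage)
        meta_idx = metadata.table.set_index("sample_id")
        call_idx = calls.table.set_index("sample_id")
        cov_samples = [s for s in coverage.library_sizes.index
                       if s in call_idx.index]
        low_patients = sorted({meta_idx.loc[s, "patient_id"]
                               for s in cov_samples
                               if call_idx.loc[s, "low_y"]})
        depth_patients = sorted(set(
            meta_idx.loc[depths["sample_id"], "patient_id"]))
        other_patients = [p for p in depth_patients if p not in low_patients]
        y_genes = sorted(depths.loc[depths["chromosome"] == "Y", "gene"]
                         .unique())
        pct = {}
        for p in depth_patients:
            try:
                pct[p] = loy_mod.percent_loy(depths, metadata.table, p,
                                             genes=y_genes)
            except ValueError:
                continue
        pct_table = pd.DataFrame(
            {"patient_id": list(pct), "percent_loy": list(pct.values())})
        pct_table["low_y"] = pct_table["patient_id"].isin(low_patients)
        out["depths"] = depths
        out["percent_loy"] = pct_table
        if len(low_patients) >= 2:
            try:
                v, est, ci, p = loy_mod.paired_depth_test(
                    depths, metadata.table, low_patients, genes=y_genes)
                out["paired_depth_low"] = {"V": v, "estimate": est,
                                           "ci": ci, "p": p}
            except ValueError:
                pass
        if len(other_patients) >= 2:
            try:
                v, est, ci, p = loy_mod.paired_depth_test(
                    depths, metadata.table, other_patients, genes=y_genes)
                out["paired_depth_other"] = {"V": v, "estimate": est,
                                             "ci": ci, "p": p}
            except ValueError:
                pass
        a = pct_table.loc[pct_table["low_y"], "percent_loy"]
        b = pct_table.loc[~pct_table["low_y"], "percent_loy"]
        if len(a) >= 3 and len(b) >= 3:
            name, statv, p = loy_mod.group_loss_test(a, b)
            out["group_loss_test"] = {"test": name, "statistic": statv, "p": p}
    logger.info("loy stage: %d low-Y of %d male tumours",
                int(calls.table["low_y"].sum()),
                int(((metadata.table["sex"] == "M")
                     & (metadata.table["tissue"] == "tumour")).sum()))
    return out


def stage_methylation(tables, metadata: SampleMetadata,
                      low_y_calls: pd.DataFrame, min_coverage: int = 5):
    """Per-sample medians, the paired/unpaired comparisons, and DMRs."""
    medians = pd.DataFrame(
        {"sample_id": [t.sample_id for t in tables],
         "median_pct": [meth_mod.median_methylation(t, min_coverage)
                        for t in tables]})
    meta_idx = metadata.table.set_index("sample_id")
    calls = low_y_calls.set_index("sample_id")["low_y"]
    medians["patient_id"] = meta_idx.loc[medians["sample_id"],
                                         "patient_id"].to_numpy()
    medians["tissue"] = meta_idx.loc[medians["sample_id"], "tissue"].to_numpy()
    medians["low_y"] = [bool(calls.get(s, False))
                        for s in medians["sample_id"]]
    low_patients = set(medians.loc[medians["low_y"], "patient_id"])
    wide = medians.pivot_table(index="patient_id", columns="tissue",
                               values="median_pct", aggfunc="first")
    wide = wide.dropna(subset=["tumour", "normal"])
    out = {"medians": medians}
    for label, patients in (("low", low_patients),
                            ("other", set(wide.index) - low_patients)):
        sub = wide.loc[[p for p in wide.index if p in patients]]
        if len(sub) >= 4:
            out[f"paired_test_{label}"] = dict(zip(
                ("test", "statistic", "estimate", "ci", "p"),
                meth_mod.paired_methylation_test(sub["tumour"], sub["normal"])))
    tum = medians[medians["tissue"] == "tumour"]
    a = tum.loc[tum["low_y"], "median_pct"]
    b = tum.loc[~tum["low_y"], "median_pct"]
    if len(a) >= 3 and len(b) >= 3:
        out["unpaired_test"] = dict(zip(
            ("U", "estimate", "ci", "p"),
            meth_mod.unpaired_methylation_test(a, b)))
    by_sample = {t.sample_id: t for t in tables}
    g1 = [by_sample[s] for s in medians.loc[medians["low_y"], "sample_id"]]
    g2 = []
    for p in sorted(low_patients):
        normal_id = medians.loc[(medians["patient_id"] == p)
                                & (medians["tissue"] == "normal"),
                                "sample_id"]
        g2.extend(by_sample[s] for s in normal_id)
    if g1 and g2:
        dmrs = meth_mod.call_dmrs(g1, g2)
        out["dmrs"] = meth_mod.dmrs_to_frame(dmrs)
    logger.info("methylation stage: %d samples, %d DMRs", len(tables),
                len(out.get("dmrs", [])))
    return out


def stage_survival(tumour: ExpressionMatrix, metadata: SampleMetadata,
                   low_y_calls: pd.DataFrame | None = None,
                   gene: str = "KDM5D"):
    """Deficiency classification, Cox models, KM curves, mortality table."""
    ann = tumour.annotation
    rows = ann.index[ann["gene_symbol"] == gene]
    if len(rows) == 0:
        raise ValueError(f"no transcript annotated to {gene!r}")
    meta_idx = metadata.table.set_index("sample_id")
    expr = tumour.values.loc[rows[0]]
    male_tumours = [s for s in expr.index
                    if meta_idx.loc[s, "sex"] == "M"
                    and meta_idx.loc[s, "tissue"] == "tumour"]
    by_patient = pd.Series(
        expr[male_tumours].to_numpy(),
        index=meta_idx.loc[male_tumours, "patient_id"])
    calls = surv.classify_deficiency(by_patient)
    deficient = calls.table.set_index("patient_id")["deficient"]
    covs = ["age", "sex", "histology", "smoking", "stage"]
    design = surv.encode_covariates(metadata.table, covs, outlier=deficient)
    fit = surv.fit_cox(design)
    out = {"deficiency": calls.table, "cox": fit,
           "cox_summary": fit.summary}
    # males only, covariates minus sex
    males = metadata.table[metadata.table["sex"] == "M"]
    design_m = surv.encode_covariates(
        males, ["age", "histology", "smoking", "stage"], outlier=deficient)
    try:
        out["cox_male"] = surv.fit_cox(design_m)
        out["cox_male_summary"] = out["cox_male"].summary
    except (surv.NoEventsError, RuntimeError):
        pass
    if low_y_calls is not None:
        lowy = low_y_calls.set_index("sample_id")["low_y"]
        low_patient = pd.Series(False, index=deficient.index)
        for s, flag in lowy.items():
            if flag and s in meta_idx.index:
                pid = meta_idx.loc[s, "patient_id"]
                if pid in low_patient.index:
                    low_patient[pid] = True
        design_low = surv.encode_covariates(metadata.table, covs,
                                            outlier=low_patient)
        common = design.index.intersection(design_low.index)
        try:
            fit_a = surv.fit_cox(design.loc[common])
            fit_b = surv.fit_cox(design_low.loc[common])
            out["cox_lowy"] = fit_b
            t_stat, p = surv.compare_nonnested_cox(fit_a, fit_b)
            out["model_comparison"] = {"statistic": t_stat, "p": p}
        except (surv.NoEventsError, RuntimeError, ValueError):
            pass
    groups = design["outlier"].map({0.0: "normal-range", 1.0: "deficient"})
    curves, medians = surv.km_estimate(design, groups)
    out["km_curves"] = curves
    out["km_medians"] = medians
    out["mortality"] = surv.summarize_mortality(calls, metadata.table)
    logger.info("survival stage: n=%d, events=%d, deficient=%d",
                fit.n, fit.n_events, int(deficient.sum()))
    return out
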