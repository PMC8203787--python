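"""Synthetic paired tumour/normal cohorts with planted truth.

The generator emulates the statistical structure the analysis assumes: a
sex-determined gonosomal co-expression module (Y transcripts high in males,
X-escape transcripts high in females, a few sex-biased autosomal members),
additional latent-factor modules shared by both tissues, one module whose
co-ordination exists in normal tissue only (the tissue-specificity target),
a subset of male tumours with fractional loss of chromosome Y (reduced Y
expression, reduced Y read depth, autosomal hypomethylation), and survival
times with an elevated hazard for KDM5D-deficient tumours. Every planted
effect is returned in TruthLabels.

Modules follow a one-factor Gaussian model: for member transcript i of
module M in sample s,

    x_is = mu_i + shifts_is + sigma * (lambda * f_Ms + sqrt(1-lambda^2) * eps_is)

with loading lambda = ``within_module_cor`` (so the expected within-module
correlation is lambda^2), residual scale sigma a fixed array-like noise
level, and f, eps standard normal. The loss-of-Y expression effect is
multiplicative on the intensity scale and floored at a background constant:
x -> log2(2^x * (1 - 0.9 f_cell) + background).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, MethylationTable, CoverageTable, \
    SampleMetadata

# array-like residual noise (log2 scale) and expression background intensity
RESIDUAL_SD = 0.35
BACKGROUND_INTENSITY = 2.0  # 2^1 on the log2 scale
LOY_EXPRESSION_ATTENUATION = 0.9  # purity-like attenuation of the cell fraction
ESCAPE_VARIABILITY = 0.25  # sd of the per-female X-escape penetrance multiplier

_Y_SYMBOLS = ("KDM5D", "DDX3Y", "EIF1AY", "RPS4Y1", "TXLNGY", "USP9Y", "UTY",
              "ZFY", "PRKY", "NLGN4Y", "TMSB4Y", "TBL1Y", "AMELY", "BPY2",
              "DAZ1", "HSFY1")
_X_SYMBOLS = ("KDM5C", "DDX3X", "EIF1AX", "RPS4X", "TXLNG", "USP9X", "KDM6A",
              "ZFX", "PRKX", "NLGN4X", "TMSB4X", "TBL1X", "AMELX", "SMC1A",
              "EIF2S3")

_SMOKING_P = {"NS": 0.10, "EX": 0.55, "CS": 0.35}
_STAGE_P = {"IA": 0.32, "IB": 0.21, "IIA": 0.13, "IIB": 0.10, "IIIA": 0.21,
            "IV": 0.03}
_HISTOLOGY_P_LUAD = 0.74

BASELINE_MEDIAN_SURVIVAL_MONTHS = 36.0
FOLLOW_UP_CAP_MONTHS = 120.0


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedDMR:
    chromosome: str
    start: int
    end: int
    delta_pct: float  # applied to low-Y tumour samples within the region


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 126
    male_fraction: float = 66 / 126
    paired_fraction: float = 111 / 126
    n_transcripts: int = 2000
    module_sizes: tuple = (39, 40, 45, 50, 60)  # first: sex module;
    #                                              second: degraded in tumour
    within_module_cor: float = 0.7  # latent-factor loading
    sex_effect: float = 4.0  # log2 shift, concordant sex
    loy_fraction: float = 0.28
    loy_cell_fraction: float = 0.8
    n_y_genes_depth: int = 20
    methylation_shift: float = 10.0  # percentage points
    n_cpgs: int = 4000
    log_hr_deficiency: float = math.log(3.8)
    censor_rate: float = 0.5
    planted_dmrs: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("male_fraction", "paired_fraction", "loy_fraction",
                     "loy_cell_fraction", "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if not 0.0 <= self.within_module_cor <= 1.0:
            raise ConfigurationError("within_module_cor must be in [0,1]")
        for name in ("n_patients", "n_transcripts", "n_y_genes_depth",
                     "n_cpgs"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if any(s <= 0 for s in self.module_sizes):
            raise ConfigurationError("module sizes must be positive")
        if sum(self.module_sizes) > self.n_transcripts:
            raise ConfigurationError(
                "module_sizes sum exceeds n_transcripts")

    def with_(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


@dataclass
class TruthLabels:
    """Planted ground truth for one cohort."""

    low_y: pd.Series  # sample id -> bool (True only on male tumours)
    modules: pd.Series  # transcript id -> planted module id (0 = noise)
    deficient: pd.Series  # patient id -> bool
    log_hr: float
    methylation_shift: float
    degraded_module: int | None  # module whose factor is normal-only

    def consensus_modules(self) -> pd.Series:
        """Planted labels restricted to tissue-shared structure."""
        out = self.modules.copy()
        if self.degraded_module is not None:
            out[out == self.degraded_module] = 0
        return out


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# cohort layout


def _largest_remainder(total: int, weights) -> list[int]:
    """Integer allocation of ``total`` proportional to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() == 0:
        return [0] * len(weights)
    exact = total * weights / weights.sum()
    base = np.floor(exact).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(exact - base))
    for i in order[:rem]:
        base[i] += 1
    return base.tolist()


def _cohort_layout(config: SyntheticConfig):
    """Patients, sexes and the sample list (which tissues each contributes).

    Category sizes (paired / tumour-only / normal-only) and the male count
    within each category are deterministic given the config, so the cohort
    composition (e.g. number of male tumours) does not drift across seeds;
    the seed only permutes which patient is which.
    """
    rng = _rng(config, 0)
    n = config.n_patients
    patients = [f"P{i + 1:03d}" for i in range(n)]
    n_male = round(config.male_fraction * n)
    n_paired = round(config.paired_fraction * n)
    n_unpaired = n - n_paired
    n_tumour_only = round(0.87 * n_unpaired)
    n_normal_only = n_unpaired - n_tumour_only
    cat_sizes = [n_paired, n_tumour_only, n_normal_only]
    males_per_cat = _largest_remainder(n_male, cat_sizes)
    cats, sexes = [], []
    for (size, males), cat in zip(zip(cat_sizes, males_per_cat),
                                  ("paired", "tumour_only", "normal_only")):
        cats += [cat] * size
        sexes += ["M"] * males + ["F"] * (size - males)
    order = rng.permutation(n)
    cats = np.asarray(cats)[order]
    sexes = np.asarray(sexes)[order]
    rows = []
    for i, pid in enumerate(patients):
        if cats[i] in ("paired", "tumour_only"):
            rows.append((f"{pid}_T", pid, "tumour", sexes[i]))
        if cats[i] in ("paired", "normal_only"):
            rows.append((f"{pid}_N", pid, "normal", sexes[i]))
    samples = pd.DataFrame(rows, columns=["sample_id", "patient_id",
                                          "tissue", "sex"])
    return patients, pd.Series(sexes, index=patients), samples


def _plant_low_y(config: SyntheticConfig, samples: pd.DataFrame) -> pd.Series:
    rng = _rng(config, 1)
    male_tumours = samples.loc[(samples["sex"] == "M")
                               & (samples["tissue"] == "tumour"), "sample_id"]
    n_low = round(config.loy_fraction * len(male_tumours))
    chosen = rng.choice(male_tumours.to_numpy(), size=n_low, replace=False)
    low = pd.Series(False, index=samples["sample_id"])
    low[chosen] = True
    return low


# ---------------------------------------------------------------------------
# expression


def _transcript_annotation(config: SyntheticConfig, rng) -> pd.DataFrame:
    nt = config.n_transcripts
    ids = [f"TC{i + 1:05d}" for i in range(nt)]
    sizes = list(config.module_sizes)
    sex_size = sizes[0]
    # sex module split: proportions of the 16/15/8 gonosomal composition
    n_y = max(1, round(sex_size * 16 / 39))
    n_x = max(1, round(sex_size * 15 / 39))
    n_auto = max(0, sex_size - n_y - n_x)
    chroms = []
    symbols = []
    for i in range(n_y):
        chroms.append("Y")
        symbols.append(_Y_SYMBOLS[i] if i < len(_Y_SYMBOLS) else f"YG{i:03d}")
    for i in range(n_x):
        chroms.append("X")
        symbols.append(_X_SYMBOLS[i] if i < len(_X_SYMBOLS) else f"XG{i:03d}")
    for i in range(n_auto):
        chroms.append(str(rng.integers(1, 23)))
        symbols.append(f"SBA{i:03d}")  # sex-biased autosomal
    n_rest = nt - sex_size
    chroms.extend(str(c) for c in rng.integers(1, 23, size=n_rest))
    symbols.extend(f"GENE{i:05d}" for i in range(n_rest))
    ann = pd.DataFrame({
        "chromosome": chroms,
        "gene_symbol": symbols,
        "cross_hybridisation": 1,
        "mrna_assigned": True,
        "probe_category": "main",
    }, index=pd.Index(ids, name="transcript_id"))
    # a sprinkling of annotation-filter casualties among noise transcripts
    n_bad = max(0, int(0.02 * n_rest))
    bad_pos = sum(sizes) + rng.choice(nt - sum(sizes), size=n_bad,
                                      replace=False)
    third = max(1, n_bad // 3)
    ann.iloc[bad_pos[:third], ann.columns.get_loc("cross_hybridisation")] = 2
    ann.iloc[bad_pos[third:2 * third], ann.columns.get_loc("mrna_assigned")] = False
    ann.iloc[bad_pos[2 * third:], ann.columns.get_loc("probe_category")] = "control"
    return ann


def generate_expression(config: SyntheticConfig):
    """Paired tumour/normal expression matrices plus planted truth.

    Returns (tumour ExpressionMatrix, normal ExpressionMatrix, TruthLabels).
    """
    _, _, samples = _cohort_layout(config)
    low_y = _plant_low_y(config, samples)
    rng = _rng(config, 2)
    ann = _transcript_annotation(config, rng)
    nt = config.n_transcripts
    ids = ann.index
    sizes = list(config.module_sizes)

    modules = pd.Series(0, index=ids)
    offset = 0
    for k, size in enumerate(sizes, start=1):
        modules.iloc[offset:offset + size] = k
        offset += size
    degraded = 2 if len(sizes) >= 2 else None

    # baselines
    mu = np.empty(nt)
    mu[offset:] = rng.normal(7.0, 1.5, size=nt - offset)  # noise transcripts
    is_y = (ann["chromosome"] == "Y").to_numpy() & (modules == 1).to_numpy()
    is_x_esc = (ann["chromosome"] == "X").to_numpy() & (modules == 1).to_numpy()
    in_sex_mod = (modules == 1).to_numpy()
    is_sba = in_sex_mod & ~is_y & ~is_x_esc
    for k in range(2, len(sizes) + 1):
        mask = (modules == k).to_numpy()
        mu[mask] = rng.normal(7.5, 0.8, size=mask.sum())
    # male Y level (baseline + sex_effect) sits above the global median so
    # expressed Y genes survive the median-exceedance filter, as on arrays
    mu[is_y] = 3.2
    mu[is_x_esc] = 6.0
    mu[is_sba] = rng.normal(7.5, 0.8, size=is_sba.sum())

    lam = config.within_module_cor
    resid = math.sqrt(max(0.0, 1.0 - lam**2))

    def one_tissue(tissue: str, stream: int) -> pd.DataFrame:
        r = _rng(config, stream)
        sub = samples[samples["tissue"] == tissue]
        ns = len(sub)
        X = np.tile(mu[:, None], (1, ns))
        male = (sub["sex"] == "M").to_numpy()
        X[np.ix_(is_y, male)] += config.sex_effect
        # X-inactivation escape is variably penetrant: each female sample
        # expresses the escape shift with its own multiplier, giving the
        # within-sex heterogeneity real cohorts show on the module eigengene
        escape = 1.0 + ESCAPE_VARIABILITY * r.standard_normal((~male).sum())
        X[np.ix_(is_x_esc, ~male)] += config.sex_effect * escape[None, :]
        X[np.ix_(is_sba, male)] += config.sex_effect / 2.0
        for k in range(1, len(sizes) + 1):
            mask = (modules == k).to_numpy()
            factor_active = not (k == degraded and tissue == "tumour")
            f = r.standard_normal(ns) if factor_active else np.zeros(ns)
            eps = r.standard_normal((mask.sum(), ns))
            lam_k = lam if factor_active else 0.0
            resid_k = math.sqrt(max(0.0, 1.0 - lam_k**2))
            X[mask] += RESIDUAL_SD * (lam_k * f[None, :] + resid_k * eps)
        noise_mask = (modules == 0).to_numpy()
        X[noise_mask] += RESIDUAL_SD * r.standard_normal((noise_mask.sum(), ns))
        if tissue == "tumour":
            lowy_cols = low_y[sub["sample_id"]].to_numpy()
            if lowy_cols.any():
                block = X[np.ix_(is_y, lowy_cols)]
                atten = 1.0 - LOY_EXPRESSION_ATTENUATION * config.loy_cell_fraction
                X[np.ix_(is_y, lowy_cols)] = np.log2(
                    np.exp2(block) * atten + BACKGROUND_INTENSITY)
        return pd.DataFrame(X, index=ids, columns=list(sub["sample_id"]))

    tumour_vals = one_tissue("tumour", 3)
    normal_vals = one_tissue("normal", 4)
    tumour = ExpressionMatrix(tumour_vals, ann)
    normal = ExpressionMatrix(normal_vals, ann)

    tumour_patients = samples[samples["tissue"] == "tumour"].set_index(
        "sample_id")["patient_id"]
    deficient = pd.Series(False,
                          index=pd.Index(sorted(samples["patient_id"].unique()),
                                         name="patient_id"))
    for sid, flag in low_y.items():
        if flag:
            deficient[tumour_patients[sid]] = True
    truth = TruthLabels(low_y=low_y, modules=modules, deficient=deficient,
                        log_hr=config.log_hr_deficiency,
                        methylation_shift=config.methylation_shift,
                        degraded_module=degraded)
    return tumour, normal, truth


# ---------------------------------------------------------------------------
# metadata and survival


def generate_metadata(config: SyntheticConfig, truth: TruthLabels) -> SampleMetadata:
    """Clinical covariates per sample; survival fields filled by generate_survival."""
    rng = _rng(config, 5)
    _, _, samples = _cohort_layout(config)
    patients = sorted(samples["patient_id"].unique())
    per = pd.DataFrame(index=pd.Index(patients, name="patient_id"))
    per["age"] = np.round(np.clip(rng.normal(68.8, 8.4, len(patients)), 40, 90), 1)
    per["histology"] = rng.choice(["LUAD", "LUSC"], size=len(patients),
                                  p=[_HISTOLOGY_P_LUAD, 1 - _HISTOLOGY_P_LUAD])
    per["smoking"] = rng.choice(list(_SMOKING_P), size=len(patients),
                                p=list(_SMOKING_P.values()))
    per["stage"] = rng.choice(list(_STAGE_P), size=len(patients),
                              p=list(_STAGE_P.values()))
    per["fev1"] = np.round(rng.normal(85, 18, len(patients)), 1)
    per.loc[rng.random(len(patients)) < 0.30, "fev1"] = np.nan
    per["bmi"] = np.round(np.clip(rng.normal(27, 4.5, len(patients)), 15, 45), 1)
    per.loc[rng.random(len(patients)) < 0.25, "bmi"] = np.nan
    meta = samples.merge(per, left_on="patient_id", right_index=True)
    meta["time"] = np.nan
    meta["event"] = False
    return SampleMetadata(meta)


def generate_survival(config: SyntheticConfig, truth: TruthLabels,
                      metadata: SampleMetadata) -> SampleMetadata:
    """Plant exponential survival times with the configured deficiency hazard.

    h(t|x) = h0 * exp(beta_def * deficient + small covariate effects); h0 is
    constant (exponential baseline) so proportional hazards holds exactly.
    Censoring is independent exponential tuned to ``censor_rate`` plus an
    administrative cap.
    """
    rng = _rng(config, 6)
    meta = metadata.table.copy()
    per = meta.sort_values("tissue", ascending=False).drop_duplicates(
        "patient_id").set_index("patient_id")
    h0 = math.log(2) / BASELINE_MEDIAN_SURVIVAL_MONTHS
    stage_ord = per["stage"].map({"IA": 1, "IB": 2, "IIA": 3, "IIB": 4,
                                  "IIIA": 5, "IV": 6}).fillna(2)
    lp = (truth.log_hr * per.index.map(truth.deficient).astype(float)
          + 0.02 * (per["age"] - per["age"].mean())
          + 0.15 * (stage_ord - 2)
          + 0.10 * (per["histology"] == "LUSC").astype(float)
          + 0.15 * (per["smoking"] == "CS").astype(float))
    hazard = h0 * np.exp(lp.to_numpy(dtype=float))
    t_event = rng.exponential(1.0 / hazard)
    if config.censor_rate >= 1.0:
        event = np.zeros(len(per), dtype=bool)
        time = np.round(rng.uniform(1, FOLLOW_UP_CAP_MONTHS, len(per)), 1)
    else:
        c_rate = h0 * config.censor_rate / max(1e-12, 1.0 - config.censor_rate)
        t_cens = (rng.exponential(1.0 / c_rate, len(per))
                  if c_rate > 0 else np.full(len(per), np.inf))
        t_cens = np.minimum(t_cens, FOLLOW_UP_CAP_MONTHS)
        event = t_event <= t_cens
        time = np.round(np.minimum(t_event, t_cens), 2)
    surv = pd.DataFrame({"time": time, "event": event}, index=per.index)
    meta["time"] = surv.loc[meta["patient_id"], "time"].to_numpy()
    meta["event"] = surv.loc[meta["patient_id"], "event"].to_numpy()
    return SampleMetadata(meta)


def survival_replicate(n: int, log_hr: float, prevalence: float = 0.1,
                       censor_rate: float = 0.3,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Minimal one-covariate survival design for estimator-consistency checks."""
    rng = rng or np.random.default_rng()
    x = (rng.random(n) < prevalence).astype(float)
    h0 = math.log(2) / BASELINE_MEDIAN_SURVIVAL_MONTHS
    t_event = rng.exponential(1.0 / (h0 * np.exp(log_hr * x)))
    c_rate = h0 * censor_rate / max(1e-12, 1.0 - censor_rate)
    t_cens = (rng.exponential(1.0 / c_rate, n) if c_rate > 0
              else np.full(n, np.inf))
    event = t_event <= t_cens
    return pd.DataFrame({"time": np.minimum(t_event, t_cens),
                         "event": event, "covariate": x})


# ---------------------------------------------------------------------------
# read coverage


def generate_coverage(config: SyntheticConfig, truth: TruthLabels) -> CoverageTable:
    """Per-gene read counts for paired male patients, Y depth scaled by 1-f.

    Expected Y-gene counts in low-Y tumours are scaled by (1 - f) with
    f = ``loy_cell_fraction``; autosomal genes are unscaled; library sizes
    vary log-normally and counts are Poisson.
    """
    rng = _rng(config, 7)
    _, _, samples = _cohort_layout(config)
    paired = samples.groupby("patient_id")["tissue"].nunique() == 2
    male = samples.drop_duplicates("patient_id").set_index(
        "patient_id")["sex"] == "M"
    keep_patients = paired.index[paired & male.reindex(paired.index,
                                                       fill_value=False)]
    sub = samples[samples["patient_id"].isin(keep_patients)]
    ng = config.n_y_genes_depth
    genes = ([(f"YD{i + 1:03d}", "Y") for i in range(ng)]
             + [(f"AD{i + 1:03d}", str(1 + i % 22)) for i in range(ng)])
    lengths = np.round(rng.lognormal(math.log(2000), 0.4, len(genes))).astype(int)
    lengths = np.maximum(lengths, 200)
    reads_per_kb = 300.0  # ~30x with 100-bp reads
    lib_ref = 3e7
    rows = []
    libsizes = {}
    f = config.loy_cell_fraction
    for _, srow in sub.iterrows():
        sid = srow["sample_id"]
        lib = float(np.round(rng.lognormal(math.log(lib_ref), 0.15)))
        libsizes[sid] = lib
        is_low = bool(truth.low_y.get(sid, False))
        for (gene, chrom), length in zip(genes, lengths):
            rate = reads_per_kb * (length / 1000.0) * (lib / lib_ref)
            if chrom == "Y" and is_low:
                rate *= (1.0 - f)
            rows.append((sid, gene, chrom, int(length),
                         int(rng.poisson(rate))))
    table = pd.DataFrame(rows, columns=["sample_id", "gene", "chromosome",
                                        "gene_length", "read_count"])
    return CoverageTable(table, pd.Series(libsizes, name="library_size"))


# ---------------------------------------------------------------------------
# methylation


def generate_methylation(config: SyntheticConfig,
                         truth: TruthLabels) -> list[MethylationTable]:
    """Beta-binomial CpG tables for paired male patients.

    Autosomal CpG means drop by ``methylation_shift`` percentage points in
    low-Y tumours (shifting the per-sample median by the same amount);
    planted DMRs add region-specific deltas for recovery tests. X and Y
    CpGs are included untouched so the autosome restriction is exercised.
    """
    rng = _rng(config, 8)
    _, _, samples = _cohort_layout(config)
    paired = samples.groupby("patient_id")["tissue"].nunique() == 2
    male = samples.drop_duplicates("patient_id").set_index(
        "patient_id")["sex"] == "M"
    keep = paired.index[paired & male.reindex(paired.index, fill_value=False)]
    sub = samples[samples["patient_id"].isin(keep)]

    chrom_names = [str(c) for c in range(1, 6)] + ["X", "Y"]
    n_auto = config.n_cpgs
    n_sex = max(50, n_auto // 20)
    counts = {c: n_auto // 5 for c in chrom_names[:5]}
    counts["X"] = n_sex
    counts["Y"] = n_sex
    cpgs = []
    for c in chrom_names:
        # CpG-island-like density: ~150 bp mean spacing so the 1-kb DMR
        # merge distance is meaningful
        span = 150 * counts[c]
        pos = np.sort(rng.choice(np.arange(1, span), size=counts[c],
                                 replace=False))
        cpgs.append(pd.DataFrame({"chromosome": c, "position": pos}))
    grid = pd.concat(cpgs, ignore_index=True)
    # bimodal CpG landscape: mostly methylated, a hypomethylated minority
    high = rng.random(len(grid)) < 0.8
    base = np.where(high, rng.beta(8, 2, len(grid)), rng.beta(1, 9, len(grid)))
    # planted DMR regions start from a fixed intermediate level so the
    # planted delta is unambiguous
    for dmr in config.planted_dmrs:
        region = ((grid["chromosome"] == dmr.chromosome)
                  & (grid["position"] >= dmr.start)
                  & (grid["position"] <= dmr.end)).to_numpy()
        base[region] = 0.75
    autosomal = grid["chromosome"].isin([str(c) for c in range(1, 6)]).to_numpy()

    nu = 60.0  # beta-binomial concentration (biological variability)
    mean_cov = 30.0
    shift = config.methylation_shift / 100.0
    tables = []
    for _, srow in sub.iterrows():
        sid = srow["sample_id"]
        m = base.copy()
        if bool(truth.low_y.get(sid, False)):
            m[autosomal] = m[autosomal] - shift
            for dmr in config.planted_dmrs:
                region = ((grid["chromosome"] == dmr.chromosome)
                          & (grid["position"] >= dmr.start)
                          & (grid["position"] <= dmr.end)).to_numpy()
                m[region] = m[region] + dmr.delta_pct / 100.0
        m = np.clip(m, 0.01, 0.99)
        p = rng.beta(m * nu, (1.0 - m) * nu)
        cov = rng.poisson(mean_cov, len(grid))
        meth = rng.binomial(cov, p)
        tab = grid.copy()
        tab["coverage"] = cov
        tab["methylated"] = meth
        tables.append(MethylationTable(sample_id=sid, table=tab))
    return tables


# ---------------------------------------------------------------------------
# one-call cohort


def generate_cohort(config: SyntheticConfig):
    """Expression, metadata with survival, coverage and methylation at once."""
    tumour, normal, truth = generate_expression(config)
    metadata = generate_metadata(config, truth)
    metadata = generate_survival(config, truth, metadata)
    coverage = generate_coverage(config, truth)
    methylation = generate_methylation(config, truth)
    return {"tumour": tumour, "normal": normal, "truth": truth,
            "metadata": metadata, "coverage": coverage,
            "methylation": methylation}
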