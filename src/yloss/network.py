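"""Weighted co-expression network construction and characterisation.

Implements, from first principles: the biweight midcorrelation (bicor) with
outlier capping, unsigned soft-threshold adjacency, topological overlap
(TOM), quantile-matched TOM scaling and entrywise-minimum consensus, a
hybrid dynamic tree cut, module eigengenes, eigengene-based module merging,
module-trait association, module membership (kME), Fisher-exact module
overlap specificity, and eigengene-network preservation.

Conventions: networks are unsigned (adjacency |bicor|^beta); dendrograms are
average linkage on 1 - TOM; module label 0 means unassigned and labels are
ordered by decreasing module size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from .datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """Correlation undefined: zero MAD together with zero variance."""


@dataclass
class CorrelationOptions:
    max_p_outliers: float = 0.05
    robust_y: bool = False  # traits enter with unit weights
    tuning_constant: float = 9.0

    def __post_init__(self) -> None:
        if not 0 < self.max_p_outliers <= 0.5:
            raise ValueError("max_p_outliers must be in (0, 0.5]")


@dataclass
class NetworkParams:
    power: float = 5.0
    scale_quantile: float = 0.95
    min_module_size: int = 30
    cut_height: float = 0.995
    deep_split: int = 2
    merge_height: float = 0.25

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("soft-threshold power must be >= 1")
        if not 0 < self.scale_quantile < 1:
            raise ValueError("scale_quantile must be in (0,1)")
        if not 0 < self.cut_height <= 1:
            raise ValueError("cut_height must be in (0,1]")
        if not 0 < self.merge_height < 1:
            raise ValueError("merge_height must be in (0,1)")


@dataclass
class ModuleSet:
    """Module labels plus derived summaries for one analysis."""

    labels: pd.Series  # transcript -> module id, 0 unassigned
    eigengenes: pd.DataFrame | None = None  # samples x ME<k>
    kme: pd.DataFrame | None = None
    kme_p: pd.DataFrame | None = None
    dendrogram: np.ndarray | None = None  # scipy linkage matrix
    extra: dict = field(default_factory=dict)

    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})


# ---------------------------------------------------------------------------
# biweight midcorrelation


def _biweight_prepared(x: np.ndarray, opts: CorrelationOptions) -> np.ndarray:
    """Weighted, centred, unit-norm vector entering the bicor inner product."""
    med = np.median(x)
    res = x - med
    mad = np.median(np.abs(res))
    if mad == 0.0:
        if np.var(x) == 0.0:
            raise UndefinedCorrelationError("zero MAD and zero variance")
        logger.warning("zero MAD; falling back to unit weights")
        v = x - x.mean()
    else:
        u = res / (opts.tuning_constant * mad)
        u = _cap_outliers(u, opts.max_p_outliers)
        w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
        v = res * w
    norm = np.sqrt((v**2).sum())
    if norm == 0.0:
        raise UndefinedCorrelationError("all observations down-weighted")
    return v / norm


def _cap_outliers(u: np.ndarray, max_p: float) -> np.ndarray:
    """Widen the biweight scale so at most max_p per tail gets zero weight."""
    ql = np.quantile(u, max_p)
    qu = np.quantile(u, 1.0 - max_p)
    out = u.copy()
    if ql < -1.0:
        out[u < 0] = u[u < 0] / (-ql)
    if qu > 1.0:
        out[u > 0] = u[u > 0] / qu
    return out


def _pearson_prepared(y: np.ndarray) -> np.ndarray:
    v = y - y.mean()
    norm = np.sqrt((v**2).sum())
    if norm == 0.0:
        raise UndefinedCorrelationError("zero-variance vector")
    return v / norm


def _cor_p(r: float, n: int) -> float:
    """Two-sided p from the Student-t approximation with n-2 df."""
    r = min(max(r, -1.0), 1.0)
    if n < 3:
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def bicor(x, y, opts: CorrelationOptions | None = None,
          robust_y: bool | None = None) -> tuple[float, float]:
    """Biweight midcorrelation of x and y with a two-sided p-value.

    Pairwise missing data are removed first. With ``robust_y`` false
    (CorrelationOptions default, intended for binary/ordinal traits) y enters
    with unit weights, i.e. Pearson-style centring.
    """
    opts = opts or CorrelationOptions()
    if robust_y is None:
        robust_y = opts.robust_y
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 complete observations")
    vx = _biweight_prepared(x, opts)
    vy = _biweight_prepared(y, opts) if robust_y else _pearson_prepared(y)
    r = float(np.clip(vx @ vy, -1.0, 1.0))
    return r, _cor_p(r, n)


def bicor_matrix(X: np.ndarray, opts: CorrelationOptions | None = None) -> np.ndarray:
    """All-pairs bicor of the rows of X (variables x observations).

    Weights depend on each variable alone, so the matrix factorises into an
    inner product of prepared rows. Rows whose correlation is undefined
    (constant) yield NaN against everything; callers decide the fallback.
    """
    opts = opts or CorrelationOptions()
    X = np.asarray(X, dtype=float)
    v, dead = _prepare_rows_robust(X, opts, return_dead=True)
    r = np.clip(v @ v.T, -1.0, 1.0)
    if dead.any():
        r[dead, :] = np.nan
        r[:, dead] = np.nan
    np.fill_diagonal(r, 1.0)
    return r


# ---------------------------------------------------------------------------
# adjacency, TOM, consensus


def adjacency(m: ExpressionMatrix | np.ndarray, power: float = 5.0,
              opts: CorrelationOptions | None = None) -> np.ndarray:
    """Unsigned adjacency a_ij = |bicor(x_i, x_j)|^power, unit diagonal."""
    X = m.values.to_numpy() if isinstance(m, ExpressionMatrix) else np.asarray(m, float)
    r = bicor_matrix(X, opts)
    n_undef = int(np.isnan(r).sum())
    if n_undef:
        logger.warning("%d undefined correlations set to 0", n_undef // 2)
        r = np.nan_to_num(r, nan=0.0)
    a = np.abs(r) ** power
    np.fill_diagonal(a, 1.0)
    return a


def tom_similarity(a: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    l_ij sums shared-neighbour adjacency, k is connectivity excluding the
    diagonal; the diagonal of the result is 1.
    """
    a = np.asarray(a, dtype=float)
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    l = a0 @ a0
    k = a0.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    tom = (l + a0) / (kmin + 1.0 - a0)
    np.fill_diagonal(tom, 1.0)
    return tom


def scale_and_consensus(toms: list[np.ndarray], q: float = 0.95):
    """Quantile-match TOMs to the first (reference) and take the entrywise min.

    Each non-reference TOM is raised to log(Q_ref)/log(Q_k) where Q is the
    q-quantile of the off-diagonal entries, so the q-quantiles agree after
    scaling (a monotone power transform).
    """
    if len(toms) < 2:
        raise ValueError("need at least two TOMs")
    if not 0 < q < 1:
        raise ValueError("scaling quantile must be in (0,1)")
    iu = np.triu_indices_from(toms[0], k=1)
    q_ref = float(np.quantile(toms[0][iu], q))
    if not 0 < q_ref < 1:
        raise ValueError("degenerate reference quantile")
    scaled = [toms[0]]
    exponents = [1.0]
    for t in toms[1:]:
        q_k = float(np.quantile(t[iu], q))
        if not 0 < q_k < 1:
            raise ValueError("degenerate quantile in TOM to be scaled")
        e = np.log(q_ref) / np.log(q_k)
        exponents.append(float(e))
        scaled.append(t**e)
    consensus = np.minimum.reduce(scaled)
    np.fill_diagonal(consensus, 1.0)
    return consensus, exponents


# ---------------------------------------------------------------------------
# soft threshold choice


def pick_soft_threshold(m: ExpressionMatrix | np.ndarray, powers=None,
                        opts: CorrelationOptions | None = None,
                        n_bins: int = 10) -> pd.DataFrame:
    """Scale-free fit R^2 and mean connectivity for a grid of powers.

    R^2 is the squared correlation of log10 p(k) vs log10 k over equal-width
    connectivity bins, reported negative when the slope is positive (i.e.
    away from scale-free behaviour).
    """
    X = m.values.to_numpy() if isinstance(m, ExpressionMatrix) else np.asarray(m, float)
    if X.shape[0] < 30:
        raise ValueError("need >= 30 transcripts to assess scale independence")
    powers = list(powers) if powers is not None else [1, 2, 3, 4, 5, 6, 7, 8, 10, 12]
    r = bicor_matrix(X, opts)
    r = np.nan_to_num(r, nan=0.0)
    rows = []
    for beta in powers:
        a = np.abs(r) ** beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        rows.append({"power": beta, "fit_r2": _scale_free_fit(k, n_bins),
                     "mean_connectivity": float(k.mean())})
    return pd.DataFrame(rows)


def _scale_free_fit(k: np.ndarray, n_bins: int) -> float:
    k = k[k > 0]
    if k.size < n_bins or np.ptp(k) == 0:
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(idx, minlength=n_bins).astype(float)
    mean_k = np.array([k[idx == b].mean() if freq[b] else np.nan
                       for b in range(n_bins)])
    ok = (freq > 0) & (mean_k > 0)
    if ok.sum() < 3:
        return float("nan")
    lx = np.log10(mean_k[ok])
    ly = np.log10(freq[ok] / freq[ok].sum())
    slope, _ = np.polyfit(lx, ly, 1)
    r2 = float(np.corrcoef(lx, ly)[0, 1] ** 2)
    return -r2 if slope > 0 else r2


# ---------------------------------------------------------------------------
# dynamic tree cut

# deep-split sensitivity: required merge-height gap (as a fraction of the
# branch's height range) before a branch is split into its two children
_DEEP_SPLIT_GAP = {0: 0.40, 1: 0.30, 2: 0.20, 3: 0.10, 4: 0.05}


def cut_tree_dynamic(tom: np.ndarray, params: NetworkParams,
                     transcripts=None) -> pd.Series:
    """Hybrid-style adaptive branch pruning of the 1-TOM dendrogram.

    Maximal subtrees joining below ``cut_height`` form candidate branches;
    a branch splits into its two children when both would satisfy the
    minimum size and the merge sits clearly above the children (gap
    criterion set by ``deep_split``). Branches smaller than
    ``min_module_size`` dissolve to label 0. Returns labels ordered by
    decreasing module size. All traversal is iterative (noise dendrograms
    can be chain-like and arbitrarily deep).
    """
    n = tom.shape[0]
    index = (pd.Index(transcripts) if transcripts is not None
             else pd.RangeIndex(n))
    if n < params.min_module_size:
        logger.warning("fewer transcripts (%d) than min_module_size; "
                       "all unassigned", n)
        return pd.Series(0, index=index)
    d = 1.0 - tom
    np.fill_diagonal(d, 0.0)
    z = average(squareform(d, checks=False))
    gap_frac = _DEEP_SPLIT_GAP[int(params.deep_split)]

    # node ids: 0..n-1 leaves, n..2n-2 internal (internal i holds merge i-n)
    left = z[:, 0].astype(int)
    right = z[:, 1].astype(int)
    dist = z[:, 2]
    count = z[:, 3].astype(int)

    def node_count(i):
        return 1 if i < n else count[i - n]

    def node_dist(i):
        return 0.0 if i < n else dist[i - n]

    # min merge height within each subtree (children precede parents)
    min_dist = np.full(n - 1, np.inf)
    for i in range(n - 1):
        m = dist[i]
        for c in (left[i], right[i]):
            if c >= n:
                m = min(m, min_dist[c - n])
        min_dist[i] = m

    # collect maximal subtrees below cut_height
    branch_roots: list[int] = []
    stack = [2 * n - 2]
    while stack:
        node = stack.pop()
        if node < n or dist[node - n] <= params.cut_height:
            branch_roots.append(node)
        else:
            stack.extend((left[node - n], right[node - n]))

    # deep-split refinement
    final: list[int] = []
    stack = branch_roots
    while stack:
        node = stack.pop()
        if node < n or node_count(node) < 2 * params.min_module_size:
            final.append(node)
            continue
        i = node - n
        l, r = left[i], right[i]
        if (node_count(l) >= params.min_module_size
                and node_count(r) >= params.min_module_size):
            floor = min_dist[i]
            gap = dist[i] - max(node_dist(l), node_dist(r))
            if gap > gap_frac * (dist[i] - floor):
                stack.extend((l, r))
                continue
        final.append(node)

    def leaves_of(node):
        out, st = [], [node]
        while st:
            v = st.pop()
            if v < n:
                out.append(v)
            else:
                st.extend((left[v - n], right[v - n]))
        return out

    labels = np.zeros(n, dtype=int)
    sized = sorted(((node_count(b), b) for b in final
                    if node_count(b) >= params.min_module_size),
                   key=lambda t: (-t[0], t[1]))
    for lab, (_, b) in enumerate(sized, start=1):
        labels[leaves_of(b)] = lab
    out = pd.Series(labels, index=index)
    out.attrs["linkage"] = z
    return out


# ---------------------------------------------------------------------------
# eigengenes, merging


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def module_eigengenes(m: ExpressionMatrix | pd.DataFrame,
                      labels: pd.Series) -> pd.DataFrame:
    """First principal component per module across samples, unit variance.

    Sign is oriented so the eigengene correlates positively with the mean
    standardized expression of the module's members. A single-member module
    yields the standardized member itself.
    """
    values = m.values if isinstance(m, ExpressionMatrix) else m
    modules = sorted(set(labels) - {0})
    if not modules:
        raise ValueError("no modules to summarise")
    out = {}
    for lab in modules:
        members = labels.index[labels == lab]
        Z = _standardize_rows(values.loc[members].to_numpy())
        if Z.shape[0] == 1:
            e = Z[0]
        else:
            # samples x members; PC1 of sample scores
            u, s, vt = np.linalg.svd(Z.T, full_matrices=False)
            e = u[:, 0] * s[0]
        sd = e.std(ddof=0)
        e = e / (sd if sd else 1.0)
        mean_profile = Z.mean(axis=0)
        if np.dot(e, mean_profile) < 0:
            e = -e
        out[f"ME{lab}"] = e
    return pd.DataFrame(out, index=values.columns)


def merge_close_modules(m: ExpressionMatrix | pd.DataFrame, labels: pd.Series,
                        eigengenes: pd.DataFrame | None = None,
                        merge_height: float = 0.25):
    """Iteratively merge module pairs with eigengene dissimilarity < merge_height.

    After each merge the eigengenes are recomputed. Returns (labels,
    eigengenes) with labels renumbered by decreasing size.
    """
    values = m.values if isinstance(m, ExpressionMatrix) else m
    labels = labels.copy()
    while True:
        modules = sorted(set(labels) - {0})
        if len(modules) < 2:
            break
        E = module_eigengenes(values, labels)
        cor = np.corrcoef(E.to_numpy().T)
        dis = 1.0 - cor
        np.fill_diagonal(dis, np.inf)
        i, j = np.unravel_index(np.argmin(dis), dis.shape)
        if dis[i, j] >= merge_height:
            break
        a, b = modules[i], modules[j]
        labels[labels == b] = a
    labels = relabel_by_size(labels)
    E = (module_eigengenes(values, labels)
         if set(labels) - {0} else pd.DataFrame(index=values.columns))
    return labels, E


def relabel_by_size(labels: pd.Series) -> pd.Series:
    sizes = labels[labels != 0].value_counts()
    # stable ordering: size desc, then old label asc
    order = sorted(sizes.index, key=lambda lab: (-sizes[lab], lab))
    mapping = {old: new for new, old in enumerate(order, start=1)}
    mapping[0] = 0
    return labels.map(mapping)


# ---------------------------------------------------------------------------
# module-trait association, membership, specificity, preservation


def module_trait_correlation(eigengenes: pd.DataFrame, traits: pd.DataFrame,
                             opts: CorrelationOptions | None = None) -> pd.DataFrame:
    """bicor of each eigengene with each trait (unit-weight trait side).

    Traits must be numeric; binary traits coded {0,1}, ordered traits by
    rank. Missing trait values are dropped pairwise; nObs reports the pairs
    actually used.
    """
    opts = opts or CorrelationOptions()
    rows = []
    for me in eigengenes.columns:
        e = eigengenes[me].to_numpy(dtype=float)
        for trait in traits.columns:
            tvals = traits[trait].to_numpy(dtype=float)
            keep = np.isfinite(e) & np.isfinite(tvals)
            n = int(keep.sum())
            if n < 3:
                rows.append({"module": me, "trait": trait, "bicor": np.nan,
                             "p": np.nan, "n_obs": n})
                continue
            r, p = bicor(e[keep], tvals[keep], opts, robust_y=False)
            rows.append({"module": me, "trait": trait, "bicor": r, "p": p,
                         "n_obs": n})
    return pd.DataFrame(rows)


def module_membership(m: ExpressionMatrix | pd.DataFrame,
                      eigengenes: pd.DataFrame,
                      opts: CorrelationOptions | None = None):
    """kME: bicor of every transcript with every module eigengene, with p."""
    values = m.values if isinstance(m, ExpressionMatrix) else m
    opts = opts or CorrelationOptions()
    n = values.shape[1]
    kme = pd.DataFrame(index=values.index, columns=eigengenes.columns,
                       dtype=float)
    kme_p = kme.copy()
    X = values.to_numpy()
    E = eigengenes.to_numpy()
    # vectorize: prepared transcripts against prepared eigengenes
    Vx = _prepare_rows_robust(X, opts)
    Ve = _prepare_rows_robust(E.T, opts)
    R = np.clip(Vx @ Ve.T, -1.0, 1.0)
    kme.iloc[:, :] = R
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt((n - 2) / np.maximum(1.0 - R**2, 1e-300))
    kme_p.iloc[:, :] = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return kme, kme_p


def _prepare_rows_robust(X: np.ndarray, opts: CorrelationOptions,
                         return_dead: bool = False):
    """Row-wise biweight preparation; the bicor of rows i,j is V_i . V_j.

    Rows with zero MAD fall back to Pearson centring; rows that remain
    constant are 'dead' (correlation undefined).
    """
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    res = X - med
    mad = np.median(np.abs(res), axis=1, keepdims=True)
    fallback = (mad == 0.0).ravel()
    u = np.zeros_like(X, dtype=float)
    nz = ~fallback
    u[nz] = res[nz] / (opts.tuning_constant * mad[nz])
    ql = np.quantile(u, opts.max_p_outliers, axis=1, keepdims=True)
    qu = np.quantile(u, 1.0 - opts.max_p_outliers, axis=1, keepdims=True)
    u = np.where(u < 0, u / np.maximum(-ql, 1.0), u / np.maximum(qu, 1.0))
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    v = res * w
    if fallback.any():
        xf = X[fallback]
        v[fallback] = xf - xf.mean(axis=1, keepdims=True)
    norms = np.sqrt((v**2).sum(axis=1, keepdims=True))
    dead = (norms == 0.0).ravel()
    norms[dead] = 1.0
    v = v / norms
    return (v, dead) if return_dead else v


def hub_transcripts(kme: pd.DataFrame, labels: pd.Series) -> dict[int, str]:
    """argmax kME among each module's members; ties -> lowest transcript id."""
    hubs = {}
    for lab in sorted(set(labels) - {0}):
        members = labels.index[labels == lab]
        col = f"ME{lab}"
        vals = kme.loc[members, col]
        best = vals.max()
        hubs[lab] = sorted(vals.index[vals == best])[0]
    return hubs


def module_overlap_specificity(labels_single: pd.Series,
                               labels_consensus: pd.Series,
                               threshold: float = 10.0):
    """Fisher-exact overlap of single-tissue vs consensus modules.

    Returns (flags, table): ``flags`` maps each single-tissue module to True
    when NO consensus module overlaps it at -log10 p >= threshold (i.e. the
    module is tissue-specific); ``table`` holds every pairwise 2x2 test.
    """
    if not labels_single.index.equals(labels_consensus.index):
        raise ValueError("label series must share a transcript universe")
    total = len(labels_single)
    rows = []
    flags = {}
    for s in sorted(set(labels_single) - {0}):
        in_s = labels_single == s
        if in_s.sum() == 0:
            logger.warning("empty module %s skipped", s)
            continue
        best = 0.0
        for c in sorted(set(labels_consensus) - {0}):
            in_c = labels_consensus == c
            a = int((in_s & in_c).sum())
            b = int((in_s & ~in_c).sum())
            cc = int((~in_s & in_c).sum())
            dd = total - a - b - cc
            _, p = stats.fisher_exact([[a, b], [cc, dd]], alternative="two-sided")
            neglog = float(-np.log10(p)) if p > 0 else np.inf
            rows.append({"single_module": s, "consensus_module": c,
                         "overlap": a, "single_only": b, "consensus_only": cc,
                         "neither": dd, "p": p, "neg_log10_p": neglog})
            best = max(best, neglog)
        flags[s] = best < threshold
    return flags, pd.DataFrame(rows)


def eigengene_network_preservation(e_a: pd.DataFrame, e_b: pd.DataFrame) -> float:
    """D = 1 - mean_{i<j} |cor_A(Ei,Ej) - cor_B(Ei,Ej)| / 2, in [0,1]."""
    cols = list(e_a.columns)
    if cols != list(e_b.columns):
        raise ValueError("eigengene sets must cover the same modules")
    if len(cols) < 2:
        raise ValueError("need >= 2 modules")
    ca = np.corrcoef(e_a.to_numpy().T)
    cb = np.corrcoef(e_b.to_numpy().T)
    iu = np.triu_indices(len(cols), k=1)
    return float(1.0 - np.mean(np.abs(ca[iu] - cb[iu])) / 2.0)


def count_unassigned(labels: pd.Series) -> tuple[float, int]:
    n0 = int((labels == 0).sum())
    return n0 / len(labels), n0


# ---------------------------------------------------------------------------
# pipelines


def build_network(m: ExpressionMatrix, params: NetworkParams | None = None,
                  opts: CorrelationOptions | None = None) -> ModuleSet:
    """Single-tissue pipeline: adjacency -> TOM -> tree cut -> merge -> kME."""
    params = params or NetworkParams()
    opts = opts or CorrelationOptions()
    a = adjacency(m, params.power, opts)
    tom = tom_similarity(a)
    labels = cut_tree_dynamic(tom, params, transcripts=m.transcripts)
    z = labels.attrs.get("linkage")
    if set(labels) - {0}:
        labels, eig = merge_close_modules(m, labels,
                                          merge_height=params.merge_height)
        kme, kme_p = module_membership(m, eig, opts)
    else:
        eig = pd.DataFrame(index=m.samples)
        kme = kme_p = pd.DataFrame(index=m.transcripts)
    logger.info("network: %d transcripts, %d modules, %.1f%% unassigned",
                len(labels), len(set(labels) - {0}),
                100 * count_unassigned(labels)[0])
    return ModuleSet(labels=labels, eigengenes=eig, kme=kme, kme_p=kme_p,
                     dendrogram=z)


def build_consensus(ms: list[ExpressionMatrix],
                    params: NetworkParams | None = None,
                    opts: CorrelationOptions | None = None) -> ModuleSet:
    """Consensus pipeline over >= 2 tissues sharing a transcript universe.

    TOMs are quantile-scaled to the first tissue and combined by entrywise
    minimum; merging uses the maximum eigengene dissimilarity across
    tissues. Per-tissue eigengenes/kME are stored in ``extra``.
    """
    params = params or NetworkParams()
    opts = opts or CorrelationOptions()
    base = ms[0].transcripts
    for m in ms[1:]:
        if not m.transcripts.equals(base):
            raise ValueError("tissues must share an identical transcript set")
    toms = [tom_similarity(adjacency(m, params.power, opts)) for m in ms]
    consensus, exponents = scale_and_consensus(toms, params.scale_quantile)
    labels = cut_tree_dynamic(consensus, params, transcripts=base)
    z = labels.attrs.get("linkage")
    if set(labels) - {0}:
        labels = _merge_consensus(ms, labels, params.merge_height)
    eigs = {i: module_eigengenes(m, labels) if set(labels) - {0}
            else pd.DataFrame(index=m.samples) for i, m in enumerate(ms)}
    kme = {}
    for i, m in enumerate(ms):
        if set(labels) - {0}:
            kme[i] = module_membership(m, eigs[i], opts)[0]
    logger.info("consensus: %d modules, %.1f%% unassigned",
                len(set(labels) - {0}), 100 * count_unassigned(labels)[0])
    return ModuleSet(labels=labels, eigengenes=eigs.get(0), dendrogram=z,
                     extra={"eigengenes_per_set": eigs, "kme_per_set": kme,
                            "scaling_exponents": exponents})


def _merge_consensus(ms, labels, merge_height):
    labels = labels.copy()
    while True:
        modules = sorted(set(labels) - {0})
        if len(modules) < 2:
            break
        dis = np.zeros((len(modules), len(modules)))
        for m in ms:
            E = module_eigengenes(m, labels)
            cor = np.corrcoef(E.to_numpy().T)
            dis = np.maximum(dis, 1.0 - cor)
        np.fill_diagonal(dis, np.inf)
        i, j = np.unravel_index(np.argmin(dis), dis.shape)
        if dis[i, j] >= merge_height:
            break
        labels[labels == modules[j]] = modules[i]
    return relabel_by_size(labels)
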