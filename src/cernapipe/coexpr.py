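"""Weighted co-expression network core.

The standard weighted-network workflow: low-count gene filtering (row sum
strictly greater than 10), a simplified variance-stabilizing transform
``log2(count/size_factor + 1)``, soft-threshold selection by scale-free
topology fit, unsigned adjacency ``|cor|^beta``, topological overlap,
average-linkage module detection with a static height cut, module
eigengenes (first principal component), module-trait correlation with
Student-t p-values, and kME-based hub calling.

Deliberate simplifications relative to the reference R implementation, all
documented in the methods note: the VST is the log2 of normalized counts
plus one rather than the parametric fit; module detection uses a static cut
of the average-linkage tree at an absolute dissimilarity (default 0.95)
instead of the dynamic hybrid tree cut; the network is unsigned.  Module
counts on real data will therefore differ from the R package's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "CoexprParams",
    "CoexpressionResult",
    "vst_transform",
    "filter_genes",
    "pick_soft_threshold",
    "select_power",
    "scale_free_fit",
    "adjacency",
    "tom_similarity",
    "detect_modules",
    "module_eigengenes",
    "module_trait",
    "hub_genes",
    "run_coexpr",
]


@dataclass(frozen=True)
class CoexprParams:
    min_sum_counts: float = 10.0
    candidate_powers: tuple[int, ...] = tuple(range(1, 21))
    scale_free_r2_target: float = 0.8
    min_module_size: int = 30
    cut_height: float | None = None  # None = automatic largest-gap cut
    kme_hub_threshold: float = 0.8
    module_p_threshold: float = 0.05
    n_bins: int = 10

    def __post_init__(self) -> None:
        if min(self.candidate_powers) < 1:
            raise ValueError("powers must be >= 1")
        thresholds = [self.scale_free_r2_target, self.kme_hub_threshold, self.module_p_threshold]
        if self.cut_height is not None:
            thresholds.append(self.cut_height)
        for thr in thresholds:
            if not 0 < thr <= 1:
                raise ValueError("thresholds must lie in (0, 1]")


@dataclass
class CoexpressionResult:
    power: int
    scale_free_r2: dict[int, float]
    labels: pd.Series  # module label per gene; 0 = unassigned (grey)
    eigengenes: pd.DataFrame  # modules x samples, unit norm
    variance_explained: dict[int, float]
    module_trait_r: pd.DataFrame  # modules x traits
    module_trait_p: pd.DataFrame
    hub_sets: dict[int, set[str]]


def vst_transform(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Simplified variance-stabilizing transform: log2(count/factor + 1)."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    f = factors.reindex(counts.columns).to_numpy(dtype=float)
    if (f <= 0).any() or np.isnan(f).any():
        raise ValueError("size factors must be positive for every sample")
    return pd.DataFrame(
        np.log2(counts.to_numpy(dtype=float) / f[None, :] + 1.0),
        index=counts.index,
        columns=counts.columns,
    )


def filter_genes(counts: pd.DataFrame, min_sum_counts: float = 10.0) -> pd.Index:
    """Genes whose total count across samples strictly exceeds the threshold."""
    sums = counts.sum(axis=1)
    return counts.index[sums > min_sum_counts]


def _connectivity(abs_cor: np.ndarray, beta: int) -> np.ndarray:
    a = abs_cor**beta
    return a.sum(axis=0) - np.diag(a)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log10(freq) ~ log10(mean k) regression over k bins."""
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        raise ValueError("degenerate connectivity distribution (single-valued)")
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(logk, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return 0.0
    res = stats.linregress(xs, ys)
    return float(res.rvalue**2)


def pick_soft_threshold(
    expr: pd.DataFrame, params: CoexprParams = CoexprParams()
) -> tuple[int, dict[int, float]]:
    """Choose the soft power by scale-free topology fit.

    For each candidate power, form the unsigned adjacency, compute per-gene
    connectivity, bin log10(k) into ``n_bins`` bins and regress log10 bin
    frequency on log10 mean connectivity.  The chosen power is the smallest
    one whose R^2 reaches the target (0.8 by default), else the argmax R^2.
    """
    if expr.shape[1] < 8:
        warnings.warn("fewer than 8 samples: scale-free fit will be unstable")
    abs_cor = np.abs(np.corrcoef(expr.to_numpy(dtype=float)))
    abs_cor = np.nan_to_num(abs_cor)
    r2: dict[int, float] = {}
    for beta in params.candidate_powers:
        k = _connectivity(abs_cor, beta)
        r2[beta] = scale_free_fit(k, params.n_bins)
    return select_power(r2, params.scale_free_r2_target), r2


def select_power(r2: dict[int, float], target: float) -> int:
    """Smallest power whose fit reaches the target, else the argmax R^2."""
    admissible = [b for b in sorted(r2) if r2[b] >= target]
    return admissible[0] if admissible else max(sorted(r2), key=lambda b: r2[b])


def adjacency(expr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned adjacency a_ij = |Pearson r|^beta, unit diagonal.

    Zero-variance genes get an all-zero row/column (diagonal aside) with a
    warning.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        warnings.warn("zero-variance genes: adjacency rows set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.abs(np.corrcoef(x)) ** beta
    a = np.nan_to_num(a, nan=0.0)
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def tom_similarity(adj: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``k_i = sum_{u != i} a_iu``; the diagonal is excluded from all sums and
    ``TOM_ii = 1``.
    """
    a = np.asarray(adj, dtype=float).copy()
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if np.abs(a - a.T).max() > 1e-8:
        raise ValueError("adjacency is asymmetric beyond tolerance 1e-8")
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    tom: np.ndarray, gene_ids: pd.Index, params: CoexprParams = CoexprParams()
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    With ``cut_height=None`` (the default) the cut is placed automatically
    at the midpoint of the largest gap in the sorted merge heights: tight
    within-module merges sit well below the near-1 dissimilarities at which
    unrelated genes agglomerate, and the widest gap in the dendrogram
    height distribution separates the two regimes without an
    instance-specific constant.  Clusters smaller than ``min_module_size``
    are assigned label 0 (grey); surviving modules are renumbered by
    decreasing size (ties broken by the smallest member's position, for
    determinism).
    """
    n = len(gene_ids)
    labels = pd.Series(0, index=gene_ids, name="module")
    if n < params.min_module_size:
        warnings.warn("fewer genes than min_module_size: all genes left grey")
        return labels
    dissim = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    z = linkage(squareform(dissim, checks=False), method="average")
    if params.cut_height is None:
        heights = np.sort(z[:, 2])
        gaps = np.diff(heights)
        i = int(np.argmax(gaps))
        cut = float((heights[i] + heights[i + 1]) / 2.0)
    else:
        cut = params.cut_height
    raw = fcluster(z, t=cut, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = [c for c in sizes.index if sizes[c] >= params.min_module_size]
    # order: decreasing size, then first occurrence
    first_pos = {c: int(np.argmax(raw == c)) for c in keep}
    keep.sort(key=lambda c: (-sizes[c], first_pos[c]))
    for new, old in enumerate(keep, start=1):
        labels.iloc[np.flatnonzero(raw == old)] = new
    return labels


def module_eigengenes(
    expr: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, dict[int, float]]:
    """First principal component of each module's standardized expression.

    Eigengenes are unit-norm sample profiles, sign-oriented to correlate
    positively with the module's mean standardized expression; the fraction
    of variance explained is reported per module.  A single-gene module's
    eigengene is that gene's standardized profile (unit norm).
    """
    modules = sorted(set(labels) - {0})
    if not modules:
        raise ValueError("no non-grey module")
    eg = {}
    varexp = {}
    for m in modules:
        sub = expr.loc[labels.index[labels == m]].to_numpy(dtype=float)
        mean = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)
        z = (sub - mean) / np.where(sd == 0, 1.0, sd)
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        v = vt[0]
        varexp[m] = float(s[0] ** 2 / np.sum(s**2)) if np.sum(s**2) > 0 else 0.0
        profile = z.mean(axis=0)
        if np.dot(v, profile) < 0:
            v = -v
        eg[m] = v / np.linalg.norm(v)
    out = pd.DataFrame(eg, index=expr.columns).T
    out.index.name = "module"
    return out, varexp


def module_trait(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided Student-t p per (module, trait) pair.

    ``traits`` is a samples x traits matrix (e.g. binary stage indicators);
    p is from ``t = r * sqrt((n-2) / (1-r^2))`` with n-2 degrees of freedom.
    Constant traits yield NaN with a warning.
    """
    n = eigengenes.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    tr = traits.reindex(eigengenes.columns)
    if tr.isna().any().any():
        raise ValueError("traits must cover every sample")
    tsd = tr.std(axis=0, ddof=0)
    if (tsd == 0).any():
        warnings.warn("constant trait columns: correlation undefined (NaN)")
    ez = eigengenes.sub(eigengenes.mean(axis=1), axis=0)
    ez = ez.div(ez.std(axis=1, ddof=0).replace(0, np.nan), axis=0)
    tz = tr.sub(tr.mean(axis=0), axis=1).div(tsd.replace(0, np.nan), axis=1)
    r = ez.to_numpy() @ tz.to_numpy() / n
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    rdf = pd.DataFrame(r, index=eigengenes.index, columns=traits.columns)
    pdf = pd.DataFrame(p, index=eigengenes.index, columns=traits.columns)
    return rdf, pdf


def hub_genes(
    expr: pd.DataFrame,
    labels: pd.Series,
    eigengenes: pd.DataFrame,
    params: CoexprParams = CoexprParams(),
) -> dict[int, set[str]]:
    """kME-based hubs: |cor(gene, its module's eigengene)| >= threshold.

    Grey (label 0) genes are never hubs.
    """
    hubs: dict[int, set[str]] = {}
    x = expr.to_numpy(dtype=float)
    xz = x - x.mean(axis=1, keepdims=True)
    sd = xz.std(axis=1)
    xz = xz / np.where(sd == 0, np.nan, sd)[:, None]
    for m in eigengenes.index:
        members = np.flatnonzero((labels.reindex(expr.index) == m).to_numpy())
        e = eigengenes.loc[m].to_numpy(dtype=float)
        ez = (e - e.mean()) / e.std()
        kme = np.abs(xz[members] @ ez / x.shape[1])
        hubs[int(m)] = {
            str(expr.index[members[i]])
            for i in range(len(members))
            if kme[i] >= params.kme_hub_threshold
        }
    return hubs


def run_coexpr(
    counts: pd.DataFrame,
    factors: pd.Series,
    stage_of_sample: pd.Series,
    params: CoexprParams = CoexprParams(),
) -> CoexpressionResult:
    """Counts -> modules -> eigengenes -> stage association -> hubs."""
    kept = filter_genes(counts, params.min_sum_counts)
    expr = vst_transform(counts.loc[kept], factors)
    power, r2 = pick_soft_threshold(expr, params)
    adj = adjacency(expr, power)
    tom = tom_similarity(adj.to_numpy())
    labels = detect_modules(tom, expr.index, params)
    if (labels != 0).sum() == 0:
        warnings.warn("no module detected")
        empty = pd.DataFrame(index=pd.Index([], name="module"), columns=expr.columns)
        traits = pd.get_dummies(stage_of_sample.reindex(expr.columns)).astype(float)
        return CoexpressionResult(power, r2, labels, empty, {}, empty, empty, {})
    eigengenes, varexp = module_eigengenes(expr, labels)
    traits = pd.get_dummies(stage_of_sample.reindex(expr.columns)).astype(float)
    mt_r, mt_p = module_trait(eigengenes, traits)
    hubs = hub_genes(expr, labels, eigengenes, params)
    return CoexpressionResult(power, r2, labels, eigengenes, varexp, mt_r, mt_p, hubs)
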