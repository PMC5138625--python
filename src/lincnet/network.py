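"""Signed weighted co-expression network analysis.

The pipeline mirrors the standard WGCNA workflow, implemented from first
principles: pretreatment (expression and variance filters, log transform),
soft-threshold selection by scale-free topology fit, signed adjacency
a_ij = ((1 + cor_ij)/2)^beta, topological overlap (TOM), average-linkage
clustering of 1 − TOM with a dynamic (static-height + minimum-size) tree cut,
module eigengenes (first principal component), eigengene-correlation module
merging, module–stage correlation statistics, and kME-based hub extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

UNASSIGNED = "unassigned"


@dataclass
class PreprocessConfig:
    """Pretreatment of the FPKM matrix before network construction.

    Genes whose maximum FPKM falls below ``min_max_fpkm`` are dropped; of the
    remainder the top ``variance_quantile_kept`` fraction by variance is kept;
    values are log2(FPKM + ``log_offset``).
    """

    min_max_fpkm: float = 0.05
    variance_quantile_kept: float = 0.75
    log_offset: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.variance_quantile_kept <= 1):
            raise ValueError("variance_quantile_kept must lie in (0, 1]")


def preprocess(values: pd.DataFrame, config: PreprocessConfig | None = None) -> pd.DataFrame:
    """Filter and log-transform an FPKM matrix (genes × samples)."""
    config = config or PreprocessConfig()
    expressed = values[values.max(axis=1) >= config.min_max_fpkm]
    if expressed.empty:
        raise ValueError("all genes dropped by the expression filter")
    n_keep = int(np.ceil(len(expressed) * config.variance_quantile_kept))
    variances = expressed.var(axis=1)
    order = variances.sort_values(ascending=False, kind="stable")
    # deterministic tie-break: variance desc, then gene id
    ranked = sorted(order.index, key=lambda g: (-variances[g], g))
    kept = expressed.loc[sorted(ranked[:n_keep], key=list(values.index).index)]
    return np.log2(kept + config.log_offset)


# --------------------------------------------------------------------------
# Adjacency and TOM


def signed_adjacency(expr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Signed adjacency a_ij = ((1 + cor_ij) / 2)^beta over genes (rows).

    Diagonal is 1 by convention; connectivity sums exclude it.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    sd = expr.values.std(axis=1)
    flat = [g for g, s in zip(expr.index, sd) if s == 0]
    if flat:
        raise ValueError(f"zero-variance genes (remove in preprocess): {flat[:10]}")
    cor = np.corrcoef(expr.values)
    adj = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=expr.index, columns=expr.index)


def connectivity(adjacency: pd.DataFrame) -> pd.Series:
    """k_i = sum of adjacency to all other genes (diagonal excluded)."""
    a = adjacency.values.copy()
    np.fill_diagonal(a, 0.0)
    return pd.Series(a.sum(axis=1), index=adjacency.index, name="k")


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit of a connectivity distribution.

    Bins k into ``n_bins`` equal-width bins, regresses log10 p(k) on
    log10(mean k) over non-empty bins, and returns (signed R², slope) where
    the sign is that of the negative slope (scale-free networks have
    decreasing p(k)).
    """
    k = np.asarray(k, dtype=float)
    if np.allclose(k, k[0]):
        return float("nan"), float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        mean_k = k[mask].mean()
        p = mask.mean()
        if mean_k > 0 and p > 0:
            xs.append(np.log10(mean_k))
            ys.append(np.log10(p))
    if len(xs) < 3:
        return float("nan"), float("nan")
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(r**2 * np.sign(-slope)), float(slope)


@dataclass
class SoftThresholdResult:
    beta: int
    reached_target: bool
    fit_table: pd.DataFrame  # per candidate power: signed R², slope, mean k


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers: Sequence[int] = tuple(range(1, 21)),
    target_r2: float = 0.9,
) -> SoftThresholdResult:
    """Smallest power whose signed scale-free fit R² reaches ``target_r2``.

    Falls back (with a warning) to the argmax power when no candidate reaches
    the target — the pure-noise regime.
    """
    rows = []
    for beta in powers:
        adj = signed_adjacency(expr, beta)
        k = connectivity(adj).values
        r2, slope = scale_free_fit(k)
        rows.append({"power": beta, "signed_r2": r2, "slope": slope, "mean_k": float(k.mean())})
    table = pd.DataFrame(rows).set_index("power")
    ok = table[table["signed_r2"] >= target_r2]
    if not ok.empty:
        return SoftThresholdResult(int(ok.index[0]), True, table)
    warnings.warn(
        f"no power reached signed R^2 >= {target_r2}; using the best fit", stacklevel=2
    )
    best = int(table["signed_r2"].idxmax()) if table["signed_r2"].notna().any() else int(table.index[-1])
    return SoftThresholdResult(best, False, table)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a signed adjacency.

    t_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij) with
    l_ij = Σ_{u≠i,j} a_iu a_uj; the diagonal is 1.
    """
    a = adjacency.values.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a  # zero diagonal makes the sum skip u=i and u=j automatically
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


# --------------------------------------------------------------------------
# Clustering, dynamic cut, eigengenes


@dataclass
class ModuleAssignment:
    """Gene → module label; genes in no module carry the ``unassigned`` label."""

    labels: pd.Series

    @property
    def module_ids(self) -> list[str]:
        return sorted(set(self.labels) - {UNASSIGNED})

    def members(self, module: str) -> list[str]:
        return sorted(self.labels.index[self.labels == module])

    def sizes(self) -> pd.Series:
        return self.labels[self.labels != UNASSIGNED].value_counts()


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    """Deterministic module names M1, M2, ... ordered by size then first gene."""
    genes = list(labels.index)
    groups: dict[str, list[str]] = {}
    for g, lab in labels.items():
        if lab != UNASSIGNED:
            groups.setdefault(lab, []).append(g)
    order = sorted(groups, key=lambda m: (-len(groups[m]), min(genes.index(g) for g in groups[m])))
    mapping = {old: f"M{i + 1}" for i, old in enumerate(order)}
    mapping[UNASSIGNED] = UNASSIGNED
    return labels.map(mapping)


def cluster_and_cut(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_height_quantile: float = 0.9,
) -> tuple[np.ndarray, ModuleAssignment]:
    """Average-linkage clustering of 1 − TOM with a static-height dynamic cut.

    The dendrogram is cut at the given quantile of its merge heights; branches
    below the cut that contain at least ``min_module_size`` genes become
    modules (labelled by decreasing size), all other genes are unassigned.
    The 0.9 default leaves room between the within-module merges and the
    high-dissimilarity joins through which unclustered genes attach; cutting
    at the very top of the tree would absorb those genes into modules.
    """
    genes = list(tom.index)
    if len(genes) < 2:
        raise ValueError("need at least two genes to cluster")
    d = 1.0 - tom.values
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # enforce exact symmetry for squareform
    z = linkage(squareform(d, checks=False), method="average")
    heights = z[:, 2]
    # quantile cut plus a small height-range slack: without it, a coherent
    # branch whose last few internal merges sit just above the quantile would
    # be truncated and its members orphaned
    cut = float(np.quantile(heights, cut_height_quantile))
    cut += 0.05 * float(heights.max() - heights.min())
    flat = fcluster(z, t=cut, criterion="distance")
    labels = pd.Series([str(c) for c in flat], index=genes)
    sizes = labels.value_counts()
    small = sizes.index[sizes < min_module_size]
    labels[labels.isin(small)] = UNASSIGNED
    if (labels == UNASSIGNED).all():
        warnings.warn("no branch reached the minimum module size; all genes unassigned",
                      stacklevel=2)
    return z, ModuleAssignment(_relabel_by_size(labels))


@dataclass
class Eigengenes:
    """Module eigengenes: first principal component of each module's profiles.

    ``values`` is modules × samples with unit-norm rows, oriented so the
    eigengene correlates non-negatively with the module's mean profile.
    """

    values: pd.DataFrame
    explained_variance: pd.Series


def module_eigengenes(expr: pd.DataFrame, assignment: ModuleAssignment) -> Eigengenes:
    rows, ev = {}, {}
    for module in assignment.module_ids:
        members = assignment.members(module)
        X = expr.loc[members].values
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        u, s, vt = np.linalg.svd(Xs, full_matrices=False)
        e = vt[0]
        e = e / np.linalg.norm(e)
        mean_profile = Xs.mean(axis=0)
        if mean_profile.std() > 0 and np.corrcoef(e, mean_profile)[0, 1] < 0:
            e = -e
        rows[module] = e
        ev[module] = float(s[0] ** 2 / np.sum(s**2))
    values = pd.DataFrame(rows, index=expr.columns).T
    return Eigengenes(values, pd.Series(ev, name="explained_variance"))


def merge_modules(
    expr: pd.DataFrame,
    assignment: ModuleAssignment,
    threshold: float = 0.7,
) -> ModuleAssignment:
    """Iteratively merge the module pair with the highest eigengene correlation
    above ``threshold``, recomputing eigengenes after every merge, to fixpoint.

    Ties break by label order; the merged module keeps the lexicographically
    first label and the final assignment is relabelled by size.
    """
    labels = assignment.labels.copy()
    while True:
        current = ModuleAssignment(labels)
        modules = current.module_ids
        if len(modules) < 2:
            break
        eg = module_eigengenes(expr, current).values
        cor = np.corrcoef(eg.values)
        # highest-correlation pair above threshold; ties break by label order
        candidates = [
            (cor[i, j], modules[i], modules[j])
            for i in range(len(modules))
            for j in range(i + 1, len(modules))
            if cor[i, j] > threshold
        ]
        if not candidates:
            break
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        best = candidates[0][1:]
        keep, absorb = sorted(best)
        labels[labels == absorb] = keep
    return ModuleAssignment(_relabel_by_size(labels))


# --------------------------------------------------------------------------
# Module–stage statistics and hubs


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the Student t transform."""
    if n <= 2:
        raise ValueError("need more than two samples")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def module_stage_stats(eigengenes: Eigengenes, stage_design: pd.Series) -> pd.DataFrame:
    """Pearson r and p of each eigengene against one-hot stage indicators.

    Returns a long table (module, stage, r, p); the design maps sample → stage
    and must cover the eigengene samples.
    """
    samples = list(eigengenes.values.columns)
    stages_per_sample = stage_design.loc[samples]
    stages = list(dict.fromkeys(stages_per_sample))
    n = len(samples)
    if n < 4:
        raise ValueError("need at least four samples for module-stage statistics")
    rows = []
    for module in eigengenes.values.index:
        e = eigengenes.values.loc[module].values
        for stage in stages:
            indicator = (stages_per_sample == stage).astype(float).values
            if indicator.std() == 0 or e.std() == 0:
                r = float("nan")
                p = float("nan")
            else:
                r = float(np.corrcoef(e, indicator)[0, 1])
                p = correlation_pvalue(r, n)
            rows.append({"module": module, "stage": stage, "r": r, "p": p})
    return pd.DataFrame(rows, columns=["module", "stage", "r", "p"])


def stage_specific_modules(
    stats_table: pd.DataFrame, r_threshold: float = 0.7, p_threshold: float = 1e-4
) -> pd.DataFrame:
    """Modules whose eigengene correlates with one stage (r > 0.7, p < 1e-4)."""
    hits = stats_table[(stats_table["r"] > r_threshold) & (stats_table["p"] < p_threshold)]
    return hits.sort_values(["module", "stage"]).reset_index(drop=True)


def kme_table(expr: pd.DataFrame, eigengenes: Eigengenes) -> pd.DataFrame:
    """Module membership kME(i, q) = cor(x_i, E_q) for every gene × module."""
    X = expr.values
    out = {}
    for module in eigengenes.values.index:
        e = eigengenes.values.loc[module].values
        ex = X - X.mean(axis=1, keepdims=True)
        ee = e - e.mean()
        denom = np.sqrt((ex**2).sum(axis=1) * (ee**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            out[module] = (ex @ ee) / denom
    return pd.DataFrame(out, index=expr.index)


def kme_and_hubs(
    expr: pd.DataFrame,
    eigengenes: Eigengenes,
    assignment: ModuleAssignment,
    top_n: int = 100,
    lincrna_ids: Iterable[str] = (),
) -> pd.DataFrame:
    """Per-module hub table: members ranked by kME (desc, then gene id), top_n kept.

    If a module has fewer than ``top_n`` members the whole module is emitted.
    The ``is_lincrna`` flag marks features found in ``lincrna_ids``.
    """
    linc = set(lincrna_ids)
    kme = kme_table(expr, eigengenes)
    rows = []
    for module in assignment.module_ids:
        members = assignment.members(module)
        scores = kme.loc[members, module]
        ranked = sorted(members, key=lambda g: (-scores[g], g))
        for rank, g in enumerate(ranked[:top_n], start=1):
            rows.append(
                {
                    "module": module,
                    "gene_id": g,
                    "kme": float(scores[g]),
                    "rank": rank,
                    "is_lincrna": g in linc,
                }
            )
    return pd.DataFrame(rows, columns=["module", "gene_id", "kme", "rank", "is_lincrna"])


def hub_pair_weights(expr: pd.DataFrame, genes: Sequence[str], beta: int = 13) -> pd.DataFrame:
    """Pairwise signed-adjacency weights among selected genes (hub-neighbor report)."""
    return signed_adjacency(expr.loc[list(genes)], beta)
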