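"""Weighted co-expression network analysis and the k-means compendium.

The weighted-network route follows the standard WGCNA recipe: Pearson
correlation → soft-powered adjacency (unsigned ``|r|^β`` by default, with
β chosen for approximate scale-free topology) → topological overlap
matrix (TOM) → average-linkage clustering of 1−TOM with a static cut →
small clusters to grey → merging of modules with highly correlated
eigengenes. Module eigengenes (first principal components) are then
correlated against binary sample-trait indicators with Student-t
p-values.

Module detection here uses a static tree cut plus eigengene merging
rather than the dynamic-hybrid cut; the simplified procedure is fully
deterministic and configurable (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats
from sklearn.cluster import KMeans

from .matrix import ExpressionMatrix

#: module colors in assignment order (decreasing module size); grey = unassigned
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]
GREY = "grey"


@dataclass
class NetworkParams:
    power_grid: tuple = tuple(range(1, 21))
    r2_target: float = 0.8          # scale-free topology fit target
    sign_mode: str = "unsigned"     # or "signed"
    min_module_size: int = 30
    cut_height: float = 0.99        # static cut on the 1−TOM dendrogram
    merge_cut: float = 0.75         # eigengene-correlation merge threshold
    kmeans_k: int = 80
    kmeans_seed: int = 0
    edge_threshold: float = 0.1
    n_connectivity_bins: int = 10

    def __post_init__(self) -> None:
        if min(self.power_grid) < 1:
            raise ValueError("powers must be ≥ 1")
        if not 0 < self.cut_height <= 1 or not 0 < self.merge_cut <= 1:
            raise ValueError("cut heights must lie in (0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be ≥ 2")
        if self.sign_mode not in ("unsigned", "signed"):
            raise ValueError(f"unknown sign_mode {self.sign_mode!r}")


@dataclass
class ModuleAssignment:
    labels: pd.Series        # gene -> color label, "grey" = unassigned
    method: str
    meta: dict = field(default_factory=dict)

    def module_sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def genes_in(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    @property
    def modules(self) -> list[str]:
        sizes = self.module_sizes()
        return [m for m in sizes.index if m != GREY]


def select_coexpression_genes(deg_sets) -> list[str]:
    """Union of genes labelled in at least one mutant contrast, sorted."""
    genes: set = set()
    for s in deg_sets:
        genes |= s.labelled_genes
    if not genes:
        warnings.warn("no labelled genes in any DEG set")
    return sorted(genes)


def _color_by_size(cluster_ids: pd.Series, min_size: int = 0) -> pd.Series:
    """Map integer cluster ids to color names by decreasing cluster size;
    clusters below min_size become grey."""
    sizes = cluster_ids.value_counts()
    labels = pd.Series(GREY, index=cluster_ids.index, dtype=object)
    kept = [c for c in sizes.index if sizes[c] >= min_size]
    for color, cid in zip(MODULE_COLORS, kept):
        labels[cluster_ids == cid] = color
    if len(kept) > len(MODULE_COLORS):
        for i, cid in enumerate(kept[len(MODULE_COLORS):]):
            labels[cluster_ids == cid] = f"module{len(MODULE_COLORS) + i + 1}"
    return labels


def kmeans_modules(expr: ExpressionMatrix, k: int, seed: int = 0) -> ModuleAssignment:
    """k-means co-expression compendium on logCLR gene profiles.

    Squared-Euclidean k-means with k-means++ seeding, 10 restarts, best
    inertia kept; deterministic for a fixed seed.
    """
    if k <= 0:
        raise ValueError("K must be positive")
    if expr.transform != "logclr":
        raise ValueError(f"kmeans_modules expects logclr values, got {expr.transform!r}")
    if k > expr.values.shape[0]:
        raise ValueError("K exceeds the number of genes")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    ids = pd.Series(km.fit_predict(expr.values.to_numpy()), index=expr.values.index)
    labels = _color_by_size(ids)
    return ModuleAssignment(labels, "kmeans",
                            {"K": k, "seed": seed, "inertia": float(km.inertia_)})


def _adjacency(expr_values: pd.DataFrame, power: float, sign_mode: str) -> np.ndarray:
    if (expr_values.std(axis=1) == 0).any():
        bad = expr_values.index[expr_values.std(axis=1) == 0].tolist()
        raise ValueError(f"zero-variance gene(s): {bad[:5]}")
    r = np.corrcoef(expr_values.to_numpy())
    if sign_mode == "signed":
        a = ((1.0 + r) / 2.0) ** power
    else:
        a = np.abs(r) ** power
    np.fill_diagonal(a, 0.0)
    return a


def _scale_free_fit(k: np.ndarray, n_bins: int) -> float:
    """R² of the log10 p(k) vs log10 k fit over binned connectivities,
    forced to 0 when the slope is not negative."""
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(r ** 2) if slope < 0 else 0.0


def pick_soft_threshold(expr: ExpressionMatrix,
                        params: NetworkParams | None = None
                        ) -> tuple[int, pd.DataFrame]:
    """Smallest power on the grid reaching the scale-free fit target; if
    none qualifies, the power maximizing the fit (with a warning)."""
    params = params or NetworkParams()
    if expr.values.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    rows = []
    for power in params.power_grid:
        a = _adjacency(expr.values, power, params.sign_mode)
        k = a.sum(axis=1)
        rows.append((power, _scale_free_fit(k, params.n_connectivity_bins),
                     float(k.mean())))
    diag = pd.DataFrame(rows, columns=["power", "r2", "mean_connectivity"])
    ok = diag[diag["r2"] >= params.r2_target]
    if len(ok):
        beta = int(ok["power"].iloc[0])
    else:
        beta = int(diag.loc[diag["r2"].idxmax(), "power"])
        warnings.warn(f"no power reached R² ≥ {params.r2_target}; "
                      f"using β = {beta} (max fit)")
    return beta, diag


def adjacency_and_tom(expr: ExpressionMatrix, power: float,
                      sign_mode: str = "unsigned") -> pd.DataFrame:
    """Topological overlap matrix from soft-powered adjacency.

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij), diagonal 1.
    """
    a = _adjacency(expr.values, power, sign_mode)
    k = a.sum(axis=1)
    shared = a @ a
    kmin = np.minimum.outer(k, k)
    tom = (shared + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=expr.values.index, columns=expr.values.index)


def detect_modules(tom: pd.DataFrame, params: NetworkParams | None = None,
                   expr: ExpressionMatrix | None = None) -> ModuleAssignment:
    """Average-linkage clustering of 1−TOM with a static cut.

    Clusters smaller than ``min_module_size`` become grey. When ``expr`` is
    given, modules whose eigengenes correlate above ``merge_cut`` are merged
    iteratively (most-correlated pair first). Labels are colors assigned by
    decreasing module size.
    """
    params = params or NetworkParams()
    dissim = 1.0 - tom.to_numpy()
    np.fill_diagonal(dissim, 0.0)
    link = sch.linkage(sch.distance.squareform(dissim, checks=False),
                       method="average")
    ids = pd.Series(sch.fcluster(link, t=params.cut_height, criterion="distance"),
                    index=tom.index)
    sizes = ids.value_counts()
    ids[ids.map(sizes) < params.min_module_size] = -1
    if expr is not None:
        ids = _merge_close_modules(ids, expr, params.merge_cut)
    labels = _color_by_size(ids[ids != -1], params.min_module_size).reindex(
        ids.index, fill_value=GREY)
    return ModuleAssignment(labels, "tree_cut",
                            {"cut_height": params.cut_height,
                             "min_module_size": params.min_module_size})


def _merge_close_modules(ids: pd.Series, expr: ExpressionMatrix,
                         merge_cut: float) -> pd.Series:
    ids = ids.copy()
    while True:
        modules = [m for m in ids.unique() if m != -1]
        if len(modules) < 2:
            return ids
        eig = {m: _eigengene(expr.values.loc[ids.index[ids == m]])[0]
               for m in modules}
        best, best_r = None, merge_cut
        for i, mi in enumerate(modules):
            for mj in modules[i + 1:]:
                r = abs(np.corrcoef(eig[mi], eig[mj])[0, 1])
                if r > best_r:
                    best, best_r = (mi, mj), r
        if best is None:
            return ids
        ids[ids == best[1]] = best[0]


@dataclass
class EigengeneMatrix:
    values: pd.DataFrame             # modules × samples, unit-norm rows
    variance_explained: pd.Series    # per module


def _eigengene(submatrix: pd.DataFrame) -> tuple[np.ndarray, float]:
    """First principal component of the row-standardized module submatrix,
    unit norm. The sign is fixed self-referentially — the largest-magnitude
    entry is made positive — so the eigengene is invariant both to gene
    order and to flipping the sign of every module gene."""
    x = submatrix.to_numpy(float)
    sd = x.std(axis=1, ddof=0)
    if (sd == 0).any():
        raise ValueError("zero-variance gene(s) in module")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    if e[int(np.argmax(np.abs(e)))] < 0:
        e = -e
    var_explained = float(s[0] ** 2 / (s ** 2).sum())
    return e, var_explained


def module_eigengenes(expr: ExpressionMatrix,
                      assignment: ModuleAssignment) -> EigengeneMatrix:
    rows, ve = {}, {}
    for module in assignment.modules:
        genes = assignment.genes_in(module)
        if len(genes) < 2:
            raise ValueError(f"module {module} has fewer than 2 genes")
        rows[module], ve[module] = _eigengene(expr.values.loc[genes])
    values = pd.DataFrame(rows, index=expr.values.columns).T
    return EigengeneMatrix(values, pd.Series(ve, name="variance_explained"))


def corr_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the Student-t transform,
    t = r√(n−2)/√(1−r²) with n−2 degrees of freedom."""
    if n < 3:
        raise ValueError("need n ≥ 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@dataclass
class ModuleTraitMatrix:
    r: pd.DataFrame     # modules × traits
    p: pd.DataFrame


def module_trait(eig: EigengeneMatrix, traits: pd.DataFrame) -> ModuleTraitMatrix:
    """Pearson correlation of each eigengene with each binary trait
    indicator, with Student-t p-values. Constant traits give NaN."""
    if list(eig.values.columns) != list(traits.index):
        traits = traits.reindex(eig.values.columns)
        if traits.isna().any().any():
            raise ValueError("trait matrix does not cover the eigengene samples")
    n = traits.shape[0]
    r = pd.DataFrame(index=eig.values.index, columns=traits.columns, dtype=float)
    p = r.copy()
    for trait in traits.columns:
        tv = traits[trait].to_numpy(float)
        if tv.std() == 0:
            continue  # leave NaN: correlation undefined
        for module in eig.values.index:
            rv = float(np.corrcoef(eig.values.loc[module], tv)[0, 1])
            r.loc[module, trait] = rv
            p.loc[module, trait] = corr_pvalue(rv, n)
    return ModuleTraitMatrix(r, p)


def export_network(tom: pd.DataFrame, assignment: ModuleAssignment,
                   threshold: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Undirected edge list (weight ≥ threshold, each pair once) and a node
    table with module labels, ready for Cytoscape/Gephi."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    genes = list(tom.index)
    t = tom.to_numpy()
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = t[iu, ju] >= threshold
    edges = pd.DataFrame({
        "source": [genes[i] for i in iu[keep]],
        "target": [genes[j] for j in ju[keep]],
        "weight": t[iu, ju][keep],
    })
    nodes = assignment.labels.rename("module").rename_axis("gene_id").reset_index()
    return edges, nodes


def write_sif(edges: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, row in edges.iterrows():
            fh.write(f"{row['source']}\tco\t{row['target']}\n")
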