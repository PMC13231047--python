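"""Weighted co-expression network analysis.

Implements the standard workflow: sample-outlier exclusion by mean
inter-sample correlation (mu - 3*sigma rule), selection of the most variable
genes by median absolute deviation, soft-threshold selection against a
scale-free topology fit, unsigned adjacency a_ij = |cor(i,j)|^beta,
topological overlap, average-linkage module detection with a static tree
cut, module eigengenes, and module-trait correlation.

Everything here is deterministic given the input matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix

__all__ = [
    "OutlierReport",
    "SoftThresholdScan",
    "ModuleAssignment",
    "detect_outlier_samples",
    "select_variable_genes",
    "pick_soft_threshold",
    "adjacency",
    "tom",
    "detect_modules",
    "module_eigengenes",
    "module_trait_correlation",
]


@dataclass
class OutlierReport:
    table: pd.DataFrame  # per sample: mean_similarity, excluded
    mu: float
    sigma: float

    @property
    def excluded(self) -> list[str]:
        return list(self.table.index[self.table["excluded"]])

    @property
    def retained(self) -> list[str]:
        return list(self.table.index[~self.table["excluded"]])


@dataclass
class SoftThresholdScan:
    table: pd.DataFrame  # per power: scale_free_r2, mean_connectivity
    chosen_beta: int
    reached_r2: bool


@dataclass
class ModuleAssignment:
    labels: pd.Series  # gene -> module int; 0 = unassigned (grey)
    eigengenes: pd.DataFrame | None = None  # modules x samples
    module_trait: pd.DataFrame | None = None  # per module: cor, p
    strongest_module: int | None = None

    def module_genes(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])

    @property
    def modules(self) -> list[int]:
        return sorted(m for m in self.labels.unique() if m != 0)


def detect_outlier_samples(expr: ExpressionMatrix, n_sigma: float = 3.0) -> OutlierReport:
    """Flag samples whose mean correlation with all other samples falls
    strictly below mu - n_sigma * sigma."""
    x = expr.values
    if x.shape[1] < 4:
        raise ValueError("need >=4 samples for outlier detection")
    sds = x.std(axis=0, ddof=1)
    constant = sds[sds == 0]
    if len(constant):
        raise ValueError(f"constant sample(s): {list(constant.index)}")
    cor = np.corrcoef(x.values.T)
    n = cor.shape[0]
    mean_sim = (cor.sum(axis=1) - 1.0) / (n - 1)
    mu = float(mean_sim.mean())
    sigma = float(mean_sim.std(ddof=1))
    excluded = mean_sim < mu - n_sigma * sigma
    table = pd.DataFrame(
        {"mean_similarity": mean_sim, "excluded": excluded}, index=x.columns
    )
    return OutlierReport(table=table, mu=mu, sigma=sigma)


def select_variable_genes(expr: ExpressionMatrix, k: int = 5000) -> ExpressionMatrix:
    """Keep the top-k genes by median absolute deviation (ties broken
    lexicographically by gene id)."""
    x = expr.values
    med = x.median(axis=1)
    mad = (x.sub(med, axis=0)).abs().median(axis=1)
    # sort on MAD descending; equal-MAD ties resolve lexicographically
    order = pd.DataFrame({"gene": mad.index.astype(str), "mad": mad.values})
    order = order.sort_values(
        ["mad", "gene"], ascending=[False, True], kind="mergesort"
    )
    keep = order["gene"].head(min(k, len(order))).tolist()
    return expr.subset_genes(keep)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log10 p(k) vs log10 k regression over
    equal-occupancy degree bins.

    With equal-occupancy bins the raw per-bin frequency is constant by
    construction, so p(k) is estimated as the per-bin density
    (count / (n * bin width)); zero-width bins (massive degree ties) are
    dropped.
    """
    if len(k) < n_bins:
        raise ValueError(f"need at least {n_bins} genes for the scale-free fit")
    edges = np.quantile(k, np.linspace(0.0, 1.0, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 4:
        return 0.0  # nearly constant degrees: no meaningful fit
    counts, _ = np.histogram(k, bins=edges)
    widths = np.diff(edges)
    centers = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = k[(k >= lo) & (k <= hi)]
        centers.append(in_bin.mean() if len(in_bin) else 0.0)
    centers = np.array(centers)
    density = counts / (len(k) * widths)
    ok = (centers > 0) & (density > 0)
    if ok.sum() < 3:
        return 0.0
    slope, _, r, _, _ = stats.linregress(np.log10(centers[ok]), np.log10(density[ok]))
    return float(np.sign(-slope) * r**2)


def pick_soft_threshold(
    expr: ExpressionMatrix,
    powers=range(1, 21),
    r2_min: float = 0.85,
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Scan candidate powers; choose the smallest whose scale-free fit R^2
    exceeds ``r2_min``, else the first plateau of the R^2 curve."""
    powers = list(powers)
    if len(powers) < 2:
        raise ValueError("scan at least two powers")
    s = np.abs(np.corrcoef(expr.values.values))
    np.fill_diagonal(s, 0.0)
    rows = []
    for beta in powers:
        a = s**beta
        k = a.sum(axis=1)
        rows.append(
            {
                "power": beta,
                "scale_free_r2": _scale_free_fit(k, n_bins=n_bins),
                "mean_connectivity": float(k.mean()),
            }
        )
    table = pd.DataFrame(rows).set_index("power")
    passing = table.index[table["scale_free_r2"] > r2_min]
    if len(passing):
        return SoftThresholdScan(table, int(passing[0]), True)
    r2 = table["scale_free_r2"].values
    chosen = powers[-1]
    for i in range(len(powers) - 1):
        if abs(r2[i + 1] - r2[i]) < 0.01:
            chosen = powers[i]
            break
    warnings.warn(
        f"no power reached scale-free R^2 > {r2_min}; "
        f"using plateau power {chosen}",
        stacklevel=2,
    )
    return SoftThresholdScan(table, int(chosen), False)


def adjacency(expr: ExpressionMatrix, beta: int) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency a_ij = |cor(i, j)|^beta."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    sds = expr.values.std(axis=1, ddof=1)
    zero = sds[sds == 0]
    if len(zero):
        raise ValueError(f"zero-variance gene(s): {list(zero.index)[:5]}")
    s = np.abs(np.corrcoef(expr.values.values)) ** beta
    np.fill_diagonal(s, 1.0)
    return pd.DataFrame(s, index=expr.values.index, columns=expr.values.index)


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) where
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu; TOM_ii = 1.
    """
    a = np.asarray(adj, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be square and symmetric")
    n = a.shape[0]
    off = a.copy()
    np.fill_diagonal(off, 0.0)
    k = off.sum(axis=1)
    l = off @ off  # (A^2)_ij minus diagonal contributions = sum over u != i,j
    t = (l + off) / (np.minimum.outer(k, k) + 1.0 - off)
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=adj.index, columns=adj.columns)


def detect_modules(
    dissim: pd.DataFrame, min_module_size: int = 30, cut_height: float = 0.99
) -> ModuleAssignment:
    """Average-linkage clustering of the TOM dissimilarity with a static
    tree cut; clusters below ``min_module_size`` become module 0 (grey);
    surviving modules are renumbered by size, largest first."""
    d = np.asarray(dissim, dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    genes = dissim.index
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    keep = sizes.index[sizes >= min_module_size]
    # renumber by size descending; stable tie-break on original label
    keep = sorted(keep, key=lambda c: (-sizes[c], c))
    mapping = {c: i + 1 for i, c in enumerate(keep)}
    out = labels.map(lambda c: mapping.get(c, 0))
    return ModuleAssignment(labels=out)


def module_eigengenes(
    expr: ExpressionMatrix, assignment: ModuleAssignment
) -> pd.DataFrame:
    """First principal component of each module's standardized submatrix,
    sign-aligned so its correlation with the module mean profile is
    positive. Rows = modules, columns = samples."""
    rows = {}
    for m in assignment.modules:
        genes = assignment.module_genes(m)
        sub = expr.values.loc[genes]
        z = sub.sub(sub.mean(axis=1), axis=0)
        sd = sub.std(axis=1, ddof=1).replace(0.0, 1.0)
        z = z.div(sd, axis=0)
        # samples as observations: PC scores from SVD of (samples x genes)
        u, s, vt = np.linalg.svd(z.values.T, full_matrices=False)
        pc = u[:, 0] * s[0]
        mean_profile = z.values.mean(axis=0)
        if np.dot(pc, mean_profile) < 0:
            pc = -pc
        rows[m] = pc
    return pd.DataFrame.from_dict(rows, orient="index", columns=expr.values.columns)


def module_trait_correlation(
    eigengenes: pd.DataFrame, trait: pd.Series
) -> tuple[pd.DataFrame, int]:
    """Pearson correlation of each module eigengene with a 0/1 trait.

    Returns the per-module (cor, p) table and the strongest module (argmax
    |cor|, smaller label on ties).
    """
    t = trait.reindex(eigengenes.columns).astype(float)
    if t.isna().any():
        raise ValueError("trait missing for some samples")
    if t.nunique() < 2:
        raise ValueError("trait is constant")
    rows = {}
    for m in eigengenes.index:
        r, p = stats.pearsonr(eigengenes.loc[m].values, t.values)
        rows[m] = {"cor": r, "p": p}
    table = pd.DataFrame.from_dict(rows, orient="index")
    strongest = int(
        min(table.index, key=lambda m: (-abs(table.loc[m, "cor"]), m))
    )
    return table, strongest


def complete_assignment(
    expr: ExpressionMatrix, assignment: ModuleAssignment, trait: pd.Series
) -> ModuleAssignment:
    """Convenience: eigengenes + module-trait correlation in one step."""
    eig = module_eigengenes(expr, assignment)
    table, strongest = module_trait_correlation(eig, trait)
    return ModuleAssignment(
        labels=assignment.labels,
        eigengenes=eig,
        module_trait=table,
        strongest_module=strongest,
    )
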