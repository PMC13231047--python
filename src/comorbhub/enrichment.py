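"""Gene-set analyses: hypergeometric over-representation, ranked GSEA with
a gene-set permutation null, single-sample GSEA (ssGSEA) immune scoring,
Wilcoxon infiltration contrasts and Spearman gene-cell correlations.

ssGSEA is purely rank-based per sample, so scores are invariant to any
strictly monotone transform of a sample's expression values; the final
score matrix is min-max normalized to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .preprocess import bh_adjust

__all__ = [
    "GSEAResult",
    "ora",
    "shared_terms",
    "gsea",
    "gsea_collection",
    "ssgsea",
    "compare_infiltration",
    "correlate_genes_cells",
]


def ora(
    query: set[str],
    collection: dict[str, list[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each term of
    ``collection`` against ``universe``; BH adjustment across the
    collection; sorted by (adj_p, p, term)."""
    universe = set(universe)
    dropped = set(query) - universe
    if dropped:
        warnings.warn(
            f"{len(dropped)} query genes outside the universe were dropped",
            stacklevel=2,
        )
    q = set(query) & universe
    if not q:
        raise ValueError("query is empty after restriction to the universe")
    n_univ = len(universe)
    rows = []
    for term, genes in collection.items():
        term_genes = set(genes) & universe
        k = len(q & term_genes)
        bigk = len(term_genes)
        p = float(stats.hypergeom.sf(k - 1, n_univ, bigk, len(q)))
        rows.append({"term": term, "k": k, "K": bigk, "n": len(q), "N": n_univ, "p": p})
    res = pd.DataFrame(rows).set_index("term")
    res["adj_p"] = bh_adjust(res["p"].values)
    res = res.sort_values(["adj_p", "p"], kind="mergesort")
    res = res.loc[
        sorted(res.index, key=lambda t: (res.loc[t, "adj_p"], res.loc[t, "p"], t))
    ]
    return res


def shared_terms(res_a: pd.DataFrame, res_b: pd.DataFrame, top_n: int = 20) -> list[str]:
    """Intersection of the top-n term ids of two sorted enrichment tables."""
    top_a = set(res_a.index[:top_n])
    top_b = set(res_b.index[:top_n])
    return sorted(top_a & top_b)


@dataclass
class GSEAResult:
    es: float
    nes: float
    p: float
    n_hits: int
    adj_p: float = np.nan

    @property
    def significant(self) -> bool:
        return bool(self.adj_p < 0.05 and abs(self.nes) > 1.0)


def _enrichment_score(
    scores: np.ndarray, in_set: np.ndarray, weight: float
) -> float:
    """Weighted Kolmogorov-Smirnov running-sum extremum over a ranked list.

    ``scores`` must already be sorted descending; ``in_set`` is a boolean
    hit mask in the same order.
    """
    n = len(scores)
    nh = int(in_set.sum())
    if nh == 0 or nh == n:
        return 0.0
    w = np.abs(scores) ** weight
    hit_w = np.where(in_set, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit scores are zero: fall back to unweighted steps
        hit_w = in_set.astype(float)
        denom = float(nh)
    steps = hit_w / denom - (~in_set) / float(n - nh)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea(
    ranked: pd.Series,
    gene_set,
    n_perm: int = 1000,
    weight: float = 1.0,
    rng=None,
) -> GSEAResult:
    """GSEA of one gene set against a gene -> score ranking.

    Null distribution by gene-set permutation: ``n_perm`` random sets of
    the same size drawn from the ranked genes. NES normalizes the observed
    ES by the mean |null ES| of matching sign; p is the same-sign
    exceedance fraction.
    """
    rng = np.random.default_rng(rng)
    ranked = ranked.sort_index().sort_values(ascending=False, kind="mergesort")
    genes = np.array(ranked.index)
    scores = ranked.values.astype(float)
    hits = np.isin(genes, list(gene_set))
    nh = int(hits.sum())
    if nh < 3:
        raise ValueError(f"gene set overlaps only {nh} ranked genes (<3)")
    es = _enrichment_score(scores, hits, weight)
    null = np.empty(n_perm)
    n = len(genes)
    for b in range(n_perm):
        idx = rng.choice(n, size=nh, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        null[b] = _enrichment_score(scores, mask, weight)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if len(same_sign) == 0:
        nes = np.inf * np.sign(es)
        p = 1.0 / (n_perm + 1)
    else:
        nes = es / np.mean(np.abs(same_sign))
        p = float(np.mean(np.abs(same_sign) >= abs(es)))
    return GSEAResult(es=es, nes=float(nes), p=p, n_hits=nh)


def gsea_collection(
    ranked: pd.Series,
    collection: dict[str, list[str]],
    n_perm: int = 1000,
    weight: float = 1.0,
    rng=None,
    nes_min: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run gsea per set, BH-adjust across the collection, flag significance
    at adj_p < alpha and |NES| > nes_min."""
    rng = np.random.default_rng(rng)
    rows = {}
    for name, genes in collection.items():
        try:
            r = gsea(ranked, genes, n_perm=n_perm, weight=weight, rng=rng)
        except ValueError:
            warnings.warn(f"set {name!r} skipped (too small overlap)", stacklevel=2)
            continue
        rows[name] = {"es": r.es, "nes": r.nes, "p": r.p, "n_hits": r.n_hits}
    if not rows:
        return pd.DataFrame(columns=["es", "nes", "p", "n_hits", "adj_p", "significant"])
    res = pd.DataFrame.from_dict(rows, orient="index")
    res["adj_p"] = bh_adjust(res["p"].values)
    res["significant"] = (res["adj_p"] < alpha) & (res["nes"].abs() > nes_min)
    return res.sort_values(["adj_p", "p"], kind="mergesort")


def _ssgsea_sample(values: pd.Series, sets: dict[str, set], alpha: float) -> dict:
    n = len(values)
    # ranks: 1..n ascending in expression; ties share the average rank
    ranks = pd.Series(stats.rankdata(values.values, method="average"), index=values.index)
    # walk the list from highest expression down (ties broken by gene id
    # for determinism)
    order = sorted(values.index, key=lambda g: (-values[g], g))
    r = ranks.loc[order].values
    out = {}
    for name, gset in sets.items():
        mask = np.array([g in gset for g in order])
        nh = int(mask.sum())
        if nh == 0:
            out[name] = np.nan
            continue
        w = np.where(mask, np.abs(r) ** alpha, 0.0)
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~mask) / float(n - nh) if n > nh else np.zeros(n)
        out[name] = float(np.sum(p_in - p_out))
    return out


def ssgsea(
    expr: ExpressionMatrix | pd.DataFrame,
    collection: dict[str, list[str]],
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-sample rank-based enrichment scores (samples x sets).

    Sets with no expressed member are reported as missing (NaN) with a
    warning. With ``normalize`` the whole matrix is min-max scaled to
    [0, 1].
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    genes = set(values.index)
    sets = {name: set(g) & genes for name, g in collection.items()}
    empty = [name for name, s in sets.items() if not s]
    if empty:
        warnings.warn(f"sets with no expressed genes: {empty}", stacklevel=2)
    scores = pd.DataFrame(
        {s: _ssgsea_sample(values[s], sets, alpha) for s in values.columns}
    ).T
    scores = scores[list(collection.keys())]
    if normalize:
        lo, hi = np.nanmin(scores.values), np.nanmax(scores.values)
        if hi > lo:
            scores = (scores - lo) / (hi - lo)
    return scores


def compare_infiltration(scores: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum (normal approximation, tie and
    continuity corrected) of each cell-type score between case and control
    samples; direction is the sign of the case-minus-control median."""
    groups = groups.reindex(scores.index)
    case = scores.index[groups == "case"]
    ctrl = scores.index[groups == "control"]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("both groups need >=2 samples")
    rows = {}
    for ct in scores.columns:
        a = scores.loc[case, ct].dropna().values
        b = scores.loc[ctrl, ct].dropna().values
        w, p = stats.mannwhitneyu(
            a, b, alternative="two-sided", use_continuity=True, method="asymptotic"
        )
        diff = float(np.median(a) - np.median(b))
        rows[ct] = {
            "W": float(w),
            "p": float(p),
            "direction": "up" if diff > 0 else ("down" if diff < 0 else "none"),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def correlate_genes_cells(
    expr: ExpressionMatrix | pd.DataFrame,
    scores: pd.DataFrame,
    cor_min: float = 0.3,
    alpha: float = 0.05,
    absolute: bool = False,
) -> pd.DataFrame:
    """Spearman correlation of each (hub) gene's expression with each
    cell-type score over the shared samples.

    Returns a long table (gene, cell_type, rho, p, flagged); flagged means
    rho > cor_min (or |rho| > cor_min with ``absolute``) and p < alpha.
    p comes from the t approximation with n - 2 df.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    samples = [s for s in values.columns if s in scores.index]
    n = len(samples)
    if n < 4:
        raise ValueError("need >=4 shared samples")
    x = values[samples]
    y = scores.loc[samples]
    rows = []
    for gene in x.index:
        rx = stats.rankdata(x.loc[gene].values)
        for ct in y.columns:
            ry = stats.rankdata(y[ct].values)
            rho = float(np.corrcoef(rx, ry)[0, 1])
            if abs(rho) >= 1.0:
                p = 0.0
            else:
                t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
                p = float(2.0 * stats.t.sf(abs(t), n - 2))
            crit = abs(rho) if absolute else rho
            rows.append(
                {
                    "gene": gene,
                    "cell_type": ct,
                    "rho": rho,
                    "p": p,
                    "flagged": bool(crit > cor_min and p < alpha),
                }
            )
    return pd.DataFrame(rows)
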