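"""Normalization and moderated differential expression.

The DE model is a two-group comparison per gene with empirical-Bayes
variance moderation: residual variances s^2 (d = n1 + n2 - 2 df) are shrunk
toward a prior variance s0^2 with prior df d0,

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d),

and (d0, s0^2) are estimated in closed form by moment-matching the
distribution of log s^2 using digamma/trigamma inversion. The moderated t
uses d0 + d degrees of freedom. Setting ``moderated=False`` gives the
ordinary two-sample t (d0 = 0 limit), the second configuration used to
cross-validate DEG calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import ExpressionMatrix

__all__ = [
    "DEResult",
    "preprocess",
    "quantile_normalize",
    "fit_de",
    "classify_degs",
    "intersect_consistent",
    "bh_adjust",
]


@dataclass
class DEResult:
    """Per-gene differential expression results plus moderation parameters."""

    table: pd.DataFrame  # columns: log2FC, t, p, adj_p, direction
    d0: float  # prior degrees of freedom (may be inf)
    s0sq: float  # prior variance
    df_residual: float


def preprocess(
    raw: ExpressionMatrix,
    log_transform: bool = True,
    collapse: bool = True,
    quantile_norm: bool = False,
) -> ExpressionMatrix:
    """Log2(x+1) transform, collapse duplicate gene rows by mean, optionally
    quantile-normalize.

    Synthetic input is already on a log2-like scale, so ``log_transform``
    can be toggled off.
    """
    values = raw.values.copy()
    if log_transform:
        if (values.values < 0).any():
            raise ValueError("negative values are incompatible with log2(x+1)")
        values = np.log2(values + 1.0)
    if collapse and values.index.has_duplicates:
        values = values.groupby(level=0, sort=False).mean()
    if quantile_norm:
        values = quantile_normalize(values)
    return ExpressionMatrix(values, raw.sample_group, raw.survival)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Classic rank/mean quantile normalization across samples."""
    sorted_means = np.sort(values.values, axis=0).mean(axis=1)
    # ties receive the mean of the reference values they span
    mean_rank = values.rank(method="average", axis=0).values
    frac = mean_rank - np.floor(mean_rank)
    lo = sorted_means[np.clip(np.floor(mean_rank).astype(int) - 1, 0, len(sorted_means) - 1)]
    hi = sorted_means[np.clip(np.ceil(mean_rank).astype(int) - 1, 0, len(sorted_means) - 1)]
    out = lo + frac * (hi - lo)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def _fit_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from the spread of log s^2.

    If the empirical variance of log s^2 shows no excess dispersion over
    trigamma(d/2), d0 is infinite and the prior variance is the common
    variance implied by the mean of log s^2.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 0.0
    e = np.log(s2[ok])
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    if e_var < 1e-15:
        # zero observed scatter: the variances are not chi-square
        # distributed at all; take the common value at face value
        return np.inf, float(np.exp(e_mean))
    excess = e_var - float(special.polygamma(1, d / 2.0))
    bias = float(special.digamma(d / 2.0) - np.log(d / 2.0))
    if excess <= 0:
        d0 = np.inf
        log_s0sq = e_mean - bias
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        log_s0sq = (
            e_mean
            - bias
            + float(special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    return d0, float(np.exp(log_s0sq))


def fit_de(expr: ExpressionMatrix, moderated: bool = True) -> DEResult:
    """Per-gene case-vs-control differential expression.

    log2FC = mean(case) - mean(control) on the (assumed log2) scale.
    """
    if expr.sample_group is None:
        raise ValueError("expression matrix has no group labels")
    case = expr.samples_in_group("case")
    ctrl = expr.samples_in_group("control")
    n1, n2 = len(case), len(ctrl)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >=2 samples (case={n1}, control={n2})")
    x1 = expr.values[case].values
    x2 = expr.values[ctrl].values
    d = float(n1 + n2 - 2)
    lfc = x1.mean(axis=1) - x2.mean(axis=1)
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d

    if moderated:
        d0, s0sq = _fit_prior(s2, d)
        if np.isinf(d0):
            s2_tilde = np.full_like(s2, s0sq)
        else:
            s2_tilde = (d0 * s0sq + d * s2) / (d0 + d)
        df_total = d0 + d if np.isfinite(d0) else np.inf
    else:
        d0, s0sq = 0.0, 0.0
        s2_tilde = s2
        df_total = d

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, np.where(lfc == 0, 0.0, np.sign(lfc) * np.inf))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    adj = bh_adjust(p)
    table = pd.DataFrame(
        {"log2FC": lfc, "t": t, "p": p, "adj_p": adj},
        index=expr.values.index,
    )
    table["direction"] = _directions(table)
    return DEResult(table=table, d0=float(d0), s0sq=float(s0sq), df_residual=d)


def _directions(table: pd.DataFrame, lfc: float = 1.0, alpha: float = 0.05) -> pd.Series:
    up = (table["log2FC"] > lfc) & (table["adj_p"] < alpha)
    down = (table["log2FC"] < -lfc) & (table["adj_p"] < alpha)
    out = pd.Series("none", index=table.index)
    out[up] = "up"
    out[down] = "down"
    return out


def classify_degs(
    de: DEResult, lfc: float = 1.0, alpha: float = 0.05
) -> tuple[set[str], set[str]]:
    """Split genes into (up, down) DEG sets at strict thresholds
    |log2FC| > lfc and adj_p < alpha."""
    t = de.table
    up = set(t.index[(t["log2FC"] > lfc) & (t["adj_p"] < alpha)])
    down = set(t.index[(t["log2FC"] < -lfc) & (t["adj_p"] < alpha)])
    return up, down


def intersect_consistent(
    degs_1: tuple[set[str], set[str]], degs_2: tuple[set[str], set[str]]
) -> tuple[set[str], set[str]]:
    """Keep only genes with the same direction call in both datasets."""
    up1, down1 = degs_1
    up2, down2 = degs_2
    return up1 & up2, down1 & down2


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with enforced monotonicity."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
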