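"""Median-split survival stratification: Kaplan-Meier estimation and
log-rank testing (via lifelines), with the short-follow-up filter applied
before analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .containers import ExpressionMatrix

__all__ = [
    "KMEstimate",
    "filter_followup",
    "median_split",
    "km_estimate",
    "logrank",
    "survival_by_gene",
]


@dataclass
class KMEstimate:
    """Product-limit estimate: event times with at-risk counts, deaths and
    the right-continuous survival step function."""

    table: pd.DataFrame  # index: time; columns: at_risk, deaths, survival

    def survival_at(self, t: float) -> float:
        times = self.table.index.values
        surv = self.table["survival"].values
        mask = times <= t
        return float(surv[mask][-1]) if mask.any() else 1.0


def filter_followup(records: pd.DataFrame, min_days: float = 30.0) -> pd.DataFrame:
    """Drop records with follow-up shorter than ``min_days`` (strict <)."""
    if (records["time_days"] <= 0).any():
        raise ValueError("survival times must be positive")
    return records[records["time_days"] >= min_days].copy()


def median_split(
    expr: ExpressionMatrix, gene: str, samples=None, ties: str = "low"
) -> pd.Series:
    """Split samples into 'high' (> median) and 'low' (< median) by one
    gene's expression; values exactly at the median join the ``ties``
    group (default 'low')."""
    if gene not in expr.values.index:
        raise KeyError(gene)
    vals = expr.values.loc[gene]
    if samples is not None:
        vals = vals.loc[list(samples)]
    if len(vals) < 4:
        raise ValueError("need >=4 samples")
    if vals.nunique() == 1:
        raise ValueError(f"gene {gene} is constant; no median split possible")
    med = float(vals.median())
    out = pd.Series(ties, index=vals.index, dtype=object)
    out[vals > med] = "high"
    out[vals < med] = "low"
    return out


def km_estimate(records: pd.DataFrame) -> KMEstimate:
    """Kaplan-Meier product-limit estimator for one group.

    ``records`` needs ``time_days`` and ``event`` columns.
    """
    if len(records) == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time_days"], event_observed=records["event"])
    ev = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    table = pd.DataFrame(
        {
            "at_risk": ev["at_risk"].astype(int),
            "deaths": ev["observed"].astype(int),
            "survival": surv,
        }
    )
    table = table[table.index > 0] if 0 in table.index and table.loc[0, "deaths"] == 0 else table
    table.index.name = "time"
    return KMEstimate(table=table)


def logrank(group_high: pd.DataFrame, group_low: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p)."""
    if len(group_high) == 0 or len(group_low) == 0:
        raise ValueError("both groups must be non-empty")
    if int(group_high["event"].sum()) + int(group_low["event"].sum()) == 0:
        raise ValueError("no events in either group; log-rank undefined")
    res = logrank_test(
        group_high["time_days"],
        group_low["time_days"],
        event_observed_A=group_high["event"],
        event_observed_B=group_low["event"],
    )
    return float(res.test_statistic), float(res.p_value)


def survival_by_gene(
    expr: ExpressionMatrix,
    records: pd.DataFrame,
    genes,
    min_days: float = 30.0,
) -> pd.DataFrame:
    """Per-gene median-split log-rank summary over samples that carry
    survival information. Returns (gene, n_high, n_low, chi2, p)."""
    records = filter_followup(records, min_days=min_days)
    samples = [s for s in expr.sample_ids if s in records.index]
    rows = []
    for gene in genes:
        split = median_split(expr, gene, samples=samples)
        high = records.loc[split.index[split == "high"]]
        low = records.loc[split.index[split == "low"]]
        chi2, p = logrank(high, low)
        rows.append(
            {"gene": gene, "n_high": len(high), "n_low": len(low), "chi2": chi2, "p": p}
        )
    return pd.DataFrame(rows).set_index("gene")
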