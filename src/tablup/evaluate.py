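"""Evaluation metrics for genomic prediction and replicate aggregation.

Accuracy is the Pearson correlation between GEBV and TBV among
individuals without phenotypic records; rank correlation (Spearman)
matters for truncation selection; the least-squares regression of TBV
on GEBV measures bias (1 = unbiased); the per-generation accuracy
decline measures persistency of the prediction across generations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "accuracy",
    "rank_correlation",
    "regression_bias",
    "decline_per_generation",
    "aggregate",
    "ScenarioResult",
]


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if a.size < 3:
        raise ValueError("need at least 3 individuals")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("metric undefined for a zero-variance vector")
    return a, b


def accuracy(tbv, gebv) -> float:
    """Pearson correlation between true and estimated breeding values."""
    tbv, gebv = _check_pair(tbv, gebv)
    return float(stats.pearsonr(gebv, tbv).statistic)


def rank_correlation(tbv, gebv) -> float:
    """Spearman correlation (Pearson on average ranks)."""
    tbv, gebv = _check_pair(tbv, gebv)
    return float(stats.spearmanr(gebv, tbv).statistic)


def regression_bias(tbv, gebv) -> float:
    """Slope of the least-squares regression of TBV on GEBV."""
    tbv, gebv = _check_pair(tbv, gebv)
    cov = np.cov(tbv, gebv, ddof=1)
    return float(cov[0, 1] / cov[1, 1])


def decline_per_generation(accuracies) -> float:
    """Mean one-generation accuracy drop: (first - last) / (n - 1)."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.size < 2:
        raise ValueError("need accuracies for at least two generations")
    return float((acc[0] - acc[-1]) / (acc.size - 1))


@dataclass
class ScenarioResult:
    """Per-replicate metric records plus scenario metadata.

    ``records`` is tidy: one row per (replicate, method, generation,
    metric) with a ``value`` column.
    """

    records: pd.DataFrame
    scenario: dict | None = None

    def aggregate(self) -> pd.DataFrame:
        return aggregate(self.records)

    def table(self, generation: int = 2, statistic: str = "mean") -> pd.DataFrame:
        """Method x metric table for one generation (Tables 2-4 layout)."""
        agg = self.aggregate()
        sub = agg[agg["generation"] == generation]
        return sub.pivot(index="method", columns="metric", values=statistic)

    def to_markdown(self, generation: int = 2) -> str:
        agg = self.aggregate()
        sub = agg[agg["generation"] == generation]
        metrics = sorted(sub["metric"].unique())
        lines = ["| Method | " + " | ".join(metrics) + " |"]
        lines.append("|" + "---|" * (len(metrics) + 1))
        for method, grp in sub.groupby("method"):
            cells = []
            for metric in metrics:
                row = grp[grp["metric"] == metric]
                if row.empty:
                    cells.append("")
                else:
                    m = row["mean"].iloc[0]
                    se = row["se"].iloc[0]
                    cells.append(
                        f"{m:.3f}" if np.isnan(se) else f"{m:.3f}+/-{se:.3f}"
                    )
            lines.append(f"| {method} | " + " | ".join(cells) + " |")
        return "\n".join(lines)


def aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error over replicates per (method, generation,
    metric); SE is NaN when only one replicate exists."""
    if records.empty:
        raise ValueError("no records to aggregate")
    grouped = records.groupby(["method", "generation", "metric"])["value"]
    out = grouped.agg(
        mean="mean",
        se=lambda v: np.nan if len(v) < 2 else v.std(ddof=1) / np.sqrt(len(v)),
        n="count",
    ).reset_index()
    return out
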