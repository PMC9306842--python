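"""Aggregate per-replicate delimitation counts and concordance metrics
across subset fractions: means, sample SDs and t-based 95% confidence
intervals, plus accumulation-curve tables (optionally loess-smoothed for
display)."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReplicateRecord",
    "EnsembleSummary",
    "records_frame",
    "summarize",
    "accumulation_curve",
]

#: Numeric per-replicate statistics that get summarized.
STATISTICS = (
    "entities",
    "clusters",
    "singletons",
    "m_incl",
    "m_excl",
    "sr_incl",
    "sr_excl",
    "singleton_pct",
)


@dataclass(frozen=True)
class ReplicateRecord:
    """Flattened results of one GMYC run on one subsample replicate."""

    fraction: float
    replicate_index: int
    entities: int
    clusters: int
    singletons: int
    m_incl: float = math.nan
    m_excl: float = math.nan
    sr_incl: float = math.nan
    sr_excl: float = math.nan
    singleton_pct: float = math.nan

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.entities != self.clusters + self.singletons:
            raise ValueError("entities must equal clusters + singletons")


@dataclass(frozen=True)
class EnsembleSummary:
    """Long-format per-(fraction, statistic) summary table.

    Columns: fraction, statistic, mean, sd, n, ci_low, ci_high.  With a
    single replicate, sd and the CI are NaN.
    """

    table: pd.DataFrame
    confidence: float = 0.95

    def get(self, fraction: float, statistic: str) -> pd.Series:
        t = self.table
        rows = t[(t["fraction"] == fraction) & (t["statistic"] == statistic)]
        if rows.empty:
            raise KeyError((fraction, statistic))
        return rows.iloc[0]

    @property
    def fractions(self) -> list[float]:
        return sorted(self.table["fraction"].unique())


def records_frame(records: Iterable[ReplicateRecord]) -> pd.DataFrame:
    cols = [f.name for f in fields(ReplicateRecord)]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])


def summarize(
    records: Sequence[ReplicateRecord], confidence: float = 0.95
) -> EnsembleSummary:
    """Per fraction and statistic: mean, sample SD (n-1) and t-based CI.

    Replicates with a missing statistic (NaN, e.g. a failed or undefined
    metric) are dropped from that statistic's summary; nothing is imputed.
    """
    if not records:
        raise ValueError("no replicate records to summarize")
    df = records_frame(records)
    rows: list[dict] = []
    for fraction, sub in df.groupby("fraction"):
        for stat in STATISTICS:
            # sorted so summaries are exactly permutation-invariant
            values = np.sort(sub[stat].dropna().to_numpy(dtype=float))
            n = len(values)
            if n == 0:
                continue
            mean = float(np.mean(values))
            if n > 1:
                sd = float(np.std(values, ddof=1))
                half = float(
                    stats.t.ppf(0.5 + confidence / 2, n - 1) * sd / math.sqrt(n)
                )
                ci_low, ci_high = mean - half, mean + half
            else:
                sd = math.nan
                ci_low = ci_high = math.nan
            rows.append(
                {
                    "fraction": float(fraction),
                    "statistic": stat,
                    "mean": mean,
                    "sd": sd,
                    "n": n,
                    "ci_low": ci_low,
                    "ci_high": ci_high,
                }
            )
    return EnsembleSummary(
        table=pd.DataFrame(rows).sort_values(
            ["fraction", "statistic"], ignore_index=True
        ),
        confidence=confidence,
    )


def accumulation_curve(
    summary: EnsembleSummary,
    statistic: str = "entities",
    *,
    total_records: int | None = None,
    smooth: bool = False,
) -> pd.DataFrame:
    """Accumulation-curve table for one statistic, ordered by sample size.

    Columns: fraction, n_sequences (when ``total_records`` is given), mean,
    ci_low, ci_high and, with ``smooth=True``, a loess-smoothed mean for
    display parity with generic plot smoothers.
    """
    if statistic not in ("clusters", "entities") and statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    t = summary.table
    rows = t[t["statistic"] == statistic].sort_values("fraction")
    if rows.empty:
        raise KeyError(statistic)
    if len(rows) < 2:
        warnings.warn("only one fraction: degenerate single-point curve")
    out = rows[["fraction", "mean", "ci_low", "ci_high"]].reset_index(drop=True)
    if total_records is not None:
        out.insert(
            1,
            "n_sequences",
            [int(round(f * total_records)) for f in out["fraction"]],
        )
    if smooth and len(out) >= 2:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        fitted = lowess(
            out["mean"].to_numpy(),
            out["fraction"].to_numpy(),
            frac=1.0,
            return_sorted=False,
        )
        out["smoothed"] = fitted
    return out
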