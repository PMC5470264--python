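"""Reporting computations over an event table.

Per-gene event counts, the upper-triangular time-pair event matrix with
its adjacent-diagonal statistics, dataset-level percentages/ratios and
the events-per-gene histogram.  Percentages use round-half-away-from-zero
(the convention under which the published summary arithmetic of the
cerebellar CAGE survey reproduces exactly from its printed numerators
and denominators).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .datatypes import SwitchEventTable


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round to ``decimals`` places with ties going away from zero."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-away-from-zero."""
    if denominator == 0:
        raise ZeroDivisionError("percent() with zero denominator")
    return round_half_away(100.0 * numerator / denominator, decimals)


def ratio(numerator: float, denominator: float, decimals: int = 2) -> float:
    """numerator / denominator rounded half-away-from-zero (default 2 dp)."""
    if denominator == 0:
        raise ZeroDivisionError("ratio() with zero denominator")
    return round_half_away(numerator / denominator, decimals)


def per_gene_counts(events: SwitchEventTable, top_n: int | None = None) -> pd.DataFrame:
    """Per-gene total / non-crossover / crossover event counts.

    Sorted by total descending with deterministic gene_id tie-break;
    ``top_n`` truncates (the published survey tabulates the top 20).
    """
    df = events.df
    if len(df) == 0:
        return pd.DataFrame(
            columns=["gene_id", "total", "non_crossover", "crossover"]
        ).astype({"total": int, "non_crossover": int, "crossover": int})
    counts = (
        df.groupby(["gene_id", "class"]).size().unstack(fill_value=0)
        .reindex(columns=["non_crossover", "crossover"], fill_value=0)
    )
    counts["total"] = counts["non_crossover"] + counts["crossover"]
    out = counts.reset_index()[["gene_id", "total", "non_crossover", "crossover"]]
    out = out.sort_values(
        ["total", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if top_n is not None:
        out = out.head(top_n).reset_index(drop=True)
    return out


@dataclass
class TimePairMatrix:
    """Upper-triangular grid of event counts per time-point pair."""

    time_points: tuple[str, ...]
    counts: np.ndarray  # (T, T) int, strictly upper-triangular occupancy
    class_filter: str | None = None

    def __post_init__(self) -> None:
        T = len(self.time_points)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (T, T):
            raise ValueError("counts grid must be T x T")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(np.tril(self.counts) != 0):
            raise ValueError("counts must be strictly upper-triangular")

    @property
    def n_pairs(self) -> int:
        T = len(self.time_points)
        return T * (T - 1) // 2

    def total(self) -> int:
        return int(self.counts.sum())

    def cell(self, t1: str, t2: str) -> int:
        i = self.time_points.index(t1)
        j = self.time_points.index(t2)
        if i > j:
            i, j = j, i
        return int(self.counts[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.time_points, columns=self.time_points
        )


def time_pair_matrix(
    events: SwitchEventTable,
    time_points: list[str] | tuple[str, ...],
    class_filter: str | None = None,
) -> TimePairMatrix:
    """Count events per (t1, t2) cell over an ordered time axis."""
    tps = tuple(time_points)
    idx = {tp: i for i, tp in enumerate(tps)}
    df = events.df
    if class_filter is not None:
        df = df[df["class"] == class_filter]
    T = len(tps)
    grid = np.zeros((T, T), dtype=int)
    for t1, t2 in zip(df["t1"], df["t2"]):
        if t1 not in idx or t2 not in idx:
            raise ValueError(f"event time label {t1!r}/{t2!r} not on the time axis")
        i, j = idx[t1], idx[t2]
        if i > j:
            i, j = j, i
        grid[i, j] += 1
    return TimePairMatrix(tps, grid, class_filter)


def adjacent_pair_stats(
    matrix: TimePairMatrix, total_events: int
) -> tuple[int, tuple[str, str] | None, float | None]:
    """Adjacent-diagonal summary: (sum, argmax pair, percent of total).

    "Adjacent" means consecutive in time order (the bold diagonal of the
    published matrix).  The fraction is a 1-decimal percentage of
    ``total_events``; ``None`` when that total is zero.
    """
    T = len(matrix.time_points)
    diag = [int(matrix.counts[i, i + 1]) for i in range(T - 1)]
    adjacent_sum = int(sum(diag))
    if total_events < adjacent_sum:
        raise ValueError("total_events smaller than the adjacent sum")
    if adjacent_sum > 0:
        k = int(np.argmax(diag))
        argmax_pair = (matrix.time_points[k], matrix.time_points[k + 1])
    else:
        argmax_pair = None
    fraction = percent(adjacent_sum, total_events, 1) if total_events else None
    return adjacent_sum, argmax_pair, fraction


def dataset_summary(events: SwitchEventTable, n_genes_total: int) -> dict:
    """Dataset-level totals, percentages and the non-crossover:crossover ratio.

    Percentages are 1-decimal except the two gene-level shares the field
    reports as whole percents (genes with exactly one event; crossover
    genes that also carry a non-crossover event).
    """
    df = events.df
    n_events = len(df)
    n_cross = int((df["class"] == "crossover").sum())
    n_noncross = n_events - n_cross
    genes = df["gene_id"].unique()
    n_genes = len(genes)
    if n_genes_total < n_genes:
        raise ValueError("n_genes_total smaller than the genes present in events")
    cross_genes = set(df.loc[df["class"] == "crossover", "gene_id"])
    noncross_genes = set(df.loc[df["class"] == "non_crossover", "gene_id"])
    both = cross_genes & noncross_genes
    per_gene = df.groupby("gene_id").size()
    n_single = int((per_gene == 1).sum())
    out = {
        "n_events": n_events,
        "n_non_crossover": n_noncross,
        "n_crossover": n_cross,
        "n_genes": n_genes,
        "n_crossover_genes": len(cross_genes),
        "n_non_crossover_genes": len(noncross_genes),
        "pct_switching_genes": percent(n_genes, n_genes_total, 1)
        if n_genes_total else None,
        "pct_non_crossover": percent(n_noncross, n_events, 1) if n_events else None,
        "pct_crossover": percent(n_cross, n_events, 1) if n_events else None,
        "ratio_non_to_crossover": ratio(n_noncross, n_cross, 2) if n_cross else None,
        "pct_single_event_genes": percent(n_single, n_genes, 0) if n_genes else None,
        "pct_crossover_genes_with_non_crossover": percent(
            len(both), len(cross_genes), 0
        ) if cross_genes else None,
    }
    return out


def events_per_gene_histogram(events: SwitchEventTable) -> dict[int, int]:
    """Histogram of per-gene event totals: {event count: number of genes}."""
    df = events.df
    if len(df) == 0:
        return {}
    per_gene = df.groupby("gene_id").size()
    hist = per_gene.value_counts().sort_index()
    return {int(k): int(v) for k, v in hist.items()}
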