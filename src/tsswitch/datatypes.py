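"""Domain containers for the TSS switching pipeline.

Containers are thin dataclasses around numpy/pandas structures; the
expression grid itself lives in a pandas DataFrame so that the usual
selection/alignment machinery applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: columns of a serialized event table, in file order
EVENT_COLUMNS = [
    "gene_id",
    "tss_a",
    "tss_b",
    "t1",
    "t2",
    "d1",
    "d2",
    "se_d1",
    "se_d2",
    "class",
    "p_switch",
    "q_switch",
    "p_agg",
    "q_agg",
    "fq_stat",
    "p_fq",
    "q_fq",
]

_FLOAT_EVENT_COLUMNS = [
    "d1", "d2", "se_d1", "se_d2",
    "p_switch", "q_switch", "p_agg", "q_agg",
    "fq_stat", "p_fq", "q_fq",
]

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class TssRecord:
    """One promoter/TSS region (BED 0-based half-open) with its gene."""

    tss_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"TSS {self.tss_id}: start {self.start} < 0")
        if self.end <= self.start:
            raise ValueError(
                f"TSS {self.tss_id}: end {self.end} must exceed start {self.start}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"TSS {self.tss_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class SampleDesign:
    """Ordered sample sheet: (sample_id, time_point, time_rank, replicate).

    ``time_rank`` is a strict total order on the distinct time points; the
    developmental series the package was built around has twelve points
    (E11..E18, P0, P3, P6, P9) with three replicate pools each.
    """

    samples: tuple[tuple[str, str, int, int], ...]

    def __post_init__(self) -> None:
        ids = [s[0] for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_id(s): {dupes}")
        rank_of: dict[str, int] = {}
        seen_pairs: set[tuple[str, int]] = set()
        for sid, tp, rank, rep in self.samples:
            if rep < 1:
                raise ValueError(f"sample {sid}: replicate index {rep} < 1")
            if tp in rank_of and rank_of[tp] != rank:
                raise ValueError(
                    f"time point {tp} has inconsistent ranks "
                    f"{rank_of[tp]} and {rank}"
                )
            rank_of[tp] = rank
            if (tp, rep) in seen_pairs:
                raise ValueError(f"duplicate (time_point, replicate) = ({tp}, {rep})")
            seen_pairs.add((tp, rep))
        ranks = list(rank_of.values())
        if len(set(ranks)) != len(ranks):
            raise ValueError("time_rank must be distinct across time points")

    @property
    def sample_ids(self) -> list[str]:
        return [s[0] for s in self.samples]

    @property
    def time_points(self) -> list[str]:
        """Distinct time point labels, ordered by time_rank."""
        rank_of = {s[1]: s[2] for s in self.samples}
        return sorted(rank_of, key=rank_of.get)

    def time_rank(self, time_point: str) -> int:
        for _, tp, rank, _ in self.samples:
            if tp == time_point:
                return rank
        raise KeyError(time_point)

    def replicate_samples(self, time_point: str) -> list[str]:
        """Sample ids of one time point, ordered by replicate index."""
        reps = [(rep, sid) for sid, tp, _, rep in self.samples if tp == time_point]
        return [sid for _, sid in sorted(reps)]

    def n_replicates(self, time_point: str) -> int:
        return len(self.replicate_samples(time_point))


@dataclass
class ExpressionMatrix:
    """TSS x sample expression grid bound to a :class:`SampleDesign`.

    ``values`` is a DataFrame indexed by tss_id with one column per sample,
    in design order.  ``unit`` is ``"counts"`` (raw tags) or ``"tpm"``.
    """

    values: pd.DataFrame
    design: SampleDesign
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "tpm"):
            raise ValueError(f"unit must be 'counts' or 'tpm', got {self.unit!r}")
        if list(self.values.columns) != self.design.sample_ids:
            raise ValueError("matrix columns must match design sample order")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate tss_id rows in expression matrix")

    @property
    def tss_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class PairContrast:
    """One (gene, TSS pair, time-point pair) testing unit.

    ``diffs_t1``/``diffs_t2`` hold the per-replicate tpm differences
    tpm(tss_a) - tpm(tss_b) at the two time points (replicates paired by
    pool index, both TSSs being measured in the same pool); d1/d2 are
    their means and se_d1/se_d2 the standard errors of those means.
    ``agg_t1``/``agg_t2`` carry the per-replicate pair means
    (tpm(a)+tpm(b))/2 used by the aggregate-expression filter.
    """

    gene_id: str
    tss_a: str
    tss_b: str
    t1: str
    t2: str
    diffs_t1: np.ndarray
    diffs_t2: np.ndarray
    agg_t1: np.ndarray
    agg_t2: np.ndarray

    def __post_init__(self) -> None:
        if self.tss_a >= self.tss_b:
            raise ValueError("tss_a must precede tss_b lexicographically")
        for name in ("diffs_t1", "diffs_t2", "agg_t1", "agg_t2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.diffs_t1) < 2 or len(self.diffs_t2) < 2:
            raise ValueError("each time point needs >=2 replicates")

    @property
    def d1(self) -> float:
        return float(np.mean(self.diffs_t1))

    @property
    def d2(self) -> float:
        return float(np.mean(self.diffs_t2))

    @property
    def se_d1(self) -> float:
        x = self.diffs_t1
        return float(np.std(x, ddof=1) / np.sqrt(len(x)))

    @property
    def se_d2(self) -> float:
        x = self.diffs_t2
        return float(np.std(x, ddof=1) / np.sqrt(len(x)))


@dataclass(frozen=True)
class TestResult:
    """Outcome of one t-test; ``q`` is filled after BH adjustment."""

    statistic: float
    df: float
    p: float
    q: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0,1]")
        if self.q is not None and self.q < self.p - 1e-12:
            raise ValueError("adjusted p must be >= raw p")


@dataclass
class SwitchEventTable:
    """Final event table (one row per called event) plus run provenance.

    Rows are canonically keyed by (gene_id, tss_a, tss_b, t1, t2) with
    tss_a < tss_b and time_rank(t1) < time_rank(t2); ``class`` is
    ``crossover`` or ``non_crossover``; the fq_* columns are NaN for
    non-crossover rows.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        self.df = self.df[EVENT_COLUMNS].reset_index(drop=True)
        for c in _FLOAT_EVENT_COLUMNS:
            self.df[c] = self.df[c].astype(float)
        bad = set(self.df["class"]) - {"crossover", "non_crossover"}
        if bad:
            raise ValueError(f"unknown event class(es): {sorted(bad)}")
        keys = self.df[["gene_id", "tss_a", "tss_b", "t1", "t2"]]
        if keys.duplicated().any():
            raise ValueError("duplicate (gene, tss pair, time pair) rows")
        if (self.df["tss_a"] >= self.df["tss_b"]).any():
            raise ValueError("tss_a must precede tss_b lexicographically")

    def __len__(self) -> int:
        return len(self.df)

    def sort_canonical(self, design: SampleDesign | None = None) -> "SwitchEventTable":
        """Stable canonical ordering; chronological time if a design is given."""
        df = self.df.copy()
        if design is not None:
            rank = {tp: design.time_rank(tp) for tp in design.time_points}
            df["_r1"] = df["t1"].map(rank)
            df["_r2"] = df["t2"].map(rank)
            df = df.sort_values(
                ["gene_id", "tss_a", "tss_b", "_r1", "_r2"], kind="mergesort"
            ).drop(columns=["_r1", "_r2"])
        else:
            df = df.sort_values(
                ["gene_id", "tss_a", "tss_b", "t1", "t2"], kind="mergesort"
            )
        return SwitchEventTable(df.reset_index(drop=True), dict(self.provenance))


def empty_event_frame() -> pd.DataFrame:
    """An empty DataFrame with the canonical event-table columns."""
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in EVENT_COLUMNS})
    for c in _FLOAT_EVENT_COLUMNS:
        df[c] = df[c].astype(float)
    return df
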