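"""Readers/writers for the plain-text formats the pipeline touches.

Formats: BED6 TSS annotation (optionally with a 7th gene_id column),
tab-separated expression matrix, sample sheet and event table.  All TSVs
are UTF-8 with a header row and '.' decimal point.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import (
    EVENT_COLUMNS,
    ExpressionMatrix,
    SampleDesign,
    SwitchEventTable,
    TssRecord,
    empty_event_frame,
)

logger = logging.getLogger(__name__)

_FLOAT_COLS = [
    "d1", "d2", "se_d1", "se_d2",
    "p_switch", "q_switch", "p_agg", "q_agg",
    "fq_stat", "p_fq", "q_fq",
]


def read_tss_bed(path: str | Path, gene_id_column: bool = False) -> list[TssRecord]:
    """Read a BED6 promoter annotation into :class:`TssRecord` records.

    By default the BED name column encodes the gene association as
    ``gene_id:tss_id`` (FANTOM5 promoter names embed their gene link);
    with ``gene_id_column=True`` a 7th column carries the gene id and the
    name column is the tss_id alone.  Coordinates are taken verbatim
    (0-based half-open); input order is preserved.
    """
    path = Path(path)
    records: list[TssRecord] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            min_cols = 7 if gene_id_column else 6
            if len(fields) < min_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected >={min_cols} tab-separated "
                    f"columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name = fields[:4]
            strand = fields[5] if fields[5] else "."
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if gene_id_column:
                gene_id, tss_id = fields[6], name
            else:
                gene_id, sep, tss_id = name.partition(":")
                if not sep or not tss_id:
                    raise ValueError(
                        f"{path}:{lineno}: name column {name!r} is not "
                        f"'gene_id:tss_id' (use gene_id_column=True for the "
                        f"7-column dialect)"
                    )
            if tss_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate tss_id {tss_id!r}")
            seen.add(tss_id)
            try:
                records.append(
                    TssRecord(tss_id, gene_id, chrom, start, end, strand)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def read_sample_sheet(path: str | Path) -> SampleDesign:
    """Read a sample sheet TSV (sample_id, time_point, time_rank, replicate)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "time_point", "time_rank", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: sample sheet missing column(s) {missing}")
    try:
        ranks = df["time_rank"].astype(int)
        reps = df["replicate"].astype(int)
    except ValueError as exc:
        raise ValueError(f"{path}: time_rank and replicate must be integers") from exc
    samples = tuple(
        (str(sid), str(tp), int(rank), int(rep))
        for sid, tp, rank, rep in zip(df["sample_id"], df["time_point"], ranks, reps)
    )
    design = SampleDesign(samples)
    for tp in design.time_points:
        n = design.n_replicates(tp)
        if n < 2:
            logger.warning(
                "time point %s has %d replicate(s); it will be skipped in testing",
                tp, n,
            )
    return design


def read_expression_table(
    path: str | Path, design: SampleDesign, unit: str = "counts"
) -> ExpressionMatrix:
    """Read an expression TSV (rows = TSS, columns = samples) against a design.

    Columns are re-ordered to design order; extra (undesigned) columns are
    dropped with a warning so public matrices can be subset by sample sheet.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [s for s in design.sample_ids if s not in df.columns]
    if missing:
        raise ValueError(f"{path}: design samples absent from header: {missing}")
    extra = [c for c in df.columns if c not in set(design.sample_ids)]
    if extra:
        logger.warning("%s: ignoring %d undesigned sample column(s): %s",
                       path, len(extra), extra)
    df = df[design.sample_ids]
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path}: non-numeric value at row {row!r}, column {col!r}"
            )
        df[col] = coerced
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression value")
    return ExpressionMatrix(df.astype(float), design, unit=unit)


def write_event_table(path: str | Path, table: SwitchEventTable) -> None:
    """Write an event table as TSV (floats at 12 significant digits, NA blanks)."""
    path = Path(path)
    df = table.df.copy()
    for c in _FLOAT_COLS:
        df[c] = df[c].map(lambda v: "NA" if pd.isna(v) else format(v, ".12g"))
    df.to_csv(path, sep="\t", index=False)


def read_event_table(path: str | Path) -> SwitchEventTable:
    """Re-read a TSV written by :func:`write_event_table`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: event table missing columns {missing}")
    if len(df) == 0:
        return SwitchEventTable(empty_event_frame())
    for c in _FLOAT_COLS:
        df[c] = pd.to_numeric(df[c].mask(df[c] == "NA"))
    return SwitchEventTable(df)
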