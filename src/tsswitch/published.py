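"""Published summary statistics of the FANTOM5 mouse cerebellar CAGE survey.

The raw cerebellar time-course CAGE libraries behind the published
promoter-switching survey are not redistributable at package scale, but
its printed summary tables are small and serve as fixed inputs for
validating the reporting arithmetic (time-pair matrices, adjacent-pair
statistics, percentage/ratio conventions).  Everything in this module is
a constant transcribed from the published tables; nothing is computed.

Note: the printed crossover time-pair matrix sums to 9768 while its
caption reports N = 9767 (a one-count inconsistency in the published
table); percentage checks use the printed totals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import SwitchEventTable, empty_event_frame
from .summaries import TimePairMatrix

CEREBELLUM_TIME_POINTS = (
    "E11", "E12", "E13", "E14", "E15", "E16", "E17", "E18", "P0", "P3", "P6", "P9",
)

#: Published headline totals of the cerebellar survey and the comparison series.
PUBLISHED_TOTALS = {
    "n_events": 48489,
    "n_non_crossover": 38722,
    "n_crossover": 9767,
    "n_genes": 5433,
    "n_non_crossover_genes": 5293,
    "n_crossover_genes": 1511,
    "n_crossover_genes_with_non_crossover": 1371,
    "n_single_event_genes": 1534,
    "n_genes_total": 25207,
    "n_time_points": 12,
    "top20_total_events": 6567,
    # comparison series (total events, crossover events)
    "emt_n_events": 132661,
    "emt_n_crossover": 23409,
    "adipocyte_n_events": 66087,
    "adipocyte_n_crossover": 8230,
}

#: Published per-time-pair crossover event counts (upper triangle, row-major
#: from each time point to every later one).
_CROSSOVER_ROWS = {
    "E11": (31, 180, 290, 340, 320, 333, 236, 291, 354, 279, 429),
    "E12": (93, 159, 200, 209, 238, 162, 228, 274, 225, 381),
    "E13": (21, 59, 99, 97, 76, 118, 190, 180, 327),
    "E14": (34, 55, 86, 69, 114, 203, 198, 303),
    "E15": (35, 30, 29, 56, 129, 143, 301),
    "E16": (29, 23, 53, 103, 113, 226),
    "E17": (13, 39, 58, 91, 204),
    "E18": (20, 42, 76, 123),
    "P0": (39, 60, 134),
    "P3": (25, 76),
    "P6": (17,),
}

#: Published top-20 genes by total switching events:
#: (gene, total, non_crossover, crossover).
TOP_GENES = (
    ("Frmd4a", 852, 509, 343),
    ("Ank3", 801, 464, 337),
    ("Abr", 386, 275, 111),
    ("Ednrb", 356, 211, 145),
    ("Iqsec1", 348, 206, 142),
    ("Bcat1", 329, 221, 108),
    ("Pde4d", 308, 176, 132),
    ("Ldb1", 304, 167, 137),
    ("Sorbs2", 297, 175, 122),
    ("Cnpy1", 273, 158, 115),
    ("Dlg2", 266, 223, 43),
    ("Ebf1", 262, 160, 102),
    ("Ablim1", 254, 204, 50),
    ("Zeb2", 246, 218, 28),
    ("Trim2", 233, 168, 65),
    ("Celf2", 227, 162, 65),
    ("Map2", 226, 170, 56),
    ("Itgb8", 208, 126, 82),
    ("Ank2", 197, 126, 71),
    ("Ptprg", 194, 111, 83),
)


def crossover_time_pair_matrix() -> TimePairMatrix:
    """The published crossover event counts as a :class:`TimePairMatrix`."""
    tps = CEREBELLUM_TIME_POINTS
    T = len(tps)
    grid = np.zeros((T, T), dtype=int)
    for i, tp in enumerate(tps[:-1]):
        grid[i, i + 1 : i + 1 + len(_CROSSOVER_ROWS[tp])] = _CROSSOVER_ROWS[tp]
    return TimePairMatrix(tps, grid, class_filter="crossover")


def gene_counts_event_table(rows=TOP_GENES) -> SwitchEventTable:
    """A synthetic event table realizing published per-gene count rows.

    Each (gene, total, non_crossover, crossover) row is expanded into
    that many placeholder events (distinct TSS/time keys, uninformative
    statistics) so per-gene counting can be exercised against the
    printed marginals.  The rows are synthetic stand-ins; only the
    counts are real.
    """
    recs = []
    for gene, total, non_cross, cross in rows:
        if non_cross + cross != total:
            raise ValueError(f"{gene}: {non_cross}+{cross} != {total}")
        for k in range(total):
            cls = "non_crossover" if k < non_cross else "crossover"
            recs.append(
                {
                    "gene_id": gene,
                    "tss_a": f"{gene}.A{k:04d}",
                    "tss_b": f"{gene}.B{k:04d}",
                    "t1": "t1",
                    "t2": "t2",
                    "d1": 1.0,
                    "d2": -1.0 if cls == "crossover" else 2.0,
                    "se_d1": 1.0,
                    "se_d2": 1.0,
                    "class": cls,
                    "p_switch": 0.01,
                    "q_switch": 0.01,
                    "p_agg": 0.9,
                    "q_agg": 0.9,
                    "fq_stat": 1.0 if cls == "crossover" else np.nan,
                    "p_fq": 0.01 if cls == "crossover" else np.nan,
                    "q_fq": 0.01 if cls == "crossover" else np.nan,
                }
            )
    if not recs:
        return SwitchEventTable(empty_event_frame())
    return SwitchEventTable(pd.DataFrame(recs))
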