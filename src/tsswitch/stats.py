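"""Normalization, replicate-level t-tests and FDR adjustment.

The two t-tests the pipeline relies on are Welch (unequal-variance,
unpaired across time points — replicate pools are different animals)
two-sided tests on replicate-level quantities:

* the *switch* test compares the per-replicate TSS-pair differences at
  the two time points (null: d1 = d2, no switching);
* the *aggregate* test compares the per-replicate pair means (null: the
  pair's overall expression is the same at both time points), used to
  filter out events confounded by plain differential expression.

Sample variances are floored at ``1e-12 * (1 + mean^2)`` so that exactly
noise-free (synthetic) replicates yield a finite statistic instead of a
division by zero; contrasts hitting the floor are still well-defined
because a zero numerator gives t = 0.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, PairContrast, TestResult

logger = logging.getLogger(__name__)

VAR_FLOOR_REL = 1e-12


def tpm_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale raw tag counts to tags-per-million, per sample.

    value[i, s] = 1e6 * count[i, s] / sum_i count[i, s]; every column of
    the result sums to 1e6 (within 1e-6 relative).  Idempotent on tpm
    input (a column already summing to 1e6 is returned unchanged).
    """
    totals = matrix.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero) > 0:
        raise ValueError(
            f"zero library size in sample(s): {list(zero.index)}"
        )
    tpm = matrix.values.div(totals, axis=1) * 1e6
    return ExpressionMatrix(tpm, matrix.design, unit="tpm")


def _floored_var(x: np.ndarray, axis: int = -1) -> tuple[np.ndarray, np.ndarray]:
    """Sample mean and floored sample variance along ``axis``."""
    m = np.mean(x, axis=axis)
    v = np.var(x, axis=axis, ddof=1)
    floor = VAR_FLOOR_REL * (1.0 + m**2)
    return m, np.maximum(v, floor)


def welch_t(
    m1: np.ndarray, v1: np.ndarray, n1: np.ndarray,
    m2: np.ndarray, v2: np.ndarray, n2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-sided Welch t-test from summary statistics.

    Returns (t, Welch-Satterthwaite df, p).  Inputs broadcast; variances
    are assumed already floored (positive).
    """
    m1, v1, n1 = np.asarray(m1, float), np.asarray(v1, float), np.asarray(n1, float)
    m2, v2, n2 = np.asarray(m2, float), np.asarray(v2, float), np.asarray(n2, float)
    a, b = v1 / n1, v2 / n2
    se2 = a + b
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, df, np.minimum(p, 1.0)


def _two_sample_welch(x: np.ndarray, y: np.ndarray) -> TestResult:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs >=2 replicates")
    m1, v1 = _floored_var(x)
    m2, v2 = _floored_var(y)
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and m1 != m2:
        logger.warning("zero replicate variance with unequal means; variance floored")
    t, df, p = welch_t(m1, v1, len(x), m2, v2, len(y))
    return TestResult(float(t), float(df), float(p))


def build_pair_contrast(
    tpm: ExpressionMatrix,
    gene_id: str,
    tss_a: str,
    tss_b: str,
    t1: str,
    t2: str,
    gene_of: dict[str, str] | None = None,
) -> PairContrast:
    """Assemble the replicate-level contrast for one TSS pair and time pair.

    Replicates are paired by replicate index (both TSSs of a pair are
    measured in the same pool), so the per-replicate difference vector is
    simply tpm(tss_a) - tpm(tss_b) over matched pools.  ``gene_of``
    optionally maps tss_id -> gene_id for membership validation.
    """
    if tss_a > tss_b:
        tss_a, tss_b = tss_b, tss_a
    if gene_of is not None:
        for t in (tss_a, tss_b):
            if gene_of.get(t) != gene_id:
                raise ValueError(f"TSS {t!r} does not belong to gene {gene_id!r}")
    design = tpm.design
    if design.time_rank(t1) > design.time_rank(t2):
        t1, t2 = t2, t1
    for tp in (t1, t2):
        if design.n_replicates(tp) < 2:
            raise ValueError(f"time point {tp} has <2 replicates; contrast untestable")
    cols1 = design.replicate_samples(t1)
    cols2 = design.replicate_samples(t2)
    a1 = tpm.values.loc[tss_a, cols1].to_numpy(float)
    b1 = tpm.values.loc[tss_b, cols1].to_numpy(float)
    a2 = tpm.values.loc[tss_a, cols2].to_numpy(float)
    b2 = tpm.values.loc[tss_b, cols2].to_numpy(float)
    return PairContrast(
        gene_id=gene_id, tss_a=tss_a, tss_b=tss_b, t1=t1, t2=t2,
        diffs_t1=a1 - b1, diffs_t2=a2 - b2,
        agg_t1=(a1 + b1) / 2.0, agg_t2=(a2 + b2) / 2.0,
    )


def switch_t_test(contrast: PairContrast) -> TestResult:
    """Welch t-test of d1 = d2 (no switching) on the replicate differences."""
    return _two_sample_welch(contrast.diffs_t1, contrast.diffs_t2)


def aggregate_t_test(contrast: PairContrast) -> TestResult:
    """Welch t-test of equal pair-mean expression at the two time points."""
    return _two_sample_welch(contrast.agg_t1, contrast.agg_t2)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
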