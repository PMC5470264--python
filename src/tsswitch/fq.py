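"""Qualitative-interaction (crossover) test on standardized contrasts.

Given Q estimated contrasts with standard errors, the statistic splits
the standardized values z_q = estimate_q / se_q into one-sided quadratic
forms

    Q+ = sum(max(z_q, 0)^2),    Q- = sum(min(z_q, 0)^2),
    F_Q = min(Q+, Q-),

so F_Q is zero exactly when all contrasts share one sign and grows only
when there is evidence on *both* sides — a crossover.  In this pipeline
the contrasts are the TSS-pair expression differences d1, d2 at the two
time points of a comparison (Q = 2); opposite signs mean the dominant
TSS changed.

The null hypothesis is "no qualitative interaction": all true contrasts
lie in one orthant.  Its least-favorable configuration pins one contrast
at +infinity and leaves the remaining Q-1 at zero, giving the
chi-bar-square supremum p-value

    p(c) = sum_{i=1..Q-1} C(Q-1, i) (1/2)^(Q-1) P(chi2_i > c),  p(0) = 1,

which for Q = 2 reduces to p = (1/2) P(chi2_1 > c).  A Monte-Carlo
simulation of the boundary configuration is provided as an independent
oracle for the closed form.

Standardization uses plug-in replicate-based standard errors with a
normal reference; with n = 3 replicates this is mildly anti-conservative,
and the Monte-Carlo oracle therefore also supports a t reference for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats as sps


@dataclass
class FqResult:
    """F_Q statistic decomposition for one set of contrasts."""

    q_plus: float
    q_minus: float
    fq_stat: float
    n_contrasts: int
    p_exact: float | None = None
    p_mc: float | None = None
    mc_se: float | None = None

    def __post_init__(self) -> None:
        if abs(self.fq_stat - min(self.q_plus, self.q_minus)) > 1e-9 * (
            1.0 + self.fq_stat
        ):
            raise ValueError("fq_stat must equal min(q_plus, q_minus)")


def fq_statistic(estimates, ses) -> FqResult:
    """Compute (Q+, Q-, F_Q) from contrast estimates and standard errors."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.shape != se.shape:
        raise ValueError("estimates and ses must have equal length")
    if est.size < 2:
        raise ValueError("need at least Q = 2 contrasts")
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    z = est / se
    q_plus = float(np.sum(np.maximum(z, 0.0) ** 2))
    q_minus = float(np.sum(np.minimum(z, 0.0) ** 2))
    return FqResult(
        q_plus=q_plus,
        q_minus=q_minus,
        fq_stat=min(q_plus, q_minus),
        n_contrasts=int(est.size),
    )


def _chi_bar_sf(c, n_contrasts: int) -> np.ndarray:
    """Vectorized chi-bar-square tail sum over i = 1..Q-1 (binomial weights)."""
    c = np.asarray(c, dtype=float)
    q = n_contrasts
    w = 0.5 ** (q - 1)
    out = np.zeros_like(c)
    for i in range(1, q):
        out += comb(q - 1, i) * w * sps.chi2.sf(c, i)
    return np.where(c <= 0, 1.0, np.minimum(out, 1.0))


def fq_pvalue_exact(fq: FqResult | float, n_contrasts: int | None = None) -> float:
    """Least-favorable-configuration exact p-value for an F_Q statistic.

    Accepts either an :class:`FqResult` (filled in place) or a bare
    statistic with ``n_contrasts``.
    """
    if isinstance(fq, FqResult):
        c, q = fq.fq_stat, fq.n_contrasts
    else:
        if n_contrasts is None:
            raise ValueError("n_contrasts required with a bare statistic")
        c, q = float(fq), int(n_contrasts)
    if c < 0:
        raise ValueError("fq_stat must be >= 0")
    p = float(_chi_bar_sf(np.asarray(c), q))
    if isinstance(fq, FqResult):
        fq.p_exact = p
    return p


def fq_pvalue_mc(
    fq_stat: float,
    n_contrasts: int,
    draws: int = 10**5,
    seed: int = 0,
    boundary_mean: float = 10.0,
    reference: str = "normal",
    t_df: float = 2.0,
) -> tuple[float, float]:
    """Monte-Carlo p-value at the least-favorable boundary configuration.

    Simulates one contrast with standardized mean ``boundary_mean`` (far
    on the positive side) and the remaining Q-1 at zero, unit variance;
    recomputes F_Q per draw and returns the exceedance fraction with its
    binomial standard error.  ``reference="t"`` replaces the unit-normal
    errors with scaled t(t_df) errors to probe plug-in-SE sensitivity.
    Deterministic given ``seed``.
    """
    if draws < 10**4:
        raise ValueError("draws must be >= 1e4 for a usable oracle")
    if n_contrasts < 2:
        raise ValueError("need at least Q = 2 contrasts")
    rng = np.random.default_rng(seed)
    if reference == "normal":
        z = rng.standard_normal((draws, n_contrasts))
    elif reference == "t":
        z = rng.standard_t(t_df, size=(draws, n_contrasts))
    else:
        raise ValueError(f"unknown reference {reference!r}")
    z[:, 0] += boundary_mean
    q_plus = np.sum(np.maximum(z, 0.0) ** 2, axis=1)
    q_minus = np.sum(np.minimum(z, 0.0) ** 2, axis=1)
    f = np.minimum(q_plus, q_minus)
    p = float(np.mean(f >= fq_stat))
    mc_se = float(np.sqrt(max(p * (1.0 - p), 1.0 / draws) / draws))
    return p, mc_se


def fq_test(estimates, ses) -> FqResult:
    """Statistic plus exact p-value in one call."""
    res = fq_statistic(estimates, ses)
    fq_pvalue_exact(res)
    return res
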