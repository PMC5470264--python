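"""Candidate enumeration, staged filtering and event classification.

The detection pipeline, applied to a tpm-normalized matrix:

1. enumerate every (gene, TSS pair, time-point pair) contrast for TSS
   passing the expression floor;
2. Welch-test the replicate differences (null d1 = d2); BH across all
   contrasts; keep adjusted p < alpha_candidate (default 0.2);
3. Welch-test the pair-mean aggregate expression on the survivors; BH
   across survivors; *drop* rows whose aggregate change is significant
   (adjusted p < alpha_aggregate, default 0.1) — those are confounded by
   plain differential expression;
4. classify by the signs of (d1, d2): strictly opposite signs are
   crossover (the dominant TSS changes), equal nonzero signs with
   d1 != d2 are non-crossover, anything touching zero or d1 = d2 is not
   an event;
5. crossover rows get the F_Q qualitative-interaction statistic on the
   standardized (d1, d2) contrasts with its exact chi-bar-square p-value,
   BH-adjusted across crossover rows;
6. the final table keeps non-crossover rows with q_switch < alpha_final
   and crossover rows with q_fq < alpha_final (default 0.05).

All orderings are canonical (lexicographic TSS ids, chronological time)
so repeated runs are byte-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import (
    ExpressionMatrix,
    PairContrast,
    SwitchEventTable,
    TssRecord,
    empty_event_frame,
)
from .fq import _chi_bar_sf
from .stats import VAR_FLOOR_REL, bh_adjust, welch_t


@dataclass
class DetectConfig:
    """Thresholds and modes of the detection pipeline."""

    alpha_candidate: float = 0.2
    alpha_aggregate: float = 0.1
    alpha_final: float = 0.05
    min_tpm: float = 1.0
    scale: str = "tpm"          # "tpm" or "log2" (log2(tpm+1))
    t_test: str = "welch"       # "welch" or "student" (pooled variance)
    fq_mode: str = "per_event"  # "per_event" or "per_gene"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_candidate", "alpha_aggregate", "alpha_final"):
            a = getattr(self, name)
            if not (0.0 < a < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {a}")
        if self.scale not in ("tpm", "log2"):
            raise ValueError(f"scale must be 'tpm' or 'log2', got {self.scale!r}")
        if self.t_test not in ("welch", "student"):
            raise ValueError(f"t_test must be 'welch' or 'student'")
        if self.fq_mode not in ("per_event", "per_gene"):
            raise ValueError(f"fq_mode must be 'per_event' or 'per_gene'")


def classify_contrast(d1: float, d2: float) -> str:
    """Sign-based event class of a (d1, d2) contrast pair.

    ``crossover`` iff the signs are strictly opposite; ``non_crossover``
    iff both are nonzero with the same sign and d1 != d2; ``none``
    otherwise (d1 = d2, or either difference exactly zero — a zero
    difference carries no dominant TSS, so it cannot witness a switch).
    """
    if (d1 > 0 and d2 < 0) or (d1 < 0 and d2 > 0):
        return "crossover"
    if d1 != 0 and d2 != 0 and np.sign(d1) == np.sign(d2) and d1 != d2:
        return "non_crossover"
    return "none"


def _gene_map(annotation: list[TssRecord]) -> dict[str, str]:
    return {rec.tss_id: rec.gene_id for rec in annotation}


def _testable_times(design) -> list[str]:
    return [tp for tp in design.time_points if design.n_replicates(tp) >= 2]


def _qualifying_pairs(
    tpm: ExpressionMatrix, annotation: list[TssRecord], config: DetectConfig
) -> list[tuple[str, str, str]]:
    """(gene, tss_a, tss_b) pairs whose TSSs pass the expression floor.

    A TSS qualifies when its replicate-mean tpm reaches ``min_tpm`` at
    one or more time points (a stand-in for upstream promoter
    thresholding); pairs are formed within genes, tss_a < tss_b.
    """
    gene_of = _gene_map(annotation)
    missing = [t for t in tpm.tss_ids if t not in gene_of]
    if missing:
        raise ValueError(
            f"{len(missing)} matrix TSS(s) absent from annotation, "
            f"e.g. {missing[:3]}"
        )
    design = tpm.design
    times = _testable_times(design)
    arr = tpm.values
    max_mean = pd.concat(
        [arr[design.replicate_samples(tp)].mean(axis=1) for tp in times], axis=1
    ).max(axis=1)
    ok = set(max_mean.index[max_mean >= config.min_tpm])
    by_gene: dict[str, list[str]] = {}
    for tss in tpm.tss_ids:
        if tss in ok:
            by_gene.setdefault(gene_of[tss], []).append(tss)
    pairs = []
    for gene in sorted(by_gene):
        for a, b in itertools.combinations(sorted(by_gene[gene]), 2):
            pairs.append((gene, a, b))
    return pairs


def enumerate_candidates(
    tpm: ExpressionMatrix, annotation: list[TssRecord], config: DetectConfig
) -> list[PairContrast]:
    """Materialize every testable contrast as a :class:`PairContrast`.

    For T testable time points each TSS pair contributes T(T-1)/2
    chronologically ordered time pairs.  Intended for small inputs and
    verification; :func:`detect_switches` runs the same enumeration
    vectorized.
    """
    design = tpm.design
    times = _testable_times(design)
    reps = {tp: design.replicate_samples(tp) for tp in times}
    arr = tpm.values
    out: list[PairContrast] = []
    for gene, a, b in _qualifying_pairs(tpm, annotation, config):
        va = {tp: arr.loc[a, reps[tp]].to_numpy(float) for tp in times}
        vb = {tp: arr.loc[b, reps[tp]].to_numpy(float) for tp in times}
        for t1, t2 in itertools.combinations(times, 2):
            out.append(
                PairContrast(
                    gene_id=gene, tss_a=a, tss_b=b, t1=t1, t2=t2,
                    diffs_t1=va[t1] - vb[t1], diffs_t2=va[t2] - vb[t2],
                    agg_t1=(va[t1] + vb[t1]) / 2.0,
                    agg_t2=(va[t2] + vb[t2]) / 2.0,
                )
            )
    return out


def _moments(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise mean and floored sample variance of a (pairs, reps) block."""
    m = x.mean(axis=1)
    v = x.var(axis=1, ddof=1)
    return m, np.maximum(v, VAR_FLOOR_REL * (1.0 + m**2))


def _pair_tests(m1, v1, n1, m2, v2, n2, kind: str):
    if kind == "welch":
        return welch_t(m1, v1, n1, m2, v2, n2)
    # pooled-variance Student's t
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    df = np.broadcast_to(np.asarray(n1 + n2 - 2, float), t.shape)
    p = np.minimum(2.0 * sps.t.sf(np.abs(t), df), 1.0)
    return t, df, p


def _contrast_frame(
    tpm: ExpressionMatrix, annotation: list[TssRecord], config: DetectConfig
) -> pd.DataFrame:
    """All contrasts with d/se and raw switch/aggregate p-values (long form)."""
    design = tpm.design
    times = _testable_times(design)
    pairs = _qualifying_pairs(tpm, annotation, config)
    if len(pairs) == 0 or len(times) < 2:
        return pd.DataFrame(
            columns=["gene_id", "tss_a", "tss_b", "t1", "t2", "d1", "d2",
                     "se_d1", "se_d2", "p_switch", "p_agg"]
        )
    values = tpm.values
    if config.scale == "log2":
        values = np.log2(values + 1.0)
    row_of = {t: i for i, t in enumerate(tpm.tss_ids)}
    ia = np.array([row_of[a] for _, a, _ in pairs])
    ib = np.array([row_of[b] for _, _, b in pairs])
    npairs, T = len(pairs), len(times)

    d_mean = np.empty((npairs, T))
    d_var = np.empty((npairs, T))
    g_mean = np.empty((npairs, T))
    g_var = np.empty((npairs, T))
    n_rep = np.empty(T)
    for k, tp in enumerate(times):
        cols = [values.columns.get_loc(s) for s in design.replicate_samples(tp)]
        block = values.to_numpy()[:, cols]
        A, B = block[ia], block[ib]
        d_mean[:, k], d_var[:, k] = _moments(A - B)
        g_mean[:, k], g_var[:, k] = _moments((A + B) / 2.0)
        n_rep[k] = len(cols)

    i_idx, j_idx = np.triu_indices(T, k=1)
    _, _, p_sw = _pair_tests(
        d_mean[:, i_idx], d_var[:, i_idx], n_rep[i_idx],
        d_mean[:, j_idx], d_var[:, j_idx], n_rep[j_idx],
        config.t_test,
    )
    _, _, p_ag = _pair_tests(
        g_mean[:, i_idx], g_var[:, i_idx], n_rep[i_idx],
        g_mean[:, j_idx], g_var[:, j_idx], n_rep[j_idx],
        config.t_test,
    )
    ntp = len(i_idx)
    genes = np.repeat([g for g, _, _ in pairs], ntp)
    tss_a = np.repeat([a for _, a, _ in pairs], ntp)
    tss_b = np.repeat([b for _, _, b in pairs], ntp)
    t1 = np.tile(np.array(times, dtype=object)[i_idx], npairs)
    t2 = np.tile(np.array(times, dtype=object)[j_idx], npairs)
    se = np.sqrt(d_var / n_rep)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "tss_a": tss_a,
            "tss_b": tss_b,
            "t1": t1,
            "t2": t2,
            "d1": d_mean[:, i_idx].ravel(),
            "d2": d_mean[:, j_idx].ravel(),
            "se_d1": se[:, i_idx].ravel(),
            "se_d2": se[:, j_idx].ravel(),
            "p_switch": p_sw.ravel(),
            "p_agg": p_ag.ravel(),
        }
    )


def detect_switches(
    tpm: ExpressionMatrix, annotation: list[TssRecord], config: DetectConfig | None = None
) -> SwitchEventTable:
    """Run the full staged detection pipeline; returns the final event table."""
    config = config or DetectConfig()
    if tpm.unit != "tpm":
        raise ValueError("detect_switches expects a tpm-normalized matrix")
    df = _contrast_frame(tpm, annotation, config)
    prov = {
        "config": asdict(config),
        "n_contrasts": int(len(df)),
        "package": "tsswitch",
    }
    if len(df) == 0:
        return SwitchEventTable(empty_event_frame(), prov)

    # stage 1: switching t-test, BH over all contrasts
    df["q_switch"] = bh_adjust(df["p_switch"].to_numpy())
    df = df[df["q_switch"] < config.alpha_candidate].copy()
    prov["n_candidates"] = int(len(df))
    if len(df) == 0:
        return SwitchEventTable(empty_event_frame(), prov)

    # stage 2: aggregate-expression filter, BH over survivors; keep the
    # contrasts whose overall pair expression does NOT change
    df["q_agg"] = bh_adjust(df["p_agg"].to_numpy())
    df = df[df["q_agg"] >= config.alpha_aggregate].copy()
    prov["n_after_aggregate_filter"] = int(len(df))

    # stage 3: sign classification
    d1 = df["d1"].to_numpy()
    d2 = df["d2"].to_numpy()
    cls = np.where(
        (np.sign(d1) * np.sign(d2)) < 0,
        "crossover",
        np.where((d1 != 0) & (d2 != 0) & (np.sign(d1) == np.sign(d2)) & (d1 != d2),
                 "non_crossover", "none"),
    )
    df["class"] = cls
    df = df[df["class"] != "none"].copy()

    # stage 4: F_Q on crossover rows
    df["fq_stat"] = np.nan
    df["p_fq"] = np.nan
    df["q_fq"] = np.nan
    xo = df["class"] == "crossover"
    if xo.any():
        z1 = df.loc[xo, "d1"].to_numpy() / df.loc[xo, "se_d1"].to_numpy()
        z2 = df.loc[xo, "d2"].to_numpy() / df.loc[xo, "se_d2"].to_numpy()
        z = np.stack([z1, z2], axis=1)
        q_plus = np.sum(np.maximum(z, 0.0) ** 2, axis=1)
        q_minus = np.sum(np.minimum(z, 0.0) ** 2, axis=1)
        fq = np.minimum(q_plus, q_minus)
        df.loc[xo, "fq_stat"] = fq
        if config.fq_mode == "per_event":
            p_fq = _chi_bar_sf(fq, 2)
            df.loc[xo, "p_fq"] = p_fq
            df.loc[xo, "q_fq"] = bh_adjust(p_fq)
        else:
            # per-gene pooling: all standardized contrasts of a gene's
            # crossover rows enter one F_Q with Q = 2 * n_rows
            sub = df.loc[xo].copy()
            sub["_z1"], sub["_z2"] = z1, z2
            gene_p: dict[str, float] = {}
            gene_f: dict[str, float] = {}
            for gene, grp in sub.groupby("gene_id"):
                zg = np.concatenate([grp["_z1"].to_numpy(), grp["_z2"].to_numpy()])
                qp = float(np.sum(np.maximum(zg, 0.0) ** 2))
                qm = float(np.sum(np.minimum(zg, 0.0) ** 2))
                f = min(qp, qm)
                gene_f[gene] = f
                gene_p[gene] = float(_chi_bar_sf(np.asarray(f), len(zg)))
            genes = sorted(gene_p)
            q_by_gene = dict(zip(genes, bh_adjust([gene_p[g] for g in genes])))
            df.loc[xo, "fq_stat"] = df.loc[xo, "gene_id"].map(gene_f).to_numpy()
            df.loc[xo, "p_fq"] = df.loc[xo, "gene_id"].map(gene_p).to_numpy()
            df.loc[xo, "q_fq"] = df.loc[xo, "gene_id"].map(q_by_gene).to_numpy()

    # stage 5: final significance
    keep = ((df["class"] == "non_crossover") & (df["q_switch"] < config.alpha_final)) | (
        (df["class"] == "crossover") & (df["q_fq"] < config.alpha_final)
    )
    df = df[keep]
    prov["n_events"] = int(len(df))
    if len(df) == 0:
        return SwitchEventTable(empty_event_frame(), prov)
    table = SwitchEventTable(df.reset_index(drop=True), prov)
    return table.sort_canonical(tpm.design)
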