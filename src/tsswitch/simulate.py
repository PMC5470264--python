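"""CAGE-like replicated time-course simulator with planted switching events.

The generator emulates a thresholded FANTOM5-style promoter expression
table: per-gene multiple TSSs, a 12-point developmental series (E11-E18,
P0, P3, P6, P9) with triplicate pools, log-normal baseline expression
and either direct multiplicative log-normal tpm noise or negative
binomial tag counts (to be passed through ``tpm_normalize``).

A planted switching event fixes the *expected* TSS-pair difference
d(t) = E[tpm(a) - tpm(b)] as a step trajectory: d = d1 at time points up
to the midpoint of the nominated (t1, t2) pair and d = d2 afterwards,
with the pair mean held constant so the aggregate-expression filter is
not triggered.  Crossover plants use (d1, d2) = (+e, -e); non-crossover
plants use (+e, +3e).  Because every time pair spanning the step is then
a genuine switching event, the emitted truth ledger enumerates all
implied (gene, TSS pair, time pair) events, not only the nominated pair,
so recovery scoring is exact.

In negative-binomial mode the remaining library mass is carried by
background single-TSS genes (invisible to pair enumeration) so that
realized library sizes match the configured size and nominal tpm values
stay interpretable after renormalization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, SampleDesign, SwitchEventTable, TssRecord
from .detect import classify_contrast

DEFAULT_TIME_POINTS = (
    "E11", "E12", "E13", "E14", "E15", "E16", "E17", "E18", "P0", "P3", "P6", "P9",
)


@dataclass(frozen=True)
class PlantedEvent:
    """One nominated switching event on a gene's TSS pair.

    ``effect`` is the tpm-scale half-trajectory magnitude e; the nominal
    differences are (+e, -e) for crossover and (+e, +3e) for
    non-crossover plants.
    """

    gene_id: str
    tss_a: str
    tss_b: str
    t1: str
    t2: str
    event_type: str  # "crossover" | "non_crossover"
    effect: float

    def __post_init__(self) -> None:
        if self.event_type not in ("crossover", "non_crossover"):
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not np.isfinite(self.effect) or self.effect <= 0:
            raise ValueError("effect must be a positive finite tpm value")

    @property
    def nominal_d(self) -> tuple[float, float]:
        if self.event_type == "crossover":
            return (+self.effect, -self.effect)
        return (+self.effect, +3.0 * self.effect)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic dataset."""

    n_genes: int = 200
    tss_per_gene: int = 2
    time_points: tuple[str, ...] = DEFAULT_TIME_POINTS
    n_replicates: int = 3
    baseline_meanlog: float = 3.0
    baseline_sdlog: float = 1.0
    noise_mode: str = "nb"        # "nb" (counts) or "lognormal" (direct tpm)
    dispersion: float = 0.02      # NB overdispersion (squared biological CV)
    library_size: float = 1e6     # expected tags per sample (NB mode)
    n_background: int = 50        # background single-TSS genes carrying library mass
    lognormal_sdlog: float = 0.1  # sd of log tpm noise (lognormal mode)
    planted_events: tuple[PlantedEvent, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_mode not in ("nb", "lognormal"):
            raise ValueError(f"unknown noise mode {self.noise_mode!r}")
        if self.n_genes < 1 or self.tss_per_gene < 1 or self.n_replicates < 1:
            raise ValueError("n_genes, tss_per_gene, n_replicates must be >= 1")
        for ev in self.planted_events:
            if not np.isfinite(ev.effect):
                raise ValueError("planted effects must be finite")


@dataclass
class SyntheticTruth:
    """Ledger of true events: one row per implied (gene, pair, time pair)."""

    df: pd.DataFrame  # gene_id, tss_a, tss_b, t1, t2, class, d1, d2
    planted: tuple[PlantedEvent, ...] = ()

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class RecoveryReport:
    """Recovery of planted truth by a detected event table."""

    n_true: int
    n_detected: int
    n_matched: int
    sensitivity: float
    fdr: float
    class_confusions: int
    confusion: dict


def nb_tpm_sd(mean_tpm: float, dispersion: float, library_size: float = 1e6) -> float:
    """Per-replicate tpm standard deviation of the NB noise model.

    Counts have mean m = tpm * L / 1e6 and variance m + dispersion * m^2;
    converted back to the tpm scale the sd is
    sqrt(tpm * 1e6/L + dispersion * tpm^2).
    """
    return float(np.sqrt(mean_tpm * 1e6 / library_size + dispersion * mean_tpm**2))


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _build_means(config: GeneratorConfig, rng: np.random.Generator):
    """Expected tpm per (tss, time) plus the implied truth ledger."""
    genes = _gene_ids(config.n_genes)
    tss_of: dict[str, list[str]] = {
        g: [f"{g}.T{k}" for k in range(1, config.tss_per_gene + 1)] for g in genes
    }
    all_tss = [t for g in genes for t in tss_of[g]]
    T = len(config.time_points)
    base = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, len(all_tss))
    means = np.tile(base[:, None], (1, T))
    row = {t: i for i, t in enumerate(all_tss)}
    rank = {tp: i for i, tp in enumerate(config.time_points)}

    planted_pairs: set[tuple[str, str, str]] = set()
    truth_rows = []
    for ev in config.planted_events:
        if ev.gene_id not in tss_of:
            raise ValueError(f"planted event references unknown gene {ev.gene_id!r}")
        members = tss_of[ev.gene_id]
        if len(members) < 2:
            raise ValueError(
                f"planted event references 1-TSS gene {ev.gene_id!r}"
            )
        a, b = sorted((ev.tss_a, ev.tss_b))
        if a not in members or b not in members:
            raise ValueError(f"planted TSS pair ({a}, {b}) not in gene {ev.gene_id!r}")
        key = (ev.gene_id, a, b)
        if key in planted_pairs:
            raise ValueError(f"TSS pair {key} planted more than once")
        planted_pairs.add(key)
        if ev.t1 not in rank or ev.t2 not in rank or rank[ev.t1] >= rank[ev.t2]:
            raise ValueError(f"bad planted time pair ({ev.t1}, {ev.t2})")

        d1, d2 = ev.nominal_d
        mid = (rank[ev.t1] + rank[ev.t2]) / 2.0
        delta = np.array([d1 if rank[tp] <= mid else d2 for tp in config.time_points])
        mu_pair = max(
            (base[row[a]] + base[row[b]]) / 2.0, 0.75 * max(abs(d1), abs(d2))
        )
        means[row[a]] = mu_pair + delta / 2.0
        means[row[b]] = mu_pair - delta / 2.0
        for i, j in itertools.combinations(range(T), 2):
            cls = classify_contrast(delta[i], delta[j])
            if cls != "none":
                truth_rows.append(
                    (ev.gene_id, a, b, config.time_points[i], config.time_points[j],
                     cls, float(delta[i]), float(delta[j]))
                )
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "tss_a", "tss_b", "t1", "t2", "class", "d1", "d2"],
    )
    return all_tss, tss_of, means, truth


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[list[TssRecord], ExpressionMatrix, SampleDesign, SyntheticTruth]:
    """Draw one synthetic dataset; deterministic given ``config.seed``.

    Returns (annotation, matrix, design, truth); the matrix holds raw
    counts in NB mode (run :func:`tsswitch.tpm_normalize`) and tpm in
    lognormal mode.
    """
    rng = np.random.default_rng(config.seed)
    all_tss, tss_of, means, truth_df = _build_means(config, rng)
    T = len(config.time_points)
    R = config.n_replicates

    samples = tuple(
        (f"{tp}_r{r}", tp, k, r)
        for k, tp in enumerate(config.time_points)
        for r in range(1, R + 1)
    )
    design = SampleDesign(samples)

    # expected tpm per sample column
    mean_cols = np.repeat(means, R, axis=1)  # (n_tss, T*R)
    tss_ids = list(all_tss)
    gene_rows = [(t, g) for g, members in tss_of.items() for t in members]

    if config.noise_mode == "lognormal":
        s = config.lognormal_sdlog
        if s > 0:
            factor = np.exp(rng.normal(0.0, s, mean_cols.shape) - s**2 / 2.0)
        else:
            factor = 1.0
        values = mean_cols * factor
        unit = "tpm"
    else:
        L = config.library_size
        scale = L / 1e6
        count_means = mean_cols * scale
        fg_total = means.sum(axis=0) * scale  # per time point
        bg_total = L - fg_total
        if np.any(bg_total <= 0):
            raise ValueError(
                "foreground expected tags exceed library_size; "
                "lower baselines or raise library_size"
            )
        nbg = config.n_background
        bg_means = np.repeat(bg_total[None, :] / nbg, nbg, axis=0)  # (nbg, T)
        bg_cols = np.repeat(bg_means, R, axis=1)
        count_means = np.vstack([count_means, bg_cols])
        bg_ids = [f"BG{i:04d}.T1" for i in range(1, nbg + 1)]
        tss_ids = tss_ids + bg_ids
        gene_rows += [(t, t.rsplit(".", 1)[0]) for t in bg_ids]
        phi = config.dispersion
        if phi > 0:
            n_param = 1.0 / phi
            p_param = n_param / (n_param + count_means)
            values = rng.negative_binomial(n_param, p_param).astype(float)
        else:
            values = rng.poisson(count_means).astype(float)
        unit = "counts"

    frame = pd.DataFrame(values, index=tss_ids, columns=design.sample_ids)
    matrix = ExpressionMatrix(frame, design, unit=unit)
    annotation = [
        TssRecord(t, g, "chr1", 1000 * i, 1000 * i + 100, "+")
        for i, (t, g) in enumerate(gene_rows)
    ]
    truth = SyntheticTruth(truth_df, config.planted_events)
    return annotation, matrix, design, truth


def benchmark_config(
    seed: int,
    n_genes: int = 200,
    n_crossover: int = 20,
    n_non_crossover: int = 20,
    effect_multiple: float = 10.0,
    dispersion: float = 0.02,
    library_size: float = 1e6,
    reference_tpm: float = 50.0,
) -> GeneratorConfig:
    """Standard parameter-recovery benchmark configuration.

    Plants ``n_crossover + n_non_crossover`` events on distinct genes at
    effect ``effect_multiple`` times the per-replicate NB noise sd
    evaluated at a 50-tpm reference promoter; genes and time pairs are
    drawn at random from the 12 x 3 design.
    """
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    n_plant = n_crossover + n_non_crossover
    if n_plant > n_genes:
        raise ValueError("more plants than genes")
    chosen = rng.choice(n_genes, size=n_plant, replace=False)
    effect = effect_multiple * nb_tpm_sd(reference_tpm, dispersion, library_size)
    tps = DEFAULT_TIME_POINTS
    plants = []
    for k, gi in enumerate(chosen):
        i, j = sorted(rng.choice(len(tps), size=2, replace=False))
        g = genes[gi]
        plants.append(
            PlantedEvent(
                gene_id=g, tss_a=f"{g}.T1", tss_b=f"{g}.T2",
                t1=tps[i], t2=tps[j],
                event_type="crossover" if k < n_crossover else "non_crossover",
                effect=effect,
            )
        )
    return GeneratorConfig(
        n_genes=n_genes,
        noise_mode="nb",
        dispersion=dispersion,
        library_size=library_size,
        planted_events=tuple(plants),
        seed=seed,
    )


_KEY = ["gene_id", "tss_a", "tss_b", "t1", "t2"]


def score_recovery(events: SwitchEventTable, truth: SyntheticTruth) -> RecoveryReport:
    """Match detected events to the truth ledger on (gene, pair, time pair)."""
    det = events.df[_KEY + ["class"]].copy()
    tru = truth.df[_KEY + ["class"]].copy() if len(truth.df) else pd.DataFrame(
        columns=_KEY + ["class"]
    )
    merged = det.merge(tru, on=_KEY, how="outer", suffixes=("_det", "_true"),
                       indicator=True)
    matched = merged["_merge"] == "both"
    n_true = len(tru)
    n_det = len(det)
    n_matched = int(matched.sum())
    sensitivity = n_matched / n_true if n_true else float("nan")
    fdr = (n_det - n_matched) / n_det if n_det else 0.0
    confusion: dict[tuple[str, str], int] = {}
    for _, r in merged[matched].iterrows():
        key = (r["class_true"], r["class_det"])
        confusion[key] = confusion.get(key, 0) + 1
    confusions = sum(v for (t, d), v in confusion.items() if t != d)
    return RecoveryReport(
        n_true=n_true,
        n_detected=n_det,
        n_matched=n_matched,
        sensitivity=sensitivity,
        fdr=fdr,
        class_confusions=confusions,
        confusion=confusion,
    )
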