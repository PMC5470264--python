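import numpy as np
import pandas as pd
import pytest

from tsswitch import (
    GeneratorConfig,
    PlantedEvent,
    SwitchEventTable,
    SyntheticTruth,
    benchmark_config,
    generate_dataset,
    nb_tpm_sd,
    score_recovery,
)
from tsswitch.datatypes import empty_event_frame


def _plant(event_type="crossover", effect=50.0, t1="E11", t2="P9", gene="G0001"):
    return PlantedEvent(
        gene_id=gene, tss_a=f"{gene}.T1", tss_b=f"{gene}.T2",
        t1=t1, t2=t2, event_type=event_type, effect=effect,
    )


class TestGenerateDataset:
    def test_shapes_match_design(self):
        cfg = GeneratorConfig(n_genes=10, tss_per_gene=3, noise_mode="lognormal",
                              seed=1)
        ann, mat, design, truth = generate_dataset(cfg)
        assert len(design.samples) == 12 * 3
        assert mat.values.shape == (30, 36)
        genes = {r.gene_id for r in ann}
        assert len(genes) == 10

    def test_same_seed_reproduces_bytes(self):
        cfg = GeneratorConfig(n_genes=5, seed=42)
        _, m1, _, _ = generate_dataset(cfg)
        _, m2, _, _ = generate_dataset(cfg)
        assert m1.values.equals(m2.values)

    def test_different_seed_differs(self):
        _, m1, _, _ = generate_dataset(GeneratorConfig(n_genes=5, seed=1))
        _, m2, _, _ = generate_dataset(GeneratorConfig(n_genes=5, seed=2))
        assert not m1.values.equals(m2.values)

    def test_noiseless_crossover_plant_is_exact(self):
        cfg = GeneratorConfig(
            n_genes=3, noise_mode="lognormal", lognormal_sdlog=0.0,
            planted_events=(_plant(effect=50.0),), seed=0,
        )
        ann, mat, design, truth = generate_dataset(cfg)
        a = mat.values.loc["G0001.T1", design.replicate_samples("E11")]
        b = mat.values.loc["G0001.T2", design.replicate_samples("E11")]
        np.testing.assert_allclose((a.values - b.values), 50.0)
        a2 = mat.values.loc["G0001.T1", design.replicate_samples("P9")]
        b2 = mat.values.loc["G0001.T2", design.replicate_samples("P9")]
        np.testing.assert_allclose((a2.values - b2.values), -50.0)

    def test_doubling_effect_doubles_noiseless_difference(self):
        diffs = []
        for e in (25.0, 50.0):
            cfg = GeneratorConfig(
                n_genes=3, noise_mode="lognormal", lognormal_sdlog=0.0,
                planted_events=(_plant(effect=e),), seed=0,
            )
            _, mat, design, _ = generate_dataset(cfg)
            a = mat.values.loc["G0001.T1", design.replicate_samples("E11")].iloc[0]
            b = mat.values.loc["G0001.T2", design.replicate_samples("E11")].iloc[0]
            diffs.append(a - b)
        assert diffs[1] == pytest.approx(2 * diffs[0])

    def test_truth_ledger_enumerates_implied_spanning_pairs(self):
        cfg = GeneratorConfig(
            n_genes=3, noise_mode="lognormal",
            planted_events=(_plant(t1="E11", t2="E12"),), seed=0,
        )
        _, _, _, truth = generate_dataset(cfg)
        # step sits between E11 and E12: 1 early x 11 late time points
        assert len(truth.df) == 11
        assert set(truth.df["class"]) == {"crossover"}
        assert (truth.df["t1"] == "E11").all()

    def test_plant_on_single_tss_gene_errors(self):
        cfg = GeneratorConfig(
            n_genes=2, tss_per_gene=1, planted_events=(_plant(),), seed=0
        )
        with pytest.raises(ValueError, match="1-TSS"):
            generate_dataset(cfg)

    def test_nb_library_sizes_near_configured_mean(self):
        totals = []
        for seed in range(20):
            cfg = GeneratorConfig(n_genes=20, library_size=1e6, seed=seed)
            _, mat, _, _ = generate_dataset(cfg)
            totals.extend(mat.values.sum(axis=0).tolist())
        totals = np.asarray(totals)
        # relative spread of realized library sizes stays small
        assert abs(totals.mean() - 1e6) / 1e6 < 0.05
        assert totals.std() / 1e6 < 0.10

    def test_nb_mode_emits_counts_lognormal_emits_tpm(self):
        _, m1, _, _ = generate_dataset(GeneratorConfig(n_genes=3, seed=0))
        assert m1.unit == "counts"
        _, m2, _, _ = generate_dataset(
            GeneratorConfig(n_genes=3, noise_mode="lognormal", seed=0)
        )
        assert m2.unit == "tpm"


class TestNbTpmSd:
    def test_poisson_plus_overdispersion_terms(self):
        assert nb_tpm_sd(50.0, 0.02, 1e6) == pytest.approx(np.sqrt(50 + 0.02 * 2500))
        assert nb_tpm_sd(50.0, 0.0, 1e6) == pytest.approx(np.sqrt(50))


class TestBenchmarkConfig:
    def test_plants_forty_events_on_distinct_genes(self):
        cfg = benchmark_config(seed=5)
        assert len(cfg.planted_events) == 40
        genes = {p.gene_id for p in cfg.planted_events}
        assert len(genes) == 40
        kinds = [p.event_type for p in cfg.planted_events]
        assert kinds.count("crossover") == 20

    def test_effect_scales_with_multiple(self):
        e10 = benchmark_config(seed=1, effect_multiple=10).planted_events[0].effect
        e20 = benchmark_config(seed=1, effect_multiple=20).planted_events[0].effect
        assert e20 == pytest.approx(2 * e10)


def _truth_from_rows(rows):
    df = pd.DataFrame(
        rows, columns=["gene_id", "tss_a", "tss_b", "t1", "t2", "class", "d1", "d2"]
    )
    return SyntheticTruth(df)


def _events_from_keys(keys):
    df = empty_event_frame()
    for i, (g, a, b, t1, t2, cls) in enumerate(keys):
        df.loc[i] = {
            "gene_id": g, "tss_a": a, "tss_b": b, "t1": t1, "t2": t2,
            "d1": 1.0, "d2": -1.0 if cls == "crossover" else 2.0,
            "se_d1": 1.0, "se_d2": 1.0, "class": cls,
            "p_switch": 0.01, "q_switch": 0.01, "p_agg": 0.9, "q_agg": 0.9,
            "fq_stat": np.nan, "p_fq": np.nan, "q_fq": np.nan,
        }
    return SwitchEventTable(df)


class TestScoreRecovery:
    def _truth10(self):
        return _truth_from_rows(
            [(f"G{i}", "a", "b", "t1", "t2", "crossover", 1.0, -1.0)
             for i in range(10)]
        )

    def test_perfect_recovery(self):
        truth = self._truth10()
        events = _events_from_keys(
            [(g, "a", "b", "t1", "t2", "crossover") for g in truth.df["gene_id"]]
        )
        rep = score_recovery(events, truth)
        assert rep.sensitivity == 1.0 and rep.fdr == 0.0

    def test_empty_events_zero_sensitivity(self):
        rep = score_recovery(SwitchEventTable(empty_event_frame()), self._truth10())
        assert rep.sensitivity == 0.0 and rep.fdr == 0.0

    def test_hand_counted_confusion_table(self):
        truth = self._truth10()
        found = [(f"G{i}", "a", "b", "t1", "t2", "crossover") for i in range(8)]
        spurious = [("GX", "a", "b", "t1", "t2", "crossover")]
        rep = score_recovery(_events_from_keys(found + spurious), truth)
        assert rep.sensitivity == pytest.approx(0.8)
        assert rep.fdr == pytest.approx(1 / 9)
        assert rep.class_confusions == 0

    def test_class_mismatch_counted_as_confusion(self):
        truth = _truth_from_rows(
            [("G0", "a", "b", "t1", "t2", "crossover", 1.0, -1.0)]
        )
        rep = score_recovery(
            _events_from_keys([("G0", "a", "b", "t1", "t2", "non_crossover")]), truth
        )
        assert rep.class_confusions == 1
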