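"""Generator invariants: tiling geometry, determinism, planted-effect fidelity."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import medipdiff as md
from medipdiff.simulate import (
    OFFSETS,
    PROBES_PER_PROMOTER,
    ConfigurationError,
    generate_target_map,
    simulate_promoter_sequences,
)


def test_layout_tiling_geometry():
    cfg = md.SimulationConfig(n_promoters=2, n_mirnas=1, seed=3)
    layout = md.generate_genome_layout(cfg)
    assert layout.n_probes == 2 * PROBES_PER_PROMOTER == 26
    for _, probes in layout.probes.groupby("promoter_id"):
        offs = np.sort(probes["offset"].to_numpy())
        assert np.array_equal(offs, OFFSETS)
        assert np.all(np.diff(offs) == 100)
    # every probe maps to exactly one promoter
    assert layout.probes["probe_id"].is_unique
    assert set(layout.probes["promoter_id"]) == set(layout.promoters["promoter_id"])


def test_layout_tss_strictly_increasing(small_data):
    prom = small_data["layout"].promoters
    for _, sub in prom.groupby("chromosome"):
        assert np.all(np.diff(sub["tss"].to_numpy()) > 0)


def test_layout_probe_coordinates_match_strand(small_data):
    layout = small_data["layout"]
    merged = layout.probes.merge(layout.promoters[["promoter_id", "tss"]], on="promoter_id")
    plus = merged["strand"] == "+"
    assert (merged.loc[plus, "start"] == merged.loc[plus, "tss"] + merged.loc[plus, "offset"]).all()
    minus = ~plus
    assert (
        merged.loc[minus, "end"] == merged.loc[minus, "tss"] - merged.loc[minus, "offset"]
    ).all()


def test_same_seed_is_bit_identical():
    cfg = md.SimulationConfig(n_promoters=80, n_mirnas=5, seed=42)
    runs = []
    for _ in range(2):
        layout = md.generate_genome_layout(cfg)
        truth = md.simulate_truth(layout, cfg)
        bound, input_, sheet = md.simulate_arrays(layout, truth, cfg)
        runs.append((layout, truth, bound, input_, sheet))
    pd.testing.assert_frame_equal(runs[0][0].probes, runs[1][0].probes)
    pd.testing.assert_frame_equal(runs[0][0].promoters, runs[1][0].promoters)
    pd.testing.assert_series_equal(runs[0][1].dm_effects, runs[1][1].dm_effects)
    pd.testing.assert_frame_equal(runs[0][2], runs[1][2])
    pd.testing.assert_frame_equal(runs[0][3], runs[1][3])


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        md.generate_genome_layout(md.SimulationConfig(n_promoters=0))
    with pytest.raises(ConfigurationError):
        md.SimulationConfig(fraction_dm=1.5).validate()
    with pytest.raises(ConfigurationError):
        md.SimulationConfig(individual_sd=-0.1).validate()


def test_truth_invariants(small_data):
    truth, cfg = small_data["truth"], small_data["cfg"]
    assert (truth.dm_effects.abs() > 0).all()
    assert len(truth.dm_effects) == round(cfg.fraction_dm * cfg.n_promoters)
    assert set(truth.dm_mirnas) <= set(truth.dm_effects.index)
    blocks = truth.cluster_blocks.sort_values(["chromosome", "start"])
    for _, sub in blocks.groupby("chromosome"):
        starts, ends = sub["start"].to_numpy(), sub["end"].to_numpy()
        assert np.all(starts[1:] >= ends[:-1])  # disjoint


def test_noise_free_limit_recovers_delta_exactly():
    cfg = md.SimulationConfig(
        n_promoters=40, n_mirnas=2, seed=5, individual_sd=0.0,
        replicate_sd=0.0, probe_jitter_sd=0.0,
    )
    layout = md.generate_genome_layout(cfg)
    truth = md.simulate_truth(layout, cfg)
    bound, input_, sheet = md.simulate_arrays(layout, truth, cfg)
    mm = md.compute_log_ratios(bound, input_)
    avg = md.average_replicates(mm, sheet)
    groups = sheet.drop_duplicates("individual_id").set_index("individual_id")["group"]
    case = avg.values.loc[:, (groups.loc[avg.values.columns] == "case").to_numpy()]
    ctrl = avg.values.loc[:, (groups.loc[avg.values.columns] == "control").to_numpy()]
    diff = case.mean(axis=1) - ctrl.mean(axis=1)
    probe_prom = layout.probes.set_index("probe_id")["promoter_id"]
    planted = probe_prom.map(truth.dm_effects).fillna(0.0)
    np.testing.assert_allclose(diff.to_numpy(), planted.to_numpy(), atol=1e-9)


def test_null_construction_has_zero_expected_difference():
    cfg = md.SimulationConfig(n_promoters=300, n_mirnas=10, fraction_dm=0.0,
                              n_dm_mirnas=0, seed=8)
    layout = md.generate_genome_layout(cfg)
    truth = md.simulate_truth(layout, cfg)
    assert truth.dm_effects.empty
    bound, input_, sheet = md.simulate_arrays(layout, truth, cfg)
    avg = md.average_replicates(md.compute_log_ratios(bound, input_), sheet)
    groups = sheet.drop_duplicates("individual_id").set_index("individual_id")["group"]
    case = avg.values.loc[:, (groups.loc[avg.values.columns] == "case").to_numpy()]
    ctrl = avg.values.loc[:, (groups.loc[avg.values.columns] != "case").to_numpy()]
    diff = (case.mean(axis=1) - ctrl.mean(axis=1)).to_numpy()
    se = np.sqrt((cfg.individual_sd**2 + cfg.replicate_sd**2 / 3) * (1 / 12 + 1 / 28))
    assert abs(diff.mean()) < 4 * se / np.sqrt(len(diff))


def test_replicate_noise_matches_configured_sd(small_data):
    """Empirical within-individual sd across replicates ~ replicate_sd."""
    cfg, sheet = small_data["cfg"], small_data["sheet"]
    mm = md.compute_log_ratios(small_data["bound"], small_data["input"])
    sds = []
    for _, sub in sheet.groupby("individual_id"):
        block = mm.values[sub["array_id"]]
        sds.append(block.std(axis=1, ddof=1).to_numpy())
    pooled = np.sqrt(np.mean(np.concatenate(sds) ** 2))
    assert pooled == pytest.approx(cfg.replicate_sd, rel=0.02)


@pytest.fixture(scope="module")
def tm_data():
    """Layout/truth with enough planted hypo genes to exercise target maps."""
    cfg = md.SimulationConfig(n_promoters=800, n_mirnas=40, fraction_dm=0.12,
                              seed=19)
    layout = md.generate_genome_layout(cfg)
    truth = md.simulate_truth(layout, cfg)
    return {"layout": layout, "truth": truth, "cfg": cfg}


class TestTargetMap:
    def test_planted_counts_exact(self, tm_data):
        layout, truth, cfg = (tm_data[k] for k in ("layout", "truth", "cfg"))
        mirna_pid = layout.promoters.loc[layout.promoters["cls"] == "miRNA",
                                         "promoter_id"].iloc[0]
        tm = generate_target_map(
            layout, truth, cfg, planted_counts={mirna_pid: (49, 10)}
        )
        mid = layout.promoters.set_index("promoter_id").loc[mirna_pid, "gene_id"]
        targets = tm[mid]
        hypo_genes = set(
            layout.promoters.loc[
                layout.promoters["promoter_id"].isin(
                    truth.dm_effects.index[truth.dm_effects < 0]
                ), "gene_id",
            ]
        )
        assert len(targets) == 49
        assert len(targets & hypo_genes) == 10

    def test_deterministic_and_size_validated(self, tm_data):
        layout, truth, cfg = (tm_data[k] for k in ("layout", "truth", "cfg"))
        a = generate_target_map(layout, truth, cfg, n_targets=30)
        b = generate_target_map(layout, truth, cfg, n_targets=30)
        assert a == b
        with pytest.raises(ValueError):
            generate_target_map(layout, truth, cfg, n_targets=10**6)

    def test_odds_one_targets_match_background_rate(self, tm_data):
        layout, truth, cfg = (tm_data[k] for k in ("layout", "truth", "cfg"))
        tm = generate_target_map(layout, truth, cfg, n_targets=50, enrichment_odds=1.0)
        assert truth.consistent_mirnas == []
        hypo_genes = set(
            layout.promoters.loc[
                layout.promoters["promoter_id"].isin(
                    truth.dm_effects.index[truth.dm_effects < 0]
                ), "gene_id",
            ]
        )
        n_genes = (layout.promoters["cls"] == "gene").sum()
        rates = [len(t & hypo_genes) / len(t) for t in tm.values()]
        background = len(hypo_genes) / n_genes
        assert np.mean(rates) == pytest.approx(background, abs=0.03)


def test_sequences_cover_layout_and_are_deterministic(small_data):
    layout, truth, cfg = (small_data[k] for k in ("layout", "truth", "cfg"))
    seqs = simulate_promoter_sequences(layout, truth, cfg)
    assert set(seqs) == set(layout.promoters["promoter_id"])
    assert {len(s) for s in seqs.values()} == {1250}
    assert seqs == simulate_promoter_sequences(layout, truth, cfg)
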