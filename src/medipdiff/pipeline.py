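"""End-to-end orchestration: load -> QC -> normalize -> average -> probe
stats -> promoter calls -> enrichment -> miRNA consistency -> genome
features -> optional permutation -> summary report.

All stages are thin calls into the library modules, driven by a
:class:`PipelineConfig` that round-trips through YAML.  Every output is a
TSV (plus a UCSC wiggle track), written under ``output_dir``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import confound, enrichment, genome, io, normalize, permutation
from . import probestats, promoters
from .simulate import (
    SimulationConfig,
    generate_gene_sets,
    generate_genome_layout,
    generate_target_map,
    simulate_arrays,
    simulate_promoter_sequences,
    simulate_truth,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    annotation: str = ""
    intensity_dir: str = ""
    sample_sheet: str = ""
    gene_sets: str = ""
    target_map: str = ""
    fasta: str = ""
    output_dir: str = "results"
    case_label: str = "case"
    probe_p: float = 0.05
    fc_cut: float = 0.25
    promoter_q: float = 0.20
    strict_probe_p: float = 0.01
    strict_promoter_q: float = 0.05
    mirna_q: float = 0.05
    window_width: int = 750_000
    window_step: int = 250_000
    distance_bin: int = 500_000
    distance_max: int = 2_000_000
    n_permutations: int = 0
    seed: int = 0

    def validate(self) -> None:
        for name in ("probe_p", "promoter_q", "strict_probe_p",
                     "strict_promoter_q", "mirna_q"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.fc_cut < 0:
            raise ValueError("fc_cut must be non-negative")
        for name in ("annotation", "sample_sheet", "intensity_dir"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{name} path missing or absent: {p!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def simulate_to_dir(config: SimulationConfig, outdir: str | Path,
                    write_sequences: bool = True) -> dict[str, Path]:
    """Generate a full synthetic dataset and write every input file.

    Returns the paths of the written artifacts (annotation, intensity dir,
    sample sheet, truth, target map, gene sets, FASTA).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = generate_genome_layout(config)
    truth = simulate_truth(layout, config)
    bound, input_, sheet = simulate_arrays(layout, truth, config)
    target_map = generate_target_map(layout, truth, config)
    gene_sets = generate_gene_sets(layout, truth, config)

    paths = {
        "annotation": outdir / "probe_annotation.tsv",
        "intensity_dir": outdir / "arrays",
        "sample_sheet": outdir / "arrays" / "sample_sheet.tsv",
        "truth": outdir / "truth.tsv",
        "truth_blocks": outdir / "truth_blocks.tsv",
        "target_map": outdir / "mirna_targets.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
    }
    io.write_probe_annotation(layout, paths["annotation"])
    io.write_arrays(bound, input_, sheet, paths["intensity_dir"])
    io.write_truth(truth, paths["truth"])
    truth.cluster_blocks.to_csv(paths["truth_blocks"], sep="\t", index=False)
    io.write_mirna_targets(target_map, paths["target_map"])
    io.write_gene_sets(gene_sets, paths["gene_sets"])
    if write_sequences:
        paths["fasta"] = outdir / "promoters.fasta"
        io.write_fasta(simulate_promoter_sequences(layout, truth, config), paths["fasta"])
    return paths


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write result tables; returns the summary dict."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("loading inputs")
    layout = io.load_probe_annotation(config.annotation)
    bound, input_, sheet = io.load_arrays(config.intensity_dir, config.sample_sheet)
    bound = bound.reindex(layout.probes["probe_id"])
    input_ = input_.reindex(layout.probes["probe_id"])

    log.info("QC and normalization")
    qc = normalize.ma_qc(bound, input_)
    qc.to_csv(outdir / "array_qc.tsv", sep="\t", index=False)
    mm = normalize.compute_log_ratios(bound, input_)
    # conservative default: drop probes missing in > 20% of arrays
    missing_frac = mm.values.isna().mean(axis=1)
    dropped = int((missing_frac > 0.2).sum())
    if dropped:
        log.info("dropping %d probes missing in > 20%% of arrays", dropped)
        mm.values = mm.values.loc[missing_frac <= 0.2]
    mm = normalize.quantile_normalize(mm)
    avg = normalize.average_replicates(mm, sheet)

    log.info("probe statistics")
    probe_to_prom = layout.probes.set_index("probe_id")["promoter_id"]
    probe_stats, eb = probestats.probe_statistics(
        avg.values, sheet, p_cut=config.probe_p, fc_cut=config.fc_cut,
        case_label=config.case_label,
    )
    probe_stats["promoter_id"] = probe_to_prom.reindex(probe_stats.index)
    probe_stats.to_csv(outdir / "probe_stats.tsv", sep="\t")

    log.info("promoter calls")
    calls = promoters.call_promoters(
        probe_stats,
        thresholds=dict(probe_p=config.probe_p, fc=config.fc_cut,
                        promoter_q=config.promoter_q),
        strict_thresholds=dict(probe_p=config.strict_probe_p, fc=config.fc_cut,
                               promoter_q=config.strict_promoter_q),
    )
    prom_meta = layout.promoters.set_index("promoter_id")
    calls_out = calls.join(prom_meta[["gene_id", "chromosome", "tss", "cls"]])
    calls_out.to_csv(outdir / "promoter_calls.tsv", sep="\t")

    called = calls.loc[calls["called_default"]]
    if len(called) >= 2:
        rep_probes = called["representative_probe"].dropna()
        Z, order = promoters.cluster_samples(avg.values.loc[rep_probes])
        pd.Series(order, name="individual_id").to_csv(
            outdir / "sample_cluster_order.tsv", sep="\t", index=False
        )
        (outdir / "sample_dendrogram.nwk").write_text(
            promoters.linkage_to_newick(Z, list(avg.values.loc[rep_probes].columns))
        )

    log.info("enrichment analyses")
    gene_calls = calls_out.loc[calls_out["cls"] == "gene"]
    universe = set(gene_calls["gene_id"])
    dm_by_dir = {
        "any": set(gene_calls.loc[gene_calls["called_default"], "gene_id"]),
        "hypo": set(gene_calls.loc[gene_calls["called_default"]
                                   & (gene_calls["direction"] == "hypo"), "gene_id"]),
        "hyper": set(gene_calls.loc[gene_calls["called_default"]
                                    & (gene_calls["direction"] == "hyper"), "gene_id"]),
    }
    summary: dict = {
        "n_probes": int(len(probe_stats)),
        "n_promoters": int(len(calls)),
        "called_promoters": int(calls["called_default"].sum()),
        "called_hyper": int((calls["called_default"] & (calls["direction"] == "hyper")).sum()),
        "called_hypo": int((calls["called_default"] & (calls["direction"] == "hypo")).sum()),
        "called_strict": int(calls["called_strict"].sum()),
        "eb_d0": float(eb.d0),
        "eb_s0_2": float(eb.s0_2),
        "thresholds": dict(probe_p=config.probe_p, fc=config.fc_cut,
                           promoter_q=config.promoter_q),
    }

    if config.gene_sets:
        sets = io.load_gene_sets(config.gene_sets, universe=universe)
        gse = enrichment.gene_set_enrichment(dm_by_dir, universe, sets)
        gse.to_csv(outdir / "gene_set_enrichment.tsv", sep="\t", index=False)
        summary["enriched_sets_fdr20"] = int(
            ((gse["direction"] == "any") & (gse["q"] < 0.2)).sum()
        )

    if config.target_map:
        target_map = io.load_mirna_targets(config.target_map, universe=universe)
        mirna_calls = calls_out.loc[calls_out["cls"] == "miRNA"].reset_index()
        mirna_calls["called"] = mirna_calls["called_default"]
        mirna = enrichment.mirna_target_consistency(
            mirna_calls, target_map, dm_by_dir["hypo"], dm_by_dir["hyper"],
            universe, q_threshold=config.mirna_q,
        )
        mirna.to_csv(outdir / "mirna_consistency.tsv", sep="\t", index=False)
        summary["dm_mirnas"] = int(mirna_calls["called"].sum())
        summary["consistent_mirnas"] = int(mirna["consistent"].sum())

    log.info("genome features")
    windows = genome.window_enrichment(
        calls, layout, width=config.window_width, step=config.window_step
    )
    windows.to_csv(outdir / "window_enrichment.tsv", sep="\t", index=False)
    summary["windows_fdr20"] = int((windows["q"] < 0.2).sum())
    chrom_rows = []
    for direction in ("hyper", "hypo"):
        per_chrom = genome.window_enrichment(
            calls, layout, direction=direction, per_chromosome=True
        )
        per_chrom["direction"] = direction
        chrom_rows.append(per_chrom)
    pd.concat(chrom_rows).to_csv(outdir / "chromosome_enrichment.tsv",
                                 sep="\t", index=False)

    rep = calls.join(prom_meta[["chromosome", "tss"]])
    rep = rep.merge(
        probe_stats.reset_index()[["probe_id", "t_mod"]],
        left_on="representative_probe", right_on="probe_id", how="left",
    ).rename(columns={"t_mod": "t"})
    profile = genome.distance_correlation(
        rep, bin_width=config.distance_bin, max_distance=config.distance_max
    )
    profile.to_csv(outdir / "distance_correlation.tsv", sep="\t", index=False)

    diffs = genome.probe_group_differences(avg.values, sheet, layout,
                                           case_label=config.case_label)
    genome.write_wiggle(diffs, outdir / "group_difference.wig")

    if config.fasta:
        sequences = io.load_fasta(config.fasta)
        freq, cpg_summary = genome.cpg_density(sequences, calls)
        cpg_summary.to_csv(outdir / "cpg_density.tsv", sep="\t")
        summary["cpg_oe_all"] = float(cpg_summary.loc["all", "mean"])
        if np.isfinite(cpg_summary.loc["hypo", "mean"]):
            summary["cpg_oe_hypo"] = float(cpg_summary.loc["hypo", "mean"])
        if np.isfinite(cpg_summary.loc["hyper", "mean"]):
            summary["cpg_oe_hyper"] = float(cpg_summary.loc["hyper", "mean"])

    if config.n_permutations > 0:
        log.info("permutation null (%d partitions)", config.n_permutations)
        avg.values.attrs["promoter_ids"] = probe_to_prom.reindex(avg.values.index).to_numpy()
        perm = permutation.permutation_percentile(
            avg.values, sheet, n_partitions=config.n_permutations,
            seed=config.seed,
            thresholds=dict(probe_p=config.probe_p, fc=config.fc_cut,
                            promoter_q=config.promoter_q),
            case_label=config.case_label,
        )
        pd.DataFrame(
            {"partition": np.arange(perm.n_partitions), "call_count": perm.null_counts}
        ).to_csv(outdir / "permutation_counts.tsv", sep="\t", index=False)
        summary["permutation_percentile"] = perm.percentile

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %d/%d promoters called (%d hyper, %d hypo)",
             summary["called_promoters"], summary["n_promoters"],
             summary["called_hyper"], summary["called_hypo"])
    return summary
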