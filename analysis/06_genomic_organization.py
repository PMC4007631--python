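#!/usr/bin/env python
"""Spatial organization of differential methylation and CpG density.

Scans 750 kb windows (250 kb step) and whole chromosomes for enrichment of
called promoters, profiles the correlation of differential statistics
against TSS distance (out to 2 Mb), compares the normalized CpG frequency
(observed/expected) of hypo- and hypermethylated promoters against all
promoters, and exports the per-probe group difference as a UCSC wiggle
track.
"""

from pathlib import Path

import pandas as pd

import medipdiff as md
from medipdiff import genome, io

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"

layout = io.load_probe_annotation(DATA / "probe_annotation.tsv")
calls = pd.read_csv(ROOT / "promoter_calls.tsv", sep="\t", index_col=0)
stats = pd.read_csv(ROOT / "probe_stats.tsv", sep="\t", index_col=0)
blocks = pd.read_csv(DATA / "truth_blocks.tsv", sep="\t")

windows = genome.window_enrichment(calls, layout)
windows.to_csv(ROOT / "window_enrichment.tsv", sep="\t", index=False)
sig = windows.loc[windows["q"] < 0.2]
print(f"{len(sig)} of {len(windows)} windows enriched at FDR < 0.2")
for _, blk in blocks.iterrows():
    hit = ((sig["chromosome"] == blk["chromosome"])
           & (sig["start"] < blk["end"]) & (sig["end"] > blk["start"])).any()
    print(f"  planted block {blk['chromosome']}:{blk['start']}-{blk['end']} "
          f"({blk['direction']}): {'recovered' if hit else 'MISSED'}")

for direction in ("hyper", "hypo"):
    chrom = genome.window_enrichment(calls, layout, direction=direction,
                                     per_chromosome=True)
    enriched = chrom.loc[chrom["q"] < 0.2, "chromosome"].tolist()
    print(f"chromosome-level {direction} enrichment (FDR<0.2): {enriched or 'none'}")

meta = layout.promoters.set_index("promoter_id")
rep = calls.join(meta[["chromosome", "tss"]])
rep = rep.merge(stats.reset_index()[["probe_id", "t_mod"]],
                left_on="representative_probe", right_on="probe_id",
                how="left").rename(columns={"t_mod": "t"})
profile = genome.distance_correlation(rep)
profile.to_csv(ROOT / "distance_correlation.tsv", sep="\t", index=False)
print("distance-correlation profile (bin center -> r):")
for _, row in profile.iterrows():
    print(f"  {row['distance'] / 1e6:.2f} Mb: r = {row['r']:+.3f} "
          f"[{row['ci_low']:+.3f}, {row['ci_high']:+.3f}] ({int(row['n_pairs'])} pairs)")

seqs = io.load_fasta(DATA / "promoters.fasta")
freq, summary = genome.cpg_density(seqs, calls)
summary.to_csv(ROOT / "cpg_density.tsv", sep="\t")
print("normalized CpG frequency (observed/expected):")
for group in ("all", "hypo", "hyper"):
    row = summary.loc[group]
    print(f"  {group}: {row['mean']:.2f} (n={int(row['n'])})")

avg = pd.read_csv(ROOT / "methylation_individual_averaged.tsv", sep="\t", index_col=0)
sheet = io.load_sample_sheet(DATA / "arrays" / "sample_sheet.tsv")
diffs = genome.probe_group_differences(avg, sheet, layout)
genome.write_wiggle(diffs, ROOT / "group_difference.wig")
print(f"wiggle track -> {ROOT / 'group_difference.wig'}")
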