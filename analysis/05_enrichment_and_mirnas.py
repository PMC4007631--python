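#!/usr/bin/env python
"""Gene-set enrichment and miRNA-target consistency.

Tests each gene set (GMT) for over-representation of differentially
methylated genes (any / hypo / hyper, hypergeometric with BH FDR per
analysis), then asks whether hypermethylated miRNAs have target genes
enriched for hypomethylated promoters — the signature of a coordinated
double layer of repression being lifted.
"""

from pathlib import Path

import pandas as pd

import medipdiff as md
from medipdiff import io

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"

layout = io.load_probe_annotation(DATA / "probe_annotation.tsv")
calls = pd.read_csv(ROOT / "promoter_calls.tsv", sep="\t", index_col=0)
meta = layout.promoters.set_index("promoter_id")
calls = calls.join(meta[["gene_id", "cls"]])

gene_calls = calls.loc[calls["cls"] == "gene"]
universe = set(gene_calls["gene_id"])
dm = {
    d: set(gene_calls.loc[gene_calls["called_default"]
                          & ((gene_calls["direction"] == d) if d != "any" else True),
                          "gene_id"])
    for d in ("any", "hypo", "hyper")
}
print(f"universe: {len(universe)} genes; DM: {len(dm['any'])} "
      f"({len(dm['hypo'])} hypo, {len(dm['hyper'])} hyper)")

sets = io.load_gene_sets(DATA / "gene_sets.gmt", universe=universe)
gse = md.gene_set_enrichment(dm, universe, sets)
gse.to_csv(ROOT / "gene_set_enrichment.tsv", sep="\t", index=False)
top = gse.loc[(gse["direction"] == "any")].nsmallest(3, "p")
print("top gene sets (any direction):")
for _, row in top.iterrows():
    print(f"  {row['set']}: k={row['k']}/{row['n']}, p={row['p']:.2e}, q={row['q']:.3f}")

target_map = io.load_mirna_targets(DATA / "mirna_targets.tsv", universe=universe)
mirna_calls = calls.loc[calls["cls"] == "miRNA"].reset_index()
mirna_calls["called"] = mirna_calls["called_default"]
res = md.mirna_target_consistency(
    mirna_calls, target_map, dm["hypo"], dm["hyper"], universe
)
res.to_csv(ROOT / "mirna_consistency.tsv", sep="\t", index=False)
n_cons = int(res["consistent"].sum())
print(f"{int(mirna_calls['called'].sum())} differentially methylated miRNAs; "
      f"{n_cons} hypermethylated with hypo-enriched targets (q < 0.05)")
for _, row in res.loc[res["consistent"]].iterrows():
    print(f"  {row['mirna']}: {row['k_hypo']}/{row['n_targets']} targets hypo, "
          f"{row['k_hyper']} hyper, p={row['p']:.2e}")
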