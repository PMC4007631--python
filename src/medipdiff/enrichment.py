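"""Hypergeometric enrichment: gene sets, miRNA targets, list intersections.

All overlap tests share one record shape: universe size N, K "interesting"
genes in the universe, unit size n, overlap k, upper-tail hypergeometric p
and a BH q across the units tested together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .promoters import bh_fdr

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    unit_id: str
    N: int
    K: int
    n: int
    k: int
    p: float
    q: float = float("nan")
    direction: str = "any"


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); p = 1 when k = 0."""
    if not 0 <= k <= min(n, K) or n > N or K > N:
        raise ValueError(f"inconsistent counts N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    return float(min(stats.hypergeom.sf(k - 1, N, K, n), 1.0))


def gene_set_enrichment(
    dm_genes: dict[str, set[str]],
    universe: set[str],
    gene_sets: dict[str, set[str]],
) -> pd.DataFrame:
    """Three enrichment analyses per gene set: any-DM, hypo-only, hyper-only.

    ``dm_genes`` maps direction context ("any", "hypo", "hyper") to gene
    sets; the universe is every gene with a profiled promoter.  BH FDR is
    computed across all sets within each direction context.
    """
    universe = {g.upper() for g in universe}
    rows = []
    for direction in ("any", "hypo", "hyper"):
        interesting = {g.upper() for g in dm_genes.get(direction, set())} & universe
        K = len(interesting)
        for name, members in gene_sets.items():
            members_u = {g.upper() for g in members} & universe
            if not members_u:
                log.info("gene set %s disjoint from universe; skipped", name)
                continue
            n = len(members_u)
            k = len(members_u & interesting)
            p = hypergeometric_tail(len(universe), K, n, k)
            rows.append((name, direction, len(universe), K, n, k, p))
    df = pd.DataFrame(
        rows, columns=["set", "direction", "N", "K", "n", "k", "p"]
    )
    df["q"] = np.nan
    for direction in df["direction"].unique():
        mask = df["direction"] == direction
        df.loc[mask, "q"] = bh_fdr(df.loc[mask, "p"].to_numpy())
    return df


def mirna_target_consistency(
    mirna_calls: pd.DataFrame,
    target_map: dict[str, set[str]],
    hypo_genes: set[str],
    hyper_genes: set[str],
    universe: set[str],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Test each differentially methylated miRNA for hypomethylated targets.

    ``mirna_calls`` needs columns gene_id (miRNA id matching the target
    map), called (bool) and direction.  For each called miRNA the upper-tail
    hypergeometric test asks whether its target genes (restricted to the
    universe) are enriched for hypomethylated genes; the hypermethylated
    target count is reported alongside.  A miRNA is flagged "consistent"
    when it is itself hypermethylated and its hypo-target enrichment q
    passes the threshold.
    """
    universe = {g.upper() for g in universe}
    hypo = {g.upper() for g in hypo_genes} & universe
    hyper = {g.upper() for g in hyper_genes} & universe
    rows = []
    for _, row in mirna_calls.loc[mirna_calls["called"]].iterrows():
        mid = row["gene_id"]
        targets = {g.upper() for g in target_map.get(mid, set())} & universe
        if not targets:
            log.info("miRNA %s has no profiled targets; skipped", mid)
            continue
        k_hypo = len(targets & hypo)
        k_hyper = len(targets & hyper)
        p = hypergeometric_tail(len(universe), len(hypo), len(targets), k_hypo)
        rows.append(
            (mid, row["direction"], len(targets), k_hypo, k_hyper, p)
        )
    df = pd.DataFrame(
        rows,
        columns=["mirna", "mirna_direction", "n_targets", "k_hypo", "k_hyper", "p"],
    )
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
        df["consistent"] = (df["mirna_direction"] == "hyper") & (df["q"] < q_threshold)
    else:
        df["q"] = pd.Series(dtype=float)
        df["consistent"] = pd.Series(dtype=bool)
    return df


def intersection_test(
    list_a: set[str], list_b: set[str], universe: set[str]
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of the overlap of two gene lists."""
    universe = {g.upper() for g in universe}
    a = {g.upper() for g in list_a} & universe
    b = {g.upper() for g in list_b} & universe
    if not a or not b:
        log.warning("empty gene list in intersection test; p = 1")
        return EnrichmentResult("intersection", len(universe), len(a), len(b), 0, 1.0)
    k = len(a & b)
    p = hypergeometric_tail(len(universe), len(a), len(b), k)
    return EnrichmentResult("intersection", len(universe), len(a), len(b), k, p)
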