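"""Two-tier promoter differential-methylation calls and sample clustering.

A promoter is called differentially methylated when two independent criteria
hold: (i) it contains at least one probe passing the probe-level thresholds,
and (ii) its probes' moderated t-statistics sit significantly higher or
lower than the average probe on the array (Wilcoxon rank-sum against the
whole-array pool), with a Benjamini-Hochberg FDR below 20% across promoters.
The strict tier tightens both criteria (probe p < 0.01, promoter q < 0.05).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = dict(probe_p=0.05, fc=0.25, promoter_q=0.20)
STRICT_THRESHOLDS = dict(probe_p=0.01, fc=0.25, promoter_q=0.05)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def promoter_shift_test(
    member_values: np.ndarray, pool_values: np.ndarray, pool_contains_member: bool = False
) -> tuple[float, str]:
    """Rank-sum test of a promoter's statistics against the array pool.

    ``pool_values`` is the reference distribution ("the average probe on the
    microarray"); when ``pool_contains_member`` the member values are ranked
    within the pool itself (null: n1 ranks drawn without replacement from
    N), otherwise the two samples are pooled first — for disjoint samples
    this is the standard two-sample Wilcoxon rank-sum test.  Exact
    enumeration when both sample sizes are <= 8, otherwise a normal
    approximation with tie and continuity corrections.  Direction is hyper
    when the promoter median exceeds the pool median.
    """
    x = np.asarray(member_values, dtype=float)
    pool = np.asarray(pool_values, dtype=float)
    if x.size < 2:
        raise ValueError("promoter needs >= 2 scored probes")
    if not pool_contains_member:
        pool = np.concatenate([x, pool])
    n1, n_all = x.size, pool.size
    n2 = n_all - n1
    ranks = stats.rankdata(pool)
    if pool_contains_member:
        # member values are a subset of the pool; locate their ranks
        sort_idx = np.argsort(pool, kind="stable")
        sorted_pool = pool[sort_idx]
        used = np.zeros(n_all, dtype=bool)
        member_ranks = []
        for v in x:
            j = np.searchsorted(sorted_pool, v)
            while used[j] or sorted_pool[j] != v:
                j += 1
            used[j] = True
            member_ranks.append(ranks[sort_idx[j]])
        w = float(np.sum(member_ranks))
    else:
        w = float(ranks[:n1].sum())
    mu = n1 * (n_all + 1) / 2.0
    direction = "hyper" if np.median(x) > np.median(pool) else "hypo"

    if n1 <= 8 and n2 <= 8:
        dist = [
            abs(sum(combo) - mu)
            for combo in itertools.combinations(ranks, n1)
        ]
        observed = abs(w - mu)
        p = sum(d >= observed - 1e-9 for d in dist) / len(dist)
        return min(p, 1.0), direction

    _, counts = np.unique(pool, return_counts=True)
    tie_term = float(((counts**3) - counts).sum())
    var = n1 * n2 / 12.0 * ((n_all + 1) - tie_term / (n_all * (n_all - 1)))
    if var <= 0:
        return 1.0, direction
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(max(z, 0.0))
    return min(p, 1.0), direction


def shift_tests(
    t_mod: np.ndarray, promoter_codes: np.ndarray, n_promoters: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized rank-sum shift test of every promoter against the array pool.

    Normal approximation with tie and continuity corrections; promoters with
    fewer than 2 scored probes receive NaN.  Returns (p, hyper) arrays of
    length ``n_promoters`` where ``hyper`` flags a promoter median above the
    array median.
    """
    t = np.asarray(t_mod, dtype=float)
    ok = np.isfinite(t)
    codes = np.asarray(promoter_codes)
    N = int(ok.sum())
    ranks = np.full(t.shape, np.nan)
    ranks[ok] = stats.rankdata(t[ok])
    valid = ok & (codes >= 0)
    w = np.bincount(codes[valid], weights=ranks[valid], minlength=n_promoters)
    n1 = np.bincount(codes[valid], minlength=n_promoters).astype(float)
    mu = n1 * (N + 1) / 2.0
    _, counts = np.unique(t[ok], return_counts=True)
    tie_term = float(((counts**3) - counts).sum())
    var = n1 * (N - n1) / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (np.abs(w - mu) - 0.5) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(np.clip(z, 0.0, None))
    p = np.minimum(p, 1.0)
    p[(n1 < 2) | (var <= 0)] = np.nan

    med_all = np.median(t[ok])
    prom_median = (
        pd.Series(t[valid]).groupby(codes[valid]).median()
        .reindex(range(n_promoters))
        .to_numpy()
    )
    hyper = prom_median > med_all
    return p, hyper


def representative_probe(probe_stats: pd.DataFrame) -> pd.Series:
    """Per promoter, the member probe most associated with the phenotype.

    Smallest p; ties broken by larger |log2 fold-difference|, then
    lexicographic probe_id.
    """
    df = probe_stats.reset_index()
    df["_absfc"] = -df["beta"].abs()
    df = df.sort_values(["p", "_absfc", "probe_id"], kind="stable")
    first = df.drop_duplicates("promoter_id")
    return first.set_index("promoter_id")["probe_id"]


def call_promoters(
    probe_stats: pd.DataFrame,
    promoter_ids: pd.Series | None = None,
    thresholds: dict | None = None,
    strict_thresholds: dict | None = None,
) -> pd.DataFrame:
    """Apply the two-tier promoter call to scored probes.

    ``probe_stats`` must carry promoter_id, beta, p, t_mod columns (one row
    per scored probe).  Returns one row per promoter with the shift-test p,
    BH q across promoters, direction, default/strict calls and the
    representative probe.
    """
    thr = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    strict = {**STRICT_THRESHOLDS, **(strict_thresholds or {})}
    df = probe_stats.copy()
    if "promoter_id" not in df.columns:
        raise ValueError("probe_stats must include a promoter_id column")

    counts = df.groupby("promoter_id", sort=False).size()
    skipped = counts.index[counts < 2]
    if len(skipped):
        log.info("skipped %d promoters with < 2 scored probes", len(skipped))
        df = df[~df["promoter_id"].isin(skipped)]

    promoters = df["promoter_id"].drop_duplicates()
    codes = pd.Categorical(df["promoter_id"], categories=promoters).codes
    p_shift, hyper = shift_tests(df["t_mod"].to_numpy(), codes, len(promoters))

    dm_default = (df["p"] < thr["probe_p"]) & (df["beta"].abs() >= thr["fc"])
    dm_strict = (df["p"] < strict["probe_p"]) & (df["beta"].abs() >= strict["fc"])
    has_dm = np.bincount(codes, weights=dm_default.to_numpy(), minlength=len(promoters)) > 0
    has_dm_strict = np.bincount(codes, weights=dm_strict.to_numpy(), minlength=len(promoters)) > 0

    q = bh_fdr(np.clip(p_shift, np.finfo(float).tiny, 1.0))
    out = pd.DataFrame(
        {
            "promoter_id": promoters.to_numpy(),
            "n_probes": counts.loc[promoters].to_numpy(),
            "has_dm_probe": has_dm,
            "has_dm_probe_strict": has_dm_strict,
            "shift_p": p_shift,
            "q": q,
            "direction": np.where(hyper, "hyper", "hypo"),
        }
    )
    out["called_default"] = out["has_dm_probe"] & (out["q"] < thr["promoter_q"])
    out["called_strict"] = out["has_dm_probe_strict"] & (out["q"] < strict["promoter_q"])
    rep = representative_probe(df.set_index("probe_id") if df.index.name != "probe_id" else df)
    out["representative_probe"] = out["promoter_id"].map(rep)
    out.attrs["thresholds"] = thr
    out.attrs["strict_thresholds"] = strict
    return out.set_index("promoter_id")


def cluster_samples(matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Ward hierarchical clustering of sample columns on 1 - Pearson r.

    Returns the scipy linkage matrix and the deterministic leaf order of
    column labels.  Constant (zero-variance) columns have undefined
    correlations; their distances are set to the maximum (1) with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples to cluster")
    corr = matrix.corr(method="pearson")
    constant = matrix.std(skipna=True) == 0
    if constant.any():
        log.warning("%d constant sample columns; correlation undefined, distance set to 1",
                    int(constant.sum()))
    dist = 1.0 - corr.to_numpy()
    dist[~np.isfinite(dist)] = 1.0
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="ward")
    order = [matrix.columns[i] for i in leaves_list(Z)]
    return Z, order


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = node.get_left(), node.get_right()
        bl = lambda child: max(node.dist - child.dist, 0.0)
        return (
            f"({walk(left)}:{bl(left):.6g},{walk(right)}:{bl(right):.6g})"
        )

    return walk(tree) + ";"
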