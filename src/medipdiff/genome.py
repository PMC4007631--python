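"""Spatial organization of differential methylation and sequence features.

Covers megabase-scale sliding-window and per-chromosome enrichment of
called promoters, the distance-correlation profile of differential
statistics, normalized CpG frequency (observed/expected) of promoter
regions, and UCSC wiggle-track export of per-probe group differences.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import hypergeometric_tail
from .promoters import bh_fdr
from .simulate import GenomeLayout

log = logging.getLogger(__name__)


def window_enrichment(
    calls: pd.DataFrame,
    layout: GenomeLayout,
    width: int = 750_000,
    step: int = 250_000,
    direction: str = "any",
    per_chromosome: bool = False,
    call_column: str = "called_default",
) -> pd.DataFrame:
    """Sliding-window hypergeometric enrichment of called promoters.

    Promoters are assigned to windows by TSS.  Each window's called count k
    (direction-filtered) among its n promoters is tested upper-tail against
    the genome-wide rate (K called of N profiled); BH FDR across windows.
    ``per_chromosome`` tests each chromosome as a single window instead.
    """
    prom = layout.promoters.merge(
        calls.reset_index()[["promoter_id", call_column, "direction"]],
        on="promoter_id",
        how="inner",
    )
    called = prom[call_column].to_numpy(dtype=bool)
    if direction != "any":
        called = called & (prom["direction"] == direction).to_numpy()
    N, K = len(prom), int(called.sum())

    rows = []
    for chrom, length in layout.chromosomes:
        on_chrom = prom["chromosome"] == chrom
        tss = prom.loc[on_chrom, "tss"].to_numpy()
        chrom_called = called[on_chrom.to_numpy()]
        if per_chromosome:
            starts = np.array([0])
            widths = np.array([length])
        else:
            starts = np.arange(0, max(length - width, 0) + 1, step)
            widths = np.full(starts.shape, width)
        for start, w in zip(starts, widths):
            inside = (tss >= start) & (tss < start + w)
            n = int(inside.sum())
            if n == 0:
                continue
            k = int(chrom_called[inside].sum())
            p = hypergeometric_tail(N, K, n, k)
            rows.append((chrom, int(start), int(start + w), n, k, p))
    df = pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "n", "k", "p"]
    )
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
    else:
        df["q"] = pd.Series(dtype=float)
    df.attrs["direction"] = direction
    return df


def distance_correlation(
    rep_stats: pd.DataFrame,
    bin_width: int = 500_000,
    max_distance: int = 2_000_000,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Pearson correlation of promoter statistics by TSS distance bin.

    ``rep_stats`` needs chromosome, tss and t (the representative-probe
    differential statistic) columns.  Every unordered same-chromosome pair
    whose distance falls in a bin contributes once; the correlation is
    symmetrized by including both orientations.  95% CI by Fisher z with the
    unordered pair count.
    """
    edges = np.arange(0, max_distance + bin_width, bin_width)
    pairs_x: list[list[float]] = [[] for _ in range(len(edges) - 1)]
    pairs_y: list[list[float]] = [[] for _ in range(len(edges) - 1)]
    for _, sub in rep_stats.groupby("chromosome", sort=False):
        if len(sub) < 2:
            continue
        sub = sub.sort_values("tss", kind="stable")
        pos = sub["tss"].to_numpy(dtype=float)
        t = sub["t"].to_numpy(dtype=float)
        for i in range(len(sub) - 1):
            j_hi = np.searchsorted(pos, pos[i] + max_distance, side="right")
            d = pos[i + 1 : j_hi] - pos[i]
            b = np.minimum((d // bin_width).astype(int), len(edges) - 2)
            for bb, tj in zip(b, t[i + 1 : j_hi]):
                pairs_x[bb].append(t[i])
                pairs_y[bb].append(tj)

    rows = []
    for b in range(len(edges) - 1):
        n_pairs = len(pairs_x[b])
        if n_pairs < min_pairs:
            log.info("distance bin %d-%d has %d pairs (< %d); omitted",
                     edges[b], edges[b + 1], n_pairs, min_pairs)
            continue
        x = np.array(pairs_x[b] + pairs_y[b])
        y = np.array(pairs_y[b] + pairs_x[b])
        r = float(np.corrcoef(x, y)[0, 1])
        if abs(r) < 1 and n_pairs > 3:
            z = np.arctanh(r)
            se = 1.0 / np.sqrt(n_pairs - 3)
            lo, hi = np.tanh(z - 1.959964 * se), np.tanh(z + 1.959964 * se)
        else:
            lo = hi = r
        rows.append(((edges[b] + edges[b + 1]) / 2.0, r, n_pairs, lo, hi))
    return pd.DataFrame(
        rows, columns=["distance", "r", "n_pairs", "ci_low", "ci_high"]
    )


def normalized_cpg_frequency(sequence: str) -> float:
    """Observed/expected CpG frequency: (#CpG * L) / (#C * #G).

    Undefined (NaN) when the sequence has no C or no G.
    """
    seq = sequence.upper()
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c == 0 or n_g == 0:
        return float("nan")
    n_cpg = seq.count("CG")
    return n_cpg * len(seq) / (n_c * n_g)


def cpg_density(
    sequences: dict[str, str],
    calls: pd.DataFrame,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-promoter normalized CpG frequency and hyper/hypo group contrasts.

    ``calls`` is the promoter call table (index promoter_id with
    called_default and direction columns).  Returns the per-promoter
    frequencies and a summary with group means ('all', 'hyper', 'hypo') and
    two-sided Welch t-test p-values between groups.
    """
    freq = pd.Series(
        {pid: normalized_cpg_frequency(seq) for pid, seq in sequences.items()},
        name="cpg_oe",
    )
    n_undefined = int(freq.isna().sum())
    if n_undefined:
        log.warning("%d promoters with undefined CpG frequency excluded", n_undefined)
        freq = freq.dropna()

    called = calls.loc[calls["called_default"]]
    groups = {
        "all": freq,
        "hyper": freq.loc[freq.index.intersection(called.index[called["direction"] == "hyper"])],
        "hypo": freq.loc[freq.index.intersection(called.index[called["direction"] == "hypo"])],
    }
    rows = []
    for name, values in groups.items():
        rows.append((name, len(values), float(values.mean()) if len(values) else np.nan,
                     float(values.std()) if len(values) > 1 else np.nan))
    summary = pd.DataFrame(rows, columns=["group", "n", "mean", "sd"]).set_index("group")
    for a, b in (("hypo", "all"), ("hypo", "hyper"), ("hyper", "all")):
        if len(groups[a]) > 1 and len(groups[b]) > 1:
            p = float(stats.ttest_ind(groups[a], groups[b], equal_var=False).pvalue)
        else:
            p = np.nan
        summary.loc[a, f"p_vs_{b}"] = p
    return freq, summary


def write_wiggle(
    diffs: pd.DataFrame,
    path: str | Path,
    span: int = 50,
    name: str = "group_difference",
) -> None:
    """UCSC variableStep wiggle track of per-probe group mean differences.

    ``diffs`` needs chromosome, start (0-based) and value columns; wiggle
    positions are 1-based, so each probe is emitted at start + 1.  Probes
    are sorted by position within each chromosome section.
    """
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for chrom, sub in diffs.groupby("chromosome", sort=True):
            sub = sub.sort_values("start", kind="stable")
            fh.write(f"variableStep chrom={chrom} span={span}\n")
            for start, value in zip(sub["start"], sub["value"]):
                fh.write(f"{int(start) + 1}\t{value:.6g}\n")


def read_wiggle(path: str | Path) -> pd.DataFrame:
    """Parse a variableStep wiggle file back to (chromosome, start, value)."""
    rows = []
    chrom, span = None, 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("variableStep"):
                m = re.search(r"chrom=(\S+)", line)
                chrom = m.group(1) if m else None
                m = re.search(r"span=(\d+)", line)
                span = int(m.group(1)) if m else 1
                continue
            pos_s, val_s = line.split("\t")
            rows.append((chrom, int(pos_s) - 1, span, float(val_s)))
    return pd.DataFrame(rows, columns=["chromosome", "start", "span", "value"])


def probe_group_differences(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    layout: GenomeLayout,
    case_label: str = "case",
) -> pd.DataFrame:
    """Case-minus-control mean per probe, joined to genomic coordinates."""
    groups = (
        sheet.drop_duplicates("individual_id")
        .set_index("individual_id")["group"]
        .loc[matrix.columns]
    )
    case = matrix.loc[:, (groups == case_label).to_numpy()]
    ctrl = matrix.loc[:, (groups != case_label).to_numpy()]
    diff = case.mean(axis=1) - ctrl.mean(axis=1)
    out = layout.probes[["probe_id", "chromosome", "start"]].copy()
    out["value"] = diff.reindex(out["probe_id"]).to_numpy()
    return out.dropna(subset=["value"])
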