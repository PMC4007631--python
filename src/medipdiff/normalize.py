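"""Log-ratio computation, quantile normalization, replicate averaging, QC.

The methylation signal of a two-channel MeDIP array is the log2 ratio of the
bound (Cy5, methylation-enriched) over the input (Cy3) channel.  Arrays are
made comparable by quantile normalization under the assumption that all
samples share the same overall methylation distribution, then replicate
arrays of each individual are averaged.  Log base 2 is used throughout so
that the probe-level fold-difference threshold (0.25 log2 units) reads
directly off the matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class MethylationMatrix:
    """Probes x arrays matrix of log2(bound/input) with a processing stage tag."""

    values: pd.DataFrame
    stage: str  # raw | normalized | individual-averaged

    @property
    def n_probes(self) -> int:
        return len(self.values)

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]


def compute_log_ratios(bound: pd.DataFrame, input_: pd.DataFrame) -> MethylationMatrix:
    """log2(bound/input); missing wherever either channel is missing/non-positive."""
    b = bound.to_numpy(dtype=float)
    i = input_.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where((b > 0) & (i > 0), np.log2(b) - np.log2(i), np.nan)
    return MethylationMatrix(
        pd.DataFrame(values, index=bound.index, columns=bound.columns), "raw"
    )


def quantile_normalize(mm: MethylationMatrix) -> MethylationMatrix:
    """Quantile-normalize columns to their common mean distribution.

    Each column's sorted values are replaced by the across-column mean of
    sorted values; tied values within a column receive the mean of the
    reference values they span.  Missing values stay missing and are
    excluded from rank computation (columns with differing missingness are
    matched on the quantile scale by interpolation).
    """
    X = mm.values.to_numpy(dtype=float)
    n, m = X.shape
    if m < 2:
        raise ValueError("quantile normalization needs at least 2 arrays")
    grid = np.linspace(0.0, 1.0, n)
    ref = np.zeros(n)
    col_sorted: list[np.ndarray] = []
    col_mask: list[np.ndarray] = []
    for j in range(m):
        mask = np.isfinite(X[:, j])
        k = int(mask.sum())
        if k < 2:
            raise ValueError(f"column {j} has fewer than 2 non-missing values")
        v = np.sort(X[mask, j])
        col_sorted.append(v)
        col_mask.append(mask)
        ref += np.interp(grid, np.linspace(0.0, 1.0, k), v)
    ref /= m

    out = np.full_like(X, np.nan)
    for j in range(m):
        mask = col_mask[j]
        k = int(mask.sum())
        # reference distribution at this column's k quantile positions
        target = np.interp(np.linspace(0.0, 1.0, k), grid, ref)
        v = X[mask, j]
        order = np.argsort(v, kind="stable")
        assigned = np.empty(k)
        assigned[order] = target
        # ties: mean of the reference values the tie group spans
        sv = v[order]
        boundaries = np.flatnonzero(np.diff(sv) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [k]])
        for s, e in zip(starts, ends):
            if e - s > 1:
                assigned[order[s:e]] = target[s:e].mean()
        out[mask, j] = assigned
    return MethylationMatrix(
        pd.DataFrame(out, index=mm.values.index, columns=mm.values.columns),
        "normalized",
    )


def ma_qc(
    bound: pd.DataFrame,
    input_: pd.DataFrame,
    median_m_threshold: float = 0.5,
    iqr_m_threshold: float = 2.0,
    slope_threshold: float = 0.2,
    min_median_a: float = 10.0,
) -> pd.DataFrame:
    """Per-array MvA summaries: M = log2(Cy5/Cy3), A = log2(Cy5*Cy3).

    Reports median(M), IQR(M), median(A) and the least-squares slope of M on
    A (the dye-bias trend statistic); arrays beyond the configurable
    thresholds are flagged.
    """
    rows = []
    for array_id in bound.columns:
        b = bound[array_id].to_numpy(dtype=float)
        i = input_[array_id].to_numpy(dtype=float)
        ok = (b > 0) & (i > 0)
        m = np.log2(b[ok]) - np.log2(i[ok])
        a = np.log2(b[ok]) + np.log2(i[ok])
        q1, med_m, q3 = np.percentile(m, [25, 50, 75])
        med_a = float(np.median(a))
        slope = float(np.polyfit(a, m, 1)[0]) if a.std() > 0 else 0.0
        flagged = (
            abs(med_m) > median_m_threshold
            or (q3 - q1) > iqr_m_threshold
            or abs(slope) > slope_threshold
            or med_a < min_median_a
        )
        rows.append((array_id, med_m, q3 - q1, med_a, slope, flagged))
    return pd.DataFrame(
        rows,
        columns=["array_id", "median_M", "iqr_M", "median_A", "slope_MA", "flagged"],
    )


def average_replicates(mm: MethylationMatrix, sheet: pd.DataFrame) -> MethylationMatrix:
    """Average each individual's replicate arrays probe-wise, ignoring missing."""
    cols = {}
    for ind, sub in sheet.groupby("individual_id", sort=False):
        arrays = [a for a in sub["array_id"] if a in mm.values.columns]
        if not arrays:
            raise ValueError(f"individual {ind} has no arrays in the matrix")
        cols[ind] = mm.values[arrays].mean(axis=1, skipna=True)
    out = pd.DataFrame(cols, index=mm.values.index)
    return MethylationMatrix(out, "individual-averaged")


def replicate_variance_explained(
    mm: MethylationMatrix, sheet: pd.DataFrame, top_k: int = 500
) -> float:
    """Mean fraction of probe variance attributable to individuals.

    On the ``top_k`` most variable probes, a one-way variance-component
    decomposition (individuals as groups) estimates the between-individual
    variance sigma_b^2 = (MSB - MSW) / n0 per probe.  Components are pooled
    (averaged) across probes before forming the fraction
    sigma_b^2 / (sigma_b^2 + MSW): clipping negative per-probe estimates
    first would bias the fraction upward when individuals do not differ.
    """
    X = mm.values
    groups = sheet.set_index("array_id").loc[X.columns, "individual_id"]
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ValueError("every individual needs >= 2 replicate arrays")
    if top_k > len(X):
        log.warning("top_k=%d exceeds probe count %d; capped", top_k, len(X))
        top_k = len(X)
    variances = X.var(axis=1, skipna=True)
    top = variances.nlargest(top_k).index
    Xt = X.loc[top]

    k = sizes.size
    n_total = int(sizes.sum())
    n0 = (n_total - (sizes**2).sum() / n_total) / (k - 1)

    grand = Xt.mean(axis=1)
    ssb = pd.Series(0.0, index=top)
    ssw = pd.Series(0.0, index=top)
    for ind, sub in sheet.groupby("individual_id", sort=False):
        cols = [a for a in sub["array_id"] if a in Xt.columns]
        block = Xt[cols]
        mean_i = block.mean(axis=1)
        ssb += len(cols) * (mean_i - grand) ** 2
        ssw += ((block.sub(mean_i, axis=0)) ** 2).sum(axis=1)
    msb = ssb / (k - 1)
    msw = ssw / (n_total - k)
    sigma_b2 = max(float(((msb - msw) / n0).mean()), 0.0)
    within = float(msw.mean())
    if sigma_b2 + within == 0:
        return 1.0
    return sigma_b2 / (sigma_b2 + within)
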