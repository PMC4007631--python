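"""Per-CpG-site validation statistics for targeted methylation assays.

For a site-by-sample percent-methylation table (e.g. bisulfite
pyrosequencing of a candidate region), applies a one-sided t-test per site
in a direction fixed a priori by the discovery screen, BH FDR across the
sites of the region, and the conventional significance tiers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .promoters import bh_fdr

#: FDR tier labels, strongest first
TIERS = [(0.025, "**"), (0.05, "*"), (0.1, "++"), (0.2, "+")]


def site_tests(
    table: pd.DataFrame,
    groups: pd.Series,
    direction: str = "case>control",
    case_label: str = "case",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-site one-sided Welch t-tests with FDR and significance tiers.

    ``table`` is sites x samples (percent methylation in [0, 100]);
    ``groups`` labels each sample column.  ``direction`` is
    "case>control" or "case<control".  Returns per-site t, one-sided p,
    q, tier label and group means with standard errors.
    """
    if direction not in ("case>control", "case<control"):
        raise ValueError("direction must be 'case>control' or 'case<control'")
    values = table.to_numpy(dtype=float)
    if np.nanmin(values) < 0 or np.nanmax(values) > 100:
        raise ValueError("methylation values must lie in [0, 100]")
    labels = groups.loc[table.columns]
    case = table.loc[:, (labels == case_label).to_numpy()]
    ctrl = table.loc[:, (labels != case_label).to_numpy()]
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")

    alternative = "greater" if direction == "case>control" else "less"
    res = stats.ttest_ind(
        case, ctrl, axis=1, equal_var=equal_var, alternative=alternative,
        nan_policy="omit",
    )
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # both groups constant and equal: no evidence either way
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = bh_fdr(p)

    tier = np.full(len(table), "", dtype=object)
    for cut, label in reversed(TIERS):
        tier[q < cut] = label

    out = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "q": q,
            "tier": tier,
            "mean_case": case.mean(axis=1),
            "sem_case": case.sem(axis=1),
            "mean_control": ctrl.mean(axis=1),
            "sem_control": ctrl.sem(axis=1),
        },
        index=table.index,
    )
    out.attrs["direction"] = direction
    return out
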