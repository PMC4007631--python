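"""Per-probe two-group inference with empirical-Bayes variance moderation.

The probe-level statistic is a moderated t: the ordinary two-sample t with
the per-probe sample variance replaced by a posterior variance that shrinks
it toward a prior estimated from all probes.  Writing s2_g for the pooled
residual variance of probe g on d_g degrees of freedom, the hierarchical
model places a scaled inverse-chi-square prior with d0 degrees of freedom
and scale s0^2 on the true variances, giving

    s2_tilde_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)
    t_g = beta_g / sqrt(s2_tilde_g * (1/n1 + 1/n2)),   t_g ~ t(d0 + d_g)

with beta_g the case-minus-control mean difference.  (d0, s0^2) are
estimated by closed-form moments on log s2 using digamma/trigamma (Smyth
2004); d0 = +inf collapses the statistic to a z-score against s0^2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EBayesHyperparams:
    """Prior degrees of freedom (may be +inf) and prior variance."""

    d0: float
    s0_2: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if not self.s0_2 > 0:
            raise ValueError("s0_2 must be > 0")


def fit_group_model(
    matrix: pd.DataFrame, sheet: pd.DataFrame, case_label: str = "case"
) -> pd.DataFrame:
    """Two-group linear model per probe on the individual-averaged matrix.

    Returns a DataFrame indexed by probe_id with beta (case - control mean
    difference), s2 (pooled within-group variance), df, n1, n2.  Probes with
    any group entirely missing are excluded (logged).
    """
    individuals = sheet.drop_duplicates("individual_id")
    groups = individuals.set_index("individual_id")["group"]
    labels = groups.loc[matrix.columns]
    case_cols = matrix.columns[(labels == case_label).to_numpy()]
    ctrl_cols = matrix.columns[(labels != case_label).to_numpy()]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("each group needs at least 2 individuals")
    beta, s2, df, n1, n2 = group_stats(
        matrix.to_numpy(dtype=float),
        np.asarray(matrix.columns.isin(case_cols)),
    )
    out = pd.DataFrame(
        {"beta": beta, "s2": s2, "df": df, "n1": n1, "n2": n2},
        index=matrix.index.rename("probe_id"),
    )
    keep = (out["n1"] >= 2) & (out["n2"] >= 2)
    if (~keep).any():
        log.info("excluded %d probes with a group entirely/nearly missing",
                 int((~keep).sum()))
    return out.loc[keep]


def group_stats(
    values: np.ndarray, case_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized NaN-aware two-group statistics for a probes x samples array."""
    x = values[:, case_mask]
    y = values[:, ~case_mask]
    n1 = np.isfinite(x).sum(axis=1)
    n2 = np.isfinite(y).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = np.nanmean(np.where(np.isfinite(x), x, np.nan), axis=1)
        my = np.nanmean(np.where(np.isfinite(y), y, np.nan), axis=1)
        ssx = np.nansum((x - mx[:, None]) ** 2, axis=1)
        ssy = np.nansum((y - my[:, None]) ** 2, axis=1)
        df = n1 + n2 - 2
        s2 = np.where(df > 0, (ssx + ssy) / np.maximum(df, 1), np.nan)
    return mx - my, s2, df.astype(float), n1, n2


def trigamma_inverse(y: float, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 (monotone decreasing, Newton + bisection)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    lo, hi = 1e-8, 1e8
    for _ in range(max_iter):
        f = float(special.polygamma(1, x)) - y
        if f > 0:
            lo = x
        else:
            hi = x
        fprime = float(special.polygamma(2, x))
        step = f / fprime
        x_new = x - step
        if not lo < x_new < hi:
            x_new = 0.5 * (lo + hi)
        if abs(x_new - x) <= tol * max(x, 1.0):
            return x_new
        x = x_new
    return x


def estimate_eb_hyperparameters(
    s2: np.ndarray, df: np.ndarray | float
) -> EBayesHyperparams:
    """Closed-form moment estimation of (d0, s0^2) on log variances.

    With z = log s2 and e = z - digamma(df/2) + log(df/2), the model implies
    E[e] = log s0^2 + digamma(d0/2) - log(d0/2) and
    Var[e] = trigamma(df/2) + trigamma(d0/2); d0 follows by trigamma
    inversion, falling back to d0 = +inf when the empirical dispersion does
    not exceed the sampling term.  Zero/negative variances are excluded.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if not ok.any():
        raise ValueError("all probe variances are zero; cannot moderate")
    s2, df = s2[ok], df[ok]
    n = s2.size
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1)) if n > 1 else 0.0
    excess = e_var - float(np.mean(special.polygamma(1, df / 2.0)))
    if excess <= 0:
        return EBayesHyperparams(d0=math.inf, s0_2=float(np.exp(e_mean)))
    half_d0 = trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_2 = float(np.exp(e_mean + special.digamma(half_d0) - math.log(half_d0)))
    return EBayesHyperparams(d0=d0, s0_2=s0_2)


def moderated_t(
    beta: np.ndarray,
    s2: np.ndarray,
    df: np.ndarray | float,
    hyper: EBayesHyperparams,
    n1: np.ndarray | float,
    n2: np.ndarray | float,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t statistic and two-sided p-value per probe."""
    beta = np.asarray(beta, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), beta.shape).astype(float)
    n1 = np.broadcast_to(np.asarray(n1, dtype=float), beta.shape)
    n2 = np.broadcast_to(np.asarray(n2, dtype=float), beta.shape)
    c = 1.0 / n1 + 1.0 / n2
    if math.isinf(hyper.d0):
        s2_tilde = np.full_like(beta, hyper.s0_2)
        dof = np.full_like(beta, np.inf)
    else:
        s2_tilde = (hyper.d0 * hyper.s0_2 + df * s2) / (hyper.d0 + df)
        dof = hyper.d0 + df
    zero = s2_tilde <= 0
    if zero.any():
        log.warning("%d probes with zero posterior variance; p set to minimum",
                    int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(s2_tilde * c)
    p = np.where(
        np.isinf(dof),
        2.0 * stats.norm.sf(np.abs(t)),
        2.0 * stats.t.sf(np.abs(t), np.where(np.isinf(dof), 1.0, dof)),
    )
    p = np.where(zero, np.finfo(float).tiny, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    if zero.any():
        t = np.where(zero & (beta != 0), np.sign(beta) * np.inf, t)
    return t, p


def call_probes(
    stats_df: pd.DataFrame, p_cut: float = 0.05, fc_cut: float = 0.25
) -> pd.DataFrame:
    """Probe-level differential call: p < p_cut AND |log2 fold-diff| >= fc_cut."""
    out = stats_df.copy()
    out["called"] = (out["p"] < p_cut) & (out["beta"].abs() >= fc_cut)
    out["direction"] = np.where(out["beta"] > 0, "hyper", "hypo")
    out.attrs["p_cut"] = p_cut
    out.attrs["fc_cut"] = fc_cut
    return out


def probe_statistics(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    p_cut: float = 0.05,
    fc_cut: float = 0.25,
    case_label: str = "case",
) -> tuple[pd.DataFrame, EBayesHyperparams]:
    """Convenience wrapper: fit, moderate, test and call every probe."""
    fit = fit_group_model(matrix, sheet, case_label=case_label)
    hyper = estimate_eb_hyperparameters(fit["s2"].to_numpy(), fit["df"].to_numpy())
    t, p = moderated_t(
        fit["beta"].to_numpy(), fit["s2"].to_numpy(), fit["df"].to_numpy(),
        hyper, fit["n1"].to_numpy(), fit["n2"].to_numpy(),
    )
    fit["t_mod"] = t
    fit["p"] = p
    return call_probes(fit, p_cut=p_cut, fc_cut=fc_cut), hyper
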