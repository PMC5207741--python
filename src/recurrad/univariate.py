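"""Per-feature prognostic analysis for censored recurrence endpoints.

Covers the univariate layer of the pipeline: z-score normalization,
landmark event-status classification at the median event time, Wilcoxon
rank-sum association, Harrell's concordance index with a Noether-type test
against the chance value 0.5, Benjamini-Hochberg FDR correction, and
Spearman cross-correlation between the FB and AIP feature panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "zscore_normalize",
    "event_status_at",
    "wilcoxon_association",
    "concordance_index",
    "ConcordanceResult",
    "noether_pvalue",
    "bh_fdr",
    "spearman_cross",
    "run_univariate",
]


def zscore_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Centre and scale every column to mean 0, sample (ddof=1) SD 1."""
    sd = table.std(ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()]
    if len(constant):
        raise ValueError(f"constant feature(s) cannot be z-scored: {list(constant)}")
    return (table - table.mean()) / sd


def event_status_at(
    clinical: pd.DataFrame, endpoint: str, t: float
) -> pd.Series:
    """Landmark classification at time ``t`` (months).

    ``event`` if the endpoint occurred by ``t``; ``no_event`` if the subject
    was followed event-free beyond ``t``; ``excluded`` if censored before
    ``t`` without an event (their status at ``t`` is unknowable).
    """
    if t <= 0:
        raise ValueError("landmark time must be > 0")
    time = clinical[f"time_{endpoint}"].to_numpy(dtype=float)
    event = clinical[f"event_{endpoint}"].to_numpy(dtype=int)
    if np.any(time < 0):
        raise ValueError("negative follow-up times")
    status = np.where(
        (event == 1) & (time <= t),
        "event",
        np.where(time > t, "no_event", "excluded"),
    )
    return pd.Series(status, index=clinical.index, name=f"status_{endpoint}_at_{t}")


def wilcoxon_association(
    values: np.ndarray, statuses: pd.Series | np.ndarray
) -> tuple[float, float]:
    """Median difference (event - no_event) and two-sided rank-sum p-value.

    The exact null distribution is used for combined group sizes up to 50
    without ties; otherwise the normal approximation with tie correction.
    """
    values = np.asarray(values, dtype=float)
    statuses = np.asarray(statuses)
    ev = values[statuses == "event"]
    ne = values[statuses == "no_event"]
    if len(ev) == 0 or len(ne) == 0:
        return float("nan"), float("nan")
    med_diff = float(np.median(ev) - np.median(ne))
    pooled = np.concatenate([ev, ne])
    exact = len(pooled) <= 50 and len(np.unique(pooled)) == len(pooled)
    res = stats.mannwhitneyu(
        ev, ne, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return med_diff, float(res.pvalue)


@dataclass
class ConcordanceResult:
    """Harrell concordance index plus the pair statistics its test needs."""

    ci: float
    n_comparable: int
    pc: float  # average concordance probability
    pd_: float  # average discordance probability
    pc_i: np.ndarray  # per-subject concordance proportions
    pd_i: np.ndarray


def _pairwise_concordance(x, time, event):
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(x)
    # pair (i, j) is usable iff the subject with the shorter time had an event
    ti, tj = time[:, None], time[None, :]
    ei = event[:, None]
    usable = (ti < tj) & (ei == 1)
    xi, xj = x[:, None], x[None, :]
    conc = usable & (xi > xj)
    disc = usable & (xi < xj)
    tied = usable & (xi == xj)
    # symmetrize so each unordered pair credits both members
    C = conc.astype(float) + 0.5 * tied
    D = disc.astype(float) + 0.5 * tied
    C = C + C.T
    D = D + D.T
    n_usable = int(usable.sum())
    return C, D, n_usable, n


def concordance_index(
    x, time, event, with_pairs: bool = False
) -> float | ConcordanceResult:
    """Harrell-type concordance over comparable pairs.

    A pair is comparable iff the member with the shorter follow-up had an
    event; it is concordant when that member also has the higher feature
    value ("higher value, higher risk"); feature ties count 0.5. Values
    above 0.5 mean the feature is directly proportional to risk.
    """
    C, D, n_usable, n = _pairwise_concordance(x, time, event)
    if n_usable == 0:
        raise ValueError("no usable (comparable) pairs")
    pc_i = C.sum(axis=1) / (n - 1)
    pd_i = D.sum(axis=1) / (n - 1)
    pc = float(pc_i.mean())
    pd_ = float(pd_i.mean())
    ci = pc / (pc + pd_)
    if not with_pairs:
        return float(ci)
    return ConcordanceResult(float(ci), n_usable, pc, pd_, pc_i, pd_i)


def noether_pvalue(result: ConcordanceResult) -> float:
    """Two-sided normal-approximation p-value for H0: CI = 0.5.

    The standard error comes from the asymptotic U-statistic variance of the
    concordance probability estimated from the per-subject concordance and
    discordance proportions.
    """
    n = len(result.pc_i)
    pc, pd_ = result.pc, result.pd_
    var_pc = np.var(result.pc_i, ddof=1)
    var_pd = np.var(result.pd_i, ddof=1)
    cov = np.cov(result.pc_i, result.pd_i, ddof=1)[0, 1]
    denom = (pc + pd_) ** 4
    var_ci = (4.0 / n) * (pd_**2 * var_pc + pc**2 * var_pd - 2 * pc * pd_ * cov) / denom
    if var_ci <= 0:
        return float("nan")
    z = (result.ci - 0.5) / np.sqrt(var_ci)
    return float(2 * stats.norm.sf(abs(z)))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if finite.sum():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def spearman_cross(
    fb_table: pd.DataFrame, aip_table: pd.DataFrame, threshold: float = 0.8
) -> pd.DataFrame:
    """Spearman rho for every FB x AIP feature pair, flagging |rho| > threshold."""
    if len(fb_table) != len(aip_table):
        raise ValueError("FB and AIP tables must cover the same subjects")
    rows = []
    for fa in fb_table.columns:
        a = fb_table[fa].to_numpy(dtype=float)
        for fb in aip_table.columns:
            rho = stats.spearmanr(a, aip_table[fb].to_numpy(dtype=float)).statistic
            rows.append(
                {
                    "fb_feature": fa,
                    "aip_feature": fb,
                    "spearman_rho": float(rho),
                    "strong": bool(abs(rho) > threshold),
                }
            )
    return pd.DataFrame(rows)


def run_univariate(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    endpoint: str,
    landmark: float | str = "auto",
    image_type: str = "",
) -> pd.DataFrame:
    """Full univariate table for one endpoint and image type.

    Features are z-scored; the landmark defaults to the median observed
    event time; FDR correction is applied across the feature family,
    separately for the Wilcoxon and Noether p-value sets.
    """
    z = zscore_normalize(features)
    time = clinical[f"time_{endpoint}"].to_numpy(dtype=float)
    event = clinical[f"event_{endpoint}"].to_numpy(dtype=int)
    if landmark == "auto":
        if event.sum() == 0:
            raise ValueError(f"no events for endpoint {endpoint!r}")
        landmark = float(np.median(time[event == 1]))
    statuses = event_status_at(clinical, endpoint, float(landmark))

    rows = []
    for name in z.columns:
        x = z[name].to_numpy(dtype=float)
        med_diff, wil_p = wilcoxon_association(x, statuses)
        res = concordance_index(x, time, event, with_pairs=True)
        rows.append(
            {
                "feature": name,
                "image_type": image_type,
                "endpoint": endpoint,
                "landmark_months": float(landmark),
                "median_difference": med_diff,
                "wilcoxon_p": wil_p,
                "ci": res.ci,
                "noether_p": noether_pvalue(res),
            }
        )
    out = pd.DataFrame(rows)
    out["wilcoxon_q"] = bh_fdr(out["wilcoxon_p"].to_numpy())
    out["noether_q"] = bh_fdr(out["noether_p"].to_numpy())
    return out
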