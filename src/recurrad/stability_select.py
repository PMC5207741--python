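"""Two-step feature dimension reduction: test-retest stability, then PCA.

Step one scores every feature's reproducibility across a paired re-imaging
study with the one-way random-effects single-measure intraclass correlation
coefficient (ICC) and keeps features with ICC > 0.8. Step two runs PCA on
the standardized stable features, keeps the leading components carrying 95%
of the variance, and selects, for each retained component, the original
feature whose values correlate most strongly (in absolute Pearson r) with
that component's scores; the achieved |r| is reported against the 0.99
benchmark rather than used as a hard gate, which on real spectra can select
nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = ["StabilitySelection", "icc_oneway", "stability_filter", "pca_variance_select"]


@dataclass
class StabilitySelection:
    """Result bundle of the two-step reduction."""

    icc: pd.Series
    stable_set: list[str]
    selected_set: list[str] = field(default_factory=list)
    component_correlations: dict[str, float] = field(default_factory=dict)
    icc_threshold: float = 0.8
    pca_variance_threshold: float = 0.95
    score_correlation_threshold: float = 0.99


def icc_oneway(a: np.ndarray, b: np.ndarray) -> float:
    """One-way random-effects, single-measure ICC for paired scans.

    ``ICC(1,1) = (MSB - MSW) / (MSB + (k-1) MSW)`` with k = 2 scans; can be
    negative when within-subject scatter exceeds between-subject scatter, and
    NaN when the total variance is zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("expected two equal-length 1D measurement vectors")
    n = a.size
    if n < 2:
        raise ValueError("ICC requires at least 2 subjects")
    data = np.column_stack([a, b])
    k = 2
    subj_means = data.mean(axis=1)
    grand = data.mean()
    msb = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    msw = np.sum((data - subj_means[:, None]) ** 2) / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:
        return float("nan")
    return float((msb - msw) / denom)


def stability_filter(
    table_a: pd.DataFrame, table_b: pd.DataFrame, threshold: float = 0.8
) -> StabilitySelection:
    """Keep features whose test-retest ICC strictly exceeds ``threshold``."""
    if set(table_a.columns) != set(table_b.columns):
        only_a = set(table_a.columns) ^ set(table_b.columns)
        raise ValueError(f"features present in only one table: {sorted(only_a)}")
    if len(table_a) != len(table_b):
        raise ValueError("test and retest tables must have the same subjects")
    icc = pd.Series(
        {c: icc_oneway(table_a[c].to_numpy(), table_b[c].to_numpy()) for c in table_a.columns},
        name="icc",
    )
    stable = sorted(icc.index[icc > threshold])
    return StabilitySelection(icc=icc, stable_set=stable, icc_threshold=threshold)


def pca_variance_select(
    stable_table: pd.DataFrame,
    var_threshold: float = 0.95,
    corr_threshold: float = 0.99,
) -> tuple[list[str], dict[str, float]]:
    """Variance-preserving selection of representative original features.

    Returns the selected feature names (duplicates collapsed, deterministic
    with ties broken by canonical name order) and the per-selected-feature
    best |Pearson r| to its component's scores.
    """
    if len(stable_table) < 2:
        raise ValueError("PCA requires at least 2 subjects")
    X = stable_table.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = list(stable_table.columns[sd == 0])
        raise ValueError(f"zero-variance features must be dropped first: {bad}")
    Z = (X - X.mean(axis=0)) / sd

    pca = PCA()
    scores = pca.fit_transform(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    m = int(np.searchsorted(cum, var_threshold) + 1)
    m = min(m, scores.shape[1])

    cols = list(stable_table.columns)
    selected: list[str] = []
    best_r: dict[str, float] = {}
    for c in range(m):
        s = scores[:, c]
        if s.std() == 0:
            continue
        r = np.array(
            [abs(np.corrcoef(Z[:, j], s)[0, 1]) for j in range(Z.shape[1])]
        )
        # deterministic tie-break: highest |r|, then canonical name order
        order = sorted(range(len(cols)), key=lambda j: (-round(r[j], 12), cols[j]))
        j = order[0]
        name = cols[j]
        if name not in selected:
            selected.append(name)
            best_r[name] = float(r[j])
        else:
            best_r[name] = max(best_r[name], float(r[j]))
    return selected, best_r
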