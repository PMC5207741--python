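"""Cross-validated multivariate model comparison between FB and AIP panels.

Five proportional-hazards models predict distant metastasis: a conventional
(volume + max diameter) and a radiomic model per image type, plus a combined
FB+AIP radiomic model. The cohort is split 100 times into stratified 80/20
train/validation sets with matched event ratios; radiomic panels are reduced
to 5 features per split with a lasso Cox path (first-to-enter order); each
model's linear predictor is scored on the held-out fifth with Harrell's
concordance index; and model pairs are compared with a paired sign-flip
permutation test over the shared splits.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .univariate import concordance_index

__all__ = [
    "SuiteConfig",
    "ModelRun",
    "SuiteReport",
    "stratified_splits",
    "lasso_select",
    "fit_and_validate",
    "permutation_compare",
    "run_model_suite",
    "MODEL_TYPES",
    "CONVENTIONAL_FEATURES",
]

MODEL_TYPES = ["FB_conv", "FB_rad", "AIP_conv", "AIP_rad", "COMB_rad"]
CONVENTIONAL_FEATURES = ["Volume", "Max diameter"]


@dataclass
class SuiteConfig:
    endpoint: str = "dm"
    n_splits: int = 100
    train_frac: float = 0.8
    k_radiomic: int = 5
    k_conventional: int = 2
    n_permutation: int = 200
    seed: int = 0


@dataclass
class ModelRun:
    split_id: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    selected: dict[str, list[str]] = field(default_factory=dict)
    val_ci: dict[str, float] = field(default_factory=dict)


@dataclass
class SuiteReport:
    runs: list[ModelRun]
    median_ci: dict[str, float]
    ci_table: pd.DataFrame  # splits x models
    pairwise_p: pd.DataFrame
    selection_counts: dict[str, dict[str, int]]
    n_failed: dict[str, int]
    config: SuiteConfig


def stratified_splits(
    clinical: pd.DataFrame,
    endpoint: str = "dm",
    n_splits: int = 100,
    frac: float = 0.8,
    seed: int = 0,
) -> list[ModelRun]:
    """Repeated stratified 80/20 partitions with matched event ratios.

    Events and non-events are sampled separately, so every validation set
    carries the cohort's event fraction within rounding. Deterministic given
    the seed.
    """
    if not 0 < frac < 1:
        raise ValueError("train fraction must be in (0, 1)")
    event = clinical[f"event_{endpoint}"].to_numpy(dtype=int)
    idx_ev = np.flatnonzero(event == 1)
    idx_ne = np.flatnonzero(event == 0)
    if len(idx_ev) < 2 or len(idx_ne) < 2:
        raise ValueError("each event stratum needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    runs = []
    for s in range(n_splits):
        train_parts, val_parts = [], []
        for stratum in (idx_ev, idx_ne):
            perm = rng.permutation(stratum)
            n_train = int(round(frac * len(stratum)))
            n_train = min(max(n_train, 1), len(stratum) - 1)
            train_parts.append(perm[:n_train])
            val_parts.append(perm[n_train:])
        runs.append(
            ModelRun(
                split_id=s,
                train_idx=np.sort(np.concatenate(train_parts)),
                val_idx=np.sort(np.concatenate(val_parts)),
            )
        )
    return runs


def _standardize(train: pd.DataFrame, other: pd.DataFrame | None = None):
    mu = train.mean()
    sd = train.std(ddof=1).replace(0, np.nan)
    keep = sd.index[sd.notna()]
    zt = (train[keep] - mu[keep]) / sd[keep]
    if other is None:
        return zt
    return zt, (other[keep] - mu[keep]) / sd[keep]


def lasso_select(
    X: pd.DataFrame, time: np.ndarray, event: np.ndarray, k: int = 5
) -> list[str]:
    """First ``k`` features to enter the L1 Cox regularization path.

    The path is solved from the smallest penalty that zeroes every
    coefficient downward over 100 log-spaced values; entry order defines
    selection and ties within one path step break by canonical name. If the
    whole path admits fewer than ``k`` entrants, all entrants are returned.
    """
    if event.sum() == 0:
        raise ValueError("no events in the training data")
    cols = list(X.columns)
    if k >= len(cols):
        return cols
    Z = _standardize(X)
    # collapse duplicated columns (perfect collinearity): keep first by name
    dup_groups: dict[bytes, list[str]] = {}
    for c in Z.columns:
        dup_groups.setdefault(Z[c].round(12).to_numpy().tobytes(), []).append(c)
    keep = sorted(min(sorted(g)) for g in dup_groups.values())
    Z = Z[keep]
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=100, alpha_min_ratio=0.01, max_iter=20000
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Z.to_numpy(), y)
    coefs = model.coef_  # (n_features, n_alphas), alphas descending
    entered: list[str] = []
    for a in range(coefs.shape[1]):
        active = [Z.columns[j] for j in np.flatnonzero(np.abs(coefs[:, a]) > 0)]
        for name in sorted(active):
            if name not in entered:
                entered.append(name)
        if len(entered) >= k:
            break
    return entered[:k]


def fit_and_validate(
    selected: list[str],
    train_X: pd.DataFrame,
    train_time: np.ndarray,
    train_event: np.ndarray,
    val_X: pd.DataFrame,
    val_time: np.ndarray,
    val_event: np.ndarray,
) -> float:
    """Cox fit on training, linear predictor scored on validation by CI."""
    if not selected:
        raise ValueError("no features selected")
    zt, zv = _standardize(train_X[selected], val_X[selected])
    df = zt.copy()
    df["time"] = train_time
    df["event"] = train_event
    cph = CoxPHFitter(penalizer=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    lp = zv[list(zt.columns)].to_numpy() @ cph.params_.to_numpy()
    return float(concordance_index(lp, val_time, val_event))


def permutation_compare(
    ci_a: np.ndarray, ci_b: np.ndarray, n_iter: int = 200, seed: int = 0
) -> float:
    """Paired sign-flip permutation p-value for mean CI difference.

    The observed statistic is the mean per-split difference; the null is
    built by randomly swapping the two models' labels within each split.
    """
    a = np.asarray(ci_a, dtype=float)
    b = np.asarray(ci_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("CI vectors must be paired (equal length)")
    d = a - b
    obs = abs(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_iter, len(d)))
    null = np.abs((signs * d).mean(axis=1))
    return float((1 + np.sum(null >= obs - 1e-15)) / (n_iter + 1))


def _model_candidates(
    fb: pd.DataFrame, aip: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    conv = [c for c in CONVENTIONAL_FEATURES if c in fb.columns]
    fb_rad = [c for c in fb.columns if c not in CONVENTIONAL_FEATURES]
    aip_rad = [c for c in aip.columns if c not in CONVENTIONAL_FEATURES]
    comb = pd.concat(
        [fb[fb_rad].add_prefix("FB "), aip[aip_rad].add_prefix("AIP ")], axis=1
    )
    return {
        "FB_conv": fb[conv],
        "FB_rad": fb[fb_rad],
        "AIP_conv": aip[conv],
        "AIP_rad": aip[aip_rad],
        "COMB_rad": comb,
    }


def run_model_suite(
    fb: pd.DataFrame,
    aip: pd.DataFrame,
    clinical: pd.DataFrame,
    config: SuiteConfig | None = None,
) -> SuiteReport:
    """Run all five models on shared stratified splits and compare them.

    Non-convergent or degenerate splits are flagged per model, excluded from
    summaries and counted in ``n_failed`` — never imputed. Deterministic
    given the config seed.
    """
    config = config or SuiteConfig()
    if not (len(fb) == len(aip) == len(clinical)):
        raise ValueError("FB, AIP and clinical tables must cover the same subjects")
    time = clinical[f"time_{config.endpoint}"].to_numpy(dtype=float)
    event = clinical[f"event_{config.endpoint}"].to_numpy(dtype=int)
    candidates = _model_candidates(fb.reset_index(drop=True), aip.reset_index(drop=True))
    runs = stratified_splits(
        clinical, config.endpoint, config.n_splits, config.train_frac, config.seed
    )

    n_failed = dict.fromkeys(MODEL_TYPES, 0)
    sel_counts: dict[str, Counter] = {m: Counter() for m in MODEL_TYPES}
    for run in runs:
        tr, va = run.train_idx, run.val_idx
        for m in MODEL_TYPES:
            X = candidates[m]
            k = config.k_conventional if m.endswith("conv") else config.k_radiomic
            try:
                sel = lasso_select(X.iloc[tr], time[tr], event[tr], k=k)
                ci = fit_and_validate(
                    sel, X.iloc[tr], time[tr], event[tr], X.iloc[va], time[va], event[va]
                )
            except (ConvergenceError, ValueError, ArithmeticError):
                n_failed[m] += 1
                continue
            run.selected[m] = sel
            run.val_ci[m] = ci
            sel_counts[m].update(sel)

    ci_table = pd.DataFrame(
        {m: [r.val_ci.get(m, np.nan) for r in runs] for m in MODEL_TYPES}
    )
    median_ci = {m: float(np.nanmedian(ci_table[m])) for m in MODEL_TYPES}

    pair_rng = np.random.default_rng(config.seed + 1)
    pairwise = pd.DataFrame(np.nan, index=MODEL_TYPES, columns=MODEL_TYPES)
    for i, a in enumerate(MODEL_TYPES):
        for b in MODEL_TYPES[i + 1 :]:
            ok = ci_table[[a, b]].dropna()
            if len(ok) < 2:
                continue
            p = permutation_compare(
                ok[a].to_numpy(),
                ok[b].to_numpy(),
                n_iter=config.n_permutation,
                seed=int(pair_rng.integers(2**31)),
            )
            pairwise.loc[a, b] = pairwise.loc[b, a] = p

    return SuiteReport(
        runs=runs,
        median_ci=median_ci,
        ci_table=ci_table,
        pairwise_p=pairwise,
        selection_counts={m: dict(sel_counts[m]) for m in MODEL_TYPES},
        n_failed=n_failed,
        config=config,
    )
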