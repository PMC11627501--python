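"""Repeated correlation-screening feature selection.

Stage one of the age model: per repetition, subjects are partitioned into
ten folds, nine folds form the screening/training set and one fold is
held out; every feature is correlated with age on the training set and
those with two-sided p < alpha (default 0.01) survive.  A linear model
fit on the surviving features gives the repetition's held-out MAE.  After
(default) 100 repetitions two reductions are available: the *common* set
(features surviving every repetition) and the *min-MAE* set (the
selection of the repetition with the smallest held-out MAE).  A top-K
variant (largest |r| on the full sample) supports equal-feature-count
comparisons between species.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import get_logger
from .model import fit_linear_model, evaluate

log = get_logger("xbrainage.selection")


def pearson_r_p(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p (t transform, n-2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def columnwise_r_p(features: pd.DataFrame, ages) -> tuple[pd.Series, pd.Series]:
    """Vectorized Pearson r and two-sided p of every column against age.

    Constant columns get r = p = NaN (and a warning) rather than an error,
    so screening can skip them.
    """
    X = features.to_numpy(float)
    y = np.asarray(ages, float)
    n = len(y)
    if n < 3:
        raise ValueError("need n >= 3")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    if sy == 0:
        raise ValueError("constant ages")
    constant = sx == 0
    if constant.any():
        log.warning("constant feature column(s) skipped: %s",
                    sorted(features.columns[constant])[:5])
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    r = np.where(constant, np.nan, r)
    p = np.where(constant, np.nan, p)
    return (pd.Series(r, index=features.columns, name="r"),
            pd.Series(p, index=features.columns, name="p"))


def screen_once(features: pd.DataFrame, ages, alpha: float = 0.01) -> list[str]:
    """Features whose two-sided p against age is strictly below alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    _, p = columnwise_r_p(features, ages)
    return list(features.columns[(p < alpha).to_numpy() & p.notna().to_numpy()])


@dataclass
class ScreeningRecord:
    repetition: int
    train_subjects: list = field(repr=False)
    test_subjects: list = field(repr=False)
    r: pd.Series = field(repr=False)
    p: pd.Series = field(repr=False)
    selected: list[str] = field(repr=False)
    test_mae: float = np.nan


@dataclass
class SelectionResult:
    records: list[ScreeningRecord] = field(repr=False)
    common_set: list[str] = field(default_factory=list)
    min_mae_set: list[str] = field(default_factory=list)
    min_mae_repetition: int = -1
    alpha: float = 0.01

    @property
    def n_common(self) -> int:
        return len(self.common_set)

    @property
    def n_min_mae(self) -> int:
        return len(self.min_mae_set)

    def selected_for(self, criterion: str, features=None, ages=None,
                     k: int = 62) -> list[str]:
        if criterion == "common":
            return self.common_set
        if criterion == "min_mae":
            return self.min_mae_set
        if criterion == "top_k":
            if features is None or ages is None:
                raise ValueError("top_k needs features and ages")
            return top_k_features(features, ages, k)
        raise ValueError(f"unknown criterion {criterion!r}")

    def to_json(self, path) -> None:
        payload = {
            "alpha": self.alpha,
            "common_set": self.common_set,
            "min_mae_set": self.min_mae_set,
            "min_mae_repetition": self.min_mae_repetition,
            "repetitions": [
                {"repetition": rec.repetition,
                 "n_selected": len(rec.selected),
                 "selected": rec.selected,
                 "test_mae": None if np.isnan(rec.test_mae)
                 else float(rec.test_mae)}
                for rec in self.records],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def repeated_screening(features: pd.DataFrame, ages: pd.Series,
                       n_reps: int = 100, n_folds: int = 10,
                       alpha: float = 0.01,
                       seed: int | np.random.Generator = 0) -> SelectionResult:
    """Run the screening n_reps times on fresh 9/10 train splits.

    Each repetition draws one random fold partition, holds one fold out,
    screens on the remaining nine-tenths, fits the linear model on the
    screened features and records the held-out MAE.  The common set is
    the intersection across all repetitions; empty selections are
    recorded but excluded from the min-MAE competition.
    """
    n = len(features)
    if n < n_folds:
        raise ValueError(f"n={n} smaller than n_folds={n_folds}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ages = ages.loc[features.index]
    records = []
    common: set[str] | None = None
    for rep in range(n_reps):
        perm = rng.permutation(n)
        test_idx = np.sort(perm[: n // n_folds])
        mask = np.zeros(n, bool)
        mask[test_idx] = True
        train = features.index[~mask]
        test = features.index[mask]
        r, p = columnwise_r_p(features.loc[train], ages.loc[train])
        selected = list(features.columns[(p < alpha).to_numpy()
                                         & p.notna().to_numpy()])
        if selected:
            m = fit_linear_model(features.loc[train], ages.loc[train],
                                 selected)
            pred = m.predict(features.loc[test])
            mae = float(np.abs(ages.loc[test].to_numpy()
                               - pred.to_numpy()).mean())
        else:
            log.warning("repetition %d selected no features", rep)
            mae = np.nan
        records.append(ScreeningRecord(rep, list(train), list(test),
                                       r, p, selected, mae))
        sel = set(selected)
        common = sel if common is None else (common & sel)
    result = SelectionResult(records=records, alpha=alpha)
    ordered = [f for f in features.columns if f in (common or set())]
    result.common_set = ordered
    maes = np.array([rec.test_mae for rec in records])
    if np.isfinite(maes).any():
        best = int(np.nanargmin(maes))
        result.min_mae_repetition = best
        result.min_mae_set = records[best].selected
    else:
        log.warning("every repetition had an empty selection")
    return result


def top_k_features(features: pd.DataFrame, ages, k: int) -> list[str]:
    """The k features with largest |r| against age; ties broken by schema order."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > features.shape[1]:
        raise ValueError(f"k={k} exceeds {features.shape[1]} features")
    r, _ = columnwise_r_p(features, ages)
    absr = r.abs().fillna(-np.inf)
    # stable sort keeps schema (column) order among ties
    order = np.argsort(-absr.to_numpy(), kind="stable")[:k]
    chosen = set(features.columns[order])
    return [f for f in features.columns if f in chosen]
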