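"""Brain-age gap and the brain cross-species age gap (BCAP).

The absolute brain-age gap |Δ| = |actual − predicted| measures how far a
prediction misses; its correlation with actual age describes how the
miss scales over development (a model transferred across species
typically over- or under-shoots systematically, producing strong
gap–age trends of opposite sign in the two directions of transfer).

BCAP is a per-human-subject rank statistic: the percentile of the
subject's own-species (human-model) predicted age minus the percentile
of their macaque-model predicted age, both percentiles taken across the
human cohort.  It depends only on the ranks of the two prediction
vectors, so any strictly monotone recalibration of either model leaves
it unchanged.  Percentiles use the mean-rank tie convention
100·(c_lt + 0.5·c_eq)/n, which makes the mean percentile exactly 50 and
the mean BCAP exactly 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import get_logger
from .model import evaluate

log = get_logger("xbrainage.bcap")


def brain_age_gap(actual, predicted) -> np.ndarray:
    """Elementwise |actual − predicted| (years)."""
    a = np.asarray(actual, float)
    b = np.asarray(predicted, float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    return np.abs(a - b)


def gap_age_correlation(gaps, ages) -> tuple[float, float]:
    """Pearson r (two-sided p) between |Δ| and actual age; NaN if |Δ| constant."""
    r, p, _ = evaluate(ages, gaps)   # same guarded Pearson path
    return r, p


def percentile_rank(values) -> np.ndarray:
    """Mean-rank percentiles: 100·(c_lt + 0.5·c_eq)/n per value.

    Equals 100·(average_rank − 0.5)/n, so the output mean is exactly 50
    for any input, ties included.
    """
    v = np.asarray(values, float)
    if v.ndim != 1 or len(v) == 0:
        raise ValueError("need a non-empty 1-d vector")
    if not np.isfinite(v).all():
        raise ValueError("non-finite values")
    ranks = stats.rankdata(v, method="average")
    return 100.0 * (ranks - 0.5) / len(v)


def bcap(pred_own: pd.Series, pred_foreign: pd.Series) -> pd.DataFrame:
    """Percentile-gap table for one cohort.

    Both vectors must cover the same subjects.  Returns a table with the
    two predictions, their percentile ranks and ``bcap`` =
    pct(own) − pct(foreign); mean BCAP is exactly 0.
    """
    pred_own = pd.Series(pred_own)
    pred_foreign = pd.Series(pred_foreign)
    if not pred_own.index.equals(pred_foreign.index):
        if set(pred_own.index) != set(pred_foreign.index):
            raise ValueError("subject mismatch between prediction vectors")
        pred_foreign = pred_foreign.loc[pred_own.index]
    pct_own = percentile_rank(pred_own.to_numpy())
    pct_foreign = percentile_rank(pred_foreign.to_numpy())
    return pd.DataFrame({
        "p_own": pred_own.to_numpy(),
        "p_foreign": pred_foreign.to_numpy(),
        "pct_own": pct_own,
        "pct_foreign": pct_foreign,
        "bcap": pct_own - pct_foreign,
    }, index=pred_own.index)
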