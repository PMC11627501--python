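"""Cross-species feature classification and BCAP association analyses.

Selected feature sets from the two species are partitioned into common,
human-specific and macaque-specific classes, summarised per measure
(GMV/FA/MD/AD/RD).  BCAP is related to behavioral phenotypes and to the
structural features themselves by Pearson partial correlation with
chronological age as covariate (an age-adjusted Pearson correlation IS a
partial correlation), with Benjamini–Hochberg FDR control; behavioral
tables may have missing entries, handled pairwise-complete with the
degrees of freedom adjusted per test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import get_logger
from .schema import FeatureSchema, MEASURES

log = get_logger("xbrainage.association")


@dataclass
class FeatureClassification:
    common: list[str]
    human_specific: list[str]
    macaque_specific: list[str]
    per_measure_percent: pd.DataFrame = field(repr=False, default=None)


def classify_features(human_set, macaque_set,
                      schema: FeatureSchema | None = None,
                      within: str = "measure") -> FeatureClassification:
    """Partition the two species' selections into common/specific classes.

    Percentages are computed within each measure over the union of
    selected features of that measure (``within="measure"``, the
    default), or within each class over its own size (``within="class"``).
    """
    h, m = set(human_set), set(macaque_set)
    common = sorted(h & m)
    human_only = sorted(h - m)
    macaque_only = sorted(m - h)
    fc = FeatureClassification(common=common, human_specific=human_only,
                               macaque_specific=macaque_only)
    if schema is not None:
        rows = {}
        classes = {"common": common, "human_specific": human_only,
                   "macaque_specific": macaque_only}
        for measure in MEASURES:
            names = set(schema.names_for_measure(measure))
            counts = {cls: len(names & set(feats))
                      for cls, feats in classes.items()}
            total = sum(counts.values())
            if within == "measure":
                rows[measure] = {cls: (100.0 * c / total if total else 0.0)
                                 for cls, c in counts.items()}
            else:
                rows[measure] = {cls: (100.0 * c / len(classes[cls])
                                       if classes[cls] else 0.0)
                                 for cls, c in counts.items()}
        fc.per_measure_percent = pd.DataFrame(rows).T
    return fc


def top_features(features: pd.DataFrame, ages, feature_set,
                 schema: FeatureSchema, compartment: str,
                 n: int = 5) -> pd.DataFrame:
    """Rank a compartment's selected features by |r| with age.

    Returns up to n rows with signed r, strongest first; ties broken by
    schema order.  An empty compartment subset yields an empty frame with
    a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = [f for f in schema.names_for_compartment(compartment)
             if f in set(feature_set)]
    if not names:
        log.warning("no selected features in compartment %r", compartment)
        return pd.DataFrame(columns=["feature", "r"]).set_index("feature")
    from .selection import columnwise_r_p
    r, _ = columnwise_r_p(features[names], ages)
    order = np.argsort(-r.abs().to_numpy(), kind="stable")[:n]
    return pd.DataFrame({"r": r.iloc[order]})


def partial_correlation(x, y, covariates=None) -> tuple[float, float, int]:
    """Pearson partial correlation of x and y given covariates.

    Rows with any missing value among x, y and the covariates are dropped
    (pairwise-complete).  Residualizes both variables on [1, covariates]
    by least squares and correlates the residuals; p is two-sided from
    the t transform with n − k − 2 degrees of freedom.  Returns
    (r, p, n_used).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if covariates is None:
        C = np.empty((len(x), 0))
    else:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
    if not (len(x) == len(y) == len(C)):
        raise ValueError("length mismatch")
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(C).all(axis=1)
    x, y, C = x[keep], y[keep], C[keep]
    n = len(x)
    k = C.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    design = np.hstack([np.ones((n, 1)), C])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    sx, sy = np.sqrt((rx ** 2).sum()), np.sqrt((ry ** 2).sum())
    # residuals numerically zero relative to the variables' own spread
    tol_x = 1e-8 * max(np.linalg.norm(x - x.mean()), 1e-300)
    tol_y = 1e-8 * max(np.linalg.norm(y - y.mean()), 1e-300)
    if sx <= tol_x or sy <= tol_y:
        raise ValueError("zero residual variance: variable collinear "
                         "with the covariates")
    r = float(np.clip((rx * ry).sum() / (sx * sy), -1.0, 1.0))
    df = n - k - 2
    if abs(r) >= 1.0:
        return r, 0.0, n
    t = r * np.sqrt(df / (1 - r ** 2))
    p = float(2 * stats.t.sf(abs(t), df=df))
    return r, p, n


def fdr_bh(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg adjusted q-values and significance flags.

    NaN entries are excluded from the family and returned as NaN/False.
    """
    p = np.asarray(pvalues, float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    adj = np.full(p.shape, np.nan)
    flags = np.zeros(p.shape, bool)
    if finite.any():
        rej, padj, *_ = multipletests(p[finite], alpha=q, method="fdr_bh")
        adj[finite] = padj
        flags[finite] = padj < q
    return adj, flags


def _association_table(target: pd.Series, table: pd.DataFrame,
                       ages: pd.Series, q: float,
                       min_complete: int = 10) -> pd.DataFrame:
    rows = []
    for col in table.columns:
        y = table[col].to_numpy(float)
        complete = np.isfinite(y) & np.isfinite(target.to_numpy(float))
        if complete.sum() < min_complete:
            log.warning("variable %r has <%d complete pairs; skipped",
                        col, min_complete)
            rows.append((col, int(complete.sum()), np.nan, np.nan))
            continue
        r, p, n = partial_correlation(target.to_numpy(), y,
                                      ages.to_numpy())
        rows.append((col, n, r, p))
    out = pd.DataFrame(rows, columns=["variable", "n", "partial_r", "p"]
                       ).set_index("variable")
    adj, flags = fdr_bh(out["p"].to_numpy(), q=q)
    out["q"] = adj
    out["significant"] = flags
    return out


def bcap_behavior_associations(bcap_values: pd.Series,
                               behaviors: pd.DataFrame, ages: pd.Series,
                               q: float = 0.05,
                               min_complete: int = 10) -> pd.DataFrame:
    """Age-adjusted partial correlation of BCAP with each behavior.

    One FDR family across all behaviors; missing behavior entries handled
    pairwise-complete; behaviors with fewer than ``min_complete`` complete
    pairs are skipped (NaN row).
    """
    behaviors = behaviors.loc[bcap_values.index]
    ages = ages.loc[bcap_values.index]
    return _association_table(bcap_values, behaviors, ages, q, min_complete)


def bcap_feature_associations(bcap_values: pd.Series,
                              features: pd.DataFrame, ages: pd.Series,
                              schema: FeatureSchema,
                              q: float = 0.05) -> pd.DataFrame:
    """Age-adjusted partial correlation of BCAP with every structural feature.

    FDR is controlled separately per measure family (GMV, FA, MD, AD, RD).
    """
    features = features.loc[bcap_values.index]
    ages = ages.loc[bcap_values.index]
    pieces = []
    for measure in MEASURES:
        cols = [c for c in schema.names_for_measure(measure)
                if c in features.columns]
        if not cols:
            continue
        t = _association_table(bcap_values, features[cols], ages, q,
                               min_complete=3)
        t.insert(0, "measure", measure)
        pieces.append(t)
    return pd.concat(pieces)


def ranked_significant(assoc: pd.DataFrame, measure: str,
                       n_top: int = 3, n_bottom: int = 3) -> pd.DataFrame:
    """Top/bottom significant BCAP correlates within one measure (Fig-style)."""
    sub = assoc[(assoc["measure"] == measure) & assoc["significant"]]
    sub = sub.sort_values("partial_r", ascending=False)
    return pd.concat([sub.head(n_top), sub.tail(n_bottom)]).drop_duplicates()
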