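"""Empirical-Bayes batch harmonization (ComBat-style) for feature tables.

Removes additive and multiplicative scanner/site effects from a
subjects x features table while preserving specified biological
covariates.  This is the standard parametric location/scale model: each
feature is standardized by its covariate fit and pooled variance, batch
location (gamma) and scale (delta^2) are estimated per (batch, feature),
shrunk across features with normal / inverse-gamma priors whose
hyperparameters come from method-of-moments, and the data are rebuilt
with the shrunken effects removed and covariate effects restored.

With a single batch there is nothing to remove and fit/apply are the
identity.  Setting ``eb=False`` disables shrinkage, which reduces the
method to exact per-batch location/scale standardization — useful as an
oracle for the EB variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import get_logger

log = get_logger("xbrainage.harmonize")


class HarmonizationError(ValueError):
    pass


@dataclass
class CombatModel:
    batches: list[str]
    covariate_names: list[str]
    feature_names: list[str]
    # per-subject assignments seen at fit time (index-aligned)
    batch_assignment: pd.Series = field(repr=False)
    covariate_design: pd.DataFrame = field(repr=False)
    # per-feature grand parameters
    stand_mean: np.ndarray = field(repr=False, default=None)
    beta_cov: np.ndarray = field(repr=False, default=None)   # k x p
    pooled_sd: np.ndarray = field(repr=False, default=None)
    # per-(batch, feature) shrunken effects
    gamma_star: pd.DataFrame = field(repr=False, default=None)
    delta_star_sq: pd.DataFrame = field(repr=False, default=None)
    identity: bool = False
    eb: bool = True


def _covariate_design(covariates: pd.DataFrame | None,
                      index: pd.Index) -> pd.DataFrame:
    if covariates is None or covariates.shape[1] == 0:
        return pd.DataFrame(index=index)
    cov = covariates.loc[index]
    num = pd.get_dummies(cov, drop_first=True).astype(float)
    return num


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_solve(z: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
              g_bar: float, tau2: float, a: float, b: float,
              tol: float = 1e-10, max_iter: int = 500):
    """Iterate the EB conditional posteriors for one batch.

    z: n_i x p standardized data of the batch; returns (gamma*, delta*^2).
    """
    n = z.shape[0]
    g_new, d_new = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_old, d_old = g_new, d_new
        g_new = (n * tau2 * g_hat + d_new * g_bar) / (n * tau2 + d_new)
        sse = ((z - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sse + b) / (n / 2 + a - 1)
        change = max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max())
        if change < tol:
            break
    return g_new, d_new


def combat_fit(features: pd.DataFrame, batch: pd.Series,
               covariates: pd.DataFrame | None = None,
               eb: bool = True) -> CombatModel:
    """Estimate the ComBat model on a subjects x features table.

    ``batch`` is index-aligned with ``features``; ``covariates`` (e.g. sex)
    are preserved, never removed.  Raises on batches with fewer than two
    subjects and on zero-variance features (named in the message).
    """
    batch = batch.loc[features.index].astype(str)
    levels = sorted(batch.unique())
    counts = batch.value_counts()
    small = sorted(counts.index[counts < 2])
    if small:
        raise HarmonizationError(f"batch(es) with <2 subjects: {small}")
    zero_var = sorted(features.columns[features.std(ddof=1) == 0])
    if zero_var:
        raise HarmonizationError(f"zero-variance feature(s): {zero_var}")
    cov = _covariate_design(covariates, features.index)
    model = CombatModel(batches=levels, covariate_names=list(cov.columns),
                        feature_names=list(features.columns),
                        batch_assignment=batch, covariate_design=cov, eb=eb)
    if len(levels) < 2:
        model.identity = True
        return model

    Y = features.to_numpy(float)
    n, p = Y.shape
    B = pd.get_dummies(batch).loc[:, levels].to_numpy(float)   # n x nb
    C = cov.to_numpy(float) if cov.shape[1] else np.empty((n, 0))
    X = np.hstack([B, C])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    gamma_hat_ols = beta[:len(levels), :]                      # nb x p
    beta_cov = beta[len(levels):, :]                           # k x p
    frac = (B.sum(axis=0) / n)[None, :]                        # 1 x nb
    stand_mean = (frac @ gamma_hat_ols).ravel()                # p
    resid = Y - X @ beta
    pooled_var = (resid ** 2).mean(axis=0)
    bad = pooled_var <= 0
    if bad.any():
        raise HarmonizationError(
            f"zero residual variance feature(s): "
            f"{sorted(np.array(model.feature_names)[bad])}")
    pooled_sd = np.sqrt(pooled_var)

    fitted_cov = C @ beta_cov
    Z = (Y - stand_mean[None, :] - fitted_cov) / pooled_sd[None, :]

    gamma_star = np.empty((len(levels), p))
    delta_star = np.empty((len(levels), p))
    for i, lev in enumerate(levels):
        zi = Z[(batch == lev).to_numpy()]
        g_hat = zi.mean(axis=0)
        d_hat = zi.var(axis=0, ddof=1)
        if eb:
            g_bar, tau2 = g_hat.mean(), g_hat.var(ddof=1)
            a, b = _aprior(d_hat), _bprior(d_hat)
            if tau2 <= 0 or not np.isfinite(a) or not np.isfinite(b):
                log.warning("degenerate EB hyperpriors for batch %s; "
                            "falling back to unshrunken estimates", lev)
                gamma_star[i], delta_star[i] = g_hat, d_hat
            else:
                gamma_star[i], delta_star[i] = _it_solve(
                    zi, g_hat, d_hat, g_bar, tau2, a, b)
        else:
            gamma_star[i], delta_star[i] = g_hat, d_hat
    model.stand_mean = stand_mean
    model.beta_cov = beta_cov
    model.pooled_sd = pooled_sd
    model.gamma_star = pd.DataFrame(gamma_star, index=levels,
                                    columns=model.feature_names)
    model.delta_star_sq = pd.DataFrame(delta_star, index=levels,
                                       columns=model.feature_names)
    return model


def combat_apply(model: CombatModel, features: pd.DataFrame) -> pd.DataFrame:
    """Return the batch-adjusted table for subjects known to the model."""
    missing = features.index.difference(model.batch_assignment.index)
    if len(missing):
        raise HarmonizationError(
            f"subjects unseen at fit time: {sorted(missing)[:5]}")
    if model.identity:
        return features.copy()
    if list(features.columns) != model.feature_names:
        raise HarmonizationError("feature columns differ from the fit")
    batch = model.batch_assignment.loc[features.index]
    unseen = set(batch) - set(model.batches)
    if unseen:
        raise HarmonizationError(f"unseen batch label(s): {sorted(unseen)}")
    Y = features.to_numpy(float)
    C = model.covariate_design.loc[features.index].to_numpy(float) \
        if model.covariate_design.shape[1] else np.empty((len(features), 0))
    fitted_cov = C @ model.beta_cov
    Z = (Y - model.stand_mean[None, :] - fitted_cov) / model.pooled_sd[None, :]
    g = model.gamma_star.loc[batch].to_numpy()
    d = np.sqrt(model.delta_star_sq.loc[batch].to_numpy())
    Z_adj = (Z - g) / d
    out = Z_adj * model.pooled_sd[None, :] + model.stand_mean[None, :] + fitted_cov
    return pd.DataFrame(out, index=features.index, columns=features.columns)


def harmonize_features(features: pd.DataFrame, batch: pd.Series,
                       covariates: pd.DataFrame | None = None,
                       eb: bool = True) -> pd.DataFrame:
    """Fit-and-apply convenience wrapper."""
    return combat_apply(combat_fit(features, batch, covariates, eb=eb),
                        features)


def harmonize_by_measure(features: pd.DataFrame, batch: pd.Series, schema,
                         covariates: pd.DataFrame | None = None,
                         eb: bool = True) -> pd.DataFrame:
    """Harmonize each measure family (GMV, FA, MD, AD, RD) separately.

    Mirrors running the adjustment per imaging index: EB priors then pool
    only across features of the same measure.
    """
    out = features.copy()
    from .schema import MEASURES
    for measure in MEASURES:
        cols = [c for c in schema.names_for_measure(measure)
                if c in features.columns]
        if cols:
            out[cols] = harmonize_features(features[cols], batch,
                                           covariates, eb=eb)
    return out
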