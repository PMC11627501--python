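"""Linear age-prediction models and their within/cross-species evaluation.

The model is ordinary least squares of chronological age on z-scored
structural features, fit either inside a repeated ten-fold
cross-validation loop (within-species performance) or on the full
own-species sample (the transferable model).  Cross-species application
standardizes the foreign table with the foreign species' own statistics,
so the model reads *relative* feature patterns: gross scale differences
between species (absolute volumes, diffusivity units) never enter.

Rank-deficient designs (duplicated features, p > n) are solved by the
minimum-norm least-squares solution and logged, never rejected: in the
interpolation regime predictions stay finite and well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import get_logger

log = get_logger("xbrainage.model")


def standardize(features: pd.DataFrame,
                stats_: tuple[pd.Series, pd.Series] | None = None
                ) -> tuple[pd.DataFrame, tuple[pd.Series, pd.Series]]:
    """Column-wise z-scoring; returns (z, (mean, sd)).

    With ``stats_`` given, applies those statistics (e.g. training-fold
    statistics to a held-out fold); otherwise computes fresh statistics
    from the input, raising on zero-SD columns.
    """
    if stats_ is None:
        mean = features.mean()
        sd = features.std(ddof=1)
        zero = sorted(sd.index[sd == 0])
        if zero:
            raise ValueError(f"zero-SD feature column(s): {zero}")
        stats_ = (mean, sd)
    mean, sd = stats_
    z = (features - mean) / sd
    return z, stats_


@dataclass
class TrainedAgeModel:
    """OLS age model in standardized feature space."""

    species: str
    features: list[str]
    mean: pd.Series = field(repr=False)
    sd: pd.Series = field(repr=False)
    coef: np.ndarray = field(repr=False)    # years per feature-SD
    intercept: float
    rank: int = 0
    n_train: int = 0

    def predict_standardized(self, z: pd.DataFrame) -> pd.Series:
        z = z[self.features]
        return pd.Series(z.to_numpy() @ self.coef + self.intercept,
                         index=z.index, name="predicted_age")

    def predict(self, features: pd.DataFrame) -> pd.Series:
        """Predict using the model's own (training-species) statistics."""
        z, _ = standardize(features[self.features], (self.mean, self.sd))
        return self.predict_standardized(z)

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "features": self.features,
            "mean": self.mean.to_dict(),
            "sd": self.sd.to_dict(),
            "coef": dict(zip(self.features, map(float, self.coef))),
            "intercept": float(self.intercept),
            "rank": int(self.rank),
            "n_train": int(self.n_train),
        }


def fit_linear_model(features: pd.DataFrame, ages: pd.Series,
                     feature_set, species: str = "unknown") -> TrainedAgeModel:
    """OLS (minimum-norm) of age on z-scored selected features."""
    feature_set = list(feature_set)
    if not feature_set:
        raise ValueError("empty feature set")
    if len(features) < 2:
        raise ValueError("need at least two subjects to fit")
    X = features[feature_set]
    z, (mean, sd) = standardize(X)
    design = np.hstack([np.ones((len(z), 1)), z.to_numpy()])
    y = ages.loc[features.index].to_numpy(float)
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        log.warning("rank-deficient design (rank %d < %d); using the "
                    "minimum-norm solution", rank, design.shape[1])
    return TrainedAgeModel(species=species, features=feature_set,
                           mean=mean, sd=sd, coef=beta[1:],
                           intercept=float(beta[0]), rank=int(rank),
                           n_train=len(z))


def fit_full_model(features: pd.DataFrame, ages: pd.Series, feature_set,
                   species: str = "unknown") -> TrainedAgeModel:
    """The transferable model: a plain OLS fit on the full own-species sample."""
    return fit_linear_model(features, ages, feature_set, species=species)


@dataclass
class PredictionResult:
    actual: pd.Series = field(repr=False)
    predicted: pd.Series = field(repr=False)          # mean over repetitions
    per_repetition: pd.DataFrame = field(repr=False)  # n_reps x n_subjects
    r: float = np.nan
    p: float = np.nan
    mae: float = np.nan
    provenance: dict = field(default_factory=dict)


def evaluate(actual, predicted) -> tuple[float, float, float]:
    """(Pearson R, two-sided p, MAE in years) of predicted vs actual age.

    Constant predictions leave R/p undefined (NaN) but still yield MAE.
    """
    a = np.asarray(actual, float)
    b = np.asarray(predicted, float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if len(a) < 3:
        raise ValueError("need n >= 3")
    mae = float(np.abs(a - b).mean())
    if np.std(b) == 0 or np.std(a) == 0:
        log.warning("constant vector: correlation undefined")
        return np.nan, np.nan, mae
    r, p = stats.pearsonr(a, b)
    return float(r), float(p), mae


def _fold_ids(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """A random partition into n_folds near-equal folds; returns fold id per index."""
    perm = rng.permutation(n)
    ids = np.empty(n, int)
    for f, chunk in enumerate(np.array_split(perm, n_folds)):
        ids[chunk] = f
    return ids


def cv_predict(features: pd.DataFrame, ages: pd.Series, feature_set,
               n_folds: int = 10, n_reps: int = 100,
               seed: int | np.random.Generator = 0,
               species: str = "unknown") -> PredictionResult:
    """Repeated k-fold cross-validated age prediction.

    Per repetition a fresh random fold partition is drawn; each fold is
    predicted by a model fit on the remaining folds (standardization
    statistics from the training folds only).  The final per-subject
    prediction is the mean of its held-out predictions across
    repetitions; R and MAE are computed on those final predictions.
    """
    if not np.isfinite(features[list(feature_set)].to_numpy()).all():
        raise ValueError("non-finite feature values")
    n = len(features)
    if n < n_folds:
        raise ValueError(f"n={n} smaller than n_folds={n_folds}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ages = ages.loc[features.index]
    preds = np.empty((n_reps, n))
    for rep in range(n_reps):
        ids = _fold_ids(n, n_folds, rng)
        for f in range(n_folds):
            train = features.index[ids != f]
            test = features.index[ids == f]
            m = fit_linear_model(features.loc[train], ages.loc[train],
                                 feature_set, species=species)
            preds[rep, ids == f] = m.predict(features.loc[test]).to_numpy()
    per_rep = pd.DataFrame(preds, columns=features.index)
    final = pd.Series(preds.mean(axis=0), index=features.index,
                      name="predicted_age")
    r, p, mae = evaluate(ages, final)
    return PredictionResult(actual=ages, predicted=final, per_repetition=per_rep,
                            r=r, p=p, mae=mae,
                            provenance={"species": species,
                                        "n_features": len(list(feature_set)),
                                        "n_folds": n_folds, "n_reps": n_reps})


def cross_predict(model: TrainedAgeModel,
                  foreign_features: pd.DataFrame) -> pd.Series:
    """Apply a trained model to the other species.

    The foreign table must contain every feature of the model (homologous
    schema) and is standardized with the FOREIGN species' own statistics
    before scoring, so the prediction responds to the foreign cohort's
    relative feature patterns; outputs are in the training species' age
    units.
    """
    missing = [f for f in model.features if f not in foreign_features.columns]
    if missing:
        raise KeyError(f"foreign table missing homologous feature(s): {missing}")
    z, _ = standardize(foreign_features[model.features])
    return model.predict_standardized(z)
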