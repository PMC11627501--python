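"""Table and configuration I/O.

Canonical on-disk dialect is TSV with a single header line, UTF-8, ``NA``
for missing values (tract labels such as ``Cs:Pg`` contain punctuation that
makes comma dialects ambiguous; comma-separated files are still accepted on
read).  Cohort, feature and behavior tables are all indexed by a
``subject_id`` column.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .schema import FeatureSchema, SchemaError

SPECIES = ("human", "macaque")
SEXES = ("male", "female")

_NA = "NA"


def get_logger(name: str = "xbrainage", logfile: str | None = None,
               level: int = logging.INFO) -> logging.Logger:
    """Logger writing to stderr and optionally a file; idempotent."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(fmt)
        logger.addHandler(h)
        if logfile:
            fh = logging.FileHandler(logfile)
            fh.setFormatter(fmt)
            logger.addHandler(fh)
        logger.setLevel(level)
    return logger


log = get_logger()


def _read_any(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, na_values=[_NA], keep_default_na=True)


def write_table(df: pd.DataFrame, path, *, index: bool = True) -> None:
    """Write a table as TSV with ``NA`` for missing entries."""
    df.to_csv(path, sep="\t", na_rep=_NA, index=index,
              index_label="subject_id" if index else None)


def read_feature_table(path, schema: FeatureSchema,
                       *, allow_missing: bool = False) -> pd.DataFrame:
    """Read and validate a subjects x features table.

    The column set must equal the schema exactly; column order is
    normalized to schema order.  Non-numeric cells raise a parse error
    naming the row and column.
    """
    df = _read_any(path)
    if "subject_id" not in df.columns:
        raise SchemaError("feature table lacks a subject_id column")
    df = df.set_index("subject_id")
    schema.validate_columns(df.columns)
    df = df[schema.feature_names]
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            raise SchemaError(
                f"non-numeric value in column {col!r}, subject(s) {list(bad)[:5]}")
    if df.index.duplicated().any():
        raise SchemaError(
            f"duplicated subjects: {sorted(set(df.index[df.index.duplicated()]))}")
    if not allow_missing and df.isna().any().any():
        bad = sorted(df.columns[df.isna().any()])
        raise SchemaError(f"missing values in feature columns {bad}")
    return df.astype(float)


def read_cohort_table(path) -> pd.DataFrame:
    """Read subject metadata (species, age, sex, site)."""
    df = _read_any(path)
    required = {"subject_id", "species", "age", "sex", "site"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"cohort table missing columns {sorted(missing)}")
    df = df.set_index("subject_id")
    if df.index.duplicated().any():
        raise SchemaError("duplicated subject_id in cohort table")
    bad_species = set(df["species"]) - set(SPECIES)
    if bad_species:
        raise SchemaError(f"unknown species labels {sorted(bad_species)}")
    df["age"] = pd.to_numeric(df["age"])
    return df


def read_behavior_table(path) -> pd.DataFrame:
    df = _read_any(path)
    if "subject_id" not in df.columns:
        raise SchemaError("behavior table lacks a subject_id column")
    df = df.set_index("subject_id")
    return df.astype(float)


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; mirrors the YAML config file."""

    # selection
    alpha: float = 0.01
    n_repetitions: int = 100
    n_folds: int = 10
    criterion: str = "common"          # common | min_mae | top_k
    top_k: int = 62
    # model
    n_model_reps: int = 100
    # association
    fdr_q: float = 0.05
    min_complete_pairs: int = 10
    # orchestration
    sex_stratified: bool = False
    harmonize: bool = True
    rng_seed: int = 0
    out_dir: str = "xbrainage_out"
    # simulation settings forwarded to SimConfig (when simulating)
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")
        if self.criterion not in {"common", "min_mae", "top_k"}:
            raise ValueError(f"unknown selection criterion {self.criterion!r}")
        if self.top_k < 1 or self.top_k > 260:
            raise ValueError("top_k must be in [1, 260]")


def load_config(path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(vars(config), fh, sort_keys=False)
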