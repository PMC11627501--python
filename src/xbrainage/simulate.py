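"""Synthetic two-species cohort generator.

Emulates the statistical structure the cross-species age-prediction
analysis assumes: a human cohort (default n=370, ages 8-14 y) and a
macaque cohort (default n=181, ages 2-4 y, two scanner sites) sharing one
homologous 260-feature schema.  Each feature column is

    x = baseline(species) + slope(species) * age
        [+ latent loading, human-specific features only]
        [+ site shift/scale, macaque only]
        + Gaussian noise

Features fall into four planted classes: *common-informative* (an age
slope of the same sign in both species), *human-specific* and
*macaque-specific* (nonzero slope in one species only), and pure noise.
The generator keeps full ground-truth bookkeeping (feature classes,
slopes, site effects, the latent divergence score) so downstream stages
can be tested by parameter recovery rather than eyeballing.

The *latent divergence* score is a per-human-subject standard-normal
factor loaded onto the human-specific features along their maturational
direction: a subject with high divergence expresses the human-specific
age effects more strongly than their chronological age warrants.  It is
the quantity the BCAP statistic is designed to pick up, and it drives the
planted behavior associations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import FeatureSchema, build_default_schema
from .io import write_table, save_config


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generator settings; defaults reproduce the study's cohort shape."""

    n_human: int = 370
    n_macaque: int = 181
    human_age_range: tuple[float, float] = (8.0, 14.0)
    macaque_age_range: tuple[float, float] = (2.0, 4.0)
    n_gm_regions: int = 92
    n_tracts: int = 42
    # planted feature classes
    n_common_informative: int = 40
    n_human_specific: int = 60
    n_macaque_specific: int = 10
    effect_size_range: tuple[float, float] = (0.15, 0.45)  # slope, units/year
    # macaque per-year slopes are scaled up by this factor: the macaque
    # window (2-4 y) covers a faster developmental phase, and the scaling
    # keeps feature-age correlations comparable across the two age spans
    macaque_slope_scale: float = 2.0
    noise_sd: float = 1.0
    baseline_sd: float = 1.0
    # fraction of human-specific features placed in white matter and of
    # macaque-specific features placed in gray matter
    specific_bias: float = 0.8
    # macaque scanner sites
    n_sites_macaque: int = 2
    site_proportions: tuple[float, ...] = (42 / 181, 139 / 181)
    site_shift_sd: float = 0.5
    site_scale_range: tuple[float, float] = (0.9, 1.1)
    # optional extra shared-factor loading on human-specific features
    # (noise-SD units); the latent divergence itself is always the
    # realized age-adjusted expression of those features
    latent_loading: float = 0.0
    # behaviors (human only)
    n_behaviors: int = 40
    n_informative_behaviors: int = 2
    behavior_effect: float = 2.0
    behavior_noise_sd: float = 1.0
    behavior_age_confound: float = 0.2
    behavior_missing_rate: float = 0.1
    # sex composition (male fraction per species; study: 170/370, 89/181)
    human_male_fraction: float = 170 / 370
    macaque_male_fraction: float = 89 / 181
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_human <= 0 or self.n_macaque <= 0:
            raise ConfigurationError("both cohorts need at least one subject")
        n_feat = self.n_gm_regions + 4 * self.n_tracts
        n_informative = (self.n_common_informative + self.n_human_specific
                         + self.n_macaque_specific)
        if n_informative > n_feat:
            raise ConfigurationError(
                f"feature budget exceeded: {n_informative} informative "
                f"features > {n_feat} total")
        for lo, hi in (self.human_age_range, self.macaque_age_range):
            if not (0 < lo < hi):
                raise ConfigurationError("age ranges must be positive, min < max")
        for name in ("n_common_informative", "n_human_specific",
                     "n_macaque_specific", "n_behaviors",
                     "n_informative_behaviors", "n_sites_macaque"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.noise_sd < 0 or self.site_shift_sd < 0:
            raise ConfigurationError("noise/shift SDs must be >= 0")
        if len(self.site_proportions) != self.n_sites_macaque:
            # default proportions only fit two sites; spread evenly otherwise
            object.__setattr__(self, "site_proportions",
                               tuple([1 / self.n_sites_macaque] * self.n_sites_macaque))


@dataclass
class GroundTruth:
    """Everything the generator planted, for parameter-recovery tests."""

    common_features: list[str]
    human_specific_features: list[str]
    macaque_specific_features: list[str]
    slopes_human: dict[str, float]
    slopes_macaque: dict[str, float]
    baselines_human: dict[str, float]
    baselines_macaque: dict[str, float]
    site_shifts: dict[str, dict[str, float]]   # site -> feature -> shift
    site_scales: dict[str, dict[str, float]]
    latent_divergence: pd.Series = field(repr=False)
    informative_behaviors: list[str] = field(default_factory=list)
    behavior_effects: dict[str, float] = field(default_factory=dict)

    def informative_features(self, species: str) -> list[str]:
        specific = (self.human_specific_features if species == "human"
                    else self.macaque_specific_features)
        return self.common_features + specific

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["latent_divergence"] = {
            str(k): float(v) for k, v in self.latent_divergence.items()}
        Path(path).write_text(json.dumps(payload, indent=1))


def _subject_ids(species: str, n: int) -> list[str]:
    return [f"{species}_{i:04d}" for i in range(1, n + 1)]


def _assign_classes(rng, schema: FeatureSchema, config: SimConfig):
    """Draw the common / human-specific / macaque-specific feature sets."""
    gm = np.array(schema.names_for_compartment("gray_matter"))
    wm = np.array(schema.names_for_compartment("white_matter"))
    rng.shuffle(gm)
    rng.shuffle(wm)
    gm, wm = list(gm), list(wm)

    def take(pool, k):
        taken, rest = pool[:k], pool[k:]
        if len(taken) < k:
            raise ConfigurationError("feature budget exceeded within compartment")
        return taken, rest

    n_hs_wm = int(round(config.specific_bias * config.n_human_specific))
    n_ms_gm = int(round(config.specific_bias * config.n_macaque_specific))
    hs_wm, wm = take(wm, n_hs_wm)
    hs_gm, gm = take(gm, config.n_human_specific - n_hs_wm)
    ms_gm, gm = take(gm, n_ms_gm)
    ms_wm, wm = take(wm, config.n_macaque_specific - n_ms_gm)
    pool = np.array(gm + wm)
    rng.shuffle(pool)
    common = list(pool[:config.n_common_informative])
    if len(common) < config.n_common_informative:
        raise ConfigurationError("feature budget exceeded")
    return common, hs_wm + hs_gm, ms_gm + ms_wm


def generate_cohort(config: SimConfig,
                    schema: FeatureSchema | None = None,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (cohort, features, truth) for both species.

    Deterministic given ``config.rng_seed`` (or an explicit ``rng``).
    Site effects are already injected into the returned features (macaque
    only); the clean-to-shifted transformation is recorded in the truth.
    """
    schema = schema or build_default_schema()
    if schema.n_features != config.n_gm_regions + 4 * config.n_tracts:
        raise ConfigurationError(
            "schema size does not match configured n_gm_regions/n_tracts")
    rng = rng or np.random.default_rng(config.rng_seed)

    common, human_spec, macaque_spec = _assign_classes(rng, schema, config)
    names = schema.feature_names
    lo, hi = config.effect_size_range

    slopes_h = dict.fromkeys(names, 0.0)
    slopes_m = dict.fromkeys(names, 0.0)
    mscale = config.macaque_slope_scale
    for f in common:
        sign = rng.choice([-1.0, 1.0])
        slopes_h[f] = sign * rng.uniform(lo, hi)
        slopes_m[f] = sign * mscale * rng.uniform(lo, hi)
    for f in human_spec:
        slopes_h[f] = rng.choice([-1.0, 1.0]) * rng.uniform(lo, hi)
    for f in macaque_spec:
        slopes_m[f] = rng.choice([-1.0, 1.0]) * mscale * rng.uniform(lo, hi)

    base_h = {f: rng.normal(0.0, config.baseline_sd) for f in names}
    base_m = {f: rng.normal(0.0, config.baseline_sd) for f in names}

    # cohort tables
    ages_h = rng.uniform(*config.human_age_range, size=config.n_human)
    ages_m = rng.uniform(*config.macaque_age_range, size=config.n_macaque)
    sex_h = np.where(rng.random(config.n_human) < config.human_male_fraction,
                     "male", "female")
    sex_m = np.where(rng.random(config.n_macaque) < config.macaque_male_fraction,
                     "male", "female")
    site_labels = [f"site{chr(ord('A') + i)}" for i in range(config.n_sites_macaque)]
    site_m = rng.choice(site_labels, size=config.n_macaque,
                        p=np.asarray(config.site_proportions))
    cohort = pd.DataFrame({
        "species": ["human"] * config.n_human + ["macaque"] * config.n_macaque,
        "age": np.concatenate([ages_h, ages_m]),
        "sex": np.concatenate([sex_h, sex_m]),
        "site": ["humanSite"] * config.n_human + list(site_m),
    }, index=pd.Index(_subject_ids("human", config.n_human)
                      + _subject_ids("macaque", config.n_macaque),
                      name="subject_id"))

    p = schema.n_features
    n = len(cohort)
    ages = cohort["age"].to_numpy()
    is_human = (cohort["species"] == "human").to_numpy()
    slope_mat = np.where(is_human[:, None],
                         np.array([slopes_h[f] for f in names])[None, :],
                         np.array([slopes_m[f] for f in names])[None, :])
    base_mat = np.where(is_human[:, None],
                        np.array([base_h[f] for f in names])[None, :],
                        np.array([base_m[f] for f in names])[None, :])
    expected = base_mat + slope_mat * ages[:, None]
    values = expected.copy()
    # optional shared subject factor along the human-specific maturational
    # direction (adds correlated individual variation across those features)
    if human_spec and config.latent_loading != 0:
        hcols = [names.index(f) for f in human_spec]
        direction = np.sign([slopes_h[f] for f in human_spec])
        factor = np.zeros(n)
        factor[is_human] = rng.normal(size=config.n_human)
        values[:, hcols] += (config.latent_loading
                             * factor[:, None] * direction[None, :])
    values += rng.normal(0.0, config.noise_sd, size=(n, p))
    features = pd.DataFrame(values, index=cohort.index, columns=names)

    # latent divergence: the realized age-adjusted expression of the
    # human-specific effects, i.e. the standardized per-subject mean of
    # sign(slope) * (observed - expected) over human-specific features
    if human_spec:
        hcols = [names.index(f) for f in human_spec]
        direction = np.sign([slopes_h[f] for f in human_spec])
        resid = (values[np.ix_(is_human.nonzero()[0], hcols)]
                 - expected[np.ix_(is_human.nonzero()[0], hcols)])
        latent_raw = (resid * direction[None, :]).mean(axis=1)
    else:
        latent_raw = np.zeros(config.n_human)
    if config.n_human > 1 and latent_raw.std() > 0:
        latent_raw = (latent_raw - latent_raw.mean()) / latent_raw.std()
    latent = pd.Series(latent_raw, index=cohort.index[:config.n_human],
                       name="latent_divergence")

    truth = GroundTruth(
        common_features=common,
        human_specific_features=human_spec,
        macaque_specific_features=macaque_spec,
        slopes_human=slopes_h, slopes_macaque=slopes_m,
        baselines_human=base_h, baselines_macaque=base_m,
        site_shifts={}, site_scales={},
        latent_divergence=latent,
    )
    features = inject_site_effects(features, cohort, config, rng=rng,
                                   truth=truth)
    return cohort, features, truth


def inject_site_effects(features: pd.DataFrame, cohort: pd.DataFrame,
                        config: SimConfig,
                        rng: np.random.Generator | None = None,
                        truth: GroundTruth | None = None) -> pd.DataFrame:
    """Apply per-(site, feature) multiplicative scale and additive shift.

    Only macaque subjects are touched (the human cohort is single-site by
    design).  Shift/scale draws are recorded in ``truth`` when given, so
    harmonization tests can compare against the planted effects.  With a
    single macaque site, or zero-magnitude settings, this is the identity.
    """
    rng = rng or np.random.default_rng(config.rng_seed + 1)
    out = features.copy()
    macaque = cohort.index[cohort["species"] == "macaque"]
    sites = sorted(cohort.loc[macaque, "site"].unique())
    unknown = set(cohort.loc[macaque, "site"]) - set(sites)
    if unknown:
        raise ConfigurationError(f"unknown site labels {sorted(unknown)}")
    identity = (config.site_shift_sd == 0
                and tuple(config.site_scale_range) == (1.0, 1.0))
    if len(sites) < 2 or identity:
        if truth is not None:
            truth.site_shifts = {s: dict.fromkeys(features.columns, 0.0)
                                 for s in sites}
            truth.site_scales = {s: dict.fromkeys(features.columns, 1.0)
                                 for s in sites}
        return out
    p = features.shape[1]
    shifts, scales = {}, {}
    for s in sites:
        shift = rng.normal(0.0, config.site_shift_sd, size=p)
        scale = rng.uniform(*config.site_scale_range, size=p)
        idx = cohort.index[(cohort["species"] == "macaque")
                           & (cohort["site"] == s)]
        out.loc[idx] = out.loc[idx].to_numpy() * scale + shift
        shifts[s] = dict(zip(features.columns, map(float, shift)))
        scales[s] = dict(zip(features.columns, map(float, scale)))
    if truth is not None:
        truth.site_shifts = shifts
        truth.site_scales = scales
    return out


def generate_behavior(cohort: pd.DataFrame, latent: pd.Series,
                      config: SimConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate the human-only behavioral phenotype table.

    The first ``n_informative_behaviors`` columns load on the latent
    divergence (plus an age confound); the rest are pure noise.  Missing
    entries are injected completely at random at ``behavior_missing_rate``.
    """
    if (cohort["species"] != "human").any():
        raise ConfigurationError("behaviors are generated for human subjects "
                                 "only; drop macaque rows first")
    rng = rng or np.random.default_rng(config.rng_seed + 2)
    n = len(cohort)
    ages = cohort["age"].to_numpy()
    lat = latent.reindex(cohort.index).to_numpy()
    cols, data = [], []
    for j in range(config.n_behaviors):
        name = f"behavior_{j + 1:02d}"
        y = rng.normal(0.0, config.behavior_noise_sd, size=n)
        if j < config.n_informative_behaviors:
            y = (config.behavior_effect * lat
                 + config.behavior_age_confound * (ages - ages.mean()) + y)
        cols.append(name)
        data.append(y)
    table = pd.DataFrame(np.column_stack(data), index=cohort.index,
                         columns=cols)
    if config.behavior_missing_rate > 0:
        mask = rng.random(table.shape) < config.behavior_missing_rate
        table = table.mask(mask)
    return table


def simulate_study(config: SimConfig):
    """One-call convenience: cohort, features, behaviors, truth."""
    cohort, features, truth = generate_cohort(config)
    humans = cohort[cohort["species"] == "human"]
    behaviors = generate_behavior(humans, truth.latent_divergence, config)
    truth.informative_behaviors = [
        f"behavior_{j + 1:02d}" for j in range(config.n_informative_behaviors)]
    truth.behavior_effects = {b: config.behavior_effect
                              for b in truth.informative_behaviors}
    return cohort, features, behaviors, truth


def write_study(config: SimConfig, out_dir) -> None:
    """Generate a study and write cohort/features/behavior/config/truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, features, behaviors, truth = simulate_study(config)
    write_table(cohort, out / "cohort.tsv")
    write_table(features, out / "features.tsv")
    write_table(behaviors, out / "behavior.tsv")
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in vars(config).items()}
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        import yaml
        yaml.safe_dump(cfg, fh, sort_keys=False)
    truth.to_json(out / "ground_truth.json")
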