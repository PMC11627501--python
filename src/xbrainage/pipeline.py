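"""End-to-end orchestration of the cross-species brain-age analysis.

Order of stages: simulate (or ingest) -> harmonize the macaque sites ->
feature selection per species -> within-species repeated-CV prediction ->
full-sample model transfer across species -> brain-age gap and BCAP ->
BCAP associations (behaviors and structural features) -> cross-species
feature classification.  Everything is deterministic given the single
pipeline seed, which fans out to per-stage child seeds so any stage can
be rerun in isolation.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import PipelineConfig, get_logger, write_table
from .schema import FeatureSchema, build_default_schema, MEASURES
from .simulate import SimConfig, simulate_study
from .harmonize import harmonize_by_measure
from .selection import repeated_screening, top_k_features
from .model import cv_predict, fit_full_model, cross_predict, evaluate
from .bcap import bcap, brain_age_gap, gap_age_correlation
from .association import (bcap_behavior_associations,
                          bcap_feature_associations, classify_features)

log = get_logger("xbrainage.pipeline")

_STAGES = ("simulate", "harmonize", "select_human", "select_macaque",
           "model_human", "model_macaque")


def stage_seeds(seed: int) -> dict[str, int]:
    """Fan one pipeline seed out to per-stage child seeds (< 2**31)."""
    state = np.random.SeedSequence(seed).generate_state(len(_STAGES))
    return {name: int(s % (2 ** 31)) for name, s in zip(_STAGES, state)}


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    config: dict
    seed: int
    version: str = __version__
    started: str = ""
    finished: str = ""
    selection: dict = field(default_factory=dict)
    predictions: dict = field(default_factory=dict)
    gap_age: dict = field(default_factory=dict)
    bcap_summary: dict = field(default_factory=dict)
    associations: dict = field(default_factory=dict)
    classification: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("config", "seed", "version", "started", "finished",
                 "selection", "predictions", "gap_age", "bcap_summary",
                 "associations", "classification")}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def summary(self) -> str:
        lines = [f"xbrainage {self.version} run (seed {self.seed})"]
        for cell, d in self.predictions.items():
            lines.append(f"  {cell}: R={d['r']:.4f} p={d['p']:.3g} "
                         f"MAE={d['mae']:.4f} (n={d['n']})")
        for cell, d in self.gap_age.items():
            lines.append(f"  gap-age {cell}: r={d['r']:.4f} p={d['p']:.3g}")
        b = self.bcap_summary
        if b:
            lines.append(f"  BCAP: mean={b['mean']:.3g} sd={b['sd']:.2f} "
                         f"range=[{b['min']:.1f}, {b['max']:.1f}]")
        a = self.associations
        if a:
            lines.append(f"  behavior associations: "
                         f"{a.get('behaviors', {}).get('n_significant', 'NA')} "
                         f"significant of {a.get('behaviors', {}).get('n_tested', 'NA')}")
        return "\n".join(lines)


def _select(features, ages, config: PipelineConfig, seed: int):
    """Return (used_feature_set, selection_stats_dict)."""
    stats = {}
    if config.criterion == "top_k":
        used = top_k_features(features, ages, config.top_k)
        stats.update(criterion="top_k", n_used=len(used))
        return used, stats, None
    sel = repeated_screening(features, ages, n_reps=config.n_repetitions,
                             n_folds=config.n_folds, alpha=config.alpha,
                             seed=np.random.default_rng(seed))
    used = sel.common_set if config.criterion == "common" else sel.min_mae_set
    stats.update(criterion=config.criterion, n_used=len(used),
                 n_common=sel.n_common, n_min_mae=sel.n_min_mae)
    return used, stats, sel


def run_pipeline(config: PipelineConfig,
                 data: tuple | None = None,
                 schema: FeatureSchema | None = None,
                 out_dir: str | None = None) -> RunReport:
    """Run every stage and return the report.

    ``data`` is an optional (cohort, features, behaviors_or_None, truth_or_None)
    tuple; without it a synthetic study is generated from
    ``config.simulate`` with a seed derived from the pipeline seed.
    When ``out_dir`` is given, intermediates and the report are written
    there as TSV/JSON.
    """
    seeds = stage_seeds(config.rng_seed)
    schema = schema or build_default_schema()
    report = RunReport(config=vars(config).copy(), seed=config.rng_seed,
                       started=datetime.datetime.now().isoformat())
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    truth = None
    if data is None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("rng_seed", seeds["simulate"])
        sim = SimConfig(**sim_kwargs)
        cohort, features, behaviors, truth = simulate_study(sim)
    else:
        cohort, features, behaviors, truth = (tuple(data) + (None, None))[:4]

    # harmonization: macaque multi-site batch removal, sex preserved
    if config.harmonize:
        mac = cohort.index[cohort["species"] == "macaque"]
        if cohort.loc[mac, "site"].nunique() > 1:
            adj = harmonize_by_measure(features.loc[mac],
                                       cohort.loc[mac, "site"], schema,
                                       covariates=cohort.loc[mac, ["sex"]])
            features = features.copy()
            features.loc[mac] = adj

    hum = cohort.index[cohort["species"] == "human"]
    mac = cohort.index[cohort["species"] == "macaque"]
    ages = cohort["age"]
    fh, fm = features.loc[hum], features.loc[mac]

    set_h, stats_h, sel_h = _select(fh, ages.loc[hum], config,
                                    seeds["select_human"])
    set_m, stats_m, sel_m = _select(fm, ages.loc[mac], config,
                                    seeds["select_macaque"])
    if not set_h or not set_m:
        raise RuntimeError("stage selection failed: empty feature set for "
                           + ("human" if not set_h else "macaque"))
    report.selection = {"human": stats_h, "macaque": stats_m}

    # within-species repeated-CV prediction
    cv_h = cv_predict(fh, ages.loc[hum], set_h, n_folds=config.n_folds,
                      n_reps=config.n_model_reps,
                      seed=np.random.default_rng(seeds["model_human"]),
                      species="human")
    cv_m = cv_predict(fm, ages.loc[mac], set_m, n_folds=config.n_folds,
                      n_reps=config.n_model_reps,
                      seed=np.random.default_rng(seeds["model_macaque"]),
                      species="macaque")

    # transferred full-sample models
    model_h = fit_full_model(fh, ages.loc[hum], set_h, species="human")
    model_m = fit_full_model(fm, ages.loc[mac], set_m, species="macaque")
    pred_m_on_h = cross_predict(model_m, fh)
    pred_h_on_m = cross_predict(model_h, fm)
    r_mh, p_mh, mae_mh = evaluate(ages.loc[hum], pred_m_on_h)
    r_hm, p_hm, mae_hm = evaluate(ages.loc[mac], pred_h_on_m)

    report.predictions = {
        "human_model_on_human": {"r": cv_h.r, "p": cv_h.p, "mae": cv_h.mae,
                                 "n": len(hum)},
        "macaque_model_on_macaque": {"r": cv_m.r, "p": cv_m.p,
                                     "mae": cv_m.mae, "n": len(mac)},
        "macaque_model_on_human": {"r": r_mh, "p": p_mh, "mae": mae_mh,
                                   "n": len(hum)},
        "human_model_on_macaque": {"r": r_hm, "p": p_hm, "mae": mae_hm,
                                   "n": len(mac)},
    }

    # brain-age gap vs age, all four cells
    gap_cells = {
        "human_model_on_human": (ages.loc[hum], cv_h.predicted),
        "macaque_model_on_macaque": (ages.loc[mac], cv_m.predicted),
        "macaque_model_on_human": (ages.loc[hum], pred_m_on_h),
        "human_model_on_macaque": (ages.loc[mac], pred_h_on_m),
    }
    for cell, (a, pr) in gap_cells.items():
        g = brain_age_gap(a, pr)
        r, p = gap_age_correlation(g, a)
        report.gap_age[cell] = {"r": r, "p": p}

    # BCAP over the human cohort
    bcap_table = bcap(cv_h.predicted, pred_m_on_h)
    bvals = bcap_table["bcap"]
    report.bcap_summary = {"mean": float(bvals.mean()),
                           "sd": float(bvals.std(ddof=1)),
                           "min": float(bvals.min()),
                           "max": float(bvals.max()), "n": len(bvals)}
    if truth is not None and getattr(truth, "latent_divergence", None) is not None:
        lat = truth.latent_divergence.loc[bvals.index]
        r_lat, p_lat, _ = _safe_corr(bvals, lat)
        report.bcap_summary["r_with_latent_divergence"] = r_lat

    # associations
    report.associations = {}
    if behaviors is not None:
        beh = bcap_behavior_associations(bvals, behaviors, ages.loc[hum],
                                         q=config.fdr_q,
                                         min_complete=config.min_complete_pairs)
        report.associations["behaviors"] = {
            "n_tested": int(beh["p"].notna().sum()),
            "n_significant": int(beh["significant"].sum()),
            "significant": sorted(beh.index[beh["significant"]]),
        }
        if out is not None:
            write_table(beh, out / "bcap_behavior_associations.tsv")
    feat_assoc = bcap_feature_associations(bvals, fh, ages.loc[hum], schema,
                                           q=config.fdr_q)
    report.associations["features"] = {
        m: {"n_significant": int(feat_assoc.loc[
            (feat_assoc["measure"] == m), "significant"].sum())}
        for m in MEASURES}
    if out is not None:
        write_table(feat_assoc, out / "bcap_feature_associations.tsv")

    # feature classification across species
    fc = classify_features(set_h, set_m, schema=schema)
    report.classification = {
        "n_common": len(fc.common),
        "n_human_specific": len(fc.human_specific),
        "n_macaque_specific": len(fc.macaque_specific),
        "per_measure_percent": fc.per_measure_percent.round(4).to_dict(),
    }

    report.finished = datetime.datetime.now().isoformat()
    if out is not None:
        write_table(cohort, out / "cohort.tsv")
        write_table(features, out / "features.tsv")
        write_table(bcap_table, out / "bcap.tsv")
        for name, m in (("model_human", model_h), ("model_macaque", model_m)):
            Path(out / f"{name}.json").write_text(json.dumps(m.to_dict()))
        for name, sel in (("selection_human", sel_h),
                          ("selection_macaque", sel_m)):
            if sel is not None:
                sel.to_json(out / f"{name}.json")
        report.to_json(out / "report.json")
    return report


def _safe_corr(x, y):
    from scipy import stats as st
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan"), len(x)
    r, p = st.pearsonr(x, y)
    return float(r), float(p), len(x)


def run_sex_stratified(config: PipelineConfig,
                       data: tuple | None = None,
                       schema: FeatureSchema | None = None,
                       out_dir: str | None = None
                       ) -> dict[str, RunReport]:
    """Rerun the full pipeline separately in males and females.

    The study data (real or simulated once from the pipeline seed) are
    subset by sex; a stratum smaller than ``n_folds`` in either species
    is an error naming the stratum.
    """
    if data is None:
        seeds = stage_seeds(config.rng_seed)
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("rng_seed", seeds["simulate"])
        cohort, features, behaviors, truth = simulate_study(
            SimConfig(**sim_kwargs))
    else:
        cohort, features, behaviors, truth = (tuple(data) + (None, None))[:4]
    reports = {}
    for sex in ("male", "female"):
        idx = cohort.index[cohort["sex"] == sex]
        sub = cohort.loc[idx]
        for species in ("human", "macaque"):
            n = int((sub["species"] == species).sum())
            if n < config.n_folds:
                raise ValueError(f"stratum {sex}/{species} has {n} subjects, "
                                 f"fewer than n_folds={config.n_folds}")
        beh = behaviors.loc[behaviors.index.intersection(idx)] \
            if behaviors is not None else None
        tr = truth
        reports[sex] = run_pipeline(
            config, data=(sub, features.loc[idx], beh, tr), schema=schema,
            out_dir=(str(Path(out_dir) / sex) if out_dir else None))
    return reports
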