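"""End-to-end orchestration of the study's analysis designs.

Two designs are wired up:

* **per-disease timecourse** — within one disease, each pair of timepoints
  (BT vs 3M, BT vs 6M, 3M vs 6M) is compared with the dropout-aware paired
  univariate battery (BH-adjusted within the comparison) and a sevenfold
  cross-validated PLS-DA model; biomarkers are the VIP > 1.00 AND q < 0.05
  intersection with a direction of change.
* **cross-disease** — at one timepoint, every metabolite runs through the
  three-group ANOVA/Kruskal-Wallis router with post-hocs, and the three
  pairwise PLS-DA models (RA vs AS, RA vs PsA, AS vs PsA) are validated by
  CV-ANOVA.

``run_full_study`` chains synthetic generation, preprocessing, both
designs and the clinical response summary into one versioned output
directory of TSV tables plus a run log with seeds and config hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemometrics as chem
from . import clinical, preproc, unistats
from .containers import FeatureTable
from .synthdata import (SyntheticConfig, simulate_clinical_scores,
                        simulate_cohort)

log = logging.getLogger("rheumet.pipeline")

__all__ = [
    "AnalysisPlan", "StudyConfig", "TimecourseReport", "CrossDiseaseReport",
    "run_timecourse", "run_cross_disease", "run_full_study",
]


@dataclass
class AnalysisPlan:
    """Settings shared by all comparisons of one study run."""

    timepoint_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("BT", "3M"), ("BT", "6M"), ("3M", "6M")])
    folds: int = 7
    seed: int = 0
    n_lv: int | None = None       # None = Q2-maximization policy
    vip_threshold: float = 1.00
    q_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.vip_threshold <= 0 or self.q_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class TimecourseReport:
    disease: str
    model_summaries: pd.DataFrame
    univariate: pd.DataFrame
    vip: pd.DataFrame
    selections: pd.DataFrame


@dataclass
class CrossDiseaseReport:
    timepoint: str
    model_summaries: pd.DataFrame
    univariate: pd.DataFrame
    selections: pd.DataFrame


def _route_for(a: np.ndarray, b: np.ndarray) -> str:
    try:
        pa = unistats.normality_check(a)[1]
        pb = unistats.normality_check(b)[1]
        pl = unistats.variance_check([a, b])
    except ValueError:
        return "nonparametric"
    return "parametric" if min(pa, pb) >= unistats.ALPHA \
        and pl >= unistats.ALPHA else "nonparametric"


def _paired_univariate(features: FeatureTable, tp_a: str, tp_b: str,
                       comparison: str) -> pd.DataFrame:
    meta = features.meta
    rows = []
    for metab in features.metabolites:
        col = features.values[metab]
        xa = pd.Series(col[meta.timepoint == tp_a].to_numpy(),
                       index=meta.subject_id[meta.timepoint == tp_a])
        xb = pd.Series(col[meta.timepoint == tp_b].to_numpy(),
                       index=meta.subject_id[meta.timepoint == tp_b])
        try:
            p, used = unistats.paired_timepoint_test(xa.to_dict(),
                                                     xb.to_dict())
        except ValueError as exc:
            log.warning("%s %s: %s", comparison, metab, exc)
            continue
        # central tendencies and % difference on the general dataset
        route = _route_for(xa.to_numpy(), xb.to_numpy())
        ct = np.mean if route == "parametric" else np.median
        rows.append({
            "metabolite": metab, "comparison": comparison, "test_used": used,
            "p": p, "route": route, "ct_kind":
                "mean" if route == "parametric" else "median",
            "ct_a": float(ct(xa)), "ct_b": float(ct(xb)),
            "percent_difference": unistats.percent_difference(
                xa, xb, route)})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = unistats.bh_adjust(df["p"].to_numpy())
    return df


def run_timecourse(features: FeatureTable, disease: str,
                   plan: AnalysisPlan | None = None) -> TimecourseReport:
    """Timecourse analysis of one disease: PCA overview, per-pair PLS-DA
    model rows, dropout-aware univariate q-values and the VIP AND q
    biomarker list with direction of change."""
    plan = plan or AnalysisPlan()
    sub = features.subset(features.meta.disease == disease)
    tps = set(sub.meta.timepoint)
    if len(tps) < 2:
        raise ValueError(f"need >= 2 timepoints for {disease}")
    summaries, uni_frames, vip_rows, sel_rows = [], [], [], []

    scaled, _ = chem.uv_scale(sub)
    pca = chem.fit_pca(scaled, n_pc=min(5, len(scaled) - 1,
                                        scaled.shape[1]))
    summaries.append(chem.model_summary(
        pca, comparison=" vs. ".join(
            [t for t in ("BT", "3M", "6M") if t in tps])))

    for tp_a, tp_b in plan.timepoint_pairs:
        comparison = f"{tp_a} vs. {tp_b}"
        if tp_a not in tps or tp_b not in tps:
            log.warning("%s %s skipped: timepoint missing", disease,
                        comparison)
            continue
        uni = _paired_univariate(sub, tp_a, tp_b, comparison)
        uni.insert(0, "disease", disease)
        uni_frames.append(uni)
        pair = sub.subset(sub.meta.timepoint.isin([tp_a, tp_b]))
        try:
            model = chem.fit_plsda_cv(pair, pair.meta.timepoint.to_numpy(),
                                      n_lv=plan.n_lv, folds=plan.folds,
                                      seed=plan.seed)
        except ValueError as exc:
            log.warning("%s %s PLS-DA skipped: %s", disease, comparison, exc)
            continue
        summaries.append(chem.model_summary(model, comparison=comparison))
        vip = pd.Series(model.vip, index=model.columns)
        for m, v in vip.items():
            vip_rows.append({"disease": disease, "comparison": comparison,
                             "metabolite": m, "vip": float(v)})
        if len(uni):
            q = uni.set_index("metabolite")["q"]
            chosen = chem.select_discriminant_metabolites(
                vip, q.reindex(vip.index, fill_value=1.0))
            pdiff = uni.set_index("metabolite")["percent_difference"]
            for m in chosen:
                sel_rows.append({
                    "disease": disease, "comparison": comparison,
                    "metabolite": m, "vip": float(vip[m]),
                    "q": float(q.get(m, np.nan)),
                    "direction": "increasing" if pdiff.get(m, 0) > 0
                    else "decreasing"})
    return TimecourseReport(
        disease,
        pd.DataFrame(summaries),
        pd.concat(uni_frames, ignore_index=True) if uni_frames
        else pd.DataFrame(),
        pd.DataFrame(vip_rows),
        pd.DataFrame(sel_rows))


def run_cross_disease(features: FeatureTable, timepoint: str = "BT",
                      plan: AnalysisPlan | None = None
                      ) -> CrossDiseaseReport:
    """Cross-disease comparison at one timepoint: per-metabolite three-group
    router with post-hocs plus the three pairwise PLS-DA models."""
    plan = plan or AnalysisPlan()
    sub = features.subset(features.meta.timepoint == timepoint)
    present = set(sub.meta.disease)
    diseases = [d for d in ("RA", "AS", "PsA") if d in present] \
        + sorted(present - {"RA", "AS", "PsA"})
    if len(diseases) < 3:
        raise ValueError("need all three diseases present")
    rows = []
    for metab in features.metabolites:
        vals = sub.values[metab].to_numpy()
        groups = sub.meta.disease.to_numpy()
        omnibus, posthoc, route = unistats.multigroup_compare(vals, groups)
        ct = np.mean if route == "parametric" else np.median
        row = {"metabolite": metab, "timepoint": timepoint,
               "comparison": " vs. ".join(diseases),
               "p": omnibus, "route": route,
               "ct_kind": "mean" if route == "parametric" else "median"}
        for d in diseases:
            row[f"ct_{d}"] = float(ct(vals[groups == d]))
        for (a, b), pv in posthoc.items():
            row[f"posthoc_{a}_vs_{b}"] = pv
        rows.append(row)
    uni = pd.DataFrame(rows)
    uni["q"] = unistats.bh_adjust(uni["p"].to_numpy())

    summaries = []
    scaled, _ = chem.uv_scale(sub)
    pca = chem.fit_pca(scaled, n_pc=min(2, len(scaled) - 1))
    summaries.append(chem.model_summary(
        pca, comparison=" vs. ".join(diseases)))
    sel_rows = []
    for i in range(len(diseases)):
        for j in range(i + 1, len(diseases)):
            a, b = diseases[i], diseases[j]
            pair = sub.subset(sub.meta.disease.isin([a, b]))
            comparison = f"{a} vs. {b}"
            try:
                model = chem.fit_plsda_cv(pair, pair.meta.disease.to_numpy(),
                                          n_lv=plan.n_lv, folds=plan.folds,
                                          seed=plan.seed)
            except ValueError as exc:
                log.warning("%s PLS-DA skipped: %s", comparison, exc)
                continue
            summaries.append(chem.model_summary(model,
                                                comparison=comparison))
            vip = pd.Series(model.vip, index=model.columns)
            chosen = chem.select_discriminant_metabolites(
                vip, uni.set_index("metabolite")["q"].reindex(
                    vip.index, fill_value=1.0))
            for m in chosen:
                sel_rows.append({
                    "timepoint": timepoint, "comparison": comparison,
                    "metabolite": m, "vip": float(vip[m]),
                    "q": float(uni.set_index("metabolite")["q"][m]),
                    "validated": bool(model.cv_anova_p < 0.05)})
    return CrossDiseaseReport(timepoint, pd.DataFrame(summaries), uni,
                              pd.DataFrame(sel_rows))


# --------------------------------------------------------------------------
# full study
# --------------------------------------------------------------------------

@dataclass
class StudyConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    plan: AnalysisPlan = field(default_factory=AnalysisPlan)
    noise_window: tuple[float, float] = preproc.DEFAULT_NOISE_WINDOW
    noise_mode: str = "once"
    max_shift: int = 10
    write_spectra: bool = False


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(float_format="%.10g").encode()).hexdigest()[:16]


def run_full_study(config: StudyConfig, out_dir) -> dict:
    """Synthetic generation -> preprocessing -> univariate + chemometrics
    -> clinical summary, written as TSV tables to ``out_dir``.

    Returns a dict of output paths plus the run log.  Reruns with the same
    config produce byte-identical tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(
        {"synthetic": {k: v for k, v in asdict(config.synthetic).items()
                       if k != "panel"},
         "plan": asdict(config.plan),
         "noise_window": list(config.noise_window),
         "noise_mode": config.noise_mode, "max_shift": config.max_shift},
        sort_keys=True, default=str)
    run_log = {"config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
               "seed": config.synthetic.seed, "stages": []}

    def stage(name, **info):
        log.info("stage=%s %s", name,
                 " ".join(f"{k}={v}" for k, v in info.items()))
        run_log["stages"].append({"stage": name, **info})

    sset, truth = simulate_cohort(config.synthetic)
    stage("synthdata", n_samples=sset.n_samples,
          n_points=int(sset.ppm.size))
    if config.write_spectra:
        sset.to_tsv(out / "spectra.tsv", out / "spectra_meta.tsv")
    truth.to_json(out / "ground_truth.json")

    regions = preproc.panel_to_regions(config.synthetic.panel)
    noise = preproc.NoiseSpec(config.noise_window, config.noise_mode)
    features = preproc.preprocess_set(sset, regions, noise,
                                      max_shift=config.max_shift)
    features.to_tsv(out / "features.tsv")
    stage("preproc", n_features=len(features.metabolites),
          features_hash=_hash_df(features.values))

    summaries, uni, selections = [], [], []
    for disease in config.synthetic.cohort_sizes:
        rep = run_timecourse(features, disease, config.plan)
        s = rep.model_summaries.copy()
        s.insert(0, "design", f"timecourse {disease}")
        summaries.append(s)
        uni.append(rep.univariate)
        if len(rep.selections):
            selections.append(rep.selections)
    for tp in ("BT", "6M"):
        try:
            rep = run_cross_disease(features, tp, config.plan)
        except ValueError as exc:
            log.warning("cross-disease at %s skipped: %s", tp, exc)
            continue
        s = rep.model_summaries.copy()
        s.insert(0, "design", f"cross-disease {tp}")
        summaries.append(s)
        u = rep.univariate.copy()
        u.insert(0, "disease", "all")
        uni.append(u)
        if len(rep.selections):
            sel = rep.selections.copy()
            sel.insert(0, "disease", "all")
            selections.append(sel)
    model_summaries = pd.concat(summaries, ignore_index=True)
    model_summaries["cv_folds"] = config.plan.folds
    univariate = pd.concat(uni, ignore_index=True)
    sel_df = pd.concat(selections, ignore_index=True) if selections \
        else pd.DataFrame(columns=["disease", "comparison", "metabolite"])
    for name, df in (("model_summaries", model_summaries),
                     ("univariate", univariate), ("selections", sel_df)):
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                  float_format="%.10g")
        stage(name, rows=len(df), hash=_hash_df(df))

    scores = simulate_clinical_scores(features.meta,
                                      seed=config.synthetic.seed)
    records = clinical.records_from_frame(scores)
    rates = []
    for tp in sorted(scores.timepoint.unique()):
        rates.append(clinical.summarize_response_rates(records, tp))
    rates_df = pd.concat(rates, ignore_index=True)
    rates_df.to_csv(out / "response_rates.tsv", sep="\t", index=False,
                    float_format="%.10g")
    stage("clinical", rows=len(rates_df), hash=_hash_df(rates_df))

    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=1)
    return {"out_dir": str(out), "run_log": run_log,
            "tables": ["features.tsv", "model_summaries.tsv",
                       "univariate.tsv", "selections.tsv",
                       "response_rates.tsv"]}
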