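"""End-to-end run orchestration: simulate -> preprocess -> similarity ->
classify -> biomarkers -> prognosis, under one run directory with a
machine-readable provenance manifest.

A run is a pure function of its :class:`RunConfig` (one global seed is
fanned out into per-stage substreams); floats are rounded at write time
so identical configs produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_io import (
    FeatureMatrix,
    MALIGNANT_GROUPS,
    load_cohort,
    read_matrix,
    save_cohort,
    validate_clinical,
    write_matrix,
)
from .biomarker import annotate_feature, load_compounds, panel_evaluate, select_biomarkers
from .diagnosis import (
    DEFAULT_ZOO,
    cascade_classify,
    concat_fingerprints,
    evaluate_metrics,
    evaluate_multiclass,
    fit_cascade,
    model_feature_scores,
    stratified_split,
    _proba,
)
from .errors import ConfigError, DependencyError
from .preprocess import PreprocessParams, feature_catalog, log_scale, preprocess_cohort
from .similarity import group_similarity
from .synth import CohortConfig, default_config, generate_cohort

STAGES = ("simulate", "preprocess", "similarity", "classify", "biomarkers", "prognosis")

_COHORT_KEYS = {
    "n_per_group", "n_points", "noise_sigma", "baseline_amplitude",
    "baseline_decay", "sample_scale_sigma", "peak_scale_sigma",
    "mz_jitter_sigma",
}
_CLASSIFY_KEYS = {"zoo", "folds", "ratio", "coef_threshold", "select_features"}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "runs"
    run_name: str | None = None            # default: timestamped
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    cohort: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    similarity: dict = field(default_factory=lambda: {"cutoff": 0.8})
    classify: dict = field(default_factory=dict)
    biomarkers: dict = field(default_factory=dict)
    prognosis: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        for name, block, allowed in (
            ("cohort", self.cohort, _COHORT_KEYS),
            ("preprocess", self.preprocess, set(PreprocessParams.__dataclass_fields__)),
            ("similarity", self.similarity, {"cutoff", "mode"}),
            ("classify", self.classify, _CLASSIFY_KEYS),
            ("biomarkers", self.biomarkers, {"intensity_min", "score_min", "p_max", "test", "tolerance"}),
            ("prognosis", self.prognosis, {"p_threshold", "screen_p", "penalizer"}),
        ):
            bad = set(block) - allowed
            if bad:
                raise ConfigError(f"unknown keys in {name!r} block: {sorted(bad)}")


def load_run_config(path: str | Path) -> RunConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    allowed = set(RunConfig.__dataclass_fields__)
    bad = set(raw) - allowed
    if bad:
        raise ConfigError(f"unknown run-config keys: {sorted(bad)}")
    stages = {s: True for s in STAGES}
    stages.update(raw.pop("stages", {}))
    return RunConfig(stages=stages, **raw)


def _stage_seed(seed: int, stage: str) -> int:
    return int(
        np.random.SeedSequence([seed, STAGES.index(stage)]).generate_state(1)[0]
        % (2**31 - 1)
    )


def _round_floats(obj, ndigits: int = 8):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, dict):
        return {str(k): _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _write_json(path: Path, payload) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_round_floats(payload), indent=1, sort_keys=True))


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage {needed_by!r} needs {path.name} from stage {stage!r}; "
            "enable it or place the artifact in the run directory"
        )
    return path


def build_cohort_config(config: RunConfig) -> CohortConfig:
    base = default_config(seed=_stage_seed(config.seed, "simulate"))
    overrides = {k: v for k, v in config.cohort.items()}
    return replace(base, **overrides) if overrides else base


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory."""
    run_name = config.run_name or _time.strftime("run-%Y%m%d-%H%M%S")
    rundir = Path(config.outdir) / run_name
    rundir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    t_all = _time.perf_counter()

    def _log(stage, t0, **counts):
        log.append({"stage": stage, "seconds": round(_time.perf_counter() - t0, 3), **counts})

    # ---- simulate --------------------------------------------------------
    if config.stages.get("simulate", True):
        t0 = _time.perf_counter()
        cc = build_cohort_config(config)
        cohort = generate_cohort(cc)
        save_cohort(cohort.serum, cohort.urine, cohort.clinical, rundir / "cohort")
        truth = {
            "seed": cc.seed,
            "n_per_group": dict(cc.n_per_group),
            "serum_panel": [
                {"mz": p.mz, "base_height": p.base_height,
                 "width_sigma": p.width_sigma,
                 "class_multiplier": dict(p.class_multiplier)}
                for p in cc.serum_panel
            ],
            "urine_panel": [
                {"mz": p.mz, "base_height": p.base_height,
                 "width_sigma": p.width_sigma,
                 "class_multiplier": dict(p.class_multiplier)}
                for p in cc.urine_panel
            ],
            "survival_coefficients": dict(cc.survival.coefficients),
            "risk": cohort.truth.risk.to_dict(),
        }
        _write_json(rundir / "cohort" / "truth.json", truth)
        _log("simulate", t0, subjects=len(cohort.clinical), spectra=2 * len(cohort.clinical))

    # ---- preprocess ------------------------------------------------------
    params = PreprocessParams(**config.preprocess)
    if config.stages.get("preprocess", True):
        t0 = _time.perf_counter()
        manifest = _require(rundir / "cohort" / "manifest.json", "simulate", "preprocess")
        serum, urine, clinical = load_cohort(manifest)
        smf = preprocess_cohort(serum, params)
        umf = preprocess_cohort(urine, params)
        (rundir / "matrices").mkdir(exist_ok=True)
        write_matrix(smf, clinical, rundir / "matrices" / "smf.tsv")
        write_matrix(umf, clinical, rundir / "matrices" / "umf.tsv")
        catalog = pd.concat([feature_catalog(smf), feature_catalog(umf)])
        _write_json(rundir / "matrices" / "feature_catalog.json",
                    catalog.to_dict(orient="records"))
        _log("preprocess", t0, serum_features=smf.n_features(), urine_features=umf.n_features())

    def _matrices():
        smf_path = _require(rundir / "matrices" / "smf.tsv", "preprocess", "downstream")
        umf_path = _require(rundir / "matrices" / "umf.tsv", "preprocess", "downstream")
        smf, clinical = read_matrix(smf_path)
        umf, _ = read_matrix(umf_path)
        return smf, umf, clinical

    # ---- similarity ------------------------------------------------------
    if config.stages.get("similarity", True):
        t0 = _time.perf_counter()
        smf, umf, clinical = _matrices()
        cutoff = config.similarity.get("cutoff", 0.8)
        mode = config.similarity.get("mode", "self")
        payload = {}
        for name, mat in (("serum", smf), ("urine", umf)):
            summaries = group_similarity(mat, clinical["group"], cutoff, mode)
            payload[name] = {
                g: {"mean": s.mean, "fraction_above": s.fraction_above,
                    "n_pairs": int(s.pairwise_scores.size)}
                for g, s in summaries.items()
            }
        _write_json(rundir / "similarity.json", payload)
        _log("similarity", t0)

    # ---- classify --------------------------------------------------------
    if config.stages.get("classify", True):
        t0 = _time.perf_counter()
        smf, umf, clinical = _matrices()
        fused = concat_fingerprints(log_scale(smf), log_scale(umf))
        seed = _stage_seed(config.seed, "classify")
        ratio = tuple(config.classify.get("ratio", (7, 3)))
        split = stratified_split(clinical, ratio=ratio, seed=seed)
        cascade = fit_cascade(
            fused, clinical, split,
            zoo=tuple(config.classify.get("zoo", DEFAULT_ZOO)),
            folds=int(config.classify.get("folds", 10)),
            seed=seed,
            select_features=bool(config.classify.get("select_features", True)),
            coef_threshold=float(config.classify.get("coef_threshold", 0.05)),
        )
        groups = clinical.set_index("sample_id")["group"]
        test = fused.subset_samples(split.test_ids)
        routed = cascade_classify(cascade, test)

        reports = {"split": {"train": split.train_ids, "test": split.test_ids,
                             "p_age": split.p_age, "p_sex": split.p_sex,
                             "balanced": split.balanced}}
        y_test = groups.loc[split.test_ids]
        m1, ci1, cm1 = evaluate_metrics(
            (y_test != "HC").astype(int), routed["p_tumor"], seed=seed
        )
        reports["stage1"] = {
            "algorithm": cascade.stage1.search.algorithm,
            "hyperparameters": cascade.stage1.search.hyperparameters,
            "cv_fold_auc": cascade.stage1.search.outer_fold_auc,
            "metrics": m1, "ci": {k: list(v) for k, v in ci1.items()},
            "confusion": cm1.to_dict(),
            "n_features": len(cascade.stage1.features),
        }
        tumors = [i for i in split.test_ids if groups.loc[i] != "HC"]
        if tumors and groups.loc[tumors].nunique() > 1 and (groups.loc[tumors] == "AML").any():
            p2 = _proba(
                cascade.stage2.search.model,
                test.subset_samples(tumors).subset_features(cascade.stage2.features).values,
            )[:, 1]
            m2, ci2, cm2 = evaluate_metrics(
                groups.loc[tumors].isin(MALIGNANT_GROUPS).astype(int), p2, seed=seed + 1
            )
            reports["stage2"] = {
                "algorithm": cascade.stage2.search.algorithm,
                "metrics": m2, "ci": {k: list(v) for k, v in ci2.items()},
                "confusion": cm2.to_dict(),
            }
        malig = [i for i in split.test_ids if groups.loc[i] in MALIGNANT_GROUPS]
        if malig and groups.loc[malig].nunique() > 1:
            p3 = _proba(
                cascade.stage3.search.model,
                test.subset_samples(malig).subset_features(cascade.stage3.features).values,
            )
            rep3 = evaluate_multiclass(
                groups.loc[malig].to_numpy(), p3, cascade.stage3.search.classes
            )
            rep3["confusion"] = rep3["confusion"].to_dict()
            rep3["algorithm"] = cascade.stage3.search.algorithm
            reports["stage3"] = rep3
        terminal = routed["label"].replace("malignant", "RCC")
        truth_terminal = y_test.copy()
        reports["cascade"] = {
            "terminal_accuracy": float(np.mean(
                routed["label"].to_numpy() == truth_terminal.to_numpy()
            )),
            "labels": routed["label"].to_dict(),
        }
        _write_json(rundir / "reports" / "classification.json", reports)
        routed.to_csv(rundir / "reports" / "cascade_paths.tsv", sep="\t",
                      float_format="%.6g")
        _log("classify", t0, n_train=len(split.train_ids), n_test=len(split.test_ids))

    # ---- biomarkers ------------------------------------------------------
    if config.stages.get("biomarkers", True):
        t0 = _time.perf_counter()
        from sklearn.linear_model import LogisticRegression

        smf, umf, clinical = _matrices()
        raw_fused = concat_fingerprints(smf, umf)
        log_fused = concat_fingerprints(log_scale(smf), log_scale(umf))
        seed = _stage_seed(config.seed, "biomarkers")
        groups = clinical.set_index("sample_id")["group"]
        split_report = rundir / "reports" / "classification.json"
        if split_report.exists():
            rep = json.loads(split_report.read_text())
            train_ids = rep["split"]["train"]
            test_ids = rep["split"]["test"]
        else:
            plan = stratified_split(clinical, seed=seed)
            train_ids, test_ids = plan.train_ids, plan.test_ids

        bm_cfg = config.biomarkers
        payload = {}
        compounds = load_compounds()
        for subtype in MALIGNANT_GROUPS:
            ids_tr = [i for i in train_ids if groups.loc[i] in ("HC", subtype)]
            ids_te = [i for i in test_ids if groups.loc[i] in ("HC", subtype)]
            if (groups.loc[ids_tr] == subtype).sum() < 3 or (groups.loc[ids_te] == subtype).sum() < 2:
                continue
            y_tr = (groups.loc[ids_tr] == subtype).astype(int).to_numpy()
            y_te = (groups.loc[ids_te] == subtype).astype(int).to_numpy()
            Xl_tr = log_fused.subset_samples(ids_tr)
            lr = LogisticRegression(max_iter=5000, random_state=seed)
            lr.fit(Xl_tr.values, y_tr)
            scores = model_feature_scores(lr, log_fused.feature_labels)
            selected, table = select_biomarkers(
                raw_fused.subset_samples(ids_tr), y_tr, scores.to_dict(),
                positive_class=1,
                intensity_min=float(bm_cfg.get("intensity_min", 1000.0)),
                score_min=float(bm_cfg.get("score_min", 0.0)),
                p_max=float(bm_cfg.get("p_max", 0.05)),
                test=bm_cfg.get("test", "ranksum"),
            )
            entry = {"selected": selected,
                     "stats": table.to_dict(orient="records")}
            if selected and y_te.sum() and (1 - y_te).sum():
                panel = panel_evaluate(
                    selected, Xl_tr, y_tr,
                    log_fused.subset_samples(ids_te), y_te, seed=seed,
                )
                entry["panel"] = {
                    "train_auc": panel.train_auc, "train_ci": list(panel.train_ci),
                    "test_auc": panel.test_auc, "test_ci": list(panel.test_ci),
                    "feature_auc": panel.feature_auc,
                    "directions": panel.directions,
                }
                entry["annotation"] = {
                    lab: annotate_feature(
                        float(lab[1:].split("_")[0]), compounds,
                        tolerance=float(bm_cfg.get("tolerance", 0.05)),
                    ).to_dict(orient="records")
                    for lab in selected
                }
            payload[subtype] = entry
        _write_json(rundir / "reports" / "biomarkers.json", payload)
        _log("biomarkers", t0)

    # ---- prognosis -------------------------------------------------------
    if config.stages.get("prognosis", True):
        t0 = _time.perf_counter()
        from .prognosis import fit_cox_risk, km_logrank

        smf, umf, clinical = _matrices()
        log_fused = concat_fingerprints(log_scale(smf), log_scale(umf))
        seed = _stage_seed(config.seed, "prognosis")
        surv = clinical.dropna(subset=["dfs_time", "event"]).set_index("sample_id")
        if len(surv) >= 20 and surv["event"].sum() >= MIN_EVENTS_FOR_PROGNOSIS:
            split_report = rundir / "reports" / "classification.json"
            if split_report.exists():
                rep = json.loads(split_report.read_text())
                tr = [i for i in rep["split"]["train"] if i in surv.index]
                te = [i for i in rep["split"]["test"] if i in surv.index]
            else:
                plan = stratified_split(clinical.loc[clinical["sample_id"].isin(surv.index)],
                                        seed=seed)
                tr, te = plan.train_ids, plan.test_ids
            X_tr = log_fused.subset_samples(tr)
            model = fit_cox_risk(
                X_tr, surv.loc[tr, "dfs_time"], surv.loc[tr, "event"],
                p_threshold=float(config.prognosis.get("p_threshold", 0.05)),
                screen_p=float(config.prognosis.get("screen_p", 0.1)),
                penalizer=float(config.prognosis.get("penalizer", 0.0)),
            )
            payload = {"features": model.features,
                       "coefficients": model.coefficients.to_dict(),
                       "cutoff": model.cutoff, "empty": model.empty}
            if not model.empty:
                for name, ids in (("train", tr), ("test", te)):
                    if len(ids) < 4:
                        continue
                    s = model.score(log_fused.subset_samples(ids))
                    lr = km_logrank(s.to_numpy(), model.cutoff,
                                    surv.loc[ids, "dfs_time"], surv.loc[ids, "event"])
                    payload[name] = {
                        "logrank_statistic": lr.statistic, "p_value": lr.p_value,
                        "medians": lr.medians, "group_sizes": lr.group_sizes,
                    }
            _write_json(rundir / "reports" / "prognosis.json", payload)
        else:
            _write_json(rundir / "reports" / "prognosis.json",
                        {"skipped": "too few subjects with survival data"})
        _log("prognosis", t0)

    # ---- provenance ------------------------------------------------------
    cfg_dict = asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(_round_floats(cfg_dict), sort_keys=True).encode()
    ).hexdigest()
    _write_json(rundir / "provenance.json", {
        "package": "fluidprint",
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": cfg_hash,
        "stages": log,
        "total_seconds": round(_time.perf_counter() - t_all, 3),
    })
    return rundir


MIN_EVENTS_FOR_PROGNOSIS = 10
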