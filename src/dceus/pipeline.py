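"""End-to-end orchestration: simulate -> maps -> features -> select -> models.

The pipeline is a pure function of its configuration: the same config and
seed reproduce byte-identical feature tables and model reports.  Each
stage writes its outputs plus a hash file of the configuration slice it
depends on, so a rerun with an unchanged upstream config skips completed
stages (stage-resumable caching).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dceus.bolus import FitConfig, roi_conventional_features
from dceus.features import LABEL_COLS, extract_features, feature_catalog, percent_change
from dceus.maps import compute_mapset
from dceus.models import (
    ElasticNetLogisticCV,
    PCALDAClassifier,
    ROILDAClassifier,
    cv_evaluate,
    roc_with_ci,
    spearman_to_mvd,
)
from dceus.selection import SelectionThresholds, select_features
from dceus.synth import CohortSpec, generate_cohorts

__all__ = ["PipelineConfig", "cohort_feature_table", "run_pipeline"]

log = logging.getLogger(__name__)

ROI_MODEL_COLS = ["roi_PE", "roi_AUC", "roi_TP", "roi_MTT"]


@dataclass
class PipelineConfig:
    """Everything a run depends on; round-trips losslessly through YAML."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    fit: FitConfig = field(default_factory=FitConfig)
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)
    enet_alphas: tuple[float, ...] = (0.3, 0.5, 0.7)
    pca_lda_components: tuple[int, ...] = (16, 2)
    cv_folds: int = 10
    workers: int = 1
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(klass, d):
            if d is None:
                return klass()
            fields = {f.name for f in dataclasses.fields(klass)}
            kw = {k: (tuple(v) if isinstance(v, list) else v)
                  for k, v in d.items() if k in fields}
            return klass(**kw)

        return cls(
            cohort=build(CohortSpec, raw.get("cohort")),
            fit=build(FitConfig, raw.get("fit")),
            thresholds=build(SelectionThresholds, raw.get("thresholds")),
            enet_alphas=tuple(raw.get("enet_alphas", (0.3, 0.5, 0.7))),
            pca_lda_components=tuple(raw.get("pca_lda_components", (16, 2))),
            cv_folds=int(raw.get("cv_folds", 10)),
            workers=int(raw.get("workers", 1)),
            seed=int(raw.get("seed", 0)),
        )

    def config_hash(self, *sections: str) -> str:
        d = self.to_dict()
        if sections:
            d = {k: d[k] for k in sections}
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _dataset_features(ds, fit_cfg: FitConfig, workers: int,
                      spacing) -> pd.Series:
    mapset = compute_mapset(ds.volume4d, ds.mask, ds.frame_times_s,
                            spacing_zyx=spacing, fit_config=fit_cfg,
                            workers=workers)
    roi = roi_conventional_features(ds.volume4d, ds.mask, ds.frame_times_s,
                                    config=fit_cfg)
    return extract_features(mapset, roi)


def cohort_feature_table(spec: CohortSpec, fit_cfg: FitConfig | None = None,
                         workers: int = 1,
                         cohorts: tuple[str, ...] = ("A", "B", "C", "D"),
                         ) -> pd.DataFrame:
    """Absolute-value feature table over all requested cohorts.

    One row per (subject, day, replicate) with label columns first, then
    the 1128 catalog features, then the per-subject MVD where defined.
    """
    fit_cfg = fit_cfg or FitConfig()
    coll = generate_cohorts(spec)
    rows = []
    for cohort in cohorts:
        for ds in coll.datasets(cohort):
            feats = _dataset_features(ds, fit_cfg, workers, spec.spacing_zyx)
            rec = {"subject": ds.subject_id, "day": ds.day,
                   "replicate": ds.replicate, "cohort": ds.cohort,
                   "arm": ds.arm}
            rec.update(feats.to_dict())
            man = coll.manifest
            sel = man[(man["subject"] == ds.subject_id) & (man["day"] == ds.day)
                      & (man["replicate"] == ds.replicate)]
            rec["mvd"] = float(sel["mvd"].iloc[0]) if len(sel) else np.nan
            rows.append(rec)
    cols = list(LABEL_COLS) + feature_catalog() + ["mvd"]
    return pd.DataFrame(rows, columns=cols)


def fast_study_spec(seed: int) -> CohortSpec:
    """Reduced-scale study conditions for full end-to-end runs on one CPU:
    16^3 voxels, 1 Hz x 90 s (inside the 1-5 Hz 3D frame-rate regime),
    otherwise the default cohort design (n=10/group, days 0/1/3/7/10,
    responder effect 0.4)."""
    return CohortSpec(shape_zyx=(16, 16, 16), frame_rate_hz=1.0,
                      duration_s=90.0, seed=seed)


FAST_FIT = FitConfig(max_iter=8)


def discrimination_study(spec: CohortSpec, fit_cfg: FitConfig | None = None,
                         cv_seed: int = 0, thresholds=None) -> dict:
    """One end-to-end run: simulate A/B/C, select features, CV-evaluate models.

    Returns the 10-fold CV ROC-AUC of PCA-LDA1/PCA-LDA2 (on the selected
    features) and ROI-LDA (on the conventional parameters), plus the
    number of selected features.
    """
    fit_cfg = fit_cfg or FitConfig()
    feats = feature_catalog()
    table = cohort_feature_table(spec, fit_cfg, cohorts=("A", "B", "C"))
    pc_a = percent_change(table[table["cohort"] == "A"][list(LABEL_COLS) + feats])
    pc_b = percent_change(table[table["cohort"] == "B"][list(LABEL_COLS) + feats])
    repeat = table[table["cohort"] == "C"]
    selection = select_features(repeat, pc_a, pc_b, thresholds)
    train = pd.concat([pc_a, pc_b], ignore_index=True)
    y = _labels(train)
    sel_cols = selection.kept if selection.kept else feats
    Xsel = train[sel_cols].to_numpy(dtype=float)
    out = {
        "n_selected": len(selection.kept),
        "PCA-LDA1": cv_evaluate(PCALDAClassifier(n_components=16), Xsel, y,
                                k=10, seed=cv_seed).auc,
        "PCA-LDA2": cv_evaluate(PCALDAClassifier(n_components=2), Xsel, y,
                                k=10, seed=cv_seed).auc,
        "ROI-LDA": cv_evaluate(ROILDAClassifier(),
                               train[ROI_MODEL_COLS].to_numpy(dtype=float), y,
                               k=10, seed=cv_seed).auc,
    }
    return out


def _labels(table: pd.DataFrame) -> np.ndarray:
    # positive class: treated responder; negative: controls and the whole
    # treatment-resistant line
    return ((table["cohort"].isin(["A", "D"])) &
            (table["arm"] == "treated")).to_numpy().astype(int)


def _stage_cached(outdir: Path, stage: str, h: str) -> bool:
    f = outdir / f".{stage}.hash"
    return f.exists() and f.read_text() == h


def _mark_stage(outdir: Path, stage: str, h: str) -> None:
    (outdir / f".{stage}.hash").write_text(h)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full study and return the report dict (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    # ---- stage 1: simulate + fit maps + extract features -----------------
    feat_hash = config.config_hash("cohort", "fit", "workers")
    feat_path = outdir / "features.csv"
    if _stage_cached(outdir, "features", feat_hash) and feat_path.exists():
        log.info("features stage cached; skipping")
        table = pd.read_csv(feat_path)
    else:
        table = cohort_feature_table(config.cohort, config.fit, config.workers)
        table.to_csv(feat_path, index=False)
        _mark_stage(outdir, "features", feat_hash)

    feats = feature_catalog()
    pc_a = percent_change(table[table["cohort"] == "A"][list(LABEL_COLS) + feats])
    pc_b = percent_change(table[table["cohort"] == "B"][list(LABEL_COLS) + feats])
    pc_d = percent_change(table[table["cohort"] == "D"][list(LABEL_COLS) + feats])
    repeat_c = table[table["cohort"] == "C"]

    # ---- stage 2: feature selection --------------------------------------
    sel_hash = config.config_hash("cohort", "fit", "workers", "thresholds")
    sel_path = outdir / "selection.csv"
    selection = select_features(repeat_c, pc_a, pc_b, config.thresholds)
    if not _stage_cached(outdir, "select", sel_hash):
        selection.audit.to_csv(sel_path)
        (outdir / "kept_features.txt").write_text("\n".join(selection.kept) + "\n")
        _mark_stage(outdir, "select", sel_hash)

    # ---- stage 3: models ---------------------------------------------------
    # PCA-LDA models run on the selected features (selection precedes the
    # PCA); the elastic net deliberately receives the full table.
    train = pd.concat([pc_a, pc_b], ignore_index=True)
    sel_cols = selection.kept if selection.kept else feats
    Xsel = train[sel_cols].to_numpy(dtype=float)
    X = train[feats].to_numpy(dtype=float)
    y = _labels(train)
    Xd_sel = pc_d[sel_cols].to_numpy(dtype=float)
    Xd = pc_d[feats].to_numpy(dtype=float)
    yd = _labels(pc_d)
    cv_seed = config.seed + 1

    report: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                    "n_features": len(feats),
                    "n_selected": len(selection.kept),
                    "models": {}}

    def eval_model(name, est, Xtr, ytr, Xte=None, yte=None):
        roc = cv_evaluate(est, Xtr, ytr, k=config.cv_folds, seed=cv_seed)
        entry = {"cv_auc": roc.auc, "cv_ci": [roc.ci_low, roc.ci_high]}
        if Xte is not None and len(np.unique(yte)) == 2:
            fitted = est.fit(Xtr, ytr)
            test_roc = roc_with_ci(fitted.decision_function(Xte), yte.astype(bool))
            entry["test_auc"] = test_roc.auc
            entry["test_ci"] = [test_roc.ci_low, test_roc.ci_high]
        report["models"][name] = entry
        return entry

    for k in config.pca_lda_components:
        name = "PCA-LDA1" if k == max(config.pca_lda_components) else "PCA-LDA2"
        eval_model(name, PCALDAClassifier(n_components=k), Xsel, y, Xd_sel, yd)

    roi_tr = train[ROI_MODEL_COLS].to_numpy(dtype=float)
    roi_te = pc_d[ROI_MODEL_COLS].to_numpy(dtype=float)
    eval_model("ROI-LDA", ROILDAClassifier(), roi_tr, y, roi_te, yd)
    for col in ROI_MODEL_COLS:
        eval_model(f"{col.removeprefix('roi_')}-LDA", ROILDAClassifier(),
                   train[[col]].to_numpy(dtype=float), y,
                   pc_d[[col]].to_numpy(dtype=float), yd)

    # the elastic net is trained once per alpha (lambda by internal 10-fold
    # CV deviance) and evaluated on the held-out test cohort, so no outer CV
    for alpha in config.enet_alphas:
        est = ElasticNetLogisticCV(alpha=alpha, cv=config.cv_folds,
                                   n_lambda=20, max_iter=150,
                                   random_state=config.seed + 2)
        fitted = est.fit(X, y)
        entry = {"n_nonzero": int(fitted.selected_features_.size),
                 "lambda": fitted.lambda_}
        if len(np.unique(yd)) == 2:
            test_roc = roc_with_ci(fitted.decision_function(Xd),
                                   yd.astype(bool))
            entry["test_auc"] = test_roc.auc
            entry["test_ci"] = [test_roc.ci_low, test_roc.ci_high]
        report["models"][f"GLMNET-a{alpha}"] = entry

    # ---- stage 4: histology correlation on cohort D (absolute day-1) ------
    d1 = table[(table["cohort"] == "D") & (table["day"] == 1)]
    mvd = d1["mvd"].to_numpy(dtype=float)
    corr = {}
    if np.isfinite(mvd).sum() >= 5:
        mean_auc = d1["AUC_fo_mean"].to_numpy(dtype=float)
        rho, p = spearman_to_mvd(mean_auc, mvd)
        corr["AUC_fo_mean"] = {"rho": rho, "p": p}
    report["mvd_correlation"] = corr

    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
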