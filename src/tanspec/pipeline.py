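"""Config-driven orchestration of the full experiment grid.

The grid mirrors the standard design of a powdered-herb HSI study:

* classification: 6 pretreatments (ORI, D1, D2, SG, MSC, SNV) x 2 classifiers
  (PLS-DA, SVM) on a stratified 75/25 calibration/prediction split;
* regression: 4 targets (tan_i, tan_iia, cts, total) x 6 pretreatments x 3
  regressors (PLSR, BPNN, RF) on a stratified 70/30 split;
* selection: for the best classifier and each target's best regressor, SPA
  and VISSA channel selection on the calibration set, refit on the selected
  channels and a reduced-vs-full comparison.

One split is shared within each grid so model comparisons are paired.  All
randomness derives from a single root seed through named substreams, so a
full run is bit-reproducible; every stage appends a (stage, seed,
config-hash) record to the run log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import models, preprocess, selection, synthetic
from .evaluation import (
    RegressionReport,
    SplitSpec,
    classification_metrics,
    grade_model,
    regression_metrics,
    split,
)
from .errors import ConfigError
from .synthetic import SyntheticDataset

logger = logging.getLogger(__name__)

CLASSIFIERS = ("PLS-DA", "SVM")
REGRESSORS = ("PLSR", "BPNN", "RF")
TARGETS = ("tan_i", "tan_iia", "cts", "total")


@dataclass
class PipelineConfig:
    """Everything a full run needs; serializable to/from YAML."""

    seed: int = 0
    n_per_origin: int = 84
    scatter_sd: float = 0.05
    noise_sd: float = 0.003
    pretreatments: tuple = preprocess.METHODS
    classifiers: tuple = CLASSIFIERS
    regressors: tuple = REGRESSORS
    targets: tuple = TARGETS
    classification_ratio: float = 0.75
    regression_ratio: float = 0.7
    window: int = 11
    polyorder: int = 2
    plsda_lv_min: int = 4
    plsda_lv_max: int = 15
    plsr_max_lv: int = 15
    bpnn_hidden: int = 10
    bpnn_epochs: int = 500
    svm_c: float = 1.0
    svm_gamma: float | None = None
    rf_trees: int = 500
    cv_folds: int = 5
    selection: selection.SelectionConfig = field(default_factory=selection.SelectionConfig)

    def __post_init__(self) -> None:
        for m in self.pretreatments:
            if m not in preprocess.METHODS:
                raise ConfigError(f"unknown pretreatment {m!r}")
        for c in self.classifiers:
            if c not in CLASSIFIERS:
                raise ConfigError(f"unknown classifier {c!r}")
        for r in self.regressors:
            if r not in REGRESSORS:
                raise ConfigError(f"unknown regressor {r!r}")
        for t in self.targets:
            if t not in TARGETS:
                raise ConfigError(f"unknown target {t!r}")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["pretreatments"] = list(self.pretreatments)
        d["classifiers"] = list(self.classifiers)
        d["regressors"] = list(self.regressors)
        d["targets"] = list(self.targets)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "selection" in d and isinstance(d["selection"], dict):
            d["selection"] = selection.SelectionConfig(**d["selection"])
        for key in ("pretreatments", "classifiers", "regressors", "targets"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage substream seed derived from the root seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % 2**31


@dataclass
class RunLog:
    records: list = field(default_factory=list)

    def add(self, stage: str, seed: int, config_hash: str, **extra) -> None:
        self.records.append({"stage": stage, "seed": seed, "config_hash": config_hash, **extra})

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.records, indent=1))


def make_default_dataset(config: PipelineConfig) -> SyntheticDataset:
    return synthetic.make_dataset(
        seed=config.stage_seed("simulate"),
        n_per_origin=config.n_per_origin,
        scatter_sd=config.scatter_sd,
        noise_sd=config.noise_sd,
    )


def _preprocess_pair(method, X_cal, X_pred, config, segments):
    spec = preprocess.PreprocessSpec(method=method, window=config.window, polyorder=config.polyorder)
    pp = preprocess.Preprocessor(spec, segments=segments)
    return pp.fit_transform(X_cal), pp.transform(X_pred)


# --------------------------------------------------------------------------
# Classification grid
# --------------------------------------------------------------------------


@dataclass
class ClassificationGridResult:
    table: pd.DataFrame  # pretreatment x model accuracies
    best: dict  # {"pretreatment", "model", "accuracy_pred"}
    best_confusion: pd.DataFrame
    cal_idx: np.ndarray
    pred_idx: np.ndarray


def run_classification_grid(
    dataset: SyntheticDataset, config: PipelineConfig, log: RunLog | None = None
) -> ClassificationGridResult:
    """Accuracy of every pretreatment x classifier cell on a shared split."""
    chash = config.config_hash()
    seed = config.stage_seed("classification")
    cal_idx, pred_idx = split(
        dataset.samples, SplitSpec(config.classification_ratio, "origin", seed)
    )
    X = dataset.reflectance
    labels = dataset.samples["origin"].to_numpy()
    segments = dataset.axis.segments()
    rows = []
    confusions = {}
    for method in config.pretreatments:
        Xc, Xp = _preprocess_pair(method, X[cal_idx], X[pred_idx], config, segments)
        for clf_name in config.classifiers:
            if clf_name == "PLS-DA":
                clf = models.fit_plsda(
                    Xc,
                    labels[cal_idx],
                    lv_range=range(config.plsda_lv_min, config.plsda_lv_max + 1),
                    cv_folds=config.cv_folds,
                    seed=seed,
                )
            else:
                clf = models.fit_svm(Xc, labels[cal_idx], C=config.svm_c, gamma=config.svm_gamma)
            rep_cal = classification_metrics(labels[cal_idx], clf.predict(Xc))
            rep_pred = classification_metrics(labels[pred_idx], clf.predict(Xp))
            rows.append(
                {
                    "pretreatment": method,
                    "model": clf_name,
                    "accuracy_cal_percent": rep_cal.accuracy_percent,
                    "accuracy_pred_percent": rep_pred.accuracy_percent,
                    "n_lv": getattr(clf, "n_lv", None),
                }
            )
            confusions[(method, clf_name)] = rep_pred.confusion
            if log is not None:
                log.add("classification", seed, chash, pretreatment=method, model=clf_name)
    table = pd.DataFrame(rows)
    ib = table["accuracy_pred_percent"].idxmax()
    best = {
        "pretreatment": table.loc[ib, "pretreatment"],
        "model": table.loc[ib, "model"],
        "accuracy_pred": float(table.loc[ib, "accuracy_pred_percent"]),
    }
    return ClassificationGridResult(
        table=table,
        best=best,
        best_confusion=confusions[(best["pretreatment"], best["model"])],
        cal_idx=cal_idx,
        pred_idx=pred_idx,
    )


# --------------------------------------------------------------------------
# Regression grid
# --------------------------------------------------------------------------


def _fit_regressor(kind, X_cal, y_cal, config, seed):
    if kind == "PLSR":
        lv, _ = models.select_plsr_lv(
            X_cal, y_cal, range(1, min(config.plsr_max_lv, len(y_cal) - 1) + 1),
            cv_folds=config.cv_folds, seed=seed,
        )
        return models.fit_plsr(X_cal, y_cal, lv)
    if kind == "BPNN":
        return models.fit_bpnn(
            X_cal, y_cal, hidden_nodes=config.bpnn_hidden, epochs=config.bpnn_epochs, seed=seed
        )
    if kind == "RF":
        return models.fit_rf(X_cal, y_cal, n_trees=config.rf_trees, seed=seed)
    raise ConfigError(f"unknown regressor {kind!r}")


@dataclass
class RegressionGridResult:
    table: pd.DataFrame  # target x pretreatment x model metrics
    best: dict  # target -> {"pretreatment", "model", "rpd", ...}
    component_sum: dict  # diagnostic: total predicted as sum of component models
    cal_idx: np.ndarray
    pred_idx: np.ndarray


def run_regression_grid(
    dataset: SyntheticDataset, config: PipelineConfig, log: RunLog | None = None
) -> RegressionGridResult:
    """Fit every target x pretreatment x regressor cell on a shared split."""
    chash = config.config_hash()
    seed = config.stage_seed("regression")
    cal_idx, pred_idx = split(
        dataset.samples, SplitSpec(config.regression_ratio, "origin", seed)
    )
    X = dataset.reflectance
    segments = dataset.axis.segments()
    rows = []
    pred_store: dict = {}
    pre_cache = {
        m: _preprocess_pair(m, X[cal_idx], X[pred_idx], config, segments)
        for m in config.pretreatments
    }
    for target in config.targets:
        y = dataset.samples[target].to_numpy(dtype=float)
        y_cal, y_pred = y[cal_idx], y[pred_idx]
        for method in config.pretreatments:
            Xc, Xp = pre_cache[method]
            for kind in config.regressors:
                model = _fit_regressor(kind, Xc, y_cal, config, seed)
                mc = regression_metrics(y_cal, model.predict(Xc))
                mp = regression_metrics(y_pred, model.predict(Xp))
                rows.append(
                    RegressionReport(
                        target=target,
                        pretreatment=method,
                        model=kind,
                        r2_cal=mc["r2"],
                        rmsec=mc["rmse"],
                        r2_pred=mp["r2"],
                        rmsep=mp["rmse"],
                        rpd=mp["rpd"],
                    ).__dict__
                )
                pred_store[(target, method, kind)] = model.predict(Xp)
                if log is not None:
                    log.add("regression", seed, chash, target=target, pretreatment=method, model=kind)
    table = pd.DataFrame(rows)
    best = {}
    for target in config.targets:
        sub = table[table["target"] == target]
        ib = sub["rpd"].idxmax()
        best[target] = {
            "pretreatment": table.loc[ib, "pretreatment"],
            "model": table.loc[ib, "model"],
            "r2_pred": float(table.loc[ib, "r2_pred"]),
            "rmsep": float(table.loc[ib, "rmsep"]),
            "rpd": float(table.loc[ib, "rpd"]),
            "grade": table.loc[ib, "grade"],
        }
    component_sum: dict = {}
    if "total" in config.targets and all(t in config.targets for t in synthetic.ANALYTES):
        # diagnostic: predict the total as the sum of each component's best model
        summed = sum(
            pred_store[(t, best[t]["pretreatment"], best[t]["model"])]
            for t in synthetic.ANALYTES
        )
        m = regression_metrics(dataset.samples["total"].to_numpy(dtype=float)[pred_idx], summed)
        component_sum = {
            "r2_pred": m["r2"],
            "rmsep": m["rmse"],
            "rpd": m["rpd"],
            "grade": grade_model(m["r2"], m["rpd"]),
        }
    return RegressionGridResult(
        table=table, best=best, component_sum=component_sum, cal_idx=cal_idx, pred_idx=pred_idx
    )


# --------------------------------------------------------------------------
# Selection stage
# --------------------------------------------------------------------------


@dataclass
class SelectionStageResult:
    table: pd.DataFrame
    selections: dict  # (task, method) -> SelectionResult


def run_selection_stage(
    dataset: SyntheticDataset,
    config: PipelineConfig,
    classification_best: dict | None = None,
    regression_best: dict | None = None,
    log: RunLog | None = None,
) -> SelectionStageResult:
    """SPA and VISSA screening for the best models, with refits.

    For each task the calibration set alone drives selection (SPA's internal
    validation split is carved out of it); the untouched prediction set then
    scores the refit model on the selected channels.
    """
    chash = config.config_hash()
    seed = config.stage_seed("selection")
    segments = dataset.axis.segments()
    X = dataset.reflectance
    rows = []
    selections: dict = {}
    rng_val = np.random.default_rng(seed)

    def run_both(task, Xc, Xp, Yc_sel, refit_eval):
        """Run SPA + VISSA on (Xc, Yc_sel); refit_eval(selected) -> metrics row."""
        n_cal = Xc.shape[0]
        inner = rng_val.permutation(n_cal)
        n_fit = max(2, int(round(0.75 * n_cal)))
        fit_i, val_i = inner[:n_fit], inner[n_fit:]
        k_max = min(config.selection.spa_k_max, n_fit - 2, Xc.shape[1] - 1)
        spa = selection.spa_select(
            Xc[fit_i], Yc_sel[fit_i], Xc[val_i], Yc_sel[val_i],
            k_min=min(config.selection.spa_k_min, k_max), k_max=k_max,
        )
        vissa = selection.vissa_select(Xc, Yc_sel, config.selection, seed=seed)
        overlap = len(np.intersect1d(spa.selected, vissa.selected))
        for res in (spa, vissa):
            selections[(task, res.method)] = res
            entry = {
                "task": task,
                "method": res.method,
                "n_selected": res.n_selected,
                "reduction_percent": selection.reduction_percent(res.n_selected, X.shape[1]),
                "spa_vissa_overlap": overlap,
            }
            if res.n_selected < 2:
                logger.warning("%s/%s selected < 2 channels; refit skipped", task, res.method)
                entry["refit_skipped"] = True
            else:
                entry.update(refit_eval(res.selected))
            rows.append(entry)
            if log is not None:
                log.add("selection", seed, chash, task=task, method=res.method)

    if classification_best is not None:
        cal_idx, pred_idx = split(
            dataset.samples,
            SplitSpec(config.classification_ratio, "origin", config.stage_seed("classification")),
        )
        labels = dataset.samples["origin"].to_numpy()
        method = classification_best["pretreatment"]
        Xc, Xp = _preprocess_pair(method, X[cal_idx], X[pred_idx], config, segments)
        classes = list(pd.unique(labels[cal_idx]))
        Y_ind = (labels[cal_idx, None] == np.asarray(classes, dtype=object)[None, :]).astype(float)

        def refit_cls(sel):
            clf = models.fit_plsda(
                Xc[:, sel], labels[cal_idx],
                lv_range=range(config.plsda_lv_min, min(config.plsda_lv_max, len(sel)) + 1),
                cv_folds=config.cv_folds, seed=seed,
            )
            return {
                "accuracy_cal_percent": classification_metrics(
                    labels[cal_idx], clf.predict(Xc[:, sel])
                ).accuracy_percent,
                "accuracy_pred_percent": classification_metrics(
                    labels[pred_idx], clf.predict(Xp[:, sel])
                ).accuracy_percent,
                "n_lv": clf.n_lv,
            }

        run_both(f"classify:{method}-PLS-DA", Xc, Xp, Y_ind, refit_cls)

    if regression_best:
        cal_idx, pred_idx = split(
            dataset.samples,
            SplitSpec(config.regression_ratio, "origin", config.stage_seed("regression")),
        )
        for target, info in regression_best.items():
            method, kind = info["pretreatment"], info["model"]
            Xc, Xp = _preprocess_pair(method, X[cal_idx], X[pred_idx], config, segments)
            y = dataset.samples[target].to_numpy(dtype=float)
            y_cal, y_pred = y[cal_idx], y[pred_idx]

            def refit_reg(sel, Xc=Xc, Xp=Xp, y_cal=y_cal, y_pred=y_pred, kind=kind):
                model = _fit_regressor(kind, Xc[:, sel], y_cal, config, seed)
                mc = regression_metrics(y_cal, model.predict(Xc[:, sel]))
                mp = regression_metrics(y_pred, model.predict(Xp[:, sel]))
                return {
                    "r2_cal": mc["r2"], "rmsec": mc["rmse"],
                    "r2_pred": mp["r2"], "rmsep": mp["rmse"], "rpd": mp["rpd"],
                    "grade": grade_model(mp["r2"], mp["rpd"]),
                }

            run_both(f"regress:{target}:{method}-{kind}", Xc, Xp, y_cal, refit_reg)

    return SelectionStageResult(table=pd.DataFrame(rows), selections=selections)


# --------------------------------------------------------------------------
# Full run
# --------------------------------------------------------------------------


def run_all(config: PipelineConfig, outdir=None) -> dict:
    """Simulate, run both grids and the selection stage; optionally write
    tables, selection JSON and the run log under *outdir*."""
    log = RunLog()
    chash = config.config_hash()
    log.add("simulate", config.stage_seed("simulate"), chash)
    dataset = make_default_dataset(config)
    cls_res = run_classification_grid(dataset, config, log)
    reg_res = run_regression_grid(dataset, config, log)
    sel_res = run_selection_stage(
        dataset, config, classification_best=cls_res.best,
        regression_best=reg_res.best, log=log,
    )
    results = {
        "dataset": dataset,
        "classification": cls_res,
        "regression": reg_res,
        "selection": sel_res,
        "log": log,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
        cls_res.table.to_csv(outdir / "classification_grid.csv", index=False)
        cls_res.best_confusion.to_csv(outdir / "best_confusion.csv")
        reg_res.table.to_csv(outdir / "regression_grid.csv", index=False)
        sel_res.table.to_csv(outdir / "selection_stage.csv", index=False)
        for (task, method), res in sel_res.selections.items():
            safe = task.replace(":", "_").replace("/", "_")
            res.to_json(outdir / f"selection_{safe}_{method}.json", dataset.axis.wavelengths_nm)
        log.write(outdir / "run_log.json")
    return results
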