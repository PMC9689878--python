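"""End-to-end study orchestration.

Runs the full design on one dataset: PCA/T^2 outlier gate -> Kennard-
Stone split -> {raw, MSC+SD} x {none, VIP, LVs, SPA, CARS} x
{PLS-DA, SVM}, plus {raw plots, MSC+SD plots, synchronous 2DCOS maps} x
residual CNN on a 60/30/10 three-way split — and collects everything in
a machine-readable RunReport (the analogue of the study's result
tables).

Leak control: in the default leak-free mode the MSC reference, every
variable selection, every latent-variable choice, and every model fit
see training rows only; the report's leak audit records which sample
indices entered each fitted stage so this can be asserted. A
paper-faithful mode (preprocess before splitting, dataset-wide class
means for 2DCOS) is available behind a flag.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import pls as plsmod
from . import varsel
from .dataset import SpectralDataset
from .pca_outliers import gate_outliers
from .preprocess import SavGolConfig, msc, preprocess_pipeline, savgol_second_derivative
from .rescnn import CNNConfig, build_model, evaluate as cnn_evaluate, rasterize_spectra, sync_maps_to_images, train as cnn_train
from .sampling import split_dataset
from .svm_grid import CannotBuildError, default_c_grid, default_g_grid, evaluate_svm, grid_search_svm
from .synthetic import SyntheticConfig, generate_dataset
from .twodcos import bin_to_grid

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "summarize", "load_config"]

VARIANTS = ("raw", "mscsd")
SELECTIONS = ("none", "vip", "lvs", "spa", "cars")
CNN_INPUTS = ("raw", "mscsd", "sync2dcos")


@dataclass
class PipelineConfig:
    seed: int = 0
    dataset_path: str | None = None  # delimited table; None -> synthetic
    synthetic: dict = field(default_factory=dict)
    leak_free: bool = True
    outlier_components: int = 2
    outlier_alpha: float = 0.05
    train_fraction: float = 0.7
    cnn_fractions: dict = field(
        default_factory=lambda: {"train": 0.6, "test": 0.3, "validation": 0.1}
    )
    variants: tuple = VARIANTS
    selections: tuple = SELECTIONS
    cnn_inputs: tuple = CNN_INPUTS
    savgol_window: int = 15
    savgol_polyorder: int = 2
    max_lv: int = 10
    k_folds: int = 7
    vip_threshold: float = 1.0
    spa_max_vars: int = 25
    spa_start_stride: int = 1
    cars_runs: int = 50
    cars_mc_fraction: float = 0.8
    svm_grid_step: float = 1.0
    run_permutation: bool = False
    n_permutations: int = 200
    cnn_epochs: int = 20
    cnn_batch_size: int = 16
    n_bins: int = 64

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        for key in ("variants", "selections", "cnn_inputs"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


def load_config(path: str | Path) -> PipelineConfig:
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


@dataclass
class RunReport:
    config: dict
    removed_outliers: list
    split: dict
    plsda: dict = field(default_factory=dict)
    svm: dict = field(default_factory=dict)
    cnn: dict = field(default_factory=dict)
    selections: dict = field(default_factory=dict)
    overlaps: dict = field(default_factory=dict)
    leak_audit: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, (np.bool_,)):
                return bool(o)
            raise TypeError(type(o))

        Path(path).write_text(json.dumps(asdict(self) | {"plsda": self.plsda, "svm": self.svm, "cnn": self.cnn}, indent=2, default=_default))


def _record_stage(report: RunReport, stage: str, indices: np.ndarray) -> None:
    report.leak_audit[stage] = sorted(int(i) for i in np.asarray(indices).ravel())


def audit_leak_free(report: RunReport) -> bool:
    """True iff no held-out index entered any fitted-stage computation.

    The PLS/SVM branch and the CNN branch use different splits; each
    stage is checked against the holdout of its own branch.
    """
    plsvm_held = set(report.split.get("test", []))
    cnn_held = set(report.split.get("cnn_test", [])) | set(
        report.split.get("cnn_validation", [])
    )
    for stage, used in report.leak_audit.items():
        held = cnn_held if stage.startswith("cnn_") else plsvm_held
        if held & set(used):
            return False
    return True


# ------------------------------------------------------------ features


def _preprocessed_matrices(
    dataset: SpectralDataset,
    train_idx: np.ndarray,
    cfg: PipelineConfig,
    report: RunReport,
    stage: str,
):
    """MSC (train-mean reference in leak-free mode) followed by SD."""
    sg = SavGolConfig(cfg.savgol_window, cfg.savgol_polyorder, 2)
    if cfg.leak_free:
        reference = dataset.absorbance[train_idx].mean(axis=0)
        _record_stage(report, f"{stage}:msc_reference", train_idx)
    else:
        reference = None  # grand mean over all rows, as when preprocessing precedes the split
    corrected = msc(dataset, reference=reference).corrected
    return savgol_second_derivative(corrected, sg)


def _selection_features(
    X_train: np.ndarray,
    labels_train: np.ndarray,
    X_test: np.ndarray,
    selection: str,
    cfg: PipelineConfig,
    seed: int,
):
    """Return (features_train, features_test, SelectionResult | None, lv_hint)."""
    p = X_train.shape[1]
    if selection == "none":
        return X_train, X_test, None, None
    if selection == "vip":
        a, _ = plsmod.select_lv_by_q2(X_train, labels_train, min(cfg.max_lv, X_train.shape[0] - 1, p), k_folds=cfg.k_folds, seed=seed)
        model = plsmod.fit_plsda(X_train, labels_train, a)
        result = varsel.select_vip(plsmod.vip_scores(model), cfg.vip_threshold, grid_points=p)
    elif selection == "lvs":
        a, curve = plsmod.select_lv_by_q2(X_train, labels_train, min(cfg.max_lv, X_train.shape[0] - 1, p), k_folds=cfg.k_folds, seed=seed)
        model = plsmod.fit_plsda(X_train, labels_train, a)
        result = varsel.SelectionResult(
            method="lvs",
            indices=np.arange(a),
            curve={"n_components": list(range(1, len(curve) + 1)), "q2": curve.tolist()},
            settings={"n_components": a},
            grid_points=p,
        )
        return model.T.copy(), model.transform(X_test), result, a
    elif selection == "spa":
        starts = np.arange(0, p, cfg.spa_start_stride)
        result = varsel.spa(
            X_train, labels_train, cfg.spa_max_vars, k_folds=cfg.k_folds, seed=seed, starts=starts
        )
    elif selection == "cars":
        result = varsel.cars(
            X_train,
            labels_train,
            n_runs=cfg.cars_runs,
            mc_fraction=cfg.cars_mc_fraction,
            k_folds=cfg.k_folds,
            seed=seed,
        )
    else:
        raise ValueError(f"unknown selection {selection!r}")
    cols = result.indices
    return X_train[:, cols], X_test[:, cols], result, None


def _plsda_cell(Xtr, ytr, Xte, yte, cfg: PipelineConfig, seed: int, lv_hint: int | None) -> dict:
    max_a = min(cfg.max_lv, Xtr.shape[0] - 1, Xtr.shape[1])
    if lv_hint is not None:
        a = min(lv_hint, max_a)
    else:
        a, _ = plsmod.select_lv_by_q2(Xtr, ytr, max_a, k_folds=cfg.k_folds, seed=seed)
    model = plsmod.fit_plsda(Xtr, ytr, a)
    cv = plsmod.cross_validate(Xtr, ytr, a, k_folds=cfg.k_folds, seed=seed)
    metrics = plsmod.compute_metrics(model, Xtr, ytr, Xte, yte, cv)
    cell = {
        "n_components": a,
        "r2": metrics.r2,
        "q2": metrics.q2,
        "rmsee": metrics.rmsee,
        "rmsecv": metrics.rmsecv,
        "rmsep": metrics.rmsep,
        "train_accuracy": metrics.train_accuracy,
        "test_accuracy": metrics.test_accuracy,
    }
    if cfg.run_permutation:
        verdict = plsmod.permutation_test(
            Xtr, ytr, a, n_permutations=cfg.n_permutations, k_folds=cfg.k_folds, seed=seed
        )
        cell["permutation"] = {
            "r2_intercept": verdict.r2_intercept,
            "q2_intercept": verdict.q2_intercept,
            "overfitting": verdict.overfitting,
        }
    return cell


def _svm_cell(Xtr, ytr, Xte, yte, cfg: PipelineConfig, seed: int) -> dict:
    try:
        search = grid_search_svm(
            Xtr,
            ytr,
            c_grid=default_c_grid(cfg.svm_grid_step),
            g_grid=default_g_grid(cfg.svm_grid_step),
            k_folds=cfg.k_folds,
            seed=seed,
        )
    except CannotBuildError as exc:
        return {"error": str(exc), "best_c": None, "best_g": None}
    accuracy, cm = evaluate_svm(search, Xte, yte)
    return {
        "best_c": search.best_c,
        "best_g": search.best_g,
        "train_accuracy": search.train_accuracy,
        "test_accuracy": accuracy,
        "confusion_matrix": cm.tolist(),
    }


def _cnn_images(dataset: SpectralDataset, kind: str, split, cfg: PipelineConfig, report: RunReport) -> np.ndarray:
    """64 x 64 single-channel inputs for every sample, by input kind."""
    if kind == "raw":
        return rasterize_spectra(dataset.absorbance, 64)
    if kind == "mscsd":
        pre = _preprocessed_matrices(dataset, split.train, cfg, report, "cnn_mscsd")
        return rasterize_spectra(pre.absorbance, 64)
    if kind == "sync2dcos":
        # Scatter-correct before the correlation transform: multiplicative
        # scatter otherwise dominates the dynamic spectra and buries the
        # compositional cross-peak structure the maps are meant to expose.
        if cfg.leak_free:
            reference = dataset.absorbance[split.train].mean(axis=0)
            _record_stage(report, "cnn_sync2dcos:msc_reference", split.train)
        else:
            reference = None
        corrected = msc(dataset, reference=reference).corrected
        binned = bin_to_grid(corrected, cfg.n_bins)
        maps = []
        ref_idx = split.train if cfg.leak_free else np.arange(dataset.n_samples)
        _record_stage(report, "cnn_sync2dcos:class_means", ref_idx)
        for i in range(binned.n_samples):
            label = binned.labels[i]
            cls = np.intersect1d(binned.class_indices(label), ref_idx)
            if cls.size < 2:
                cls = binned.class_indices(label)
            d = binned.absorbance[i] - binned.absorbance[cls].mean(axis=0)
            maps.append(np.outer(d, d) / (cls.size - 1))
        return sync_maps_to_images(maps)
    raise ValueError(f"unknown CNN input kind {kind!r}")


def _cnn_cell(dataset: SpectralDataset, kind: str, cfg: PipelineConfig, report: RunReport) -> dict:
    split = split_dataset(dataset, dict(cfg.cnn_fractions))
    report.split.setdefault("cnn_train", dataset.sample_ids[split.train].tolist())
    report.split.setdefault("cnn_test", sorted(int(i) for i in split.test))
    report.split.setdefault("cnn_validation", sorted(int(i) for i in split.validation))
    images = _cnn_images(dataset, kind, split, cfg, report)
    classes = np.unique(dataset.labels)
    y = np.searchsorted(classes, dataset.labels)
    net_cfg = CNNConfig(
        n_classes=classes.size,
        max_epochs=cfg.cnn_epochs,
        batch_size=cfg.cnn_batch_size,
        seed=cfg.seed,
    )
    net = build_model(net_cfg)
    _record_stage(report, f"cnn_{kind}:fit", split.train)
    history = cnn_train(
        net, images[split.train], y[split.train], images[split.test], y[split.test], net_cfg
    )
    test_acc, test_cm = cnn_evaluate(net, images[split.test], y[split.test])
    val_acc, val_cm = cnn_evaluate(net, images[split.validation], y[split.validation])
    return {
        "epochs": history.n_epochs,
        "final_loss": history.loss[-1],
        "train_accuracy": 100.0 * history.train_accuracy[-1],
        "test_accuracy": 100.0 * test_acc,
        "validation_accuracy": 100.0 * val_acc,
        "history_loss": history.loss,
        "history_train_accuracy": history.train_accuracy,
        "history_test_accuracy": history.test_accuracy,
        "validation_confusion": val_cm.tolist(),
    }


# ------------------------------------------------------------- driver


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    if cfg.dataset_path is not None:
        dataset = SpectralDataset.from_table(cfg.dataset_path)
    else:
        syn = SyntheticConfig(**({"seed": cfg.seed} | dict(cfg.synthetic)))
        dataset, _ = generate_dataset(syn)

    gated, verdict, pca = gate_outliers(dataset, cfg.outlier_components, cfg.outlier_alpha)
    report = RunReport(
        config=asdict(cfg),
        removed_outliers=gated.meta.get("removed_outlier_ids", []),
        split={},
    )
    report.config["pca_explained_variance_ratio"] = pca.explained_variance_ratio.tolist()
    report.config["t2_limit"] = verdict.limit

    split = split_dataset(gated, {"train": cfg.train_fraction})
    report.split["train"] = sorted(int(i) for i in split.train)
    report.split["test"] = sorted(int(i) for i in split.test)
    report.split["train_ids"] = gated.sample_ids[split.train].tolist()
    report.split["test_ids"] = gated.sample_ids[split.test].tolist()

    labels = gated.labels
    for variant in cfg.variants:
        if variant == "raw":
            data = gated
        elif variant == "mscsd":
            data = _preprocessed_matrices(gated, split.train, cfg, report, "mscsd")
        else:
            raise ValueError(f"unknown variant {variant!r}")
        Xtr_full, Xte_full = data.absorbance[split.train], data.absorbance[split.test]
        ytr, yte = labels[split.train], labels[split.test]
        variant_selections = {}
        for selection in cfg.selections:
            cell_name = f"{variant}/{selection}"
            _record_stage(report, f"{cell_name}:selection_and_fit", split.train)
            try:
                Xtr, Xte, sel, lv_hint = _selection_features(
                    Xtr_full, ytr, Xte_full, selection, cfg, cfg.seed
                )
            except varsel.EmptySelectionError as exc:
                report.plsda[cell_name] = {"error": str(exc)}
                report.svm[cell_name] = {"error": str(exc)}
                continue
            if sel is not None:
                report.selections[cell_name] = {
                    "method": sel.method,
                    "n_selected": sel.n_selected,
                    "indices": sel.indices.tolist(),
                    "score": sel.score,
                    "settings": dict(sel.settings),
                }
                if sel.method in ("vip", "spa", "cars"):
                    variant_selections[sel.method] = sel
            try:
                report.plsda[cell_name] = _plsda_cell(Xtr, ytr, Xte, yte, cfg, cfg.seed, lv_hint)
            except ValueError as exc:
                report.plsda[cell_name] = {"error": str(exc)}
            try:
                report.svm[cell_name] = _svm_cell(Xtr, ytr, Xte, yte, cfg, cfg.seed)
            except ValueError as exc:
                report.svm[cell_name] = {"error": str(exc)}
        if len(variant_selections) >= 2:
            report.overlaps[variant] = varsel.compare_selections(list(variant_selections.values()))

    for kind in cfg.cnn_inputs:
        try:
            report.cnn[kind] = _cnn_cell(gated, kind, cfg, report)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"CNN cell {kind} failed: {exc}")
            report.cnn[kind] = {"error": str(exc)}
    return report


def summarize(report: RunReport) -> dict:
    """Best cell per model family by test accuracy."""
    if not (report.plsda or report.svm or report.cnn):
        raise ValueError("empty report")
    summary: dict[str, Any] = {}
    for family, cells in (("plsda", report.plsda), ("svm", report.svm), ("cnn", report.cnn)):
        best_name, best_acc = None, -1.0
        for name, cell in cells.items():
            acc = cell.get("test_accuracy")
            if acc is not None and acc > best_acc:
                best_name, best_acc = name, acc
        if best_name is not None:
            summary[family] = {"cell": best_name, "test_accuracy": best_acc}
    return summary
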