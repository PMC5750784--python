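"""End-to-end orchestration: simulate -> preprocess -> cycles -> images ->
per-source identifiers -> fusion -> report.

The pipeline mirrors the identification system's flow on the bundled
synthetic simulator, with every random draw tied to a single seed.  Two
evaluation protocols are available: a stratified holdout split (default;
suited to desk-scale runs) and the full ten-fold cross-validation protocol
(``split="10cv"``, ten times the training cost).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .cnn import DcnnConfig, Model, build_model, train_model
from .cycles import (estimate_cycle_frequency, extract_cycles,
                     find_local_windows, map_cycles_to_sensors)
from .evaluate import (evaluate_accuracy, make_10cv_splits,
                       relative_error_reduction)
from .fusion import (CANONICAL_SOURCES, ScoreTensor, early_fuse, fuse_scores,
                     learn_thresholds, llr_normalize, mesf_learn,
                     predict_identity, sum_fusion, svm_fusion_apply,
                     svm_fusion_train)
from .preprocess import bandpass, calibrate_rest_bias, resultant_of
from .simulate import (SessionSpec, make_population, random_rotation,
                       simulate_session)
from .tfr import TFConfig, cycle_image, load_colormap

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; serializable to/from JSON."""

    n_subjects: int = 5
    duration: float = 50.0
    rest_seconds: float = 5.0
    fs: float = 50.0
    seed: int = 0
    image_size: int = 120
    resample_len: int = 128
    epochs: int = 19
    batch_size: int = 40
    learning_rate: float = 0.001
    momentum: float = 0.9
    pool_mode: str = "max"
    amp_thresh: float = 0.05
    split: str = "holdout"       # "holdout" or "10cv"
    test_frac: float = 0.2
    val_frac: float = 0.16
    fusion_methods: Tuple[str, ...] = ("mesf", "sum", "svm")
    early_fusion: bool = False

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "fusion_methods" in d:
            d["fusion_methods"] = tuple(d["fusion_methods"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Stage 1: synthetic sessions -> per-source image tensors
# ---------------------------------------------------------------------------

def build_image_dataset(cfg: PipelineConfig):
    """Simulate every subject, extract cycles, and render all TF images.

    Returns (per-source image tensors {source: (T, 3, H, W)}, labels (T,),
    early-fusion tensor (T, 30, H, W) or None, diagnostics).
    """
    profiles = make_population(cfg.n_subjects, cfg.seed)
    rot_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x507)))
    tfcfg = TFConfig(resample_len=cfg.resample_len, image_size=cfg.image_size)
    lut = load_colormap()
    per_source: Dict[Tuple[int, str], List[np.ndarray]] = \
        {k: [] for k in CANONICAL_SOURCES}
    labels: List[int] = []
    early_stacks: List[np.ndarray] = []
    diagnostics = {"fcycle_true": {}, "fcycle_est": {}, "n_cycles": {}}
    for profile in profiles:
        spec = SessionSpec(duration=cfg.duration, fs=cfg.fs,
                           rest_seconds=cfg.rest_seconds,
                           rotation=random_rotation(rot_rng), seed=cfg.seed)
        recs = simulate_session(profile, spec)
        calibrated = {k: calibrate_rest_bias(r) for k, r in recs.items()}
        resultants = {k: resultant_of(r) for k, r in calibrated.items()}
        filtered = {k: bandpass(r) for k, r in resultants.items()}
        ref = filtered[(1, "acc")]
        est = estimate_cycle_frequency(resultants[(1, "acc")])
        windows = find_local_windows(ref, amp_thresh=cfg.amp_thresh)
        cycles = extract_cycles(ref, windows, est.fcycle)
        gaits = map_cycles_to_sensors(cycles, filtered,
                                      subject_id=profile.subject_id)
        sid = profile.subject_id
        diagnostics["fcycle_true"][sid] = profile.fcycle
        diagnostics["fcycle_est"][sid] = est.fcycle
        diagnostics["n_cycles"][sid] = len(gaits)
        for g in gaits:
            imgs = {}
            for key in CANONICAL_SOURCES:
                img = cycle_image(g.excerpts[key], cfg.fs, tfcfg, label=sid,
                                  colormap=lut,
                                  provenance=(key[0], key[1], g.cycle_id))
                imgs[key] = img
                per_source[key].append(img.pixels.transpose(2, 0, 1))
            labels.append(sid)
            if cfg.early_fusion:
                early_stacks.append(early_fuse(imgs).pixels.transpose(2, 0, 1))
    X = {k: np.stack(v).astype(np.float32) for k, v in per_source.items()}
    y = np.asarray(labels, dtype=int)
    X_early = np.stack(early_stacks).astype(np.float32) if early_stacks else None
    return X, y, X_early, diagnostics


# ---------------------------------------------------------------------------
# Stage 2: splits
# ---------------------------------------------------------------------------

def holdout_split(labels: np.ndarray, seed: int, test_frac: float,
                  val_frac: float):
    """One stratified (train, val, test) split of segment indices."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5711)))
    train, val, test = [], [], []
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        n_test = max(1, int(round(test_frac * len(idx))))
        n_val = max(1, int(round(val_frac * len(idx))))
        test.extend(idx[:n_test])
        val.extend(idx[n_test:n_test + n_val])
        train.extend(idx[n_test + n_val:])
    return np.sort(train), np.sort(val), np.sort(test)


# ---------------------------------------------------------------------------
# Stage 3+4: training and fusion on one split
# ---------------------------------------------------------------------------

def _score_tensor(models: List[Model], X_by_source, idx, labels) -> ScoreTensor:
    cols = []
    for model, key in zip(models, CANONICAL_SOURCES):
        log_p, _ = model.predict_scores(X_by_source[key][idx])
        cols.append(log_p)
    return ScoreTensor(scores=np.stack(cols, axis=1), labels=labels[idx])


def run_split(cfg: PipelineConfig, X, y, X_early, train_idx, val_idx, test_idx,
              seed_offset: int = 0) -> Dict:
    """Train the per-source identifiers on one split and fuse their scores."""
    M = int(y.max())
    models: List[Model] = []
    for s_idx, key in enumerate(CANONICAL_SOURCES):
        dcfg = DcnnConfig(learning_rate=cfg.learning_rate,
                          momentum=cfg.momentum, batch_size=cfg.batch_size,
                          epochs=cfg.epochs, num_classes=M,
                          image_size=cfg.image_size, pool_mode=cfg.pool_mode,
                          seed=(cfg.seed * 1000 + seed_offset * 20 + s_idx) % (2 ** 31))
        model = build_model(dcfg, source_id=key)
        train_model(model, X[key][train_idx], y[train_idx], dcfg)
        models.append(model)
        logger.info("trained source %s: final train acc %.1f%%", key,
                    model.history[-1]["train_acc"])

    train_scores = _score_tensor(models, X, train_idx, y)
    val_scores = _score_tensor(models, X, val_idx, y)
    test_scores = _score_tensor(models, X, test_idx, y)

    result: Dict = {"per_source_test_acc": {}}
    for i, key in enumerate(CANONICAL_SOURCES):
        preds = np.argmax(test_scores.scores[:, i, :], axis=1) + 1
        result["per_source_test_acc"]["%s_%s" % key] = \
            evaluate_accuracy(preds, test_scores.labels).overall
    best_key = max(result["per_source_test_acc"],
                   key=result["per_source_test_acc"].get)
    result["best_single"] = {"source": best_key,
                             "accuracy": result["per_source_test_acc"][best_key]}

    if "sum" in cfg.fusion_methods:
        preds = np.argmax(sum_fusion(test_scores.scores), axis=1) + 1
        result["sum"] = {"accuracy": evaluate_accuracy(
            preds, test_scores.labels).overall}
    if "mesf" in cfg.fusion_methods:
        theta = learn_thresholds(llr_normalize(sum_fusion(val_scores.scores)),
                                 val_scores.labels)
        weights = mesf_learn(train_scores, theta)
        preds, _ = predict_identity(test_scores.scores, weights.w, weights.theta)
        report = evaluate_accuracy(preds, test_scores.labels)
        result["mesf"] = {"accuracy": report.overall,
                          "per_subject": report.per_subject,
                          "error_trace": weights.error_trace,
                          "theta": weights.theta.tolist(),
                          "w": weights.w.tolist()}
    if "svm" in cfg.fusion_methods:
        svm = svm_fusion_train(train_scores)
        preds = np.argmax(svm_fusion_apply(svm, test_scores.scores), axis=1) + 1
        result["svm"] = {"accuracy": evaluate_accuracy(
            preds, test_scores.labels).overall}

    if cfg.early_fusion and X_early is not None:
        dcfg = DcnnConfig(learning_rate=cfg.learning_rate,
                          momentum=cfg.momentum, batch_size=cfg.batch_size,
                          epochs=cfg.epochs, num_classes=M,
                          input_channels=30, image_size=cfg.image_size,
                          pool_mode=cfg.pool_mode,
                          seed=(cfg.seed * 1000 + seed_offset * 20 + 11) % (2 ** 31))
        model = build_model(dcfg, source_id=(0, "early"))
        train_model(model, X_early[train_idx], y[train_idx], dcfg)
        preds = model.predict(X_early[test_idx])
        result["early"] = {"accuracy": evaluate_accuracy(
            preds, y[test_idx]).overall}
    return result


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig, out_dir: Optional[str] = None) -> Dict:
    """Full run: simulate, identify, fuse, report.

    Returns the report dict; when ``out_dir`` is given the report and config
    are also written there as JSON.
    """
    t0 = time.time()
    logger.info("pipeline seed = %d", cfg.seed)
    X, y, X_early, diagnostics = build_image_dataset(cfg)
    n = len(y)
    report: Dict = {"config": {**asdict(cfg),
                               "fusion_methods": list(cfg.fusion_methods)},
                    "seed": cfg.seed, "n_segments": n,
                    "diagnostics": diagnostics}
    if cfg.split == "holdout":
        train_idx, val_idx, test_idx = holdout_split(
            y, cfg.seed, cfg.test_frac, cfg.val_frac)
        report["split_sizes"] = {"train": len(train_idx), "val": len(val_idx),
                                 "test": len(test_idx)}
        report.update(run_split(cfg, X, y, X_early, train_idx, val_idx, test_idx))
    elif cfg.split == "10cv":
        splits = make_10cv_splits(n, cfg.seed, labels=y)
        fold_results = []
        for f, (test_idx, val_idx, train_idx) in enumerate(splits):
            fold_results.append(run_split(cfg, X, y, X_early, train_idx,
                                          val_idx, test_idx, seed_offset=f))
        report["folds"] = fold_results
        for method in ("sum", "mesf", "svm", "early"):
            accs = [fr[method]["accuracy"] for fr in fold_results
                    if method in fr]
            if accs:
                report[method] = {"accuracy": float(np.mean(accs)),
                                  "per_fold": accs}
        best = [fr["best_single"]["accuracy"] for fr in fold_results]
        report["best_single"] = {"accuracy": float(np.mean(best))}
    else:
        raise ValueError(f"unknown split protocol {cfg.split!r}")

    if "mesf" in report and "best_single" in report:
        a = report["mesf"]["accuracy"]
        b = report["best_single"]["accuracy"]
        if b < 100.0 and a >= b:
            report["mesf_relative_error_reduction"] = \
                relative_error_reduction(a, b)
    report["elapsed_s"] = round(time.time() - t0, 1)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=float)
    return report
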