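"""End-to-end stratified cross-validation of the seating classifier.

Wires together ray-feature extraction, training-time augmentation
(contralateral mirroring once per fold; per-epoch rigid jitter of the
hemisphere with stochastic imputation) and the feed-forward classifier,
then pools the per-fold validation predictions into the final confusion
matrix and metrics.  Mirrored copies inherit their source joint's fold, so
a joint and its mirror never straddle the train/validation boundary.
Validation features are always cast with zero perturbation and midpoint
imputation, so evaluation is deterministic.

Every random stream (split, augmentation, weight init, imputation) has its
own seed derived by name from a single master seed, making two runs with
the same master seed byte-identical.
"""

from __future__ import annotations

import json
import zlib
from typing import Dict, Optional

import numpy as np

from .augmentation import (
    AugmentationConfig,
    imputation_seed,
    mirror_pair,
    sample_perturbation,
)
from .classifier import (
    FeedForwardClassifier,
    NetworkSpec,
    PredictionConfig,
    TrainingConfig,
)
from .evaluation import (
    ConfusionMatrix,
    compute_metrics,
    confusion,
    roc_auc,
    stratified_kfold,
)
from .geometry import DirectionSet
from .io import LabelVolume
from .raycast import extract_features


def derive_seed(master_seed: int, name: str) -> int:
    """A named child seed in [0, 2^31), stable across runs and platforms."""
    return zlib.crc32(f"{master_seed}:{name}".encode("utf-8")) % (2**31)


def extract_feature_matrix(
    volumes: Dict[str, LabelVolume],
    joint_ids: list,
    ds: DirectionSet,
) -> np.ndarray:
    """Deterministic features (no perturbation, midpoint imputation)."""
    return np.stack(
        [
            extract_features(volumes[j], ds, joint_id=j).distances
            for j in joint_ids
        ]
    )


def run_cross_validation(
    volumes: Dict[str, LabelVolume],
    labels: Dict[str, str],
    ds: DirectionSet,
    net: Optional[NetworkSpec] = None,
    tcfg: Optional[TrainingConfig] = None,
    pcfg: Optional[PredictionConfig] = None,
    aug: Optional[AugmentationConfig] = None,
    k: int = 5,
    epochs: Optional[int] = None,
    master_seed: int = 0,
) -> dict:
    """Full k-fold protocol; returns a JSON-serialisable results dict."""
    net = net or NetworkSpec(input_dim=ds.n)
    if net.input_dim != ds.n:
        raise ValueError(f"network input_dim {net.input_dim} != n directions {ds.n}")
    tcfg = tcfg or TrainingConfig()
    pcfg = pcfg or PredictionConfig()
    aug = aug or AugmentationConfig(rng_seed=derive_seed(master_seed, "augment"))
    epochs = tcfg.epochs if epochs is None else epochs

    split = stratified_kfold(labels, k=k, rng_seed=derive_seed(master_seed, "split"))
    mirrored: Dict[str, LabelVolume] = {}
    if aug.mirror:
        mirrored = {j: mirror_pair(volumes[j]) for j in labels}

    fold_results = []
    pooled_ids: list = []
    pooled_conf: list = []
    pooled_true: list = []
    pooled_pred: list = []

    for fold in range(k):
        train_ids = split.training_ids(fold)
        val_ids = split.validation_ids(fold)
        # mirrored copies double the training fold, never the validation fold
        train_units = [(j, volumes[j], j) for j in train_ids]
        if aug.mirror:
            train_units += [(j + "_mirror", mirrored[j], j) for j in train_ids]
        y_train = np.array(
            [labels[src] == "incorrect" for _, _, src in train_units], dtype=float
        )

        def provider(epoch: int, units=train_units) -> tuple:
            rows = []
            for unit_id, vol, _src in units:
                p = sample_perturbation(aug, epoch, unit_id)
                fv = extract_features(
                    vol,
                    ds,
                    perturbation=p,
                    imputation="uniform",
                    rng_seed=imputation_seed(aug.rng_seed, epoch, unit_id),
                    joint_id=unit_id,
                )
                rows.append(fv.distances)
            return np.stack(rows), y_train

        fold_cfg = TrainingConfig(
            base_lr=tcfg.base_lr,
            max_lr=tcfg.max_lr,
            step_size=tcfg.step_size,
            lr_policy=tcfg.lr_policy,
            batch_size=tcfg.batch_size,
            epochs=epochs,
            class_balancing=tcfg.class_balancing,
            rng_seed=derive_seed(master_seed, f"fold{fold}:init"),
        )
        model = FeedForwardClassifier(net, fold_cfg)
        model.fit_stream(provider, y_train, epochs=epochs)

        X_val = extract_feature_matrix(volumes, val_ids, ds)
        y_val = np.array([labels[j] == "incorrect" for j in val_ids])
        conf, pred = model.predict(X_val, pcfg)
        cm = confusion(y_val, pred)
        fold_results.append(
            {
                "fold": fold,
                "n_validation": len(val_ids),
                "joint_ids": val_ids,
                "confidences": [float(c) for c in conf],
                "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
                "metrics": compute_metrics(cm),
                "auc": roc_auc(conf, y_val),
                "final_training_loss": model.loss_trace[-1],
            }
        )
        pooled_ids += val_ids
        pooled_conf += [float(c) for c in conf]
        pooled_true += [bool(v) for v in y_val]
        pooled_pred += [bool(v) for v in pred]

    pooled_cm = confusion(pooled_true, pooled_pred)
    results = {
        "k": k,
        "master_seed": master_seed,
        "n_joints": len(labels),
        "epochs": epochs,
        "cutoff": pcfg.cutoff,
        "folds": fold_results,
        "pooled": {
            "confusion": {
                "tp": pooled_cm.tp,
                "fp": pooled_cm.fp,
                "tn": pooled_cm.tn,
                "fn": pooled_cm.fn,
            },
            "metrics": compute_metrics(pooled_cm),
            "auc": roc_auc(pooled_conf, pooled_true),
        },
        "mean_fold_auc": float(np.mean([f["auc"] for f in fold_results])),
    }
    return results


def results_to_json(results: dict) -> str:
    """Canonical JSON rendering (sorted keys) for determinism checks."""
    return json.dumps(results, sort_keys=True, indent=1)
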