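"""Patch-level solid/cystic classification and nodule-level aggregation.

A random-forest ensemble is trained on labeled patch feature vectors and
its per-patch predictions are aggregated into a nodule-level cystic
percentage: 100 x (cystic-predicted patches) / (all patches). Cross-
validation is always grouped by nodule so that no nodule contributes
patches to both sides of a fold.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GroupKFold, cross_val_predict

from .config import RunConfig
from .synthetic import LABEL_CYSTIC, SyntheticNodule
from .texture import TexturePatch, extract_patches, patch_features

__all__ = [
    "FEATURE_LAYOUT_VERSION",
    "LabeledFeatureSet",
    "RegionModel",
    "CysticEstimate",
    "label_patch",
    "build_training_set",
    "train_region_model",
    "estimate_cystic_percentage",
    "evaluate_recovery",
    "cross_validated_recovery",
    "save_model",
    "load_model",
]

FEATURE_LAYOUT_VERSION = "ar2-bands3-signals4-v1"

CLASS_SOLID = 0
CLASS_CYSTIC = 1


@dataclasses.dataclass
class LabeledFeatureSet:
    """Per-patch features with class labels and nodule group ids."""

    features: np.ndarray
    labels: np.ndarray  # CLASS_SOLID / CLASS_CYSTIC per patch
    group_ids: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.features) == len(self.labels) == len(self.group_ids)):
            raise ValueError("features, labels and group_ids must align")


@dataclasses.dataclass
class RegionModel:
    """Trained patch classifier plus the metadata needed to reuse it."""

    classifier: RandomForestClassifier
    feature_layout_version: str
    training_seed: int
    cv_accuracy: float | None = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.classifier.predict(features)


@dataclasses.dataclass
class CysticEstimate:
    nodule_id: str
    cystic_percent: float
    n_patches: int

    @property
    def solid_percent(self) -> float:
        return 100.0 - self.cystic_percent


def label_patch(patch: TexturePatch, label_mask: np.ndarray) -> int:
    """Majority rule: cystic iff > 50% of the patch's in-nodule pixels
    carry the cystic truth label."""
    r, c = patch.origin_px
    ps = patch.pixels.shape[0]
    block = label_mask[r : r + ps, c : c + ps]
    inside = block > 0
    if not inside.any():
        return CLASS_SOLID
    cystic_frac = float((block[inside] == LABEL_CYSTIC).mean())
    return CLASS_CYSTIC if cystic_frac > 0.5 else CLASS_SOLID


def _nodule_patches(nodule: SyntheticNodule, config: RunConfig) -> list[TexturePatch]:
    return extract_patches(
        nodule.image,
        nodule.nodule_mask,
        stride_px=config.stride_px,
        min_inside_fraction=config.min_inside_fraction,
        patch_size_px=config.patch_size_px,
    )


def build_training_set(
    nodules: Sequence[SyntheticNodule], config: RunConfig | None = None
) -> LabeledFeatureSet:
    """Extract, featurize and truth-label every qualifying patch."""
    config = config or RunConfig()
    feats, labels, groups = [], [], []
    for nodule in nodules:
        for patch in _nodule_patches(nodule, config):
            feats.append(
                patch_features(patch, config.ar_order, config.band_edges).values
            )
            labels.append(label_patch(patch, nodule.label_mask))
            groups.append(nodule.nodule_id)
    if not feats:
        raise ValueError("no qualifying patches in the provided nodules")
    return LabeledFeatureSet(
        features=np.vstack(feats),
        labels=np.array(labels),
        group_ids=np.array(groups),
    )


def _make_classifier(config: RunConfig, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.rf_trees, random_state=seed, n_jobs=1
    )


def train_region_model(
    data: LabeledFeatureSet,
    seed: int,
    config: RunConfig | None = None,
    cv_splits: int = 5,
) -> RegionModel:
    """Fit the ensemble and report grouped cross-validation accuracy.

    Folds are grouped by nodule id, so accuracy reflects generalization to
    unseen nodules rather than memorized intra-nodule texture.
    """
    config = config or RunConfig()
    classes = np.unique(data.labels)
    if classes.size < 2:
        raise ValueError("training data must contain both solid and cystic patches")
    n_groups = np.unique(data.group_ids).size
    cv_accuracy = None
    if n_groups >= 2:
        splits = min(cv_splits, n_groups)
        pred = cross_val_predict(
            _make_classifier(config, seed),
            data.features,
            data.labels,
            groups=data.group_ids,
            cv=GroupKFold(n_splits=splits),
            n_jobs=1,
        )
        cv_accuracy = float(np.mean(pred == data.labels))
    clf = _make_classifier(config, seed)
    clf.fit(data.features, data.labels)
    return RegionModel(
        classifier=clf,
        feature_layout_version=FEATURE_LAYOUT_VERSION,
        training_seed=seed,
        cv_accuracy=cv_accuracy,
    )


def estimate_cystic_percentage(
    model: RegionModel,
    patches: Sequence[TexturePatch],
    nodule_id: str = "nodule",
    config: RunConfig | None = None,
) -> CysticEstimate:
    """Nodule-level cystic percent from per-patch predictions.

    cystic% = 100 x (# cystic-predicted patches) / (# patches); the solid
    percent is the exact complement.
    """
    if not patches:
        raise ValueError("no patches inside nodule; cannot estimate composition")
    config = config or RunConfig()
    feats = np.vstack(
        [patch_features(p, config.ar_order, config.band_edges).values for p in patches]
    )
    pred = model.predict(feats)
    pct = 100.0 * float(np.mean(pred == CLASS_CYSTIC))
    return CysticEstimate(nodule_id=nodule_id, cystic_percent=pct, n_patches=len(patches))


def evaluate_recovery(
    truths: Sequence[SyntheticNodule],
    model: RegionModel,
    config: RunConfig | None = None,
) -> dict:
    """Mean absolute error of estimated vs true cystic percentages."""
    if len(truths) < 5:
        raise ValueError("need at least 5 nodules for a recovery evaluation")
    config = config or RunConfig()
    rows = []
    for nodule in truths:
        est = estimate_cystic_percentage(
            model, _nodule_patches(nodule, config), nodule.nodule_id, config
        )
        true_pct = 100.0 * nodule.cystic_fraction_true
        rows.append(
            {
                "nodule_id": nodule.nodule_id,
                "true_pct": true_pct,
                "estimated_pct": est.cystic_percent,
                "residual": est.cystic_percent - true_pct,
                "n_patches": est.n_patches,
            }
        )
    per_nodule = pd.DataFrame(rows)
    return {
        "mae_points": float(per_nodule["residual"].abs().mean()),
        "per_nodule": per_nodule,
    }


def cross_validated_recovery(
    nodules: Sequence[SyntheticNodule],
    seed: int,
    config: RunConfig | None = None,
    n_splits: int = 5,
) -> dict:
    """Grouped cross-fitted evaluation of the whole pipeline.

    Each fold's nodules are estimated by a model trained only on the other
    folds, giving an honest patch accuracy and nodule-level MAE on unseen
    nodules.
    """
    config = config or RunConfig()
    data = build_training_set(nodules, config)
    by_id = {n.nodule_id: n for n in nodules}
    ids = np.unique(data.group_ids)
    if ids.size < n_splits:
        n_splits = int(ids.size)
    cv = GroupKFold(n_splits=n_splits)
    n_correct = 0
    rows = []
    for train_idx, test_idx in cv.split(data.features, data.labels, data.group_ids):
        clf = _make_classifier(config, seed)
        clf.fit(data.features[train_idx], data.labels[train_idx])
        pred = clf.predict(data.features[test_idx])
        n_correct += int(np.sum(pred == data.labels[test_idx]))
        for gid in np.unique(data.group_ids[test_idx]):
            sel = data.group_ids[test_idx] == gid
            pct = 100.0 * float(np.mean(pred[sel] == CLASS_CYSTIC))
            true_pct = 100.0 * by_id[str(gid)].cystic_fraction_true
            rows.append(
                {
                    "nodule_id": str(gid),
                    "true_pct": true_pct,
                    "estimated_pct": pct,
                    "residual": pct - true_pct,
                    "n_patches": int(sel.sum()),
                }
            )
    per_nodule = pd.DataFrame(rows).sort_values("nodule_id").reset_index(drop=True)
    return {
        "cv_accuracy": n_correct / len(data.labels),
        "mae_points": float(per_nodule["residual"].abs().mean()),
        "per_nodule": per_nodule,
    }


def save_model(model: RegionModel, path) -> None:
    """Persist the trained model (joblib, feature layout embedded)."""
    joblib.dump(
        {
            "feature_layout_version": model.feature_layout_version,
            "training_seed": model.training_seed,
            "cv_accuracy": model.cv_accuracy,
            "classifier": model.classifier,
        },
        path,
    )


def load_model(path) -> RegionModel:
    blob = joblib.load(path)
    if blob.get("feature_layout_version") != FEATURE_LAYOUT_VERSION:
        raise ValueError(
            "model feature layout "
            f"{blob.get('feature_layout_version')!r} does not match "
            f"{FEATURE_LAYOUT_VERSION!r}"
        )
    return RegionModel(
        classifier=blob["classifier"],
        feature_layout_version=blob["feature_layout_version"],
        training_seed=blob["training_seed"],
        cv_accuracy=blob.get("cv_accuracy"),
    )
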