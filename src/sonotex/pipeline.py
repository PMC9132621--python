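"""End-to-end orchestration: images -> features -> selection -> classifiers.

High-level helpers used by the CLI, the examples and the acceptance
script.  Feature extraction is deterministic; selection and evaluation
take explicit seeds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import classify, metrics, selection
from .descriptors import (HOGParams, IMAGE_FEATURE_LENGTH, LPQParams,
                          patchset_feature_matrix)
from .imaging import build_pyramid, extract_patches, load_image, resize_to_standard

__all__ = [
    "extract_image_features",
    "extract_features",
    "extract_from_manifest",
    "save_features",
    "load_features",
    "evaluate_families",
    "run_pipeline",
]


def extract_image_features(img: np.ndarray, side: int = 256,
                           lpq: LPQParams | None = None,
                           hog: HOGParams | None = None) -> np.ndarray:
    """Standardise one image and return its 99,572-long feature vector."""
    std = resize_to_standard(img, side)
    ps = extract_patches(build_pyramid(std, side))
    return patchset_feature_matrix(ps, lpq, hog).ravel()


def extract_features(images, side: int = 256, lpq: LPQParams | None = None,
                     hog: HOGParams | None = None) -> np.ndarray:
    """Feature matrix (n_images x 99,572) for an iterable of images."""
    rows = [extract_image_features(img, side, lpq, hog) for img in images]
    if not rows:
        raise ValueError("no images supplied")
    return np.stack(rows)


def extract_from_manifest(manifest_path, side: int = 256,
                          lpq: LPQParams | None = None,
                          hog: HOGParams | None = None):
    """Read a (path,label) manifest CSV, extract features for every row.

    Unreadable images are collected and reported together; the run aborts
    rather than silently skipping files.
    """
    import pandas as pd

    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    for col in ("path", "label"):
        if col not in df.columns:
            raise ValueError(f"manifest {manifest_path} lacks required column {col!r}")
    if len(df) == 0:
        raise ValueError(f"manifest {manifest_path} is empty")
    root = manifest_path.parent
    failures = []
    rows = []
    for p in df["path"]:
        path = Path(p)
        if not path.is_absolute():
            path = root / path
        try:
            rows.append(extract_image_features(load_image(path), side, lpq, hog))
        except OSError as exc:
            failures.append(str(exc))
    if failures:
        raise OSError("unreadable images:\n" + "\n".join(failures))
    return np.stack(rows), df["label"].to_numpy(), df["path"].tolist()


def save_features(path, X: np.ndarray, labels, ids=None) -> None:
    """Binary array file plus a JSON sidecar describing the columns."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), X)
    sidecar = {"n_images": int(X.shape[0]), "n_features": int(X.shape[1]),
               "labels": list(map(str, labels)),
               "ids": list(map(str, ids)) if ids is not None else None,
               "layout": "341 patches x (256 LPQ + 36 HOG), patch-major"}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_features(path):
    path = Path(path)
    X = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return X, np.array(meta["labels"]), meta


def evaluate_families(X: np.ndarray, y: np.ndarray, families=classify.FAMILIES,
                      tune: bool = True, budget: int = 20, folds: int = 10,
                      seed: int = 0, positive=metrics.DEFAULT_POSITIVE) -> dict:
    """Tune (optionally) and cross-validate each classifier family.

    Tuning uses one seeded fold partition; the reported metrics come from
    a fresh partition (seed + 1) so the headline numbers are not the
    tuning incumbents themselves.
    """
    out = {}
    for family in families:
        if tune:
            trace = classify.bayes_tune(family, X, y, budget=budget,
                                        seed=seed, folds=folds)
            spec = trace.best
        else:
            trace = None
            spec = classify.default_specs()[family]
        cv = classify.cross_validate(spec, X, y, folds=folds, seed=seed + 1,
                                     positive=positive)
        cm = metrics.confusion(cv.y_true, cv.y_pred, positive=positive)
        report = metrics.summarize(cm)
        fpr, tpr, auc = metrics.roc_auc(cv.y_true, cv.scores, positive=positive)
        out[family] = {"spec": spec, "cv": cv, "report": report,
                       "roc": (fpr, tpr, auc), "auc": auc, "trace": trace}
    return out


def run_pipeline(images, labels, selector: selection.SelectorConfig | None = None,
                 families=classify.FAMILIES, tune: bool = True, budget: int = 20,
                 folds: int = 10, seed: int = 0,
                 positive=metrics.DEFAULT_POSITIVE) -> dict:
    """Full run on in-memory images: extract, select, classify, score."""
    selector = selector or selection.SelectorConfig()
    X = extract_features(images)
    assert X.shape[1] == IMAGE_FEATURE_LENGTH
    sel = selection.chi2_nca_select(X, np.asarray(labels), selector, seed=seed)
    Xsel = selection.minmax_scale(X[:, sel.selected])
    results = evaluate_families(Xsel, np.asarray(labels), families=families,
                                tune=tune, budget=budget, folds=folds,
                                seed=seed, positive=positive)
    return {"features": X, "selection": sel, "results": results}
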