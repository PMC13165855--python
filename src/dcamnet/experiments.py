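"""Desk-scale end-to-end experiments on synthetic cohorts.

These presets wire the generator, the classifier, and the evaluation
protocols into the three standard synthetic studies:

* a subject-mixed run on a strongly separated cohort (large class effects),
* a LOSO comparison of the full dynamic-convolution model against its
  single-static-kernel ablation across several seeds,
* a single-band masking sweep of a trained model.

Problem sizes are deliberately small (4 subjects, 24 epochs per class and
subject, 8 channels, 2 s epochs at 200 Hz, a 16-map network) so a full study
runs on one CPU in minutes; docs/methods.md discusses what these scales do
and do not demonstrate.
"""

from __future__ import annotations

import numpy as np

from .evaluation import (
    ConfusionMatrix,
    aggregate_folds,
    confusion_metrics,
    make_loso_folds,
    make_subject_mixed_split,
)
from .filterbank import FilterBankSpec, filter_bank_transform
from .model import DCAMNetClassifier, mask_bands
from .simulate import SimConfig, SimulatedDataset, simulate_dataset

__all__ = [
    "desk_sim_config",
    "desk_model_params",
    "run_subject_mixed",
    "run_loso_variants",
    "run_band_masking",
]

#: Class effects for the "strongly separated" cohort used by the
#: subject-mixed benchmark; the LOSO comparison keeps the generator defaults.
STRONG_EFFECTS = {"theta_effect_db": 6.0, "alpha_effect_db": 4.0, "beta_effect_db": -4.0}


def desk_sim_config(seed: int, strong: bool = False, **overrides) -> SimConfig:
    """Synthetic cohort at desk scale: 4 subjects x 24 epochs/class, 2 s epochs."""
    params = dict(
        n_subjects=4,
        epochs_per_class_per_subject=24,
        C=8,
        fs=200.0,
        T=400,
        seed=seed,
    )
    if strong:
        params.update(STRONG_EFFECTS)
    params.update(overrides)
    return SimConfig(**params)


def desk_model_params(seed: int, **overrides) -> dict:
    """Classifier at desk scale: half-width network, shortened schedule."""
    params = dict(
        fs=200.0,
        K=4,
        N=8,
        L=33,
        r=4,
        m=8,
        w=25,
        h=4,
        dropout=0.5,
        lr=1e-3,
        max_epochs=25,
        patience=8,
        batch_size=32,
        seed=seed,
    )
    params.update(overrides)
    return params


def _fit_on_split(ds: SimulatedDataset, seed: int, variant: str = "full", **model_overrides):
    plan = make_subject_mixed_split(ds.y, ds.subjects, train_fraction=0.7, seed=seed)
    fold = plan.folds[0]
    clf = DCAMNetClassifier(variant=variant, **desk_model_params(seed, **model_overrides))
    val = (ds.X[fold.val_idx], ds.y[fold.val_idx]) if len(fold.val_idx) else None
    clf.fit(ds.X[fold.train_idx], ds.y[fold.train_idx], val=val)
    return clf, fold


def run_subject_mixed(seed: int, ds: SimulatedDataset | None = None) -> dict:
    """Train/test under the segment-level stratified protocol.

    Uses the strongly separated cohort by default; returns the test-set
    metrics together with the fitted classifier and held-out indices.
    """
    if ds is None:
        ds = simulate_dataset(desk_sim_config(seed, strong=True))
    clf, fold = _fit_on_split(ds, seed)
    y_pred = clf.predict(ds.X[fold.test_idx])
    cm = ConfusionMatrix.from_predictions(ds.y[fold.test_idx], y_pred)
    return {
        "classifier": clf,
        "dataset": ds,
        "test_idx": fold.test_idx,
        "metrics": confusion_metrics(cm),
        "confusion": cm,
    }


def run_loso_variants(
    seeds=(0, 1, 2),
    variants=("full", "static_K1"),
    ds: SimulatedDataset | None = None,
) -> dict:
    """LOSO accuracy of several ablation variants across seeds.

    The cohort keeps the generator's default (moderate) class effects and its
    per-subject spectral offsets, which is what makes held-out subjects hard;
    returns per-variant fold matrices and the grand mean over seeds x folds.
    """
    if ds is None:
        ds = simulate_dataset(desk_sim_config(seeds[0]))
    out: dict = {"per_variant": {}, "dataset": ds}
    for variant in variants:
        accs, matrices = [], []
        for seed in seeds:
            plan = make_loso_folds(ds.subjects, ds.y, seed=seed)
            for fold in plan.folds:
                clf = DCAMNetClassifier(variant=variant, **desk_model_params(seed))
                val = (ds.X[fold.val_idx], ds.y[fold.val_idx]) if len(fold.val_idx) else None
                clf.fit(ds.X[fold.train_idx], ds.y[fold.train_idx], val=val)
                y_pred = clf.predict(ds.X[fold.test_idx])
                cm = ConfusionMatrix.from_predictions(ds.y[fold.test_idx], y_pred)
                matrices.append(cm)
                accs.append(confusion_metrics(cm).accuracy)
        out["per_variant"][variant] = {
            "fold_accuracies": np.array(accs),
            "mean": float(np.mean(accs)),
            "sd": float(np.std(accs, ddof=1)),
            "aggregate": aggregate_folds(matrices).aggregate,
        }
    return out


def run_band_masking(clf: DCAMNetClassifier, X, y, renormalize: bool = True) -> dict:
    """Accuracy with a single filter-bank band retained, per band.

    The trained network is probed without retraining: all other band slices
    are zeroed before the forward pass.  By default the probe re-normalizes
    batch-norm statistics on the masked probe set itself (`renormalize`),
    since the frozen running statistics encode the unmasked input scale and
    would otherwise saturate the activations; set False for frozen-statistic
    probing.
    """
    spec = FilterBankSpec.default()
    Xfb = filter_bank_transform(np.asarray(X, dtype=np.float64), clf.fs, clf.band_spec)
    y = np.asarray(y)
    net = clf.network_
    results = {}
    for b, band in enumerate(spec.bands):
        Xm = mask_bands(Xfb, [b])
        proba = net.predict_proba(Xm, probe_batch_stats=renormalize)
        y_pred = clf.classes_[(proba[:, 1] > proba[:, 0]).astype(int)]
        cm = ConfusionMatrix.from_predictions(y, y_pred)
        results[band.name] = confusion_metrics(cm).accuracy
    return results
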