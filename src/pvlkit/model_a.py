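"""Conventional baseline ("Model A"): 35 tabular features, five classifiers.

The candidates are L1/L2 logistic regression (penalty chosen by inner CV on
each training split), a single-hidden-layer MLP, a random forest, and a
gradient boosting machine, all with class-balanced sample weighting; the
winner is the candidate with the best mean cross-validated AUC, and its
out-of-fold predictions are returned in the same schema as the fusion model
so the two can be compared on identical folds.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegressionCV
from sklearn.neural_network import MLPClassifier

from .phantom import OUTCOME_COLUMN
from .training import FoldPlan, PredictionSet
from .evaluate import roc_auc

__all__ = ["FEATURE_MANIFEST", "assemble_features", "fit_and_select",
           "ClassifierSpec", "make_classifier"]

#: The 33 cohort-table variables plus two derived indices = 35 features.
FEATURE_MANIFEST = [
    # clinical
    "sex_male", "age_yr", "bmi_kg_m2", "sts_score_pct",
    "hypertension", "diabetes", "copd", "cad", "ckd", "af", "pvd",
    "prior_stroke",
    # CT-derived anatomy
    "calc_volume_mm3", "annular_angle_deg", "annular_perimeter_mm",
    "annular_area_mm2", "sov_perimeter_mm", "stj_diameter_mm",
    "lca_ostium_height_mm", "rca_ostium_height_mm", "max_ascending_ao_mm",
    "lvot_perimeter_mm",
    # echocardiographic
    "ar_ge_moderate", "mean_av_gradient_mmhg", "peak_av_velocity_m_s",
    "lvef_pct", "lvedd_mm", "ivs_mm",
    # procedural
    "new_generation_thv", "thv_lt_26mm", "transfemoral", "pre_dilatation",
    "post_dilatation_balloon_mm",
    # derived indices
    "annular_area_derived_diameter_mm",   # sqrt(4 * area / pi)
    "balloon_annulus_ratio",              # balloon / perimeter-derived diameter
]

BINARY_FEATURES = {
    "sex_male", "hypertension", "diabetes", "copd", "cad", "ckd", "af", "pvd",
    "prior_stroke", "ar_ge_moderate", "new_generation_thv", "thv_lt_26mm",
    "transfemoral", "pre_dilatation",
}

CLASSIFIER_KINDS = ("LR-L1", "LR-L2", "MLP", "RF", "GBM")


@dataclasses.dataclass(frozen=True)
class ClassifierSpec:
    kind: str
    class_balanced: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")


def assemble_features(clinical: pd.DataFrame) -> pd.DataFrame:
    """Build the 35-column feature table (manifest order, binaries as 0/1).

    Raises with the manifest diff if source columns are missing.
    """
    df = clinical.copy()
    df["annular_area_derived_diameter_mm"] = np.sqrt(
        4.0 * df["annular_area_mm2"] / np.pi)
    df["balloon_annulus_ratio"] = df["post_dilatation_balloon_mm"] / (
        df["annular_perimeter_mm"] / np.pi)
    missing = [c for c in FEATURE_MANIFEST if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing manifest columns: {missing}")
    table = df[FEATURE_MANIFEST].astype(float)
    if table.isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise ValueError(f"missing values in features: {bad}")
    if "patient_id" in clinical and clinical["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id rows")
    return table


def make_classifier(spec: ClassifierSpec):
    """Instantiate one candidate with its published hyperparameters."""
    if spec.kind == "LR-L1":
        return LogisticRegressionCV(
            penalty="l1", solver="liblinear", Cs=np.logspace(-3, 3, 13),
            cv=5, scoring="roc_auc", max_iter=2000, random_state=spec.seed)
    if spec.kind == "LR-L2":
        return LogisticRegressionCV(
            penalty="l2", solver="lbfgs", Cs=np.logspace(-3, 3, 13),
            cv=5, scoring="roc_auc", max_iter=2000, random_state=spec.seed)
    if spec.kind == "MLP":
        return MLPClassifier(hidden_layer_sizes=(32,), alpha=0.001,
                             max_iter=500, random_state=spec.seed)
    if spec.kind == "RF":
        return RandomForestClassifier(
            n_estimators=200, max_leaf_nodes=16, min_samples_leaf=5,
            random_state=spec.seed)
    if spec.kind == "GBM":
        return GradientBoostingClassifier(
            n_estimators=100, max_depth=3, learning_rate=0.05, subsample=0.8,
            random_state=spec.seed)
    raise AssertionError


def _balanced_weights(y: np.ndarray) -> np.ndarray:
    w = np.ones(len(y))
    for cls in (0, 1):
        n_c = max(int((y == cls).sum()), 1)
        w[y == cls] = len(y) / (2.0 * n_c)
    return w


def _fit_one(spec: ClassifierSpec, Xtr, ytr, warn_log: list[str]):
    clf = make_classifier(spec)
    w = _balanced_weights(ytr) if spec.class_balanced else None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        if isinstance(clf, MLPClassifier):
            # MLPClassifier has no sample_weight: emulate class balancing by
            # replicating minority rows to near-equal class mass
            if spec.class_balanced:
                n0, n1 = int((ytr == 0).sum()), int((ytr == 1).sum())
                minority = 1 if n1 < n0 else 0
                reps = max(1, int(round(max(n0, n1) / max(min(n0, n1), 1))))
                idx = np.concatenate(
                    [np.where(ytr != minority)[0]]
                    + [np.where(ytr == minority)[0]] * reps)
                clf.fit(Xtr[idx], ytr[idx])
            else:
                clf.fit(Xtr, ytr)
        else:
            clf.fit(Xtr, ytr, sample_weight=w)
        for c in caught:
            if issubclass(c.category, ConvergenceWarning):
                warn_log.append(f"{spec.kind}: {c.message}")
    return clf


def fit_and_select(features: pd.DataFrame, outcome: np.ndarray,
                   folds: FoldPlan, seed: int = 0,
                   patient_ids: list[str] | None = None,
                   ) -> tuple[str, PredictionSet, pd.DataFrame]:
    """Cross-validate all five candidates on the shared fold plan and select
    the winner by mean AUC.

    Returns (winner tag, winner's out-of-fold PredictionSet, candidate table
    with per-fold and mean AUCs).
    """
    if list(features.columns) != FEATURE_MANIFEST:
        diff = set(features.columns) ^ set(FEATURE_MANIFEST)
        raise ValueError(f"feature table does not match manifest: {diff}")
    X = features.to_numpy(dtype=float)
    y = np.asarray(outcome).astype(int)
    n = len(y)
    if patient_ids is None:
        patient_ids = [f"idx-{i}" for i in range(n)]

    continuous = [i for i, c in enumerate(FEATURE_MANIFEST)
                  if c not in BINARY_FEATURES]
    warn_log: list[str] = []
    oof = {kind: np.full(n, np.nan) for kind in CLASSIFIER_KINDS}
    fold_aucs = {kind: [] for kind in CLASSIFIER_KINDS}

    for fold in range(folds.k):
        tr, va = folds.train_indices(fold), folds.val_indices(fold)
        Xz = X.copy()
        mu = X[np.ix_(tr, continuous)].mean(axis=0)
        sd = X[np.ix_(tr, continuous)].std(axis=0)
        sd[sd == 0] = 1.0
        Xz[:, continuous] = (X[:, continuous] - mu) / sd
        for kind in CLASSIFIER_KINDS:
            spec = ClassifierSpec(kind=kind, seed=seed)
            clf = _fit_one(spec, Xz[tr], y[tr], warn_log)
            p = clf.predict_proba(Xz[va])[:, 1]
            oof[kind][va] = p
            fold_aucs[kind].append(roc_auc(y[va], p))

    rows = []
    for kind in CLASSIFIER_KINDS:
        rows.append({"classifier": kind,
                     **{f"fold{f}_auc": fold_aucs[kind][f]
                        for f in range(folds.k)},
                     "mean_auc": float(np.mean(fold_aucs[kind]))})
    table = pd.DataFrame(rows)
    winner = table.loc[table["mean_auc"].idxmax(), "classifier"]
    pred = PredictionSet(patient_ids=patient_ids, y=y, p=oof[winner],
                         fold=folds.fold_of.copy(), model_tag="A")
    table.attrs["warnings"] = warn_log
    return str(winner), pred, table
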