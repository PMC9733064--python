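"""Classification and differential analysis on hotspot features.

Cancer-vs-control discrimination uses a linear SVM (C = 1, no internal
re-standardisation — the features are already z-scored) under stratified
k-fold cross-validation repeated with fresh random splits.  Controls can
be downsampled to the case count within each training fold so neither
class dominates pooled hotspot discovery.  The AUC summary follows the
normal-approximation interval: SE = sd / sqrt(iterations), CI = mean
+/- z * SE with z = 1.96.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureMatrix, build_feature_matrix, zscore_by_chrom
from .hotspots import benjamini_hochberg, call_hotspots, pool_samples

logger = logging.getLogger(__name__)

Z_95 = 1.96


@dataclass(frozen=True)
class CVConfig:
    """Repeated stratified cross-validation settings."""

    folds: int = 10
    repeats: int = 10
    seed: int = 0
    downsample_controls: bool = True

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class AUCSummary:
    """Mean AUC with a normal-approximation confidence interval."""

    mean_auc: float
    se: float
    ci_low: float
    ci_high: float
    aucs: np.ndarray = field(default_factory=lambda: np.array([]))
    sensitivity_at_full_specificity: float | None = None


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC of scores against binary labels (1 = positive class)."""
    return float(roc_auc_score(labels, scores))


def auc_confidence_interval(aucs: Sequence[float], z: float = Z_95) -> AUCSummary:
    """Mean, SE = sd/sqrt(n) and mean +/- z*SE over per-iteration AUCs."""
    aucs = np.asarray(list(aucs), dtype=float)
    if len(aucs) < 1:
        raise ValueError("need at least one AUC")
    mean = float(aucs.mean())
    sd = float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0
    se = sd / np.sqrt(len(aucs))
    return AUCSummary(mean_auc=mean, se=se, ci_low=mean - z * se, ci_high=mean + z * se, aucs=aucs)


def sensitivity_at_specificity(
    scores: np.ndarray, labels: np.ndarray, specificity: float = 1.0
) -> float:
    """Case-detection fraction at a fixed specificity.

    The threshold is the most permissive one misclassifying at most
    ``(1 - specificity)`` of controls; at 100% specificity it sits
    strictly above the highest control score.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    controls = np.sort(scores[labels == 0])[::-1]
    cases = scores[labels == 1]
    if len(controls) == 0 or len(cases) == 0:
        raise ValueError("both classes required")
    allowed = int(np.floor((1.0 - specificity) * len(controls) + 1e-12))
    threshold = controls[min(allowed, len(controls) - 1)]
    return float((cases > threshold).mean())


def _downsample_majority(
    idx: np.ndarray, y: np.ndarray, control_label, case_label, rng: np.random.Generator
) -> np.ndarray:
    ctrl = idx[y[idx] == control_label]
    case = idx[y[idx] == case_label]
    if len(ctrl) > len(case):
        ctrl = rng.choice(ctrl, size=len(case), replace=False)
    return np.sort(np.concatenate([case, ctrl]))


def cross_validate_svm(
    matrix: FeatureMatrix,
    cv: CVConfig = CVConfig(),
    case_label: str | None = None,
) -> tuple[AUCSummary, pd.DataFrame]:
    """Repeated stratified CV of a linear SVM on a fixed feature matrix.

    One AUC per fold x repeat; control downsampling (training folds
    only) is seeded and reproducible.  Per-sample decision scores from
    every repeat are returned alongside the AUC summary.

    This is the fast path operating on a pre-computed feature matrix.
    :func:`cross_validate_pipeline` re-derives hotspots from the pooled
    training fragments within every fold, avoiding any feature-selection
    leakage, and is the faithful (but far slower) procedure.
    """
    X = matrix.values.to_numpy()
    labels = matrix.labels.to_numpy()
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("binary classification requires exactly 2 classes")
    case = case_label if case_label is not None else classes[0]
    control = [c for c in classes if c != case][0]
    y = (labels == case).astype(int)
    rng = np.random.default_rng(cv.seed)
    aucs = []
    score_rows = []
    for rep in range(cv.repeats):
        skf = StratifiedKFold(n_splits=cv.folds, shuffle=True, random_state=int(rng.integers(2**31)))
        for fold, (train, test) in enumerate(skf.split(X, y)):
            if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
                raise ValueError("fold with a single class; reduce folds or rebalance")
            if cv.downsample_controls:
                train = _downsample_majority(train, labels, control, case, rng)
            clf = SVC(kernel="linear", C=1.0)
            clf.fit(X[train], y[train])
            s = clf.decision_function(X[test])
            aucs.append(roc_auc(y[test], s))
            for i, sc in zip(test, s):
                score_rows.append((matrix.values.index[i], rep, fold, float(sc), int(y[i])))
    summary = auc_confidence_interval(aucs)
    scores = pd.DataFrame(score_rows, columns=["sample", "repeat", "fold", "score", "is_case"])
    pooled = scores.groupby("sample").agg(score=("score", "mean"), is_case=("is_case", "first"))
    summary.sensitivity_at_full_specificity = sensitivity_at_specificity(
        pooled["score"].to_numpy(), pooled["is_case"].to_numpy(), specificity=1.0
    )
    return summary, scores


def cross_validate_pipeline(
    sample_frags: Mapping[str, pd.DataFrame],
    labels: Mapping[str, str],
    case_label: str,
    grids,
    cv: CVConfig = CVConfig(folds=5, repeats=1),
    chrom_sizes: Mapping[str, int] | None = None,
    hotspot_kwargs: dict | None = None,
) -> AUCSummary:
    """Fold-faithful CV: hotspots re-called from pooled training samples.

    Within each fold, training controls are (optionally) downsampled,
    case and control training fragments are pooled separately, hotspots
    are called per class and their union becomes the feature set; test
    samples only ever contribute fragments at feature-extraction time.
    """
    from .ifs import compute_ifs

    sample_ids = np.array(list(sample_frags))
    y_lab = np.array([labels[s] for s in sample_ids])
    y = (y_lab == case_label).astype(int)
    control_label = [c for c in np.unique(y_lab) if c != case_label][0]
    rng = np.random.default_rng(cv.seed)
    hotspot_kwargs = hotspot_kwargs or {}
    aucs = []
    for rep in range(cv.repeats):
        skf = StratifiedKFold(n_splits=cv.folds, shuffle=True, random_state=int(rng.integers(2**31)))
        for train, test in skf.split(sample_ids, y):
            if cv.downsample_controls:
                train = _downsample_majority(train, y_lab, control_label, case_label, rng)
            spots = []
            for group in (case_label, control_label):
                members = [sample_frags[s] for s in sample_ids[train] if labels[s] == group]
                pooled = pool_samples(members, saturation_floor=0)
                track = compute_ifs(pooled, grids)
                spots.append(call_hotspots(track, **hotspot_kwargs))
            union = (
                pd.concat(spots, ignore_index=True)
                .sort_values(["chrom", "start"], kind="mergesort")
                .drop_duplicates(["chrom", "center"])
                .reset_index(drop=True)
            )
            fold_samples = {s: sample_frags[s] for s in sample_ids[np.concatenate([train, test])]}
            fm = build_feature_matrix(fold_samples, union, labels, chrom_sizes=chrom_sizes)
            X = fm.values
            ytr = (fm.labels.loc[sample_ids[train]] == case_label).astype(int)
            yte = (fm.labels.loc[sample_ids[test]] == case_label).astype(int)
            clf = SVC(kernel="linear", C=1.0)
            clf.fit(X.loc[sample_ids[train]].to_numpy(), ytr.to_numpy())
            s = clf.decision_function(X.loc[sample_ids[test]].to_numpy())
            aucs.append(roc_auc(yte.to_numpy(), s))
    return auc_confidence_interval(aucs)


@dataclass
class DifferentialHotspots:
    """Per-hotspot case-control differences on z-scored IFS."""

    table: pd.DataFrame  # columns: hotspot, delta_z, pvalue, fdr, hotspot_class

    @property
    def class_i(self) -> pd.DataFrame:
        return self.table[self.table["hotspot_class"] == "I"]

    @property
    def class_ii(self) -> pd.DataFrame:
        return self.table[self.table["hotspot_class"] == "II"]


def differential_hotspots(
    matrix: FeatureMatrix,
    case_label: str,
    control_label: str,
    fdr_cutoff: float = 0.01,
) -> DifferentialHotspots:
    """Two-sample t-test per hotspot with BH correction.

    Hotspots significant at FDR < ``fdr_cutoff`` are split by the sign of
    (case mean - control mean) of the z-scored IFS: class I for positive
    differences (hypo-fragmented in cases — hotspots are IFS-depleted
    regions, so higher z-scored IFS means *less* fragmentation there),
    class II for negative.
    """
    A = matrix.values[matrix.labels == case_label].to_numpy()
    B = matrix.values[matrix.labels == control_label].to_numpy()
    if len(A) < 3 or len(B) < 3:
        raise ValueError("need >=3 samples per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(A, B, axis=0)
    degenerate = np.isnan(p)
    if degenerate.any():
        logger.warning("%d hotspots with zero within-group variance; p set to 1", int(degenerate.sum()))
        p = np.where(degenerate, 1.0, p)
    fdr = benjamini_hochberg(p)
    delta = A.mean(axis=0) - B.mean(axis=0)
    cls = np.where(fdr < fdr_cutoff, np.where(delta > 0, "I", "II"), "none")
    table = pd.DataFrame(
        {
            "hotspot": matrix.values.columns,
            "delta_z": delta,
            "pvalue": p,
            "fdr": fdr,
            "hotspot_class": cls,
        }
    )
    return DifferentialHotspots(table=table)


def predict_open_chromatin(
    features: np.ndarray,
    labels: np.ndarray,
    trees: int = 100,
    folds: int = 10,
    seed: int = 0,
) -> AUCSummary:
    """Random-forest benchmark: do IFS + dimer features separate open
    from closed chromatin regions?

    ``features`` is (regions x [IFS, 16 dimer frequencies]); a 100-tree
    forest is scored by out-of-fold probability under stratified k-fold
    CV, one AUC per fold.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    balance = labels.mean()
    if not 0.4 <= balance <= 0.6:
        logger.warning("class balance %.2f outside 40-60%%; the benchmark assumes balanced sampling", balance)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for train, test in skf.split(features, labels):
        clf = RandomForestClassifier(n_estimators=trees, random_state=seed)
        clf.fit(features[train], labels[train])
        prob = clf.predict_proba(features[test])[:, 1]
        aucs.append(roc_auc(labels[test], prob))
    return auc_confidence_interval(aucs)
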