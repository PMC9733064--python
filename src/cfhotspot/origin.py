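"""Tissue-of-origin assignment for cancer-positive samples.

Each eligible cancer type gets a centroid — the mean z-scored IFS vector
of its training samples over the training hotspot union.  A test sample
is ranked against every centroid by Spearman correlation (rank-based, so
any strictly monotone rescaling of the sample vector leaves the ranking
unchanged); the top two candidates are then arbitrated by a decision
tree trained on that specific pair of types.  Types whose pooled
training fragments fall below 2e8 are excluded as unsaturated, and
over-represented types are downsampled to the median per-type sample
count before fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.proportion import proportion_confint

from .features import FeatureMatrix
from .hotspots import SATURATION_FLOOR

logger = logging.getLogger(__name__)


@dataclass
class OriginModel:
    cancer_types: list[str]
    centroids: pd.DataFrame  # types x features
    pairwise_trees: dict[frozenset, DecisionTreeClassifier]
    eligibility: pd.DataFrame  # type, fragment_count, eligible
    feature_ids: pd.Index = field(default=None)

    def __post_init__(self):
        if self.feature_ids is None:
            self.feature_ids = self.centroids.columns


def build_origin_model(
    matrix: FeatureMatrix,
    fragment_counts: Mapping[str, int],
    min_fragments: int = SATURATION_FLOOR,
    seed: int = 0,
) -> OriginModel:
    """Fit centroids and pairwise decision trees on training samples.

    ``fragment_counts`` maps each type to its pooled training fragment
    count; types under ``min_fragments`` are excluded (logged).  Types
    with more samples than the median per-type count are downsampled to
    the median (seeded), mirroring the handling of over-sequenced types.
    """
    labels = matrix.labels
    types = [t for t in labels.unique()]
    elig_rows = []
    eligible = []
    for t in types:
        count = int(fragment_counts.get(t, 0))
        ok = count >= min_fragments
        elig_rows.append((t, count, ok))
        if ok:
            eligible.append(t)
        else:
            logger.info("type %s excluded: %d pooled fragments < %d", t, count, min_fragments)
    if len(eligible) < 2:
        raise ValueError("fewer than 2 eligible cancer types")

    rng = np.random.default_rng(seed)
    counts = {t: int((labels == t).sum()) for t in eligible}
    median_n = int(np.median(list(counts.values())))
    keep_samples: list = []
    for t in eligible:
        members = labels.index[labels == t].to_numpy()
        if len(members) > median_n:
            members = rng.choice(members, size=median_n, replace=False)
        keep_samples.extend(members.tolist())
    sub = matrix.values.loc[keep_samples]
    sub_labels = labels.loc[keep_samples]

    centroids = pd.DataFrame(
        {t: sub[sub_labels == t].mean(axis=0) for t in eligible}
    ).T.loc[eligible]

    trees: dict[frozenset, DecisionTreeClassifier] = {}
    for i, a in enumerate(eligible):
        for b in eligible[i + 1 :]:
            mask = sub_labels.isin([a, b])
            tree = DecisionTreeClassifier(random_state=seed)
            tree.fit(sub[mask].to_numpy(), sub_labels[mask].to_numpy())
            trees[frozenset((a, b))] = tree

    return OriginModel(
        cancer_types=eligible,
        centroids=centroids,
        pairwise_trees=trees,
        eligibility=pd.DataFrame(elig_rows, columns=["type", "fragment_count", "eligible"]),
    )


def rank_candidates(sample: np.ndarray, model: OriginModel) -> pd.DataFrame:
    """Rank cancer types by Spearman correlation with each centroid."""
    sample = np.asarray(sample, dtype=float)
    if np.ptp(sample) == 0:
        raise ValueError("constant sample vector: Spearman correlation undefined")
    rows = []
    for t in model.cancer_types:
        rho = sps.spearmanr(sample, model.centroids.loc[t].to_numpy()).statistic
        rows.append((t, float(rho)))
    out = pd.DataFrame(rows, columns=["type", "spearman"]).sort_values(
        "spearman", ascending=False, kind="mergesort"
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def resolve_top2(sample: np.ndarray, top2: Sequence[str], model: OriginModel) -> str:
    """Arbitrate the top-2 candidates with their pairwise decision tree."""
    pair = frozenset(top2)
    if pair not in model.pairwise_trees:
        raise KeyError(f"no pairwise model for {sorted(pair)}")
    tree = model.pairwise_trees[pair]
    return str(tree.predict(np.asarray(sample, dtype=float).reshape(1, -1))[0])


def predict_origin(matrix: FeatureMatrix, model: OriginModel) -> pd.DataFrame:
    """Full assignment for a test cohort: rank, take top 2, arbitrate."""
    rows = []
    for sample_id, x in matrix.values.iterrows():
        ranks = rank_candidates(x.to_numpy(), model)
        top1, top2 = ranks["type"].iloc[0], ranks["type"].iloc[1]
        final = resolve_top2(x.to_numpy(), (top1, top2), model)
        rows.append((sample_id, top1, top2, final, ranks["spearman"].iloc[0], ranks["spearman"].iloc[1]))
    return pd.DataFrame(rows, columns=["sample", "top1", "top2", "final", "rho1", "rho2"])


def evaluate_origin(predictions: pd.DataFrame, truths: Mapping[str, str]) -> pd.DataFrame:
    """Top-1 / top-2 accuracy per type and overall, with binomial CIs.

    Top-1 uses the tree-arbitrated final call; top-2 counts a sample as
    localised when the truth is either Spearman candidate.  A frequency-
    weighted random-guess baseline accompanies each row.
    """
    df = predictions.copy()
    df["truth"] = df["sample"].map(truths)
    df["top1_hit"] = df["final"] == df["truth"]
    df["top2_hit"] = (df["top1"] == df["truth"]) | (df["top2"] == df["truth"])
    k = df["truth"].nunique()
    rows = []
    groups = list(df.groupby("truth")) + [("mean", df)]
    for name, g in groups:
        n = len(g)
        for metric in ("top1_hit", "top2_hit"):
            hits = int(g[metric].sum())
            lo, hi = proportion_confint(hits, n, alpha=0.05, method="normal")
            rows.append(
                {
                    "type": name,
                    "metric": metric.replace("_hit", ""),
                    "n": n,
                    "accuracy": hits / n,
                    "ci_low": lo,
                    "ci_high": hi,
                    "random_baseline": (1 if metric == "top1_hit" else 2) / k,
                }
            )
    return pd.DataFrame(rows)
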