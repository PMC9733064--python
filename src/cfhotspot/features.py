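"""Per-sample hotspot features for classification.

Each sample's IFS is re-computed over a fixed 200-bp region centred on
every hotspot (centre +/- 100 bp, regardless of the merged hotspot's
length), with L taken from that sample's fragments on the hotspot's
chromosome.  Values are then z-scored within each chromosome of each
sample, which removes sample- and chromosome-level scale differences
(depth, chromosome-arm copy number) before any model sees them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fragments import midpoints
from .ifs import GcLoessModel

logger = logging.getLogger(__name__)

FEATURE_HALF_WIDTH = 100


@dataclass
class FeatureMatrix:
    """Samples x hotspots matrix of z-scored IFS with labels.

    ``values``: DataFrame indexed by sample id, one column per hotspot id
    (``chrom:center+/-100``); ``labels``: per-sample class label;
    ``hotspot_chroms``: chromosome of each column, needed for
    per-chromosome operations.
    """

    values: pd.DataFrame
    labels: pd.Series
    hotspot_chroms: pd.Series
    fold_ids: pd.Series | None = None

    def __post_init__(self):
        if not self.values.index.equals(self.labels.index):
            self.labels = self.labels.reindex(self.values.index)


def hotspot_ids(hotspots: pd.DataFrame, half_width: int = FEATURE_HALF_WIDTH) -> list[str]:
    return [f"{r.chrom}:{r.center}±{half_width}" for r in hotspots.itertuples(index=False)]


def extract_sample_ifs(
    frags: pd.DataFrame,
    hotspots: pd.DataFrame,
    half_width: int = FEATURE_HALF_WIDTH,
    chrom_sizes: Mapping[str, int] | None = None,
    gc_model: GcLoessModel | None = None,
    region_gc: np.ndarray | None = None,
    chrom_mean_ifs: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Raw per-hotspot IFS vector for one sample.

    For each hotspot the IFS is evaluated over ``[center - half_width,
    center + half_width)``: n fragments by midpoint, their mean length,
    IFS = n (1 + l/L) with L this sample's mean fragment length on the
    hotspot's chromosome.  Empty regions score 0.  With ``gc_model`` (a
    loess fitted on this sample's genome-wide windows), the region's GC
    value is regressed out and the sample's per-chromosome mean window
    IFS added back, mirroring the window-level correction.
    """
    out = np.zeros(len(hotspots), dtype=float)
    by_chrom = dict(tuple(frags.groupby("chrom", sort=False)))
    for chrom, idx in hotspots.groupby("chrom", sort=False).indices.items():
        sub = by_chrom.get(chrom)
        if sub is None or len(sub) == 0:
            continue
        mids = midpoints(sub)
        order = np.argsort(mids, kind="mergesort")
        mids = mids[order]
        lens = sub["length"].to_numpy()[order].astype(np.float64)
        L = float(lens.mean())
        cum = np.concatenate([[0.0], np.cumsum(lens)])
        centers = hotspots["center"].to_numpy()[idx]
        starts = centers - half_width
        ends = centers + half_width
        if chrom_sizes is not None and chrom in chrom_sizes:
            clipped = (starts < 0) | (ends > chrom_sizes[chrom])
            if clipped.any():
                logger.warning("%s: %d feature regions clipped at chromosome bounds", chrom, int(clipped.sum()))
            starts = np.clip(starts, 0, None)
            ends = np.clip(ends, None, chrom_sizes[chrom])
        lo = np.searchsorted(mids, starts, side="left")
        hi = np.searchsorted(mids, ends, side="left")
        n = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_len = np.where(n > 0, (cum[hi] - cum[lo]) / np.maximum(n, 1), 0.0)
        out[idx] = np.where(n > 0, n * (1.0 + mean_len / L), 0.0)
        if gc_model is not None and region_gc is not None:
            add_back = chrom_mean_ifs.get(chrom, 0.0) if chrom_mean_ifs else 0.0
            out[idx] = out[idx] - gc_model.predict(region_gc[idx]) + add_back
    return out


def zscore_by_chrom(
    raw: np.ndarray, chroms: Sequence[str], ddof: int = 1
) -> np.ndarray:
    """z-score a per-hotspot vector within each chromosome.

    Sample (``ddof=1``) standard deviation by default.  Chromosomes with
    fewer than two hotspots or zero spread get zeros (degenerate).
    """
    raw = np.asarray(raw, dtype=float)
    out = np.zeros_like(raw)
    chroms = pd.Series(list(chroms))
    for chrom, idx in chroms.groupby(chroms, sort=False).indices.items():
        x = raw[idx]
        if len(x) < 2:
            logger.warning("%s: <2 hotspots, z-score set to 0", chrom)
            continue
        sd = x.std(ddof=ddof)
        if sd == 0:
            logger.warning("%s: zero spread, z-score set to 0", chrom)
            continue
        out[idx] = (x - x.mean()) / sd
    return out


def build_feature_matrix(
    sample_frags: Mapping[str, pd.DataFrame],
    hotspots: pd.DataFrame,
    labels: Mapping[str, str],
    half_width: int = FEATURE_HALF_WIDTH,
    chrom_sizes: Mapping[str, int] | None = None,
    ddof: int = 1,
) -> FeatureMatrix:
    """Extract and z-score features for a cohort against one hotspot set."""
    ids = hotspot_ids(hotspots, half_width)
    chroms = hotspots["chrom"].astype(str).tolist()
    rows = {}
    for sample_id, frags in sample_frags.items():
        raw = extract_sample_ifs(frags, hotspots, half_width=half_width, chrom_sizes=chrom_sizes)
        rows[sample_id] = zscore_by_chrom(raw, chroms, ddof=ddof)
    values = pd.DataFrame.from_dict(rows, orient="index", columns=ids)
    return FeatureMatrix(
        values=values,
        labels=pd.Series({s: labels[s] for s in values.index}, name="label"),
        hotspot_chroms=pd.Series(chroms, index=ids),
    )


def select_variable_hotspots(
    matrix: FeatureMatrix,
    k: int | None = None,
    method: str = "variance",
    p_threshold: float = 0.01,
) -> list[str]:
    """Select informative hotspot columns.

    ``variance`` ranks by cross-sample variance and returns the top
    ``k``; ``anova`` keeps columns whose one-way ANOVA p-value across the
    label groups falls below ``p_threshold``.  Ties break by column
    (coordinate) order, so selection is deterministic.
    """
    X = matrix.values
    if method == "variance":
        if k is None or k <= 0:
            raise ValueError("variance selection requires k > 0")
        k = min(k, X.shape[1])
        var = X.var(axis=0, ddof=1).to_numpy()
        # stable sort on negated variance keeps coordinate order for ties
        order = np.argsort(-var, kind="mergesort")[:k]
        return [X.columns[i] for i in sorted(order)]
    if method == "anova":
        groups = [X[matrix.labels == g].to_numpy() for g in matrix.labels.unique()]
        with np.errstate(invalid="ignore", divide="ignore"):
            _, pvals = sps.f_oneway(*groups, axis=0)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        cols = [c for c, p in zip(X.columns, pvals) if p < p_threshold]
        if k is not None and k > 0:
            cols = cols[:k]
        return cols
    raise ValueError(f"unknown selection method: {method!r}")
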