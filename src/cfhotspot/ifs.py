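"""Integrated fragmentation score (IFS) and bias corrections.

For window *i* on a chromosome with chromosome-wide mean fragment length
``L``::

    IFS_i = n_i * (1 + l_i / L)
    C_i   = floor(IFS_i)

where ``n_i`` counts fragments whose midpoint falls in the window and
``l_i`` is their mean length.  The size weighting makes regions that
release both *more* and *shorter-than-average* fragments stand out in a
single score; ``C_i`` is the integer score the count model tests.

Two optional corrections address sequence-composition artefacts:

* ``gc_correct`` — loess (span 0.75) of IFS on window GC; the corrected
  score is the residual plus the per-chromosome mean raw IFS, so each
  chromosome's mean is preserved exactly.
* ``kmer_correct`` — divides each window's IFS by its expected IFS under
  genome-wide per-dinucleotide mean scores, then restores the
  per-chromosome scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .fragments import midpoints
from .windows import WindowCovariates, WindowGrid

logger = logging.getLogger(__name__)

LOESS_SPAN = 0.75
LOESS_MAX_POINTS = 200_000
MIN_LOESS_WINDOWS = 100


@dataclass
class GcLoessModel:
    """A fitted IFS-vs-GC loess curve, evaluated by linear interpolation."""

    gc_grid: np.ndarray
    fitted: np.ndarray
    span: float = LOESS_SPAN

    def predict(self, gc: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(gc, dtype=float), self.gc_grid, self.fitted)


@dataclass
class WindowTrack:
    """Per-window scores for all analysed chromosomes.

    ``windows`` has one row per *kept, valid* window with columns
    ``chrom, start, end, n, mean_len, ifs`` plus correction columns as
    they are added; ``chrom_mean_length`` maps each chromosome to its
    mean fragment length L; ``chrom_mean_ifs`` to its mean raw IFS.
    """

    windows: pd.DataFrame
    chrom_mean_length: dict[str, float]
    chrom_mean_ifs: dict[str, float] = field(default_factory=dict)
    gc_model: GcLoessModel | None = None

    def score_column(self, correction: str = "none") -> str:
        col = {"none": "ifs", "gc": "ifs_gc", "kmer": "ifs_kmer"}[correction]
        if col not in self.windows.columns:
            raise KeyError(f"correction {correction!r} has not been computed on this track")
        return col

    def integer_scores(self, correction: str = "none") -> np.ndarray:
        """C_i = floor of the selected IFS variant."""
        return np.floor(self.windows[self.score_column(correction)].to_numpy()).astype(np.int64)


def region_ifs(
    mid_sorted: np.ndarray,
    len_cumsum: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    L: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised IFS over arbitrary regions of one chromosome.

    ``mid_sorted`` are sorted fragment midpoints; ``len_cumsum`` is the
    cumulative sum of the matching fragment lengths with a leading 0.
    Returns (n, mean_len, ifs) with ifs = 0 where n = 0.
    """
    lo = np.searchsorted(mid_sorted, starts, side="left")
    hi = np.searchsorted(mid_sorted, ends, side="left")
    n = (hi - lo).astype(np.int64)
    length_sum = len_cumsum[hi] - len_cumsum[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_len = np.where(n > 0, length_sum / np.maximum(n, 1), np.nan)
        ifs = np.where(n > 0, n * (1.0 + mean_len / L), 0.0)
    return n, mean_len, ifs


def compute_ifs(
    frags: pd.DataFrame,
    grids: Mapping[str, WindowGrid],
    covariates: Mapping[str, WindowCovariates] | None = None,
) -> WindowTrack:
    """Compute per-window IFS over all kept windows of every grid.

    Fragments are assigned by midpoint; a fragment therefore contributes
    to every overlapping window (width/step of them on the default grid).
    Chromosomes without any fragment are skipped with a warning.  When
    ``covariates`` are given, their per-window values are attached and
    invalid windows (ambiguous sequence) are dropped.
    """
    frames = []
    chrom_L: dict[str, float] = {}
    chrom_mean_ifs: dict[str, float] = {}
    by_chrom = dict(tuple(frags.groupby("chrom", sort=True)))
    for chrom, grid in grids.items():
        sub = by_chrom.get(chrom)
        if sub is None or len(sub) == 0:
            logger.warning("%s: no fragments, chromosome skipped", chrom)
            continue
        mids = midpoints(sub)
        order = np.argsort(mids, kind="mergesort")
        mids = mids[order]
        lens = sub["length"].to_numpy()[order].astype(np.float64)
        L = float(lens.mean())
        chrom_L[chrom] = L
        len_cumsum = np.concatenate([[0.0], np.cumsum(lens)])

        keep = grid.keep.copy()
        cov = covariates.get(chrom) if covariates else None
        if cov is not None:
            keep &= cov.valid
        starts = grid.starts[keep]
        n, mean_len, ifs = region_ifs(mids, len_cumsum, starts, starts + grid.width, L)
        frame = pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts,
                "end": starts + grid.width,
                "n": n,
                "mean_len": mean_len,
                "ifs": ifs,
            }
        )
        if cov is not None:
            frame["gc"] = cov.gc[keep]
            if cov.mappability is not None:
                frame["mappability"] = cov.mappability[keep]
            for d in range(16):
                frame[f"dimer_{d}"] = cov.dimer_freq[keep, d]
        chrom_mean_ifs[chrom] = float(frame["ifs"].mean())
        frames.append(frame)
    if not frames:
        raise ValueError("no chromosome had both windows and fragments")
    table = pd.concat(frames, ignore_index=True)
    return WindowTrack(windows=table, chrom_mean_length=chrom_L, chrom_mean_ifs=chrom_mean_ifs)


def fit_gc_loess(
    ifs: np.ndarray,
    gc: np.ndarray,
    span: float = LOESS_SPAN,
    max_points: int = LOESS_MAX_POINTS,
    seed: int = 0,
) -> GcLoessModel:
    """Fit the IFS-on-GC loess, subsampling above ``max_points`` windows.

    The subsample is uniform and deterministic under ``seed``; the fitted
    curve is evaluated on the subsample's GC values and interpolated for
    everything else.
    """
    ifs = np.asarray(ifs, dtype=float)
    gc = np.asarray(gc, dtype=float)
    if len(ifs) > max_points:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(ifs), size=max_points, replace=False)
        ifs_fit, gc_fit = ifs[idx], gc[idx]
    else:
        ifs_fit, gc_fit = ifs, gc
    if np.ptp(gc_fit) == 0:
        # constant GC: the best local fit is the global mean
        return GcLoessModel(gc_grid=np.array([gc_fit[0]]), fitted=np.array([ifs_fit.mean()]), span=span)
    # it=0: plain local least squares, the R loess default family;
    # robustness iterations would bias the conditional mean low on
    # right-skewed count data
    sm = lowess(ifs_fit, gc_fit, frac=span, it=0, return_sorted=True)
    grid_x, uniq = np.unique(sm[:, 0], return_index=True)
    return GcLoessModel(gc_grid=grid_x, fitted=sm[uniq, 1], span=span)


def gc_correct(
    track: WindowTrack,
    span: float = LOESS_SPAN,
    max_points: int = LOESS_MAX_POINTS,
    seed: int = 0,
) -> WindowTrack:
    """Regress GC out of the raw IFS; add back per-chromosome means.

    The loess is fitted genome-wide; residuals are recentred within each
    chromosome before the chromosome's mean raw IFS is added back, so
    per-chromosome means are preserved exactly.  With fewer than
    ``MIN_LOESS_WINDOWS`` windows the correction is skipped (pass-through
    with a warning).
    """
    w = track.windows
    if "gc" not in w.columns:
        raise ValueError("track has no GC covariate; run compute_ifs with covariates")
    if len(w) < MIN_LOESS_WINDOWS:
        logger.warning("only %d windows; GC correction skipped (pass-through)", len(w))
        track.windows = w.assign(ifs_gc=w["ifs"].to_numpy())
        return track
    model = fit_gc_loess(w["ifs"].to_numpy(), w["gc"].to_numpy(), span=span, max_points=max_points, seed=seed)
    resid = w["ifs"].to_numpy() - model.predict(w["gc"].to_numpy())
    ifs_gc = np.empty_like(resid)
    for chrom, idx in w.groupby("chrom", sort=False).indices.items():
        r = resid[idx]
        ifs_gc[idx] = r - r.mean() + track.chrom_mean_ifs[chrom]
    track.windows = w.assign(ifs_gc=ifs_gc)
    track.gc_model = model
    return track


def kmer_correct(track: WindowTrack) -> WindowTrack:
    """Adjust IFS for dinucleotide composition.

    The genome-wide mean IFS per dimer type, ``m_d``, is the dimer-
    frequency-weighted average of window IFS.  A window's expected IFS is
    ``sum_d f_d m_d``; the adjusted score divides observed by expected
    and is rescaled per chromosome by mean(expected)/mean(adjusted) to
    restore the original IFS scale.  Windows with zero expected score are
    flagged and excluded (NaN).
    """
    w = track.windows
    dimer_cols = [f"dimer_{d}" for d in range(16)]
    if not set(dimer_cols) <= set(w.columns):
        raise ValueError("track has no dimer covariates; run compute_ifs with covariates")
    F = w[dimer_cols].to_numpy()  # (n_windows, 16)
    ifs = w["ifs"].to_numpy()
    weights = F.sum(axis=0)
    m_d = np.where(weights > 0, (F * ifs[:, None]).sum(axis=0) / np.maximum(weights, 1e-300), 0.0)
    expected = F @ m_d
    with np.errstate(invalid="ignore", divide="ignore"):
        adjusted = np.where(expected > 0, ifs / expected, np.nan)
    n_flagged = int(np.isnan(adjusted).sum())
    if n_flagged:
        logger.warning("%d windows with zero expected IFS flagged NaN", n_flagged)
    ifs_kmer = np.full_like(adjusted, np.nan)
    for chrom, idx in w.groupby("chrom", sort=False).indices.items():
        a, e = adjusted[idx], expected[idx]
        ok = ~np.isnan(a)
        if ok.any() and np.nanmean(a[ok]) != 0:
            scale = e[ok].mean() / a[ok].mean()
        else:
            scale = 1.0
        ifs_kmer[idx] = a * scale
    track.windows = w.assign(ifs_kmer=ifs_kmer)
    return track
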